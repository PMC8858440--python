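"""Multi-omics overlay.

Pre-filtered lists of dysregulated genes (gene symbols or loci) and proteins
(UniProt accessions or gene symbols) are superimposed onto the pathway
results: per pathway we intersect the list with the pathway's annotated gene
symbols / UniProt accessions. The overlay is annotation-only — it never
changes the metabolite-level statistics — and offers a systems-level glance
at which dysregulated pathways are independently supported by
transcriptomics or proteomics.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

from .errors import ParameterError
from .meta import MetaPathwayResult
from .model import MetabolicModel

__all__ = ["OmicsList", "parse_omics_list", "overlay"]

logger = logging.getLogger(__name__)

_ISOFORM_SUFFIX = re.compile(r"-\d+$")
# UniProt accession shapes (6 or 10 characters), used only to decide whether a
# protein identifier can fall back to gene-symbol matching
_UNIPROT = re.compile(r"^[OPQ][0-9][A-Z0-9]{3}[0-9]$|^[A-NR-Z][0-9][A-Z][A-Z0-9]{2}[0-9](?:[A-Z][A-Z0-9]{2}[0-9])?$")


def normalize_identifier(identifier: str, kind: str) -> str:
    """Upper-case; protein accessions additionally lose an isoform suffix."""
    out = identifier.strip().upper()
    if kind == "protein":
        out = _ISOFORM_SUFFIX.sub("", out)
    return out


@dataclass(frozen=True)
class OmicsList:
    """A normalized, deduplicated identifier list."""

    kind: str  # "gene" | "protein"
    identifiers: frozenset[str]
    n_input: int

    def __post_init__(self) -> None:
        if self.kind not in ("gene", "protein"):
            raise ParameterError(f"kind must be gene/protein, got {self.kind!r}")
        if not self.identifiers:
            raise ParameterError(f"{self.kind} list is empty after parsing")


def parse_omics_list(path: str | Path, kind: str) -> OmicsList:
    """Parse a one-identifier-per-line (or single-column) file.

    Blank lines are dropped; extra whitespace-separated columns beyond the
    identifier are ignored (the lists arrive already thresholded upstream).
    """
    path = Path(path)
    identifiers: set[str] = set()
    n_input = 0
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            text = line.strip()
            if not text or (line_no == 1 and text.lower() in ("gene", "genes", "protein", "proteins", "id", "identifier", "symbol")):
                continue
            token = text.split("\t")[0].split(",")[0].strip()
            if not token:
                continue
            n_input += 1
            identifiers.add(normalize_identifier(token, kind))
    if not identifiers:
        raise ParameterError(f"{path}: no {kind} identifiers found")
    dropped = n_input - len(identifiers)
    if dropped:
        logger.info("%s: deduplicated %d of %d identifiers", path, dropped, n_input)
    return OmicsList(kind=kind, identifiers=frozenset(identifiers), n_input=n_input)


def overlay(
    results: Sequence[MetaPathwayResult],
    model: MetabolicModel,
    genes: Optional[OmicsList] = None,
    proteins: Optional[OmicsList] = None,
) -> list[MetaPathwayResult]:
    """Attach gene/protein hits to each pathway result.

    Gene hits are the intersection of the gene list with the pathway's gene
    symbols (case-insensitive). Protein hits intersect UniProt accessions;
    protein identifiers that are not accession-shaped (gene symbols in a
    protein list) fall back to gene-symbol matching. Metabolite statistics
    and ordering are untouched.
    """
    if genes is None and proteins is None:
        return list(results)
    out: list[MetaPathwayResult] = []
    for result in results:
        pathway = model.pathway(result.pathway_id)
        symbols = {s.upper() for s in pathway.gene_symbols}
        gene_hits: frozenset[str] = result.gene_hits
        protein_hits: frozenset[str] = result.protein_hits
        if genes is not None:
            gene_hits = frozenset(genes.identifiers & symbols)
        if proteins is not None:
            accessions = {a.upper() for a in pathway.uniprot_ids}
            hits = proteins.identifiers & accessions
            # gene-symbol fallback for entries that are not UniProt-shaped,
            # or when the model lacks UniProt annotation for this pathway
            fallback = {
                ident
                for ident in proteins.identifiers
                if ident in symbols and (not _UNIPROT.match(ident) or not accessions)
            }
            protein_hits = frozenset(hits | fallback)
        out.append(replace(result, gene_hits=gene_hits, protein_hits=protein_hits))
    return out
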