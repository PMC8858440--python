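"""Metabolic model store.

A :class:`MetabolicModel` is the pathway database that putatively annotated
features are queried against: compounds carry neutral monoisotopic masses,
pathways carry compound sets plus the gene symbols and UniProt accessions used
by the multi-omics overlay.

Two on-disk formats are supported so users can substitute their own model
(e.g. an export of mummichog's human network):

* JSON — ``{"metadata": {...}, "compounds": [...], "pathways": [...]}``
* TSV pair — a directory holding ``compounds.tsv`` and ``pathways.tsv`` with
  semicolon-joined multi-valued cells.

``builtin_toy_model()`` returns a compact, fully deterministic model of real
human metabolites (masses derived from elemental monoisotopic masses) that is
large enough to exercise every stage of the pipeline offline.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ModelFormatError, ModelValidationError

__all__ = [
    "Compound",
    "Pathway",
    "MetabolicModel",
    "load_model",
    "save_model",
    "builtin_toy_model",
    "monoisotopic_mass",
    "normalize_name",
    "toy_model_path",
]

#: Monoisotopic masses of the most abundant isotope, in Da.
ELEMENT_MASS = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def monoisotopic_mass(formula: str) -> float:
    """Neutral monoisotopic mass (Da) of a molecular formula like ``C6H12O6``."""
    mass = 0.0
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = match.end()
        element, count = match.group(1), match.group(2)
        if element not in ELEMENT_MASS:
            raise ValueError(f"unknown element {element!r} in {formula!r}")
        mass += ELEMENT_MASS[element] * (int(count) if count else 1)
    if pos != len(formula) or mass <= 0:
        raise ValueError(f"cannot parse formula {formula!r}")
    return mass


def normalize_name(name: str) -> str:
    """Case-insensitive, whitespace-collapsed form used for name matching."""
    return " ".join(name.strip().lower().split())


@dataclass(frozen=True)
class Compound:
    """A model metabolite with its neutral monoisotopic mass."""

    id: str
    name: str
    monoisotopic_mass: float
    aliases: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("compound id must be nonempty")
        if not self.monoisotopic_mass > 0:
            raise ModelValidationError(
                f"compound {self.id!r}: monoisotopic_mass must be > 0, "
                f"got {self.monoisotopic_mass}"
            )
        object.__setattr__(
            self, "aliases", frozenset(normalize_name(a) for a in self.aliases)
        )


@dataclass(frozen=True)
class Pathway:
    """A metabolic pathway: compound members plus omics-overlay annotations."""

    id: str
    name: str
    compound_ids: frozenset[str]
    gene_symbols: frozenset[str] = frozenset()
    uniprot_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "compound_ids", frozenset(self.compound_ids))
        object.__setattr__(self, "gene_symbols", frozenset(self.gene_symbols))
        object.__setattr__(self, "uniprot_ids", frozenset(self.uniprot_ids))
        if not self.compound_ids:
            raise ModelValidationError(f"pathway {self.id!r} has no compounds")


@dataclass
class MetabolicModel:
    """Validated collection of compounds and pathways."""

    compounds: dict[str, Compound]
    pathways: list[Pathway]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.pathways:
            raise ModelValidationError("a model must contain at least one pathway")
        for cid, compound in self.compounds.items():
            if cid != compound.id:
                raise ModelValidationError(
                    f"compound table key {cid!r} does not match id {compound.id!r}"
                )
        seen: set[str] = set()
        dangling: list[str] = []
        for pathway in self.pathways:
            if pathway.id in seen:
                raise ModelValidationError(f"duplicate pathway id {pathway.id!r}")
            seen.add(pathway.id)
            dangling.extend(
                cid for cid in sorted(pathway.compound_ids)
                if cid not in self.compounds
            )
        if dangling:
            raise ModelValidationError(
                "pathways reference unknown compound ids: "
                + ", ".join(sorted(set(dangling)))
            )

    # -- lookup helpers -------------------------------------------------

    def pathway(self, pathway_id: str) -> Pathway:
        for p in self.pathways:
            if p.id == pathway_id:
                return p
        raise KeyError(pathway_id)

    def compounds_by_name(self) -> dict[str, str]:
        """Map normalized compound names/aliases -> compound id."""
        out: dict[str, str] = {}
        for compound in self.compounds.values():
            out.setdefault(normalize_name(compound.name), compound.id)
            for alias in compound.aliases:
                out.setdefault(alias, compound.id)
        return out

    @property
    def mass_range(self) -> tuple[float, float]:
        masses = [c.monoisotopic_mass for c in self.compounds.values()]
        return min(masses), max(masses)


# ---------------------------------------------------------------------------
# serialization

def _split_multi(cell: object) -> list[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return []
    text = str(cell).strip()
    return [part.strip() for part in text.split(";") if part.strip()]


def load_model(path: str | Path, format: str = "auto") -> MetabolicModel:
    """Load and validate a metabolic model.

    ``format`` is ``json``, ``tsv-pair`` (a directory with ``compounds.tsv``
    and ``pathways.tsv``) or ``auto`` (inferred from the path).
    """
    path = Path(path)
    if format == "auto":
        format = "tsv-pair" if path.is_dir() else "json"
    if format == "json":
        return _load_json(path)
    if format == "tsv-pair":
        return _load_tsv_pair(path)
    raise ModelFormatError(f"unknown model format {format!r}")


def _load_json(path: Path) -> MetabolicModel:
    try:
        with open(path) as handle:
            raw = json.load(handle)
    except FileNotFoundError:
        raise ModelFormatError(f"model file not found: {path}") from None
    except json.JSONDecodeError as exc:
        raise ModelFormatError(
            f"{path}: not valid JSON (line {exc.lineno}: {exc.msg})"
        ) from None
    try:
        compounds = {
            entry["id"]: Compound(
                id=entry["id"],
                name=entry.get("name", entry["id"]),
                monoisotopic_mass=float(entry["monoisotopic_mass"]),
                aliases=frozenset(entry.get("aliases", [])),
            )
            for entry in raw["compounds"]
        }
        pathways = [
            Pathway(
                id=entry["id"],
                name=entry.get("name", entry["id"]),
                compound_ids=frozenset(entry["compound_ids"]),
                gene_symbols=frozenset(entry.get("gene_symbols", [])),
                uniprot_ids=frozenset(entry.get("uniprot_ids", [])),
            )
            for entry in raw.get("pathways", [])
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"{path}: malformed model JSON ({exc})") from None
    return MetabolicModel(
        compounds=compounds, pathways=pathways, metadata=dict(raw.get("metadata", {}))
    )


def _load_tsv_pair(path: Path) -> MetabolicModel:
    compounds_file = path / "compounds.tsv"
    pathways_file = path / "pathways.tsv"
    for file in (compounds_file, pathways_file):
        if not file.exists():
            raise ModelFormatError(f"tsv-pair model is missing {file}")
    ctab = pd.read_csv(compounds_file, sep="\t", dtype=str)
    ptab = pd.read_csv(pathways_file, sep="\t", dtype=str)
    for col in ("id", "name", "monoisotopic_mass"):
        if col not in ctab.columns:
            raise ModelFormatError(f"{compounds_file}: missing column {col!r}")
    for col in ("id", "name", "compound_ids"):
        if col not in ptab.columns:
            raise ModelFormatError(f"{pathways_file}: missing column {col!r}")
    try:
        compounds = {
            row["id"]: Compound(
                id=row["id"],
                name=row["name"],
                monoisotopic_mass=float(row["monoisotopic_mass"]),
                aliases=frozenset(_split_multi(row.get("aliases"))),
            )
            for _, row in ctab.iterrows()
        }
    except ValueError as exc:
        raise ModelFormatError(f"{compounds_file}: {exc}") from None
    pathways = [
        Pathway(
            id=row["id"],
            name=row["name"],
            compound_ids=frozenset(_split_multi(row["compound_ids"])),
            gene_symbols=frozenset(_split_multi(row.get("gene_symbols"))),
            uniprot_ids=frozenset(_split_multi(row.get("uniprot_ids"))),
        )
        for _, row in ptab.iterrows()
    ]
    return MetabolicModel(compounds=compounds, pathways=pathways)


def save_model(model: MetabolicModel, path: str | Path, format: str = "json") -> None:
    """Serialize a model; ``load_model(save_model(...))`` round-trips."""
    path = Path(path)
    if format == "json":
        payload = {
            "metadata": model.metadata,
            "compounds": [
                {
                    "id": c.id,
                    "name": c.name,
                    "monoisotopic_mass": c.monoisotopic_mass,
                    "aliases": sorted(c.aliases),
                }
                for c in model.compounds.values()
            ],
            "pathways": [
                {
                    "id": p.id,
                    "name": p.name,
                    "compound_ids": sorted(p.compound_ids),
                    "gene_symbols": sorted(p.gene_symbols),
                    "uniprot_ids": sorted(p.uniprot_ids),
                }
                for p in model.pathways
            ],
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=1, sort_keys=True)
            handle.write("\n")
    elif format == "tsv-pair":
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [
                {
                    "id": c.id,
                    "name": c.name,
                    "monoisotopic_mass": repr(c.monoisotopic_mass),
                    "aliases": ";".join(sorted(c.aliases)),
                }
                for c in model.compounds.values()
            ]
        ).to_csv(path / "compounds.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "id": p.id,
                    "name": p.name,
                    "compound_ids": ";".join(sorted(p.compound_ids)),
                    "gene_symbols": ";".join(sorted(p.gene_symbols)),
                    "uniprot_ids": ";".join(sorted(p.uniprot_ids)),
                }
                for p in model.pathways
            ]
        ).to_csv(path / "pathways.tsv", sep="\t", index=False)
    else:
        raise ModelFormatError(f"unknown model format {format!r}")


def toy_model_path() -> Path:
    """Path to the bundled 12-compound / 3-pathway JSON fixture."""
    return Path(__file__).parent / "data" / "toy_model.json"


# ---------------------------------------------------------------------------
# built-in model
#
# (id, display name, molecular formula). Masses are computed from the element
# table above, so the model is deterministic and carries true monoisotopic
# masses. Near-isobaric pairs that plain mass matching cannot separate
# (leucine/isoleucine, citrate/isocitrate, ...) are represented once.

_COMPOUNDS: list[tuple[str, str, str]] = [
    ("glucose", "D-Glucose", "C6H12O6"),
    ("glucose_6_phosphate", "Glucose 6-phosphate", "C6H13O9P"),
    ("fructose_16_bisphosphate", "Fructose 1,6-bisphosphate", "C6H14O12P2"),
    ("glyceraldehyde_3_phosphate", "Glyceraldehyde 3-phosphate", "C3H7O6P"),
    ("phosphoenolpyruvate", "Phosphoenolpyruvate", "C3H5O6P"),
    ("pyruvate", "Pyruvate", "C3H4O3"),
    ("lactate", "L-Lactate", "C3H6O3"),
    ("oxaloacetate", "Oxaloacetate", "C4H4O5"),
    ("malate", "L-Malate", "C4H6O5"),
    ("glycerol_3_phosphate", "sn-Glycerol 3-phosphate", "C3H9O6P"),
    ("citrate", "Citrate", "C6H8O7"),
    ("alpha_ketoglutarate", "2-Oxoglutarate", "C5H6O5"),
    ("succinate", "Succinate", "C4H6O4"),
    ("fumarate", "Fumarate", "C4H4O4"),
    ("glutamate", "L-Glutamate", "C5H9NO4"),
    ("glutamine", "L-Glutamine", "C5H10N2O3"),
    ("aspartate", "L-Aspartate", "C4H7NO4"),
    ("asparagine", "L-Asparagine", "C4H8N2O3"),
    ("arginine", "L-Arginine", "C6H14N4O2"),
    ("ornithine", "L-Ornithine", "C5H12N2O2"),
    ("citrulline", "L-Citrulline", "C6H13N3O3"),
    ("argininosuccinate", "N-(L-Arginino)succinate", "C10H18N4O6"),
    ("urea", "Urea", "CH4N2O"),
    ("putrescine", "Putrescine", "C4H12N2"),
    ("spermidine", "Spermidine", "C7H19N3"),
    ("spermine", "Spermine", "C10H26N4"),
    ("n1_acetylspermidine", "N1-Acetylspermidine", "C9H21N3O"),
    ("n1_acetylspermine", "N1-Acetylspermine", "C12H28N4O"),
    ("glycine", "Glycine", "C2H5NO2"),
    ("serine", "L-Serine", "C3H7NO3"),
    ("alanine", "L-Alanine", "C3H7NO2"),
    ("threonine", "L-Threonine", "C4H9NO3"),
    ("cysteine", "L-Cysteine", "C3H7NO2S"),
    ("methionine", "L-Methionine", "C5H11NO2S"),
    ("adenine", "Adenine", "C5H5N5"),
    ("guanine", "Guanine", "C5H5N5O"),
    ("hypoxanthine", "Hypoxanthine", "C5H4N4O"),
    ("xanthine", "Xanthine", "C5H4N4O2"),
    ("urate", "Urate", "C5H4N4O3"),
    ("adenosine", "Adenosine", "C10H13N5O4"),
    ("inosine", "Inosine", "C10H12N4O5"),
    ("guanosine", "Guanosine", "C10H13N5O5"),
    ("amp", "AMP", "C10H14N5O7P"),
    ("uracil", "Uracil", "C4H4N2O2"),
    ("cytosine", "Cytosine", "C4H5N3O"),
    ("thymine", "Thymine", "C5H6N2O2"),
    ("uridine", "Uridine", "C9H12N2O6"),
    ("cytidine", "Cytidine", "C9H13N3O5"),
    ("cholate", "Cholate", "C24H40O5"),
    ("chenodeoxycholate", "Chenodeoxycholate", "C24H40O4"),
    ("taurocholate", "Taurocholate", "C26H45NO7S"),
    ("taurochenodeoxycholate", "Taurochenodeoxycholate", "C26H45NO6S"),
    ("glycocholate", "Glycocholate", "C26H43NO6"),
    ("taurine", "Taurine", "C2H7NO3S"),
    ("hypotaurine", "Hypotaurine", "C2H7NO2S"),
    ("carnitine", "L-Carnitine", "C7H15NO3"),
    ("acetylcarnitine", "O-Acetylcarnitine", "C9H17NO4"),
    ("propionylcarnitine", "Propionylcarnitine", "C10H19NO4"),
    ("butyrylcarnitine", "Butyrylcarnitine", "C11H21NO4"),
    ("palmitoylcarnitine", "Palmitoylcarnitine", "C23H45NO4"),
    ("tyrosine", "L-Tyrosine", "C9H11NO3"),
    ("phenylalanine", "L-Phenylalanine", "C9H11NO2"),
    ("dopa", "L-DOPA", "C9H11NO4"),
    ("dopamine", "Dopamine", "C8H11NO2"),
    ("homovanillate", "Homovanillate", "C9H10O4"),
    ("tryptophan", "L-Tryptophan", "C11H12N2O2"),
    ("kynurenine", "L-Kynurenine", "C10H12N2O3"),
    ("serotonin", "Serotonin", "C10H12N2O"),
    ("tryptamine", "Tryptamine", "C10H12N2"),
    ("glycerophosphocholine", "sn-Glycero-3-phosphocholine", "C8H20NO6P"),
    ("phosphocholine", "Phosphocholine", "C5H14NO4P"),
    ("ethanolamine", "Ethanolamine", "C2H7NO"),
    ("lysine", "L-Lysine", "C6H14N2O2"),
    ("leucine", "L-Leucine", "C6H13NO2"),
    ("valine", "L-Valine", "C5H11NO2"),
    ("proline", "L-Proline", "C5H9NO2"),
    ("histidine", "L-Histidine", "C6H9N3O2"),
    ("creatinine", "Creatinine", "C4H7N3O"),
]

_PATHWAYS: list[tuple[str, str, list[str], list[str], list[str]]] = [
    (
        "P1", "Glycolysis and gluconeogenesis",
        ["glucose", "glucose_6_phosphate", "fructose_16_bisphosphate",
         "glyceraldehyde_3_phosphate", "phosphoenolpyruvate", "pyruvate",
         "lactate", "oxaloacetate", "malate", "glycerol_3_phosphate"],
        ["HK1", "GPI", "PFKM", "GAPDH", "PKM", "LDHA"],
        ["P19367", "P06744", "P04406", "P14618"],
    ),
    (
        "P2", "TCA cycle",
        ["citrate", "alpha_ketoglutarate", "succinate", "fumarate", "malate",
         "oxaloacetate", "pyruvate", "glutamate"],
        ["CS", "IDH1", "SDHA", "FH", "MDH2"],
        ["O75390", "P07954", "Q99798"],
    ),
    (
        "P3", "Aspartate and asparagine metabolism",
        ["aspartate", "asparagine", "glutamate", "glutamine", "oxaloacetate",
         "alpha_ketoglutarate", "arginine", "ornithine", "citrulline",
         "argininosuccinate", "spermidine", "spermine"],
        ["ASNS", "ASS1", "ASL", "GOT1", "GOT2", "ODC1"],
        ["P08243", "P00966", "P04424", "P17174"],
    ),
    (
        "P4", "Glycine, serine, alanine and threonine metabolism",
        ["glycine", "serine", "alanine", "threonine", "cysteine", "pyruvate",
         "methionine", "glutamate"],
        ["SHMT1", "SHMT2", "GLDC", "PHGDH", "GPT"],
        ["P34896", "P34897", "P23378", "O43175"],
    ),
    (
        "P5", "Urea cycle and polyamine metabolism",
        ["arginine", "ornithine", "citrulline", "argininosuccinate", "urea",
         "putrescine", "spermidine", "spermine", "n1_acetylspermidine",
         "n1_acetylspermine", "aspartate"],
        ["OTC", "ARG1", "ODC1", "SRM", "SMS", "SAT1"],
        ["P00480", "P05089", "P11926", "P19623", "P52788", "P21673"],
    ),
    (
        "P6", "Purine metabolism",
        ["adenine", "guanine", "hypoxanthine", "xanthine", "urate",
         "adenosine", "inosine", "guanosine", "amp", "glutamine"],
        ["PNP", "XDH", "HPRT1", "ADA"],
        ["P00491", "P47989", "P00492", "P00813"],
    ),
    (
        "P7", "Pyrimidine metabolism",
        ["uracil", "cytosine", "thymine", "uridine", "cytidine", "glutamine",
         "aspartate"],
        ["CAD", "UPP1", "TYMS", "DPYD"],
        ["P27708", "Q16831", "P04818"],
    ),
    (
        "P8", "Bile acid biosynthesis",
        ["cholate", "chenodeoxycholate", "taurocholate",
         "taurochenodeoxycholate", "glycocholate", "taurine", "glycine",
         "cysteine"],
        ["CYP7A1", "CYP8B1", "BAAT", "SLC10A1"],
        ["P22680", "Q9UNU6", "Q14032"],
    ),
    (
        "P9", "Taurine and hypotaurine metabolism",
        ["taurine", "hypotaurine", "cysteine", "serine"],
        ["CDO1", "CSAD", "GGT1"],
        ["Q16878", "Q9Y600"],
    ),
    (
        "P10", "Carnitine shuttle",
        ["carnitine", "acetylcarnitine", "propionylcarnitine",
         "butyrylcarnitine", "palmitoylcarnitine", "lysine"],
        ["CPT1A", "CPT2", "CRAT", "SLC22A5"],
        ["P50416", "P23786", "P43155"],
    ),
    (
        "P11", "Tyrosine metabolism",
        ["tyrosine", "phenylalanine", "dopa", "dopamine", "homovanillate"],
        ["TH", "TAT", "DDC", "COMT", "MAOA"],
        ["P07101", "P20711", "P21964"],
    ),
    (
        "P12", "Tryptophan metabolism",
        ["tryptophan", "kynurenine", "serotonin", "tryptamine"],
        ["TPH1", "IDO1", "TDO2", "MAOA"],
        ["P17752", "P14902", "P48775", "P21397"],
    ),
    (
        "P13", "Glycerophospholipid metabolism",
        ["glycerophosphocholine", "phosphocholine", "ethanolamine",
         "glycerol_3_phosphate", "serine"],
        ["PCYT1A", "CHKA", "PLA2G4A", "GPD1"],
        ["P49585", "P35790", "P47712", "P21695"],
    ),
]


def builtin_toy_model() -> MetabolicModel:
    """Deterministic built-in model: 78 real metabolites, 13 overlapping pathways.

    Pathway sizes span 4-12 compounds on purpose, so that null pathway scores
    take many distinct values when pooled across pathways.
    """
    compounds = {
        cid: Compound(id=cid, name=name, monoisotopic_mass=monoisotopic_mass(formula))
        for cid, name, formula in _COMPOUNDS
    }
    pathways = [
        Pathway(
            id=pid,
            name=name,
            compound_ids=frozenset(cids),
            gene_symbols=frozenset(genes),
            uniprot_ids=frozenset(proteins),
        )
        for pid, name, cids, genes, proteins in _PATHWAYS
    ]
    return MetabolicModel(
        compounds=compounds,
        pathways=pathways,
        metadata={"name": "pathmeta built-in human metabolite subset", "version": "1.0"},
    )
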