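"""Cross-study merging and meta-analysis.

Per-study annotation indexes are merged compound-wise: the universe is the
union of the per-study matched reference compounds, and a compound seen
significant in several studies is represented once with the best (smallest)
per-study p-value. Enrichment then runs on the merged sets — either the
union of per-study significant compounds (default) or only the compounds
shared by at least ``min_studies`` studies — and the merged scores are
validated against a permutation null that resamples each study independently
before merging, mirroring how the observed statistic is built.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .annotate import AdductRule, AnnotationIndex, attach_confirmed, match_study
from .enrich import (
    CompoundSets,
    NullDistribution,
    PathwayStat,
    adjust_p,
    null_values_for_indexes,
    pathway_stats,
)
from .errors import MetaAnalysisError, ParameterError
from .io import NamedMetaboliteRecord, Study
from .model import MetabolicModel

__all__ = [
    "StudyResult",
    "MergedCompound",
    "MetaPathwayResult",
    "MetaConfig",
    "MetaAnalysis",
    "merge_studies",
    "meta_analyze",
    "filter_results",
]

logger = logging.getLogger(__name__)


@dataclass
class StudyResult:
    """One study's annotation index and its own pathway ranking."""

    study_id: str
    index: AnnotationIndex
    per_pathway: list[PathwayStat]


@dataclass(frozen=True)
class MergedCompound:
    """A compound's merged evidence across studies."""

    compound_id: str
    per_study_p: dict[str, Optional[float]]
    provenance: frozenset[tuple[str, float, str, str]]  # (study, mz, adduct, source file)

    @property
    def n_studies_seen(self) -> int:
        return len(self.per_study_p)

    @property
    def best_p(self) -> Optional[float]:
        numeric = [p for p in self.per_study_p.values() if p is not None]
        return min(numeric) if numeric else None

    @property
    def adducts(self) -> frozenset[str]:
        return frozenset(adduct for _, _, adduct, _ in self.provenance)

    @property
    def source_files(self) -> frozenset[str]:
        return frozenset(source for _, _, _, source in self.provenance)


def merge_studies(
    results: Sequence[StudyResult | AnnotationIndex],
    merge_mode: str = "union",
    min_studies: int | None = None,
) -> tuple[set[str], dict[str, MergedCompound]]:
    """Merge per-study compound hits with best-p selection.

    Returns ``(merged_reference, merged_significant)``. In ``union`` mode the
    significant map holds every compound significant in at least one study;
    in ``shared`` mode only compounds significant in at least ``min_studies``
    studies (default: all of them) are kept.
    """
    if merge_mode not in ("union", "shared"):
        raise ParameterError(f"merge_mode must be union/shared, got {merge_mode!r}")
    indexes = [r.index if isinstance(r, StudyResult) else r for r in results]
    if not indexes:
        raise ParameterError("at least one study is required")
    ids = [ix.study_id for ix in indexes]
    if len(set(ids)) != len(ids):
        raise ParameterError(f"duplicate study ids in merge: {ids}")
    if min_studies is None:
        min_studies = len(indexes)

    merged_reference: set[str] = set()
    per_study_p: dict[str, dict[str, Optional[float]]] = {}
    provenance: dict[str, set[tuple[str, float, str, str]]] = {}
    for index in indexes:
        merged_reference |= index.matched_reference_compounds
        for cid, p in index.matched_significant_compounds.items():
            per_study_p.setdefault(cid, {})[index.study_id] = p
        for match in index.matches:
            if match.significant:
                provenance.setdefault(match.compound_id, set()).add(
                    (
                        index.study_id,
                        match.feature.mz,
                        match.adduct_name,
                        match.feature.source_tag,
                    )
                )

    merged_significant = {
        cid: MergedCompound(
            compound_id=cid,
            per_study_p=dict(study_ps),
            provenance=frozenset(provenance.get(cid, ())),
        )
        for cid, study_ps in per_study_p.items()
        if merge_mode == "union" or len(study_ps) >= min_studies
    }
    return merged_reference, merged_significant


@dataclass
class MetaPathwayResult:
    """Meta-analysis output for one pathway."""

    pathway_id: str
    pathway_name: str
    pathway_size: int
    matched_in_reference: int
    per_study_hits: dict[str, int]
    shared_count: int
    merged_hits: int
    p_raw: float
    p_adjusted: float
    shared_compounds: list[MergedCompound] = field(default_factory=list)
    gene_hits: frozenset[str] = frozenset()
    protein_hits: frozenset[str] = frozenset()
    #: studies a compound must be seen in to count as shared
    min_studies_shared: int = 1


@dataclass(frozen=True)
class MetaConfig:
    """Knobs of the merged analysis."""

    merge_mode: str = "union"
    min_studies: Optional[int] = None  # shared-compound threshold; None = all studies
    permutations: int = 100
    seed: int = 42
    adjust_method: str = "empirical"
    adducts: Optional[tuple[AdductRule, ...]] = None
    confirmed_as: str = "sig"


@dataclass
class MetaAnalysis:
    """Full result bundle of :func:`meta_analyze`."""

    pathways: list[MetaPathwayResult]
    study_results: list[StudyResult]
    merged_reference: set[str]
    merged_significant: dict[str, MergedCompound]
    null: NullDistribution
    config: MetaConfig


def meta_analyze(
    studies: Sequence[Study],
    model: MetabolicModel,
    named: Optional[dict[str, Sequence[NamedMetaboliteRecord]]] = None,
    config: MetaConfig | None = None,
) -> MetaAnalysis:
    """Run the full meta-analysis pipeline.

    Per study: annotate (honoring that study's own thresholds), attach any
    confirmed metabolites, rank pathways. Across studies: merge compound hits
    with best-p selection, score pathways on the merged sets, build the
    permutation null by resampling each study independently and merging, and
    calibrate the merged scores against it. The shared-compound count
    (compounds significant in >= ``min_studies`` studies) is reported for
    every pathway regardless of merge mode.
    """
    config = config or MetaConfig()
    named = named or {}
    study_results: list[StudyResult] = []
    for study in studies:
        try:
            index = match_study(study, model, config.adducts)
            records = named.get(study.study_id)
            if records:
                attach_confirmed(
                    records, model, index,
                    p_cutoff=study.params.p_cutoff,
                    confirmed_as=config.confirmed_as,
                )
            per_pathway = pathway_stats(index, model)
        except Exception as exc:
            raise MetaAnalysisError(f"study {study.study_id!r}: {exc}") from exc
        logger.info(
            "study %s: %d reference / %d significant compounds matched",
            study.study_id,
            len(index.matched_reference_compounds),
            len(index.matched_significant_compounds),
        )
        study_results.append(StudyResult(study.study_id, index, per_pathway))

    n_studies = len(study_results)
    min_studies = config.min_studies if config.min_studies is not None else n_studies
    merged_reference, merged_significant = merge_studies(
        study_results, merge_mode=config.merge_mode, min_studies=min_studies
    )
    # shared counts are reported regardless of merge mode
    _, union_significant = merge_studies(study_results, merge_mode="union")
    if not merged_significant:
        raise MetaAnalysisError(
            "no shared compounds across studies"
            if config.merge_mode == "shared"
            else "no significant compounds after merging"
        )

    merged_sets = CompoundSets(
        reference=frozenset(merged_reference),
        significant=frozenset(merged_significant),
    )
    stats = pathway_stats(merged_sets, model)

    rng = np.random.default_rng(config.seed)
    null_values = null_values_for_indexes(
        [r.index for r in study_results],
        model,
        config.permutations,
        rng,
        min_studies=min_studies if config.merge_mode == "shared" else None,
    )
    null = NullDistribution(
        values=null_values, n_permutations=config.permutations, seed=config.seed
    )

    pathways: list[MetaPathwayResult] = []
    for stat in stats:
        pathway = model.pathway(stat.pathway_id)
        members = [
            union_significant[cid]
            for cid in sorted(pathway.compound_ids & set(union_significant))
        ]
        shared = sum(1 for mc in members if mc.n_studies_seen >= min_studies)
        pathways.append(
            MetaPathwayResult(
                pathway_id=stat.pathway_id,
                pathway_name=stat.pathway_name,
                pathway_size=stat.pathway_size,
                matched_in_reference=stat.matched_in_reference,
                per_study_hits={
                    r.study_id: len(
                        pathway.compound_ids
                        & set(r.index.matched_significant_compounds)
                    )
                    for r in study_results
                },
                shared_count=shared,
                merged_hits=stat.hits,
                p_raw=stat.p_raw,
                p_adjusted=adjust_p(stat.p_raw, null, method=config.adjust_method),
                shared_compounds=members,
                min_studies_shared=min_studies,
            )
        )
    return MetaAnalysis(
        pathways=pathways,
        study_results=study_results,
        merged_reference=merged_reference,
        merged_significant=merged_significant,
        null=null,
        config=config,
    )


def filter_results(
    results: Sequence[MetaPathwayResult],
    min_shared: int = 10,
    adduct_filter: Optional[set[str]] = None,
    study_filter: Optional[set[str]] = None,
    on: str = "shared",
) -> list[MetaPathwayResult]:
    """Filter the pathway table.

    ``min_shared`` keeps pathways whose shared-compound count (``on="shared"``,
    the default reporting rule) or merged hit count (``on="merged"``) is at
    least the threshold. Adduct/study filters prune compound provenance and
    recompute the displayed counts; p-values are never recomputed.
    """
    if on not in ("shared", "merged"):
        raise ParameterError(f"on must be shared/merged, got {on!r}")
    out: list[MetaPathwayResult] = []
    for result in results:
        members = result.shared_compounds
        if adduct_filter is not None or study_filter is not None:
            pruned = []
            for mc in members:
                keep = frozenset(
                    entry
                    for entry in mc.provenance
                    if (adduct_filter is None or entry[2] in adduct_filter)
                    and (study_filter is None or entry[0] in study_filter)
                )
                studies_left = {entry[0] for entry in keep}
                if not keep:
                    continue
                pruned.append(
                    MergedCompound(
                        compound_id=mc.compound_id,
                        per_study_p={
                            sid: p
                            for sid, p in mc.per_study_p.items()
                            if sid in studies_left
                        },
                        provenance=keep,
                    )
                )
            result = replace(
                result,
                shared_compounds=pruned,
                merged_hits=len(pruned),
                shared_count=sum(
                    1
                    for mc in pruned
                    if mc.n_studies_seen >= result.min_studies_shared
                ),
            )
        count = result.shared_count if on == "shared" else result.merged_hits
        if count >= min_shared:
            out.append(result)
    return out
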