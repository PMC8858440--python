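"""Pathway enrichment statistics.

The pathway score is the EASE variant of the one-sided Fisher's exact test:
the right hypergeometric tail with the hit count decremented by one,

    p = P(X >= max(k-1, 1)),   X ~ Hypergeom(N, m, n_sig),

with p = 1 when max(k-1, 0) = 0. ``N`` is the number of model compounds
matched by any reference feature (the universe), ``m`` the pathway's
compounds inside that universe, ``n_sig`` the significant compound count and
``k`` the pathway's significant hits. The decrement makes the score
conservative for single-hit pathways, which matters when annotation is
putative.

Raw scores are validated against a permutation null: pseudo-significant
feature lists of the observed size are redrawn from the reference features,
pushed through the same annotation, and scored for every pathway; the pooled
scores calibrate the observed ones (empirically, or through a gamma fit to
the -log10 scores).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .annotate import AnnotationIndex
from .errors import MetaAnalysisError, ParameterError
from .model import MetabolicModel

__all__ = [
    "PathwayStat",
    "NullDistribution",
    "CompoundSets",
    "ease_fisher_p",
    "pathway_stats",
    "permutation_null",
    "adjust_p",
]

logger = logging.getLogger(__name__)


def ease_fisher_p(k: int, m: int, n_sig: int, N: int) -> float:
    """EASE-adjusted right-tail hypergeometric p-value.

    Computed as an exact integer tail sum (correctly rounded on division), so
    it agrees with brute-force enumeration to floating-point precision for
    any admissible arguments.
    """
    if not (0 <= m <= N and 0 <= n_sig <= N and 0 <= k <= min(m, n_sig)):
        raise ParameterError(
            f"inadmissible contingency: k={k}, m={m}, n_sig={n_sig}, N={N}"
        )
    k_prime = max(k - 1, 0)
    if k_prime == 0:
        return 1.0
    numerator = sum(
        math.comb(m, i) * math.comb(N - m, n_sig - i)
        for i in range(k_prime, min(m, n_sig) + 1)
    )
    return numerator / math.comb(N, n_sig)


@dataclass(frozen=True)
class CompoundSets:
    """Universe/significant compound sets, detached from any one study."""

    reference: frozenset[str]
    significant: frozenset[str]

    def __post_init__(self) -> None:
        if not self.significant <= self.reference:
            raise ParameterError("significant compounds must be a subset of the universe")


@dataclass(frozen=True)
class PathwayStat:
    """Enrichment result for one pathway against one compound-set pair."""

    pathway_id: str
    pathway_name: str
    pathway_size: int
    matched_in_reference: int
    hits: int
    hit_compound_ids: frozenset[str]
    p_raw: float
    p_adjusted: Optional[float] = None


def _as_sets(index) -> CompoundSets:
    if isinstance(index, CompoundSets):
        return index
    if isinstance(index, AnnotationIndex):
        return CompoundSets(
            reference=frozenset(index.matched_reference_compounds),
            significant=frozenset(index.matched_significant_compounds),
        )
    raise TypeError(f"expected AnnotationIndex or CompoundSets, got {type(index)!r}")


def pathway_stats(index, model: MetabolicModel) -> list[PathwayStat]:
    """Score every pathway that intersects the matched universe.

    Results are sorted by ascending raw p-value, ties broken by descending
    hits and then pathway id.
    """
    sets = _as_sets(index)
    if not sets.reference:
        raise MetaAnalysisError("no compounds matched; check mode/tolerance")
    N = len(sets.reference)
    n_sig = len(sets.significant)
    out: list[PathwayStat] = []
    for pathway in model.pathways:
        in_universe = pathway.compound_ids & sets.reference
        if not in_universe:
            continue
        hits = in_universe & sets.significant
        out.append(
            PathwayStat(
                pathway_id=pathway.id,
                pathway_name=pathway.name,
                pathway_size=len(pathway.compound_ids),
                matched_in_reference=len(in_universe),
                hits=len(hits),
                hit_compound_ids=frozenset(hits),
                p_raw=ease_fisher_p(len(hits), len(in_universe), n_sig, N),
            )
        )
    out.sort(key=lambda s: (s.p_raw, -s.hits, s.pathway_id))
    return out


@dataclass
class NullDistribution:
    """Pooled pathway scores from permutation resampling."""

    values: np.ndarray
    n_permutations: int
    seed: int
    gamma_params: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_permutations < 1:
            raise ParameterError("n_permutations must be >= 1")
        if self.values.size == 0:
            raise ParameterError("null distribution is empty")


def null_values_for_indexes(
    indexes: Sequence[AnnotationIndex],
    model: MetabolicModel,
    n_permutations: int,
    rng: np.random.Generator,
    min_studies: int | None = None,
) -> np.ndarray:
    """Permutation scores for one or several studies analyzed jointly.

    Each permutation redraws, per study, a pseudo-significant feature list of
    the observed significant size (uniformly, without replacement) from that
    study's reference features, re-derives compound sets through the stored
    annotation, merges them across studies exactly as the observed statistic
    does (union, or >= ``min_studies`` intersection), and scores every pathway
    that intersects the observed universe.
    """
    if n_permutations < 1:
        raise ParameterError("n_permutations must be >= 1")
    universe: set[str] = set()
    for index in indexes:
        universe |= index.matched_reference_compounds
    if not universe:
        raise MetaAnalysisError("no compounds matched; cannot build a null")
    N = len(universe)
    per_study: list[tuple[list[frozenset[str]], int]] = []
    for index in indexes:
        compound_sets = [cs for _, cs in index.reference_feature_compounds]
        n_draw = index.n_significant_features
        if n_draw > len(compound_sets):
            raise MetaAnalysisError(
                f"study {index.study_id}: significant feature list larger than reference"
            )
        per_study.append((compound_sets, n_draw))
    members = [
        pathway.compound_ids & universe
        for pathway in model.pathways
        if pathway.compound_ids & universe
    ]
    values = np.empty(n_permutations * len(members))
    pos = 0
    for _ in range(n_permutations):
        seen: dict[str, int] = {}
        for compound_sets, n_draw in per_study:
            chosen: set[str] = set()
            for j in rng.choice(len(compound_sets), size=n_draw, replace=False):
                chosen |= compound_sets[j]
            for cid in chosen:
                seen[cid] = seen.get(cid, 0) + 1
        threshold = 1 if min_studies is None else min_studies
        pseudo_sig = {cid for cid, n in seen.items() if n >= threshold}
        n_sig = len(pseudo_sig)
        for in_universe in members:
            k = len(in_universe & pseudo_sig)
            values[pos] = ease_fisher_p(k, len(in_universe), n_sig, N)
            pos += 1
    return values


def permutation_null(
    index: AnnotationIndex,
    model: MetabolicModel,
    n_permutations: int = 100,
    seed: int = 42,
) -> NullDistribution:
    """Single-study permutation null (see :func:`null_values_for_indexes`)."""
    rng = np.random.default_rng(seed)
    values = null_values_for_indexes([index], model, n_permutations, rng)
    return NullDistribution(values=values, n_permutations=n_permutations, seed=seed)


def adjust_p(p_raw: float, null: NullDistribution, method: str = "empirical") -> float:
    """Calibrate a raw pathway score against a permutation null.

    ``empirical`` (default): the add-one empirical tail probability
    ``(1 + #{v < p} + #{v = p}/2) / (1 + |values|)``; ties between the
    observed score and null scores count half, which keeps the adjusted
    p-value calibrated for the discrete pathway statistic (with a tie-free
    null this is the usual ``(1 + #{v <= p}) / (1 + n)`` rule).

    ``gamma``: fit a gamma distribution to the -log10 null scores and return
    its upper tail at -log10 p_raw; falls back to empirical (with a warning)
    when the fit degenerates.
    """
    values = null.values
    if method == "gamma":
        transformed = -np.log10(np.clip(values, 1e-300, 1.0))
        try:
            if np.ptp(transformed) <= 0:
                raise ValueError("degenerate null (all scores equal)")
            shape, loc, scale = stats.gamma.fit(transformed)
            if not (np.isfinite([shape, loc, scale]).all() and shape > 0 and scale > 0):
                raise ValueError("gamma fit produced invalid parameters")
        except Exception as exc:  # scipy raises various types on bad fits
            warnings.warn(
                f"gamma fit failed ({exc}); falling back to empirical adjustment",
                stacklevel=2,
            )
            return adjust_p(p_raw, null, method="empirical")
        tail = float(
            stats.gamma.sf(-math.log10(max(p_raw, 1e-300)), shape, loc=loc, scale=scale)
        )
        return min(max(tail, 1.0 / (1 + values.size)), 1.0)
    if method != "empirical":
        raise ParameterError(f"unknown adjustment method {method!r}")
    below = int(np.count_nonzero(values < p_raw))
    ties = int(np.count_nonzero(values == p_raw))
    return (1.0 + below + 0.5 * ties) / (1.0 + values.size)
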