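"""Synthetic-study generator.

Emulates the peak lists of independent untargeted LC-MS studies of the same
biology, with known ground truth, so every pipeline stage is testable
offline:

* one feature per compound of each *enriched* pathway, placed at a random
  mode-appropriate adduct m/z with Gaussian ppm jitter and a p-value drawn
  from Beta(a, 1) with a << 1 (strongly shifted toward 0);
* ``n_background`` features on random non-enriched compounds with
  p ~ Uniform(0, 1);
* ``floor(frac_decoy * n_background)`` decoy features whose m/z is uniform
  over the model's neutral-mass range — matching a decoy is a
  tolerance-driven false annotation.

With an empty enriched set ("null mode") no feature carries a systematically
small p-value. Everything is deterministic given the model, the truth record
and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotate import mz_from_neutral, rules_for_mode
from .errors import ParameterError
from .io import Feature, Study, StudyParams
from .model import MetabolicModel

__all__ = ["SyntheticTruth", "generate_study", "generate_meta_set"]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth shared by a set of generated studies."""

    enriched_pathway_ids: frozenset[str] = frozenset()
    effect: float = 0.05  # Beta(a, 1) shape for enriched p-values
    n_background: int = 100
    frac_decoy: float = 0.2
    ppm_jitter_sd: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "enriched_pathway_ids", frozenset(self.enriched_pathway_ids)
        )
        if not self.effect > 0:
            raise ParameterError(f"Beta shape must be > 0, got {self.effect}")
        if self.n_background < 0:
            raise ParameterError("n_background must be >= 0")
        if not 0.0 <= self.frac_decoy <= 1.0:
            raise ParameterError("frac_decoy must be in [0, 1]")
        if self.ppm_jitter_sd < 0:
            raise ParameterError("ppm_jitter_sd must be >= 0")


def _jittered_mz(mass: float, rule, rng: np.random.Generator, sd_ppm: float) -> float:
    mz = mz_from_neutral(mass, rule)
    return mz * (1.0 + rng.normal(0.0, sd_ppm) * 1e-6)


def generate_study(
    model: MetabolicModel,
    truth: SyntheticTruth,
    mode: str = "positive",
    seed: int = 0,
    study_id: str | None = None,
    params: StudyParams | None = None,
) -> tuple[Study, SyntheticTruth]:
    """Generate one synthetic peak list; returns (study, truth echo)."""
    known = {p.id for p in model.pathways}
    missing = truth.enriched_pathway_ids - known
    if missing:
        raise ParameterError(f"enriched pathway ids not in model: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    rules = rules_for_mode(mode)
    study_id = study_id or f"synthetic_{seed}"
    source_tag = f"{study_id}.tsv"

    enriched_compounds: set[str] = set()
    for pid in sorted(truth.enriched_pathway_ids):
        enriched_compounds |= model.pathway(pid).compound_ids
    background_pool = sorted(set(model.compounds) - enriched_compounds)
    lo_mass, hi_mass = model.mass_range

    features: list[Feature] = []

    def emit(mass: float | None, p: float) -> None:
        if mass is None:  # decoy: uniform over the model's neutral-mass range
            mz = rng.uniform(lo_mass, hi_mass)
        else:
            rule = rules[rng.integers(len(rules))]
            mz = _jittered_mz(mass, rule, rng, truth.ppm_jitter_sd)
        features.append(
            Feature(
                mz=float(mz),
                p_value=float(p),
                rt=float(rng.uniform(10.0, 600.0)),
                intensity=float(10 ** rng.normal(5.0, 0.7)),
                source_tag=source_tag,
            )
        )

    for cid in sorted(enriched_compounds):
        emit(model.compounds[cid].monoisotopic_mass, rng.beta(truth.effect, 1.0))
    if truth.n_background and background_pool:
        for idx in rng.integers(len(background_pool), size=truth.n_background):
            emit(
                model.compounds[background_pool[idx]].monoisotopic_mass,
                rng.uniform(),
            )
    for _ in range(int(truth.frac_decoy * truth.n_background)):
        emit(None, rng.uniform())

    study = Study(
        study_id=study_id,
        features=tuple(features),
        mode=mode,
        params=params or StudyParams(),
    )
    return study, truth


def generate_meta_set(
    model: MetabolicModel,
    truth: SyntheticTruth,
    n_studies: int = 2,
    base_seed: int = 0,
    mode: str = "positive",
    params: StudyParams | None = None,
) -> list[Study]:
    """Independent studies of the same biology: shared enriched pathways,
    distinct derived seeds (``base_seed + i``)."""
    if n_studies < 2:
        raise ParameterError("a meta-set needs at least 2 studies")
    return [
        generate_study(
            model,
            truth,
            mode=mode,
            seed=base_seed + i,
            study_id=f"synthetic_study_{i + 1}",
            params=params,
        )[0]
        for i in range(n_studies)
    ]
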