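"""Simulation harnesses that validate the pipeline's statistical behavior.

Two standing experiments, both fully deterministic given a seed:

* **null calibration** — replicate null-mode meta-analyses (no spiked
  pathway) and pool the adjusted pathway p-values; under a correctly
  calibrated pipeline the pooled values are approximately uniform and the
  fraction below 0.05 is close to 0.05. Null-mode studies use dense peak
  lists (500 background features per study, ~6.5 features per model
  compound) so that the significant compound set is a sizeable fraction of
  the universe and the pathway statistic takes many distinct values — the
  regime in which a uniformity check is informative.

* **spike-in recovery** — replicate two-study meta-sets sharing one
  enriched pathway (Beta(0.05, 1) p-values, 2 ppm mass jitter against a
  10 ppm tolerance, 100 background features) and measure how often that
  pathway ranks first by merged raw p-value.

These functions are used by the test suite and by the reproduction script;
they are part of the public API so users can rerun the calibration against
their own models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meta import MetaConfig, meta_analyze
from .model import MetabolicModel, builtin_toy_model
from .synthetic import SyntheticTruth, generate_meta_set

__all__ = [
    "NullCalibrationResult",
    "SpikeRecoveryResult",
    "null_calibration_experiment",
    "spike_recovery_experiment",
]

#: study conditions of the null-calibration experiment (see module docstring)
NULL_MODE_TRUTH = SyntheticTruth(
    enriched_pathway_ids=frozenset(), n_background=500, frac_decoy=0.2
)


@dataclass(frozen=True)
class NullCalibrationResult:
    p_adjusted: np.ndarray  # pooled across pathways and replicates
    n_replicates: int

    @property
    def fraction_below_005(self) -> float:
        return float(np.mean(self.p_adjusted < 0.05))


@dataclass(frozen=True)
class SpikeRecoveryResult:
    n_rank_one: int
    n_replicates: int

    @property
    def fraction_rank_one(self) -> float:
        return self.n_rank_one / self.n_replicates


def null_calibration_experiment(
    n_replicates: int = 200,
    seed: int = 42,
    model: MetabolicModel | None = None,
    permutations: int = 100,
) -> NullCalibrationResult:
    """Pooled adjusted p-values from ``n_replicates`` null-mode two-study
    meta-analyses."""
    model = model or builtin_toy_model()
    pooled: list[float] = []
    for rep in range(n_replicates):
        studies = generate_meta_set(
            model, NULL_MODE_TRUTH, n_studies=2,
            base_seed=seed * 1_000_000 + 10 * rep,
        )
        analysis = meta_analyze(
            studies, model,
            config=MetaConfig(permutations=permutations, seed=seed + rep),
        )
        pooled.extend(r.p_adjusted for r in analysis.pathways)
    return NullCalibrationResult(
        p_adjusted=np.asarray(pooled), n_replicates=n_replicates
    )


def spike_recovery_experiment(
    n_replicates: int = 50,
    seed: int = 42,
    model: MetabolicModel | None = None,
    enriched_pathway_id: str = "P3",
    effect: float = 0.05,
    ppm_jitter_sd: float = 2.0,
) -> SpikeRecoveryResult:
    """How often the spiked pathway ranks first by merged raw p-value."""
    model = model or builtin_toy_model()
    truth = SyntheticTruth(
        enriched_pathway_ids=frozenset({enriched_pathway_id}),
        effect=effect,
        ppm_jitter_sd=ppm_jitter_sd,
    )
    wins = 0
    for rep in range(n_replicates):
        studies = generate_meta_set(
            model, truth, n_studies=2, base_seed=seed * 1_000_000 + 10 * rep
        )
        analysis = meta_analyze(
            studies, model, config=MetaConfig(permutations=10, seed=seed + rep)
        )
        wins += analysis.pathways[0].pathway_id == enriched_pathway_id
    return SpikeRecoveryResult(n_rank_one=wins, n_replicates=n_replicates)
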