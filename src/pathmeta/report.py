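"""Result tables and run configuration.

Two deterministic tsv outputs mirror the web tool's downloadable tables:

* pathway results — one row per jointly dysregulated pathway, with per-study
  hit counts, shared/merged metabolite counts, raw and permutation-adjusted
  p-values and the omics overlay columns;
* metabolite results — one row per merged dysregulated compound with its
  best p-value, per-study p-values, adducts and source files.

Rerunning with the same inputs and seed produces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .errors import ConfigurationError, ParameterError
from .io import StudyParams
from .meta import MergedCompound, MetaPathwayResult
from .model import MetabolicModel

__all__ = [
    "StudySpec",
    "RunConfig",
    "load_run_config",
    "write_pathway_results",
    "write_metabolite_results",
    "write_manifest",
]


def _fmt(value: Optional[float]) -> str:
    """Floats with 6 significant digits; empty cell for missing values."""
    if value is None:
        return ""
    return f"{value:.6g}"


def write_pathway_results(
    results: Sequence[MetaPathwayResult],
    path: str | Path,
    study_ids: Sequence[str] | None = None,
) -> None:
    """Write the pathway results table (tsv, sorted by raw p-value)."""
    if study_ids is None:
        study_ids = list(results[0].per_study_hits) if results else []
    header = (
        ["pathway_id", "pathway_name", "pathway_size", "matched_in_reference"]
        + [f"sig_hits_{sid}" for sid in study_ids]
        + [
            "shared_metabolites",
            "merged_hits",
            "p_raw",
            "p_adjusted",
            "gene_hits_n",
            "gene_hits",
            "protein_hits_n",
            "protein_hits",
            "compound_hits",
        ]
    )
    rows = sorted(results, key=lambda r: (r.p_raw, -r.merged_hits, r.pathway_id))
    with open(path, "w", newline="") as handle:
        handle.write("\t".join(header) + "\n")
        for r in rows:
            cells = [
                r.pathway_id,
                r.pathway_name,
                str(r.pathway_size),
                str(r.matched_in_reference),
                *[str(r.per_study_hits.get(sid, 0)) for sid in study_ids],
                str(r.shared_count),
                str(r.merged_hits),
                _fmt(r.p_raw),
                _fmt(r.p_adjusted),
                str(len(r.gene_hits)),
                ";".join(sorted(r.gene_hits)),
                str(len(r.protein_hits)),
                ";".join(sorted(r.protein_hits)),
                ";".join(sorted(mc.compound_id for mc in r.shared_compounds)),
            ]
            handle.write("\t".join(cells) + "\n")


def write_metabolite_results(
    merged: dict[str, MergedCompound] | Sequence[MergedCompound],
    path: str | Path,
    model: MetabolicModel | None = None,
    study_ids: Sequence[str] | None = None,
) -> None:
    """Write the merged metabolite table (tsv, sorted by best p-value)."""
    compounds = list(merged.values()) if isinstance(merged, dict) else list(merged)
    if study_ids is None:
        seen: list[str] = []
        for mc in compounds:
            for sid in mc.per_study_p:
                if sid not in seen:
                    seen.append(sid)
        study_ids = seen
    header = (
        ["compound_id", "compound_name", "n_studies_seen", "best_p"]
        + [f"p_{sid}" for sid in study_ids]
        + ["adducts", "source_files"]
    )
    compounds.sort(
        key=lambda mc: (mc.best_p if mc.best_p is not None else -1.0, mc.compound_id)
    )
    with open(path, "w", newline="") as handle:
        handle.write("\t".join(header) + "\n")
        for mc in compounds:
            name = ""
            if model is not None and mc.compound_id in model.compounds:
                name = model.compounds[mc.compound_id].name
            cells = [
                mc.compound_id,
                name,
                str(mc.n_studies_seen),
                _fmt(mc.best_p),
                *[
                    _fmt(mc.per_study_p[sid]) if sid in mc.per_study_p else ""
                    for sid in study_ids
                ],
                ";".join(sorted(mc.adducts)),
                ";".join(sorted(mc.source_files)),
            ]
            handle.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# run configuration


@dataclasses.dataclass(frozen=True)
class StudySpec:
    """One input peak list and its per-study settings."""

    path: str
    dialect: str = "generic"
    mode: str = "positive"
    p_cutoff: float = 0.05
    ppm: float = 10.0
    intensity_cutoff: float = 0.0
    group: Optional[str] = None
    named_metabolites: Optional[str] = None

    def params(self) -> StudyParams:
        return StudyParams(
            p_cutoff=self.p_cutoff,
            mz_tolerance_ppm=self.ppm,
            intensity_cutoff=self.intensity_cutoff,
        )


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Parsed run configuration (yaml or json)."""

    studies: tuple[StudySpec, ...]
    model: str = "toy"
    merge_mode: str = "union"
    min_shared: int = 10
    permutations: int = 100
    seed: int = 42
    adjust_method: str = "empirical"
    confirmed_as: str = "sig"
    genes: Optional[str] = None
    proteins: Optional[str] = None
    adducts: Optional[str] = None
    out_dir: str = "."


def load_run_config(path: str | Path) -> RunConfig:
    path = Path(path)
    try:
        with open(path) as handle:
            raw = yaml.safe_load(handle)
    except FileNotFoundError:
        raise ConfigurationError(f"config file not found: {path}") from None
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{path}: cannot parse config ({exc})") from None
    if not isinstance(raw, dict) or "studies" not in raw:
        raise ConfigurationError(f"{path}: config must be a mapping with a 'studies' list")
    base = path.parent

    def resolve(p: Optional[str]) -> Optional[str]:
        if p is None:
            return None
        candidate = Path(p)
        return str(candidate if candidate.is_absolute() else base / candidate)

    studies = []
    for entry in raw["studies"]:
        if not isinstance(entry, dict) or "path" not in entry:
            raise ConfigurationError(f"{path}: each study needs at least a 'path'")
        try:
            spec = StudySpec(
                path=resolve(entry["path"]),
                dialect=entry.get("dialect", "generic"),
                mode=entry.get("mode", "positive"),
                p_cutoff=float(entry.get("p_cutoff", 0.05)),
                ppm=float(entry.get("ppm", 10.0)),
                intensity_cutoff=float(entry.get("intensity_cutoff", 0.0)),
                group=entry.get("group"),
                named_metabolites=resolve(entry.get("named_metabolites")),
            )
            spec.params()  # validate thresholds eagerly
        except (TypeError, ValueError, ParameterError) as exc:
            raise ConfigurationError(f"{path}: bad study entry ({exc})") from None
        studies.append(spec)
    if not studies:
        raise ConfigurationError(f"{path}: at least one study is required")
    model = raw.get("model", "toy")
    return RunConfig(
        studies=tuple(studies),
        model=model if model == "toy" else resolve(model),
        merge_mode=raw.get("merge_mode", "union"),
        min_shared=int(raw.get("min_shared", 10)),
        permutations=int(raw.get("permutations", 100)),
        seed=int(raw.get("seed", 42)),
        adjust_method=raw.get("adjust_method", "empirical"),
        confirmed_as=raw.get("confirmed_as", "sig"),
        genes=resolve(raw.get("genes")),
        proteins=resolve(raw.get("proteins")),
        adducts=resolve(raw.get("adducts")),
        out_dir=resolve(raw.get("out_dir", ".")),
    )


def write_manifest(config: RunConfig, path: str | Path) -> None:
    """Echo the effective configuration next to the outputs (reproducibility)."""
    from . import __version__

    payload = {
        "pathmeta_version": __version__,
        "config": dataclasses.asdict(config),
    }
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=1, sort_keys=True)
        handle.write("\n")
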