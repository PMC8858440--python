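"""Peak-list input.

Heterogeneous tsv/csv peak lists (generic exports, XCMS diffreports,
Metabolomics-Workbench-style feature tables) are parsed into a uniform
:class:`Study`. Every feature is tagged with the basename of its input file so
it can be traced through annotation, merging and reporting. Named-metabolite
tables ("confirmed metabolites") are read separately and attached during
annotation.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import DialectError, ParameterError, RowParseError
from .model import normalize_name

__all__ = [
    "Feature",
    "StudyParams",
    "Study",
    "NamedMetaboliteRecord",
    "read_feature_table",
    "read_named_metabolites",
    "partition_significant",
    "write_feature_table",
]


@dataclass(frozen=True)
class Feature:
    """One detected (m/z, rt) peak with its pairwise statistics."""

    mz: float
    p_value: Optional[float]
    source_tag: str
    rt: Optional[float] = None
    intensity: Optional[float] = None
    fold_change: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ParameterError(f"feature m/z must be > 0, got {self.mz}")
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ParameterError(f"feature p-value outside [0, 1]: {self.p_value}")
        if not self.source_tag:
            raise ParameterError("feature source_tag must be nonempty")


@dataclass(frozen=True)
class StudyParams:
    """Per-study thresholds: significance, mass tolerance, intensity floor."""

    p_cutoff: float = 0.05
    mz_tolerance_ppm: float = 10.0
    intensity_cutoff: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_cutoff <= 1.0:
            raise ParameterError(f"p_cutoff must be in (0, 1], got {self.p_cutoff}")
        if not self.mz_tolerance_ppm > 0:
            raise ParameterError(
                f"mz_tolerance_ppm must be > 0, got {self.mz_tolerance_ppm}"
            )
        if not self.intensity_cutoff >= 0 or not math.isfinite(self.intensity_cutoff):
            raise ParameterError(
                f"intensity_cutoff must be finite and >= 0, got {self.intensity_cutoff}"
            )


@dataclass(frozen=True)
class Study:
    """One peak list with its ionization mode and thresholds.

    Several analytical modalities of the same biological study (e.g. HILIC
    negative + RP positive) are separate Study objects sharing a ``group``
    label; their annotated compound sets are unioned downstream.
    """

    study_id: str
    features: tuple[Feature, ...]
    mode: str = "positive"
    params: StudyParams = field(default_factory=StudyParams)
    group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in ("positive", "negative"):
            raise ParameterError(f"mode must be positive/negative, got {self.mode!r}")
        object.__setattr__(self, "features", tuple(self.features))


@dataclass(frozen=True)
class NamedMetaboliteRecord:
    """An already-identified metabolite from an archived study."""

    name: str
    compound_id: Optional[str] = None
    p_value: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ParameterError("named metabolite must have a nonempty name")


# ---------------------------------------------------------------------------
# dialects

# canonical column -> accepted header spellings (lowercased) per dialect
_DIALECTS: dict[str, dict[str, tuple[str, ...]]] = {
    "generic": {
        "mz": ("mz", "m/z", "mass"),
        "p_value": ("p_value", "pvalue", "p-value", "p"),
        "rt": ("rt", "retention_time", "rtime"),
        "intensity": ("intensity", "into", "maxint"),
        "fold_change": ("fold_change", "fold", "fc"),
    },
    "xcms_diffreport": {
        "mz": ("mzmed", "mz"),
        "p_value": ("pvalue", "p_value"),
        "rt": ("rtmed", "rt"),
        "fold_change": ("fold", "fold_change"),
    },
    "workbench_features": {
        "mz": ("mz", "m/z", "quantified_mz"),
        "p_value": ("p_value", "pvalue", "p-value"),
        "rt": ("rt", "retention_time", "retention_index"),
        "intensity": ("intensity",),
        "name": ("metabolite_name", "name"),
    },
}

_REQUIRED = ("mz", "p_value")

# diffreport bookkeeping columns that are numeric but are not sample intensities
_DIFFREPORT_META = {
    "fold", "tstat", "pvalue", "mzmed", "mzmin", "mzmax", "rtmed", "rtmin",
    "rtmax", "npeaks", "anova", "qvalue",
}


def _sniff_table(path: Path) -> pd.DataFrame:
    with open(path, newline="") as handle:
        sample = handle.read(8192)
    try:
        delimiter = csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        delimiter = "\t"
    return pd.read_csv(path, sep=delimiter)


def _resolve_columns(columns: Iterable[str], dialect: str) -> dict[str, str]:
    lookup = {str(c).strip().lower(): str(c) for c in columns}
    resolved: dict[str, str] = {}
    for canonical, synonyms in _DIALECTS[dialect].items():
        for synonym in synonyms:
            if synonym in lookup:
                resolved[canonical] = lookup[synonym]
                break
    return resolved


def _as_float(value: object, column: str, line: int, path: Path,
              skip_bad_rows: bool) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        if skip_bad_rows:
            return math.nan  # sentinel: caller drops the row
        raise RowParseError(
            f"{path}, line {line}: non-numeric {column} value {value!r}"
        ) from None


def read_feature_table(
    path: str | Path,
    dialect: str = "generic",
    mode: str = "positive",
    params: StudyParams | None = None,
    study_id: str | None = None,
    group: str | None = None,
    skip_bad_rows: bool = False,
) -> Study:
    """Parse a tsv/csv peak list into a :class:`Study`.

    The delimiter is auto-detected (tab or comma). Column headers are matched
    case-insensitively against per-dialect synonym tables; m/z and p-value are
    required, everything else optional. A malformed numeric cell raises
    :class:`RowParseError` with the offending line number unless
    ``skip_bad_rows`` is set, in which case the row is dropped.
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise DialectError(
            f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}"
        )
    table = _sniff_table(path)
    resolved = _resolve_columns(table.columns, dialect)
    missing = [c for c in _REQUIRED if c not in resolved]
    if missing:
        raise DialectError(
            f"{path}: dialect {dialect!r} requires column(s) "
            + ", ".join(repr(m) for m in missing)
            + f"; found {list(table.columns)}"
        )

    intensity_cols: list[str] = []
    if dialect == "xcms_diffreport" and "intensity" not in resolved:
        # remaining numeric columns are per-sample intensities; keep the max
        mapped = {v for v in resolved.values()}
        for col in table.columns:
            if col in mapped or str(col).strip().lower() in _DIFFREPORT_META:
                continue
            if pd.api.types.is_numeric_dtype(table[col]):
                intensity_cols.append(col)

    source_tag = path.name
    features: list[Feature] = []
    for i, row in table.iterrows():
        line = int(i) + 2  # 1-based, after the header row
        mz = _as_float(row[resolved["mz"]], "m/z", line, path, skip_bad_rows)
        p = _as_float(row[resolved["p_value"]], "p-value", line, path, skip_bad_rows)
        if (mz is not None and math.isnan(mz)) or (p is not None and math.isnan(p)):
            continue  # skip_bad_rows sentinel
        if mz is None:
            if skip_bad_rows:
                continue
            raise RowParseError(f"{path}, line {line}: missing m/z value")
        kwargs: dict[str, Optional[float]] = {}
        for optional in ("rt", "intensity", "fold_change"):
            if optional in resolved:
                kwargs[optional] = _as_float(
                    row[resolved[optional]], optional, line, path, True
                )
                if kwargs[optional] is not None and math.isnan(kwargs[optional]):
                    kwargs[optional] = None
        if intensity_cols:
            sample_max = pd.to_numeric(row[intensity_cols], errors="coerce").max()
            kwargs["intensity"] = None if pd.isna(sample_max) else float(sample_max)
        features.append(Feature(mz=mz, p_value=p, source_tag=source_tag, **kwargs))

    return Study(
        study_id=study_id or path.stem,
        features=tuple(features),
        mode=mode,
        params=params or StudyParams(),
        group=group,
    )


def write_feature_table(study: Study, path: str | Path) -> None:
    """Serialize a study back to a generic-dialect tsv (round-trip safe)."""
    rows = [
        {
            "mz": repr(f.mz),
            "rt": "" if f.rt is None else repr(f.rt),
            "p_value": "" if f.p_value is None else repr(f.p_value),
            "intensity": "" if f.intensity is None else repr(f.intensity),
            "fold_change": "" if f.fold_change is None else repr(f.fold_change),
        }
        for f in study.features
    ]
    pd.DataFrame(rows, columns=["mz", "rt", "p_value", "intensity", "fold_change"]).to_csv(
        path, sep="\t", index=False
    )


def read_named_metabolites(path: str | Path) -> list[NamedMetaboliteRecord]:
    """Read a table of identified metabolites (confirmed compounds).

    Requires a ``name`` (or ``metabolite_name``/``metabolite``) or ``compound_id``
    column; optional ``p_value``. Names are normalized the way the model store
    normalizes compound names.
    """
    path = Path(path)
    table = _sniff_table(path)
    lookup = {str(c).strip().lower(): str(c) for c in table.columns}
    name_col = next(
        (lookup[c] for c in ("name", "metabolite_name", "metabolite") if c in lookup),
        None,
    )
    id_col = next((lookup[c] for c in ("compound_id", "id") if c in lookup), None)
    if name_col is None and id_col is None:
        raise DialectError(f"{path}: need a name or compound_id column")
    p_col = next(
        (lookup[c] for c in ("p_value", "pvalue", "p-value", "p") if c in lookup), None
    )
    records: list[NamedMetaboliteRecord] = []
    for i, row in table.iterrows():
        raw_name = row[name_col] if name_col else None
        raw_id = row[id_col] if id_col else None
        name = "" if pd.isna(raw_name) else normalize_name(str(raw_name))
        cid = None if raw_id is None or pd.isna(raw_id) else str(raw_id).strip()
        if not name and not cid:
            continue
        p = None
        if p_col is not None and not pd.isna(row[p_col]):
            p = _as_float(row[p_col], "p-value", int(i) + 2, path, False)
        records.append(
            NamedMetaboliteRecord(name=name or cid, compound_id=cid, p_value=p)
        )
    if not records:
        raise DialectError(f"{path}: no records")
    return records


def partition_significant(study: Study) -> tuple[list[Feature], list[Feature]]:
    """Split a study into (significant, reference) feature lists.

    The reference list holds every feature passing the intensity floor
    (features without an intensity pass only when the floor is 0); the
    significant list is the subset with ``p < p_cutoff`` (strict). Features
    without a p-value are never significant. ``significant ⊆ reference``.
    """
    params = study.params
    reference = [
        f
        for f in study.features
        if (f.intensity is not None and f.intensity >= params.intensity_cutoff)
        or (f.intensity is None and params.intensity_cutoff == 0)
    ]
    significant = [
        f for f in reference if f.p_value is not None and f.p_value < params.p_cutoff
    ]
    return significant, reference


def with_params(study: Study, **kwargs) -> Study:
    """Return a copy of ``study`` with updated threshold parameters."""
    return replace(study, params=replace(study.params, **kwargs))
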