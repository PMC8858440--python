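"""Putative annotation by adduct enumeration and neutral-mass matching.

Each feature m/z is turned into candidate neutral masses through a table of
adduct rules (M = (mz·|z| − shift) / n), and candidates are matched against
model compounds inside the study's relative mass tolerance
(|Δm| / compound mass × 1e6 ≤ ppm). A compound hit by several features or
adducts appears once in the compound sets with its best (smallest) feature
p-value; every contributing (feature, adduct) pair is kept so results can be
filtered by adduct or source file later.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .errors import ConfigurationError
from .io import Feature, NamedMetaboliteRecord, Study, partition_significant
from .model import MetabolicModel, normalize_name

__all__ = [
    "AdductRule",
    "CompoundMatch",
    "AnnotationIndex",
    "DEFAULT_ADDUCTS",
    "neutral_mass",
    "mz_from_neutral",
    "enumerate_candidates",
    "match_study",
    "attach_confirmed",
    "load_adduct_table",
    "rules_for_mode",
]

logger = logging.getLogger(__name__)

PROTON = 1.007276


@dataclass(frozen=True)
class AdductRule:
    """One ionized form: observed mz = (n·M + mass_shift) / |charge|."""

    name: str
    mass_shift: float
    charge: int
    mol_multiplier: int = 1
    mode: str = "positive"

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ConfigurationError(f"adduct {self.name!r}: charge must be nonzero")
        if self.mol_multiplier < 1:
            raise ConfigurationError(
                f"adduct {self.name!r}: mol_multiplier must be >= 1"
            )
        if self.mode not in ("positive", "negative"):
            raise ConfigurationError(f"adduct {self.name!r}: bad mode {self.mode!r}")
        if (self.charge > 0) != (self.mode == "positive"):
            raise ConfigurationError(
                f"adduct {self.name!r}: charge sign inconsistent with {self.mode} mode"
            )


#: Common electrospray adducts; user-overridable via a tsv table (--adducts).
DEFAULT_ADDUCTS: tuple[AdductRule, ...] = (
    AdductRule("M+H", PROTON, 1, 1, "positive"),
    AdductRule("M+Na", 22.989218, 1, 1, "positive"),
    AdductRule("M+K", 38.963158, 1, 1, "positive"),
    AdductRule("M+NH4", 18.033823, 1, 1, "positive"),
    AdductRule("M+H-H2O", -17.002740, 1, 1, "positive"),
    AdductRule("2M+H", PROTON, 1, 2, "positive"),
    AdductRule("M-H", -PROTON, -1, 1, "negative"),
    AdductRule("M+Cl", 34.969402, -1, 1, "negative"),
    AdductRule("M-H-H2O", -19.017840, -1, 1, "negative"),
    AdductRule("2M-H", -PROTON, -1, 2, "negative"),
)


def load_adduct_table(path) -> tuple[AdductRule, ...]:
    """Read adduct rules from a tsv with columns name, mass_shift, charge,
    mol_multiplier, mode."""
    table = pd.read_csv(path, sep="\t")
    required = {"name", "mass_shift", "charge", "mol_multiplier", "mode"}
    missing = required - set(table.columns)
    if missing:
        raise ConfigurationError(f"{path}: adduct table missing columns {sorted(missing)}")
    return tuple(
        AdductRule(
            name=str(row["name"]),
            mass_shift=float(row["mass_shift"]),
            charge=int(row["charge"]),
            mol_multiplier=int(row["mol_multiplier"]),
            mode=str(row["mode"]),
        )
        for _, row in table.iterrows()
    )


def neutral_mass(mz: float, rule: AdductRule) -> float:
    """Candidate neutral mass implied by observing ``mz`` under ``rule``.

    May be nonpositive for small m/z with subtractive adducts; callers discard
    those candidates.
    """
    return (mz * abs(rule.charge) - rule.mass_shift) / rule.mol_multiplier


def mz_from_neutral(mass: float, rule: AdductRule) -> float:
    """Inverse of :func:`neutral_mass`: the m/z at which ``mass`` is observed."""
    return (mass * rule.mol_multiplier + rule.mass_shift) / abs(rule.charge)


def rules_for_mode(mode: str, rules: Sequence[AdductRule] | None = None) -> tuple[AdductRule, ...]:
    rules = tuple(rules) if rules is not None else DEFAULT_ADDUCTS
    applicable = tuple(r for r in rules if r.mode == mode)
    if not applicable:
        raise ConfigurationError(f"no adduct rules available for {mode} mode")
    return applicable


def enumerate_candidates(
    mz: float, mode: str, rules: Sequence[AdductRule] | None = None
) -> list[tuple[float, str]]:
    """All (neutral mass, adduct name) candidates for one m/z, in rule-table
    order; candidates with nonpositive neutral mass are dropped."""
    out = []
    for rule in rules_for_mode(mode, rules):
        mass = neutral_mass(mz, rule)
        if mass > 0:
            out.append((mass, rule.name))
    return out


@dataclass(frozen=True)
class CompoundMatch:
    """One (feature, adduct) → compound assignment."""

    feature: Feature
    compound_id: str
    adduct_name: str
    inferred_neutral_mass: Optional[float]
    ppm_error: Optional[float]
    confirmed: bool = False
    significant: bool = False


@dataclass
class AnnotationIndex:
    """Feature↔compound matches for one study, split by partition.

    ``matched_reference_compounds`` is the study's contribution to the
    enrichment universe; ``matched_significant_compounds`` maps each
    dysregulated compound to the best feature p-value (None for confirmed
    metabolites that carry no statistic). ``reference_feature_compounds``
    keeps, for every reference feature, the set of compounds it annotates —
    this is what the permutation null resamples.
    """

    study_id: str
    matches: list[CompoundMatch] = field(default_factory=list)
    by_compound: dict[str, set[Feature]] = field(default_factory=dict)
    matched_reference_compounds: set[str] = field(default_factory=set)
    matched_significant_compounds: dict[str, Optional[float]] = field(default_factory=dict)
    reference_feature_compounds: list[tuple[Feature, frozenset[str]]] = field(default_factory=list)
    n_significant_features: int = 0
    unmatched_confirmed: list[str] = field(default_factory=list)

    def record(self, match: CompoundMatch) -> None:
        self.matches.append(match)
        self.by_compound.setdefault(match.compound_id, set()).add(match.feature)
        self.matched_reference_compounds.add(match.compound_id)
        if match.significant:
            best = self.matched_significant_compounds.get(match.compound_id, 1.0)
            p = match.feature.p_value
            if match.compound_id not in self.matched_significant_compounds:
                self.matched_significant_compounds[match.compound_id] = p
            elif p is not None and (best is None or p < best):
                self.matched_significant_compounds[match.compound_id] = p


def match_study(
    study: Study,
    model: MetabolicModel,
    rules: Sequence[AdductRule] | None = None,
) -> AnnotationIndex:
    """Annotate every feature of a study against the model.

    A compound matches a feature under a rule iff
    ``|inferred_neutral − compound_mass| / compound_mass × 1e6`` is within the
    study's ppm tolerance. Matching runs over both the reference and the
    significant partitions; the significant partition drives the best-p
    compound statistics.
    """
    applicable = rules_for_mode(study.mode, rules)
    tol = study.params.mz_tolerance_ppm * 1e-6

    ordered = sorted(model.compounds.values(), key=lambda c: c.monoisotopic_mass)
    masses = [c.monoisotopic_mass for c in ordered]

    significant, reference = partition_significant(study)
    sig_set = set(significant)

    index = AnnotationIndex(study_id=study.study_id)
    index.n_significant_features = len(significant)

    for feature in reference:
        feature_compounds: set[str] = set()
        is_sig = feature in sig_set
        for rule in applicable:
            inferred = neutral_mass(feature.mz, rule)
            if inferred <= 0:
                continue
            # mass m satisfies |inferred - m| <= m*tol  <=>  m in [lo, hi]
            lo = inferred / (1.0 + tol)
            hi = inferred / (1.0 - tol) if tol < 1 else float("inf")
            for j in range(bisect_left(masses, lo), bisect_right(masses, hi)):
                compound = ordered[j]
                ppm = (inferred - compound.monoisotopic_mass) / compound.monoisotopic_mass * 1e6
                if abs(ppm) <= study.params.mz_tolerance_ppm:
                    feature_compounds.add(compound.id)
                    index.record(
                        CompoundMatch(
                            feature=feature,
                            compound_id=compound.id,
                            adduct_name=rule.name,
                            inferred_neutral_mass=inferred,
                            ppm_error=ppm,
                            significant=is_sig,
                        )
                    )
        index.reference_feature_compounds.append((feature, frozenset(feature_compounds)))
    return index


def attach_confirmed(
    records: Sequence[NamedMetaboliteRecord],
    model: MetabolicModel,
    index: AnnotationIndex,
    p_cutoff: float = 0.05,
    confirmed_as: str = "sig",
) -> AnnotationIndex:
    """Add already-identified metabolites to an annotation index.

    Records are resolved against the model by compound id first, then by
    normalized name/alias. A confirmed metabolite joins the reference set
    always, and the significant set when its p-value beats the cutoff or is
    absent (``confirmed_as="sig"``; with ``"ref"`` statistic-free records stay
    reference-only). Unresolvable names are logged and returned in
    ``index.unmatched_confirmed``, never fatal.
    """
    if confirmed_as not in ("sig", "ref"):
        raise ConfigurationError(f"confirmed_as must be 'sig' or 'ref', got {confirmed_as!r}")
    by_name = model.compounds_by_name()
    for record in records:
        normalized = normalize_name(record.name)
        if record.compound_id and record.compound_id in model.compounds:
            cid = record.compound_id
        elif normalized in model.compounds:  # names are often bare ids
            cid = normalized
        else:
            cid = by_name.get(normalized)
        if cid is None:
            index.unmatched_confirmed.append(record.name)
            logger.warning(
                "study %s: confirmed metabolite %r not in model", index.study_id, record.name
            )
            continue
        compound = model.compounds[cid]
        feature = Feature(
            mz=compound.monoisotopic_mass,
            p_value=record.p_value,
            source_tag=f"confirmed:{index.study_id}",
        )
        if record.p_value is None:
            significant = confirmed_as == "sig"
        else:
            significant = record.p_value < p_cutoff
        index.record(
            CompoundMatch(
                feature=feature,
                compound_id=cid,
                adduct_name="confirmed",
                inferred_neutral_mass=None,
                ppm_error=None,
                confirmed=True,
                significant=significant,
            )
        )
        index.reference_feature_compounds.append((feature, frozenset({cid})))
        if significant:
            index.n_significant_features += 1
    return index
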