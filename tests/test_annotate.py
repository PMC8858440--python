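"""Adduct algebra, candidate enumeration, and mass matching vs. a brute force."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pathmeta as pm
from pathmeta.annotate import DEFAULT_ADDUCTS, rules_for_mode
from pathmeta.errors import ConfigurationError

M_H = DEFAULT_ADDUCTS[0]
M_NA = DEFAULT_ADDUCTS[1]
TWO_M_H = next(r for r in DEFAULT_ADDUCTS if r.name == "2M+H")
M_MINUS_H = next(r for r in DEFAULT_ADDUCTS if r.name == "M-H")


class TestNeutralMass:
    @pytest.mark.parametrize(
        "mz,rule,expected",
        [
            (181.070664, M_H, 180.063388),
            (179.056112, M_MINUS_H, 180.063388),
            (361.134052, TWO_M_H, 180.063388),
        ],
    )
    def test_known_adduct_arithmetic(self, mz, rule, expected):
        assert pm.neutral_mass(mz, rule) == pytest.approx(expected, abs=1e-9)

    @given(
        mass=st.floats(50.0, 2000.0),
        rule=st.sampled_from(DEFAULT_ADDUCTS),
    )
    def test_round_trip_through_mz(self, mass, rule):
        mz = pm.mz_from_neutral(mass, rule)
        assert pm.neutral_mass(mz, rule) == pytest.approx(mass, abs=1e-9)


class TestEnumerateCandidates:
    def test_positive_mode_candidates(self):
        candidates = dict(
            (name, mass) for mass, name in pm.enumerate_candidates(181.070664, "positive")
        )
        assert candidates["M+H"] == pytest.approx(180.063388, abs=1e-6)
        assert candidates["M+Na"] == pytest.approx(158.081446, abs=1e-6)

    def test_nonpositive_neutral_mass_excluded(self):
        names = [name for _, name in pm.enumerate_candidates(0.5, "positive")]
        assert "2M+H" not in names  # (0.5 - 1.007276)/2 < 0
        assert "M+H" not in names

    def test_mode_without_rules_is_configuration_error(self):
        positive_only = [r for r in DEFAULT_ADDUCTS if r.mode == "positive"]
        with pytest.raises(ConfigurationError):
            pm.enumerate_candidates(181.07, "negative", positive_only)

    def test_order_follows_rule_table(self):
        names = [name for _, name in pm.enumerate_candidates(500.0, "positive")]
        table = [r.name for r in rules_for_mode("positive")]
        assert names == [n for n in table if n in names]


def _study(features, ppm=10.0, mode="positive", p_cutoff=0.05):
    return pm.Study(
        study_id="s1",
        features=tuple(features),
        mode=mode,
        params=pm.StudyParams(p_cutoff=p_cutoff, mz_tolerance_ppm=ppm),
    )


def _feature(mz, p, tag="s1.tsv"):
    return pm.Feature(mz=mz, p_value=p, source_tag=tag)


class TestMatchStudy:
    def test_exact_match_via_m_plus_h(self, model):
        study = _study([_feature(181.070664, 0.01)])
        index = pm.match_study(study, model)
        # (the same ion also annotates lactate via 2M+H: glucose is its dimer)
        assert index.matched_significant_compounds["glucose"] == 0.01
        glucose_matches = [m for m in index.matches if m.compound_id == "glucose"]
        assert any(m.adduct_name == "M+H" for m in glucose_matches)
        assert min(abs(m.ppm_error) for m in glucose_matches) < 0.1

    def test_out_of_tolerance_feature_not_matched(self, model):
        # independent ppm arithmetic: the implied neutral mass is ~10.2 ppm off
        mz = 181.072500
        implied = mz - 1.007276
        ppm_off = abs(implied - 180.063388) / 180.063388 * 1e6
        assert ppm_off > 10
        index = pm.match_study(_study([_feature(mz, 0.01)], ppm=1.0), model)
        assert "glucose" not in index.matched_reference_compounds

    def test_best_p_kept_on_duplicate_compound(self, model):
        study = _study([_feature(181.070664, 0.04), _feature(181.070664, 0.002)])
        index = pm.match_study(study, model)
        assert index.matched_significant_compounds["glucose"] == 0.002

    def test_nonsignificant_features_enter_reference_only(self, model):
        study = _study([_feature(181.070664, 0.8)])
        index = pm.match_study(study, model)
        assert "glucose" in index.matched_reference_compounds
        assert "glucose" not in index.matched_significant_compounds

    def test_monotone_in_tolerance(self, model):
        rng = np.random.default_rng(5)
        features = [
            _feature(float(mz), float(p))
            for mz, p in zip(rng.uniform(80, 550, 150), rng.uniform(0, 1, 150))
        ]
        sizes = []
        for ppm in (1.0, 5.0, 20.0, 100.0):
            index = pm.match_study(_study(features, ppm=ppm), model)
            sizes.append(len(index.matched_reference_compounds))
        assert sizes == sorted(sizes)

    def test_agrees_with_brute_force(self, model):
        """Sorted-array matcher == triple loop over (feature, rule, compound)."""
        rng = np.random.default_rng(17)
        for trial in range(10):
            mzs = rng.uniform(60, 900, 40)
            ps = rng.uniform(0, 1, 40)
            study = _study(
                [_feature(float(mz), float(p)) for mz, p in zip(mzs, ps)], ppm=12.0
            )
            index = pm.match_study(study, model)

            expected_pairs = set()
            for f in study.features:
                for rule in rules_for_mode(study.mode):
                    neutral = pm.neutral_mass(f.mz, rule)
                    if neutral <= 0:
                        continue
                    for compound in model.compounds.values():
                        ppm_err = (
                            (neutral - compound.monoisotopic_mass)
                            / compound.monoisotopic_mass
                            * 1e6
                        )
                        if abs(ppm_err) <= study.params.mz_tolerance_ppm:
                            expected_pairs.add((f.mz, rule.name, compound.id))
            got_pairs = {
                (m.feature.mz, m.adduct_name, m.compound_id) for m in index.matches
            }
            assert got_pairs == expected_pairs


class TestAttachConfirmed:
    def test_confirmed_without_p_is_significant(self, model):
        index = pm.match_study(_study([]), model)
        pm.attach_confirmed([pm.NamedMetaboliteRecord(name="Glucose")], model, index)
        assert "glucose" in index.matched_reference_compounds
        assert "glucose" in index.matched_significant_compounds
        assert index.matched_significant_compounds["glucose"] is None

    def test_confirmed_with_large_p_stays_reference_only(self, model):
        index = pm.match_study(_study([]), model)
        pm.attach_confirmed(
            [pm.NamedMetaboliteRecord(name="taurine", p_value=0.8)], model, index
        )
        assert "taurine" in index.matched_reference_compounds
        assert "taurine" not in index.matched_significant_compounds

    def test_unknown_name_warns_but_does_not_fail(self, model):
        index = pm.match_study(_study([_feature(181.070664, 0.01)]), model)
        before = set(index.matched_reference_compounds)
        pm.attach_confirmed([pm.NamedMetaboliteRecord(name="unobtainium")], model, index)
        assert index.unmatched_confirmed == ["unobtainium"]
        assert index.matched_reference_compounds == before

    def test_confirmed_as_ref_mode(self, model):
        index = pm.match_study(_study([]), model)
        pm.attach_confirmed(
            [pm.NamedMetaboliteRecord(name="Glucose")], model, index, confirmed_as="ref"
        )
        assert "glucose" in index.matched_reference_compounds
        assert "glucose" not in index.matched_significant_compounds
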