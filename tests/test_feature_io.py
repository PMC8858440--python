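"""Peak-list parsing, dialects, and the significance/intensity partition."""


import pytest
from hypothesis import given
from hypothesis import strategies as st

import pathmeta as pm
from pathmeta.errors import DialectError, ParameterError, RowParseError
from pathmeta.io import partition_significant, with_params

GENERIC_TSV = "mz\tp_value\trt\tintensity\n181.07\t0.01\t30.0\t1e5\n204.08\t0.5\t40.0\t2e5\n132.10\t0.2\t\t\n"


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadFeatureTable:
    def test_generic_tsv(self, tmp_path):
        study = pm.read_feature_table(_write(tmp_path, "a.tsv", GENERIC_TSV))
        assert len(study.features) == 3
        assert all(f.source_tag == "a.tsv" for f in study.features)
        assert study.features[0].mz == 181.07
        assert study.features[2].intensity is None

    def test_comma_delimiter_equivalent(self, tmp_path):
        tsv = pm.read_feature_table(_write(tmp_path, "a.tsv", GENERIC_TSV))
        csv = pm.read_feature_table(
            _write(tmp_path, "a.csv", GENERIC_TSV.replace("\t", ","))
        )
        assert [(f.mz, f.p_value, f.rt, f.intensity) for f in tsv.features] == [
            (f.mz, f.p_value, f.rt, f.intensity) for f in csv.features
        ]

    def test_missing_p_value_column_named(self, tmp_path):
        path = _write(tmp_path, "a.tsv", "mz\trt\n181.07\t30\n")
        with pytest.raises(DialectError, match="p_value"):
            pm.read_feature_table(path)

    def test_non_numeric_mz_reports_line(self, tmp_path):
        path = _write(tmp_path, "a.tsv", "mz\tp_value\n181.07\t0.01\noops\t0.5\n")
        with pytest.raises(RowParseError, match="line 3"):
            pm.read_feature_table(path)

    def test_skip_bad_rows(self, tmp_path):
        path = _write(tmp_path, "a.tsv", "mz\tp_value\n181.07\t0.01\noops\t0.5\n")
        study = pm.read_feature_table(path, skip_bad_rows=True)
        assert len(study.features) == 1

    def test_xcms_diffreport_dialect(self, tmp_path):
        text = (
            "name\tfold\ttstat\tpvalue\tmzmed\trtmed\tnpeaks\ts1\ts2\n"
            "M181T30\t2.0\t3.1\t0.003\t181.0707\t30.2\t4\t1000\t5000\n"
            "M204T40\t1.1\t0.4\t0.7\t204.0899\t40.1\t4\t300\t200\n"
        )
        study = pm.read_feature_table(
            _write(tmp_path, "diff.tsv", text), dialect="xcms_diffreport"
        )
        f = study.features[0]
        assert f.mz == 181.0707
        assert f.p_value == 0.003
        assert f.fold_change == 2.0
        assert f.intensity == 5000.0  # max over sample columns
        assert study.features[1].intensity == 300.0

    def test_workbench_dialect(self, tmp_path):
        text = "metabolite_name,mz,p_value\nGlucose,181.0707,0.02\n,204.0899,0.6\n"
        study = pm.read_feature_table(
            _write(tmp_path, "wb.csv", text), dialect="workbench_features"
        )
        assert len(study.features) == 2

    def test_round_trip_idempotent(self, tmp_path):
        study = pm.read_feature_table(_write(tmp_path, "a.tsv", GENERIC_TSV))
        out = tmp_path / "rewritten.tsv"
        pm.write_feature_table(study, out)
        again = pm.read_feature_table(out, study_id=study.study_id)
        assert len(again.features) == len(study.features)
        for f, g in zip(study.features, again.features):
            assert g.mz == pytest.approx(f.mz, abs=1e-9)
            assert g.p_value == pytest.approx(f.p_value, abs=1e-9)
            assert (g.intensity is None) == (f.intensity is None)


class TestNamedMetabolites:
    def test_names_normalized(self, tmp_path):
        path = _write(tmp_path, "named.tsv", "name\nGlucose\nTaurine\n")
        records = pm.read_named_metabolites(path)
        assert [r.name for r in records] == ["glucose", "taurine"]

    def test_compound_id_kept_verbatim(self, tmp_path):
        path = _write(tmp_path, "named.tsv", "name\tcompound_id\tp_value\nGlucose\tC00031\t0.01\n")
        (record,) = pm.read_named_metabolites(path)
        assert record.compound_id == "C00031"
        assert record.p_value == 0.01

    def test_header_only_file_errors(self, tmp_path):
        path = _write(tmp_path, "named.tsv", "name\n")
        with pytest.raises(DialectError, match="no records"):
            pm.read_named_metabolites(path)


class TestPartition:
    def _study(self, p_values, intensities=None, **params):
        intensities = intensities or [None] * len(p_values)
        features = tuple(
            pm.Feature(mz=100.0 + i, p_value=p, intensity=inten, source_tag="s")
            for i, (p, inten) in enumerate(zip(p_values, intensities))
        )
        return pm.Study(study_id="s", features=features, params=pm.StudyParams(**params))

    def test_counting(self):
        study = self._study([0.001] * 3 + [0.5] * 7)
        sig, ref = partition_significant(study)
        assert (len(sig), len(ref)) == (3, 10)

    def test_p_cutoff_one_keeps_everything_with_p_below_one(self):
        study = self._study([0.0, 0.5, 0.999], **{"p_cutoff": 1.0})
        sig, ref = partition_significant(study)
        assert sig == ref

    def test_intensity_floor_empties_both(self):
        study = self._study([0.01, 0.5], intensities=[10.0, 20.0], intensity_cutoff=100.0)
        sig, ref = partition_significant(study)
        assert sig == [] and ref == []

    def test_missing_intensity_dropped_under_nonzero_cutoff(self):
        study = self._study([0.01, 0.01], intensities=[None, 50.0], intensity_cutoff=10.0)
        sig, ref = partition_significant(study)
        assert len(ref) == 1 and ref[0].intensity == 50.0

    def test_bad_p_cutoff_rejected(self):
        with pytest.raises(ParameterError):
            pm.StudyParams(p_cutoff=0.0)
        with pytest.raises(ParameterError):
            pm.StudyParams(p_cutoff=1.5)

    @given(
        ps=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40),
        cutoff=st.floats(0.01, 1.0),
        intensity_cutoff=st.floats(0.0, 1e6),
    )
    def test_partition_is_nested(self, ps, cutoff, intensity_cutoff):
        study = with_params(
            self._study(ps, intensities=[1e3 * i for i in range(len(ps))]),
            p_cutoff=cutoff,
            intensity_cutoff=intensity_cutoff,
        )
        sig, ref = partition_significant(study)
        assert set(sig) <= set(ref) <= set(study.features)
        assert all(f.p_value < cutoff for f in sig)


def test_feature_invariants_enforced():
    with pytest.raises(ParameterError):
        pm.Feature(mz=-1.0, p_value=0.5, source_tag="s")
    with pytest.raises(ParameterError):
        pm.Feature(mz=100.0, p_value=1.5, source_tag="s")
    with pytest.raises(ParameterError):
        pm.Feature(mz=100.0, p_value=0.5, source_tag="")
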