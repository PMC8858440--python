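"""Cross-study merging, the meta-analysis pipeline, result filtering."""

import dataclasses

import pytest

import pathmeta as pm
from pathmeta.annotate import AnnotationIndex, CompoundMatch
from pathmeta.errors import MetaAnalysisError, ParameterError
from pathmeta.meta import MergedCompound, MetaPathwayResult


def _index(study_id, sig, ref=None):
    """Hand-built annotation index from {compound: p} maps."""
    index = AnnotationIndex(study_id=study_id)
    ref = dict(ref or {})
    ref.update(sig)
    for cid, p in ref.items():
        feature = pm.Feature(mz=100.0, p_value=p, source_tag=f"{study_id}.tsv")
        index.record(
            CompoundMatch(
                feature=feature,
                compound_id=cid,
                adduct_name="M+H",
                inferred_neutral_mass=99.0,
                ppm_error=0.0,
                significant=cid in sig,
            )
        )
        index.reference_feature_compounds.append((feature, frozenset({cid})))
        if cid in sig:
            index.n_significant_features += 1
    return index


class TestMergeStudies:
    A = {"C1": 0.01, "C2": 0.04}
    B = {"C1": 0.003, "C3": 0.02}

    def test_union_takes_best_p(self):
        _, merged = pm.merge_studies([_index("A", self.A), _index("B", self.B)])
        assert {cid: mc.best_p for cid, mc in merged.items()} == {
            "C1": 0.003,
            "C2": 0.04,
            "C3": 0.02,
        }
        assert merged["C1"].n_studies_seen == 2

    def test_shared_mode_intersects(self):
        _, merged = pm.merge_studies(
            [_index("A", self.A), _index("B", self.B)], merge_mode="shared"
        )
        assert set(merged) == {"C1"}
        assert merged["C1"].best_p == 0.003

    def test_single_study_identity(self):
        for mode in ("union", "shared"):
            _, merged = pm.merge_studies([_index("A", self.A)], merge_mode=mode)
            assert {cid: mc.best_p for cid, mc in merged.items()} == self.A

    def test_duplicate_study_id_rejected(self):
        with pytest.raises(ParameterError, match="duplicate"):
            pm.merge_studies([_index("A", self.A), _index("A", self.B)])

    def test_provenance_traces_source_files(self):
        _, merged = pm.merge_studies([_index("A", self.A), _index("B", self.B)])
        assert merged["C1"].source_files == {"A.tsv", "B.tsv"}
        assert merged["C2"].source_files == {"A.tsv"}


class TestMetaAnalyze:
    def test_self_merge_idempotent(self, model, spiked_pair):
        study = spiked_pair[0][0]
        copy = dataclasses.replace(study, study_id=study.study_id + "_copy")
        single = pm.meta_analyze([study], model, config=pm.MetaConfig(permutations=5))
        double = pm.meta_analyze(
            [study, copy], model, config=pm.MetaConfig(permutations=5)
        )
        assert {r.pathway_id: r.p_raw for r in single.pathways} == {
            r.pathway_id: r.p_raw for r in double.pathways
        }

    def test_study_order_invariance(self, model, spiked_pair):
        studies, _ = spiked_pair
        config = pm.MetaConfig(permutations=20, seed=3)
        forward = pm.meta_analyze(studies, model, config=config)
        backward = pm.meta_analyze(list(reversed(studies)), model, config=config)
        assert {r.pathway_id: r.p_raw for r in forward.pathways} == {
            r.pathway_id: r.p_raw for r in backward.pathways
        }
        assert {r.pathway_id: r.shared_count for r in forward.pathways} == {
            r.pathway_id: r.shared_count for r in backward.pathways
        }

    def test_spiked_pathway_ranks_first(self, model, spiked_pair):
        studies, truth = spiked_pair
        analysis = pm.meta_analyze(studies, model, config=pm.MetaConfig(permutations=20))
        assert analysis.pathways[0].pathway_id in truth.enriched_pathway_ids

    def test_counts_are_nested(self, model, spiked_pair):
        studies, _ = spiked_pair
        analysis = pm.meta_analyze(studies, model, config=pm.MetaConfig(permutations=5))
        for r in analysis.pathways:
            assert r.shared_count <= r.merged_hits <= sum(r.per_study_hits.values())
            assert r.merged_hits <= r.matched_in_reference <= r.pathway_size

    def test_shared_count_monotone_in_min_studies(self, model, spiked_pair):
        studies, _ = spiked_pair
        counts = []
        for min_studies in (1, 2):
            analysis = pm.meta_analyze(
                studies,
                model,
                config=pm.MetaConfig(permutations=5, min_studies=min_studies),
            )
            counts.append({r.pathway_id: r.shared_count for r in analysis.pathways})
        assert all(counts[1][pid] <= counts[0][pid] for pid in counts[1])

    def test_disjoint_studies_in_shared_mode_error(self, model):
        # two studies whose significant compounds do not overlap at all
        a = pm.Study(
            study_id="a",
            features=(pm.Feature(mz=181.070664, p_value=0.001, source_tag="a.tsv"),),
        )
        b = pm.Study(
            study_id="b",
            features=(pm.Feature(mz=205.097154, p_value=0.001, source_tag="b.tsv"),),
        )
        with pytest.raises(MetaAnalysisError, match="no shared compounds"):
            pm.meta_analyze(
                [a, b], model, config=pm.MetaConfig(merge_mode="shared", permutations=2)
            )


def _result(pid, shared, merged, compounds=()):
    return MetaPathwayResult(
        pathway_id=pid,
        pathway_name=pid,
        pathway_size=20,
        matched_in_reference=15,
        per_study_hits={"A": merged, "B": merged},
        shared_count=shared,
        merged_hits=merged,
        p_raw=0.01,
        p_adjusted=0.05,
        shared_compounds=list(compounds),
        min_studies_shared=2,
    )


class TestFilterResults:
    def test_min_shared_threshold(self):
        results = [_result(f"P{i}", shared=i, merged=i) for i in range(101)]
        kept = pm.filter_results(results, min_shared=10)
        assert [r.pathway_id for r in kept] == [f"P{i}" for i in range(10, 101)]

    def test_zero_threshold_is_identity(self):
        results = [_result(f"P{i}", shared=i, merged=i) for i in range(5)]
        assert pm.filter_results(results, min_shared=0) == list(results)

    def test_adduct_filter_prunes_provenance(self):
        mc = MergedCompound(
            compound_id="C1",
            per_study_p={"A": 0.01},
            provenance=frozenset({("A", 100.0, "M+Na", "a.tsv")}),
        )
        result = _result("P1", shared=1, merged=1, compounds=[mc])
        (kept,) = pm.filter_results([result], min_shared=0, adduct_filter={"M+H"})
        assert kept.shared_compounds == []
        assert kept.merged_hits == 0
        assert kept.p_raw == result.p_raw  # p-values never recomputed

    def test_study_filter_recomputes_counts(self):
        mc = MergedCompound(
            compound_id="C1",
            per_study_p={"A": 0.01, "B": 0.02},
            provenance=frozenset(
                {("A", 100.0, "M+H", "a.tsv"), ("B", 100.0, "M+H", "b.tsv")}
            ),
        )
        result = _result("P1", shared=1, merged=1, compounds=[mc])
        (kept,) = pm.filter_results([result], min_shared=0, study_filter={"A"})
        assert kept.merged_hits == 1
        assert kept.shared_count == 0  # no longer seen in 2 studies
        (km,) = kept.shared_compounds
        assert set(km.per_study_p) == {"A"}
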