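import numpy as np
import pytest

from liqtrace.core_data import Phase, SampleRecord, Tissue, validate_study
from liqtrace.filtering import (
    FilterConfig,
    compute_fold_changes,
    filter1_expressed,
    filter2_downregulated,
    filter3_recurrence,
    run_triple_filter,
)
from liqtrace.normalization import compute_size_factors, normalize
from liqtrace.simulate import SimConfig, simulate_study

from .conftest import make_matrix


def trajectories_for(study, patient_id="p1"):
    sub = study.patient_matrix(patient_id)
    sf = compute_size_factors(sub)
    norm = normalize(sub, sf)
    return norm, compute_fold_changes(norm, study.samples_for(patient_id), patient_id)


def by_id(trajs):
    return {t.feature_id: t for t in trajs}


class TestFoldChanges:
    def test_worked_example_fold_changes(self, worked_study):
        _, trajs = trajectories_for(worked_study)
        t = by_id(trajs)["mrna_like"]
        assert t.baseline == pytest.approx(100.0)
        assert t.fc["post_early"] == pytest.approx(0.6)
        assert t.fc["post_late"] == pytest.approx(0.09)
        assert t.fc["rec"] == pytest.approx(3.0)
        m = by_id(trajs)["mirna_like"]
        assert m.fc["post_early"] == pytest.approx(0.4)
        assert m.fc["post_late"] == pytest.approx(0.1)
        assert m.fc["rec"] == pytest.approx(2.9)

    def test_constant_feature_has_unit_fold_changes(self, worked_study):
        _, trajs = trajectories_for(worked_study)
        t = by_id(trajs)["bg0"]
        assert all(v == pytest.approx(1.0) for v in t.fc.values())

    def test_tumor_column_excluded_from_trajectories(self, worked_study):
        _, trajs = trajectories_for(worked_study)
        assert "tumor" not in by_id(trajs)["mrna_like"].fc

    def test_zero_baseline_flagged_undefined(self):
        samples = [
            SampleRecord("pre", "p1", Tissue.BLOOD, Phase.PRE_SURGERY, -1),
            SampleRecord("post", "p1", Tissue.BLOOD, Phase.POST_SURGERY, 5),
        ]
        m = make_matrix([[0, 7], [5, 5]], feature_ids=["dead", "ok"], sample_ids=["pre", "post"])
        norm = m.values.astype(float)
        trajs = compute_fold_changes(norm, samples, "p1")
        t = by_id(trajs)["dead"]
        assert not t.defined and t.fc == {}

    def test_missing_pre_surgery_sample_rejected(self):
        samples = [SampleRecord("post", "p1", Tissue.BLOOD, Phase.POST_SURGERY, 5)]
        m = make_matrix([[7]], feature_ids=["f"], sample_ids=["post"])
        with pytest.raises(ValueError, match="pre-surgery"):
            compute_fold_changes(m.values.astype(float), samples, "p1")


class TestFilter1:
    def setup_method(self):
        self.samples = [
            SampleRecord("pre", "p1", Tissue.BLOOD, Phase.PRE_SURGERY, -1),
            SampleRecord("post", "p1", Tissue.BLOOD, Phase.POST_SURGERY, 5),
            SampleRecord("tum", "p1", Tissue.TUMOR, Phase.PRE_SURGERY, 0),
        ]

    def test_expressed_in_blood_and_tumor(self):
        m = make_matrix([[12, 1, 15]], feature_ids=["f"], sample_ids=["pre", "post", "tum"])
        got = filter1_expressed(m.values.astype(float), self.samples, FilterConfig(), "p1")
        assert got == {"f"}

    def test_low_tumor_expression_excluded_under_auto(self):
        m = make_matrix([[12, 1, 3]], feature_ids=["f"], sample_ids=["pre", "post", "tum"])
        cfg = FilterConfig()
        assert filter1_expressed(m.values.astype(float), self.samples, cfg, "p1") == frozenset()
        blood_only = FilterConfig(tumor_requirement="blood_only")
        assert filter1_expressed(m.values.astype(float), self.samples, blood_only, "p1") == {"f"}

    def test_without_tumor_sample_auto_equals_blood_only(self):
        sim = simulate_study(
            SimConfig(n_features=100, n_signal=10, n_surgery_response=10, seed=2)
        )
        study = sim.study
        pid = "P5"  # no tumor sample in this design
        sub = study.patient_matrix(pid)
        norm = normalize(sub, compute_size_factors(sub))
        recs = study.samples_for(pid)
        auto = filter1_expressed(norm, recs, FilterConfig(), pid)
        blood = filter1_expressed(norm, recs, FilterConfig(tumor_requirement="blood_only"), pid)
        assert auto == blood


class TestFilter2:
    def _study(self, post_values):
        samples = [
            SampleRecord("pre", "p1", Tissue.BLOOD, Phase.PRE_SURGERY, -1),
        ] + [
            SampleRecord(f"post{i}", "p1", Tissue.BLOOD, Phase.POST_SURGERY, 5 + i)
            for i in range(len(post_values))
        ]
        row = [100] + [int(round(100 * v)) for v in post_values]
        m = make_matrix([row], feature_ids=["f"], sample_ids=[s.sample_id for s in samples])
        trajs = compute_fold_changes(m.values.astype(float), samples, "p1")
        return trajs, samples

    def test_half_of_samples_down_is_enough(self):
        # fc (0.6, 0.09): exactly half the post-surgery samples 2-fold down
        trajs, samples = self._study([0.6, 0.09])
        assert filter2_downregulated(trajs, samples, FilterConfig()) == {"f"}

    def test_no_sample_down_fails(self):
        trajs, samples = self._study([0.6, 0.6])
        assert filter2_downregulated(trajs, samples, FilterConfig()) == frozenset()

    def test_fc_boundary_is_inclusive(self):
        trajs, samples = self._study([0.5])
        assert filter2_downregulated(trajs, samples, FilterConfig()) == {"f"}

    def test_strict_majority_reading_available(self):
        trajs, samples = self._study([0.6, 0.09])
        strict = FilterConfig(frac_down=0.51)
        assert filter2_downregulated(trajs, samples, strict) == frozenset()

    def test_recurrence_samples_not_counted(self):
        samples = [
            SampleRecord("pre", "p1", Tissue.BLOOD, Phase.PRE_SURGERY, -1),
            SampleRecord("post0", "p1", Tissue.BLOOD, Phase.POST_SURGERY, 5),
            SampleRecord("rec", "p1", Tissue.BLOOD, Phase.RECURRENCE, 90, day_rel_recurrence=0),
        ]
        m = make_matrix([[100, 80, 10]], feature_ids=["f"],
                        sample_ids=["pre", "post0", "rec"])
        trajs = compute_fold_changes(m.values.astype(float), samples, "p1")
        # the deeply-down recurrence sample must not rescue filter 2
        assert filter2_downregulated(trajs, samples, FilterConfig()) == frozenset()


class TestFilter3:
    def _study(self, rec_values):
        samples = [
            SampleRecord("pre", "p1", Tissue.BLOOD, Phase.PRE_SURGERY, -1),
        ] + [
            SampleRecord(f"rec{i}", "p1", Tissue.BLOOD, Phase.RECURRENCE, 90 + i,
                         day_rel_recurrence=i)
            for i in range(len(rec_values))
        ]
        row = [1000] + [int(round(1000 * v)) for v in rec_values]
        m = make_matrix([row], feature_ids=["f"], sample_ids=[s.sample_id for s in samples])
        trajs = compute_fold_changes(m.values.astype(float), samples, "p1")
        return trajs, samples

    @pytest.mark.parametrize("fc,passes", [(3.0, True), (0.99, False), (1.0, True)])
    def test_rebound_boundary(self, fc, passes):
        trajs, samples = self._study([fc])
        got = filter3_recurrence(trajs, samples, FilterConfig())
        assert (got == {"f"}) is passes

    def test_rule_semantics_with_two_recurrence_samples(self):
        trajs, samples = self._study([0.4, 1.2])
        assert filter3_recurrence(trajs, samples, FilterConfig(recur_rule="any")) == {"f"}
        assert filter3_recurrence(trajs, samples, FilterConfig(recur_rule="all")) == frozenset()
        assert filter3_recurrence(trajs, samples, FilterConfig(recur_rule="majority")) == frozenset()


class TestTripleFilter:
    def test_worked_example_features_are_candidates(self, worked_study):
        results = run_triple_filter(worked_study)
        cs = results["p1"]
        assert {"mrna_like", "mirna_like"} <= set(cs.candidates)
        assert not any(f.startswith("bg") for f in cs.candidates)

    def test_impossible_expression_threshold_empties_cascade(self, worked_study):
        cfg = FilterConfig(min_norm_count=1e12)
        cs = run_triple_filter(worked_study, cfg)["p1"]
        assert cs.cascade_counts[1:] == (0, 0, 0)

    def test_cascade_counts_non_increasing(self):
        sim = simulate_study(
            SimConfig(n_features=300, n_signal=20, n_surgery_response=20, seed=9)
        )
        for cs in run_triple_filter(sim.study).values():
            u, f1, f2, f3 = cs.cascade_counts
            assert u >= f1 >= f2 >= f3

    def test_threshold_monotonicity(self):
        sim = simulate_study(
            SimConfig(n_features=300, n_signal=20, n_surgery_response=20, seed=4)
        )
        base = run_triple_filter(sim.study)
        stricter = [
            FilterConfig(min_norm_count=20),
            FilterConfig(frac_down=0.8),
            FilterConfig(fc_down=0.3),
            FilterConfig(fc_recur=1.5),
        ]
        for cfg in stricter:
            tight = run_triple_filter(sim.study, cfg)
            for pid in base:
                assert tight[pid].candidates <= base[pid].candidates

    def test_sample_order_invariance(self):
        sim = simulate_study(
            SimConfig(n_features=200, n_signal=15, n_surgery_response=15, seed=6)
        )
        study = sim.study
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(study.matrix.sample_ids))
        shuffled = validate_study(
            study.matrix.subset_samples([study.matrix.sample_ids[i] for i in perm]),
            study.samples,
        )
        a = run_triple_filter(study)
        b = run_triple_filter(shuffled)
        for pid in a:
            assert a[pid].candidates == b[pid].candidates
            assert a[pid].cascade_counts == b[pid].cascade_counts

    def test_patient_without_recurrence_yields_no_candidates(self):
        samples = [
            SampleRecord("pre", "p1", Tissue.BLOOD, Phase.PRE_SURGERY, -1),
            SampleRecord("post", "p1", Tissue.BLOOD, Phase.POST_SURGERY, 30),
        ]
        m = make_matrix(
            [[100, 5], [50, 50], [80, 30]], sample_ids=["pre", "post"]
        )
        study = validate_study(m, samples)
        cs = run_triple_filter(study)["p1"]
        assert not cs.has_recurrence_sample
        assert cs.pass_f3 == frozenset()
        assert len(cs.pass_f2) > 0  # earlier filters still reported

    def test_cohort_scope_normalization(self):
        sim = simulate_study(
            SimConfig(n_features=200, n_signal=15, n_surgery_response=15, seed=13)
        )
        per_patient = run_triple_filter(sim.study, scope="per_patient")
        cohort = run_triple_filter(sim.study, scope="cohort")
        assert set(cohort) == set(per_patient)
        for cs in cohort.values():
            u, f1, f2, f3 = cs.cascade_counts
            assert u >= f1 >= f2 >= f3

    def test_one_failing_patient_does_not_abort_others(self, worked_study):
        # a second patient whose every feature is zero cannot be normalized
        samples = list(worked_study.samples) + [
            SampleRecord("z_pre", "p2", Tissue.BLOOD, Phase.PRE_SURGERY, -1),
            SampleRecord("z_post", "p2", Tissue.BLOOD, Phase.POST_SURGERY, 5),
        ]
        values = worked_study.matrix.values.copy()
        values["z_pre"] = 0
        values["z_post"] = 0
        study = validate_study(make_matrix(values.to_numpy(),
                                           feature_ids=list(values.index),
                                           sample_ids=list(values.columns)),
                               samples)
        results = run_triple_filter(study)
        assert "p1" in results and "p2" not in results
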