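import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nilmon as nm
from nilmon.io_formats import ConfigurationError
from nilmon.monitor import ObservationStore

from conftest import make_activation

LN2 = math.log(2.0)


def point_curve(bin_idx, date=dt.date(2014, 1, 1), bins=24, activity="cooking"):
    b = np.zeros(bins)
    b[bin_idx] = 1.0
    return nm.ActivityCurve(date, activity, b, total_duration=600.0)


def store_of(curves, feedback=None, activity="cooking"):
    st_ = ObservationStore()
    feedback = feedback or [False] * len(curves)
    for i, (c, f) in enumerate(zip(curves, feedback)):
        st_.add_day(dt.date(2014, 1, 1) + dt.timedelta(days=i), {activity: c}, [], feedback=f)
    return st_


def brute_force_jsd(curve_list, weights):
    """Independent bin-by-bin implementation of the weighted divergence."""
    n_bins = len(curve_list[0])
    m = [sum(w * p[x] for w, p in zip(weights, curve_list)) for x in range(n_bins)]
    total = 0.0
    for w, p in zip(weights, curve_list):
        if w == 0:
            continue
        d = sum(p[x] * math.log(p[x] / m[x]) for x in range(n_bins) if p[x] > 0)
        total += w * d
    return total


class TestBuildActivityCurve:
    MAP = {"cooking": frozenset({"kettle"})}
    DATE = dt.date(2014, 1, 6)

    def test_hour_aligned_activation(self):
        act = make_activation(7.0, duration=3600.0, date=self.DATE)
        curve = nm.build_activity_curve([act], self.MAP, "cooking", self.DATE)
        assert curve.bins[7] == 1.0 and curve.bins.sum() == 1.0
        assert curve.total_duration == 3600.0

    def test_two_bins_symmetric(self):
        acts = [
            make_activation(7.0, duration=1800.0, date=self.DATE),
            make_activation(19.0, duration=1800.0, date=self.DATE),
        ]
        curve = nm.build_activity_curve(acts, self.MAP, "cooking", self.DATE)
        assert curve.bins[7] == 0.5 and curve.bins[19] == 0.5

    def test_boundary_straddling_split(self):
        act = make_activation(7.5, duration=3600.0, date=self.DATE)  # 07:30-08:30
        curve = nm.build_activity_curve([act], self.MAP, "cooking", self.DATE)
        assert curve.bins[7] == pytest.approx(0.5) and curve.bins[8] == pytest.approx(0.5)

    def test_empty_day(self):
        curve = nm.build_activity_curve([], self.MAP, "cooking", self.DATE)
        assert curve.empty and curve.total_duration == 0.0

    def test_unknown_activity(self):
        with pytest.raises(ConfigurationError):
            nm.build_activity_curve([], self.MAP, "gardening", self.DATE)

    def test_unmapped_appliance_ignored(self):
        act = make_activation(7.0, appliance="tv", date=self.DATE)
        curve = nm.build_activity_curve([act], self.MAP, "cooking", self.DATE)
        assert curve.empty


class TestSummarizeProfile:
    def test_single_curve_identity(self):
        c = point_curve(7)
        np.testing.assert_allclose(nm.summarize_profile(store_of([c]), "cooking").bins, c.bins)

    def test_mean_of_point_masses(self):
        prof = nm.summarize_profile(store_of([point_curve(7), point_curve(9)]), "cooking")
        assert prof.bins[7] == 0.5 and prof.bins[9] == 0.5

    def test_idempotent_on_identical(self):
        prof = nm.summarize_profile(store_of([point_curve(7)] * 3), "cooking")
        assert prof.bins[7] == 1.0

    def test_no_observations(self):
        with pytest.raises(ValueError, match="no observations"):
            nm.summarize_profile(store_of([]), "cooking")


class TestComputeWeights:
    def test_all_plain(self):
        w = nm.compute_weights(store_of([point_curve(7)] * 5), beta=2.0)
        np.testing.assert_allclose(w.pi, 0.2)

    def test_mixed_feedback(self):
        w = nm.compute_weights(
            store_of([point_curve(7)] * 3, feedback=[True, False, False]), beta=2.0
        )
        np.testing.assert_allclose(w.pi, [0.2, 0.4, 0.4])

    def test_all_feedback_uniform(self):
        w = nm.compute_weights(store_of([point_curve(7)] * 4, feedback=[True] * 4), beta=3.0)
        np.testing.assert_allclose(w.pi, 0.25)

    def test_beta_below_two_rejected(self):
        with pytest.raises(ConfigurationError):
            nm.compute_weights(store_of([point_curve(7)]), beta=1.0)

    @settings(deadline=None, max_examples=200)
    @given(st.integers(0, 50), st.integers(0, 50), st.sampled_from([2.0, 3.0, 5.0]))
    def test_normalisation_property(self, n1, n2, beta):
        if n1 + n2 == 0:
            return
        flags = [True] * n1 + [False] * n2
        w = nm.compute_weights(store_of([point_curve(7)] * (n1 + n2), feedback=flags), beta)
        assert w.pi.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(w.pi > 0)


class TestGeneralizedJsd:
    def test_identical_curves_zero(self):
        assert nm.generalized_jsd([point_curve(7), point_curve(7)], [0.3, 0.7]) == 0.0

    def test_disjoint_equal_weight_ln2(self):
        v = nm.generalized_jsd([point_curve(2), point_curve(10)], [0.5, 0.5])
        assert v == pytest.approx(LN2, abs=1e-12)

    def test_degenerate_weight_zero(self):
        assert nm.generalized_jsd([point_curve(2), point_curve(10)], [1.0, 0.0]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            nm.generalized_jsd([point_curve(2)], [0.5, 0.5])

    @settings(deadline=None, max_examples=100)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 5))
    def test_matches_brute_force(self, seed, n):
        rng = np.random.default_rng(seed)
        curves = rng.dirichlet(np.ones(24) * 0.3, size=n)
        w = rng.dirichlet(np.ones(n))
        got = nm.generalized_jsd(list(curves), list(w / w.sum()))
        assert got == pytest.approx(brute_force_jsd(curves, w / w.sum()), abs=1e-12)
        assert got >= 0

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_permutation_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        curves = rng.dirichlet(np.ones(24), size=3)
        w = rng.dirichlet(np.ones(3))
        perm = rng.permutation(3)
        a = nm.generalized_jsd(list(curves), list(w))
        b = nm.generalized_jsd(list(curves[perm]), list(w[perm]))
        assert a == pytest.approx(b, abs=1e-12)


class TestDayScore:
    def test_identical_to_single_day_store(self):
        s = nm.day_score(point_curve(7), store_of([point_curve(7)]))
        assert s.jsd == 0.0 and not s.empty_day

    def test_disjoint_support_ln2(self):
        night = point_curve(2, date=dt.date(2014, 3, 1))
        s = nm.day_score(night, store_of([point_curve(7), point_curve(8)]))
        assert s.jsd == pytest.approx(LN2, abs=1e-12)

    def test_empty_day_short_circuits(self):
        empty = nm.ActivityCurve(dt.date(2014, 3, 1), "cooking", np.zeros(24), 0.0, empty=True)
        assert nm.day_score(empty, store_of([point_curve(7)])).empty_day

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_bounded_by_ln2(self, seed):
        rng = np.random.default_rng(seed)
        curves = [
            nm.ActivityCurve(dt.date(2014, 1, 1), "cooking", b, 600.0)
            for b in rng.dirichlet(np.ones(24) * 0.2, size=6)
        ]
        s = nm.day_score(curves[0], store_of(curves[1:]))
        assert s.jsd <= LN2 + 1e-12


class TestIqrInterval:
    def test_hand_computed_quartiles(self):
        iv = nm.iqr_interval([1, 2, 3, 4, 5])
        assert (iv.q1, iv.q3) == (2.0, 4.0)
        assert (iv.lower, iv.upper) == (-1.0, 7.0)

    def test_constant_scores(self):
        iv = nm.iqr_interval([3.0] * 6)
        assert iv.lower == iv.upper == 3.0

    def test_too_few_scores(self):
        with pytest.raises(ValueError, match="insufficient"):
            nm.iqr_interval([1, 2, 3])

    def test_normal_coverage(self):
        rng = np.random.default_rng(123)
        x = rng.normal(size=10_000)
        iv = nm.iqr_interval(x)
        cover = ((x >= iv.lower) & (x <= iv.upper)).mean()
        assert 0.985 <= cover <= 0.998


class TestClassifyDay:
    CFG = nm.PipelineConfig()

    def test_identical_store_and_day_normal(self):
        store = store_of([point_curve(7)] * 6)
        decision, score, interval = nm.classify_day(point_curve(7), store, self.CFG)
        assert decision == "normal" and score.jsd == 0.0
        assert interval.lower == interval.upper == 0.0

    def test_night_only_day_flagged(self):
        rng = np.random.default_rng(4)
        days = []
        for b in rng.dirichlet(np.ones(4), size=10):
            bins = np.zeros(24)
            bins[7:11] = b
            days.append(nm.ActivityCurve(dt.date(2014, 1, 1), "cooking", bins, 600.0))
        decision, score, interval = nm.classify_day(point_curve(2), store_of(days), self.CFG)
        assert decision == "anomalous"
        assert score.jsd == pytest.approx(LN2, abs=1e-9)
        assert score.jsd > interval.upper

    def test_empty_day_always_anomalous(self):
        store = store_of([point_curve(7)] * 6)
        empty = nm.ActivityCurve(dt.date(2014, 3, 1), "cooking", np.zeros(24), 0.0, empty=True)
        decision, score, _ = nm.classify_day(empty, store, self.CFG)
        assert decision == "anomalous" and score.empty_day


class TestSimilarityMatrix:
    def test_identical_pair(self):
        acts = [make_activation(7.0), make_activation(7.0)]
        np.testing.assert_array_equal(nm.build_similarity_matrix(acts), np.zeros((2, 2)))

    def test_circular_hour_distance(self):
        m = nm.build_similarity_matrix([make_activation(1.0), make_activation(23.0)])
        assert m[0, 1] == pytest.approx(2.0)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        acts = [make_activation(h, duration=d) for h, d in
                zip(rng.uniform(0, 24, 8), rng.uniform(60, 600, 8))]
        m = nm.build_similarity_matrix(acts)
        np.testing.assert_allclose(m, m.T)
        np.testing.assert_array_equal(np.diag(m), 0.0)

    def test_needs_two(self):
        with pytest.raises(ValueError):
            nm.build_similarity_matrix([make_activation(7.0)])


class TestClassifyActivation:
    @staticmethod
    def _store_with(acts):
        st_ = ObservationStore()
        st_.add_day(dt.date(2014, 1, 1), {}, acts)
        return st_

    def test_identical_to_history_is_variation(self):
        rng = np.random.default_rng(1)
        hist = [make_activation(7 + rng.normal(0, 0.2)) for _ in range(20)]
        store = self._store_with(hist)
        assert nm.classify_activation(hist[0], store) == "variation"

    def test_far_from_tight_cluster_is_deviation(self):
        rng = np.random.default_rng(1)
        hist = [make_activation(7 + rng.normal(0, 0.2)) for _ in range(20)]
        store = self._store_with(hist)
        assert nm.classify_activation(make_activation(17.0), store) == "deviation"

    def test_inside_one_of_two_clusters_is_variation(self):
        rng = np.random.default_rng(1)
        hist = [make_activation(7 + rng.normal(0, 0.2)) for _ in range(10)]
        hist += [make_activation(19 + rng.normal(0, 0.2)) for _ in range(10)]
        store = self._store_with(hist)
        assert nm.classify_activation(make_activation(19.1), store) == "variation"

    def test_no_history(self):
        with pytest.raises(ValueError, match="no history"):
            nm.classify_activation(make_activation(7.0), self._store_with([]))


class TestClassifyAnomalyType:
    DATE = dt.date(2014, 2, 1)

    def test_no_activations_absence(self):
        assert nm.classify_anomaly_type(self.DATE, [], "anomalous") == "absence"

    def test_night_start_wins(self):
        acts = [make_activation(2.5), make_activation(15.0)]
        assert nm.classify_anomaly_type(self.DATE, acts, "anomalous") == "night_usage"

    def test_daytime_fallthrough(self):
        acts = [make_activation(15.0)]
        assert nm.classify_anomaly_type(self.DATE, acts, "anomalous") == "abnormal_usage_time"

    def test_normal_day_rejected(self):
        with pytest.raises(ValueError):
            nm.classify_anomaly_type(self.DATE, [], "normal")
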