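"""VIP scoring, interval extraction and restricted refitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pyrocal import (
    GridSpec,
    IntervalSet,
    NipalsPLS,
    SplitSpec,
    VIPIntervalSelector,
    VIPProfile,
    extract_intervals,
    interval_jaccard,
    refit_and_compare,
    restrict_to_intervals,
    split_dataset,
    vip_scores,
)
from pyrocal.experiments import (
    TARGET_WINDOWS,
    interval_recovery_trial,
    single_target_experiment,
)


class TestVIPScores:
    def test_single_predictor_scores_exactly_one(self, rng):
        X = rng.normal(0, 1, (12, 1))
        y = 2 * X[:, 0] + rng.normal(0, 0.1, 12)
        prof = vip_scores(NipalsPLS(1).fit(X, y), np.array([105.0]))
        assert prof.vip.tolist() == [1.0]

    def test_normalization_identity(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 40))
            p = int(rng.integers(2, 60))
            A = int(rng.integers(1, min(n - 1, p) + 1))
            X = rng.normal(0, 1, (n, p))
            y = rng.normal(0, 1, n)
            m = NipalsPLS(A).fit(X, y)
            prof = vip_scores(m, np.arange(p, dtype=float))
            assert np.mean(prof.vip**2) == pytest.approx(1.0, abs=1e-6)

    def test_single_relevant_variable_concentrates_score(self):
        # one latent variable, orthonormal X, y tied to variable 3
        p = 6
        X = np.vstack([np.eye(p), -np.eye(p)])
        y = X[:, 3]
        m = NipalsPLS(1).fit(X, y)
        prof = vip_scores(m, np.arange(p, dtype=float))
        assert prof.vip[3] == pytest.approx(np.sqrt(p), rel=1e-6)
        others = np.delete(prof.vip, 3)
        assert np.all(others < 1e-8)

    def test_length_mismatch_rejected(self, rng):
        X = rng.normal(0, 1, (10, 4))
        m = NipalsPLS(2).fit(X, rng.normal(0, 1, 10))
        with pytest.raises(ValueError):
            vip_scores(m, np.arange(3, dtype=float))


class TestExtractIntervals:
    def test_pointwise_thresholding_example(self):
        prof = VIPProfile(
            temperatures=np.array([105.0, 105.1, 105.2, 105.3, 105.4]),
            vip=np.array([0.5, 1.2, 1.3, 0.8, 1.1]),
        )
        got = extract_intervals(prof, threshold=1.0, min_run=0.0, merge_gap=0.0)
        assert list(got) == [(105.1, 105.2), (105.4, 105.4)]

    def test_all_below_threshold_empty(self):
        prof = VIPProfile(np.arange(105.0, 110.0), np.full(5, 0.5))
        assert len(extract_intervals(prof)) == 0

    def test_gap_merging_and_min_run_filtering(self):
        temps = np.arange(105.0, 145.0, 1.0)
        vip = np.zeros(40)
        vip[0:10] = 2.0   # 105-114
        vip[13:23] = 2.0  # 118-127: gap of 3 °C → merged at merge_gap=5
        vip[30] = 2.0     # single point run → dropped by min_run=2
        got = extract_intervals(
            VIPProfile(temps, vip), threshold=1.0, min_run=2.0, merge_gap=5.0
        )
        assert list(got) == [(105.0, 127.0)]

    def test_compact_string_matches_report_style(self):
        # intervals exceeding 1 on three known ranges format as 'lo-hi,...'
        g = GridSpec(105, 900, 1.0)
        temps = g.temperatures()
        vip = np.full(g.count, 0.5)
        for lo, hi in ((150, 390), (510, 520), (688, 701)):
            vip[(temps >= lo) & (temps <= hi)] = 1.5
        got = extract_intervals(VIPProfile(temps, vip))
        assert got.compact() == "150-390,510-520,688-701"

    @given(st.integers(0, 5000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_raising_threshold_never_enlarges_union(self, seed):
        r = np.random.default_rng(seed)
        temps = np.arange(105.0, 205.0, 1.0)
        vip = np.abs(r.normal(1.0, 0.5, len(temps)))
        lo = extract_intervals(VIPProfile(temps, vip), 0.8, 0.0, 0.0)
        hi = extract_intervals(VIPProfile(temps, vip), 1.2, 0.0, 0.0)

        def covered(ivs):
            mask = np.zeros(len(temps), dtype=bool)
            for a, b in ivs:
                mask |= (temps >= a) & (temps <= b)
            return mask

        assert not np.any(covered(hi) & ~covered(lo))

    def test_parameters_validated(self):
        prof = VIPProfile(np.arange(105.0, 110.0), np.ones(5))
        with pytest.raises(ValueError):
            extract_intervals(prof, threshold=0.0)
        with pytest.raises(ValueError):
            extract_intervals(prof, min_run=-1.0)


class TestIntervalSet:
    def test_sorted_and_disjoint_enforced(self):
        s = IntervalSet(intervals=[(300.0, 400.0), (105.0, 200.0)])
        assert list(s) == [(105.0, 200.0), (300.0, 400.0)]
        with pytest.raises(ValueError):
            IntervalSet(intervals=[(105.0, 200.0), (150.0, 250.0)])
        with pytest.raises(ValueError):
            IntervalSet(intervals=[(200.0, 100.0)])

    def test_json_roundtrip(self):
        s = IntervalSet(intervals=[(105.0, 200.0), (300.0, 310.5)])
        assert IntervalSet.from_json(s.to_json()).intervals == s.intervals


class TestRestrict:
    def test_full_cover_is_identity(self, rng):
        temps = np.arange(105.0, 125.0, 1.0)
        X = rng.normal(0, 1, (5, len(temps)))
        Xr, kept = restrict_to_intervals(X, temps, IntervalSet(intervals=[(100.0, 130.0)]))
        assert np.array_equal(Xr, X)
        assert np.array_equal(kept, temps)

    def test_fine_grid_column_count(self, rng):
        g = GridSpec(105.0, 106.0, 0.1)
        temps = g.temperatures()
        X = rng.normal(0, 1, (3, g.count))
        Xr, _ = restrict_to_intervals(X, temps, IntervalSet(intervals=[(105.0, 105.2)]))
        assert Xr.shape[1] == 3

    def test_disjoint_intervals_additive(self, rng):
        temps = np.arange(105.0, 205.0, 1.0)
        X = rng.normal(0, 1, (4, len(temps)))
        a = IntervalSet(intervals=[(110.0, 119.0)])
        b = IntervalSet(intervals=[(150.0, 154.0)])
        both = IntervalSet(intervals=[(110.0, 119.0), (150.0, 154.0)])
        na = restrict_to_intervals(X, temps, a)[0].shape[1]
        nb = restrict_to_intervals(X, temps, b)[0].shape[1]
        nboth = restrict_to_intervals(X, temps, both)[0].shape[1]
        assert nboth == na + nb

    def test_empty_set_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            restrict_to_intervals(np.ones((2, 3)), np.arange(3.0), IntervalSet())


class TestJaccard:
    def test_basic_cases(self):
        assert interval_jaccard([(0, 10)], [(0, 10)]) == 1.0
        assert interval_jaccard([(0, 10)], [(20, 30)]) == 0.0
        assert interval_jaccard([(0, 10)], [(5, 15)]) == pytest.approx(5 / 15)
        assert interval_jaccard([], []) == 1.0

    def test_overlapping_inputs_unioned_first(self):
        assert interval_jaccard([(0, 6), (4, 10)], [(0, 10)]) == 1.0


class TestRefit:
    def test_full_grid_intervals_change_nothing(self, small_study):
        study = small_study
        X = study["X"][:, ::4]
        temps = study["temps"][::4]
        y = study["measured"].values_for("Reducing sugar")
        split = split_dataset(len(y), SplitSpec(seed=3))
        full_cover = IntervalSet(intervals=[(float(temps[0]), float(temps[-1]))])
        cmp = refit_and_compare(
            X, y, temps, full_cover, split, max_components=8, cv_folds=4, seed=3
        )
        assert cmp.delta_r2_train == pytest.approx(0.0, abs=1e-12)
        assert cmp.delta_r2_test == pytest.approx(0.0, abs=1e-12)

    def test_excluding_signal_windows_collapses_performance(self):
        # negative control: restrict to a signal-free high-temperature band
        X, temps, y, spec, target = single_target_experiment(0)
        split = split_dataset(len(y), SplitSpec(seed=0))
        dead_zone = IntervalSet(intervals=[(600.0, 700.0)])
        cmp = refit_and_compare(
            X, y, temps, dead_zone, split, max_components=5, cv_folds=4, seed=0
        )
        assert cmp.r2_test_restricted < 0.3
        assert cmp.r2_test_full > 0.8

    def test_vip_intervals_preserve_performance(self):
        j, found = interval_recovery_trial(1)
        assert j >= 0.5
        X, temps, y, spec, target = single_target_experiment(1)
        split = split_dataset(len(y), SplitSpec(seed=1))
        cmp = refit_and_compare(
            X, y, temps, found, split, max_components=10, cv_folds=5, seed=1
        )
        assert cmp.delta_r2_test <= 0.05


class TestSelectorEstimator:
    def test_fit_transform_and_support(self):
        X, temps, y, spec, target = single_target_experiment(4)
        sel = VIPIntervalSelector(
            temperatures=temps, n_components=3, threshold=1.0
        ).fit(X, y)
        Xt = sel.transform(X)
        assert Xt.shape == (X.shape[0], sel.support_.sum())
        assert len(sel.intervals_) >= 1
        # selected columns overlap the true windows
        truth = IntervalSet(intervals=list(TARGET_WINDOWS))
        assert interval_jaccard(sel.intervals_, truth) >= 0.5

    def test_sklearn_params_protocol(self):
        sel = VIPIntervalSelector(threshold=1.3, min_run=4.0)
        params = sel.get_params()
        assert params["threshold"] == 1.3
        clone = VIPIntervalSelector(**params)
        assert clone.get_params() == params
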