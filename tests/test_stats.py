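"""Ethograms, cumulative/transition probabilities and the statistical
tests, each checked against an independent brute-force oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ethome import stats as st
from ethome.classify import ActionInterval
from ethome.io import Track, TrackSet


def _iv(larva, start, end, label):
    coarse = {
        "Crawl": "Crawl",
        "HeadCast": "Bend",
        "StaticBend": "Bend",
        "CShape": "Bend",
        "Hunch": "Hunch",
        "HeadAndTail": "Hunch",
        "Roll": "Roll",
        "BackUp": "Back",
        "Stop": "Stop",
    }[label]
    return ActionInterval(larva, start, end, coarse, refined_label=label)


def _track(larva_id, n=100, t0=0.0, valid_mask=None, dt=0.1):
    K = 5
    base = np.stack([np.linspace(0, 4, K), np.zeros(K)], axis=1)
    pts = np.stack([base] * n)
    valid = np.ones(n, dtype=bool) if valid_mask is None else np.asarray(valid_mask)
    pts = np.where(valid[:, None, None], pts, np.nan)
    return Track(larva_id=larva_id, t=t0 + np.arange(n) * dt, points=pts, valid=valid)


class TestEthogram:
    def test_single_action_fills_bins(self):
        ts = TrackSet(tracks=[_track("a", n=60)])
        etho = st.build_ethogram([_iv("a", 0.0, 5.0, "Hunch")], ts, bin_s=1.0)
        labels = etho.table.loc["a"].tolist()
        assert labels[:5] == ["Hunch"] * 5

    def test_tracking_gap_marks_untracked(self):
        mask = np.ones(60, dtype=bool)
        mask[20:30] = False  # 2–3 s
        ts = TrackSet(tracks=[_track("a", n=60, valid_mask=mask)])
        etho = st.build_ethogram([_iv("a", 0.0, 6.0, "Crawl")], ts, bin_s=1.0)
        labels = etho.table.loc["a"].tolist()
        assert labels[2] == st.UNTRACKED
        assert labels[0] == "Crawl"

    def test_straddling_bin_takes_midpoint_label(self):
        ts = TrackSet(tracks=[_track("a", n=60)])
        ivs = [_iv("a", 0.0, 1.4, "Crawl"), _iv("a", 1.4, 5.0, "Hunch")]
        etho = st.build_ethogram(ivs, ts, bin_s=1.0)
        # bin [1, 2) has midpoint 1.5, inside the Hunch interval
        assert etho.table.loc["a"].tolist()[1] == "Hunch"

    def test_overlapping_intervals_rejected(self):
        ts = TrackSet(tracks=[_track("a")])
        with pytest.raises(ValueError, match="overlapping"):
            st.build_ethogram(
                [_iv("a", 0.0, 2.0, "Crawl"), _iv("a", 1.0, 3.0, "Hunch")], ts
            )


class TestCumulativeProbability:
    def _ts(self, n_larvae=10, untracked=()):
        tracks = []
        for i in range(n_larvae):
            larva = f"l{i}"
            if larva in untracked:
                mask = np.zeros(100, dtype=bool)
                mask[60:] = True  # picked up only after t=6
                tracks.append(_track(larva, valid_mask=mask))
            else:
                tracks.append(_track(larva))
        return TrackSet(tracks=tracks)

    def test_four_of_ten_hunchers(self):
        ts = self._ts()
        ivs = [_iv(f"l{i}", 5.2, 5.8, "Hunch") for i in range(4)]
        p, n = st.cumulative_probability(ivs, ts, "Hunch", (5.0, 8.0))
        assert (p, n) == (0.4, 10)

    def test_double_performance_counted_once(self):
        ts = self._ts()
        ivs = [_iv("l0", 5.2, 5.5, "Hunch"), _iv("l0", 6.0, 6.4, "Hunch")]
        p, n = st.cumulative_probability(ivs, ts, "Hunch", (5.0, 8.0))
        assert (p, n) == (0.1, 10)

    def test_untracked_at_onset_fully_excluded(self):
        ts = self._ts(untracked=("l9",))
        ivs = [_iv("l9", 6.5, 7.0, "Hunch")]  # acts within window but untracked at t0
        p, n = st.cumulative_probability(ivs, ts, "Hunch", (5.0, 8.0))
        assert n == 9 and p == 0.0

    def test_overlap_at_window_edge_counts(self):
        ts = self._ts()
        ivs = [_iv("l0", 4.0, 5.5, "Hunch")]  # starts before, overlaps window
        p, n = st.cumulative_probability(ivs, ts, "Hunch", (5.0, 8.0))
        assert p == 0.1

    def test_zero_denominator_rejected(self):
        ts = self._ts(untracked=tuple(f"l{i}" for i in range(10)))
        with pytest.raises(ValueError, match="no larvae tracked"):
            st.cumulative_probability([], ts, "Hunch", (5.0, 8.0))


class TestTransitionMatrix:
    def test_half_half_split(self):
        ivs = [
            _iv("a", 0.0, 1.0, "CShape"),
            _iv("a", 1.0, 2.0, "Roll"),
            _iv("b", 0.0, 1.0, "CShape"),
            _iv("b", 1.0, 2.0, "Crawl"),
        ]
        tm = st.transition_matrix(ivs)
        assert tm.probabilities.loc["CShape", "Roll"] == pytest.approx(0.5)
        assert tm.probabilities.loc["CShape", "Crawl"] == pytest.approx(0.5)
        assert tm.counts.loc["CShape"].sum() == 2

    def test_single_interval_per_larva_empty(self):
        ivs = [_iv("a", 0.0, 1.0, "Crawl"), _iv("b", 0.0, 1.0, "Hunch")]
        tm = st.transition_matrix(ivs)
        assert tm.counts.to_numpy().sum() == 0

    def test_subthreshold_cell_retained_but_hidden(self):
        ivs = []
        for i in range(49):
            ivs += [_iv(f"l{i}", 0.0, 1.0, "CShape"), _iv(f"l{i}", 1.0, 2.0, "Roll")]
        ivs += [_iv("l49", 0.0, 1.0, "CShape"), _iv("l49", 1.0, 2.0, "Crawl")]
        tm = st.transition_matrix(ivs, threshold=0.03)
        assert tm.probabilities.loc["CShape", "Crawl"] == pytest.approx(0.02)
        assert bool(tm.hidden.loc["CShape", "Crawl"])
        assert np.isnan(tm.displayed().loc["CShape", "Crawl"])
        assert not bool(tm.hidden.loc["CShape", "Roll"])

    def test_window_filter_uses_destination_start(self):
        ivs = [
            _iv("a", 0.0, 2.9, "Crawl"),
            _iv("a", 2.9, 4.0, "Hunch"),  # transition at 2.9, inside (0, 3)
            _iv("a", 4.0, 5.0, "Roll"),  # transition at 4.0, outside
        ]
        tm = st.transition_matrix(ivs, window=(0.0, 3.0))
        assert tm.counts.loc["Crawl", "Hunch"] == 1
        assert tm.counts.loc["Hunch", "Roll"] == 0

    def test_rows_renormalize_to_one_against_recount(self, rng):
        labels = ["Crawl", "Hunch", "Roll", "CShape"]
        ivs = []
        for i in range(20):
            t = 0.0
            seq = rng.choice(labels, size=8)
            for lab in seq:
                ivs.append(_iv(f"l{i}", t, t + 1.0, lab))
                t += 1.0
        tm = st.transition_matrix(ivs)
        # oracle: recount transitions directly from the interval lists
        recount = {}
        for i in range(20):
            mine = [iv for iv in ivs if iv.larva_id == f"l{i}"]
            for a, b in zip(mine, mine[1:]):
                if a.label != b.label:
                    recount[(a.label, b.label)] = recount.get((a.label, b.label), 0) + 1
        for (a, b), c in recount.items():
            assert tm.counts.loc[a, b] == c
        sums = tm.probabilities.sum(axis=1, skipna=True)
        for lab in tm.counts.index:
            if tm.counts.loc[lab].sum() > 0:
                assert sums[lab] == pytest.approx(1.0)


class TestChi2:
    def test_identical_proportions_zero_statistic(self):
        chi2, df, p = st.chi2_compare([[10, 90], [10, 90]])
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0) and df == 1

    def test_closed_form_two_by_two(self):
        chi2, df, p = st.chi2_compare([[30, 70], [10, 90]])
        assert chi2 == pytest.approx(12.5)

    def test_matches_closed_form_on_random_tables(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(1, 50, 4)
            chi2, _, _ = st.chi2_compare([[a, b], [c, d]])
            n = a + b + c + d
            expect = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert chi2 == pytest.approx(expect, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="zero margin"):
            st.chi2_compare([[0, 0], [5, 5]])


def _bh_oracle(pvals, alpha):
    """Literal step-up definition: largest k with p_(k) <= k*alpha/n."""
    n = len(pvals)
    order = np.argsort(pvals, kind="stable")
    sorted_p = np.asarray(pvals)[order]
    k_star = 0
    for k in range(1, n + 1):
        if sorted_p[k - 1] <= k * alpha / n:
            k_star = k
    reject = np.zeros(n, dtype=bool)
    reject[order[:k_star]] = True
    return reject


class TestBenjaminiHochberg:
    def test_textbook_example_all_rejected(self):
        p_adj, reject = st.bh_adjust([0.01, 0.02, 0.04], alpha=0.05)
        assert reject.all()

    def test_single_p_unchanged(self):
        p_adj, _ = st.bh_adjust([0.03])
        assert p_adj[0] == pytest.approx(0.03)

    def test_all_ones_nothing_rejected(self):
        _, reject = st.bh_adjust([1.0, 1.0, 1.0])
        assert not reject.any()

    def test_matches_exhaustive_step_up_for_small_n(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 9))
            p = rng.uniform(0, 1, n)
            _, reject = st.bh_adjust(p, alpha=0.05)
            np.testing.assert_array_equal(reject, _bh_oracle(p, 0.05))

    def test_planned_comparison_mode_skips_adjustment(self):
        p_adj, reject = st.bh_adjust([0.04, 0.04, 0.04], alpha=0.05, adjust=False)
        np.testing.assert_allclose(p_adj, [0.04, 0.04, 0.04])
        assert reject.all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            st.bh_adjust([0.5, 1.5])


def _ks_oracle(x, y):
    """O(n*m) supremum of |F_n − G_m| over all sample points."""
    best = 0.0
    for pt in np.concatenate([x, y]):
        fn = np.mean(x <= pt)
        gm = np.mean(y <= pt)
        best = max(best, abs(fn - gm))
    return best


class TestKolmogorovSmirnov:
    def test_identical_samples_zero(self):
        D, _ = st.ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert D == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        D, _ = st.ks_two_sample([0.0, 0.0], [1.0, 1.0])
        assert D == pytest.approx(1.0)

    def test_offset_triplets(self):
        D, _ = st.ks_two_sample([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert D == pytest.approx(1.0 / 3.0)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(100):
            x = rng.normal(0, 1, int(rng.integers(3, 30)))
            y = rng.normal(0.3, 1.2, int(rng.integers(3, 30)))
            D, _ = st.ks_two_sample(x, y)
            assert D == pytest.approx(_ks_oracle(x, y), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            st.ks_two_sample([], [1.0])


class TestKde:
    def test_standard_normal_density_at_zero(self, rng):
        sample = rng.normal(0, 1, 10_000)
        grid, dens = st.kde_density(sample)
        at0 = dens[np.argmin(np.abs(grid))]
        assert at0 == pytest.approx(1 / np.sqrt(2 * np.pi), abs=0.03)

    def test_integrates_to_one(self, rng):
        sample = rng.exponential(2.0, 2000)
        grid, dens = st.kde_density(sample)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_single_point_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            grid, dens = st.kde_density([2.0, 2.0])
        assert grid[np.argmax(dens)] == pytest.approx(2.0, abs=0.05)


class TestCrawlSpeedComparison:
    def _setup(self):
        from ethome.pipeline import compute_series
        from ethome.synth import BehaviorScript, simulate_larva

        tracks, ivs = [], []
        for i in range(8):
            script = BehaviorScript.of(("Crawl", 10.0), ("FastCrawl", 10.0))
            tr, truth = simulate_larva(script, seed=100 + i, larva_id=f"l{i}")
            tracks.append(tr)
            for tiv in truth:
                ivs.append(_iv(tiv.larva_id, tiv.start, tiv.end, "Crawl"))
        ts = TrackSet(tracks=tracks)
        return ts, ivs, compute_series(ts)

    def test_fast_crawl_speed_ratio_recovered(self):
        ts, ivs, series = self._setup()
        res = st.crawl_speed_comparison(ts, ivs, (0.0, 10.0), (10.0, 20.0), series)
        assert res["mean_during"] / res["mean_before"] == pytest.approx(1.5, rel=0.05)
        assert res["ks_D"] == pytest.approx(1.0)  # cleanly separated distributions

    def test_identical_windows_give_zero_D(self):
        ts, ivs, series = self._setup()
        res = st.crawl_speed_comparison(ts, ivs, (0.0, 10.0), (0.0, 10.0), series)
        assert res["ks_D"] == pytest.approx(0.0)

    def test_missing_crawls_error_names_window(self):
        ts, ivs, series = self._setup()
        with pytest.raises(ValueError, match="before"):
            st.crawl_speed_comparison(ts, ivs, (90.0, 95.0), (10.0, 20.0), series)
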