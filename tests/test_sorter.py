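import dataclasses

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.proportion import proportion_confint

import deldrop as d
from deldrop.screen import EventStream, ScreenConfig


def make_stream(times, rfus, n_beads=None, duration_min=None, bead_member=None, bead_droplet=None):
    times = np.asarray(times, float)
    rfus = np.asarray(rfus, float)
    if n_beads is None:
        n_beads = np.zeros(len(times), dtype=int)
    if duration_min is None:
        duration_min = max(times.max() / 60.0, 1e-3)
    cfg = ScreenConfig(uv_intensity=0.0, seed=0, duration_min=duration_min)
    return EventStream(
        events=pd.DataFrame({"time_s": times, "rfu": rfus, "n_beads": n_beads}),
        bead_member=np.asarray(bead_member if bead_member is not None else [], dtype=int),
        bead_droplet=np.asarray(bead_droplet if bead_droplet is not None else [], dtype=int),
        config=cfg,
    )


class TestBinStats:
    def test_bins_partition_all_events(self):
        stream = make_stream(np.linspace(0.1, 119.9, 50), np.full(50, 100.0), duration_min=2.0)
        bins = d.compute_bin_stats(stream, time_bin=60.0)
        assert len(bins) == 2
        assert bins["droplet_count"].sum() == 50

    def test_constant_signal_zero_sigma(self):
        stream = make_stream([1, 2, 3, 61, 62], [100.0] * 5, duration_min=2.0)
        bins = d.compute_bin_stats(stream, 60.0)
        assert np.allclose(bins["mu"], 100.0)
        assert np.allclose(bins["sigma"], 0.0)

    def test_drifting_stream_matches_brute_force_means(self, rng):
        t = np.sort(rng.uniform(0, 300, 400))
        rfu = 100 + 0.05 * t + rng.normal(0, 2, 400)
        stream = make_stream(t, rfu, duration_min=5.0)
        bins = d.compute_bin_stats(stream, 60.0)
        for k in range(5):
            sel = (t >= 60 * k) & (t < 60 * (k + 1))
            assert bins["mu"].iloc[k] == pytest.approx(rfu[sel].mean())
            assert bins["sigma"].iloc[k] == pytest.approx(rfu[sel].std(ddof=1))

    def test_empty_bin_recorded_not_dropped(self):
        stream = make_stream([5.0, 130.0], [100.0, 100.0], duration_min=3.0)
        bins = d.compute_bin_stats(stream, 60.0)
        assert len(bins) == 3
        assert bins["droplet_count"].iloc[1] == 0
        assert np.isnan(bins["mu"].iloc[1])


class TestDynamicThreshold:
    def _stats(self, mus, sigmas, counts):
        return pd.DataFrame(
            {
                "bin_start": np.arange(len(mus)) * 60.0,
                "bin_width": 60.0,
                "mu": mus,
                "sigma": sigmas,
                "droplet_count": counts,
                "bead_count": 0,
            }
        )

    def test_mu_minus_n_sigma(self):
        thr = d.dynamic_threshold(self._stats([100.0], [10.0], [500]), n_sigma=4.5)
        assert thr["threshold"].iloc[0] == pytest.approx(55.0)

    def test_stricter_six_sigma_preset(self):
        thr = d.dynamic_threshold(self._stats([100.0], [10.0], [500]), n_sigma=6.0)
        assert thr["threshold"].iloc[0] == pytest.approx(40.0)

    def test_zero_sigma_threshold_is_mean(self):
        thr = d.dynamic_threshold(self._stats([100.0], [0.0], [500]), n_sigma=4.5)
        assert thr["threshold"].iloc[0] == 100.0

    def test_sparse_bin_carries_forward_and_flags(self):
        thr = d.dynamic_threshold(
            self._stats([100.0, 90.0, 100.0], [10.0, 5.0, 10.0], [500, 10, 500]), n_sigma=4.0
        )
        assert thr["threshold"].iloc[1] == pytest.approx(60.0)  # carried from bin 0
        assert bool(thr["carried"].iloc[1]) and not bool(thr["carried"].iloc[0])

    def test_leading_sparse_bin_backfills_and_flags(self):
        thr = d.dynamic_threshold(
            self._stats([100.0, 90.0], [10.0, 5.0], [10, 500]), n_sigma=4.0
        )
        assert thr["threshold"].iloc[0] == pytest.approx(70.0)
        assert bool(thr["carried"].iloc[0])

    def test_all_sparse_errors(self):
        with pytest.raises(ValueError, match="min_events"):
            d.dynamic_threshold(self._stats([100.0], [10.0], [5]), n_sigma=4.0)


class TestSortEvents:
    def test_events_at_mean_are_not_hits(self):
        n = 200
        stream = make_stream(np.linspace(0, 59, n), np.full(n, 100.0), duration_min=1.0)
        res = d.run_sorter(stream, n_sigma=4.5)
        assert res.n_hit_droplets == 0

    def test_deep_outlier_is_hit_and_retains_bead_identity(self):
        n = 200
        rfu = np.full(n, 100.0)
        rfu[:100] += np.concatenate([np.full(50, 1.0), np.full(50, -1.0)])  # sigma > 0
        rfu[7] = 100 - 7 * rfu.std(ddof=1) - 50
        stream = make_stream(
            np.linspace(0, 59, n), rfu, n_beads=np.ones(n, int),
            bead_member=np.arange(n) % 5, bead_droplet=np.arange(n), duration_min=1.0,
        )
        res = d.run_sorter(stream, n_sigma=6.0)
        assert res.n_hit_droplets == 1
        assert res.hits["droplet_index"].iloc[0] == 7
        assert list(res.hit_bead_member) == [7 % 5]

    def test_threshold_monotone_in_n_sigma(self, rng):
        n = 3000
        stream = make_stream(
            np.sort(rng.uniform(0, 60, n)), rng.normal(100, 5, n), duration_min=1.0
        )
        hits = [d.run_sorter(stream, ns).n_hit_droplets for ns in (2.0, 3.0, 4.0, 5.0)]
        assert hits == sorted(hits, reverse=True)

    def test_event_outside_coverage_errors(self):
        stream = make_stream(np.linspace(0, 59, 200), np.full(200, 100.0), duration_min=1.0)
        thr = pd.DataFrame(
            {"bin_start": [0.0], "bin_width": [30.0], "threshold": [50.0], "carried": [False]}
        )
        with pytest.raises(ValueError, match="coverage"):
            d.sort_events(stream, thr)


class TestHitRateAccounting:
    def _result(self, hit_beads, beads_screened):
        return d.SortResult(
            hits=pd.DataFrame(),
            hit_bead_member=np.zeros(hit_beads, dtype=int),
            thresholds=pd.DataFrame(),
            n_sigma=4.5,
            n_droplets=beads_screened,
            beads_screened=beads_screened,
        )

    def test_paper_scale_hit_rate(self):
        hr = d.hit_rate(self._result(400, 500_000))
        assert hr.percent == pytest.approx(0.08)

    def test_zero_hits(self):
        hr = d.hit_rate(self._result(0, 1000))
        assert hr.percent == 0.0 and hr.ci_low == 0.0

    def test_zero_beads_error(self):
        with pytest.raises(ValueError):
            d.hit_rate(self._result(0, 0))

    @pytest.mark.parametrize("k,n", [(0, 50), (3, 50), (17, 100), (50, 50)])
    def test_ci_matches_clopper_pearson(self, k, n):
        hr = d.hit_rate(self._result(k, n))
        lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
        assert hr.ci_low == pytest.approx(100 * lo, abs=1e-9)
        assert hr.ci_high == pytest.approx(100 * hi, abs=1e-9)

    def test_library_equivalents(self):
        assert d.library_equivalents(55_296, 55_296) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            d.library_equivalents(10, 0)
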