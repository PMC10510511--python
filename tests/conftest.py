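import dataclasses

import numpy as np
import pytest
from hypothesis import settings

import deldrop as d

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_catalog():
    rng = np.random.default_rng(7)
    aa = d.make_building_blocks(8, cycle=1, rng=rng)
    ca = d.make_building_blocks(12, cycle=2, rng=rng)
    return d.enumerate_library(aa, ca)


@pytest.fixture(scope="session")
def full_catalog():
    """The production-scale two-cycle library (192 x 288 = 55,296 members)."""
    rng = np.random.default_rng(0)
    aa = d.make_building_blocks(192, cycle=1, rng=rng)
    ca = d.make_building_blocks(288, cycle=2, rng=rng)
    return d.enumerate_library(aa, ca)


@pytest.fixture(scope="session")
def calibration():
    return d.DoseCalibration()


def run_two_dose_screen(catalog, activity, calibration, epsilon, seed, uv_pair=(1.0, 0.3)):
    """Simulate/sort/deconvolve both doses of one screening campaign."""
    base = d.ScreenConfig(uv_intensity=1.0, seed=0, duration_min=1.0)
    dur = d.duration_for_equivalents(epsilon, catalog.n_members, base)
    out = {}
    for i, uv in enumerate(uv_pair):
        cfg = dataclasses.replace(base, uv_intensity=uv, duration_min=dur, seed=seed * 10 + i)
        stream = d.simulate_screen(catalog, activity, calibration, cfg)
        sort = d.run_sorter(stream, n_sigma=4.5)
        reads = d.reads_from_hits(sort, catalog, error_rate=0.005, seed=seed * 10 + 5 + i)
        ktab = d.k_class_table(d.decode_reads(reads, catalog), catalog, f"uv{uv:g}")
        out[uv] = {"sort": sort, "ktab": ktab, "hit_rate": d.hit_rate(sort)}
    return out


@pytest.fixture(scope="session")
def standard_suite(full_catalog, calibration):
    """20-seed standard planted fixture: 2 AA + 1 CA series, 3 library
    equivalents screened at 100% and 30% UV with generator defaults."""
    results = []
    for s in range(20):
        activity = d.plant_actives(full_catalog, d.SeriesSpec(), seed=200 + s)
        screens = run_two_dose_screen(full_catalog, activity, calibration, epsilon=3.0, seed=900 + s)
        report = d.dose_compare(screens[1.0]["ktab"], screens[0.3]["ktab"])
        metrics = d.score_recovery(report, activity, full_catalog)
        results.append(
            {
                "activity": activity,
                "hit_rate_high": screens[1.0]["hit_rate"].percent,
                "hit_rate_low": screens[0.3]["hit_rate"].percent,
                "report": report,
                "metrics": metrics,
            }
        )
    return results
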