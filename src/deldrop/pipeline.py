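"""End-to-end reproducible runs: library -> plant -> screen -> sort -> deconvolve.

``run_pipeline`` wires every stage into one run directory with recorded
sub-seeds and artifact checksums; the same configuration always produces a
byte-identical summary.  Each stage is also individually re-runnable from
the written intermediate files via the module functions (or the thin CLI).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import deconvolution, ground_truth, library, screen, sorter, validation
from .ground_truth import ActivityMap, DoseCalibration, SeriesSpec
from .library import LibraryCatalog
from .screen import ScreenConfig
from .sorter import N_SIGMA_PRESETS

log = logging.getLogger("deldrop")


@dataclass
class RunConfig:
    """Configuration for a full dose-response screening run.

    ``uv_intensities`` must be given high dose first; the first two doses
    feed the dose-comparison report.  Every stochastic stage receives a
    sub-seed derived from ``seed`` (recorded in the summary).
    """

    seed: int
    outdir: str = "deldrop_run"
    aa_count: int = 192
    ca_count: int = 288
    tag_length: int = 12
    enzyme: str = "fxa"
    n_sigma: float | None = None  # default: enzyme preset
    uv_intensities: tuple[float, ...] = (1.0, 0.3)
    epsilon: float = 3.0  # library equivalents screened per dose
    series: SeriesSpec = field(default_factory=SeriesSpec)
    calibration: DoseCalibration = field(default_factory=DoseCalibration)
    mean_bead_occupancy: float = 0.2
    droplet_rate: float = 400.0
    signal_gain: float = 100.0
    noise_sd: float = 5.0
    baseline_rfu: float = 20.0
    baseline_drift: float = 0.0
    time_bin_s: float = 60.0
    min_events: int = 100
    seq_error_rate: float = 0.005
    min_k: int = 4
    noise_k: int = 3
    n_validation_fits: int = 4
    write_events: bool = False  # per-droplet CSVs are large; opt in
    make_plots: bool = True

    def __post_init__(self):
        if self.seed is None or not isinstance(self.seed, (int, np.integer)):
            raise ValueError("a run seed is required (integer)")
        if len(self.uv_intensities) < 2:
            raise ValueError("need at least a high and a low UV intensity")
        if sorted(self.uv_intensities, reverse=True) != list(self.uv_intensities):
            raise ValueError("uv_intensities must be ordered high dose first")
        if self.n_sigma is None:
            self.n_sigma = N_SIGMA_PRESETS[self.enzyme.lower()]

    def to_json(self, path) -> None:
        d = asdict(self)
        d["calibration"] = {"anchors": self.calibration.anchors, "mode": self.calibration.mode}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True, default=list)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "seed" not in d:
            raise ValueError("config is missing the mandatory seed")
        if "series" in d and isinstance(d["series"], dict):
            d["series"]["potency_range"] = tuple(d["series"]["potency_range"])
            d["series"] = SeriesSpec(**d["series"])
        if "calibration" in d and isinstance(d["calibration"], dict):
            d["calibration"] = DoseCalibration(
                anchors=tuple(tuple(a) for a in d["calibration"]["anchors"]),
                mode=d["calibration"].get("mode", "piecewise"),
            )
        if "uv_intensities" in d:
            d["uv_intensities"] = tuple(d["uv_intensities"])
        return cls(**d)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    # independent 31-bit sub-seeds, reproducibly derived from the run seed
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def screen_one_dose(
    catalog: LibraryCatalog,
    activity: ActivityMap,
    cfg: RunConfig,
    uv: float,
    sim_seed: int,
    seq_seed: int,
) -> dict:
    """Simulate, sort and deconvolve one UV dose; returns all stage outputs."""
    base = ScreenConfig(
        uv_intensity=uv,
        seed=sim_seed,
        enzyme=cfg.enzyme,
        droplet_rate=cfg.droplet_rate,
        mean_bead_occupancy=cfg.mean_bead_occupancy,
        signal_gain=cfg.signal_gain,
        noise_sd=cfg.noise_sd,
        baseline_rfu=cfg.baseline_rfu,
        baseline_drift=cfg.baseline_drift,
        duration_min=1.0,
    )
    duration = screen.duration_for_equivalents(cfg.epsilon, catalog.n_members, base)
    scfg = dataclasses.replace(base, duration_min=duration)
    stream = screen.simulate_screen(catalog, activity, cfg.calibration, scfg)
    sort = sorter.run_sorter(stream, cfg.n_sigma, cfg.time_bin_s, cfg.min_events)
    reads = deconvolution.reads_from_hits(sort, catalog, cfg.seq_error_rate, seq_seed)
    decoded = deconvolution.decode_reads(reads, catalog)
    ktab = deconvolution.k_class_table(decoded, catalog, screen_label=f"uv{uv:g}")
    return {
        "stream": stream,
        "sort": sort,
        "reads": reads,
        "decoded": decoded,
        "ktab": ktab,
        "hit_rate": sorter.hit_rate(sort) if sort.n_hit_beads else None,
        "epsilon": sorter.library_equivalents(stream.beads_screened, catalog.n_members),
    }


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full pipeline and write every artifact to ``cfg.outdir``.

    Returns the run directory.  Stage order: build library, plant
    activity, then per UV dose simulate/sort/deconvolve, then the
    high-vs-low dose comparison, recovery scoring, and 4PL validation fits
    of the top disynthons.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    seeds = _spawn_seeds(cfg.seed, 3 + 2 * len(cfg.uv_intensities))
    lib_seed, plant_seed, fit_seed, *dose_seeds = seeds

    cfg.to_json(out / "config.json")

    log.info("building %d x %d library", cfg.aa_count, cfg.ca_count)
    rng = np.random.default_rng(lib_seed)
    aa = library.make_building_blocks(cfg.aa_count, cycle=1, rng=rng, tag_length=cfg.tag_length)
    ca = library.make_building_blocks(cfg.ca_count, cycle=2, rng=rng, tag_length=cfg.tag_length)
    catalog = library.enumerate_library(aa, ca)
    aa.to_csv(out / "building_blocks_aa.tsv", sep="\t", index=False)
    ca.to_csv(out / "building_blocks_ca.tsv", sep="\t", index=False)
    catalog.write(out / "catalog.tsv")
    profile = library.profile_properties(catalog)

    activity = ground_truth.plant_actives(catalog, cfg.series, seed=plant_seed, target_id=cfg.enzyme)
    activity.write(out / "activity.tsv", catalog)
    activity.series.to_csv(out / "planted_series.tsv", sep="\t", index=False)
    cfg.calibration.to_json(out / "calibration.json")

    per_dose = {}
    for i, uv in enumerate(cfg.uv_intensities):
        log.info("screening at uv=%g (epsilon=%g)", uv, cfg.epsilon)
        res = screen_one_dose(
            catalog, activity, cfg, uv, dose_seeds[2 * i], dose_seeds[2 * i + 1]
        )
        tag = f"uv{uv:g}"
        if cfg.write_events:
            res["stream"].write_csv(out / f"events_{tag}.csv", catalog)
        res["sort"].hits.to_csv(out / f"hits_{tag}.csv", index=False, float_format="%.4f")
        res["sort"].write_summary(out / f"sort_summary_{tag}.json")
        deconvolution.write_fastq(res["reads"], out / f"hit_reads_{tag}.fastq")
        res["ktab"].write(out / f"kclass_{tag}")
        per_dose[uv] = res

    uv_high, uv_low = cfg.uv_intensities[0], cfg.uv_intensities[1]
    report = deconvolution.dose_compare(
        per_dose[uv_high]["ktab"], per_dose[uv_low]["ktab"], cfg.min_k, cfg.noise_k
    )
    report.write_tsv(out / "dose_comparison.tsv")
    report.write_json(out / "dose_comparison.json")
    metrics = validation.score_recovery(report, activity, catalog)

    # validate the top disynthons: simulated microplate dose-response + 4PL fit
    fits = []
    top = report.disynthons.head(cfg.n_validation_fits)
    member_pos = pd.Series(
        np.arange(catalog.n_members), index=catalog.members["member_id"]
    )
    for j, row in top.iterrows():
        pos = int(member_pos[row["member_id"]])
        true_ic50 = activity.ic50[pos]
        if not np.isfinite(true_ic50):
            continue
        conc, resp = validation.simulate_dose_response(
            true_ic50, hill=float(activity.hill[pos]), seed=fit_seed + j
        )
        fits.append(validation.fit_ic50(conc, resp, member_id=row["member_id"]))
    if fits:
        validation.fits_to_frame(fits).to_csv(out / "validation_fits.tsv", sep="\t", index=False)

    if cfg.make_plots:
        from . import plots

        plots.plot_dose_comparison(report, out / "dose_comparison.png")
        if fits:
            pos = int(member_pos[fits[0].member_id])
            conc, resp = validation.simulate_dose_response(
                activity.ic50[pos], hill=float(activity.hill[pos]), seed=fit_seed
            )
            plots.plot_dose_response(fits[0], conc, resp, out / "top_hit_dose_response.png")

    artifacts = sorted(
        p for p in out.iterdir() if p.suffix in {".tsv", ".csv", ".json", ".fastq"}
        # config.json records the invocation (incl. the outdir path), not results
        and p.name not in {"summary.json", "config.json"}
    )
    summary = {
        "seed": cfg.seed,
        "sub_seeds": seeds,
        "library": {
            "aa_count": catalog.aa_count,
            "ca_count": catalog.ca_count,
            "n_members": catalog.n_members,
            "rule_of_5_fraction": round(profile.fractions["rule_of_5"], 4),
            "rule_of_3_fraction": round(profile.fractions["rule_of_3"], 4),
        },
        "n_active_members": activity.n_active,
        "screens": {
            f"uv{uv:g}": {
                "beads_screened": res["stream"].beads_screened,
                "library_equivalents": round(res["epsilon"], 3),
                "n_hit_beads": res["sort"].n_hit_beads,
                "hit_rate_pct": round(res["hit_rate"].percent, 4) if res["hit_rate"] else 0.0,
                "decoded_reads": res["decoded"].n_decoded,
                "discards": dict(res["decoded"].discards),
            }
            for uv, res in per_dose.items()
        },
        "recovery": {
            "precision": metrics.precision,
            "recall": metrics.recall,
            "spearman_rho": metrics.spearman_rho,
        },
        "validation_fits": [
            {"member_id": f.member_id, "ic50_uM": round(f.ic50, 3), "converged": f.converged}
            for f in fits
        ],
        "checksums": {p.name: _sha256(p) for p in artifacts},
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    log.info("run complete in %.1f s -> %s", time.time() - t0, out)
    return out
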