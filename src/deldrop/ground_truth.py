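"""Planted-activity ground truth and the UV-dose -> released-concentration model.

The droplet screen releases compound from each bead by photocleavage, and
the released concentration scales with the applied UV intensity.  The
calibration here is anchored on droplet measurements with photocleavable
fluorescein surrogate beads: 90, 60 and 50 uM released at 100%, 30% and
20% UV.  Those anchors are sub-linear, so the default interpolation is
piecewise-linear through the measured points (a strictly proportional mode
is available).

Ground-truth inhibitor activity is planted as building-block series: a
"warm" building block defines a series whose active partner combinations
share a common potency scale, mirroring how real hit series are defined by
a shared synthon.  Potencies are latent IC50s in micromolar; inactive
members carry IC50 = inf.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .library import LibraryCatalog

#: fluorescein released in droplets at 100/30/20% UV dose
DEFAULT_ANCHORS = ((0.0, 0.0), (0.2, 50.0), (0.3, 60.0), (1.0, 90.0))


@dataclass(frozen=True)
class DoseCalibration:
    """UV intensity (fraction of maximum) -> released compound concentration (uM)."""

    anchors: tuple[tuple[float, float], ...] = DEFAULT_ANCHORS
    mode: str = "piecewise"  # "piecewise" | "proportional"

    def __post_init__(self):
        pts = sorted(self.anchors)
        if pts != list(self.anchors):
            object.__setattr__(self, "anchors", tuple(pts))
        uv = [p[0] for p in self.anchors]
        conc = [p[1] for p in self.anchors]
        if (0.0, 0.0) != self.anchors[0]:
            raise ValueError("calibration must include the anchor (0, 0)")
        if any(b < a for a, b in zip(conc, conc[1:])):
            raise ValueError("released concentration must be non-decreasing in UV")
        if len(set(uv)) != len(uv):
            raise ValueError("duplicate UV anchor")
        if self.mode not in ("piecewise", "proportional"):
            raise ValueError(f"unknown interpolation mode {self.mode!r}")

    @property
    def max_concentration(self) -> float:
        return self.anchors[-1][1]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"anchors": self.anchors, "mode": self.mode}, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "DoseCalibration":
        with open(path) as fh:
            d = json.load(fh)
        return cls(anchors=tuple(tuple(a) for a in d["anchors"]), mode=d["mode"])


def dose_to_concentration(uv, cal: DoseCalibration = DoseCalibration()):
    """Released compound concentration (uM) at UV intensity ``uv`` in [0, 1].

    Monotone interpolation through the calibration anchors; exactly 0 at
    ``uv = 0``.  Scalar or array input.
    """
    uv_arr = np.asarray(uv, dtype=float)
    if np.any((uv_arr < 0) | (uv_arr > 1)):
        raise ValueError("uv intensity must lie in [0, 1]")
    if cal.mode == "proportional":
        out = uv_arr * cal.max_concentration / cal.anchors[-1][0]
    else:
        xs = np.array([a[0] for a in cal.anchors])
        ys = np.array([a[1] for a in cal.anchors])
        out = np.interp(uv_arr, xs, ys)
    return float(out) if np.isscalar(uv) else out


@dataclass(frozen=True)
class SeriesSpec:
    """How activity is planted.

    n_aa_series / n_ca_series
        number of warm amino-acid / carboxylic-acid building blocks.
    potency_range
        (low, high) in uM; each series' mean IC50 is log-uniform in this
        range, spanning potent binders down to marginal actives near the
        screen's detection boundary.
    partner_fraction
        fraction of a warm block's partners that are genuinely active
        (real series enrich a subset of combinations, not the whole row).
    background_rate
        fraction of library members that are isolated actives outside any
        series.
    jitter_sd
        within-series spread of log10(IC50) around the series mean.
    truncate_rate / truncate_factor
        fraction of members whose beads deliver a reduced dose (failed
        synthesis / truncates), and the delivery factor they receive.
    """

    n_aa_series: int = 2
    n_ca_series: int = 1
    potency_range: tuple[float, float] = (1.0, 500.0)
    partner_fraction: float = 0.15
    background_rate: float = 5e-4
    jitter_sd: float = 0.2
    hill: float = 1.0
    truncate_rate: float = 0.1
    truncate_factor: float = 0.25

    def __post_init__(self):
        lo, hi = self.potency_range
        if not (0 < lo <= hi <= 1000):
            raise ValueError("potency_range must lie within (0, 1000] uM")
        for name in ("partner_fraction", "background_rate", "truncate_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_aa_series < 0 or self.n_ca_series < 0:
            raise ValueError("series counts must be non-negative")


@dataclass
class ActivityMap:
    """Latent per-member ground truth for one target.

    ``ic50`` is a dense array aligned with catalog member positions
    (inf = inactive); ``delivery`` is the per-member dose delivery factor;
    ``series`` records the planted warm building blocks.
    """

    target_id: str
    ic50: np.ndarray
    hill: np.ndarray
    delivery: np.ndarray
    series: pd.DataFrame
    seed: int

    @property
    def active_mask(self) -> np.ndarray:
        return np.isfinite(self.ic50)

    @property
    def n_active(self) -> int:
        return int(self.active_mask.sum())

    def write(self, path, catalog: LibraryCatalog) -> None:
        df = pd.DataFrame(
            {
                "member_id": catalog.members["member_id"],
                "ic50_uM": self.ic50,
                "hill": self.hill,
                "delivery": self.delivery,
            }
        )
        with open(path, "w") as fh:
            fh.write(f"# target={self.target_id} seed={self.seed}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read(cls, path, series: pd.DataFrame | None = None) -> "ActivityMap":
        with open(path) as fh:
            header = fh.readline().strip().lstrip("# ")
            meta = dict(kv.split("=") for kv in header.split())
            df = pd.read_csv(fh, sep="\t")
        return cls(
            target_id=meta["target"],
            ic50=df["ic50_uM"].to_numpy(float),
            hill=df["hill"].to_numpy(float),
            delivery=df["delivery"].to_numpy(float),
            series=series if series is not None else pd.DataFrame(),
            seed=int(meta["seed"]),
        )


def _exact_count(rate: float, n: int) -> int:
    return int(round(rate * n))


def plant_actives(
    catalog: LibraryCatalog,
    spec: SeriesSpec = SeriesSpec(),
    seed: int = 0,
    target_id: str = "target",
) -> ActivityMap:
    """Plant warm-building-block inhibitor series plus isolated background actives.

    Series membership is exact-count (no sampling in how many members are
    active), so the number of actives is analytically determined by the
    spec; which members and their potencies are drawn from ``seed``.
    Re-generation with the same seed is byte-identical.
    """
    if spec.n_aa_series > catalog.aa_count:
        raise ValueError(f"{spec.n_aa_series} AA series exceed {catalog.aa_count} blocks")
    if spec.n_ca_series > catalog.ca_count:
        raise ValueError(f"{spec.n_ca_series} CA series exceed {catalog.ca_count} blocks")

    rng = np.random.default_rng(seed)
    n = catalog.n_members
    ic50 = np.full(n, np.inf)
    lo, hi = np.log10(spec.potency_range[0]), np.log10(spec.potency_range[1])

    warm_aa = rng.choice(catalog.aa_count, size=spec.n_aa_series, replace=False)
    warm_ca = rng.choice(catalog.ca_count, size=spec.n_ca_series, replace=False)
    series_rows = []
    sid = 0
    for cycle, warm, n_partner in ((1, warm_aa, catalog.ca_count), (2, warm_ca, catalog.aa_count)):
        for w in warm:
            sid += 1
            mean_log = rng.uniform(lo, hi)
            k_active = max(1, _exact_count(spec.partner_fraction, n_partner))
            partners = rng.choice(n_partner, size=k_active, replace=False)
            if cycle == 1:
                pos = catalog.member_position(np.full(k_active, w), partners)
                bb_id = catalog.aa["bb_id"].iloc[w]
            else:
                pos = catalog.member_position(partners, np.full(k_active, w))
                bb_id = catalog.ca["bb_id"].iloc[w]
            vals = 10.0 ** (mean_log + rng.normal(0.0, spec.jitter_sd, k_active))
            ic50[pos] = np.minimum(ic50[pos], vals)  # overlap keeps the more potent value
            series_rows.append(
                {
                    "series_id": f"S{sid}",
                    "cycle": cycle,
                    "bb_id": bb_id,
                    "mean_ic50_uM": 10.0 ** mean_log,
                    "n_active_partners": k_active,
                }
            )

    n_bg = _exact_count(spec.background_rate, n)
    if n_bg:
        inactive = np.flatnonzero(~np.isfinite(ic50))
        bg = rng.choice(inactive, size=min(n_bg, len(inactive)), replace=False)
        ic50[bg] = 10.0 ** rng.uniform(lo, hi, len(bg))

    delivery = np.ones(n)
    n_trunc = _exact_count(spec.truncate_rate, n)
    if n_trunc:
        delivery[rng.choice(n, size=n_trunc, replace=False)] = spec.truncate_factor

    series = pd.DataFrame(
        series_rows, columns=["series_id", "cycle", "bb_id", "mean_ic50_uM", "n_active_partners"]
    )
    return ActivityMap(
        target_id=target_id,
        ic50=ic50,
        hill=np.full(n, spec.hill),
        delivery=delivery,
        series=series,
        seed=seed,
    )
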