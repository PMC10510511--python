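"""Hit validation: four-parameter logistic IC50 fits and planted-truth recovery.

Dose-response validation follows microplate practice: fractional enzyme
activity (1 = uninhibited control) measured over a concentration ladder is
fitted with the four-parameter logistic (4PL)

    y(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill)

and the *relative* IC50 (the curve's inflection point) is reported, along
with the maximal inhibition so partial inhibitors can be flagged.

Recovery scoring closes the simulation loop: given the planted activity
map, it measures how well the dose-comparison report's high-priority tier
captures the planted warm building blocks, and whether cumulative k tracks
planted potency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .deconvolution import DoseComparisonReport
from .ground_truth import ActivityMap

PARTIAL_INHIBITION_CUTOFF = 80.0  # % max inhibition below which a hit is "partial"


def four_pl(conc, ic50, hill, top, bottom):
    """Four-parameter logistic response at concentration ``conc``."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (conc / ic50) ** hill)


@dataclass(frozen=True)
class Ic50Fit:
    member_id: str
    ic50: float  # uM, relative (inflection point)
    ic50_se: float
    hill: float
    hill_se: float
    top: float
    bottom: float
    max_inhibition_pct: float
    partial_inhibitor: bool
    converged: bool


def fit_ic50(concentrations, responses, member_id: str = "") -> Ic50Fit:
    """Least-squares 4PL fit of a dose-response series.

    ``concentrations`` in uM (> 0), ``responses`` as fraction of the
    uninhibited control.  Requires at least 5 points.  Non-convergence is
    flagged on the result, never raised.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.size != resp.size:
        raise ValueError("concentrations and responses differ in length")
    if conc.size < 5:
        raise ValueError("need at least 5 concentration points")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")

    top0 = float(resp.max())
    bottom0 = float(resp.min())
    mid = 0.5 * (top0 + bottom0)
    ic50_0 = float(conc[np.argmin(np.abs(resp - mid))])
    p0 = [ic50_0, 1.0, top0, bottom0]
    bounds = ([1e-9, 0.1, -1.0, -1.0], [1e9, 10.0, 2.0, 2.0])
    try:
        popt, pcov = optimize.curve_fit(
            four_pl, conc, resp, p0=p0, bounds=bounds, maxfev=20000, xtol=1e-14, ftol=1e-14
        )
        se = np.sqrt(np.diag(pcov))
        converged = bool(np.all(np.isfinite(popt)))
    except (RuntimeError, ValueError):
        popt = [np.nan] * 4
        se = [np.nan] * 4
        converged = False

    ic50, hill, top, bottom = popt
    if converged and top != 0:
        max_inh = float(np.clip(100.0 * (1.0 - bottom / top), 0.0, 100.0))
    else:
        max_inh = np.nan
    return Ic50Fit(
        member_id=member_id,
        ic50=float(ic50),
        ic50_se=float(se[0]),
        hill=float(hill),
        hill_se=float(se[1]),
        top=float(top),
        bottom=float(bottom),
        max_inhibition_pct=max_inh,
        partial_inhibitor=bool(converged and max_inh < PARTIAL_INHIBITION_CUTOFF),
        converged=converged,
    )


def simulate_dose_response(
    ic50: float,
    hill: float = 1.0,
    concentrations=None,
    noise_sd: float = 0.02,
    seed: int = 0,
    top: float = 1.0,
    bottom: float = 0.0,
):
    """Synthetic microplate dose-response series for a compound of known potency."""
    if concentrations is None:
        concentrations = np.logspace(-1, 2.5, 8)  # 0.1 .. ~316 uM
    conc = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    resp = four_pl(conc, ic50, hill, top, bottom)
    if noise_sd > 0:
        resp = resp + rng.normal(0.0, noise_sd, conc.size)
    return conc, resp


@dataclass(frozen=True)
class RecoveryMetrics:
    """How well the dose-comparison report recovers the planted series."""

    precision: float | None
    recall: float | None
    spearman_rho: float | None
    n_planted: int
    n_high_priority: int
    defined: bool


def score_recovery(
    report: DoseComparisonReport, truth: ActivityMap, catalog=None
) -> RecoveryMetrics:
    """Recovery of the planted series by the high-priority tier.

    Recall asks whether the warm series-defining building blocks were
    prioritised.  Precision asks whether prioritised blocks carry real
    activity; a block counts as a true positive if it is contained in any
    planted active member (partner blocks of active compounds genuinely
    enrich and are not false positives).  When ``catalog`` is omitted,
    precision falls back to the warm-block set.  Also reports the Spearman
    correlation between planted series potency (-log10 mean IC50) and
    cumulative k at the high dose, over planted series observed in the
    report.  Degenerate inputs (no planted series, empty high-priority
    tier) yield None metrics with ``defined=False``.
    """
    planted = set(zip(truth.series["bb_id"], truth.series["cycle"])) if len(truth.series) else set()
    high = set(
        zip(
            report.bb.loc[report.bb["tier"] == "high_priority", "bb_id"],
            report.bb.loc[report.bb["tier"] == "high_priority", "cycle"],
        )
    )
    truly_active = planted
    if catalog is not None:
        active = catalog.members[truth.active_mask]
        truly_active = (
            {(b, 1) for b in active["aa_id"]} | {(b, 2) for b in active["ca_id"]} | planted
        )
    precision = len(truly_active & high) / len(high) if high else None
    recall = len(planted & high) / len(planted) if planted else None

    rho = None
    if len(truth.series) >= 2:
        merged = truth.series.merge(
            report.bb[["bb_id", "cycle", "k_high"]], on=["bb_id", "cycle"], how="left"
        ).fillna({"k_high": 0})
        observed = merged[merged["k_high"] > 0]
        if len(observed) >= 2:
            import warnings

            with warnings.catch_warnings():
                # constant ranks (e.g. all series equally enriched) -> undefined rho
                warnings.simplefilter("ignore", stats.ConstantInputWarning)
                r, _ = stats.spearmanr(-np.log10(observed["mean_ic50_uM"]), observed["k_high"])
            if np.isfinite(r):
                rho = float(r)
    return RecoveryMetrics(
        precision=precision,
        recall=recall,
        spearman_rho=rho,
        n_planted=len(planted),
        n_high_priority=len(high),
        defined=precision is not None and recall is not None,
    )


def fits_to_frame(fits: list[Ic50Fit]) -> pd.DataFrame:
    return pd.DataFrame([f.__dict__ for f in fits])
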