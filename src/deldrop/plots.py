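"""Report figures: dose-response curves and dose-comparison scatter plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .deconvolution import DoseComparisonReport
from .validation import Ic50Fit, four_pl

_TIER_COLORS = {
    "high_priority": "#1a6faf",
    "dose_limited": "#d95f02",
    "noise": "#999999",
    "unobserved": "#dddddd",
}


def plot_dose_response(fit: Ic50Fit, concentrations, responses, path) -> None:
    """Measured points plus the fitted 4PL curve on a log concentration axis."""
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.semilogx(concentrations, responses, "o", color="k", label="measured")
    if fit.converged:
        grid = np.logspace(np.log10(min(concentrations)), np.log10(max(concentrations)), 200)
        ax.semilogx(grid, four_pl(grid, fit.ic50, fit.hill, fit.top, fit.bottom), "-", color="#1a6faf")
        ax.axvline(fit.ic50, ls="--", color="#1a6faf", lw=0.8)
        ax.set_title(f"{fit.member_id}  IC50 = {fit.ic50:.3g} uM")
    ax.set_xlabel("[inhibitor] (uM)")
    ax.set_ylabel("fractional activity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dose_comparison(report: DoseComparisonReport, path, max_points: int = 200) -> None:
    """Cumulative k at the high vs low UV dose, point size ~ combined k."""
    df = report.bb.head(max_points)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    for tier, grp in df.groupby("tier"):
        ax.scatter(
            grp["k_high"],
            grp["k_low"],
            s=10 + 3 * grp["combined_k"],
            alpha=0.7,
            color=_TIER_COLORS.get(tier, "k"),
            label=tier,
        )
    lim = max(df["k_high"].max(), df["k_low"].max(), 1) * 1.1
    ax.plot([0, lim], [0, lim], ls=":", color="k", lw=0.7)
    ax.set_xlabel(f"cumulative k @ {report.label_high}")
    ax.set_ylabel(f"cumulative k @ {report.label_low}")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
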