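"""Mean-difference and coverage plots.

The mean-difference (Bland-Altman) plot scatters per-subject means against
per-subject differences with horizontal lines at each interval bound; after
a log back-transform the axes become geometric means and ratios and the
reference line moves from difference 0 to ratio 1.  Acceptance bands are
drawn as constant lines, sloped lines (percentage bands) or steps
(two-threshold bands).  By default the two tolerance intervals are drawn;
the agreement interval is opt-in and visually de-emphasised since it is
approximate and too narrow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .coverage import CoverageGrid
from .pipeline import MDResult, acceptance_band

__all__ = ["PlotSpec", "md_plot", "coverage_plot"]

_KIND_STYLE = {
    "PI_bTI": dict(color="tab:blue", linestyle="--"),
    "bgTI_exact": dict(color="tab:red", linestyle="-."),
    "bgTI_approx": dict(color="tab:orange", linestyle=":"),
    "AI": dict(color="0.6", linestyle=":", linewidth=1.0),
}


@dataclass(frozen=True)
class PlotSpec:
    """What to draw on a mean-difference plot."""

    which_intervals: Tuple[str, ...] = ("PI_bTI", "bgTI_exact")
    title: Optional[str] = None
    xlabel: Optional[str] = None
    ylabel: Optional[str] = None
    xlim: Optional[Tuple[float, float]] = None
    ylim: Optional[Tuple[float, float]] = None
    draw_acceptance: bool = True
    styles: dict = field(default_factory=dict)


def _interval_label(kind: str, iv) -> str:
    pct = f"{iv.beta:.0%}"
    if kind == "PI_bTI":
        return f"{pct} βTI (PI)"
    if kind.startswith("bgTI"):
        tag = "exact" if kind.endswith("exact") else "approx"
        return f"{pct} βγTI, γ={iv.gamma:.0%} ({tag})"
    if kind == "AI":
        return f"{pct} AI"
    return kind


def md_plot(result: MDResult, spec: Optional[PlotSpec] = None, path=None):
    """Render the mean-difference plot for an analysis result.

    Returns the matplotlib figure; writes it to ``path`` when given
    (format follows the extension: .png/.svg/.pdf).
    """
    spec = spec or PlotSpec()
    if len(result.md.diffs) == 0:
        raise ValueError("empty result: nothing to plot")
    missing = [k for k in spec.which_intervals if k not in result.intervals]
    if missing:
        raise ValueError(f"requested interval(s) not in result: {missing}")

    ratio = result.back_transformed
    x = result.md.means
    y = result.md.diffs
    if ratio:
        x = result.base ** np.asarray(x)
        y = result.base ** np.asarray(y)

    fig, ax = plt.subplots(figsize=(7, 5))
    ax.scatter(x, y, color="k", zorder=3, s=25)
    ax.axhline(1.0 if ratio else 0.0, color="0.3", linewidth=0.8)
    if ratio:
        ax.set_yscale("log")

    for kind in spec.which_intervals:
        iv = result.intervals[kind]
        style = {**_KIND_STYLE.get(kind, {}), **spec.styles.get(kind, {})}
        label = _interval_label(kind, iv)
        ax.axhline(iv.lower, label=label, **style)
        ax.axhline(iv.upper, **style)

    if spec.draw_acceptance and result.acceptance is not None:
        acc = result.acceptance
        if ratio:
            bounds = acc.ratio_bounds
            if bounds is not None:
                for b in bounds:
                    ax.axhline(b, color="tab:green", linewidth=1.5,
                               label="acceptance" if b == bounds[0] else None)
        else:
            grid = np.linspace(float(np.min(x)), float(np.max(x)), 200)
            if acc.threshold is not None:  # draw the step exactly
                grid = np.sort(np.concatenate([
                    grid, [acc.threshold - 1e-9, acc.threshold]]))
            bands = np.array([acceptance_band(acc, m) for m in grid])
            ax.plot(grid, bands[:, 0], color="tab:green", linewidth=1.5,
                    label="acceptance")
            ax.plot(grid, bands[:, 1], color="tab:green", linewidth=1.5)

    xname, yname = result.method_names
    if ratio:
        ax.set_xlabel(spec.xlabel or f"Geometric mean of {xname} and {yname}")
        ax.set_ylabel(spec.ylabel or f"Ratio {xname} / {yname}")
    else:
        ax.set_xlabel(spec.xlabel or f"Mean of {xname} and {yname}")
        ax.set_ylabel(spec.ylabel or f"Difference {xname} − {yname}")
    if spec.title:
        ax.set_title(spec.title)
    if spec.xlim:
        ax.set_xlim(*spec.xlim)
    if spec.ylim:
        ax.set_ylim(*spec.ylim)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def coverage_plot(grid: CoverageGrid, path=None, logx: bool = False):
    """Two-panel plot of a coverage study: mean effective predictive level
    (left) and effective confidence level of the βγ intervals (right)
    against sample size."""
    if len(grid) == 0:
        raise ValueError("empty coverage grid")
    df = grid.table
    beta = grid.config.beta
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 4.5), sharex=True)

    def _series_label(kind, gamma):
        if kind == "AI":
            return "AI"
        if kind == "PI_bTI":
            return "βTI (PI)"
        tag = "exact" if kind.endswith("exact") else "approx"
        return f"βγTI γ={gamma:.0%} ({tag})"

    for (kind, gamma), sub in df.groupby(["kind", "gamma"], dropna=False):
        sub = sub.sort_values("n")
        lbl = _series_label(kind, gamma)
        ax1.plot(sub["n"], sub["mean_effective_predictive_level"], marker="o", label=lbl)
        if kind.startswith("bgTI"):
            ax2.plot(sub["n"], sub["effective_confidence_level"], marker="o", label=lbl)

    ax1.axhline(beta, color="0.3", linewidth=0.8)
    ax1.set_ylabel("Mean effective predictive level")
    ax2.set_ylabel("Effective confidence level")
    for gamma in grid.config.gammas:
        ax2.axhline(gamma, color="0.8", linewidth=0.8)
    for ax in (ax1, ax2):
        ax.set_xlabel("Sample size n")
        if logx:
            ax.set_xscale("log")
        ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
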