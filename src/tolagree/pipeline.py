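"""Mean-difference (Bland-Altman) analysis pipeline.

Takes paired, possibly replicated, measurements of the same subjects by two
methods, builds the per-subject means M and differences D, computes the
agreement / prediction / tolerance intervals, tests normality of the
differences, and applies the acceptance-interval equivalence rule: the two
methods are declared equivalent only when every requested tolerance interval
lies entirely inside the clinically tolerable band Δ.

Log-normal data are handled by analysing log-transformed measurements and
back-transforming the intervals to the ratio scale, where the plot becomes
geometric means (x) versus ratios (y) and a tolerated relative difference f
maps to the asymmetric ratio band (1 - f, 1/(1 - f)).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .intervals import (
    DifferenceSummary,
    StatInterval,
    agreement_interval,
    agreement_interval_with_cis,
    bg_tolerance_interval,
    prediction_interval,
)

__all__ = [
    "PairedSample",
    "MDData",
    "AcceptanceSpec",
    "MDResult",
    "build_md",
    "analyze",
    "antilog_intervals",
    "acceptance_band",
    "normality_check",
]

logger = logging.getLogger(__name__)

Scale = Literal["raw", "log10", "ln"]
Decision = Literal["equivalent", "not_demonstrated", "not_assessed"]


@dataclass(frozen=True)
class PairedSample:
    """Wide-format paired measurements: one row per subject, one or more
    replicate columns per method."""

    subject_ids: Tuple
    x_values: np.ndarray  # shape (n_subjects, n_replicates_x)
    y_values: np.ndarray  # shape (n_subjects, n_replicates_y)
    method_names: Tuple[str, str] = ("X", "Y")

    def __post_init__(self) -> None:
        x = np.atleast_2d(np.asarray(self.x_values, dtype=float))
        y = np.atleast_2d(np.asarray(self.y_values, dtype=float))
        if x.shape[0] == 1 and len(self.subject_ids) > 1:
            x = x.T
        if y.shape[0] == 1 and len(self.subject_ids) > 1:
            y = y.T
        object.__setattr__(self, "x_values", x)
        object.__setattr__(self, "y_values", y)
        n = len(self.subject_ids)
        if x.shape[0] != n or y.shape[0] != n:
            raise ValueError(
                f"subject count mismatch: {n} ids, {x.shape[0]} X rows, "
                f"{y.shape[0]} Y rows"
            )
        if x.shape[1] < 1 or y.shape[1] < 1:
            raise ValueError("every subject needs at least one replicate per method")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("measurements must be finite (drop incomplete subjects first)")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


@dataclass(frozen=True)
class MDData:
    """Per-subject means M and differences D on the analysis scale.

    On a log scale, antilog(M) are geometric means and antilog(D) are
    X/Y ratios.
    """

    means: np.ndarray
    diffs: np.ndarray
    scale: Scale = "raw"

    def __post_init__(self) -> None:
        if len(self.means) != len(self.diffs):
            raise ValueError("means and diffs must have equal length")


@dataclass(frozen=True)
class AcceptanceSpec:
    """Clinically tolerable band of differences.

    ``delta1`` alone gives a constant band ±Δ.  With ``percent`` the band is
    ±(Δ/100)·M, growing with the mean measure.  With ``threshold`` (and
    ``delta2``) the band is ±delta1 for M strictly below the threshold and
    ±delta2 at or above it.  ``ratio_fraction`` f defines the ratio-scale
    band (1-f, 1/(1-f)) used after a log back-transform.
    """

    delta1: float
    delta2: Optional[float] = None
    threshold: Optional[float] = None
    percent: bool = False
    ratio_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.delta1 <= 0:
            raise ValueError(f"delta1 must be > 0, got {self.delta1}")
        if self.threshold is not None and self.delta2 is None:
            raise ValueError("threshold requires delta2")
        if self.delta2 is not None and self.delta2 <= 0:
            raise ValueError(f"delta2 must be > 0, got {self.delta2}")
        if self.ratio_fraction is not None and not (0 < self.ratio_fraction < 1):
            raise ValueError("ratio_fraction must lie in (0, 1)")

    @property
    def ratio_bounds(self) -> Optional[Tuple[float, float]]:
        if self.ratio_fraction is None:
            return None
        f = self.ratio_fraction
        return (1.0 - f, 1.0 / (1.0 - f))


@dataclass(frozen=True)
class MDResult:
    """Full output of one mean-difference analysis."""

    summary: DifferenceSummary
    intervals: Dict[str, StatInterval]
    md: MDData
    normality_p: Optional[float]
    acceptance: Optional[AcceptanceSpec]
    decision: Decision
    method_names: Tuple[str, str] = ("X", "Y")
    back_transformed: bool = False
    base: Optional[float] = None


# ---------------------------------------------------------------------------

def build_md(sample: PairedSample, transform: Literal["none", "log10", "ln"] = "none") -> MDData:
    """Build the (M, D) data: replicates are averaged per subject per method
    on the analysis scale, then M = (X̄ᵢ + Ȳᵢ)/2 and D = X̄ᵢ - Ȳᵢ."""
    x = sample.x_values
    y = sample.y_values
    if transform != "none":
        bad = np.where((x <= 0).any(axis=1) | (y <= 0).any(axis=1))[0]
        if bad.size:
            ids = [sample.subject_ids[i] for i in bad[:5]]
            raise ValueError(
                f"log transform requires strictly positive measurements; "
                f"offending subject(s): {ids}"
            )
        log = np.log10 if transform == "log10" else np.log
        x, y = log(x), log(y)
    xm = x.mean(axis=1)
    ym = y.mean(axis=1)
    scale: Scale = "raw" if transform == "none" else transform
    return MDData(means=(xm + ym) / 2.0, diffs=xm - ym, scale=scale)


def acceptance_band(spec: AcceptanceSpec, m_value: float) -> Tuple[float, float]:
    """Tolerable-difference band at a given mean measure M."""
    if spec.percent:
        if m_value < 0:
            raise ValueError("percentage acceptance band needs non-negative M")
        h = spec.delta1 / 100.0 * m_value
    elif spec.threshold is not None:
        h = spec.delta1 if m_value < spec.threshold else spec.delta2
    else:
        h = spec.delta1
    return (-h, h)


def normality_check(diffs: Sequence[float]) -> Optional[float]:
    """Shapiro-Wilk p-value on the differences; advisory only.

    Returns None (with a warning) outside the test's 3..5000 size range or
    for a constant vector.
    """
    d = np.asarray(diffs, dtype=float)
    if not (3 <= d.size <= 5000):
        warnings.warn(
            f"Shapiro-Wilk test needs 3..5000 observations, got {d.size}; "
            "normality p-value omitted", UserWarning,
        )
        return None
    if np.ptp(d) == 0.0:
        warnings.warn("differences are constant; normality test undefined", UserWarning)
        return None
    return float(stats.shapiro(d).pvalue)


def _interval_inside_band(
    interval: StatInterval,
    spec: AcceptanceSpec,
    m_values: np.ndarray,
) -> bool:
    """Containment check, pointwise over the observed M range for bands
    that vary with M."""
    for m in np.atleast_1d(m_values):
        lo, hi = acceptance_band(spec, float(m))
        if interval.lower < lo or interval.upper > hi:
            return False
    return True


def _ratio_interval_inside(interval: StatInterval, bounds: Tuple[float, float]) -> bool:
    return bounds[0] <= interval.lower and interval.upper <= bounds[1]


_DECISION_KINDS = ("PI_bTI", "bgTI_exact", "bgTI_approx")


def _decide(
    intervals: Dict[str, StatInterval],
    acceptance: Optional[AcceptanceSpec],
    m_values: np.ndarray,
    ratio_scale: bool = False,
) -> Decision:
    """Equivalence rule: every tolerance interval present among the
    requested kinds must lie wholly inside the acceptance band."""
    if acceptance is None:
        return "not_assessed"
    checked = [iv for kind, iv in intervals.items() if kind in _DECISION_KINDS]
    if not checked:
        return "not_assessed"
    if ratio_scale:
        bounds = acceptance.ratio_bounds
        if bounds is None:
            return "not_assessed"
        ok = all(_ratio_interval_inside(iv, bounds) for iv in checked)
    else:
        ok = all(_interval_inside_band(iv, acceptance, m_values) for iv in checked)
    return "equivalent" if ok else "not_demonstrated"


def analyze(
    sample: PairedSample,
    beta: float = 0.95,
    gamma: Optional[float] = 0.8,
    transform: Literal["none", "log10", "ln"] = "none",
    acceptance: Optional[AcceptanceSpec] = None,
    exact: bool = True,
) -> MDResult:
    """Run the full mean-difference analysis.

    Computes the difference summary on the analysis scale and attaches the
    agreement interval (with and without bound CIs), the prediction /
    β-expectation tolerance interval, and — when ``gamma`` is given — the
    β-γ content tolerance interval (both the closed-form and, if ``exact``,
    the integral-equation factor).  ``gamma=None`` suppresses the βγ
    intervals, leaving the confidence level to be fixed a priori by the
    study objectives.
    """
    if sample.n_subjects < 3:
        raise ValueError(f"need at least 3 subjects, got {sample.n_subjects}")
    md = build_md(sample, transform)
    summary = DifferenceSummary.from_differences(md.diffs)
    intervals: Dict[str, StatInterval] = {
        "AI": agreement_interval(summary, beta),
        "AI_with_CIs": agreement_interval_with_cis(summary, beta),
        "PI_bTI": prediction_interval(summary, beta),
    }
    if gamma is not None:
        intervals["bgTI_approx"] = bg_tolerance_interval(summary, beta, gamma, "bg_approx")
        if exact:
            intervals["bgTI_exact"] = bg_tolerance_interval(summary, beta, gamma, "bg_exact")
    normality_p = normality_check(md.diffs)
    if md.scale != "raw" and acceptance is not None and acceptance.ratio_fraction is None:
        warnings.warn(
            "an absolute acceptance band is not meaningful on a log scale; "
            "supply ratio_fraction and back-transform instead", UserWarning,
        )
    decision = (
        _decide(intervals, acceptance, md.means)
        if md.scale == "raw"
        else "not_assessed"
    )
    corr = float(np.corrcoef(md.means, md.diffs)[0, 1]) if summary.sd_diff > 0 and np.ptp(md.means) > 0 else 0.0
    if abs(corr) > 0.7:
        logger.warning(
            "strong trend between means and differences (r=%.2f): horizontal "
            "tolerance limits may be inappropriate; consider a regression approach",
            corr,
        )
    return MDResult(
        summary=summary, intervals=intervals, md=md, normality_p=normality_p,
        acceptance=acceptance, decision=decision, method_names=sample.method_names,
    )


def antilog_intervals(result: MDResult, base: Literal[10, "e"] = 10) -> MDResult:
    """Back-transform a log-scale analysis to the ratio scale.

    Every interval bound b becomes base**b, centers become geometric-mean
    ratios, and the equivalence decision is re-evaluated against the ratio
    acceptance band (1-f, 1/(1-f)) when a tolerated relative difference f
    was supplied.
    """
    if result.md.scale == "raw":
        raise ValueError("antilog_intervals needs a result computed on a log scale")
    if result.back_transformed:
        raise ValueError("result is already back-transformed")
    expected = 10 if result.md.scale == "log10" else "e"
    if base != expected:
        raise ValueError(
            f"scale {result.md.scale!r} requires base {expected!r}, got {base!r}"
        )
    b = 10.0 if base == 10 else math.e
    fn = lambda v: b ** v
    intervals = {kind: iv.transform_bounds(fn) for kind, iv in result.intervals.items()}
    decision = _decide(intervals, result.acceptance, result.md.means, ratio_scale=True)
    return replace(
        result, intervals=intervals, decision=decision,
        back_transformed=True, base=b,
    )
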