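"""Statistical intervals on paired-method differences.

Every interval here describes the distribution of differences D = X - Y
between two measurement methods, summarised by the sample size ``n``, the
mean difference ``D̄`` and the sample standard deviation ``S`` (divisor
n - 1).  Four interval families are provided:

* the classic Bland-Altman *agreement interval* D̄ ± z_{(1+β)/2}·S, an
  approximate (too narrow) description of the central β mass of D;
* the same interval with a confidence interval wrapped around each bound;
* the exact *prediction interval* / β-expectation tolerance interval
  D̄ ± t_{(1+β)/2, n-1}·S·√(1 + 1/n), which contains on average a
  proportion β of future differences at every n;
* the *β-γ content tolerance interval* D̄ ± k·S, which contains at least a
  proportion β of the differences with confidence γ.  The multiplier k is
  available both in closed form (a first-order approximation built from a
  χ² lower confidence bound on the variance) and as the exact solution of
  a one-dimensional integral equation over the noncentral χ² distribution.

All levels are two-sided and cumulative-from-left: a content level β uses
the (1+β)/2 quantile of the reference distribution.
"""

from __future__ import annotations

import functools
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence, Tuple

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "DifferenceSummary",
    "ToleranceFactor",
    "StatInterval",
    "normal_quantile",
    "t_quantile",
    "chisq_quantile",
    "agreement_interval",
    "agreement_interval_with_cis",
    "prediction_interval",
    "bg_tolerance_factor_approx",
    "bg_tolerance_factor_exact",
    "bg_confidence_of_k",
    "bg_tolerance_interval",
    "bootstrap_t_prediction_interval",
    "sidak_adjust",
]

IntervalKind = Literal[
    "AI", "AI_with_CIs", "PI_bTI", "bgTI_approx", "bgTI_exact", "bootstrap_t_PI"
]


@dataclass(frozen=True)
class DifferenceSummary:
    """Sufficient statistics of the paired differences.

    Parameters
    ----------
    n : int
        Number of subjects (paired differences), at least 2.
    mean_diff : float
        D̄, the mean of the differences, in measurement units.
    sd_diff : float
        S, the sample standard deviation of the differences (divisor n-1).
    """

    n: int
    mean_diff: float
    sd_diff: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"need at least 2 subjects, got n={self.n}")
        if self.sd_diff < 0:
            raise ValueError(f"sd_diff must be >= 0, got {self.sd_diff}")
        if not (np.isfinite(self.mean_diff) and np.isfinite(self.sd_diff)):
            raise ValueError("mean_diff and sd_diff must be finite")

    @classmethod
    def from_differences(cls, diffs: Sequence[float]) -> "DifferenceSummary":
        d = np.asarray(diffs, dtype=float)
        if d.ndim != 1 or d.size < 2:
            raise ValueError("need a 1-d vector of at least 2 differences")
        if not np.all(np.isfinite(d)):
            raise ValueError("differences must be finite")
        return cls(n=int(d.size), mean_diff=float(d.mean()),
                   sd_diff=float(d.std(ddof=1)))


@dataclass(frozen=True)
class ToleranceFactor:
    """Multiplier k of S such that D̄ ± k·S meets a content/confidence goal."""

    n: int
    beta: float
    gamma: Optional[float]
    k: float
    method: Literal["agreement", "beta_expectation", "bg_approx", "bg_exact"]


@dataclass(frozen=True)
class StatInterval:
    """A computed two-sided interval on the difference scale.

    ``ci_lower_bound``/``ci_upper_bound`` are only populated for the
    agreement interval with confidence intervals around each bound (six
    values total).  ``extras`` carries method-specific diagnostics such as
    the bootstrap skip count.
    """

    kind: IntervalKind
    beta: float
    lower: float
    upper: float
    center: float
    gamma: Optional[float] = None
    ci_lower_bound: Optional[Tuple[float, float]] = None
    ci_upper_bound: Optional[Tuple[float, float]] = None
    extras: dict = field(default_factory=dict)

    @property
    def width(self) -> float:
        return self.upper - self.lower

    @property
    def half_width(self) -> float:
        return 0.5 * (self.upper - self.lower)

    def transform_bounds(self, fn) -> "StatInterval":
        """Return a copy with ``fn`` applied to every bound and the center."""
        return replace(
            self,
            lower=fn(self.lower),
            upper=fn(self.upper),
            center=fn(self.center),
            ci_lower_bound=None if self.ci_lower_bound is None
            else (fn(self.ci_lower_bound[0]), fn(self.ci_lower_bound[1])),
            ci_upper_bound=None if self.ci_upper_bound is None
            else (fn(self.ci_upper_bound[0]), fn(self.ci_upper_bound[1])),
        )


# ---------------------------------------------------------------------------
# quantiles

def _check_prob(p: float, name: str = "p") -> None:
    if not (0.0 < p < 1.0):
        raise ValueError(f"{name} must lie strictly in (0, 1), got {p}")


def normal_quantile(p: float) -> float:
    """Standard-normal quantile z_p (cumulative from the left)."""
    _check_prob(p)
    return float(stats.norm.ppf(p))


def t_quantile(p: float, df: float) -> float:
    """Student-t quantile t_{p, df}."""
    _check_prob(p)
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return float(stats.t.ppf(p, df))


def chisq_quantile(p: float, df: float) -> float:
    """Central chi-square quantile χ²_{p, df}."""
    _check_prob(p)
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return float(stats.chi2.ppf(p, df))


# ---------------------------------------------------------------------------
# agreement / prediction intervals

def _warn_if_degenerate(summary: DifferenceSummary) -> None:
    if summary.sd_diff == 0.0:
        warnings.warn(
            "sd_diff is 0: interval degenerates to the single point D̄",
            UserWarning,
            stacklevel=3,
        )


def agreement_interval(summary: DifferenceSummary, beta: float = 0.95) -> StatInterval:
    """Bland-Altman agreement interval D̄ ± z_{(1+β)/2}·S.

    Approximate: it ignores the sampling error of D̄ and S and is too
    narrow at small n.
    """
    _check_prob(beta, "beta")
    _warn_if_degenerate(summary)
    z = normal_quantile((1.0 + beta) / 2.0)
    h = z * summary.sd_diff
    return StatInterval(
        kind="AI", beta=beta, center=summary.mean_diff,
        lower=summary.mean_diff - h, upper=summary.mean_diff + h,
    )


def agreement_interval_with_cis(
    summary: DifferenceSummary, beta: float = 0.95, conf: float = 0.95
) -> StatInterval:
    """Agreement interval with a confidence interval around each bound.

    Each AI bound D̄ ± z·S is wrapped by
    ± t_{(1+conf)/2, n-1} · S · √(1/n + z²/(2(n-1))), giving six values.
    """
    _check_prob(beta, "beta")
    _check_prob(conf, "conf")
    _warn_if_degenerate(summary)
    n, dbar, s = summary.n, summary.mean_diff, summary.sd_diff
    z = normal_quantile((1.0 + beta) / 2.0)
    t = t_quantile((1.0 + conf) / 2.0, n - 1)
    h = z * s
    ci_h = t * s * math.sqrt(1.0 / n + z * z / (2.0 * (n - 1)))
    lo, up = dbar - h, dbar + h
    return StatInterval(
        kind="AI_with_CIs", beta=beta, gamma=conf, center=dbar,
        lower=lo, upper=up,
        ci_lower_bound=(lo - ci_h, lo + ci_h),
        ci_upper_bound=(up - ci_h, up + ci_h),
    )


def prediction_interval(summary: DifferenceSummary, beta: float = 0.95) -> StatInterval:
    """Prediction interval / β-expectation tolerance interval.

    D̄ ± t_{(1+β)/2, n-1} · S · √(1 + 1/n).  Exact at every sample size:
    it contains on average exactly a proportion β of future differences.
    """
    _check_prob(beta, "beta")
    _warn_if_degenerate(summary)
    n, dbar, s = summary.n, summary.mean_diff, summary.sd_diff
    h = t_quantile((1.0 + beta) / 2.0, n - 1) * s * math.sqrt(1.0 + 1.0 / n)
    return StatInterval(
        kind="PI_bTI", beta=beta, center=dbar, lower=dbar - h, upper=dbar + h
    )


# ---------------------------------------------------------------------------
# beta-gamma content tolerance factors

def bg_tolerance_factor_approx(n: int, beta: float = 0.95, gamma: float = 0.8) -> ToleranceFactor:
    """Closed-form β-γ content tolerance factor.

    k = z_{(1+β)/2} · √(1 + 1/n) · √((n-1) / χ²_{1-γ, n-1}); the χ² term
    replaces S by the upper bound of its one-sided γ confidence interval.
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    _check_prob(beta, "beta")
    _check_prob(gamma, "gamma")
    z = normal_quantile((1.0 + beta) / 2.0)
    k = z * math.sqrt(1.0 + 1.0 / n) * math.sqrt((n - 1) / chisq_quantile(1.0 - gamma, n - 1))
    return ToleranceFactor(n=n, beta=beta, gamma=gamma, k=k, method="bg_approx")


_GL_NODES = 128
_U_MAX = 12.0  # half-normal mass beyond 12 is ~2e-33


@functools.lru_cache(maxsize=512)
def _exact_nodes(n: int, beta: float):
    """Quadrature nodes for the exact-k integral, after u = √n·z.

    Returns (u nodes, GL weights, noncentral-χ² quantiles χ²_{1,β,u²/n}),
    all independent of k so a root search reuses them.
    """
    x, w = leggauss(_GL_NODES)
    u = 0.5 * _U_MAX * (x + 1.0)
    w = 0.5 * _U_MAX * w
    ncq = stats.ncx2.ppf(beta, 1, u * u / n)
    return u, w, ncq


def _confidence_from_nodes(k: float, n: int, u, w, ncq) -> float:
    vals = stats.chi2.sf((n - 1) * ncq / (k * k), n - 1) * np.exp(-0.5 * u * u)
    return math.sqrt(2.0 / math.pi) * float(np.sum(w * vals))


def bg_confidence_of_k(n: int, beta: float, k: float) -> float:
    """Achieved confidence γ of the factor k: the probability, over repeated
    samples of size n, that D̄ ± k·S contains at least a proportion β of the
    normal difference distribution.

    Evaluates √(2n/π)·∫₀^∞ P(χ²_{n-1} > (n-1)·χ²_{1,β,z²}/k²)·e^{-nz²/2} dz
    by Gauss-Legendre quadrature after the substitution u = √n·z.
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    _check_prob(beta, "beta")
    if k <= 0:
        raise ValueError(f"k must be > 0, got {k}")
    u, w, ncq = _exact_nodes(n, beta)
    return _confidence_from_nodes(k, n, u, w, ncq)


def bg_tolerance_factor_exact(
    n: int, beta: float = 0.95, gamma: float = 0.8, rtol: float = 1e-10
) -> ToleranceFactor:
    """Exact two-sided β-γ content tolerance factor.

    Solves the integral equation ``bg_confidence_of_k(n, beta, k) = gamma``
    for k by bracketed root-finding seeded at the closed-form approximation.

    Raises
    ------
    RuntimeError
        If a sign-changing bracket cannot be found (diagnostics included).
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    _check_prob(beta, "beta")
    _check_prob(gamma, "gamma")
    u, w, ncq = _exact_nodes(n, beta)

    def resid(k: float) -> float:
        return _confidence_from_nodes(k, n, u, w, ncq) - gamma

    k0 = bg_tolerance_factor_approx(n, beta, gamma).k
    lo, hi = 0.8 * k0, 1.3 * k0
    for _ in range(60):  # confidence is increasing in k, so expand outward
        if resid(lo) < 0.0 < resid(hi):
            break
        if resid(lo) >= 0.0:
            lo *= 0.5
        if resid(hi) <= 0.0:
            hi *= 2.0
    else:
        raise RuntimeError(
            f"could not bracket the exact tolerance factor: n={n}, beta={beta}, "
            f"gamma={gamma}, bracket=({lo:.4g}, {hi:.4g}), "
            f"residuals=({resid(lo):.4g}, {resid(hi):.4g})"
        )
    k = brentq(resid, lo, hi, xtol=1e-12, rtol=rtol)
    return ToleranceFactor(n=n, beta=beta, gamma=gamma, k=float(k), method="bg_exact")


def bg_tolerance_interval(
    summary: DifferenceSummary,
    beta: float = 0.95,
    gamma: float = 0.8,
    method: Literal["bg_approx", "bg_exact"] = "bg_exact",
) -> StatInterval:
    """β-γ content tolerance interval D̄ ± k·S.

    Contains at least a proportion β of the differences with confidence γ;
    the higher γ, the larger the interval.
    """
    if method == "bg_approx":
        factor = bg_tolerance_factor_approx(summary.n, beta, gamma)
        kind: IntervalKind = "bgTI_approx"
    elif method == "bg_exact":
        factor = bg_tolerance_factor_exact(summary.n, beta, gamma)
        kind = "bgTI_exact"
    else:
        raise ValueError(f"unknown method {method!r}")
    _warn_if_degenerate(summary)
    h = factor.k * summary.sd_diff
    return StatInterval(
        kind=kind, beta=beta, gamma=gamma, center=summary.mean_diff,
        lower=summary.mean_diff - h, upper=summary.mean_diff + h,
        extras={"k": factor.k},
    )


# ---------------------------------------------------------------------------
# bootstrap-t prediction interval

def bootstrap_t_prediction_interval(
    diffs: Sequence[float],
    beta: float = 0.95,
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> StatInterval:
    """Bootstrap-t prediction interval on the differences.

    Resamples the raw differences with replacement.  Each bootstrap
    iteration mimics the prediction pivot of the analytic interval, whose
    exact distribution is t_{n-1}: from the pseudo-sample's mean D̄* and
    standard deviation S*, together with one further resampled "future"
    difference d*, the pivotal root r = (d* - D̄*) / (S*·√(1 + 1/n)) is
    formed, and the t-quantiles of the analytic interval are replaced by
    the empirical ((1-β)/2, (1+β)/2) quantiles of r.  Resamples with zero
    standard deviation are skipped; the skip count is reported in
    ``extras``.  Coverage runs slightly below nominal at small n.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 3:
        raise ValueError("need at least 3 differences for the bootstrap")
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    _check_prob(beta, "beta")
    n = d.size
    dbar = float(d.mean())
    s = float(d.std(ddof=1))
    scale = math.sqrt(1.0 + 1.0 / n)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    future = d[rng.integers(0, n, size=n_boot)]
    boot = d[idx]
    bmeans = boot.mean(axis=1)
    bsds = boot.std(ddof=1, axis=1)
    ok = bsds > 0.0
    n_skipped = int(n_boot - ok.sum())
    if ok.sum() < 10:
        raise ValueError("nearly all bootstrap resamples were degenerate")
    r = (future[ok] - bmeans[ok]) / (bsds[ok] * scale)
    q_lo, q_hi = np.quantile(r, [(1.0 - beta) / 2.0, (1.0 + beta) / 2.0])
    return StatInterval(
        kind="bootstrap_t_PI", beta=beta, center=dbar,
        lower=dbar + float(q_lo) * s * scale,
        upper=dbar + float(q_hi) * s * scale,
        extras={"n_boot": n_boot, "n_skipped": n_skipped, "seed": seed},
    )


def sidak_adjust(overall_gamma: float, m: int) -> float:
    """Per-comparison confidence level γ^(1/m) giving simultaneous
    confidence γ across m independent tolerance intervals."""
    _check_prob(overall_gamma, "overall_gamma")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return overall_gamma ** (1.0 / m)
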