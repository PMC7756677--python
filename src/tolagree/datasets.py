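"""Synthetic paired-measurement fixtures.

The generator emulates an unreplicated method-comparison experiment: each
subject has a true value drawn around a base level; device Y reads the
truth, device X reads the truth plus a systematic bias plus Gaussian
measurement noise, so the paired differences are Normal(bias, sd_diff).
``calibrate_to_summary`` then pins the sample's difference mean and SD to
exact target values, which lets a worked example be driven by printed
summary statistics when the raw data are unavailable.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .intervals import DifferenceSummary
from .pipeline import PairedSample

__all__ = ["generate_fixture", "calibrate_to_summary", "lognormal_fixture"]


def generate_fixture(
    n: int,
    true_bias: float = 0.0,
    sd_diff: float = 1.0,
    base_level: float = 10.0,
    between_subject_sd: float = 1.0,
    seed: Optional[int] = None,
    method_names: tuple = ("X", "Y"),
) -> PairedSample:
    """Simulate an unreplicated paired sample with known difference law.

    Differences X - Y are exactly Normal(true_bias, sd_diff); with
    ``sd_diff=0`` every difference equals the bias.
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    if sd_diff < 0:
        raise ValueError("sd_diff must be >= 0")
    rng = np.random.default_rng(seed)
    truth = base_level + between_subject_sd * rng.standard_normal(n)
    noise = sd_diff * rng.standard_normal(n) if sd_diff > 0 else np.zeros(n)
    y = truth
    x = truth + true_bias + noise
    return PairedSample(
        subject_ids=tuple(range(1, n + 1)),
        x_values=x[:, None], y_values=y[:, None], method_names=method_names,
    )


def calibrate_to_summary(
    sample: PairedSample, target_mean: float, target_sd: float
) -> PairedSample:
    """Affinely rescale the difference component so the sample's differences
    have exactly the target mean and SD (divisor n-1).

    Only the differences are adjusted (via X); the per-subject means move by
    half the difference adjustment.  Idempotent: calibrating twice with the
    same targets is a no-op.
    """
    if sample.x_values.shape[1] != 1 or sample.y_values.shape[1] != 1:
        raise ValueError("calibration requires a single-replicate sample")
    if target_sd < 0:
        raise ValueError("target_sd must be >= 0")
    x = sample.x_values[:, 0]
    y = sample.y_values[:, 0]
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot calibrate a sample with zero difference spread")
    d_new = target_mean + (d - d.mean()) * (target_sd / sd)
    return PairedSample(
        subject_ids=sample.subject_ids,
        x_values=(y + d_new)[:, None],
        y_values=y[:, None],
        method_names=sample.method_names,
    )


def lognormal_fixture(
    n: int,
    log10_bias: float = 0.0,
    log10_sd: float = 0.3,
    base_log10_level: float = 0.0,
    between_subject_sd: float = 0.8,
    seed: Optional[int] = None,
    method_names: tuple = ("X", "Y"),
) -> PairedSample:
    """Paired sample whose log10 differences are exactly Normal: the ratio
    X/Y is log-normal, as for assay data spanning orders of magnitude."""
    base = generate_fixture(
        n, true_bias=log10_bias, sd_diff=log10_sd,
        base_level=base_log10_level, between_subject_sd=between_subject_sd,
        seed=seed, method_names=method_names,
    )
    return PairedSample(
        subject_ids=base.subject_ids,
        x_values=10.0 ** base.x_values,
        y_values=10.0 ** base.y_values,
        method_names=method_names,
    )
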