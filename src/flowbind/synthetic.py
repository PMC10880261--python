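"""Synthetic assay generation with known ground truth.

Stands in for instrument output: the forward chamber model provides the
expected counts per 1-min channel and Poisson noise is drawn on top —
the physical noise model for gamma counting; no additional electronics
noise is simulated.  Defaults follow the prototype's operating point
(0.5 ug/mL ligand, 100 kBq/ug, 3.2 mL/h, 3 h uptake + 2 h washout) and
the batch sampler draws truths spanning the range of kinetic constants
observed across the 17 reproducibility runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .chamber import predict_channel_signals
from .core import (
    AssayConfig,
    DetectorCalib,
    InvalidParameterError,
    KineticParams,
    TimeActivityCurve,
)

#: Ranges spanned by the fitted constants of the 17 application runs;
#: the default truth sampler draws within them.
KON_RANGE = (3.18e4, 7.94e4)  # M^-1 s^-1
KOFF_RANGE = (0.11e-5, 4.2e-5)  # s^-1
NAR_RANGE = (0.3e12, 2.2e12)  # molecules


@dataclass(frozen=True)
class SyntheticAssay:
    """One generated assay: configuration, calibration, truth, and curve."""

    config: AssayConfig
    calib: DetectorCalib
    truth: KineticParams
    curve: TimeActivityCurve
    seed: int


def generate_curve(
    config: AssayConfig,
    calib: DetectorCalib,
    params: KineticParams,
    seed: int | np.random.Generator,
    n_channels: int | None = None,
) -> TimeActivityCurve:
    """Draw one Poisson time-activity curve from the forward model.

    Channel means are exact integrals of the observed (dead-time-distorted,
    background-included) rate over each channel; counts are Poisson with
    those means, reproducible bit-exactly from the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sig = predict_channel_signals(config, calib, params, n_channels=n_channels)
    counts = rng.poisson(sig.observed_counts)
    return TimeActivityCurve(sig.channel_start_s, counts, sig.channel_width_s)


def expected_curve(
    config: AssayConfig,
    calib: DetectorCalib,
    params: KineticParams,
    n_channels: int | None = None,
) -> TimeActivityCurve:
    """Noise-free curve carrying the expected (real-valued) channel counts."""
    sig = predict_channel_signals(config, calib, params, n_channels=n_channels)
    return TimeActivityCurve(sig.channel_start_s, sig.observed_counts, sig.channel_width_s)


def scale_for_peak_rate(
    config: AssayConfig,
    calib: DetectorCalib,
    params: KineticParams,
    target_peak_observed_cps: float,
) -> AssayConfig:
    """Return a config whose specific activity puts the peak observed
    channel rate at the target.

    The true rate is linear in specific activity while binding kinetics
    are unaffected by it, so the scaling is exact: the target observed
    rate is converted through the dead-time model to a target true rate,
    and the specific activity scaled by the ratio to the current peak.
    """
    from dataclasses import replace

    if target_peak_observed_cps <= 0:
        raise InvalidParameterError("target peak rate must be > 0")
    if calib.dead_time_s * target_peak_observed_cps >= 1.0:
        raise InvalidParameterError("target observed rate is beyond detector saturation")
    sig = predict_channel_signals(config, calib, params)
    peak_true = float(np.max(sig.true_counts)) / config.channel_width_s
    target_true = target_peak_observed_cps / (
        1.0 - target_peak_observed_cps * calib.dead_time_s
    )
    return replace(
        config,
        specific_activity_kBq_ug=config.specific_activity_kBq_ug * target_true / peak_true,
    )


def default_truth_sampler(rng: np.random.Generator) -> KineticParams:
    """Draw one ground truth: log-uniform rate constants over the observed
    ranges, uniform antigen number."""
    k_on = float(np.exp(rng.uniform(np.log(KON_RANGE[0]), np.log(KON_RANGE[1]))))
    k_off = float(np.exp(rng.uniform(np.log(KOFF_RANGE[0]), np.log(KOFF_RANGE[1]))))
    n_ar = float(rng.uniform(*NAR_RANGE))
    return KineticParams(k_on=k_on, k_off=k_off, n_antigens_total=n_ar)


def generate_batch(
    n_assays: int,
    seed: int,
    config: AssayConfig | None = None,
    calib: DetectorCalib | None = None,
    truth_sampler: Callable[[np.random.Generator], KineticParams] | None = None,
) -> list[SyntheticAssay]:
    """Generate ``n_assays`` independent assays with per-assay truths.

    Each assay receives its own integer sub-seed (derived from ``seed``
    via a seed sequence), so any single assay is reproducible from its
    recorded seed alone.
    """
    if n_assays < 1:
        raise InvalidParameterError(f"n_assays must be >= 1, got {n_assays}")
    config = config or AssayConfig()
    calib = calib or DetectorCalib()
    sampler = truth_sampler or default_truth_sampler
    child_seeds = np.random.SeedSequence(seed).generate_state(n_assays)
    out = []
    for s in child_seeds:
        s = int(s)
        rng = np.random.default_rng(s)
        truth = sampler(rng)
        curve = generate_curve(config, calib, truth, rng)
        out.append(SyntheticAssay(config=config, calib=calib, truth=truth, curve=curve, seed=s))
    return out


def generate_lindmo_series(
    irf_true: float,
    antigen_excess_levels: Sequence[float] = (2.0, 4.0, 8.0, 16.0, 32.0),
    seed: int | None = 0,
    total_counts: float = 20_000.0,
    half_saturation_excess: float = 1.0,
) -> pd.DataFrame:
    """Dilution series for the immunoreactive-fraction extrapolation assay.

    At antigen excess x the bound/total fraction follows the saturation
    form B/T = irf / (1 + c/x) with c = ``half_saturation_excess``; the
    immunoreactive fraction is the extrapolation to infinite excess.
    ``seed=None`` returns the noise-free fractions; otherwise bound counts
    are Poisson around ``total_counts`` * fraction.
    """
    if not (0.0 < irf_true <= 1.0):
        raise InvalidParameterError(f"irf_true must be in (0, 1], got {irf_true}")
    x = np.asarray(antigen_excess_levels, dtype=float)
    if x.size < 3 or np.any(x <= 0) or np.unique(x).size != x.size:
        raise InvalidParameterError("need >= 3 distinct positive antigen-excess levels")
    frac = irf_true / (1.0 + half_saturation_excess / x)
    if seed is None:
        bound = total_counts * frac
    else:
        rng = np.random.default_rng(seed)
        bound = rng.poisson(total_counts * frac).astype(float)
        bound = np.maximum(bound, 1.0)  # guard the ratio
    return pd.DataFrame(
        {
            "antigen_excess": x,
            "inverse_excess": 1.0 / x,
            "total_counts": np.full_like(x, float(total_counts)),
            "bound_counts": bound,
            "total_over_bound": total_counts / bound,
        }
    )


__all__ = [
    "KOFF_RANGE",
    "KON_RANGE",
    "NAR_RANGE",
    "SyntheticAssay",
    "default_truth_sampler",
    "expected_curve",
    "generate_batch",
    "generate_curve",
    "generate_lindmo_series",
    "scale_for_peak_rate",
]
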