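"""Batch summaries, immunoreactive fraction, and antigens-per-cell arithmetic.

Summaries follow the conventions of the published reproducibility table:
sample standard deviation (n-1), coefficient of variation in percent,
median as the midpoint of the middle two values, and — crucially — k_off
statistics computed over the assays where k_off was actually estimated,
excluding imputed values (including them would shift the mean toward the
fallback).  Display scalings are 1e3 M^-1 s^-1 for k_on, 1e-5 s^-1 for
k_off and 1e6 per cell for B_max, with the table's rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

from .core import AVOGADRO, InvalidParameterError, activity_to_moles


class NonEstimableError(ValueError):
    """The requested quantity cannot be estimated from the given data."""


@dataclass(frozen=True)
class ParamStats:
    n_used: int
    mean: float
    sd: float
    cv_percent: float
    median: float


@dataclass(frozen=True)
class BatchSummary:
    """Per-parameter statistics over a batch of fits."""

    k_on: ParamStats
    k_off: ParamStats | None
    b_max_per_cell: ParamStats
    n_assays: int
    n_koff_imputed: int
    koff_policy: str


def _stats(values: np.ndarray) -> ParamStats:
    n = values.size
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    cv = 100.0 * sd / mean if mean != 0 else math.inf
    return ParamStats(n_used=n, mean=mean, sd=sd, cv_percent=cv, median=float(np.median(values)))


def _extract(r: Any) -> tuple[float, float, float, bool]:
    if isinstance(r, Mapping):
        return (
            float(r["k_on"]),
            float(r["k_off"]),
            float(r["b_max_per_cell"]),
            bool(r.get("koff_imputed", False)),
        )
    k_on = r.params.k_on if hasattr(r, "params") else r.k_on
    k_off = r.params.k_off if hasattr(r, "params") else r.k_off
    return (
        float(k_on),
        float(k_off),
        float(r.b_max_per_cell),
        bool(getattr(r, "koff_imputed", False)),
    )


def summarize_batch(results: Iterable[Any], include_imputed_koff: bool = False) -> BatchSummary:
    """Mean / SD / CV / median per parameter over a batch of fit results.

    ``results`` may be ``FitResult`` objects or mappings with keys
    ``k_on``, ``k_off``, ``b_max_per_cell`` and optional ``koff_imputed``.
    k_off statistics cover non-imputed fits only unless
    ``include_imputed_koff`` is set.
    """
    rows = [_extract(r) for r in results]
    if not rows:
        raise InvalidParameterError("summarize_batch requires at least one result")
    k_on = np.array([r[0] for r in rows])
    b_max = np.array([r[2] for r in rows])
    if include_imputed_koff:
        k_off = np.array([r[1] for r in rows])
        policy = "all values (imputed included)"
    else:
        k_off = np.array([r[1] for r in rows if not r[3]])
        policy = "estimated values only (imputed excluded)"
    return BatchSummary(
        k_on=_stats(k_on),
        k_off=_stats(k_off) if k_off.size else None,
        b_max_per_cell=_stats(b_max),
        n_assays=len(rows),
        n_koff_imputed=sum(1 for r in rows if r[3]),
        koff_policy=policy,
    )


def format_summary(summary: BatchSummary) -> str:
    """Render the summary in the display units and rounding of the
    reproducibility table (k_on x1e3, k_off x1e-5, B_max x1e6)."""

    lines = [
        "parameter           k_on(x1e3)  k_off(x1e-5)  B_max(x1e6)",
    ]
    koff = summary.k_off

    def fmt(stat_name: str, spec_kon: str, spec_koff: str, spec_b: str) -> str:
        a = getattr(summary.k_on, stat_name)
        b = getattr(koff, stat_name) if koff is not None else None
        c = getattr(summary.b_max_per_cell, stat_name)
        sa = format(a / 1e3, spec_kon)
        sb = format(b / 1e-5, spec_koff) if b is not None else "n/a"
        sc = format(c / 1e6, spec_b)
        return f"{stat_name:<20}{sa:>10}{sb:>14}{sc:>13}"

    lines.append(fmt("mean", ".1f", ".2f", ".2f"))
    lines.append(fmt("sd", ".1f", ".2f", ".2f"))
    cv_koff = f"{koff.cv_percent:.0f}" if koff is not None else "n/a"
    lines.append(
        f"{'cv_percent':<20}{summary.k_on.cv_percent:>10.0f}{cv_koff:>14}"
        f"{summary.b_max_per_cell.cv_percent:>13.0f}"
    )
    lines.append(fmt("median", ".1f", ".2f", ".2f"))
    n_koff = koff.n_used if koff is not None else 0
    lines.append(
        f"{'n_used':<20}{summary.k_on.n_used:>10d}{n_koff:>14d}"
        f"{summary.b_max_per_cell.n_used:>13d}"
    )
    lines.append(
        f"k_off policy: {summary.koff_policy} "
        f"({summary.n_koff_imputed}/{summary.n_assays} imputed)"
    )
    return "\n".join(lines)


@dataclass(frozen=True)
class IrfEstimate:
    """Immunoreactive fraction by linear extrapolation to infinite excess."""

    irf: float
    intercept: float
    slope: float
    out_of_range: bool


def lindmo_irf(
    inverse_excess: Sequence[float], total_over_bound: Sequence[float]
) -> IrfEstimate:
    """Immunoreactive fraction from a dilution series.

    Ordinary least squares of total/bound against inverse antigen excess;
    the intercept at infinite excess (x -> 0) is 1/IRF.  Estimates above 1
    are clipped to 1 and flagged; a non-positive intercept raises.
    """
    x = np.asarray(inverse_excess, dtype=float)
    y = np.asarray(total_over_bound, dtype=float)
    if x.size < 3 or x.shape != y.shape:
        raise InvalidParameterError("need >= 3 paired points")
    if np.any(x <= 0) or np.unique(x).size != x.size:
        raise InvalidParameterError("inverse excess values must be positive and distinct")
    slope, intercept = np.polyfit(x, y, 1)
    if intercept <= 0:
        raise NonEstimableError(
            f"non-positive intercept ({intercept:.4g}); series does not extrapolate "
            "to a valid immunoreactive fraction"
        )
    irf = 1.0 / float(intercept)
    out_of_range = irf > 1.0
    return IrfEstimate(
        irf=min(irf, 1.0),
        intercept=float(intercept),
        slope=float(slope),
        out_of_range=out_of_range,
    )


def saturation_antigens_per_cell(
    bound_activity_kBq: float,
    specific_activity_kBq_ug: float,
    molar_mass_g_mol: float,
    n_cells: float,
) -> float:
    """Antigens per cell from a saturation assay plateau.

    Converts the plateau cell-bound activity to molecules and divides by
    the number of incubated cells.
    """
    if n_cells <= 0:
        raise InvalidParameterError(f"n_cells must be > 0, got {n_cells}")
    mol = activity_to_moles(bound_activity_kBq, specific_activity_kBq_ug, molar_mass_g_mol)
    return mol * AVOGADRO / n_cells


__all__ = [
    "BatchSummary",
    "IrfEstimate",
    "NonEstimableError",
    "ParamStats",
    "format_summary",
    "lindmo_irf",
    "saturation_antigens_per_cell",
    "summarize_batch",
]
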