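"""Domain types and unit conversions for flow-through radioligand binding assays.

The package models a shallow flow-through cuvette in which tumor cells,
grown as a monolayer on a glass coverslip, are exposed to a continuous
flow of radiolabelled antibody while a shielded gamma detector underneath
records counts in fixed-width time channels.  This module defines the
assay description (flow, geometry, radiochemistry, phase schedule), the
detector calibration, the kinetic parameters that the fitting stage
estimates, and the time-activity-curve container, together with the unit
conversions shared by every downstream stage.

Unit conventions
----------------
Configuration is written in bench units (mL/h for flow, ug/mL for ligand
concentration, kBq/ug for specific activity, seconds for durations);
internal computation uses SI seconds, litres and moles, with kilobecquerel
for activity.  Conversion happens once, at the boundary, through the
helpers in this module; kinetic parameters are always SI
(M^-1 s^-1, s^-1, molecules).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.constants import Avogadro

AVOGADRO = Avogadro
LN2 = math.log(2.0)

#: Molar mass of an IgG antibody such as trastuzumab, g/mol.  Needed to
#: express the association rate constant in molar units; configurable.
DEFAULT_MOLAR_MASS = 148_000.0

SourceName = Literal["radioligand", "blank"]


class InvalidParameterError(ValueError):
    """A physical parameter violates its validity constraints."""


class ConfigError(ValueError):
    """A configuration file or structure is malformed."""


# ---------------------------------------------------------------------------
# conversions


def mass_conc_to_molar(c_ug_per_mL: float, molar_mass_g_mol: float) -> float:
    """Convert a mass concentration (ug/mL) to molarity (mol/L)."""
    if molar_mass_g_mol <= 0:
        raise InvalidParameterError(
            f"molar_mass must be > 0 g/mol, got {molar_mass_g_mol}"
        )
    if c_ug_per_mL < 0:
        raise InvalidParameterError(f"mass concentration must be >= 0, got {c_ug_per_mL}")
    # ug/mL = mg/L = 1e-3 g/L
    return c_ug_per_mL * 1e-3 / molar_mass_g_mol


def molar_to_mass_conc(c_mol_per_L: float, molar_mass_g_mol: float) -> float:
    """Inverse of :func:`mass_conc_to_molar`."""
    if molar_mass_g_mol <= 0:
        raise InvalidParameterError(
            f"molar_mass must be > 0 g/mol, got {molar_mass_g_mol}"
        )
    return c_mol_per_L * molar_mass_g_mol * 1e3


def activity_to_moles(
    a_kBq: float, specific_activity_kBq_ug: float, molar_mass_g_mol: float
) -> float:
    """Convert an activity (kBq) to the molar amount of labelled compound.

    The specific activity ties detected activity to ligand mass; the molar
    mass then gives moles: ``(a / SA) * 1e-6 / M``.
    """
    if specific_activity_kBq_ug <= 0:
        raise InvalidParameterError(
            f"specific_activity must be > 0 kBq/ug, got {specific_activity_kBq_ug}"
        )
    if molar_mass_g_mol <= 0:
        raise InvalidParameterError(
            f"molar_mass must be > 0 g/mol, got {molar_mass_g_mol}"
        )
    if a_kBq < 0:
        raise InvalidParameterError(f"activity must be >= 0 kBq, got {a_kBq}")
    return (a_kBq / specific_activity_kBq_ug) * 1e-6 / molar_mass_g_mol


def moles_to_activity(
    n_mol: float, specific_activity_kBq_ug: float, molar_mass_g_mol: float
) -> float:
    """Inverse of :func:`activity_to_moles`: moles of compound to kBq."""
    if specific_activity_kBq_ug <= 0:
        raise InvalidParameterError(
            f"specific_activity must be > 0 kBq/ug, got {specific_activity_kBq_ug}"
        )
    return n_mol * molar_mass_g_mol * 1e6 * specific_activity_kBq_ug


def decay_factor(t_s: float | np.ndarray, half_life_s: float | None) -> float | np.ndarray:
    """Radioactive decay factor exp(-ln2 * t / T_half); 1.0 if no half-life.

    Decay matters for short-lived alpha emitters (At-211, Bi-213); for
    I-125-length runs of a few hours it is below 0.15% and off by default.
    """
    if half_life_s is None:
        return np.ones_like(t_s, dtype=float) if isinstance(t_s, np.ndarray) else 1.0
    if half_life_s <= 0:
        raise InvalidParameterError(f"half_life must be > 0 s, got {half_life_s}")
    return np.exp(-LN2 * np.asarray(t_s, dtype=float) / half_life_s) if isinstance(
        t_s, np.ndarray
    ) else math.exp(-LN2 * t_s / half_life_s)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Phase:
    """One stage of the inflow schedule: radioligand solution or blank medium."""

    duration_s: float
    source: SourceName

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise InvalidParameterError(f"phase duration must be > 0 s, got {self.duration_s}")
        if self.source not in ("radioligand", "blank"):
            raise InvalidParameterError(
                f"phase source must be 'radioligand' or 'blank', got {self.source!r}"
            )


def _coerce_phases(phases: Iterable) -> tuple[Phase, ...]:
    out = []
    for p in phases:
        if isinstance(p, Phase):
            out.append(p)
        elif isinstance(p, dict):
            out.append(Phase(float(p["duration_s"]), p["source"]))
        else:
            dur, src = p
            out.append(Phase(float(dur), src))
    return tuple(out)


@dataclass(frozen=True)
class AssayConfig:
    """Physical and chemical description of one flow-through binding run.

    Defaults reproduce the prototype's standard operating point: a 0.16 mL
    cuvette (8 x 40 x 0.5 mm), 3.2 mL/h flow, 0.5 ug/mL antibody at
    100 kBq/ug, 1-min counting channels, 3 h of radioligand uptake followed
    by 2 h of ligand-free washout, and one million seeded cells.
    """

    flow_rate_mL_h: float = 3.2
    chamber_volume_mL: float = 0.16
    inflow_mass_conc_ug_mL: float = 0.5
    molar_mass_g_mol: float = DEFAULT_MOLAR_MASS
    specific_activity_kBq_ug: float = 100.0
    irf: float = 0.95
    half_life_s: float | None = None
    phases: tuple[Phase, ...] = (
        Phase(3 * 3600.0, "radioligand"),
        Phase(2 * 3600.0, "blank"),
    )
    channel_width_s: float = 60.0
    n_cells_seeded: float = 1e6
    transport_delay_s: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", _coerce_phases(self.phases))
        bad = []
        for name in (
            "flow_rate_mL_h",
            "chamber_volume_mL",
            "molar_mass_g_mol",
            "specific_activity_kBq_ug",
            "channel_width_s",
            "n_cells_seeded",
        ):
            if getattr(self, name) <= 0:
                bad.append(name)
        if self.inflow_mass_conc_ug_mL < 0:
            bad.append("inflow_mass_conc_ug_mL")
        if not (0.0 < self.irf <= 1.0):
            bad.append("irf")
        if self.transport_delay_s < 0:
            bad.append("transport_delay_s")
        if self.half_life_s is not None and self.half_life_s <= 0:
            bad.append("half_life_s")
        if len(self.phases) == 0:
            bad.append("phases")
        if bad:
            raise InvalidParameterError(f"invalid assay configuration values: {', '.join(bad)}")

    # -- derived SI quantities -------------------------------------------
    @property
    def flow_L_s(self) -> float:
        return self.flow_rate_mL_h * 1e-3 / 3600.0

    @property
    def volume_L(self) -> float:
        return self.chamber_volume_mL * 1e-3

    @property
    def inflow_molar_M(self) -> float:
        """Total inflow ligand concentration (reactive + inert), mol/L."""
        return mass_conc_to_molar(self.inflow_mass_conc_ug_mL, self.molar_mass_g_mol)

    @property
    def activity_per_mol_kBq(self) -> float:
        """kBq per mole of labelled compound at assay start."""
        return moles_to_activity(1.0, self.specific_activity_kBq_ug, self.molar_mass_g_mol)

    @property
    def decay_lambda(self) -> float:
        return 0.0 if self.half_life_s is None else LN2 / self.half_life_s

    @property
    def total_duration_s(self) -> float:
        return sum(p.duration_s for p in self.phases)

    @property
    def n_channels(self) -> int:
        return int(round(self.total_duration_s / self.channel_width_s))

    def uptake_duration_s(self, until: float | None = None) -> float:
        """Total radioligand-inflow time within [0, until]."""
        end = self.total_duration_s if until is None else until
        t, total = 0.0, 0.0
        for p in self.phases:
            lo, hi = t, t + p.duration_s
            if p.source == "radioligand":
                total += max(0.0, min(hi, end) - lo)
            t = hi
        return total

    def washout_duration_s(self, until: float | None = None) -> float:
        """Blank-inflow time after the first radioligand phase, within [0, until]."""
        end = self.total_duration_s if until is None else until
        t, total, seen_uptake = 0.0, 0.0, False
        for p in self.phases:
            lo, hi = t, t + p.duration_s
            if p.source == "radioligand":
                seen_uptake = True
            elif seen_uptake:
                total += max(0.0, min(hi, end) - lo)
            t = hi
        return total


@dataclass(frozen=True)
class DetectorCalib:
    """Gamma-detector calibration for the cuvette geometry.

    ``eff_bound`` converts coverslip-bound activity to count rate
    (cps/kBq); ``eff_solution`` converts the activity concentration of the
    chamber liquid to count rate (cps per kBq/mL).  Dead time is
    non-paralyzable; ``wall_fraction`` is the steady fraction of the
    solution-derived signal contributed by cuvette-wall adsorption
    (calibrated below 2% on the prototype, default 0).
    """

    eff_bound: float = 65.0
    eff_solution: float = 5.1
    dead_time_s: float = 0.0
    background_cps: float = 0.0
    wall_fraction: float = 0.0

    def __post_init__(self) -> None:
        bad = []
        if self.eff_bound <= 0:
            bad.append("eff_bound")
        if self.eff_solution < 0:
            bad.append("eff_solution")
        if self.dead_time_s < 0:
            bad.append("dead_time_s")
        if self.background_cps < 0:
            bad.append("background_cps")
        if not (0.0 <= self.wall_fraction < 1.0):
            bad.append("wall_fraction")
        if bad:
            raise InvalidParameterError(f"invalid detector calibration values: {', '.join(bad)}")


@dataclass(frozen=True)
class KineticParams:
    """The three quantities the fit recovers.

    k_on (M^-1 s^-1) and k_off (s^-1) are the association/dissociation rate
    constants; ``n_antigens_total`` is N_ar, the total number of antigens
    available for binding in the cuvette (molecules).  B_max per cell is
    N_ar divided by the number of seeded cells.
    """

    k_on: float
    k_off: float
    n_antigens_total: float

    def __post_init__(self) -> None:
        bad = []
        if self.k_on <= 0:
            bad.append("k_on")
        if self.k_off < 0:
            bad.append("k_off")
        if self.n_antigens_total < 0:
            bad.append("n_antigens_total")
        if bad:
            raise InvalidParameterError(f"invalid kinetic parameters: {', '.join(bad)}")

    @property
    def r_tot_mol(self) -> float:
        """Total antigen amount in moles."""
        return self.n_antigens_total / AVOGADRO

    @property
    def k_d(self) -> float:
        """Equilibrium dissociation constant k_off / k_on, mol/L."""
        return self.k_off / self.k_on

    def b_max_per_cell(self, n_cells_seeded: float) -> float:
        if n_cells_seeded <= 0:
            raise InvalidParameterError(f"n_cells_seeded must be > 0, got {n_cells_seeded}")
        return self.n_antigens_total / n_cells_seeded


@dataclass(frozen=True)
class TimeActivityCurve:
    """Counts per fixed-width time channel.

    Measured curves carry non-negative integer counts; model-expected
    curves (used for noise-free self-consistency work) may carry real
    values.  ``channel_start_s`` holds channel start times, uniformly
    spaced by ``channel_width_s``, with 0 = acquisition start.
    """

    channel_start_s: np.ndarray
    counts: np.ndarray
    channel_width_s: float

    def __post_init__(self) -> None:
        t = np.asarray(self.channel_start_s, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "channel_start_s", t)
        object.__setattr__(self, "counts", c)
        if self.channel_width_s <= 0:
            raise InvalidParameterError(f"channel_width must be > 0 s, got {self.channel_width_s}")
        if t.ndim != 1 or c.shape != t.shape or t.size == 0:
            raise InvalidParameterError("channel_start and counts must be matching 1-D arrays")
        if np.any(c < 0):
            raise InvalidParameterError("counts must be non-negative")
        if t.size > 1:
            dt = np.diff(t)
            if np.any(dt <= 0) or not np.allclose(dt, self.channel_width_s, rtol=1e-9, atol=1e-6):
                raise InvalidParameterError(
                    "channel_start must be strictly increasing with uniform "
                    f"spacing equal to channel_width ({self.channel_width_s} s)"
                )

    @property
    def n_channels(self) -> int:
        return int(self.channel_start_s.size)

    @property
    def t_mid_s(self) -> np.ndarray:
        return self.channel_start_s + 0.5 * self.channel_width_s

    @property
    def end_s(self) -> float:
        return float(self.channel_start_s[-1] + self.channel_width_s)

    def truncated(self, duration_s: float) -> "TimeActivityCurve":
        """Keep only channels that end at or before ``duration_s``."""
        keep = self.channel_start_s + self.channel_width_s <= duration_s + 1e-9
        if not np.any(keep):
            raise InvalidParameterError("truncation leaves no complete channel")
        return TimeActivityCurve(
            self.channel_start_s[keep], self.counts[keep], self.channel_width_s
        )


__all__ = [
    "AVOGADRO",
    "DEFAULT_MOLAR_MASS",
    "AssayConfig",
    "ConfigError",
    "DetectorCalib",
    "InvalidParameterError",
    "KineticParams",
    "Phase",
    "TimeActivityCurve",
    "activity_to_moles",
    "decay_factor",
    "mass_conc_to_molar",
    "molar_to_mass_conc",
    "moles_to_activity",
    "replace",
]
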