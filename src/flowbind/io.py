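"""File formats: TOML configuration, curve/trajectory CSV, run manifests.

The configuration file mirrors the :class:`~flowbind.core.AssayConfig`
and :class:`~flowbind.core.DetectorCalib` fields in two tables, with
units encoded in the key names::

    [assay]
    flow_rate_mL_h = 3.2
    chamber_volume_mL = 0.16
    inflow_mass_conc_ug_mL = 0.5
    specific_activity_kBq_ug = 100.0
    irf = 0.95
    channel_width_s = 60.0
    n_cells_seeded = 1e6
    phases = [
        { duration_s = 10800, source = "radioligand" },
        { duration_s = 7200, source = "blank" },
    ]

    [detector]
    eff_bound = 65.0
    eff_solution = 5.1
    dead_time_s = 0.0
    background_cps = 0.0
    wall_fraction = 0.0

Validation is strict: unknown keys are rejected with an error listing
them.  Curve CSVs carry a header row with columns ``channel_start_s``
(integer seconds, 0 = acquisition start) and ``counts``.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import tomllib
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .chamber import ChamberTrajectory
from .core import AssayConfig, ConfigError, DetectorCalib, KineticParams, TimeActivityCurve

_ASSAY_FIELDS = {f.name for f in dataclasses.fields(AssayConfig)}
_DETECTOR_FIELDS = {f.name for f in dataclasses.fields(DetectorCalib)}


def load_config(path: str | Path) -> tuple[AssayConfig, DetectorCalib]:
    """Read and validate an assay + detector configuration file."""
    with open(path, "rb") as fh:
        try:
            raw = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"{path}: not valid TOML: {exc}") from exc
    unknown_sections = set(raw) - {"assay", "detector"}
    if unknown_sections:
        raise ConfigError(
            f"{path}: unknown sections: {', '.join(sorted(unknown_sections))} "
            "(expected [assay] and [detector])"
        )
    assay_raw = dict(raw.get("assay", {}))
    det_raw = dict(raw.get("detector", {}))
    bad = sorted(set(assay_raw) - _ASSAY_FIELDS)
    if bad:
        raise ConfigError(f"{path}: unknown [assay] keys: {', '.join(bad)}")
    bad = sorted(set(det_raw) - _DETECTOR_FIELDS)
    if bad:
        raise ConfigError(f"{path}: unknown [detector] keys: {', '.join(bad)}")
    try:
        return AssayConfig(**assay_raw), DetectorCalib(**det_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def write_default_config(path: str | Path) -> None:
    """Write a template configuration with the package defaults."""
    cfg, cal = AssayConfig(), DetectorCalib()
    lines = ["[assay]"]
    for f in dataclasses.fields(AssayConfig):
        v = getattr(cfg, f.name)
        if f.name == "phases":
            items = ", ".join(
                f'{{ duration_s = {p.duration_s:g}, source = "{p.source}" }}' for p in v
            )
            lines.append(f"phases = [ {items} ]")
        elif v is None:
            lines.append(f"# {f.name} omitted (no decay)")
        else:
            lines.append(f"{f.name} = {v!r}" if isinstance(v, str) else f"{f.name} = {v:g}")
    lines.append("")
    lines.append("[detector]")
    for f in dataclasses.fields(DetectorCalib):
        lines.append(f"{f.name} = {getattr(cal, f.name):g}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# curves


def read_curve_csv(path: str | Path, channel_width_s: float | None = None) -> TimeActivityCurve:
    """Read a time-activity curve (columns channel_start_s, counts)."""
    df = pd.read_csv(path)
    missing = {"channel_start_s", "counts"} - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing columns: {', '.join(sorted(missing))}")
    t = df["channel_start_s"].to_numpy(dtype=float)
    if channel_width_s is None:
        if t.size < 2:
            raise ConfigError(f"{path}: cannot infer channel width from one channel")
        channel_width_s = float(t[1] - t[0])
    return TimeActivityCurve(t, df["counts"].to_numpy(dtype=float), channel_width_s)


def write_curve_csv(curve: TimeActivityCurve, path: str | Path) -> None:
    counts = curve.counts
    as_int = np.allclose(counts, np.round(counts))
    pd.DataFrame(
        {
            "channel_start_s": curve.channel_start_s.astype(int)
            if np.allclose(curve.channel_start_s, np.round(curve.channel_start_s))
            else curve.channel_start_s,
            "counts": counts.astype(int) if as_int else counts,
        }
    ).to_csv(path, index=False)


def write_net_curve_csv(net, path: str | Path) -> None:
    """Write a net cell-bound curve (columns t_s, net_counts,
    solution_model_counts)."""
    pd.DataFrame(
        {
            "t_s": net.t_s,
            "net_counts": net.net_counts,
            "solution_model_counts": net.solution_model_counts,
        }
    ).to_csv(path, index=False)


def write_truth_sidecar(curve_path: str | Path, truth: KineticParams, seed: int) -> Path:
    """Ground-truth sidecar for a generated curve (same stem, `.truth`)."""
    p = Path(curve_path).with_suffix(".truth")
    p.write_text(
        json.dumps(
            {
                "k_on_M_s": truth.k_on,
                "k_off_s": truth.k_off,
                "n_antigens_total": truth.n_antigens_total,
                "seed": seed,
            },
            indent=2,
        )
        + "\n"
    )
    return p


def read_truth_sidecar(path: str | Path) -> tuple[KineticParams, int]:
    d = json.loads(Path(path).read_text())
    return (
        KineticParams(d["k_on_M_s"], d["k_off_s"], d["n_antigens_total"]),
        int(d["seed"]),
    )


def write_trajectory_csv(traj: ChamberTrajectory, path: str | Path) -> None:
    pd.DataFrame(
        {
            "t_s": traj.t_s,
            "L_reactive_M": traj.L_reactive_M,
            "L_inert_M": traj.L_inert_M,
            "B_mol": traj.B_mol,
            "A_bound_kBq": traj.A_bound_kBq,
            "C_solution_kBq_per_mL": traj.C_solution_kBq_mL,
            "true_cps": traj.true_cps,
            "observed_cps": traj.observed_cps,
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fit rows


FIT_ROW_COLUMNS = [
    "assay_id",
    "k_on",
    "k_off",
    "n_ar",
    "b_max_per_cell",
    "koff_imputed",
    "ssr",
    "converged",
]


def fit_results_to_frame(results, assay_ids=None) -> pd.DataFrame:
    ids = assay_ids if assay_ids is not None else list(range(1, len(results) + 1))
    return pd.DataFrame(
        [
            {
                "assay_id": i,
                "k_on": r.params.k_on,
                "k_off": r.params.k_off,
                "n_ar": r.params.n_antigens_total,
                "b_max_per_cell": r.b_max_per_cell,
                "koff_imputed": r.koff_imputed,
                "ssr": r.ssr,
                "converged": r.converged,
            }
            for i, r in zip(ids, results)
        ],
        columns=FIT_ROW_COLUMNS,
    )


def read_fit_rows(path: str | Path) -> pd.DataFrame:
    """Read a CSV of fit rows for summarization.

    Requires columns ``k_on``, ``k_off``, ``b_max_per_cell``; an absent
    ``koff_imputed`` column is treated as all-estimated.
    """
    df = pd.read_csv(path)
    missing = {"k_on", "k_off", "b_max_per_cell"} - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing columns: {', '.join(sorted(missing))}")
    if "koff_imputed" not in df.columns:
        df["koff_imputed"] = False
    return df


# ---------------------------------------------------------------------------
# manifest


def write_manifest(out_path: str | Path, command: str, **fields: Any) -> Path:
    """Sidecar manifest recording everything needed to reproduce an output."""
    p = Path(str(out_path) + ".manifest.json")
    payload = {
        "tool": "flowbind",
        "version": __version__,
        "command": command,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        **fields,
    }
    p.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return p


__all__ = [
    "FIT_ROW_COLUMNS",
    "fit_results_to_frame",
    "load_config",
    "read_curve_csv",
    "read_fit_rows",
    "read_truth_sidecar",
    "write_curve_csv",
    "write_default_config",
    "write_manifest",
    "write_net_curve_csv",
    "write_trajectory_csv",
    "write_truth_sidecar",
]
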