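"""Delimited-text I/O for traces, curves and qPCR tables.

Dialect is fixed: tab-separated, UTF-8, ``.`` decimal, mandatory header row.
Column names carry their units (``time_s``, ``extension_um``, ``force_pn``,
``turns``), so files round-trip unambiguously across locales.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .mt import HatCurve, Trace
from .trap import FECurve

__all__ = ["read_trace", "write_trace", "read_fe_curve", "write_fe_curve",
           "read_hat_curve", "write_hat_curve", "read_dlc_table",
           "write_events"]

_TRACE_REQUIRED = ("time_s", "extension_um")
_FE_REQUIRED = ("extension_um", "force_pn")
_HAT_REQUIRED = ("turns", "extension_um")
_DLC_REQUIRED = ("strain", "timepoint_h", "replicate", "eff_dlc", "cp_dlc",
                 "eff_lig", "cp_lig")


def _read_tsv(path, required, sep="\t"):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}; "
                         f"found {list(df.columns)}")
    return df


def read_trace(path) -> Trace:
    """Read a bead trace TSV (``time_s  extension_um`` plus optional
    ``turns  force_pn  condition  bead_id``). Columns are header-keyed, so
    their order is free. Non-monotone time is rejected with the offending
    line number."""
    df = _read_tsv(path, _TRACE_REQUIRED)
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        # +2: one for the header line, one for 1-based numbering
        raise ValueError(f"{path}: time not strictly increasing at line "
                         f"{int(bad[0]) + 3}")
    force = df["force_pn"].to_numpy(dtype=float) if "force_pn" in df else 0.0
    if isinstance(force, np.ndarray) and np.ptp(force) == 0 and force.size:
        force = float(force[0])
    return Trace(
        time=t, extension=df["extension_um"].to_numpy(dtype=float),
        turns=float(df["turns"].iloc[0]) if "turns" in df else 0.0,
        force=force,
        condition=str(df["condition"].iloc[0]) if "condition" in df else "",
        bead_id=str(df["bead_id"].iloc[0]) if "bead_id" in df else "")


def write_trace(trace: Trace, path) -> None:
    df = pd.DataFrame({"time_s": trace.time, "extension_um": trace.extension})
    df["turns"] = trace.turns
    df["force_pn"] = trace.force
    if trace.condition:
        df["condition"] = trace.condition
    if trace.bead_id:
        df["bead_id"] = trace.bead_id
    df.to_csv(path, sep="\t", index=False)


def read_fe_curve(path) -> FECurve:
    """Read a force–extension pull TSV (``extension_um  force_pn``)."""
    df = _read_tsv(path, _FE_REQUIRED)
    return FECurve(extension=df["extension_um"].to_numpy(dtype=float),
                   force=df["force_pn"].to_numpy(dtype=float))


def write_fe_curve(curve: FECurve, path) -> None:
    pd.DataFrame({"extension_um": curve.extension,
                  "force_pn": curve.force}).to_csv(path, sep="\t", index=False)


def read_hat_curve(path) -> HatCurve:
    """Read a rotation–extension TSV (``turns  extension_um``)."""
    df = _read_tsv(path, _HAT_REQUIRED)
    return HatCurve(turns=df["turns"].to_numpy(dtype=float),
                    extension=df["extension_um"].to_numpy(dtype=float))


def write_hat_curve(hat: HatCurve, path) -> None:
    pd.DataFrame({"turns": hat.turns,
                  "extension_um": hat.extension}).to_csv(path, sep="\t",
                                                         index=False)


def read_dlc_table(path) -> pd.DataFrame:
    """Read a qPCR Cp table (CSV with strain, timepoint_h, replicate,
    eff_dlc, cp_dlc, eff_lig, cp_lig)."""
    return _read_tsv(path, _DLC_REQUIRED, sep=",")


def write_events(events, path, bead_id: str = "") -> None:
    """Write event calls as the events TSV."""
    rows = [{"bead_id": bead_id, "start_s": e.start, "end_s": e.end,
             "amplitude_um": e.peak_amplitude, "pos_rate_um_s": e.positive_rate,
             "neg_rate_um_s": e.negative_rate, "lifetime_s": e.lifetime,
             "censored": e.censored} for e in events]
    pd.DataFrame(rows, columns=["bead_id", "start_s", "end_s", "amplitude_um",
                                "pos_rate_um_s", "neg_rate_um_s", "lifetime_s",
                                "censored"]).to_csv(path, sep="\t", index=False)
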