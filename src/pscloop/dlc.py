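"""D-loop capture (DLC) quantification from qPCR crossing points.

The DLC assay traps nascent D-loops by psoralen cross-linking, converts them
to a chimeric restriction/ligation amplicon, and quantifies that amplicon
against an intramolecular-ligation control by qPCR. Template content scales
as efficiency^(−Cp), so

    DLC signal = eff_dlc^(−Cp_dlc) / eff_lig^(−Cp_lig)

and strain-level capture efficiencies are compared as fold-changes of mean
signal against a reference strain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DLCMeasurement", "DLCSignal", "content", "signal", "strain_summary"]


@dataclass(frozen=True)
class DLCMeasurement:
    """One qPCR replicate: efficiencies and crossing points of both channels."""

    eff_dlc: float  # fold/cycle, in (1, 2]
    cp_dlc: float  # cycles
    eff_lig: float
    cp_lig: float
    strain: str = ""
    timepoint: float = 3.0  # h after break induction

    def __post_init__(self) -> None:
        for eff in (self.eff_dlc, self.eff_lig):
            if not 1.0 < eff <= 2.0:
                raise ValueError(f"amplification efficiency must be in (1, 2], got {eff}")
        for cp in (self.cp_dlc, self.cp_lig):
            if not 0.0 < cp < 50.0:
                raise ValueError(f"Cp must be in (0, 50), got {cp}")


@dataclass(frozen=True)
class DLCSignal:
    dlc_content: float
    ligation_content: float
    signal: float  # dlc_content / ligation_content
    strain: str = ""


def content(eff: float, cp: float) -> float:
    """Relative template content from a crossing point: eff^(−cp)."""
    if eff <= 1.0:
        raise ValueError(f"efficiency must exceed 1 fold/cycle, got {eff}")
    if cp <= 0:
        raise ValueError(f"cp must be positive, got {cp}")
    return float(eff ** (-cp))


def signal(m: DLCMeasurement) -> DLCSignal:
    """Chimera-to-ligation signal ratio for one replicate."""
    dlc = content(m.eff_dlc, m.cp_dlc)
    lig = content(m.eff_lig, m.cp_lig)
    return DLCSignal(dlc_content=dlc, ligation_content=lig,
                     signal=dlc / lig, strain=m.strain)


def strain_summary(samples, reference: str) -> pd.DataFrame:
    """Per-strain mean signal, SEM, and fold-change versus ``reference``.

    ``samples`` is an iterable of :class:`DLCSignal`; every strain needs at
    least 3 replicates for a meaningful SEM. The fold-change is computed on
    strain means as reference_mean / strain_mean, i.e. the fold *reduction*
    in capture efficiency relative to the reference (1 for the reference
    itself, > 1 for strains that capture less).
    """
    rows = [(s.strain, s.signal) for s in samples]
    df = pd.DataFrame(rows, columns=["strain", "signal"])
    counts = df.groupby("strain").size()
    if (counts < 3).any():
        bad = counts[counts < 3]
        raise ValueError("need >= 3 replicates per strain for SEM; got "
                         + ", ".join(f"{k}: {v}" for k, v in bad.items()))
    if reference not in counts.index:
        raise ValueError(f"reference strain {reference!r} not in samples")
    out = (df.groupby("strain")["signal"]
           .agg(mean_signal="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)),
                n="size").reset_index())
    ref_mean = float(out.loc[out.strain == reference, "mean_signal"].iloc[0])
    out["fold_vs_reference"] = ref_mean / out["mean_signal"]
    return out
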