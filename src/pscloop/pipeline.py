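"""Run configuration and the end-to-end demo pipeline.

``run_pipeline`` wires the generators to the analyses for a declared
experiment set — loop-formation-rate simulation, magnetic-tweezer event
calling and lifetimes, hat-curve slopes, force–extension sawtooth
decomposition, clamp velocity, torque plot with stall extrapolation, and
DLC quantification — and writes a machine-readable JSON report plus TSV/CSV
outputs. Every random stage consumes a child seed derived deterministically
from the master seed and the stage name, so reordering stages cannot
silently change results.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dlc as dlc_mod
from . import io as io_mod
from .loop_model import lfr_table
from .mechanics import (CouplingModel, HatCurveModel, TorqueModel, WLCParams,
                        force_to_torque)
from .mt import (EventDetectionConfig, Trace, baseline_stats, detect_events,
                 fit_lifetimes, hat_slope)
from .synthetic import (TraceGenConfig, gen_clamp_trace, gen_dlc_table,
                        gen_fe_curve, gen_hat_curve, gen_mt_trace)
from .torque import build_torque_plot, convert_plot_units, fit_stall
from .trap import clamp_velocity, compare_to_theory

__all__ = ["RunConfig", "load_config", "child_seed", "run_pipeline"]


def child_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed: stable hash of the stage name mixed
    with the master seed (always < 2^31)."""
    key = zlib.crc32(stage.encode("utf-8"))
    return int(np.random.SeedSequence([int(master), key])
               .generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Validated parameter blocks for a pipeline run."""

    wlc: WLCParams = field(default_factory=WLCParams)
    torque: TorqueModel = field(default_factory=TorqueModel)
    coupling: CouplingModel = field(default_factory=CouplingModel)
    events: EventDetectionConfig = field(default_factory=EventDetectionConfig)
    seed: int = 0
    output_dir: str = "pscloop-out"
    log_level: str = "INFO"


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file.

    Recognized keys: ``wlc.contour_bp``, ``wlc.rise_nm``, ``wlc.lp_nm``,
    ``wlc.k_pn``, ``torque.coefficient``, ``torque.exponent``,
    ``coupling.bp_per_turn``, ``coupling.efficiency``, ``events.window``,
    ``events.sd``, ``events.min_duration``, ``seed``, ``output_dir``.
    Each block re-validates its module's invariants on load.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    w = raw.get("wlc", {})
    wlc = WLCParams(
        contour_length_bp=int(w.get("contour_bp", WLCParams.contour_length_bp)),
        rise_per_bp=float(w.get("rise_nm", WLCParams.rise_per_bp)),
        persistence_length=float(w.get("lp_nm", WLCParams.persistence_length)),
        stretch_modulus=float(w.get("k_pn", WLCParams.stretch_modulus)))
    tq = raw.get("torque", {})
    torque = TorqueModel(
        coefficient=float(tq.get("coefficient", TorqueModel.coefficient)),
        exponent=float(tq.get("exponent", TorqueModel.exponent)))
    cp = raw.get("coupling", {})
    coupling = CouplingModel(
        bp_per_turn=float(cp.get("bp_per_turn", CouplingModel.bp_per_turn)),
        coupling_efficiency=float(cp.get("efficiency",
                                         CouplingModel.coupling_efficiency)))
    ev = raw.get("events", {})
    events = EventDetectionConfig(
        window=float(ev.get("window", EventDetectionConfig.window)),
        sd_multiplier=float(ev.get("sd", EventDetectionConfig.sd_multiplier)),
        min_duration=float(ev.get("min_duration",
                                  EventDetectionConfig.min_duration)))
    return RunConfig(wlc=wlc, torque=torque, coupling=coupling, events=events,
                     seed=int(raw.get("seed", 0)),
                     output_dir=str(raw.get("output_dir", "pscloop-out")),
                     log_level=str(raw.get("log_level", "INFO")))


def run_pipeline(config: RunConfig) -> dict:
    """Generate, analyze and summarize the full demo experiment set.

    Returns the report dict and writes ``report.json`` (plus per-stage TSVs)
    under ``config.output_dir``. Byte-identical for identical config + seed.
    A stage failure aborts with the stage name; outputs of completed stages
    are left on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}
    stage = "init"
    try:
        # --- loop-formation-rate simulation -------------------------------
        stage = "lfr"
        lfr = lfr_table(mu=65.0, sigma=65.0, folds=[1, 2, 3, 5, 10], n=1000,
                        seed=child_seed(config.seed, stage))
        lfr.to_csv(out / "lfr.tsv", sep="\t", index=False)
        report["lfr"] = {f"fold_{int(r.fold)}_mean_bp_s": round(r.mean_bp_s, 3)
                         for r in lfr.itertuples()}

        # --- magnetic-tweezer traces --------------------------------------
        stage = "mt"
        seed0 = child_seed(config.seed, stage)
        base_cfg = TraceGenConfig(event_count=0, seed=seed0)
        baseline_trace, _ = gen_mt_trace(base_cfg)
        baseline = baseline_stats(baseline_trace)
        all_events = []
        for k in range(5):
            tr, _ = gen_mt_trace(TraceGenConfig(seed=seed0 + 1 + k))
            all_events.extend(detect_events(tr, baseline, config.events))
        io_mod.write_events(all_events, out / "events.tsv", bead_id="sim")
        fit = fit_lifetimes([e for e in all_events if not e.censored])
        report["mt"] = {"n_events": len(all_events),
                        "baseline_mean_um": round(baseline[0], 4),
                        "baseline_sd_um": round(baseline[1], 4),
                        "half_life_s": round(fit.half_life, 3),
                        "half_life_ci95_s": [round(v, 3) for v in fit.ci95]}

        # --- hat curve ----------------------------------------------------
        stage = "hat"
        hat = gen_hat_curve(HatCurveModel(), noise_sd=0.05,
                            seed=child_seed(config.seed, stage))
        io_mod.write_hat_curve(hat, out / "hat.tsv")
        hs = hat_slope(hat)
        report["hat"] = {"slope_um_per_turn": round(hs.slope, 5),
                         "r2": round(hs.r2, 4)}

        # --- force-extension sawtooth --------------------------------------
        stage = "fe"
        loops = [(2000.0, 15.0), (2000.0, 20.0), (2000.0, 25.0),
                 (2000.0, 30.0)]
        curve, truth = gen_fe_curve(config.wlc, loops,
                                    initial_constrained_bp=15000.0,
                                    seed=child_seed(config.seed, stage))
        io_mod.write_fe_curve(curve, out / "fe.tsv")
        dev = compare_to_theory(curve, config.wlc)
        report["fe"] = {
            "first_deviation_bp": round(dev.first_deviation_bp, 1),
            "final_deviation_bp": round(dev.final_deviation_bp, 1),
            "n_intermediates": dev.n_intermediates,
            "mean_loop_bp": round(float(np.mean(
                [b for b, _ in dev.intermediates])), 1)
            if dev.intermediates else None,
            "rupture_forces_pn": [round(f, 2) for _, f in dev.intermediates]}

        # --- force clamp ----------------------------------------------------
        stage = "clamp"
        clamp = gen_clamp_trace(velocity_bp_s=202.0, duration=30.0, force=0.5,
                                wlc=config.wlc,
                                seed=child_seed(config.seed, stage))
        cres = clamp_velocity(clamp, config.wlc)
        report["clamp"] = {"velocity_bp_s": round(cres.velocity_bp_s, 1),
                           "mode": cres.mode, "force_pn": cres.force}

        # --- torque plot and stall extrapolation ---------------------------
        stage = "torque"
        rng = np.random.default_rng(child_seed(config.seed, stage))
        forces = [0.3, 0.5, 1.0, 2.0]
        per_force = []
        for f in forces:
            tq = force_to_torque(config.torque, f)
            true_rate = max(0.3 - 0.015 * tq, 0.0)  # stall at 20 pN·nm
            per_force.append((f, rng.normal(true_rate, 0.04, 30)))
        points = build_torque_plot(per_force, config.torque)
        line = fit_stall(points)
        bp_points = {
            str(c): [p.mean_rate for p in convert_plot_units(
                points, hat_slope=abs(HatCurveModel().slope_pos),
                coupling=CouplingModel(coupling_efficiency=c))]
            for c in (1.0, 0.75, 0.5)}
        report["torque"] = {
            "stall_torque_pn_nm": round(line.intercept_torque_at_zero_rate, 3)
            if line.intercept_torque_at_zero_rate is not None else None,
            "no_torque_rate_um_s": round(line.intercept_rate_at_zero_torque, 4),
            "r2": round(line.r2, 4),
            "rates_bp_s_by_coupling": {k: [round(v, 1) for v in vals]
                                       for k, vals in bp_points.items()}}

        # --- DLC quantification --------------------------------------------
        stage = "dlc"
        sd = child_seed(config.seed, stage)
        tables = [gen_dlc_table(3.3e-2, cp_noise_sd=0.05, seed=sd, strain="WT"),
                  gen_dlc_table(1.7e-4, cp_noise_sd=0.05, seed=sd + 1,
                                strain="rad54d")]
        table = pd.concat(tables, ignore_index=True)
        table.to_csv(out / "dlc.csv", index=False)
        signals = [dlc_mod.signal(dlc_mod.DLCMeasurement(
            eff_dlc=r.eff_dlc, cp_dlc=r.cp_dlc, eff_lig=r.eff_lig,
            cp_lig=r.cp_lig, strain=r.strain)) for r in table.itertuples()]
        summary = dlc_mod.strain_summary(signals, reference="WT")
        summary.to_csv(out / "dlc_summary.csv", index=False)
        report["dlc"] = {
            r.strain: {"mean_signal": float(r.mean_signal),
                       "sem": float(r.sem),
                       "fold_vs_reference": round(float(r.fold_vs_reference), 2)}
            for r in summary.itertuples()}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=2,
                                                sort_keys=True) + "\n")
    return report
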