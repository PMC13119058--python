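# pscloop

Quantitative machinery for single-molecule studies of the eukaryotic
homology-search machine — the presynaptic complex (PSC) of a Rad51–ssDNA
filament and the Rad54 translocase — remodeling donor DNA. The package
bundles, as a tested Python library:

- a **stochastic two-motor loop-formation-rate model**: a translocase dimer
  holds two DNA contacts, one activated A-fold by its recombinase partner;
  velocities are drawn as v₁ ~ N(µ, σ²) and v₂ ~ N(Aµ, σ²) (negatives
  redrawn) and the loop grows at LFR = |v₁ − v₂|;
- **DNA mechanics primitives**: the extensible worm-like chain
  F·Lp/kT = ¼(1 − x/L + F/K)⁻² − ¼ + x/L − F/K with closed-form forward
  solution and fast inversion, the empirical post-buckling torque law
  Γ = 12.7825 · F^0.63447 pN·nm, piecewise-linear rotation–extension (hat)
  curves, and turns↔bp conversion at 10.5 bp/turn with a coupling
  efficiency;
- **magnetic-tweezer trace analysis**: 5 s sliding-window smoothing,
  Gaussian baseline statistics, event calling at mean + 3 SD sustained
  > 2.5 s, per-event extension rates, exponential lifetime fits with exact
  chi-square confidence intervals, buckling-arm slopes, and compaction
  screening;
- **optical-trap analyses**: sawtooth decomposition of re-extension
  force–extension curves into an initial constrained-DNA deviation, per-loop
  sizes and rupture forces; force-clamp compaction/translocation velocities;
  per-event maximum force output;
- **torque plots** with linear stall-torque extrapolation and
  force–velocity fits (rectangular hyperbola, single-phase exponential
  decay);
- **D-loop capture (DLC) qPCR quantification**:
  signal = eff_dlc^(−Cp_dlc) / eff_lig^(−Cp_lig), with strain-level
  fold-changes;
- seeded **synthetic-data generators** for every input (traces with ground
  truth events, hat curves, sawtooth pulls, Cp tables), so the entire
  pipeline runs and is scored without instrument files.

## Worked example

```python
from pscloop import MotorModel, sample_lfr

res = sample_lfr(MotorModel(mu=65, sigma=65, fold_activation=5,
                            n_samples=1000, seed=1))
print(f"{res.mean:.1f} +/- {res.sd:.1f} bp/s")
```

prints `246.2 +/- 84.7 bp/s`: with the unactivated motor at 65 bp/s and a
fivefold-activated partner, loops grow at ~240–250 bp/s — the measured
regime for the active complex. The `examples/` directory holds one short
narrative script per capability (`01_loop_formation_rates.py` …
`06_dlc_quantification.py`); each builds a small synthetic input, runs the
analysis, and prints what the numbers mean. `examples/04_fe_sawtooth.py`,
for instance, programs four 2 kb loops on a 15 kb constraint and prints

```
first deviation :    14990 bp (programmed 15000)
intermediates   : 4 (programmed 4)
  loop 1:   2043 bp ruptured at  14.7 pN
  ...
```

A thin CLI mirrors the library (`pscloop simulate-lfr`, `gen`, `mt-analyze`,
`fe-analyze`, `clamp-analyze`, `maxforce`, `torque-plot`, `dlc`, `run`).
`pscloop run --seed 1 --out out/` executes the whole
generate → analyze → summarize pipeline and writes `report.json`.

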