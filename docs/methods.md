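# Methods

## The system

A presynaptic complex (PSC) — a Rad51 filament on recipient ssDNA plus the
Rad54 dsDNA translocase — probes donor duplex DNA for sequence homology.
Tracking the helical groove while translocating, the motor adds net twist to
any topologically constrained region; when the complex holds two contacts on
the donor it extrudes an underwound loop between them. This package models
that loop-extrusion kinetics and implements the trace analyses that measure
it on magnetic-tweezer (MT) and dual-optical-trap instruments, plus the in
vivo D-loop capture (DLC) qPCR readout.

## Two-motor loop-formation-rate model

Velocities of the anchoring and activated motors are drawn as
v₁ ~ N(µ, σ²) and v₂ ~ N(Aµ, σ²); a draw below zero is redrawn (motors do
not run backward), which makes each marginal a zero-truncated normal; the
loop-formation rate per replicate is LFR = |v₁ − v₂|, and a run returns
exactly `n_samples` (default 1000) accepted replicates. A `mode="sum"`
switch credits v₁ + v₂ instead, for the reading in which both contacts reel
DNA into one loop; the difference form is the default because it is the
form with a defined sampling procedure.

Parameters: µ = 65 bp/s is the measured velocity of the unactivated motor.
σ is not known experimentally; the package defaults to σ = µ, consistent
with the broad, overlapping velocity distributions observed and with the
±132 bp/s spread of measured compaction rates. All quantitative tests state
σ explicitly. Known consequence (not a bug): with σ = µ = 65 the truncated
sampler gives a mean LFR of ≈ 241 bp/s at fivefold activation but only
≈ 118 bp/s at threefold, whereas the reported pair is 250/150. No plausible
σ reproduces 150 at threefold under this sampling scheme (σ → 0 gives the
ceiling µ(A−1) = 130; larger σ lowers the mean through the truncation of
v₁). The sampler is kept faithful to its stated procedure rather than tuned.

## DNA mechanics

Extensible worm-like chain (Marko–Siggia interpolation with enthalpic
stretch): F·Lp/kT = ¼(1 − x/L + F/K)⁻² − ¼ + x/L − F/K. Substituting
w = 1 − x/L + F/K turns the force→extension direction into the cubic
w³ + (F·Lp/kT − ¾)w² − ¼ = 0, solved in closed form (Cardano, taking the
largest real root — the physical branch with w → 1 at F → 0). The inverse
uses a safeguarded vectorized Newton iteration on that closed form
(round-trip error < 1 µpN over 0–60 pN; a 10⁴-point inversion takes
~0.2 s). Elastic defaults, all configurable: persistence length 43.3 nm,
stretch modulus 1205 pN, rise 0.338 nm/bp, kT = 4.114 pN·nm (25 °C) —
canonical values for λ-DNA in near-physiological buffer. The quantities the
analyses report (loop counts, bp differences at matched forces, intercepts)
are insensitive to these defaults at the few-percent level.

Torque: post-buckling torque on a magnetically twisted tether follows the
empirical power law Γ = 12.7825 · F^0.63447 pN·nm. Twist–translocation
coupling: at coupling efficiency c, bp/s = (turns/s) × 10.5 / c — a motor
converting only a fraction c of its 10.5 bp steps into net turns must travel
1/c as far per observed turn, so lower coupling implies a faster motor.

Hat curves are modeled piecewise-linear: a torsion-absorbing plateau at the
apex extension between the two buckling turns, then linear plectonemic arms
(clamped at zero extension). Only the apex and arm slopes are consumed
downstream, so no smoothed apex shape is fitted.

## Magnetic-tweezer trace analysis

Traces are smoothed with a centered 5 s moving average (centered to avoid
event-onset bias; endpoints use truncated windows). The baseline is a
Gaussian fit to the extension histogram of a protein-free tether; a poor fit
(r² < 0.9, e.g. bimodal plateaus) triggers a warning rather than silent
acceptance. Events are contiguous excursions of the smoothed trace above
mean + 3 SD lasting > 2.5 s; thresholding happens after smoothing, matching
the stated smoothing-then-analysis order. Per event, the highest local
maximum (prominence ≥ 1 baseline SD, earliest sample on ties) anchors two
linear fits: the rising segment into it (positive rate, reported ≥ 0) and
the falling segment out of it (negative rate, stored signed). The event
lifetime is the time between threshold crossings; for a trapezoidal event
this exceeds the plateau dwell by 2(amplitude − threshold)/rise-rate, and
the generator exposes that predicted value (`GroundTruth.threshold_dwell`)
so recovery tests compare like with like. Events reaching the end of the
record are kept but flagged right-censored; a 10-minute monitor will
truncate long dwells.

Lifetimes are fit by maximum likelihood for an exponential (half-life =
ln 2 × mean dwell) with the exact chi-square interval for the rate (the
dwell sum is Gamma-distributed); a least-squares fit of the empirical
survival curve is available as `method="survival"`. Coverage of the 95% CI
at n = 300 is ≈ 95% by construction and is verified empirically.

Compaction screening truncates a trace at the first smoothed sample below
the initial smoothed extension (optionally minus a baseline-SD tolerance)
and discards everything after, even if the bead recovers.

## Optical-trap analyses

A re-extension pull is compared to the bare-DNA WLC in force space: the
deviation at each point is measured force minus the theory force at that
extension. A deviation counts when it exceeds 0.5 pN sustained over ≥ 50 nm
of extension (above trap force noise, below the smallest sawtooth of
interest; both configurable). Ruptures are force peaks (prominence ≥ 1 pN on
a lightly median-filtered channel) still deviating from theory. Constrained
DNA at force F is the extension deficit converted through the rise *and*
the fractional extension: Δbp = (x_th(F) − x)/(rise · g(F)) with
g(F) = x_th(F)/L. The g(F) factor matters: a contour deficit ΔL appears as
an extension deficit ΔL·g(F), and at post-rupture trough forces
(g ≈ 0.94–0.97) omitting it inflates loop sizes by ~6%. Loop size is the
change in constrained bp from a rupture peak to the following trough;
ruptures releasing < 250 bp are discarded as noise (force noise near a drop
can split one peak in two; real intermediates are kb-scale). The first
deviation is sized at the first rupture peak, where g ≈ 1; the final
deviation is the residual constrained bp at the end of the pull and is
flagged as a lower bound when the curve never rejoins theory (measured at
the last rejoin otherwise, a choice the data cannot discriminate).

Clamp velocities are linear fits of bead separation over an active segment
(≥ 2 s), converted through the rise; the sign selects compaction versus
translocation. Maximum force output is the per-event maximum of the
smoothed force channel, events delimited by return to within 1 pN of the
pre-event baseline.

## Torque plots

Mean rates (not raw per-event rates) with t-distribution 95% CIs are plotted
against torque and fit by unweighted OLS (statsmodels), matching the plain
linear fit presented with the data; 1/CI² weighting is easy to add but not
default. Both intercepts are named explicitly — stall torque (torque at zero
rate) and no-torque rate — because "X-intercept" is ambiguous across axis
conventions. Extrapolating the stall assumes the rate–torque relation stays
linear beyond the measured range; the fit object carries confidence bands
from the OLS covariance so the extrapolation uncertainty is visible.
Force–velocity data are fit by nonlinear least squares to a rectangular
hyperbola v = V_max·F/(K+F) (translocation, rising) or a single-phase
exponential decay v = v₀·e^(−F/τ_F) + c (twist-coupled extrusion, falling);
poor fits (r² < 0.5) and degenerate parameters are flagged, not hidden.

## DLC quantification

Template content scales as efficiency^(−Cp); the DLC signal is the chimera
content over the intramolecular-ligation content, and strain comparisons are
fold-changes of strain means (reference/strain, so a weaker strain reads as
an N-fold reduction). Amplification efficiencies are user-supplied inputs;
standard-curve estimation is out of scope. The programmed comparison of
3.3 × 10⁻² versus 1.7 × 10⁻⁴ yields the unrounded ratio 194.1.

## Synthetic data: what it does and does not emulate

Generators are pure functions of config + seed (bit-identical reruns).
MT traces: Gaussian white baseline noise (no drift, creep, camera blur, or
spectral structure — baseline statistics in the assay are mean/SD-based),
trapezoidal events (linear slopes between extrema, as the rate analysis
assumes) with normal amplitudes floored at zero and exponential dwells
(rate ln 2/half-life), overlapping draws merged; 50 Hz default sampling
(typical camera-based MT; thresholds are in seconds so results are
rate-independent). FE pulls: quasi-static WLC force at the imposed
extension with an effective contour that grows at each programmed rupture;
Gaussian force noise; no bead/trap dynamics. Hat curves: model plus noise.
Cp tables: ligation Cp uniform in a reference window, chimera Cp set to
encode the programmed signal, Gaussian cycle noise on both channels.
Passing recovery tests therefore demonstrates correctness of the analysis
chain under these idealizations, not robustness to instrument drift,
anharmonic trap effects, or non-exponential dwell mixtures.

## Problem sizes and determinism

Default study-scale runs: 1000 LFR replicates; 10-minute traces at 50 Hz;
pulls at 100 Hz over ~10 µm; statistical suites use 50–100 seeds and cohorts
of 300 dwells. The full demo pipeline (`pscloop run`) completes in seconds.
A single master seed fans out to per-stage child seeds by a stable hash of
the stage name, so stage reordering cannot silently change results.

## Limitations

No twistable-WLC or plectoneme free-energy theory beyond the empirical
torque law; no mechanochemical (ATP-coupled) motor schemes; no kymograph
particle tracking (manual in the source workflow); no chromatin. The
threefold-activation LFR discrepancy described above is reported, not
reconciled.
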