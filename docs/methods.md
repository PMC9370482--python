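# Methods

This note documents the models behind each module, the parameters that
matter, the numerical choices made where the design was genuinely open, and
what the synthetic-data generators do and do not emulate.

## Indentation protocol

The probe rests at h₀ = 20 μm above the coverslip and performs a train of
excursions of travelled distance D = d_start, d_start + d_step, …, d_max
(defaults 8, 2, 18 μm → six steps), each at speed v = 3 μm/s followed by an
equal retraction and a dwell of 40 s. Tip height at the bottom of an
excursion is Z = h₀ − D; indentation depth into a cell of group-average
maximal thickness ⟨T_max⟩ is δ = ⟨T_max⟩ − Z, negative when the tip does not
reach the cell (the first two default steps for ⟨T_max⟩ ≈ 9 μm). Step
timestamps accumulate down-travel, up-travel and dwell; the first step
starts at t = 10 s by default so that a resting-baseline window exists
before any stimulus. Depths default to the group mean thickness (per-cell
thickness can be supplied instead by building a per-cell `DepthMap`).

The emitted motion program uses relative moves (G91), millimetre units
(G21), linear moves `G1 Z… F…` with the feed rate in mm/min (3 μm/s →
F0.18) and dwells `G4 P<s>`. When an overshoot plan is given, slack-takeup
moves are inserted before each direction reversal and tagged so the parser
ignores them; parsing an emitted program returns the original D sequence
exactly.

## Stage model and calibration statistics

The simulator models a screw-driven stage as a **dead-band hysteresis**:
after every direction reversal the first B μm of commanded travel are
absorbed by the screw slack before the carriage moves, with independent gap
widths per reversal sense (defaults B₊₋ = 3.7 μm entering the negative
direction, B₋₊ = 3.1 μm entering the positive direction, actual step sizes
21.1/18.9 nm per direction). Asymmetric gaps make the hysteresis loop
non-closing, so uncorrected saw-tooth trajectories accumulate a small drift
per cycle — visible in the uncorrected E. Noise has two parts, both
independent across records: actuation noise with standard deviation
`step_noise_sd_nm · sqrt(travel/1 μm)` per commanded move, and readout noise
`position_noise_sd_um`. Actuation noise is deliberately *not* integrated
into a persistent random walk: backlash estimation and error statistics are
averaging estimators whose convergence with the number of positions is part
of their design, and a persistent walk would make trajectory length
counterproductive rather than informative.

Statistics follow the ISO-style bidirectional definitions: per-position,
per-direction mean deviation and sample standard deviation over repeats
(zero for a single repeat, so small fixtures run); E is the span of the
means; A widens each mean by k standard uncertainties (k = 2 default)
before taking the span, so A ≥ E on any dataset.

**Backlash estimation.** Adjacent opposite-direction sweeps are paired in
acquisition order and matched by position index; the per-reversal offset is
the **median** over common positions of the deviation difference, and each
B is the mean magnitude over reversals of its sense. The median is exact on
noiseless saw-tooths because the handful of positions recorded while the
slack is still being traversed sit at intermediate offsets and would bias a
plain mean; pairing adjacent sweeps makes the estimator immune to the
cycle-to-cycle drift of the asymmetric loop.

**Overshoot correction.** `plan_overshoot` rounds each backlash estimate to
integer motor steps of the corresponding direction (3.7 μm / 21.1 nm → 175
steps; 3.1 μm / 18.9 nm → 164 steps); `apply_overshoot` shifts the command
stream further into the new direction after every reversal so the slack is
consumed by extra travel and the carriage lands on the original targets.
Residual E after correction is bounded by the rounding residual (at most
half a step per reversal sense) plus noise; note that the post-reversal
move carries the overshoot travel (≈ 1 + B μm) and therefore proportionally
larger actuation noise, which dominates the corrected E at realistic noise
levels. `E_R` is operationalised as the mean absolute deviation of measured
from target over the corrected trajectory, and Δz = E + E_R.

## Holographic morphometry

Thickness follows the linear phase relation Φ = (2π/λ)(n_c − n_m)T with
n_c = 1.38, n_m = 1.34, λ = 635 nm by default; T_max per ROI is the single
maximum phase pixel converted to micrometres (a percentile variant is
available for noisy maps but the default is the plain maximum). Background
calibration subtracts the mean phase over a medium-only mask and is
idempotent. No phase unwrapping is performed: at these constants the phase
stays below 2π for T ≲ 15.9 μm, comfortably above the ~9–10 μm cells the
assay targets; maps exceeding 2π trigger a wrap warning. Cohort summaries
report mean ± standard error of the mean, the convention used for
group-thickness figures of this kind (consistent with μm-scale
cell-to-cell spread at n of several tens).

The generator places raised-cosine domes `T(r) = T_max cos²(πr/2R)` on a
non-overlapping grid, centred on integer pixels so the centre pixel encodes
the drawn T_max exactly; at zero phase noise the round trip through
`cell_tmax` is exact to machine precision. Drawn thicknesses are
Normal(9.4, 1.5) μm by default, clipped at zero. The generator makes no
attempt to simulate interference fringes, hologram reconstruction,
refractive-index heterogeneity or segmentation errors — masks always match
footprints exactly, so morphometry tests validate the phase-to-thickness
arithmetic, not a segmentation pipeline.

## Trace model

Resting two-channel fluorescence is F340 = 500, F380 = 1000 (arbitrary
units; the resting ratio only fixes FR₀ and cancels in R). An activation
transient is a Gaussian excursion of the normalised ratio with FWHM 40 s
whose maximum reaches `peak_ratio_amplitude` (default 3.0); it is split
anti-symmetrically between the channels — F340 scaled by √R, F380 by 1/√R —
so the configured R amplitude is met exactly in the noiseless limit and the
channels are exactly anti-correlated. The transient's 10 %-of-amplitude
onset falls uniformly within 0–10 s after the activating indentation's
retraction completes. Membrane rupture at the deepest point of the rupture
step multiplies both channels by a shared exponential decay (τ = 3 s) to
10 % of baseline, after which the underlying ratio is forced to baseline:
the dye has left the cell and reports nothing. Per-frame noise is
multiplicative Gaussian with coefficient of variation 0.02 per channel.

Each cell additionally carries, with probability 0.5, one **spontaneous
sub-threshold excursion** with amplitude drawn U(1.25, 1.45), the same 40 s
kernel and ratiometric construction, placed so it does not overlap the
activation transient. These emulate the low-amplitude spontaneous calcium
activity that makes very permissive thresholds unusable in real recordings:
they are what the threshold sweep's noise regime below R_T ≈ 1.5 is made
of, and without them the lower bound of the stable threshold interval would
be degenerate. The amplitude ceiling is set so that, after detection
(smoothing plus noise), the control group's activation rate reaches zero at
R_T = 1.5 — the noise-regime edge characteristic of this assay.

Cohorts fix exactly `round(n_cells × responsive_fraction)` responsive cells
(the calcium-free group is forced fully unresponsive regardless of the
requested fraction); every cell ruptures at the last indentation. Default
responsive fractions per group are WT 0.18, Piezo1 0.32, GsMTx4 0.07,
CaFree 0 — the GsMTx4 group is modelled purely as a reduced responsive
fraction, with no toxin kinetics. Activation steps are drawn uniformly from
the two deepest steps at which a complete transient (latency plus
10 %-edge-to-edge span, ≈ 83 s) still fits before the rupture; with the
default protocol these are the third and fourth steps. Steps closer to the
rupture would generate ground-truth "responsive" cells whose transients are
physically cut off, which is a property of the protocol, not of the
classifier. An explicit `responsive_depth_index` overrides the draw.

What the trace generator does **not** emulate: photobleaching, focus drift
and motion artefacts, cell-to-cell variation in transient amplitude or
kinetics, multi-peaked responses, partial ruptures, and baseline trends.
Classification performance measured on these traces therefore demonstrates
the detector logic under the assay's stated signal and noise scales, not
robustness to every pathology of real recordings.

## Detection and classification

R is formed samplewise and normalised by the mean ratio over the window
before the first indentation (default the first 10 s; at least five samples
required). All peak analysis runs on signals lightly smoothed with a
Gaussian kernel of σ = 2 s (≈ 4.5 frames): frame noise splits broad peaks
into several jittering local maxima, and smoothing at a scale far below the
30 s width criterion suppresses them without measurably attenuating the
transients (< 1 % for a 40 s-FWHM peak).

A qualifying event must (i) be a local maximum of smoothed R above R_T with
prominence ≥ 0.2 over baseline, (ii) have width ≥ 30 s at the near-baseline
level `1 + 0.1 (peak − 1)` — the 10 % guard avoids measuring widths at a
level the noise crosses constantly, (iii) coincide within 10 s with a local
maximum of smoothed F340 and a local minimum of smoothed F380, each with
prominence at least five baseline standard deviations. The 10 s coincidence
window was sized from the measured jitter between the R-peak location and
the channel-extremum locations at the assay's signal scales (95th
percentile ≈ 3 s, worst cases ≈ 7 s); it remains far below the 30 s width
rule and the 40 s dwell, so it cannot confuse events from neighbouring
indentations. Events at or after the detected rupture are discarded.

Rupture is the earliest time at which both channels have fallen by ≥ 50 %
of their level 5 s earlier while R stays flat (sd < 0.05) over the
following 20 s. The two-channel requirement distinguishes rupture from an
activation transient, where F380 dips but F340 rises; keying on the dual
drop rather than on a particular R plateau level avoids assuming anything
about the post-rupture ratio, which depends on background.

A responsive cell's first event (ordered by onset) is attributed to the
indentation in whose observation window — down-travel, up-travel and the
following dwell, i.e. until the next step begins — its **half-maximum
rise** falls. The half-rise is used rather than the near-baseline onset
because a sub-threshold spontaneous excursion overlapping the transient's
flank can drag the 10 %-level crossing tens of seconds early, while the
half-maximum level is above anything a sub-threshold excursion can reach.
Unattributable events leave the cell responsive with an unassigned depth
and a warning; such cells are counted in a dedicated bin of the AR_δ
histogram so that Σ_δ AR_δ = AR holds identically.

## Threshold sweep and selection

The sweep evaluates AR(R_T) per group on a grid of 0.1 over [0, 4.5].
Because normalisation, rupture detection, the width rule and the
channel-coincidence test are all independent of R_T, event detection runs
once per trace and only the threshold test is repeated; raising R_T can
only remove events, so the curves are non-increasing by construction. The
selected threshold is the midpoint of [lower, upper], where *lower* is the
smallest grid value at which the control group's AR is zero and stays zero
(guarding against non-monotone blips in a finite control) and *upper* is
the largest grid value at which any group still responds. The GsMTx4 group
may participate in sweeps but only the calcium-free control defines the
lower bound. A control whose AR never settles to zero raises an error
rather than returning a meaningless midpoint.

## Problem sizes and determinism

Simulations are sized so the full test suite and the acceptance script each
run in seconds: calibration uses 20 positions × 1 μm × 3 repeats (and 100
positions for noisy-recovery properties), morphometry a 512×512 map with 65
cells, classification fidelity a 100-cell cohort, activation-rate recovery
20 replicates of cohorts of 28–33 cells. Every generator is driven by
`numpy.random.default_rng` seeded from its config; cohorts spawn per-cell
child seeds from a `SeedSequence`, so identical configurations are
bit-identical and independent of each other.

## Known limitations

- The stage model's asymmetric dead-band is a generative convenience; a
  physical single-gap screw has one loop width, and the asymmetry observed
  on real hardware mixes gap, step-size asymmetry and measurement noise.
- Backlash estimation assumes sweeps long enough that most positions are
  recorded with the slack fully traversed (position count ≫ backlash/step).
- The classifier's thresholds (prominence 0.2, 5σ channel prominence, 50 %
  drop, 0.05 flatness, σ = 2 s smoothing) are conventions chosen for the
  stated signal scales and are all exposed as parameters; real recordings
  with different dye loading or optics may need different values.
- Absolute calcium concentrations are never computed from R; the analysis
  is purely ratiometric and threshold-based.
- ROI extraction from movies and cell segmentation are out of scope; traces
  and label masks are inputs.
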