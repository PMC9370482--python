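# mechanoindent

Analysis pipeline for a single-cell **microindentation mechanosensitivity
assay**: a glass microprobe on a motorised stage indents adherent cells in
progressively deeper steps while ratiometric fura-2 calcium imaging reports
whether mechanosensitive channels (Piezo1) opened. The package implements the
full data path of such an assay — stage metrology, cell morphometry, the
indentation protocol, calcium-trace classification and cohort statistics —
together with seeded synthetic-data generators, so every stage is testable
without lab recordings.

It is written for experimentalists running calcium-imaging indentation
assays and for anyone building or validating low-cost motorised
micromanipulation hardware.

## What it computes

**Stage calibration** (`stage_calibration`). From a saw-tooth trajectory of
target vs. interferometrically measured positions it computes the
bidirectional positioning statistics: per-position mean deviations z̄ᵢ± and
uncertainties σᵢ±, the bidirectional systematic deviation
`E = max[z̄ᵢ₊; z̄ᵢ₋] − min[z̄ᵢ₊; z̄ᵢ₋]`, the backlash estimates B₊₋ and B₋₊
(offsets between positionings of the same target from opposite approach
directions), the bidirectional positioning accuracy
`A = max[z̄ᵢ± + kσᵢ±] − min[z̄ᵢ± − kσᵢ±]` (coverage factor k = 2), and the
total positioning uncertainty `Δz = E + E_R`. Backlash is corrected
open-loop by *overshooting* — extending the first move after each direction
reversal by a rounded integer number of motor steps.

**Holographic morphometry** (`holography_morphometry`). Digital holography
phase maps are converted to cell thickness through
`Φ = (2π/λ)(n_c − n_m) T`, so the maximal thickness of a cell is
`T_max = (λ/2π)·max Φ/(n_c − n_m)` with reference indices n_c = 1.38,
n_m = 1.34 at λ = 635 nm. Cohorts are summarised as ⟨T_max⟩ ± SEM.

**Indentation protocol** (`indentation_protocol`). The train of progressive
indentations D = 8, 10, …, 18 μm from a rest height h₀ = 20 μm at
v = 3 μm/s with a 40 s dwell; tip height `Z = h₀ − D`, indentation depth
`δ = ⟨T_max⟩ − Z`, and the corresponding G-code motion program.

**Trace classification** (`trace_classification`). Dual-channel traces are
reduced to the normalised fluorescence ratio `R = (F340/F380)/FR₀`. A cell
is *responsive* when, before membrane rupture (a rapid simultaneous drop of
both channels with R flat thereafter), R shows a transient peak that exceeds
the activation threshold R_T, is at least w = 30 s wide at baseline, and
coincides with an F340 peak and an F380 dip. The event inherits the depth δ
of the indentation that elicited it.

**Cohort statistics** (`cohort_statistics`). Activation rate
`AR = responsive/total` per group, its depth-resolved histogram AR_δ, the
sweep of AR over R_T ∈ [0, 4.5], and threshold selection as the median of
the stable interval between the point where the calcium-free control
silences and the largest threshold at which any group still responds.

## Worked example

```python
import numpy as np
from mechanoindent import (
    ProtocolConfig, build_train, depth_map, build_report,
    classify_cohort, select_threshold, threshold_sweep,
)
from mechanoindent.synthetic_data import CohortSpec, TraceGenConfig, gen_cohort

train = build_train(ProtocolConfig())          # D = 8..18 um, v = 3 um/s, 40 s dwell
depths = depth_map(train, tmax_mean_um=9.2)    # delta = <T_max> - Z per step

cfg = TraceGenConfig()                         # 440 ms frames, 40 s FWHM transients
traces = []
for group, n, frac in [("WT", 33, 0.18), ("Piezo1", 28, 0.32), ("CaFree", 16, 0.0)]:
    spec = CohortSpec(group_name=group, n_cells=n, responsive_fraction=frac, seed=1)
    traces += gen_cohort(spec, cfg, train, peak_amplitude=3.5)

sweep = threshold_sweep(traces, train, depths)           # AR(R_T) over [0, 4.5]
rt = select_threshold(sweep, control_group="CaFree")     # median of the stable interval
report = build_report(classify_cohort(traces, train, depths, rt), sweep, rt, depths)

print(f"selected R_T = {rt:g}")
for group, ar in report.ar_percent.items():
    print(f"AR[{group}] = {ar:.1f}%  (n = {report.n_per_group[group]})")
```

prints

```
selected R_T = 2.5
AR[WT] = 18.2%  (n = 33)
AR[Piezo1] = 32.1%  (n = 28)
AR[CaFree] = 0.0%  (n = 16)
```

The threshold lands at 2.5 because the calcium-free control (whose only R
excursions are sub-threshold spontaneous fluctuations) silences at R_T = 1.5
while the largest transients reach R ≈ 3.5; the activation rates recover the
responsive fractions the cohorts were generated with — here one responsive
cell short of a third of the Piezo1-overexpressing group against roughly one
in five wild-type cells, and nothing in calcium-free buffer, where no
extracellular calcium can enter through mechanically opened channels.

A command-line interface mirrors the library: `mechanoindent protocol`,
`mechanoindent calibrate`, `mechanoindent morphometry`,
`mechanoindent classify`, `mechanoindent stats` and
`mechanoindent simulate {traces,stage,phase-map}`. See `--help` on each.

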