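# octaflow

Semiquantitative OCT angiography (OCTA) processing for repeated-B-scan
amplitude volumes, plus a correlated-speckle flow phantom that makes the
whole pipeline testable at desk scale.

OCTA highlights moving erythrocytes by comparing repeated B-scans of the
same tissue position: between two repeats separated by the interscan
time τ, amplitude decorrelation

&nbsp;&nbsp;&nbsp;&nbsp;*D* = (*A*₁ − *A*₂)² / (*A*₁² + *A*₂²)

grows monotonically with the distance the scatterers travelled, up to a
saturation set by the optical resolution element. Acquiring the same
field with several raster patterns at different interscan times —
256 × 256 A-scans at 1.5 ms, 512 × 512 at 3.0 ms, 1024 × 1024 at 5.8 ms
— and summing their depth-layer projections therefore grades capillary
flow speed over a wider range than any single acquisition. The package
implements the full chain used in kidney ischemia–reperfusion imaging:

1. **Decorrelation** — average of the M−1 consecutive-pair difference
   images per B-scan position (two images for the standard M = 3), with
   structural-intensity noise masking;
2. **Surface segmentation** — adaptive threshold crossing plus median
   filtering, so depth layers can be referenced to the tissue surface;
3. **En-face projection** — maximum of D over physical depth slabs below
   the surface (superficial 50–70 µm; deep 320–340 µm);
4. **Multiscale fusion** — per-pattern projections resampled to a common
   grid and summed (all three patterns for the superficial layer, 256 and
   512 only for the deep layer), with pseudocolor rendering;
5. **Flow index** — total fused signal over a circular ROI, normalized
   per subject to baseline (F̂ = F / F_baseline);
6. **Statistics** — exact Wilcoxon signed-rank tests against baseline
   within groups, exact Mann–Whitney rank-sum tests between groups, and
   least-squares correlation of the mean 45/60-minute F̂ with a
   per-subject outcome.

The phantom simulator generates repeat-B-scan speckle volumes whose
frame-to-frame field correlation follows ρ(v, τ) = exp(−(vτ)²/2w²), with
a curved surface under a noise-only medium, two vascular layers at
protocol depths, and multi-subject cohort timelines (baseline, ischemia,
1–60 min reperfusion) with known ground truth. See
[docs/methods.md](docs/methods.md) for the model, parameter choices and
limitations.

## Worked example

Simulate a two-group ischemia–reperfusion cohort (8 "mild" subjects that
recover fully, 9 "moderate" subjects with a sustained 0.4× superficial
deficit from 15 min) and run the whole pipeline in memory:

```python
from octaflow.pipeline import cohort_flow_table
from octaflow.metrics import (timecourse_stats, reperfusion_representative,
                              outcome_correlation)
from octaflow.studies import (mini_phantom, mini_patterns, mini_layers,
                              mini_roi, recovery_cohort)

table, truth = cohort_flow_table(
    recovery_cohort(seed=42), mini_phantom(), mini_patterns(),
    mini_layers(), roi=mini_roi(),
)
print(table.groupby(["group", "layer", "time_point"])["F_hat"]
           .median().unstack("time_point").round(2))
```

```
time_point               1    15    30    45    60  baseline  ischemia
group    layer
mild     deep         1.07  1.00  0.97  0.98  1.14       1.0      0.08
         superficial  0.91  0.89  0.95  0.92  0.99       1.0      0.08
moderate deep         0.76  0.94  0.96  0.61  0.63       1.0      0.06
         superficial  1.13  0.48  0.43  0.45  0.38       1.0      0.10
```

Baseline is 1 by construction; during ischemia the flow signal collapses
to the noise floor (F̂ ≈ 0.08); the moderate group's superficial F̂
tracks its true 0.4× deficit from 15 min while the mild group stays
near 1. The between-group rank-sum tests flag that deficit:

```python
stats = timecourse_stats(table)
print(stats.between[stats.between.layer == "superficial"])
```

```
      layer time_point  n_1  n_2  p_value  significant
superficial   ischemia    8    9 0.235870        False
superficial          1    8    9 0.015220         True
superficial         15    8    9 0.000082         True
superficial         30    8    9 0.000082         True
superficial         45    8    9 0.000082         True
superficial         60    8    9 0.000082         True
```

(The 1-minute flag is a chance finding — both groups truly sit at
multiplier 1 there; with per-time-point testing at α = 0.05 such
false positives are expected occasionally.) Correlating the mean
45/60-minute F̂ with the simulated outcome (generated at R² = 0.75
against the superficial deficit) recovers the generating relationship:

```python
rep = reperfusion_representative(table)
print(outcome_correlation(rep, truth.outcomes).table.round(3))
```

```
      layer   slope  intercept  r_squared   n
       deep -29.650     54.709      0.593  17
superficial -30.341     51.171      0.757  17
```

## Command line

A small ready-made configuration lives at `examples/config.json`.

```sh
octaflow schema                                   # JSON config schema
octaflow all --config examples/config.json --seed 1   # simulate + process
octaflow simulate --config config.json            # volumes only (TIFF + sidecar)
octaflow octa vol.tiff --out octa.tiff            # one-stage commands:
octaflow enface vol.tiff --layer superficial --out sup.tiff
octaflow fuse --layer deep --map 256=a.tiff --map 512=b.tiff --out fused.tiff
octaflow index fused.tiff --out indices.csv
octaflow stats flow_indices.csv --out-prefix stats
```

Volumes are multi-page TIFFs (pages ordered position-major,
repeat-minor) with a JSON sidecar carrying the scan pattern, interscan
time, pixel pitches and seed; round trips are bit-exact. Every run
writes its resolved configuration and root seed next to its outputs.

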