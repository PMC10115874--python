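# Methods

## Background and scope

Optical coherence tomography angiography (OCTA) derives motion contrast
from repeated B-scans at the same tissue position: moving erythrocytes
decorrelate the backscattered speckle between repeats while static
tissue does not. Because the mean distance travelled during the
interscan time tau sets the decorrelation, and that distance saturates
once it reaches the optical resolution element, acquiring the same field
at several interscan times and summing the projections grades capillary
flow speed semiquantitatively over a wider range than any single
acquisition.

`octaflow` implements this processing chain for repeated-B-scan
amplitude volumes — decorrelation computation, automatic surface
segmentation, depth-referenced en-face maximum projection, multiscale
fusion, circular-ROI flow indices with baseline normalization, and the
nonparametric time-course statistics used in ischemia–reperfusion
experiments — together with a correlated-speckle flow-phantom simulator
that makes every stage testable without instrument data. Physical OCT
signal formation (interferometry, dispersion, k-clocking) and bulk-motion
correction are out of scope; acquisition is assumed motion-stabilized.

## Decorrelation metric

For nonnegative amplitudes of two repeats the per-pixel decorrelation is

    D = (A1 − A2)^2 / (A1^2 + A2^2),

with D = 0 where both amplitudes vanish (no evidence of flow). This
normalized squared difference is bounded in [0, 1] and invariant to
global gain; the normalization is isolated in one function
(`pairwise_decorrelation`) so an alternative convention (e.g. dividing
by the mean squared amplitude) can be swapped without touching the rest
of the chain. With M repeats per position the M−1 *consecutive* pairs
are averaged (`octa_bframe`); for the standard M = 3 this averages
exactly two difference images. The non-adjacent pair (1, 3) is excluded
because its effective interscan time is doubled, which would mix two
different speed scales into one map.

Noise masking: decorrelation of pure noise is large, so without masking
the background dominates projections. Before projection D is zeroed
wherever the structural (repeat-mean) amplitude falls below a threshold;
`"auto"` estimates it as mean + k·SD of the above-surface noise region
(top `noise_rows` depth rows), k = 3 by default. The threshold is a
logged configuration value, not part of the decorrelation definition.

## Surface segmentation

Layer projections are referenced to the automatically segmented tissue
surface. Per A-line the axial profile is median-smoothed (window 3,
which unlike a linear filter does not displace an intensity step), then
the first sample exceeding an adaptive threshold (noise mean + k·SD from
the top rows, k = 4) marks the surface. A-lines without a crossing are
flagged and filled from the nearest segmented neighbour
(Euclidean-distance transform), and the height map is cleaned with a
3×3 median filter. If more than half of a volume's A-lines have no
crossing the segmentation raises instead of guessing. On synthetic
tilted and curved surfaces at amplitude SNR 10 the recovered surface is
well within 2 voxels RMS of the generating profile (measured ≈ 0.3).

## Projection, fusion, flow index

A layer is a physical depth slab (d1, d2) in micrometres below the
surface; the axial pitch from the volume metadata converts it to voxel
offsets `round(d/pitch)`, inclusive at both ends and clipped to the
volume (an A-line whose clipped slab is empty projects 0; only a slab
that misses the volume everywhere is an error). Defaults follow the
renal-cortex protocol: superficial 50–70 µm fused from the 256, 512 and
1024 rasters; deep 320–340 µm fused from 256 and 512 only, the 1024
pattern's long interscan time being saturated at those speeds. (An
alternative reading of the deep range as 220–340 µm exists; 320–340 µm
is used because it matches the superficial slab's 20 µm thickness, and
the range is fully configurable.)

Per-pattern maximum projections are resampled to a common grid —
bilinear, pixel centers aligned at the field-of-view corners, defaulting
to the finest contributing grid — and summed with equal weights. No
inter-pattern registration is applied by default (sequential acquisition
under fixation); the fusion stage operates on aligned grids.

The flow index F is the sum of the fused image over a circular ROI
(pixel centers within Euclidean distance ≤ r). The protocol does not
pin down the ROI geometry; the default is a centered circle of radius
0.4 × min(image dims), always recorded in the run log. Each subject's
indices are divided by that subject's baseline value, so the
dimensionless F̂ is exactly invariant to any per-subject global gain —
the stated purpose of baseline normalization.

## Statistics

Within each group, F̂ at every post-baseline time point is compared to
the baseline value 1 with an exact two-sided Wilcoxon signed-rank test;
between the two groups F̂ is compared per time point and layer with a
two-sided Mann–Whitney rank-sum test, exact whenever the pooled sample
is untied (forced at these sample sizes — scipy's default would switch
to the normal approximation above n = 8). All-zero difference vectors
return p = 1. No multiplicity correction is applied by default,
matching per-time-point reporting; Holm adjustment is available. The
representative short-term reperfusion index is the mean of F̂ at 45 and
60 minutes, correlated with a per-subject outcome by ordinary least
squares (R² = 1 − SS_res/SS_tot, n ≥ 3 required; a zero-variance
outcome reports R² as not applicable).

## Speckle phantom

Each voxel's repeat sequence is an order-1 autoregressive chain of
circular-Gaussian complex fields,

    E_{k+1} = rho · E_k + sqrt(1 − rho^2) · xi_k,
    rho(v, tau) = exp(−(v·tau)^2 / (2 w^2)),

so every *consecutive* pair has field correlation rho — matching the
consecutive-pair processing downstream. Only monotone decay of rho with
displacement is physically required; the Gaussian law is the standard
choice for a Gaussian beam and is configurable, with the resolution
radius w defaulting to 4 µm (half a typical ~8 µm spot). Amplitude is
the field modulus (Rayleigh speckle, scale set so the mean tissue
amplitude is 1) plus additive Gaussian noise clipped at zero; voxels
above the surface contain noise only, so surface segmentation is
nontrivial. The Monte-Carlo oracle `analytic_decorr_oracle` computes
E[D] for correlated Rayleigh pairs by brute force; the frozen rho = 0
plateau is 0.21461 (2×10⁷ draws), and simulated voxel populations agree
with the oracle within Monte-Carlo error at all tested correlations.

Cohort simulation adds the experiment design: groups of subjects on the
baseline / ischemia / 1–60 min timeline, per-layer flow-speed
multiplier schedules (ischemia is forced to multiplier 0), a
subject-level lognormal speed factor with configurable CV (default
0.15) emulating intersubject variation in absolute flow, and a linear
per-subject outcome (outcome = a + b·true late-reperfusion multiplier +
noise) standing in for a late fibrosis readout. Ground-truth tables are
emitted for recovery testing.

### What the phantom does and does not emulate

It reproduces the features the pipeline's correctness depends on:
speed- and tau-dependent speckle decorrelation with saturation, a
curved surface under a noise-only medium, two vascular layers at
protocol depths, intersubject gain/flow variation, and the cohort
timeline. It does **not** model vessel geometry beyond cylinders
(disks × depth slab), flow profiles within a vessel, hematocrit or
vessel-caliber dependence, depth-dependent signal roll-off, bulk
motion, or multiple scattering. Passing tests therefore validate the
*processing* — they do not certify accuracy on real tissue, where those
effects add bias terms the baseline normalization only partly removes.

## Study conditions and numerical choices

Replicate studies use scaled-down stand-ins for the instrument rasters:
24 × 8 A-lines over a 0.288 × 0.096 mm field (12 µm lateral pitch) at
the protocol's interscan times 1.5 / 3.0 / 5.8 ms, over a 42-voxel-deep
grid at 12 µm axial pitch; groups of 8 and 9 subjects. These sizes keep
a full two-group, seven-time-point, three-pattern cohort under a second
of compute so hundreds of replicate cohorts are practical, while every
stage runs exactly the code used at full size (all array operations
accept leading batch axes, so a whole cohort is processed in single
vectorized calls).

Baseline capillary speeds are 0.55 µm/ms (superficial) and 0.9 µm/ms
(deep) — realistic red-cell speeds — calibrated once by a pilot
measurement of the fused flow-index-versus-speed response so that the
response is within about ±12% of proportional over multipliers 0.4–1.2.
Two effects push the operating point below the single-tau theoretical
optimum: the maximum projection's upper-tail bias inflates weak signals,
and the noise floor (0.02 relative to unit amplitude, i.e. amplitude
SNR 50) adds a small background that the ROI sum carries along. At this
operating point replicate cohorts recover ground-truth multipliers
within ±20% (observed worst case ≈ 12%), the ischemia time point
collapses to F̂ ≈ 0.07, a 0.4× superficial deficit from 15 min is
detected by the rank-sum test in ≈ 100% of cohorts, and the between-
group type-I error rate sits at ≈ 0.04 (slightly conservative, as
expected for a discrete exact test thresholded at 0.05).

Other numerical conventions: µm→voxel conversion rounds to nearest with
inclusive slab ends; resampling preserves constants exactly; ties and
zero differences in the rank tests follow scipy's exact-conditional
conventions; all randomness in a run flows from one recorded root seed,
and identical seeds give bit-identical volumes, tables and CSVs.

## Known limitations

- The decorrelation–speed response is only piecewise-linearizable; the
  semiquantitative index grades speeds, it does not measure them. Real
  instruments need the same kind of calibration this package performs
  on its phantom.
- The noise mask threshold and ROI geometry are conventions, not
  protocol constants; both are logged per run.
- The surface finder assumes the medium above the tissue contributes
  noise only (no specular reflections).
- Statistics assume two groups; more require a different design.
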