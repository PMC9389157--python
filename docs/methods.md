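# Methods

This note records the models, estimators, parameter choices and numerical
conventions behind `tenmech`, and what the synthetic-data tests do and do not
demonstrate about real instrument data.

## Force-volume AFM

**Model.** Each pixel's approach curve (piezo extension `z`, cantilever
deflection `d`, both nm) is modelled as a flat baseline followed by an
elastic contact branch. Force is `F = k·(d−d₀)` (spring constant `k`,
baseline offset `d₀`) and indentation `δ = (z−z₀) − (d−d₀)`. Two contact
laws are supported: the four-sided pyramid
`F = C·tan(α)·E/(1−ν²)·δ²` with geometry coefficient `C` (default 0.7453,
the Bilodeau convention — both this and cone-type coefficients circulate in
AFM practice, so `C` is a configurable knob recorded in output metadata) and
the Hertz sphere `F = (4/3)·E/(1−ν²)·√R·δ^{3/2}`.

**Probe defaults** (all configurable, all must be supplied for real data):
spring constant 0.06 N/m, tip half-angle 18°, tip radius 20 nm, Poisson
ratio 0.5 (incompressible soft tissue), deflection trigger 40 nm, approach
speed 6 µm/s (metadata only — the model is rate-independent, so viscoelastic
effects are a known limitation).

**Contact point.** For each candidate index `j`, the curve is fitted
piecewise — constant baseline before `j`, power-law branch (amplitude in
closed form) after — and the total squared residual in deflection units is
minimized. The search runs on a stride-2 grid and refines around the
minimum; it is deterministic with no tuned parameters beyond a minimum
baseline/contact length of 8 samples. A fit is declared invalid (and
excluded, not zero-filled) when the pre-contact segment is not flat: scatter
RMS or linear drift above 5% of the trigger deflection — this catches curves
whose deflection rises from the first sample — or when fewer than 8
post-contact samples carry positive indentation and force.

**Fitting.** The amplitude of `F = A·δ^p` is linear in `E`, so the
least-squares solution over the window from the contact sample to the
trigger deflection is closed-form: `A = Σ F δ^p / Σ δ^{2p}`. The fit is
exactly scale-invariant (rescaling z and d rescales E by the inverse unit
factor). Map summaries use the **median** over valid pixels — modulus
distributions in heterogeneous soft tissue are right-skewed — plus a
relative-frequency histogram (default 5 kPa bins) whose edges can be shared
across treatment groups for comparable panels. A map with more than half
its pixels invalid carries a quality warning.

## Tensile metrics

Engineering conventions: `strain = displacement/gauge length`,
`stress = load/area` (mN/mm² = kPa, reported MPa). The linear region is
found deterministically in two stages: (1) exhaustive scan of contiguous
windows of 20% of the pre-peak samples, keeping the maximum-slope window
whose linear fit reaches the r² floor (default 0.99; ties to the later
window); (2) sample-by-sample expansion on both sides, accepting a sample
only while the whole-window fit stays at or above the floor *and* the
sample's residual against the current fit is within 3× the window residual
RMS. The residual rule matters: r² alone improves as the span grows, so it
cannot detect a curved toe being swallowed; the residual test stops the
expansion at the toe while still returning the whole range for a globally
linear trace. Peak stress is the maximum stress; on exact ties the earliest
sample wins; peak strain is the strain at that sample. Cross-sectional area
is a required input (not estimated).

## Histology

**PSR content**: 8-bit grayscale conversion, Otsu threshold by default (a
fixed threshold mode exists for reproducibility across batches), stained
area fraction in percent.

**Maturity**: per-pixel red:green ratio with inclusive boundaries — red if
I_R/I_G ≥ 1.8, green if ≤ 1.1, yellow strictly between. Pixels whose
maximum channel is at or below the background floor (default 10/255) are
excluded before ratio computation: dark pixels give unstable ratios.
Percentages are over classified (non-background) pixels, configurable.
I_G = 0 with I_R above the floor classifies red (the ratio's limit). The
classification is invariant to common scaling of R and G, so it tolerates
illumination differences that preserve hue. `calibrate_maturity_report`
summarizes reviewer-labeled red/green regions (≥ 20 required) by their
region-mean ratios; it reports, and deliberately does not auto-set, the
cutoffs.

**Nuclei counting**: global threshold → 8-connected components → area
filter (default ≥ 5 px). No watershed declumping: touching nuclei merge,
which is acceptable at the cell densities these assays target and is a
documented limitation. Viability uses one threshold shared across a batch.
H&E counting in practice is manual; `cell_density` simply converts a count
per square tile (default 120 µm side) to cells/mm².

## SHG directionality

The mean-subtracted image is Fourier-transformed; spectral power inside an
annulus (radius 10 px to 0.4×min(H, W), excluding the DC region where
angular resolution collapses and the axis-aligned corner region) is binned
by orientation — the spectrum angle rotated 90°, since a fiber's energy lies
perpendicular to it — into 3° bins over [−90°, 90°). Windowing is off by
default: fiber signal on a dark background has no frame-edge discontinuity,
and a Hann taper (available as `window='hann'` for full-frame tissue images)
reweights fibers by position, which distorts the orientation distribution.

Two statistics are extracted. The **peak angle** and goodness come from a
Gaussian wrapped on the 180° period fitted to the histogram with the
baseline pinned at the 10th percentile and bins weighted by their value
(spectral power carries multiplicative speckle noise). The **dispersion** is
the doubled-angle circular-moment sd of the baseline-subtracted histogram,
trimmed iteratively to ±3 sd about the center (4 iterations). The trimmed
moment was chosen over the fitted Gaussian sd because, under speckle, the
shape fit occasionally misreads broad distributions by several degrees while
the moment stays within ~±3° of the generating angular sd across spreads of
5–30°; the trimming removes the residual-background inflation that plagues
untrimmed circular moments at small spreads. A fit r² below 0.5 sets a
low-goodness flag (isotropic or near-delta spectra; the latter because a
one-bin spike is poorly described by any smooth Gaussian). Dispersion values
are estimator- and parameter-convention-dependent; no cross-study numeric
comparability is claimed.

## Crosslink statistics

Crosslink density is content over dry mass (pmol/mg), for HP, LP and their
sum. The dose-response law is the exponential-plateau convention
`Y = Y_M − (Y_M − Y₀)·e^{−k·x}` with `x` the dose multiplier
({0, 1, 2, 5}; a µg/ml axis is just a rescaling of `k`). The nonlinear fit
is multi-started from 10 log-spaced `k` values in [0.01, 10] per x-unit and
keeps the lowest-SSE solution — deterministic without user tuning; r² is
against the mean-only model. Constant responses return `y0 = ym = const`
with `k` flagged unidentifiable. Regression reports OLS slope/intercept,
Pearson r (r² ≡ r² of the regression by construction) and the exact
t-distribution two-sided p with n−2 df. Group tests: two-sided pooled
t-test (a paired mode exists for contralateral-limb designs), or one-way
ANOVA with Tukey HSD p-values from the studentized-range distribution, one
row per pair.

## Synthetic generators

Each generator emits its data plus a ground-truth record, and is bit-repro-
ducible from (parameters, seed). Noise is additive Gaussian everywhere —
the simplest model sufficient for recovery testing. Defaults describe a
plausible embryonic-tendon experiment: AFM fields of ~tens of kPa with a
40 nm trigger and 0.5 nm deflection noise; tensile moduli of ~40 MPa at 1%/s
with a 5% toe; 8-bit images with stated µm/px scales.

Choices that make closed-loop tests *exact*: PSR class pixel counts follow
largest-remainder rounding (background included as a class) and are laid
down as contiguous blobs by quota-limited multi-seed region growing, with
per-blob brightness varying only by a common channel scale (ratio-
preserving); the apoptotic count is `round(total × fraction)` of the same
disk centers; SHG fibers are equal-length, equal-amplitude segments placed
fully inside the frame so every fiber carries the same spectral weight and
the power-weighted orientation histogram is comparable to the plain sample
sd of the drawn angles.

What the generators do **not** emulate: optics (polarization physics, SHG
point-spread, detector noise statistics), cantilever dynamics and hydro-
dynamic drag, adhesion, stain variability, uneven illumination, cell
morphology, or biological replicate variability. Passing recovery tests
therefore demonstrates the correctness of the estimators under their own
modelling assumptions — not robustness to every artifact of real
micrographs or force curves; the configurable thresholds (backgrounds,
windows, r² floors) exist precisely because real data need them adjusted.

## Pipeline

A run is a validated config (defaults filled, unknown keys rejected,
thresholds range-checked, referenced files existence-checked) plus a root
seed. Per-stage randomness comes from named `SeedSequence` substreams of
the root seed, so stages are independent and the whole run reproduces
byte-identically: CSV floats are written with a fixed format, JSON with
sorted keys, and no timestamps enter any output. Stage failures are
recorded in the manifest while independent stages continue. Demo problem
sizes (16×16 AFM grids, 128–256 px images, 5 replicates per dose) keep the
full pipeline in the seconds range while exercising every code path; all
sizes scale up through the config.
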