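# Methods

## Kinetic model

The tracer model is the irreversible two-tissue compartment model for FDG:
free tracer C1 exchanges with plasma (influx K1 in mL·min⁻¹·mL⁻¹, efflux
k2 in min⁻¹) and is phosphorylated into a trapped pool C2 at rate k3
(min⁻¹); dephosphorylation is neglected over a one-hour scan (k4 = 0).
The measured concentration optionally includes a fractional blood volume
vB; by default vB = 0 (the classic three-parameter brain fit) and it can
be freed within [0, 0.2].  The macro-parameter Ki = K1·k3/(k2 + k3) is the
net trapping flux; when k2 + k3 underflows, Ki is defined as 0 (limit
choice, documented in `compute_ki`).

All activity curves are assumed decay-corrected to injection time, so no
physical-decay term appears anywhere.  Rate constants are per minute;
frame schedules are kept in seconds with explicit converters, so the
printed frame durations stay exact.

### Forward solution and its accuracy

The model curve is the convolution of the plasma input with the analytic
impulse response h(t) = (K1/β)[k3 + k2·e^(−βt)], β = k2 + k3.  Inputs are
piecewise-linear between samples (zero before the first sample, constant
within the final half frame beyond the last).  On a uniform 0.5 s grid the
convolution is evaluated *exactly* for that representation: the running
input integral is the trapezoid (exact for piecewise-linear curves), the
exponential channel uses the closed-form segment integral propagated by a
one-step recursion, and frame averages come from exact running integrals
of the solution (the integral of the exponential channel follows from its
own ODE, ∫y = (Q − y)/β).  Against an independent stiff ODE integrator
(LSODA at rtol 1e−10) the frame-averaged model agrees to better than 1e−5
relative over a broad parameter grid; the tests enforce this.  A series
expansion guards the β·h → 0 limit, and β < 1e−8 falls back to the pure
accumulation limit C = K1·∫Cp.

### Fitting

Weighted nonlinear least squares (scipy trust-region reflective) within
physiological bounds K1 ∈ [0, 1], k2 ∈ [0, 2], k3 ∈ [0, 1] min⁻¹,
vB ∈ [0, 0.2], with five multi-starts: one fixed physiological start and
four drawn from a seeded generator, making fits deterministic given the
config seed.  Frame weights default to frame duration, a robust
approximation to uniform variance rate.  True inverse-variance weighting
under the simulator's multiplicative noise model is pathological — frames
with near-zero activity would carry unbounded weight — and in cohort
experiments it roughly doubled the spread of asymmetry estimates, so it is
not the default; `duration_sq_over_activity` and `uniform` remain
selectable.  Standard errors come from the Gauss–Newton curvature at the
optimum.  Non-convergence is flagged, never silent; an all-zero TAC
returns the lower-bound estimate with a degenerate flag.

## Frame schedule

The default dynamic protocol is 12×5 s, 6×10 s, 6×30 s, 5×60 s, 10×300 s:
39 frames covering exactly 60 minutes.  Clinical descriptions of this
protocol sometimes circulate with a garbled middle group whose arithmetic
(40 frames, 67 min) contradicts both the stated frame count and scan
length; the default here is the unique minimal layout consistent with
39 frames and 60 minutes.  `make_frame_schedule` accepts any
(count, duration) groups laid end-to-end from t = 0, so other protocols
are one call away.

## Image-derived input function

The carotid measurement mixes the true input with surrounding activity,
Cmeas = RC·Cinput + SP·Cbkgd; the correction inverts this pointwise and
clips (and counts) small negative early-frame samples.  No venous-sample
scaling is applied anywhere: the downstream asymmetry index is invariant
under a common rescaling of both hemispheres, which is precisely why an
uncalibrated IDIF is admissible.

RC and SP are estimated from a phantom simulation: an infinite uniform
cylinder (default diameter 6 mm, an adult common carotid) in a uniform
background, blurred by an isotropic Gaussian at the reconstructed
resolution (FWHM/√(8 ln 2) → σ), sampled on a 0.1 mm in-plane grid (the
z-invariance of the cylinder makes the 2-D computation exact for every
slice).  RC is the ROI mean of the blurred vessel-only image, SP of the
blurred background-only image; with a normalized blur the two sum to 1
(signal conservation), and RC decreases / SP increases monotonically with
FWHM — both properties are asserted in the tests, along with agreement
within 1 % against a brute-force explicit-kernel convolution.

## Regions

Any integer label volume plus a TSV lookup table (label_id, name,
hemisphere, homolog_id) serves as the atlas; no reference atlas is
bundled.  The homolog map must be an involution, hemispheres come from
the table (never from coordinate signs), extraction is the frame-wise
voxel mean, and merged VOIs (id tuples) pool voxels with volume weighting.
Spatial normalization is a precondition: volumes and atlas must share a
grid.  Static concentrations are used raw (no SUV normalization): the
asymmetry index is scale-invariant, so the choice is immaterial.

## Asymmetry conventions and statistics

ASYM = (contra − ipsi)·2/(contra + ipsi), positive for a hypometabolic
focus.  Patients contribute signed ASYM of the epileptogenic region;
controls, who have no focus side, contribute the mean *absolute*
left/right ASYM over the six focus-type evaluation regions; reference
(non-epileptogenic) regions are pooled per subject as absolute ASYM.
Reports label the convention per row.

"Wilcoxon rank test" resolves by data structure: independent groups
(patients vs controls) use the rank-sum / Mann–Whitney form;
within-patient comparisons across parameters use the paired signed-rank
form.  For combined n ≤ 12 (rank-sum) or ≤ 12 nonzero differences
(signed-rank) p-values come from exact enumeration of the permutation
null on midranks; larger samples use the normal approximation with tie
correction.  Degenerate all-tied samples return p = 1 with a flag.
Spearman correlations use midranks with the two-sided t approximation
(approximate below n = 20, as documented).  No multiple-testing
correction is applied by default; a Holm step-down option exists.
Correlation matrices are emitted fully symmetric; undefined correlations
(constant columns) are reported missing rather than imputed.

## Synthetic cohort

The generator's defaults are the emulated study conditions: 17 patients,
8 controls, the 39-frame protocol, and epileptogenic micro-parameter
asymmetries centred on the reported patient cohort means (K1 0.12,
k2 0.14, k3 0.21).  Design choices:

* **Input function** — continuous Feng tri-exponential bolus,
  Cp(u) = (A1·u − A2 − A3)e^(−λ1 u) + A2·e^(−λ2 u) + A3·e^(−λ3 u) for
  u = t − τ ≥ 0 (defaults A1 = 800 kBq·mL⁻¹·min⁻¹, A2 = 20, A3 = 21
  kBq·mL⁻¹, λ = 4.1, 0.01, 0.12 min⁻¹, τ = 0.5 min), continuous at onset
  and peaking ~45 s after appearance.  Per-subject dose proxies jitter
  the amplitude ±20 %; absolute scale is immaterial to ASYM.
* **Asymmetry injection** — only the micro-parameters are asymmetric:
  contralateral values are drawn uniformly from gray-matter ranges
  (K1 0.08–0.12, k2 0.10–0.16, k3 0.04–0.08) and the ipsilateral value is
  the exact inversion ipsi = contra·(2 − a)/(2 + a) of a truncated-normal
  ASYM draw.  Ki and static-AC asymmetry are never injected — they emerge
  from the kinetics, preserving the causal structure (phosphorylation
  drives hypometabolism) and making the Ki-consistency test meaningful.
  Between-subject ASYM sd defaults to 0.05 (a modelling choice; the
  emulated study reports only means); controls default to exactly zero
  true asymmetry, reference regions to sd 0.02 biological jitter.
* **Noise** — zero-mean Gaussian per frame with
  sd = CV·value·√(T_ref/T_frame), T_ref = 5 s: the stated CV applies to
  the shortest frames and longer frames are proportionally less noisy
  (0.39 % on the 5-minute frames at CV 3 %), a plausible profile for
  VOI-level means.  True Poisson sinogram physics, attenuation, scatter,
  motion and dispersion are out of scope, so passing tests demonstrate
  estimator correctness under this idealized noise, not robustness to
  reconstruction artefacts.
* **Carotid time base** — the carotid/background curves are recorded per
  time sample (≤2 s effective samples during frames ≤30 s, ≤30 s within
  the 1–5 min frames), emulating fine early rebinning.  One sample per
  5-minute frame would force the piecewise-linear input reconstruction
  through 5-minute chords and bias fitted k2 by ~1 %; with the sub-frame
  base the noiseless end-to-end recovery error is below 0.03 %.
* **Static scan** — emulated as the 45–60 min average of the noiseless
  model curve plus CV-level noise, not a separate acquisition.
* **Seeds** — one master seed spawns independent per-subject child
  streams (`SeedSequence`), so cohorts are bit-reproducible and
  insensitive to subject order.

## Pipeline

A run is a validated config (pydantic, YAML-loadable) plus a master seed;
it writes a self-contained directory (manifest with config hash, truth,
TAC/carotid tables, fits, ASYM table, statistics, markdown report whose
every number is read back from the emitted tables).  Re-running with
`resume` over a completed identical-config run does nothing.  Exit codes:
0 success, 2 config error, 3 data error, 4 convergence failure when
configured fatal.  The acceptance experiment uses 17 patients with the
epileptogenic region pair only (34 fits, a few seconds); unit and
integration tests use 2–5 subject cohorts — sizes chosen to exercise every
code path at desk scale while the full 25-subject default remains one
config line away.

## Known limitations

VOI-level only (no voxelwise parametric maps); irreversible model only
(no k4, no reference-tissue models); no registration or carotid
segmentation (inputs must share a grid); the exact-enumeration tests are
O(2^n)/O(C(n, k)) and deliberately capped at combined n = 12; Spearman
p-values are approximate at study-sized n.
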