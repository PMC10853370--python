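# Methods

## The ALPS model and its geometric premise

The ALPS index rests on an anatomical idealization at the level of the
lateral ventricle body: projection-fiber tracts run inferior–superior
(image *z*), association-fiber tracts anterior–posterior (image *y*),
and the medullary perivascular space runs left–right (image *x*),
orthogonal to both. Diffusivity along *x* inside the two fiber regions is
therefore read as perivascular water transport, and the index

ALPS = mean(D<sub>xx</sub><sup>proj</sup>, D<sub>xx</sub><sup>assoc</sup>) /
mean(D<sub>yy</sub><sup>proj</sup>, D<sub>zz</sub><sup>assoc</sup>)

normalizes it by the fiber-perpendicular diffusivities. The package
evaluates the index per hemisphere from four 5 mm spherical ROIs and
averages hemispheres for the wholebrain value. D<sub>xx/yy/zz</sub> are
tensor *diagonal elements in the image frame*, deliberately not
eigenvalues — the method's premise is that the relevant axes are the
image axes.

## Phantom design

Each synthetic subject is a voxel grid (default 32×32×20 at 2 mm
isotropic; a 16×16×10 "small" variant with identical tissue parameters is
used for fast studies) containing four homogeneous tensor spheres — {left,
right} × {projection, association} — in an isotropic background
(0.8×10⁻³ mm²/s). Region tensors are diagonal, which is the ALPS
idealization itself and keeps the subject's true index in closed form:

- projection: diag(1.0, 0.7, 1.7) × 10⁻³ mm²/s (z-dominant),
- association: diag(1.0, 1.7, 0.7) × 10⁻³ mm²/s (y-dominant),

giving a baseline ALPS of 10/7 ≈ 1.43, a realistic healthy value that
brackets the clinically reported discrimination threshold (≈1.2) once
impairment is applied. All diffusivities are constrained to
(0, 4×10⁻³) mm²/s, the physical range of water at body temperature.

Glymphatic impairment is modelled as a multiplicative attenuation of the
*x*-axis diffusivity inside both fiber regions — exactly the component
the ALPS numerator averages — so the planted effect is interpretable and
the true index remains closed-form. Group attenuation defaults are
1.0 / 0.85 / 0.70 for pre-RT / post-RT-RE− / post-RT-RE+; these are
generator conventions chosen to produce a clear, ordered effect, not
estimates of the clinical effect size.

## Acquisition and noise model

The simulated acquisition mirrors a single-shell clinical DTI protocol:
one b=0 volume plus 30 directions at b = 1000 s/mm². The direction set is
a deterministic spherical Fibonacci lattice (minimum pairwise angle
≈ 33° at n=30), removing scanner-specific direction tables as a hidden
source of variance. Signals follow the monoexponential tensor model
S = S₀·exp(−b·gᵀDg); noise is Rician, implemented as the magnitude of a
complex Gaussian perturbation with per-channel standard deviation σ. SNR
is defined as S₀/σ and defaults to 30 — an assumption (documented, not a
measured scanner property) typical of 3 T echo-planar DTI.

## Cohort generator

Cohorts default to the three-group structure 35 / 58 / 16 (n = 109).
Between-subject variability multiplies every region-diagonal entry by
1 + cv·ε (ε ~ N(0,1), cv default 0.05), independently per subject,
hemisphere, region, and axis; this is what gives the index a realistic
spread (≈5–7% CV) and makes table-level calibration studies meaningful.
Post-RT subjects receive an ipsilateral maximum radiotherapy dose (MDRT)
drawn from N(67, 7.6²) Gy, matching published cohort summaries; the
subject's x-attenuation is reduced by `dose_slope` (default 0.02) per
dose SD, planting a recoverable negative dose–ALPS correlation of
moderate size. Pre-RT subjects carry no dose.

A master seed spawns per-subject seeds through `numpy.random.SeedSequence`,
so cohorts are bit-reproducible and any subject can be regenerated alone.
`simulate_cohort_table` draws the same per-subject parameters without
synthesizing images, for calibration studies that only need tables.

What the generator does **not** emulate: motion, eddy currents,
susceptibility distortion, partial-volume mixing, crossing fibers,
anatomically realistic background, or atlas registration. Passing tests
therefore demonstrate correctness of the estimation and statistics
chain under the ALPS geometric idealization, not robustness to real-world
artifacts — on patient data those preprocessing steps remain necessary
and are out of scope here.

## Tensor estimation

Per-voxel ordinary least squares on log-signals (log-linear fit), the
standard first-pass DTI estimator; it inverts the noiseless model
exactly, which the tests exploit for machine-precision round trips.
Numerical choices:

- The design matrix columns are equilibrated by b<sub>max</sub> before
  solving (condition number ≈ 13 versus ≈ 3×10³ for the raw SI-units
  matrix); the recovered tensor is rescaled afterwards.
- Signals ≤ 0 (possible under magnitude noise) are floored to a tiny
  positive constant before the logarithm.
- Negative eigenvalues are clamped to zero by eigen-reconstruction and
  the affected voxel count reported; no refitting, so the correction is
  deterministic and auditable. A weighted or nonlinear fit would reduce
  the small Rician bias (< 2% at SNR 30) and is a possible extension.
- In-mask voxels with no usable signal are flagged invalid and excluded
  from ROI means; an ROI with more than 50% invalid voxels raises a
  quality-control error.
- The principal eigenvector's sign is canonicalized (largest-magnitude
  component non-negative) so color-FA maps are reproducible.

## ROI discretization

A voxel belongs to a spherical ROI when its center lies within the
closed ball. The rule matters: a 5 mm sphere on a 2 mm grid centered on
a voxel center contains exactly 7 voxels (center + 6 face neighbors).
ROI centers are configuration with phantom-space defaults; atlas-space
placement and manual adjustment, as practiced on patient data, are not
reproducible without the atlas and rater and are out of scope. ROI means
are plain arithmetic means — no trimming, since the clinical procedure
specifies none.

## Statistics

All statistics are implemented at formula level (scipy supplies only
distribution functions):

- One-way fixed-effects ANOVA, from raw data or from printed (n, mean,
  SD) summaries — the latter allows published demographic tables to be
  checked without raw data.
- LSD post hoc: pairwise t on the pooled ANOVA error, df = N − k,
  deliberately without multiplicity correction (that is the method's
  definition). Null simulation confirms the per-comparison type-I rate.
- Pooled-variance two-sample t (not Welch), consistent with the
  ANOVA/LSD framework.
- Pearson r with Fisher-z CI, tanh(atanh r ± z/√(n−3)), and a t-based
  two-sided p. The companion `ci_from_r_n` reconstructs intervals from a
  printed (r, n) pair; n = 38 is the unique sample size in [4, 109]
  whose 95% half-width reproduces both published dose-correlation
  intervals, and is used as a derived, not stated, quantity.
- Pearson chi-squared without continuity correction; expected cells < 5
  trigger a warning but no automatic switch to exact tests.
- ROC: thresholds at midpoints between adjacent distinct scores plus ∓∞
  sentinels. The positive class is RE+ and the default orientation is
  lower-positive (a lower ALPS index predicts RE), matching the clinical
  direction of the effect. Trapezoidal AUC equals the Mann–Whitney
  pair-probability with ties counted ½ (verified exhaustively in tests);
  the Youden cutoff maximizes sens + spec − 1 with ties broken toward
  higher sensitivity, then the lower threshold. AUC grades: ≥0.9
  excellent, 0.7–0.9 good, 0.6–0.7 fair, else poor.
- All tests two-sided at α = 0.05; CI level 95% unless configured.

## Pipeline determinism and problem sizes

A run is a pure function of its `RunConfig`; the SHA-256 hash of the
canonical config JSON stamps every artifact, and reruns are
byte-identical. The bundled studies use the reduced 16×16×10 phantom:
since ALPS only reads ROI voxels and tissue parameters are
grid-independent, the small grid changes nothing about the index while
keeping a 109-subject cohort under a second to simulate and fit. The
power study uses 100 seeded cohorts; null calibration uses 1000
table-level replicates (type-I rate) and 50 seeded cohorts (AUC band).

## Known limitations

- The ALPS geometric premise is taken as given; the phantom cannot probe
  its anatomical validity.
- No preprocessing chain (brain extraction, motion/eddy correction,
  registration) is implemented; synthetic data are artifact-free by
  construction.
- The log-linear fit carries a small Rician bias at low SNR; clamping
  reports but does not repair degenerate voxels.
- Null-cohort AUC variability is governed by group sizes: at the 58/16
  split of the modeled cohort the null AUC has standard deviation
  ≈ 0.08, so individual zero-effect cohorts frequently fall outside
  ±0.1 of 0.5 — a sample-size fact worth keeping in mind when reading
  single-cohort AUCs at this scale.
- Statistical conventions (pooled t, no Yates correction, LSD without
  adjustment) mirror the clinical analysis they reproduce; they are not
  recommendations for new study designs.
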