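# alpskit

Synthetic-phantom pipeline for the **DTI-ALPS index** — the
diffusion-tensor measure of glymphatic (perivascular fluid-exchange)
function — with the full statistical battery used to characterize
radiation-induced glymphatic impairment in nasopharyngeal-carcinoma
patients after radiotherapy.

No patient imaging is required or used: the package generates
diffusion-weighted MRI phantoms whose ground-truth ALPS index is known in
closed form, so every stage of the analysis — tensor fitting, ROI
extraction, group statistics, diagnostic ROC — can be validated end to
end. It is aimed at neuroimaging methodologists who want a tested,
reproducible reference implementation of the ALPS procedure and at
readers who want to audit the arithmetic behind the published cohort
statistics.

## The method

At the level of the lateral ventricle body, projection fibers run
inferior–superior (*z*), association fibers anterior–posterior (*y*), and
the perivascular space left–right (*x*), perpendicular to both fiber
populations. Water mobility along *x* inside those fiber regions is
therefore attributed to perivascular (glymphatic) transport. With
D<sub>xx</sub>, D<sub>yy</sub>, D<sub>zz</sub> the diagonal elements of
the diffusion tensor in the image frame (not eigenvalues), the index is

```
ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)
```

evaluated in 5 mm spherical ROIs placed in the projection and association
areas of each hemisphere; the wholebrain value is the mean of the left
and right indices. ALPS ≈ 1 means no preferential perivascular
diffusivity; lower values indicate poorer presumed glymphatic transport.

The pipeline stages, each usable on its own:

- **phantom** — tensor-field phantoms implementing the geometry above,
  monoexponential DWI simulation (one b=0 + 30 directions at
  b=1000 s/mm², 2 mm isotropic voxels) with Rician noise, and a
  three-group cohort generator (35 pre-RT / 58 post-RT-RE− / 16
  post-RT-RE+) with configurable glymphatic-impairment effect sizes and a
  planted negative dose–ALPS coupling.
- **tensorfit** — log-linear least-squares tensor fit; FA, MD, principal
  direction, color-FA, and the axis-wise diffusivity maps.
- **alps** — spherical-ROI extraction and the index itself.
- **cohortstats** — formula-level one-way ANOVA, LSD post hoc, Pearson
  correlation with Fisher-z intervals, chi-squared, pooled t, and
  ROC/AUC/Youden analysis.
- **pipeline / cli** — one-command reproducible runs.

## Worked example

```python
from alpskit.pipeline import default_run_config, run_pipeline, format_report

config = default_run_config(seed=42, small=True)   # 16x16x10 voxel phantom
report = run_pipeline(config)
print(format_report(report))
```

prints (abridged):

```
alpskit run  config=7023a0c5c1589deb  seed=42
subjects: 109  clamped voxels: 0

alps_wholebrain: F(2,106) = 225.364, p = 6.639e-39
  LSD pre-RT vs post-RT-RE-: diff = +0.2096, p = 1.769e-25
  LSD pre-RT vs post-RT-RE+: diff = +0.4394, p = 8.696e-39
  LSD post-RT-RE- vs post-RT-RE+: diff = +0.2298, p = 2.423e-20

corr alps_left~mdrt_left: r = -0.416 [-0.589, -0.207], p = 0.0002254 (n=74)

ROC alps_wholebrain: AUC = 0.991 (excellent), cutoff = 1.108, sens = 1.000, spec = 0.914, J = 0.914
```

Reading it: the three simulated groups (109 subjects) differ strongly in
wholebrain ALPS (the generator planted x-axis attenuations of
1.0/0.85/0.70), every LSD pair separates, the planted negative
correlation between ALPS and ipsilateral maximum radiotherapy dose (MDRT)
is recovered with its Fisher-z 95% interval, and a lower-ALPS-positive
ROC discriminates the subjects who develop radiation encephalopathy
(RE+) with the Youden-optimal cutoff. The same run is available from the
shell:

```sh
alpskit run --seed 42 --out results/run42
alpskit stats chisq "26 45 15; 9 13 1"     # chi2(2) = 2.6271, p = 0.2689
```

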