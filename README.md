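# ccfd — choriocapillaris flow-deficit quantification

`ccfd` is a Python package for quantifying **flow deficits (FDs)** of the
choriocapillaris — the capillary layer feeding the retinal pigment
epithelium — from en face swept-source OCT angiography slabs, for
image-analysis staff and researchers studying age-related macular
degeneration (AMD) and related choroidal disease.

Given a co-registered pair of 3 × 3 mm en face slabs per eye (a *flow*
slab and a *structure* slab), the pipeline:

1. **compensates drusen shadowing** — drusen attenuate the OCT beam and
   darken both slabs; the flow slab is multiplied by the blurred,
   inverted structure slab, `rescale(flow × G_σ(1 − structure))`, which
   brightens the flow signal exactly where the structural signal says
   the beam was attenuated;
2. **binarizes** with the Phansalkar local threshold over a circular
   window of radius *r* pixels (default 15 px ≈ 90.82 µm):
   `T = µ(1 + 2e^(−10µ) + 0.25(σ/0.5 − 1))`, flow iff intensity > T;
3. **measures** the 8-connected deficit components: FD% of image area,
   FD count, mean FD size (µm²) and total FD area (mm²), plus a
   sensitivity sweep across window radii 4/8/10/15 px
   (26.37/49.80/61.52/90.82 µm at the default 3000/512 µm pixel pitch);
4. **runs the cohort statistics** used in such studies: group summaries,
   two-sided Fisher exact tests (exact integer minimum-likelihood rule)
   for imaging flags, Mann–Whitney comparisons for quantitative
   covariates, a univariate p < 0.20 screen feeding a multivariate OLS
   model, and the log–log regression of FD count on FD size.

Because patient scans for this kind of study are not publicly deposited,
the package ships a first-class **synthetic-data generator**: scenes
with a planted deficit fraction, controllable texture scale, noise and
soft-edged drusen shadows that attenuate both channels (ground truth
included), and cohort tables with planted covariate effects — so every
stage is validated by ground-truth recovery. See `docs/methods.md` for
the full model description and its limitations.

## Worked example

```python
from ccfd import (SceneParams, generate_scene, quantify_eye,
                  PhansalkarParams, binarize, compute_metrics)

params = SceneParams(seed=5)   # 512 px, FD fraction 0.45, 0.6x drusen shadows
flow, structure, truth = generate_scene(params)
compensated, metrics = quantify_eye(flow, structure, radii=[4, 8, 10, 15])
print(f"planted FD fraction: {truth.realized_fd_fraction:.3f}")
for m in metrics:
    print(f"radius {m.radius_px:>2} px: FD% = {m.fd_percent:5.2f}  "
          f"n_FD = {m.n_fd:5d}  mean size = {m.mean_fd_size_um2:7.1f} um^2  "
          f"total = {m.total_fd_area_mm2:.2f} mm^2")
uncomp = compute_metrics(binarize(flow, PhansalkarParams(15)))
print(f"without compensation (radius 15): FD% = {uncomp.fd_percent:.2f}")
```

prints

```
planted FD fraction: 0.450
radius  4 px: FD% = 32.59  n_FD =  8557  mean size =   342.8 um^2  total = 2.93 mm^2
radius  8 px: FD% = 35.48  n_FD =  7049  mean size =   453.0 um^2  total = 3.19 mm^2
radius 10 px: FD% = 36.76  n_FD =  6387  mean size =   518.0 um^2  total = 3.31 mm^2
radius 15 px: FD% = 38.98  n_FD =  5047  mean size =   695.1 um^2  total = 3.51 mm^2
without compensation (radius 15): FD% = 55.11
```

Reading the numbers: FD count falls and mean FD size rises as the
threshold window widens — the sensitivity behavior these studies report
— while FD% moves by a few points, which is why the window radius must
always be quoted alongside FD%. The last line shows the point of the
compensation step: on the same scene, skipping it lets the 0.6×
drusen shadows inflate FD% by some 16 points (55.1 vs 39.0), while the
compensated value is within a fraction of a point of the same scene
rendered without drusen.

On the statistics side:

```python
from ccfd import fisher_exact_two_sided, ContingencyTable2x2
fisher_exact_two_sided(ContingencyTable2x2(7, 1, 37, 52))   # 0.0214...
```

## Command line

```sh
ccfd synth scene  --out-dir scene0 --seed 1          # flow.tif, structure.tif, truth
ccfd synth cohort --out cohort.csv --n-eyes 89
ccfd quantify --manifest manifest.csv --out-dir out --radius 4 --radius 15
ccfd stats    --cohort cohort.csv --out-dir out
ccfd run      --config run.yaml                      # full pipeline
```

`quantify` expects a manifest CSV (`eye_id,flow_path,structure_path`)
and writes per-eye metrics and the per-radius sensitivity summary;
`stats` writes the group-comparison table, the regression screen report
and the log–log fit; every run writes a manifest with the configuration
hash and seed so outputs reproduce byte-identically.

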