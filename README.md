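# marginrad

Radiomic margin characteristics of lung tumors on CT: a 76-feature
extractor quantifying the morphology and edge texture of the tumor
boundary, plus the prognostic pipeline built around such features.

## The problem

The periphery of a lung adenocarcinoma — its margin against the
surrounding parenchyma — carries prognostic information: spiculated and
lobulated margins reflect infiltrative growth, and the tumor
microenvironment concentrates vessels and immune cells at the boundary.
`marginrad` quantifies the margin with 76 named features in four
categories:

| category | count | contents |
|---|---|---|
| `shape3d` | 7 | volume V, surface area A, S/V ratio, sphericity, compactness, convexity, max 3D diameter |
| `log` | 63 | 9 histogram statistics × (original image + Laplacian-of-Gaussian responses at scales 1, 1.5, 2.0, 2.5, 3.0, 3.5 voxels) |
| `shape2d` | 3 | roundness factor, eccentricity, solidity on the maximal-area axial slice |
| `fractal` | 3 | box-counting dimension of the boundary voxels, gliding-box lacunarity, blanket-method fractal signature dissimilarity (FSD) |

Key definitions, with V the tumor volume, A its surface area, and
A₂/P the in-plane area/perimeter of the maximal axial slice:

- sphericity = π^(1/3) (6V)^(2/3) / A (1 for a ball, lower for irregular solids)
- convexity = V / V_hull (1 for convex tumors, lower for spiculated ones)
- roundness factor = 4π A₂ / P² (1 for a disk)
- lacunarity Λ(r) = var(m_r)/mean(m_r)² + 1 over gliding-box masses m_r
- blanket signature S(ε) = 2 − d log A(ε)/d log ε from upper/lower
  intensity envelopes; FSD contrasts the margin rim's signature with the
  tumor core's

Around the extractor, the package implements the accompanying modelling
chain: min–max normalization, two-rater ICC(2,1) reproducibility, LASSO
(L1-penalized Cox or logistic) feature selection with 10-fold
cross-validated penalty choice, proportional-hazards fits with Harrell's
C-index and backward-stepwise pruning, Kaplan–Meier risk stratification
with log-rank tests, IPCW time-dependent AUC, and a split-data-validated
logistic model of the micropapillary (MP) histologic subtype.

Patient data are not required anywhere: a digital-phantom generator
(spheres, ellipsoids, cuboids, spiculated and lobulated tumors with
textured interiors) and a cohort simulator (exponential
proportional-hazards survival with calibrated censoring, logistic MP
labels) make every stage testable with known ground truth.

## Worked example

```python
import marginrad as mr

# a spiculated phantom: r=12 sphere + 8 radial spikes of length 6
spec = mr.PhantomSpec(kind="spiculated", radius=12, n_spikes=8, spike_length=6,
                      texture="gaussian_noise", seed=7)
vol, mask = mr.make_phantom(spec, grid_shape=(48, 48, 48))
fv = mr.extract_all(vol, mask, subject_id="phantom-7")
print(fv.to_series()[["shape3d.sphericity", "shape3d.convexity",
                      "shape2d.roundness_factor", "log.kurtosis_3",
                      "fractal.lacunarity", "fractal.fsd_blanket"]].round(3))
```

```
shape3d.sphericity          0.812
shape3d.convexity           0.565
shape2d.roundness_factor    0.793
log.kurtosis_3              1.909
fractal.lacunarity          2.851
fractal.fsd_blanket         0.061
```

The spikes drag convexity down to 0.565 (a smooth sphere of the same
radius scores 0.956) and sphericity to 0.81 — the directions associated
with worse prognosis.  On a simulated cohort, adding informative margin
features to the clinical covariates raises the cross-validated C-index:

```python
df = mr.simulate_cohort(mr.CohortSpec(
    n_subjects=400, n_features=10,
    true_coefficients={"age": 0.4, "feature_1": 0.6},
    censoring_fraction_target=0.3, seed=11))
clinical = ["age", "sex", "tumor_size", "differentiation"]
print(mr.internal_cv(df, clinical, seed=1).cv_c_index)                    # 0.577
print(mr.internal_cv(df, clinical + ["feature_1"], seed=1,
                     normalize_columns=["feature_1"]).cv_c_index)         # 0.683
```

## Command line

```bash
marginrad phantom --kind spiculated --radius 12 --n-spikes 8 --spike-length 6 \
    --seed 7 --out-image img.nii.gz --out-mask mask.nii.gz
marginrad extract --image img.nii.gz --mask mask.nii.gz --out features.csv
marginrad cohort simulate --n-subjects 300 --seed 1 --out cohort.csv
marginrad cohort fit --table cohort.csv --mode combined --report report.json
marginrad cohort mp --table cohort.csv --split 0.7 --seed 1
```

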