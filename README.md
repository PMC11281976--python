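# morphosize

Multivariate size-and-shape analysis of traditional (linear) morphometric
measurements, built for studies of body-size evolution — e.g. insular
dwarfing in domestic horse populations — where the question is how much of
the shape variation among specimens is carried by size.

Given a wide-format measurement table (one row per specimen, one column per
variable: linear distances in mm, angles in degrees), the package provides:

- **A geometric-mean size proxy.** Per specimen, GM = (∏ⱼ xⱼ)^(1/n) over
  the n linear variables — an overall-size measure that privileges no single
  variable.
- **Three data treatments.** *Form* (raw values: size + shape together);
  *Mosimann log shape ratios* (each linear xⱼ → ln(xⱼ/GM), angles passed
  through untouched; the linear components of every row sum to zero);
  *allometry-free shape* (OLS residuals of each raw variable on GM — the
  residual matrix of the multivariate linear model of all variables on size).
- **Covariance PCA morphospaces** with eigenvalues, percent variance,
  loadings and a deterministic sign convention (the largest-|loading|
  variable on each axis is positive), so results are bit-reproducible.
- **A multivariate allometry test** in the Jolicoeur tradition: OLS of the
  PC1 scores of the log-shape-ratio PCA on ln GM, an F test of the slope
  (df 1, n−2, α = 0.05), and the R² between shape and size.
- **Sampling filters** that encode standard craniometric practice: only
  skeletally mature specimens, listwise deletion of specimens with any
  missing measurement, coercion of impossible values (non-positive lengths)
  to missing.
- **A seeded synthetic generator** drawing tables from the allometric model
  ln xᵢⱼ = αⱼ + βⱼ ln sᵢ + εᵢⱼ with log-normal latent size sᵢ per group, so
  every stage is testable against known ground truth.

Packaged variable catalogs cover the horse cranium (9 linear measurements:
BL, SBL, PL, MDL, PW, SI, CRL, FL, SW), bony labyrinth (7 linear) and
braincase endocast (13 = 9 linear + 4 angles: IHA, HPA, CSA, OFA).

## Worked example

Simulate an island-dwarf scenario (a small-bodied island group of 30
against a comparative sample of 140, length-like variables hyperallometric,
width-like hypoallometric), then run the canonical shape-and-allometry
chain:

```python
import morphosize as m

cfg = m.make_scenario("island_dwarf")
table, truth = m.simulate_measurements(cfg)

shape = m.log_shape_ratios(table)      # Mosimann log shape ratios + GM sizes
model = m.fit_pca(shape)               # covariance PCA, oriented axes
fit = m.allometry_test(model.scores_[:, 0], shape.size)

print("PC1 %var:", round(model.pct_variance_[0], 2))
print("allometry:", fit.r_squared_pct, "p =", f"{fit.p_value:.3g}",
      "slope =", round(fit.slope, 3), "n =", fit.n)
```

prints

```
PC1 %var: 58.25
allometry: 85.39% p = 4.54e-72 slope = -0.264 n = 170
```

PC1 carries 58% of the shape variation, and 85% of that axis is explained
by log size — the simulated allometry is recovered as a strongly
significant shape–size regression. The PC1 loadings show the built-in
pattern: negative loadings on the length measurements (BL −0.24, PL −0.30,
MDL −0.42) against positive loadings on the widths (PW +0.54, SW +0.45),
i.e. small specimens have relatively wider, shorter muzzles.

The same analysis runs from the shell:

```sh
morphosize simulate --scenario island_dwarf --out table.csv
morphosize allometry --input table.csv --structure cranium
morphosize run --config analysis.yaml --outdir results/
```

`run` executes the full grid {form, log shape ratio, allometry-free} ×
structures from a YAML config and writes scores/loadings/percent-variance
CSVs plus a deterministic `summary.json`.

## Analysing real measurement tables

Input is UTF-8 CSV (or read-only XLSX) with a header of variable
abbreviations plus metadata columns
`specimen_id, breed, group, maturity, sex, age, locality, source`.
`morphosize.study_report(data_dir)` runs the full pipeline on tables named
`cranium.csv`, `bony_labyrinth.csv`, `brain_endocast.csv` in a directory
and compares the computed sample sizes, percent variances and allometry R²
against published reference values for the horse insular-dwarfism dataset;
structures whose file is absent are flagged rather than failed.

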