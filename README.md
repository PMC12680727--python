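# sersmix

Shift-tolerant spectral unmixing and cohort statistics for
surface-enhanced Raman (SERS) spectra of human serum.

## The problem

SERS spectra of serum on silver substrates at 785 nm show a highly
conserved band pattern, yet the biochemical interpretation of those
bands has been contested for a decade — the same 638 cm⁻¹ band has
been attributed to tyrosine, lactose, coenzyme A or uric acid by
different groups. Because SERS intensity is governed by surface
affinity rather than concentration, a handful of strongly adsorbing
metabolites — uric acid (in free and albumin-bound forms, the bound
form carrying the intense 1650–1660 cm⁻¹ C6=O band) and hypoxanthine
(725 cm⁻¹) — can dominate the spectrum of a fluid containing thousands
of compounds.

`sersmix` packages the quantitative side of that attribution argument
as a tested, reusable pipeline for spectroscopists working with
biofluid SERS cohorts:

* **preprocess** — crop to 400–1800 cm⁻¹, iterative modified-polynomial
  (modpoly, degree 4) baseline subtraction, vector normalization;
* **peaks** — MAD-based noise estimation, line-preserving adaptive
  smoothing, band-maximum detection and peak-to-reference matching;
* **decompose** — fit each spectrum as
  y(ν) ≈ Σₖ aₖ·cₖ(ν − sₖ) with non-negative amplitudes aₖ and
  per-component shifts |sₖ| ≤ 0.1 cm⁻¹ (L-BFGS-B with NNLS
  initialization); figures of merit R², range-normalized RMSE and
  reduced χ², with bootstrap confidence intervals for cohort medians
  (1000 donor resamples);
* **cohort_stats** — band-intensity Spearman correlation against
  anchor bands (membership at ρ > 0.6) and centered, unscaled PCA with
  loading-to-component matching;
* **synth** — a generator of serum-like donor cohorts, spiking and
  isotopologue scenarios with known ground truth, so every stage is
  testable end-to-end without instrument data.

## Worked example

```python
import numpy as np
from sersmix import (CohortConfig, default_library, generate_cohort,
                     preprocess_set, fit_cohort, run_pca,
                     band_intensity_matrix, spearman_with_anchor)
from sersmix.synth import noise_sd_for_snr

library = default_library()                      # free UA, bound UA, hypoxanthine
config = CohortConfig(n_donors=81, noise_sd=noise_sd_for_snr(50, library), seed=1)
spectra, truth = generate_cohort(config, library)
pre = preprocess_set(spectra)                    # crop + modpoly + normalize

fit = fit_cohort(pre, library, seed=1)           # 3-component shift-tolerant fit
s = fit.summary
print(f"median R2      {s['R2']['median']:.3f}  (95% CI {s['R2']['ci'][0]:.3f}-{s['R2']['ci'][1]:.3f})")
print(f"median nRMSE   {s['nRMSE']['median']:.3f}")

mat = band_intensity_matrix(pre, [638.0, 725.0, 867.0, 1002.0, 1125.0])
rep = spearman_with_anchor(mat, 638.0)
for band in (725.0, 867.0, 1002.0, 1125.0):
    print(f"rho(638, {band:.0f}) = {rep.rho(band):+.2f}  member: {band in rep.members()}")

pca = run_pca(pre, 3)
print("PC1 explained:", f"{100*pca.explained_variance_ratio[0]:.0f}%")
```

Output:

```
median R2      0.946  (95% CI 0.939-0.954)
median nRMSE   0.027
rho(638, 725) = -0.87  member: False
rho(638, 867) = +0.73  member: True
rho(638, 1002) = +0.73  member: True
rho(638, 1125) = +0.85  member: True
PC1 explained: 61%
```

Reading: the three-component model explains ~95% of the variance of
each donor spectrum; every uric-acid band co-varies with the 638 cm⁻¹
anchor across donors (ρ > 0.6) while the hypoxanthine 725 cm⁻¹ band
does not — exactly the correlation signature by which serum bands are
grouped by parent metabolite — and the leading principal component of
inter-donor variability is the uric-acid : hypoxanthine intensity
ratio.

The same pipeline runs from the shell on a config file or a directory
of instrument ASCII exports:

```
sersmix all --seed 1 --out results/run1          # synthetic donors scenario
sersmix simulate --scenario donors --n-donors 81 --seed 1 --out data/
```

Each run writes the preprocessed matrix, peak lists, the per-spectrum
decomposition table, a summary JSON with bootstrap CIs, correlation
reports, PCA tables and a MANIFEST embedding the seed and config hash;
re-runs with the same seed are byte-identical.

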