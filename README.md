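# spdharm

Geometry-aware harmonization of multi-site functional-connectivity
matrices, with a permutation-testing battery for patient–control
comparisons.

## Who this is for

Functional connectomes — correlation matrices over `n` brain regions —
are symmetric positive-definite (SPD) and live on a curved manifold. When
a study pools subjects scanned at different imaging sites, the matrices
cluster by site: site means are displaced from one another (inter-site
bias) and sites spread unequally around their means (intra-site bias).
Entrywise statistics run on the pooled data then confound scanner with
biology. `spdharm` is for researchers who need to remove the site effect
*without* distorting within-site (presumably biological) variability, and
to quantify what harmonization buys in detection power.

## What it computes

Three harmonization transforms, each an exact isometry of within-site
geodesic distances that relocates every site's Fréchet mean to a common
target:

* **Matrix whitening (MW)** — `Σᵢ⁽ᵏ⁾ → (Σ̄⁽ᵏ⁾)^(-1/2) Σᵢ⁽ᵏ⁾ (Σ̄⁽ᵏ⁾)^(-1/2)`
  with `Σ̄⁽ᵏ⁾` the site's affine-invariant (AIRM) Fréchet mean; site means
  land on the identity.
* **Parallel transport (PT)** — transport each site to the mean of site
  means via the closed-form congruence `C = (Σ₀ (Σ̄⁽ᵏ⁾)⁻¹)^(1/2)`, then
  whiten; provably identical to MW when site means commute with the
  global mean (the commutator diagnostic is included).
* **Rigid log-Euclidean translation (RLET)** —
  `Log Σᵢ⁽ᵏ⁾ → Log Σ̄ + λ⁽ᵏ⁾ (Log Σᵢ⁽ᵏ⁾ − Log Σ̄⁽ᵏ⁾)`, a rigid translation
  in log space (target `Σ̄` or `I`); the λ-rescaled variant equalizes
  mean intra-site dispersion across sites.

Downstream, a geometry-aware permutation battery compares conditions via
the entrywise difference of group Fréchet means across many small
subsampled experiments, accumulates per-entry detection counts into a
frequency matrix `F` (with an analytic binomial calculus for chance
recurrence), summarizes `F` by the sensitivity `S(n)`, and maps surviving
"anomalies" onto 10 large-scale functional components (7 Yeo-derived
cortical networks + brain stem, cerebellum, basal ganglia). A synthetic
cohort generator with controllable site bias and planted condition
effects makes the whole pipeline testable without any imaging data.

## Worked example

```python
import numpy as np
from spdharm import (SimulationConfig, generate_cohort, rlet, run_battery,
                     BatteryConfig, sensitivity, pairwise_distances,
                     block_summary)

# 3-site cohort, 8 patients + 8 controls per site, strong site bias,
# condition effect planted on two connections
synthetic = generate_cohort(SimulationConfig(
    dim=12, n_sites=3, n_per_site_per_condition=8,
    site_scale=0.5, site_dispersion=0.1,
    effect_entries=((1, 4), (2, 9)), effect_size=0.4, seed=0))
cohort = synthetic.cohort

D, ordered = pairwise_distances(cohort, "lerm")
s = block_summary(D, ordered)
print("mean intra-site LERM distance:",
      round(s.loc[s.kind == "intra", "mean_distance"].mean(), 3))
print("mean inter-site LERM distance:",
      round(s.loc[s.kind == "inter", "mean_distance"].mean(), 3))

harmonized, report = rlet(cohort, target="global_mean")
print("max site-mean-to-target distance after RLET:",
      f"{max(report.site_mean_to_target.values()):.2e}")
print("max intra-site distance distortion:",
      f"{report.max_intra_site_distortion:.2e}")

config = BatteryConfig(n_experiments=15, subsample=6, n_permutations=200,
                       alpha=0.01, metric="lerm", seed=1)
F_raw, _, _ = run_battery(cohort, config)
F_harm, _, _ = run_battery(harmonized, config)
print("max frequency without harmonization:", int(F_raw.counts.max()))
print("max frequency after RLET:           ", int(F_harm.counts.max()))
print("S(3) after RLET:", round(sensitivity(F_harm, 3), 3))
print("planted-entry frequencies after RLET:",
      [int(F_harm.counts[i, j]) for i, j in synthetic.effect_entries])
```

Output:

```
mean intra-site LERM distance: 1.778
mean inter-site LERM distance: 8.209
max site-mean-to-target distance after RLET: 4.84e-14
max intra-site distance distortion: 2.07e-14
max frequency without harmonization: 0
max frequency after RLET:            14
S(3) after RLET: 0.412
planted-entry frequencies after RLET: [14, 10]
```

Reading it: before harmonization, subjects from different sites are ~4.6×
farther apart than subjects within a site — the site effect dominates,
and across 15 permutation experiments *no* connection is ever declared
significant. RLET moves every site mean onto the global mean (distances
~1e-14) while changing no within-site distance, after which the two
planted effects are detected in 14/15 and 10/15 experiments, and 41% of
ever-significant connections recur at least 3 times.

## Command line

The same pipeline as a shell tool:

```bash
spdharm simulate  --out cohort/ --dim 20 --sites 4 --per-site 10 --seed 1
spdharm harmonize --manifest cohort/manifest.tsv --out harmonized/ \
                  --method rlet_global
spdharm distances --manifest harmonized/manifest.tsv --out D.txt --metric lerm
spdharm permtest  --manifest harmonized/manifest.tsv --out battery/ \
                  --experiments 20 --subsample 8 --permutations 200 --alpha 0.01
spdharm summarize --frequency battery/frequency_matrix.txt \
                  --atlas atlas.tsv --threshold 2 --out summary/
```

Cohorts are a TSV manifest (`subject_id  site  condition  path`) plus one
delimited-text matrix file per subject; the atlas is a TSV of
`roi_index  label` with Yeo-17 ids or explicit BS/CRB/BG labels.

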