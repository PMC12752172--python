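# microcore

Community analysis for agricultural soil microbiomes: from a filtered OTU
table, sample metadata and a phylogeny to diversity, assembly mechanisms,
the core microbiome, and taxon–covariate associations.

Soil surveys of arable land ask which management practices — organic
amendments (farmyard manure, anaerobic-digestion digestate, slurry), crop
rotation, cultivation — and which soil properties (texture, pH, calcium,
loss on ignition) shape the bacterial community, and whether that shaping
is deterministic (environmental selection) or stochastic (neutral drift and
dispersal). `microcore` implements the statistical toolchain such a survey
needs, end to end, for ecologists and agronomists working with 16S
amplicon count data:

- **Preprocessing** — library-size filtering (strictly > 5,000 reads by
  default), organellar contaminant removal by lineage substring, removal
  of taxonomically unassigned OTUs, total-sum scaling and the centred
  log-ratio transform.
- **Diversity and ordination** — rarefied Shannon entropy
  (H = −Σ pᵢ ln pᵢ) and bias-corrected Chao1
  (S_obs + F₁(F₁−1)/(2(F₂+1))), Bray–Curtis and unweighted UniFrac
  distances, classical-scaling PCoA with explicit negative-eigenvalue
  reporting.
- **Permutation inference** — sequential (Type I) PERMANOVA over an
  ordered covariate list, and forward/backward distance-based RDA variable
  selection with permutation pseudo-F tests.
- **Assembly null models** — abundance-weighted βMNTD and βNTI against a
  tip-shuffle null (|βNTI| > 2 read as deterministic assembly), and the
  Sloan neutral community model: occupancy predicted from metacommunity
  relative abundance through a single immigration parameter m, with taxa
  partitioned above / within / below the 95% envelope of the fitted curve.
- **Core microbiome** — abundance–occupancy ranking
  Index = (site-specific occupancy + replication consistency)/2, a
  cumulative Bray–Curtis contribution curve E(k) (reported alongside its
  complement C = 1 − BC_core/BC_all), and a 2% diminishing-returns
  stopping rule; per-amendment occupancy models with Venn overlaps.
- **Association models** — a generalised linear latent variable model
  g(μᵢⱼ) = ηᵢⱼ = β₀ⱼ + xᵢᵀβⱼ + uᵢᵀθⱼ for negative-binomial counts, with
  95% CIs giving per-taxon directionality; and CODA-LASSO, a sparse
  log-contrast regression with a zero-sum coefficient constraint and
  elastic-net penalty, for compositional microbial signatures of
  continuous soil properties or management splits.
- **Synthetic surveys** — a generator reproducing the survey design the
  analyses assume (14 farms, four amendment groups with two rare levels,
  four textures, 5,079–41,827 reads/sample, lognormal metacommunity,
  Sloan-type neutral sampling, clade-confined environmental filtering)
  with full ground truth for calibration and recovery testing.

## Worked example

```python
from microcore import (
    SimulationConfig, simulate_dataset, bray_curtis, permanova,
    fit_sloan_neutral, occupancy_models, neutral_overlay,
)

ds = simulate_dataset(SimulationConfig(n_taxa=150, n_samples=40, seed=1))
table = ds.table.select_otus(
    [o for o, t in zip(ds.table.otu_ids, ds.table.counts.sum(axis=1)) if t > 0]
)

dm = bray_curtis(table)
print(permanova(dm, ds.metadata, ["amendment", "Ca", "LOI"], n_perm=999, seed=1))

fit = fit_sloan_neutral(table)
print(f"Sloan neutral model: m = {fit.m_hat:.3f}, R2 = {fit.r_squared:.2f}")

cores = occupancy_models(table, ds.metadata, model_var="amendment")
pooled = cores["all"]
print(f"core: {len(pooled.core)} taxa, minimum occupancy "
      f"{pooled.min_core_occupancy:.0%}")
```

prints

```
           df  SumOfSqs     R2       F      p
amendment   2    0.0313 0.0454  1.4844 0.1050
Ca          1    0.1566 0.2272 14.8631 0.0010
LOI         1    0.1327 0.1925 12.5974 0.0010
Residual   35    0.3688 0.5349     NaN    NaN
Total      39    0.6894 1.0000     NaN    NaN
Sloan neutral model: m = 0.098, R2 = 0.80
core: 7 taxa, minimum occupancy 100%
```

This synthetic survey injects deterministic filtering tied to soil calcium
and organic matter (LOI) into an otherwise neutral community: PERMANOVA
attributes ~23% and ~19% of compositional variance to Ca and LOI
(p = 0.001) while the amendment factor alone stays non-significant; the
Sloan fit recovers the generating immigration rate (m_true = 0.1) almost
exactly; and seven ubiquitous taxa (100% occupancy) absorb the
between-sample Bray–Curtis structure before the 2% stopping rule halts the
core expansion.

The same stages are available from the shell:

```bash
microcore simulate --out survey/ --seed 3
microcore filter --table survey/otu_table.tsv --taxonomy survey/taxonomy.tsv --out filtered.tsv
microcore permanova --distance bc_distance.tsv --metadata survey/metadata.tsv \
    --terms farm_id,texture,amendment,Ca,LOI --perms 999 --seed 1
microcore run --out results/ --seed 1       # whole pipeline, one seed
```

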