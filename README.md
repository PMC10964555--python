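# urbiome

Ecological-process inference for small-mammal gut microbiota along an
urbanization gradient.

Urbanization reshapes both wildlife communities and the gut microbiota
(GM) of the animals that persist in cities. Given ASV-level 16S count
tables, a rooted ASV phylogeny, predicted-function tables and trapping
records from a multi-site, multi-species field design, this package asks:
which ecological process — environmental filtering, competition, neutral
drift, selection, or dysbiosis-style stochastic divergence — shapes GM
diversity and composition in each species-site group? It is aimed at
microbial and community ecologists who want the full inference chain as
reusable, tested code, with a synthetic-data generator providing a ground
truth for every stage.

## What it computes

* **Amplicon false-positive filtering** (`urbiome.filtering`): per-ASV
  cross-contamination thresholds T<sub>CC</sub> (maximum count in any
  negative control) and false-assignment thresholds
  T<sub>FA</sub> = ⌈run-total × misassignment rate⌉ (rate re-estimable
  from an internal DNA control); replicate confirmation; taxonomy-based
  removal; a rarefaction plateau check; group-size filtering; proportional
  normalization.
* **Diversity** (`urbiome.diversity`): richness, Shannon *H* (nats),
  Faith PD, MNTD and the Nearest Taxon Index
  NTI = −(MNTD<sub>obs</sub> − μ<sub>null</sub>)/σ<sub>null</sub>
  under taxa-label randomization (NTI > 2 clustering, < −2
  overdispersion); Bray–Curtis, Jaccard, unweighted and normalized
  weighted UniFrac.
* **Assembly null models** (`urbiome.assembly`): βMNTD and
  βNTI = (βMNTD<sub>obs</sub> − μ<sub>null</sub>)/σ<sub>null</sub> from
  tip-shuffling nulls; pairs labelled homogeneous selection (βNTI < −2),
  variable selection (βNTI > 2) or stochastic; per-group selection
  percentages with a chi-square test.
* **Multivariate tests** (`urbiome.multivariate`): PERMANOVA pseudo-F via
  the Gower-centered form, PERMDISP (betadisper) with negative-eigenvalue
  handling, db-RDA with Lingoes correction and adjusted-R² forward
  selection, pairwise PERMANOVA with BH correction, Mantel and partial
  Mantel.
* **Univariate models** (`urbiome.models`): Gaussian and
  negative-binomial GLMs by IRLS with Cox–Reid-adjusted dispersion
  profiling, AICc all-subsets selection, order-averaged variance
  partitioning, Wald contrasts, the functional-redundancy ANCOVA
  (slope of functional on taxonomic richness; slope < 1 ⇒ redundancy)
  and a simplified negative-binomial Wald differential-abundance test
  (+1 pseudocount, median-of-ratios size factors, BH correction).
* **Host community** (`urbiome.hosts`): trapping success
  −100 ln(1 − captures/trap-nights), the PCA urbanization axis, site
  dissimilarity, and the urban avoider / adapter / dweller classification.
* **Pipeline** (`urbiome.pipeline`): orchestrates everything and emits a
  per-group decision record — flexible? redundant? clustered or
  overdispersed? selection or stochastic? Anna Karenina dysbiosis flag? —
  with an overall verdict of `stable`, `adaptive_flexibility` or
  `dysbiosis_risk`.
* **Synthetic data** (`urbiome.synthetic`): seeded generators for trees,
  communities with known assembly processes, function maps with tunable
  redundancy, raw sequencing runs with known artifact injections, and
  trapping designs.

## Worked example

```python
import pandas as pd
from urbiome import assembly, diversity, synthetic

tree = synthetic.simulate_tree(200, seed=0)
parts = []
for process, strength, seed in [
    ("filtering", 5, 1), ("neutral", 100, 3),
]:
    table, _ = synthetic.simulate_assembly(
        tree, process, strength, n_samples=30, richness_target=15,
        seed=seed, depth=2000,
    )
    table.index = [f"{process}_{i}" for i in range(30)]
    parts.append(table)
table = pd.concat(parts).fillna(0).astype(int)
groups = pd.Series([i.rsplit("_", 1)[0] for i in table.index],
                   index=table.index)

result = assembly.bnti_matrix(table, tree, n_null=200, seed=4)
props = assembly.process_proportions(result.to_frame(), groups)
print(props[["pct_selection", "pct_stochastic"]].round(1))
```

prints

```
           pct_selection  pct_stochastic
group
filtering           96.6             3.4
neutral              6.0            94.0
```

i.e. 96.6 % of within-group sample pairs in the environmental-filtering
group have |βNTI| > 2 (selection dominates their turnover), while the
neutral-drift group sits at 6 %, consistent with the ±2 stochasticity
band. A full decision-tree run is
`urbiome run --config config.yaml --out report/` from the command line, or
`urbiome.pipeline.run_pipeline(synthetic.standard_design(seed=42))` from
Python.

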