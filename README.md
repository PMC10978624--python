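# promiscuity

Tools for studying why enzymes are either specialists or generalists.

Most enzymes catalyse reactions with more than one substrate, and in curated
kinetic databases the distribution of how *evenly* an enzyme spreads its
catalytic power across substrates is strikingly bimodal: enzymes cluster at
the specialist and generalist extremes, with few intermediates.  This package
implements three complementary analyses of that observation for researchers
in enzyme evolution:

1. **Empirical prong** (`promiscuity.kinetics`) — curate a kinetic table
   (turnover number k_cat in s⁻¹, Michaelis constant K_M in mM, one row per
   enzyme–substrate pair) into per-enzyme catalytic-efficiency profiles
   x₁…x_n (x = k_cat/K_M), and summarise each enzyme by the promiscuity
   index

   I = −(1/log n) Σᵢ pᵢ log pᵢ,  pᵢ = xᵢ / Σⱼ xⱼ,

   the normalised Shannon entropy of the efficiency shares: I = 1 for a
   perfect generalist, I = 0 for a pure specialist.

2. **Biophysical null** (`promiscuity.null_model`) — transition-state theory
   maps an activation free energy ΔG‡ to a rate k = (k_BT/h)·exp(−ΔG‡/RT).
   Sampling (ΔG₁‡, ΔG₂‡) pairs from the empirically known Gaussian
   (mean ≈ −6 kcal/mol, sd σ) yields a null distribution of I driven purely
   by enzyme biochemistry, summarised by maximum-likelihood beta fits
   (both shapes < 1 ⇔ U-shaped/bimodal).

3. **Selection-with-constraints model** (`promiscuity.constraints` /
   `promiscuity.duplication`) — an enzyme catalysing n reactions is a point
   in [0,1]ⁿ of scaled efficiencies; each reaction pair carries one of five
   linear constraint classes from strong antagonism (xᵢ+xⱼ ≤ 1) to strong
   synergism (|xᵢ−xⱼ| ≤ 0.1).  A generalist ancestor maximises a
   diminishing-returns fitness Σ xᵢ/(xᵢ+K) over the feasible polytope; after
   gene duplication each copy maximises one xᵢ by linear programming while
   its neutral activities erode to their variability minima.  *Frustration*
   — the mean shortfall 1 − xᵢ over selected reactions — measures how much
   the constraints prevent efficient catalysis, and the duplicates'
   promiscuity distribution is the model's prediction to compare with data.

A synthetic-data generator (`promiscuity.synthetic`) emulates the
statistical structure of curated kinetic databases (log-normal efficiencies
with median 26 mM⁻¹s⁻¹, ≈4.9 substrates per enzyme, a specialist/generalist
mixture), so the empirical pipeline is testable without any database
download, and simulates ascertainment bias in substrate discovery.

## Worked example

```python
import numpy as np
from promiscuity import (GeneratorConfig, generate_profiles, dataset_summary,
                         duplication_study, compare_distributions)

# constraint model: all 35 three-reaction feasible spaces, 105 duplicates
study = duplication_study(3)
print(len(study))                                            # 105
print(np.corrcoef(study["A_hat"], study["gain"])[0, 1])      # 0.630

# synthetic kinetic dataset, 2000 enzymes
profiles, records = generate_profiles(GeneratorConfig(n_enzymes=2000, seed=1))
summary = dataset_summary(profiles)
print(summary.median_efficiency)                             # 26.000
print(summary.mean_substrates)                               # 4.907

# model prediction vs synthetic data: two-sample KS distance
indices = [p.promiscuity for p in profiles]
print(compare_distributions(study["duplicate_promiscuity"], indices))  # 0.4
```

The correlation of 0.630 says that the more antagonistic a space's pairwise
constraints are (mean antagonism score Â → 1), the more catalytic efficiency
its duplicates gain by specialising.  Of the 35 spaces, 71 % frustrate their
generalist ancestor (`frustrated_fraction(3)` → 71): exactly those containing
at least one antagonistic pair.  The duplicate promiscuity distribution is
end-heavy — many values at 0 (resolved frustration, full specialisation) and
above 0.98 (irresolvable frustration) with almost none in the middle — the
bimodality the model predicts.

The same analyses are available from the shell:

```sh
promiscuity model --n 3 --outdir out/
promiscuity simulate --n-enzymes 2000 --seed 1 --outdir out/
promiscuity curate --records out/synthetic_records.tsv --outdir out/curated/
promiscuity null --sigma 0.2 --sigma 2 --sigma 4 --seed 1 --outdir out/
promiscuity report --left out/duplication_study_n3.csv --right other.csv
```

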