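# Methods

This note documents the models implemented in `promiscuity`, the choices
made where the design was genuinely open, and what the synthetic data can
and cannot show.

## Promiscuity index and curation

The promiscuity index of an enzyme with catalytic efficiencies x₁…x_n is the
Shannon entropy of the efficiency shares pᵢ = xᵢ/Σxⱼ divided by its maximum
log n.  Natural logarithms are used throughout; the index is invariant to
the base, to rescaling all efficiencies by a common factor, and to
permutation.  Zero efficiencies contribute nothing (0·log 0 ≡ 0), so I = 0
exactly when one substrate carries all activity and I = 1 exactly when all
substrates are equally catalysed.  The index needs n ≥ 2.

Curation of a kinetic table proceeds in a fixed order: rows with
non-positive k_cat or K_M are dropped with a logged warning; substrate
aliases are mapped to canonical names via a user-supplied synonym table;
rows whose canonical substrate is a common cofactor are removed (default
list: ATP, NAD+, NADPH, NADH, NADP+ and the frequent spelling variant
NAP+; user-overridable); every enzyme sharing a protein accession that
appears under more than one species is discarded as mislabelled; replicate
measurements of the same enzyme–substrate pair are averaged — arithmetic
mean of k_cat and of K_M separately, then efficiency = mean k_cat / mean
K_M.  The alternative convention (mean of the per-replicate ratios) is
available behind `mean_of_ratios=True`; the two differ whenever replicate
K_M values differ.  Inputs are assumed unit-harmonised (s⁻¹ and mM) before
averaging.  Only enzymes with ≥ 2 surviving substrates are retained, sorted
by enzyme key for deterministic output.

Dataset summaries report the Pearson correlation between the index and
log10 of the best (largest) efficiency — the log scale matches the
log-normal distribution of efficiencies — and Kendall's tau between
substrate count and index in the tau-b (tie-corrected) variant, because
substrate counts are heavily tied.  With fewer than three profiles, or
all-tied input, correlations are reported as NaN with a warning rather than
raising.  The paired-efficiency correlation samples, per enzyme, two
substrates uniformly without replacement (both when n = 2), randomises
which is plotted first, and correlates the log10 efficiencies; the seed is
mandatory.

## Synthetic kinetic tables

The generator is a mixture of two archetypes.  A *specialist* draws one
log-normal "best" efficiency and places each other substrate
`dominance_decades` (default 3.0, jitter sd 0.5) decades below it.  A
*generalist* draws all its efficiencies around a per-enzyme centre with a
small within-enzyme spread (`within_sd`, default 0.15 decades).  Per-enzyme
centres have a between-enzyme spread of 1.5 decades.  Substrate counts
follow 2 + a zero-truncated geometric with mean 2.9, giving mean 4.9
substrates per enzyme; note the minimum is therefore 3, whereas real curated
databases have their mode at exactly 2 — a deliberate simplification that
does not affect any statistic the package computes from the counts.  After
sampling, all log10 efficiencies are shifted by one constant so that the
realized dataset median equals the configured `efficiency_median`
(26 mM⁻¹s⁻¹ by default): the configured median is a property of the emitted
dataset rather than of a latent distribution, which keeps it meaningful
under the heavy lower tail the specialists create.  Michaelis constants are
drawn log-normally (median 0.199 mM, sd 0.8 decades) and k_cat = x·K_M, so
the emitted kinetic records reproduce the target efficiencies exactly and
round-trip through curation.

Defaults were chosen once, when the generator was designed, to make a 50/50
mixture end-heavy (both extreme deciles of the index distribution heavier
than the middle) at realistic spreads.  What passing tests on these data
show is that the *pipeline* is correct and that the mixture structure
produces bimodality; they do not show that any particular real database is
such a mixture — the generator has no EC taxonomy, no species sampling
bias, and no measurement error beyond log-normal noise.

The ascertainment simulation models discovery bias: each enzyme's first
substrate draws its log10 efficiency around log10(26), and every later
substrate around the running mean of the already-known ones, all with sd
`discovery_sd` (default 1.0 decade).  Indices are reported at each point of
an increasing substrates-per-enzyme schedule (default 2, 5, 10, 20) from
the same discovery sequence, so schedule points are nested.  Under this
kernel the apparent bimodality at 2 substrates (little mass in the middle
tercile of I) fills in monotonically as more substrates are characterised.
The bias kernel is one documented choice among several plausible ones; the
running-mean centring is the simplest kernel that biases discovery toward
"similar catalytic efficiency".

## Biophysical null

Transition-state theory gives k = (k_BT/h)·exp(−ΔG‡/RT); catalytic
efficiency is taken proportional to this rate, with RT = 0.5925 kcal/mol at
the default 298.15 K.  For a two-reaction enzyme the index then depends
only on the energy gap: p = 1/(1 + exp((ΔG₁‡−ΔG₂‡)/RT)) and I is the binary
entropy of p normalised by log 2 — independent of the pre-exponential
factor, which is why no diffusion-limit ceiling is applied by default (a
ceiling would matter only if absolute efficiencies were compared).
Activation energies are sampled from a Gaussian with mean −6 kcal/mol (the
empirical range is −4 to −7) and user-chosen sd; 10³ pairs per condition by
default.  Because the index depends only on (z₁−z₂)·σ for fixed standard
normals, the mean sampled index is strictly decreasing in σ at a fixed seed.

Beta fits are maximum likelihood on samples clipped into [10⁻⁶, 1−10⁻⁶]
(exact 0s and 1s are outside the beta support), with a method-of-moments
start.  Modality follows the standard beta-shape taxonomy: both shapes < 1
is U-shaped/bimodal; both ≥ 1 unimodal interior; otherwise J-shaped toward
0 or 1.  Sweeps over σ derive the seed of the i-th (sorted) point as
master_seed + i.  The exact σ at which the null turns bimodal depends on
the chosen efficiency mapping; with the pure transition-state form used
here the transition happens at smaller σ than with bounded mappings, so
only the mapping's monotonicity and the classifier's correctness are
asserted, not a particular threshold.

## Constraint model

Efficiencies are scaled to [0,1] per reaction (1 ≈ the diffusion limit).
The five pairwise classes use the canonical geometry

* strong antagonism: xᵢ + xⱼ ≤ 1 (antagonism score A = 1)
* weak antagonism: xᵢ + xⱼ ≤ c_B = 1.5 (A = 0.75)
* unconstrained: unit box only (A = 0.5)
* weak synergism: |xᵢ − xⱼ| ≤ w_D = 0.5 (A = 0.25)
* strong synergism: |xᵢ − xⱼ| ≤ ε_E = 0.1 (A = 0)

with c_B, w_D, ε_E configurable (`ConstraintGeometry`).  These coordinates
pin the class-level corner semantics — the origin is always feasible, (1,1)
is feasible exactly for the unconstrained/synergistic classes, (1,0)
exactly for the antagonistic/unconstrained ones — and every class-level
result (space counts, the 71 % frustrated fraction, gain signs) is
invariant to the exact values within those semantics; only the worked
coordinate-level numbers (e.g. the (0.6, 0.4, 0.5) duplicate) depend on
them.

A feasible space assigns one class per unordered reaction pair.  Spaces are
enumerated one per *multiset* of classes — C(k+4, k) spaces for k = n(n−1)/2
pairs — with the canonical representative assigning the multiset, sorted by
descending antagonism score, to pairs in lexicographic order.  For n ≥ 4
non-isomorphic labeled assignments sharing a multiset exist; one
representative per multiset is deliberate, matching the multiset counting
law.  The mean antagonism score Â and the dissimilarity
D = Σ_{i<j}|Aᵢ−Aⱼ| (reported relative to the maximum over same-n spaces,
computed by enumeration and cached) summarise each space.

The ancestor maximises F(x) = Σᵢ xᵢ/(xᵢ+K), K = 0.5 — strictly increasing
and strictly concave, a standard diminishing-returns form — over the
polytope, via SLSQP started from the Chebyshev centre (a deterministic
interior point) with ftol 10⁻¹², verified feasible to 10⁻⁶.  Strict
concavity makes the optimum unique, so one ancestor is reported per space;
a fitness with plateaus would instead admit ties (the lexicographically
largest candidate is kept should the solver produce numerically tied
candidates).  Frustration is the mean of 1 − xᵢ over selected reactions,
with a space counted as frustrated above 10⁻⁶ — equivalently, when the
all-ones vector is infeasible, which happens exactly when the space
contains an antagonistic pair.

Each duplicate maximises one coordinate by linear programming (HiGHS), then
a variability analysis fixes x_r at its optimum (slack 10⁻⁹) and solves two
LPs per neutral reaction for its attainable range.  Loss-of-function drift
is abstracted as erosion to the per-neutral variability *minimum*; these
minima need not be jointly attainable, so a flag
(`joint_neutral_minimum=True`) switches to a single LP minimising the sum
of neutral activities at fixed x_r, which is always feasible as a vector.
Gain is the duplicate's x_r minus the ancestor's, non-negative because the
duplicate's program relaxes the ancestor's; values below −10⁻⁷ raise, and
round-off negatives are clamped to zero.

The study table at n reactions has n·C(k+4, k) rows.  Problem sizes: the
full study is run at n = 3 (105 duplicates, ≈ 500 LPs) in the tests and
examples; enumeration-only results (space and duplicate counts) are
computed up to n = 8, where halfspaces are built lazily so counting stays
combinatorial.

## Pipeline

Distributions from different prongs are compared with the two-sample
Kolmogorov–Smirnov statistic (maximum ECDF distance, symmetric).  The
pipeline runs any subset of the four stages from one YAML config with a
master seed, writes CSV/JSON outputs and a manifest (package and library
versions, seeds, output paths); identical configs produce byte-identical
outputs.

## Known limitations

* The constraint classes are symmetric and additive; real mutational
  constraints can be asymmetric and epistatic.
* Drift is abstracted as instantaneous erosion to the variability minimum;
  there is no population-genetic dynamics.
* The generator's substrate-count law has no enzymes with exactly two
  substrates, and its archetype mixture is a phenomenological stand-in, not
  a mechanistic model of database composition.
* The biophysical null's bimodality threshold in σ is mapping-dependent and
  therefore not asserted quantitatively.
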