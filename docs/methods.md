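# Methods

## Data model and deletion policy

The unit of analysis is an aligned set of equal-length mtDNA sequences
over `ACGTN-`, each tagged with a sampling deme; demes pool into three
regions (MEX, SAL, PER).  `N` and `-` are missing data.  By default all
statistics use *complete deletion* (any site with missing data in any
sequence is dropped alignment-wide), the common Arlequin convention;
*pairwise deletion* is available as a switch.  Haplotype identity is
plain string equality over the retained sites — no IUPAC-aware
matching.

## Diversity and neutrality statistics

Per deme: segregating sites S; mean pairwise differences k (raw
nucleotide differences, no substitution-model correction — the
convention of the standard population-genetics packages for these
estimators); nucleotide diversity π = k / L over the analysed length;
unbiased haplotype diversity H = n/(n−1)(1 − Σp²) with Nei's (1987)
large-sample variance; the SD of k uses Tajima's (1983)
no-recombination total variance b₁k + b₂k², and SD(π) = SD(k)/L.
Tajima's D follows the 1989 definition.  Fu's F_S uses the exact Ewens
sampling probability S' = P(K ≥ observed haplotype count | θ̂ = k),
with the unsigned-Stirling-number recursion evaluated in log space
(exact to ~1e-15 relative error for n ≤ 200); F_S = ln(S'/(1−S')).
R2 is the Ramos-Onsins & Rozas (2002) statistic from singleton counts
per sequence (folded: any allele carried by exactly one sequence).

P-values are simulation-based and seedable: D and R2 against neutral
constant-size coalescent samples conditioned on n and the observed S
(S mutations placed on branches proportionally to length; 10,000
replicates by default), two-sided for D and lower-tailed for R2; F_S
against neutral samples at θ = k̂ (Poisson mutations, infinite sites),
lower-tailed.  Raw p-values are reported; the conventional reading of
F_S significance (p < 0.02 as the 0.05-level criterion) is left to the
reader.  Tajima's beta approximation is provided only as a cross-check
(`tajimas_d_beta_pvalue`).  At S = 0, D and R2 are NaN — explicitly
undefined, never numeric zero.

## Mismatch distributions

The sudden-expansion model: after an instantaneous change from θ₀ to
θ₁ at τ = 2ut mutational units before present, the expected pairwise
difference distribution is the Poisson smearing

F_j = F^eq_j(θ₁) + exp(−τ(θ₁+1)/θ₁) Σ_{i≤j} τ^{j−i}/(j−i)! [F^eq_i(θ₀) − F^eq_i(θ₁)],

F^eq_j(θ) = θ^j/(θ+1)^{j+1}.  Fitting minimises the sum of squared
deviations over (τ, θ₀, θ₁) with θ₀ ≤ θ₁ ≤ 99999 (multi-start bounded
Nelder-Mead; ties broken toward the smallest τ).  SSD and Harpending's
raggedness r get parametric-bootstrap p-values: simulate under the
fitted expansion (a coalescent with one resize event at τ/2u), refit
each replicate, and report (count ≥ observed + 1)/(n_boot + 1).

## Distances, Φ_ST, AMOVA, SAMOVA

Model-corrected distances: p, JC69, K2P, TN93, each optionally with
gamma rate heterogeneity (−ln x replaced by α(x^{−1/α} − 1)).  TN93
with default settings is the working model — the closest analogue of a
codon-partitioned GTR/F81/SYM+G selection that the AMOVA framework
accommodates; p-distance is used wherever exact oracle comparisons are
needed.  Saturated pairs whose logarithms would be undefined fall back
to p-distance with a warning.  Base frequencies for TN93 are estimated
alignment-wide.

AMOVA treats the distance matrix entries as squared Euclidean
distances, partitions sums of squares hierarchically and converts mean
squares to variance components with the standard unequal-sample-size
coefficients; negative components are retained.  Permutation schemes
per level: individuals among populations (F_ST, and the pairwise
Φ_ST), individuals among populations within groups (F_SC), whole
populations among groups (F_CT); p-values use (count+1)/(n_perm+1).
Bonferroni correction divides α by the number of pairs actually
tested.  SAMOVA maximises F_CT over deme partitions: exhaustively
(restricted-growth enumeration, feasible to ~10 demes) or by seeded
simulated annealing (single-deme reassignment moves, geometric cooling
0.95, default 10,000 steps) over a precomputed population-pair
distance-sum cache, which makes each candidate partition O(P²).

## Coalescent simulator

Continuous-time structured coalescent with piecewise-constant sizes:
within each deme, pair-coalescence rate 1/N_e(t) (haploid scaling — N_e
is the mitochondrial effective number of individuals; no ploidy
factor, a choice that scales all times and is therefore stated
prominently).  Events: resizes, timed bottlenecks (a size held over an
interval), merges.  Migration is fixed at zero in all scenarios — the
isolation-with-migration analyses this pipeline accompanies found no
significant gene flow between regions.  Time is in generations with
one generation = one year, so years and generations coincide.  A
demography whose lineages can never fully coalesce is rejected with a
configuration error.

Mutations: Poisson(μ_locus × total branch length), branch chosen
proportionally to length, site uniform (or gamma-weighted), target
base from JC69 (default), HKY(κ), or infinite-sites-on-L.  Same-site
mutations are applied oldest-first so younger hits overwrite nested
leaf subsets correctly.  The default μ_locus = 5.9×10⁻⁶ per generation
comes from halving the mean of three trans-isthmian COI divergence
rates (1.32, 1.7, 3 %/My → 1.0033×10⁻⁸ per site per year) and scaling
by L = 590 and the one-year generation time
(`derive_mutation_rates`); full-precision and convention-rounded
values are both reported.

## The four demographic scenarios

Modern sizes default to MEX 1.5×10⁶, SAL 2×10⁶, PER 7.5×10⁵.  In the
vicariance models the peripheral demes merge (pastward) into SAL, and
SAL is resized to Anc × its modern N_e at each split, Anc applying to
the tropical lineage.  In the stepping-stone models the colonisation
chain is unwound pastward with Anc resizes on the source lineage at
each split.

Founder bottlenecks are modelled as *exponential recovery*: a founded
deme grows from Bot × modern N_e at its founding to the modern N_e at
present — implemented pastward as an 8-step piecewise-geometric
decline ladder.  The design alternative, a fixed short bottleneck
pulse (e.g. 10 generations at the drawn size), is genealogically
invisible at these effective sizes (pair-coalescence intensity
~10⁻⁵), which would make the Bot parameters inert and collapse each
stepping-stone model onto its vicariance mirror image; the recovery
model keeps the founder effect a real, estimable feature of the
scenario, and matches how serial-coalescent founder events are
conventionally parameterised.  The step count is a config knob
(`founder_steps`).

Priors: t1 ~ U(150, 300) ka, t0 ~ U(50, 150) ka with t0 < t1 enforced
by rejection; Anc₀, Anc₁ ~ U(1, 20); Bot₀, Bot₁ ~ Exp(mean 0.2)
fractions of the founded deme's modern N_e (floored at 10⁻⁶).  Prior
bounds are configuration, not code: they summarise published
isolation-with-migration posterior ranges rather than exact original
prior files, so downstream reproduction of model-selection numbers is
expected at the level of rankings and bands, not digits.

## ABC

The 15-entry summary vector (fixed, versioned order): per region π, H,
S, Tajima's D (D at S = 0 is imputed as 0 in the vector, the one place
an undefined statistic is coerced — reference-table rows must be
finite), then Φ_ST for MEX–SAL, MEX–PER, SAL–PER computed on raw
difference counts (a haplotype-frequency F_ST is available as a
switch).  Statistics are standardised by median absolute deviation
(robust to the long-tailed simulated distributions); zero-MAD columns
are dropped with a warning.  Tolerance δ is the accepted *fraction* of
simulations, accepted count = round(δ × rows).

Model choice: rejection posterior = accepted-model frequencies;
neural-net posterior = class probabilities of a single-hidden-layer
MLP classifier (10 hidden units, L2 weight decay 0.01, L-BFGS, best of
n_restarts by training loss) fit on the accepted rows and evaluated at
the observed vector.  Bayes factors are posterior-probability ratios.
Parameter estimation adjusts accepted draws on the log scale,
θ* = m(s_obs) + (log θ − m(s)) with an MLP regression m, weights
Epanechnikov in acceptance distance; summaries are the weighted
median, mean, and mode (weighted Gaussian KDE, Silverman bandwidth).
With `max_iter = 0` or `method="rejection"` the adjustment disappears
and unweighted-by-regression rejection posteriors are returned —
useful both as a degeneracy check and for exact coverage properties.
Cross-validation is leave-one-out: each pseudo-observed row is
classified against the tables with itself removed; the MAD scaling is
computed once on the full table (removing one row perturbs it
negligibly).

## Synthetic data

`synthetic.generate_dataset` emulates the sampling design: 188
sequences over 8 sites (25, 21, 24, 25, 15, 31, 20, 27) in 3 regions,
L = 590, μ_locus = 5.9×10⁻⁶.  Regions are panmictic in the generating
model; sequences are scattered uniformly over the region's sites
(within-region structure is deliberately absent, consistent with the
scenarios' assumptions).  The site-size column is treated as sequence
counts (haploid mtDNA), whatever its original table called it.  The
generator does not emulate sequencing error, alignment artifacts, or
within-region structure — so passing tests demonstrate correctness of
the inference machinery under the stated model, not robustness to
those real-data complications.

## Problem sizes and numerical choices

Reference tables in the shipped acceptance script use 12,000
simulations per model with 100 pseudo-observed datasets per model for
cross-validation — chosen so a complete run finishes in roughly a
quarter of an hour on one CPU while keeping ≥ 48 accepted rows at the
smallest tolerance.  At this scale the neural-net classifier at
δ = 0.001 trains on tens of rows and is accordingly noisy;
percent-correct values are stable to a few points between seeds.  Test
suites use smaller tables still.  Weighted medians use the
lower-weighted-quantile convention; annealing accepts equal-score
moves; p-value conventions are (count+1)/(n_perm+1) throughout except
the large-ensemble neutrality nulls, which use plain fractions.

## Known limitations

No recombination, selection, migration, or serial sampling; exactly
three regions and the four published topologies; priors are
reconstructions (see above); the exact substitution model and gamma
shape behind the original Φ_ST runs are unknown, so TN93(+gamma)
versus p-distance sensitivity should be reported alongside any
reanalysis of real data.
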