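# Methods

## Scan algorithm

For one chromosome panel of n rare-variant sites, each site k has a carrier
set C_k (individuals with ≥ 1 minor allele at k, as a length-N bit vector).
The carrier set of a bin is B(i, j) = C_i ∪ … ∪ C_j. The scan iterates
starts i = 0…n−1 and grows j from i, maintaining U = B(i, j) and
V = B(i+1, j) (V is the empty set while j == i, which makes the rule total:
a non-empty single-site carrier set never equals it). At each j, in this
order:

1. **break** if U == V (every longer bin from start i has a carrier set
   already reachable from start i+1) or U is the full set (the collapsing
   table would be degenerate, p = 1, and all extensions stay full);
2. **continue** without evaluating if variant j+1 exists and adds no new
   carrier (U == B(i, j+1)); the check order matters when U equals both V
   and B(i, j+1);
3. otherwise **emit** bin (i, j, U) and evaluate the statistic. At the last
   variant of the chromosome step 2 is vacuous, so a bin that survived
   step 1 is emitted — dropping it would silently lose rightmost maximal
   bins.

Because V ⊆ U ⊆ B(i, j+1), the set-equality tests are popcount
comparisons; carrier sets are Python arbitrary-precision integers, so they
are plain `==` on machine words. Emitted carrier sets are exactly the
distinct non-full carrier sets over all n(n+1)/2 bins; identical carrier
sets emitted at different loci are deliberately kept as separate emissions
(each is a separate test; they share a p value). Chromosomes are scanned
independently, and the same physical bin retained under two MAF thresholds
counts as two tests.

## Statistics

* Collapsing test: Pearson 1-df χ² on the carrier × phenotype 2×2 table,
  no continuity correction (the permutation calibration absorbs the
  finite-sample anticonservatism a correction would address). Zero margins
  (empty or full carrier set) give χ² = 0, p = 1. p values are floored at
  the smallest positive double so they stay in (0, 1].
* Odds ratio: ad/bc with Woolf's log-OR 95% CI,
  exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d)). Any zero cell leaves OR and
  CI undefined ('.') rather than inventing a continuity-corrected estimate.
* Single-marker analysis (SMA): allelic 2×2 Pearson χ² on minor- vs
  major-allele counts by phenotype, missing genotypes excluded. The
  statistic is invariant under allele orientation. SMA runs on all
  polymorphic sites (no MAF filter), as the genome-wide single-marker
  comparator.

## Genotype handling

The minor allele at each site is the allele with combined-sample frequency
≤ 0.5 (ALT on an exact tie). MAF is computed over all non-missing alleles
of cases and controls combined — a deliberate choice: combined MAF is
invariant under phenotype permutation, which is what allows carrier sets
and panels to be built once and reused across all permutation replicates.
Missing genotypes count as non-carriers and are excluded from the
allele-frequency denominator (conservative for a carrier-based test).
Retention is inclusive (maf ≤ maf_t); monomorphic sites are dropped;
multiallelic VCF records are skipped with a warning rather than decomposed
(decomposition would change carrier semantics). Sites at duplicated
positions are kept in input order; the scan operates on variant indices.

## Permutation engine

R label permutations are drawn once; both evaluation paths consume the
identical stream. The fast path stacks each panel's emitted bin masks into
a 0/1 matrix and obtains case-carrier counts for all replicates via a
float32 matrix product (sums of 0/1 entries are exact in float32 below
2²⁴, far above any supported N), then evaluates χ² in float64 through the
same function the scalar test uses — so it is bit-identical to the naive
path that re-runs the full scan per replicate (`method="naive"`, kept as a
cross-check and exercised in the tests on randomized small studies).
Replicates are processed in chunks of 128 columns to bound memory.

The empirical threshold is the k-th smallest per-replicate minimum p with
k = floor(FWER·(R+1)), and significance is declared for observed p
strictly below it — the standard ordering that guarantees FWER ≤ nominal.
R < 1/FWER raises an error (k = 0); R below 1/FWER per replicate warns.
The companion adjusted p value is (1 + #{min-p ≤ p})/(R+1), monotone in p
and consistent with the threshold (adjusted p at α ≈ FWER).

## Simulator

The generator is this package's own, fully specified model (the scan makes
no assumptions about how data arose):

* **Null model.** Per-site MAF from a density ∝ 1/x truncated to
  [1/(2N), maf_max] (a crude neutral-spectrum stand-in; `uniform` is also
  available), Hardy–Weinberg dosages Binomial(2, MAF) i.i.d. across sites
  and individuals, strictly increasing integer positions (gaps uniform on
  [100, 10000] bp), labels assigned to the first n_case individuals (under
  the null the labels carry no information). Defaults: maf_max = 0.05 (the
  largest scan threshold), 2 chromosomes × 500 variants, N = 200 with 100
  cases for calibration experiments.
* **Disease model.** A window of w consecutive variants on one chromosome
  is causal; each causal variant is independently detrimental
  (probability pdv, per-allele OR ~ Uniform(or_low, or_high)), neutral
  (probability pnv, OR = 1) or protective (OR = reciprocal of an interval
  draw). Disease probability is logistic,
  P(case) = expit(β0 + Σ_v dosage_v·ln OR_v), with β0 solved by bisection
  on a 200,000-draw Monte-Carlo estimate of the population prevalence
  (exact closed form logit(K) when no site has an effect). Cases and
  controls are collected by rejection sampling from the population until
  the design quotas are met; an unattainable prevalence raises after a
  bounded number of draws.
* **What it does not emulate:** linkage disequilibrium between sites,
  realistic demography or site-frequency spectra, genotyping/imputation
  error, covariate structure, quantitative phenotypes. Passing tests
  therefore demonstrate the scan's combinatorial correctness and the
  calibration's error control under independent-site sampling, not
  performance on LD-structured real data (where carrier sets of nearby
  variants are far more redundant and the pruning reduction is much
  larger than in these simulations).

## Power estimation

Power is the fraction of simulated disease studies whose genome-wide
minimum p (combined over MAF thresholds for the scan; over all sites for
SMA) falls strictly below a pre-computed threshold; both methods are
scored on the same replicates, with binomial standard errors. Thresholds
should come from permutations on a null study of the same design (the
`power` CLI subcommand does this when no alphas are supplied).

The power-comparison scenario exercised in the tests uses a balanced
N = 2000 study (1000 cases — balanced designs maximize the χ² power at
fixed N), one chromosome of 100 variants containing a 20-variant causal
window with pdv = 0.7, pnv = 0.3, per-allele OR 1.5, prevalence K = 0.01,
200 replicates. These problem sizes were chosen as the smallest design in
which the scan-vs-SMA contrast is clearly resolved above Monte-Carlo
noise.

## Numerical and design choices

* Equality of carrier sets uses integer equality; the popcount shortcut of
  the subset structure is what makes the inner loop O(1) per step.
* The calibration experiment (one null study, R = 999, α at FWER 5%, then
  400 independent null studies) reproduces the nominal 5% family-wise
  error within binomial tolerance; it is recomputed from scratch by
  `scripts/acceptance.py` and by the test suite.
* Blocks merge significant bins by transitive base-pair interval overlap,
  touching endpoints included, across MAF thresholds (a bin's physical
  extent does not depend on the threshold it was found at); the reported
  top bin ties break by smaller p, then smaller span, then leftmost start.
* All outputs are deterministic given (data, seed, R); every source of
  randomness is a numpy Generator seeded from one user-visible seed.

## Limitations

The collapsing test dichotomizes carrier status only: it cannot use allele
counts, covariates or mixed effect directions, and the scan's pruning
logic is specific to union-of-carriers statistics — it does not generalize
to variance-component tests. The simulator's independence assumptions
understate the pruning gains and overstate the effective number of
independent tests relative to sequenced human data.
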