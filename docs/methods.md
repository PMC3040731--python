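# Methods

## The union test

For a window of k biallelic markers and a coding scheme (dominant or
recessive with respect to the minor allele), each individual contributes a
three-valued indicator: 1 if the coded risk state is present at any member
marker, 0 if it is absent at every member marker with all genotypes
observed, missing otherwise. Missingness propagates by Kleene three-valued
OR — `1 ∨ ? = 1`, `0 ∨ ? = ?` — which is the unique monotone extension of
the published two-marker rules to arbitrary k: one observed hit settles
the union regardless of missing members, while an all-zero observation
with any member missing could still hide a hit. Individuals with a missing
indicator are excluded from that union only and reported in the output as
`n_excluded_missing`.

The 2 × 2 table of indicator counts among cases and controls is tested
with two-sided Fisher's exact test, so every union costs one degree of
freedom whatever its size. The test conditions on the table margins and
needs no estimate of per-marker frequencies, of the correlation r between
markers, or of haplotype phase, and it assumes neither Hardy–Weinberg
equilibrium nor linkage equilibrium. Because the union frequency depends
on inter-marker correlation through
P(X ∪ Y) = P(X) + P(Y) − P(X)P(Y) − r·√(P(X)(1−P(X))P(Y)(1−P(Y))),
the test is a *composite* test: it responds to genotype-frequency
differences and to differential correlation between groups, and cannot
attribute a rejection to either source.

## Scan construction and multiplicity

Markers (sorted by chromosome and position) are partitioned into
consecutive, non-overlapping windows of k markers; the last window on a
chromosome may be short. Windows never span chromosome boundaries: unions
are motivated by linkage disequilibrium among neighbouring markers, which
does not cross chromosomes. The testing burden for union sizes K and
coding schemes S is |S| · Σ_{k∈K} ⌈M/k⌉ over the M scanned markers, and
the per-test threshold is α divided by that burden — always recomputed
from the marker count actually scanned. Untestable unions (an empty case
or control row after missing-data exclusion) are recorded as skipped but
still count toward the burden, which by construction depends only on M.
Unions mix markers under one scheme at a time; heterogeneous per-marker
coding within a union is left as an extension point.

## Numerical conventions

* **Two-sided p-value**: the sum of probabilities, under the
  hypergeometric null at fixed margins, of all tables whose point
  probability does not exceed the observed table's — the convention of R's
  `fisher.test` and SciPy. For table totals ≤ 200 the sum is evaluated in
  exact integer arithmetic (ties are exact, no floating-point tie
  tolerance needed); larger tables are delegated to
  `scipy.stats.fisher_exact`. The two routes agree to ~1e-15 where they
  overlap and are cross-checked in the test suite.
* **Odds ratio**: the sample cross-product ratio
  (cases₁·controls₀)/(cases₀·controls₁), with the Haldane–Anscombe +0.5
  added to all four cells only when some cell is zero, and a Woolf
  log-normal 95% CI, exp(log OR ± 1.96·√Σ 1/cell), on the possibly
  corrected cells. A degenerate indicator (everyone 0 or everyone 1)
  reports p = 1 with OR and CI as NA. The conditional-MLE odds ratio is a
  known alternative; the cross-product convention was fixed because it is
  the common epidemiological default.
* **Allele orientation**: the minor allele is the strictly rarer allele in
  the pooled sample (cases + controls); an exact tie goes to the
  lexicographically smaller character, making orientation deterministic.
  Monomorphic markers are flagged (dosage all zero, minor allele unknown)
  since PLINK MAP files carry no allele columns from which to recover the
  unobserved allele. Half-missing PED genotypes ("A 0") are treated as
  fully missing, matching PLINK.

## The simulation generator

The generator emulates the validity/power study design directly at the
level of *coded* genotypes: each marker is a Bernoulli(f_j) indicator
(no three-state genotypes, no Hardy–Weinberg layer), disease status
follows a logistic model
P(disease|x) = expit(Σ_j log(OR_j)·x_j + Σ log(OR_epi)·x_i·x_j) with
intercept β₀ = 0, and each experiment uses 938 cases, 863 controls, and
1,000 replicates by default. Choices where the design was open:

* **β₀ = 0** (baseline risk ½). The published design fixes the group
  sizes but not the intercept or prevalence; since the test conditions on
  the table margins, β₀ affects only sampling efficiency, and ½ maximizes
  it. Quotas are filled by rejection: individuals are drawn in batches,
  status is sampled from the logistic model, and draws land in whichever
  group still has room until exactly 938/863 are collected; a capped draw
  budget turns degenerate specifications into an explicit generation
  error reporting acceptance rates.
* **Correlated pairs** are drawn from the bivariate Bernoulli law with
  p₁₁ = f_i f_j + r·√(f_i(1−f_i)f_j(1−f_j)), realized by sampling x_i
  marginally and x_j from its conditional law, which keeps both marginals
  exact. Every pair is checked against the Fréchet bounds before any
  sampling. When a design states only r², the coupling phase r = +√r² is
  assumed (the sign is configurable). Each marker may belong to one pair;
  higher-order correlation structures would compose pairwise and are not
  part of the shipped panels.
* **Differential correlation** (unequal r between cases and controls with
  equal marginal frequencies) is realized by drawing each group's
  genotypes directly from its own joint law; when any odds ratio differs
  from 1 the logistic model additionally acts by retention within each
  stream (accept a case-stream draw with probability P(disease|x), a
  control-stream draw with the complement).
* **Panel suite**: panels A–H cover the null (k = 1..5), per-SNP odds
  ratios 1.5 and 2, opposing-effect pairs (2, 0.5), (1.5, 0.67), (1, 1),
  one effect marker diluted by four nulls, correlated vs independent
  2-marker unions (r² ∈ {0, 0.8}), pure epistasis (OR_epi ∈ {1, 2, 0.5}),
  and differential correlation ((case r², control r²) ∈ {(0.8, 0),
  (0, 0.8)} at OR ∈ {1, 2}). The default frequency grid is
  (0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5), spanning the rare-variant
  to common-variant regimes on the minor-genotype-frequency axis.

What the generator does **not** emulate: genotyping error, population
stratification, cryptic relatedness, sex chromosomes, realistic
chromosome-scale LD beyond designated pairs, and the three-genotype
structure underlying the coded values. Passing simulation tests therefore
demonstrate the statistical behavior of the test under its own model —
validity and relative power — not robustness to those real-data artifacts.

## Problem sizes in the automated checks

The test suite runs the null-calibration and directional power checks at
the study's own scale (938/863, 1,000 replicates per configuration) with
Monte-Carlo tolerances of 3–4 binomial standard errors, the resolution a
1,000-replicate experiment supports. Exactness of the Fisher p-value is
verified against exhaustive enumeration over every margin configuration
with table total ≤ 60 (about 600,000 tables), and format round-trips and
algebraic invariants use small randomized fixtures. The acceptance script
reports the pooled null rejection proportion over the five union sizes
(5,000 replicate tests), the unbiased Monte-Carlo estimate of the
per-comparison error rate.

## Known limitations

* Sliding (overlapping) windows, covariate-adjusted regression variants,
  permutation-based multiplicity control, and mixture modelling of
  risk-increasing vs risk-decreasing components are out of scope.
* A significant union does not identify which member marker or haplotype
  drives the signal; the scan is hypothesis-generating.
* Power decreases when unions mix risk-increasing and risk-decreasing
  effects or grow too large relative to the signal (dilution); both
  behaviors are quantified by the shipped panels rather than corrected
  for.
* Binary PLINK (BED), VCF and dosage formats are not read; input is text
  PED/MAP.
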