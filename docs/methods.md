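# Methods

This note documents the statistical procedures the package implements, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that affect results.

## Data model

A cohort is a subjects × loci matrix of ternary genotypes with a binary
phenotype (case = 1). Each locus declares an ordered triple of genotype
labels; that order indexes everything downstream (contingency rows, one-hot
columns, CPT columns, tie-breaks). Published count tables write homozygotes
as single letters ("A", "G") and the heterozygote as a two-letter string
("AG"), so the reader accepts per-locus labels verbatim via a schema file and
both the "A/AG/G" and "AA/AG/GG" dialects work. The heterozygote is
identified structurally (the two-character label with distinct characters),
which the Hardy–Weinberg test needs to count alleles.

Missing calls (empty string or "NA" in CSV; −1 internally) are treated as
missing completely at random throughout. The published per-locus totals
(~920 typed subjects out of 980) are consistent with roughly 6% per-locus
missingness, which the generator adopts; no exclusion rule is documented, so
MCAR is an assumption, not a finding.

Train/test splitting is stratified by phenotype by default with per-class
train size ⌊fraction · class size + 0.5⌋. The protocol's 7:3 ratio is the
default fraction; whether the original split was stratified is unstated, so
stratification is exposed as a flag.

## Association testing

Each locus yields a 3×2 genotype-by-phenotype table over its complete cases.
Empty genotype categories are dropped before testing (this leaves the
statistic unchanged and keeps margins valid). The branch rule: Pearson
chi-square without continuity correction when every expected count is ≥ 5,
otherwise the Fisher–Freeman–Halton exact test — the r×k generalisation of
Fisher's test, computed by exhaustive enumeration of all tables with the
observed margins, summing multivariate-hypergeometric probabilities of
tables no more probable than the observed one (log-gamma arithmetic; a
configurable table-count cap guards the recursion, with the chi-square test
suggested beyond it). This branch rule reproduces the published P-values
exactly (to the printed three decimals) for every locus whose expected
counts clear 5: 0.880, 0.005, 0.375, 0.269, 0.992 for rs1042522, rs1801133,
rs1994798, rs7744, rs7851696. Two published small-cell P-values (rs56221660
0.049, rs17884306 0.309) match neither Pearson chi-square (0.056, 0.256) nor
our exact test (0.063, 0.316); the exact-test variant behind them is
unrecoverable, so they are not treated as reproducible reference values.

P-values are reported raw (the reference analysis reports raw values); a
Bonferroni option exists but is off by default. The Hardy–Weinberg check is
the classical 1-df chi-square of observed genotype counts against
(p², 2pq, q²)·n, pooled over cases and controls by default (configurable to
controls-only; the reference protocol does not say which). Note the pooled
published counts for rs1801133 (42/701/177) show a gross heterozygote excess
(χ² ≈ 286), so equilibrium is checked per locus, never asserted globally.

## Random-forest locus selection

Genotypes are one-hot encoded (3 columns per locus; 27 loci → 81 features)
after complete-case filtering, and scored with Gini mean-decrease-impurity
from a random forest (500 trees, √p feature subsampling, fixed seed, no
class weighting — the reference analysis states no hyperparameters, so these
are conventional defaults, all configurable). Scores are normalised to sum
to 1; per-locus importance is the sum of the locus's three feature scores,
so total importance is conserved. Selection takes loci with aggregate
importance strictly greater than 0.05 and unions in externally flagged loci
(association-significant and/or literature-reported), which is how the
nine-locus modelling set arises in the reference analysis.

## Structure learning

Candidate adjacencies are screened by pairwise Cramér's V,
φ_c = √(χ²/(n·min(k−1, r−1))), clipped to [0, 1]; for a 3×2
locus-phenotype table this is √(χ²/n). Each pair is tabulated over its own
complete cases, so a missing call at one locus does not discard the subject
from other pairs. The "strong correlation" cutoff is nowhere quantified in
the reference analysis; the default threshold is 0.1 because SNP-phenotype
φ_c values at published-count scale are ≈ 0.1 (rs1801133 gives 0.108) and a
textbook "strong" cutoff of 0.25+ would empty the candidate set. The
threshold is therefore an exposed parameter, not a constant. Expert
knowledge enters as whitelist edges (always present; must respect the
ordering) and blacklist edges (never present).

The K2 search walks a fixed node ordering; per node it greedily adds the
admissible predecessor that maximally increases the Cooper–Herskovits log
marginal likelihood

log Π_j [ (r−1)! / (N_j + r − 1)! · Π_k N_jk! ],

stopping when no addition improves or `max_parents` (default 3, bounding CPT
size at cohort scale) is reached. Restricting parents to predecessors makes
the result acyclic by construction. The default ordering ranks loci by
descending aggregate importance (lexicographic ties) with the disease node
last, so every locus is a candidate parent of disease.

## Parameter learning and inference

CPTs are posterior means under a symmetric Dirichlet prior:
(N_jk + α)/(N_j + r·α), α = 1 by default, with α → 0 giving maximum
likelihood and unobserved parent configurations falling back to uniform. The
prior actually used in the reference analysis is unrecoverable (its printed
CPT excerpts imply heterogeneous effective smoothing), so α is exposed. For
data with missing calls, `fit_cpts_available_case` estimates each node's CPT
from the subjects complete at that node and its parents — unbiased under
MCAR and far more data-efficient than joint complete-case deletion (0.94²
vs 0.94⁹ retention at 6% missingness and nine loci).

Posteriors are computed by exact variable elimination with a min-degree
elimination heuristic. A junction-tree engine would give numerically
identical answers at this scale; the arbiter is the brute-force
joint-enumeration oracle shipped alongside, and the two agree to ~1e−12 on
every network small enough to enumerate (tested on hundreds of random
ternary networks). Zero-likelihood evidence raises an error that
distinguishes structurally impossible evidence (zero CPT entries exist) from
numerical underflow.

The MAP search clamps disease to a state, enumerates every complete genotype
assignment over the modeled loci (3⁹ = 19 683 for nine ternary loci; a
configurable cap refuses larger enumerations), accumulates log-joint
probabilities, and ranks by P(combination | disease) with lexicographic
tie-breaking over state indices in locus order. P(disease | combination) is
reported for every combination because both conditional directions are
scientifically interesting and the reference analysis quotes both.

## Synthetic data

The generator draws ancestral samples from a ground-truth network and
rejects on the disease node until exact case/control quotas are met, then
appends independent null loci at stated genotype frequencies and applies an
MCAR mask to genotype cells. Identical seeds give byte-identical datasets.

The shipped scenario mirrors the study layout: nine modeled loci plus
disease in a 10-node / 10-edge topology (three loci parent the disease node;
locus–locus edges follow gene clusters: a folate-pathway chain, a TP53 pair,
a MYD88 pair), 18 null loci using the published pooled genotype frequencies,
490/490 subjects, 6% missingness. Two deliberate departures from strict
realism: (i) modeled-locus marginals avoid rare genotype states (minimum
state probability 0.15–0.18) so that the encoded dependencies are
identifiable at cohort scale — the published frequency spectrum, including
very rare homozygotes, is carried by the null loci instead; (ii) disease
effect sizes are moderate fixed constants (per-genotype log-odds increments
≤ 0.9, intercept solved by bisection so the marginal prevalence equals the
reported 48.2%). The generator does not model linkage disequilibrium from
population genetics, covariates, or subtype labels, so passing tests
demonstrate correctness of the estimators under the stated model, not
robustness to those real-data features.

The published-counts fixture expands each locus's printed 3×2 block into an
individual-level dataset whose tallies equal the printed counts exactly.
Only marginals are published, so the fixture is strictly per-locus: no joint
individual-level dataset across loci is fabricated, because the joint
structure is not identified by marginal counts.

## Recovery experiments and their scope

`recovery_experiment` simulates from a known truth, runs screen → K2 → fit,
and reports skeleton precision/recall against the true adjacencies plus the
maximum absolute CPT cell error of parameters refitted on the true
structure. The cell-error metric is scoped to parent configurations observed
at least `min_obs` times (default 900): a binomial proportion estimated from
N draws has sampling standard error up to 0.5/√N, so a 0.05 convergence band
lies three standard errors from the truth only for N ≥ (3·0.5/0.05)² = 900 —
at 20 observations the noise floor alone is ≈ 0.1, and no estimator could
certify convergence there. Sparser configurations are excluded from the
metric, not from the fit.

Benchmarks used by the test suite: a strong 4-node ternary chain
(dependence weight 0.8) for structure recovery — skeleton recall averages
1.0 over 20 seeds at n = 2 000 — and the shipped scenario at a 5 000-subject
draw for parameter recovery, where the maximum scoped cell error stays below
0.05.

## Evaluation

Disease prediction thresholds P(disease | observed genotypes) at 0.5
(configurable); subjects with missing genotypes are scored on reduced
evidence rather than dropped. The report is the 2×2 confusion matrix
(predicted × actual, case row/column first) with accuracy, per-class
precision/recall/F1. External validation scores labelled held-out samples
and reports per-sample probabilities plus the fraction of correct calls.
Published performance figures (accuracy 78.39%, etc.) depend on the
unavailable cohort and an unstated split seed; they are format references,
not targets, and the package reports whatever the data at hand produce.

## Known limitations

- The exact test enumerates tables; very large sparse tables exceed the cap
  and must fall back to chi-square.
- K2 is greedy and ordering-dependent by design; no search over orderings,
  bootstrap confidence, or structure averaging is provided.
- Inference is exact and exponential in treewidth; intended for the ≤ 10-node
  models this analysis targets.
- No imputation: missingness is handled by complete-case or available-case
  deletion under MCAR only.
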