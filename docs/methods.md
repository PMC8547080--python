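# Methods

`omegatrait` screens protein-coding genes for evolutionary-rate signatures
associated with a discrete phenotype on a species tree. The package was
built around the mammalian testicular-position problem — scrotal (CDT)
versus ascrotal (IDT/UDT) lineages — but every component is generic over
any two- or three-class trait. This note records the models, their
assumptions, the defaults, and the numerical and design choices.

## Codon substitution model

The likelihood engine implements the GY94 family over the 61 sense codons
of the standard genetic code. The generator is

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]

for codon pairs differing at exactly one nucleotide, zero otherwise, with
the diagonal set so rows sum to zero. Each matrix is rescaled so the
expected substitution rate at stationarity is one; branch lengths `t` are
therefore expected substitutions per codon, per branch, under that branch's
own omega. Codon frequencies `pi` default to F3x4 (position-specific
nucleotide frequencies estimated from the alignment, with a quarter-count
guard against zeros); F61 and uniform are available. Ambiguous codons and
partially gapped codons are treated as missing data (all-ones partial
likelihoods), the standard pruning convention; `---` columns are kept
distinct from ambiguity because the substitution scan needs true gap
structure.

Likelihoods use Felsenstein pruning over unique site patterns with
per-node rescaling. The chain is reversible, so transition matrices come
from a single symmetric eigendecomposition per (kappa, omega, pi) and
`P(t)` is cheap for any `t`.

### Model hierarchy and fitting

* **one-ratio**: single omega; kappa, omega and all branch lengths are
  estimated jointly by bounded L-BFGS-B on log-parameters
  (kappa in [0.05, 50], omega in [1e-4, 50], t in [1e-6, 20]).
* **two-ratio (branch model)**: separate foreground/background omega on a
  labeled tree; kappa and the omegas are re-optimized from the one-ratio
  solution with branch lengths held at the one-ratio MLEs (a config flag
  re-estimates them). Starting at the one-ratio optimum guarantees the
  nested log-likelihood ordering.
* **free-ratio**: an independent omega per branch, kappa re-optimized,
  branch lengths again fixed at the one-ratio MLEs.
* **branch-site model A**: four site classes — 0 (0 < omega0 < 1
  everywhere), 1 (neutral everywhere), 2a (background omega0, foreground
  omega2) and 2b (background neutral, foreground omega2) — with
  proportions p0, p1, p2*p0/(p0+p1), p2*p1/(p0+p1). The null fixes
  omega2 = 1; the alternative allows omega2 >= 1. kappa and branch
  lengths are fixed at the one-ratio MLEs. Site posteriors are naive
  empirical Bayes at the MLEs (not BEB), a documented divergence from
  codeml. The LRT uses chi-square with df = 1, the conservative choice
  rather than the 50:50 boundary mixture.

Fixing branch lengths after the one-ratio fit trades a little likelihood
for an order-of-magnitude speedup and is the main reason genome-scale
branch tests are feasible at desk scale; the decision rules downstream are
threshold-based and insensitive to the small lnL differences involved.

Gradients: branch-length derivatives are computed analytically with the
standard inside/outside two-pass scheme
(`dlnL/dt_v = sum_s w_s (B_v . Q up_v) / (B_v . up_v)`); per-branch omega
derivatives in the free-ratio fit use one-branch local central
differences against the cached outside vectors; the two global parameters
(kappa, shared omega) use central finite differences. The optimizer runs a
single deterministic start by default (`n_restarts` adds seeded random
restarts): with exact branch-length gradients the surfaces encountered in
practice are well-behaved, and restarts would triple the cost of every
simulation-based check for no observed benefit.

### Per-branch dN and dS

The substitution flux under the fitted matrix splits into nonsynonymous
and synonymous shares rho_N + rho_S = 1; site proportions p_N, p_S come
from the same matrix with omega set to one. Then dN = t*rho_N/(3 p_N) and
dS = t*rho_S/(3 p_S), which makes dN/dS reproduce omega exactly. These
values exist only to drive the root-to-tip filter below, where convention
differences between decompositions are immaterial.

## Selection tests and decision rules

Branch tests (two- vs one-ratio) and branch-site tests (alternative vs
null) are chi-square LRTs with df = 1, corrected across genes by
Benjamini–Hochberg; the FDR cutoff defaults to 0.05.

* **REG (rapidly evolving gene)**: adjusted p < 0.05 AND
  (omega_fg/omega_bg > 5, evaluated as +inf when omega_bg = 0 and
  omega_fg > 0, OR omega_fg > 0.5 with omega_fg > omega_bg). Both
  cutoffs are strict inequalities. The clause that fired is reported.
* **PSG (positively selected gene)**: adjusted branch-site p < 0.05 AND at
  least one codon with posterior probability of the positively selected
  classes (2a + 2b) above 0.8. Selected codons are reported as 1-based
  alignment columns.

## Root-to-tip omega and the calibrated PGLS screen

For each gene the free-ratio fit yields per-branch omega; the root-to-tip
omega of a species is the unweighted arithmetic mean over the branches on
its root-to-tip path after removing branches with dN < 2e-4 or
dS < 2e-4, where the ratio is numerically meaningless. A species whose
whole path is filtered is missing for that gene.

Association uses PGLS: the numeric phenotype encoding (two-class
scrotal = 0 / ascrotal = 1; three-class CDT = 0, IDT = 1, UDT = 2,
ordinal by completeness of descent) is regressed on root-to-tip omega
under Brownian-motion covariance `C[i,j] = depth of the MRCA of i and j`
computed from the time tree. Pagel's lambda is fixed at 1 (pure Brownian
residuals). The slope's two-sided t test uses df = n - 2. A flag swaps
response and predictor for sensitivity analysis. Genes with fewer than 4
usable species are skipped with a logged reason.

The two-step calibration guards against single-species artifacts:
`p_all` from all usable species; `p_robust` after dropping the species
with the largest absolute residual; `p_max`, the worst (largest) p over
all leave-one-species-out refits. A gene is significant when p_all < alpha
AND p_max < alpha; whether p_robust must also clear alpha is configurable
(`require_robust`, off by default) — p_robust is always reported. Refits
that would drop below 4 species contribute a conservative p = 1.

Phenotype is the response and omega the predictor by default. Note the
leverage consequence: with a binary response a single species can never
carry p_all below ~0.1, so single-species artifacts enter through the
three-class encoding (one extreme-class species with an extreme rate),
which is exactly the construction the calibration tests use.

## Phylogenetic ANOVA

Group differences in per-species counts (gene-family expansions and
contractions) are tested with a simulation-based phylogenetic ANOVA: the
observed statistic is the ordinary one-way ANOVA F over tips; the null
distribution comes from Brownian-motion simulations on the tree with rate
set to the phylogenetically corrected variance of the observed tips (GLS
mean, quadratic form over C, divided by n - 1);
p = (#{F_sim >= F_obs} + 1)/(nsim + 1) with nsim = 1000 by default,
seeded. Groups need at least two members each.

## Substitution scan

Codon alignments are translated (gaps propagate as `-`, ambiguity as `X`)
and scanned column by column for group-specific replacements. A column is
reported when the background is conserved at the reference residue (zero
derived background residues by default), at least `min_fg_fraction = 0.75`
of non-missing foreground residues are derived (several derived states may
co-occur, reported slash-separated), and background coverage is at least
0.8. The 0.75 default tolerates the incomplete carriage seen in real
group-specific substitutions (e.g. 10 of 13 carriers) while excluding
sporadic states; it is fully configurable because no canonical threshold
exists. Positions are reported in 1-based coordinates of the ungapped
reference row — alignment-derived, so they can shift against a database's
canonical isoform; an offset option exists for that case.

## Overlap statistics and shared expansions

Overlap between two gene lists in a finite universe uses the one-sided
Fisher exact test (upper hypergeometric tail — the enrichment convention)
and the sample odds ratio (a*d)/(b*c), 0 when the intersection is empty,
+inf when a zero off-diagonal cell makes the association unbounded. The
universe defaults to the set of genes analyzed and is a required choice:
it changes p-values materially. Shared expansions reduce per-species
expanded-family sets to families expanded in at least k members of a
group (default k = 6).

## Synthetic data: what it emulates and what it does not

The generators produce every input the pipeline reads, with recorded
ground truth:

* **Trees**: pure-birth (Yule) ultrametric trees scaled to a requested
  depth, plus a fixed 30-tip working tree (depth 100 time units) with a
  study-like phenotype layout — 17 scrotal, 9 IDT, 4 UDT, mixing pure
  ascrotal clades with scattered singletons so both foreground-labeling
  modes are exercised.
* **Codon alignments**: exact sampling from the exponentiated generator
  branch by branch (site-independent, no indels, no alignment error, no
  selection heterogeneity beyond what is planted). Stop codons cannot
  arise. Default simulation conditions: kappa = 2, omega_background =
  0.2, 300 codons, tree depth 0.4–0.8 substitutions per codon — typical
  mammalian ortholog divergence.
* **Trait–rate tables**: per-species root-to-tip omega around a base of
  0.2 with Brownian-correlated noise (tip SD 0.05); signal genes add
  0.1 x the phenotype encoding (a ~50% rate elevation in the foreground),
  or the whole effect on one species for the calibration stress test.
* **Family counts**: gamma-Poisson (negative-binomial-like) counts, base
  mean 120, dispersion 8, with optional group mean shifts and planted
  shared expansions.
* **Gene lists**: exact requested intersection sizes.

Passing tests on these data show the inference machinery is correct and
calibrated under the stated generative model. They do not certify
robustness to alignment error, indels, selection on synonymous sites,
non-Brownian trait evolution, or model misspecification in real
alignments.

## Problem sizes and tolerances

The statistical checks run at fixed, seeded sizes chosen to give stable
pass/fail behavior at interactive cost: likelihood-vs-enumeration on
3-taxon/50-codon instances (agreement to 1e-6), omega recovery at 8
taxa/500 codons, type-I error of the branch test over 100 null replicates
at 6 taxa/300 codons (binomial band [0.01, 0.11]), branch-site null over
100 replicates at 200 codons (<= 7 rejections, reflecting the
conservative df = 1 reference), detection over 25 replicates at 300
codons on 10-taxon trees with 4 foreground species (a study-like ~40%
foreground fraction — detection power depends directly on the summed
foreground branch length, so sparse foregrounds are underpowered by
construction), PGLS against the explicit normal-equations oracle to 1e-8, and
overlap p against exhaustive hypergeometric tails for every universe up
to N = 30. The uniform-effect calibration construction uses effect 0.065
on the 20-tip tree, sized so that median p_all is near 1e-4.

## Known limitations

* No bit-compatibility with codeml: F3x4 estimation details, optimizer
  paths, and the naive-EB site posteriors all differ; only the decision
  rules and statistical behavior are matched.
* Branch lengths fixed after the one-ratio fit slightly deflate LRT
  statistics (conservative).
* The branch-site alternative often drives omega2 to its upper bound on
  small data; the LRT and posterior gates, not omega2 itself, carry the
  inference.
* PGLS treats the ordinal three-class encoding as numeric, as is common
  practice; no cumulative-link phylogenetic model is provided.
* The phylogenetic ANOVA assumes Brownian evolution of counts; counts are
  bounded below at zero, so extreme-rate regimes can violate the null
  model.
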