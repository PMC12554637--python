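# Methods

## Model

`treede` performs differential expression (DE) testing for single-cell
RNA-seq with multiple annotated cell types, jointly across the cell types.
Counts are first aggregated to pseudo-bulk: for gene *g*, subject *i* and
cell type *k* the cells' counts are summed and log-normalized
(`Y = ln(1 + count / libsize × 10⁴)`, library size per pseudo-bulk column
over the retained genes).

Given a latent binary DE state `Z_gk`, the normalized pseudo-bulk is modeled
as Gaussian

    Y_gik | Z_gk ~ N( μ_gk + C_i'β_gk + Z_gk · A_i'δ_gk ,  σ²_gk )

where `A_i` is the tested factor (binary or continuous, possibly
multi-column) and `C_i` are nuisance covariates.  For every (gene, type)
both the null (`1, C`) and alternative (`1, C, A`) models are fit by OLS;
each carries its own MLE variance `σ̂² = RSS / N_k` (N_k = subjects present
for that type), floored at 1e-8 so zero-residual genes cannot contribute
unbounded likelihoods, and the two plug-in Gaussian log-likelihoods are
stored.

## Cell-type tree and priors

DE states are correlated across related cell types.  The correlation is
encoded by a rooted tree whose leaves are the K cell types.  Per gene, every
node has a binary state; the root is on with probability π_root, any other
node is on with probability p given its parent is on and off with certainty
given its parent is off, and siblings are independent given an active
parent.

The tree topology is estimated by agglomerative clustering (UPGMA by
default) of `distance(k₁,k₂) = (1 − cor(tstat_{k₁}, tstat_{k₂}))/2`, where
`tstat` comes from a first-pass per-type screen restricted to genes with
|tstat| > 2.58 (the two-sided normal critical value at p = .01) in at least
one type.  A user-supplied newick tree bypasses construction.

Node probabilities are estimated genome-wide from the screen's p-values:
a node's marginal π̂ is the fraction of genes with min p-value over its
descendant types below .01, and conditionals are ratios of child to parent
marginals.  Child descendant sets nest inside parent sets, so π̂ is monotone
down the tree and every p̂ lies in (0, 1]; boundary estimates are moved
1/(2G) off 0 or 1 to keep logs finite.

For likelihood evaluation an internal node's state is collapsed to the OR
of its descendant leaves, making the joint a function of the 2^K leaf
configurations alone.  The top-down cascade also permits "node on, all
children off" paths that the collapse excludes, so the collapsed prior
carries slightly less than unit mass; posteriors are normalized within the
2^K set and are therefore proper.

## Posterior computation

Because the likelihood factorizes over cell types given Z, the
log-likelihood of any configuration is a sum of per-type pieces.  For each
gene all 2^K configuration log-joints (likelihood + prior) are assembled,
the marginal obtained by log-sum-exp, and the per-leaf posterior
`P(Z_gk = 1 | Y_g)` by log-sum-exp over configurations with that leaf on.
Enumeration is exact; the tool refuses K > 16 (override via `kmax`).
Log-sum-exp keeps the computation stable for log-likelihood gaps up to
±1e4.  Genes with posterior strictly above 0.95 (default) are called DE,
ranked by posterior with ties broken by gene identifier.

## Screening backends

The screen is defined by its contract — one signed statistic and one
two-sided p-value per gene per type:

* `nb_wald` (default): negative-binomial GLM Wald test on raw pseudo-bulk
  counts with a log-library-size offset, the role a bulk NB tool plays in
  a standard workflow.  Per-gene NB2 dispersion by method of moments from a
  Poisson pass, floored at 1e-8, no shrinkage; the GLM is solved by IRLS
  vectorized across genes.
* `ols_t`: OLS t statistic of the tested factor on the log-normalized
  matrix; with no covariates and binary A this equals the pooled-variance
  two-sample t.

Missing statistics (degenerate designs, failed fits) are excluded pairwise
from correlations and treated as non-significant in prior estimation.

## Synthetic data generator

The generator emulates a two-group whole-blood style study with six immune
cell types of unequal abundance (NK 0.08, B 0.10, CD4 0.35, CD8 0.28,
Mono 0.18, DC 0.01; only the DC value is a fixed reference point, the rest
are realistic configurable defaults).  Defaults: 13,653 genes, 200,000
cells, 20 subjects per group.

* **DE states**: drawn per gene by the top-down cascade on the default tree
  ((NK,(B,(CD4,CD8))),(Mono,DC)) with π_root = 0.5, p values 0.667 / 0.8 /
  0.6 / 0.833 / 0.75 / 0.9 / 0.9 / 0.444 / 0.9 / 0.9, which imply a 20%
  marginal DE rate per leaf and pairwise DE overlaps 0.90 (CD4–CD8,
  Mono–DC), 0.75 (B vs CD4/CD8), 0.60 (NK vs CD4/CD8), 0.40 across the two
  clusters.  `independent_tree()` gives the no-sharing control (root always
  on, leaves independent Bernoulli(0.2)).
* **Counts**: `X ~ NB(s·μ, φ)` with variance `s·μ + φ(s·μ)²`; per-cell size
  factor `s ~ U(0, 0.12)` (shallow droplet-style depth), dispersion
  `φ = 0.01/μ + 0.05` from the unscaled mean, and group-2 means multiplied
  by `2^lfc` with `lfc ~ N(0.065, 0.12²)` for DE entries and `N(0, 0.001²)`
  otherwise, drawn independently per (gene, type).
* **Baselines** are synthetic (no external dataset is read): gene mean
  ~ LogNormal(log 5, 1.2²) clipped below at 0.05, times a multiplicative
  LogNormal(0, 0.25²) effect drawn per (gene, subject, cell type).  The
  subject-level term makes the ~10²–10³ cells of one subject correlated —
  the pseudo-replication that wrecks cell-level tests — while keeping cell
  types conditionally independent, matching the model's own assumption.
  Drawing it per cell type rather than once per subject is deliberate: a
  shared draw would couple null evidence across the whole tree and no joint
  model of this family could control FDR.

What the generator does **not** emulate: dropout/zero-inflation beyond the
NB law, batch effects, empirically estimated per-gene baseline profiles,
cell-count imbalance between subjects.  Tests passing on this generator
therefore demonstrate correctness of the machinery and the designed
information-sharing behavior, not performance on any particular real
dataset.

## Benchmarking

`pr_auc` evaluates precision/recall at every distinct score threshold
(ties grouped), anchors the curve at recall 0 with the top group's
precision, and integrates by the trapezoid rule.  `observed_fdr` is
|called ∩ null| / max(1, |called|) (0 when nothing is called).  Comparator
baselines: a pseudo-bulk pooled two-sample t-test (identical to the
`ols_t` screen with no covariates) and a cell-level pooled t-test that
deliberately ignores subject structure, both called at BH-adjusted
p < 0.05.  Permutation utilities shuffle the tested factor across subjects
(covariates untouched), 20 permutations and median overlap by default.

When summarizing the cell-level t-test's FDR inflation across cell types,
types with zero discoveries are excluded from the minimum: an empty
discovery set has FDP 0 by convention but carries no information about
inflation, and at reduced cell budgets the rarest type (DC, 1%) often makes
no calls at all.

## Problem sizes used in the checks

The automated checks run a scaled-down study — 2,000 genes, 10,000 cells,
10 subjects per group — chosen so the full pipeline (simulation, screen,
tree, priors, 2⁶-configuration posteriors, comparators) runs in seconds per
replicate.  Monte-Carlo checks of the tree-implied DE-state arithmetic use
50,000 genes.  At the scaled cell budget the per-type effect sizes implied
by the lfc law (mean |log2 FC| ≈ 0.10) are small relative to the
between-subject heterogeneity (sd 0.25 on the natural-log scale), so
absolute detection power is low; the checks therefore target calibration,
ordering and information-sharing properties rather than absolute power.
In this low-power regime the posterior-0.95 discoveries are themselves
dominated by chance coincidences of subject-level noise across types, and
their observed FDR is far above what deeper studies achieve — a known
limitation of plug-in (OLS/MLE) likelihoods documented here so that small
pilot analyses are interpreted with care.

## Numerical choices

* Variance floors: 1e-8 on Gaussian σ̂², 1e-8 on NB dispersion, 1e-12 on
  the OLS screen variance.
* Prior flooring: 1/(2G) off the 0/1 boundary.
* Tree determinism: cell types are clustered in sorted-label order and
  children ordered by smallest leaf label, so the topology is invariant to
  input order; merge-height ties resolve lexicographically.
* Missing (subject, type) pairs are dropped from that type's likelihood
  only (the likelihood factorizes over types); zero-library pseudo-bulk
  columns are dropped with a warning (error in strict mode).
* Multi-column tested factors are supported; the DE call then tests joint
  inclusion of all columns.

## Known limitations

* Plug-in likelihoods (each hypothesis keeps its own MLE variance) are not
  integrated marginal likelihoods; posteriors are sharper than a fully
  Bayesian treatment would give, which matters most in low-power designs.
* The Gaussian model on log-normalized pseudo-bulk is an approximation
  that degrades for very sparse genes; the expressed-in-≥10-cells filter
  is the only guard.
* Priors are estimated once genome-wide and shared across genes; there is
  no empirical-Bayes refinement loop.
* Exact enumeration limits the tree to ~16 leaves.
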