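# Methods

## Expression model and thresholds

All analyses operate on feature × tissue matrices of median TPM (genes or
transcripts) or RPKM (developmental stages). A feature is *expressed* in a
tissue when its value passes an `ExpressionThreshold`; the default is
TPM ≥ 1.5 with an inclusive comparator (`ge`), configurable to strict
(`gt`) because reference resources phrase the same cutoff both ways. The
comparator in force is recorded in outputs.

Correlation between a tissue of interest (TI) and a candidate tissue of
analysis (TA) is Pearson's r = cov(x, y)/(SD_x·SD_y) with covariance and
standard deviations both on the sample (n−1) convention; r is invariant
to that convention as long as it is applied consistently. Gene selection
for a TI–TA pair defaults to *either_tissue* — a gene of the input list
enters the computation if it passes the threshold in at least one of the
two tissues — which keeps presence/absence differences informative;
`ti_only` and `both_tissues` are selectable. Correlation is computed on
raw median TPM by default (no transform is implied by the correlation
definition); a `log2(TPM + 1)` mode is exposed because raw TPM is heavy-
tailed and a handful of highly expressed genes can dominate r. Undefined
correlations (fewer than 3 qualifying genes, or a zero-variance column)
are flagged (NaN plus a warning), never raised, so scans over many TAs
complete; identical input vectors short-circuit to r = 1 exactly so that
a duplicated column is reported as a perfect proxy free of rounding.

## Randomization contest and its significance call

To control for the influence of the particular gene list, the TI–TA
contest is replayed `n_iterations = 100` times on gene lists sampled
uniformly without replacement from all genes in the matrix (optionally
only from genes expressed in the TI), with the same threshold and
selection rule as the real analysis. Each round awards one win to the TA
with the highest r; ties break to the lexicographically smallest label
and are counted; a TA with undefined r cannot win a round, and a round
where every TA is undefined is redrawn (bounded, logged). A single seeded
generator drives all rounds and the seed is recorded.

Two significance figures accompany the winner's count k out of n rounds
among m TAs:

* `top_ta_tail_p` — the exact binomial tail P(X ≥ k | n, p₀ = 1/m),
  computed by direct summation. This is the textbook binomial test
  applied to the winning tissue, but it ignores that the tissue was
  *selected* for having the most wins, and is therefore anti-conservative
  as a test of "is some TA preferred".
* `binomial_p` — the package's significance call: the exact probability
  that the *largest* of m exchangeable win counts reaches k,
  P(max_j X_j ≥ k) under Multinomial(n, uniform), computed by
  inclusion–exclusion over which cells exceed k (terms with j·k > n
  vanish; no approximation). This is the selection-aware version of the
  same exchangeability null.

### Known limitation: dataset re-use makes the contest over-disperse

Even the selection-aware call is only exact when rounds are independent
multinomial trials. They are not: all rounds re-use one finite expression
matrix, so whichever TA happens to correlate best with the TI *in that
matrix as a whole* (a fluctuation of order 1/√n_genes) enjoys a tilted
win probability in every round — and because all TAs are scored on the
same random list per round, the shared sampling noise cancels out of the
comparison and amplifies the tilt. Measured on 200 synthetic references
with TI and 4 TAs i.i.d. (1000 genes, 100 rounds, list size 39), the
fraction of datasets with p < 0.05 is ≈ 0.52 for the plain binomial tail
and ≈ 0.22 for the exact max-adjusted call, against a nominal 0.05 — while
the max-adjusted call is correctly calibrated (≈ 0.037) when win counts
are truly multinomial. The residual anti-conservativeness is therefore a
property of the resampling design itself, shrinking only as
list_size/n_genes → 0. Consequence: `binomial_p` orders evidence well and
separates a genuinely planted proxy from noise by many orders of
magnitude, but at these problem sizes it should be read as an index of
stability, not as a frequentist error rate over reference datasets.

## Overlap and capture

Per-tissue expressed sets are restricted to the input gene list; genes of
the list absent from the matrix are reported in `not_in_matrix`, never
silently dropped (phenotype lists routinely contain RNA genes missing
from expression references). With multiple TIs or TAs the *at-least-one*
union rule applies on each side. `captured` = input genes expressed in
≥ 1 TA; `not_covered` = expressed in no TA; `not_in_ti` is also reported.
Exclusive Venn regions (keyed by the exact set of tissues containing a
feature) are enumerated for up to 5 tissues — beyond that only per-tissue
sets, unions and capture statistics are emitted. At the transcript level
the identical set algebra runs on isoforms of the input genes; a
transcript qualifies on its own TPM, without additionally requiring its
parent gene to pass the gene-level threshold (the stricter alternative
would only shrink every set and is easy to impose upstream).

## PPI functional-module enrichment

The study set (e.g. genes silent in the TI) is extended with its
first-degree interaction partners to increase power; study genes absent
from the network are retained. For every GO term two exact hypergeometric
upper tails are computed (integer arithmetic, converted to float at the
end):

* conventional (gene-counted): universe N = annotated genes present in
  the network (configurable to all annotated genes), K = universe genes
  with the term, n = extended genes in the universe, k = extended genes
  with the term;
* network-wise (edge-counted): population N = all network edges,
  K = *functional* edges for the term (both endpoints annotated with it),
  draws n = edges of the subgraph induced by the term's module genes
  within the extended set (an `incident` variant — all edges touching a
  module gene — is exposed as an option), k = functional edges among the
  draws.

Terms with K < 2 genes (conventional) or < 1 functional edge
(network-wise) are skipped as degenerate; both cutoffs are configurable.
Benjamini–Hochberg step-up adjustment is applied separately within each
family, and a module is *significant* when both adjusted p < 0.05 and it
contains at least one original study gene.

Because the tails are exact and discrete, raw null p-values are
super-uniform (P(p ≤ α) ≤ α with strict inequality between atoms), so a
two-sided KS test of raw p against Uniform(0,1) rejects for structural
reasons. Null behaviour is therefore validated two ways: the
conservativeness bound P(p ≤ α) ≤ α is asserted directly, and uniformity
is tested on the randomized probability integral transform
u = P(X ≥ k+1) + U·P(X = k), which is exactly Uniform(0,1) if and only if
the claimed null distribution is the true one.

## Developmental stages

A stage matrix holds one RPKM value per gene per stage, the stages in
explicit ontogenetic order (prenatal first by default); the value is the
maximum over the structures/donors measured within the stage, a
pre-aggregation performed by `StageMatrix.from_structures` with `max` as
the default reducer (the reducer is the loader's explicit choice, not
hidden). Each gene is assigned the stage of its maximum; ties go to the
earliest declared stage and are counted and logged; all-zero genes get an
`unexpressed` pseudo-stage and are excluded from counts. Stage
differences are tested by one-way ANOVA with stages as groups and genes
as observations (the only reading in which stages are the groups), with
Tukey HSD for all pairwise stage contrasts; a matrix with zero
within-group variance everywhere is flagged degenerate rather than
tested. Enrichment of prenatal-max genes is an exact one-sided binomial
test of the prenatal count against p₀ = 1/n_stages over assigned genes —
the natural null that a gene's maximum lands in any stage equally often.

## Synthetic data

The generator emulates the statistical shape of the real resources, not
their content. Log TPM of the TI is Normal(μ = 1.0, σ = 2.0) per gene
(natural log — a wide, heavy-tailed TPM distribution); a TA with latent
correlation ρ is ρ·z + √(1−ρ²)·ε with independent ε from the same
marginal, then exponentiated, so ρ is the correlation of *log*
expression and the TPM-scale Pearson correlation is systematically lower
— properties tied to ρ are accordingly asserted on the log scale. A 30%
per-tissue silent fraction is forced to exactly threshold/10 = 0.15 (not
zero), so threshold-boundary logic is exercised. Transcript matrices
split each gene over 1–k isoforms by Dirichlet weights with exact
per-gene conservation. PPI networks draw edges with Pareto-weighted
(heavy-tailed) degree propensities and random GO term labels; the planted
module wires a term's genes (part study genes, part partners attached to
them) densely, guaranteeing excess functional edges inside the extended
study set by construction. Stage matrices are i.i.d. log-normal across
stages except for a plantable fraction of genes whose prenatal value is
multiplied by 2^effect.

What the generators do not emulate: read counts and library-size noise,
splicing structure beyond isoform proportions, correlated gene modules
within a tissue, GO term hierarchy, or annotation bias. Passing tests
therefore demonstrate correctness of the statistics and recovery of
planted structure under a clean generative model, not performance on
real GTEx/HPO/PPI data.

Problem sizes used by the acceptance checks — 100 simulated references
of 5000 genes for proxy recovery, 200 null datasets of 1000 genes for
calibration, 100 networks of 300 genes/~1200 edges for enrichment — were
chosen so the whole battery completes in well under a minute while
keeping Monte-Carlo error comfortably inside the asserted margins.

## Numerical choices

* Exact tails (binomial, hypergeometric, multinomial-maximum) are
  computed by direct summation / inclusion–exclusion, not normal
  approximations; hypergeometric sums use exact integers.
* BH adjustment follows the step-up definition
  adj_(i) = min_{j ≥ i} p_(j)·m/j capped at 1, returned in input order.
* GCT writing uses `repr` of Python floats, making write→read round
  trips bit-exact; readers reject malformed files (wrong version
  literal, dimension mismatch, non-numeric cells) with line numbers
  rather than repairing them, and accept LF or CRLF.
* Ranking ties (equal r, equal win counts, equal coverage) break
  lexicographically by tissue label so all outputs are deterministic.
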