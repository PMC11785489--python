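# Methods

This note documents the models implemented in `tcrfate`, the choices made
where the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## Repertoire quality control and clonotypes

Contigs are read from the 10x contig CSV or AIRR Rearrangement TSV dialects;
loci other than TRA/TRB are dropped with a logged count. A cell is retained
if it has exactly one productive α and one productive β chain (dual-α and
dual-β cells are excluded), all four V/J gene names resolved with the V
genes present in the gene table and not flagged as pseudogenes, and CDR3
lengths within 10–17 (α) and 11–18 (β) amino acids, counted on the
junction-inclusive string with its conserved C…F/W anchors. The rules apply
in that fixed order and the QC report attributes each removed cell to its
first failing rule, which makes reports reproducible and additive. QC is
idempotent.

Clonotypes are defined at the amino acid level as the concatenation of the
Vα, Jα, Vβ, Jβ gene names (allele suffixes stripped, since contig dialects
disagree about allele reporting) with both CDR3 sequences. One cell is
sampled uniformly at random per (donor, clonotype) group before any model
fitting, so expanded clones cannot dominate a fit; the sampling is
deterministic per seed.

**TCR twins** are clonotypes observed in exactly two donors (clonotypes in
one donor are clonal expansions; in three or more they are increasingly
likely to be convergent artifacts or very high-frequency public receptors).
Each twin member's transcriptional state is the majority cluster over that
donor's member cells. The majority rule needs a tie-break that upstream
conventions do not fix; we break ties to the lexicographically smallest
cluster label and log the event, so results are deterministic.

## Featurization

Six CDR loops are encoded: CDR1/CDR2 of both chains (germline, looked up
from the V-gene table) and the CDR3 junction interiors. For CDR3 we drop the
two invariant anchor residues and featurize the interior, since invariant
positions carry no information; all per-loop quantities (slots, composition,
length) then refer consistently to that interior.

Default slot allocation: CDR1α=7, CDR2α=8, CDR3α=15, CDR1β=6, CDR2β=6,
CDR3β=16 — 58 slots total, hence 290 positional features (5 Atchley factors
per slot). Composition contributes 19 features per loop (percent of the loop
occupied by each amino acid except glycine, the reference; denominators are
true loop lengths, not slot counts), lengths contribute 6, and each pair of
sequence-adjacent slots within a loop contributes the 25 products of one
slot's factor with its neighbour's. The registry is config-driven: slot
allocations are overridable and the registry hash is embedded in every
trained model, which refuses matrices built under a different registry. The
full default registry has 1,710 columns; the positional/interaction
structural constants (290 positional over 58 slots, 25 per adjacent pair)
are the fixed design points, while the total width follows from the
within-loop adjacency scope.

Loops shorter than their frame are gapped middle-out (first ⌈L/2⌉ residues
left-aligned, remaining ⌊L/2⌋ right-aligned): CDR loop length variation
concentrates in the loop middle, so anchor-proximal slots stay comparable
across receptors. Interaction features are masked whenever either member
slot is a gap, mirroring positional gap handling.

Scaling standardizes each feature to mean 0 / variance 1 over non-gap
entries of the training matrix (population sd); gap entries are set to 0
*after* scaling, i.e. to the training mean, and features with zero training
variance (e.g. all-gap slots) map to 0. Applying a trained model to external
data always uses the frozen training statistics.

The Atchley factor table is bundled as published (the five columns are
centered across the 20 residues; the test suite asserts this). Note the
columns are centered but not unit-variance.

The bundled V-gene table is **synthetic**: real IMGT gene names with random
but fixed CDR1/CDR2 sequences of realistic lengths. It exists so the
generator and tests run without downloads; analyses of real data should
substitute an IMGT-derived table, which is a drop-in CSV.

## Regularized CCA

`RegularizedCCA` finds paired weight vectors maximizing the correlation of
projections of a TCR feature matrix X and a state matrix Y (expression-PC
scores supplied by the caller; PC computation is out of scope). Covariances
are ridge-inflated, `Cxx + λx I` and `Cyy + λy I`, and the weights are the
top singular triplets of the whitened cross-covariance
`Cxx^{-1/2} Cxy Cyy^{-1/2}` — the standard rCCA formulation; at λ = 0 this
reduces to classical CCA (verified against a brute-force eigendecomposition
to 1e-8). Reported correlations are empirical Pearson correlations of the
projected inputs. The solution is deterministic up to column sign; we orient
each component so its largest-magnitude X weight is positive and expose
`flip_signs` for presentation choices.

Penalties are tuned by 5-fold cross-validation maximizing the mean held-out
first canonical correlation (fold assignment fixed by seed, ties to the
earliest grid pair). Significance uses an empirical permutation null: Y rows
are permuted, the model refitted, and `p = (1 + #{null ≥ observed})/(n_perm + 1)`
per component, optionally also on held-out data. Permutation p-values are
calibrated under the null (checked by simulation).

## Ridge-logistic scoring functions

Scoring functions regress a binary state on the standardized features with
an L2 penalty, via scikit-learn's `LogisticRegressionCV` (5 stratified
folds, held-out binomial deviance — the conventional criterion; λ is
reported as 1/C). The default grid is log-spaced over λ ∈ [1e-2, 1e4]; for
large problems a coarser documented grid (10/100/1000) is used. No class
reweighting is applied. An exclusion mask (e.g. innate-like cells when
training CD8/regulatory/memory contrasts) removes rows from both fitting
and score standardization. Raw scores β·x + β₀ are standardized by the
training-score mean and sd, so a score unit is one training sd everywhere;
single-chain variants are trained on one chain's feature columns and
standardized independently, since the combined standardization would not be
meaningful for a score that never sees the other chain.

Per-CDR contribution shares are computed by partition masking: for each
loop, the mean absolute score change when that loop's features are zeroed,
averaged over positive-class cells and normalized to sum to 1. For a linear
score over disjoint groups this equals the exact Shapley decomposition of
absolute group contributions; it is documented as a simplification in that
it ignores nothing only because the model is linear.

## Association statistics

The primary association model is a logistic regression of state on score
with a per-donor random intercept. The marginal likelihood integrates the
intercept with fixed-order Gauss–Hermite quadrature (25 nodes; accurate for
random-intercept binary models at the intercept scales used here), is
maximized by L-BFGS-B over (coefficients, log σ_u), and Wald standard
errors come from the numerical Hessian at the optimum. With one donor the
model reduces exactly to plain logistic regression and is fitted directly.
The implementation is cross-checked in the test suite against
`lme4::glmer(nAGQ=25)` on a fixture. Non-convergence is flagged on the
result, never silent. A one-tailed option supports directional hypotheses
within antigen-specific populations.

Per-donor effects use plain logistic regression per donor, with donors
eligible only if they contribute ≥100 cells including ≥10 in and ≥10 out of
the target state; ineligible donors are listed with reasons. Pooling uses a
normal-normal random-effects model with (μ, τ²) estimated by maximum
likelihood (cross-checked against `metafor::rma(method="ML")`), Q computed
with fixed-effects weights, I² = max(0, (Q−df)/Q)·100, H² = Q/df, and the
local false sign rate Φ(−μ/τ) (indicator of μ ≤ 0 at τ = 0) — the
probability under the fitted effect distribution that a donor-level true
effect opposes the pooled sign.

The twin concordance test computes the chance probability that two randomly
drawn twin-member cells share a cluster, `P_null = Σ_j n_j(n_j−1)/(N(N−1))`
from cluster sizes n_j (or accepts a probability directly, for when cluster
sizes are unavailable), then evaluates the exact binomial upper tail
P(X ≥ k | Bin(n, P_null)) by log-gamma summation with logsumexp, which keeps
full relative precision for tails far below 1e-30 (verified against
arbitrary-precision rational summation). A down-sampling control re-runs any
association test on a seeded uniform subsample, to show that absence of
association in a smaller comparison set is not mere loss of power.

## Dextramer background model

For each non-control dextramer, a negative-binomial (NB2) regression with
log link models the UMI count from technical factors only: the
negative-control dextramer counts (ambient/sticky background), TCR
expression (log CP10K of CDR3 UMIs, α+β summed), CLR-normalized CD3 and CD8
surface counts (more receptor/co-receptor → more binding opportunity), and
donor indicators (reference level: lexicographically first donor). The
number of negative controls is a parameter of the panel. Dispersion is
estimated by maximum likelihood (statsmodels `NegativeBinomial`). The
normalized staining value is `Dnorm = log(observed/expected + 1)`: 0 at zero
counts, log 2 when the count matches its technical expectation, monotone in
the observed count, and typically bimodal when genuine binders are present.

Binder thresholds are per-dextramer configuration values; an automatic
antimode finder (kernel-density minimum between the two modes) is provided
as a convenience extension for the common bimodal case, and cells called by
more than one dextramer can be flagged. Within each antigen-specific
population with ≥10 distinct clones, a plain logistic regression tests the
memory/naive split against the memory score with Dnorm (binding intensity)
and donor indicators (only for multi-donor populations) as covariates;
populations with a single-class outcome are flagged inestimable rather than
erroring. Per-antigen estimates are pooled by the ML random-effects
meta-analysis above.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, with
every draw governed by a single seed:

- **Receptors**: V/J genes uniform over the bundled gene table, CDR3
  junctions `C + interior + F` with interior residues i.i.d. uniform over
  the 20 letters and lengths from a shifted-binomial law peaked mid-window
  (within the QC windows, so generated data always pass QC with zero
  removals). A position-specific residue frequency table can be substituted.
- **Clones**: geometric clone sizes (default p = 0.6, mean ≈ 1.7 cells);
  public clonotypes are planted by overwriting a singleton clone of a second
  donor with a verbatim receptor copy, so each planted clonotype spans
  exactly two donors and cell counts stay fixed.
- **States**: Bernoulli with logit `w·x + b + u_donor`, where x is the
  *actual scaled featurization* of the receptor, w is sparse (default 10
  features of magnitude 0.5, random signs), b = −1, and donor intercepts are
  N(0, 0.5²). Eligible effect carriers are CDR3 positional features on slots
  occupied in ≥95% of cells: junction residues vary independently across
  cells so each planted weight is an identifiable per-sd effect, whereas
  germline CDR1/CDR2 features are perfectly collinear within a V gene's
  block (only ~|V genes| degrees of freedom) and cannot carry an
  attributable single-feature effect.
- **Expression PCs**: PC1 loads 0.75 on the standardized TCR-driven latent
  axis, remaining PCs are noise — the minimal structure rCCA needs.
- **Twin cohorts**: each planted pair spans two random distinct donors;
  with probability δ the pair is forced concordant, otherwise both labels
  are drawn independently from the base cluster frequencies, so δ = 0
  reproduces the chance-concordance null exactly.
- **Dextramer panels**: negative-control counts Poisson(2); target log-means
  linear in the negative controls and expression covariates with small donor
  effects; NB2 dispersion 0.25 (a realistic technical-background value
  consistent with clear 20× spike separation); planted binders (5% of cells
  per dextramer, disjoint across dextramers) multiply the mean by the spike
  factor (default 20).

What the generator does **not** emulate: V(D)J nucleotide-level generation
(no insertion/deletion model), thymic selection, position-dependent residue
usage, HLA-driven sharing structure, batch effects, or doublet/ambient
artifacts in the Dextramer counts. Passing tests therefore demonstrate the
correctness and calibration of the machinery under its assumed statistical
structure — not that real repertoires satisfy those assumptions.

## Numerical choices and problem sizes

- Ridge-logistic solver: lbfgs, tol 1e-4, max 300 iterations; scores of a
  degenerate (constant-score) fit standardize with sd 1 to avoid division
  by zero.
- rCCA whitening clips covariance eigenvalues at 1e-12 (pseudo-inverse
  behavior for rank-deficient inputs).
- Gauss–Hermite order 25; meta-analysis likelihood maximized by Nelder–Mead
  from three τ² starts; τ² below 1e-10 reported as 0.
- Exact binomial tails: log-gamma + logsumexp; p-values never exactly 0.
- Tie-breaks: twin state ties → lexicographically smallest label; λ-grid
  ties → first/most-penalized grid point encountered.
- Verification problem sizes (package defaults, chosen to make each check
  sharp at interactive scale): scoring-function recovery at 20,000 cells /
  10 donors; mixed-model calibration at 20 donors × 50 cells with 200
  within-donor permutations; power at 50 donors × 400 cells; meta-analysis
  at k = 50; Dextramer fits at 12,000–20,000 cells; end-to-end pipeline at
  8 donors × 250 cells over 20 seeds, training on half the donors and
  testing association on the held-out half.

## Known limitations

- The bundled gene table is synthetic; germline-feature weights learned on
  it are meaningless for real biology (the machinery is unaffected).
- The default registry's total width (1,710) reflects the within-loop
  adjacency scope; other published feature lists with the same positional
  accounting may differ in their interaction-term inventory.
- The mixed model supports a single random intercept (donor); no random
  slopes or crossed effects.
- CDR contribution shares assume the linear score; they are not Shapley
  values for any nonlinear extension.
- γδ TCRs, nucleotide-level clonotyping, and dual-chain cells are out of
  scope by design.
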