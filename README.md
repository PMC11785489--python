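# tcrfate

**Biophysical TCR-sequence scoring of T cell fate from paired single-cell
repertoires.**

Every T cell carries a unique αβ T cell receptor (TCR) created by V(D)J
recombination, and the receptor's amino acid sequence is not neutral with
respect to the cell's later life: particular sequence features bias cells
toward innate-like, CD8⁺, regulatory, or memory transcriptional fates.
`tcrfate` is a toolkit for quantifying that bias from single-cell data that
pairs TCR sequencing with transcriptome (and optionally surface-protein and
pMHC-Dextramer) readouts. It is aimed at immunologists and computational
biologists who have contig-level TCR calls (10x `filtered_contig_annotations.csv`
or AIRR Rearrangement TSV) plus per-cell state annotations, and who want to
train, apply, or statistically interrogate linear TCR scoring functions.

## What it does

**Featurization.** Each paired receptor is mapped to a fixed-length vector
built from its six CDR loops. Residues are encoded by the five Atchley
factors (hydrophobicity/polarity, secondary structure, size, codon
composition, charge); loops shorter than their slot frame are gapped
middle-out and gap entries are masked to 0 after scaling. The default
registry spans 58 residue slots → 290 positional features, plus per-loop
amino acid composition (19 letters, glycine as reference), loop lengths, and
25 products of adjacent-residue factor pairs. Features are standardized to
mean 0 / variance 1 on the training set, and those statistics are frozen
into every trained model.

**Scoring functions.** A TCR scoring function for target state *S* is a
ridge-penalized logistic regression

```
logit P(state_i = S) = Σ_j β_j · feature_{j,i} + β_0
```

with the penalty chosen by 5-fold cross-validation on held-out binomial
deviance. Returned scores are standardized to the training score
distribution, so one score unit is one training-set standard deviation in
any dataset. Single-chain (α-only / β-only) variants support nonproductive-
rearrangement controls. Regularized CCA (ridge-inflated covariances,
whitened cross-covariance SVD) discovers TCR↔state axes without
pre-specifying states, with penalties tuned by cross-validation and
significance from a permutation null.

**Statistics.** The association between a score and a state is estimated by
logistic regression with a per-donor random intercept (Gauss–Hermite
marginal likelihood, Wald inference), per-donor effects are pooled by
maximum-likelihood random-effects meta-analysis (with Q/I²/H² heterogeneity
and the local false sign rate Φ(−μ/τ)), and "TCR twins" — identical
clonotypes observed in exactly two donors — are tested for transcriptional
concordance with an exact log-space binomial tail against the chance
probability `P_null = Σ_j n_j(n_j−1)/(N(N−1))` computed from cluster sizes.

**Dextramer analysis.** Multiplexed pMHC-Dextramer UMI counts are
background-corrected per dextramer by a negative-binomial regression on
negative-control counts, TCR/CD3/CD8 expression, and donor; the normalized
staining value `Dnorm = log(observed/expected + 1)` separates binders from
background, and per-antigen score↔memory associations are pooled across
antigen-specific populations by random-effects meta-analysis.

**Synthetic data.** A fully seeded generator produces multi-donor
repertoires (clonal expansion, public clonotypes, states drawn from a known
linear model on the actual featurization, donor random intercepts),
twin cohorts with tunable concordance, and Dextramer panels with spiked
binders — so the whole pipeline is testable with known ground truth and no
downloads.

## Worked example

Simulate an 8-donor repertoire with a planted TCR→memory effect, QC it,
train a scorer on four donors, and test the association on the held-out
donors:

```python
import numpy as np
import tcrfate as tf

cfg = tf.SimConfig(n_donors=8, cells_per_donor=500)
sim = tf.simulate_repertoire(cfg, seed=7)

gene_table = tf.load_bundled_gene_table()
chains = [c for t in sim.tcrs for c in (t.alpha, t.beta)]
pairs, report = tf.pair_and_qc(chains, gene_table)
print(report.summary())

train = np.isin(sim.donor_ids, [f"D{j:02d}" for j in range(4)])
fm = sim.features
fm_train = tf.FeatureMatrix([c for c, t in zip(fm.cell_ids, train) if t],
                            sim.registry, fm.values[train], fm.mask[train])
scorer = tf.train_scorer(fm_train, sim.states[train], target="mem",
                         lambda_grid=(10, 100, 1000), seed=0)
print(scorer.summary(sim.registry, top=3))

fm_test = tf.FeatureMatrix([c for c, t in zip(fm.cell_ids, train) if not t],
                           sim.registry, fm.values[~train], fm.mask[~train])
scores = scorer.score(fm_test)
res = tf.mixed_logit(sim.states[~train], scores, sim.donor_ids[~train])
print(res.summary())
```

Output:

```
cells in: 4000
cells retained: 4000
removed (multiplet): 0
removed (unresolved_genes): 0
removed (pseudogene): 0
removed (length_window): 0
TCR scoring function: mem
  chain mask: both
  n train cells: 2000
  ridge lambda: 1000
  raw-score mean/sd (train): -0.4246 / 0.6348
  top 3 |weights|:
    pos_CDR3b_s14_F4: +0.1074
    pos_CDR3a_s4_F1: +0.0944
    pos_CDR3a_s5_F2: +0.0898
mixed_logit_gauss_hermite: beta = 1.0345 (se 0.0735), 95% CI [0.8905, 1.1786],
OR = 2.814, p = 5.35e-45 (two-sided Wald), n = 2000 cells / 4 donor(s)
```

All 4,000 simulated cells pass the repertoire QC (the generator respects the
CDR3 length windows and gene table by construction). The scorer's largest
weights sit on CDR3 positional features — where the generator planted its
effects — and on held-out donors one standard deviation of the score
multiplies the odds of the memory state by ≈2.8, with donor structure
absorbed by the random intercept.

The same steps are available from a shell via the `tcrfate` CLI
(`simulate`, `qc`, `twins`, `featurize`, `train`, `score`, `assoc`,
`twins-test`).

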