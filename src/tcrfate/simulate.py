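"""Synthetic multi-donor repertoires with known ground truth.

The generator emulates the statistical structure the analysis modules
assume, so every stage of the pipeline can be exercised end to end without
external cohorts:

* paired alpha/beta receptors with V/J genes drawn from the bundled gene
  table and CDR3 junctions with C...F anchors and lengths inside the QC
  windows (so generated data always pass QC untouched);
* clonal expansion (geometric clone sizes) and public clonotypes copied
  verbatim into a second donor, to exercise twin finding;
* binary cell states drawn from a logistic model that is linear in the
  *actual featurization* of each receptor, with a known sparse weight
  vector, global intercept and donor random intercepts;
* expression-PC-like state scores correlated with the same latent axis, for
  the canonical correlation machinery;
* Dextramer count panels with negative-control-driven negative binomial
  background, expression covariates and spiked binder populations.

Everything is bit-reproducible given (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .atchley import AMINO_ACIDS
from .dextramer import DextramerPanel
from .features import (
    FeatureMatrix,
    FeatureRegistry,
    ScalingStats,
    apply_scaling,
    build_registry,
    featurize_matrix,
    fit_scaling,
)
from .io import CellRecord, GeneTable, PairedTcr, TcrChain, clonotype_key, load_bundled_gene_table

__all__ = [
    "SimConfig",
    "SimTruth",
    "RepertoireSim",
    "simulate_repertoire",
    "simulate_dextramer",
    "simulate_twin_cohort",
]

TRAJ_GENES = ("TRAJ11", "TRAJ17", "TRAJ20", "TRAJ31", "TRAJ33", "TRAJ45", "TRAJ50")
TRBJ_GENES = ("TRBJ1-2", "TRBJ1-5", "TRBJ2-7")


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohorts.

    Defaults describe a modest multi-donor single-cell repertoire: 10 donors
    of 500 cells with mild clonal expansion, a 1% public-clonotype rate, a
    sparse TCR-sequence effect on the binary state (10 features at 0.5 sd),
    and donor random intercepts of sd 0.5.
    """

    n_donors: int = 10
    cells_per_donor: int = 500
    clone_geom_p: float = 0.6  # clone size ~ Geometric(p), mean 1/p
    public_rate: float = 0.01
    cdr3a_len_range: tuple[int, int] = (10, 17)
    cdr3b_len_range: tuple[int, int] = (11, 18)
    # state model: logit P(state) = w.x + base_logit + u_donor
    n_true_features: int = 10
    effect_size: float = 0.5
    base_logit: float = -1.0
    donor_sd: float = 0.5
    positive_label: str = "memory"
    negative_label: str = "naive"
    # expression-PC block (state matrix for canonical correlation analyses)
    n_pcs: int = 5
    pc_latent_loading: float = 0.75
    # twin cohort
    n_twin_pairs: int = 100
    concordance_boost: float = 0.0  # delta: force-concordant probability
    cluster_labels: tuple[str, ...] = tuple(f"A{i}" for i in range(1, 10))
    cluster_freqs: tuple[float, ...] | None = None
    # dextramer panel
    n_dextramers: int = 4
    n_negative_controls: int = 3
    background_mean: float = 2.0
    nb_dispersion: float = 0.25  # NB2 alpha: var = mu + alpha mu^2
    spike_factor: float = 20.0
    binder_fraction: float = 0.05

    def __post_init__(self) -> None:
        probs = [self.clone_geom_p, self.public_rate, self.binder_fraction]
        if not all(0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if not (0 <= self.concordance_boost <= 1):
            raise ValueError("concordance_boost must lie in [0, 1]")
        if self.cdr3a_len_range[0] < 10 or self.cdr3a_len_range[1] > 17:
            raise ValueError("cdr3a lengths must stay within the QC window [10, 17]")
        if self.cdr3b_len_range[0] < 11 or self.cdr3b_len_range[1] > 18:
            raise ValueError("cdr3b lengths must stay within the QC window [11, 18]")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


@dataclass
class SimTruth:
    """Ground truth serialized alongside every simulated dataset."""

    seed: int
    true_weight_indices: list[int] = field(default_factory=list)
    true_weight_values: list[float] = field(default_factory=list)
    base_logit: float = 0.0
    donor_intercepts: dict[str, float] = field(default_factory=dict)
    public_clonotypes: list[str] = field(default_factory=list)
    binder_cells: dict[str, list[int]] = field(default_factory=dict)
    forced_concordant: list[bool] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class RepertoireSim:
    """Bundle returned by :func:`simulate_repertoire`."""

    tcrs: list[PairedTcr]
    cells: list[CellRecord]
    truth: SimTruth
    features: FeatureMatrix  # scaled
    scaling: ScalingStats
    registry: FeatureRegistry
    pc_scores: np.ndarray  # cells x n_pcs
    states: np.ndarray  # binary

    @property
    def donor_ids(self) -> np.ndarray:
        return np.asarray([c.donor_id for c in self.cells])


def _sample_cdr3(rng: np.random.Generator, lo: int, hi: int) -> str:
    # length law: shifted binomial, peaked mid-window like real junctions
    L = lo + int(rng.binomial(hi - lo, 0.5))
    interior = "".join(
        AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=L - 2)
    )
    return "C" + interior + "F"


def _sample_receptor(
    rng: np.random.Generator, gene_table: GeneTable, config: SimConfig
) -> tuple[str, str, str, str, str, str]:
    av = gene_table.v_genes("alpha")
    bv = gene_table.v_genes("beta")
    return (
        av[int(rng.integers(len(av)))],
        TRAJ_GENES[int(rng.integers(len(TRAJ_GENES)))],
        bv[int(rng.integers(len(bv)))],
        TRBJ_GENES[int(rng.integers(len(TRBJ_GENES)))],
        _sample_cdr3(rng, *config.cdr3a_len_range),
        _sample_cdr3(rng, *config.cdr3b_len_range),
    )


def _make_pair(cell_id: str, donor: str, rec: tuple[str, ...]) -> PairedTcr:
    va, ja, vb, jb, c3a, c3b = rec
    return PairedTcr(
        cell_id=cell_id,
        donor_id=donor,
        alpha=TcrChain(cell_id, "alpha", va, ja, c3a, True),
        beta=TcrChain(cell_id, "beta", vb, jb, c3b, True),
    )


def simulate_repertoire(
    config: SimConfig | None = None,
    seed: int = 0,
    gene_table: GeneTable | None = None,
    registry: FeatureRegistry | None = None,
) -> RepertoireSim:
    """Generate a multi-donor repertoire with states driven by TCR features.

    States are Bernoulli(logit^{-1}(w.x_i + b + u_donor)) where x_i is the
    scaled featurization of cell i's receptor and w is sparse with
    ``n_true_features`` entries of magnitude ``effect_size`` and random sign.
    """
    config = config or SimConfig()
    gene_table = gene_table or load_bundled_gene_table()
    registry = registry or build_registry()
    rng = np.random.default_rng(seed)

    # -- clones and cells --------------------------------------------------
    donors = [f"D{j:02d}" for j in range(config.n_donors)]
    clone_recs: list[tuple[str, tuple[str, ...]]] = []  # (donor, receptor)
    clone_sizes: list[int] = []
    for donor in donors:
        total = 0
        while total < config.cells_per_donor:
            size = int(rng.geometric(config.clone_geom_p))
            size = min(size, config.cells_per_donor - total)
            rec = _sample_receptor(rng, gene_table, config)
            clone_recs.append((donor, rec))
            clone_sizes.append(size)
            total += size

    # public clonotypes: overwrite a singleton clone of another donor with a
    # verbatim copy of this clone's receptor, so each planted public
    # clonotype spans exactly two donors and cell counts stay fixed
    public: list[str] = []
    if config.n_donors >= 2 and config.public_rate > 0:
        singleton_pool = [
            j for j, size in enumerate(clone_sizes) if size == 1
        ]
        rng.shuffle(singleton_pool)
        taken: set[int] = set()
        for i in range(len(clone_recs)):
            if i in taken or rng.random() >= config.public_rate:
                continue
            donor, rec = clone_recs[i]
            target = next(
                (j for j in singleton_pool if j not in taken and j != i
                 and clone_recs[j][0] != donor),
                None,
            )
            if target is None:
                break
            clone_recs[target] = (clone_recs[target][0], rec)
            taken.add(target)
            taken.add(i)
            public.append("|".join(rec[:4]) + "|" + rec[4] + "|" + rec[5])

    tcrs: list[PairedTcr] = []
    for ci, ((donor, rec), size) in enumerate(zip(clone_recs, clone_sizes)):
        for m in range(size):
            tcrs.append(_make_pair(f"{donor}_c{ci:05d}_{m}", donor, rec))

    # -- featurize + state model ------------------------------------------
    raw = featurize_matrix(tcrs, gene_table, registry)
    scaling = fit_scaling(raw)
    scaled = apply_scaling(raw, scaling)

    # eligible effect carriers: CDR3 positional features on slots occupied in
    # (almost) every cell.  CDR3 junction residues vary independently across
    # cells, so each planted weight is a genuine, identifiable
    # `effect_size`-per-sd effect; germline CDR1/CDR2 features are perfectly
    # collinear within a V gene's block (only ~|V genes| degrees of freedom)
    # and cannot carry an attributable single-feature effect.
    pos_idx = np.concatenate(
        [
            np.arange(len(registry))[registry.block_slice("position_atchley", loop)]
            for loop in ("CDR3a", "CDR3b")
        ]
    )
    gap_frac = scaled.mask[:, pos_idx].mean(axis=0)
    usable = pos_idx[(scaling.sd[pos_idx] > 0) & (gap_frac <= 0.05)]
    w_idx = rng.choice(usable, size=config.n_true_features, replace=False)
    w_val = config.effect_size * rng.choice([-1.0, 1.0], size=config.n_true_features)
    w = np.zeros(len(registry))
    w[w_idx] = w_val

    donor_u = {d: float(rng.normal(0, config.donor_sd)) for d in donors}
    donor_arr = np.asarray([donor_u[t.donor_id] for t in tcrs])
    eta = scaled.values @ w + config.base_logit + donor_arr
    states = rng.random(len(tcrs)) < 1.0 / (1.0 + np.exp(-eta))
    states = states.astype(int)

    # expression-PC scores: PC1 loads on the TCR-driven latent axis
    latent = scaled.values @ w
    sdl = latent.std()
    latent = latent / sdl if sdl > 0 else latent
    loadings = np.zeros(config.n_pcs)
    loadings[0] = config.pc_latent_loading
    noise_sd = np.sqrt(np.maximum(1.0 - loadings**2, 1e-12))
    pcs = latent[:, None] * loadings[None, :] + rng.normal(
        0, 1, (len(tcrs), config.n_pcs)
    ) * noise_sd[None, :]

    cells = [
        CellRecord(
            cell_id=t.cell_id,
            donor_id=t.donor_id,
            clonotype_key=clonotype_key(t),
            state_label=config.positive_label if st else config.negative_label,
        )
        for t, st in zip(tcrs, states)
    ]
    truth = SimTruth(
        seed=seed,
        true_weight_indices=[int(i) for i in w_idx],
        true_weight_values=[float(v) for v in w_val],
        base_logit=config.base_logit,
        donor_intercepts=donor_u,
        public_clonotypes=sorted(set(public)),
    )
    return RepertoireSim(
        tcrs=tcrs,
        cells=cells,
        truth=truth,
        features=scaled,
        scaling=scaling,
        registry=registry,
        pc_scores=pcs,
        states=states,
    )


def simulate_twin_cohort(
    config: SimConfig | None = None, seed: int = 0
) -> tuple[list[CellRecord], SimTruth]:
    """Planted TCR-twin cohort with tunable state concordance.

    Each of ``n_twin_pairs`` clonotypes appears once in each of two distinct
    donors.  With probability ``concordance_boost`` the pair is forced
    concordant (one label drawn for both members); otherwise both labels are
    drawn independently from the base cluster frequencies, so a boost of 0
    calibrates the chance-concordance null.
    """
    config = config or SimConfig()
    if config.n_donors < 2:
        raise ValueError("twin cohort needs at least two donors")
    rng = np.random.default_rng(seed)
    labels = list(config.cluster_labels)
    freqs = (
        np.asarray(config.cluster_freqs, dtype=float)
        if config.cluster_freqs is not None
        else np.ones(len(labels)) / len(labels)
    )
    freqs = freqs / freqs.sum()
    donors = [f"D{j:02d}" for j in range(config.n_donors)]
    gene_table = load_bundled_gene_table()

    cells: list[CellRecord] = []
    forced: list[bool] = []
    for i in range(config.n_twin_pairs):
        rec = _sample_receptor(rng, gene_table, config)
        d_a, d_b = rng.choice(len(donors), size=2, replace=False)
        key = "|".join(rec[:4]) + "|" + rec[4] + "|" + rec[5]
        if rng.random() < config.concordance_boost:
            lab = labels[int(rng.choice(len(labels), p=freqs))]
            pair_labels = (lab, lab)
            forced.append(True)
        else:
            pair_labels = tuple(
                labels[int(rng.choice(len(labels), p=freqs))] for _ in range(2)
            )
            forced.append(False)
        for donor_ix, lab in zip((d_a, d_b), pair_labels):
            donor = donors[donor_ix]
            cells.append(
                CellRecord(
                    cell_id=f"{donor}_twin{i:04d}",
                    donor_id=donor,
                    clonotype_key=key,
                    state_label=lab,
                )
            )
    truth = SimTruth(
        seed=seed,
        public_clonotypes=sorted({c.clonotype_key for c in cells}),
        forced_concordant=forced,
    )
    return cells, truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB2 draw (var = mu + alpha mu^2) via Gamma-Poisson mixture."""
    if alpha <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    return rng.poisson(lam)


def simulate_dextramer(
    config: SimConfig | None = None,
    seed: int = 0,
    cells: Sequence[CellRecord] | None = None,
) -> tuple[DextramerPanel, SimTruth]:
    """Dextramer UMI panel with technical background and spiked binders.

    Background log-means are linear in the simulated negative-control counts
    and expression covariates (the structure the background regression
    assumes); planted binder cells multiply the mean by ``spike_factor``.
    Binder assignments are disjoint across dextramers.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    if cells is None:
        n = config.n_donors * config.cells_per_donor
        donors = np.repeat(
            [f"D{j:02d}" for j in range(config.n_donors)], config.cells_per_donor
        )
        cell_ids = [f"cell{i:06d}" for i in range(n)]
    else:
        n = len(cells)
        donors = np.asarray([c.donor_id for c in cells])
        cell_ids = [c.cell_id for c in cells]

    nc_names = [f"NC{k + 1}" for k in range(config.n_negative_controls)]
    dex_names = [f"DEX{k + 1}" for k in range(config.n_dextramers)]
    nc_counts = rng.poisson(config.background_mean, size=(n, len(nc_names)))
    tcr_exp = rng.normal(2.0, 0.5, n)
    cd3_exp = rng.normal(0.0, 1.0, n)
    cd8_exp = rng.normal(0.0, 1.0, n)

    donor_levels = sorted(set(donors.tolist()))
    donor_eff = {d: float(rng.normal(0, 0.1)) for d in donor_levels}
    donor_term = np.asarray([donor_eff[d] for d in donors])

    truth = SimTruth(seed=seed)
    unassigned = np.arange(n)
    rng.shuffle(unassigned)
    counts = {}
    cursor = 0
    n_binders = int(round(config.binder_fraction * n))
    for dex in dex_names:
        binders = unassigned[cursor : cursor + n_binders]
        cursor += n_binders
        truth.binder_cells[dex] = sorted(int(i) for i in binders)
        log_mu = (
            np.log(config.background_mean)
            + 0.05 * nc_counts.sum(axis=1)
            + 0.10 * (tcr_exp - tcr_exp.mean())
            + 0.05 * cd3_exp
            + 0.05 * cd8_exp
            + donor_term
        )
        mu = np.exp(log_mu)
        mu[binders] *= config.spike_factor
        counts[dex] = _nb_draw(rng, mu, config.nb_dispersion)
    for k, nc in enumerate(nc_names):
        counts[nc] = nc_counts[:, k]

    panel = DextramerPanel(
        counts=pd.DataFrame(counts, index=cell_ids, columns=dex_names + nc_names),
        negative_controls=nc_names,
        covariates=pd.DataFrame(
            {"tcr_exp": tcr_exp, "cd3_exp": cd3_exp, "cd8_exp": cd8_exp, "donor_id": donors},
            index=cell_ids,
        ),
    )
    return panel, truth
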