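"""Statistical tests linking TCR scores to T cell states.

* donor-random-intercept logistic regression (the primary association model),
  with per-individual fits feeding a maximum-likelihood random-effects
  meta-analysis and the local false sign rate;
* the TCR-twin concordance machinery: the chance-concordance probability
  P_null from cluster sizes and a log-space exact binomial upper-tail test;
* the down-sampling control used to match statistical power between
  productive and nonproductive repertoires.

The mixed model integrates the donor random intercept out of the likelihood
with fixed-order Gauss-Hermite quadrature and reports Wald inference from
the numerical Hessian of the marginal log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
import statsmodels.api as sm

__all__ = [
    "AssociationResult",
    "DonorEffect",
    "MetaResult",
    "TwinNull",
    "MixedLogit",
    "RandomEffectsMeta",
    "mixed_logit",
    "per_individual_betas",
    "random_effects_meta",
    "twin_pnull",
    "twin_binomial_test",
    "downsample_match",
]


@dataclass
class AssociationResult:
    """Wald inference for the TCR-score coefficient of one association test."""

    beta: float
    se: float
    p: float
    n_cells: int
    n_donors: int
    model: str
    converged: bool = True
    sigma_u: float = 0.0  # random-intercept sd (0 for plain logistic)
    one_tailed: bool = False

    @property
    def ci(self) -> tuple[float, float]:
        return (self.beta - 1.96 * self.se, self.beta + 1.96 * self.se)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    def summary(self) -> str:
        lo, hi = self.ci
        tail = "one-tailed" if self.one_tailed else "two-sided"
        return (
            f"{self.model}: beta = {self.beta:.4f} (se {self.se:.4f}), "
            f"95% CI [{lo:.4f}, {hi:.4f}], OR = {self.odds_ratio:.3f}, "
            f"p = {self.p:.3g} ({tail} Wald), n = {self.n_cells} cells / "
            f"{self.n_donors} donor(s)"
            + ("" if self.converged else "  [WARNING: did not converge]")
        )


@dataclass(frozen=True)
class DonorEffect:
    donor_id: str
    beta: float
    se: float
    n_cells: int


@dataclass
class MetaResult:
    """Random-effects meta-analysis (maximum-likelihood heterogeneity)."""

    mu: float
    se_mu: float
    tau2: float
    k: int
    Q: float
    Q_p: float
    I2: float  # percent
    H2: float
    lfsr: float

    @property
    def tau(self) -> float:
        return float(np.sqrt(self.tau2))

    @property
    def p(self) -> float:
        return float(2 * stats.norm.sf(abs(self.mu) / self.se_mu))

    def summary(self) -> str:
        return (
            f"random-effects meta-analysis (ML), k = {self.k}\n"
            f"  pooled mu = {self.mu:.4f} (se {self.se_mu:.4f}), p = {self.p:.3g}\n"
            f"  tau^2 = {self.tau2:.5f}, Q = {self.Q:.2f} (p = {self.Q_p:.3g}), "
            f"I^2 = {self.I2:.1f}%, H^2 = {self.H2:.2f}\n"
            f"  local false sign rate = {self.lfsr:.3g}"
        )

    def plot_forest(self, betas=None, ses=None, labels=None, ax=None):
        """Forest plot of per-study estimates with the pooled effect."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 0.3 * (0 if betas is None else len(betas)) + 2))
        if betas is not None:
            betas = np.asarray(betas, dtype=float)
            ses = np.asarray(ses, dtype=float)
            ys = np.arange(len(betas))
            ax.errorbar(betas, ys, xerr=1.96 * ses, fmt="o", color="k", ms=3, lw=1)
            if labels is not None:
                ax.set_yticks(ys)
                ax.set_yticklabels(labels)
        ax.axvline(self.mu, color="firebrick", lw=1.5, label=f"pooled = {self.mu:.3f}")
        ax.axvline(0, color="grey", lw=0.8, ls=":")
        ax.set_xlabel("log odds ratio per 1 sd of TCR score")
        ax.legend(loc="best", frameon=False)
        return ax


@dataclass
class TwinNull:
    """Chance concordance probability for TCR twins from cluster sizes."""

    cluster_sizes: list[int]
    p_cluster: list[float]
    p_null: float


# ---------------------------------------------------------------------------
# mixed-effects logistic regression (donor random intercept)
# ---------------------------------------------------------------------------

class MixedLogit:
    """Random-intercept-per-donor logistic regression.

        logit P(y_i = 1) = beta_score * score_i + x_i'gamma + b0 + u_{donor(i)},
        u_j ~ N(0, sigma_u^2)

    The marginal likelihood integrates u_j out with fixed-order Gauss-Hermite
    quadrature (default 25 nodes), maximized by L-BFGS-B over
    (coefficients, log sigma_u).  With a single donor the model reduces to a
    plain logistic regression, which is fitted directly via statsmodels.
    """

    def __init__(self, states, scores, donor_ids, covariates=None, n_nodes: int = 25):
        y = np.asarray(states, dtype=float)
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("states must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("single-class outcome: association is inestimable")
        s = np.asarray(scores, dtype=float)
        donors = np.asarray(donor_ids)
        if not (len(y) == len(s) == len(donors)):
            raise ValueError("states, scores and donor_ids must be equally long")
        X = [np.ones(len(y)), s]
        if covariates is not None:
            cov = np.atleast_2d(np.asarray(covariates, dtype=float))
            if cov.shape[0] != len(y):
                cov = cov.T
            X.extend(cov.T)
        self.y = y
        self.X = np.column_stack(X)  # column 1 is the score
        self.donors = donors
        self.n_nodes = n_nodes
        # sort cells by donor for grouped reductions
        order = np.argsort(donors, kind="stable")
        self._y = y[order]
        self._X = self.X[order]
        uniq, idx = np.unique(donors[order], return_index=True)
        self.donor_levels = uniq
        self._starts = idx
        nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
        self._nodes = nodes
        self._logw = np.log(weights) - 0.5 * np.log(np.pi)

    def _neg_loglik(self, params: np.ndarray) -> float:
        beta, log_sigma = params[:-1], params[-1]
        sigma = np.exp(log_sigma)
        eta = self._X @ beta
        # per-node: log-lik of each cell at intercept shift sqrt(2)*sigma*node
        shifts = np.sqrt(2.0) * sigma * self._nodes  # Q
        z = eta[:, None] + shifts[None, :]  # n x Q
        cell_ll = np.where(self._y[:, None] == 1, -np.logaddexp(0, -z), -np.logaddexp(0, z))
        donor_ll = np.add.reduceat(cell_ll, self._starts, axis=0)  # J x Q
        total = special.logsumexp(donor_ll + self._logw[None, :], axis=1).sum()
        return -total

    def fit(self, one_tailed: bool = False) -> AssociationResult:
        n_donors = len(self.donor_levels)
        if n_donors < 2:
            return _plain_logit(self.y, self.X, n_donors, one_tailed)

        # start from the plain-logistic solution
        start_fit = sm.Logit(self.y, self.X).fit(disp=0, maxiter=200)
        x0 = np.append(start_fit.params, np.log(0.5))
        res = optimize.minimize(
            self._neg_loglik, x0, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
        )
        from statsmodels.tools.numdiff import approx_hess

        H = approx_hess(res.x, self._neg_loglik)
        converged = bool(res.success)
        try:
            cov = np.linalg.inv(H)
            se = float(np.sqrt(cov[1, 1]))
            if not np.isfinite(se) or se <= 0:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            se = float("nan")
            converged = False
        beta = float(res.x[1])
        p = _wald_p(beta, se, one_tailed)
        return AssociationResult(
            beta=beta,
            se=se,
            p=p,
            n_cells=len(self.y),
            n_donors=n_donors,
            model="mixed_logit_gauss_hermite",
            converged=converged,
            sigma_u=float(np.exp(res.x[-1])),
            one_tailed=one_tailed,
        )


def _wald_p(beta: float, se: float, one_tailed: bool) -> float:
    if not np.isfinite(se) or se <= 0:
        return float("nan")
    z = beta / se
    return float(stats.norm.sf(z)) if one_tailed else float(2 * stats.norm.sf(abs(z)))


def _plain_logit(y, X, n_donors, one_tailed) -> AssociationResult:
    fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    beta, se = float(fit.params[1]), float(fit.bse[1])
    return AssociationResult(
        beta=beta,
        se=se,
        p=_wald_p(beta, se, one_tailed),
        n_cells=len(y),
        n_donors=n_donors,
        model="logit",
        converged=bool(fit.mle_retvals.get("converged", True)),
        one_tailed=one_tailed,
    )


def mixed_logit(states, scores, donor_ids, covariates=None, one_tailed: bool = False) -> AssociationResult:
    """Association between a standardized TCR score and a binary cell state.

    beta is the log odds ratio per 1 sd of TCR score, with a random intercept
    per donor; reduces to plain logistic regression for a single donor.
    """
    return MixedLogit(states, scores, donor_ids, covariates).fit(one_tailed=one_tailed)


def per_individual_betas(
    states,
    scores,
    donor_ids,
    min_cells: int = 100,
    min_pos: int = 10,
    min_neg: int = 10,
) -> tuple[list[DonorEffect], dict[str, str]]:
    """Plain logistic fit per eligible donor.

    A donor is eligible with at least ``min_cells`` cells of which at least
    ``min_pos`` are in the target state and ``min_neg`` are not.  Ineligible
    donors are returned with their exclusion reason.
    """
    y = np.asarray(states, dtype=float)
    s = np.asarray(scores, dtype=float)
    donors = np.asarray(donor_ids)
    effects: list[DonorEffect] = []
    excluded: dict[str, str] = {}
    for d in np.unique(donors):
        m = donors == d
        n, npos = int(m.sum()), int(y[m].sum())
        if n < min_cells:
            excluded[str(d)] = f"fewer than {min_cells} cells (n={n})"
            continue
        if npos < min_pos:
            excluded[str(d)] = f"fewer than {min_pos} state-positive cells (n={npos})"
            continue
        if n - npos < min_neg:
            excluded[str(d)] = f"fewer than {min_neg} state-negative cells (n={n - npos})"
            continue
        X = np.column_stack([np.ones(n), s[m]])
        fit = sm.Logit(y[m], X).fit(disp=0, maxiter=200)
        effects.append(DonorEffect(str(d), float(fit.params[1]), float(fit.bse[1]), n))
    return effects, excluded


# ---------------------------------------------------------------------------
# random-effects meta-analysis
# ---------------------------------------------------------------------------

class RandomEffectsMeta:
    """Normal-normal random-effects model  beta_i ~ N(mu, tau^2 + se_i^2),
    with (mu, tau^2) estimated by maximum likelihood.

    The local false sign rate is the probability, under the fitted
    effect distribution N(mu, tau^2), that a unit-level true effect has
    non-positive sign: Phi(-mu/tau), or the indicator {mu <= 0} at tau = 0.
    """

    def __init__(self, betas, ses):
        b = np.asarray(betas, dtype=float)
        s = np.asarray(ses, dtype=float)
        if b.size == 0:
            raise ValueError("meta-analysis needs at least one study")
        if b.shape != s.shape or np.any(s <= 0):
            raise ValueError("betas and ses must match and ses must be positive")
        self.betas = b
        self.ses = s

    def _nll(self, params) -> float:
        mu, log_tau2 = params
        v = self.ses**2 + np.exp(log_tau2)
        return float(0.5 * np.sum(np.log(v) + (self.betas - mu) ** 2 / v))

    def fit(self) -> MetaResult:
        k = len(self.betas)
        w = 1.0 / self.ses**2
        mu_fe = float(np.sum(w * self.betas) / np.sum(w))
        Q = float(np.sum(w * (self.betas - mu_fe) ** 2))
        df = max(k - 1, 1)
        Q_p = float(stats.chi2.sf(Q, df)) if k > 1 else 1.0
        I2 = max(0.0, (Q - df) / Q) * 100 if Q > 0 else 0.0
        H2 = Q / df if k > 1 else 1.0

        if k == 1:
            mu, tau2, se_mu = float(self.betas[0]), 0.0, float(self.ses[0])
        else:
            best = None
            for t0 in (1e-8, 0.01, 0.1):
                res = optimize.minimize(
                    self._nll, x0=[mu_fe, np.log(t0)], method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
                )
                if best is None or res.fun < best.fun:
                    best = res
            mu, tau2 = float(best.x[0]), float(np.exp(best.x[1]))
            if tau2 < 1e-10:
                tau2 = 0.0
            se_mu = float(np.sqrt(1.0 / np.sum(1.0 / (self.ses**2 + tau2))))

        if tau2 > 0:
            lfsr = float(stats.norm.cdf(-mu / np.sqrt(tau2)))
        else:
            lfsr = 1.0 if mu <= 0 else 0.0
        return MetaResult(
            mu=mu, se_mu=se_mu, tau2=tau2, k=k, Q=Q, Q_p=Q_p, I2=I2, H2=H2, lfsr=lfsr
        )


def random_effects_meta(betas, ses) -> MetaResult:
    """ML random-effects pooling of per-study (beta, se) estimates."""
    return RandomEffectsMeta(betas, ses).fit()


# ---------------------------------------------------------------------------
# TCR twin concordance test
# ---------------------------------------------------------------------------

def twin_pnull(cluster_counts: Sequence[int]) -> TwinNull:
    """Chance probability that two randomly drawn twin-member cells share a cluster.

    For cluster j holding n_j of the N twin-member cells,
    P_j = n_j (n_j - 1) / (N (N - 1)) and P_null = sum_j P_j.
    """
    counts = [int(c) for c in cluster_counts]
    if any(c < 0 for c in counts):
        raise ValueError("cluster counts must be non-negative")
    N = sum(counts)
    if N < 2:
        raise ValueError("need at least two twin-member cells")
    p_cluster = [c * (c - 1) / (N * (N - 1)) for c in counts]
    return TwinNull(cluster_sizes=counts, p_cluster=p_cluster, p_null=float(sum(p_cluster)))


def twin_binomial_test(n_pairs: int, n_concordant: int, p_null: float) -> float:
    """Exact binomial upper tail P(X >= n_concordant), X ~ Bin(n_pairs, p_null).

    Summed in log space (log-gamma binomial coefficients + logsumexp), so
    tail probabilities far below 1e-30 keep full relative accuracy.
    """
    if not (0 < p_null < 1):
        raise ValueError("p_null must lie strictly between 0 and 1")
    if not (0 <= n_concordant <= n_pairs):
        raise ValueError("n_concordant must lie in [0, n_pairs]")
    if n_concordant == 0:
        return 1.0
    ks = np.arange(n_concordant, n_pairs + 1)
    log_terms = (
        special.gammaln(n_pairs + 1)
        - special.gammaln(ks + 1)
        - special.gammaln(n_pairs - ks + 1)
        + ks * np.log(p_null)
        + (n_pairs - ks) * np.log1p(-p_null)
    )
    return float(np.exp(special.logsumexp(log_terms)))


def downsample_match(
    states,
    scores,
    donor_ids,
    n_target: int,
    seed: int,
    test: Callable[..., AssociationResult] = mixed_logit,
) -> AssociationResult:
    """Re-run an association test on a uniform subsample of the cells.

    Used to match the sample size of a smaller comparison set (e.g.
    nonproductive TCRs) and show that loss of association is not merely loss
    of power.  Deterministic per seed.
    """
    y = np.asarray(states)
    n = len(y)
    if n_target > n:
        raise ValueError(f"cannot subsample {n_target} from {n} cells")
    idx = np.sort(np.random.default_rng(seed).choice(n, size=n_target, replace=False))
    s = np.asarray(scores)[idx]
    d = np.asarray(donor_ids)[idx]
    return test(y[idx], s, d)
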