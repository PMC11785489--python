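"""Background correction and analysis of multiplexed pMHC-Dextramer counts.

Raw Dextramer UMI counts mix true antigen binding with technical background
(ambient reagent, surface stickiness, receptor expression).  For each
dextramer a negative-binomial regression predicts the count expected from
technical factors alone — the negative-control dextramer counts, TCR
expression (log CP10K of CDR3 UMIs, alpha+beta), CLR-normalized CD3 and CD8
surface protein, and donor indicators.  The normalized staining value

    Dnorm_i = log(observed_i / expected_i + 1)

is ~log 2 when a cell's count matches its technical expectation, 0 at zero
counts, and large for genuine binders, which typically form a separated
upper mode.  Binders are called by a per-dextramer threshold; within each
antigen-specific population (>= 10 distinct clones) a logistic regression
tests whether TCR-mem explains the memory/naive split, adjusting for Dnorm
(binding intensity) and donor; per-antigen effects are pooled by ML
random-effects meta-analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.discrete.discrete_model import NegativeBinomial

from .association import AssociationResult, MetaResult, random_effects_meta

__all__ = [
    "DextramerPanel",
    "DextramerBackgroundModel",
    "BackgroundFit",
    "NormalizedStain",
    "AntigenAssocResult",
    "fit_background",
    "normalize_stain",
    "call_binders",
    "find_threshold_antimode",
    "antigen_assoc",
    "across_antigen_meta",
]

REQUIRED_COVARIATES = ("tcr_exp", "cd3_exp", "cd8_exp", "donor_id")


@dataclass
class DextramerPanel:
    """cells x dextramers UMI counts with technical covariates.

    ``counts`` must be non-negative integers; ``negative_controls`` names at
    least one column used to model ambient background; ``covariates`` carries
    tcr_exp, cd3_exp, cd8_exp and donor_id per cell (same index as counts).
    """

    counts: pd.DataFrame
    negative_controls: list[str]
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise ValueError("dextramer counts must be non-negative integers")
        missing_nc = [c for c in self.negative_controls if c not in self.counts.columns]
        if missing_nc:
            raise ValueError(f"negative controls absent from counts: {missing_nc}")
        if len(self.negative_controls) < 1:
            raise ValueError("at least one negative-control dextramer is required")
        missing_cov = [c for c in REQUIRED_COVARIATES if c not in self.covariates.columns]
        if missing_cov:
            raise ValueError(f"covariates table missing columns: {missing_cov}")
        if len(self.covariates) != len(self.counts):
            raise ValueError("counts and covariates describe different numbers of cells")

    @property
    def dextramers(self) -> list[str]:
        return [c for c in self.counts.columns if c not in self.negative_controls]

    @property
    def n_cells(self) -> int:
        return len(self.counts)


@dataclass
class BackgroundFit:
    """NB background regression for one dextramer."""

    dex_id: str
    params: pd.Series  # named coefficients incl. const and alpha (dispersion)
    converged: bool
    design_columns: list[str]
    donor_levels: list[str]
    bse: pd.Series | None = None  # Wald standard errors, same index as params

    @property
    def dispersion(self) -> float:
        return float(self.params["alpha"])

    def summary(self) -> str:
        coefs = "\n".join(f"    {k}: {v:+.4f}" for k, v in self.params.items())
        return (
            f"NB background model for {self.dex_id} "
            f"({'converged' if self.converged else 'NOT CONVERGED'})\n{coefs}"
        )


@dataclass
class NormalizedStain:
    """Per-cell normalized staining values and (optional) binder calls."""

    dex_id: str
    values: np.ndarray  # Dnorm per cell
    threshold: float | None = None
    calls: np.ndarray | None = None

    def plot_hist(self, ax=None, bins: int = 60):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.values, bins=bins, color="steelblue")
        if self.threshold is not None:
            ax.axvline(self.threshold, color="firebrick", ls="--", label="threshold")
            ax.legend(frameon=False)
        ax.set_xlabel(f"normalized {self.dex_id} staining (Dnorm)")
        ax.set_ylabel("cells")
        return ax


@dataclass
class AntigenAssocResult:
    """TCR-mem vs memory-state association within one antigen population."""

    antigen: str
    n_clones: int
    n_donors: int
    eligible: bool
    estimable: bool
    beta: float = float("nan")
    se: float = float("nan")
    p: float = float("nan")
    reason: str = ""


def _design(panel: DextramerPanel) -> tuple[np.ndarray, list[str], list[str]]:
    """Technical design matrix: const + nc counts + expression + donor dummies."""
    cov = panel.covariates
    cols: list[np.ndarray] = [np.ones(panel.n_cells)]
    names = ["const"]
    for nc in panel.negative_controls:
        cols.append(panel.counts[nc].to_numpy(dtype=float))
        names.append(f"nc_{nc}")
    for c in ("tcr_exp", "cd3_exp", "cd8_exp"):
        cols.append(cov[c].to_numpy(dtype=float))
        names.append(c)
    donors = sorted(cov["donor_id"].astype(str).unique())
    for d in donors[1:]:  # reference level: lexicographically first donor
        cols.append((cov["donor_id"].astype(str) == d).to_numpy(dtype=float))
        names.append(f"donor_{d}")
    return np.column_stack(cols), names, donors


class DextramerBackgroundModel:
    """Model object: NB regression of one dextramer's UMI counts on
    technical factors (negative controls, expression covariates, donor)."""

    def __init__(self, panel: DextramerPanel, dex_id: str):
        if dex_id in panel.negative_controls:
            raise ValueError(f"{dex_id} is a negative control, not a target dextramer")
        if dex_id not in panel.counts.columns:
            raise KeyError(f"unknown dextramer: {dex_id}")
        self.panel = panel
        self.dex_id = dex_id

    def fit(self) -> BackgroundFit:
        y = self.panel.counts[self.dex_id].to_numpy(dtype=float)
        if np.all(y == 0):
            raise ValueError(f"all counts for {self.dex_id} are zero; background fit is degenerate")
        X, names, donors = _design(self.panel)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = NegativeBinomial(y, X, loglike_method="nb2")
            try:
                res = model.fit(disp=0, maxiter=200)
                converged = bool(res.mle_retvals.get("converged", True))
            except Exception:
                # fall back to a Poisson start with tiny dispersion
                start = np.append(sm.Poisson(y, X).fit(disp=0).params, 0.1)
                res = model.fit(start_params=start, disp=0, maxiter=200)
                converged = bool(res.mle_retvals.get("converged", True))
        index = names + ["alpha"]
        return BackgroundFit(
            dex_id=self.dex_id,
            params=pd.Series(res.params, index=index),
            converged=converged,
            design_columns=names,
            donor_levels=donors,
            bse=pd.Series(res.bse, index=index),
        )

    def normalize(self, fit: BackgroundFit | None = None) -> NormalizedStain:
        fit = fit or self.fit()
        return normalize_stain(fit, self.panel, self.dex_id)


def fit_background(panel: DextramerPanel, dex_id: str) -> BackgroundFit:
    """NB background regression for one dextramer (functional surface)."""
    return DextramerBackgroundModel(panel, dex_id).fit()


def normalize_stain(fit: BackgroundFit, panel: DextramerPanel, dex_id: str) -> NormalizedStain:
    """Dnorm_i = log(observed_i / expected_i + 1) with the NB fitted mean."""
    if fit.dex_id != dex_id:
        raise ValueError(f"fit is for {fit.dex_id}, not {dex_id}")
    X, names, _ = _design(panel)
    if names != fit.design_columns:
        raise ValueError("panel design does not match the fitted background model")
    expected = np.exp(X @ fit.params[names].to_numpy())
    assert np.all(expected > 0), "log link guarantees positive fitted means"
    observed = panel.counts[dex_id].to_numpy(dtype=float)
    return NormalizedStain(dex_id=dex_id, values=np.log(observed / expected + 1.0))


def call_binders(stain: NormalizedStain, threshold: float) -> NormalizedStain:
    """Call binders as cells with Dnorm >= threshold (per-dextramer config)."""
    if threshold is None or not np.isfinite(threshold):
        raise ValueError(f"no valid threshold configured for {stain.dex_id}")
    return NormalizedStain(
        dex_id=stain.dex_id,
        values=stain.values,
        threshold=float(threshold),
        calls=stain.values >= threshold,
    )


def flag_multibinders(stains: Mapping[str, NormalizedStain]) -> np.ndarray:
    """True for cells called binder by more than one dextramer."""
    called = [s.calls for s in stains.values() if s.calls is not None]
    if not called:
        raise ValueError("no binder calls available")
    return np.sum(np.column_stack(called), axis=1) > 1


def find_threshold_antimode(stain: NormalizedStain, grid: int = 512) -> float:
    """Convenience threshold: the KDE density minimum between the two modes.

    An automatic stand-in for the per-dextramer thresholds that would
    otherwise be set by inspecting the bimodal Dnorm histogram.
    """
    from scipy.stats import gaussian_kde

    v = stain.values
    kde = gaussian_kde(v)
    xs = np.linspace(v.min(), v.max(), grid)
    dens = kde(xs)
    peaks = [
        i for i in range(1, grid - 1) if dens[i] >= dens[i - 1] and dens[i] >= dens[i + 1]
    ]
    if len(peaks) < 2:
        raise ValueError("Dnorm distribution is not bimodal; set a manual threshold")
    lo, hi = peaks[0], peaks[-1]
    return float(xs[lo + int(np.argmin(dens[lo:hi + 1]))])


def antigen_assoc(
    memory,
    tcr_mem_scores,
    dnorm,
    donor_ids,
    antigen: str = "antigen",
    min_clones: int = 10,
    one_tailed: bool = False,
) -> AntigenAssocResult:
    """Logistic regression of memory state on TCR-mem within one antigen group.

    Inputs are one row per distinct TCR clone (choose one cell at random per
    clone upstream).  Dnorm and donor indicators enter as covariates; donor
    terms only for populations spanning more than one donor.  Populations
    with fewer than ``min_clones`` clones are ineligible.
    """
    y = np.asarray(memory, dtype=float)
    s = np.asarray(tcr_mem_scores, dtype=float)
    d = None if dnorm is None else np.asarray(dnorm, dtype=float)
    donors = np.asarray([str(x) for x in donor_ids])
    n = len(y)
    if n < min_clones:
        return AntigenAssocResult(
            antigen=antigen, n_clones=n, n_donors=len(set(donors)),
            eligible=False, estimable=False,
            reason=f"fewer than {min_clones} distinct clones",
        )
    if len(np.unique(y)) < 2:
        return AntigenAssocResult(
            antigen=antigen, n_clones=n, n_donors=len(set(donors)),
            eligible=True, estimable=False, reason="single-class memory outcome",
        )
    cols = [np.ones(n), s] + ([] if d is None else [d])
    levels = sorted(set(donors))
    for lvl in levels[1:]:
        cols.append((donors == lvl).astype(float))
    X = np.column_stack(cols)
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as err:  # perfect separation etc.
        return AntigenAssocResult(
            antigen=antigen, n_clones=n, n_donors=len(levels),
            eligible=True, estimable=False, reason=f"fit failed: {err}",
        )
    beta, se = float(fit.params[1]), float(fit.bse[1])
    from scipy import stats as _st

    z = beta / se
    p = float(_st.norm.sf(z)) if one_tailed else float(2 * _st.norm.sf(abs(z)))
    return AntigenAssocResult(
        antigen=antigen, n_clones=n, n_donors=len(levels),
        eligible=True, estimable=True, beta=beta, se=se, p=p,
    )


def across_antigen_meta(results: Sequence[AntigenAssocResult]) -> MetaResult:
    """ML random-effects pooling of per-antigen TCR-mem effects."""
    usable = [r for r in results if r.eligible and r.estimable]
    if len(usable) < 2:
        raise ValueError("need at least two eligible antigen-specific estimates")
    return random_effects_meta([r.beta for r in usable], [r.se for r in usable])
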