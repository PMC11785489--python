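"""Ridge-penalized logistic TCR scoring functions (TCR-innate/-CD8/-reg/-mem).

A scoring function is a linear model on the standardized TCR feature vector:

    logit P(state_i = 1) = sum_j beta_j * feature_{j,i} + beta_0

fitted with an L2 penalty chosen by k-fold cross-validation (held-out
binomial deviance) to handle the strong collinearity between sequence
features.  The returned score is standardized to the *training* score
distribution, so one score unit always means one training-set standard
deviation, in any dataset the model is later applied to.

Single-chain variants (alpha-only / beta-only) restrict both fitting and
scoring to one chain's features; they serve the analysis of nonproductive
rearrangements, where usually only one chain is observed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .features import LOOPS, FeatureMatrix, FeatureRegistry

__all__ = ["TcrStateScorer", "ScoringResults", "train_scorer", "score", "cdr_contribution"]

#: default log-spaced ridge penalty grid (lambda = 1/C in sklearn's convention)
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-2, 4, 7))

CHAIN_MASKS = ("both", "alpha_only", "beta_only")


@dataclass
class ScoringResults:
    """A trained TCR scoring function.

    ``weights`` always has full registry length; features excluded by the
    chain mask carry weight 0.  ``train_mean``/``train_sd`` are the raw-score
    moments over the (non-excluded) training cells and define the score unit.
    """

    target: str
    weights: np.ndarray
    intercept: float
    lam: float
    registry_hash: str
    train_mean: float
    train_sd: float
    chain_mask: str
    n_obs: int

    def score(self, features: FeatureMatrix) -> np.ndarray:
        """Standardized scores for a scaled feature matrix."""
        if features.registry.hash != self.registry_hash:
            raise ValueError(
                "feature registry does not match the one the model was trained "
                f"under ({features.registry.hash} != {self.registry_hash})"
            )
        raw = features.values @ self.weights + self.intercept
        return (raw - self.train_mean) / self.train_sd

    def summary(self, registry: FeatureRegistry | None = None, top: int = 10) -> str:
        lines = [
            f"TCR scoring function: {self.target}",
            f"  chain mask: {self.chain_mask}",
            f"  n train cells: {self.n_obs}",
            f"  ridge lambda: {self.lam:g}",
            f"  raw-score mean/sd (train): {self.train_mean:.4f} / {self.train_sd:.4f}",
        ]
        order = np.argsort(-np.abs(self.weights))[:top]
        names = registry.names if registry is not None else None
        lines.append(f"  top {top} |weights|:")
        for j in order:
            label = names[j] if names else f"feature[{j}]"
            lines.append(f"    {label}: {self.weights[j]:+.4f}")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "schema_version": 1,
                    "target": self.target,
                    "weights": self.weights.tolist(),
                    "intercept": self.intercept,
                    "lambda": self.lam,
                    "registry_hash": self.registry_hash,
                    "train_mean": self.train_mean,
                    "train_sd": self.train_sd,
                    "chain_mask": self.chain_mask,
                    "n_obs": self.n_obs,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "ScoringResults":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            target=d["target"],
            weights=np.asarray(d["weights"], dtype=float),
            intercept=float(d["intercept"]),
            lam=float(d["lambda"]),
            registry_hash=d["registry_hash"],
            train_mean=float(d["train_mean"]),
            train_sd=float(d["train_sd"]),
            chain_mask=d["chain_mask"],
            n_obs=int(d["n_obs"]),
        )


class TcrStateScorer:
    """Model object: ridge logistic regression of a binary state on TCR features.

    Parameters
    ----------
    features : FeatureMatrix
        Scaled feature matrix (one row per clone; the caller is responsible
        for clone deduplication via ``sample_one_per_clone``).
    labels : array of {0, 1}
        Whether each cell is observed in the target state.
    target : str
        Name of the contrast (e.g. "mem", "cd8").
    chain_mask : {"both", "alpha_only", "beta_only"}
    exclude_mask : bool array, optional
        Cells excluded from both fitting and score standardization (e.g.
        innate-like cells for the CD8/reg/mem contrasts).
    """

    def __init__(
        self,
        features: FeatureMatrix,
        labels,
        target: str = "state",
        chain_mask: str = "both",
        exclude_mask=None,
    ):
        labels = np.asarray(labels)
        if labels.shape[0] != features.shape[0]:
            raise ValueError("labels and feature matrix have different row counts")
        if not set(np.unique(labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if chain_mask not in CHAIN_MASKS:
            raise ValueError(f"chain_mask must be one of {CHAIN_MASKS}")
        self.features = features
        self.labels = labels.astype(int)
        self.target = target
        self.chain_mask = chain_mask
        if exclude_mask is None:
            exclude_mask = np.zeros(labels.shape[0], dtype=bool)
        self.exclude_mask = np.asarray(exclude_mask, dtype=bool)

    def fit(
        self,
        lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
        folds: int = 5,
        seed: int = 0,
    ) -> ScoringResults:
        """Fit, selecting the penalty by k-fold held-out binomial deviance."""
        keep = ~self.exclude_mask
        y = self.labels[keep]
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present after exclusions")
        registry = self.features.registry
        if self.chain_mask == "both":
            cols = np.arange(len(registry))
        else:
            chain = "alpha" if self.chain_mask == "alpha_only" else "beta"
            cols = registry.chain_indices(chain)
        X = self.features.values[np.ix_(keep, cols)]

        Cs = np.sort(1.0 / np.asarray(list(lambda_grid), dtype=float))
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        clf = LogisticRegressionCV(
            Cs=Cs,
            cv=cv,
            penalty="l2",
            scoring="neg_log_loss",
            solver="lbfgs",
            max_iter=300,
            tol=1e-4,
            refit=True,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            warnings.simplefilter("ignore", UserWarning)
            clf.fit(X, y)

        weights = np.zeros(len(registry))
        weights[cols] = clf.coef_[0]
        intercept = float(clf.intercept_[0])
        raw = self.features.values[keep] @ weights + intercept
        train_mean = float(raw.mean())
        train_sd = float(raw.std())
        if train_sd == 0:
            train_sd = 1.0  # degenerate (e.g. lambda -> inf); scores collapse to 0
        return ScoringResults(
            target=self.target,
            weights=weights,
            intercept=intercept,
            lam=float(1.0 / clf.C_[0]),
            registry_hash=registry.hash,
            train_mean=train_mean,
            train_sd=train_sd,
            chain_mask=self.chain_mask,
            n_obs=int(keep.sum()),
        )


def train_scorer(
    features: FeatureMatrix,
    labels,
    target: str = "state",
    folds: int = 5,
    exclude_mask=None,
    chain_mask: str = "both",
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    seed: int = 0,
) -> ScoringResults:
    """Functional wrapper over :class:`TcrStateScorer`."""
    return TcrStateScorer(
        features, labels, target=target, chain_mask=chain_mask, exclude_mask=exclude_mask
    ).fit(lambda_grid=lambda_grid, folds=folds, seed=seed)


def score(model: ScoringResults, features: FeatureMatrix) -> np.ndarray:
    """Standardized scores of ``features`` under a trained model."""
    return model.score(features)


def cdr_contribution(
    model: ScoringResults,
    features: FeatureMatrix,
    labels=None,
    grouping: Mapping[str, np.ndarray] | None = None,
) -> dict[str, float]:
    """Share of the score attributable to each CDR loop (partition masking).

    For each feature group the contribution is the mean absolute change in
    score when the group's features are masked to 0, averaged over the
    positive-class cells (all cells if ``labels`` is None); shares are
    normalized to sum to 1.  This is a partition-masking simplification of a
    Shapley-value decomposition: it ignores interactions *between* groups,
    which is exact for a linear score with disjoint groups.
    """
    registry = features.registry
    if grouping is None:
        grouping = {loop: registry.loop_indices(loop) for loop in LOOPS}
    covered = np.concatenate([np.asarray(ix) for ix in grouping.values()])
    if len(covered) != len(registry) or len(np.unique(covered)) != len(registry):
        raise ValueError("grouping must partition the feature registry")

    rows = np.ones(features.shape[0], dtype=bool)
    if labels is not None:
        rows = np.asarray(labels).astype(bool)
    full = features.values[rows] @ model.weights
    contrib = {}
    for name, ix in grouping.items():
        ix = np.asarray(ix, dtype=int)
        masked = full - features.values[np.ix_(np.flatnonzero(rows), ix)] @ model.weights[ix]
        contrib[name] = float(np.mean(np.abs(full - masked))) / model.train_sd
    total = sum(contrib.values())
    if total == 0:
        return {k: 1.0 / len(contrib) for k in contrib}
    return {k: v / total for k, v in contrib.items()}
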