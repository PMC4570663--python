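"""Regression-tree trend model: element concentration as a step function of
CT grayscale.

With a single ordered covariate a CART fit is a piecewise-constant step
function, so the fitted tree is stored as ordered split thresholds plus leaf
means. Cost-complexity pruning with a cross-validated 1-SE rule guards
against over-fitting, which matters because the step-function family can
absorb arbitrarily many parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor


class TreeError(ValueError):
    pass


@dataclass(frozen=True)
class TreeConfig:
    """Fitting controls.

    ``min_leaf`` (pixels per leaf) and ``max_leaves`` (None: unlimited) bound
    tree size before pruning; ``prune`` enables cost-complexity pruning with
    ``cv_folds``-fold cross-validation and the 1-SE rule; ``seed`` fixes the
    CV shuffle.
    """

    min_leaf: int = 50
    max_leaves: Optional[int] = 32
    prune: bool = True
    cv_folds: int = 5
    seed: int = 0


@dataclass
class RegressionTree:
    """Piecewise-constant fit on grayscale.

    ``thresholds`` are strictly increasing split points; a value ``g`` maps to
    leaf ``sum(thresholds <= g)`` (splits read ``g < t`` left, ``g >= t``
    right). ``leaf_means`` has one more entry than ``thresholds``.
    """

    thresholds: np.ndarray
    leaf_means: np.ndarray
    n_train: int
    leaf_counts: np.ndarray
    cfg: TreeConfig
    ccp_alphas: Optional[np.ndarray] = None
    chosen_alpha: float = 0.0

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.leaf_means = np.asarray(self.leaf_means, dtype=float)
        if len(self.leaf_means) != len(self.thresholds) + 1:
            raise TreeError("need exactly one more leaf mean than thresholds")
        if len(self.thresholds) and np.any(np.diff(self.thresholds) <= 0):
            raise TreeError("thresholds must be strictly increasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_means)

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds.tolist(),
            "leaf_means": self.leaf_means.tolist(),
            "cfg": self.cfg.__dict__,
        }


def _extract_steps(tree: DecisionTreeRegressor) -> tuple[np.ndarray, np.ndarray]:
    """In-order traversal of a single-feature tree -> (thresholds, leaf means)."""
    t = tree.tree_
    thresholds: list[float] = []
    means: list[float] = []

    def visit(node: int) -> None:
        if t.children_left[node] == -1:
            means.append(float(t.value[node, 0, 0]))
            return
        visit(t.children_left[node])
        thresholds.append(float(t.threshold[node]))
        visit(t.children_right[node])

    visit(0)
    return np.asarray(thresholds), np.asarray(means)


def _leaf_counts(thresholds: np.ndarray, gray: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(thresholds, gray, side="right")
    return np.bincount(idx, minlength=len(thresholds) + 1)


def fit_tree(gray: np.ndarray, conc: np.ndarray, cfg: TreeConfig = TreeConfig()) -> RegressionTree:
    """Fit a CART with squared-error splitting on the grayscale covariate.

    All-identical grayscale with a non-constant response degrades to a
    single-leaf tree with a warning (there is nothing to split on).
    """
    gray = np.asarray(gray, dtype=float).ravel()
    conc = np.asarray(conc, dtype=float).ravel()
    if len(gray) != len(conc):
        raise TreeError("gray and conc must have equal length")
    n = len(gray)
    if n < 2 * cfg.min_leaf:
        raise TreeError(f"need at least 2*min_leaf = {2 * cfg.min_leaf} points, got {n}")

    if np.ptp(gray) == 0:
        if np.ptp(conc) > 0:
            warnings.warn("grayscale is constant; fitting a single-leaf tree")
        return RegressionTree(
            thresholds=np.empty(0),
            leaf_means=np.array([conc.mean()]),
            n_train=n,
            leaf_counts=np.array([n]),
            cfg=cfg,
        )

    X = gray[:, None]

    def make(alpha: float) -> DecisionTreeRegressor:
        return DecisionTreeRegressor(
            criterion="squared_error",
            min_samples_leaf=cfg.min_leaf,
            max_leaf_nodes=cfg.max_leaves,
            ccp_alpha=alpha,
            random_state=cfg.seed,
        )

    full = make(0.0).fit(X, conc)
    chosen_alpha = 0.0
    alphas = None
    if cfg.prune and full.get_n_leaves() > 1:
        path = full.cost_complexity_pruning_path(X, conc)
        alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
        if len(alphas) > 16:  # thin the path; endpoints kept
            pick = np.unique(np.linspace(0, len(alphas) - 1, 16).round().astype(int))
            alphas = alphas[pick]
        if len(alphas) > 1:
            kf = KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
            fold_mse = np.empty((cfg.cv_folds, len(alphas)))
            for f, (tr, te) in enumerate(kf.split(X)):
                for a, alpha in enumerate(alphas):
                    m = make(alpha).fit(X[tr], conc[tr])
                    fold_mse[f, a] = np.mean((m.predict(X[te]) - conc[te]) ** 2)
            mse = fold_mse.mean(axis=0)
            se = fold_mse.std(axis=0, ddof=1) / np.sqrt(cfg.cv_folds)
            best = int(np.argmin(mse))
            # 1-SE rule: largest alpha (smallest subtree) within one SE of the best
            ok = np.flatnonzero(mse <= mse[best] + se[best])
            chosen_alpha = float(alphas[ok.max()])
        full = make(chosen_alpha).fit(X, conc)

    thresholds, means = _extract_steps(full)
    return RegressionTree(
        thresholds=thresholds,
        leaf_means=means,
        n_train=n,
        leaf_counts=_leaf_counts(thresholds, gray),
        cfg=cfg,
        ccp_alphas=alphas,
        chosen_alpha=chosen_alpha,
    )


@dataclass
class LinearTrend:
    """Simple linear trend on grayscale, kept for comparison only.

    A straight line underfits the banded grayscale-to-concentration
    relationship; the step-function tree is the supported trend model.
    """

    intercept: float
    slope: float
    n_train: int


def fit_linear(gray: np.ndarray, conc: np.ndarray) -> LinearTrend:
    """Ordinary least squares of concentration on grayscale."""
    gray = np.asarray(gray, dtype=float).ravel()
    conc = np.asarray(conc, dtype=float).ravel()
    if len(gray) != len(conc) or len(gray) < 2:
        raise TreeError("need two equal-length vectors with n >= 2")
    if np.ptp(gray) == 0:
        return LinearTrend(intercept=float(conc.mean()), slope=0.0, n_train=len(gray))
    slope, intercept = np.polyfit(gray, conc, 1)
    return LinearTrend(intercept=float(intercept), slope=float(slope), n_train=len(gray))


def predict_trend(model, gray: np.ndarray) -> np.ndarray:
    """Evaluate either trend form (tree or linear) on grayscale."""
    if isinstance(model, LinearTrend):
        return model.intercept + model.slope * np.asarray(gray, dtype=float)
    return predict_tree(model, gray)


def predict_tree(tree: RegressionTree, gray: np.ndarray) -> np.ndarray:
    """Map each grayscale value to its leaf mean.

    Values below the first / above the last threshold fall in the extreme
    leaves; a value exactly at a threshold goes to the right leaf.
    """
    gray = np.asarray(gray, dtype=float)
    idx = np.searchsorted(tree.thresholds, gray, side="right")
    return tree.leaf_means[idx]


def residuals(tree: RegressionTree, gray: np.ndarray, conc: np.ndarray) -> np.ndarray:
    """Observed minus tree-predicted concentrations."""
    conc = np.asarray(conc, dtype=float)
    return conc - predict_tree(tree, gray)
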