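"""Boruta all-relevant feature selection with shadow features.

Each iteration permutes every real feature into a "shadow" copy, fits a
random-forest regressor on the augmented matrix, and scores a real feature
a *hit* when its importance exceeds a chosen percentile of the shadow
importances. Binomial tests on the accumulated hit counts (p = 1/2 under
the null) promote features to *confirmed* or demote them to *rejected*;
anything undecided at the iteration limit stays *tentative*.

The two-step correction scheme follows the reference procedure: acceptance
and rejection first pass a Benjamini-Hochberg FDR gate across features, then
a Bonferroni gate across iterations; with ``two_step=False`` a single
Bonferroni correction over the feature count is applied instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

__all__ = ["BorutaConfig", "BorutaResult", "boruta_select"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BorutaConfig:
    """Configuration mirroring the reference Boruta defaults.

    tree_depth caps each forest tree (shallow trees, 3-7, give the cleanest
    shadow contrast); n_estimators 'auto' scales the forest to the feature
    count as 100 * sqrt(2 p) / depth; perc is the shadow-importance
    percentile a real feature must beat to score a hit. The default
    importance is permutation importance on a per-iteration held-out split
    (fraction ``holdout_fraction``): impurity importance scored in-sample
    rewards chance in-sample correlations and inflates false confirmations.
    """

    tree_depth: int = 4
    n_estimators: int | str = "auto"
    perc: float = 100.0
    alpha: float = 0.05
    two_step: bool = True
    max_iter: int = 100
    importance: str = "permutation"  # or "impurity"
    holdout_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.perc <= 100):
            raise ValueError("perc must lie in (0, 100]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.importance not in ("impurity", "permutation"):
            raise ValueError("importance must be 'impurity' or 'permutation'")
        if not (0 < self.holdout_fraction < 1):
            raise ValueError("holdout_fraction must lie in (0, 1)")


@dataclass
class BorutaResult:
    confirmed: list = field(default_factory=list)
    rejected: list = field(default_factory=list)
    tentative: list = field(default_factory=list)
    hit_counts: dict = field(default_factory=dict)
    n_iterations_run: int = 0

    def __post_init__(self) -> None:
        names = self.confirmed + self.rejected + self.tentative
        if len(names) != len(set(names)):
            raise ValueError("confirmed/rejected/tentative must be disjoint")


def _auto_n_estimators(n_feat: int, depth: int) -> int:
    # each feature should be examined ~100 times across the forest
    return max(10, int(100.0 * np.sqrt(2.0 * n_feat) / depth))


def _held_out_permutation_importance(
    forest, Z_test: np.ndarray, y_test: np.ndarray, rng: np.random.Generator, n_repeats: int = 3
) -> np.ndarray:
    """Mean decrease in held-out R^2 when each column is permuted.

    All permuted copies are scored in one stacked predict call, which is
    much cheaper than per-column scoring on a forest.
    """
    n, p = Z_test.shape
    base_mse = float(np.mean((y_test - forest.predict(Z_test)) ** 2))
    stacks = []
    for _ in range(n_repeats):
        for j in range(p):
            Zp = Z_test.copy()
            Zp[:, j] = rng.permutation(Zp[:, j])
            stacks.append(Zp)
    preds = forest.predict(np.vstack(stacks)).reshape(n_repeats, p, n)
    mse = np.mean((preds - y_test[None, None, :]) ** 2, axis=2)
    var_y = float(np.var(y_test)) or 1.0
    return (mse.mean(axis=0) - base_mse) / var_y


def _fdr_reject(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, n + 1) / n)
    passed = p[order] <= thresh
    out = np.zeros(n, dtype=bool)
    if passed.any():
        out[order[: np.max(np.nonzero(passed)[0]) + 1]] = True
    return out


def boruta_select(
    features: pd.DataFrame, target: pd.Series | np.ndarray, config: BorutaConfig = BorutaConfig()
) -> BorutaResult:
    """Run Boruta on a feature table against a numeric target.

    Requires >= 2 features and no missing values. Constant features are
    auto-rejected up front (a shadow of a constant is itself); a constant
    target is an error.
    """
    X = pd.DataFrame(features).copy()
    y = np.asarray(target, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("boruta_select needs at least 2 features")
    if X.isna().any().any() or np.any(~np.isfinite(y)):
        raise ValueError("boruta_select: missing values are not supported")
    if np.ptp(y) == 0:
        raise ValueError("boruta_select: target is constant")

    const_cols = [c for c in X.columns if X[c].nunique() <= 1]
    for c in const_cols:
        logger.info("boruta: auto-rejecting constant feature %r", c)
    active_cols = [c for c in X.columns if c not in const_cols]

    rng = np.random.default_rng(config.seed)
    names = list(active_cols)
    p = len(names)
    # decision: 0 tentative, 1 confirmed, -1 rejected
    decision = np.zeros(p, dtype=int)
    hits = np.zeros(p, dtype=int)

    it = 0
    for it in range(1, config.max_iter + 1):
        undecided = np.where(decision == 0)[0]
        if undecided.size == 0:
            break
        Xa = X[names].to_numpy(dtype=float)
        shadow = Xa.copy()
        for j in range(shadow.shape[1]):
            shadow[:, j] = rng.permutation(shadow[:, j])
        # keep at least 5 shadow columns for a stable percentile
        while shadow.shape[1] < 5:
            extra = Xa[:, rng.integers(0, Xa.shape[1])].copy()
            shadow = np.column_stack([shadow, rng.permutation(extra)])
        Z = np.hstack([Xa, shadow])

        n_est = (
            _auto_n_estimators(p, config.tree_depth)
            if config.n_estimators == "auto"
            else int(config.n_estimators)
        )
        forest = RandomForestRegressor(
            n_estimators=n_est,
            max_depth=config.tree_depth,
            max_features=1 / 3,  # classic regression-forest mtry = p/3
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        if config.importance == "impurity":
            forest.fit(Z, y)
            imp = forest.feature_importances_
        else:
            # held-out permutation importance: chance in-sample association
            # does not generalise, so only genuinely relevant features beat
            # their shadows systematically (same rationale as out-of-bag
            # mean-decrease-accuracy in the classic algorithm)
            order = rng.permutation(len(y))
            n_te = max(1, int(config.holdout_fraction * len(y)))
            te, tr = order[:n_te], order[n_te:]
            forest.fit(Z[tr], y[tr])
            imp = _held_out_permutation_importance(forest, Z[te], y[te], rng)
        real_imp, shadow_imp = imp[:p], imp[p:]
        cut = np.percentile(shadow_imp, config.perc)
        hits += (real_imp > cut).astype(int)

        # binomial bookkeeping on the active (still tentative) features
        act = np.where(decision == 0)[0]
        if act.size:
            h = hits[act]
            p_accept = stats.binom.sf(h - 1, it, 0.5)
            p_reject = stats.binom.cdf(h, it, 0.5)
            if config.two_step:
                acc = _fdr_reject(p_accept, config.alpha) & (p_accept <= config.alpha / it)
                rej = _fdr_reject(p_reject, config.alpha) & (p_reject <= config.alpha / it)
            else:
                acc = p_accept <= config.alpha / p
                rej = p_reject <= config.alpha / p
            decision[act[acc]] = 1
            decision[act[rej & ~acc]] = -1

    result = BorutaResult(
        confirmed=[names[i] for i in range(p) if decision[i] == 1],
        rejected=[names[i] for i in range(p) if decision[i] == -1] + const_cols,
        tentative=[names[i] for i in range(p) if decision[i] == 0],
        hit_counts={**{names[i]: int(hits[i]) for i in range(p)}, **{c: 0 for c in const_cols}},
        n_iterations_run=it,
    )
    return result
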