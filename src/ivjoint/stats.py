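"""Statistical battery for study outputs.

Normality screening (chi-squared goodness of fit with a Kolmogorov-Smirnov
fallback), rank correlations (Spearman, or tie-corrected Kendall tau-b when
ties are present) with Bonferroni adjustment, the Friedman rank-sum test for
unreplicated blocked data, regression-tree variable importance with
cost-complexity pruning, and Bland-Altman agreement tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError

__all__ = [
    "CorrelationReport",
    "TreeReport",
    "normality_test",
    "rank_correlation",
    "friedman_blocked",
    "regression_tree_importance",
    "bland_altman",
]

ALPHA = 0.05


@dataclass
class CorrelationReport:
    method: str  # "spearman" | "kendall"
    coefficient: float
    p_value: float
    adjusted_p: float
    family_size: int

    @property
    def significant(self) -> bool:
        return self.adjusted_p < ALPHA


@dataclass
class TreeReport:
    tree: object  # fitted sklearn DecisionTreeRegressor
    feature_names: list[str]
    importances: np.ndarray  # per feature, sums to 1 (or all 0 if no splits)
    block_importances: dict[str, float]
    ccp_alpha: float
    degenerate: bool = False  # constant response -> root-only tree

    @property
    def n_leaves(self) -> int:
        return int(self.tree.get_n_leaves())


def normality_test(sample: np.ndarray) -> dict:
    """Test the null hypothesis that a sample is normally distributed.

    Chi-squared goodness of fit against a normal with the sample mean and SD,
    using sqrt(n) equal-probability bins and bins - 3 degrees of freedom.
    Falls back to the one-sample Kolmogorov-Smirnov test when the chi-squared
    test is unsuitable (any expected bin count below 5, or zero variance).
    Rejection is at p < 0.05.
    """
    x = np.asarray(sample, dtype=float).ravel()
    n = x.size
    if n < 8:
        raise InputError("normality test requires n >= 8")
    mu = x.mean()
    sd = x.std(ddof=1)
    degenerate = sd <= 1e-12 * max(1.0, abs(mu))
    n_bins = int(round(np.sqrt(n)))
    expected = n / n_bins

    if degenerate or expected < 5.0:
        # degenerate or sparse-bin case: one-sample KS fallback
        if degenerate:
            # a constant sample is maximally non-normal; KS against any
            # non-degenerate normal rejects
            return {"statistic": np.inf, "p": 0.0, "method_used": "ks",
                    "reject": True}
        stat, p = sps.kstest(x, "norm", args=(mu, sd))
        return {"statistic": float(stat), "p": float(p), "method_used": "ks",
                "reject": bool(p < ALPHA)}

    edges = sps.norm.ppf(np.linspace(0.0, 1.0, n_bins + 1), loc=mu, scale=sd)
    observed, _ = np.histogram(x, bins=edges)
    stat = float(np.sum((observed - expected) ** 2) / expected)
    df = n_bins - 3
    p = float(sps.chi2.sf(stat, df))
    return {"statistic": stat, "p": p, "method_used": "chi2",
            "reject": bool(p < ALPHA)}


def rank_correlation(
    x: np.ndarray, y: np.ndarray, family_size: int = 1
) -> CorrelationReport:
    """Rank correlation with automatic tie handling and Bonferroni adjustment.

    Kendall's tau-b (tie-corrected) is used when either variable contains
    ties, Spearman's rho otherwise.  ``family_size`` is the number of tests
    in the correlation family; the adjusted p is min(1, family_size * p).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 5:
        raise InputError("rank correlation requires equal lengths >= 5")
    if family_size < 1:
        raise InputError("family_size must be >= 1")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise InputError("correlation undefined for zero-variance input")
    has_ties = np.unique(x).size < x.size or np.unique(y).size < y.size
    if has_ties:
        r = sps.kendalltau(x, y)  # tau-b by default
        method = "kendall"
    else:
        r = sps.spearmanr(x, y)
        method = "spearman"
    p = float(r.pvalue)
    return CorrelationReport(
        method=method,
        coefficient=float(r.statistic),
        p_value=p,
        adjusted_p=min(1.0, family_size * p),
        family_size=family_size,
    )


def friedman_blocked(errors: np.ndarray) -> dict:
    """Friedman rank-sum test on a blocks x treatments matrix.

    One observation per cell (unreplicated blocked data); within-block ranks
    with average ranks for ties; chi-squared reference with k - 1 degrees of
    freedom.
    """
    m = np.asarray(errors, dtype=float)
    if m.ndim != 2:
        raise InputError("expected a 2-D blocks x treatments matrix")
    if not np.all(np.isfinite(m)):
        raise InputError("missing cells are not allowed")
    n_blocks, k = m.shape
    if k < 3 or n_blocks < 2:
        raise InputError("need >= 3 treatments and >= 2 blocks")
    ranks = np.vstack([sps.rankdata(row) for row in m])
    if np.all(ranks == ranks[:, :1]):
        # every block fully tied: no evidence of treatment differences
        return {"statistic": 0.0, "p": 1.0, "df": k - 1}
    stat, p = sps.friedmanchisquare(*[m[:, j] for j in range(k)])
    return {"statistic": float(stat), "p": float(p), "df": k - 1}


def regression_tree_importance(
    features: pd.DataFrame,
    response: np.ndarray,
    pose_features: list[str] | None = None,
    stiffness_features: list[str] | None = None,
    seed: int = 0,
    n_folds: int = 10,
    min_samples_leaf: int = 5,
) -> TreeReport:
    """Variance-reduction regression tree with 1-SE cost-complexity pruning.

    The pruning strength is chosen by cross-validation: among the candidate
    ccp_alpha values, the largest one whose CV error is within one standard
    error of the minimum (favouring the simplest tree the data supports).
    Importance is the normalised impurity reduction per feature; block
    importances sum each block's features (default: columns named pose_*
    versus stiffness k_*).
    """
    from sklearn.model_selection import KFold
    from sklearn.tree import DecisionTreeRegressor

    x = features.to_numpy(dtype=float)
    y = np.asarray(response, dtype=float).ravel()
    if x.shape[0] != y.size or x.shape[0] < 30:
        raise InputError("regression tree requires >= 30 matching rows")
    names = list(features.columns)
    if pose_features is None:
        pose_features = [c for c in names if not c.startswith("k_")]
    if stiffness_features is None:
        stiffness_features = [c for c in names if c.startswith("k_")]

    if np.allclose(y, y[0]):
        tree = DecisionTreeRegressor(
            min_samples_leaf=min_samples_leaf, random_state=seed
        ).fit(x, y)
        zeros = np.zeros(len(names))
        return TreeReport(tree, names, zeros,
                          {"pose": 0.0, "stiffness": 0.0}, 0.0, degenerate=True)

    full = DecisionTreeRegressor(
        min_samples_leaf=min_samples_leaf, random_state=seed
    ).fit(x, y)
    path = full.cost_complexity_pruning_path(x, y)
    alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))

    kf = KFold(n_splits=min(n_folds, len(y)), shuffle=True, random_state=seed)
    cv_err = np.zeros((kf.get_n_splits(), len(alphas)))
    for f, (tr, te) in enumerate(kf.split(x)):
        for a, alpha in enumerate(alphas):
            t = DecisionTreeRegressor(
                min_samples_leaf=min_samples_leaf, random_state=seed,
                ccp_alpha=alpha,
            ).fit(x[tr], y[tr])
            cv_err[f, a] = np.mean((t.predict(x[te]) - y[te]) ** 2)
    mean_err = cv_err.mean(axis=0)
    se_err = cv_err.std(axis=0, ddof=1) / np.sqrt(cv_err.shape[0])
    i_min = int(np.argmin(mean_err))
    threshold = mean_err[i_min] + se_err[i_min]
    # 1-SE rule: simplest tree (largest alpha) within one SE of the best
    candidates = np.where(mean_err <= threshold)[0]
    alpha_1se = float(alphas[candidates.max()])

    tree = DecisionTreeRegressor(
        min_samples_leaf=min_samples_leaf, random_state=seed,
        ccp_alpha=alpha_1se,
    ).fit(x, y)
    if tree.get_n_leaves() <= 1:
        importances = np.zeros(len(names))
        degenerate = False
    else:
        importances = tree.feature_importances_
        degenerate = False
    blocks = {
        "pose": float(sum(importances[names.index(c)] for c in pose_features)),
        "stiffness": float(
            sum(importances[names.index(c)] for c in stiffness_features)
        ),
    }
    return TreeReport(tree, names, importances, blocks, alpha_1se, degenerate)


def bland_altman(a: np.ndarray, b: np.ndarray) -> dict:
    """Bland-Altman agreement: bias and 95 % limits of agreement.

    Returns the bias (mean difference a - b), limits bias +/- 1.96 * SD of
    the differences, and a plot-ready table of pair means vs differences.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size or a.size < 3:
        raise InputError("Bland-Altman requires equal lengths >= 3")
    d = a - b
    bias = float(d.mean())
    half = 1.96 * float(d.std(ddof=1))
    table = pd.DataFrame({"mean": (a + b) / 2.0, "difference": d})
    return {
        "bias": bias,
        "limits": (bias - half, bias + half),
        "half_width": half,
        "table": table,
    }
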