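"""Differential-abundance and multivariate statistics.

Mirrors the analyses behind the study's figure panels: an
interquartile-range pre-filter, volcano statistics (Welch or pooled t,
two-tailed, on log/Pareto-transformed values with log2 fold-changes
from untransformed normalized areas), top-k selection for heatmaps,
two-component PLS-DA with VIP scores, and one-way ANOVA with Šídák
multiple-comparison adjustment.

PLS regression itself is the NIPALS implementation of scikit-learn;
VIP scores are computed here from its weights and score sums of
squares, normalized so the mean squared VIP over metabolites is 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cross_decomposition import PLSRegression


@dataclass
class ContrastResult:
    """Per-metabolite two-group test result."""

    metabolite: str
    log2_fold_change: float
    t_statistic: float
    p_value: float
    test: str
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    constant: bool = False


@dataclass
class PlsdaResult:
    """Scores, loadings and per-metabolite VIP from PLS-DA."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    weights: pd.DataFrame
    explained_variance: np.ndarray
    vip: pd.Series


def iqr_filter(matrix: pd.DataFrame, frac: float) -> pd.DataFrame:
    """Drop the ``floor(frac * n)`` features with the smallest IQR."""
    if not 0 <= frac < 1:
        raise ValueError("frac must lie in [0, 1)")
    n_drop = int(np.floor(frac * len(matrix)))
    if n_drop == 0:
        return matrix.copy()
    iqr = matrix.apply(lambda r: np.nanpercentile(r, 75) - np.nanpercentile(r, 25),
                       axis=1)
    order = iqr.sort_values(kind="stable")
    drop = set(order.index[:n_drop])
    return matrix.loc[[i for i in matrix.index if i not in drop]]


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def _student(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def volcano(values: pd.DataFrame, groups: pd.Series, test: str = "welch",
            transformed: pd.DataFrame | None = None) -> list[ContrastResult]:
    """Two-group volcano statistics per metabolite.

    ``values`` are untransformed normalized areas (used for the group
    means and log2 fold-change); the t-test runs on ``transformed``
    values (log/Pareto) when given, else on the raw values.  Exactly two
    group labels with >=2 samples each are required.  Constant rows are
    flagged and reported with p = 1.
    """
    labels = pd.unique(groups.dropna())
    if len(labels) != 2:
        raise ValueError(f"volcano requires exactly 2 groups, got {list(labels)}")
    ga, gb = labels
    a_ids = groups.index[groups == ga]
    b_ids = groups.index[groups == gb]
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError("each group needs at least 2 samples")
    tmat = transformed if transformed is not None else values
    stat_fn = {"welch": _welch, "student": _student}[test]
    out = []
    for met in values.index:
        va = values.loc[met, a_ids].dropna().to_numpy(dtype=float)
        vb = values.loc[met, b_ids].dropna().to_numpy(dtype=float)
        ta = tmat.loc[met, a_ids].dropna().to_numpy(dtype=float)
        tb = tmat.loc[met, b_ids].dropna().to_numpy(dtype=float)
        mean_a = float(va.mean()) if va.size else np.nan
        mean_b = float(vb.mean()) if vb.size else np.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            lfc = float(np.log2(mean_a / mean_b)) if mean_b > 0 and mean_a > 0 else np.nan
        if ta.size < 2 or tb.size < 2 or (np.ptp(np.concatenate([ta, tb])) == 0):
            out.append(ContrastResult(met, 0.0 if np.isnan(lfc) else lfc, 0.0, 1.0,
                                      test, mean_a, mean_b, len(va), len(vb),
                                      constant=True))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t, p = stat_fn(ta, tb)
        if not np.isfinite(p):
            t, p = 0.0, 1.0
        out.append(ContrastResult(met, lfc, t, p, test, mean_a, mean_b,
                                  len(va), len(vb)))
    return out


def results_to_frame(results: list[ContrastResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "metabolite": [r.metabolite for r in results],
            "log2_fold_change": [r.log2_fold_change for r in results],
            "t_statistic": [r.t_statistic for r in results],
            "p_value": [r.p_value for r in results],
            "test": [r.test for r in results],
            "mean_a": [r.mean_a for r in results],
            "mean_b": [r.mean_b for r in results],
            "n_a": [r.n_a for r in results],
            "n_b": [r.n_b for r in results],
            "constant": [r.constant for r in results],
        }
    ).set_index("metabolite")
    # optional BH column; not used for headline selection
    p = df["p_value"].to_numpy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
    bh = np.empty_like(adj)
    bh[order] = adj
    df["p_bh"] = bh
    return df


def volcano_hits(results: list[ContrastResult], p_max: float = 0.05,
                 min_abs_log2fc: float = 1.0) -> list[str]:
    """Metabolites significantly changed on the volcano: p below ``p_max``
    and at least ``min_abs_log2fc`` (default 2-fold) change."""
    return [r.metabolite for r in results
            if r.p_value < p_max and np.isfinite(r.log2_fold_change)
            and abs(r.log2_fold_change) >= min_abs_log2fc]


def top_changed(results: list[ContrastResult], k: int = 25) -> list[str]:
    """The ``k`` metabolites with the smallest p-values.

    Ties break by larger |log2 fold-change|, then name.
    """
    if not results:
        raise ValueError("no results to rank")
    if k > len(results):
        warnings.warn(f"top_changed: k={k} > {len(results)} metabolites, returning all")
    ranked = sorted(results, key=lambda r: (r.p_value,
                                            -abs(r.log2_fold_change) if np.isfinite(
                                                r.log2_fold_change) else 0.0,
                                            r.metabolite))
    return [r.metabolite for r in ranked[:k]]


def plsda(matrix: pd.DataFrame, labels: pd.Series, n_components: int = 2
          ) -> PlsdaResult:
    """Partial least squares discriminant analysis with VIP scores.

    ``matrix`` is metabolites × samples, already log/Pareto transformed;
    ``labels`` gives the class per sample.  The class response is a
    centered one-hot indicator; components come from NIPALS
    (scikit-learn).  VIP follows the standard definition
    ``VIP_j = sqrt(p * sum_a w_ja^2 SSY_a / sum_a SSY_a)`` so the mean
    squared VIP over the p metabolites is exactly 1.
    """
    classes = pd.unique(labels.dropna())
    if len(classes) < 2:
        raise ValueError("plsda requires at least 2 classes")
    X = matrix.T.loc[labels.index].to_numpy(dtype=float)  # samples × metabolites
    Y = np.zeros((len(labels), len(classes)))
    for k, c in enumerate(classes):
        Y[np.asarray(labels == c), k] = 1.0
    Y = Y - Y.mean(axis=0, keepdims=True)
    Xc = X - X.mean(axis=0, keepdims=True)
    n_components = min(n_components, Xc.shape[0] - 1, Xc.shape[1])

    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xc, Y)
    T = pls.x_scores_  # samples × A
    W = pls.x_weights_  # p × A
    P = pls.x_loadings_
    Q = pls.y_loadings_  # classes × A

    # sum of squares of Y explained per component
    ssy = np.array([(T[:, a] ** 2).sum() * (Q[:, a] ** 2).sum()
                    for a in range(n_components)])
    p_vars = W.shape[0]
    wnorm2 = (W**2) / (W**2).sum(axis=0, keepdims=True)
    vip = np.sqrt(p_vars * (wnorm2 * ssy).sum(axis=1) / ssy.sum())

    total_var = (Xc**2).sum()
    expl = np.array([(np.outer(T[:, a], P[:, a]) ** 2).sum() / total_var
                     for a in range(n_components)])
    comp_names = [f"comp{a + 1}" for a in range(n_components)]
    return PlsdaResult(
        scores=pd.DataFrame(T, index=labels.index, columns=comp_names),
        loadings=pd.DataFrame(P, index=matrix.index, columns=comp_names),
        weights=pd.DataFrame(W, index=matrix.index, columns=comp_names),
        explained_variance=expl,
        vip=pd.Series(vip, index=matrix.index, name="vip"),
    )


def sidak_adjust(p: float, m: int) -> float:
    """Šídák family-wise adjustment: ``1 - (1 - p)^m``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(1.0 - (1.0 - p) ** m)


def anova_sidak(matrix: pd.DataFrame, groups: pd.Series,
                comparisons: list[tuple[str, str]]) -> pd.DataFrame:
    """One-way ANOVA per metabolite with Šídák-adjusted pairwise tests.

    Each requested pair gets a pooled-variance two-sample t p-value,
    adjusted as ``1 - (1 - p)^m`` over the ``m`` requested comparisons.
    Returns a long frame (metabolite, group_a, group_b, p_anova, p_pair,
    p_adjusted, mean_diff).
    """
    known = set(pd.unique(groups.dropna()))
    for a, b in comparisons:
        if a not in known or b not in known:
            raise ValueError(f"unknown group in comparison ({a}, {b})")
    for g in known:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    m = len(comparisons)
    rows = []
    for met in matrix.index:
        by_group = {g: matrix.loc[met, groups.index[groups == g]].dropna().to_numpy(float)
                    for g in known}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                p_anova = float(sps.f_oneway(*by_group.values()).pvalue)
            except Exception:
                p_anova = 1.0
        if not np.isfinite(p_anova):
            p_anova = 1.0
        for a, b in comparisons:
            va, vb = by_group[a], by_group[b]
            if np.ptp(np.concatenate([va, vb])) == 0:
                p_pair = 1.0
            else:
                p_pair = float(sps.ttest_ind(va, vb, equal_var=True).pvalue)
            rows.append((met, a, b, p_anova, p_pair, sidak_adjust(p_pair, m),
                         float(va.mean() - vb.mean())))
    return pd.DataFrame(rows, columns=["metabolite", "group_a", "group_b",
                                       "p_anova", "p_pair", "p_adjusted",
                                       "mean_diff"])
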