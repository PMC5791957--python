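"""Relevancy-based feature selection.

Each feature column F_i of a calibration MP table is scored against the
number of chewing strokes with a relevancy

    q_i = ( |rho(F_i)| + (gamma(F_i) / C(n,2))^2 ) / 2

where ``rho`` is the Spearman rank correlation of the feature with the
stroke count, ``gamma`` counts the Bonferroni-corrected pairwise class
differences confirmed after a significant one-way ANOVA over the ``n``
stroke classes (so 0 <= gamma <= C(n,2)), and the halving maps q into
[0, 1].  Features with q < 0.5 are discarded.  The surviving set can
optionally be reduced further with standardized PCA.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .errors import ParameterError, SelectionError

Q_THRESHOLD = 0.5


@dataclass
class FeatureRelevancy:
    mfc_code: str
    rho: float
    gamma: int
    q: float
    kept: bool
    degenerate: bool = False  # constant feature; rho forced to 0


def spearman_rho(feature_values, stroke_labels) -> tuple[float, bool]:
    """Spearman rank correlation with the stroke count.

    Returns ``(rho, degenerate)``; a constant feature yields rho = 0
    with the degenerate flag set.
    """
    x = np.asarray(feature_values, dtype=np.float64)
    y = np.asarray(stroke_labels, dtype=np.float64)
    if x.size < 3 or np.unique(y).size < 2:
        raise SelectionError("need >=3 samples and >=2 distinct stroke labels")
    if np.all(x == x[0]):
        return 0.0, True
    rho = stats.spearmanr(x, y).statistic
    return float(rho), False


def gamma_count(feature_values, stroke_labels, alpha: float = 0.05) -> int:
    """Number of Bonferroni-significant stroke-class pairs.

    A one-way ANOVA with the stroke count as fixed factor gates the
    pairwise tests: if the omnibus test is not significant at ``alpha``,
    gamma is 0.  Otherwise each class pair is compared with a two-sample
    t-test at the Bonferroni-corrected level ``alpha / C(n,2)``.
    """
    x = np.asarray(feature_values, dtype=np.float64)
    y = np.asarray(stroke_labels)
    classes = np.unique(y)
    groups = [x[y == c] for c in classes]
    if any(len(g) < 2 for g in groups):
        raise SelectionError("every stroke class needs >=2 samples")
    if all(np.all(g == g[0]) for g in groups) and len({g[0] for g in groups}) == 1:
        return 0
    n_pairs = comb(len(classes), 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        omnibus = stats.f_oneway(*groups)
    if not np.isfinite(omnibus.pvalue) or omnibus.pvalue >= alpha:
        return 0
    level = alpha / n_pairs
    gamma = 0
    for i, j in combinations(range(len(classes)), 2):
        with np.errstate(invalid="ignore", divide="ignore"):
            p = stats.ttest_ind(groups[i], groups[j]).pvalue
        if np.isfinite(p) and p < level:
            gamma += 1
    return gamma


def q_score(rho: float, gamma: int, n: int) -> float:
    """Relevancy ``q = (|rho| + (gamma / C(n,2))^2) / 2`` in [0, 1]."""
    if n < 2:
        raise ParameterError("need at least 2 stroke classes")
    n_pairs = comb(n, 2)
    if not -1.0 <= rho <= 1.0:
        raise ParameterError("|rho| must be <= 1")
    if not 0 <= gamma <= n_pairs:
        raise ParameterError(f"gamma must be in [0, {n_pairs}]")
    return (abs(rho) + (gamma / n_pairs) ** 2) / 2.0


def select_features(mp_table: pd.DataFrame, stroke_labels,
                    alpha: float = 0.05) -> tuple[list[str], pd.DataFrame]:
    """Score every MP column; keep those with q >= 0.5.

    Returns ``(kept_codes, relevancy_table)`` with the table sorted by
    q descending.  ``kept_codes`` preserves the original column order so
    downstream feature matrices stay aligned with the registry.
    """
    y = np.asarray(stroke_labels)
    n = int(np.unique(y).size)
    rows = []
    for code in mp_table.columns:
        x = mp_table[code].to_numpy(dtype=np.float64)
        rho, degenerate = spearman_rho(x, y)
        gamma = 0 if degenerate else gamma_count(x, y, alpha=alpha)
        q = q_score(rho, gamma, n)
        rows.append(FeatureRelevancy(
            mfc_code=str(code), rho=rho, gamma=gamma, q=q,
            kept=q >= Q_THRESHOLD, degenerate=degenerate,
        ))
    table = pd.DataFrame([r.__dict__ for r in rows])
    table = table.sort_values("q", ascending=False, kind="stable").reset_index(drop=True)
    kept = [str(c) for c in mp_table.columns
            if bool(table.loc[table.mfc_code == c, "kept"].iloc[0])]
    return kept, table


def pca_reduce(kept_feature_table: pd.DataFrame, n_components: int = 3):
    """Standardized PCA over the kept features.

    Returns ``(scores, loadings, explained_variance_ratio)``; loadings
    are unrotated component weights (features x components).
    """
    if kept_feature_table.shape[1] < 2:
        raise SelectionError("PCA needs at least 2 kept features")
    n_components = min(n_components, *kept_feature_table.shape)
    x = StandardScaler().fit_transform(kept_feature_table.to_numpy(dtype=np.float64))
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(x)
    loadings = pd.DataFrame(
        pca.components_.T, index=kept_feature_table.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return scores, loadings, pca.explained_variance_ratio_
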