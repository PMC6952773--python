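"""Combinatorial MANOVA search for synergistic biomarker panels.

Single features can miss discriminative structure that only appears jointly
(e.g. two proteins whose difference, not their levels, tracks the exposure).
The search tests all combinations of 1–``max_panel`` features from a
candidate pool with multivariate analysis of variance: Wilks' Λ — the ratio
of within-group to total generalized variance — with Rao's F approximation
(exact for two groups).  A panel is flagged synergistic when its p-value
beats every member's singleton p-value.

Testing every combination over thousands of features is combinatorially
impossible, so the pool is restricted to the top ``pool_size`` features by
univariate p-value; the restriction is recorded in the result metadata.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SingularityError, StatisticsError
from .preprocess import OmicsLayer, log2_with_floor

__all__ = ["ManovaResult", "manova_test", "search_panels"]


@dataclass(frozen=True)
class ManovaResult:
    wilks_lambda: float
    f_statistic: float
    pvalue: float
    df1: float
    df2: float


def manova_test(
    X: np.ndarray,
    labels: Sequence,
    cond_threshold: float = 1e12,
    feature_names: Sequence[str] | None = None,
) -> ManovaResult:
    """Wilks' Λ MANOVA of an (n_samples, n_features) matrix against labels.

    Uses Rao's F approximation, which is exact for two groups (and reduces
    to the one-way ANOVA F for a single feature).  Near-singular total
    scatter (condition number above ``cond_threshold``, e.g. duplicated or
    collinear panel members) raises :class:`SingularityError` naming the
    features.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    n, p = X.shape
    groups = np.unique(labels)
    g = len(groups)
    if g < 2:
        raise StatisticsError("MANOVA needs at least two groups")
    if n <= p + g:
        raise StatisticsError(
            f"MANOVA needs n_samples > n_features + n_groups ({n} <= {p} + {g})"
        )
    names = list(feature_names) if feature_names is not None else [f"x{i}" for i in range(p)]

    grand = X.mean(axis=0)
    T = (X - grand).T @ (X - grand)
    W = np.zeros((p, p))
    for grp in groups:
        sub = X[labels == grp]
        centered = sub - sub.mean(axis=0)
        W += centered.T @ centered
    if np.linalg.cond(T) > cond_threshold:
        raise SingularityError(
            f"near-singular panel {names}: collinear or constant features"
        )
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_w <= 0 or sign_t <= 0:
        raise SingularityError(f"degenerate scatter for panel {names}")
    wilks = float(np.exp(logdet_w - logdet_t))

    # Rao's F approximation
    q = g - 1
    t_num = p * p * q * q - 4.0
    t_den = p * p + q * q - 5.0
    t = np.sqrt(t_num / t_den) if t_den > 0 else 1.0
    w = n - 1 - (p + g) / 2.0
    df1 = p * q
    df2 = w * t - (df1 - 2.0) / 2.0
    lam_t = wilks ** (1.0 / t)
    f_stat = (1.0 - lam_t) / lam_t * (df2 / df1)
    pvalue = float(stats.f.sf(f_stat, df1, df2))
    return ManovaResult(wilks, float(f_stat), pvalue, float(df1), float(df2))


def search_panels(
    layer: OmicsLayer,
    metadata: pd.DataFrame,
    group: str | None = None,
    condition_col: str = "condition",
    pool_size: int = 20,
    max_panel: int = 6,
) -> pd.DataFrame:
    """Exhaustive MANOVA over all 1–``max_panel`` combinations from a pool.

    The candidate pool is the ``pool_size`` features with the smallest
    univariate one-way ANOVA p-value (on log2 intensities) for the condition
    labels; within the pool every combination is tested and the table is
    ranked by panel p ascending.  Panel sizes infeasible for the sample
    count are skipped and listed in ``result.attrs['skipped_sizes']``;
    singular panels are dropped and counted in ``attrs['n_singular']``.
    """
    meta = metadata
    if group is not None:
        meta = meta[meta["group"] == group]
    meta = meta[meta["sample_id"].isin(layer.samples)]
    labels = meta[condition_col].to_numpy()
    samples = meta["sample_id"].tolist()
    n_groups = len(np.unique(labels))
    if n_groups < 2 or min(np.bincount(pd.factorize(labels)[0])) < 2:
        raise StatisticsError("need >=2 samples in each of >=2 condition groups")
    if pool_size < max_panel:
        raise StatisticsError(
            f"pool_size {pool_size} smaller than max_panel {max_panel}"
        )
    X_all = log2_with_floor(layer.values)[samples].to_numpy().T  # samples x features
    n = len(samples)

    # univariate screen: one-way ANOVA per feature
    group_arrays = [X_all[labels == grp] for grp in np.unique(labels)]
    _, uni_p = stats.f_oneway(*group_arrays, axis=0)
    uni_p = np.where(np.isfinite(uni_p), uni_p, 1.0)
    screen = pd.Series(uni_p, index=layer.features).sort_values(kind="mergesort")
    pool = list(screen.index[: min(pool_size, len(screen))])
    pool_idx = {f: i for i, f in enumerate(layer.features)}

    singleton_p: dict[str, float] = {}
    rows = []
    skipped_sizes = []
    n_singular = 0
    for size in range(1, max_panel + 1):
        if n <= size + n_groups:
            skipped_sizes.append(size)
            continue
        for panel in combinations(pool, size):
            idx = [pool_idx[f] for f in panel]
            try:
                res = manova_test(X_all[:, idx], labels, feature_names=panel)
            except SingularityError:
                n_singular += 1
                continue
            if size == 1:
                singleton_p[panel[0]] = res.pvalue
            rows.append(
                {
                    "panel": "+".join(panel),
                    "size": size,
                    "wilks_lambda": res.wilks_lambda,
                    "F": res.f_statistic,
                    "p": res.pvalue,
                    "members": panel,
                }
            )
    result = pd.DataFrame(rows)
    if len(result):
        from statsmodels.stats.multitest import multipletests

        result["bh"] = multipletests(result["p"].to_numpy(), method="fdr_bh")[1]
        result["synergy"] = [
            row["size"] > 1
            and all(m in singleton_p for m in row["members"])
            and row["p"] < min(singleton_p[m] for m in row["members"])
            for _, row in result.iterrows()
        ]
        result = result.sort_values(["p", "panel"], kind="mergesort").reset_index(drop=True)
    result.attrs["pool"] = pool
    result.attrs["pool_size"] = pool_size
    result.attrs["max_panel"] = max_panel
    result.attrs["skipped_sizes"] = skipped_sizes
    result.attrs["n_singular"] = n_singular
    return result
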