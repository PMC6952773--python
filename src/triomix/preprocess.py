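"""Quantitative-table preprocessing and sample-level structure.

This module normalizes intensity matrices under an equal total-ion-count
assumption, removes proteins identified by a single unique peptide, computes
per-feature differential statistics for a hypoxia-vs-normoxia contrast, and
summarizes sample structure with PCA and silhouette-guided K-means.

Differential calls follow the thresholds used throughout the analysis: a
feature is significant when its linear fold change departs from 1 by more
than ``min_change`` (default 15%) and the two-sided p-value is below
``alpha`` (default 0.05).  The location test is a Welch two-sample t-test on
log2 intensities: variances are not assumed equal across conditions, which
is the conservative default for small replicate groups.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .errors import (
    DegenerateInputError,
    InputError,
    NormalizationError,
    ParameterError,
    StatisticsError,
)

__all__ = [
    "OmicsLayer",
    "log2_with_floor",
    "tic_normalize",
    "filter_singletons",
    "differential_test",
    "pca_project",
    "PCAResult",
    "kmeans_silhouette",
    "KMeansSelection",
]

LAYER_TAGS = ("transcript", "protein", "metabolite")


@dataclass
class OmicsLayer:
    """One quantitative feature-by-sample matrix with a layer tag.

    ``values`` holds non-negative intensities (features in rows).  Protein
    layers may carry a per-feature unique-peptide count used by
    :func:`filter_singletons`.
    """

    tag: str
    values: pd.DataFrame
    unique_peptides: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.tag not in LAYER_TAGS:
            raise InputError(f"unknown layer tag {self.tag!r}; expected one of {LAYER_TAGS}")
        if self.values.index.has_duplicates:
            raise InputError(f"{self.tag} layer has duplicate feature ids")
        if self.values.columns.has_duplicates:
            raise InputError(f"{self.tag} layer has duplicate sample ids")
        if (self.values.to_numpy() < 0).any():
            raise InputError(f"{self.tag} layer contains negative intensities")
        if self.unique_peptides is not None:
            if not self.unique_peptides.index.equals(self.values.index):
                raise InputError(
                    f"{self.tag} layer: unique-peptide counts do not cover the feature index"
                )

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def select_features(self, features: Sequence[str]) -> "OmicsLayer":
        up = None if self.unique_peptides is None else self.unique_peptides.loc[list(features)]
        return OmicsLayer(self.tag, self.values.loc[list(features)], up)


def log2_with_floor(values: pd.DataFrame) -> pd.DataFrame:
    """log2 transform with zeros replaced by half the smallest positive value.

    The replacement keeps zero intensities finite on the log scale without
    imputing structure; layers with no positive entry are rejected.
    """
    arr = values.to_numpy(dtype=float)
    positive = arr[arr > 0]
    if positive.size == 0:
        raise DegenerateInputError("matrix has no positive intensities")
    floor = positive.min() / 2.0
    return pd.DataFrame(
        np.log2(np.where(arr > 0, arr, floor)), index=values.index, columns=values.columns
    )


def tic_normalize(layer: OmicsLayer) -> OmicsLayer:
    """Rescale each sample column so all column totals equal the mean total.

    Emulates per-experiment normalization under an equal total-ion-count
    assumption: within-sample feature proportions are unchanged.
    """
    totals = layer.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise NormalizationError(
            f"{layer.tag} layer: sample {zero.index[0]!r} has non-positive total intensity"
        )
    target = totals.to_numpy().mean()
    scaled = layer.values * (target / totals)
    return OmicsLayer(layer.tag, scaled, layer.unique_peptides)


def filter_singletons(layer: OmicsLayer) -> OmicsLayer:
    """Drop features identified by a single unique peptide (count < 2)."""
    if layer.unique_peptides is None:
        raise InputError(f"{layer.tag} layer has no unique-peptide counts; cannot filter singlets")
    keep = layer.unique_peptides[layer.unique_peptides >= 2].index
    return layer.select_features(list(keep))


def differential_test(
    layer: OmicsLayer,
    metadata: pd.DataFrame,
    contrast: tuple[str, str] = ("hypoxia", "normoxia"),
    group: str | None = None,
    min_change: float = 0.15,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature differential statistics for ``contrast`` = (numerator, denominator).

    Returns a frame indexed by feature with columns ``ratio`` (linear-scale
    mean ratio, numerator over denominator), ``log2_ratio``, ``t`` (signed
    Welch statistic on log2 intensities), ``p`` (two-sided) and
    ``significant`` (|ratio − 1| > min_change and p < alpha).

    ``metadata`` needs columns ``sample_id``, ``group`` and ``condition``;
    ``group=None`` pools all groups (used for the persistent-change analysis).
    """
    numerator, denominator = contrast
    meta = metadata
    if group is not None:
        meta = meta[meta["group"] == group]
    meta = meta[meta["sample_id"].isin(layer.samples)]
    num_samples = meta.loc[meta["condition"] == numerator, "sample_id"].tolist()
    den_samples = meta.loc[meta["condition"] == denominator, "sample_id"].tolist()
    if len(num_samples) < 2 or len(den_samples) < 2:
        raise StatisticsError(
            f"{layer.tag} layer: need >=2 samples per condition for contrast "
            f"{numerator}:{denominator}"
            + (f" within group {group!r}" if group else "")
        )
    log_values = log2_with_floor(layer.values)
    a = log_values[num_samples].to_numpy()
    b = log_values[den_samples].to_numpy()
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # degenerate features (zero variance in both conditions) yield NaN: treat as no evidence
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)

    # linear-scale ratio on zero-floored intensities (means of linear values)
    floored = np.power(2.0, log_values.to_numpy())
    frame = pd.DataFrame(floored, index=layer.features, columns=log_values.columns)
    ratio = frame[num_samples].mean(axis=1) / frame[den_samples].mean(axis=1)

    result = pd.DataFrame(
        {
            "ratio": ratio,
            "log2_ratio": np.log2(ratio),
            "t": t,
            "p": p,
        },
        index=layer.features,
    )
    result["significant"] = (np.abs(result["ratio"] - 1.0) > min_change) & (result["p"] < alpha)
    return result


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # features x components


def pca_project(
    layer: OmicsLayer | pd.DataFrame,
    n_components: int,
    log_transform: bool = True,
) -> PCAResult:
    """Project samples onto principal axes of the column-centered log matrix.

    Samples are the observations (one point per sample column); explained
    variance fractions are non-increasing and sum to at most 1.
    """
    values = layer.values if isinstance(layer, OmicsLayer) else layer
    X = (log2_with_floor(values) if log_transform else values).to_numpy().T
    n_samples, n_features = X.shape
    if n_components > min(n_samples, n_features):
        raise ParameterError(
            f"n_components={n_components} exceeds min(n_features={n_features}, "
            f"n_samples={n_samples})"
        )
    if np.allclose(X.var(axis=0).sum(), 0.0):
        raise DegenerateInputError("constant matrix: PCA is undefined")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=values.columns, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        loadings=pd.DataFrame(pca.components_.T, index=values.index, columns=cols),
    )


@dataclass
class KMeansSelection:
    k: int
    labels: np.ndarray
    silhouettes: dict[int, float] = field(default_factory=dict)


def kmeans_silhouette(
    points: np.ndarray,
    k_range: Iterable[int] = range(2, 11),
    n_init: int = 25,
    random_state: int = 0,
) -> KMeansSelection:
    """K-means over a range of k, choosing the k with the best mean silhouette.

    Ties go to the smallest k.  Each k runs ``n_init`` restarts from a fixed
    base seed so the selection is reproducible.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise InputError("points must be a 2-D array (n_points, n_dims)")
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ParameterError("empty k range")
    n = pts.shape[0]
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ParameterError(f"k range {ks[0]}..{ks[-1]} outside [2, n_points-1={n - 1}]")
    n_distinct = np.unique(pts, axis=0).shape[0]
    if n_distinct < ks[-1]:
        raise InputError(
            f"only {n_distinct} distinct points but k up to {ks[-1]} requested"
        )
    best_k, best_s, best_labels = None, -np.inf, None
    silhouettes: dict[int, float] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=random_state)
        labels = km.fit_predict(pts)
        s = float(silhouette_score(pts, labels)) if len(np.unique(labels)) > 1 else -1.0
        silhouettes[k] = s
        if s > best_s:  # strict: ties keep the smaller k
            best_k, best_s, best_labels = k, s, labels
    assert best_k is not None and best_labels is not None
    return KMeansSelection(k=best_k, labels=best_labels, silhouettes=silhouettes)
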