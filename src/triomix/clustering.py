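"""Seeded t-SNE embedding, outlier-cluster extraction, and set enrichment.

Feature profiles (one point per gene/protein, one dimension per sample or
sample-group summary) are embedded in 2-D with t-SNE run several times from
different seeds; cluster stability is summarized as the mean pairwise
adjusted Rand index of density-based labels across runs.  Clusters that
separate from the main data stream are extracted by consensus over the runs
and directed by the sign of their mean fetal-minus-adult profile: group 1 is
up in fetal samples, group 2 down.  Extracted (or any) query sets are tested
for annotation enrichment with a one-sided hypergeometric test and
Benjamini–Hochberg FDR control.

The density rule that draws cluster boundaries on the t-SNE plane is a
reproducible stand-in for the visual inspection such plots usually get; its
radius and minimum size are exposed and its use is recorded in the outputs.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .errors import InputError, ParameterError

__all__ = [
    "EmbeddingResult",
    "tsne_embed",
    "density_labels",
    "ClusterAssignment",
    "extract_outlier_clusters",
    "enrich",
]


@dataclass
class EmbeddingResult:
    """Coordinates and density labels for each seeded t-SNE run."""

    feature_ids: list[str]
    coordinates: list[np.ndarray]  # one (n_features, 2) array per run
    seeds: list[int]
    run_labels: np.ndarray  # (n_runs, n_features) density-cluster labels, -1 = noise
    stability: float  # mean pairwise adjusted Rand index across runs

    @property
    def n_runs(self) -> int:
        return len(self.coordinates)


def density_labels(
    coords: np.ndarray,
    knn: int = 5,
    radius_quantile: float = 0.9,
    min_cluster_size: int = 5,
) -> np.ndarray:
    """DBSCAN labels on 2-D coordinates with a data-driven radius.

    The neighborhood radius is the ``radius_quantile`` quantile of each
    point's distance to its ``knn``-th neighbor — scale-free across t-SNE
    runs, whose absolute coordinates are meaningless.
    """
    coords = np.asarray(coords, dtype=float)
    nn = NearestNeighbors(n_neighbors=knn + 1).fit(coords)
    dist, _ = nn.kneighbors(coords)
    eps = float(np.quantile(dist[:, -1], radius_quantile))
    if eps <= 0:
        eps = np.finfo(float).eps
    return DBSCAN(eps=eps, min_samples=min_cluster_size).fit_predict(coords)


def tsne_embed(
    profiles: pd.DataFrame,
    perplexity: float = 20.0,
    n_pca: int = 50,
    exaggeration: float = 4.0,
    n_runs: int = 15,
    base_seed: int = 0,
    min_cluster_size: int = 5,
) -> EmbeddingResult:
    """Repeated seeded t-SNE of feature profiles (rows = features).

    Profiles are first reduced to at most ``n_pca`` principal components
    (all available dimensions when fewer exist); run *i* is seeded
    ``base_seed + i``.  ``exaggeration`` is applied as t-SNE's
    early-exaggeration factor, which inflates attractive forces early in the
    optimisation so well-separated clusters detach cleanly.
    """
    X = profiles.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise InputError("profiles contain non-finite values")
    n_features = X.shape[0]
    if perplexity >= (n_features - 1) / 3:
        raise ParameterError(
            f"perplexity {perplexity} too large for {n_features} features "
            f"(needs perplexity < (n_features-1)/3)"
        )
    n_comp = min(n_pca, X.shape[1], n_features)
    if n_comp < X.shape[1]:
        X = PCA(n_components=n_comp, svd_solver="full").fit_transform(X)

    coordinates, labels = [], []
    seeds = [base_seed + i for i in range(n_runs)]
    for seed in seeds:
        emb = TSNE(
            n_components=2,
            perplexity=perplexity,
            early_exaggeration=exaggeration,
            random_state=seed,
            init="pca",
        ).fit_transform(X)
        coordinates.append(np.asarray(emb, dtype=float))
        labels.append(density_labels(emb, min_cluster_size=min_cluster_size))
    run_labels = np.vstack(labels)
    pairs = [
        adjusted_rand_score(run_labels[i], run_labels[j])
        for i in range(n_runs)
        for j in range(i + 1, n_runs)
    ]
    stability = float(np.mean(pairs)) if pairs else 1.0
    return EmbeddingResult(
        feature_ids=[str(f) for f in profiles.index],
        coordinates=coordinates,
        seeds=seeds,
        run_labels=run_labels,
        stability=stability,
    )


@dataclass
class ClusterAssignment:
    """Consensus outlier-cluster labels with direction.

    ``labels`` maps each feature to ``group1`` (up in fetal), ``group2``
    (down in fetal) or ``background`` (the main data stream, including
    density noise).  ``status`` records degenerate outcomes and stability
    warnings.
    """

    labels: dict[str, str]
    cluster_direction: dict[int, str]
    consensus: np.ndarray
    status: str = "ok"

    def members(self, label: str) -> list[str]:
        return sorted(f for f, l in self.labels.items() if l == label)


def align_run_labels(run_labels: np.ndarray, reference_run: int = 0) -> np.ndarray:
    """Relabel every run's clusters to best-overlap clusters of a reference run."""
    aligned = np.full_like(run_labels, -1)
    ref = run_labels[reference_run]
    for r in range(run_labels.shape[0]):
        for cluster in np.unique(run_labels[r]):
            if cluster == -1:
                continue
            mask = run_labels[r] == cluster
            overlap = Counter(ref[mask].tolist())
            target, _ = max(overlap.items(), key=lambda kv: (kv[1], -kv[0]))
            aligned[r, mask] = target
    return aligned


def consensus_labels(aligned: np.ndarray) -> np.ndarray:
    """Per-feature majority vote over aligned run labels (ties to smaller label)."""
    n = aligned.shape[1]
    out = np.empty(n, dtype=int)
    for j in range(n):
        votes = Counter(aligned[:, j].tolist())
        out[j] = min(
            votes, key=lambda lab: (-votes[lab], lab)
        )
    return out


def extract_outlier_clusters(
    embedding: EmbeddingResult,
    fetal_minus_adult: pd.Series,
    stability_min: float = 0.8,
    min_cluster_size: int = 5,
) -> ClusterAssignment:
    """Extract clusters separated from the main data stream and direct them.

    Per-run density labels are aligned to the first run and combined by
    majority vote; the largest consensus cluster (plus noise) is the
    background stream.  Each remaining cluster is labeled ``group1`` when
    the mean fetal-minus-adult profile of its members is positive and
    ``group2`` otherwise.  A stability below ``stability_min`` does not
    abort extraction but is flagged in ``status``.
    """
    status = "ok" if embedding.stability >= stability_min else "low_stability"
    n_clusters_per_run = [
        len(set(row.tolist()) - {-1}) for row in embedding.run_labels
    ]
    if all(n <= 1 for n in n_clusters_per_run):
        return ClusterAssignment(
            labels={f: "background" for f in embedding.feature_ids},
            cluster_direction={},
            consensus=np.full(len(embedding.feature_ids), -1),
            status="no_clusters",
        )
    aligned = align_run_labels(embedding.run_labels)
    consensus = consensus_labels(aligned)

    sizes = Counter(consensus[consensus >= 0].tolist())
    background_cluster = max(sizes, key=lambda lab: (sizes[lab], -lab)) if sizes else -1
    directions: dict[int, str] = {}
    labels: dict[str, str] = {}
    fm = fetal_minus_adult.reindex(embedding.feature_ids)
    for cluster in sorted(sizes):
        if cluster == background_cluster or sizes[cluster] < min_cluster_size:
            continue
        members = [
            f for f, c in zip(embedding.feature_ids, consensus) if c == cluster
        ]
        mean_dir = float(fm.loc[members].mean())
        directions[cluster] = "group1" if mean_dir > 0 else "group2"
    for f, c in zip(embedding.feature_ids, consensus):
        labels[f] = directions.get(int(c), "background")
    if not directions:
        status = "no_clusters"
    return ClusterAssignment(
        labels=labels, cluster_direction=directions, consensus=consensus, status=status
    )


def enrich(
    query: Iterable[str],
    annotation_db: Mapping[str, tuple[str, Sequence[str]]] | Mapping[str, Sequence[str]],
    universe: Iterable[str],
    min_term_size: int = 3,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``query`` against annotation terms.

    Terms are intersected with the universe first and skipped when fewer
    than ``min_term_size`` members remain.  Returns one row per tested term:
    ``k`` (hits in query), ``K`` (term size in universe), ``count_in_set``
    ("k/K"), ``p`` (upper tail) and BH ``fdr``, sorted by p then term id.
    """
    universe_set = set(universe)
    if not universe_set:
        raise InputError("empty universe")
    query_set = set(query)
    if not query_set <= universe_set:
        extra = sorted(query_set - universe_set)
        raise InputError(f"query not contained in universe (e.g. {extra[:5]})")
    N, n = len(universe_set), len(query_set)
    rows = []
    for term in sorted(annotation_db):
        entry = annotation_db[term]
        members = entry[1] if isinstance(entry, tuple) else entry
        term_set = set(members) & universe_set
        K = len(term_set)
        if K < min_term_size:
            continue
        k = len(term_set & query_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "count_in_set": f"{k}/{K}", "p": p})
    result = pd.DataFrame(rows, columns=["term", "k", "K", "count_in_set", "p"])
    if len(result):
        result["fdr"] = multipletests(result["p"].to_numpy(), method="fdr_bh")[1]
        result = result.sort_values(["p", "term"]).reset_index(drop=True)
    else:
        result["fdr"] = []
    return result
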