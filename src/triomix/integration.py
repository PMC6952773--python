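"""Pathway-level integration of the three omics layers.

Every layer is mapped onto pathways through genes: metabolites via the
pathway's metabolite members, proteins via their gene ids, and transcripts
via gene clusters (groups of genes similar in sequence and function, in the
KEGG SSDB sense).  For each pathway a per-layer p-value is computed with a
competitive permutation test on the mean absolute differential statistic of
its members; the per-layer p-values are combined with Fisher's method
(X² = −2 Σ ln pᵢ against chi-square with 2k degrees of freedom, treating
each omics layer as an independent observation of the same system), and the
combined scores are ranked under a per-entity assignment cap that removes
repetitive use of the same data point across overlapping pathways.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InputError, ParameterError

__all__ = [
    "PathwayDefinition",
    "map_layers",
    "MembershipTables",
    "pathway_pvalue",
    "PathwayPValue",
    "score_pathways",
    "fisher_combine",
    "FisherResult",
    "dp_rank",
    "AssignmentSolution",
    "rank_report",
    "integrated_significant_features",
]


@dataclass(frozen=True)
class PathwayDefinition:
    """A pathway with gene and metabolite members."""

    pathway_id: str
    genes: frozenset[str]
    metabolites: frozenset[str] = frozenset()
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.genes and not self.metabolites:
            raise InputError(f"pathway {self.pathway_id!r} has no members")


@dataclass
class MembershipTables:
    """Entity-to-pathway memberships plus the features that mapped nowhere.

    ``memberships`` has one row per (entity, layer, pathway); entity ids are
    layer-tagged (``protein:Gxxx``, ``transcript:Gxxx``, ``metabolite:Mxxx``)
    so the assignment cap treats each omics data point independently.
    """

    memberships: pd.DataFrame
    unmapped: pd.DataFrame

    def features_by_layer(self, pathway_id: str) -> dict[str, list[str]]:
        """Member feature ids per layer for one pathway."""
        sub = self.memberships[self.memberships["pathway"] == pathway_id]
        out: dict[str, list[str]] = {}
        for layer, grp in sub.groupby("layer"):
            out[str(layer)] = sorted(grp["feature"].unique())
        return out

    def entities_by_pathway(self) -> dict[str, frozenset[str]]:
        out: dict[str, frozenset[str]] = {}
        for pw, grp in self.memberships.groupby("pathway"):
            out[str(pw)] = frozenset(grp["entity"])
        return out


def map_layers(
    layers: Mapping[str, "object"],
    pathway_db: Sequence[PathwayDefinition],
    gene_cluster_map: Mapping[str, str] | None = None,
) -> MembershipTables:
    """Map quantified features of each layer onto pathways.

    ``layers`` maps layer tags to :class:`~triomix.preprocess.OmicsLayer`.
    Proteins join a pathway when their gene is a member; transcripts when any
    gene of their cluster is a member; metabolites when listed among the
    pathway's metabolite members.  Features matching no pathway end up in the
    ``unmapped`` table — a valid outcome, not an error.
    """
    if not pathway_db:
        raise InputError("empty pathway database")
    gene_cluster_map = dict(gene_cluster_map or {})
    cluster_of = lambda g: gene_cluster_map.get(g, f"__self__:{g}")
    cluster_members: dict[str, set[str]] = {}
    for gene, cluster in gene_cluster_map.items():
        cluster_members.setdefault(cluster, set()).add(gene)

    rows: list[tuple[str, str, str, str]] = []
    unmapped_rows: list[tuple[str, str]] = []
    for tag, layer in layers.items():
        features = list(layer.features)
        for feat in features:
            hits: list[str] = []
            if tag == "metabolite":
                hits = [pw.pathway_id for pw in pathway_db if feat in pw.metabolites]
            elif tag == "protein":
                hits = [pw.pathway_id for pw in pathway_db if feat in pw.genes]
            elif tag == "transcript":
                mates = cluster_members.get(cluster_of(feat), {feat}) | {feat}
                hits = [pw.pathway_id for pw in pathway_db if mates & pw.genes]
            else:
                raise InputError(f"unknown layer tag {tag!r}")
            if hits:
                for pw_id in hits:
                    rows.append((f"{tag}:{feat}", tag, feat, pw_id))
            else:
                unmapped_rows.append((feat, tag))
    memberships = pd.DataFrame(rows, columns=["entity", "layer", "feature", "pathway"])
    unmapped = pd.DataFrame(unmapped_rows, columns=["feature", "layer"])
    return MembershipTables(memberships=memberships, unmapped=unmapped)


@dataclass(frozen=True)
class PathwayPValue:
    p: float
    n_members: int
    observed: float
    method: str  # "exact" (full subset enumeration) or "sampled"


def pathway_pvalue(
    feature_stats: pd.Series,
    members: Sequence[str],
    n_permutations: int = 10_000,
    rng: np.random.Generator | None = None,
    exact_limit: int = 50_000,
) -> PathwayPValue:
    """Competitive permutation p-value for one pathway in one layer.

    The pathway score is the mean absolute differential statistic of its
    members; the p-value is the tail probability that a random member set of
    equal size drawn from all scored features has a mean at least as large.
    When the number of possible member sets is at most ``exact_limit`` the
    tail is enumerated exactly (the observed set counts itself, so p is at
    least 1/C(n, k)); otherwise ``n_permutations`` random sets are drawn and
    the +1 continuity correction puts p on [1/(B+1), 1].
    """
    members = [m for m in members if m in feature_stats.index]
    if not members:
        raise InputError("pathway has no members with statistics")
    scores = np.abs(feature_stats.to_numpy(dtype=float))
    member_scores = np.abs(feature_stats.loc[members].to_numpy(dtype=float))
    k = len(members)
    n = scores.size
    if k > n:
        raise InputError("more members than scored features")
    observed = float(member_scores.mean())

    n_sets = math.comb(n, k)
    if n_sets <= exact_limit:
        count = 0
        for combo in combinations(range(n), k):
            if scores[list(combo)].mean() >= observed:
                count += 1
        return PathwayPValue(p=count / n_sets, n_members=k, observed=observed, method="exact")

    if n_permutations < 1:
        raise ParameterError("n_permutations must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    # vectorized sampling without replacement: k smallest of a random key per row
    keys = rng.random((n_permutations, n))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    perm_means = scores[idx].mean(axis=1)
    count = int(np.sum(perm_means >= observed))
    p = (1 + count) / (n_permutations + 1)
    return PathwayPValue(p=p, n_members=k, observed=observed, method="sampled")


@dataclass(frozen=True)
class FisherResult:
    statistic: float
    df: int
    pvalue: float


def fisher_combine(p_values: Sequence[float]) -> FisherResult:
    """Fisher's combined probability test: X² = −2 Σ ln pᵢ, df = 2k."""
    ps = [float(p) for p in p_values]
    if not ps:
        raise InputError("no p-values to combine")
    for p in ps:
        if not (0.0 < p <= 1.0):
            raise ParameterError(f"p-value {p} outside (0, 1]")
    x2 = -2.0 * sum(math.log(p) for p in ps)
    df = 2 * len(ps)
    combined = float(stats.chi2.sf(x2, df))
    return FisherResult(statistic=x2, df=df, pvalue=combined)


def score_pathways(
    layer_stats: Mapping[str, pd.Series],
    membership: MembershipTables,
    pathway_ids: Iterable[str] | None = None,
    min_members: int = 3,
    n_permutations: int = 10_000,
    rng: np.random.Generator | None = None,
    exact_limit: int = 50_000,
) -> pd.DataFrame:
    """Per-layer permutation p-values and Fisher combination for every pathway.

    Layers contributing fewer than ``min_members`` mapped features to a
    pathway are omitted from the combination for that pathway (the degrees of
    freedom shrink rather than imputing p = 1); pathways with no testable
    layer are reported with NaN combined p (not testable).
    """
    rng = np.random.default_rng() if rng is None else rng
    if pathway_ids is None:
        pathway_ids = sorted(membership.memberships["pathway"].unique())
    rows = []
    for pw_id in pathway_ids:
        by_layer = membership.features_by_layer(pw_id)
        per_layer_p: dict[str, float] = {}
        for tag, series in layer_stats.items():
            members = [m for m in by_layer.get(tag, []) if m in series.index]
            if len(members) < min_members:
                continue
            res = pathway_pvalue(
                series, members, n_permutations=n_permutations, rng=rng, exact_limit=exact_limit
            )
            per_layer_p[tag] = res.p
        if per_layer_p:
            fisher = fisher_combine(list(per_layer_p.values()))
            stat, df, comb = fisher.statistic, fisher.df, fisher.pvalue
        else:
            stat, df, comb = np.nan, 0, np.nan
        row = {"pathway": pw_id, "statistic": stat, "df": df, "combined_p": comb}
        for tag in layer_stats:
            row[f"p_{tag}"] = per_layer_p.get(tag, np.nan)
        rows.append(row)
    return pd.DataFrame(rows).set_index("pathway")


@dataclass
class AssignmentSolution:
    """Result of assignment-capped pathway selection.

    ``retained`` is ordered by (score desc, assigned entities desc, id) and
    defines the post-deduplication rank; ``objective`` is the sum of retained
    pathway scores (−log10 combined p).
    """

    retained: tuple[str, ...]
    assignments: dict[str, tuple[str, ...]]
    objective: float
    regime: str  # "exact" or "greedy"
    n_assigned: dict[str, int] = field(default_factory=dict)


def _flow_feasible(
    subset: Sequence[str],
    members: Mapping[str, frozenset[str]],
    cap: int,
    min_members: int,
) -> dict[str, list[str]] | None:
    """Feasibility of retaining ``subset``: every pathway can keep at least
    ``min_members`` entities with no entity claimed more than ``cap`` times.

    Solved as a max-flow problem (source → entity [cap] → pathway [1] →
    sink [min_members]); returns a minimal witness assignment or None.
    """
    entities = sorted(set().union(*(members[p] for p in subset)) if subset else set())
    G = nx.DiGraph()
    for e in entities:
        G.add_edge("S", f"e:{e}", capacity=cap)
    for p in subset:
        if len(members[p]) < min_members:
            return None
        G.add_edge(f"p:{p}", "T", capacity=min_members)
        for e in members[p]:
            G.add_edge(f"e:{e}", f"p:{p}", capacity=1)
    if not subset:
        return {}
    value, flow = nx.maximum_flow(G, "S", "T")
    if value < min_members * len(subset):
        return None
    witness: dict[str, list[str]] = {p: [] for p in subset}
    for e in entities:
        for p, amount in flow.get(f"e:{e}", {}).items():
            if amount > 0 and p.startswith("p:"):
                witness[p[2:]].append(e)
    return witness


def dp_rank(
    scores: Mapping[str, float],
    members: Mapping[str, frozenset[str] | set[str]],
    cap: int = 2,
    min_members: int = 3,
    regime: str = "auto",
    exact_max_pathways: int = 16,
) -> AssignmentSolution:
    """Select and rank pathways under a per-entity assignment cap.

    Maximizes the summed pathway score (−log10 combined p) over retained
    pathways subject to: each entity is assigned to at most ``cap`` retained
    pathways, and each retained pathway keeps at least ``min_members``
    assigned entities.  Small instances are solved exactly (subsets examined
    in decreasing total-score order; because feasibility is closed under
    taking subsets, the first feasible subset is optimal).  Larger instances
    use a documented greedy: pathways are processed in decreasing score
    order, claim their members' remaining capacity, and are dropped when
    fewer than ``min_members`` entities remain available.
    """
    if cap < 1:
        raise ConfigurationError(f"assignment cap must be >= 1, got {cap}")
    if min_members < 1:
        raise ConfigurationError(f"min_members must be >= 1, got {min_members}")
    members = {p: frozenset(ms) for p, ms in members.items()}
    candidates = [
        p for p in scores if p in members and len(members[p]) >= min_members
        and np.isfinite(scores[p])
    ]
    # deterministic processing order: score desc, member count desc, id asc
    order = sorted(candidates, key=lambda p: (-scores[p], -len(members[p]), p))

    if regime == "auto":
        regime = "exact" if len(order) <= exact_max_pathways else "greedy"
    if regime not in ("exact", "greedy"):
        raise ConfigurationError(f"unknown regime {regime!r}")

    if regime == "exact":
        retained, witness = _exact_select(order, scores, members, cap, min_members)
    else:
        retained, witness = _greedy_select(order, members, cap, min_members)

    # fill up: give entities with spare capacity their other retained pathways
    entity_pool = set().union(*(members[p] for p in retained)) if retained else set()
    counts = {e: 0 for e in entity_pool}
    assignments: dict[str, list[str]] = {e: [] for e in counts}
    for p in retained:
        for e in witness[p]:
            assignments[e].append(p)
            counts[e] += 1
    by_rank = sorted(retained, key=lambda p: (-scores[p], -len(witness[p]), p))
    for p in by_rank:
        for e in sorted(members[p]):
            if e in counts and counts[e] < cap and p not in assignments[e]:
                assignments[e].append(p)
                counts[e] += 1
    n_assigned = {p: sum(1 for e, pws in assignments.items() if p in pws) for p in retained}
    ordered = tuple(sorted(retained, key=lambda p: (-scores[p], -n_assigned[p], p)))
    objective = float(sum(scores[p] for p in retained))
    return AssignmentSolution(
        retained=ordered,
        assignments={e: tuple(pws) for e, pws in sorted(assignments.items())},
        objective=objective,
        regime=regime,
        n_assigned=n_assigned,
    )


def _exact_select(order, scores, members, cap, min_members):
    n = len(order)
    subsets = []
    for mask in range(1 << n):
        subset = tuple(order[i] for i in range(n) if mask >> i & 1)
        total = sum(scores[p] for p in subset)
        subsets.append((total, subset))
    # decreasing objective; prefer larger subsets, then lexicographic ids
    subsets.sort(key=lambda ts: (-ts[0], -len(ts[1]), ts[1]))
    for total, subset in subsets:
        witness = _flow_feasible(subset, members, cap, min_members)
        if witness is not None:
            return list(subset), witness
    return [], {}


def _greedy_select(order, members, cap, min_members):
    capacity: dict[str, int] = {}
    for p in order:
        for e in members[p]:
            capacity.setdefault(e, cap)
    retained: list[str] = []
    witness: dict[str, list[str]] = {}
    for p in order:
        avail = sorted(e for e in members[p] if capacity[e] > 0)
        if len(avail) < min_members:
            continue
        retained.append(p)
        witness[p] = avail
        for e in avail:
            capacity[e] -= 1
    return retained, witness


def rank_report(
    solution: AssignmentSolution,
    score_table: pd.DataFrame,
) -> pd.DataFrame:
    """Ranked pathway table with BH-adjusted combined p-values.

    Sorted by combined p ascending; exact ties are broken by the number of
    entities each pathway kept after assignment capping (more first — the
    pathway explaining more of the data outranks), then by pathway id.
    BH FDR is computed over testable pathways only.
    """
    table = score_table.copy()
    table["n_entities_retained"] = [
        solution.n_assigned.get(pw, 0) for pw in table.index
    ]
    table["retained"] = [pw in solution.n_assigned for pw in table.index]
    testable = table["combined_p"].notna()
    fdr = pd.Series(np.nan, index=table.index)
    if testable.any():
        fdr.loc[testable] = multipletests(
            table.loc[testable, "combined_p"].to_numpy(), method="fdr_bh"
        )[1]
    table["fdr"] = fdr
    # deterministic sort (NaN combined p last)
    order_key = pd.DataFrame(
        {
            "p": table["combined_p"].fillna(np.inf),
            "neg_n": -table["n_entities_retained"],
            "id": table.index,
        }
    )
    table = table.loc[order_key.sort_values(["p", "neg_n", "id"]).index]
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def integrated_significant_features(
    differential: Mapping[str, pd.DataFrame], min_layers: int = 2
) -> list[str]:
    """Features flagged significant in at least ``min_layers`` omics layers.

    The integrated query mirrors the cross-validation idea: a feature backed
    by several independent layers is kept even when any single layer's call
    would be marginal.
    """
    votes: dict[str, int] = {}
    for table in differential.values():
        for feat in table.index[table["significant"]]:
            votes[feat] = votes.get(feat, 0) + 1
    return sorted(f for f, v in votes.items() if v >= min_layers)
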