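"""Pathway mapping, permutation p-values, Fisher combination and
assignment-capped ranking, each checked against an independent oracle."""
import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triomix.errors import ConfigurationError, InputError, ParameterError
from triomix.integration import (
    PathwayDefinition,
    dp_rank,
    fisher_combine,
    map_layers,
    pathway_pvalue,
    rank_report,
    score_pathways,
)
from triomix.preprocess import OmicsLayer


def chi2_sf_even_df(x, df):
    """Closed-form chi-square survival for even df: exp(-x/2) * sum (x/2)^j/j!."""
    k = df // 2
    half = x / 2.0
    return math.exp(-half) * sum(half**j / math.factorial(j) for j in range(k))


class TestFisherCombine:
    def test_all_ones(self):
        res = fisher_combine([1.0, 1.0])
        assert res.statistic == 0.0 and res.pvalue == pytest.approx(1.0)

    def test_single_p_identity(self):
        res = fisher_combine([0.05])
        assert res.pvalue == pytest.approx(0.05, abs=1e-14)

    def test_matches_closed_form_oracle(self):
        res = fisher_combine([0.01, 0.02, 0.03])
        assert res.df == 6
        assert res.pvalue == pytest.approx(chi2_sf_even_df(res.statistic, 6), abs=1e-12)

    @pytest.mark.parametrize("bad", [[0.0], [1.1], [0.5, -0.2], []])
    def test_domain_errors(self, bad):
        with pytest.raises((ParameterError, InputError)):
            fisher_combine(bad)

    @given(st.lists(st.floats(min_value=1e-10, max_value=1.0), min_size=2, max_size=6))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_permutation_invariant_and_monotone(self, ps):
        base = fisher_combine(ps).pvalue
        assert fisher_combine(ps[::-1]).pvalue == pytest.approx(base, rel=1e-12)
        shrunk = [ps[0] * 0.5] + ps[1:]
        assert fisher_combine(shrunk).pvalue <= base + 1e-15


class TestMapLayers:
    def make_layers(self, genes, mets, dataset=None):
        samples = ["s0", "s1"]
        mk = lambda tag, ids: OmicsLayer(
            tag, pd.DataFrame(np.ones((len(ids), 2)), index=ids, columns=samples)
        )
        return {
            "transcript": mk("transcript", genes),
            "protein": mk("protein", genes),
            "metabolite": mk("metabolite", mets),
        }

    def test_metabolite_single_pathway(self):
        layers = self.make_layers(["g1"], ["m1"])
        db = [PathwayDefinition("pw1", frozenset(["g1"]), frozenset(["m1"]))]
        tables = map_layers(layers, db, {})
        met_rows = tables.memberships.query("layer == 'metabolite'")
        assert len(met_rows) == 1 and met_rows.iloc[0]["pathway"] == "pw1"

    def test_unmapped_feature_listed(self):
        layers = self.make_layers(["g1", "orphan"], ["m1"])
        db = [PathwayDefinition("pw1", frozenset(["g1"]), frozenset(["m1"]))]
        tables = map_layers(layers, db, {})
        assert "orphan" in set(tables.unmapped["feature"])
        assert "orphan" not in set(tables.memberships["feature"])

    def test_transcript_maps_through_gene_cluster(self):
        layers = self.make_layers(["gA", "gB"], ["m1"])
        db = [PathwayDefinition("pw1", frozenset(["gA"]), frozenset())]
        tables = map_layers(layers, db, {"gA": "c1", "gB": "c1"})
        tx = tables.memberships.query("layer == 'transcript'")
        # gB joins pw1 because its cluster contains the member gA
        assert set(tx["feature"]) == {"gA", "gB"}

    def test_matches_exhaustive_join_oracle(self, small_dataset):
        tables = map_layers(
            small_dataset.layers(), small_dataset.pathway_db,
            small_dataset.gene_cluster_map,
        )
        cluster_members = {}
        for g, c in small_dataset.gene_cluster_map.items():
            cluster_members.setdefault(c, set()).add(g)
        expected = set()
        for pw in small_dataset.pathway_db:
            for m in small_dataset.metabolite_layer.features:
                if m in pw.metabolites:
                    expected.add(("metabolite", m, pw.pathway_id))
            for g in small_dataset.protein_layer.features:
                if g in pw.genes:
                    expected.add(("protein", g, pw.pathway_id))
            for g in small_dataset.transcript_layer.features:
                mates = cluster_members.get(
                    small_dataset.gene_cluster_map.get(g, ""), set()
                ) | {g}
                if mates & pw.genes:
                    expected.add(("transcript", g, pw.pathway_id))
        got = set(
            map(tuple, tables.memberships[["layer", "feature", "pathway"]].to_numpy())
        )
        assert got == expected


class TestPathwayPValue:
    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        stats_ = pd.Series(rng.normal(size=10), index=[f"f{i}" for i in range(10)])
        members = ["f0", "f3", "f7"]
        res = pathway_pvalue(stats_, members, n_permutations=100, rng=rng)
        assert res.method == "exact"
        scores = np.abs(stats_.to_numpy())
        obs = scores[[0, 3, 7]].mean()
        count = sum(
            1 for c in combinations(range(10), 3) if scores[list(c)].mean() >= obs
        )
        assert res.p == pytest.approx(count / math.comb(10, 3))

    def test_top_ranked_pathway_hits_floor(self):
        rng = np.random.default_rng(1)
        stats_ = pd.Series(rng.normal(size=100), index=[f"f{i}" for i in range(100)])
        top = list(stats_.abs().sort_values(ascending=False).index[:3])
        res = pathway_pvalue(stats_, top, n_permutations=500, rng=rng, exact_limit=0)
        assert res.method == "sampled"
        assert res.p == pytest.approx(1 / 501)

    def test_sampled_p_has_continuity_floor_and_ceiling(self):
        rng = np.random.default_rng(2)
        stats_ = pd.Series(rng.normal(size=50), index=[f"f{i}" for i in range(50)])
        res = pathway_pvalue(stats_, ["f0", "f1", "f2"], n_permutations=200,
                             rng=rng, exact_limit=0)
        assert 1 / 201 <= res.p <= 1.0

    def test_no_scored_members_rejected(self):
        stats_ = pd.Series([1.0], index=["f0"])
        with pytest.raises(InputError):
            pathway_pvalue(stats_, ["missing"])


def brute_force_best_objective(scores, members, cap, min_members):
    """Independent oracle: enumerate retained subsets; feasibility by
    recursive assignment of entities with memoisation."""
    pathways = sorted(scores)
    entities = sorted(set().union(*(members[p] for p in pathways)))

    def feasible(subset):
        if any(len(members[p]) < min_members for p in subset):
            return False
        if not subset:
            return True
        from functools import lru_cache

        idx = {p: i for i, p in enumerate(subset)}
        options = []
        for e in entities:
            containing = tuple(idx[p] for p in subset if e in members[p])
            subs = [()]
            for r in range(1, min(cap, len(containing)) + 1):
                subs.extend(combinations(containing, r))
            options.append(subs)

        @lru_cache(maxsize=None)
        def rec(i, need):
            if all(v == 0 for v in need):
                return True
            if i == len(entities):
                return False
            if sum(need) > (len(entities) - i) * cap:
                return False
            for sub in options[i]:
                new = list(need)
                for j in sub:
                    new[j] = max(0, new[j] - 1)
                if rec(i + 1, tuple(new)):
                    return True
            return False

        return rec(0, tuple(min_members for _ in subset))

    best = 0.0
    for r in range(len(pathways) + 1):
        for subset in combinations(pathways, r):
            if feasible(subset):
                best = max(best, sum(scores[p] for p in subset))
    return best


def random_instance(rng, n_pathways, n_entities, max_memb=3):
    entities = [f"e{i}" for i in range(n_entities)]
    members = {}
    scores = {}
    for j in range(n_pathways):
        size = int(rng.integers(1, n_entities + 1))
        members[f"p{j}"] = frozenset(rng.choice(entities, size=size, replace=False))
        scores[f"p{j}"] = float(np.round(rng.uniform(0.1, 5.0), 3))
    return scores, members


class TestDpRank:
    def test_disjoint_members_all_retained(self):
        scores = {"a": 2.0, "b": 1.0}
        members = {"a": frozenset({"e1", "e2", "e3"}), "b": frozenset({"e4", "e5", "e6"})}
        sol = dp_rank(scores, members, cap=1, min_members=3)
        assert set(sol.retained) == {"a", "b"}
        assert sol.objective == pytest.approx(3.0)

    def test_identical_members_dominance(self):
        members = {"hi": frozenset({"e1", "e2", "e3"}), "lo": frozenset({"e1", "e2", "e3"})}
        sol = dp_rank({"hi": 5.0, "lo": 3.0}, members, cap=1, min_members=3)
        assert sol.retained == ("hi",)
        assert sol.objective == pytest.approx(5.0)

    def test_cap_below_one_rejected(self):
        with pytest.raises(ConfigurationError):
            dp_rank({"a": 1.0}, {"a": frozenset({"e"})}, cap=0)

    def test_exact_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(12)
        for trial in range(40):
            n_pw = int(rng.integers(2, 7))
            n_ent = int(rng.integers(4, 9))
            cap = int(rng.integers(1, 3))
            min_members = int(rng.integers(1, 3))
            scores, members = random_instance(rng, n_pw, n_ent)
            sol = dp_rank(scores, members, cap=cap, min_members=min_members,
                          regime="exact")
            oracle = brute_force_best_objective(scores, members, cap, min_members)
            assert sol.objective == pytest.approx(oracle), f"trial {trial}"

    def test_exact_at_least_greedy_and_greedy_at_least_single_best(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            scores, members = random_instance(rng, 6, 8)
            cap = int(rng.integers(1, 3))
            exact = dp_rank(scores, members, cap=cap, min_members=2, regime="exact")
            greedy = dp_rank(scores, members, cap=cap, min_members=2, regime="greedy")
            assert exact.objective >= greedy.objective - 1e-12
            eligible = [p for p in scores if len(members[p]) >= 2]
            if eligible:
                single_best = max(scores[p] for p in eligible)
                assert greedy.objective >= single_best - 1e-12

    def test_cap_respected_and_retained_keep_min_members(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            scores, members = random_instance(rng, 5, 7)
            sol = dp_rank(scores, members, cap=1, min_members=2)
            for pws in sol.assignments.values():
                assert len(pws) <= 1
            for p in sol.retained:
                assert sol.n_assigned[p] >= 2


class TestRankReport:
    def make_scores(self, ps):
        return pd.DataFrame(
            {
                "statistic": [1.0] * len(ps),
                "df": [2] * len(ps),
                "combined_p": ps,
            },
            index=pd.Index([f"pw{i}" for i in range(len(ps))], name="pathway"),
        )

    def solution_for(self, table):
        members = {pw: frozenset({f"{pw}_e{j}" for j in range(3)}) for pw in table.index}
        scores = {pw: -np.log10(p) for pw, p in table["combined_p"].items()}
        return dp_rank(scores, members, cap=1, min_members=3)

    def test_single_pathway_fdr_equals_p(self):
        table = self.make_scores([0.02])
        report = rank_report(self.solution_for(table), table)
        assert report["fdr"].iloc[0] == pytest.approx(0.02)

    def test_all_p_one(self):
        table = self.make_scores([1.0, 1.0, 1.0])
        report = rank_report(self.solution_for(table), table)
        assert (report["fdr"] == 1.0).all()

    def test_bh_matches_step_up_oracle(self):
        rng = np.random.default_rng(20)
        ps = rng.uniform(size=15)
        table = self.make_scores(list(ps))
        report = rank_report(self.solution_for(table), table)
        order = np.argsort(ps)
        adj = np.empty(15)
        prev = 1.0
        for rank_pos in range(14, -1, -1):
            i = order[rank_pos]
            prev = min(prev, ps[i] * 15 / (rank_pos + 1))
            adj[i] = prev
        for i in range(15):
            assert report.loc[f"pw{i}", "fdr"] == pytest.approx(adj[i], abs=1e-12)

    def test_rank_order_and_tie_break(self):
        table = self.make_scores([0.5, 0.01, 0.5])
        sol = self.solution_for(table)
        report = rank_report(sol, table)
        assert list(report.index[:1]) == ["pw1"]
        # tied p: equal entity counts here, id breaks the tie
        assert list(report.index[1:]) == ["pw0", "pw2"]


class TestScorePathways:
    def test_small_layer_omitted_and_df_shrinks(self, small_dataset):
        layers = small_dataset.layers()
        tables = map_layers(layers, small_dataset.pathway_db,
                            small_dataset.gene_cluster_map)
        rng = np.random.default_rng(0)
        stats_ = {
            tag: pd.Series(
                rng.normal(size=len(layer.features)), index=layer.features
            )
            for tag, layer in layers.items()
        }
        table = score_pathways(stats_, tables, min_members=3,
                               n_permutations=200, rng=rng)
        # null pathways carry only 2 metabolites: metabolite layer omitted
        null_rows = table.loc[[i for i in table.index if i.startswith("pw_null")]]
        assert null_rows["p_metabolite"].isna().all()
        assert (null_rows["df"] == 4).all()
        assert (table.loc["pw_planted_1", "df"]) == 6
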