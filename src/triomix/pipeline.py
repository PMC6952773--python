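"""End-to-end orchestration of the integration pipeline.

``run_pipeline`` executes the eleven analysis stages — normalize, singlet
filter, differential statistics, pathway mapping, per-layer pathway
p-values, Fisher combination, assignment-capped ranking, t-SNE embedding,
outlier-cluster extraction, enrichment, and biomarker panel search — writing
every intermediate as a commented TSV/JSON and returning a manifest with
per-file checksums.  Reruns with the same configuration reproduce identical
checksums: every random stage draws from the single master seed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .biomarker import search_panels
from .clustering import enrich, extract_outlier_clusters, tsne_embed
from .errors import ConfigurationError
from .integration import (
    dp_rank,
    integrated_significant_features,
    map_layers,
    rank_report,
    score_pathways,
)
from .preprocess import (
    OmicsLayer,
    differential_test,
    filter_singletons,
    log2_with_floor,
    tic_normalize,
)
from .simulate import (
    MultiOmicsDataset,
    SimulationConfig,
    config_from_jsonable,
    read_fixtures,
    simulate_dataset,
)

STAGES = (
    "normalize",
    "filter",
    "differential",
    "map",
    "pathway_pvalues",
    "fisher",
    "dp_rank",
    "tsne",
    "clusters",
    "enrichment",
    "biomarkers",
)


@dataclass
class PipelineConfig:
    """All stage parameters plus input/output paths and the master seed."""

    out_dir: str = "triomix_run"
    fixtures_dir: str | None = None  # if None, simulate with `simulation`
    simulation: SimulationConfig | None = None
    seed: int = 0
    contrast: tuple[str, str] = ("hypoxia", "normoxia")
    min_change: float = 0.15
    alpha: float = 0.05
    min_members: int = 3
    n_permutations: int = 10_000
    cap: int = 2
    perplexity: float = 20.0
    n_pca: int = 50
    exaggeration: float = 4.0
    tsne_runs: int = 15
    stability_min: float = 0.8
    min_cluster_size: int = 5
    pool_size: int = 20
    max_panel: int = 6
    biomarker_group: str | None = None
    min_query_layers: int = 2
    skip_stages: tuple[str, ...] = ()

    def validate(self) -> None:
        unknown = set(self.skip_stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages to skip: {sorted(unknown)}")
        if self.fixtures_dir is not None and not Path(self.fixtures_dir).exists():
            raise ConfigurationError(f"fixtures_dir {self.fixtures_dir!r} does not exist")
        if self.cap < 1:
            raise ConfigurationError("cap must be >= 1")

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            from .simulate import _config_to_jsonable

            d["simulation"] = _config_to_jsonable(self.simulation)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if raw.get("simulation") is not None:
            raw["simulation"] = config_from_jsonable(raw["simulation"])
        if "contrast" in raw:
            raw["contrast"] = tuple(raw["contrast"])
        if "skip_stages" in raw:
            raw["skip_stages"] = tuple(raw["skip_stages"])
        return cls(**raw)

    def params_hash(self) -> str:
        """Digest of the analysis parameters (output location excluded)."""
        params = self.to_jsonable()
        params.pop("out_dir", None)
        payload = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def feature_profiles(
    layers: Mapping[str, OmicsLayer],
    tags: tuple[str, ...] = ("transcript", "protein"),
) -> pd.DataFrame:
    """Per-feature standardized log2 profiles concatenated across layers.

    Features quantified in every requested layer get one row; each layer's
    log2 vector is z-scored per feature so the embedding sees expression
    *patterns*, not absolute abundance.
    """
    shared = None
    for tag in tags:
        idx = set(layers[tag].features)
        shared = idx if shared is None else shared & idx
    shared = sorted(shared or set())
    blocks = []
    for tag in tags:
        log_vals = log2_with_floor(layers[tag].values).loc[shared]
        arr = log_vals.to_numpy()
        sd = arr.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0
        z = (arr - arr.mean(axis=1, keepdims=True)) / sd[:, None]
        blocks.append(
            pd.DataFrame(z, index=shared, columns=[f"{tag}:{c}" for c in log_vals.columns])
        )
    return pd.concat(blocks, axis=1)


def fetal_minus_adult(
    layers: Mapping[str, OmicsLayer],
    metadata: pd.DataFrame,
    features: list[str],
    tags: tuple[str, ...] = ("transcript", "protein"),
) -> pd.Series:
    """Mean log2 difference (fetal − adult) per feature, averaged over layers."""
    fetal = metadata.loc[metadata["group"] == "fetal", "sample_id"].tolist()
    adult = metadata.loc[metadata["group"] != "fetal", "sample_id"].tolist()
    diffs = []
    for tag in tags:
        log_vals = log2_with_floor(layers[tag].values).reindex(features)
        diffs.append(log_vals[fetal].mean(axis=1) - log_vals[adult].mean(axis=1))
    return sum(diffs) / len(diffs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    phash = config.params_hash()
    header = [f"triomix {__version__}", f"seed={config.seed}", f"params={phash}"]
    rng = np.random.default_rng(config.seed)

    if config.fixtures_dir is not None:
        dataset = read_fixtures(config.fixtures_dir)
    else:
        sim = config.simulation or SimulationConfig(seed=config.seed)
        dataset = simulate_dataset(sim)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "params_hash": phash,
        "parameters": config.to_jsonable(),
        "stages": {},
    }
    active = [s for s in STAGES if s not in config.skip_stages]

    def record(stage: str, files: dict[str, Path], extra: dict | None = None) -> None:
        manifest["stages"][stage] = {
            "files": {k: p.name for k, p in files.items()},
            "checksums": {p.name: io.file_sha256(p) for p in files.values()},
            **(extra or {}),
        }

    layers = dataset.layers()

    if "normalize" in active:
        layers = {tag: tic_normalize(layer) for tag, layer in layers.items()}
        files = {}
        for tag, layer in layers.items():
            values = layer.values.copy()
            if layer.unique_peptides is not None:
                values["unique_peptides"] = layer.unique_peptides
            files[tag] = io.write_matrix(values, out / f"normalized_{tag}.tsv", header)
        record("normalize", files)

    if "filter" in active:
        layers = dict(layers)
        layers["protein"] = filter_singletons(layers["protein"])
        values = layers["protein"].values.copy()
        values["unique_peptides"] = layers["protein"].unique_peptides
        record(
            "filter",
            {"protein": io.write_matrix(values, out / "filtered_protein.tsv", header)},
            {"n_retained": int(len(layers["protein"].features))},
        )

    differential: dict[str, pd.DataFrame] = {}
    if "differential" in active:
        files = {}
        for tag, layer in layers.items():
            diff = differential_test(
                layer,
                dataset.metadata,
                contrast=config.contrast,
                min_change=config.min_change,
                alpha=config.alpha,
            )
            differential[tag] = diff
            files[tag] = io.write_matrix(diff, out / f"differential_{tag}.tsv", header)
        record("differential", files)

    membership = None
    if "map" in active:
        membership = map_layers(layers, dataset.pathway_db, dataset.gene_cluster_map)
        f_m = out / "pathway_memberships.tsv"
        f_u = out / "unmapped_features.tsv"
        with open(f_m, "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            membership.memberships.to_csv(fh, sep="\t", index=False)
        with open(f_u, "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            membership.unmapped.to_csv(fh, sep="\t", index=False)
        record("map", {"memberships": f_m, "unmapped": f_u})

    scores_table = None
    if "pathway_pvalues" in active and membership is not None and differential:
        layer_stats = {tag: diff["t"] for tag, diff in differential.items()}
        scores_table = score_pathways(
            layer_stats,
            membership,
            min_members=config.min_members,
            n_permutations=config.n_permutations,
            rng=rng,
        )
        p_cols = [c for c in scores_table.columns if c.startswith("p_")]
        record(
            "pathway_pvalues",
            {
                "pvalues": io.write_matrix(
                    scores_table[p_cols], out / "pathway_pvalues.tsv", header
                )
            },
        )

    if "fisher" in active and scores_table is not None:
        record(
            "fisher",
            {
                "fisher": io.write_matrix(
                    scores_table[["statistic", "df", "combined_p"]],
                    out / "fisher_combined.tsv",
                    header,
                )
            },
        )

    solution = None
    ranking = None
    if "dp_rank" in active and scores_table is not None and membership is not None:
        testable = scores_table["combined_p"].dropna()
        scores = {
            pw: float(-np.log10(max(p, np.finfo(float).tiny)))
            for pw, p in testable.items()
        }
        entities = membership.entities_by_pathway()
        solution = dp_rank(
            scores, entities, cap=config.cap, min_members=config.min_members
        )
        ranking = rank_report(solution, scores_table)
        f_r = io.write_matrix(ranking, out / "pathway_ranking.tsv", header)
        f_a = out / "assignments.json"
        with open(f_a, "w") as fh:
            json.dump(
                {
                    "regime": solution.regime,
                    "objective": solution.objective,
                    "retained": list(solution.retained),
                    "assignments": {e: list(p) for e, p in solution.assignments.items()},
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        record("dp_rank", {"ranking": f_r, "assignments": f_a}, {"regime": solution.regime})

    embedding = None
    profiles = None
    if "tsne" in active:
        profiles = feature_profiles(layers)
        embedding = tsne_embed(
            profiles,
            perplexity=config.perplexity,
            n_pca=config.n_pca,
            exaggeration=config.exaggeration,
            n_runs=config.tsne_runs,
            base_seed=config.seed,
            min_cluster_size=config.min_cluster_size,
        )
        rows = []
        for r, coords in enumerate(embedding.coordinates):
            for f, (x, y) in zip(embedding.feature_ids, coords):
                rows.append((r, embedding.seeds[r], f, x, y))
        coords_df = pd.DataFrame(rows, columns=["run", "seed", "feature", "x", "y"])
        f_c = out / "tsne_coordinates.tsv"
        with open(f_c, "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            coords_df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        record("tsne", {"coordinates": f_c}, {"stability": embedding.stability})

    assignment = None
    if "clusters" in active and embedding is not None:
        direction = fetal_minus_adult(layers, dataset.metadata, embedding.feature_ids)
        assignment = extract_outlier_clusters(
            embedding,
            direction,
            stability_min=config.stability_min,
            min_cluster_size=config.min_cluster_size,
        )
        label_df = pd.DataFrame(
            {
                "feature": embedding.feature_ids,
                "label": [assignment.labels[f] for f in embedding.feature_ids],
                "consensus_cluster": assignment.consensus,
            }
        )
        f_l = out / "cluster_labels.tsv"
        with open(f_l, "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            fh.write("# cluster boundaries: density-based consensus (stand-in for "
                     "visual selection on the embedding)\n")
            label_df.to_csv(fh, sep="\t", index=False)
        record("clusters", {"labels": f_l}, {"status": assignment.status})

    if "enrichment" in active:
        universe = sorted(
            set(layers["transcript"].features) & set(layers["protein"].features)
        )
        query: list[str] = []
        query_source = "clusters"
        if assignment is not None:
            query = [f for f in universe if assignment.labels.get(f, "background") != "background"]
        if not query and differential:
            query = [f for f in integrated_significant_features(
                differential, config.min_query_layers) if f in universe]
            query_source = "integrated_differential"
        table = enrich(query, dataset.annotation_db, universe)
        f_e = out / "enrichment.tsv"
        with open(f_e, "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            fh.write(f"# query_source={query_source} n_query={len(query)}\n")
            table.to_csv(fh, sep="\t", index=False)
        record("enrichment", {"enrichment": f_e}, {"query_source": query_source,
                                                   "n_query": len(query)})

    if "biomarkers" in active:
        panels = search_panels(
            layers["protein"],
            dataset.metadata,
            group=config.biomarker_group,
            pool_size=config.pool_size,
            max_panel=config.max_panel,
        )
        f_b = out / "biomarker_panels.tsv"
        with open(f_b, "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            fh.write(f"# pool restricted to top {config.pool_size} univariate features\n")
            panels.drop(columns=["members"]).to_csv(fh, sep="\t", index=False,
                                                    float_format="%.6g")
        record("biomarkers", {"panels": f_b}, {"n_panels": int(len(panels))})

    f_manifest = out / "manifest.json"
    with open(f_manifest, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest
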