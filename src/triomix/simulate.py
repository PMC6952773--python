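"""Synthetic multi-omics datasets with planted cross-layer structure.

The generator emulates the study design the pipeline targets: three omics
layers (transcript, protein, metabolite) measured over six sample groups —
fetal, adult-male and adult-female animals under normoxia or gestational
hypoxia — with a small "mitochondrion-like" module of genes and metabolites
perturbed coherently (same sign, same log2 effect) by hypoxia in every group
and every layer, embedded among uncorrelated null features.

Noise is multiplicative log-normal on all three layers (transcript counts
are rounded log-normal intensities rather than negative-binomial counts:
the pipeline consumes normalized intensities, not raw reads).  Alongside
the matrices the generator emits pathway and annotation GMT files consistent
with the planted structure — including one designated decoy pathway
overlapping the planted module by 50%, which gives the assignment-capped
ranking something meaningful to deduplicate — a gene → gene-cluster map, and
transcript/reference-proteome FASTA fixtures for the proteogenomics stage.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from . import io
from .errors import ConfigurationError, FormatError
from .integration import PathwayDefinition
from .preprocess import OmicsLayer

__all__ = [
    "PlantedModule",
    "SimulationConfig",
    "MultiOmicsDataset",
    "simulate_dataset",
    "write_fixtures",
    "read_fixtures",
]

GROUPS = ("fetal", "adult_male", "adult_female")
CONDITIONS = ("normoxia", "hypoxia")
LAYERS = ("transcript", "protein", "metabolite")


@dataclass(frozen=True)
class PlantedModule:
    """A coherent cross-layer module: ids plus per-layer hypoxia log2 effect.

    ``fetal_log2_shift`` adds a constant developmental offset (fetal vs
    adult baseline) to the module's features in every layer, so embedding
    stages can recover an "up-in-fetal" or "down-in-fetal" direction.
    """

    genes: tuple[str, ...]
    metabolites: tuple[str, ...] = ()
    log2_effect: Mapping[str, float] = None  # type: ignore[assignment]
    fetal_log2_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.log2_effect is None:
            object.__setattr__(
                self, "log2_effect", {tag: 1.0 for tag in LAYERS}
            )

    def effect(self, tag: str) -> float:
        return float(self.log2_effect.get(tag, 0.0))


def _default_modules() -> tuple[PlantedModule, ...]:
    return (
        PlantedModule(
            genes=tuple(f"g{i:04d}" for i in range(1, 13)),
            metabolites=tuple(f"m{i:04d}" for i in range(1, 5)),
            log2_effect={"transcript": 1.0, "protein": 1.0, "metabolite": 1.0},
            fetal_log2_shift=1.0,
        ),
    )


@dataclass
class SimulationConfig:
    """Study-condition parameters of the generator.

    Defaults reflect the emulated design: 5 replicates per (group,
    condition) cell, log2 effect 1.0 for the planted module in every layer,
    and log-scale noise sd 0.25.
    """

    n_replicates: int = 5
    n_genes: int = 240
    n_metabolites: int = 60
    n_pathways: int = 12
    planted_modules: tuple[PlantedModule, ...] = field(default_factory=_default_modules)
    noise_sd: float = 0.25
    seed: int = 0
    baseline_log2: tuple[float, float] = (6.0, 12.0)
    singlet_fraction: float = 0.2
    n_annotation_terms: int = 15
    n_transcript_seqs: int = 40
    n_reference_proteins: int = 50
    encoded_fraction: float = 0.7

    def validate(self) -> None:
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")
        for name in ("n_genes", "n_metabolites", "n_pathways"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not self.noise_sd > 0:
            raise ConfigurationError("noise_sd must be > 0")
        genes = {f"g{i:04d}" for i in range(1, self.n_genes + 1)}
        mets = {f"m{i:04d}" for i in range(1, self.n_metabolites + 1)}
        for module in self.planted_modules:
            if not set(module.genes) <= genes:
                raise ConfigurationError("planted module genes outside the feature universe")
            if not set(module.metabolites) <= mets:
                raise ConfigurationError(
                    "planted module metabolites outside the feature universe"
                )


@dataclass
class MultiOmicsDataset:
    """Three coherent omics layers plus the maps and sequences around them."""

    transcript_layer: OmicsLayer
    protein_layer: OmicsLayer
    metabolite_layer: OmicsLayer
    metadata: pd.DataFrame
    pathway_db: list[PathwayDefinition]
    annotation_db: dict[str, tuple[str, tuple[str, ...]]]
    gene_cluster_map: dict[str, str]
    transcripts: dict[str, str]
    reference_proteome: dict[str, str]
    truth: dict

    def layers(self) -> dict[str, OmicsLayer]:
        return {
            "transcript": self.transcript_layer,
            "protein": self.protein_layer,
            "metabolite": self.metabolite_layer,
        }


def _sample_table(n_replicates: int) -> pd.DataFrame:
    rows = [
        (f"{g}_{c}_r{r + 1}", g, c)
        for g in GROUPS
        for c in CONDITIONS
        for r in range(n_replicates)
    ]
    return pd.DataFrame(rows, columns=["sample_id", "group", "condition"])


def _layer_matrix(
    rng: np.random.Generator,
    features: list[str],
    metadata: pd.DataFrame,
    tag: str,
    config: SimulationConfig,
) -> pd.DataFrame:
    lo, hi = config.baseline_log2
    baseline = rng.uniform(lo, hi, size=len(features))
    log2 = np.tile(baseline[:, None], (1, len(metadata)))
    is_hypoxia = (metadata["condition"] == "hypoxia").to_numpy()
    is_fetal = (metadata["group"] == "fetal").to_numpy()
    index = pd.Index(features)
    for module in config.planted_modules:
        ids = module.genes if tag in ("transcript", "protein") else module.metabolites
        rows = index.isin(ids)
        log2[np.ix_(rows, is_hypoxia)] += module.effect(tag)
        log2[np.ix_(rows, is_fetal)] += module.fetal_log2_shift
    log2 = log2 + rng.normal(0.0, config.noise_sd, size=log2.shape)
    values = np.power(2.0, log2)
    if tag == "transcript":
        values = np.rint(values)
    return pd.DataFrame(values, index=index, columns=metadata["sample_id"].tolist())


_CODON_OF = {}
for _codon, _aa in sorted(standard_dna_table.forward_table.items()):
    _CODON_OF.setdefault(_aa, _codon)
_AA_ALPHABET = sorted(_CODON_OF)


def _encode(protein: str) -> str:
    return "".join(_CODON_OF[aa] for aa in protein)


def _sequence_fixtures(rng: np.random.Generator, config: SimulationConfig):
    """Reference proteins plus transcripts; a known fraction of the proteins
    is exactly encoded (over an 80-aa window) by some transcript."""
    aa = np.array(_AA_ALPHABET)
    nt = np.array(list("ACGT"))
    proteins = {
        f"prot_{i + 1:03d}": "".join(rng.choice(aa, size=180))
        for i in range(config.n_reference_proteins)
    }
    n_encoded = int(round(config.encoded_fraction * config.n_reference_proteins))
    encoded_ids = sorted(proteins)[:n_encoded]
    transcripts: dict[str, str] = {}
    for i in range(config.n_transcript_seqs):
        tx_id = f"tx_{i + 1:03d}"
        if i < n_encoded:
            window = proteins[encoded_ids[i]][10:90]
            flank5 = "".join(rng.choice(nt, size=30))
            flank3 = "".join(rng.choice(nt, size=30))
            transcripts[tx_id] = flank5 + _encode(window) + flank3
        else:
            transcripts[tx_id] = "".join(rng.choice(nt, size=300))
    return transcripts, proteins, encoded_ids


def simulate_dataset(config: SimulationConfig | None = None) -> MultiOmicsDataset:
    """Generate one dataset; identical config and seed give identical output.

    Planted features have their per-condition mean log2 intensity shifted by
    the module's stated effect in every group and layer; null features carry
    no effect.  All randomness flows from ``config.seed`` through a single
    PCG64 generator, so outputs are byte-identical across runs and platforms.
    """
    config = SimulationConfig() if config is None else config
    config.validate()
    rng = np.random.default_rng(config.seed)
    metadata = _sample_table(config.n_replicates)
    genes = [f"g{i:04d}" for i in range(1, config.n_genes + 1)]
    mets = [f"m{i:04d}" for i in range(1, config.n_metabolites + 1)]

    transcript = OmicsLayer(
        "transcript", _layer_matrix(rng, genes, metadata, "transcript", config)
    )
    protein_values = _layer_matrix(rng, genes, metadata, "protein", config)
    metabolite = OmicsLayer(
        "metabolite", _layer_matrix(rng, mets, metadata, "metabolite", config)
    )

    planted_genes = sorted({g for m in config.planted_modules for g in m.genes})
    planted_mets = sorted({m for mod in config.planted_modules for m in mod.metabolites})
    null_genes = [g for g in genes if g not in planted_genes]
    null_mets = [m for m in mets if m not in planted_mets]

    # unique-peptide counts: planted proteins always multi-peptide, a fixed
    # fraction of null proteins are singlets (single unique peptide)
    counts = pd.Series(0, index=pd.Index(genes), dtype=int)
    counts.loc[planted_genes] = rng.integers(2, 11, size=len(planted_genes))
    n_singlets = int(round(config.singlet_fraction * len(null_genes)))
    singlets = rng.choice(null_genes, size=n_singlets, replace=False)
    counts.loc[null_genes] = rng.integers(2, 11, size=len(null_genes))
    counts.loc[singlets] = 1
    protein = OmicsLayer("protein", protein_values, unique_peptides=counts)

    # pathways: one per planted module, one 50%-overlap decoy for the first
    # module, the rest null pathways over null features
    pathway_db: list[PathwayDefinition] = []
    for i, module in enumerate(config.planted_modules, start=1):
        pathway_db.append(
            PathwayDefinition(
                f"pw_planted_{i}",
                frozenset(module.genes),
                frozenset(module.metabolites),
            )
        )
    half = 0
    if config.planted_modules:
        first = config.planted_modules[0]
        half = len(first.genes) // 2
        decoy_genes = list(first.genes[:half]) + null_genes[:half]
        pathway_db.append(PathwayDefinition("pw_decoy_1", frozenset(decoy_genes)))
    n_null_pw = max(config.n_pathways - len(pathway_db), 0)
    pool_genes = null_genes[half:]
    for i in range(n_null_pw):
        pw_genes = rng.choice(pool_genes, size=min(10, len(pool_genes)), replace=False)
        pw_mets = rng.choice(null_mets, size=min(2, len(null_mets)), replace=False)
        pathway_db.append(
            PathwayDefinition(f"pw_null_{i + 1:02d}", frozenset(pw_genes), frozenset(pw_mets))
        )

    # annotation terms (GMT): one term per planted module plus null terms
    annotation_db: dict[str, tuple[str, tuple[str, ...]]] = {}
    for i, module in enumerate(config.planted_modules, start=1):
        annotation_db[f"term_planted_{i}"] = (
            "planted cross-layer module",
            tuple(module.genes),
        )
    for i in range(config.n_annotation_terms):
        members = rng.choice(null_genes, size=min(15, len(null_genes)), replace=False)
        annotation_db[f"term_null_{i + 1:02d}"] = ("null annotation term", tuple(sorted(members)))

    # gene clusters: planted genes are singleton clusters; the first forty
    # null genes pair up so transcript->cluster mapping is exercised
    gene_cluster_map: dict[str, str] = {g: f"cl_{g}" for g in planted_genes}
    paired = null_genes[:40]
    for j in range(0, len(paired) - 1, 2):
        gene_cluster_map[paired[j]] = f"cl_pair_{j // 2 + 1:02d}"
        gene_cluster_map[paired[j + 1]] = f"cl_pair_{j // 2 + 1:02d}"
    for g in null_genes[40:]:
        gene_cluster_map[g] = f"cl_{g}"

    transcripts, proteome, encoded_ids = _sequence_fixtures(rng, config)

    truth = {
        "planted_genes": planted_genes,
        "planted_metabolites": planted_mets,
        "planted_pathways": [f"pw_planted_{i + 1}" for i in range(len(config.planted_modules))],
        "decoy_pathways": ["pw_decoy_1"] if config.planted_modules else [],
        "planted_terms": [f"term_planted_{i + 1}" for i in range(len(config.planted_modules))],
        "singlet_proteins": sorted(singlets.tolist()),
        "encoded_reference_proteins": encoded_ids,
        "config": _config_to_jsonable(config),
    }
    return MultiOmicsDataset(
        transcript_layer=transcript,
        protein_layer=protein,
        metabolite_layer=metabolite,
        metadata=metadata,
        pathway_db=pathway_db,
        annotation_db=annotation_db,
        gene_cluster_map=gene_cluster_map,
        transcripts=transcripts,
        reference_proteome=proteome,
        truth=truth,
    )


def _config_to_jsonable(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["planted_modules"] = [
        {
            "genes": list(m.genes),
            "metabolites": list(m.metabolites),
            "log2_effect": dict(m.log2_effect),
            "fetal_log2_shift": m.fetal_log2_shift,
        }
        for m in config.planted_modules
    ]
    return d


def config_from_jsonable(d: Mapping) -> SimulationConfig:
    d = dict(d)
    modules = tuple(
        PlantedModule(
            genes=tuple(m["genes"]),
            metabolites=tuple(m["metabolites"]),
            log2_effect=dict(m["log2_effect"]),
            fetal_log2_shift=float(m["fetal_log2_shift"]),
        )
        for m in d.pop("planted_modules")
    )
    d["baseline_log2"] = tuple(d["baseline_log2"])
    return SimulationConfig(planted_modules=modules, **d)


FIXTURE_FILES = {
    "transcript_matrix": "transcript_matrix.tsv",
    "protein_matrix": "protein_matrix.tsv",
    "metabolite_matrix": "metabolite_matrix.tsv",
    "metadata": "sample_metadata.tsv",
    "pathways": "pathways.gmt",
    "annotations": "annotations.gmt",
    "gene_clusters": "gene_clusters.tsv",
    "transcripts_fasta": "transcripts.fasta",
    "reference_proteome_fasta": "reference_proteome.fasta",
}


def write_fixtures(dataset: MultiOmicsDataset, directory: str | Path) -> dict[str, str]:
    """Write a dataset to plain-text fixture files; returns the manifest.

    The manifest (also written as ``manifest.json``) lists the three matrix
    files, the sample metadata, the two GMT files, the gene-cluster map and
    the two FASTA files, plus the generator truth needed to evaluate
    recovery downstream.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    f = {k: directory / v for k, v in FIXTURE_FILES.items()}

    io.write_matrix(dataset.transcript_layer.values, f["transcript_matrix"])
    protein_out = dataset.protein_layer.values.copy()
    protein_out["unique_peptides"] = dataset.protein_layer.unique_peptides
    io.write_matrix(protein_out, f["protein_matrix"])
    io.write_matrix(dataset.metabolite_layer.values, f["metabolite_matrix"])
    dataset.metadata.to_csv(f["metadata"], sep="\t", index=False)
    io.write_gmt(
        {
            pw.pathway_id: ("pathway", tuple(sorted(pw.genes) + sorted(pw.metabolites)))
            for pw in dataset.pathway_db
        },
        f["pathways"],
    )
    io.write_gmt(dataset.annotation_db, f["annotations"])
    io.write_two_column_map(dataset.gene_cluster_map, f["gene_clusters"])
    io.write_fasta(dataset.transcripts, f["transcripts_fasta"])
    io.write_fasta(dataset.reference_proteome, f["reference_proteome_fasta"])

    manifest = {
        "files": {k: v.name for k, v in f.items()},
        "truth": dataset.truth,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest["files"]


def read_fixtures(directory: str | Path) -> MultiOmicsDataset:
    """Read back a fixture directory written by :func:`write_fixtures`."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"{manifest_path}: file not found")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    f = {k: directory / v for k, v in manifest["files"].items()}

    metadata = pd.read_csv(f["metadata"], sep="\t", comment="#")
    for col in ("sample_id", "group", "condition"):
        if col not in metadata.columns:
            raise FormatError(f"{f['metadata']}: missing column {col!r}")
    samples = metadata["sample_id"].tolist()

    transcript = OmicsLayer(
        "transcript", io.read_matrix(f["transcript_matrix"])[samples].astype(float)
    )
    protein_raw = io.read_matrix(f["protein_matrix"])
    if "unique_peptides" not in protein_raw.columns:
        raise FormatError(f"{f['protein_matrix']}: missing 'unique_peptides' column")
    protein = OmicsLayer(
        "protein",
        protein_raw[samples],
        unique_peptides=protein_raw["unique_peptides"].astype(int),
    )
    metabolite = OmicsLayer("metabolite", io.read_matrix(f["metabolite_matrix"])[samples])

    met_ids = set(metabolite.features)
    pathway_db = []
    for term, (_desc, members) in io.read_gmt(f["pathways"]).items():
        genes = frozenset(m for m in members if m not in met_ids)
        mets = frozenset(m for m in members if m in met_ids)
        pathway_db.append(PathwayDefinition(term, genes, mets))
    annotation_db = io.read_gmt(f["annotations"])
    gene_cluster_map = io.read_two_column_map(f["gene_clusters"])
    transcripts = io.read_fasta(f["transcripts_fasta"])
    proteome = io.read_fasta(f["reference_proteome_fasta"])
    return MultiOmicsDataset(
        transcript_layer=transcript,
        protein_layer=protein,
        metabolite_layer=metabolite,
        metadata=metadata,
        pathway_db=pathway_db,
        annotation_db=annotation_db,
        gene_cluster_map=gene_cluster_map,
        transcripts=transcripts,
        reference_proteome=proteome,
        truth=manifest.get("truth", {}),
    )
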