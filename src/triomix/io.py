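"""Plain-text I/O for the formats the pipeline exchanges.

Quantitative matrices travel as TSV with features in rows (first column the
feature id, header row of sample ids); gene/metabolite sets as GMT; sequences
as FASTA; small maps as two-column TSV.  Writers can prepend ``#`` provenance
comments, which every reader skips.
"""
from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "read_fasta",
    "write_fasta",
    "read_two_column_map",
    "write_two_column_map",
    "file_sha256",
]


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a features-by-samples TSV matrix, skipping ``#`` comment lines."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse matrix TSV ({exc})") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: matrix has no sample columns")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate feature ids {dup[:5]}")
    if df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate sample ids")
    df.index = df.index.astype(str)
    df.index.name = "feature"
    return df


def write_matrix(
    df: pd.DataFrame,
    path: str | Path,
    comments: Iterable[str] = (),
    float_format: str = "%.10g",
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", float_format=float_format, index_label="feature")
    return path


def read_gmt(path: str | Path) -> dict[str, tuple[str, tuple[str, ...]]]:
    """Read a GMT file into ``{term: (description, members)}``.

    Lines need at least three tab-separated fields (term, description, one or
    more members); anything shorter is rejected with the line number.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT record needs term, description "
                    f"and at least one member (got {len(fields)} fields)"
                )
            term, desc = fields[0], fields[1]
            members = tuple(m for m in fields[2:] if m)
            if not members:
                raise FormatError(f"{path}: line {lineno}: term {term!r} has an empty member list")
            if term in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate term {term!r}")
            sets[term] = (desc, members)
    return sets


def write_gmt(
    sets: Mapping[str, tuple[str, Iterable[str]]],
    path: str | Path,
    comments: Iterable[str] = (),
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        for term in sets:
            desc, members = sets[term]
            fh.write("\t".join([term, desc, *members]) + "\n")
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise FormatError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
    return path


def read_two_column_map(path: str | Path) -> dict[str, str]:
    """Read a key→value TSV (e.g. the gene → gene-cluster map)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns, got {len(fields)}")
            key, value = fields
            if key in mapping:
                raise FormatError(f"{path}: line {lineno}: duplicate key {key!r}")
            mapping[key] = value
    return mapping


def write_two_column_map(
    mapping: Mapping[str, str], path: str | Path, comments: Iterable[str] = ()
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        for key in mapping:
            fh.write(f"{key}\t{mapping[key]}\n")
    return path


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
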