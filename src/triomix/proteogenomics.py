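"""Transcript-evidence filtering of a reference proteome.

Standard reference proteomes include every protein known for the organism,
regardless of whether the tissue under study expresses it; searching spectra
against unexpressed entries costs statistical power.  This module performs a
six-frame in-silico translation of assembled transcripts to enumerate all
possible encoded protein stretches, then retains only those reference
proteins that share an exact ungapped amino-acid substring of at least
``min_match_len`` residues with some open reading frame — the operational
definition of "transcript-level evidence" used here.

ORFs are maximal stop-free stretches in each of the six frames (no initiator
methionine required, maximizing coverage); codons containing N translate to
``X``.  Offsets are 0-based half-open coordinates on the forward strand of
the transcript.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .errors import InputError, ParameterError

__all__ = [
    "Orf",
    "six_frame_translate",
    "build_custom_db",
    "CustomProteomeDB",
    "RetainedProtein",
]

_VALID_NT = set("ACGTN")
FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class Orf:
    """One stop-free translated stretch.

    ``start``/``end`` are nucleotide offsets of the codons on the forward
    strand of the transcript (0-based, half-open), for every frame including
    the reverse ones.
    """

    transcript_id: str
    frame: int
    aa_seq: str
    start: int
    end: int


def _translate_frames(seq: str) -> dict[int, str]:
    """Full-length translation of all six frames (``*`` marks stops)."""
    fwd = Seq(seq)
    rev = fwd.reverse_complement()
    out: dict[int, str] = {}
    for f in (1, 2, 3):
        sub = fwd[f - 1 :]
        sub = sub[: len(sub) - len(sub) % 3]
        out[f] = str(sub.translate()) if len(sub) else ""
    for f in (1, 2, 3):
        sub = rev[f - 1 :]
        sub = sub[: len(sub) - len(sub) % 3]
        out[-f] = str(sub.translate()) if len(sub) else ""
    return out


def six_frame_translate(
    dna: str, min_orf_len: int = 20, transcript_id: str = "seq"
) -> list[Orf]:
    """Enumerate maximal stop-free ORFs in all six reading frames.

    Returns ORFs of at least ``min_orf_len`` amino acids, translated with the
    standard codon table; the returned order is frames +1, +2, +3, −1, −2, −3
    and within each frame 5'→3' on the strand read.
    """
    if min_orf_len < 1:
        raise ParameterError(f"min_orf_len must be >= 1, got {min_orf_len}")
    seq = dna.upper()
    bad = set(seq) - _VALID_NT
    if bad:
        raise InputError(
            f"{transcript_id}: sequence contains characters outside ACGTN: {sorted(bad)}"
        )
    L = len(seq)
    orfs: list[Orf] = []
    for frame, protein in _translate_frames(seq).items():
        aa_pos = 0
        for stretch in protein.split("*"):
            if len(stretch) >= min_orf_len:
                a0, a1 = aa_pos, aa_pos + len(stretch)
                f = abs(frame)
                if frame > 0:
                    start, end = (f - 1) + 3 * a0, (f - 1) + 3 * a1
                else:  # coordinates of the same codons on the forward strand
                    start, end = L - ((f - 1) + 3 * a1), L - ((f - 1) + 3 * a0)
                orfs.append(Orf(transcript_id, frame, stretch, start, end))
            aa_pos += len(stretch) + 1  # +1 skips the stop codon
    return orfs


@dataclass(frozen=True)
class RetainedProtein:
    protein_id: str
    sequence: str
    transcript_id: str
    match_start: int  # on the protein, 0-based half-open
    match_end: int

    @property
    def match_length(self) -> int:
        return self.match_end - self.match_start


@dataclass
class CustomProteomeDB:
    """Transcript-evidence-filtered reference proteome."""

    retained: list[RetainedProtein]
    removed: dict[str, str]  # protein id -> reason
    min_match_len: int

    def retained_sequences(self) -> dict[str, str]:
        return {r.protein_id: r.sequence for r in self.retained}

    def report(self):
        import pandas as pd

        rows = [
            {
                "protein": r.protein_id,
                "status": "retained",
                "best_match_length": r.match_length,
                "transcript": r.transcript_id,
            }
            for r in self.retained
        ] + [
            {"protein": pid, "status": "removed", "best_match_length": 0, "transcript": ""}
            for pid in self.removed
        ]
        return pd.DataFrame(rows).sort_values("protein").reset_index(drop=True)


def build_custom_db(
    transcripts: Mapping[str, str],
    reference_proteome: Mapping[str, str],
    min_orf_len: int = 20,
    min_match_len: int = 30,
) -> CustomProteomeDB:
    """Retain reference proteins with transcript-level evidence.

    A protein is retained iff some six-frame ORF of some transcript shares an
    exact ungapped substring of at least ``min_match_len`` amino acids with
    it.  Matching is seeded on shared ``min_match_len``-mers and extended
    greedily in both directions; the longest extension over all seed hits is
    recorded as the supporting match.
    """
    if not transcripts:
        raise InputError("empty transcript set")
    if not reference_proteome:
        raise InputError("empty reference proteome")
    if min_match_len < 1:
        raise ParameterError(f"min_match_len must be >= 1, got {min_match_len}")
    L = min_match_len

    # seed index: L-mer -> (transcript id, ORF sequence, position in ORF)
    seed_index: dict[str, tuple[str, str, int]] = {}
    for tx_id in sorted(transcripts):
        for orf in six_frame_translate(transcripts[tx_id], min_orf_len, tx_id):
            aa = orf.aa_seq
            for i in range(len(aa) - L + 1):
                seed_index.setdefault(aa[i : i + L], (tx_id, aa, i))

    retained: list[RetainedProtein] = []
    removed: dict[str, str] = {}
    for pid in sorted(reference_proteome):
        pseq = reference_proteome[pid]
        best: RetainedProtein | None = None
        for j in range(len(pseq) - L + 1):
            hit = seed_index.get(pseq[j : j + L])
            if hit is None:
                continue
            tx_id, orf_seq, i = hit
            lo_p, lo_o = j, i
            while lo_p > 0 and lo_o > 0 and pseq[lo_p - 1] == orf_seq[lo_o - 1]:
                lo_p -= 1
                lo_o -= 1
            hi_p, hi_o = j + L, i + L
            while hi_p < len(pseq) and hi_o < len(orf_seq) and pseq[hi_p] == orf_seq[hi_o]:
                hi_p += 1
                hi_o += 1
            if best is None or (hi_p - lo_p) > best.match_length:
                best = RetainedProtein(pid, pseq, tx_id, lo_p, hi_p)
        if best is not None:
            retained.append(best)
        else:
            removed[pid] = f"no shared substring of >= {L} aa with any ORF"
    return CustomProteomeDB(retained=retained, removed=removed, min_match_len=L)
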