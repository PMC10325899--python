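"""Readers, writers and the shared coordinate convention.

Every coordinate in this package is 0-based, half-open, in *transcript*
space (position 0 is the first nucleotide of the transcript, not the CDS).
Positions inside a coding region are additionally expressed in "CDS frame":
nucleotides counted from the start codon. :func:`to_one_based` is the single
place where display coordinates are produced.

Transcript sequences travel as FASTA; annotations, coverage, peaks, reads
and count tables travel as plain TSV/BED so that every intermediate is
diffable. All readers accept gzip-compressed files transparently.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "TranscriptModel",
    "PeakRecord",
    "read_transcripts",
    "write_transcripts",
    "read_peaks",
    "write_peaks",
    "filter_peaks",
    "read_bed6",
    "write_bed6",
    "to_one_based",
]


class TranscriptError(ValueError):
    """A transcript model violates the frame or alphabet contract."""


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with its CDS partition and derived protein.

    ``cds_start``/``cds_end`` are 0-based half-open transcript coordinates;
    the CDS includes the terminal stop codon, which is excluded from
    ``protein``. ``N`` bases translate to ``X``.
    """

    id: str
    sequence: str
    cds_start: int
    cds_end: int
    protein: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
            raise TranscriptError(
                f"{self.id}: CDS [{self.cds_start},{self.cds_end}) outside "
                f"sequence of length {len(self.sequence)}"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise TranscriptError(
                f"{self.id}: CDS length {self.cds_end - self.cds_start} "
                "not divisible by 3"
            )
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise TranscriptError(f"{self.id}: unexpected bases {sorted(bad)}")
        if not self.protein:
            object.__setattr__(self, "protein", self._translate())

    def _translate(self) -> str:
        cds = self.sequence[self.cds_start : self.cds_end]
        aa = str(Seq(cds).translate())
        if aa and aa[-1] == "*":
            aa = aa[:-1]
        else:
            raise TranscriptError(f"{self.id}: CDS does not end in a stop codon")
        if "*" in aa:
            raise TranscriptError(
                f"{self.id}: internal stop codon at protein position "
                f"{aa.index('*')}"
            )
        return aa

    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def n_codons(self) -> int:
        """Coding codons, terminal stop excluded."""
        return self.cds_len // 3 - 1

    def codon_of(self, nt_in_transcript: int) -> int:
        """Codon index of a transcript-space nucleotide inside the CDS."""
        return (nt_in_transcript - self.cds_start) // 3


@dataclass(frozen=True)
class PeakRecord:
    """A crosslink peak interval with its enrichment statistics."""

    transcript_id: str
    start: int
    end: int
    fold_enrichment: float
    p_value: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak on {self.transcript_id}: start >= end")
        if self.fold_enrichment < 0:
            raise ValueError("fold_enrichment < 0")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")

    @property
    def center(self) -> int:
        # Midpoint; the least-assumption collapse of an interval to an anchor.
        return (self.start + self.end) // 2


def read_transcripts(
    fasta_path: str | Path, annotation_path: str | Path
) -> dict[str, TranscriptModel]:
    """Load transcripts from a FASTA plus a CDS annotation TSV.

    The annotation needs columns ``transcript_id``, ``cds_start``,
    ``cds_end`` (0-based half-open). Every annotation row must name a FASTA
    record; frame violations and internal stops raise
    :class:`TranscriptError` naming the transcript.
    """
    with _open_text(fasta_path) as fh:
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    ann = pd.read_csv(annotation_path, sep="\t")
    out: dict[str, TranscriptModel] = {}
    for row in ann.itertuples(index=False):
        tid = str(row.transcript_id)
        if tid not in seqs:
            raise TranscriptError(f"annotation names {tid}, absent from FASTA")
        out[tid] = TranscriptModel(
            id=tid,
            sequence=seqs[tid],
            cds_start=int(row.cds_start),
            cds_end=int(row.cds_end),
        )
    return out


def write_transcripts(
    transcripts: Iterable[TranscriptModel],
    fasta_path: str | Path,
    annotation_path: str | Path,
) -> None:
    transcripts = list(transcripts)
    with _open_text(fasta_path, "wt") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n")
            for i in range(0, len(t.sequence), 70):
                fh.write(t.sequence[i : i + 70] + "\n")
    pd.DataFrame(
        {
            "transcript_id": [t.id for t in transcripts],
            "cds_start": [t.cds_start for t in transcripts],
            "cds_end": [t.cds_end for t in transcripts],
        }
    ).to_csv(annotation_path, sep="\t", index=False)


PEAK_COLUMNS = ["transcript_id", "start", "end", "fold_enrichment", "p_value"]


def read_peaks(path: str | Path) -> list[PeakRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        PeakRecord(
            transcript_id=str(r.transcript_id),
            start=int(r.start),
            end=int(r.end),
            fold_enrichment=float(r.fold_enrichment),
            p_value=float(r.p_value),
        )
        for r in df.itertuples(index=False)
    ]


def write_peaks(peaks: Sequence[PeakRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            (p.transcript_id, p.start, p.end, p.fold_enrichment, p.p_value)
            for p in peaks
        ],
        columns=PEAK_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def filter_peaks(
    peaks: Iterable[PeakRecord],
    min_fold: float = 8.0,
    max_p: float = 1e-5,
) -> list[PeakRecord]:
    """Keep peaks with fold enrichment strictly above ``min_fold`` and
    p-value strictly below ``max_p`` — both inequalities strict."""
    return [
        p for p in peaks if p.fold_enrichment > min_fold and p.p_value < max_p
    ]


BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed6(path: str | Path) -> pd.DataFrame:
    """BED6 footprints: chrom = transcript id, score = read length."""
    df = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["score"] = df["score"].astype(int)
    return df


def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(
    counts_by_transcript: dict[str, "np.ndarray"], path: str | Path,
    offset_by_transcript: dict[str, int] | None = None,
) -> None:
    """Write per-nucleotide counts as bedGraph (runs of equal value).

    ``offset_by_transcript`` shifts positions into transcript coordinates
    (e.g. the CDS start) so CDS-frame vectors land where they belong.
    """
    import numpy as np

    with _open_text(path, "wt") as fh:
        for tid in sorted(counts_by_transcript):
            counts = np.asarray(counts_by_transcript[tid])
            shift = (offset_by_transcript or {}).get(tid, 0)
            if counts.size == 0:
                continue
            edges = np.flatnonzero(np.diff(counts)) + 1
            starts = np.concatenate([[0], edges])
            ends = np.concatenate([edges, [len(counts)]])
            for s, e in zip(starts, ends):
                fh.write(f"{tid}\t{s + shift}\t{e + shift}\t{counts[s]}\n")


def read_bedgraph(path: str | Path) -> dict[str, dict[int, float]]:
    """Read a bedGraph into per-transcript sparse position→value maps."""
    out: dict[str, dict[int, float]] = {}
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split("\t")
            d = out.setdefault(chrom, {})
            for pos in range(int(start), int(end)):
                d[pos] = float(value)
    return out


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive display."""
    return start + 1, end
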