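"""P-site offset calibration and nucleotide-resolution CDS coverage.

Ribosome footprints protect ~26–34 nt of mRNA; the ribosomal P-site sits a
length-dependent distance downstream of the footprint's 5′ end. Offsets are
calibrated per read length from the start-codon metagene: for footprints
whose P-site is the start codon, ``cds_start − five_prime_end`` equals the
offset, so the modal value of that difference over many reads recovers it.

Coverage vectors count P-sites per CDS nucleotide for one library
(condition × replicate). Genes enter downstream analysis only when their
mean P-site count per CDS nucleotide is at least 1 in every library.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import TranscriptModel

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageVector",
    "OffsetTable",
    "estimate_offsets",
    "build_coverage",
    "filter_genes",
    "filter_genes_rpkm",
]


@dataclass
class CoverageVector:
    """Per-nucleotide P-site counts over one gene's CDS in one library."""

    transcript_id: str
    replicate: int
    condition: str
    counts: np.ndarray  # length = CDS length, non-negative ints
    library_size: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError(f"{self.transcript_id}: negative counts")

    @property
    def library(self) -> str:
        return f"{self.condition}:{self.replicate}"

    @property
    def mean_coverage(self) -> float:
        return float(self.counts.mean())


@dataclass
class OffsetTable:
    """Map read length → P-site offset, with the calibration histograms."""

    offsets: dict[int, int]
    histograms: dict[int, dict[int, int]] = field(default_factory=dict)

    def __contains__(self, length: int) -> bool:
        return length in self.offsets

    def __getitem__(self, length: int) -> int:
        return self.offsets[length]


class CalibrationError(RuntimeError):
    pass


def estimate_offsets(
    footprints: pd.DataFrame,
    transcripts: dict[str, TranscriptModel],
    search_window: tuple[int, int] = (8, 16),
    length_range: tuple[int, int] = (26, 34),
    min_reads_per_length: int = 100,
) -> OffsetTable:
    """Calibrate the P-site offset for each read length.

    For every footprint, the candidate offset is ``cds_start − 5′ end`` of
    the read on its transcript. Per length, the offset is the argmax of the
    histogram of candidates restricted to ``search_window`` (inclusive);
    ties break toward the smaller offset. Lengths with fewer than
    ``min_reads_per_length`` reads in the window are left uncalibrated and
    excluded downstream.
    """
    lo_w, hi_w = search_window
    lo_l, hi_l = length_range
    hists: dict[int, Counter] = {}
    cds_start = footprints["chrom"].map(
        lambda t: transcripts[t].cds_start if t in transcripts else np.nan
    )
    cand = cds_start - footprints["start"]
    lengths = footprints["score"]
    ok = (
        cand.notna()
        & (cand >= lo_w)
        & (cand <= hi_w)
        & (lengths >= lo_l)
        & (lengths <= hi_l)
    )
    for length, offset in zip(lengths[ok], cand[ok].astype(int)):
        hists.setdefault(int(length), Counter())[offset] += 1

    offsets: dict[int, int] = {}
    for length, hist in sorted(hists.items()):
        total = sum(hist.values())
        if total < min_reads_per_length:
            logger.info(
                "length %d: only %d reads in window, not calibrated",
                length,
                total,
            )
            continue
        best = max(hist.values())
        # tie-break toward the smaller offset
        offsets[length] = min(o for o, c in hist.items() if c == best)
    if not offsets:
        raise CalibrationError("no read length could be calibrated")
    return OffsetTable(offsets, {k: dict(v) for k, v in hists.items()})


def build_coverage(
    footprints: pd.DataFrame,
    offsets: OffsetTable,
    transcripts: dict[str, TranscriptModel],
) -> tuple[list[CoverageVector], dict[str, int]]:
    """Assign each footprint's P-site to a CDS position.

    A read of calibrated length L with 5′ end f increments CDS position
    ``f + offset[L] − cds_start`` when that lands in ``[0, cds_len)``.
    Reads of uncalibrated length and P-sites outside the CDS are tallied in
    the returned exclusion log, never silently dropped. Footprints carry a
    ``name`` column of the form ``condition:replicate`` identifying the
    library.
    """
    excluded = {"uncalibrated_length": 0, "outside_cds": 0, "unknown_transcript": 0}
    vectors: dict[tuple[str, str], CoverageVector] = {}
    lib_sizes: Counter = Counter()

    lengths = footprints["score"].to_numpy()
    starts = footprints["start"].to_numpy()
    chroms = footprints["chrom"].to_numpy()
    names = footprints["name"].to_numpy()

    for chrom, start, length, name in zip(chroms, starts, lengths, names):
        if chrom not in transcripts:
            excluded["unknown_transcript"] += 1
            continue
        if int(length) not in offsets:
            excluded["uncalibrated_length"] += 1
            continue
        t = transcripts[chrom]
        pos = int(start) + offsets[int(length)] - t.cds_start
        lib_sizes[name] += 1
        if not 0 <= pos < t.cds_len:
            excluded["outside_cds"] += 1
            continue
        key = (chrom, name)
        if key not in vectors:
            cond, rep = name.rsplit(":", 1)
            vectors[key] = CoverageVector(
                transcript_id=chrom,
                replicate=int(rep),
                condition=cond,
                counts=np.zeros(t.cds_len, dtype=np.int64),
            )
        vectors[key].counts[pos] += 1

    out = []
    for (chrom, name), vec in sorted(vectors.items()):
        vec.library_size = lib_sizes[name]
        out.append(vec)
    logger.info("coverage built; exclusions: %s", excluded)
    return out, excluded


def filter_genes(coverages: list[CoverageVector]) -> list[str]:
    """Genes whose mean P-site count per CDS nucleotide is ≥ 1 (inclusive)
    in every library present in ``coverages``."""
    by_gene: dict[str, list[CoverageVector]] = {}
    libraries = set()
    for vec in coverages:
        by_gene.setdefault(vec.transcript_id, []).append(vec)
        libraries.add(vec.library)
    kept = []
    for gene, vecs in sorted(by_gene.items()):
        libs_here = {v.library for v in vecs}
        if libs_here != libraries:
            continue  # absent from some library: mean coverage there is 0
        if all(v.mean_coverage >= 1.0 for v in vecs):
            kept.append(gene)
    return kept


def filter_genes_rpkm(
    coverages: list[CoverageVector], min_rpkm: float = 1.0
) -> list[str]:
    """Alternative expression filter: reads per kilobase of CDS per million
    library reads ≥ ``min_rpkm`` in every library."""
    by_gene: dict[str, list[CoverageVector]] = {}
    libraries = set()
    for vec in coverages:
        by_gene.setdefault(vec.transcript_id, []).append(vec)
        libraries.add(vec.library)
    kept = []
    for gene, vecs in sorted(by_gene.items()):
        if {v.library for v in vecs} != libraries:
            continue
        ok = True
        for v in vecs:
            if v.library_size == 0:
                ok = False
                break
            rpkm = v.counts.sum() / (len(v.counts) / 1e3) / (v.library_size / 1e6)
            if rpkm < min_rpkm:
                ok = False
                break
        if ok:
            kept.append(gene)
    return kept


def frame_to_coverage(df: pd.DataFrame) -> list[CoverageVector]:
    """Inverse of :func:`coverage_to_frame`."""
    lib_cols = [c for c in df.columns if c not in ("transcript_id", "position")]
    out = []
    totals = {lib: int(df[lib].sum()) for lib in lib_cols}
    for tid, sub in df.groupby("transcript_id", sort=True):
        sub = sub.sort_values("position")
        for lib in lib_cols:
            cond, rep = lib.rsplit(":", 1)
            out.append(
                CoverageVector(
                    transcript_id=tid,
                    replicate=int(rep),
                    condition=cond,
                    counts=sub[lib].to_numpy(dtype=np.int64),
                    library_size=totals[lib],
                )
            )
    return out


def coverage_to_frame(coverages: list[CoverageVector]) -> pd.DataFrame:
    """Wide TSV layout: transcript, position, one count column per library."""
    rows: dict[tuple[str, int], dict[str, int]] = {}
    for vec in coverages:
        for pos, c in enumerate(vec.counts):
            rows.setdefault((vec.transcript_id, pos), {})[vec.library] = int(c)
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    df.index = pd.MultiIndex.from_tuples(df.index, names=["transcript_id", "position"])
    return df.sort_index().reset_index()
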