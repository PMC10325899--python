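"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:

* transcripts whose CDSs carry planted glutamate/lysine-rich tracts;
* per-nucleotide footprint counts drawn negative-binomially around a
  gene-level mean shared across replicates, with multiplicative pause
  elevations planted a few codons downstream of tract ends;
* a knockdown condition in which the pause elevation is attenuated;
* footprint reads whose 5′ ends sit a length-dependent offset upstream of
  the P-site;
* crosslink peaks just downstream of tract ends, with enrichment/p-value
  columns of which a configurable fraction fails the significance filter;
* spectral-count tables with compartment bias and a mock-bead background.

All randomness flows from ``SimConfig.seed`` through fixed per-stage
streams, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageVector
from .io import TranscriptModel

__all__ = [
    "SimConfig",
    "TruthTable",
    "gen_transcripts",
    "gen_coverage",
    "gen_footprints",
    "gen_peaks",
    "gen_spectra",
    "CONDITIONS",
]

CONDITIONS = ("control", "knockdown")

# sense codons per residue (standard code), stop codons excluded everywhere
# except the single terminal stop appended to each CDS
_CODON_TABLE: dict[str, tuple[str, ...]] = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "N": ("AAT", "AAC"),
    "D": ("GAT", "GAC"),
    "C": ("TGT", "TGC"),
    "Q": ("CAA", "CAG"),
    "E": ("GAA", "GAG"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "K": ("AAA", "AAG"),
    "M": ("ATG",),
    "F": ("TTT", "TTC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
}
_STOPS = ("TAA", "TAG", "TGA")
_RESIDUES = tuple(sorted(_CODON_TABLE))

# stage identifiers for deterministic per-stage random streams
_STAGE_TRANSCRIPTS = 1
_STAGE_COVERAGE = 2
_STAGE_FOOTPRINTS = 3
_STAGE_PEAKS = 4
_STAGE_SPECTRA = 5


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment.

    Defaults describe a small but realistic ribosome-profiling experiment:
    moderately expressed genes (log-normal mean coverage around 10
    reads/nt), overdispersed counts (NB size 5), strong tenfold pauses
    downstream of charged tracts, three replicates per condition, footprint
    lengths 26–34 nt with canonical ~12 nt P-site offsets.
    """

    n_genes: int = 50
    cds_len_range: tuple[int, int] = (300, 900)  # nt, coding part
    tract_rate: float = 2.0  # expected charged tracts per gene (Poisson)
    tract_len_range: tuple[int, int] = (6, 12)  # aa
    tract_residues: tuple[str, ...] = ("E", "K")
    expr_log_mean: float = float(np.log(10.0))  # log reads/nt
    expr_log_sd: float = 0.6
    nb_size: float = 5.0  # variance = mu + mu^2/nb_size
    pause_rate: float = 1.5  # expected pauses per gene
    pause_factor: float = 10.0  # multiplicative elevation, > 1
    pause_offset_range: tuple[int, int] = (1, 3)  # codons downstream of tract end
    knockdown_attenuation: float = 0.2  # fraction of elevation retained
    n_replicates: int = 3
    read_len_range: tuple[int, int] = (26, 34)
    true_offsets: Mapping[int, int] = field(
        default_factory=lambda: {26: 10, 27: 10, 28: 11, 29: 11, 30: 12,
                                 31: 12, 32: 13, 33: 13, 34: 14}
    )
    utr5_len_range: tuple[int, int] = (30, 100)
    utr3_len_range: tuple[int, int] = (30, 150)
    init_peak_factor: float = 8.0  # start-codon read pileup vs gene mean
    depth_factors: Mapping[str, Sequence[float]] | None = None  # per condition
    # gene-level occupancy shift in the knockdown condition: a random
    # gene_shift_fraction of genes has its whole coverage vector (pauses
    # included) multiplied by gene_shift_factor — a biological shift a
    # normalization against the unshifted genes cannot remove
    gene_shift_factor: float = 1.0
    gene_shift_fraction: float = 0.0
    peak_width: int = 20  # nt
    peak_fraction_failing: float = 0.2  # peaks drawn to fail the 8x/1e-5 filter
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cds_len_range", "tract_len_range", "pause_offset_range",
                     "read_len_range", "utr5_len_range", "utr3_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name}: empty range ({lo}, {hi})")
        if self.pause_factor <= 1:
            raise ConfigurationError("pause_factor must exceed 1")
        if not 0 <= self.knockdown_attenuation <= 1:
            raise ConfigurationError("knockdown_attenuation must be in [0, 1]")
        if self.nb_size <= 0:
            raise ConfigurationError("nb_size must be positive")
        unknown = set(self.tract_residues) - set(_RESIDUES)
        if unknown:
            raise ConfigurationError(f"unknown tract residues {sorted(unknown)}")
        missing = [
            L for L in range(self.read_len_range[0], self.read_len_range[1] + 1)
            if L not in self.true_offsets
        ]
        if missing:
            raise ConfigurationError(f"true_offsets missing lengths {missing}")

    def pause_factor_for(self, condition: str) -> float:
        if condition == "control":
            return self.pause_factor
        if condition == "knockdown":
            return 1.0 + (self.pause_factor - 1.0) * self.knockdown_attenuation
        raise ValueError(f"unknown condition {condition!r}")

    def depth_factor(self, condition: str, replicate: int) -> float:
        if self.depth_factors is None:
            return 1.0
        return float(self.depth_factors[condition][replicate])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_offsets"] = {int(k): int(v) for k, v in self.true_offsets.items()}
        return d

    def _rng(self, stage: int, *extra: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage, *extra])


@dataclass
class TruthTable:
    """Ground truth: what the generator planted, per gene.

    ``tracts``: transcript_id, codon_start, codon_end (codon coordinates,
    half-open). ``pauses``: transcript_id, cds_pos (nt, CDS frame), codon,
    factor_control, factor_knockdown. ``peaks``: transcript_id, center
    (transcript nt). ``gene_means``: transcript_id, mean_coverage.
    ``size_factors``: library, depth.
    """

    gene_means: pd.DataFrame
    tracts: pd.DataFrame
    pauses: pd.DataFrame
    peaks: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["transcript_id", "center"])
    )
    size_factors: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["library", "depth"])
    )

    def validate(self, transcripts: Mapping[str, TranscriptModel]) -> None:
        for row in self.pauses.itertuples(index=False):
            t = transcripts[row.transcript_id]
            if not 0 <= row.cds_pos < t.cds_len:
                raise AssertionError(f"pause outside CDS on {row.transcript_id}")
        for row in self.peaks.itertuples(index=False):
            t = transcripts[row.transcript_id]
            if not t.cds_start <= row.center < t.cds_end:
                raise AssertionError(f"peak outside CDS on {row.transcript_id}")


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    residues = rng.choice(_RESIDUES, size=n)
    return [_CODON_TABLE[a][rng.integers(len(_CODON_TABLE[a]))] for a in residues]


def gen_transcripts(
    cfg: SimConfig,
) -> tuple[dict[str, TranscriptModel], TruthTable]:
    """Generate transcripts with planted charged tracts and pause truth.

    Tract count per gene is Poisson(``tract_rate``); tract residues are
    drawn from ``tract_residues``; overlapping placements are resampled up
    to 100 times and then raise. Pauses (Poisson(``pause_rate``) per gene,
    capped at the tract count) sit at the first nucleotide of a codon
    ``pause_offset_range`` codons downstream of a tract end.
    """
    rng = cfg._rng(_STAGE_TRANSCRIPTS)
    max_tract = cfg.tract_len_range[1]
    if cfg.tract_rate > 0 and cfg.cds_len_range[0] // 3 < max_tract:
        raise ConfigurationError(
            "cds_len_range too small to host requested tracts"
        )

    transcripts: dict[str, TranscriptModel] = {}
    mean_rows, tract_rows, pause_rows = [], [], []

    for g in range(cfg.n_genes):
        tid = f"gene{g:04d}"
        coding_len = int(rng.integers(cfg.cds_len_range[0], cfg.cds_len_range[1] + 1))
        n_codons = coding_len // 3  # coding codons, stop appended separately

        # place non-overlapping tracts
        n_tracts = rng.poisson(cfg.tract_rate) if cfg.tract_rate > 0 else 0
        placed: list[tuple[int, int]] = []
        for _ in range(n_tracts):
            tlen = int(rng.integers(cfg.tract_len_range[0], cfg.tract_len_range[1] + 1))
            # keep tracts off the start codon and leave room downstream
            lo, hi = 1, n_codons - tlen - cfg.pause_offset_range[1]
            if hi <= lo:
                raise ConfigurationError(
                    f"{tid}: CDS of {n_codons} codons cannot host a "
                    f"{tlen}-codon tract"
                )
            for attempt in range(100):
                start = int(rng.integers(lo, hi))
                iv = (start, start + tlen)
                if all(iv[1] <= a or iv[0] >= b for a, b in placed):
                    placed.append(iv)
                    break
            else:
                raise ConfigurationError(
                    f"{tid}: could not place tract after 100 attempts"
                )
        placed.sort()

        # build the protein: ATG start, tract residues, random elsewhere
        codons = ["ATG"] + _random_codons(rng, n_codons - 1)
        for start, end in placed:
            for c in range(start, end):
                aa = cfg.tract_residues[rng.integers(len(cfg.tract_residues))]
                codons[c] = _CODON_TABLE[aa][rng.integers(len(_CODON_TABLE[aa]))]
        stop = _STOPS[rng.integers(len(_STOPS))]
        cds = "".join(codons) + stop

        utr5 = "".join(rng.choice(list("ACGT"),
                                  size=rng.integers(cfg.utr5_len_range[0],
                                                    cfg.utr5_len_range[1] + 1)))
        utr3 = "".join(rng.choice(list("ACGT"),
                                  size=rng.integers(cfg.utr3_len_range[0],
                                                    cfg.utr3_len_range[1] + 1)))
        seq = utr5 + cds + utr3
        transcripts[tid] = TranscriptModel(
            id=tid,
            sequence=seq,
            cds_start=len(utr5),
            cds_end=len(utr5) + len(cds),
        )

        mu = float(np.exp(rng.normal(cfg.expr_log_mean, cfg.expr_log_sd)))
        shifted = (cfg.gene_shift_fraction > 0
                   and rng.random() < cfg.gene_shift_fraction)
        mean_rows.append((tid, mu, cfg.gene_shift_factor if shifted else 1.0))
        for start, end in placed:
            tract_rows.append((tid, start, end))

        # pauses downstream of a subset of tract ends
        if placed and cfg.pause_rate > 0:
            n_pauses = min(int(rng.poisson(cfg.pause_rate)), len(placed))
            chosen = rng.choice(len(placed), size=n_pauses, replace=False)
            for idx in sorted(chosen):
                _, tract_end = placed[idx]
                off = int(rng.integers(cfg.pause_offset_range[0],
                                       cfg.pause_offset_range[1] + 1))
                codon = tract_end + off - 1  # last tract codon is tract_end-1
                if codon >= n_codons:
                    continue
                pause_rows.append(
                    (
                        tid,
                        3 * codon,  # first nt of the codon, CDS frame
                        codon,
                        cfg.pause_factor_for("control"),
                        cfg.pause_factor_for("knockdown"),
                    )
                )

    sf_rows = [
        (f"{cond}:{r}", cfg.depth_factor(cond, r))
        for cond in CONDITIONS
        for r in range(cfg.n_replicates)
    ]
    truth = TruthTable(
        gene_means=pd.DataFrame(
            mean_rows,
            columns=["transcript_id", "mean_coverage", "knockdown_shift"],
        ),
        tracts=pd.DataFrame(tract_rows,
                            columns=["transcript_id", "codon_start", "codon_end"]),
        pauses=pd.DataFrame(
            pause_rows,
            columns=["transcript_id", "cds_pos", "codon",
                     "factor_control", "factor_knockdown"],
        ),
        size_factors=pd.DataFrame(sf_rows, columns=["library", "depth"]),
    )
    truth.validate(transcripts)
    return transcripts, truth


def gen_coverage(
    transcripts: Mapping[str, TranscriptModel],
    truth: TruthTable,
    cfg: SimConfig,
    condition: str,
) -> list[CoverageVector]:
    """Draw NB per-nucleotide P-site counts for every gene and replicate.

    Non-pause positions have mean ``gene_mean × depth``; pause positions
    have that mean multiplied by the condition's pause factor. Replicates
    are independent draws sharing means.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    cond_idx = CONDITIONS.index(condition)
    k = cfg.nb_size
    means = dict(zip(truth.gene_means["transcript_id"],
                     truth.gene_means["mean_coverage"]))
    shifts = dict(zip(truth.gene_means["transcript_id"],
                      truth.gene_means.get("knockdown_shift",
                                           np.ones(len(truth.gene_means)))))
    pause_by_gene: dict[str, list[tuple[int, float]]] = {}
    fcol = "factor_control" if condition == "control" else "factor_knockdown"
    for row in truth.pauses.itertuples(index=False):
        pause_by_gene.setdefault(row.transcript_id, []).append(
            (row.cds_pos, getattr(row, fcol))
        )

    out: list[CoverageVector] = []
    for tid in sorted(transcripts):
        t = transcripts[tid]
        base = means[tid]
        if condition == "knockdown":
            base = base * shifts.get(tid, 1.0)
        for rep in range(cfg.n_replicates):
            rng = cfg._rng(_STAGE_COVERAGE, cond_idx, rep, _gene_key(tid))
            mu = np.full(t.cds_len, base * cfg.depth_factor(condition, rep))
            for pos, factor in pause_by_gene.get(tid, []):
                mu[pos] *= factor
            p = k / (k + mu)
            counts = rng.negative_binomial(k, p)
            out.append(
                CoverageVector(
                    transcript_id=tid,
                    replicate=rep,
                    condition=condition,
                    counts=counts.astype(np.int64),
                )
            )
    totals: dict[str, int] = {}
    for vec in out:
        totals[vec.library] = totals.get(vec.library, 0) + int(vec.counts.sum())
    for vec in out:
        vec.library_size = totals[vec.library]
    return out


def _gene_key(tid: str) -> int:
    return int(tid.replace("gene", "")) if tid.startswith("gene") else abs(hash(tid)) % (2**31)


def gen_footprints(
    coverages: Iterable[CoverageVector],
    transcripts: Mapping[str, TranscriptModel],
    cfg: SimConfig,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Emit BED6 footprint reads realizing the given P-site coverage.

    Each P-site count at CDS position p becomes a read of random length L
    (uniform over ``read_len_range``) whose 5′ end is
    ``cds_start + p − true_offsets[L]`` in transcript coordinates. On top
    of the coverage an initiation pileup of
    Poisson((init_peak_factor − 1) × gene mean) extra reads is emitted at
    the start codon — the feature metagene offset calibration relies on.
    Reads that would extend past the transcript are dropped and counted.
    Returns the reads plus ``{"n_clipped": ..., "n_init": ...}`` so that
    read totals remain reconcilable with the coverage
    (reads + clipped = coverage sum + initiation reads). BED columns:
    chrom = transcript id, name = ``condition:replicate``, score = read
    length.
    """
    lengths_avail = np.arange(cfg.read_len_range[0], cfg.read_len_range[1] + 1)
    offsets = np.array([cfg.true_offsets[int(L)] for L in lengths_avail])

    chroms, starts, ends, names, scores = [], [], [], [], []
    n_clipped = 0
    n_init = 0
    for vec in coverages:
        t = transcripts[vec.transcript_id]
        rng = cfg._rng(
            _STAGE_FOOTPRINTS,
            CONDITIONS.index(vec.condition),
            vec.replicate,
            _gene_key(vec.transcript_id),
        )
        counts = np.asarray(vec.counts)
        positions = np.repeat(np.arange(len(counts)), counts)
        if cfg.init_peak_factor > 1:
            extra = int(rng.poisson((cfg.init_peak_factor - 1)
                                    * counts.mean()))
            n_init += extra
            positions = np.concatenate(
                [np.zeros(extra, dtype=positions.dtype), positions]
            )
        if positions.size == 0:
            continue
        li = rng.integers(0, len(lengths_avail), size=positions.size)
        L = lengths_avail[li]
        five = t.cds_start + positions - offsets[li]
        keep = (five >= 0) & (five + L <= len(t.sequence))
        n_clipped += int((~keep).sum())
        chroms.append(np.full(keep.sum(), t.id, dtype=object))
        starts.append(five[keep])
        ends.append((five + L)[keep])
        names.append(np.full(keep.sum(), vec.library, dtype=object))
        scores.append(L[keep])

    stats = {"n_clipped": n_clipped, "n_init": n_init}
    if not chroms:
        df = pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
        return df, stats
    df = pd.DataFrame(
        {
            "chrom": np.concatenate(chroms),
            "start": np.concatenate(starts),
            "end": np.concatenate(ends),
            "name": np.concatenate(names),
            "score": np.concatenate(scores),
            "strand": "+",
        }
    )
    return df, stats


def gen_peaks(
    transcripts: Mapping[str, TranscriptModel],
    truth: TruthTable,
    cfg: SimConfig,
) -> pd.DataFrame:
    """Place one crosslink peak downstream of each planted tract end.

    The peak center sits ``pause_offset_range`` codons downstream of the
    tract end (first nucleotide of that codon, transcript coordinates).
    Fold-enrichment and p-value columns are drawn so that a
    ``peak_fraction_failing`` fraction of peaks fails the ">8-fold,
    p < 1e−5" significance filter. Peak centers are recorded in
    ``truth.peaks``.
    """
    rng = cfg._rng(_STAGE_PEAKS)
    rows, truth_rows = [], []
    w = cfg.peak_width
    for row in truth.tracts.itertuples(index=False):
        t = transcripts[row.transcript_id]
        off = int(rng.integers(cfg.pause_offset_range[0],
                               cfg.pause_offset_range[1] + 1))
        center_codon = row.codon_end + off - 1
        center = t.cds_start + 3 * center_codon
        if not t.cds_start <= center < t.cds_end:
            continue
        start = max(0, center - w // 2)
        end = min(len(t.sequence), start + w)
        failing = rng.random() < cfg.peak_fraction_failing
        if failing:
            if rng.random() < 0.5:
                fold = float(rng.uniform(1.0, 8.0))
                p = float(10 ** rng.uniform(-12, -6))
            else:
                fold = float(rng.uniform(9.0, 50.0))
                p = float(10 ** rng.uniform(-5, -2))
        else:
            fold = float(rng.uniform(9.0, 50.0))
            p = float(10 ** rng.uniform(-12, -6))
        rows.append((t.id, start, end, fold, p))
        truth_rows.append((t.id, center))

    truth.peaks = pd.DataFrame(truth_rows, columns=["transcript_id", "center"])
    return pd.DataFrame(
        rows, columns=["transcript_id", "start", "end", "fold_enrichment", "p_value"]
    )


SPECTRA_POOLS = ("rna_dep", "ribosome", "mrnp")


def gen_spectra(
    n_proteins: int,
    compartment_bias: float,
    mock_background: float,
    n_replicates: int = 3,
    seed: int = 0,
    n_experiments: int = 2,
    frac_interactors: float = 0.4,
    abundance_log_mean: float = 3.0,
    abundance_log_sd: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spectral-count tables for ER/cytosol fractionation pools.

    Per protein: an endoplasmic-reticulum fraction
    ``0.5 + compartment_bias·(u − 0.5)`` (u uniform; bias 0 puts every
    protein at 50% ER), a log-normal abundance, and a Bernoulli interactor
    flag. Counts are Poisson about pool means: interactors carry their
    abundance into the mRNP (oligo-dT) pool, non-interactors leave only
    mock-level background there; the mock pool has mean
    ``mock_background``. Returns the long count table
    (protein, experiment, pool, compartment, replicate, count) and a truth
    table (protein, true_percent_er, interactor).
    """
    if not 0 <= compartment_bias <= 1:
        raise ValueError("compartment_bias must be in [0, 1]")
    rng = np.random.default_rng([seed, _STAGE_SPECTRA])
    u = rng.uniform(size=n_proteins)
    er_frac = 0.5 + compartment_bias * (u - 0.5)
    abundance = np.exp(rng.normal(abundance_log_mean, abundance_log_sd, n_proteins))
    interactor = rng.uniform(size=n_proteins) < frac_interactors

    rows = []
    for i in range(n_proteins):
        pid = f"prot{i:04d}"
        for exp in range(n_experiments):
            for pool in SPECTRA_POOLS:
                for comp, f in (("ER", er_frac[i]), ("Cyto", 1 - er_frac[i])):
                    if pool == "mrnp" and not interactor[i]:
                        # non-specific background: mock level split by compartment
                        mean = mock_background * f
                    else:
                        mean = abundance[i] * f
                    for rep in range(n_replicates):
                        rows.append(
                            (pid, exp, pool, comp, rep, int(rng.poisson(mean)))
                        )
            # one mock-bead pulldown per oligo-dT experiment
            for rep in range(n_replicates):
                rows.append(
                    (pid, exp, "mock", "NA", rep, int(rng.poisson(mock_background)))
                )

    table = pd.DataFrame(
        rows,
        columns=["protein_id", "experiment", "pool", "compartment",
                 "replicate", "count"],
    )
    truth = pd.DataFrame(
        {
            "protein_id": [f"prot{i:04d}" for i in range(n_proteins)],
            "true_percent_er": 100 * er_frac,
            "interactor": interactor,
        }
    )
    return table, truth
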