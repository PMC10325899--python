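"""Scoring of spectral-count fractionation tables.

Proteins are scored present in the RNA-dependent and ribosome-bound
polysome fractions when peptides appear in at least two of three
biological replicates. For the oligo-dT (mRNP) pulldowns a protein must
additionally be at least two-fold enriched over the matched mock-bead
pulldown in both experiments (summed peptide counts; a zero mock total is
replaced by a 0.5 pseudo-count). High-confidence polysome interactors are
the intersection: present in the mRNP pool AND in either the RNA-dependent
or ribosome-bound pool. Percent ER is
100 × ER peptides / (ER + cytosolic peptides) per experiment, averaged
over experiments with nonzero totals.

Input is a long table with columns protein_id, experiment, pool
(rna_dep | ribosome | mrnp | mock), compartment (ER | Cyto | NA),
replicate, count — the layout :func:`ribostall.simulate.gen_spectra`
emits and the TSV reader accepts.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "presence_call",
    "oligodt_call",
    "percent_er",
    "call_interactors",
]

MOCK_PSEUDOCOUNT = 0.5


def presence_call(
    counts: Sequence[float], min_replicates: int = 2
) -> bool:
    """True iff the count is positive in at least ``min_replicates``
    replicates."""
    return int(sum(1 for c in counts if c > 0)) >= min_replicates


def oligodt_call(
    counts: np.ndarray,
    mock_counts: np.ndarray,
    fold: float = 2.0,
    min_replicates: int = 2,
) -> bool:
    """Oligo-dT interactor rule across matched experiments.

    ``counts`` and ``mock_counts`` are (n_experiments, n_replicates)
    arrays. The protein must pass the replicate presence call in every
    experiment and have a summed count at least ``fold`` times the mock
    total in every experiment (inclusive ≥). A zero mock total is
    replaced by a 0.5 pseudo-count and logged.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    mock = np.atleast_2d(np.asarray(mock_counts, dtype=float))
    if counts.shape[0] != mock.shape[0]:
        raise ValueError("experiments must be matched between pulldown and mock")
    for exp in range(counts.shape[0]):
        if not presence_call(counts[exp], min_replicates=min_replicates):
            return False
        mock_total = mock[exp].sum()
        if mock_total == 0:
            logger.info("mock total zero; using %.1f pseudo-count",
                        MOCK_PSEUDOCOUNT)
            mock_total = MOCK_PSEUDOCOUNT
        if counts[exp].sum() / mock_total < fold:
            return False
    return True


def percent_er(
    er_peptides: Sequence[float], cyto_peptides: Sequence[float]
) -> float:
    """Percent ER: 100 × ER/(ER + cytosol) per experiment, averaged.

    Experiments where both totals are zero are excluded; if every
    experiment is zero-total the result is NaN (flagged by the caller).
    """
    er = np.asarray(er_peptides, dtype=float)
    cy = np.asarray(cyto_peptides, dtype=float)
    if er.shape != cy.shape:
        raise ValueError("ER and cytosol vectors must align per experiment")
    total = er + cy
    ok = total > 0
    if not ok.any():
        return float("nan")
    return float(np.mean(100.0 * er[ok] / total[ok]))


def _pool_matrix(
    sub: pd.DataFrame, pool: str, compartments: Iterable[str]
) -> np.ndarray:
    """(n_experiments, n_replicates) per-replicate totals over compartments."""
    sel = sub[(sub["pool"] == pool) & (sub["compartment"].isin(compartments))]
    piv = sel.pivot_table(
        index="experiment", columns="replicate", values="count",
        aggfunc="sum", fill_value=0,
    )
    return piv.to_numpy(dtype=float)


def call_interactors(
    table: pd.DataFrame,
    min_replicates: int = 2,
    fold: float = 2.0,
    exclude: Iterable[str] = (),
) -> pd.DataFrame:
    """Score every protein in a long spectral-count table.

    Returns one row per protein with the presence calls, the
    high-confidence intersection flag, percent ER per fraction pool and
    averaged. Proteins on the curated ``exclude`` list are removed; the
    number removed is stored in ``result.attrs["n_excluded"]``.
    """
    exclude = set(exclude)
    n_excluded = len(set(table["protein_id"]) & exclude)
    table = table[~table["protein_id"].isin(exclude)].copy()
    # TSV readers may parse the mock pool's "NA" compartment as missing
    table["compartment"] = table["compartment"].fillna("NA")

    rows = []
    for pid, sub in table.groupby("protein_id", sort=True):
        present = {}
        for pool in ("rna_dep", "ribosome"):
            mat = _pool_matrix(sub, pool, ("ER", "Cyto"))
            present[pool] = any(
                presence_call(mat[e], min_replicates=min_replicates)
                for e in range(mat.shape[0])
            )
        mrnp = _pool_matrix(sub, "mrnp", ("ER", "Cyto"))
        mock = _pool_matrix(sub, "mock", ("NA",))
        present_oligo = oligodt_call(mrnp, mock, fold=fold,
                                     min_replicates=min_replicates)
        high_conf = present_oligo and (present["ribosome"] or present["rna_dep"])

        pct = {}
        for pool in ("rna_dep", "ribosome", "mrnp"):
            er = sub[(sub["pool"] == pool) & (sub["compartment"] == "ER")]
            cy = sub[(sub["pool"] == pool) & (sub["compartment"] == "Cyto")]
            er_t = er.groupby("experiment")["count"].sum()
            cy_t = cy.groupby("experiment")["count"].sum()
            exps = sorted(set(er_t.index) | set(cy_t.index))
            pct[pool] = percent_er(
                [er_t.get(e, 0) for e in exps], [cy_t.get(e, 0) for e in exps]
            )
        pool_vals = [v for v in pct.values() if not np.isnan(v)]
        rows.append(
            {
                "protein_id": pid,
                "present_rna_dep": present["rna_dep"],
                "present_ribosome": present["ribosome"],
                "present_oligo_dt": present_oligo,
                "high_confidence": high_conf,
                "percent_er_rna_dep": pct["rna_dep"],
                "percent_er_ribosome": pct["ribosome"],
                "percent_er_mrnp": pct["mrnp"],
                "percent_er_mean": float(np.mean(pool_vals))
                if pool_vals
                else float("nan"),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_excluded"] = int(n_excluded)
    return out
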