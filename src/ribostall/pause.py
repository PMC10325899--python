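"""Nucleotide-resolution ribosome pause-site calling.

A gene's ribosome-occupancy coverage vector is modelled, per replicate, as
negative-binomial after trimming the 5% largest and 5% smallest positions
(pauses are by definition top outliers and must not inflate the fit; they
are still scanned and assigned p-values). Each position gets the inclusive
upper-tail probability P(X ≥ x) under the replicate's fitted distribution;
replicate p-values are combined with Fisher's method
(−2·Σ ln p ~ χ² with 2R degrees of freedom) and positions with a combined
p-value strictly below 1e−7 are called pause sites.

The NB is parameterized by mean μ and size k with variance μ + μ²/k;
the default estimator is method-of-moments with a Poisson fallback when
the sample variance does not exceed the mean, and a maximum-likelihood
estimator is available behind ``estimator="mle"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .coverage import CoverageVector

logger = logging.getLogger(__name__)

__all__ = [
    "NBParams",
    "trim_outliers",
    "fit_nb",
    "correct_trimmed_fit",
    "position_pvalue",
    "fisher_combine",
    "call_pauses",
]

PAUSE_THRESHOLD = 1e-7
ZERO_P_FLOOR = 1e-300


@dataclass(frozen=True)
class NBParams:
    """Fitted count distribution for one gene in one replicate."""

    mu: float
    size: float  # NB size k; variance = mu + mu^2/k
    fit_kind: str  # "negative_binomial" | "poisson_fallback" | "degenerate"
    n_used: int

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.fit_kind == "negative_binomial" and self.size <= 0:
            raise ValueError("NB size must be positive")


def trim_outliers(
    counts: np.ndarray, frac: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Drop the ``floor(frac·L)`` largest and smallest values.

    Ties are broken by position order, leftmost removed first. Returns
    (retained values, removed indices). Vectors shorter than 20 positions
    lose nothing at the default 5% (floor(0.95) = 0).
    """
    x = np.asarray(counts)
    L = len(x)
    m = int(np.floor(frac * L))
    if m == 0:
        return x.copy(), np.array([], dtype=int)
    asc = np.argsort(x, kind="stable")
    bottom = asc[:m]
    desc = np.argsort(-x, kind="stable")
    top = desc[~np.isin(desc, bottom)][:m]
    removed = np.concatenate([bottom, top])
    keep = np.ones(L, dtype=bool)
    keep[removed] = False
    return x[keep], np.sort(removed)


def fit_nb(retained: np.ndarray, estimator: str = "mom") -> NBParams:
    """Fit the NB by method of moments (default) or maximum likelihood.

    Method of moments: μ = m̄, k = m̄²/(s² − m̄) with the unbiased sample
    variance; when s² ≤ m̄ the data are not overdispersed and a Poisson
    with mean m̄ is used instead. An all-zero vector gives a degenerate
    fit whose p-values are all 1.
    """
    x = np.asarray(retained, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 retained positions to fit")
    m = float(x.mean())
    if m == 0.0:
        return NBParams(mu=0.0, size=np.inf, fit_kind="degenerate", n_used=len(x))
    s2 = float(x.var(ddof=1))
    if estimator == "mom":
        if s2 <= m:
            return NBParams(mu=m, size=np.inf, fit_kind="poisson_fallback",
                            n_used=len(x))
        return NBParams(mu=m, size=m * m / (s2 - m),
                        fit_kind="negative_binomial", n_used=len(x))
    if estimator == "mle":
        return _fit_nb_mle(x, m, s2)
    raise ValueError(f"unknown estimator {estimator!r}")


def _fit_nb_mle(x: np.ndarray, m: float, s2: float) -> NBParams:
    # profile likelihood in k; the mean MLE equals the sample mean
    def nll(log_k: float) -> float:
        k = np.exp(log_k)
        return -float(stats.nbinom.logpmf(x, k, k / (k + m)).sum())

    k0 = m * m / (s2 - m) if s2 > m else 10.0
    res = optimize.minimize_scalar(
        nll, bracket=(np.log(k0) - 2, np.log(k0) + 2), method="brent"
    )
    k = float(np.exp(res.x))
    if k > 1e6:  # effectively Poisson
        return NBParams(mu=m, size=np.inf, fit_kind="poisson_fallback",
                        n_used=len(x))
    return NBParams(mu=m, size=k, fit_kind="negative_binomial", n_used=len(x))


def _trimmed_moments(mu: float, k: float, frac: float) -> tuple[float, float]:
    """Asymptotic mean and variance of an NB(mu, k) sample after removing
    the ``frac`` smallest and largest order statistics.

    Computed as quantile integrals ∫ Q(u) du over u ∈ [frac, 1 − frac]:
    boundary mass points of the discrete distribution get fractional
    weight, exactly as count-based trimming splits them.
    """
    dist = stats.nbinom(k, k / (k + mu))
    b = int(dist.ppf(1 - frac / 4)) + 2
    xs = np.arange(0, b + 1)
    F = dist.cdf(xs)
    F_prev = np.concatenate([[0.0], F[:-1]])
    w = np.clip(np.minimum(F, 1 - frac) - np.maximum(F_prev, frac), 0, None)
    total = w.sum()
    if total <= 0:
        return float(mu), float(mu + mu * mu / k)
    w = w / total
    m = float((xs * w).sum())
    v = float((xs * xs * w).sum() - m * m)
    return m, v


def correct_trimmed_fit(params: NBParams, frac: float = 0.05) -> NBParams:
    """Undo the variance shrinkage caused by top/bottom trimming.

    Trimming exists to keep pause outliers out of the fit, but on null
    data it also clips the distribution's own tails, so moments of the
    retained counts understate the true spread and upper-tail p-values
    become anti-conservative. This solves for the NB whose *central*
    (1 − 2·frac) moments match the trimmed-sample moments; degenerate
    and Poisson-fallback fits pass through unchanged (a trimmed Poisson
    that still looks under-dispersed has no overdispersion to restore).
    """
    if params.fit_kind != "negative_binomial" or frac <= 0:
        return params
    m_t, k_mom = params.mu, params.size
    v_t = m_t + m_t * m_t / k_mom

    def resid(logp: np.ndarray) -> list[float]:
        mu, k = np.exp(logp)
        m, v = _trimmed_moments(mu, k, frac)
        if m <= 0 or v <= 0:
            return [10.0, 10.0]
        return [np.log(m / m_t), np.log(v / v_t)]

    try:
        sol = optimize.root(resid, [np.log(m_t), np.log(k_mom)], method="hybr")
    except Exception:  # pragma: no cover - numerical failure path
        return params
    if not sol.success:
        return params
    mu, k = np.exp(sol.x)
    if not (np.isfinite(mu) and np.isfinite(k) and mu > 0 and 0 < k < 1e6):
        return params
    return NBParams(mu=float(mu), size=float(k),
                    fit_kind="negative_binomial", n_used=params.n_used)


def position_pvalue(x: int | np.ndarray, params: NBParams) -> float | np.ndarray:
    """Inclusive upper-tail probability P(X ≥ x) under the fitted model.

    P(X ≥ 0) = 1 by construction; a degenerate (all-zero) fit returns 1
    everywhere so no position can be called.
    """
    x = np.asarray(x)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if params.fit_kind == "degenerate":
        p = np.ones(x.shape)
    elif params.fit_kind == "poisson_fallback":
        p = stats.poisson.sf(x - 1, params.mu)
    else:
        k = params.size
        p = stats.nbinom.sf(x - 1, k, k / (k + params.mu))
    return float(p) if p.ndim == 0 else p


def fisher_combine(pvalues) -> tuple[float, float]:
    """Fisher's method: −2·Σ ln pᵢ against χ² with 2R degrees of freedom.

    Zero p-values are floored at 1e−300 (and logged) so the statistic
    stays finite.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    n_zero = int((p == 0).sum())
    if n_zero:
        logger.warning("flooring %d zero p-values at %g", n_zero, ZERO_P_FLOOR)
        p = np.maximum(p, ZERO_P_FLOOR)
    stat = float(-2.0 * np.log(p).sum())
    combined = float(stats.chi2.sf(stat, df=2 * p.size))
    return stat, combined


def _fisher_combine_rows(pmat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pmat = np.maximum(pmat, ZERO_P_FLOOR)
    stat = -2.0 * np.log(pmat).sum(axis=1)
    return stat, stats.chi2.sf(stat, df=2 * pmat.shape[1])


def call_pauses(
    coverages: list[CoverageVector],
    threshold: float = PAUSE_THRESHOLD,
    trim_frac: float = 0.05,
    estimator: str = "mom",
    trim_correction: bool = True,
) -> pd.DataFrame:
    """Scan every CDS position of every gene for ribosome pauses.

    ``coverages`` holds one vector per (gene, replicate) for a single
    condition (or pooled conditions — the caller decides). Per replicate
    the gene's vector is trimmed and fitted; every position (including
    trimmed ones) gets a p-value from that replicate's own fit; p-values
    are Fisher-combined across replicates and a site is called when the
    combined p is strictly below ``threshold``.

    Returns a tidy frame sorted by transcript then position with columns
    transcript_id, position, codon_index, p_rep<i>..., fisher_stat,
    combined_p, called.
    """
    by_gene: dict[str, list[CoverageVector]] = {}
    for vec in coverages:
        by_gene.setdefault(vec.transcript_id, []).append(vec)

    frames = []
    for tid in sorted(by_gene):
        vecs = sorted(by_gene[tid], key=lambda v: (v.condition, v.replicate))
        L = len(vecs[0].counts)
        pmat = np.empty((L, len(vecs)))
        for j, vec in enumerate(vecs):
            if len(vec.counts) != L:
                raise ValueError(f"{tid}: replicate CDS lengths differ")
            retained, removed = trim_outliers(vec.counts, frac=trim_frac)
            params = fit_nb(retained, estimator=estimator)
            if trim_correction and len(removed):
                params = correct_trimmed_fit(params, frac=trim_frac)
            pmat[:, j] = position_pvalue(vec.counts, params)
        stat, combined = _fisher_combine_rows(pmat)
        df = pd.DataFrame(
            {
                "transcript_id": tid,
                "position": np.arange(L),
                "codon_index": np.arange(L) // 3,
            }
        )
        for j in range(pmat.shape[1]):
            df[f"p_rep{j + 1}"] = pmat[:, j]
        df["fisher_stat"] = stat
        df["combined_p"] = combined
        df["called"] = combined < threshold
        frames.append(df)

    if not frames:
        return pd.DataFrame(
            columns=["transcript_id", "position", "codon_index",
                     "fisher_stat", "combined_p", "called"]
        )
    return pd.concat(frames, ignore_index=True)
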