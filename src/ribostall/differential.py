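"""Differential pause-site testing between two conditions.

Pause-site counts are compared between conditions with a negative-binomial
likelihood-ratio test at a common dispersion estimated by method of moments
across all sites on normalized counts. Libraries are normalized by
median-of-ratios size factors. Site p-values are Benjamini–Hochberg
adjusted; significant sites in genes whose overall ribosome occupancy also
changed are removed when the site's log2 fold change merely tracks the
gene's (|log2FC_site − log2FC_gene| < 0.8) — the gene-coherence filter.

Fold changes use a 0.5 pseudo-count on normalized group means so zero
counts stay finite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .coverage import CoverageVector

__all__ = [
    "estimate_size_factors",
    "site_test",
    "site_test_matrix",
    "bh_adjust",
    "gene_occupancy_fc",
    "coherence_filter",
    "differential_pause_analysis",
]

DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5
FDR_THRESHOLD = 0.05
COHERENCE_DELTA = 0.8


def estimate_size_factors(counts: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Median-of-ratios size factors against a geometric-mean reference.

    ``counts`` is genes × libraries. Falls back to total-count ratios
    (scaled to geometric mean 1) when fewer than 10 genes are nonzero in
    every library.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a genes x libraries matrix with >= 2 libraries")
    if x.sum() == 0:
        raise ValueError("all-zero count matrix")
    all_nonzero = (x > 0).all(axis=1)
    if all_nonzero.sum() >= 10:
        xa = x[all_nonzero]
        ref = np.exp(np.log(xa).mean(axis=1))
        return np.median(xa / ref[:, None], axis=0)
    totals = x.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("a library has zero total counts")
    return totals / np.exp(np.log(totals).mean())


def _common_dispersion_mom(norm: np.ndarray, groups: np.ndarray) -> float:
    """Method-of-moments common dispersion alpha = 1/k on normalized counts,
    pooling within-group moments across sites."""
    alphas = []
    for g in np.unique(groups):
        sub = norm[:, groups == g]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / (m * m)
        alphas.append(a)
    a = np.nanmean(np.column_stack(alphas), axis=1)
    a = a[np.isfinite(a)]
    if a.size == 0:
        return DISPERSION_FLOOR
    return max(float(np.median(a)), DISPERSION_FLOOR)


def _full_ll(x: np.ndarray, s: np.ndarray, k: float, mu: np.ndarray) -> float:
    """Complete NB log-likelihood (including the x- and k-dependent
    gamma terms that cancel in the LRT but matter for dispersion)."""
    mu_s = np.maximum(mu[:, None] * s[None, :], 1e-300)
    ll = (
        special.gammaln(x + k) - special.gammaln(k) - special.gammaln(x + 1)
        + k * (np.log(k) - np.log(k + mu_s))
        + x * (np.log(mu_s) - np.log(k + mu_s))
    )
    # a zero group mean contributes pmf(0) = 1 at x = 0
    zero = (mu[:, None] * s[None, :]) == 0
    ll = np.where(zero, np.where(x == 0, 0.0, -np.inf), ll)
    return float(ll.sum())


def _common_dispersion(
    x: np.ndarray, s: np.ndarray, groups: np.ndarray
) -> float:
    """Common dispersion by Cox–Reid adjusted profile likelihood.

    The naive profile likelihood over the group-mean model is biased low
    because every fitted group mean absorbs residual degrees of freedom;
    subtracting ½·log of the mean's Fisher information per (site, group)
    corrects this. Initialized at the pooled moment estimate.
    """
    norm = x / s[None, :]
    a0 = _common_dispersion_mom(norm, groups)

    def nll(log_a: float) -> float:
        alpha = np.exp(log_a)
        k = 1.0 / alpha
        total = 0.0
        for g in np.unique(groups):
            sel = groups == g
            mu_g = _nb_mle_mu(x[:, sel], s[sel], k)
            total += _full_ll(x[:, sel], s[sel], k, mu_g)
            # Cox-Reid: -0.5 log I(mu) with I = sum_j s_j^2/(m_j + alpha m_j^2)
            m_js = mu_g[:, None] * s[sel][None, :]
            info = (s[sel][None, :] ** 2 / (m_js + alpha * m_js**2 + 1e-300)
                    ).sum(axis=1)
            total -= 0.5 * float(np.log(info[info > 0]).sum())
        return -total

    try:
        res = optimize.minimize_scalar(
            nll,
            bounds=(np.log(max(a0 / 50, DISPERSION_FLOOR)),
                    np.log(max(a0 * 50, 1e-4))),
            method="bounded",
            options={"xatol": 1e-3},
        )
        return max(float(np.exp(res.x)), DISPERSION_FLOOR)
    except Exception:  # pragma: no cover - numerical failure path
        return a0


def _nb_profile_ll(x: np.ndarray, s: np.ndarray, k: float,
                   mu: np.ndarray) -> np.ndarray:
    """NB log-likelihood per site summed over libraries, dropping terms
    that depend only on (x, k) and therefore cancel in the LRT."""
    mu_s = mu[:, None] * s[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = k * (np.log(k) - np.log(k + mu_s))
        t2 = x * (np.log(mu_s) - np.log(k + mu_s))
    t1 = np.where(mu_s == 0, 0.0, t1)
    t2 = np.where(x == 0, 0.0, t2)
    return (t1 + t2).sum(axis=1)


def _nb_mle_mu(x: np.ndarray, s: np.ndarray, k: float,
               n_iter: int = 50) -> np.ndarray:
    """Per-site MLE of the common mean given size factors, by Newton.

    Solves sum_j x_j/mu = sum_j (x_j + k) s_j / (k + mu s_j); exact at the
    start value sum(x)/sum(s) whenever all size factors are equal.
    """
    tot = x.sum(axis=1)
    mu = tot / s.sum()
    active = tot > 0
    mu = np.where(active, mu, 0.0)
    for _ in range(n_iter):
        mu_s = mu[:, None] * s[None, :]
        denom = k + mu_s
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(active, tot / np.maximum(mu, 1e-300), 0.0) - (
                ((x + k) * s[None, :]) / denom
            ).sum(axis=1)
            fp = -np.where(active, tot / np.maximum(mu, 1e-300) ** 2, 0.0) + (
                ((x + k) * s[None, :] ** 2) / denom**2
            ).sum(axis=1)
        step = np.where(active & (fp != 0), f / fp, 0.0)
        mu_new = mu - step
        mu = np.where(mu_new > 0, mu_new, mu / 2)
        if np.all(np.abs(step) < 1e-10 * (mu + 1)):
            break
    return mu


def site_test_matrix(
    counts: np.ndarray,
    size_factors: np.ndarray,
    groups: np.ndarray,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """NB likelihood-ratio test for every row of a sites × libraries matrix.

    ``groups`` labels each library 0 (reference/control) or 1
    (perturbed); the log2 fold change is perturbed over control on
    normalized group means with a 0.5 pseudo-count. Returns a frame with
    log2fc, lrt_stat and p_value per site.
    """
    x = np.asarray(counts, dtype=float)
    s = np.asarray(size_factors, dtype=float)
    groups = np.asarray(groups)
    if set(np.unique(groups)) - {0, 1}:
        raise ValueError("groups must be coded 0/1")
    for g in (0, 1):
        if (groups == g).sum() < 2:
            raise ValueError("need >= 2 replicates per group")

    norm = x / s[None, :]
    if dispersion is None:
        dispersion = _common_dispersion(x, s, groups)
    k = 1.0 / dispersion

    mu_null = _nb_mle_mu(x, s, k)
    ll_null = _nb_profile_ll(x, s, k, mu_null)
    ll_alt = np.zeros(x.shape[0])
    group_means = {}
    for g in (0, 1):
        sel = groups == g
        mu_g = _nb_mle_mu(x[:, sel], s[sel], k)
        ll_alt += _nb_profile_ll(x[:, sel], s[sel], k, mu_g)
        group_means[g] = norm[:, sel].mean(axis=1)

    stat = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    p = stats.chi2.sf(stat, df=1)
    log2fc = np.log2(
        (group_means[1] + PSEUDOCOUNT) / (group_means[0] + PSEUDOCOUNT)
    )
    return pd.DataFrame(
        {"log2fc": log2fc, "lrt_stat": stat, "p_value": p,
         "dispersion": dispersion}
    )


def site_test(
    counts, size_factors, groups, dispersion: float | None = None
) -> tuple[float, float]:
    """One-site convenience wrapper: returns (log2fc, p_value)."""
    res = site_test_matrix(
        np.asarray(counts, dtype=float)[None, :], size_factors, groups,
        dispersion=dispersion,
    )
    return float(res["log2fc"].iloc[0]), float(res["p_value"].iloc[0])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gene_occupancy_fc(
    gene_counts: np.ndarray | pd.DataFrame,
    size_factors: np.ndarray,
    groups: np.ndarray,
    fdr_threshold: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """Gene-level differential ribosome occupancy on summed CDS counts.

    Same NB LRT applied to the genes × libraries total-count matrix with
    BH across genes; a gene is differential when its FDR is ≤ the
    threshold. Returns log2fc, p_value, fdr, gene_is_differential per row.
    """
    x = np.asarray(gene_counts, dtype=float)
    if x.size == 0 or (x.ndim == 2 and x.shape[0] == 0):
        raise ValueError("empty gene count matrix")
    res = site_test_matrix(x, size_factors, groups)
    res = res.rename(columns={"log2fc": "log2fc_gene"})
    res["fdr"] = bh_adjust(res["p_value"].to_numpy())
    res["gene_is_differential"] = res["fdr"] <= fdr_threshold
    return res


def coherence_filter(
    records: pd.DataFrame,
    delta: float = COHERENCE_DELTA,
    fdr_threshold: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """Assign each tested pause site a disposition.

    Sites with FDR above the threshold are ``not_significant``.
    Significant sites in genes without differential occupancy are
    ``retained``. Significant sites in differential genes are
    ``removed_coherence`` when |log2FC_site − log2FC_gene| < delta —
    the site change merely tracks the gene change — and ``retained``
    otherwise.
    """
    rec = records.copy()
    delta_fc = (rec["log2fc_site"] - rec["log2fc_gene"]).abs()
    disposition = np.where(
        rec["fdr"] > fdr_threshold,
        "not_significant",
        np.where(
            rec["gene_is_differential"] & (delta_fc < delta),
            "removed_coherence",
            "retained",
        ),
    )
    rec["disposition"] = disposition
    return rec


def differential_pause_analysis(
    pause_sites: pd.DataFrame,
    coverages: list[CoverageVector],
    control: str = "control",
    perturbed: str = "knockdown",
    fdr_threshold: float = FDR_THRESHOLD,
    delta: float = COHERENCE_DELTA,
) -> pd.DataFrame:
    """End-to-end differential analysis for called pause sites.

    ``pause_sites`` needs columns transcript_id and position (CDS frame);
    ``coverages`` holds vectors for both conditions. Size factors come
    from the gene-level total matrix; site and gene NB LRTs, BH and the
    coherence filter are applied. Returns one row per pause site with
    counts, fold changes, p, fdr, gene flags and disposition.
    """
    libs = sorted({(v.condition, v.replicate) for v in coverages})
    lib_order = [f"{c}:{r}" for c, r in libs]
    groups = np.array([0 if c == control else 1 for c, r in libs])
    if not ((groups == 0).any() and (groups == 1).any()):
        raise ValueError(f"need both {control!r} and {perturbed!r} libraries")

    by_key = {(v.transcript_id, v.library): v for v in coverages}
    genes = sorted({v.transcript_id for v in coverages})

    gene_mat = np.array(
        [[by_key[(g, lib)].counts.sum() for lib in lib_order] for g in genes],
        dtype=float,
    )
    size_factors = estimate_size_factors(gene_mat)
    gene_res = gene_occupancy_fc(gene_mat, size_factors, groups,
                                 fdr_threshold=fdr_threshold)
    gene_res.index = genes

    site_mat = np.array(
        [
            [by_key[(row.transcript_id, lib)].counts[row.position]
             for lib in lib_order]
            for row in pause_sites.itertuples(index=False)
        ],
        dtype=float,
    )
    if site_mat.size == 0:
        return pd.DataFrame(
            columns=["transcript_id", "position", "log2fc_site",
                     "log2fc_gene", "p_value", "fdr",
                     "gene_is_differential", "disposition"]
        )
    site_res = site_test_matrix(site_mat, size_factors, groups)

    out = pause_sites[["transcript_id", "position"]].reset_index(drop=True)
    for j, lib in enumerate(lib_order):
        out[f"count_{lib}"] = site_mat[:, j].astype(int)
    out["log2fc_site"] = site_res["log2fc"].to_numpy()
    out["p_value"] = site_res["p_value"].to_numpy()
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    out["log2fc_gene"] = gene_res.loc[out["transcript_id"],
                                      "log2fc_gene"].to_numpy()
    out["gene_is_differential"] = gene_res.loc[
        out["transcript_id"], "gene_is_differential"
    ].to_numpy()
    return coherence_filter(out, delta=delta, fdr_threshold=fdr_threshold)
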