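"""Two-group negative-binomial differential expression.

A deliberately minimal, self-contained test: median-of-ratios size factors,
per-gene method-of-moments dispersion (variance = μ + αμ²) with a pooled-
median fallback, a Wald statistic on the log2 ratio of normalized group
means with a delta-method standard error, and Benjamini–Hochberg FDR within
the comparison. No shrinkage curve, no covariates, no outlier refitting —
those are documented limitations, not omissions.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from triohet.io_formats import CountMatrix

LN2_SQ = math.log(2.0) ** 2

#: Lower floor on the per-gene dispersion estimate.
MIN_DISPERSION = 1e-8


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, rescaled to geometric mean 1.

    For each sample j, the factor is the median over genes (restricted to
    genes with a positive geometric mean across samples) of
    count[g, j] / geometric_mean_g.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    mat = df.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_mat = np.log(mat)
    finite = np.isfinite(log_mat).all(axis=1)
    if not finite.any():
        raise ValueError(
            "no gene has positive counts in every sample; size factors are "
            "undefined (consider a pseudo-reference fallback)"
        )
    log_geomean = log_mat[finite].mean(axis=1)
    ratios = np.exp(log_mat[finite] - log_geomean[:, None])
    factors = np.median(ratios, axis=0)
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean of factors == 1
    return pd.Series(factors, index=df.columns, name="size_factor")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def estimate_dispersions(norm: pd.DataFrame, groups: list[list[str]]) -> np.ndarray:
    """Per-gene method-of-moments NB dispersion α from pooled within-group residuals.

    With Var = μ + αμ², the pooled within-group variance has expectation
    Σ_g (n_g − 1)(μ_g + α μ_g²) / Σ_g (n_g − 1), so the moment estimator is
    α̂ = (s² − m₁) / m₂ with m₁, m₂ the dof-weighted means of the group
    means and squared group means (this stays unbiased when the groups have
    genuinely different means, unlike dividing by the overall mean). Raw
    method-of-moments estimates at 2–3 replicates are extremely noisy and a
    downward-noisy α̂ makes the Wald test anti-conservative, so every
    estimate is floored at the median of the positive per-gene estimates
    (genes with no usable estimate get exactly that median). This is a
    deliberately simple moderation — a one-number stand-in for the
    dispersion-shrinkage curves of full-featured DE packages.
    """
    n_total = sum(len(g) for g in groups)
    dof = n_total - len(groups)
    if dof < 1:
        raise ValueError("need at least one within-group degree of freedom")
    ss = np.zeros(len(norm))
    m1 = np.zeros(len(norm))
    m2 = np.zeros(len(norm))
    for g in groups:
        x = norm[g].to_numpy(dtype=float)
        mean_g = x.mean(axis=1)
        ss += ((x - mean_g[:, None]) ** 2).sum(axis=1)
        m1 += (len(g) - 1) * mean_g
        m2 += (len(g) - 1) * mean_g**2
    s2 = ss / dof
    m1 /= dof
    m2 /= dof
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - m1) / m2
    alpha[~np.isfinite(alpha)] = 0.0
    positive = alpha[alpha > 0]
    floor = float(np.median(positive)) if positive.size else MIN_DISPERSION
    return np.maximum(alpha, max(floor, MIN_DISPERSION))


def test_de(
    counts: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    pseudocount: float = 0.5,
    dispersion: pd.Series | None = None,
) -> pd.DataFrame:
    """Wald test of group B over group A on normalized NB means.

    Returns one row per gene with ``base_mean``, ``log2fc`` (B over A, with
    the pseudocount applied for display), ``se_log2fc``, ``p`` and ``padj``.
    The Wald statistic itself uses the fitted group means without
    pseudocount; a group whose mean is exactly zero is floored at half a
    count to keep the statistic finite.

    ``dispersion`` optionally supplies per-gene dispersions estimated
    elsewhere (e.g. once from all groups of a multi-group design, which is
    both more stable and keeps the gene's dispersion identical across the
    contrasts of that design); by default they are estimated from the two
    groups being compared.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 replicates")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"samples in both groups: {sorted(overlap)}")
    sub = counts.subset_samples(list(group_a) + list(group_b))
    factors = size_factors(sub)
    norm = sub.counts / factors.to_numpy()

    if dispersion is not None:
        alpha = dispersion.reindex(sub.counts.index).to_numpy(dtype=float)
        if np.isnan(alpha).any():
            raise ValueError("dispersion series does not cover all genes")
        alpha = np.maximum(alpha, MIN_DISPERSION)
    else:
        alpha = estimate_dispersions(norm, [list(group_a), list(group_b)])
    a = norm[list(group_a)].to_numpy(dtype=float)
    b = norm[list(group_b)].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    base_mean = norm.to_numpy(dtype=float).mean(axis=1)

    all_zero = (mean_a == 0) & (mean_b == 0)
    ma = np.maximum(mean_a, 0.5 / na)
    mb = np.maximum(mean_b, 0.5 / nb)
    lfc_test = np.log2(mb / ma)
    se2 = ((1.0 / ma + alpha) / na + (1.0 / mb + alpha) / nb) / LN2_SQ
    se = np.sqrt(se2)
    with np.errstate(invalid="ignore"):
        z = lfc_test / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[all_zero] = 1.0

    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    log2fc[all_zero] = 0.0

    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se_log2fc": se,
            "p": p,
            "padj": bh_adjust(p),
        },
        index=sub.counts.index,
    )
    out.index.name = "gene_id"
    return out


def call_degs(
    results: pd.DataFrame, alpha: float = 0.05, min_abs_log2fc: float = 1.0
) -> pd.DataFrame:
    """Add an up/down/ns direction column using strict thresholds.

    A gene is "up" when padj < alpha and log2fc > min_abs_log2fc, "down"
    when padj < alpha and log2fc < −min_abs_log2fc, else "ns". Both
    inequalities are strict, matching the conventional printed rule
    (adjusted p < 0.05, |log2 fold change| > 1).
    """
    out = results.copy()
    sig = out["padj"] < alpha
    out["direction"] = "ns"
    out.loc[sig & (out["log2fc"] > min_abs_log2fc), "direction"] = "up"
    out.loc[sig & (out["log2fc"] < -min_abs_log2fc), "direction"] = "down"
    return out
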