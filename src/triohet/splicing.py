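"""PSI (percent spliced-in) computation and differential alternative splicing.

ψ for one sample is the effective-length-normalized inclusion fraction

    ψ = (I / lI) / (I / lI + S / lS)

where I and S count junction reads supporting the inclusion and skipping
forms and lI, lS are the number of read positions able to support each. The
two-group test places all replicates of a group in a joint binomial
likelihood whose success probability is the length-weighted inclusion rate

    p(ψ) = ψ·lI / (ψ·lI + (1−ψ)·lS),

fits ψ per group (alternative) versus one shared ψ (null) by maximum
likelihood, and refers 2·(ℓ1 − ℓ0) to χ²₁. Because p(ψ) is a monotone
reparameterization, the binomial MLE p̂ = ΣI/Σ(I+S) gives the ψ MLE in
closed form. Events are called differentially spliced when |Δψ| > 0.10
(strict) and BH FDR ≤ 0.05 (inclusive).

This is a simplified model: replicate-level overdispersion in ψ is not
modeled; replicates enter the likelihood as exchangeable binomial draws.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from triohet.io_formats import SpliceEvent

#: Minimum I+S for a sample's ψ to be considered observed.
DEFAULT_MIN_TOTAL = 10


def compute_psi(I: int, S: int, lI: int, lS: int, min_total: int = DEFAULT_MIN_TOTAL) -> float:
    """ψ for one sample, or NaN when I+S is below ``min_total``."""
    if I < 0 or S < 0:
        raise ValueError("counts must be non-negative")
    if lI < 1 or lS < 1:
        raise ValueError("effective lengths must be >= 1")
    if I + S < min_total:
        return math.nan
    return psi_from_counts(I, S, lI, lS)


def psi_from_counts(I: float, S: float, lI: int, lS: int) -> float:
    """Length-normalized inclusion fraction (no minimum-coverage gate)."""
    num = I / lI
    den = num + S / lS
    if den == 0:
        return math.nan
    return num / den


def psi_to_prob(psi: float, lI: int, lS: int) -> float:
    """Binomial success probability (inclusion-read rate) for a given ψ."""
    num = psi * lI
    den = num + (1.0 - psi) * lS
    return num / den if den > 0 else 0.0


def binomial_loglik(I: float, S: float, p: float) -> float:
    """Binomial log-likelihood kernel I·log p + S·log(1−p), with 0·log 0 = 0."""
    ll = 0.0
    if I > 0:
        if p <= 0:
            return -math.inf
        ll += I * math.log(p)
    if S > 0:
        if p >= 1:
            return -math.inf
        ll += S * math.log(1.0 - p)
    return ll


def usable_counts(
    event: SpliceEvent, samples: Sequence[str], min_total: int = DEFAULT_MIN_TOTAL
) -> tuple[int, int]:
    """Summed (I, S) over the samples whose per-sample total passes ``min_total``."""
    I = S = 0
    for s in samples:
        i, k = event.inclusion_counts[s], event.skipping_counts[s]
        if i + k >= min_total:
            I += i
            S += k
    return I, S


def group_psi(
    event: SpliceEvent, samples: Sequence[str], min_total: int = DEFAULT_MIN_TOTAL
) -> float:
    """Group-level ψ MLE from pooled usable counts (NaN if none usable)."""
    I, S = usable_counts(event, samples, min_total)
    if I + S == 0:
        return math.nan
    return psi_from_counts(I, S, event.eff_len_inclusion, event.eff_len_exclusion)


def psi_table(
    events: Sequence[SpliceEvent], sample_ids: Sequence[str], min_total: int = DEFAULT_MIN_TOTAL
) -> pd.DataFrame:
    """Event × sample ψ matrix (NaN where coverage is insufficient)."""
    rows = {
        ev.event_id: [
            compute_psi(
                ev.inclusion_counts[s],
                ev.skipping_counts[s],
                ev.eff_len_inclusion,
                ev.eff_len_exclusion,
                min_total,
            )
            for s in sample_ids
        ]
        for ev in events
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(sample_ids))
    df.index.name = "event_id"
    return df


def test_das(
    event: SpliceEvent,
    group_a: Sequence[str],
    group_b: Sequence[str],
    min_total: int = DEFAULT_MIN_TOTAL,
) -> dict:
    """Binomial likelihood-ratio test of ψ between two groups for one event.

    Returns a dict with psi_a, psi_b, delta_psi (= psi_b − psi_a), lrt_stat
    and p. If every replicate of a group is below the coverage gate the
    event is untestable: p and Δψ are NaN.
    """
    lI, lS = event.eff_len_inclusion, event.eff_len_exclusion
    Ia, Sa = usable_counts(event, group_a, min_total)
    Ib, Sb = usable_counts(event, group_b, min_total)
    base = {"event_id": event.event_id, "gene_id": event.gene_id}
    if Ia + Sa == 0 or Ib + Sb == 0:
        return base | {
            "psi_a": math.nan,
            "psi_b": math.nan,
            "delta_psi": math.nan,
            "lrt_stat": math.nan,
            "p": math.nan,
        }
    pa = Ia / (Ia + Sa)
    pb = Ib / (Ib + Sb)
    p0 = (Ia + Ib) / (Ia + Sa + Ib + Sb)
    ll1 = binomial_loglik(Ia, Sa, pa) + binomial_loglik(Ib, Sb, pb)
    ll0 = binomial_loglik(Ia, Sa, p0) + binomial_loglik(Ib, Sb, p0)
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    psi_a = psi_from_counts(Ia, Sa, lI, lS)
    psi_b = psi_from_counts(Ib, Sb, lI, lS)
    return base | {
        "psi_a": psi_a,
        "psi_b": psi_b,
        "delta_psi": psi_b - psi_a,
        "lrt_stat": lrt,
        "p": float(stats.chi2.sf(lrt, df=1)),
    }


def test_das_many(
    events: Sequence[SpliceEvent],
    group_a: Sequence[str],
    group_b: Sequence[str],
    min_total: int = DEFAULT_MIN_TOTAL,
) -> pd.DataFrame:
    """Run :func:`test_das` over events and BH-adjust across testable ones."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 replicates")
    rows = [test_das(ev, group_a, group_b, min_total) for ev in events]
    df = pd.DataFrame(rows).set_index("event_id")
    padj = np.full(len(df), np.nan)
    testable = df["p"].notna().to_numpy()
    if testable.any():
        from triohet.diffexpr import bh_adjust

        padj[testable] = bh_adjust(df.loc[testable, "p"].to_numpy())
    df["padj"] = padj
    return df


def call_das(
    results: pd.DataFrame, min_dpsi: float = 0.10, max_fdr: float = 0.05
) -> pd.DataFrame:
    """Flag events with |Δψ| strictly above ``min_dpsi`` and FDR ≤ ``max_fdr``."""
    out = results.copy()
    # NaN Δψ/padj compare False, so untestable events are never called.
    out["called"] = (out["delta_psi"].abs() > min_dpsi) & (out["padj"] <= max_fdr)
    return out


def das_genes(results: pd.DataFrame) -> set[str]:
    """Genes with at least one called event."""
    if "called" not in results.columns:
        raise ValueError("run call_das first")
    return set(results.loc[results["called"], "gene_id"])
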