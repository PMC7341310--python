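"""Gene-action (inheritance mode) classification for trio designs.

Each feature — a gene's expression level or a splicing event's PSI — is
classified from four statistical comparisons: hybrid vs paternal parent
(H vs P), hybrid vs maternal parent (H vs M), parent vs parent (P vs M),
and hybrid vs the mid-parent value ½(P+M). Each comparison yields a
relation (greater / less / equal), where "equal" means *not significantly
different* at the BH-adjusted level alpha; the relations then map onto the
classical heterosis vocabulary:

========================  ====================================================
mode                      definition
========================  ====================================================
conserved                 H = P, H = M, P = M (no differences anywhere)
over_dominance            H > P and H > M
under_dominance           H < P and H < M
high_parent_dominance     (H = P and P > M) or (H = M and M > P)
low_parent_dominance      (H = P and P < M) or (H = M and M < P)
additive                  P ≠ M and H = ½(P + M)
other_non_additive        anything else (e.g. H strictly between the parents
                          but off the mid-parent value)
========================  ====================================================

The rules are applied in the order listed; the first match wins, which
makes the classification a total, deterministic function of the four
relations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from triohet import diffexpr, splicing
from triohet.io_formats import CountMatrix, SampleSheet, SpliceEvent

logger = logging.getLogger(__name__)


class GeneActionMode(str, Enum):
    ADDITIVE = "additive"
    HIGH_PARENT_DOMINANCE = "high_parent_dominance"
    LOW_PARENT_DOMINANCE = "low_parent_dominance"
    OVER_DOMINANCE = "over_dominance"
    UNDER_DOMINANCE = "under_dominance"
    OTHER_NON_ADDITIVE = "other_non_additive"
    CONSERVED = "conserved"


#: Modes counted as "classified" (conserved features show no signal at all
#: and are excluded from summaries, mirroring how only differential features
#: are classified in practice).
CLASSIFIED_MODES = (
    GeneActionMode.OVER_DOMINANCE,
    GeneActionMode.HIGH_PARENT_DOMINANCE,
    GeneActionMode.ADDITIVE,
    GeneActionMode.LOW_PARENT_DOMINANCE,
    GeneActionMode.UNDER_DOMINANCE,
    GeneActionMode.OTHER_NON_ADDITIVE,
)

NON_ADDITIVE_MODES = (
    GeneActionMode.OVER_DOMINANCE,
    GeneActionMode.HIGH_PARENT_DOMINANCE,
    GeneActionMode.LOW_PARENT_DOMINANCE,
    GeneActionMode.UNDER_DOMINANCE,
    GeneActionMode.OTHER_NON_ADDITIVE,
)

CONTRASTS = ("H_vs_P", "H_vs_M", "P_vs_M", "H_vs_MID")

Relation = str  # "greater" | "less" | "equal"


@dataclass(frozen=True)
class PairwiseCall:
    """Outcome of one pairwise comparison within the trio."""

    contrast: str
    relation: Relation
    p: float
    padj: float
    estimate: float


@dataclass(frozen=True)
class TrioCalls:
    """The four pairwise comparison outcomes for one feature."""

    feature_id: str
    h_vs_p: PairwiseCall
    h_vs_m: PairwiseCall
    p_vs_m: PairwiseCall
    h_vs_mid: PairwiseCall
    alpha: float


def pairwise_call(estimate: float, padj: float, alpha: float = 0.05) -> Relation:
    """Turn (effect estimate, adjusted p) into a greater/less/equal relation.

    "equal" means not significant at the BH-adjusted ``alpha``; a missing
    (NaN) adjusted p is treated as untestable, hence "equal".
    """
    if not math.isnan(padj) and not 0.0 <= padj <= 1.0:
        raise ValueError(f"padj must be in [0, 1], got {padj}")
    if math.isnan(padj) or padj >= alpha:
        return "equal"
    if estimate > 0:
        return "greater"
    if estimate < 0:
        return "less"
    logger.warning("significant padj=%g with estimate exactly 0; treating as equal", padj)
    return "equal"


def classify_mode(trio: TrioCalls) -> GeneActionMode:
    """Classify one feature from its four trio relations (first match wins)."""
    return classify_relations(
        trio.h_vs_p.relation,
        trio.h_vs_m.relation,
        trio.p_vs_m.relation,
        trio.h_vs_mid.relation,
    )


def classify_relations(
    h_vs_p: Relation, h_vs_m: Relation, p_vs_m: Relation, h_vs_mid: Relation
) -> GeneActionMode:
    """Mode from bare relations; the decision sequence documented in the module docstring."""
    hp, hm, pm, mid = h_vs_p, h_vs_m, p_vs_m, h_vs_mid
    for r in (hp, hm, pm, mid):
        if r not in ("greater", "less", "equal"):
            raise ValueError(f"unknown relation {r!r}")
    if hp == hm == pm == "equal":
        return GeneActionMode.CONSERVED
    if hp == "greater" and hm == "greater":
        return GeneActionMode.OVER_DOMINANCE
    if hp == "less" and hm == "less":
        return GeneActionMode.UNDER_DOMINANCE
    # P > M means the paternal side is higher: relation of the P_vs_M
    # contrast is "greater" when P exceeds M. Dominance requires the hybrid
    # to track one parent while the parents differ.
    if (hp == "equal" and pm == "greater") or (hm == "equal" and pm == "less"):
        return GeneActionMode.HIGH_PARENT_DOMINANCE
    if (hp == "equal" and pm == "less") or (hm == "equal" and pm == "greater"):
        return GeneActionMode.LOW_PARENT_DOMINANCE
    if pm != "equal" and mid == "equal":
        return GeneActionMode.ADDITIVE
    return GeneActionMode.OTHER_NON_ADDITIVE


# ---------------------------------------------------------------------------
# Mid-parent tests


def midparent_test_expression(
    h: np.ndarray, p: np.ndarray, m: np.ndarray, dispersion: float
) -> tuple[float, float]:
    """Wald test of log2(mean_H) against log2(½(mean_P + mean_M)).

    Operates on normalized counts. The standard error comes from the delta
    method under the negative-binomial variance Var = μ + αμ². Returns
    (log2 estimate H/mid-parent, two-sided p).
    """
    h, p, m = (np.asarray(x, dtype=float) for x in (h, p, m))
    mean_h, mean_p, mean_m = h.mean(), p.mean(), m.mean()
    mid = 0.5 * (mean_p + mean_m)
    if mean_h <= 0 and mid <= 0:
        return 0.0, 1.0
    mean_h = max(mean_h, 0.5 / len(h))
    mid = max(mid, 0.25 * (1.0 / len(p) + 1.0 / len(m)))
    var_mean = lambda mu, n: (mu + dispersion * mu * mu) / n  # noqa: E731
    var_mid = 0.25 * (var_mean(mean_p, len(p)) + var_mean(mean_m, len(m)))
    est = math.log2(mean_h / mid)
    se2 = (var_mean(mean_h, len(h)) / mean_h**2 + var_mid / mid**2) / math.log(2) ** 2
    if se2 <= 0:
        return est, 1.0
    z = est / math.sqrt(se2)
    return est, 2.0 * stats.norm.sf(abs(z))


def midparent_test_psi(
    event: SpliceEvent, hybrid_samples: Sequence[str], psi_p: float, psi_m: float,
    min_total: int = 10,
) -> tuple[float, float]:
    """Likelihood-ratio test of the hybrid's ψ against the fixed mid-parent ψ.

    The hybrid's inclusion/skipping counts enter a binomial likelihood; the
    alternative fits ψ_H freely, the null pins it at ½(ψ̂_P + ψ̂_M). Returns
    (ψ̂_H − ψ_mid, p from χ²₁). NaN p if the hybrid is untestable or a
    parent ψ is missing.
    """
    if math.isnan(psi_p) or math.isnan(psi_m):
        return math.nan, math.nan
    psi_mid = 0.5 * (psi_p + psi_m)
    I, S = splicing.usable_counts(event, hybrid_samples, min_total=min_total)
    if I + S == 0:
        return math.nan, math.nan
    lI, lS = event.eff_len_inclusion, event.eff_len_exclusion
    psi_hat = splicing.psi_from_counts(I, S, lI, lS)
    ll1 = splicing.binomial_loglik(I, S, splicing.psi_to_prob(psi_hat, lI, lS))
    ll0 = splicing.binomial_loglik(I, S, splicing.psi_to_prob(psi_mid, lI, lS))
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    return psi_hat - psi_mid, float(stats.chi2.sf(lrt, df=1))


# ---------------------------------------------------------------------------
# Trio classification pipelines


def _calls_frame(
    estimates: Mapping[str, pd.Series], padjs: Mapping[str, pd.Series], alpha: float
) -> pd.DataFrame:
    """Relations per feature for each contrast, as a DataFrame."""
    out = {}
    for contrast in CONTRASTS:
        est, padj = estimates[contrast], padjs[contrast]
        out[contrast] = [
            pairwise_call(e, q, alpha) for e, q in zip(est.to_numpy(), padj.to_numpy())
        ]
    return pd.DataFrame(out, index=next(iter(estimates.values())).index)


def classify_expression_trio(
    counts: CountMatrix,
    samples: SampleSheet,
    tissue: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the three pairwise DE tests plus the mid-parent test and classify genes.

    Returns one row per gene: the log2 fold changes and adjusted p-values of
    each contrast, the derived relations, and the assigned mode.
    """
    hyb = samples.samples_for("hybrid", tissue)
    pat = samples.samples_for("paternal_parent", tissue)
    mat = samples.samples_for("maternal_parent", tissue)
    for name, group in (("hybrid", hyb), ("paternal_parent", pat), ("maternal_parent", mat)):
        if len(group) < 2:
            raise ValueError(f"need >= 2 replicates for {name}, found {len(group)}")

    all_samples = hyb + pat + mat
    sub = counts.subset_samples(all_samples)
    factors = diffexpr.size_factors(sub)
    norm = sub.counts / factors.to_numpy()
    # one dispersion per gene, estimated from all three groups and shared by
    # every contrast — more within-group degrees of freedom than any single
    # pairwise comparison provides, and the gene's variance model stays
    # consistent across the trio
    disp = diffexpr.estimate_dispersions(norm, [hyb, pat, mat])
    disp_series = pd.Series(disp, index=norm.index)

    # test_de reports log2(group_b / group_a): put the parent (or the
    # maternal side) in group_a so estimates read H/P, H/M and P/M.
    de_hp = diffexpr.test_de(counts, pat, hyb, dispersion=disp_series)
    de_hm = diffexpr.test_de(counts, mat, hyb, dispersion=disp_series)
    de_pm = diffexpr.test_de(counts, mat, pat, dispersion=disp_series)

    mid_est = np.empty(len(norm))
    mid_p = np.empty(len(norm))
    nh, np_, nm = norm[hyb].to_numpy(), norm[pat].to_numpy(), norm[mat].to_numpy()
    for i in range(len(norm)):
        mid_est[i], mid_p[i] = midparent_test_expression(nh[i], np_[i], nm[i], disp[i])
    mid_padj = diffexpr.bh_adjust(mid_p)

    idx = norm.index
    estimates = {
        "H_vs_P": de_hp["log2fc"].reindex(idx),
        "H_vs_M": de_hm["log2fc"].reindex(idx),
        "P_vs_M": de_pm["log2fc"].reindex(idx),
        "H_vs_MID": pd.Series(mid_est, index=idx),
    }
    padjs = {
        "H_vs_P": de_hp["padj"].reindex(idx),
        "H_vs_M": de_hm["padj"].reindex(idx),
        "P_vs_M": de_pm["padj"].reindex(idx),
        "H_vs_MID": pd.Series(mid_padj, index=idx),
    }
    relations = _calls_frame(estimates, padjs, alpha)
    modes = [
        classify_relations(r.H_vs_P, r.H_vs_M, r.P_vs_M, r.H_vs_MID)
        for r in relations.itertuples()
    ]
    out = pd.DataFrame(index=idx)
    for c in CONTRASTS:
        out[f"est_{c}"] = estimates[c]
        out[f"padj_{c}"] = padjs[c]
        out[f"rel_{c}"] = relations[c]
    out["mode"] = [m.value for m in modes]
    out.index.name = "feature_id"
    return out


def classify_splicing_trio(
    events: Sequence[SpliceEvent],
    samples: SampleSheet,
    tissue: str | None = None,
    alpha: float = 0.05,
    min_total: int = 10,
) -> pd.DataFrame:
    """Classify splicing events into gene-action modes from their PSI values.

    Same contrast structure as :func:`classify_expression_trio`, with Δψ as
    the effect estimate and the binomial likelihood-ratio test supplying
    p-values.
    """
    hyb = samples.samples_for("hybrid", tissue)
    pat = samples.samples_for("paternal_parent", tissue)
    mat = samples.samples_for("maternal_parent", tissue)

    # test_das_many reports Δψ = ψ(group_b) − ψ(group_a): parent-first
    # argument order makes estimates read H−P, H−M and P−M.
    das_hp = splicing.test_das_many(events, pat, hyb, min_total=min_total)
    das_hm = splicing.test_das_many(events, mat, hyb, min_total=min_total)
    das_pm = splicing.test_das_many(events, mat, pat, min_total=min_total)

    mid_est = np.empty(len(events))
    mid_p = np.empty(len(events))
    for i, ev in enumerate(events):
        psi_p = splicing.group_psi(ev, pat, min_total=min_total)
        psi_m = splicing.group_psi(ev, mat, min_total=min_total)
        mid_est[i], mid_p[i] = midparent_test_psi(ev, hyb, psi_p, psi_m, min_total=min_total)
    mid_padj = diffexpr.bh_adjust(np.nan_to_num(mid_p, nan=1.0))
    mid_padj[np.isnan(mid_p)] = np.nan

    idx = pd.Index([ev.event_id for ev in events], name="feature_id")
    # test_das_many reports psi_b - psi_a with (a, b) order of its arguments,
    # so delta_psi is already hybrid-minus-parent / paternal-minus-maternal.
    estimates = {
        "H_vs_P": das_hp["delta_psi"].reindex(idx),
        "H_vs_M": das_hm["delta_psi"].reindex(idx),
        "P_vs_M": das_pm["delta_psi"].reindex(idx),
        "H_vs_MID": pd.Series(mid_est, index=idx),
    }
    padjs = {
        "H_vs_P": das_hp["padj"].reindex(idx),
        "H_vs_M": das_hm["padj"].reindex(idx),
        "P_vs_M": das_pm["padj"].reindex(idx),
        "H_vs_MID": pd.Series(mid_padj, index=idx),
    }
    relations = _calls_frame(estimates, padjs, alpha)
    modes = [
        classify_relations(r.H_vs_P, r.H_vs_M, r.P_vs_M, r.H_vs_MID)
        for r in relations.itertuples()
    ]
    out = pd.DataFrame(index=idx)
    out["gene_id"] = [ev.gene_id for ev in events]
    for c in CONTRASTS:
        out[f"est_{c}"] = estimates[c]
        out[f"padj_{c}"] = padjs[c]
        out[f"rel_{c}"] = relations[c]
    out["mode"] = [m.value for m in modes]
    return out


# ---------------------------------------------------------------------------
# Summaries


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed report tables)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class ModeSummary:
    """Counts and percentages of classified (non-conserved) features per mode."""

    counts: dict[GeneActionMode, int]
    total_classified: int
    n_conserved: int

    @property
    def percentages(self) -> dict[GeneActionMode, float]:
        """Percent of classified features per mode, rounded to 1 decimal."""
        return {
            m: round_half_away(100.0 * c / self.total_classified, 1)
            for m, c in self.counts.items()
        }

    @property
    def non_additive_total(self) -> int:
        return sum(self.counts.get(m, 0) for m in NON_ADDITIVE_MODES)

    @property
    def over_plus_under(self) -> int:
        return self.counts.get(GeneActionMode.OVER_DOMINANCE, 0) + self.counts.get(
            GeneActionMode.UNDER_DOMINANCE, 0
        )

    @property
    def high_plus_low(self) -> int:
        return self.counts.get(GeneActionMode.HIGH_PARENT_DOMINANCE, 0) + self.counts.get(
            GeneActionMode.LOW_PARENT_DOMINANCE, 0
        )


def summarize_modes(assignments: Iterable[GeneActionMode | str]) -> ModeSummary:
    """Tally mode assignments; conserved features count only toward n_conserved."""
    counts = {m: 0 for m in CLASSIFIED_MODES}
    n_conserved = 0
    for a in assignments:
        mode = GeneActionMode(a)
        if mode is GeneActionMode.CONSERVED:
            n_conserved += 1
        else:
            counts[mode] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no classified (non-conserved) features to summarize")
    return ModeSummary(counts=counts, total_classified=total, n_conserved=n_conserved)


def summary_from_counts(counts: Mapping[GeneActionMode | str, int]) -> ModeSummary:
    """Build a summary directly from per-mode counts (e.g. a published table row)."""
    clean = {m: 0 for m in CLASSIFIED_MODES}
    n_conserved = 0
    for mode, c in counts.items():
        mode = GeneActionMode(mode)
        if mode is GeneActionMode.CONSERVED:
            n_conserved = c
        else:
            clean[mode] = int(c)
    total = sum(clean.values())
    if total == 0:
        raise ValueError("no classified features in counts")
    return ModeSummary(counts=clean, total_classified=total, n_conserved=n_conserved)
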