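"""Synthetic trio datasets with planted inheritance modes.

Emulates a hybrid + two-parent RNA-seq study: negative-binomial gene counts
whose group means encode a planted gene-action mode, binomial
inclusion/skipping junction counts around planted group-wise ψ for
alternative-splicing events, and long reads emitted as BED12 intron chains
supporting the inclusion or exclusion isoform at configurable coverage.

All randomness flows from one master seed through named per-stage
substreams (counts / events / reads), so each stage is individually
reproducible and adding a stage never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from triohet.io_formats import CountMatrix, LongReadAlignment, SampleSheet, SpliceEvent
from triohet.modes import GeneActionMode
from triohet.splicing import psi_to_prob

#: Read positions supporting one splice junction (read length 100, matching
#: common short-read effective-length conventions).
JUNCTION_EFF_LEN = 99

_ROLE_SHORT = {"hybrid": "hyb", "paternal_parent": "pat", "maternal_parent": "mat"}
_ROLE_SPECIES = {"hybrid": "mule", "paternal_parent": "horse", "maternal_parent": "donkey"}

#: Default mode mix: most features conserved, the rest spread over the five
#: informative modes so every classifier branch is exercised.
DEFAULT_MODE_PROPORTIONS = {
    GeneActionMode.CONSERVED: 0.70,
    GeneActionMode.ADDITIVE: 0.06,
    GeneActionMode.HIGH_PARENT_DOMINANCE: 0.06,
    GeneActionMode.LOW_PARENT_DOMINANCE: 0.06,
    GeneActionMode.OVER_DOMINANCE: 0.06,
    GeneActionMode.UNDER_DOMINANCE: 0.06,
}


@dataclass(frozen=True)
class TrioSimConfig:
    """Parameters of the synthetic trio study.

    Defaults describe a modest bulk RNA-seq trio: 3 replicates per group,
    log-normal baseline expression around 200 normalized counts,
    NB dispersion 0.1 (variance = μ + 0.1·μ²), 2-fold (log2) planted
    effects, planted Δψ of 0.3 on splice events with ~200 junction reads of
    coverage, and a mean of 5 long reads per event.
    """

    n_genes: int = 2000
    n_events: int = 500
    replicates_per_group: int = 3
    tissues: tuple[str, ...] = ("muscle",)
    mode_proportions: dict = field(default_factory=lambda: dict(DEFAULT_MODE_PROPORTIONS))
    effect_size_log2: float = 2.0
    baseline_log_mean: tuple[float, float] = (math.log(200.0), 1.0)
    dispersion: float = 0.1
    library_size_range: tuple[float, float] = (0.8, 1.25)
    psi_base_range: tuple[float, float] = (0.2, 0.8)
    delta_psi_planted: float = 0.3
    event_coverage_mean: float = 200.0
    longread_depth: float = 5.0
    uncovered_fraction: float = 0.0
    tissue_effect_log2_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.mode_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mode proportions must sum to 1, got {total}")
        if self.replicates_per_group < 2:
            raise ValueError("replicates_per_group must be >= 2 (tests need within-group variance)")
        if not 0 < self.delta_psi_planted < 1:
            raise ValueError("delta_psi_planted must be in (0, 1)")
        for name in ("effect_size_log2", "dispersion", "event_coverage_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.longread_depth < 0 or not 0 <= self.uncovered_fraction <= 1:
            raise ValueError("invalid long-read parameters")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ValueError("library_size_range must be positive with lo <= hi")
        lo, hi = self.psi_base_range
        if not 0 < lo <= hi < 1:
            raise ValueError("psi_base_range must lie inside (0, 1)")

    def with_seed(self, seed: int) -> "TrioSimConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Planted truth: per-gene modes and means, per-event modes and ψ.

    ``genes`` columns: gene_id, true_mode, mu_h, mu_p, mu_m (group means of
    the first tissue).  ``events`` columns: event_id, gene_id, true_mode,
    psi_h, psi_p, psi_m, das_vs_p / das_vs_m / das_any (planted
    |Δψ| ≥ delta flags), and — after long-read simulation — n_reads_inclusion
    / n_reads_exclusion.  ``library_factors``: sample → multiplier.
    """

    genes: pd.DataFrame
    events: pd.DataFrame
    library_factors: pd.Series


def _substream(config: TrioSimConfig, stage: str) -> np.random.Generator:
    stage_index = {"counts": 0, "events": 1, "reads": 2}[stage]
    ss = np.random.SeedSequence(config.seed, spawn_key=(stage_index,))
    return np.random.default_rng(ss)


def build_sample_sheet(config: TrioSimConfig) -> SampleSheet:
    """The sample sheet implied by the config (shared by all generator stages)."""
    rows = []
    for tissue in config.tissues:
        for role in ("hybrid", "paternal_parent", "maternal_parent"):
            for rep in range(1, config.replicates_per_group + 1):
                rows.append(
                    {
                        "sample_id": f"{tissue}_{_ROLE_SHORT[role]}_{rep}",
                        "species_role": role,
                        "species_name": _ROLE_SPECIES[role],
                        "tissue": tissue,
                        "replicate": rep,
                    }
                )
    return SampleSheet(pd.DataFrame(rows))


def _draw_modes(rng: np.random.Generator, n: int, proportions: dict) -> list[GeneActionMode]:
    modes = [GeneActionMode(m) for m in proportions]
    probs = np.fromiter((proportions[m] for m in proportions), dtype=float)
    idx = rng.choice(len(modes), size=n, p=probs / probs.sum())
    return [modes[i] for i in idx]


def _group_means_for_mode(
    mode: GeneActionMode, baseline: float, effect_log2: float, rng: np.random.Generator
) -> tuple[float, float, float]:
    """(μ_H, μ_P, μ_M) encoding the planted mode around a baseline mean.

    Modes that need unequal parents separate them by the full planted effect
    (symmetrically in log2 around the baseline); which parent is high is
    random. Over/under-dominance keep equal parents and move the hybrid by
    the effect; additivity places the hybrid on the arithmetic mid-parent.
    """
    half = 2.0 ** (effect_log2 / 2.0)
    hi, lo = baseline * half, baseline / half
    pat_high = bool(rng.integers(2))
    if mode is GeneActionMode.CONSERVED:
        return baseline, baseline, baseline
    if mode is GeneActionMode.OVER_DOMINANCE:
        return baseline * 2.0**effect_log2, baseline, baseline
    if mode is GeneActionMode.UNDER_DOMINANCE:
        return baseline / 2.0**effect_log2, baseline, baseline
    mu_p, mu_m = (hi, lo) if pat_high else (lo, hi)
    if mode is GeneActionMode.ADDITIVE:
        return 0.5 * (mu_p + mu_m), mu_p, mu_m
    if mode is GeneActionMode.HIGH_PARENT_DOMINANCE:
        return max(mu_p, mu_m), mu_p, mu_m
    if mode is GeneActionMode.LOW_PARENT_DOMINANCE:
        return min(mu_p, mu_m), mu_p, mu_m
    raise ValueError(f"cannot plant mode {mode}")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB with variance μ + αμ², via the (n, p) gamma–Poisson parameterization."""
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_trio_counts(config: TrioSimConfig) -> tuple[CountMatrix, SampleSheet, GroundTruth]:
    """Simulate gene counts for the trio design with planted modes.

    Counts are NB(mean = s_j · μ_{g, group(j), tissue(j)}, dispersion α)
    with per-sample library factors s_j drawn log-uniform. With more than
    one tissue, each gene additionally carries an independent per-tissue
    log2-normal offset (sd ``tissue_effect_log2_sd``) shared by all three
    groups, so tissue separation dominates species separation in the
    correlation structure.
    """
    rng = _substream(config, "counts")
    sheet = build_sample_sheet(config)
    n_genes = config.n_genes
    gene_ids = [f"gene_{i:05d}" for i in range(n_genes)]

    modes = _draw_modes(rng, n_genes, config.mode_proportions)
    mu, sigma = config.baseline_log_mean
    baseline = rng.lognormal(mean=mu, sigma=sigma, size=n_genes)
    means = np.array(
        [
            _group_means_for_mode(mode, b, config.effect_size_log2, rng)
            for mode, b in zip(modes, baseline)
        ]
    )  # n_genes × (H, P, M)

    n_tissues = len(config.tissues)
    if n_tissues > 1:
        tissue_offsets = 2.0 ** rng.normal(0.0, config.tissue_effect_log2_sd, size=(n_genes, n_tissues))
    else:
        tissue_offsets = np.ones((n_genes, 1))

    lo, hi = config.library_size_range
    sample_ids = sheet.sample_ids
    lib = pd.Series(
        np.exp(rng.uniform(math.log(lo), math.log(hi), size=len(sample_ids))),
        index=sample_ids,
        name="library_factor",
    )

    role_col = {"hybrid": 0, "paternal_parent": 1, "maternal_parent": 2}
    tissue_idx = {t: i for i, t in enumerate(config.tissues)}
    counts = np.empty((n_genes, len(sample_ids)), dtype=np.int64)
    for j, row in enumerate(sheet.frame.itertuples()):
        mean_j = (
            means[:, role_col[row.species_role]]
            * tissue_offsets[:, tissue_idx[row.tissue]]
            * lib[row.sample_id]
        )
        counts[:, j] = _nb_draw(rng, mean_j, config.dispersion)

    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids))
    genes_df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_mode": [m.value for m in modes],
            "mu_h": means[:, 0],
            "mu_p": means[:, 1],
            "mu_m": means[:, 2],
        }
    )
    truth = GroundTruth(genes=genes_df, events=pd.DataFrame(), library_factors=lib)
    return cm, sheet, truth


def _psi_for_mode(
    mode: GeneActionMode, delta: float, lo: float, hi: float, rng: np.random.Generator
) -> tuple[float, float, float]:
    """(ψ_H, ψ_P, ψ_M) encoding the planted mode, kept inside (0.02, 0.98)."""
    margin = 0.02
    pat_high = bool(rng.integers(2))
    if mode is GeneActionMode.CONSERVED:
        base = rng.uniform(lo, hi)
        return base, base, base
    if mode in (GeneActionMode.OVER_DOMINANCE, GeneActionMode.UNDER_DOMINANCE):
        if mode is GeneActionMode.OVER_DOMINANCE:
            base = rng.uniform(max(lo, margin), min(hi, 1.0 - margin - delta))
            return base + delta, base, base
        base = rng.uniform(max(lo, margin + delta), min(hi, 1.0 - margin))
        return base - delta, base, base
    # parents differ by delta, centered inside the feasible window
    center = rng.uniform(max(lo, margin + delta / 2), min(hi, 1.0 - margin - delta / 2))
    psi_hi, psi_lo = center + delta / 2, center - delta / 2
    psi_p, psi_m = (psi_hi, psi_lo) if pat_high else (psi_lo, psi_hi)
    if mode is GeneActionMode.ADDITIVE:
        return center, psi_p, psi_m
    if mode is GeneActionMode.HIGH_PARENT_DOMINANCE:
        return psi_hi, psi_p, psi_m
    if mode is GeneActionMode.LOW_PARENT_DOMINANCE:
        return psi_lo, psi_p, psi_m
    raise ValueError(f"cannot plant mode {mode}")


def _event_chains(index: int, event_type: str) -> tuple[list, list, str, str]:
    """Structurally valid synthetic chains for one event, spaced along a contig."""
    o = 10_000 * index
    strand = "+" if index % 2 == 0 else "-"
    up = (o, o + 200)
    down = (o + 1000, o + 1200)
    if event_type == "SE":
        inc = [up, (o + 500, o + 600), down]
        exc = [up, down]
    elif event_type == "MXE":
        inc = [up, (o + 400, o + 500), down]
        exc = [up, (o + 700, o + 800), down]
    elif event_type == "A5SS":
        inc = [(o, o + 300), down]
        exc = [up, down]
    elif event_type == "A3SS":
        inc = [up, (o + 900, o + 1200)]
        exc = [up, down]
    elif event_type == "RI":
        inc = [(o, o + 1200)]
        exc = [up, down]
    else:
        raise ValueError(f"unknown event type {event_type}")
    return inc, exc, "chrSim", strand


def _eff_len(chain: list) -> int:
    n_junctions = len(chain) - 1
    return JUNCTION_EFF_LEN * max(1, n_junctions)


def simulate_splice_events(
    config: TrioSimConfig, event_type: str = "SE"
) -> tuple[list[SpliceEvent], SampleSheet, GroundTruth]:
    """Simulate splice events with planted group-wise ψ.

    Per sample, the total junction count is Poisson(event_coverage_mean) and
    the inclusion count is Binomial(total, p(ψ_group)); the planted ψ values
    follow the event's mode exactly as gene means do, with DAS events
    separated from the relevant parent by at least ``delta_psi_planted``.
    Events are attached to genes gene_00000, gene_00001, … so they line up
    with a count simulation from the same config.
    """
    rng = _substream(config, "events")
    sheet = build_sample_sheet(config)
    tissue = config.tissues[0]
    roles = {
        "hybrid": sheet.samples_for("hybrid", tissue),
        "paternal_parent": sheet.samples_for("paternal_parent", tissue),
        "maternal_parent": sheet.samples_for("maternal_parent", tissue),
    }
    lo, hi = config.psi_base_range
    delta = config.delta_psi_planted
    modes = _draw_modes(rng, config.n_events, config.mode_proportions)

    events: list[SpliceEvent] = []
    truth_rows = []
    for i, mode in enumerate(modes):
        psi_h, psi_p, psi_m = _psi_for_mode(mode, delta, lo, hi, rng)
        inc, exc, chrom, strand = _event_chains(i, event_type)
        lI, lS = _eff_len(inc), _eff_len(exc)
        inc_counts: dict[str, int] = {}
        skp_counts: dict[str, int] = {}
        for role, psi in (
            ("hybrid", psi_h),
            ("paternal_parent", psi_p),
            ("maternal_parent", psi_m),
        ):
            prob = psi_to_prob(psi, lI, lS)
            for s in roles[role]:
                total = rng.poisson(config.event_coverage_mean)
                I = rng.binomial(total, prob) if total > 0 else 0
                inc_counts[s] = int(I)
                skp_counts[s] = int(total - I)
        eid = f"event_{i:05d}"
        events.append(
            SpliceEvent(
                event_id=eid,
                gene_id=f"gene_{i:05d}",
                event_type=event_type,
                chrom=chrom,
                strand=strand,
                inclusion_chain=inc,
                exclusion_chain=exc,
                eff_len_inclusion=lI,
                eff_len_exclusion=lS,
                inclusion_counts=inc_counts,
                skipping_counts=skp_counts,
            )
        )
        truth_rows.append(
            {
                "event_id": eid,
                "gene_id": f"gene_{i:05d}",
                "true_mode": mode.value,
                "psi_h": psi_h,
                "psi_p": psi_p,
                "psi_m": psi_m,
                "das_vs_p": abs(psi_h - psi_p) >= delta - 1e-12,
                "das_vs_m": abs(psi_h - psi_m) >= delta - 1e-12,
            }
        )
    events_df = pd.DataFrame(truth_rows)
    events_df["das_any"] = events_df["das_vs_p"] | events_df["das_vs_m"]
    truth = GroundTruth(
        genes=pd.DataFrame(),
        events=events_df,
        library_factors=pd.Series(dtype=float),
    )
    return events, sheet, truth


def simulate_long_reads(
    events: list[SpliceEvent], truth: GroundTruth, config: TrioSimConfig
) -> list[LongReadAlignment]:
    """Emit long reads copying each event's inclusion or exclusion chain.

    Per event: with probability ``uncovered_fraction`` no reads at all;
    otherwise N ~ Poisson(longread_depth) reads, each the inclusion chain
    with probability equal to the hybrid's true ψ. The truth table gains
    n_reads_inclusion / n_reads_exclusion columns.
    """
    rng = _substream(config, "reads")
    psi_by_event = truth.events.set_index("event_id")["psi_h"] if not truth.events.empty else {}
    reads: list[LongReadAlignment] = []
    n_inc_col, n_exc_col = [], []
    for ev in events:
        n_inc = n_exc = 0
        if rng.uniform() >= config.uncovered_fraction:
            n = rng.poisson(config.longread_depth)
            psi = float(psi_by_event.get(ev.event_id, 0.5))
            for k in range(n):
                use_inclusion = rng.uniform() < psi
                chain = ev.inclusion_chain if use_inclusion else ev.exclusion_chain
                reads.append(
                    LongReadAlignment(
                        read_id=f"lr_{ev.event_id}_{k}",
                        chrom=ev.chrom,
                        strand=ev.strand,
                        blocks=tuple(chain),
                    )
                )
                if use_inclusion:
                    n_inc += 1
                else:
                    n_exc += 1
        n_inc_col.append(n_inc)
        n_exc_col.append(n_exc)
    if not truth.events.empty:
        truth.events["n_reads_inclusion"] = n_inc_col
        truth.events["n_reads_exclusion"] = n_exc_col
    return reads
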