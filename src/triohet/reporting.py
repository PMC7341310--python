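"""Pipeline orchestration, report tables and sample-correlation clustering.

The full pipeline on one tissue: differential expression for the three trio
contrasts, differential splicing, gene-action classification of both, long-
read verification of the called splicing events, optional gene-set
enrichment of the differential gene lists, and correlation/clustering
reports. Every stage writes a TSV; a JSON manifest records thresholds and
the seed so runs are auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from triohet import __version__, diffexpr, enrichment, longread_validation, modes, splicing
from triohet.io_formats import CountMatrix
from triohet.modes import GeneActionMode, ModeSummary

logger = logging.getLogger(__name__)

#: Column order of the printed mode tables (classified modes only).
MODE_TABLE_ORDER = (
    GeneActionMode.OTHER_NON_ADDITIVE,
    GeneActionMode.OVER_DOMINANCE,
    GeneActionMode.HIGH_PARENT_DOMINANCE,
    GeneActionMode.ADDITIVE,
    GeneActionMode.LOW_PARENT_DOMINANCE,
    GeneActionMode.UNDER_DOMINANCE,
)


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson sample–sample correlations plus their average-linkage dendrogram."""

    corr: pd.DataFrame
    linkage: np.ndarray
    leaf_order: list[str]

    def top_split(self) -> tuple[set[str], set[str]]:
        """The two sample clusters produced by cutting the dendrogram once."""
        labels = hierarchy.fcluster(self.linkage, t=2, criterion="maxclust")
        samples = list(self.corr.index)
        return (
            {s for s, l in zip(samples, labels) if l == 1},
            {s for s, l in zip(samples, labels) if l == 2},
        )


def log_normalized(counts: CountMatrix) -> pd.DataFrame:
    """log2(median-of-ratios-normalized count + 1), the expression-space input to clustering."""
    factors = diffexpr.size_factors(counts)
    return np.log2(counts.counts / factors.to_numpy() + 1.0)


def correlation_matrix(values: pd.DataFrame) -> CorrelationReport:
    """Pearson correlations between sample columns, clustered by average linkage on 1 − r.

    Missing values (e.g. low-coverage ψ) are handled pairwise-complete.
    Raises if any sample has zero variance (its correlations are undefined).
    """
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    stds = values.std(axis=0, ddof=0)
    flat = stds[stds == 0].index.tolist()
    if flat:
        raise ValueError(f"zero-variance sample(s), correlation undefined: {flat}")
    corr = values.corr(method="pearson")  # pairwise-complete by construction
    if corr.isna().any().any():
        bad = corr.columns[corr.isna().any()].tolist()
        raise ValueError(f"undefined correlations involving sample(s): {bad}")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    linkage = hierarchy.average(squareform(dist, checks=False))
    order = [corr.index[i] for i in hierarchy.leaves_list(linkage)]
    return CorrelationReport(corr=corr, linkage=linkage, leaf_order=order)


def mode_table(summaries: Mapping[tuple[str, str], ModeSummary]) -> pd.DataFrame:
    """One row per (tissue, hybrid) with mode counts in the printed column order.

    Adds the aggregate columns: total classified, non-additive total,
    over+under and high+low dominance sums.
    """
    if not summaries:
        raise ValueError("no summaries to tabulate")
    rows = []
    for (tissue, hybrid), s in summaries.items():
        row: dict[str, object] = {"tissue": tissue, "hybrid": hybrid}
        for m in MODE_TABLE_ORDER:
            row[m.value] = s.counts.get(m, 0)
        row["total_classified"] = s.total_classified
        row["non_additive_total"] = s.non_additive_total
        row["over_plus_under"] = s.over_plus_under
        row["high_plus_low"] = s.high_plus_low
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs: inputs, thresholds, output directory."""

    counts: Path
    samples: Path
    events: Path | None = None
    reads: Path | None = None
    gene_sets: Path | None = None
    tissue: str | None = None
    alpha: float = 0.05
    min_abs_log2fc: float = 1.0
    min_dpsi: float = 0.10
    max_fdr: float = 0.05
    min_total: int = 10
    validation_mode: str = "both_isoforms"
    validation_tolerance: int = 10
    min_set_size: int = 3
    outdir: Path = Path("triohet_out")
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("alpha", "max_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0 <= self.min_dpsi < 1:
            raise ValueError("min_dpsi must be in [0, 1)")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute DE → DAS → classification → validation → enrichment → reports.

    Returns a bundle dict with every in-memory result; writes one TSV per
    stage plus ``run_manifest.json`` under ``config.outdir``. Stage failures
    are re-raised annotated with the stage name.
    """
    from triohet import io_formats

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    def stage(name):
        logger.info("pipeline stage: %s", name)
        return name

    try:
        name = stage("load")
        counts = io_formats.read_counts(config.counts)
        sheet = io_formats.read_sample_sheet(config.samples)
        events = io_formats.read_events(config.events) if config.events else []
        reads = io_formats.read_bed12(config.reads) if config.reads else []

        name = stage("de")
        tissue = config.tissue
        hyb = sheet.samples_for("hybrid", tissue)
        pat = sheet.samples_for("paternal_parent", tissue)
        mat = sheet.samples_for("maternal_parent", tissue)
        de_tables = {}
        deg_counts_rows = []
        for contrast, (ga, gb) in {
            "hybrid_vs_paternal": (pat, hyb),
            "hybrid_vs_maternal": (mat, hyb),
            "paternal_vs_maternal": (mat, pat),
        }.items():
            res = diffexpr.call_degs(
                diffexpr.test_de(counts, ga, gb), config.alpha, config.min_abs_log2fc
            )
            de_tables[contrast] = res
            res.to_csv(out / f"de_{contrast}.tsv", sep="\t")
            deg_counts_rows.append(
                {
                    "contrast": contrast,
                    "up": int((res["direction"] == "up").sum()),
                    "down": int((res["direction"] == "down").sum()),
                }
            )
        deg_counts = pd.DataFrame(deg_counts_rows)
        deg_counts.to_csv(out / "deg_counts.tsv", sep="\t", index=False)
        bundle["de"] = de_tables
        bundle["deg_counts"] = deg_counts

        name = stage("classify_expression")
        expr_modes = modes.classify_expression_trio(counts, sheet, tissue, config.alpha)
        expr_modes.to_csv(out / "modes_expression.tsv", sep="\t")
        bundle["expression_modes"] = expr_modes
        expr_nonconserved = expr_modes.loc[expr_modes["mode"] != "conserved", "mode"]
        summaries: dict[tuple[str, str], ModeSummary] = {}
        if not expr_nonconserved.empty:
            summaries[(tissue or "all", "expression")] = modes.summarize_modes(expr_nonconserved)

        name = stage("correlation_expression")
        corr = correlation_matrix(log_normalized(counts))
        corr.corr.to_csv(out / "correlation_expression.tsv", sep="\t")
        bundle["correlation_expression"] = corr

        das_table = None
        if events:
            name = stage("das")
            das_table = splicing.call_das(
                splicing.test_das_many(events, hyb, pat, config.min_total),
                config.min_dpsi,
                config.max_fdr,
            )
            das_table.to_csv(out / "das_hybrid_vs_paternal.tsv", sep="\t")
            bundle["das"] = das_table
            bundle["das_genes"] = splicing.das_genes(das_table)
            pd.DataFrame(
                {
                    "n_events_called": [int(das_table["called"].sum())],
                    "n_genes_called": [len(bundle["das_genes"])],
                }
            ).to_csv(out / "das_counts.tsv", sep="\t", index=False)

            name = stage("classify_splicing")
            psi_modes = modes.classify_splicing_trio(
                events, sheet, tissue, config.alpha, config.min_total
            )
            psi_modes.to_csv(out / "modes_splicing.tsv", sep="\t")
            bundle["splicing_modes"] = psi_modes
            psi_nonconserved = psi_modes.loc[psi_modes["mode"] != "conserved", "mode"]
            if not psi_nonconserved.empty:
                summaries[(tissue or "all", "splicing")] = modes.summarize_modes(psi_nonconserved)

            name = stage("correlation_psi")
            psi = splicing.psi_table(events, sheet.sample_ids, config.min_total)
            try:
                corr_psi = correlation_matrix(psi)
                corr_psi.corr.to_csv(out / "correlation_psi.tsv", sep="\t")
                bundle["correlation_psi"] = corr_psi
            except ValueError as exc:
                logger.warning("PSI correlation skipped: %s", exc)

            if reads:
                name = stage("validate")
                called_ids = set(das_table.index[das_table["called"]])
                called_events = [ev for ev in events if ev.event_id in called_ids]
                report = longread_validation.validate(
                    called_events, reads, config.validation_mode, config.validation_tolerance
                )
                report.detail.to_csv(out / "validation_detail.tsv", sep="\t", index=False)
                pd.DataFrame(
                    {
                        "n_das_genes": [report.n_das_genes],
                        "covered": [report.covered],
                        "verified": [report.verified],
                        "pct_verified_of_covered": [report.pct_verified_of_covered],
                    }
                ).to_csv(out / "validation_summary.tsv", sep="\t", index=False)
                bundle["validation"] = report

        if summaries:
            name = stage("mode_table")
            table = mode_table(summaries)
            table.to_csv(out / "mode_summary.tsv", sep="\t", index=False)
            bundle["mode_summaries"] = summaries
            bundle["mode_table"] = table

        if config.gene_sets:
            name = stage("enrich")
            sets = io_formats.read_gmt(config.gene_sets, universe=counts.gene_ids)
            degs = de_tables["hybrid_vs_paternal"]
            query = set(degs.index[degs["direction"] != "ns"])
            if query:
                enr = enrichment.enrich(query, sets, config.min_set_size)
                enr.to_csv(out / "enrichment_degs.tsv", sep="\t", index=False)
                bundle["enrichment"] = enr
            else:
                logger.warning("no differential genes; enrichment skipped")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "tissue": config.tissue,
        "alpha": config.alpha,
        "min_abs_log2fc": config.min_abs_log2fc,
        "min_dpsi": config.min_dpsi,
        "max_fdr": config.max_fdr,
        "min_total": config.min_total,
        "validation_mode": config.validation_mode,
        "validation_tolerance": config.validation_tolerance,
        "inputs": {
            "counts": str(config.counts),
            "samples": str(config.samples),
            "events": str(config.events) if config.events else None,
            "reads": str(config.reads) if config.reads else None,
            "gene_sets": str(config.gene_sets) if config.gene_sets else None,
        },
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle
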