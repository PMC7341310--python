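"""Readers and writers for every external format the pipeline touches.

All genomic intervals are 0-based, half-open, end-exclusive — in memory, in
the event table, and in BED12 (which is natively 0-based, so no conversion
happens anywhere). The event table is a documented tab-separated format of
this package, not an rMATS interchange format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Allowed values of the ``species_role`` column: the hybrid, its sire-side
#: parent species and its dam-side parent species.
ROLES = ("hybrid", "paternal_parent", "maternal_parent")

#: The five canonical alternative-splicing event classes: skipped exon,
#: mutually exclusive exons, alternative 5'/3' splice site, retained intron.
EVENT_TYPES = ("SE", "MXE", "A5SS", "A3SS", "RI")

SAMPLE_SHEET_COLUMNS = ("sample_id", "species_role", "species_name", "tissue", "replicate")

Interval = tuple[int, int]


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


def _check_blocks(blocks: Sequence[Interval], what: str) -> list[Interval]:
    """Validate that exon blocks are well-formed, sorted and non-overlapping."""
    if len(blocks) == 0:
        raise FormatError(f"{what}: at least one block required")
    out = [(int(s), int(e)) for s, e in blocks]
    for s, e in out:
        if s < 0 or e <= s:
            raise FormatError(f"{what}: invalid block [{s}, {e})")
    for (s0, e0), (s1, e1) in zip(out, out[1:]):
        if s1 < e0:
            raise FormatError(f"{what}: blocks [{s0},{e0}) and [{s1},{e1}) overlap or are unsorted")
    return out


@dataclass(frozen=True)
class SampleSheet:
    """Sample metadata: one row per sample with its role in the trio design.

    ``species_role`` is one of :data:`ROLES`; ``species_name`` carries the
    actual species (e.g. mule / horse / donkey) and is never used to select
    groups — analyses select on role so the same code serves a mule trio
    (horse sire) and a hinny trio (donkey dam) alike.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        if df.empty:
            raise FormatError("sample sheet has no rows")
        dup = df["sample_id"][df["sample_id"].duplicated()]
        if not dup.empty:
            raise FormatError(f"duplicate sample ids: {sorted(dup)}")
        bad = sorted(set(df["species_role"]) - set(ROLES))
        if bad:
            raise FormatError(f"unknown species_role values {bad}; allowed: {list(ROLES)}")
        if (df["replicate"].astype(int) < 1).any():
            raise FormatError("replicate numbers must be positive integers")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def samples_for(self, role: str, tissue: str | None = None) -> list[str]:
        """Sample ids with the given role, optionally restricted to one tissue."""
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}; allowed: {list(ROLES)}")
        df = self.frame
        mask = df["species_role"] == role
        if tissue is not None:
            mask &= df["tissue"] == tissue
        return list(df.loc[mask, "sample_id"])

    @property
    def tissues(self) -> list[str]:
        return sorted(self.frame["tissue"].unique())


@dataclass(frozen=True)
class CountMatrix:
    """Integer gene × sample expression counts (genes as rows)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.duplicated().any():
            raise FormatError("duplicate sample ids in count matrix")
        if not all(np.issubdtype(dt, np.integer) for dt in df.dtypes):
            raise FormatError("counts must be integers")
        if (df.to_numpy() < 0).any():
            raise FormatError("negative counts not allowed")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)])


@dataclass
class SpliceEvent:
    """One alternative-splicing event with its two isoform structures.

    The inclusion chain is the exon-block structure of the isoform that
    includes the alternative segment (e.g. the cassette exon of an SE
    event); the exclusion chain skips it. ``inclusion_counts`` /
    ``skipping_counts`` hold per-sample junction read counts supporting each
    form, and the effective lengths give the number of read positions able
    to support each form (used to debias PSI).
    """

    event_id: str
    gene_id: str
    event_type: str
    chrom: str
    strand: str
    inclusion_chain: list[Interval]
    exclusion_chain: list[Interval]
    eff_len_inclusion: int
    eff_len_exclusion: int
    inclusion_counts: dict[str, int] = field(default_factory=dict)
    skipping_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise FormatError(
                f"event {self.event_id}: unknown event type {self.event_type!r}; "
                f"allowed: {list(EVENT_TYPES)}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"event {self.event_id}: strand must be + or -")
        self.inclusion_chain = _check_blocks(self.inclusion_chain, f"event {self.event_id} inclusion chain")
        self.exclusion_chain = _check_blocks(self.exclusion_chain, f"event {self.event_id} exclusion chain")
        if self.eff_len_inclusion < 1 or self.eff_len_exclusion < 1:
            raise FormatError(f"event {self.event_id}: effective lengths must be >= 1")
        for name, counts in (("inclusion", self.inclusion_counts), ("skipping", self.skipping_counts)):
            for s, c in counts.items():
                if c < 0:
                    raise FormatError(f"event {self.event_id}: negative {name} count for sample {s}")
        if set(self.inclusion_counts) != set(self.skipping_counts):
            raise FormatError(f"event {self.event_id}: inclusion/skipping sample sets differ")


@dataclass(frozen=True)
class LongReadAlignment:
    """One aligned long read as its chrom/strand/exon-block chain (BED12 semantics)."""

    read_id: str
    chrom: str
    strand: str
    blocks: tuple[Interval, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(_check_blocks(self.blocks, f"read {self.read_id}")))
        if self.strand not in ("+", "-"):
            raise FormatError(f"read {self.read_id}: strand must be + or -")


@dataclass(frozen=True)
class GeneSets:
    """Named gene sets plus the gene universe they are tested against.

    Members absent from the universe are dropped at construction with a
    logged count, so downstream hypergeometric tests see consistent
    parameters.
    """

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_members(
        cls,
        sets: dict[str, Iterable[str]],
        universe: Iterable[str],
        descriptions: dict[str, str] | None = None,
    ) -> "GeneSets":
        uni = frozenset(universe)
        clean: dict[str, frozenset[str]] = {}
        n_dropped = 0
        for sid, members in sets.items():
            mem = frozenset(members)
            outside = mem - uni
            if outside:
                n_dropped += len(outside)
                mem = mem & uni
            clean[sid] = mem
        if n_dropped:
            logger.info("dropped %d gene-set members absent from the universe", n_dropped)
        return cls(sets=clean, universe=uni, descriptions=dict(descriptions or {}))

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# counts.tsv


def read_counts(path: str | Path) -> CountMatrix:
    """Read a genes × samples TSV (first column gene id, header sample ids)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty count table") from None
    if df.empty and df.columns.empty:
        raise FormatError(f"{path}: empty count table")
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids in header")
    out = pd.DataFrame(index=df.index.astype(str))
    for col in df.columns:
        try:
            vals = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: non-numeric cell in column {col!r}: {exc}") from None
        if not np.allclose(vals, np.round(vals)):
            bad = df.index[vals != np.round(vals)][0]
            raise FormatError(f"{path}: non-integer count at gene {bad!r}, column {col!r}")
        if (vals < 0).any():
            bad = df.index[vals < 0][0]
            raise FormatError(f"{path}: negative count at gene {bad!r}, column {col!r}")
        out[col] = vals.astype(np.int64)
    return CountMatrix(out)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# samples.tsv


def read_sample_sheet(path: str | Path) -> SampleSheet:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty sample sheet") from None
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    try:
        df["replicate"] = df["replicate"].astype(int)
    except ValueError:
        raise FormatError(f"{path}: replicate column must be integer") from None
    return SampleSheet(df[list(SAMPLE_SHEET_COLUMNS)])


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# events.tsv

_EVENT_FIXED_COLS = (
    "event_id",
    "gene_id",
    "event_type",
    "chrom",
    "strand",
    "inclusion_chain",
    "exclusion_chain",
    "eff_len_inclusion",
    "eff_len_exclusion",
)


def _format_chain(blocks: Sequence[Interval]) -> str:
    return ",".join(f"{s}-{e}" for s, e in blocks)


def _parse_chain(text: str, what: str) -> list[Interval]:
    blocks = []
    for part in str(text).strip().split(","):
        if not part:
            continue
        try:
            s, e = part.split("-")
            blocks.append((int(s), int(e)))
        except ValueError:
            raise FormatError(f"{what}: malformed block {part!r} (expected start-end)") from None
    return blocks


def read_events(path: str | Path) -> list[SpliceEvent]:
    """Read the event table: fixed columns plus per-sample ``I:``/``S:`` columns."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _EVENT_FIXED_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    i_cols = [c for c in df.columns if c.startswith("I:")]
    s_cols = [c for c in df.columns if c.startswith("S:")]
    i_samples = [c[2:] for c in i_cols]
    s_samples = [c[2:] for c in s_cols]
    if set(i_samples) != set(s_samples):
        raise FormatError(f"{path}: I:/S: sample columns do not pair up")
    if df["event_id"].duplicated().any():
        dups = sorted(df["event_id"][df["event_id"].duplicated()])
        raise FormatError(f"{path}: duplicate event ids {dups[:5]}")
    events = []
    for _, row in df.iterrows():
        eid = row["event_id"]
        try:
            inc_counts = {s: int(row[f"I:{s}"]) for s in i_samples}
            skp_counts = {s: int(row[f"S:{s}"]) for s in i_samples}
        except ValueError:
            raise FormatError(f"{path}: non-integer count in event {eid!r}") from None
        events.append(
            SpliceEvent(
                event_id=eid,
                gene_id=row["gene_id"],
                event_type=row["event_type"],
                chrom=row["chrom"],
                strand=row["strand"],
                inclusion_chain=_parse_chain(row["inclusion_chain"], f"event {eid} inclusion"),
                exclusion_chain=_parse_chain(row["exclusion_chain"], f"event {eid} exclusion"),
                eff_len_inclusion=int(row["eff_len_inclusion"]),
                eff_len_exclusion=int(row["eff_len_exclusion"]),
                inclusion_counts=inc_counts,
                skipping_counts=skp_counts,
            )
        )
    return events


def write_events(events: Sequence[SpliceEvent], path: str | Path) -> None:
    if not events:
        raise ValueError("no events to write")
    samples = sorted(events[0].inclusion_counts)
    rows = []
    for ev in events:
        row: dict[str, object] = {
            "event_id": ev.event_id,
            "gene_id": ev.gene_id,
            "event_type": ev.event_type,
            "chrom": ev.chrom,
            "strand": ev.strand,
            "inclusion_chain": _format_chain(ev.inclusion_chain),
            "exclusion_chain": _format_chain(ev.exclusion_chain),
            "eff_len_inclusion": ev.eff_len_inclusion,
            "eff_len_exclusion": ev.eff_len_exclusion,
        }
        for s in samples:
            row[f"I:{s}"] = ev.inclusion_counts[s]
            row[f"S:{s}"] = ev.skipping_counts[s]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED12


def read_bed12(path: str | Path) -> list[LongReadAlignment]:
    """Read long-read alignments from BED12 (blockCount/Sizes/Starts columns).

    Trailing commas in blockSizes/blockStarts (the common dialect emitted by
    UCSC tools) are accepted.
    """
    path = Path(path)
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BED fields, got {len(fields)}")
            chrom, chrom_start, _, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5]
            block_count = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != block_count or len(starts) != block_count:
                raise FormatError(
                    f"{path}:{lineno}: blockCount={block_count} but "
                    f"{len(sizes)} sizes / {len(starts)} starts"
                )
            blocks = tuple(
                (chrom_start + st, chrom_start + st + sz) for st, sz in zip(starts, sizes)
            )
            reads.append(LongReadAlignment(read_id=name, chrom=chrom, strand=strand, blocks=blocks))
    return reads


def write_bed12(reads: Sequence[LongReadAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            start = r.blocks[0][0]
            end = r.blocks[-1][1]
            sizes = ",".join(str(e - s) for s, e in r.blocks)
            starts = ",".join(str(s - start) for s, e in r.blocks)
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(start),
                        str(end),
                        r.read_id,
                        "0",
                        r.strand,
                        str(start),
                        str(end),
                        "0,0,0",
                        str(len(r.blocks)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSets:
    """Read gene sets from GMT (set_id, description, member...).

    If ``universe`` is None, the union of all members is used.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs set_id, description, >=1 member")
            sid, desc, *members = fields
            if sid in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set id {sid!r}")
            sets[sid] = [m for m in members if m]
            descriptions[sid] = desc
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    return GeneSets.from_members(sets, universe, descriptions)
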