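"""SV query semantics: sample database, coordinate extension, strand matching.

A query names an SV type (DEL, DUP, INV, BND) and two breakpoint intervals in
genome order.  Both breakpoints are widened by a window that accounts for the
cohort's insert-size spread — in a type-specific direction, because each SV
type displaces the flanking read pairs to a predictable side of its
breakpoints — and evidence records are retained when one end overlaps the
widened left breakpoint, the other end overlaps the widened right breakpoint,
and the record's strand pair is the one the SV type produces.  The result is
a per-sample count of supporting alignments, split by evidence class, with
one row for every sample in the cohort database (zeros included).

Strand configurations by SV type (genome-ordered end orientations):

========  =================  ===================
SV type   paired-end         split read
========  =================  ===================
DEL       ``+/-``            ``+/+`` or ``-/-``
DUP       ``-/+``            ``+/+`` or ``-/-``
INV       ``+/+`` or ``-/-`` ``+/-`` or ``-/+``
BND       any                any
========  =================  ===================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .evidence import EvidenceClass, EvidenceRecord, chrom_key, intervals_overlap

__all__ = [
    "SVType",
    "Breakpoint",
    "SVQuery",
    "QueryProbe",
    "SampleRecord",
    "QueryResult",
    "PedConfigError",
    "QueryConfigError",
    "DEFAULT_WINDOW",
    "load_ped",
    "extend_query",
    "match_strand_config",
    "run_query",
    "format_result",
]

DEFAULT_WINDOW = 500


class PedConfigError(ValueError):
    """Raised for malformed sample-database (PED) input."""


class QueryConfigError(ValueError):
    """Raised when a query cannot be answered against the given index."""


class SVType(str, Enum):
    DEL = "DEL"
    DUP = "DUP"
    INV = "INV"
    BND = "BND"


@dataclass(frozen=True, slots=True)
class Breakpoint:
    """One breakpoint confidence interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"breakpoint start must be <= end: {self}")

    def shifted(self, delta: int) -> "Breakpoint":
        return Breakpoint(self.chrom, max(0, self.start + delta), max(0, self.end + delta))


@dataclass(frozen=True, slots=True)
class QueryProbe:
    """One extended (left, right) probe pair.

    ``inv_sign`` is +1/-1 for the two inversion sub-queries (which extend in
    opposite directions and select +/+ vs -/- paired ends) and None otherwise.
    """

    left: Breakpoint
    right: Breakpoint
    inv_sign: int | None = None


@dataclass(frozen=True)
class SVQuery:
    """An SV query: type, genome-ordered breakpoints, and search window (bp)."""

    sv_type: SVType
    left: Breakpoint
    right: Breakpoint
    window: int = DEFAULT_WINDOW

    def __post_init__(self):
        object.__setattr__(self, "sv_type", SVType(self.sv_type))
        if self.window < 0:
            raise ValueError("window must be >= 0")
        lk, rk = chrom_key(self.left.chrom), chrom_key(self.right.chrom)
        if self.sv_type is not SVType.BND and self.left.chrom != self.right.chrom:
            raise ValueError(f"{self.sv_type.value} queries require a single chromosome")
        if lk > rk or (lk == rk and self.left.start > self.right.start):
            if self.sv_type is SVType.BND:
                # interchromosomal queries are normalized so the left probe
                # sits on the bytewise-smaller chromosome
                warnings.warn(
                    "BND query coordinates were not in genome order; swapping left and right",
                    stacklevel=3,
                )
                l, r = self.left, self.right
                object.__setattr__(self, "left", r)
                object.__setattr__(self, "right", l)
            else:
                raise ValueError("left breakpoint must not be downstream of the right breakpoint")


@dataclass(frozen=True, slots=True)
class SampleRecord:
    """One cohort sample: id, evidence file name, and arbitrary PED metadata."""

    sample_id: str
    evidence_file: str
    metadata: tuple[tuple[str, str], ...] = ()

    @property
    def metadata_dict(self) -> dict[str, str]:
        return dict(self.metadata)


def load_ped(path, bed_column_index: int) -> list[SampleRecord]:
    """Load the cohort sample database from a headered tab-separated PED file.

    Parameters
    ----------
    path : path
        Tab-separated file whose first row is a header; the first column is
        the sample name.
    bed_column_index : int
        1-based index of the column holding each sample's evidence file name.

    All header columns are preserved as metadata, in file order.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise PedConfigError(f"{path}: PED file is empty (missing header)")
    header = lines[0].split("\t")
    if not (1 <= bed_column_index <= len(header)):
        raise PedConfigError(
            f"{path}: evidence-file column {bed_column_index} out of range (1..{len(header)})"
        )
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise PedConfigError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}"
            )
        sample_id = fields[0]
        if sample_id in seen:
            raise PedConfigError(f"{path}:{lineno}: duplicate sample name {sample_id!r}")
        seen.add(sample_id)
        records.append(
            SampleRecord(
                sample_id=sample_id,
                evidence_file=fields[bed_column_index - 1],
                metadata=tuple(zip(header, fields)),
            )
        )
    return records


def extend_query(q: SVQuery) -> list[QueryProbe]:
    """Widen the query breakpoints by the window, in the type-specific direction.

    DEL extends the left breakpoint downstream and the right upstream (the
    supporting +/- pairs sit outside the deleted segment); DUP the opposite;
    INV yields two probe pairs, extended downstream for the +/+ sub-query and
    upstream for the -/- sub-query; BND probes are used unchanged.  Starts
    are clamped at zero.
    """
    w = q.window
    l, r = q.left, q.right
    t = q.sv_type
    if t is SVType.DEL:
        return [QueryProbe(Breakpoint(l.chrom, l.start, l.end + w),
                           Breakpoint(r.chrom, max(0, r.start - w), r.end))]
    if t is SVType.DUP:
        return [QueryProbe(Breakpoint(l.chrom, max(0, l.start - w), l.end),
                           Breakpoint(r.chrom, r.start, r.end + w))]
    if t is SVType.INV:
        return [
            QueryProbe(Breakpoint(l.chrom, l.start, l.end + w),
                       Breakpoint(r.chrom, r.start, r.end + w), inv_sign=1),
            QueryProbe(Breakpoint(l.chrom, max(0, l.start - w), l.end),
                       Breakpoint(r.chrom, max(0, r.start - w), r.end), inv_sign=-1),
        ]
    return [QueryProbe(l, r)]


_PAIREND_CONFIGS = {
    SVType.DEL: {(1, -1)},
    SVType.DUP: {(-1, 1)},
    SVType.INV: {(1, 1), (-1, -1)},
}
_SPLIT_CONFIGS = {
    SVType.DEL: {(1, 1), (-1, -1)},
    SVType.DUP: {(1, 1), (-1, -1)},
    SVType.INV: {(1, -1), (-1, 1)},
}


def match_strand_config(record: EvidenceRecord, sv_type) -> bool:
    """Does this record's genome-ordered strand pair fit the SV type?

    BND accepts any configuration; for the other types the table in the
    module docstring applies, keyed by evidence class.
    """
    sv_type = SVType(sv_type)
    if sv_type is SVType.BND:
        return True
    table = _PAIREND_CONFIGS if record.evidence_class is EvidenceClass.PAIREND else _SPLIT_CONFIGS
    return record.strand_pair in table[sv_type]


def _resolve_samples(searcher, samples: Sequence[SampleRecord]) -> dict[str, SampleRecord]:
    """Map index sample ids onto PED records, via evidence file name or id."""
    by_file = {fname: sid for sid, fname in searcher.files.items()}
    known = set(searcher.sample_ids)
    resolved: dict[str, SampleRecord] = {}
    missing: list[str] = []
    for rec in samples:
        if rec.evidence_file in by_file:
            resolved[by_file[rec.evidence_file]] = rec
        elif rec.sample_id in known:
            resolved[rec.sample_id] = rec
        else:
            missing.append(f"{rec.sample_id} ({rec.evidence_file})")
    if missing:
        raise QueryConfigError(
            "samples in the PED database have no indexed evidence file: " + ", ".join(missing)
        )
    return resolved


@dataclass
class QueryResult:
    """Per-sample support counts for one query, with PED metadata attached.

    ``table`` holds one row per database sample — zero-count samples
    included — with the PED metadata columns followed by ``Pairend`` and
    ``Split``.
    """

    query: SVQuery
    table: pd.DataFrame

    def counts_for(self, sample_id: str) -> tuple[int, int]:
        row = self.table.loc[self.table["Sample"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return int(row["Pairend"].iloc[0]), int(row["Split"].iloc[0])

    def samples_with_evidence(self, min_support: int = 1) -> set[str]:
        total = self.table["Pairend"] + self.table["Split"]
        return set(self.table.loc[total >= min_support, "Sample"])

    @property
    def n_samples_with_evidence(self) -> int:
        return len(self.samples_with_evidence())

    @property
    def total_pairend(self) -> int:
        return int(self.table["Pairend"].sum())

    @property
    def total_split(self) -> int:
        return int(self.table["Split"].sum())

    @property
    def max_per_sample_evidence(self) -> int:
        if self.table.empty:
            return 0
        return int((self.table["Pairend"] + self.table["Split"]).max())


def run_query(searcher, samples: Sequence[SampleRecord], q: SVQuery) -> QueryResult:
    """Execute one SV query against an index (or its brute-force twin).

    For each extended probe pair the left probe is searched, and hits are
    retained when the record's left end overlaps the left probe, its right
    end overlaps the right probe, and the strand configuration matches the SV
    type (inversion sub-queries additionally pin the paired-end strand sign).
    Each evidence record is counted at most once per query, however many
    probe pairs or index entries it matched.
    """
    resolved = _resolve_samples(searcher, samples)
    counted: set[tuple[str, int]] = set()
    pairend: dict[str, int] = {}
    split: dict[str, int] = {}
    for probe in extend_query(q):
        lp, rp = probe.left, probe.right
        for hit in searcher.search(lp.chrom, lp.start, lp.end):
            key = (hit.sample_id, hit.ordinal)
            if key in counted:
                continue
            r = hit.record
            if r.left_chrom != lp.chrom or not intervals_overlap(r.left_start, r.left_end, lp.start, lp.end):
                continue
            if r.right_chrom != rp.chrom or not intervals_overlap(r.right_start, r.right_end, rp.start, rp.end):
                continue
            if not match_strand_config(r, q.sv_type):
                continue
            if (
                probe.inv_sign is not None
                and r.evidence_class is EvidenceClass.PAIREND
                and r.strand_pair != (probe.inv_sign, probe.inv_sign)
            ):
                continue
            counted.add(key)
            bucket = pairend if r.evidence_class is EvidenceClass.PAIREND else split
            bucket[hit.sample_id] = bucket.get(hit.sample_id, 0) + 1

    # one row per PED sample, in PED order, zeros included
    header = list(dict(samples[0].metadata)) if samples else ["Sample"]
    rows = []
    index_id_of = {ped.sample_id: iid for iid, ped in resolved.items()}
    for rec in samples:
        iid = index_id_of[rec.sample_id]
        row = dict(rec.metadata)
        row.setdefault("Sample", rec.sample_id)
        row["Pairend"] = pairend.get(iid, 0)
        row["Split"] = split.get(iid, 0)
        rows.append(row)
    columns = (header if "Sample" in header else ["Sample"] + header) + ["Pairend", "Split"]
    if not rows:
        table = pd.DataFrame(columns=columns)
    else:
        table = pd.DataFrame(rows, columns=columns)
    # normalize the sample-name column label to "Sample" for downstream use
    if "Sample" not in table.columns:
        table = table.rename(columns={table.columns[0]: "Sample"})
    return QueryResult(query=q, table=table)


def format_result(result: QueryResult, mode: str = "table") -> str:
    """Render a query result as tab-separated text.

    ``table`` mode emits a header plus one row per sample, with a leading
    ``Id`` row number, the PED metadata columns, then ``Pairend`` and
    ``Split``.  ``summary`` mode emits a single line with three integers:
    samples with any evidence, total paired-end count, total split count.
    """
    if mode == "summary":
        return f"{result.n_samples_with_evidence}\t{result.total_pairend}\t{result.total_split}"
    if mode != "table":
        raise ValueError(f"unknown format mode: {mode!r}")
    df = result.table.copy()
    df.insert(0, "Id", range(len(df)))
    return df.to_csv(sep="\t", index=False).rstrip("\n")
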