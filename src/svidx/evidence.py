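"""Discordant-alignment evidence extraction.

Paired-end sequencing of a genome carrying a structural variant (SV) leaves a
characteristic footprint in the alignments: read pairs that straddle a
breakpoint map with an unexpected separation, orientation, or chromosome pair,
and reads that cross the junction itself align in two segments (split reads).
This module scans per-sample alignment files, classifies each alignment
against an insert-size model, and reads/writes a compact sorted BED-like
evidence file with one line per discordant pair or split read.

Conventions
-----------
All coordinates are 0-based half-open (BED style).  Strands are encoded as
``+1`` / ``-1``.  Chromosome names are compared bytewise (``LC_ALL=C``
collation), so ``"10" < "2" < "X"``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

__all__ = [
    "EvidenceClass",
    "InsertSizeModel",
    "EvidenceRecord",
    "AlignmentView",
    "RecordFilters",
    "InsufficientDataError",
    "EvidenceParseError",
    "estimate_insert_model",
    "classify_alignment",
    "make_evidence_records",
    "extract_evidence",
    "iter_evidence_records",
    "sort_evidence",
    "read_evidence",
    "write_evidence",
    "chrom_key",
    "intervals_overlap",
]

DEFAULT_DISCORDANT_DISTANCE = 500


class InsufficientDataError(ValueError):
    """Raised when too few observations are available to fit a model."""


class EvidenceParseError(ValueError):
    """Raised when an evidence file line cannot be parsed.

    Carries the offending path and 1-based line number.
    """

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


class EvidenceClass(IntEnum):
    """Kind of SV evidence an alignment provides."""

    PAIREND = 0
    SPLIT = 1


def chrom_key(chrom: str) -> bytes:
    """Bytewise sort key for chromosome names (C-locale collation)."""
    return chrom.encode()


def intervals_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """Half-open interval overlap: ``[a_start, a_end)`` vs ``[b_start, b_end)``."""
    return a_start < b_end and b_start < a_end


@dataclass(frozen=True, slots=True)
class InsertSizeModel:
    """Fragment-size model used to call a pair distance-discordant.

    Parameters
    ----------
    mean_fragment, sd_fragment : float
        Mean and standard deviation of the concordant fragment (outer insert)
        length, in base pairs.
    discordant_distance : int
        Outer-span threshold beyond which a same-chromosome +/- pair is
        considered discordant.  When fit from data this is
        ``round(mean + 2*sd)``; it may also be supplied directly (500 is the
        conventional short-read default).
    """

    mean_fragment: float
    sd_fragment: float
    discordant_distance: int

    def __post_init__(self):
        if self.mean_fragment <= 0:
            raise ValueError("mean_fragment must be > 0")
        if self.sd_fragment < 0:
            raise ValueError("sd_fragment must be >= 0")
        if self.discordant_distance <= 0:
            raise ValueError("discordant_distance must be > 0")


def estimate_insert_model(concordant_fragment_lengths) -> InsertSizeModel:
    """Fit an :class:`InsertSizeModel` from concordant fragment lengths.

    The discordant distance is set to ``round(mean + 2*sd)``, the usual
    choice for separating SV-supporting pairs from the bulk of the library.

    Raises
    ------
    InsufficientDataError
        If fewer than 2 lengths are supplied.
    ValueError
        If any length is not positive.
    """
    arr = np.asarray(list(concordant_fragment_lengths), dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(
            f"need at least 2 fragment lengths to fit an insert-size model, got {arr.size}"
        )
    if np.any(arr <= 0):
        raise ValueError("fragment lengths must be positive")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=0))
    return InsertSizeModel(mean, sd, int(round(mean + 2.0 * sd)))


@dataclass(frozen=True, slots=True)
class EvidenceRecord:
    """One piece of SV evidence: two genome-ordered ends with orientations.

    ``left``/``right`` refer to genome order: the left chromosome is bytewise
    <= the right one, and on equal chromosomes ``left_start <= right_start``.
    For paired-end evidence each end interval is breakpoint-padded (see
    :func:`make_evidence_records`); split-read ends are exact segment spans.
    """

    left_chrom: str
    left_start: int
    left_end: int
    left_strand: int
    right_chrom: str
    right_start: int
    right_end: int
    right_strand: int
    evidence_class: EvidenceClass

    def __post_init__(self):
        if not (self.left_start < self.left_end and self.right_start < self.right_end):
            raise ValueError(f"end intervals must be non-empty: {self}")
        if self.left_strand not in (1, -1) or self.right_strand not in (1, -1):
            raise ValueError(f"strands must be +1/-1: {self}")
        lk, rk = chrom_key(self.left_chrom), chrom_key(self.right_chrom)
        if lk > rk or (lk == rk and self.left_start > self.right_start):
            raise ValueError(f"ends must be genome-ordered: {self}")

    @property
    def strand_pair(self) -> tuple[int, int]:
        return (self.left_strand, self.right_strand)

    def end_interval(self, side: str) -> tuple[str, int, int]:
        if side == "left":
            return (self.left_chrom, self.left_start, self.left_end)
        if side == "right":
            return (self.right_chrom, self.right_start, self.right_end)
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")


@dataclass(slots=True)
class AlignmentView:
    """Minimal projection of one alignment record.

    Only the fields that evidence classification needs: the aligned span, the
    mate placement (for paired records), and an optional split (supplementary)
    segment taken from the SA tag.
    """

    chrom: str
    start: int
    end: int
    strand: int
    paired: bool = False
    mate_chrom: str | None = None
    mate_start: int | None = None
    mate_end: int | None = None
    mate_strand: int | None = None
    has_split: bool = False
    split_chrom: str | None = None
    split_start: int | None = None
    split_end: int | None = None
    split_strand: int | None = None
    is_read1: bool = True
    is_primary: bool = True
    is_duplicate: bool = False
    is_qcfail: bool = False
    mapq: int = 60
    name: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"alignment span must be non-empty: {self.name} {self.chrom}:{self.start}-{self.end}")


@dataclass(frozen=True, slots=True)
class RecordFilters:
    """Which alignment records are retained before classification.

    Secondary, duplicate and QC-fail records are dropped by default; no
    mapping-quality threshold is applied unless ``min_mapq`` is raised.
    """

    drop_secondary: bool = True
    drop_duplicate: bool = True
    drop_qcfail: bool = True
    min_mapq: int = 0

    def keep(self, aln: AlignmentView) -> bool:
        if self.drop_secondary and not aln.is_primary:
            return False
        if self.drop_duplicate and aln.is_duplicate:
            return False
        if self.drop_qcfail and aln.is_qcfail:
            return False
        if aln.mapq < self.min_mapq:
            return False
        return True


def _ordered_pair(aln: AlignmentView) -> tuple[tuple[str, int, int, int], tuple[str, int, int, int]]:
    """Return the (read, mate) ends in genome order as (chrom, start, end, strand)."""
    mate_end = aln.mate_end if aln.mate_end is not None else aln.mate_start + (aln.end - aln.start)
    this = (aln.chrom, aln.start, aln.end, aln.strand)
    mate = (aln.mate_chrom, aln.mate_start, mate_end, aln.mate_strand)
    tk = (chrom_key(aln.chrom), aln.start)
    mk = (chrom_key(aln.mate_chrom), aln.mate_start)
    if tk < mk or (tk == mk and aln.is_read1):
        return this, mate
    return mate, this


def is_pairend_emitter(aln: AlignmentView) -> bool:
    """True when this record is the one that emits the pair-level evidence.

    Each template's paired-end record is emitted exactly once, from the
    genome-leftmost primary alignment (ties broken in favour of read 1), so
    mates are never double-counted.
    """
    if not aln.paired or aln.mate_chrom is None:
        return False
    tk = (chrom_key(aln.chrom), aln.start)
    mk = (chrom_key(aln.mate_chrom), aln.mate_start)
    if tk != mk:
        return tk < mk
    return aln.is_read1


def classify_alignment(aln: AlignmentView, model: InsertSizeModel) -> set[EvidenceClass]:
    """Classify one alignment as SV evidence.

    A paired alignment is pair-level evidence when any of the following
    holds: the mates map to different chromosomes, the genome-ordered strand
    configuration is not +/-, or the outer distance between the two aligned
    ends exceeds ``model.discordant_distance``.  An alignment carrying a
    supplementary (split) segment is additionally split-read evidence.
    Concordant, non-split alignments yield the empty set.
    """
    classes: set[EvidenceClass] = set()
    if aln.paired and aln.mate_chrom is not None and aln.mate_start is not None:
        if aln.mate_chrom != aln.chrom:
            classes.add(EvidenceClass.PAIREND)
        else:
            (_, ls, le, lstrand), (_, rs, re, rstrand) = _ordered_pair(aln)
            outer = max(le, re) - min(ls, rs)
            if (lstrand, rstrand) != (1, -1) or outer > model.discordant_distance:
                classes.add(EvidenceClass.PAIREND)
    if aln.has_split:
        classes.add(EvidenceClass.SPLIT)
    return classes


def _pad_end(start: int, end: int, strand: int, distance: int) -> tuple[int, int]:
    # A + alignment points downstream at a breakpoint within `distance`
    # of its start; a - alignment points upstream.  Extend the interval to
    # cover every position the originating fragment could have spanned.
    if strand > 0:
        return start, max(end, start + distance)
    return max(0, min(start, end - distance)), end


def make_evidence_records(
    aln: AlignmentView, classes: Iterable[EvidenceClass], model: InsertSizeModel
) -> list[EvidenceRecord]:
    """Build evidence records for an alignment's assigned classes.

    Pair-end records store both mates' spans with breakpoint padding: the
    interval of a + end is extended downstream to ``start + discordant_distance``
    and the interval of a - end upstream to ``end - discordant_distance``
    (clamped at 0), so any breakpoint the fragment could span overlaps the
    record.  Split records store the exact spans of the two aligned segments.
    Ends are always placed in genome order.
    """
    out: list[EvidenceRecord] = []
    for cls in sorted(classes):
        cls = EvidenceClass(cls)
        if cls is EvidenceClass.PAIREND:
            if not aln.paired or aln.mate_chrom is None:
                raise ValueError("pairend evidence requested for an alignment without mate information")
            (lc, ls, le, lstrand), (rc, rs, re, rstrand) = _ordered_pair(aln)
            d = model.discordant_distance
            ls, le = _pad_end(ls, le, lstrand, d)
            rs, re = _pad_end(rs, re, rstrand, d)
            if lc == rc and ls > rs:
                # upstream padding of a -/- pair with unequal clipped spans
                # can reorder the interval starts; restore genome order
                (ls, le, lstrand), (rs, re, rstrand) = (rs, re, rstrand), (ls, le, lstrand)
            out.append(EvidenceRecord(lc, ls, le, lstrand, rc, rs, re, rstrand, cls))
        else:
            if not aln.has_split or aln.split_chrom is None:
                raise ValueError("split evidence requested for an alignment without a split segment")
            this = (aln.chrom, aln.start, aln.end, aln.strand)
            seg = (aln.split_chrom, aln.split_start, aln.split_end, aln.split_strand)
            first, second = sorted((this, seg), key=lambda t: (chrom_key(t[0]), t[1], t[2]))
            out.append(EvidenceRecord(*first, *second, cls))
    return out


def sort_evidence(records: Sequence[EvidenceRecord]) -> list[EvidenceRecord]:
    """Order records by (left chromosome bytewise, left start, left end), stably."""
    return sorted(records, key=lambda r: (chrom_key(r.left_chrom), r.left_start, r.left_end))


# ---------------------------------------------------------------------------
# Evidence file dialect: 9 tab-separated columns
#   left_chrom left_start left_end left_strand(1/-1)
#   right_chrom right_start right_end right_strand(1/-1)
#   evidence_class (0 = pairend, 1 = split)
# ---------------------------------------------------------------------------

def _open_text(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            return pysam.BGZFile(str(path), "wb")
        return gzip.open(path, "rb")
    return open(path, mode + "b")


def write_evidence(records: Iterable[EvidenceRecord], path) -> Path:
    """Write records in the 9-column dialect; ``.gz`` paths are bgzip-compressed."""
    path = Path(path)
    with _open_text(path, "w") as fh:
        for r in records:
            line = (
                f"{r.left_chrom}\t{r.left_start}\t{r.left_end}\t{r.left_strand}\t"
                f"{r.right_chrom}\t{r.right_start}\t{r.right_end}\t{r.right_strand}\t"
                f"{int(r.evidence_class)}\n"
            )
            fh.write(line.encode())
    return path


def read_evidence(path) -> list[EvidenceRecord]:
    """Parse an evidence file; malformed lines raise :class:`EvidenceParseError`."""
    out: list[EvidenceRecord] = []
    with _open_text(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.decode().rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise EvidenceParseError(path, lineno, f"expected 9 columns, got {len(fields)}")
            try:
                lc, ls, le, lst, rc, rs, re, rst, cls = fields
                ls, le, rs, re = int(ls), int(le), int(rs), int(re)
                lst, rst, cls = int(lst), int(rst), int(cls)
            except ValueError as exc:
                raise EvidenceParseError(path, lineno, f"non-integer field: {exc}") from None
            if lst not in (1, -1) or rst not in (1, -1):
                raise EvidenceParseError(path, lineno, f"strand must be 1 or -1, got {lst}/{rst}")
            if cls not in (0, 1):
                raise EvidenceParseError(path, lineno, f"evidence class must be 0 or 1, got {cls}")
            try:
                out.append(EvidenceRecord(lc, ls, le, lst, rc, rs, re, rst, EvidenceClass(cls)))
            except ValueError as exc:
                raise EvidenceParseError(path, lineno, str(exc)) from None
    return out


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def _cigar_reference_length(cigar: str) -> int:
    n = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in "MDN=X":
                n += int(num)
            num = ""
    return n


def _views_from_alignment_file(path, filters: RecordFilters) -> Iterator[AlignmentView]:
    """Project SAM/BAM records onto :class:`AlignmentView`.

    Supplementary lines are skipped: the primary record carries the split
    segment through its SA tag.  Mate spans come from the MC (mate CIGAR) tag
    when present, else the mate is assumed to span the read's own length.
    """
    path = str(path)
    try:
        af = pysam.AlignmentFile(path, check_sq=False)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read alignment file {path}: {exc}") from exc
    with af:
        for rec in af:
            if rec.is_unmapped or rec.is_supplementary:
                continue
            if rec.is_secondary and filters.drop_secondary:
                continue
            view = AlignmentView(
                chrom=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                strand=-1 if rec.is_reverse else 1,
                paired=rec.is_paired,
                is_read1=(not rec.is_paired) or rec.is_read1,
                is_primary=not rec.is_secondary,
                is_duplicate=rec.is_duplicate,
                is_qcfail=rec.is_qcfail,
                mapq=rec.mapping_quality,
                name=rec.query_name,
            )
            if rec.is_paired and not rec.mate_is_unmapped and rec.next_reference_name is not None:
                view.mate_chrom = rec.next_reference_name
                view.mate_start = rec.next_reference_start
                view.mate_strand = -1 if rec.mate_is_reverse else 1
                if rec.has_tag("MC"):
                    view.mate_end = rec.next_reference_start + _cigar_reference_length(rec.get_tag("MC"))
                else:
                    view.mate_end = rec.next_reference_start + (rec.reference_end - rec.reference_start)
            if rec.has_tag("SA"):
                sa = rec.get_tag("SA").split(";")[0]
                chrom, pos, strand, cigar, _mapq, _nm = sa.split(",")
                start = int(pos) - 1
                view.has_split = True
                view.split_chrom = chrom
                view.split_start = start
                view.split_end = start + _cigar_reference_length(cigar)
                view.split_strand = 1 if strand == "+" else -1
            yield view


def iter_evidence_records(
    views: Iterable[AlignmentView], model: InsertSizeModel, filters: RecordFilters | None = None
) -> Iterator[EvidenceRecord]:
    """Classify a stream of alignment views and yield evidence records.

    Pair-level evidence is emitted once per template (from the leftmost
    primary, see :func:`is_pairend_emitter`); split evidence is emitted from
    every split-bearing record.
    """
    filters = filters or RecordFilters()
    for aln in views:
        if not filters.keep(aln):
            continue
        classes = classify_alignment(aln, model)
        if EvidenceClass.PAIREND in classes and not is_pairend_emitter(aln):
            classes = classes - {EvidenceClass.PAIREND}
        if classes:
            yield from make_evidence_records(aln, classes, model)


def extract_evidence(
    source,
    model: InsertSizeModel,
    filters: RecordFilters | None = None,
    out_path=None,
) -> Path:
    """Extract sorted SV evidence from an alignment file or view stream.

    Parameters
    ----------
    source : path or iterable of AlignmentView
        A SAM/BAM file, or an in-memory alignment stream.
    model : InsertSizeModel
        Supplies the discordant-distance threshold and end padding.
    out_path : path, optional
        Output evidence file; required for stream input.  Defaults to
        ``<source>.bed.gz`` for file input.

    The output is deterministic: a fixed input always produces a
    byte-identical file.
    """
    filters = filters or RecordFilters()
    if isinstance(source, (str, Path)):
        views: Iterable[AlignmentView] = _views_from_alignment_file(source, filters)
        if out_path is None:
            out_path = Path(str(source)) .with_suffix("") .with_suffix("")
            out_path = Path(str(out_path) + ".bed.gz")
    else:
        views = source
        if out_path is None:
            raise ValueError("out_path is required when extracting from an in-memory stream")
    records = sort_evidence(list(iter_evidence_records(views, model, filters)))
    return write_evidence(records, out_path)
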