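"""Synthetic cohorts with known SV genotypes and paired-end alignments.

The simulator is coordinate-level: no sequence is generated and no aligner is
run.  Each sample's two haplotypes are represented as ordered lists of
reference segments (a deletion removes a segment, a tandem duplication
repeats one, an inversion flips one's orientation, a break end fuses flanks
of two chromosomes), fragments are drawn along the donor haplotype at the
requested coverage with truncated-Gaussian lengths, and each read is mapped
back through the segment map.  A read pair straddling a junction therefore
acquires exactly the discordant geometry the junction type implies — longer
apparent fragments for deletions, -/+ pairs for tandem duplications, +/+ or
-/- pairs for inversions, interchromosomal pairs for break ends — and a read
crossing a junction with at least :data:`MIN_SPLIT_OVERLAP` bp on both sides
becomes a split read (shorter overhangs are soft-clipped to the major side).
A configurable fraction of templates has its second read relocated uniformly
at random, emulating nonspecific discordant alignments from mapping
artifacts.

Everything is reproducible: each sample draws from its own RNG stream keyed
by (cohort seed, sample id), so adding samples never perturbs existing ones.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam

from .evidence import (
    AlignmentView,
    EvidenceClass,
    EvidenceRecord,
    InsertSizeModel,
    chrom_key,
    sort_evidence,
    write_evidence,
)
from .query_engine import Breakpoint, SVQuery, SVType

__all__ = [
    "StructuralVariant",
    "CohortSpec",
    "TruthTable",
    "CohortStreams",
    "CohortData",
    "simulate_fragments",
    "emit_alignments",
    "default_test_cohort",
    "realize_cohort",
    "MIN_SPLIT_OVERLAP",
]

#: minimum read overhang on each side of a junction for a split alignment
MIN_SPLIT_OVERLAP = 20

#: reference flank kept on each side of a simulated break-end fusion
BND_FLANK = 2000

#: hard cap on the nonspecific-discordant fraction; real libraries run below this
MAX_NOISE_RATE = 0.05


@dataclass(frozen=True, slots=True)
class StructuralVariant:
    """One implanted SV.

    DEL/DUP/INV occupy ``chrom:[start, end)``.  A BND joins ``chrom:start``
    to ``chrom2:pos2`` (both point coordinates; ``end`` is unused and kept at
    ``start + 1``).
    """

    sv_id: str
    sv_type: str
    chrom: str
    start: int
    end: int
    chrom2: str | None = None
    pos2: int | None = None

    def __post_init__(self):
        SVType(self.sv_type)  # validates
        if self.sv_type == "BND":
            if self.chrom2 is None or self.pos2 is None:
                raise ValueError(f"{self.sv_id}: BND requires chrom2/pos2")
            if chrom_key(self.chrom) >= chrom_key(self.chrom2):
                raise ValueError(f"{self.sv_id}: BND ends must be on distinct, genome-ordered chromosomes")
        elif self.start >= self.end:
            raise ValueError(f"{self.sv_id}: SV interval must be non-empty")


@dataclass
class CohortSpec:
    """Everything needed to simulate a cohort deterministically.

    ``genotypes`` has one row per SV (in ``svs`` order) and one column per
    sample, values in {0, 1, 2} counting variant haplotypes.  Coverage is the
    total read coverage per sample (both haplotypes combined).
    """

    sample_ids: list[str]
    chrom_lengths: dict[str, int]
    svs: list[StructuralVariant]
    genotypes: np.ndarray
    fragment_mean: float = 300.0
    fragment_sd: float = 50.0
    read_length: int = 100
    coverage: float = 10.0
    noise_discordant_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        if self.genotypes.shape != (len(self.svs), len(self.sample_ids)):
            raise ValueError(
                f"genotypes must be (n_svs, n_samples) = ({len(self.svs)}, {len(self.sample_ids)}), "
                f"got {self.genotypes.shape}"
            )
        if self.genotypes.size and (self.genotypes.min() < 0 or self.genotypes.max() > 2):
            raise ValueError("genotypes must be in {0, 1, 2}")
        if not (0 <= self.noise_discordant_rate < MAX_NOISE_RATE):
            raise ValueError(f"noise_discordant_rate must be in [0, {MAX_NOISE_RATE})")
        if self.fragment_mean <= 0 or self.fragment_sd < 0 or self.read_length <= 0 or self.coverage <= 0:
            raise ValueError("fragment/read/coverage parameters must be positive")
        if self.fragment_mean < 2 * self.read_length:
            raise ValueError("fragment_mean must be at least twice the read length")
        for c, L in self.chrom_lengths.items():
            if L <= 0:
                raise ValueError(f"chromosome {c} has non-positive length")
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for sv in self.svs:
            if sv.sv_type == "BND":
                for c, p in ((sv.chrom, sv.start), (sv.chrom2, sv.pos2)):
                    if c not in self.chrom_lengths or not (0 < p < self.chrom_lengths[c]):
                        raise ValueError(f"{sv.sv_id}: break end {c}:{p} outside chromosome bounds")
            else:
                L = self.chrom_lengths.get(sv.chrom)
                if L is None or not (0 < sv.start < sv.end <= L):
                    raise ValueError(f"{sv.sv_id}: interval outside chromosome bounds")
                by_chrom.setdefault(sv.chrom, []).append((sv.start, sv.end, sv.sv_id))
        for c, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1, id1), (s2, e2, id2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"SVs {id1} and {id2} overlap on chromosome {c}")
        if len({sv.sv_id for sv in self.svs}) != len(self.svs):
            raise ValueError("SV ids must be unique")

    @property
    def fragment_cap(self) -> tuple[int, int]:
        """Truncation bounds of the fragment-length distribution (mean ± 3 sd,
        never below twice the read length)."""
        lo = max(2 * self.read_length, int(round(self.fragment_mean - 3 * self.fragment_sd)))
        hi = int(round(self.fragment_mean + 3 * self.fragment_sd))
        return lo, max(lo, hi)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "sample_ids": self.sample_ids,
                "chrom_lengths": self.chrom_lengths,
                "svs": [
                    {k: v for k, v in sv.__dict__.items() if v is not None}
                    if hasattr(sv, "__dict__")
                    else {
                        "sv_id": sv.sv_id, "sv_type": sv.sv_type, "chrom": sv.chrom,
                        "start": sv.start, "end": sv.end,
                        **({"chrom2": sv.chrom2, "pos2": sv.pos2} if sv.chrom2 else {}),
                    }
                    for sv in self.svs
                ],
                "genotypes": self.genotypes.tolist(),
                "fragment_mean": self.fragment_mean,
                "fragment_sd": self.fragment_sd,
                "read_length": self.read_length,
                "coverage": self.coverage,
                "noise_discordant_rate": self.noise_discordant_rate,
                "seed": self.seed,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        d = json.loads(text)
        d["svs"] = [StructuralVariant(**sv) for sv in d["svs"]]
        d["genotypes"] = np.asarray(d["genotypes"], dtype=np.int8)
        return cls(**d)


class TruthTable:
    """Per-(sample, SV) carrier status plus expected breakpoint coordinates."""

    def __init__(self, spec: CohortSpec):
        self.spec = spec
        self.carriers = pd.DataFrame(
            (spec.genotypes > 0).T,
            index=spec.sample_ids,
            columns=[sv.sv_id for sv in spec.svs],
        )
        self._svs = {sv.sv_id: sv for sv in spec.svs}

    def carrier_set(self, sv_id: str) -> set[str]:
        col = self.carriers[sv_id]
        return set(col.index[col])

    def sv(self, sv_id: str) -> StructuralVariant:
        return self._svs[sv_id]

    def query_for(self, sv_id: str, window: int = 500) -> SVQuery:
        """The query a user knowing the true breakpoints would submit.

        Breakpoint intervals are the single junction-adjacent base on the
        retained side of each breakpoint.
        """
        sv = self._svs[sv_id]
        c, s, e = sv.chrom, sv.start, sv.end
        t = SVType(sv.sv_type)
        if t is SVType.DEL:
            left, right = Breakpoint(c, s - 1, s), Breakpoint(c, e, e + 1)
        elif t is SVType.DUP:
            left, right = Breakpoint(c, s, s + 1), Breakpoint(c, e - 1, e)
        elif t is SVType.INV:
            left, right = Breakpoint(c, s - 1, s), Breakpoint(c, e - 1, e)
        else:
            left = Breakpoint(c, s - 1, s)
            right = Breakpoint(sv.chrom2, sv.pos2, sv.pos2 + 1)
        return SVQuery(t, left, right, window)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sv in self.spec.svs:
            for sample in self.spec.sample_ids:
                rows.append(
                    {
                        "sv_id": sv.sv_id, "sv_type": sv.sv_type, "chrom": sv.chrom,
                        "start": sv.start, "end": sv.end,
                        "chrom2": sv.chrom2 or "", "pos2": sv.pos2 if sv.pos2 is not None else "",
                        "sample": sample, "carrier": int(self.carriers.loc[sample, sv.sv_id]),
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Donor haplotype construction and fragment simulation
# ---------------------------------------------------------------------------

def _donor_contigs(spec: CohortSpec, sample_index: int, hap: int) -> list[list[tuple[str, int, int, int]]]:
    """Segment maps of one haplotype: contigs as lists of
    (ref_chrom, ref_start, ref_end, orientation)."""
    carried = spec.genotypes[:, sample_index] > hap
    contigs: list[list[tuple[str, int, int, int]]] = []
    for chrom in sorted(spec.chrom_lengths, key=chrom_key):
        L = spec.chrom_lengths[chrom]
        events = sorted(
            (sv for sv, c in zip(spec.svs, carried) if c and sv.sv_type != "BND" and sv.chrom == chrom),
            key=lambda sv: sv.start,
        )
        segs: list[tuple[str, int, int, int]] = []
        cursor = 0
        for sv in events:
            if sv.sv_type == "DEL":
                if sv.start > cursor:
                    segs.append((chrom, cursor, sv.start, 1))
            elif sv.sv_type == "DUP":
                segs.append((chrom, cursor, sv.end, 1))
                segs.append((chrom, sv.start, sv.end, 1))
            else:  # INV
                if sv.start > cursor:
                    segs.append((chrom, cursor, sv.start, 1))
                segs.append((chrom, sv.start, sv.end, -1))
            cursor = sv.end
        if cursor < L:
            segs.append((chrom, cursor, L, 1))
        contigs.append(segs or [(chrom, 0, L, 1)])
    for sv, c in zip(spec.svs, carried):
        if c and sv.sv_type == "BND":
            a0 = max(0, sv.start - BND_FLANK)
            b1 = min(spec.chrom_lengths[sv.chrom2], sv.pos2 + BND_FLANK)
            contigs.append([(sv.chrom, a0, sv.start, 1), (sv.chrom2, sv.pos2, b1, 1)])
    return contigs


class _SampleTemplates:
    """Struct-of-arrays view of one sample's simulated templates.

    Read spans are primary (post-clipping) reference spans; ``splits1`` /
    ``splits2`` map template index to the supplementary segment of read 1 / 2.
    Chromosomes are codes into ``chrom_names`` (bytewise-sorted order).
    """

    __slots__ = (
        "sample_id", "chrom_names", "c1", "s1", "e1", "st1",
        "c2", "s2", "e2", "st2", "splits1", "splits2", "n",
    )

    def __init__(self, sample_id, chrom_names, c1, s1, e1, st1, c2, s2, e2, st2, splits1, splits2):
        self.sample_id = sample_id
        self.chrom_names = chrom_names
        self.c1, self.s1, self.e1, self.st1 = c1, s1, e1, st1
        self.c2, self.s2, self.e2, self.st2 = c2, s2, e2, st2
        self.splits1, self.splits2 = splits1, splits2
        self.n = len(s1)


def _map_read(B, segs, ds: int, de: int, dstrand: int):
    """Map one donor-interval read through the segment map.

    Returns ``(primary, split)`` where each is ``(chrom, start, end, strand)``
    and ``split`` is None unless the read crosses a junction with at least
    MIN_SPLIT_OVERLAP bp on both sides (the shorter side is clipped away
    otherwise).
    """
    i = int(np.searchsorted(B, ds, side="right")) - 1
    j = int(np.searchsorted(B, de - 1, side="right")) - 1
    parts = []
    for k in range(i, j + 1):
        lo = max(ds, int(B[k]))
        hi = min(de, int(B[k + 1]))
        if hi > lo:
            parts.append((hi - lo, k, lo, hi))
    parts.sort(key=lambda p: (-p[0], p[1]))

    def to_ref(plen, k, lo, hi):
        chrom, rs, re, o = segs[k]
        off = lo - int(B[k])
        if o > 0:
            return (chrom, rs + off, rs + off + plen, dstrand)
        return (chrom, re - off - plen, re - off, -dstrand)

    primary = to_ref(*parts[0])
    split = None
    if len(parts) > 1 and parts[1][0] >= MIN_SPLIT_OVERLAP and parts[0][0] >= MIN_SPLIT_OVERLAP:
        split = to_ref(*parts[1])
    return primary, split


def _simulate_sample(spec: CohortSpec, sample_index: int) -> _SampleTemplates:
    sample_id = spec.sample_ids[sample_index]
    rng = np.random.default_rng([spec.seed, zlib.crc32(sample_id.encode())])
    chrom_names = sorted(spec.chrom_lengths, key=chrom_key)
    chrom_code = {c: i for i, c in enumerate(chrom_names)}
    chrom_len = np.asarray([spec.chrom_lengths[c] for c in chrom_names], dtype=np.int64)
    rl = spec.read_length
    flo, fhi = spec.fragment_cap
    per_hap_rate = spec.coverage / 2.0 / (2.0 * rl)  # fragments per bp per haplotype

    cols: dict[str, list[np.ndarray]] = {k: [] for k in ("c1", "s1", "e1", "st1", "c2", "s2", "e2", "st2")}
    splits1: dict[int, tuple[int, int, int, int]] = {}
    splits2: dict[int, tuple[int, int, int, int]] = {}
    offset = 0

    for hap in (0, 1):
        for segs in _donor_contigs(spec, sample_index, hap):
            seg_len = np.asarray([e - s for _, s, e, _ in segs], dtype=np.int64)
            B = np.concatenate([[0], np.cumsum(seg_len)])
            L = int(B[-1])
            n = int(rng.poisson(per_hap_rate * L))
            if n == 0 or L < flo:
                continue
            flen = np.clip(np.rint(rng.normal(spec.fragment_mean, spec.fragment_sd, n)), flo, min(fhi, L)).astype(np.int64)
            start = np.floor(rng.random(n) * (L - flen + 1)).astype(np.int64)
            ds1, de1 = start, start + rl
            ds2, de2 = start + flen - rl, start + flen

            out = {}
            for tag, ds, de, dstrand in (("1", ds1, de1, 1), ("2", ds2, de2, -1)):
                i = np.searchsorted(B, ds, side="right") - 1
                j = np.searchsorted(B, de - 1, side="right") - 1
                seg_chrom = np.asarray([chrom_code[c] for c, *_ in segs], dtype=np.int64)
                seg_s = np.asarray([s for _, s, _, _ in segs], dtype=np.int64)
                seg_e = np.asarray([e for _, _, e, _ in segs], dtype=np.int64)
                seg_o = np.asarray([o for *_, o in segs], dtype=np.int64)
                off = ds - B[i]
                plus = seg_o[i] > 0
                rs = np.where(plus, seg_s[i] + off, seg_e[i] - off - rl)
                re = rs + rl
                cc = seg_chrom[i]
                stx = dstrand * seg_o[i]
                cross = np.nonzero(i != j)[0]
                for t in cross:
                    primary, split = _map_read(B, segs, int(ds[t]), int(de[t]), dstrand)
                    cc[t] = chrom_code[primary[0]]
                    rs[t] = primary[1]
                    re[t] = primary[2]
                    stx[t] = primary[3]
                    if split is not None:
                        target = splits1 if tag == "1" else splits2
                        target[offset + int(t)] = (
                            chrom_code[split[0]], split[1], split[2], split[3]
                        )
                out[tag] = (cc, rs, re, stx)

            c1, s1, e1, st1 = out["1"]
            c2, s2, e2, st2 = out["2"]

            if spec.noise_discordant_rate > 0:
                noisy = np.nonzero(rng.random(n) < spec.noise_discordant_rate)[0]
                if noisy.size:
                    ncode = rng.integers(0, len(chrom_names), noisy.size)
                    npos = np.floor(rng.random(noisy.size) * (chrom_len[ncode] - rl)).astype(np.int64)
                    nst = rng.integers(0, 2, noisy.size) * 2 - 1
                    c2 = c2.copy(); s2 = s2.copy(); e2 = e2.copy(); st2 = st2.copy()
                    c2[noisy] = ncode
                    s2[noisy] = npos
                    e2[noisy] = npos + rl
                    st2[noisy] = nst
                    for t in noisy:
                        splits2.pop(offset + int(t), None)

            for name, arr in (("c1", c1), ("s1", s1), ("e1", e1), ("st1", st1),
                              ("c2", c2), ("s2", s2), ("e2", e2), ("st2", st2)):
                cols[name].append(arr)
            offset += n

    def cat(name):
        parts = cols[name]
        return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)

    return _SampleTemplates(
        sample_id, chrom_names,
        cat("c1"), cat("s1"), cat("e1"), cat("st1"),
        cat("c2"), cat("s2"), cat("e2"), cat("st2"),
        splits1, splits2,
    )


def _views_of(t: _SampleTemplates) -> Iterator[AlignmentView]:
    """Materialize a template block as an alignment-record stream
    (read 1 then read 2 of each template, primary records only)."""
    names = t.chrom_names
    for k in range(t.n):
        c1, s1, e1, st1 = names[t.c1[k]], int(t.s1[k]), int(t.e1[k]), int(t.st1[k])
        c2, s2, e2, st2 = names[t.c2[k]], int(t.s2[k]), int(t.e2[k]), int(t.st2[k])
        name = f"{t.sample_id}.{k}"
        sp1 = t.splits1.get(k)
        sp2 = t.splits2.get(k)
        v1 = AlignmentView(
            chrom=c1, start=s1, end=e1, strand=st1, paired=True,
            mate_chrom=c2, mate_start=s2, mate_end=e2, mate_strand=st2,
            is_read1=True, name=name,
        )
        if sp1 is not None:
            v1.has_split = True
            v1.split_chrom = names[sp1[0]]
            v1.split_start, v1.split_end, v1.split_strand = int(sp1[1]), int(sp1[2]), int(sp1[3])
        v2 = AlignmentView(
            chrom=c2, start=s2, end=e2, strand=st2, paired=True,
            mate_chrom=c1, mate_start=s1, mate_end=e1, mate_strand=st1,
            is_read1=False, name=name,
        )
        if sp2 is not None:
            v2.has_split = True
            v2.split_chrom = names[sp2[0]]
            v2.split_start, v2.split_end, v2.split_strand = int(sp2[1]), int(sp2[2]), int(sp2[3])
        yield v1
        yield v2


def _records_from_arrays(t: _SampleTemplates, model: InsertSizeModel) -> list[EvidenceRecord]:
    """Vectorized twin of streaming the sample's alignment views through
    :func:`svidx.evidence.iter_evidence_records`: identical records in
    identical pre-sort order."""
    if t.n == 0:
        return []
    d = model.discordant_distance
    names = t.chrom_names
    left_is_1 = (t.c1 < t.c2) | ((t.c1 == t.c2) & (t.s1 <= t.s2))
    interchrom = t.c1 != t.c2
    lst = np.where(left_is_1, t.st1, t.st2)
    rst = np.where(left_is_1, t.st2, t.st1)
    outer = np.maximum(t.e1, t.e2) - np.minimum(t.s1, t.s2)
    disc = interchrom | (lst != 1) | (rst != -1) | (~interchrom & (outer > d))

    lc = np.where(left_is_1, t.c1, t.c2)
    ls = np.where(left_is_1, t.s1, t.s2)
    le = np.where(left_is_1, t.e1, t.e2)
    rc = np.where(left_is_1, t.c2, t.c1)
    rs = np.where(left_is_1, t.s2, t.s1)
    re = np.where(left_is_1, t.e2, t.e1)
    # breakpoint padding, as in make_evidence_records
    pls = np.where(lst > 0, ls, np.maximum(0, np.minimum(ls, le - d)))
    ple = np.where(lst > 0, np.maximum(le, ls + d), le)
    prs = np.where(rst > 0, rs, np.maximum(0, np.minimum(rs, re - d)))
    pre = np.where(rst > 0, np.maximum(re, rs + d), re)
    # padding of -/- pairs with unequal clipped spans can reorder the starts;
    # restore genome order (mirrors make_evidence_records)
    swap = (lc == rc) & (pls > prs)
    if np.any(swap):
        pls2, ple2, lst2 = pls.copy(), ple.copy(), lst.copy()
        pls[swap], ple[swap], lst[swap] = prs[swap], pre[swap], rst[swap]
        prs[swap], pre[swap], rst[swap] = pls2[swap], ple2[swap], lst2[swap]

    interesting = set(np.nonzero(disc)[0].tolist())
    interesting.update(t.splits1)
    interesting.update(t.splits2)

    def split_record(primary, sp):
        ends = sorted(
            [primary, (names[sp[0]], int(sp[1]), int(sp[2]), int(sp[3]))],
            key=lambda x: (chrom_key(x[0]), x[1], x[2]),
        )
        return EvidenceRecord(*ends[0], *ends[1], EvidenceClass.SPLIT)

    out: list[EvidenceRecord] = []
    for k in sorted(interesting):
        pair = None
        if disc[k]:
            pair = EvidenceRecord(
                names[lc[k]], int(pls[k]), int(ple[k]), int(lst[k]),
                names[rc[k]], int(prs[k]), int(pre[k]), int(rst[k]),
                EvidenceClass.PAIREND,
            )
        sp1 = t.splits1.get(k)
        sp2 = t.splits2.get(k)
        # stream order: read 1 (pairend-if-emitter, then split), read 2 likewise
        if pair is not None and left_is_1[k]:
            out.append(pair)
        if sp1 is not None:
            out.append(split_record((names[t.c1[k]], int(t.s1[k]), int(t.e1[k]), int(t.st1[k])), sp1))
        if pair is not None and not left_is_1[k]:
            out.append(pair)
        if sp2 is not None:
            out.append(split_record((names[t.c2[k]], int(t.s2[k]), int(t.e2[k]), int(t.st2[k])), sp2))
    return out


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

class CohortStreams:
    """Lazy per-sample alignment streams; regenerable from the seed at will."""

    def __init__(self, spec: CohortSpec):
        self.spec = spec
        self.sample_ids = list(spec.sample_ids)
        self._cache: tuple[str, _SampleTemplates] | None = None

    def _templates(self, sample_id: str) -> _SampleTemplates:
        if self._cache is not None and self._cache[0] == sample_id:
            return self._cache[1]
        t = _simulate_sample(self.spec, self.sample_ids.index(sample_id))
        self._cache = (sample_id, t)
        return t

    def views(self, sample_id: str) -> Iterator[AlignmentView]:
        """Alignment records of one sample, read 1 then read 2 per template."""
        return _views_of(self._templates(sample_id))

    def n_templates(self, sample_id: str) -> int:
        return self._templates(sample_id).n


def simulate_fragments(spec: CohortSpec) -> tuple[CohortStreams, TruthTable]:
    """Simulate the cohort; returns lazy per-sample streams plus the truth table."""
    return CohortStreams(spec), TruthTable(spec)


def emit_alignments(views: Iterable[AlignmentView], path, chrom_lengths: dict[str, int]) -> Path:
    """Write an alignment-view stream as a valid SAM file.

    Mates carry RNEXT/PNEXT/MC; split reads are written as a primary plus a
    supplementary record linked by SA tags.  Sequence is omitted (coordinate
    simulation carries no bases).
    """
    path = Path(path)
    chroms = sorted(chrom_lengths, key=chrom_key)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": int(chrom_lengths[c])} for c in chroms],
        }
    )
    tid = {c: i for i, c in enumerate(chroms)}

    def sa_tag(chrom, start, end, strand):
        return f"{chrom},{start + 1},{'+' if strand > 0 else '-'},{end - start}M,60,0;"

    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for v in views:
            a = pysam.AlignedSegment(header=header)
            a.query_name = v.name
            flag = 0
            if v.paired:
                flag |= 0x1 | (0x40 if v.is_read1 else 0x80)
            if v.strand < 0:
                flag |= 0x10
            if v.paired and v.mate_strand is not None and v.mate_strand < 0:
                flag |= 0x20
            a.flag = flag
            a.reference_id = tid[v.chrom]
            a.reference_start = v.start
            a.mapping_quality = v.mapq
            a.cigartuples = [(0, v.end - v.start)]
            if v.paired and v.mate_chrom is not None:
                a.next_reference_id = tid[v.mate_chrom]
                a.next_reference_start = v.mate_start
                mate_end = v.mate_end if v.mate_end is not None else v.mate_start + (v.end - v.start)
                a.set_tag("MC", f"{mate_end - v.mate_start}M")
                if v.mate_chrom == v.chrom:
                    outer = max(v.end, mate_end) - min(v.start, v.mate_start)
                    a.template_length = outer if v.start <= v.mate_start else -outer
            if v.has_split:
                a.set_tag("SA", sa_tag(v.split_chrom, v.split_start, v.split_end, v.split_strand))
            out.write(a)
            if v.has_split:
                s = pysam.AlignedSegment(header=header)
                s.query_name = v.name
                sflag = 0x800
                if v.paired:
                    sflag |= 0x1 | (0x40 if v.is_read1 else 0x80)
                if v.split_strand < 0:
                    sflag |= 0x10
                if v.paired and v.mate_strand is not None and v.mate_strand < 0:
                    sflag |= 0x20
                s.flag = sflag
                s.reference_id = tid[v.split_chrom]
                s.reference_start = v.split_start
                s.mapping_quality = v.mapq
                s.cigartuples = [(0, v.split_end - v.split_start)]
                if v.paired and v.mate_chrom is not None:
                    s.next_reference_id = tid[v.mate_chrom]
                    s.next_reference_start = v.mate_start
                s.set_tag("SA", sa_tag(v.chrom, v.start, v.end, v.strand))
                out.write(s)
    return path


def default_test_cohort(
    seed: int,
    n_samples: int = 20,
    noise_discordant_rate: float = 0.04,
) -> CohortSpec:
    """The standard benchmark cohort.

    20 samples over two 2-Mb chromosomes carrying 30 SVs — 10 deletions, 10
    tandem duplications, 8 inversions (200–5,000 bp each) and 2
    interchromosomal break ends — with genotypes drawn under Hardy–Weinberg
    at allele frequencies uniform in [0.05, 0.5]; 10x coverage, 300±50 bp
    fragments, 100 bp reads, and 4% nonspecific discordant templates.
    """
    rng = np.random.default_rng([seed, 7919])
    chrom_lengths = {"1": 2_000_000, "2": 2_000_000}
    types = ["DEL"] * 10 + ["DUP"] * 10 + ["INV"] * 8
    sizes = rng.integers(200, 5001, len(types))
    slots: dict[str, list[int]] = {}
    n_slots = {"1": sum(1 for i in range(len(types)) if i % 2 == 0) + 2,
               "2": sum(1 for i in range(len(types)) if i % 2 == 1) + 2}
    for c in ("1", "2"):
        base = np.linspace(30_000, chrom_lengths[c] - 40_000, n_slots[c])
        slots[c] = [int(b) + int(j) for b, j in zip(base, rng.integers(0, 8000, n_slots[c]))]
    cursor = {"1": 0, "2": 0}

    def take(c):
        p = slots[c][cursor[c]]
        cursor[c] += 1
        return p

    svs: list[StructuralVariant] = []
    counters: dict[str, int] = {}
    for i, t in enumerate(types):
        c = "1" if i % 2 == 0 else "2"
        pos = take(c)
        k = counters.get(t, 0)
        counters[t] = k + 1
        svs.append(StructuralVariant(f"{t}_{k:02d}", t, c, pos, pos + int(sizes[i])))
    for k in range(2):
        pos1 = take("1")
        svs.append(
            StructuralVariant(f"BND_{k:02d}", "BND", "1", pos1, pos1 + 1,
                              chrom2="2", pos2=take("2"))
        )
    afs = rng.uniform(0.05, 0.5, len(svs))
    genotypes = rng.binomial(2, afs[:, None], (len(svs), n_samples)).astype(np.int8)
    return CohortSpec(
        sample_ids=[f"S{i:03d}" for i in range(n_samples)],
        chrom_lengths=chrom_lengths,
        svs=svs,
        genotypes=genotypes,
        noise_discordant_rate=noise_discordant_rate,
        seed=seed,
    )


def germline_benchmark(
    seed: int,
    workdir,
    n_polymorphic: int = 50,
    n_somatic: int = 50,
    n_samples: int = 10,
):
    """Panel-of-normals filtering scenario.

    Builds a noise-free cohort of ``n_samples`` normals carrying
    ``n_polymorphic`` deletions (each with at least one carrier), and a tumor
    call set that mixes those polymorphic deletions with ``n_somatic``
    somatic deletions absent from the cohort.  A filter that removes calls
    with any population evidence should discard exactly the polymorphic half.

    Returns ``(cohort_data, tumor_calls, somatic_truth)`` where the call sets
    are lists of :class:`svidx.cohort_eval.SVInterval`.
    """
    from .cohort_eval import SVInterval

    rng = np.random.default_rng([seed, 60013])
    chrom_lengths = {"1": 2_000_000, "2": 2_000_000}
    n_total = n_polymorphic + n_somatic
    per_chrom = (n_total + 1) // 2
    loci: list[tuple[str, int, int]] = []
    sizes = rng.integers(200, 2001, n_total)
    for ci, c in enumerate(("1", "2")):
        k = per_chrom if ci == 0 else n_total - per_chrom
        base = np.linspace(30_000, chrom_lengths[c] - 40_000, k)
        jit = rng.integers(0, 4000, k)
        for b, j, in zip(base, jit):
            loci.append((c, int(b) + int(j), 0))
    loci = [(c, s, s + int(sz)) for (c, s, _), sz in zip(loci, sizes)]

    polymorphic = [SVInterval(c, s, e, "DEL", f"POLY_{i:02d}") for i, (c, s, e) in enumerate(loci[:n_polymorphic])]
    somatic = [SVInterval(c, s, e, "DEL", f"SOM_{i:02d}") for i, (c, s, e) in enumerate(loci[n_polymorphic:])]

    svs = [
        StructuralVariant(iv.label, "DEL", iv.chrom, iv.start, iv.end)
        for iv in polymorphic
    ]
    genotypes = np.zeros((len(svs), n_samples), dtype=np.int8)
    for i in range(len(svs)):
        k = max(1, int(rng.binomial(n_samples, 0.3)))
        carriers = rng.choice(n_samples, size=k, replace=False)
        genotypes[i, carriers] = 1
    spec = CohortSpec(
        sample_ids=[f"N{i:03d}" for i in range(n_samples)],
        chrom_lengths=chrom_lengths,
        svs=svs,
        genotypes=genotypes,
        noise_discordant_rate=0.0,
        seed=seed,
    )
    data = realize_cohort(spec, workdir)
    tumor_calls = polymorphic + somatic
    return data, tumor_calls, somatic


@dataclass
class CohortData:
    """A realized cohort on disk: evidence files, PED, truth, and counts."""

    spec: CohortSpec
    model: InsertSizeModel
    truth: TruthTable
    workdir: Path
    sample_ids: list[str]
    evidence_files: list[Path]
    ped_path: Path
    n_templates: int
    n_records: int

    @property
    def evidence_fraction(self) -> float:
        return self.n_records / self.n_templates if self.n_templates else 0.0


def realize_cohort(
    spec: CohortSpec,
    workdir,
    discordant_distance: int = 500,
    write_sam: bool = False,
) -> CohortData:
    """Simulate, extract and lay out a cohort ready for indexing.

    Per sample this produces a sorted evidence file (``<sample>.bed.gz``) —
    through the vectorized extraction path, which is record-for-record
    identical to streaming the alignments through the classifier — plus a
    cohort PED file and, optionally, per-sample SAM files.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    model = InsertSizeModel(spec.fragment_mean, max(spec.fragment_sd, 0.0), discordant_distance)
    streams, truth = simulate_fragments(spec)
    evidence_files: list[Path] = []
    n_templates = 0
    n_records = 0
    for sid in spec.sample_ids:
        t = streams._templates(sid)
        records = sort_evidence(_records_from_arrays(t, model))
        out = workdir / f"{sid}.bed.gz"
        write_evidence(records, out)
        evidence_files.append(out)
        n_templates += t.n
        n_records += len(records)
        if write_sam:
            emit_alignments(_views_of(t), workdir / f"{sid}.sam", spec.chrom_lengths)
    ped = workdir / "cohort.ped"
    lines = ["Sample\tSex\tPopulation\tSuper_Population\tAlt_File"]
    for i, sid in enumerate(spec.sample_ids):
        lines.append(f"{sid}\t{1 + i % 2}\tSIM\tSIM\t{sid}.bed.gz")
    ped.write_text("\n".join(lines) + "\n")
    truth_path = workdir / "truth.tsv"
    truth.to_frame().to_csv(truth_path, sep="\t", index=False)
    return CohortData(
        spec=spec, model=model, truth=truth, workdir=workdir,
        sample_ids=list(spec.sample_ids), evidence_files=evidence_files,
        ped_path=ped, n_templates=n_templates, n_records=n_records,
    )
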