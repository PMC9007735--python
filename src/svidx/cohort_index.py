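"""Multi-sample searchable index over per-sample evidence files.

The index answers "which evidence records, from which samples, have an end
interval overlapping this probe?" across a whole cohort.  Every record is
entered under *both* of its end intervals so interchromosomal evidence is
findable from either side; the query layer deduplicates double hits.

The structure is a per-chromosome array sorted by interval start with a
running-maximum end column for pruning (equivalent in results to an interval
tree).  A deliberately naive linear-scan twin, :class:`BruteForceSearcher`,
applies the same overlap predicate to every stored end and serves as the
correctness oracle in tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .evidence import (
    EvidenceClass,
    EvidenceRecord,
    chrom_key,
    read_evidence,
)

__all__ = [
    "Hit",
    "CohortIndex",
    "BruteForceSearcher",
    "build_index",
    "brute_force_search",
    "IndexConfigError",
]

INDEX_FORMAT_VERSION = 1


class IndexConfigError(ValueError):
    """Raised for inconsistent index construction inputs."""


@dataclass(slots=True, frozen=True)
class Hit:
    """One end-interval overlap between a probe and a stored record."""

    sample_id: str
    record: EvidenceRecord
    matched_end: str  # "left" or "right"
    ordinal: int  # per-sample record ordinal; stable record identity

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.sample_id, self.ordinal, self.matched_end)


def _hit_sort_key(h: Hit):
    return (h.sample_id, h.ordinal, h.matched_end)


class _Shard:
    """End intervals on one chromosome, sorted by start with max-end pruning."""

    __slots__ = ("starts", "ends", "prefix_max_end", "sample_idx", "ordinal", "side")

    def __init__(self, starts, ends, sample_idx, ordinal, side):
        order = np.argsort(starts, kind="stable")
        self.starts = starts[order]
        self.ends = ends[order]
        self.sample_idx = sample_idx[order]
        self.ordinal = ordinal[order]
        self.side = side[order]
        self.prefix_max_end = np.maximum.accumulate(self.ends)

    def search(self, qstart: int, qend: int) -> np.ndarray:
        hi = int(np.searchsorted(self.starts, qend, side="left"))
        if hi == 0:
            return np.empty(0, dtype=np.int64)
        # prefix max end is nondecreasing: entries before `lo` all end <= qstart
        lo = int(np.searchsorted(self.prefix_max_end[:hi], qstart, side="right"))
        if lo >= hi:
            return np.empty(0, dtype=np.int64)
        sel = np.nonzero(self.ends[lo:hi] > qstart)[0] + lo
        return sel


class CohortIndex:
    """Searchable store of evidence records for a cohort of samples.

    Build with :func:`build_index`; persist with :meth:`save` /
    :meth:`load`.  Search results are independent of the order in which the
    per-sample files were supplied.
    """

    def __init__(self):
        self.sample_ids: list[str] = []
        self.files: dict[str, str] = {}
        self._records: dict[str, list[EvidenceRecord]] = {}
        self._shards: dict[str, _Shard] = {}

    # -- construction -------------------------------------------------------

    def _add_sample(self, sample_id: str, file_name: str, records: list[EvidenceRecord]):
        if sample_id in self._records:
            raise IndexConfigError(f"duplicate sample id: {sample_id}")
        self.sample_ids.append(sample_id)
        self.files[sample_id] = file_name
        self._records[sample_id] = records

    def _finalize(self):
        buckets: dict[str, list[tuple[int, int, int, int, int]]] = {}
        for si, sample in enumerate(sorted(self.sample_ids)):
            for k, r in enumerate(self._records[sample]):
                buckets.setdefault(r.left_chrom, []).append((r.left_start, r.left_end, si, k, 0))
                buckets.setdefault(r.right_chrom, []).append((r.right_start, r.right_end, si, k, 1))
        self._sorted_samples = sorted(self.sample_ids)
        self._shards = {}
        for chrom, rows in buckets.items():
            arr = np.asarray(rows, dtype=np.int64)
            self._shards[chrom] = _Shard(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], arr[:, 4])

    # -- queries ------------------------------------------------------------

    def search(self, chrom: str, start: int, end: int) -> list[Hit]:
        """All hits whose left or right end interval overlaps ``chrom:[start, end)``.

        An unknown chromosome yields an empty result.  A record whose two
        ends both overlap the probe is reported twice, once per end, exactly
        as the brute-force scan would.
        """
        if start >= end:
            raise ValueError(f"probe interval must be non-empty: [{start}, {end})")
        shard = self._shards.get(chrom)
        if shard is None:
            return []
        hits = []
        for i in shard.search(start, end):
            sample = self._sorted_samples[shard.sample_idx[i]]
            ordinal = int(shard.ordinal[i])
            rec = self._records[sample][ordinal]
            side = "left" if shard.side[i] == 0 else "right"
            hits.append(Hit(sample, rec, side, ordinal))
        hits.sort(key=_hit_sort_key)
        return hits

    def records_for(self, sample_id: str) -> Sequence[EvidenceRecord]:
        return self._records[sample_id]

    def manifest(self) -> dict:
        return {
            "version": INDEX_FORMAT_VERSION,
            "samples": [
                {"id": s, "file": self.files[s], "n_records": len(self._records[s])}
                for s in self.sample_ids
            ],
        }

    @property
    def n_records(self) -> int:
        return sum(len(v) for v in self._records.values())

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> Path:
        """Persist as a directory: a JSON manifest plus one TSV shard per
        left-end chromosome.  The format is versioned and text-only."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        by_chrom: dict[str, list[str]] = {}
        for sample in self.sample_ids:
            for k, r in enumerate(self._records[sample]):
                line = "\t".join(
                    str(x)
                    for x in (
                        sample, k,
                        r.left_chrom, r.left_start, r.left_end, r.left_strand,
                        r.right_chrom, r.right_start, r.right_end, r.right_strand,
                        int(r.evidence_class),
                    )
                )
                by_chrom.setdefault(r.left_chrom, []).append(line)
        shard_names = {}
        for i, chrom in enumerate(sorted(by_chrom, key=chrom_key)):
            name = f"shard_{i:04d}.tsv"
            shard_names[chrom] = name
            (directory / name).write_text("\n".join(by_chrom[chrom]) + "\n")
        manifest = self.manifest()
        manifest["shards"] = shard_names
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return directory

    @classmethod
    def load(cls, directory) -> "CohortIndex":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        if manifest.get("version") != INDEX_FORMAT_VERSION:
            raise IndexConfigError(f"unsupported index version: {manifest.get('version')}")
        idx = cls()
        per_sample: dict[str, dict[int, EvidenceRecord]] = {}
        for entry in manifest["samples"]:
            per_sample[entry["id"]] = {}
        for name in manifest["shards"].values():
            for lineno, line in enumerate((directory / name).read_text().splitlines(), 1):
                f = line.split("\t")
                if len(f) != 11:
                    raise IndexConfigError(f"{directory / name}:{lineno}: malformed shard line")
                rec = EvidenceRecord(
                    f[2], int(f[3]), int(f[4]), int(f[5]),
                    f[6], int(f[7]), int(f[8]), int(f[9]),
                    EvidenceClass(int(f[10])),
                )
                per_sample[f[0]][int(f[1])] = rec
        for entry in manifest["samples"]:
            sid = entry["id"]
            recs = per_sample[sid]
            if len(recs) != entry["n_records"]:
                raise IndexConfigError(
                    f"sample {sid}: manifest says {entry['n_records']} records, shards held {len(recs)}"
                )
            idx._add_sample(sid, entry["file"], [recs[k] for k in range(len(recs))])
        idx._finalize()
        return idx


def build_index(
    evidence_files: Sequence, sample_ids: Sequence[str] | None = None
) -> CohortIndex:
    """Build a :class:`CohortIndex` from per-sample evidence files.

    ``sample_ids`` defaults to the file basenames.  Duplicate ids are a
    configuration error; parse failures name the file and line.
    """
    files = [Path(p) for p in evidence_files]
    if sample_ids is None:
        sample_ids = [p.name for p in files]
    if len(sample_ids) != len(files):
        raise IndexConfigError("sample_ids must parallel evidence_files")
    idx = CohortIndex()
    for sid, path in zip(sample_ids, files):
        idx._add_sample(sid, path.name, read_evidence(path))
    idx._finalize()
    return idx


class BruteForceSearcher:
    """Linear-scan oracle: applies the overlap predicate to every stored end.

    No sorting, no pruning — every end interval of every record of every
    sample is tested against the probe.  Used to verify the index and as an
    alternative execution path for whole-query equivalence checks.
    """

    def __init__(self, records_by_sample: Mapping[str, Sequence[EvidenceRecord]],
                 files: Mapping[str, str] | None = None):
        self.sample_ids = list(records_by_sample)
        self.files = dict(files) if files else {s: s for s in self.sample_ids}
        self._records = {s: list(v) for s, v in records_by_sample.items()}
        rows = []
        chrom_codes: dict[str, int] = {}
        for si, sample in enumerate(self.sample_ids):
            for k, r in enumerate(self._records[sample]):
                for side_code, (c, s, e) in enumerate((r.end_interval("left"), r.end_interval("right"))):
                    code = chrom_codes.setdefault(c, len(chrom_codes))
                    rows.append((code, s, e, si, k, side_code))
        self._chrom_codes = chrom_codes
        if rows:
            arr = np.asarray(rows, dtype=np.int64)
            self._codes, self._starts, self._ends = arr[:, 0], arr[:, 1], arr[:, 2]
            self._sample_i, self._ordinal, self._side = arr[:, 3], arr[:, 4], arr[:, 5]
        else:
            self._codes = np.empty(0, dtype=np.int64)

    @classmethod
    def from_files(cls, evidence_files: Sequence, sample_ids: Sequence[str] | None = None):
        files = [Path(p) for p in evidence_files]
        if sample_ids is None:
            sample_ids = [p.name for p in files]
        recs = {}
        names = {}
        for sid, p in zip(sample_ids, files):
            if sid in recs:
                raise IndexConfigError(f"duplicate sample id: {sid}")
            recs[sid] = read_evidence(p)
            names[sid] = p.name
        return cls(recs, names)

    def records_for(self, sample_id: str) -> Sequence[EvidenceRecord]:
        return self._records[sample_id]

    def search(self, chrom: str, start: int, end: int) -> list[Hit]:
        if start >= end:
            raise ValueError(f"probe interval must be non-empty: [{start}, {end})")
        code = self._chrom_codes.get(chrom)
        if code is None or self._codes.size == 0:
            return []
        mask = (self._codes == code) & (self._starts < end) & (self._ends > start)
        hits = []
        for i in np.nonzero(mask)[0]:
            sample = self.sample_ids[self._sample_i[i]]
            ordinal = int(self._ordinal[i])
            hits.append(
                Hit(sample, self._records[sample][ordinal],
                    "left" if self._side[i] == 0 else "right", ordinal)
            )
        hits.sort(key=_hit_sort_key)
        return hits


def brute_force_search(evidence_files: Sequence, probe: tuple[str, int, int],
                       sample_ids: Sequence[str] | None = None) -> list[Hit]:
    """One-shot linear scan of evidence files for a single probe."""
    chrom, start, end = probe
    return BruteForceSearcher.from_files(evidence_files, sample_ids).search(chrom, start, end)
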