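"""Evaluation procedures for cohort-level SV evidence.

Sample-level classification is scored with the usual confusion-matrix
quantities: the positives are the cohort samples carrying the variant in the
truth set, and a sample counts as detected when the query returns any
supporting evidence for it.  Call-set comparisons (germline filtering) use
reciprocal-overlap interval matching, the bedtools-style criterion in which
two intervals match when the shared length is at least a fixed fraction
(default 0.9) of *both*.  A query-resolution sweep measures how support decays
as the query breakpoints are displaced from the true ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .query_engine import Breakpoint, QueryResult, SVQuery, run_query

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "SVInterval",
    "confusion",
    "metrics",
    "reciprocal_overlap",
    "intersect_sets",
    "germline_filter_eval",
    "resolution_sweep",
    "median_sweep",
    "evidence_summary",
    "carrier_classification",
]


@dataclass(frozen=True, slots=True)
class ConfusionCounts:
    """Sample-classification counts: P, N and the four cells."""

    P: int
    N: int
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.P, self.N, self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.TP + self.FN != self.P or self.TN + self.FP != self.N:
            raise ValueError(f"inconsistent confusion counts: {self}")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.P + other.P, self.N + other.N, self.TP + other.TP,
            self.TN + other.TN, self.FP + other.FP, self.FN + other.FN,
        )


@dataclass(frozen=True, slots=True)
class Metrics:
    """The five derived statistics; undefined ratios are NaN, never 0."""

    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
        }


def confusion(evidence_samples: set, truth_samples: set, cohort: set) -> ConfusionCounts:
    """Confusion counts for one variant over a cohort of samples.

    ``truth_samples`` are the carriers; ``evidence_samples`` are the samples
    the query flagged.  Both must be subsets of ``cohort``.
    """
    evidence_samples, truth_samples, cohort = set(evidence_samples), set(truth_samples), set(cohort)
    if not evidence_samples <= cohort or not truth_samples <= cohort:
        raise ValueError("evidence and truth sample sets must be subsets of the cohort")
    P = len(truth_samples)
    N = len(cohort) - P
    TP = len(evidence_samples & truth_samples)
    FP = len(evidence_samples - truth_samples)
    FN = len(truth_samples - evidence_samples)
    return ConfusionCounts(P=P, N=N, TP=TP, TN=N - FP, FP=FP, FN=FN)


def _ratio(num: float, den: float) -> float:
    return num / den if den else math.nan


def metrics(c: ConfusionCounts) -> Metrics:
    """accuracy (TP+TN)/(P+N); precision TP/(TP+FP); sensitivity TP/P;
    specificity TN/N; F1 2TP/(2TP+FP+FN).  Zero denominators give NaN."""
    return Metrics(
        accuracy=_ratio(c.TP + c.TN, c.P + c.N),
        precision=_ratio(c.TP, c.TP + c.FP),
        sensitivity=_ratio(c.TP, c.P),
        specificity=_ratio(c.TN, c.N),
        f1=_ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN),
    )


@dataclass(frozen=True, slots=True)
class SVInterval:
    """A call-set row: one SV as a typed genomic interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    sv_type: str = "DEL"
    label: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"SV interval must be non-empty: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start


def reciprocal_overlap(a: SVInterval, b: SVInterval) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 for different chromosomes."""
    if a.chrom != b.chrom:
        return 0.0
    overlap = max(0, min(a.end, b.end) - max(a.start, b.start))
    return min(overlap / a.length, overlap / b.length)


def intersect_sets(
    A: Sequence[SVInterval], B: Sequence[SVInterval], threshold: float = 0.9
) -> tuple[list[SVInterval], list[SVInterval]]:
    """Split ``A`` into (A∩B, A\\B) under reciprocal-overlap matching.

    An element of A is in the intersection when *any* element of B of the
    same SV type reaches the reciprocal-overlap threshold (boundary
    inclusive).  Input order of A is preserved in both outputs.
    """
    by_group: dict[tuple[str, str], list[SVInterval]] = {}
    for b in B:
        by_group.setdefault((b.sv_type, b.chrom), []).append(b)
    prepared: dict[tuple[str, str], tuple[np.ndarray, list[SVInterval], int]] = {}
    for key, items in by_group.items():
        items = sorted(items, key=lambda x: x.start)
        starts = np.asarray([x.start for x in items], dtype=np.int64)
        max_len = max(x.length for x in items)
        prepared[key] = (starts, items, max_len)

    inter: list[SVInterval] = []
    diff: list[SVInterval] = []
    for a in A:
        group = prepared.get((a.sv_type, a.chrom))
        matched = False
        if group is not None:
            starts, items, max_len = group
            # any b reaching the threshold must physically overlap a
            lo = int(np.searchsorted(starts, a.start - max_len, side="left"))
            hi = int(np.searchsorted(starts, a.end, side="left"))
            for b in items[lo:hi]:
                if reciprocal_overlap(a, b) >= threshold:
                    matched = True
                    break
        (inter if matched else diff).append(a)
    return inter, diff


def germline_filter_eval(
    tumor_calls: Sequence[SVInterval],
    population_evidence_query: Callable[[SVInterval], int],
    truth_calls: Sequence[SVInterval],
    min_evidence_samples: int = 1,
    threshold: float = 0.9,
) -> dict:
    """Score panel-of-normals filtering of a tumor call set.

    Each tumor call is queried against the population index;
    ``population_evidence_query`` returns the number of cohort samples with
    any supporting evidence.  Calls supported in fewer than
    ``min_evidence_samples`` samples pass the filter (they look somatic).
    Against the somatic truth set, at the reciprocal-overlap threshold:
    FP = passed calls not in truth, TP = passed calls in truth,
    FN = true tumor calls that were filtered away.
    """
    passed = [c for c in tumor_calls if population_evidence_query(c) < min_evidence_samples]
    filtered = [c for c in tumor_calls if c not in passed]
    tp, fp = intersect_sets(passed, truth_calls, threshold)
    fn, _ = intersect_sets(filtered, truth_calls, threshold)
    return {
        "passed": passed,
        "TP": len(tp),
        "FP": len(fp),
        "FN": len(fn),
    }


def resolution_sweep(
    searcher,
    samples,
    q: SVQuery,
    max_shift: int = 500,
    step: int = 50,
) -> dict[int, float]:
    """Support decay as the query is displaced from the true breakpoints.

    Both breakpoints are shifted jointly (preserving the SV span) by every
    multiple of ``step`` in ``[-max_shift, +max_shift]``; at each shift the
    query is re-run and the number of samples with any evidence is expressed
    as a proportion of the unshifted query's count.

    Raises
    ------
    ValueError
        If the unshifted query has no supporting samples (the proportion is
        undefined; such variants are excluded from sweep medians).
    """
    base = run_query(searcher, samples, q).n_samples_with_evidence
    if base == 0:
        raise ValueError("resolution sweep is undefined for a query with no supporting samples")
    out: dict[int, float] = {}
    for shift in range(-max_shift, max_shift + 1, step):
        if shift == 0:
            out[0] = 1.0
            continue
        shifted = SVQuery(
            q.sv_type, q.left.shifted(shift), q.right.shifted(shift), q.window
        )
        out[shift] = run_query(searcher, samples, shifted).n_samples_with_evidence / base
    return out


def median_sweep(curves: Iterable[Mapping[int, float]]) -> dict[int, float]:
    """Per-shift median over several sweep curves (e.g. one per variant)."""
    curves = list(curves)
    if not curves:
        return {}
    shifts = sorted(curves[0])
    return {s: float(np.median([c[s] for c in curves])) for s in shifts}


def evidence_summary(per_sv_results: Iterable[QueryResult]) -> pd.DataFrame:
    """Cohort-level evidence summary per queried SV.

    For each query: the number of samples with any evidence and the maximum
    per-sample evidence count (paired-end plus split).
    """
    rows = []
    for res in per_sv_results:
        rows.append(
            {
                "n_samples_with_evidence": res.n_samples_with_evidence,
                "max_per_sample_evidence": res.max_per_sample_evidence,
            }
        )
    return pd.DataFrame(rows, columns=["n_samples_with_evidence", "max_per_sample_evidence"])


def carrier_classification(
    searcher,
    samples,
    queries: Mapping[str, SVQuery],
    truth_carriers: Mapping[str, set],
    sv_types: Mapping[str, str],
    min_support: int = 1,
) -> pd.DataFrame:
    """Pooled per-type classification metrics over a set of known variants.

    Each variant's query is run; samples with at least ``min_support``
    supporting alignments are the predicted carriers, and confusion counts
    are pooled per SV type before the metrics are derived.

    Returns a data frame indexed by SV type with the six counts and five
    metrics.
    """
    cohort = {s.sample_id for s in samples}
    pooled: dict[str, ConfusionCounts] = {}
    for sv_id, q in queries.items():
        res = run_query(searcher, samples, q)
        cc = confusion(res.samples_with_evidence(min_support), truth_carriers[sv_id], cohort)
        t = sv_types[sv_id]
        pooled[t] = pooled[t] + cc if t in pooled else cc
    rows = {}
    for t, cc in pooled.items():
        m = metrics(cc)
        rows[t] = {
            "P": cc.P, "N": cc.N, "TP": cc.TP, "TN": cc.TN, "FP": cc.FP, "FN": cc.FN,
            **m.as_dict(),
        }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()
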