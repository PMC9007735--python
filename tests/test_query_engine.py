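"""PED loading, query extension, strand matching, and whole-query behaviour."""

import numpy as np
import pytest

import svidx
from svidx.cohort_index import BruteForceSearcher, build_index
from svidx.evidence import EvidenceClass, EvidenceRecord, write_evidence
from svidx.query_engine import (
    Breakpoint,
    PedConfigError,
    QueryConfigError,
    SVQuery,
    SVType,
    extend_query,
    format_result,
    load_ped,
    match_strand_config,
    run_query,
)

PED_TEXT = (
    "Sample\tSex\tPopulation\tSuper_Population\tAlt_File\n"
    "NA12812\t1\tCEU\tEUR\tNA12812.bed.gz\n"
    "HG00672\t2\tCHS\tEAS\tHG00672.bed.gz\n"
    "NA12878\t2\tCEU\tEUR\tNA12878.bed.gz\n"
    "HG00674\t1\tCHS\tEAS\tHG00674.bed.gz\n"
)


class TestPed:
    def test_four_sample_ped(self, tmp_path):
        p = tmp_path / "four.ped"
        p.write_text(PED_TEXT)
        records = load_ped(p, 5)
        assert [r.sample_id for r in records] == ["NA12812", "HG00672", "NA12878", "HG00674"]
        assert [r.evidence_file for r in records] == [
            "NA12812.bed.gz", "HG00672.bed.gz", "NA12878.bed.gz", "HG00674.bed.gz",
        ]
        assert records[0].metadata_dict["Super_Population"] == "EUR"

    def test_out_of_range_column(self, tmp_path):
        p = tmp_path / "four.ped"
        p.write_text(PED_TEXT)
        with pytest.raises(PedConfigError, match="out of range"):
            load_ped(p, 99)

    def test_header_only_gives_empty_cohort(self, tmp_path):
        p = tmp_path / "empty.ped"
        p.write_text("Sample\tAlt_File\n")
        assert load_ped(p, 2) == []

    def test_duplicate_sample_rejected(self, tmp_path):
        p = tmp_path / "dup.ped"
        p.write_text("Sample\tAlt_File\nA\ta.bed\nA\ta.bed\n")
        with pytest.raises(PedConfigError, match="duplicate"):
            load_ped(p, 2)


class TestExtendQuery:
    LEFT = Breakpoint("14", 68603030, 68603035)
    RIGHT = Breakpoint("14", 68603738, 68603743)

    def test_deletion_left_downstream_right_upstream(self):
        (probe,) = extend_query(SVQuery("DEL", self.LEFT, self.RIGHT, 500))
        assert (probe.left.start, probe.left.end) == (68603030, 68603535)
        assert (probe.right.start, probe.right.end) == (68603238, 68603743)

    def test_duplication_left_upstream_right_downstream(self):
        (probe,) = extend_query(SVQuery("DUP", self.LEFT, self.RIGHT, 500))
        assert (probe.left.start, probe.left.end) == (68602530, 68603035)
        assert (probe.right.start, probe.right.end) == (68603738, 68604243)

    def test_inversion_two_signed_probes(self):
        q = SVQuery("INV", Breakpoint("1", 100, 110), Breakpoint("1", 900, 910), 50)
        plus, minus = extend_query(q)
        assert plus.inv_sign == 1
        assert (plus.left.start, plus.left.end, plus.right.start, plus.right.end) == (100, 160, 900, 960)
        assert minus.inv_sign == -1
        assert (minus.left.start, minus.left.end, minus.right.start, minus.right.end) == (50, 110, 850, 910)

    def test_breakend_probes_unchanged(self):
        q = SVQuery("BND", Breakpoint("1", 100, 110), Breakpoint("2", 900, 910), 5000)
        (probe,) = extend_query(q)
        assert probe.left == q.left and probe.right == q.right

    def test_extension_clamped_at_zero(self):
        (probe,) = extend_query(SVQuery("DUP", Breakpoint("1", 10, 20), Breakpoint("1", 100, 110), 500))
        assert probe.left.start == 0

    def test_bnd_out_of_order_normalized_with_warning(self):
        with pytest.warns(UserWarning, match="swap"):
            q = SVQuery("BND", Breakpoint("2", 900, 910), Breakpoint("1", 100, 110))
        assert q.left.chrom == "1" and q.right.chrom == "2"

    def test_intrachromosomal_order_enforced(self):
        with pytest.raises(ValueError, match="downstream"):
            SVQuery("DEL", Breakpoint("1", 900, 910), Breakpoint("1", 100, 110))


def _rec(cls, strands):
    return EvidenceRecord("1", 0, 10, strands[0], "1", 20, 30, strands[1], cls)


STRAND_TABLE = [
    # (sv_type, evidence_class, strand pair, expected)
    ("DEL", EvidenceClass.PAIREND, (1, -1), True),
    ("DEL", EvidenceClass.PAIREND, (-1, 1), False),
    ("DEL", EvidenceClass.PAIREND, (1, 1), False),
    ("DEL", EvidenceClass.PAIREND, (-1, -1), False),
    ("DEL", EvidenceClass.SPLIT, (1, 1), True),
    ("DEL", EvidenceClass.SPLIT, (-1, -1), True),
    ("DEL", EvidenceClass.SPLIT, (1, -1), False),
    ("DEL", EvidenceClass.SPLIT, (-1, 1), False),
    ("DUP", EvidenceClass.PAIREND, (-1, 1), True),
    ("DUP", EvidenceClass.PAIREND, (1, -1), False),
    ("DUP", EvidenceClass.PAIREND, (1, 1), False),
    ("DUP", EvidenceClass.PAIREND, (-1, -1), False),
    ("DUP", EvidenceClass.SPLIT, (1, 1), True),
    ("DUP", EvidenceClass.SPLIT, (-1, -1), True),
    ("DUP", EvidenceClass.SPLIT, (1, -1), False),
    ("DUP", EvidenceClass.SPLIT, (-1, 1), False),
    ("INV", EvidenceClass.PAIREND, (1, 1), True),
    ("INV", EvidenceClass.PAIREND, (-1, -1), True),
    ("INV", EvidenceClass.PAIREND, (1, -1), False),
    ("INV", EvidenceClass.PAIREND, (-1, 1), False),
    ("INV", EvidenceClass.SPLIT, (1, -1), True),
    ("INV", EvidenceClass.SPLIT, (-1, 1), True),
    ("INV", EvidenceClass.SPLIT, (1, 1), False),
    ("INV", EvidenceClass.SPLIT, (-1, -1), False),
] + [
    ("BND", cls, strands, True)
    for cls in (EvidenceClass.PAIREND, EvidenceClass.SPLIT)
    for strands in ((1, 1), (1, -1), (-1, 1), (-1, -1))
]


@pytest.mark.parametrize("sv_type,cls,strands,expected", STRAND_TABLE)
def test_strand_configuration_table(sv_type, cls, strands, expected):
    assert match_strand_config(_rec(cls, strands), sv_type) is expected


def _single_record_setup(tmp_path):
    # one +/- pairend record spanning a putative deletion at 1000..2000
    r = EvidenceRecord("1", 900, 1400, 1, "1", 1600, 2100, -1, EvidenceClass.PAIREND)
    files, ids = [], []
    for sid, recs in (("A", [r]), ("B", [])):
        p = tmp_path / f"{sid}.bed"
        write_evidence(recs, p)
        files.append(p)
        ids.append(sid)
    ped = tmp_path / "c.ped"
    ped.write_text("Sample\tAlt_File\nA\tA.bed\nB\tB.bed\n")
    return build_index(files, ids), load_ped(ped, 2)


class TestRunQuery:
    def test_deletion_hit_counts_one_sample(self, tmp_path):
        idx, samples = _single_record_setup(tmp_path)
        q = SVQuery("DEL", Breakpoint("1", 999, 1000), Breakpoint("1", 2000, 2001), 500)
        res = run_query(idx, samples, q)
        assert res.counts_for("A") == (1, 0)
        assert res.counts_for("B") == (0, 0)
        assert len(res.table) == 2  # zero-count samples included

    def test_duplication_at_same_locus_is_empty(self, tmp_path):
        idx, samples = _single_record_setup(tmp_path)
        q = SVQuery("DUP", Breakpoint("1", 999, 1000), Breakpoint("1", 2000, 2001), 500)
        res = run_query(idx, samples, q)
        assert res.samples_with_evidence() == set()

    def test_missing_indexed_file_is_listed(self, tmp_path):
        idx, samples = _single_record_setup(tmp_path)
        from svidx.query_engine import SampleRecord

        ghost = SampleRecord("Z", "Z.bed", (("Sample", "Z"), ("Alt_File", "Z.bed")))
        with pytest.raises(QueryConfigError, match="Z"):
            run_query(idx, samples + [ghost], SVQuery("DEL", Breakpoint("1", 0, 1), Breakpoint("1", 5, 6)))

    def test_result_independent_of_ped_order(self, bench_noisy, bench_noisy_index, bench_noisy_samples):
        truth = bench_noisy.truth
        q = truth.query_for("DEL_00")
        fwd = run_query(bench_noisy_index, bench_noisy_samples, q)
        rev = run_query(bench_noisy_index, bench_noisy_samples[::-1], q)
        merged = fwd.table.set_index("Sample")[["Pairend", "Split"]]
        merged_rev = rev.table.set_index("Sample")[["Pairend", "Split"]]
        assert merged.sort_index().equals(merged_rev.sort_index())

    def test_window_monotonicity(self, bench_noisy, bench_noisy_index, bench_noisy_samples):
        truth = bench_noisy.truth
        for sv_id in ("DEL_00", "DUP_00", "INV_00"):
            prev = None
            for w in (0, 100, 300, 500, 900):
                q = truth.query_for(sv_id, window=w)
                res = run_query(bench_noisy_index, bench_noisy_samples, q)
                tot = res.table[["Pairend", "Split"]].to_numpy().sum(axis=1)
                if prev is not None:
                    assert (tot >= prev).all()
                prev = tot


class TestFormat:
    def test_table_shape_matches_ped(self, tmp_path):
        r = EvidenceRecord("1", 900, 1400, 1, "1", 1600, 2100, -1, EvidenceClass.PAIREND)
        files, ids = [], []
        for sid in ("NA12812", "HG00672", "NA12878", "HG00674"):
            p = tmp_path / f"{sid}.bed.gz"
            write_evidence([r] if sid == "NA12878" else [], p)
            files.append(p)
            ids.append(sid)
        ped = tmp_path / "four.ped"
        ped.write_text(PED_TEXT)
        samples = load_ped(ped, 5)
        idx = build_index(files, ids)
        q = SVQuery("DEL", Breakpoint("1", 999, 1000), Breakpoint("1", 2000, 2001), 500)
        out = format_result(run_query(idx, samples, q))
        lines = out.splitlines()
        assert len(lines) == 5  # header + 4 samples
        header = lines[0].split("\t")
        assert header == ["Id", "Sample", "Sex", "Population", "Super_Population",
                          "Alt_File", "Pairend", "Split"]
        na12878 = [ln for ln in lines if "NA12878" in ln][0].split("\t")
        assert na12878[-2:] == ["1", "0"]

    def test_summary_mode_single_line(self, tmp_path):
        idx, samples = _single_record_setup(tmp_path)
        q = SVQuery("DEL", Breakpoint("1", 999, 1000), Breakpoint("1", 2000, 2001), 500)
        out = format_result(run_query(idx, samples, q), "summary")
        assert out == "1\t1\t0"

    def test_empty_cohort_header_only(self, tmp_path):
        idx = build_index([], [])
        q = SVQuery("DEL", Breakpoint("1", 0, 1), Breakpoint("1", 5, 6))
        out = format_result(run_query(idx, [], q))
        assert out.splitlines() == ["Id\tSample\tPairend\tSplit"]
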