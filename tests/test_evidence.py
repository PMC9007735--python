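"""Evidence classification, record construction, and the file dialect."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import svidx
from svidx.evidence import (
    AlignmentView,
    EvidenceClass,
    EvidenceParseError,
    EvidenceRecord,
    InsertSizeModel,
    InsufficientDataError,
    classify_alignment,
    estimate_insert_model,
    extract_evidence,
    make_evidence_records,
    read_evidence,
    sort_evidence,
    write_evidence,
)


def pair(start, strand, mate_start, mate_strand, chrom="1", mate_chrom="1", rl=100, **kw):
    return AlignmentView(
        chrom=chrom, start=start, end=start + rl, strand=strand, paired=True,
        mate_chrom=mate_chrom, mate_start=mate_start, mate_end=mate_start + rl,
        mate_strand=mate_strand, **kw,
    )


class TestInsertModel:
    def test_zero_variance(self):
        m = estimate_insert_model([300, 300, 300, 300])
        assert (m.mean_fragment, m.sd_fragment, m.discordant_distance) == (300, 0, 300)

    def test_mean_plus_two_sd(self):
        # mean 300, sd 100 -> threshold 500
        m = estimate_insert_model([200, 400])
        assert m.mean_fragment == 300 and m.sd_fragment == 100
        assert m.discordant_distance == 500

    @pytest.mark.parametrize("lengths", [[], [300]])
    def test_insufficient_data(self, lengths):
        with pytest.raises(InsufficientDataError):
            estimate_insert_model(lengths)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            estimate_insert_model([300, -1])


class TestClassify:
    @pytest.mark.parametrize(
        "aln, expected",
        [
            # concordant +/- within distance: no evidence
            (pair(1000, 1, 1200, -1), set()),
            # +/- but outer span 600 > 500: distance-discordant
            (pair(1000, 1, 1500, -1), {EvidenceClass.PAIREND}),
            # -/+ orientation, short distance: orientation-discordant
            (pair(1000, -1, 1100, 1), {EvidenceClass.PAIREND}),
            # mates on different chromosomes
            (pair(1000, 1, 1200, -1, chrom="1", mate_chrom="5"), {EvidenceClass.PAIREND}),
        ],
    )
    def test_pair_criteria(self, insert_model, aln, expected):
        assert classify_alignment(aln, insert_model) == expected

    def test_concordant_with_split_segment(self, insert_model):
        aln = pair(1000, 1, 1200, -1)
        aln.has_split = True
        aln.split_chrom, aln.split_start, aln.split_end, aln.split_strand = "1", 5000, 5040, 1
        assert classify_alignment(aln, insert_model) == {EvidenceClass.SPLIT}

    def test_unpaired_without_split_is_empty(self, insert_model):
        aln = AlignmentView(chrom="1", start=10, end=110, strand=1, paired=False)
        assert classify_alignment(aln, insert_model) == set()

    def test_outer_distance_uses_genome_order_not_read_order(self, insert_model):
        # read 2 upstream of read 1: ordered configuration is still +/-
        aln = pair(2000, -1, 1000, 1, is_read1=False)
        assert classify_alignment(aln, insert_model) == {EvidenceClass.PAIREND}


class TestMakeRecords:
    def test_pairend_padding(self, insert_model):
        aln = pair(1000, 1, 2000, -1)
        (rec,) = make_evidence_records(aln, {EvidenceClass.PAIREND}, insert_model)
        # + end extends downstream to start+500, - end upstream to end-500
        assert (rec.left_start, rec.left_end) == (1000, 1500)
        assert (rec.right_start, rec.right_end) == (1600, 2100)
        assert rec.strand_pair == (1, -1)
        assert rec.evidence_class is EvidenceClass.PAIREND

    def test_split_exact_spans(self, insert_model):
        aln = AlignmentView(chrom="1", start=1000, end=1060, strand=1, paired=False)
        aln.has_split = True
        aln.split_chrom, aln.split_start, aln.split_end, aln.split_strand = "1", 5000, 5040, 1
        (rec,) = make_evidence_records(aln, {EvidenceClass.SPLIT}, insert_model)
        assert (rec.left_start, rec.left_end, rec.right_start, rec.right_end) == (1000, 1060, 5000, 5040)
        assert rec.strand_pair == (1, 1)

    def test_ends_emitted_in_genome_order(self, insert_model):
        # the view is the rightmost mate; the record must still lead with the left end
        aln = pair(2000, -1, 1000, 1, is_read1=False)
        (rec,) = make_evidence_records(aln, {EvidenceClass.PAIREND}, insert_model)
        assert rec.left_start < rec.right_start
        assert rec.strand_pair == (1, -1)

    def test_padding_clamped_at_zero(self, insert_model):
        aln = pair(10, -1, 600, 1)
        (rec,) = make_evidence_records(aln, {EvidenceClass.PAIREND}, insert_model)
        assert rec.left_start == 0

    def test_split_without_segment_is_contract_violation(self, insert_model):
        aln = pair(1000, 1, 2000, -1)
        with pytest.raises(ValueError):
            make_evidence_records(aln, {EvidenceClass.SPLIT}, insert_model)


class TestSort:
    def test_bytewise_chromosome_order(self):
        recs = [
            EvidenceRecord(c, 0, 10, 1, c, 100, 110, -1, EvidenceClass.PAIREND)
            for c in ("X", "2", "10")
        ]
        assert [r.left_chrom for r in sort_evidence(recs)] == ["10", "2", "X"]

    def test_stable_on_equal_keys(self):
        a = EvidenceRecord("1", 0, 10, 1, "1", 100, 110, -1, EvidenceClass.PAIREND)
        b = EvidenceRecord("1", 0, 10, 1, "1", 200, 210, -1, EvidenceClass.SPLIT)
        assert sort_evidence([a, b]) == [a, b]
        assert sort_evidence([b, a]) == [b, a]

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["1", "2", "10", "X", "MT"]),
                st.integers(0, 10_000),
            ),
            max_size=30,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_sort_is_idempotent(self, keys):
        recs = [
            EvidenceRecord(c, s, s + 10, 1, c, s + 100, s + 110, -1, EvidenceClass.PAIREND)
            for c, s in keys
        ]
        once = sort_evidence(recs)
        assert sort_evidence(once) == once


record_strategy = st.builds(
    lambda c, s1, l1, st1, gap, l2, st2, cls: EvidenceRecord(
        c, s1, s1 + l1, st1, c, s1 + gap, s1 + gap + l2, st2, EvidenceClass(cls)
    ),
    c=st.sampled_from(["1", "17", "X"]),
    s1=st.integers(0, 10**6),
    l1=st.integers(1, 1000),
    st1=st.sampled_from([1, -1]),
    gap=st.integers(0, 10**5),
    l2=st.integers(1, 1000),
    st2=st.sampled_from([1, -1]),
    cls=st.sampled_from([0, 1]),
)


class TestDialect:
    @given(st.lists(record_strategy, max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_round_trip(self, tmp_path_factory, recs):
        path = tmp_path_factory.mktemp("rt") / "ev.bed"
        write_evidence(recs, path)
        assert read_evidence(path) == recs

    def test_bgzip_round_trip(self, tmp_path):
        recs = [EvidenceRecord("1", 5, 50, 1, "1", 60, 100, -1, EvidenceClass.SPLIT)]
        path = tmp_path / "ev.bed.gz"
        write_evidence(recs, path)
        assert read_evidence(path) == recs

    def test_wrong_column_count_reports_line(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("1\t0\t10\t1\t1\t20\t30\t-1\t0\n1\t0\t10\t1\t1\t20\t30\t-1\n")
        with pytest.raises(EvidenceParseError, match=":2:"):
            read_evidence(path)

    def test_bad_strand_rejected(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("1\t0\t10\t2\t1\t20\t30\t-1\t0\n")
        with pytest.raises(EvidenceParseError, match="strand"):
            read_evidence(path)

    def test_class_column_one_is_split(self, tmp_path):
        path = tmp_path / "ev.bed"
        path.write_text("1\t0\t10\t1\t1\t20\t30\t-1\t1\n")
        (rec,) = read_evidence(path)
        assert rec.evidence_class is EvidenceClass.SPLIT


class TestExtract:
    def test_concordant_only_yields_empty_file(self, insert_model, tmp_path):
        views = [pair(i * 1000, 1, i * 1000 + 200, -1) for i in range(50)]
        out = extract_evidence(views, insert_model, out_path=tmp_path / "ev.bed")
        assert read_evidence(out) == []

    def test_mate_emitted_once(self, insert_model, tmp_path):
        v1 = pair(1000, 1, 2000, 1, is_read1=True)
        v2 = pair(2000, 1, 1000, 1, is_read1=False)
        out = extract_evidence([v1, v2], insert_model, out_path=tmp_path / "ev.bed")
        assert len(read_evidence(out)) == 1

    def test_het_deletion_records_flank_breakpoints(self, tiny_spec, tiny_cohort):
        sv = tiny_spec.svs[0]
        for sample in ("A", "B"):  # hom and het carriers
            recs = read_evidence(tiny_cohort.workdir / f"{sample}.bed.gz")
            assert recs, sample
            for r in recs:
                if r.evidence_class is EvidenceClass.PAIREND:
                    assert r.strand_pair == (1, -1)
                    assert r.left_start < sv.start <= r.left_end
                    assert r.right_start <= sv.end < r.right_end
                else:
                    assert r.left_end == sv.start and r.right_start == sv.end

    def test_noncarrier_has_no_evidence(self, tiny_cohort):
        assert read_evidence(tiny_cohort.workdir / "C.bed.gz") == []

    def test_extraction_is_deterministic(self, insert_model, tmp_path, tiny_spec):
        from svidx.synthetic_cohort import simulate_fragments

        streams, _ = simulate_fragments(tiny_spec)
        p1 = extract_evidence(streams.views("A"), insert_model, out_path=tmp_path / "a1.bed")
        p2 = extract_evidence(streams.views("A"), insert_model, out_path=tmp_path / "a2.bed")
        assert p1.read_bytes() == p2.read_bytes()

    def test_unreadable_file_raises_oserror(self, insert_model, tmp_path):
        with pytest.raises(OSError, match="nope.bam"):
            extract_evidence(tmp_path / "nope.bam", insert_model)
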