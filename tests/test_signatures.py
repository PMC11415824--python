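import random

import pytest

from mehunter.config import CallerConfig
from mehunter.signatures import (
    AlignmentView,
    SAPlacement,
    Signature,
    SpanIndex,
    UnsortedInputError,
    extract_cigar_signatures,
    extract_split_signatures,
    parse_cigar_string,
    scan_alignments,
)

M, I, D, S, H = 0, 1, 2, 4, 5


def make_view(cigar, ref_start=0, seq=None, **kwargs):
    if seq is None:
        qlen = sum(n for op, n in cigar if op in (M, I, S))
        seq = "A" * qlen
    return AlignmentView(
        read_name=kwargs.pop("read_name", "r1"),
        chrom=kwargs.pop("chrom", "chr1"),
        ref_start=ref_start,
        cigar=tuple(cigar),
        read_sequence=seq,
        mapq=kwargs.pop("mapq", 60),
        **kwargs,
    )


class TestCigarSignatures:
    def test_pure_match_yields_nothing(self, cfg):
        view = make_view([(M, 100)], ref_start=500)
        assert extract_cigar_signatures(view, cfg) == []

    def test_insertion_position_and_sequence(self, cfg):
        # 50M 300I 50M starting at 1000: INS at 1050 carrying read bases 50..349
        seq = "".join(random.Random(0).choice("ACGT") for _ in range(400))
        view = make_view([(M, 50), (I, 300), (M, 50)], ref_start=1000, seq=seq)
        cfg = cfg.replace(min_signature_size=50)
        sigs = extract_cigar_signatures(view, cfg)
        assert len(sigs) == 1
        sig = sigs[0]
        assert (sig.svtype, sig.pos, sig.length) == ("INS", 1050, 300)
        assert sig.inserted_sequence == seq[50:350]
        assert sig.source == "cigar"

    def test_insertion_below_threshold_dropped(self, cfg):
        view = make_view([(M, 50), (I, 20), (M, 50)])
        assert extract_cigar_signatures(view, cfg.replace(min_signature_size=50)) == []

    def test_deletion_position(self, cfg):
        view = make_view([(M, 40), (D, 310), (M, 40)], ref_start=2000)
        sigs = extract_cigar_signatures(view, cfg)
        assert len(sigs) == 1
        assert (sigs[0].svtype, sigs[0].pos, sigs[0].length) == ("DEL", 2040, 310)
        assert sigs[0].inserted_sequence == ""

    def test_soft_clips_shift_query_not_ref(self, cfg):
        seq = "C" * 10 + "G" * 50 + "T" * 40 + "G" * 50
        view = make_view([(S, 10), (M, 50), (I, 40), (M, 50)], ref_start=100, seq=seq)
        sigs = extract_cigar_signatures(view, cfg)
        assert sigs[0].pos == 150
        assert sigs[0].inserted_sequence == "T" * 40

    def test_ins_count_equals_large_i_ops(self, cfg):
        rng = random.Random(1)
        for _ in range(20):
            cigar = []
            n_large = 0
            for _ in range(rng.randint(1, 8)):
                cigar.append((M, rng.randint(1, 200)))
                if rng.random() < 0.5:
                    length = rng.randint(1, 400)
                    cigar.append((I, length))
                    n_large += length >= cfg.min_signature_size
            cigar.append((M, 10))
            sigs = extract_cigar_signatures(make_view(cigar), cfg)
            assert sum(1 for s in sigs if s.svtype == "INS") == n_large


class TestSplitSignatures:
    def test_two_segment_insertion(self, cfg):
        seq = "".join(random.Random(2).choice("ACGT") for _ in range(800))
        # segment A: ref 1000-1100 / query 0-100; segment B: ref 1100-1200 / query 700-800
        view = make_view(
            [(M, 100), (S, 700)],
            ref_start=1000,
            seq=seq,
            sa_tags=(SAPlacement("chr1", 1100, "+", parse_cigar_string("700S100M")),),
        )
        sigs = extract_split_signatures(view, cfg)
        assert len(sigs) == 1
        sig = sigs[0]
        assert (sig.svtype, sig.pos, sig.length, sig.source) == ("INS", 1100, 600, "split")
        assert sig.inserted_sequence == seq[100:700]

    def test_two_segment_deletion(self, cfg):
        view = make_view(
            [(M, 100), (S, 100)],
            ref_start=1000,
            sa_tags=(SAPlacement("chr1", 1600, "+", parse_cigar_string("100S100M")),),
        )
        sigs = extract_split_signatures(view, cfg)
        assert len(sigs) == 1
        assert (sigs[0].svtype, sigs[0].pos, sigs[0].length) == ("DEL", 1100, 500)

    def test_colinear_segments_no_gap(self, cfg):
        view = make_view(
            [(M, 100), (S, 100)],
            ref_start=1000,
            sa_tags=(SAPlacement("chr1", 1100, "+", parse_cigar_string("100S100M")),),
        )
        assert extract_split_signatures(view, cfg) == []

    def test_opposite_strands_skipped(self, cfg):
        view = make_view(
            [(M, 100), (S, 100)],
            ref_start=1000,
            sa_tags=(SAPlacement("chr1", 1600, "-", parse_cigar_string("100S100M")),),
        )
        assert extract_split_signatures(view, cfg) == []

    def test_other_chromosome_skipped(self, cfg):
        view = make_view(
            [(M, 100), (S, 100)],
            ref_start=1000,
            sa_tags=(SAPlacement("chr2", 1600, "+", parse_cigar_string("100S100M")),),
        )
        assert extract_split_signatures(view, cfg) == []

    def test_hard_clips_counted_in_query_offsets(self, cfg):
        # supplementary described with hard clips: same arithmetic must hold
        view = make_view(
            [(M, 100), (S, 100)],
            ref_start=1000,
            sa_tags=(SAPlacement("chr1", 1600, "+", parse_cigar_string("100H100M")),),
        )
        sigs = extract_split_signatures(view, cfg)
        assert len(sigs) == 1
        assert (sigs[0].svtype, sigs[0].length) == ("DEL", 500)

    def test_minus_strand_deletion(self, cfg):
        # same molecule as test_two_segment_deletion but sequenced on '-'
        view = make_view(
            [(S, 100), (M, 100)],
            ref_start=1600,
            strand="-",
            sa_tags=(SAPlacement("chr1", 1000, "-", parse_cigar_string("100M100S")),),
        )
        sigs = extract_split_signatures(view, cfg)
        assert len(sigs) == 1
        assert (sigs[0].svtype, sigs[0].pos, sigs[0].length) == ("DEL", 1100, 500)


SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:10000\n"


def write_sam(tmp_path, body, header=SAM_HEADER, name="in.sam"):
    path = tmp_path / name
    path.write_text(header + body)
    return str(path)


def sam_line(name, flag, pos1, cigar, seq, mapq=60, extra=""):
    fields = [name, str(flag), "chr1", str(pos1), str(mapq), cigar, "*", "0", "0", seq, "*"]
    if extra:
        fields.append(extra)
    return "\t".join(fields) + "\n"


class TestScanAlignments:
    def test_empty_input(self, tmp_path, cfg):
        path = write_sam(tmp_path, "")
        sigs, index, stats = scan_alignments(path, cfg)
        assert sigs == []
        assert len(index) == 0
        assert stats["reads_used"] == 0

    def test_unsorted_raises(self, tmp_path, cfg):
        body = sam_line("a", 0, 500, "100M", "A" * 100) + sam_line("b", 0, 100, "100M", "A" * 100)
        path = write_sam(tmp_path, body, header="@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:10000\n")
        with pytest.raises(UnsortedInputError, match="coordinate-sorted"):
            scan_alignments(path, cfg)

    def test_header_so_checked(self, tmp_path, cfg):
        path = write_sam(tmp_path, "", header="@HD\tVN:1.6\tSO:queryname\n@SQ\tSN:chr1\tLN:10000\n")
        with pytest.raises(UnsortedInputError):
            scan_alignments(path, cfg)

    def test_low_mapq_skipped(self, tmp_path, cfg):
        body = sam_line("a", 0, 100, "50M40I50M", "A" * 140, mapq=5)
        path = write_sam(tmp_path, body)
        sigs, _, stats = scan_alignments(path, cfg)
        assert sigs == []
        assert stats["reads_skipped"] == 1

    def test_malformed_cigar_skipped_and_tallied(self, tmp_path, cfg, monkeypatch):
        # htslib rejects length-inconsistent SAM outright, so corrupt the
        # parsed view to exercise the caller-side consistency check
        import mehunter.signatures as sigmod

        body = sam_line("bad", 0, 100, "50M40I50M", "A" * 140) + sam_line(
            "good", 0, 200, "50M40I50M", "A" * 140
        )
        path = write_sam(tmp_path, body)
        real = sigmod.view_from_pysam

        def corrupting(rec):
            view = real(rec)
            if view.read_name == "bad":
                view.read_sequence = view.read_sequence[:-1]
            return view

        monkeypatch.setattr(sigmod, "view_from_pysam", corrupting)
        sigs, _, stats = scan_alignments(path, cfg)
        assert {s.read_name for s in sigs} == {"good"}
        assert stats["reads_skipped"] == 1

    def test_region_restriction(self, tmp_path, cfg):
        body = sam_line("a", 0, 101, "50M40I50M", "A" * 140) + sam_line(
            "b", 0, 5001, "50M40I50M", "A" * 140
        )
        path = write_sam(tmp_path, body)
        sigs_all, _, _ = scan_alignments(path, cfg)
        assert len(sigs_all) == 2
        sigs_region, _, _ = scan_alignments(path, cfg, region="chr1:1-1000")
        assert len(sigs_region) == 1
        assert sigs_region[0].pos == 150
        sigs_none, _, _ = scan_alignments(path, cfg, region="chr1:3000-4000")
        assert sigs_none == []

    def test_signatures_within_alignment_span(self, small_sim, cfg):
        sigs, index, _ = scan_alignments(small_sim["paths"]["sam"], cfg)
        assert sigs
        spans = {name: (start, end) for start, end, name in index._spans["simchr1"]}
        for sig in sigs:
            if sig.source != "cigar":
                continue
            start, end = spans[sig.read_name]
            assert start <= sig.pos <= end

    def test_extraction_order_independent(self, cfg):
        rng = random.Random(3)
        views = []
        for i in range(30):
            cigar = [(M, rng.randint(50, 200)), (I, rng.randint(20, 100)), (M, 50)]
            views.append(make_view(cigar, ref_start=rng.randint(0, 5000), read_name=f"r{i}"))
        forward = [s for v in views for s in extract_cigar_signatures(v, cfg)]
        shuffled = list(views)
        rng.shuffle(shuffled)
        backward = [s for v in shuffled for s in extract_cigar_signatures(v, cfg)]
        assert sorted(forward, key=str) == sorted(backward, key=str)


class TestSpanIndex:
    def test_empty(self):
        index = SpanIndex()
        assert index.count_spanning("chr1", 100, 10) == 0

    def test_spanning_and_exclusion(self):
        index = SpanIndex()
        index.add("chr1", 0, 1000, "a")
        index.add("chr1", 480, 520, "b")  # overlaps but does not span
        index.add("chr1", 0, 400, "c")
        assert index.count_spanning("chr1", 500, 100) == 1
        assert index.count_spanning("chr1", 500, 100, exclude={"a"}) == 0
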