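import numpy as np
import pytest
from Bio import Align

from mehunter.classify import (
    KmerProfileClassifier,
    classify_consensus,
    classify_first_round,
    classify_second_round,
    kmer_prescreen,
    make_second_round_classifier,
    smith_waterman,
    trim_polya_tail,
)
from mehunter.clustering import Cluster, ConsensusCall
from mehunter.melib import MELibrary, revcomp
from mehunter.signatures import Signature

from conftest import random_dna
from oracles import sw_best_of_strands_oracle, sw_score_oracle


def consensus_call(seq):
    member = Signature("chr1", 100, "INS", len(seq), seq, "r1", "cigar")
    return ConsensusCall(Cluster("chr1", "INS", [member]), seq)


def biopython_local_score(query, target):
    """Independent library oracle with the same scoring convention."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -4
    aligner.open_gap_score = -6  # our gap_open + gap_extend for the first base
    aligner.extend_gap_score = -2
    return max(aligner.score(target, query), aligner.score(target, revcomp(query)))


class TestSmithWaterman:
    def test_perfect_self_alignment(self, cfg):
        result = smith_waterman("ACGTACGTAC", "ACGTACGTAC", cfg)
        assert result.score == 20
        assert result.identity == 1.0
        assert result.strand == "+"
        assert result.query_span == (0, 10)

    def test_minus_strand(self, cfg):
        result = smith_waterman("AAAA", "TTTT", cfg)
        assert result.score == 8
        assert result.strand == "-"

    def test_empty_sequence_raises(self, cfg):
        with pytest.raises(ValueError):
            smith_waterman("", "ACGT", cfg)

    def test_n_never_matches(self, cfg):
        result = smith_waterman("NNNN", "NNNN", cfg)
        assert result.score == 0
        result = smith_waterman("ACGTNNNNACGT", "ACGTNNNNACGT", cfg)
        assert result.matches == 8

    def test_matches_pure_python_oracle(self, cfg):
        rng = np.random.default_rng(42)
        for _ in range(40):
            q = random_dna(rng, int(rng.integers(10, 120)))
            t = random_dna(rng, int(rng.integers(10, 120)))
            expected = sw_best_of_strands_oracle(q, t)
            assert smith_waterman(q, t, cfg).score == expected

    def test_oracle_with_n_characters(self, cfg):
        rng = np.random.default_rng(43)
        for _ in range(10):
            q = list(random_dna(rng, 60))
            for pos in rng.integers(0, 60, size=5):
                q[pos] = "N"
            q = "".join(q)
            t = random_dna(rng, 80)
            assert smith_waterman(q, t, cfg).score == sw_best_of_strands_oracle(q, t)

    def test_banded_equals_full_on_related_sequences(self, cfg):
        # long, related pair: banded path with anchor must match library oracle
        rng = np.random.default_rng(44)
        t = random_dna(rng, 800)
        q = list(t[100:700])
        for pos in rng.integers(0, len(q), size=12):
            q[pos] = "ACGT"[int(rng.integers(4))]
        q = "".join(q)
        assert smith_waterman(q, t, cfg).score == biopython_local_score(q, t)

    def test_strand_closure(self, cfg):
        rng = np.random.default_rng(45)
        for _ in range(10):
            q = random_dna(rng, 80)
            t = random_dna(rng, 100)
            fwd = smith_waterman(q, t, cfg)
            rev = smith_waterman(revcomp(q), t, cfg)
            assert fwd.score == rev.score
            if fwd.score > 0 and fwd.strand != rev.strand:
                pass  # strands swapped
            assert {fwd.strand, rev.strand} <= {"+", "-"}


class TestFirstRound:
    def test_diverged_template_copy_classified(self, lib, cfg):
        rng = np.random.default_rng(5)
        template = lib.by_class("Alu")[0].sequence
        seq = list(template)
        for pos in rng.choice(len(seq), size=6, replace=False):
            seq[pos] = "ACGT"[int(rng.integers(4))]
        result = classify_first_round(consensus_call("".join(seq)), lib, cfg)
        assert result.me_class == "Alu"
        assert result.round == "first"
        assert result.sw.identity >= cfg.first_round_identity_threshold

    def test_random_sequence_unclassified(self, lib, cfg):
        rng = np.random.default_rng(6)
        for _ in range(5):
            result = classify_first_round(consensus_call(random_dna(rng, 300)), lib, cfg)
            assert result.me_class == "none"
            assert result.round == "unclassified"

    def test_revcomp_template_classified_minus(self, lib, cfg):
        template = lib.by_class("L1")[0].sequence
        result = classify_first_round(consensus_call(revcomp(template)), lib, cfg)
        assert result.me_class == "L1"
        assert result.sw.strand == "-"

    def test_fragment_falls_through_to_second_round(self, lib, cfg):
        template = lib.by_class("SVA")[0].sequence
        fragment = template[-360:]  # 40% of the template
        result = classify_first_round(consensus_call(fragment), lib, cfg)
        assert result.round == "unclassified"

    def test_empty_library_raises(self, cfg):
        with pytest.raises(ValueError):
            classify_first_round(consensus_call("ACGT" * 20), MELibrary([]), cfg)

    def test_library_order_invariant(self, lib, cfg):
        seq = lib.by_class("Alu")[0].sequence
        reordered = MELibrary(list(reversed(lib.templates)))
        a = classify_first_round(consensus_call(seq), lib, cfg)
        b = classify_first_round(consensus_call(seq), reordered, cfg)
        assert (a.me_class, a.best_template, a.sw.score) == (b.me_class, b.best_template, b.sw.score)


class TestPrescreen:
    def test_template_passes(self, lib, cfg):
        assert kmer_prescreen(lib.by_class("Alu")[0].sequence, lib, cfg)

    def test_revcomp_passes(self, lib, cfg):
        assert kmer_prescreen(revcomp(lib.by_class("SVA")[0].sequence), lib, cfg)

    def test_random_sequence_fails(self, lib, cfg):
        rng = np.random.default_rng(9)
        for _ in range(20):
            assert not kmer_prescreen(random_dna(rng, 500), lib, cfg)

    def test_shorter_than_k_fails(self, lib, cfg):
        assert not kmer_prescreen("ACGT", lib, cfg)


class _RaisingPlugin:
    threshold = 0.5

    def classify(self, sequence, lib):
        raise RuntimeError("boom")


class _ZeroConfidencePlugin:
    threshold = 0.5

    def classify(self, sequence, lib):
        return "Alu", 0.0


class TestSecondRound:
    def test_fragment_recovered(self, lib, cfg):
        rng = np.random.default_rng(10)
        template = lib.by_class("Alu")[0].sequence
        fragment = list(template[-120:])  # 40% fragment
        for pos in rng.choice(len(fragment), size=6, replace=False):  # 5% divergence
            fragment[pos] = "ACGT"[int(rng.integers(4))]
        call = consensus_call("".join(fragment))
        assert classify_first_round(call, lib, cfg).round == "unclassified"
        model = KmerProfileClassifier(lib)
        result = classify_second_round(call, lib, model, cfg)
        assert result.me_class == "Alu"
        assert result.round == "second"
        assert result.second_round_score >= model.threshold

    def test_ablation_switch(self, lib, cfg):
        template = lib.by_class("Alu")[0].sequence
        call = consensus_call(template[-120:])
        model = KmerProfileClassifier(lib)
        result = classify_consensus(call, lib, cfg.replace(second_round_enabled=False), model)
        assert result.me_class == "none"
        assert result.round == "unclassified"

    def test_zero_confidence_unclassified(self, lib, cfg):
        result = classify_second_round(consensus_call("ACGT" * 30), lib, _ZeroConfidencePlugin(), cfg)
        assert result.me_class == "none"

    def test_plugin_exception_is_contained(self, lib, cfg):
        result = classify_second_round(consensus_call("ACGT" * 30), lib, _RaisingPlugin(), cfg)
        assert result.me_class == "none"
        assert result.round == "unclassified"

    def test_second_round_never_overrides_first(self, lib, cfg):
        template = lib.by_class("L1")[0].sequence
        model = _RaisingPlugin()  # would blow up if consulted
        result = classify_consensus(consensus_call(template), lib, cfg, model)
        assert result.round == "first"
        assert result.me_class == "L1"

    def test_unknown_plugin_name(self, lib, cfg):
        with pytest.raises(ValueError, match="unknown second-round plugin"):
            make_second_round_classifier("nope", lib, cfg)

    def test_random_sequence_blocked_by_prescreen(self, lib, cfg):
        rng = np.random.default_rng(11)
        call = consensus_call(random_dna(rng, 800))
        model = _RaisingPlugin()  # prescreen must prevent the plugin call
        result = classify_consensus(call, lib, cfg, model)
        assert result.me_class == "none"


class TestPolyATrim:
    def test_trailing_a_run_removed(self):
        assert trim_polya_tail("ACGTCCGT" + "A" * 20) == "ACGTCCGT"

    def test_short_run_kept(self):
        assert trim_polya_tail("ACGTCCGTAAAA") == "ACGTCCGTAAAA"
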