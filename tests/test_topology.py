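"""Topology parsing, the hydropathy fallback, merging, and TM counting."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from memfunnel.topology import (
    KYTE_DOOLITTLE,
    SignalPeptideCall,
    TmSegment,
    TopologyParseError,
    TopologyProfile,
    merge_predictions,
    noncleaved_tm_count,
    predict_topology_fallback,
    read_topology_files,
)

from .oracles import (
    interval_union_oracle,
    noncleaved_recount_oracle,
    sliding_window_oracle,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

segments = st.lists(
    st.tuples(st.integers(1, 300), st.integers(1, 60)).map(
        lambda t: TmSegment(t[0], t[0] + t[1])
    ),
    max_size=6,
)


def profile(pid="p", sp=False, ca=None, tms=()):
    return TopologyProfile(
        pid,
        signal=SignalPeptideCall(sp, ca),
        tm_segments=tuple(TmSegment(s, e) for s, e in tms),
    )


class TestDialects:
    def test_tmhmm_short_seven_helices(self, tmp_path):
        topo = "o10-32i44-66o78-100i112-134o146-168i180-202o214-236i"
        p = tmp_path / "t.txt"
        p.write_text(
            f"prot1\tlen=260\tExpAA=161.0\tFirst60=0.0\tPredHel=7\tTopology={topo}\n"
        )
        prof = read_topology_files(p, "tmhmm-short")["prot1"]
        assert prof.tm_count == 7
        assert prof.tm_segments[0] == TmSegment(10, 32)
        assert prof.tm_segments[-1] == TmSegment(214, 236)
        assert prof.sources == {"tmhmm"}

    def test_signalp_short_cleavage(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text(
            "# header\n"
            "prot1\t0.5\t23\t0.6\t23\t0.7\t22\t0.5\t0.6\tY\t0.45\tSignalP-noTM\n"
            "prot2\t0.1\t1\t0.1\t1\t0.1\t1\t0.1\t0.1\tN\t0.45\tSignalP-noTM\n"
        )
        profs = read_topology_files(p, "signalp-short")
        assert profs["prot1"].signal == SignalPeptideCall(True, 22)
        assert not profs["prot2"].signal.present

    def test_phobius_short_with_and_without_sp(self, tmp_path):
        p = tmp_path / "p.txt"
        p.write_text(
            "SEQENCE ID\tTM\tSP\tPREDICTION\n"
            "prot1\t2\tY\tn1-15c19/20o35-55i70-90o\n"
            "prot2\t0\t0\to\n"
        )
        profs = read_topology_files(p, "phobius-short")
        assert profs["prot1"].signal == SignalPeptideCall(True, 19)
        assert profs["prot1"].tm_segments == (TmSegment(35, 55), TmSegment(70, 90))
        assert profs["prot2"].tm_count == 0

    def test_malformed_line_names_file_and_line(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("good\tlen=10\tPredHel=1\tTopology=o1-5i\nnonsense line\n")
        with pytest.raises(TopologyParseError, match=r"bad\.txt:2"):
            read_topology_files(p, "tmhmm-short")

    def test_unknown_proteins_absent_not_defaulted(self, tmp_path):
        p = tmp_path / "t.txt"
        p.write_text("only\tlen=99\tPredHel=0\tTopology=o\n")
        assert set(read_topology_files(p, "tmhmm-short")) == {"only"}

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            read_topology_files(tmp_path / "x", "hmmtop")


class TestFallback:
    def test_leucine_run_in_aspartate_context(self):
        seq = "D" * 40 + "L" * 21 + "D" * 40
        prof = predict_topology_fallback("p", seq)
        assert prof.tm_count == 1
        (seg,) = prof.tm_segments
        # the run +/- one window of slack
        assert seg.start >= 41 - 18 and seg.end <= 61 + 18
        assert seg.start <= 41 and seg.end >= 61

    def test_all_aspartate_has_no_segments(self):
        prof = predict_topology_fallback("p", "D" * 100)
        assert prof.tm_count == 0 and not prof.signal.present

    def test_short_sequence_warns(self):
        prof = predict_topology_fallback("p", "MKL")
        assert prof.warning and prof.tm_count == 0

    def test_n_terminal_run_with_cleavage_motif_reported_as_sp(self):
        seq = "M" + "L" * 14 + "ASA" + "D" * 80
        prof = predict_topology_fallback("p", seq)
        assert prof.signal.present
        assert prof.signal.cleavage_after <= 30

    def test_against_sliding_window_oracle(self, rng):
        for _ in range(500):
            n = int(rng.integers(19, 200))
            seq = "".join(rng.choice(list(AA20), size=n))
            prof = predict_topology_fallback("p", seq)
            got = [(s.start, s.end) for s in prof.tm_segments]
            assert got == sliding_window_oracle(seq, KYTE_DOOLITTLE, 19, 1.6)


class TestMerge:
    def test_idempotent_on_identical_sources(self):
        a = profile(tms=[(10, 30), (50, 70)])
        b = profile(tms=[(10, 30), (50, 70)])
        assert merge_predictions([a, b]).tm_segments == a.tm_segments

    def test_sp_union(self):
        a = profile(sp=True, ca=21)
        b = profile()
        m = merge_predictions([a, b])
        assert m.signal == SignalPeptideCall(True, 21)

    def test_overlapping_segments_merge(self):
        a = profile(tms=[(10, 30)])
        b = profile(tms=[(25, 45)])
        assert merge_predictions([a, b]).tm_segments == (TmSegment(10, 45),)

    def test_conflicting_ids_rejected(self):
        with pytest.raises(ValueError):
            merge_predictions([profile("x"), profile("y")])

    @given(segments, segments)
    def test_union_against_residue_set_oracle(self, s1, s2):
        a = TopologyProfile("p", tm_segments=())
        object.__setattr__(a, "tm_segments", tuple(s1))  # may overlap: raw input
        b = TopologyProfile("p", tm_segments=())
        object.__setattr__(b, "tm_segments", tuple(s2))
        m = merge_predictions([a, b])
        got = [(s.start, s.end) for s in m.tm_segments]
        want = interval_union_oracle(
            [(s.start, s.end) for s in list(s1) + list(s2)]
        )
        assert got == want

    @given(segments, segments, segments)
    def test_union_commutative_associative(self, s1, s2, s3):
        def prof(segs):
            p = TopologyProfile("p")
            object.__setattr__(p, "tm_segments", tuple(segs))
            return p

        a, b, c = prof(s1), prof(s2), prof(s3)
        ab_c = merge_predictions([merge_predictions([a, b]), c])
        a_bc = merge_predictions([a, merge_predictions([b, c])])
        ba = merge_predictions([b, a])
        ab = merge_predictions([a, b])
        assert ab_c.tm_segments == a_bc.tm_segments
        assert ab.tm_segments == ba.tm_segments


class TestNoncleavedCount:
    def test_sp_overlapping_helix_discounted(self):
        p = profile(sp=True, ca=22, tms=[(5, 25), (60, 80)])
        assert noncleaved_tm_count(p) == 1

    def test_no_sp_counts_all(self):
        p = profile(tms=[(5, 25), (60, 80), (100, 120)])
        assert noncleaved_tm_count(p) == 3

    def test_random_profiles_against_recount_oracle(self, rng):
        for _ in range(200):
            k = int(rng.integers(0, 6))
            pos = 1
            tms = []
            for _ in range(k):
                start = pos + int(rng.integers(1, 40))
                end = start + int(rng.integers(15, 30))
                tms.append((start, end))
                pos = end
            sp = bool(rng.random() < 0.5)
            ca = int(rng.integers(10, 40)) if sp else None
            p = profile(sp=sp, ca=ca, tms=tms)
            assert noncleaved_tm_count(p) == noncleaved_recount_oracle(
                sp, ca, tms
            )

    @given(segments.filter(lambda s: interval_union_oracle(
        [(x.start, x.end) for x in s])))
    def test_never_exceeds_total(self, segs):
        merged = interval_union_oracle([(s.start, s.end) for s in segs])
        p = profile(sp=True, ca=20, tms=merged)
        assert noncleaved_tm_count(p) <= p.tm_count
        q = profile(tms=merged)
        assert noncleaved_tm_count(q) == q.tm_count
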