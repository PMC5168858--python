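"""GPCR gate, N-terminal region delimitation, class and architecture."""

import pandas as pd
import pytest

from memfunnel.annotation import DomainHit
from memfunnel.gpcr import (
    ArchitectureFlag,
    GpcrClass,
    classify_gpcr,
    delimit_n_terminal_region,
    find_gpcr_candidates,
    gpcr_report,
)
from memfunnel.topology import SignalPeptideCall, TmSegment, TopologyProfile


def profile(n_tm, first=400, pid="p", sp=False):
    segs = []
    pos = first
    for _ in range(n_tm):
        segs.append(TmSegment(pos, pos + 20))
        pos += 40
    return TopologyProfile(
        pid,
        signal=SignalPeptideCall(sp, 20 if sp else None),
        tm_segments=tuple(segs),
    )


def dom(sig="PF1", ipr=None, start=10, end=100, desc="domain"):
    return DomainHit("p", sig, desc, ipr, start, end, 1e-10)


KEYWORD = ["putative G-protein coupled receptor"]


class TestGate:
    @pytest.mark.parametrize("n_tm,expected", [(6, 0), (7, 1), (8, 1), (9, 1),
                                               (10, 0)])
    def test_tm_count_gate(self, n_tm, expected):
        cands = find_gpcr_candidates({"p": KEYWORD}, {"p": profile(n_tm)})
        assert len(cands) == expected

    def test_keyword_required(self):
        assert find_gpcr_candidates(
            {"p": ["seven transmembrane protein"]}, {"p": profile(8)}
        ) == []

    def test_keyword_case_insensitive(self):
        cands = find_gpcr_candidates({"p": ["GPCR-like"]}, {"p": profile(7)})
        assert len(cands) == 1

    def test_raw_tm_count_used_even_with_signal_peptide(self):
        # SP-overlapping helix would be discounted by the funnel, but the
        # gate deliberately counts it
        prof = TopologyProfile(
            "p",
            signal=SignalPeptideCall(True, 22),
            tm_segments=tuple(
                [TmSegment(4, 24)]
                + [TmSegment(300 + i * 40, 320 + i * 40) for i in range(6)]
            ),
        )
        cands = find_gpcr_candidates({"p": KEYWORD}, {"p": prof})
        assert len(cands) == 1 and cands[0].tm_count == 7


class TestNTerminalRegion:
    def test_region_ends_before_bundle(self):
        prof = profile(7, first=350)
        (cand,) = find_gpcr_candidates({"p": KEYWORD}, {"p": prof})
        assert delimit_n_terminal_region(cand, prof) == (1, 349)

    def test_bundle_is_seven_most_c_terminal_tms(self):
        # 9 TMs: the first two are outside the heptahelical bundle
        prof = profile(9, first=200)
        (cand,) = find_gpcr_candidates({"p": KEYWORD}, {"p": prof})
        start, end = delimit_n_terminal_region(cand, prof)
        assert (start, end) == (1, prof.tm_segments[2].start - 1)

    def test_domain_containment(self):
        prof = profile(7, first=350)
        (cand,) = find_gpcr_candidates({"p": KEYWORD}, {"p": prof})
        cand = classify_gpcr(
            cand, prof,
            [dom("SSF53850", None, 10, 300, "sbp II"),
             dom("SSF53850", None, 340, 420, "spans bundle start")],
        )
        assert [d.start for d in cand.n_terminal_domains] == [10]
        assert cand.architecture_flags == {ArchitectureFlag.SBP_TYPE_II}

    def test_domain_between_pre_bundle_tms_included(self):
        prof = profile(9, first=100)
        (cand,) = find_gpcr_candidates({"p": KEYWORD}, {"p": prof})
        bundle_start = prof.tm_segments[2].start
        between = dom("SSF53850", None, prof.tm_segments[1].end + 2,
                      bundle_start - 2)
        cand = classify_gpcr(cand, prof, [between])
        assert cand.n_terminal_domains == [between]


class TestClassification:
    def make(self, domains, n_tm=7):
        prof = profile(n_tm, first=400)
        (cand,) = find_gpcr_candidates({"p": KEYWORD}, {"p": prof})
        return classify_gpcr(cand, prof, domains)

    def test_class_c_with_sbp_flag(self):
        cand = self.make(
            [dom("PF3", "IPR017978", 400, 600), dom("SSF53850", None, 20, 280)]
        )
        assert cand.gpcr_class is GpcrClass.CLASS_C
        assert cand.architecture_flags == {ArchitectureFlag.SBP_TYPE_II}
        assert not cand.class_conflict

    def test_rhodopsin_dicty_car(self):
        for ipr in ("IPR017452", "IPR017981"):
            cand = self.make([dom("PF1", ipr, 400, 600)])
            assert cand.gpcr_class is GpcrClass.RHODOPSIN_DICTY_CAR

    def test_no_signature_is_unclassified(self):
        assert self.make([dom()]).gpcr_class is GpcrClass.UNCLASSIFIED

    def test_both_signatures_prefer_class_c_with_conflict_flag(self):
        cand = self.make(
            [dom("PF3", "IPR017978", 400, 600), dom("PF1", "IPR017452", 400, 600)]
        )
        assert cand.gpcr_class is GpcrClass.CLASS_C and cand.class_conflict

    @pytest.mark.parametrize(
        "sig,ipr,flag",
        [
            ("PFx", "IPR001828", ArchitectureFlag.ANF),
            ("PFx", "IPR011050", ArchitectureFlag.PECTIN_LYASE),
            ("PFx", "IPR012334", ArchitectureFlag.PECTIN_LYASE),
            ("PFx", "IPR006626", ArchitectureFlag.BETA_HELIX),
            ("PFx", "IPR000742", ArchitectureFlag.EGF_LIKE),
            ("SSF53850", None, ArchitectureFlag.SBP_TYPE_II),
        ],
    )
    def test_architecture_flag_table(self, sig, ipr, flag):
        cand = self.make([dom(sig, ipr, 20, 200)])
        assert cand.architecture_flags == {flag}

    def test_flags_invariant_under_hit_order(self):
        domains = [dom("SSF53850", None, 20, 200),
                   dom("PFx", "IPR011050", 30, 250),
                   dom("PF3", "IPR017978", 400, 600)]
        a = self.make(domains)
        b = self.make(domains[::-1])
        assert a.gpcr_class == b.gpcr_class
        assert a.architecture_flags == b.architecture_flags


class TestReport:
    def make_df(self, rows):
        return pd.DataFrame(
            rows,
            columns=["strain", "gpcr_class", "flags", "n_terminal_length",
                     "has_signal_peptide"],
        )

    def test_receptor_census_totals(self):
        rows = []
        for strain, rho, cc in [("neocallimastix", 2, 51),
                                ("anaeromyces", 1, 24), ("piromyces", 2, 32)]:
            rows += [(strain, "rhodopsin_dicty_car", "", 300, False)] * rho
            rows += [(strain, "class_c", "sbp_type_ii", 600, False)] * cc
        classes = gpcr_report(self.make_df(rows))["classes"]
        assert classes.loc["total", "neocallimastix"] == 53
        assert classes.loc["total", "anaeromyces"] == 25
        assert classes.loc["total", "piromyces"] == 34
        assert classes.loc["total", "total"] == 112

    def test_architecture_fractions_and_lengths(self):
        rows = [("s", "class_c", "pectin_lyase", 200, True),
                ("s", "class_c", "sbp_type_ii", 600, False),
                ("s", "class_c", "sbp_type_ii", 1600, False),
                ("s", "unclassified", "", 400, False)]
        arch = gpcr_report(self.make_df(rows))["architecture"].iloc[0]
        assert arch["frac_sbp_type_ii"] == 0.5
        assert arch["frac_pectin_lyase"] == 0.25
        assert arch["frac_signal_peptide"] == 0.25
        assert (arch["nterm_min"], arch["nterm_max"]) == (200, 1600)
        assert arch["nterm_mean"] == 700.0

    def test_synthetic_noiseless_counts_equal_truth(self, small_synthetic):
        _, _, result, truth = small_synthetic
        planted = truth[truth["gpcr_class"] != ""]
        cands = result.reports["gpcr_candidates"]
        assert len(cands) == len(planted)
        merged = planted.merge(
            cands, left_on="transcript_id", right_on="protein_id"
        )
        assert (merged["gpcr_class_x"] == merged["gpcr_class_y"]).all()
        assert (merged["gpcr_flags"] == merged["flags"]).all()
        assert merged["tm_count"].between(7, 9).all()
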