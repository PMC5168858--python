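"""TCDB homology classification: coverage filter, best hit, TC parsing,
category binning and report tables."""

import pandas as pd
import pytest

from memfunnel.annotation import AlignmentHit
from memfunnel.transporters import (
    CategoryMap,
    SubstrateClass,
    SugarFamily,
    TcId,
    TcParseError,
    TransporterCategory,
    add_cross_strain_total,
    assign_transporters,
    best_tcdb_hit,
    categorize,
    parse_tc_id,
    passes_reciprocal_coverage,
    tabulate_transporters,
)

from .oracles import best_hit_oracle


def hit(qs=1, qe=100, qlen=100, ss=1, se=100, slen=100, e=1e-10, bits=200.0,
        q="q1", s="subj"):
    return AlignmentHit(
        query_id=q, subject_id=s, pct_identity=50.0, aln_length=qe - qs + 1,
        q_start=qs, q_end=qe, s_start=ss, s_end=se, e_value=e, bit_score=bits,
        q_len=qlen, s_len=slen,
    )


class TestReciprocalCoverage:
    @pytest.mark.parametrize(
        "qs,qe,qlen,ss,se,slen,expected",
        [
            (1, 70, 100, 1, 70, 100, True),   # exactly 70% both sides
            (1, 69, 100, 1, 70, 100, False),  # below on the query side
            (1, 100, 100, 1, 100, 150, False),  # 66.7% on the subject side
            (31, 100, 100, 16, 85, 100, True),  # internal spans count too
        ],
    )
    def test_boundary_inclusive(self, qs, qe, qlen, ss, se, slen, expected):
        h = hit(qs=qs, qe=qe, qlen=qlen, ss=ss, se=se, slen=slen)
        assert passes_reciprocal_coverage(h) is expected

    def test_lowering_min_cov_never_loses_hits(self, rng):
        hits = [
            hit(qs=1, qe=int(rng.integers(30, 100)), qlen=100,
                ss=1, se=int(rng.integers(30, 100)), slen=100)
            for _ in range(200)
        ]
        prev = -1
        for cov in (0.9, 0.8, 0.7, 0.5, 0.3, 0.0 + 1e-9):
            n = sum(passes_reciprocal_coverage(h, cov) for h in hits)
            assert n >= prev
            prev = n


class TestBestHit:
    def test_smallest_e_value_wins(self):
        hits = [hit(e=1e-5, s="a"), hit(e=1e-10, s="b")]
        assert best_tcdb_hit(hits).subject_id == "b"

    def test_all_over_cutoff_gives_none(self):
        assert best_tcdb_hit([hit(e=0.01), hit(e=0.5)]) is None

    def test_e_value_exactly_at_cutoff_passes(self):
        assert best_tcdb_hit([hit(e=1e-3)]) is not None

    def test_failing_coverage_excluded_before_e_ranking(self):
        good = hit(e=1e-5, s="pass")
        better_e_bad_cov = hit(e=1e-30, qe=50, s="fail")
        assert best_tcdb_hit([good, better_e_bad_cov]).subject_id == "pass"

    def test_tie_break_bitscore_then_subject(self):
        hits = [hit(e=1e-9, bits=100.0, s="zzz"), hit(e=1e-9, bits=300.0, s="mmm"),
                hit(e=1e-9, bits=300.0, s="aaa")]
        assert best_tcdb_hit(hits).subject_id == "aaa"

    def test_mixed_queries_rejected(self):
        with pytest.raises(ValueError):
            best_tcdb_hit([hit(q="a"), hit(q="b")])

    def test_against_brute_force_oracle(self, rng):
        for _ in range(100):
            hits = []
            for _ in range(int(rng.integers(1, 12))):
                qlen = int(rng.integers(50, 300))
                qe = int(rng.integers(20, qlen))
                slen = int(rng.integers(50, 300))
                se = int(rng.integers(20, slen))
                hits.append(
                    hit(qs=1, qe=qe, qlen=qlen, ss=1, se=se, slen=slen,
                        e=float(f"{10.0 ** -int(rng.integers(0, 12)):.1g}"),
                        bits=float(int(rng.integers(30, 500))),
                        s=f"s{int(rng.integers(0, 6))}")
                )
            assert best_tcdb_hit(hits) == best_hit_oracle(hits, 0.70, 1e-3)

    def test_permutation_invariant(self, rng):
        hits = [hit(e=10.0 ** -int(rng.integers(1, 12)), s=f"s{i}")
                for i in range(8)]
        ref = best_tcdb_hit(hits)
        for _ in range(5):
            perm = list(rng.permutation(len(hits)))
            assert best_tcdb_hit([hits[i] for i in perm]) == ref


class TestTcId:
    def test_full_five_tier_tag(self):
        tc = parse_tc_id("3.A.1.201.5")
        assert tc.tiers == ("3", "A", "1", "201", "5")
        assert str(tc) == "3.A.1.201.5"

    def test_partial_tag(self):
        tc = parse_tc_id("2.A.123")
        assert tc.tiers == ("2", "A", "123")
        assert tc.subfamily_tier is None

    def test_embedded_in_subject_id(self):
        tc = parse_tc_id("gnl|TC-DB|P0AE06|3.A.1.201.5")
        assert str(tc) == "3.A.1.201.5"

    def test_unparsable_text_raises(self):
        with pytest.raises(TcParseError):
            parse_tc_id("not-a-tag")

    def test_non_contiguous_tiers_rejected(self):
        with pytest.raises(ValueError):
            TcId(3, "A", None, 201, None)

    def test_prefixes_longest_first(self):
        assert parse_tc_id("2.A.1.2.3").prefixes() == [
            "2.A.1.2.3", "2.A.1.2", "2.A.1", "2.A", "2",
        ]


class TestCategorize:
    @pytest.mark.parametrize(
        "tag,cat,sub,fam",
        [
            ("3.A.5.8.1", "protein_biogenesis_secretion", "unassigned", "none"),
            ("2.A.1.1.8", "solute_transport", "sugars_metabolites", "mfs"),
            # DHA outranks the generic MFS sugar rule by longest prefix
            ("2.A.1.2.4", "solute_transport", "drugs_lipids", "none"),
            ("2.A.123.1.4", "solute_transport", "sugars_metabolites", "sweet"),
            ("3.A.1.1.9", "solute_transport", "sugars_metabolites", "abc_sbp"),
            ("3.A.1.201.2", "solute_transport", "drugs_lipids", "none"),
            ("3.A.20.1.1", "peroxisomal_import", "unassigned", "none"),
            ("1.B.33.1.1", "organelle_import", "unassigned", "none"),
            ("1.I.1.1.1", "nuclear_transport", "unassigned", "none"),
            ("8.A.23.1.1", "other", "unassigned", "none"),
            ("9.A.50.1.1", "nuclear_transport", "unassigned", "none"),
            ("5.B.1.1.1", "other", "unassigned", "none"),  # unmapped prefix
        ],
    )
    def test_default_map(self, tag, cat, sub, fam):
        c, s, f = categorize(parse_tc_id(tag))
        assert (c.value, s.value, f.value) == (cat, sub, fam)

    def test_duplicate_prefixes_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "2.A.1\tsolute_transport\tsugars_metabolites\tmfs\n"
            "2.A.1\tother\tunassigned\tnone\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            CategoryMap.from_tsv(p)

    def test_sugar_family_confined_to_sugar_substrate(self):
        with pytest.raises(ValueError):
            CategoryMap(
                {"2.A.66": (TransporterCategory.SOLUTE_TRANSPORT,
                            SubstrateClass.DRUGS_LIPIDS, SugarFamily.MFS)}
            )


class TestAssignAndTabulate:
    def test_category_counts_sum_to_assigned_queries(self, rng):
        hits = []
        for i in range(60):
            tag = ["2.A.1.1.1", "3.A.5.8.1", "9.B.4.1.1"][i % 3]
            hits.append(hit(q=f"q{i}", s=f"gnl|TC-DB|X|{tag}",
                            e=1e-8 if i % 4 else 0.01))
        assignments, unparsable = assign_transporters(hits)
        assert not unparsable
        df = pd.DataFrame(
            [{"strain": "s", "category": a.category.value,
              "substrate": a.substrate.value,
              "sugar_family": a.sugar_family.value} for a in assignments]
        )
        tables = tabulate_transporters(df)
        assert tables["categories"]["total"].sum() == len(assignments)

    def test_unparsable_best_hits_counted(self):
        hits = [hit(q="q1", s="no-tag-here")]
        assignments, unparsable = assign_transporters(hits)
        assert assignments == [] and unparsable == ["q1"]

    def test_cross_strain_totals(self):
        per_strain = pd.DataFrame(
            {"neocallimastix": [10], "anaeromyces": [5], "piromyces": [5]}
        )
        assert add_cross_strain_total(per_strain)["total"].iloc[0] == 20

    def test_synthetic_noiseless_tables_equal_truth(self, small_synthetic):
        _, _, result, truth = small_synthetic
        planted = truth[truth["tc_id"] != ""]
        cats = result.reports["categories"]
        for strain, grp in planted.groupby("strain"):
            tallies = grp["category"].value_counts()
            for cat in cats.index:
                assert cats.loc[cat, strain] == tallies.get(cat, 0)
        fams = result.reports["sugar_families"]
        sugar = planted[planted["sugar_family"] != "none"]
        assert fams.loc["total", "total"] == len(sugar)
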