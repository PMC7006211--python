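"""Family annotation: filters, voting, fragment joining, summaries."""

import numpy as np
import pandas as pd
import pytest

from conftest import family_dataset, gene_level
from gutatlas.families import (
    FamilyAnnotParams,
    FamilyCall,
    FamilyPanel,
    classify_family,
    has_domain,
    iterative_annotate,
    length_filter,
    merge_fragments,
    p450_candidates,
    summarize_family_expression,
)
from gutatlas.io import HitRecord


def hit(query, subject, evalue, pident=50.0, qlen=100, span=None, bitscore=None):
    span = span or qlen
    return HitRecord(
        query=query, subject=subject, pident=pident, length=span,
        mismatch=0, gapopen=0, qstart=1, qend=span, sstart=1, send=span,
        evalue=evalue, bitscore=bitscore if bitscore is not None else 100.0,
    )


def panel(name, kind, n, length=300):
    return FamilyPanel(
        name, kind, {f"{name}_m{i}": "A" * length for i in range(n)}
    )


class TestLengthFilter:
    def make_panel(self, lengths):
        return FamilyPanel(
            "F", "transporter",
            {f"m{i}": "A" * L for i, L in enumerate(lengths)},
        )

    def test_sample_sd_bound_drops_short_candidate(self):
        # sample sd of {400, 450, 500} = 50 -> window [350, 550]
        p = self.make_panel([400, 450, 500])
        assert not length_filter(340, p)

    def test_candidate_inside_window_kept(self):
        assert length_filter(360, self.make_panel([400, 450, 500]))

    def test_boundary_is_inclusive(self):
        assert length_filter(350, self.make_panel([400, 450, 500]))
        assert length_filter(550, self.make_panel([400, 450, 500]))

    def test_single_member_panel_sd_zero(self):
        p = self.make_panel([300])
        assert length_filter(300, p)
        assert not length_filter(299, p)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="no members"):
            FamilyPanel("F", "transporter", {})


class TestClassifyFamily:
    PANELS = {
        "AAAP": panel("AAAP", "transporter", 6),
        "APC": panel("APC", "transporter", 6),
        "POT": panel("POT", "transporter", 3),
    }

    def test_unanimous_top5_assigned(self):
        hits = [
            hit("q", f"AAAP_m{i}", 10.0 ** -(20 - i), pident=35.0)
            for i in range(5)
        ]
        call = classify_family("q", hits, self.PANELS)
        assert call is not None and call.family == "AAAP"
        assert call.vote_count == 5
        assert call.best_identity == pytest.approx(35.0)

    def test_three_of_five_insufficient_for_large_family(self):
        hits = (
            [hit("q", f"APC_m{i}", 10.0 ** -(20 - i)) for i in range(3)]
            + [hit("q", f"AAAP_m{i}", 10.0 ** -(16 - i)) for i in range(2)]
        )
        assert classify_family("q", hits, self.PANELS) is None

    def test_small_family_needs_all_members_in_top5(self):
        hits = (
            [hit("q", f"POT_m{i}", 10.0 ** -(20 - i), pident=25.0)
             for i in range(3)]
            + [hit("q", "AAAP_m0", 1e-10), hit("q", "APC_m0", 1e-9)]
        )
        call = classify_family("q", hits, self.PANELS)
        assert call is not None and call.family == "POT"

    def test_small_family_missing_member_fails(self):
        hits = [
            hit("q", "POT_m0", 1e-20, pident=25.0),
            hit("q", "POT_m1", 1e-19, pident=25.0),
            hit("q", "AAAP_m0", 1e-10),
            hit("q", "AAAP_m1", 1e-9),
            hit("q", "APC_m0", 1e-8),
        ]
        assert classify_family("q", hits, self.PANELS) is None

    def test_identity_below_20_percent_fails(self):
        hits = [
            hit("q", f"AAAP_m{i}", 10.0 ** -(20 - i), pident=15.0)
            for i in range(5)
        ]
        assert classify_family("q", hits, self.PANELS) is None

    def test_no_hits_no_call(self):
        assert classify_family("q", [], self.PANELS) is None

    def test_evalue_tie_breaks_by_bitscore_then_subject(self):
        hits = [
            hit("q", "APC_m0", 1e-10, bitscore=50.0),
            hit("q", "AAAP_m0", 1e-10, bitscore=80.0, pident=30.0),
        ] + [hit("q", f"AAAP_m{i}", 1e-8, pident=30.0) for i in range(1, 4)]
        call = classify_family("q", hits, self.PANELS)
        assert call is not None and call.family == "AAAP"


class TestMergeFragments:
    def test_overlap_join_arithmetic(self):
        merged = merge_fragments(
            {"a": "AAAABBBB", "b": "BBBBCCCC"}, min_overlap=4
        )
        (seq,) = merged.values()
        assert seq == "AAAABBBBCCCC"
        assert len(seq) == 8 + 8 - 4

    def test_disjoint_fragments_unmerged(self):
        frags = {"a": "AAAAAAAA", "b": "CCCCCCCC"}
        assert merge_fragments(frags, min_overlap=4) == frags

    def test_identical_candidates_collapse(self):
        merged = merge_fragments({"b": "AAAACCCC", "a": "AAAACCCC"})
        assert merged == {"a": "AAAACCCC"}

    def test_short_overlap_ignored(self):
        frags = {"a": "AAAABB", "b": "BBCCCC"}
        assert merge_fragments(frags, min_overlap=4) == frags

    def test_chain_merges_to_fixed_point(self):
        merged = merge_fragments(
            {"a": "AAAABBBB", "b": "BBBBCCCC", "c": "CCCCDDDD"},
            min_overlap=4,
        )
        assert list(merged.values()) == ["AAAABBBBCCCCDDDD"]

    def test_order_independence(self):
        frags = {"a": "AAAABBBB", "b": "BBBBCCCC", "c": "CCCCDDDD"}
        rev = dict(reversed(frags.items()))
        assert set(merge_fragments(frags, 4).values()) == set(
            merge_fragments(rev, 4).values()
        )

    def test_conflicting_joins_skipped_and_logged(self, caplog):
        # 'a' could extend into both 'b' and 'c': neither join is applied
        frags = {"a": "AAAABBBB", "b": "BBBBCCCC", "c": "BBBBDDDD"}
        merged = merge_fragments(frags, min_overlap=4)
        assert merged == frags
        assert "conflicting overlaps" in caplog.text


class TestDomainCheck:
    def test_motif_hit(self):
        assert has_domain("MMMFSAGPRNCIGMMM")

    def test_no_motif(self):
        assert not has_domain("M" * 30)

    def test_external_domain_table_wins(self):
        table = {"g1": {"PF00067"}}
        assert has_domain("M" * 30, gene_id="g1", domain_table=table)
        assert not has_domain(
            "MMMFSAGPRNCIGMMM", gene_id="g2", domain_table=table
        )


class TestP450Candidates:
    PARAMS = FamilyAnnotParams()

    def curated(self):
        return {"cyp1": "A" * 300}

    def test_short_candidate_rejected(self):
        unis = {"u1": "FSAGPRNCIG" * 10}  # length 100 < 150
        fwd = [hit("cyp1", "u1", 1e-20, qlen=300)]
        assert p450_candidates(fwd, unis, self.curated(), self.PARAMS) == []

    def test_weak_evalue_rejected(self):
        unis = {"u1": "M" * 200 + "FSAGPRNCIG"}
        fwd = [hit("cyp1", "u1", 1e-2, qlen=300)]
        assert p450_candidates(fwd, unis, self.curated(), self.PARAMS) == []

    def test_low_coverage_rejected_despite_strong_evalue(self):
        unis = {"u1": "M" * 200 + "FSAGPRNCIG"}
        fwd = [hit("cyp1", "u1", 1e-20, qlen=300, span=90)]  # 30% coverage
        assert p450_candidates(fwd, unis, self.curated(), self.PARAMS) == []


class TestSummary:
    CALLS = [
        FamilyCall("g1", "SP", "SP", 5, 40.0, 4, True, 1),
        FamilyCall("g2", "SP", "SP", 5, 45.0, 5, True, 1),
        FamilyCall("g3", "AAAP", "AAAP", 5, 50.0, 3, True, 1),
    ]

    def means(self, g3_low=False):
        rows = {
            "g1": [2.0, 2.0, 2.0, 10.0, 1.0],
            "g2": [3.0, 3.0, 3.0, 90.0, 1.0],
            "g3": [0.5, 0.5, 0.5, 0.5, 0.5] if g3_low
            else [60.0, 2.0, 2.0, 2.0, 1.0],
        }
        return pd.DataFrame(
            rows, index=["M1", "M2", "M3", "M4", "carcass"]
        ).T

    def test_family_average_and_threshold_counts(self):
        out = summarize_family_expression(self.CALLS, self.means())
        assert out.loc["SP", "avg_M4"] == pytest.approx(50.0)  # (10+90)/2
        assert out.loc["SP", "n_over_50_M4"] == 1
        assert out.loc["SP", "n_over_5_M4"] == 2

    def test_threshold_strictly_greater(self):
        calls = [FamilyCall("g1", "SP", "SP", 5, 40.0, 4, True, 1)]
        means = pd.DataFrame(
            {"g1": [50.0, 1.0, 1.0, 2.0, 0.0]},
            index=["M1", "M2", "M3", "M4", "carcass"],
        ).T
        out = summarize_family_expression(calls, means)
        assert out.loc["SP", "n_over_50_M1"] == 0  # exactly 50 not counted

    def test_single_member_family_average_is_member(self):
        out = summarize_family_expression(self.CALLS, self.means())
        assert out.loc["AAAP", "avg_M1"] == pytest.approx(60.0)

    def test_low_expression_members_filtered_first(self):
        out = summarize_family_expression(self.CALLS, self.means(g3_low=True))
        assert bool(out.loc["AAAP", "all_filtered"])
        assert out.loc["AAAP", "avg_M1"] == 0.0


class TestIterativeAnnotate:
    def test_planted_families_recovered(self):
        data = family_dataset(seed=101)
        unis = gene_level(data.sequences)
        panels = {
            n: FamilyPanel(p.name, p.kind, p.members)
            for n, p in data.panels.items()
        }
        calls = iterative_annotate(unis, panels)
        truth = {g: f for g, f in data.truth.family.items() if f}
        pred = {c.gene_id: c.family for c in calls}
        assert pred == truth

    def test_second_run_on_own_output_is_fixed_point(self):
        data = family_dataset(seed=102, n_decoys=25)
        unis = gene_level(data.sequences)
        panels = {
            n: FamilyPanel(p.name, p.kind, p.members)
            for n, p in data.panels.items()
        }
        calls1 = iterative_annotate(unis, panels)
        calls2 = iterative_annotate(unis, panels)
        assert [(c.gene_id, c.family) for c in calls1] == [
            (c.gene_id, c.family) for c in calls2
        ]

    def test_null_catalog_gets_zero_calls(self):
        data = family_dataset(seed=103, n_decoys=30, planted=False)
        ref = family_dataset(seed=103, n_decoys=5)  # panels only
        unis = gene_level(data.sequences)
        panels = {
            n: FamilyPanel(p.name, p.kind, p.members)
            for n, p in ref.panels.items()
        }
        assert iterative_annotate(unis, panels) == []

    def test_tm_and_length_filters_commute(self):
        # candidates failing either filter are excluded regardless of
        # evaluation order; equivalently, the final call set equals the
        # intersection of the two single-filter call sets
        data = family_dataset(seed=104, n_decoys=25)
        unis = gene_level(data.sequences)
        panels = {
            n: FamilyPanel(p.name, p.kind, p.members)
            for n, p in data.panels.items()
        }
        base = {
            c.gene_id
            for c in iterative_annotate(unis, panels)
            if panels[c.family].kind == "transporter"
        }
        no_tm = {
            c.gene_id
            for c in iterative_annotate(
                unis, panels, FamilyAnnotParams(min_tm=0)
            )
            if panels[c.family].kind == "transporter"
        }
        giant = FamilyAnnotParams(min_tm=3)
        loose_len_panels = {
            n: FamilyPanel(
                p.name, p.kind,
                {**dict(p.members), "pad_short": "A" * 30, "pad_long": "A" * 2000},
            )
            for n, p in panels.items()
        }
        no_len = {
            c.gene_id
            for c in iterative_annotate(unis, loose_len_panels, giant)
            if loose_len_panels[c.family].kind == "transporter"
        }
        assert base == no_tm & no_len
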