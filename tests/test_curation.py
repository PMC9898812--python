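"""Exclusion rules, region classes, TSS distances and activity inference."""

from __future__ import annotations

import pandas as pd
import pytest

from regbash.annotation import FeatureInterval, Transcript
from regbash.consequence import ConsequenceCall, TranscriptConsequence
from regbash.curation import (
    CuratedRecord,
    StudyRecord,
    aggregate_study_activity,
    apply_exclusion_rules,
    assign_regulatory_class,
    distance_to_tss,
    infer_activity,
    round_distance,
)


def _call(aid, gene_cat="non_coding_regulatory", fine="five_prime_UTR", ectopic=False):
    per = [TranscriptConsequence(aid, "t1", fine, ectopic_donor_flag=ectopic)]
    return ConsequenceCall(allele_id=aid, gene_id="g1", gene_category=gene_cat,
                           fine_category=fine, per_transcript=per)


def _table(rows):
    return pd.DataFrame(rows)


class TestExclusionRules:
    def test_synonymous_and_regulatory_retention_counts(self):
        """32 of 35 synonymous and 26 of 76 regulatory candidates excluded -> 53."""
        calls, rows = [], []
        for i in range(35):
            aid = f"syn{i}"
            calls.append(_call(aid, "synonymous", "synonymous"))
            if i < 30:
                rows.append({"item_id": aid, "protein_change_reported": 1})
            elif i < 32:
                rows.append({"item_id": aid, "passenger": 1})
        for i in range(76):
            aid = f"reg{i}"
            calls.append(_call(aid))
            if i < 20:
                rows.append({"item_id": aid, "passenger": 1})
            elif i < 26:
                rows.append({"item_id": aid, "insufficient_info": 1})
        retained, excluded, _ = apply_exclusion_rules(calls, _table(rows))
        assert len(retained) + len(excluded) == 111
        assert len(excluded) == 58
        syn_kept = [r for r in retained if r.item_id.startswith("syn")]
        reg_kept = [r for r in retained if r.item_id.startswith("reg")]
        assert len(syn_kept) == 3 and len(reg_kept) == 50
        assert len(syn_kept) + len(reg_kept) == 53

    def test_each_exclusion_has_exactly_one_reason_in_order(self):
        call = _call("a1")
        table = _table([{"item_id": "a1", "passenger": 1, "insufficient_info": 1}])
        _, excluded, _ = apply_exclusion_rules([call], table)
        assert excluded[0].exclusion_reason == "passenger"
        coding = _call("a2", "coding", "missense")
        table = _table([{"item_id": "a2", "passenger": 1}])
        _, excluded, _ = apply_exclusion_rules([coding], table)
        assert excluded[0].exclusion_reason == "protein_changing_any_isoform"

    def test_ectopic_donor_flag_forces_exclusion(self):
        call = _call("a1", "coding", "synonymous", ectopic=True)
        _, excluded, _ = apply_exclusion_rules([call], None)
        assert excluded[0].exclusion_reason == "protein_changing_any_isoform"

    def test_no_flags_all_non_coding_retained(self):
        calls = [_call(f"a{i}") for i in range(5)]
        retained, excluded, _ = apply_exclusion_rules(calls, None)
        assert len(retained) == 5 and excluded == []

    def test_unmatched_table_rows_reported(self):
        table = _table([{"item_id": "ghost", "passenger": 1}])
        with pytest.warns(UserWarning, match="ghost"):
            _, _, warns = apply_exclusion_rules([_call("a1")], table)
        assert len(warns) == 1


class TestRegionClass:
    @pytest.mark.parametrize(
        "distance,label,expected",
        [
            (40, "", "core_promoter"),
            (100, "", "core_promoter"),     # boundary inclusive
            (101, "", "promoter"),
            (101, "enhancer", "enhancer"),
            (2000, "enhancer", "enhancer"),
            (800, "", "promoter"),
        ],
    )
    def test_transcriptional_rule_table(self, distance, label, expected):
        assert assign_regulatory_class("upstream", distance, label) == expected

    @pytest.mark.parametrize(
        "fine,expected",
        [("five_prime_UTR", "five_prime_UTR"), ("three_prime_UTR", "three_prime_UTR"),
         ("intronic", "intron"), ("downstream", "downstream")],
    )
    def test_passthrough_classes(self, fine, expected):
        assert assign_regulatory_class(fine, 400, "") == expected

    def test_no_distance_is_unclassified(self):
        assert assign_regulatory_class("upstream", None, "") == "unclassified"


class TestDistanceToTss:
    def _tx(self, strand):
        return Transcript(
            "t1", "g1", "c", strand,
            exons=[FeatureInterval("c", 1000, 1400, strand, "exon", "t1", "g1"),
                   FeatureInterval("c", 1500, 2000, strand, "exon", "t1", "g1")])

    def test_intragenic_element_gets_zero(self):
        raw, disp = distance_to_tss(1450, 1480, self._tx("+"))  # intronic
        assert raw == 0 and disp == 0

    def test_upstream_gap_plus_strand(self):
        raw, _ = distance_to_tss(100, 127, self._tx("+"))  # ends 873 before TSS
        assert raw == 873

    def test_upstream_gap_minus_strand_mirror(self):
        # TSS at 1999; element starting at 2873 is 873 bp upstream
        raw, _ = distance_to_tss(2873, 2900, self._tx("-"))
        assert raw == 873

    def test_downstream_element_gets_zero(self):
        raw, _ = distance_to_tss(2100, 2150, self._tx("+"))
        assert raw == 0

    @pytest.mark.parametrize("raw,display", [
        (873, 850), (875, 900), (40, 50), (0, 0), (990, 1000),
        (1049, 1000), (1050, 1100), (4999, 5000), (8463, 8500), (5251, 5500),
    ])
    def test_display_rounding_tiers(self, raw, display):
        assert round_distance(raw) == display

    def test_rounding_stays_within_quarter_kilobase(self):
        for raw in range(0, 12_000, 7):
            disp = round_distance(raw)
            assert abs(disp - raw) <= 250 and disp >= 0


class TestActivity:
    @pytest.mark.parametrize("effect,severity,expected", [
        ("down", "null", "activating"),
        ("down", "reduced", "activating"),
        ("down", None, "activating"),
        ("up", None, "repressive"),
        (None, "null", "activating"),      # severity implies down
        (None, "reduced", "activating"),
    ])
    def test_effect_maps_to_native_activity(self, effect, severity, expected):
        assert infer_activity(effect, severity) == expected

    def test_unknown_effect_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            assert infer_activity("sideways") is None

    def test_study_unanimity_and_both(self):
        down = CuratedRecord(item_id="r1", effect="down")
        down2 = CuratedRecord(item_id="r2", effect="down")
        up = CuratedRecord(item_id="r3", effect="up")
        assert aggregate_study_activity([down, down2]) == "activating"
        assert aggregate_study_activity([up]) == "repressive"
        assert aggregate_study_activity([down, up]) == "both"

    def test_nmd_filter_drops_spurious_activating_records(self):
        nmd = CuratedRecord(item_id="r1", effect="down", mechanism="NMD",
                            region_class="three_prime_UTR")
        rep = CuratedRecord(item_id="r2", effect="up", region_class="three_prime_UTR")
        assert aggregate_study_activity([nmd, rep]) == "both"
        assert aggregate_study_activity([nmd, rep], nmd_filter=True) == "repressive"
        assert aggregate_study_activity([nmd], nmd_filter=True) == "none"

    def test_activity_involution_up_down_swap(self):
        records = [CuratedRecord(item_id=f"r{i}", effect=e)
                   for i, e in enumerate(["down", "down", "up", "down", "up", "up"])]
        flipped = [CuratedRecord(item_id=r.item_id,
                                 effect="up" if r.effect == "down" else "down")
                   for r in records]
        swap = {"activating": "repressive", "repressive": "activating", "both": "both"}
        for chunk in ([0, 1], [2], [0, 2], [3, 4, 5]):
            orig = aggregate_study_activity([records[i] for i in chunk])
            assert aggregate_study_activity([flipped[i] for i in chunk]) == swap[orig]


def test_curated_record_inclusion_invariant():
    with pytest.raises(ValueError):
        CuratedRecord(item_id="x", included=True, exclusion_reason="passenger")
    with pytest.raises(ValueError):
        CuratedRecord(item_id="x", distance_raw=-5)


def test_study_record_distance_ordering_invariant():
    with pytest.raises(ValueError):
        StudyRecord("s1", "reporter", frozenset(), 3, closest_bp=500, furthest_bp=100)
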