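import numpy as np
import pandas as pd
import pytest

from gatherparse import (
    UNIDENTIFIED,
    completeness_score,
    consensus_taxon,
    merge_fields,
    select_voucher,
)
from gatherparse.errors import ContractError
from gatherparse.voucher import COMPLETENESS_FIELDS, completeness_flags
from tests.conftest import make_occ
from tests.oracles import brute_force_consensus, brute_force_voucher

FULL = dict(recordedBy="Gardner, G.", recordNumber="417", year="1841",
            institutionCode="K", catalogNumber="K-1", locality="Serra",
            municipality="Piumhi", stateProvince="MG", fieldNotes="Shrub")


def record(**overrides):
    base = {**FULL, **overrides}
    return pd.Series(base)


class TestCompleteness:
    def test_ten_unit_flags(self):
        assert len(COMPLETENESS_FIELDS) == 10
        assert completeness_score(record(), frozenset()) == 10

    def test_fully_empty_record_with_invalid_country_scores_zero(self):
        empty = pd.Series({k: "" for k in FULL})
        assert completeness_score(empty, frozenset({"COUNTRY_INVALID"})) == 0

    def test_partial_record_hand_count(self):
        # collector, number, year populated + valid country = 4 flags
        r = pd.Series(dict(recordedBy="G", recordNumber="1", year="1900"))
        assert completeness_score(r, frozenset()) == 4

    def test_country_flag_follows_issue_not_field(self):
        assert completeness_score(record(), frozenset({"COUNTRY_INVALID"})) == 9

    def test_each_flag_scores_exactly_one(self):
        base = completeness_score(record(), frozenset())
        for col in FULL:
            assert completeness_score(record(**{col: ""}), frozenset()) == base - 1


def group_frame(members):
    """members: list of (record_id, spatial, completeness)."""
    return pd.DataFrame({
        "gbifID": [m[0] for m in members],
        "parseGBIF_spatial_score": [m[1] for m in members],
        "parseGBIF_completeness_score": [m[2] for m in members],
        "parseGBIF_event_key": "K",
    })


class TestSelectVoucher:
    def test_highest_total_wins(self):
        d = select_voucher(group_frame([("a", -3, 10), ("b", 0, 3)]))
        assert d.voucher_record_id == "a"
        assert d.total_scores == {"a": 7, "b": 3}

    def test_singleton_selects_its_only_member(self):
        assert select_voucher(group_frame([("solo", -9, 0)])).voucher_record_id == "solo"

    def test_tie_breaks_on_completeness_then_id(self):
        d = select_voucher(group_frame([("b", 0, 6), ("a", -1, 6)]))
        assert d.voucher_record_id == "b"  # totals 6 vs 5
        d = select_voucher(group_frame([("b", -1, 7), ("a", 0, 6)]))
        assert d.voucher_record_id == "b"  # tied total 6, higher completeness
        d = select_voucher(group_frame([("b", 0, 6), ("a", 0, 6)]))
        assert d.voucher_record_id == "a"  # full tie: smallest id

    def test_empty_group_is_contract_error(self):
        with pytest.raises(ContractError):
            select_voucher(group_frame([]))

    def test_matches_brute_force_on_random_groups(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(1, 33))
            members = [
                (f"r{rng.integers(0, n)}{i}", int(rng.choice([0, -1, -3, -9])),
                 int(rng.integers(0, 11)))
                for i in range(n)
            ]
            assert select_voucher(group_frame(members)).voucher_record_id == \
                brute_force_voucher(members)

    def test_total_score_bounds(self):
        rng = np.random.default_rng(3)
        members = [(f"r{i}", int(rng.choice([0, -1, -3, -9])), int(rng.integers(0, 11)))
                   for i in range(50)]
        d = select_voucher(group_frame(members))
        assert all(-9 <= t <= 10 for t in d.total_scores.values())


def named_group(entries):
    """entries: list of (accepted_name, status, rank)."""
    return pd.DataFrame({
        "gbifID": [str(i) for i in range(len(entries))],
        "wcvp_accepted_taxon_name": [e[0] for e in entries],
        "wcvp_standardized_name": [e[0] for e in entries],
        "wcvp_match_status": [e[1] for e in entries],
        "wcvp_taxon_rank": [e[2] for e in entries],
    })


class TestConsensusTaxon:
    def test_plurality_wins(self):
        g = named_group([("Aa a", "matched_accepted", "Species")] * 2
                        + [("Bb b", "matched_accepted", "Species")])
        assert consensus_taxon(g) == "Aa a"

    def test_tie_resolves_alphabetically(self):
        g = named_group([("Bb b", "matched_accepted", "Species"),
                         ("Aa a", "matched_accepted", "Species")])
        assert consensus_taxon(g) == "Aa a"

    def test_genus_only_group_is_unidentified(self):
        g = named_group([("Eugenia", "matched_accepted", "Genus")] * 3)
        assert consensus_taxon(g) == UNIDENTIFIED

    def test_unmatched_names_do_not_count(self):
        g = named_group([("", "unmatched", ""),
                         ("Aa a", "matched_accepted", "Species")])
        assert consensus_taxon(g) == "Aa a"

    def test_infraspecific_ranks_count_as_below_species(self):
        g = named_group([("Aa a var. b", "matched_accepted", "Variety")])
        assert consensus_taxon(g) == "Aa a var. b"

    def test_synonym_resolution_merges_counts(self):
        g = named_group([("Aa a", "matched_synonym_resolved", "Species"),
                         ("Aa a", "matched_accepted", "Species"),
                         ("Bb b", "matched_accepted", "Species"),
                         ("Bb b", "matched_accepted", "Species")])
        # resolved synonym + accepted tie at 2 each -> alphabetical
        assert consensus_taxon(g) == "Aa a"

    def test_matches_brute_force_on_random_multisets(self):
        rng = np.random.default_rng(5)
        pool = ["Aa a", "Bb b", "Cc c", "Dd d"]
        for _ in range(200):
            names = [pool[rng.integers(len(pool))] for _ in range(int(rng.integers(0, 6)))]
            g = named_group([(n, "matched_accepted", "Species") for n in names]
                            + [("Eugenia", "matched_accepted", "Genus")])
            assert consensus_taxon(g) == brute_force_consensus(names)


def merge_group(rows):
    df = make_occ(rows)
    df["parseGBIF_event_key"] = "K"
    return df


class TestMergeFields:
    def _decision(self, group, voucher_id, totals):
        from gatherparse.voucher import VoucherDecision
        return VoucherDecision("K", voucher_id, totals)

    def test_empty_voucher_field_filled_from_duplicate(self):
        g = merge_group([
            dict(gbifID="v", habitat=""),
            dict(gbifID="d", habitat="Cerrado"),
        ])
        merged, decision = merge_fields(g, self._decision(g, "v", {"v": 5, "d": 3}))
        assert merged["habitat"] == "Cerrado"
        assert ("habitat", "d") in decision.merge_log

    def test_non_empty_voucher_cell_never_overwritten(self):
        g = merge_group([
            dict(gbifID="v", habitat="Original"),
            dict(gbifID="d", habitat="Other"),
        ])
        merged, decision = merge_fields(g, self._decision(g, "v", {"v": 5, "d": 3}))
        assert merged["habitat"] == "Original"
        assert decision.merge_log == []

    def test_donor_with_higher_total_score_wins(self):
        g = merge_group([
            dict(gbifID="v", locality=""),
            dict(gbifID="d1", locality="From d1"),
            dict(gbifID="d2", locality="From d2"),
        ])
        merged, _ = merge_fields(g, self._decision(g, "v", {"v": 9, "d1": 2, "d2": 5}))
        assert merged["locality"] == "From d2"

    def test_coordinates_move_as_atomic_pair(self):
        g = merge_group([
            dict(gbifID="v", decimalLatitude="", decimalLongitude=""),
            dict(gbifID="d1", decimalLatitude="-20.5", decimalLongitude=""),
            dict(gbifID="d2", decimalLatitude="-21.0", decimalLongitude="-45.0"),
        ])
        merged, log = merge_fields(g, self._decision(g, "v", {"v": 5, "d1": 4, "d2": 3}))
        # d1 ranks higher but lacks the pair; d2 donates both cells
        assert merged["decimalLatitude"] == "-21.0"
        assert merged["decimalLongitude"] == "-45.0"

    def test_spatially_excluded_donor_never_donates_coordinates(self):
        g = merge_group([
            dict(gbifID="v", decimalLatitude="", decimalLongitude=""),
            dict(gbifID="d", decimalLatitude="0", decimalLongitude="0"),
        ])
        merged, _ = merge_fields(g, self._decision(g, "v", {"v": 5, "d": 1}),
                                 spatial_scores={"v": -9, "d": -9})
        assert merged["decimalLatitude"] == ""

    def test_fully_populated_voucher_yields_no_actions(self, tiny_occ):
        g = tiny_occ.head(2).copy()
        g["parseGBIF_event_key"] = "K"
        merged, decision = merge_fields(g, self._decision(g, "1", {"1": 10, "2": 5}))
        assert decision.merge_log == []
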