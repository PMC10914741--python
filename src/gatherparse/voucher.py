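"""Digital-voucher selection, consensus taxon and duplicate merging.

Within each collection-event group the best record — the digital voucher — is
the one with the highest total score, the sum of spatial data quality (0, -1,
-3, -9) and record completeness (ten unit flags, 0..10). The consensus taxon
is the accepted name most frequently applied to the duplicates at or below the
rank of species (ties alphabetical; none -> UNIDENTIFIED). Fields empty in the
voucher are then populated from the best-scoring duplicate that has them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from gatherparse.errors import ContractError
from gatherparse.wcvp import SPECIES_OR_BELOW

UNIDENTIFIED = "UNIDENTIFIED"

#: the ten record-completeness flags, in scoring order
COMPLETENESS_FIELDS = (
    "collector", "collection_number", "year", "institution_code",
    "catalog_number", "locality", "municipality", "state_province",
    "country_valid", "field_notes",
)

#: fields describing the gathering itself, safe to consolidate across duplicates;
#: identification-history fields are deliberately excluded, and the coordinate
#: pair moves atomically so a latitude is never combined with a foreign longitude
DEFAULT_MERGEABLE_FIELDS = (
    "habitat", "fieldNotes", "locality", "municipality", "stateProvince",
    "countryCode", "year", "month", "day", "elevation",
    ("decimalLatitude", "decimalLongitude"),
)


@dataclass(frozen=True)
class CompletenessFlags:
    """The ten boolean completeness flags; the score is their sum."""

    collector: bool
    collection_number: bool
    year: bool
    institution_code: bool
    catalog_number: bool
    locality: bool
    municipality: bool
    state_province: bool
    country_valid: bool
    field_notes: bool

    @property
    def score(self) -> int:
        return sum(
            getattr(self, f) for f in COMPLETENESS_FIELDS
        )


def completeness_flags(record: pd.Series, issue_tokens: frozenset[str] | set[str]) -> CompletenessFlags:
    """Evaluate the ten flags on one record.

    Nine flags test field presence; the country flag is true iff GBIF did not
    raise COUNTRY_INVALID on the record.
    """
    def has(col: str) -> bool:
        return bool(str(record.get(col, "")).strip())

    return CompletenessFlags(
        collector=has("recordedBy"),
        collection_number=has("recordNumber"),
        year=has("year"),
        institution_code=has("institutionCode"),
        catalog_number=has("catalogNumber"),
        locality=has("locality"),
        municipality=has("municipality"),
        state_province=has("stateProvince"),
        country_valid="COUNTRY_INVALID" not in issue_tokens,
        field_notes=has("fieldNotes"),
    )


def completeness_score(record: pd.Series, issue_tokens: frozenset[str] | set[str] = frozenset()) -> int:
    """Record completeness in [0, 10]: the number of satisfied flags."""
    return completeness_flags(record, issue_tokens).score


@dataclass
class VoucherDecision:
    """Outcome of voucher selection (and later merging) for one event group."""

    key_string: str
    voucher_record_id: str
    total_scores: dict[str, int]
    consensus_taxon: str = UNIDENTIFIED
    merge_log: list[tuple[str, str]] = field(default_factory=list)


def select_voucher(group: pd.DataFrame) -> VoucherDecision:
    """Pick the digital voucher: argmax of spatial + completeness score.

    Requires ``parseGBIF_spatial_score`` and ``parseGBIF_completeness_score``
    columns. Ties break on higher completeness, then lexicographically
    smallest record id, making the choice deterministic under row permutation.
    """
    if len(group) == 0:
        raise ContractError("select_voucher: empty group")
    totals = {
        rid: int(s) + int(c)
        for rid, s, c in zip(group["gbifID"], group["parseGBIF_spatial_score"],
                             group["parseGBIF_completeness_score"])
    }
    completeness = dict(zip(group["gbifID"], group["parseGBIF_completeness_score"].astype(int)))
    best = min(totals, key=lambda rid: (-totals[rid], -completeness[rid], rid))
    key = group["parseGBIF_event_key"].iloc[0] if "parseGBIF_event_key" in group.columns else ""
    return VoucherDecision(key, best, totals)


def consensus_taxon(group: pd.DataFrame, use_resolved: bool = True) -> str:
    """The accepted name most frequently applied to the group at or below species rank.

    Frequency ties resolve to the alphabetically first name; a group with no
    determination at or below species rank is UNIDENTIFIED. With
    ``use_resolved`` (default) synonyms count toward their accepted name, so
    two synonyms of one species reinforce each other; set False to count
    verbatim standardized names instead.
    """
    if len(group) == 0:
        raise ContractError("consensus_taxon: empty group")
    matched = group[
        group["wcvp_match_status"].isin(("matched_accepted", "matched_synonym_resolved"))
        & group["wcvp_taxon_rank"].str.lower().isin(SPECIES_OR_BELOW)
    ]
    col = "wcvp_accepted_taxon_name" if use_resolved else "wcvp_standardized_name"
    names = [n for n in matched[col] if n]
    if not names:
        return UNIDENTIFIED
    counts: dict[str, int] = {}
    for n in names:
        counts[n] = counts.get(n, 0) + 1
    return min(counts, key=lambda n: (-counts[n], n))


def _pair_fields(mergeable):
    for f in mergeable:
        yield (f if isinstance(f, tuple) else (f,))


def merge_fields(
    group: pd.DataFrame,
    decision: VoucherDecision,
    mergeable_fields=DEFAULT_MERGEABLE_FIELDS,
    spatial_scores: dict[str, int] | None = None,
) -> tuple[pd.Series, VoucherDecision]:
    """Fill fields empty in the voucher from its best-scoring duplicates.

    Donors are scanned in order of descending total score (ties by record id);
    a non-empty voucher cell is never overwritten. Tuple entries in
    ``mergeable_fields`` move atomically: every member cell must be empty in
    the voucher and non-empty in the donor. When ``spatial_scores`` is given,
    the coordinate pair is only accepted from donors whose own spatial score
    does not exclude them (> -9) — a flagged-invalid coordinate must not leak
    into the voucher. Each fill appends a ``(field, source_record_id)`` action
    to the merge log.
    """
    if decision.voucher_record_id not in set(group["gbifID"]):
        raise ContractError("voucher record not in group")
    voucher = group[group["gbifID"] == decision.voucher_record_id].iloc[0].copy()
    donors = group[group["gbifID"] != decision.voucher_record_id]
    donor_order = sorted(
        donors["gbifID"],
        key=lambda rid: (-decision.total_scores.get(rid, -99), rid),
    )
    donor_rows = {rid: donors[donors["gbifID"] == rid].iloc[0] for rid in donor_order}
    for fields_ in _pair_fields(mergeable_fields):
        present = [f for f in fields_ if f in group.columns]
        if len(present) != len(fields_):
            continue
        if any(str(voucher[f]).strip() for f in fields_):
            continue
        is_coord = "decimalLatitude" in fields_
        for rid in donor_order:
            if is_coord and spatial_scores is not None and spatial_scores.get(rid, -9) <= -9:
                continue
            row = donor_rows[rid]
            if all(str(row[f]).strip() for f in fields_):
                for f in fields_:
                    voucher[f] = row[f]
                    decision.merge_log.append((f, rid))
                break
    return voucher, decision
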