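"""End-to-end parsing workflow: issues -> names -> collectors -> keys -> vouchers -> partitions."""

from __future__ import annotations

import logging

import pandas as pd

from gatherparse.collectors import CollectorEntry, apply_dictionary
from gatherparse.eventkey import assign_keys
from gatherparse.export import ParseResult, partition_dataset
from gatherparse.issues import IssueScoreTable, score_table, split_issue_string
from gatherparse.voucher import (
    DEFAULT_MERGEABLE_FIELDS,
    completeness_score,
    consensus_taxon,
    merge_fields,
    select_voucher,
)
from gatherparse.wcvp import WCVP_COLUMNS, check_name_batch

logger = logging.getLogger(__name__)


def parse_dataset(
    occ: pd.DataFrame,
    wcvp: pd.DataFrame | None = None,
    dictionary: list[CollectorEntry] | None = None,
    issue_scores: IssueScoreTable | None = None,
    mergeable_fields=DEFAULT_MERGEABLE_FIELDS,
    use_resolved_names: bool = True,
) -> ParseResult:
    """Run the full parsing workflow on a prepared occurrence table.

    Steps: score spatial issues; reconcile names against the backbone (skipped
    if ``wcvp`` is None and ``wcvp_*`` columns are already present);
    standardize collectors through the dictionary; build event keys; per
    group select the digital voucher, pick the consensus taxon and merge
    duplicate content into the voucher; finally partition into
    useable / unusable / duplicate.
    """
    table = score_table(occ, issue_scores)
    if wcvp is not None:
        table = check_name_batch(table, wcvp)
    elif not set(WCVP_COLUMNS).issubset(table.columns):
        logger.warning("no names backbone supplied; all records treated as unmatched")
        for col in WCVP_COLUMNS:
            table[col] = ""
        table["wcvp_match_status"] = "unmatched"
    if "nameRecordedBy_Standard" not in table.columns:
        table = apply_dictionary(table, dictionary)
    table = assign_keys(table)

    table["parseGBIF_completeness_score"] = [
        completeness_score(row, split_issue_string(row["parseGBIF_issue_tokens"]))
        for _, row in table.iterrows()
    ]
    table["parseGBIF_total_score"] = (
        table["parseGBIF_spatial_score"].astype(int)
        + table["parseGBIF_completeness_score"].astype(int)
    )

    table = table.set_index("gbifID", drop=False)
    is_voucher = pd.Series(False, index=table.index)
    consensus = pd.Series("", index=table.index, dtype=object)
    log_rows: list[dict] = []
    for key, group in table.groupby("parseGBIF_event_key", sort=False):
        decision = select_voucher(group)
        decision.consensus_taxon = consensus_taxon(group, use_resolved=use_resolved_names)
        spatial = dict(zip(group["gbifID"], group["parseGBIF_spatial_score"].astype(int)))
        if len(group) > 1:
            merged, decision = merge_fields(group, decision, mergeable_fields, spatial)
            for col in merged.index:
                table.loc[decision.voucher_record_id, col] = merged[col]
            for field_, src in decision.merge_log:
                log_rows.append({
                    "event_key": key,
                    "voucher_record_id": decision.voucher_record_id,
                    "field": field_,
                    "source_record_id": src,
                })
        is_voucher.loc[decision.voucher_record_id] = True
        consensus.loc[group.index] = decision.consensus_taxon

    table["parseGBIF_digital_voucher"] = is_voucher
    table["parseGBIF_consensus_taxon"] = consensus
    table = partition_dataset(table.reset_index(drop=True))
    merge_log = pd.DataFrame(
        log_rows, columns=["event_key", "voucher_record_id", "field", "source_record_id"]
    )
    return ParseResult(data=table, merge_log=merge_log)
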