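"""Output partitioning, dataset summaries and degree-grid taxon richness.

Parsed records fall into three disjoint datasets: ``useable`` (vouchers with a
resolved consensus taxon and spatial data fit for analysis), ``unusable``
(vouchers failing either requirement) and ``duplicate`` (the non-voucher group
members, kept as a quality-control sidecar). Richness grids count distinct
taxa per 1x1-degree cell, indexed by floor of the signed coordinates
(half-open cells, west/south edge inclusive).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gatherparse.ingest import write_occurrence_table
from gatherparse.voucher import UNIDENTIFIED

logger = logging.getLogger(__name__)

USEABLE, UNUSABLE, DUPLICATE = "useable", "unusable", "duplicate"


def coerce_parsed_types(df: pd.DataFrame) -> pd.DataFrame:
    """Restore boolean/integer workflow columns after a text round-trip."""
    out = df.copy()
    for col in ("parseGBIF_digital_voucher", "parseGBIF_key_complete",
                "parseGBIF_unknown_collector"):
        if col in out.columns and out[col].dtype == object:
            out[col] = out[col].map(
                lambda v: v if isinstance(v, bool) else str(v).strip().lower() == "true"
            )
    for col in ("parseGBIF_spatial_score", "parseGBIF_completeness_score",
                "parseGBIF_total_score"):
        if col in out.columns:
            out[col] = out[col].astype(int)
    return out


@dataclass
class ParseResult:
    """Full workflow output: annotated records, merge log, summary counts."""

    data: pd.DataFrame
    merge_log: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["event_key", "voucher_record_id", "field", "source_record_id"]))

    @property
    def useable(self) -> pd.DataFrame:
        return self.data[self.data["parseGBIF_dataset_result"] == USEABLE]

    @property
    def unusable(self) -> pd.DataFrame:
        return self.data[self.data["parseGBIF_dataset_result"] == UNUSABLE]

    @property
    def duplicates(self) -> pd.DataFrame:
        return self.data[self.data["parseGBIF_dataset_result"] == DUPLICATE]


def _coords_present(row: pd.Series) -> bool:
    try:
        float(row["decimalLatitude"]), float(row["decimalLongitude"])
    except (TypeError, ValueError):
        return False
    return True


def partition_dataset(parsed: pd.DataFrame) -> pd.DataFrame:
    """Label each parsed record useable / unusable / duplicate.

    A voucher is useable iff its consensus taxon is resolved (not
    UNIDENTIFIED), its spatial score is above the exclusion threshold (> -9)
    and it carries coordinates. Appends ``parseGBIF_dataset_result``.
    """
    labels = []
    for _, row in parsed.iterrows():
        if not row["parseGBIF_digital_voucher"]:
            labels.append(DUPLICATE)
        elif (
            row["parseGBIF_consensus_taxon"] not in ("", UNIDENTIFIED)
            and int(row["parseGBIF_spatial_score"]) > -9
            and _coords_present(row)
        ):
            labels.append(USEABLE)
        else:
            labels.append(UNUSABLE)
    out = parsed.copy()
    out["parseGBIF_dataset_result"] = labels
    return out


def summarize(result: ParseResult) -> dict:
    """Headline totals plus merge-action and records-per-taxon summaries."""
    data = result.data
    n_records = len(data)
    vouchers = data[data["parseGBIF_digital_voucher"].astype(bool)]
    n_events = len(vouchers)
    n_useable = len(result.useable)
    taxa_all = sorted({
        t for t in vouchers["parseGBIF_consensus_taxon"] if t and t != UNIDENTIFIED
    })
    taxa_useable = sorted({
        t for t in result.useable["parseGBIF_consensus_taxon"] if t and t != UNIDENTIFIED
    })

    def _merge_freq(partition: str) -> dict:
        if result.merge_log.empty:
            return {}
        ids = set(data.loc[data["parseGBIF_dataset_result"] == partition, "gbifID"])
        sub = result.merge_log[result.merge_log["voucher_record_id"].isin(ids)]
        return sub["field"].value_counts().to_dict()

    return {
        "total_records": n_records,
        "unique_collection_events": n_events,
        "duplicate_records": n_records - n_events,
        "useable_records": n_useable,
        "unusable_records": n_events - n_useable,
        "taxa_all": len(taxa_all),
        "taxa_useable": len(taxa_useable),
        "records_per_taxon_all": (n_records / len(taxa_all)) if taxa_all else 0.0,
        "records_per_taxon_useable": (n_useable / len(taxa_useable)) if taxa_useable else 0.0,
        "merge_actions_total": int(len(result.merge_log)),
        "merge_actions_useable": _merge_freq(USEABLE),
        "merge_actions_unusable": _merge_freq(UNUSABLE),
    }


def grid_richness(
    table: pd.DataFrame,
    cell_degrees: float = 1.0,
    taxon_col: str = "parseGBIF_consensus_taxon",
) -> pd.DataFrame:
    """Distinct-taxon counts per grid cell.

    Cells are indexed by ``floor(coord / cell) * cell`` on signed degrees;
    each taxon counts once per cell. Records with unparseable or out-of-range
    coordinates are skipped with a warning. Returns columns
    ``cell_lon, cell_lat, taxon_count``.
    """
    pairs: set[tuple[float, float, str]] = set()
    skipped = 0
    for _, row in table.iterrows():
        taxon = row.get(taxon_col, "")
        if not taxon or taxon == UNIDENTIFIED:
            continue
        try:
            lat = float(row["decimalLatitude"])
            lon = float(row["decimalLongitude"])
        except (TypeError, ValueError):
            skipped += 1
            continue
        if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
            skipped += 1
            continue
        cell_lon = math.floor(lon / cell_degrees) * cell_degrees
        cell_lat = math.floor(lat / cell_degrees) * cell_degrees
        pairs.add((cell_lon, cell_lat, taxon))
    if skipped:
        logger.warning("grid_richness: skipped %d record(s) with invalid coordinates", skipped)
    if not pairs:
        return pd.DataFrame(columns=["cell_lon", "cell_lat", "taxon_count"])
    df = pd.DataFrame(sorted(pairs), columns=["cell_lon", "cell_lat", "taxon"])
    grid = (df.groupby(["cell_lon", "cell_lat"], as_index=False)["taxon"]
              .nunique().rename(columns={"taxon": "taxon_count"}))
    return grid


def richness_percent_difference(grid_a: pd.DataFrame, grid_b: pd.DataFrame) -> pd.DataFrame:
    """Per-cell percent difference 100 * (a - b) / a, relative to grid ``a``.

    Cells absent from one grid count as 0 there; cells where ``a`` is 0 yield
    NaN (the difference is undefined relative to an empty reference cell).
    """
    merged = grid_a.merge(
        grid_b, on=["cell_lon", "cell_lat"], how="outer", suffixes=("_a", "_b")
    )
    a = merged["taxon_count_a"].astype(float).fillna(0)
    b = merged["taxon_count_b"].astype(float).fillna(0)
    merged["taxon_count_a"], merged["taxon_count_b"] = a, b
    merged["percent_difference"] = np.where(a > 0, 100.0 * (a - b) / a, np.nan)
    return merged.sort_values(["cell_lon", "cell_lat"]).reset_index(drop=True)


def export_datasets(result: ParseResult, outdir: str | Path) -> dict[str, Path]:
    """Write the three partitions, the merge log and the summary to ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("useable", result.useable), ("unusable", result.unusable),
                     ("duplicates", result.duplicates)):
        p = out / f"{name}.tsv"
        write_occurrence_table(df, p)
        paths[name] = p
    paths["merge_log"] = out / "merge_log.csv"
    result.merge_log.to_csv(paths["merge_log"], index=False)
    paths["summary"] = out / "summary.json"
    with open(paths["summary"], "w", encoding="utf-8") as fh:
        json.dump(summarize(result), fh, indent=2)
    return paths
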