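"""GBIF issue extraction and spatial-quality selection scoring.

GBIF appends an ``issue`` field listing processing flags. The geospatial
subset of that vocabulary (33 categories in the shipped table) is classed by
its impact on coordinate precision — none, low, medium, exclude — and mapped
onto a selection score of 0, -1, -3 or -9. A record's spatial score is the
worst (minimum) score over its flags; -9 marks the record unsuitable for
spatial analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from gatherparse.errors import ContractError, FormatError

logger = logging.getLogger(__name__)

VALID_SCORES = (0, -1, -3, -9)
IMPACT_TO_SCORE = {"none": 0, "low": -1, "medium": -3, "exclude": -9}


@dataclass(frozen=True)
class IssueScoreTable:
    """Mapping issue token -> (impact class, selection score)."""

    scores: dict[str, int]
    impacts: dict[str, str]

    def __post_init__(self) -> None:
        for token, impact in self.impacts.items():
            expected = IMPACT_TO_SCORE.get(impact)
            if expected is None:
                raise FormatError(f"unknown impact class {impact!r} for {token!r}")
            if self.scores[token] != expected:
                raise FormatError(
                    f"{token!r}: score {self.scores[token]} inconsistent with impact {impact!r}"
                )

    def __len__(self) -> int:
        return len(self.scores)

    def __contains__(self, token: str) -> bool:
        return token in self.scores


def load_issue_scores(path: str | Path | None = None) -> IssueScoreTable:
    """Load an issue-score table from CSV; default is the shipped 33-entry table."""
    if path is None:
        with resources.as_file(resources.files("gatherparse.data") / "issue_scores.csv") as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"issue_token", "impact", "score"}
    if not required.issubset(df.columns):
        raise FormatError(f"issue-score table needs columns {sorted(required)}")
    if df["issue_token"].duplicated().any():
        raise FormatError("issue-score table has duplicate issue tokens")
    return IssueScoreTable(
        scores=dict(zip(df["issue_token"], df["score"].astype(int))),
        impacts=dict(zip(df["issue_token"], df["impact"])),
    )


@dataclass
class IssueMatrix:
    """Per-record issue-token sets plus per-category record counts."""

    tokens_by_record: dict[str, frozenset[str]]
    category_counts: pd.Series = field(repr=False)

    def tokens(self, record_id: str) -> frozenset[str]:
        return self.tokens_by_record.get(record_id, frozenset())


def split_issue_string(raw: str) -> frozenset[str]:
    """Split a semicolon-delimited issue string into a trimmed, uppercased token set."""
    if not raw or not raw.strip():
        return frozenset()
    return frozenset(t.strip().upper() for t in raw.split(";") if t.strip())


def extract_issues(table: pd.DataFrame) -> IssueMatrix:
    """Parse every record's ``issue`` field and tally per-category totals."""
    if "issue" not in table.columns:
        raise ContractError("table lacks an 'issue' column")
    tokens_by_record = {
        rid: split_issue_string(raw)
        for rid, raw in zip(table["gbifID"], table["issue"])
    }
    counts: dict[str, int] = {}
    for toks in tokens_by_record.values():
        for t in toks:
            counts[t] = counts.get(t, 0) + 1
    series = pd.Series(counts, dtype="int64").sort_index()
    return IssueMatrix(tokens_by_record, series)


def spatial_score(tokens: frozenset[str] | set[str], score_table: IssueScoreTable) -> int:
    """Worst (minimum) selection score over the record's scored issue tokens.

    Tokens absent from the score table do not contribute; a record with no
    scored geospatial issue scores 0. Unknown tokens are logged once.
    """
    scored = [score_table.scores[t] for t in tokens if t in score_table]
    unknown = [t for t in tokens if t not in score_table]
    if unknown:
        logger.debug("unscored issue tokens (kept, score 0): %s", ", ".join(sorted(unknown)))
    return min(scored) if scored else 0


def is_spatially_useable(score: int) -> bool:
    """True iff the spatial score does not exclude the record (-9) from spatial analysis."""
    if score not in VALID_SCORES:
        raise ContractError(f"spatial score must be one of {VALID_SCORES}, got {score}")
    return score > -9


def _has_coordinates(lat: str, lon: str) -> bool:
    try:
        float(lat), float(lon)
    except (TypeError, ValueError):
        return False
    return True


def score_table(table: pd.DataFrame, score_table_: IssueScoreTable | None = None) -> pd.DataFrame:
    """Append per-record spatial-quality columns.

    Adds ``parseGBIF_spatial_score`` (worst issue score, with records lacking
    parseable coordinates forced to -9: no coordinates means no spatial
    analysis) and ``parseGBIF_issue_tokens`` (the normalized token set as a
    ``;``-joined string).
    """
    st = score_table_ or load_issue_scores()
    matrix = extract_issues(table)
    out = table.copy()
    scores = []
    joined = []
    for rid, lat, lon in zip(out["gbifID"], out.get("decimalLatitude", ""), out.get("decimalLongitude", "")):
        toks = matrix.tokens(rid)
        s = spatial_score(toks, st)
        if not _has_coordinates(lat, lon):
            s = -9
        scores.append(s)
        joined.append(";".join(sorted(toks)))
    out["parseGBIF_spatial_score"] = scores
    out["parseGBIF_issue_tokens"] = joined
    return out
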