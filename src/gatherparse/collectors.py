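"""Collector-surname extraction and the curated collector dictionary.

``recordedBy`` strings arrive in many dialects ("Gardner, G.",
"G. Gardner", "Müller, K.; Silva, J.", "Gardner et al."). The primary
collector's surname is isolated heuristically, folded to uppercase ASCII,
and used in the collection-event key. A curated dictionary keyed on the raw
string overrides the heuristic and marks rows as human-checked.
"""

from __future__ import annotations

import csv
import re
import unicodedata
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

#: team-suffix phrases stripped before parsing; they never carry the surname
_TEAM_RE = re.compile(r"\b(et\.?\s*al\.?|e\s+outros|and\s+others)\b.*$", re.IGNORECASE)
#: separators between collectors in a team string
_SPLIT_RE = re.compile(r";|\||&|\bwith\b|\band\b|\s\be\b\s|(?:^|\s)\d+\s*[.)]\s", re.IGNORECASE)
_ALLOWED = re.compile(r"^[A-Z][A-Z' -]*$")


def fold_ascii_upper(text: str) -> str:
    """Diacritic-fold to ASCII and uppercase (Müller -> MULLER)."""
    folded = unicodedata.normalize("NFKD", text).encode("ascii", "ignore").decode("ascii")
    return folded.upper()


def extract_primary_surname(recorded_by: str) -> str:
    """Extract the primary collector's surname from a raw ``recordedBy`` string.

    The first collector token is isolated (splitting on ``;``, ``|``, ``&``,
    " and ", numbered-list separators), team suffixes ("et al.") are stripped,
    then: text before the first comma if a comma exists, else the last
    whitespace-delimited word. The result is folded to uppercase ASCII.
    Unparseable input yields the empty string.
    """
    if not recorded_by or not recorded_by.strip():
        return ""
    text = _TEAM_RE.sub("", recorded_by).strip()
    first = _SPLIT_RE.split(text)[0].strip()
    if not first:
        return ""
    if "," in first:
        surname = first.split(",", 1)[0]
    else:
        words = first.split()
        surname = words[-1] if words else ""
    surname = fold_ascii_upper(surname)
    surname = re.sub(r"[^A-Z' -]", "", surname).strip(" '-")
    if not surname or not _ALLOWED.match(surname):
        return ""
    return surname


@dataclass(frozen=True)
class CollectorEntry:
    """One collector-dictionary row, keyed on the raw ``recordedBy`` string."""

    recordedBy_raw: str
    surname_standard: str
    checked: bool = False


def prepare_dictionary(table: pd.DataFrame) -> list[CollectorEntry]:
    """Build dictionary entries for every distinct raw ``recordedBy`` string.

    Surnames are auto-extracted; all new entries are unchecked (pending human
    review). Entries are sorted by raw string for stable output.
    """
    distinct = sorted({v for v in table["recordedBy"] if v})
    return [CollectorEntry(raw, extract_primary_surname(raw), False) for raw in distinct]


def apply_dictionary(table: pd.DataFrame, dictionary: list[CollectorEntry] | None = None) -> pd.DataFrame:
    """Standardize collector surnames, preferring curated dictionary entries.

    Appends ``nameRecordedBy_Standard`` (the surname) and ``CollectorDictionary``
    ('checked' for dictionary hits marked reviewed, else 'unchecked'). Lookup
    is exact on the raw string — never fuzzy — so distinct team strings index
    separately.
    """
    lut = {e.recordedBy_raw: e for e in (dictionary or [])}
    surnames, status = [], []
    cache: dict[str, str] = {}
    for raw in table["recordedBy"]:
        entry = lut.get(raw)
        if entry is not None:
            surnames.append(entry.surname_standard)
            status.append("checked" if entry.checked else "unchecked")
        else:
            if raw not in cache:
                cache[raw] = extract_primary_surname(raw)
            surnames.append(cache[raw])
            status.append("unchecked")
    out = table.copy()
    out["nameRecordedBy_Standard"] = surnames
    out["CollectorDictionary"] = status
    return out


def read_dictionary(path: str | Path) -> list[CollectorEntry]:
    """Read a collector dictionary CSV (``recordedBy_raw,surname_standard,checked``)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        CollectorEntry(r["recordedBy_raw"], r["surname_standard"],
                       r.get("checked", "").strip().lower() in ("true", "1", "yes", "checked"))
        for _, r in df.iterrows()
    ]


def write_dictionary(entries: list[CollectorEntry], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["recordedBy_raw", "surname_standard", "checked"])
        for e in entries:
            w.writerow([e.recordedBy_raw, e.surname_standard, str(e.checked)])
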