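"""Collection-event key construction: FAMILY_SURNAME_COLLECTIONNUMBER.

Duplicates of one gathering share the plant family, the primary collector's
surname and the collector's own collection number; the joined uppercase string
(e.g. ``MYRTACEAE_GARDNER_417``) identifies the unique collection event.
Collection date is deliberately not part of the key: it is too often absent
from occurrence records to be useful. Records whose key is incomplete are
treated as singleton events, never grouped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from gatherparse.collectors import fold_ascii_upper

UNKNOWN_COLLECTOR = "UNKNOWN-COLLECTOR"

_LEADING_MARKER = re.compile(r"^(no\.?|nº|n°|#|n\.)\s*", re.IGNORECASE)
#: sine-numero sentinels (specimen collected without a number)
_SN_SENTINELS = {"SN", "S/N", "SINENUMERO", "SINENUM"}


def normalize_collection_number(record_number: str) -> str:
    """Normalize a collector's collection number for use in the event key.

    Trims whitespace, strips a leading "no."/"nº"/"#" marker, uppercases and
    removes internal spaces. Purely non-alphanumeric input and sine-numero
    sentinels ("s.n.") normalize to the empty string — a shared "s.n." must
    not merge distinct gatherings.
    """
    if not record_number:
        return ""
    text = _LEADING_MARKER.sub("", record_number.strip())
    text = text.upper().replace(" ", "")
    if not any(c.isalnum() for c in text):
        return ""
    if re.sub(r"[^A-Z0-9/]", "", text) in _SN_SENTINELS:
        return ""
    return text


@dataclass(frozen=True)
class CollectionEventKey:
    """A (family, surname, number) key; complete iff all three parts are non-empty."""

    family: str
    surname: str
    number: str
    unknown_collector: bool = False

    @property
    def complete(self) -> bool:
        return bool(self.family and self.surname and self.number)

    @property
    def key_string(self) -> str:
        return f"{self.family}_{self.surname}_{self.number}" if self.complete else ""


def make_event_key(family: str, surname: str, record_number: str) -> CollectionEventKey:
    """Build the event key from its raw parts.

    Family and surname are diacritic-folded and uppercased; the number is
    normalized. An empty surname additionally tags the record
    UNKNOWN-COLLECTOR.
    """
    fam = fold_ascii_upper((family or "").strip()).replace(" ", "")
    sur = fold_ascii_upper((surname or "").strip())
    num = normalize_collection_number(record_number or "")
    return CollectionEventKey(fam, sur, num, unknown_collector=not sur)


def assign_keys(table: pd.DataFrame) -> pd.DataFrame:
    """Append event-key columns to an occurrence table.

    Requires ``family``, ``nameRecordedBy_Standard`` and ``recordNumber``.
    Appends ``parseGBIF_event_key`` (records with incomplete keys receive
    their own record id as a singleton key, so they never share a group),
    ``parseGBIF_key_complete`` and ``parseGBIF_unknown_collector``.
    """
    for col in ("family", "nameRecordedBy_Standard", "recordNumber"):
        if col not in table.columns:
            raise KeyError(f"assign_keys requires column {col!r}")
    keys, complete, unknown = [], [], []
    for rid, fam, sur, num in zip(
        table["gbifID"], table["family"], table["nameRecordedBy_Standard"], table["recordNumber"]
    ):
        k = make_event_key(fam, sur, num)
        keys.append(k.key_string if k.complete else rid)
        complete.append(k.complete)
        unknown.append(k.unknown_collector)
    out = table.copy()
    out["parseGBIF_event_key"] = keys
    out["parseGBIF_key_complete"] = complete
    out["parseGBIF_unknown_collector"] = unknown
    return out
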