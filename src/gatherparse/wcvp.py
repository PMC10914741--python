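"""Scientific-name standardization and reconciliation against a WCVP-style backbone.

The World Checklist of Vascular Plants links plant names to accepted species.
Names are standardized (hybrid separator spacing, infraspecific-rank
abbreviations), matched exactly against ``taxon_name``, and synonyms resolved
one step through ``accepted_plant_name_id``. Matching ignores authorship; when
homonym rows conflict the result is flagged ambiguous rather than guessed.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from gatherparse.errors import FormatError

logger = logging.getLogger(__name__)

#: ranks counted as "at or below the rank of species"
SPECIES_OR_BELOW = {
    "species", "subspecies", "variety", "subvariety", "form", "subform",
    "nothospecies", "nothosubspecies", "nothovariety", "proles",
}

_INFRA_MARKERS = {
    "var": "var.", "variety": "var.",
    "subsp": "subsp.", "ssp": "subsp.", "subspecies": "subsp.",
    "f": "f.", "fo": "f.", "form": "f.", "forma": "f.",
}

_REQUIRED_WCVP_COLUMNS = ("plant_name_id", "taxon_name", "taxon_status", "accepted_plant_name_id")


def load_wcvp(path: str | Path) -> pd.DataFrame:
    """Load a WCVP names export (pipe- or tab-delimited; delimiter auto-detected)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    delim = "|" if header.count("|") >= header.count("\t") and "|" in header else "\t"
    df = pd.read_csv(path, sep=delim, dtype=str, keep_default_na=False,
                     quoting=csv.QUOTE_NONE, encoding="utf-8")
    missing = [c for c in ("taxon_name", "taxon_status") if c not in df.columns]
    if missing:
        raise FormatError(f"WCVP table lacks required column(s): {', '.join(missing)}")
    for col in _REQUIRED_WCVP_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    logger.info("loaded WCVP table: %d rows, %d columns", len(df), df.shape[1])
    return df


_WS = re.compile(r"\s+")
# an epithet glued to the hybrid sign. "×" is unambiguous; a plain "x" only
# counts when followed by a consonant, so genuine x-initial epithets
# (xanthocarpa, xerophila — always x + vowel) are left intact
_HYBRID_GLUED = re.compile(r"^(?:×([a-zà-ÿ][a-zà-ÿ-]+)|x([b-df-hj-np-tv-zà-ÿ][a-zà-ÿ-]+))$")


def standardize_scientific_name(raw: str) -> str:
    """Standardize a scientific-name string toward the WCVP format.

    Collapses whitespace, separates the hybrid sign from a glued epithet
    (``Salix xfragilis`` -> ``Salix x fragilis``) and normalizes
    infraspecific-rank markers to ``var.`` / ``subsp.`` / ``f.``. All other
    tokens are preserved as-is. Idempotent.
    """
    if not raw:
        return ""
    tokens = _WS.sub(" ", raw.strip()).split(" ")
    out: list[str] = []
    for i, tok in enumerate(tokens):
        prev_is_genus = i == 1 and tokens[0][:1].isupper()
        if tok == "×":
            out.append("x")
            continue
        if prev_is_genus:
            m = _HYBRID_GLUED.match(tok)
            if m:
                out.extend(["x", m.group(1) or m.group(2)])
                continue
        # rank markers only count when they introduce a lowercase epithet
        bare = tok.lower().rstrip(".")
        if bare in _INFRA_MARKERS and i + 1 < len(tokens) and tokens[i + 1][:1].islower():
            out.append(_INFRA_MARKERS[bare])
            continue
        out.append(tok)
    return " ".join(out)


@dataclass(frozen=True)
class NameCheckResult:
    """Outcome of reconciling one name against the backbone."""

    input_name: str
    standardized_name: str
    match_status: str  # matched_accepted | matched_synonym_resolved | ambiguous | unmatched
    wcvp_plant_name_id: str = ""
    accepted_taxon_name: str = ""
    accepted_plant_name_id: str = ""
    taxon_rank: str = ""
    binomial_fallback: bool = False


def _match_exact(name: str, wcvp: pd.DataFrame) -> pd.DataFrame:
    return wcvp[wcvp["taxon_name"] == name]


def _resolve(input_name: str, std: str, rows: pd.DataFrame, wcvp: pd.DataFrame,
             fallback: bool) -> NameCheckResult:
    accepted = rows[rows["taxon_status"] == "Accepted"]
    if len(accepted) == 1:
        r = accepted.iloc[0]
        return NameCheckResult(input_name, std, "matched_accepted",
                               r["plant_name_id"], r["taxon_name"], r["plant_name_id"],
                               r.get("taxon_rank", ""), fallback)
    if len(accepted) > 1:
        return NameCheckResult(input_name, std, "ambiguous", binomial_fallback=fallback)
    # no accepted homonym: try one-step synonym resolution
    targets = set(rows["accepted_plant_name_id"]) - {""}
    if len(targets) != 1:
        return NameCheckResult(input_name, std, "ambiguous", binomial_fallback=fallback)
    target_id = targets.pop()
    target = wcvp[wcvp["plant_name_id"] == target_id]
    # a synonym chaining to another synonym is reported, not chased
    if len(target) != 1 or target.iloc[0]["taxon_status"] != "Accepted":
        return NameCheckResult(input_name, std, "ambiguous", binomial_fallback=fallback)
    t = target.iloc[0]
    return NameCheckResult(input_name, std, "matched_synonym_resolved",
                           rows.iloc[0]["plant_name_id"], t["taxon_name"],
                           t["plant_name_id"], t.get("taxon_rank", ""), fallback)


def check_name(name: str, wcvp: pd.DataFrame) -> NameCheckResult:
    """Reconcile one scientific name against the backbone.

    Exact match on the standardized string; if the full (infraspecific) string
    misses, the binomial is retried and the fallback recorded.
    """
    std = standardize_scientific_name(name)
    if not std:
        return NameCheckResult(name, std, "unmatched")
    rows = _match_exact(std, wcvp)
    fallback = False
    if rows.empty and len(std.split(" ")) > 2:
        binomial = " ".join(std.split(" ")[:2])
        rows = _match_exact(binomial, wcvp)
        fallback = not rows.empty
    if rows.empty:
        return NameCheckResult(name, std, "unmatched")
    return _resolve(name, std, rows, wcvp, fallback)


#: columns appended by check_name_batch, in order
WCVP_COLUMNS = (
    "wcvp_standardized_name", "wcvp_match_status", "wcvp_plant_name_id",
    "wcvp_accepted_taxon_name", "wcvp_accepted_plant_name_id",
    "wcvp_taxon_rank", "wcvp_binomial_fallback",
)


def check_name_batch(occ: pd.DataFrame, wcvp: pd.DataFrame) -> pd.DataFrame:
    """Annotate an occurrence table with name-check results.

    Each distinct ``scientificName`` is checked once and the result broadcast;
    appended columns are prefixed ``wcvp_``. Row count and order unchanged.
    """
    if "scientificName" not in occ.columns:
        raise FormatError("occurrence table lacks 'scientificName'")
    cache = {n: check_name(n, wcvp) for n in occ["scientificName"].unique()}
    out = occ.copy()
    res = [cache[n] for n in occ["scientificName"]]
    out["wcvp_standardized_name"] = [r.standardized_name for r in res]
    out["wcvp_match_status"] = [r.match_status for r in res]
    out["wcvp_plant_name_id"] = [r.wcvp_plant_name_id for r in res]
    out["wcvp_accepted_taxon_name"] = [r.accepted_taxon_name for r in res]
    out["wcvp_accepted_plant_name_id"] = [r.accepted_plant_name_id for r in res]
    out["wcvp_taxon_rank"] = [r.taxon_rank for r in res]
    out["wcvp_binomial_fallback"] = [str(r.binomial_fallback) for r in res]
    return out
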