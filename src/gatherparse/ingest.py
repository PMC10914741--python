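"""Reading, validating and column-subsetting GBIF occurrence downloads.

GBIF "simple" downloads are tab-delimited UTF-8 text with a header row and no
quoting (a literal ``"`` is data; embedded tabs cannot occur). Records are
keyed by ``gbifID``. Two field profiles are shipped as versioned config:
``standard`` (54 columns, the fields the parsing workflow needs) and ``all``
(257 columns, the full interpreted download).
"""

from __future__ import annotations

import csv
import logging
import shutil
import urllib.error
import urllib.request
import zipfile
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from gatherparse.errors import FormatError, NetworkError

logger = logging.getLogger(__name__)

RECORD_ID = "gbifID"

#: raw tokens canonicalized to the empty string on read
MISSING_TOKENS = ("", "NA", r"\N", "NaN", "nan", "null", "NULL")


@dataclass(frozen=True)
class FieldProfile:
    """A named, ordered set of Darwin Core / GBIF column names."""

    name: str
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.columns)) != len(self.columns):
            raise ValueError(f"profile {self.name!r} has duplicate column names")


def _load_profile_file(fname: str) -> tuple[str, ...]:
    text = resources.files("gatherparse.data").joinpath(fname).read_text("utf-8")
    return tuple(line.strip() for line in text.splitlines() if line.strip())


def get_profile(name: str) -> FieldProfile:
    """Return a shipped field profile by name (``standard`` or ``all``)."""
    if name not in ("standard", "all"):
        raise ValueError(f"unknown profile {name!r}; expected 'standard' or 'all'")
    return FieldProfile(name, _load_profile_file(f"{name}_profile.txt"))


def _canonicalize_missing(df: pd.DataFrame) -> pd.DataFrame:
    return df.replace(list(MISSING_TOKENS), "")


def read_occurrence_table(path: str | Path, profile: FieldProfile | str | None = None) -> pd.DataFrame:
    """Read a GBIF occurrence TSV, optionally restricted to a field profile.

    Missing profile columns are created empty (with a logged warning); mixed
    missing-value spellings (``NA``, ``\\N`` ...) are canonicalized to the
    empty string. All cells are text.
    """
    if isinstance(profile, str):
        profile = get_profile(profile)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype=str,
            keep_default_na=False,
            quoting=csv.QUOTE_NONE,
            encoding="utf-8",
        )
    except OSError as exc:
        raise IOError(f"cannot read occurrence file {path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path} has no header row") from exc
    if RECORD_ID not in df.columns:
        raise FormatError(f"{path} lacks the {RECORD_ID!r} record-id column")
    df = _canonicalize_missing(df)
    if profile is not None:
        df = select_fields(df, profile, warn_missing=True)
    return df


def select_fields(table: pd.DataFrame, profile: FieldProfile | str, warn_missing: bool = False) -> pd.DataFrame:
    """Project the table onto the profile's columns, preserving profile order.

    Columns absent from the input are created empty. Row content on shared
    columns is unchanged.
    """
    if isinstance(profile, str):
        profile = get_profile(profile)
    missing = [c for c in profile.columns if c not in table.columns]
    if missing and warn_missing:
        logger.warning(
            "input lacks %d profile column(s), created empty: %s",
            len(missing), ", ".join(missing),
        )
    out = table.copy()
    if missing:
        empty = pd.DataFrame({col: [""] * len(out) for col in missing}, index=out.index)
        out = pd.concat([out, empty], axis=1)
    return out[list(profile.columns)]


def write_occurrence_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write in the GBIF TSV dialect (no quoting, UTF-8, header row)."""
    table.to_csv(path, sep="\t", index=False, quoting=csv.QUOTE_NONE, encoding="utf-8")


def fetch_archive(doi_url: str, dest_dir: str | Path, timeout: float = 60.0) -> Path:
    """Download and unzip a GBIF occurrence archive; return the occurrence file path.

    The archive must contain a tab-delimited occurrence table (``occurrence.txt``
    in a Darwin Core archive, or a single ``*.csv``/``*.txt`` member in a simple
    download).
    """
    dest = Path(dest_dir)
    dest.mkdir(parents=True, exist_ok=True)
    zip_path = dest / "gbif_download.zip"
    try:
        with urllib.request.urlopen(doi_url, timeout=timeout) as resp, open(zip_path, "wb") as fh:
            shutil.copyfileobj(resp, fh)
    except (urllib.error.URLError, OSError, ValueError) as exc:
        raise NetworkError(f"download of {doi_url} failed (retriable): {exc}") from exc
    try:
        with zipfile.ZipFile(zip_path) as zf:
            zf.extractall(dest)
            names = zf.namelist()
    except zipfile.BadZipFile as exc:
        raise FormatError(f"{doi_url} did not return a zip archive") from exc
    candidates = [n for n in names if Path(n).name == "occurrence.txt"]
    if not candidates:
        candidates = [n for n in names if n.lower().endswith((".csv", ".txt"))]
    if not candidates:
        raise FormatError("archive contains no occurrence table")
    return dest / candidates[0]
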