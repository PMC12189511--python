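"""Reading, validation and writing of the tabular inputs and result tables.

Three input tables drive every analysis:

* **measurements** — one row per bead x serum sample x Luminex run, carrying
  the raw MFI (mean fluorescence intensity) together with run, lot and
  patient metadata;
* **bead catalog** — per lot, the HLA allele(s) each bead is coated with and
  the locus group it is reported under (dual-coated class II beads carry an
  alpha/beta pair such as ``DQA1*02:01+DQB1*02:02``);
* **typing** — each patient's own two-field HLA alleles, used to identify
  self-allele beads whose signal reflects assay background rather than
  alloantibody.

The canonical on-disk dialect is plain comma-separated UTF-8 with a header
row, ``.`` as the decimal mark and ISO-8601 dates.  Dual-coated allele pairs
are serialized with an ASCII ``+`` separator; typing allele sets with ``;``.
Readers reject malformed rows with row-numbered diagnostics; writers emit a
deterministic row and column order so that write-then-read is the identity.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The nine locus groups a bead can be reported under.
LOCUS_GROUPS: tuple[str, ...] = (
    "A", "B", "C",
    "DRB1", "DRB3", "DRB4", "DRB5",
    "DQA1/DQB1", "DPA1/DPB1",
)

#: Locus groups whose beads belong to the class I assay.
CLASS_I_GROUPS: tuple[str, ...] = ("A", "B", "C")

#: Locus groups that may carry dual-coated (alpha/beta heterodimer) beads.
DUAL_COAT_GROUPS: tuple[str, ...] = ("DQA1/DQB1", "DPA1/DPB1")

#: Separator used to serialize a dual-coated allele pair in CSV.
ALLELE_PAIR_SEP = "+"

MEASUREMENT_COLUMNS = (
    "patient_id", "sample_id", "run_id", "run_date", "lot_id",
    "bead_id", "assay_class", "raw_mfi", "is_control_bead",
)
CATALOG_COLUMNS = ("lot_id", "bead_id", "alleles", "locus_group")
TYPING_COLUMNS = ("patient_id", "alleles")

MEASUREMENT_KEY = ["patient_id", "sample_id", "run_id", "bead_id"]


class SchemaError(ValueError):
    """The file is structurally unusable (missing columns, empty, ...)."""


class RowValidationError(ValueError):
    """One or more rows violated the table invariants.

    Attributes
    ----------
    errors : list of (row_number, message)
        1-based data row numbers (header excluded) with a description.
    """

    def __init__(self, table: str, errors: list[tuple[int, str]]):
        self.errors = errors
        shown = "; ".join(f"row {i}: {msg}" for i, msg in errors[:10])
        more = "" if len(errors) <= 10 else f" (+{len(errors) - 10} more)"
        super().__init__(f"{table}: {len(errors)} invalid row(s): {shown}{more}")


def _require_columns(df: pd.DataFrame, required: Sequence[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}; "
                          f"found {list(df.columns)}")


def is_valid_allele(name: str) -> bool:
    """Syntactic check for a two-field allele name, ``LOCUS*NN:NN``."""
    if not isinstance(name, str) or "*" not in name:
        return False
    locus, _, fields = name.partition("*")
    if not locus or not locus[0].isalpha():
        return False
    parts = fields.split(":")
    if len(parts) != 2:
        return False
    return all(p.isdigit() and len(p) >= 2 for p in parts)


def parse_allele_field(text: str) -> tuple[str, ...]:
    """Parse a catalog ``alleles`` cell into a tuple of 1 or 2 allele names."""
    parts = tuple(p.strip() for p in str(text).split(ALLELE_PAIR_SEP))
    if not all(parts):
        raise ValueError(f"empty allele in {text!r}")
    for p in parts:
        if not is_valid_allele(p):
            raise ValueError(f"malformed allele name {p!r}")
    if len(parts) > 2:
        raise ValueError(f"more than two coated alleles in {text!r}")
    return parts


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read and validate a bead-level measurement table.

    Returns a DataFrame with the canonical columns, ``run_date`` parsed to
    ``datetime64``, ``raw_mfi`` as float (values <= 0 are accepted at ingest;
    a floor policy is applied downstream) and ``is_control_bead`` as bool.

    Raises
    ------
    SchemaError
        If the file lacks a required column.
    RowValidationError
        Listing every row with an unparseable MFI/date/flag, a blank key
        field, an unknown assay class, or a duplicated
        (patient, sample, run, bead) key.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, MEASUREMENT_COLUMNS, "measurements")
    df = df.loc[:, list(MEASUREMENT_COLUMNS)].copy()

    errors: list[tuple[int, str]] = []
    rownum = df.index + 1

    for col in ("patient_id", "sample_id", "run_id", "lot_id", "bead_id"):
        for i in df.index[df[col].str.strip() == ""]:
            errors.append((int(rownum[i]), f"blank {col}"))

    mfi = pd.to_numeric(df["raw_mfi"], errors="coerce")
    for i in df.index[mfi.isna()]:
        errors.append((int(rownum[i]), f"unparseable raw_mfi {df.at[i, 'raw_mfi']!r}"))

    dates = pd.to_datetime(df["run_date"], format="%Y-%m-%d", errors="coerce")
    for i in df.index[dates.isna()]:
        errors.append((int(rownum[i]), f"unparseable ISO date {df.at[i, 'run_date']!r}"))

    bad_class = ~df["assay_class"].isin(["I", "II"])
    for i in df.index[bad_class]:
        errors.append((int(rownum[i]), f"assay_class must be I or II, got {df.at[i, 'assay_class']!r}"))

    flag = df["is_control_bead"].str.strip().str.lower()
    flag_map = {"true": True, "false": False, "1": True, "0": False}
    for i in df.index[~flag.isin(flag_map)]:
        errors.append((int(rownum[i]), f"unparseable is_control_bead {df.at[i, 'is_control_bead']!r}"))

    for i in df.index[df.duplicated(MEASUREMENT_KEY, keep="first")]:
        key = tuple(df.loc[i, MEASUREMENT_KEY])
        errors.append((int(rownum[i]), f"duplicate measurement key {key}"))

    # one bead must not switch assay class within a lot
    probe = df.loc[~bad_class].groupby(["lot_id", "bead_id"])["assay_class"].nunique()
    for (lot, bead) in probe.index[probe > 1]:
        first = df.index[(df["lot_id"] == lot) & (df["bead_id"] == bead)][0]
        errors.append((int(rownum[first]),
                       f"bead {bead!r} has inconsistent assay_class within lot {lot!r}"))

    if errors:
        errors.sort()
        raise RowValidationError("measurements", errors)

    out = df.assign(
        run_date=dates,
        raw_mfi=mfi.astype(float),
        is_control_bead=flag.map(flag_map).astype(bool),
    )
    logger.info("measurements: accepted %d rows, rejected 0 (%s)", len(out), path.name)
    return out.reset_index(drop=True)


def read_bead_catalog(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-lot bead catalog.

    The ``alleles`` column is parsed into tuples of 1 or 2 allele names;
    dual-coated entries are only legal in the DQA1/DQB1 and DPA1/DPB1 groups,
    and single-coated class I beads only in groups A/B/C.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, CATALOG_COLUMNS, "bead_catalog")
    df = df.loc[:, list(CATALOG_COLUMNS)].copy()

    errors: list[tuple[int, str]] = []
    alleles: list[tuple[str, ...] | None] = []
    for i in df.index:
        row = int(i) + 1
        group = df.at[i, "locus_group"]
        if group not in LOCUS_GROUPS:
            errors.append((row, f"unknown locus_group {group!r}"))
            alleles.append(None)
            continue
        try:
            parsed = parse_allele_field(df.at[i, "alleles"])
        except ValueError as exc:
            errors.append((row, str(exc)))
            alleles.append(None)
            continue
        if len(parsed) == 2 and group not in DUAL_COAT_GROUPS:
            errors.append((row, f"dual-coated bead not allowed in group {group!r}"))
        alleles.append(parsed)
    dup = df.duplicated(["lot_id", "bead_id"], keep="first")
    for i in df.index[dup]:
        errors.append((int(i) + 1, f"duplicate (lot_id, bead_id) "
                                   f"{(df.at[i, 'lot_id'], df.at[i, 'bead_id'])}"))
    if errors:
        errors.sort()
        raise RowValidationError("bead_catalog", errors)

    out = df.assign(alleles=alleles)
    logger.info("bead_catalog: accepted %d rows (%s)", len(out), path.name)
    return out.reset_index(drop=True)


def read_typing(path: str | Path) -> pd.DataFrame:
    """Read and validate a patient HLA typing table.

    ``alleles`` is a ``;``-separated list in the file and a ``frozenset`` of
    two-field allele names in memory.  Empty allele lists are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, TYPING_COLUMNS, "typing")
    df = df.loc[:, list(TYPING_COLUMNS)].copy()

    errors: list[tuple[int, str]] = []
    sets: list[frozenset[str] | None] = []
    for i in df.index:
        row = int(i) + 1
        if df.at[i, "patient_id"].strip() == "":
            errors.append((row, "blank patient_id"))
        raw = [a.strip() for a in df.at[i, "alleles"].split(";") if a.strip()]
        if not raw:
            errors.append((row, "empty allele list"))
            sets.append(None)
            continue
        bad = [a for a in raw if not is_valid_allele(a)]
        if bad:
            errors.append((row, f"malformed allele name(s) {bad}"))
            sets.append(None)
            continue
        sets.append(frozenset(raw))
    dup = df.duplicated("patient_id", keep="first")
    for i in df.index[dup]:
        errors.append((int(i) + 1, f"duplicate patient_id {df.at[i, 'patient_id']!r}"))
    if errors:
        errors.sort()
        raise RowValidationError("typing", errors)

    out = df.assign(alleles=sets)
    logger.info("typing: accepted %d rows (%s)", len(out), path.name)
    return out.reset_index(drop=True)


def _serialize_for_write(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Return a copy with collection columns serialized and the sort keys."""
    df = table.copy()
    if "alleles" in df.columns:
        def ser(v: object) -> str:
            if isinstance(v, (frozenset, set)):
                return ";".join(sorted(v))
            if isinstance(v, (tuple, list)):
                return ALLELE_PAIR_SEP.join(v)
            return str(v)
        df["alleles"] = df["alleles"].map(ser)
    if "run_date" in df.columns:
        df["run_date"] = pd.to_datetime(df["run_date"]).dt.strftime("%Y-%m-%d")
    cols = list(df.columns)
    if set(MEASUREMENT_COLUMNS) <= set(cols):
        keys = ["run_date", "run_id", "patient_id", "sample_id", "bead_id"]
    elif set(CATALOG_COLUMNS) <= set(cols):
        keys = ["lot_id", "bead_id"]
    elif set(TYPING_COLUMNS) == set(cols):
        keys = ["patient_id"]
    else:
        keys = [c for c in cols if df[c].dtype == object] or cols[:1]
    return df, keys


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write any package table as canonical CSV.

    Rows are sorted by the table's natural key (all string columns for ad-hoc
    result tables), columns keep their order, floats use ``repr`` precision so
    re-reading reproduces the values exactly.
    """
    df, keys = _serialize_for_write(table)
    df = df.sort_values(keys, kind="mergesort").reset_index(drop=True)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n")


def exclude_controls(measurements: pd.DataFrame) -> pd.DataFrame:
    """Drop control-bead rows; analyses operate on antigen beads only."""
    return measurements.loc[~measurements["is_control_bead"]].reset_index(drop=True)
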