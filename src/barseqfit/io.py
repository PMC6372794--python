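"""Tab-separated file formats and FASTQ output.

All tables are TSV, UTF-8, no quoting:

* pool:   ``barcode scaffold strand position locus orf_fraction`` —
  ``orf_fraction`` empty for intergenic insertions; unknown extra columns
  are preserved on round trip.
* counts: ``barcode <sample_id> ...``
* sheet:  ``sample_id condition passage replicate is_reference``
* truth:  ``locus class growth_penalty capture_1 .. capture_P``

Reading validates invariants (unique barcodes, nonnegative counts, a single
reference group) and raises distinct named errors.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DuplicateBarcodeError,
    MissingColumnError,
    NegativeCountError,
    SampleSheetError,
)

INTERGENIC = "intergenic"

POOL_COLUMNS = ["barcode", "scaffold", "strand", "position", "locus", "orf_fraction"]
SHEET_COLUMNS = ["sample_id", "condition", "passage", "replicate", "is_reference"]
CONDITIONS = ("control", "cheesecloth")


def _require(df: pd.DataFrame, columns, what: str, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{what} file {path}: missing column(s) {missing}")


# ---------------------------------------------------------------- pool


def validate_pool(pool: pd.DataFrame) -> None:
    dup = pool["barcode"][pool["barcode"].duplicated()]
    if len(dup):
        raise DuplicateBarcodeError(f"duplicate barcode(s): {sorted(set(dup))[:5]}")
    is_gene = pool["locus"] != INTERGENIC
    frac = pool["orf_fraction"]
    if frac[is_gene].isna().any():
        raise MissingColumnError("orf_fraction missing for a genic insertion")
    if frac[~is_gene].notna().any():
        raise MissingColumnError("orf_fraction present for an intergenic insertion")


def read_pool(path) -> pd.DataFrame:
    pool = pd.read_csv(path, sep="\t", dtype={"barcode": str, "locus": str})
    _require(pool, POOL_COLUMNS, "pool", path)
    pool["position"] = pool["position"].astype(int)
    pool["orf_fraction"] = pd.to_numeric(pool["orf_fraction"], errors="coerce")
    validate_pool(pool)
    return pool


def write_pool(pool: pd.DataFrame, path) -> None:
    validate_pool(pool)
    out = pool.copy()
    # keep required columns first, preserve any extras in their order
    extras = [c for c in out.columns if c not in POOL_COLUMNS]
    out = out[POOL_COLUMNS + extras]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- counts


def read_counts(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t")
    _require(counts, ["barcode"], "counts", path)
    counts = counts.set_index("barcode")
    if counts.index.duplicated().any():
        raise DuplicateBarcodeError(f"counts file {path}: duplicate barcode rows")
    for col in counts.columns:
        bad = counts.index[counts[col] < 0]
        if len(bad):
            raise NegativeCountError(
                f"counts file {path}: negative count at row {bad[0]!r}, column {col!r}"
            )
    return counts.astype("int64")


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=True, index_label="barcode")


# ---------------------------------------------------------------- sheet


def validate_sheet(sheet: pd.DataFrame) -> None:
    triples = sheet[["condition", "passage", "replicate"]].apply(tuple, axis=1)
    if triples.duplicated().any():
        raise SampleSheetError("duplicate (condition, passage, replicate) triple")
    bad_cond = set(sheet["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise SampleSheetError(f"unknown condition(s): {sorted(bad_cond)}")
    ref = sheet[sheet["is_reference"]]
    if ref.empty:
        raise SampleSheetError("no reference samples designated")
    ref_groups = set(zip(ref["condition"], ref["passage"]))
    if ref_groups != {("control", int(ref["passage"].iloc[0]))} or len(ref_groups) != 1:
        raise SampleSheetError(
            f"reference must be a single control-condition passage group, got {ref_groups}"
        )
    # every sample of the reference (condition, passage) group must be reference
    cond, pas = next(iter(ref_groups))
    group = sheet[(sheet["condition"] == cond) & (sheet["passage"] == pas)]
    if not group["is_reference"].all():
        raise SampleSheetError("reference group partially flagged")


def read_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "condition": str, "replicate": str}
    )
    _require(sheet, SHEET_COLUMNS, "sample sheet", path)
    sheet["passage"] = sheet["passage"].astype(int)
    if sheet["is_reference"].dtype != bool:
        sheet["is_reference"] = (
            sheet["is_reference"].astype(str).str.lower().map({"true": True, "false": False})
        )
        if sheet["is_reference"].isna().any():
            raise SampleSheetError(f"sheet {path}: is_reference must be true/false")
    validate_sheet(sheet)
    return sheet


def write_sheet(sheet: pd.DataFrame, path) -> None:
    validate_sheet(sheet)
    out = sheet[SHEET_COLUMNS].copy()
    out["is_reference"] = np.where(out["is_reference"], "true", "false")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- truth labels


def read_truth(path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t", dtype={"locus": str, "class": str})
    _require(truth, ["locus", "class", "growth_penalty"], "truth", path)
    return truth


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- fastq


def write_fastq(records, path) -> None:
    """Write (read_id, sequence, quality) triples as 4-line FASTQ records."""
    with open(path, "w") as handle:
        for read_id, seq, qual in records:
            handle.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def ensure_dir(path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    return path
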