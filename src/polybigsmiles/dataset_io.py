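"""Batch readers/writers mirroring the published dataset layout.

Tables arrive as txt (one SMILES per line), csv or xlsx with a SMILES
column and optionally BigSMILES, glass-transition temperature ("Tg (C)" or
"Tg (K) exp") and polymer-name columns.  Converted batches are written as
csv chunks of ``chunk_size`` records with offset nomenclature
(``stem_0.csv``, ``stem_100000.csv``, ...), the published convention for
the large machine-generated dataset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .classify_convert import EndGroupPatternTable, convert
from .bigsmiles_parse import to_smiles
from . import smiles_core as sc
from .errors import PolyBigSmilesError, RejectedInput

logger = logging.getLogger(__name__)

__all__ = ["DatasetRow", "ConversionReport", "load_table", "convert_batch"]

_TG_COLUMNS = ("Tg (C)", "Tg (K) exp", "Tg")
_NAME_COLUMNS = ("Polymer name", "polymer_name", "Name")
_BIGSMILES_COLUMNS = ("BigSMILES", "bigsmiles")


@dataclass(frozen=True)
class DatasetRow:
    smiles: Optional[str] = None
    bigsmiles: Optional[str] = None
    tg: Optional[float] = None
    tg_label: Optional[str] = None
    polymer_name: Optional[str] = None

    def __post_init__(self):
        if self.smiles is None and self.bigsmiles is None:
            raise ValueError("row needs a SMILES or a BigSMILES")
        if self.tg is not None and not math.isfinite(self.tg):
            raise ValueError("Tg must be finite")


@dataclass
class ConversionReport:
    """Per-batch outcome; ``n_input = n_converted + sum(rejections)``."""

    n_input: int = 0
    n_converted: int = 0
    n_rejected_by_reason: dict[str, int] = field(default_factory=dict)
    n_roundtrip_pass: int = 0

    @property
    def n_rejected(self) -> int:
        return sum(self.n_rejected_by_reason.values())

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_converted": self.n_converted,
            "n_rejected_by_reason": dict(self.n_rejected_by_reason),
            "n_roundtrip_pass": self.n_roundtrip_pass,
        }


def _first_present(columns, candidates):
    for c in candidates:
        if c in columns:
            return c
    return None


def load_table(path, format: Optional[str] = None,
               smiles_column: str = "SMILES",
               max_rows: Optional[int] = None,
               max_len: int = 85) -> list[DatasetRow]:
    """Load rows from a txt/csv/xlsx table.

    Rows whose SMILES exceeds ``max_len`` characters are dropped (default
    85, the published length cutoff for practically feasible repeat
    units); at most ``max_rows`` of the remainder are returned.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "txt":
        lines = [ln.strip() for ln in
                 path.read_text(encoding="utf-8").splitlines() if ln.strip()]
        if lines and lines[0] == smiles_column:
            lines = lines[1:]
        df = pd.DataFrame({smiles_column: lines})
    elif fmt == "csv":
        df = pd.read_csv(path)
    elif fmt in ("xlsx", "xls"):
        df = pd.read_excel(path)
    else:
        raise ValueError(f"unsupported format {fmt!r} (txt, csv, xlsx)")

    big_col = _first_present(df.columns, _BIGSMILES_COLUMNS)
    if smiles_column not in df.columns:
        if big_col is None:
            raise KeyError(
                f"column {smiles_column!r} not found in {path.name} "
                f"(columns: {list(df.columns)})")
        smiles_series = pd.Series([None] * len(df))
    else:
        smiles_series = df[smiles_column]
    tg_col = _first_present(df.columns, _TG_COLUMNS)
    name_col = _first_present(df.columns, _NAME_COLUMNS)

    rows: list[DatasetRow] = []
    for i in range(len(df)):
        smiles = smiles_series.iloc[i]
        smiles = None if pd.isna(smiles) else str(smiles)
        if smiles is not None and len(smiles) > max_len:
            continue
        big = df[big_col].iloc[i] if big_col else None
        big = None if big is None or pd.isna(big) else str(big)
        tg = df[tg_col].iloc[i] if tg_col else None
        tg = None if tg is None or pd.isna(tg) else float(tg)
        name = df[name_col].iloc[i] if name_col else None
        name = None if name is None or pd.isna(name) else str(name)
        rows.append(DatasetRow(smiles=smiles, bigsmiles=big, tg=tg,
                               tg_label=tg_col, polymer_name=name))
        if max_rows is not None and len(rows) >= max_rows:
            break
    return rows


def convert_batch(rows: Sequence[DatasetRow], outdir,
                  chunk_size: int = 100_000, stem: str = "bigsmiles",
                  move_parallel: int = -1,
                  table: Optional[EndGroupPatternTable] = None,
                  ) -> tuple[list[Path], ConversionReport]:
    """Convert rows and write csv chunks with offset nomenclature.

    Rejected rows are tallied in the report (with their reasons logged),
    not written to the output.  Each converted row is also round-tripped
    (BigSMILES → SMILES → cycle key) for the report.
    """
    if not rows:
        raise ValueError("convert_batch requires at least one row")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    report = ConversionReport(n_input=len(rows))
    converted: list[dict] = []
    for i, row in enumerate(rows):
        if row.smiles is None:
            report.n_rejected_by_reason["missing_smiles"] = \
                report.n_rejected_by_reason.get("missing_smiles", 0) + 1
            continue
        try:
            rec = convert(row.smiles, table=table,
                          move_parallel=move_parallel)
        except RejectedInput as exc:
            logger.info("row %d rejected (%s): %s", i, exc.reason,
                        row.smiles)
            report.n_rejected_by_reason[exc.reason] = \
                report.n_rejected_by_reason.get(exc.reason, 0) + 1
            continue
        except PolyBigSmilesError as exc:
            logger.warning("row %d failed (%s): %s", i, exc, row.smiles)
            report.n_rejected_by_reason["error"] = \
                report.n_rejected_by_reason.get("error", 0) + 1
            continue
        report.n_converted += 1
        try:
            ok = sc.cycle_key(to_smiles(rec.text)) == \
                sc.cycle_key(sc.normalize(row.smiles))
        except PolyBigSmilesError:
            ok = False
        if ok:
            report.n_roundtrip_pass += 1
        out = {}
        if row.polymer_name is not None:
            out["Polymer name"] = row.polymer_name
        out["SMILES"] = row.smiles
        out["BigSMILES"] = rec.text
        if row.tg is not None:
            out[row.tg_label or "Tg"] = row.tg
        converted.append(out)

    paths: list[Path] = []
    for offset in range(0, len(converted), chunk_size):
        chunk = converted[offset:offset + chunk_size]
        path = outdir / f"{stem}_{offset}.csv"
        pd.DataFrame(chunk).to_csv(path, index=False)
        paths.append(path)
    return paths, report
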