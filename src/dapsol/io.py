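"""Typed CSV readers/writers for all pipeline tables, plus the bundled dataset.

All files are plain CSV/TSV with dot decimals and one header line;
temperatures are always kelvin and mole fractions are stored at natural scale
(the published dapsone table prints x*10^4; the bundled fixture converted
those values once, at fixture build).  Readers validate ranges and report
offending row numbers; duplicate (solvent, fraction, T, source) keys are
rejected.
"""

from __future__ import annotations

import warnings
from importlib import resources
from typing import Iterable

import pandas as pd

from .curation import ConsensusTable, SolubilityRecord

SOLUBILITY_COLUMNS = (
    "solute_id",
    "solvent_id",
    "solvent_fraction",
    "T",
    "x",
    "s",
    "sd_x",
    "source",
)

__all__ = [
    "SOLUBILITY_COLUMNS",
    "read_solubility_csv",
    "write_solubility_csv",
    "write_consensus_csv",
    "read_descriptor_csv",
    "write_descriptor_csv",
    "load_dapsone_table1",
]


def read_solubility_csv(path) -> list[SolubilityRecord]:
    """Read solubility records, validating every row.

    Temperatures must be positive, mole fractions in (0, 1); violations are
    reported with their (1-based, data) row numbers.  An empty file yields an
    empty list with a warning.
    """
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path}: no data rows", stacklevel=2)
        return []
    missing = [c for c in ("solute_id", "solvent_id", "T", "x") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records: list[SolubilityRecord] = []
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        try:
            rec = SolubilityRecord(
                solute_id=str(d["solute_id"]),
                solvent_id=str(d["solvent_id"]),
                T=float(d["T"]),
                x=float(d["x"]),
                solvent_fraction=float(d.get("solvent_fraction", 1.0)),
                s=None if pd.isna(d.get("s")) else float(d["s"]),
                sd_x=None if pd.isna(d.get("sd_x")) else float(d["sd_x"]),
                source=str(d.get("source", "") or ""),
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
        key = (rec.solvent_id, rec.solvent_fraction, rec.T, rec.source)
        if key in seen:
            raise ValueError(f"{path}: row {i}: duplicate key {key}")
        seen.add(key)
        records.append(rec)
    return records


def write_solubility_csv(records: Iterable[SolubilityRecord], path) -> None:
    rows = [
        {
            "solute_id": r.solute_id,
            "solvent_id": r.solvent_id,
            "solvent_fraction": r.solvent_fraction,
            "T": r.T,
            "x": r.x,
            "s": r.s,
            "sd_x": r.sd_x,
            "source": r.source,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(SOLUBILITY_COLUMNS)).to_csv(path, index=False)


def write_consensus_csv(consensus: ConsensusTable, path) -> None:
    consensus.table.to_csv(path, index=False)


def read_descriptor_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "log10x" not in df.columns:
        raise ValueError(f"{path}: descriptor table lacks the 'log10x' target column")
    feature_cols = [
        c for c in df.columns if c not in ("solvent_id", "log10x")
    ]
    na = df[feature_cols + ["log10x"]].isna()
    if na.any().any():
        bad = int(na.any(axis=1).idxmax()) + 1
        raise ValueError(f"{path}: missing value in feature/target columns near row {bad}")
    return df


def write_descriptor_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def load_dapsone_table1() -> list[SolubilityRecord]:
    """The newly measured dapsone solubilities in five neat solvents.

    Twenty records (4FM, DMSO, TEPA, NMP, B3APE at 298.15-313.15 K in 5 K
    steps), with mole fractions at natural scale and molarities in mol/dm^3.
    """
    ref = resources.files("dapsol") / "data" / "dapsone_table1.csv"
    with resources.as_file(ref) as p:
        return read_solubility_csv(p)
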