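"""Tabular record schemas and delimited-text I/O.

Every dataset in the pipeline is a pandas DataFrame with a declared
:class:`TableSchema`: column names, dtypes and units are fixed at the schema
level and never inferred from files.  Files are plain CSV (comma separator,
period decimal mark, UTF-8) with a header row; floats are written at full
round-trip precision so ``read_table(write_table(df)) == df`` bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


@dataclass(frozen=True)
class TableSchema:
    """Column contract for one record type.

    ``columns`` maps column name -> numpy/pandas dtype string; ``units``
    is documentation only (one entry per column, '' for identifiers).
    """

    name: str
    columns: dict
    units: dict

    def validate(self, df: pd.DataFrame, source: str = "<memory>") -> pd.DataFrame:
        missing = [c for c in self.columns if c not in df.columns]
        if missing:
            raise SchemaError(
                f"{source}: table '{self.name}' is missing required column(s) "
                f"{missing}; expected {list(self.columns)}"
            )
        out = df.loc[:, list(self.columns)].copy()
        for col, dtype in self.columns.items():
            try:
                out[col] = out[col].astype(dtype)
            except (ValueError, TypeError) as exc:
                bad = _first_bad_row(df[col], dtype)
                raise SchemaError(
                    f"{source}: column '{col}' of table '{self.name}' has an "
                    f"unparseable value at data row {bad}: {exc}"
                ) from exc
        return out.reset_index(drop=True)


def _first_bad_row(series: pd.Series, dtype: str) -> int | str:
    for i, v in enumerate(series):
        try:
            np.dtype(dtype).type(v)
        except (ValueError, TypeError):
            return i
    return "<unknown>"


# --- schemas ---------------------------------------------------------------

#: Raw rumen-headspace spot sample: volume fractions (vol%) of the five
#: measured gases; possibly diluted by atmospheric air.
HEADSPACE = TableSchema(
    name="headspace",
    columns={
        "cow_id": "str",
        "period": "int64",
        "day": "int64",
        "time_rel_feeding": "float64",
        "co2": "float64",
        "ch4": "float64",
        "n2o": "float64",
        "n2": "float64",
        "o2": "float64",
    },
    units={
        "cow_id": "",
        "period": "",
        "day": "",
        "time_rel_feeding": "h",
        "co2": "vol%",
        "ch4": "vol%",
        "n2o": "vol%",
        "n2": "vol%",
        "o2": "vol%",
    },
)

#: Air-corrected headspace sample: CO2 + CH4 + N2O renormalised to 100 vol%.
CORRECTED_HEADSPACE = TableSchema(
    name="corrected_headspace",
    columns={
        "cow_id": "str",
        "period": "int64",
        "day": "int64",
        "time_rel_feeding": "float64",
        "co2": "float64",
        "ch4": "float64",
        "n2o": "float64",
    },
    units={
        "cow_id": "",
        "period": "",
        "day": "",
        "time_rel_feeding": "h",
        "co2": "vol%",
        "ch4": "vol%",
        "n2o": "vol%",
    },
)

#: Hourly respiration-chamber gas exchange for one cow.
CHAMBER = TableSchema(
    name="chamber",
    columns={
        "cow_id": "str",
        "period": "int64",
        "day": "int64",
        "hour_rel_feeding": "float64",
        "ch4": "float64",
        "co2": "float64",
        "h2": "float64",
        "o2": "float64",
    },
    units={
        "cow_id": "",
        "period": "",
        "day": "",
        "hour_rel_feeding": "h",
        "ch4": "g/h",
        "co2": "g/h",
        "h2": "g/h",
        "o2": "g/h",
    },
)

#: Per cow x period daily means over the measurement days.
SUMMARY = TableSchema(
    name="summary",
    columns={
        "cow_id": "str",
        "period": "int64",
        "treatment": "str",
        "sequence": "str",
        "dmi": "float64",
        "milk": "float64",
        "fat_pct": "float64",
        "protein_pct": "float64",
        "lactose_pct": "float64",
        "ch4_g_d": "float64",
        "h2_g_d": "float64",
        "co2_g_d": "float64",
        "o2_g_d": "float64",
        "ecm": "float64",
        "fpcm": "float64",
        "gei": "float64",
    },
    units={
        "cow_id": "",
        "period": "",
        "treatment": "",
        "sequence": "",
        "dmi": "kg DM/d",
        "milk": "kg/d",
        "fat_pct": "%",
        "protein_pct": "%",
        "lactose_pct": "%",
        "ch4_g_d": "g/d",
        "h2_g_d": "g/d",
        "co2_g_d": "g/d",
        "o2_g_d": "g/d",
        "ecm": "kg/d",
        "fpcm": "kg/d",
        "gei": "MJ/d",
    },
)

#: N2O:CH4 anchor ratios, one per cow x period.
ANCHOR_RATIOS = TableSchema(
    name="anchor_ratios",
    columns={
        "cow_id": "str",
        "period": "int64",
        "ratio": "float64",
        "n_samples": "int64",
        "method": "str",
    },
    units={"cow_id": "", "period": "", "ratio": "L/L", "n_samples": "", "method": ""},
)

#: Derived per cow x period emission metrics.
METRICS = TableSchema(
    name="metrics",
    columns={
        "cow_id": "str",
        "period": "int64",
        "treatment": "str",
        "ch4_g_d": "float64",
        "h2_g_d": "float64",
        "co2_g_d": "float64",
        "n2o_g_d": "float64",
        "ch4_yield": "float64",
        "h2_yield": "float64",
        "ch4_per_ecm": "float64",
        "ch4_per_fpcm": "float64",
        "ch4_gei_pct": "float64",
    },
    units={
        "cow_id": "",
        "period": "",
        "treatment": "",
        "ch4_g_d": "g/d",
        "h2_g_d": "g/d",
        "co2_g_d": "g/d",
        "n2o_g_d": "g/d",
        "ch4_yield": "g/kg DMI",
        "h2_yield": "g/kg DMI",
        "ch4_per_ecm": "g/kg",
        "ch4_per_fpcm": "g/kg",
        "ch4_gei_pct": "% of GEI",
    },
)

SCHEMAS = {
    s.name: s
    for s in (HEADSPACE, CORRECTED_HEADSPACE, CHAMBER, SUMMARY, ANCHOR_RATIOS, METRICS)
}


# --- I/O -------------------------------------------------------------------


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read a delimited-text table and validate it against ``schema``.

    Header names are matched case-insensitively; the returned frame uses the
    schema's canonical (lower-case) names, column order and dtypes, with row
    order preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    df.columns = [str(c).strip().lower() for c in df.columns]
    return schema.validate(df, source=str(path))


def write_table(df: pd.DataFrame, path: str | Path, schema: TableSchema) -> Path:
    """Write records as CSV with header, floats at full precision.

    Raises ``ValueError`` on an empty collection and ``SchemaError`` if the
    frame does not carry the schema's columns.
    """
    if len(df) == 0:
        raise ValueError(f"refusing to write empty '{schema.name}' table to {path}")
    out = schema.validate(df, source="<memory>")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # repr-precision floats make the CSV round-trip bit-identical
    out.to_csv(path, index=False, float_format=None)
    return path


def crude_protein(n_content: float) -> float:
    """Crude protein (g CP/kg) from total nitrogen (g N/kg): N x 6.25."""
    n = np.asarray(n_content, dtype=float)
    if np.any(n < 0):
        raise ValueError("nitrogen content must be non-negative")
    result = n * 6.25
    return float(result) if np.isscalar(n_content) else result
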