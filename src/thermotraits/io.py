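"""Readers and writers for the pipeline's exchange formats.

All tabular data travels as CSV (RFC-4180, '.' decimal separator), trees
as newick, summaries as JSON.  Temperatures in files are degC throughout;
Kelvin never appears in I/O.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable

import pandas as pd

from thermotraits.assay_traits import AssayRecord, DerivedTraits
from thermotraits.tpc_fitting import TPCObservation

__all__ = [
    "read_trait_table",
    "write_trait_table",
    "read_assay_records",
    "write_derived_traits",
    "read_tpc_observations",
    "write_json",
]

TRAIT_REQUIRED = ["isolate_id"]
TRAIT_NUMERIC = [
    "topt", "niche_width", "mu_max", "r_max", "log_atp",
    "carrying_capacity", "incubation_temp",
]

ASSAY_REQUIRED = [
    "isolate_id", "assay_temp", "duration_h", "initial_count",
    "final_count", "mean_diameter_um", "rtot_fgc",
]


class SchemaError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a per-isolate trait table, indexed by isolate_id.

    A header-only file yields an empty table; duplicated isolate keys and
    non-numeric cells in numeric columns are errors naming the offender.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"isolate_id": str})
    _require_columns(df, TRAIT_REQUIRED, path)
    dupes = df["isolate_id"][df["isolate_id"].duplicated()].unique().tolist()
    if dupes:
        raise SchemaError(f"{path}: duplicated isolate key(s): {', '.join(dupes)}")
    for col in TRAIT_NUMERIC:
        if col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"{path}: non-numeric value in column {col}: {exc}")
    return df.set_index("isolate_id")


def write_trait_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=True, index_label="isolate_id")


def _parse_rlu(cell: str) -> list[tuple[float, float]]:
    """RLU series packed as semicolon-separated 'minute:value' pairs."""
    out = []
    for token in str(cell).split(";"):
        token = token.strip()
        if not token:
            continue
        minute, _, value = token.partition(":")
        out.append((float(minute), float(value)))
    return out


def read_assay_records(path: str | Path) -> list[AssayRecord]:
    """Read raw assay replicates (one row each) from CSV.

    The RLU series may be packed in an ``rlu_series`` column as
    ``minute:value`` pairs separated by semicolons, or spread over wide
    columns ``rlu_t0, rlu_t2, rlu_t4, rlu_t6``.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"isolate_id": str, "replicate": str})
    _require_columns(df, ASSAY_REQUIRED, path)
    wide_rlu = [c for c in df.columns if c.startswith("rlu_t")]
    records = []
    for i, row in df.iterrows():
        try:
            if "rlu_series" in df.columns and not pd.isna(row["rlu_series"]):
                rlu = _parse_rlu(row["rlu_series"])
            elif wide_rlu:
                rlu = [
                    (float(c.removeprefix("rlu_t")), float(row[c]))
                    for c in wide_rlu if not pd.isna(row[c])
                ]
            else:
                rlu = []
            records.append(AssayRecord(
                isolate_id=row["isolate_id"],
                assay_temp=float(row["assay_temp"]),
                t=float(row["duration_h"]),
                initial_count=float(row["initial_count"]),
                final_count=float(row["final_count"]),
                diameters=[float(row["mean_diameter_um"])],
                Rtot=float(row["rtot_fgc"]),
                rlu_series=rlu,
                od600=float(row["od600"]) if "od600" in df.columns
                and not pd.isna(row["od600"]) else None,
                replicate=str(row.get("replicate", i + 1)),
            ))
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: row {i + 2}: {exc}") from exc
    return records


def write_assay_records(records: list[AssayRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "isolate_id": r.isolate_id,
            "assay_temp": r.assay_temp,
            "duration_h": r.t,
            "initial_count": r.initial_count,
            "final_count": r.final_count,
            "mean_diameter_um": float(pd.Series(r.diameters).mean()),
            "rtot_fgc": r.Rtot,
            "rlu_series": ";".join(f"{m:g}:{v:.8g}" for m, v in r.rlu_series),
            "od600": r.od600 if r.od600 is not None else "",
            "replicate": r.replicate,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_derived_traits(traits: list[DerivedTraits], path: str | Path) -> None:
    pd.DataFrame([t.__dict__ for t in traits]).to_csv(path, index=False)


def read_tpc_observations(path: str | Path) -> dict[str, list[TPCObservation]]:
    """Read temperature-rate observations grouped by isolate."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"isolate_id": str, "replicate": str})
    _require_columns(df, ["isolate_id", "temp_c", "rate"], path)
    out: dict[str, list[TPCObservation]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["isolate_id"], []).append(
            TPCObservation(
                temp=float(row["temp_c"]),
                rate=float(row["rate"]),
                replicate=str(row.get("replicate", "1")),
            )
        )
    return out


def write_tpc_observations(
    obs_by_isolate: dict[str, list[TPCObservation]], path: str | Path
) -> None:
    rows = [
        {"isolate_id": iso, "temp_c": o.temp, "rate": o.rate,
         "replicate": o.replicate}
        for iso, obs in obs_by_isolate.items()
        for o in obs
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o: Any):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
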