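"""Tabular input/output and run provenance shared by the CLI and library.

All persisted numerics are written at full double precision; display
rounding happens only at the presentation layer. JSON results carry a
provenance block (command, parameters, seed, package version) so every
run is reproducible from its own output.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Optional

import pandas as pd

from .errors import ValidationError

__all__ = ["RunConfig", "read_strata_csv", "write_results", "read_results"]

STRATA_COLUMNS = ("age_band", "frr_mz", "frr_dz")


@dataclass
class RunConfig:
    """Provenance record for one CLI or scripted run."""

    command: str
    parameters: dict = field(default_factory=dict)
    seed: Optional[int] = None
    output_path: Optional[str] = None
    log_level: str = "info"

    def provenance(self) -> dict:
        from . import __version__

        return {
            "command": self.command,
            "parameters": {k: _jsonable(v) for k, v in self.parameters.items()},
            "seed": self.seed,
            "version": __version__,
        }


def _jsonable(v: Any) -> Any:
    if isinstance(v, (Path,)):
        return str(v)
    if hasattr(v, "tolist"):
        return v.tolist()
    return v


def read_strata_csv(path) -> list[tuple[str, float, float]]:
    """Read an age-stratified FRR table (header age_band,frr_mz,frr_dz).

    Errors name the offending file line and column. An empty data section
    is a valid (empty) table.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file, expected header {','.join(STRATA_COLUMNS)}")
        header = [h.strip() for h in reader.fieldnames]
        missing = [c for c in STRATA_COLUMNS if c not in header]
        if missing:
            raise ValidationError(
                f"{path}: missing column(s) {', '.join(missing)} "
                f"(expected header {','.join(STRATA_COLUMNS)})"
            )
        rows: list[tuple[str, float, float]] = []
        for lineno, rec in enumerate(reader, start=2):  # header is line 1
            age_band = (rec.get("age_band") or "").strip()
            if not age_band and all(not (rec.get(c) or "").strip() for c in STRATA_COLUMNS):
                continue  # blank line
            vals = {}
            for col in ("frr_mz", "frr_dz"):
                raw = (rec.get(col) or "").strip()
                try:
                    vals[col] = float(raw)
                except ValueError:
                    raise ValidationError(
                        f"{path}: row {lineno}, column {col}: could not parse {raw!r} as a number"
                    ) from None
                if vals[col] < 1:
                    raise ValidationError(
                        f"{path}: row {lineno}, column {col}: FRR must be >= 1, got {vals[col]}"
                    )
            rows.append((age_band, vals["frr_mz"], vals["frr_dz"]))
    return rows


def write_results(
    records: Iterable[dict] | pd.DataFrame,
    path,
    format: str = "csv",
    provenance: Optional[dict] = None,
) -> None:
    """Write result records as CSV or JSON, round-trip stable at full precision.

    JSON output nests the records under ``results`` next to the
    ``provenance`` block; CSV writes the records alone with a header row,
    comma separation and '.' decimals.
    """
    frame = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    path = Path(path)
    if format == "csv":
        frame.to_csv(path, index=False, float_format="%.17g")
    elif format == "json":
        payload = {
            "provenance": provenance or {},
            "results": frame.to_dict(orient="records"),
        }
        with path.open("w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    else:
        raise ValidationError(f"unknown output format {format!r}; choose csv or json")


def read_results(path, format: str = "csv") -> pd.DataFrame:
    """Read back a file written by :func:`write_results`."""
    path = Path(path)
    if format == "csv":
        return pd.read_csv(path, float_precision="round_trip")
    if format == "json":
        with path.open(encoding="utf-8") as fh:
            return pd.DataFrame(json.load(fh)["results"])
    raise ValidationError(f"unknown format {format!r}; choose csv or json")
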