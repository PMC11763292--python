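"""Readers and writers for the package's CSV dialects and run manifests.

CSV (UTF-8, ``.`` decimal) is the single interchange format: the inputs are
landing tables and parameter sheets, for which no domain binary format
applies.  Coordinates are signed decimal degrees with south and west
negative.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .foodweb import CONSUMER, DETRITUS, PRODUCER
from .indices import CATCH_COLUMNS
from .massbalance import GroupParams

__all__ = ["RunConfig", "read_catch_table", "write_catch_table", "read_group_params", "write_manifest"]

log = logging.getLogger("trophicweb")

REQUIRED_CATCH_COLUMNS = ["year", "fleet", "species_code", "catch_t"]


@dataclass
class RunConfig:
    """Run-level configuration shared by the CLI subcommands."""

    reference_year: int | None = None
    te: float = 0.1
    breakpoints: list[int] = field(default_factory=list)
    balance_tol: float = 1e-9
    seed: int = 0
    out_dir: Path = Path(".")
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.te < 1):
            raise ValueError("TE must lie in (0, 1)")
        if self.balance_tol <= 0:
            raise ValueError("tolerances must be positive")
        self.out_dir = Path(self.out_dir)


def read_catch_table(path) -> pd.DataFrame:
    """Read a landings CSV in the canonical dialect.

    Missing required columns raise; malformed rows (non-numeric or negative
    catch, missing year/fleet/species) are dropped and logged with their
    line numbers.  Optional columns absent from the file are filled with NA.
    """
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_CATCH_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"catch table {path} is missing required column(s): {missing}")
    for col in CATCH_COLUMNS:
        if col not in frame.columns:
            frame[col] = pd.NA
    n0 = len(frame)
    catch = pd.to_numeric(frame["catch_t"], errors="coerce")
    year = pd.to_numeric(frame["year"], errors="coerce")
    bad = catch.isna() | (catch < 0) | year.isna() | frame["species_code"].isna() | frame["fleet"].isna()
    if bad.any():
        # +2: header line and 1-based numbering
        lines = [int(i) + 2 for i in frame.index[bad][:20]]
        log.warning("%s: rejected %d malformed row(s) at lines %s", path, int(bad.sum()), lines)
    frame = frame[~bad].copy()
    frame["catch_t"] = catch[~bad]
    frame["year"] = year[~bad].astype(int)
    for col in ("lat", "lon", "depth_m", "days_at_sea", "fishing_days", "hauls"):
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    log.info("%s: read %d record(s) (%d rejected)", path, len(frame), n0 - len(frame))
    return frame[CATCH_COLUMNS].reset_index(drop=True)


def write_catch_table(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, columns=CATCH_COLUMNS)


def read_group_params(path) -> list[GroupParams]:
    """Read a functional-group parameter sheet (the model-table dialect).

    Columns: code, name, area, TL, B, PB, QB, EE, PQ, OI, VIC, VRB — blank
    cells mark unknown parameters.  Roles are inferred: groups named/coded
    as detritus are detritus, groups without a QB are producers, the rest
    consumers.
    """
    frame = pd.read_csv(path)
    groups = []
    for _, row in frame.iterrows():
        code = str(row["code"])
        qb = row.get("QB")
        has_qb = pd.notna(qb)
        if code.upper().startswith("DET") or str(row.get("name", "")).lower() == "detritus":
            role = DETRITUS
        elif has_qb:
            role = CONSUMER
        else:
            role = PRODUCER
        catches = {}
        for fleet in ("VIC", "VRB"):
            v = row.get(fleet)
            if pd.notna(v) and float(v) > 0:
                catches[fleet] = float(v)
        ee = row.get("EE")
        groups.append(
            GroupParams(
                code=code,
                name=str(row.get("name", "")),
                role=role,
                b=float(row["B"]) if pd.notna(row.get("B")) else None,
                pb=float(row["PB"]) if pd.notna(row.get("PB")) and role != DETRITUS else None,
                qb=float(qb) if has_qb and role == CONSUMER else None,
                ee=float(ee) if pd.notna(ee) and role != DETRITUS else None,
                catches=catches,
            )
        )
    return groups


def write_manifest(path, *, command: str, inputs: dict, config: RunConfig, extra: dict | None = None) -> None:
    """JSON run manifest: everything needed to reproduce the run bit-identically."""
    manifest = {
        "command": command,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "seed": config.seed,
        "reference_year": config.reference_year,
        "te": config.te,
        "breakpoints": config.breakpoints,
        "balance_tol": config.balance_tol,
        "versions": {
            "trophicweb": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
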