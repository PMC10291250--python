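"""CSV bundle reading/writing and run manifests.

A bundle is a directory of UTF-8 CSVs (header row, '.' decimal) with the
tables a study produces: ``trees``, ``conduits``, ``flow``, ``segments``,
``leaf_areas`` (plus ``ground_truth`` for synthetic studies).  Schemas are
validated by required-column lists so that a mismatch fails with a named
column error rather than deep inside the pipeline.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Dict, Mapping

import pandas as pd

__all__ = ["REQUIRED_COLUMNS", "write_bundle", "read_bundle", "validate_bundle", "write_manifest"]

REQUIRED_COLUMNS: Dict[str, list] = {
    "trees": ["species", "tree_id", "leaf_habit", "height_m"],
    "conduits": [
        "sample_id", "species", "tree_id", "organ",
        "sector_angle_deg", "sector_area_um2", "lumen_area_um2",
    ],
    "flow": ["sample_id", "species", "tree_id", "organ", "stage",
             "pressure_kPa", "flow_g_per_h"],
    "segments": ["sample_id", "species", "tree_id", "organ", "length_m",
                 "dry_mass_g"],
    "leaf_areas": ["sample_id", "leaf_area_m2"],
}

OPTIONAL_TABLES = ("ground_truth",)


def validate_bundle(tables: Mapping[str, pd.DataFrame]) -> None:
    for name, cols in REQUIRED_COLUMNS.items():
        if name not in tables:
            raise ValueError(f"bundle is missing the {name!r} table")
        missing = [c for c in cols if c not in tables[name].columns]
        if missing:
            raise ValueError(f"table {name!r} lacks required columns: {missing}")


def write_bundle(tables: Mapping[str, pd.DataFrame], out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    return out


def read_bundle(bundle_dir) -> Dict[str, pd.DataFrame]:
    d = Path(bundle_dir)
    tables = {}
    for name in list(REQUIRED_COLUMNS) + list(OPTIONAL_TABLES):
        path = d / f"{name}.csv"
        if path.exists():
            tables[name] = pd.read_csv(path)
    validate_bundle(tables)
    return tables


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_manifest(out_dir, seed=None, config: Mapping | None = None) -> Path:
    """Traceability record: input digests, seed, config hash, timestamp."""
    out = Path(out_dir)
    files = sorted(p for p in out.glob("*.csv"))
    manifest = {
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        if config is not None
        else None,
        "files": {p.name: _digest(p) for p in files},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
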