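"""Tabular I/O with fixed column schemas.

All interchange is plain TSV (diffable, desk-scale) plus JSON for configs
and ground truth.  Floats are written at full repr precision so write/read
round-trips are exact to well below 1e-9.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

SITE_SCHEMA = ["site_id"]  # plus vol_* columns
GEOMETRY_SCHEMA = [
    "site_id",
    "d_low_mm",
    "d_high_mm",
    "area_mm2",
    "upsampling",
    "hemisphere",
    "map",
    "subject",
]


class SchemaError(ValueError):
    pass


def write_tsv(tab: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tab.to_csv(path, sep="\t", index=False)


def read_tsv(path, required: list[str] | None = None) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    if required:
        missing = [c for c in required if c not in tab.columns]
        if missing:
            raise SchemaError(
                f"{path}: missing required column(s): {', '.join(missing)}"
            )
    return tab


def read_sites_tsv(path) -> pd.DataFrame:
    tab = read_tsv(path, required=SITE_SCHEMA)
    if not any(c.startswith("vol_") for c in tab.columns):
        raise SchemaError(f"{path}: missing required column(s): vol_*")
    return tab


def read_geometry_tsv(path) -> pd.DataFrame:
    return read_tsv(path, required=GEOMETRY_SCHEMA)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
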