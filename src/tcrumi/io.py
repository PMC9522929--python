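"""Tabular interchange: molecule tables, reports, provenance blocks."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .extract import MoleculeRecord

MOLECULE_COLUMNS = ["umi", "v_id", "j_id", "junction_nt", "cdr3_nt", "read_count"]


def write_molecule_tsv(records: list[MoleculeRecord], path: str | Path) -> None:
    rows = [
        {
            "umi": r.umi,
            "v_id": r.v_id,
            "j_id": r.j_id,
            "junction_nt": r.junction_nt,
            "cdr3_nt": r.cdr3_nt,
            "read_count": r.read_count,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=MOLECULE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_molecule_tsv(path: str | Path) -> list[MoleculeRecord]:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in MOLECULE_COLUMNS[:-1]})
    return [
        MoleculeRecord(
            r["umi"], r["v_id"], r["j_id"], r["junction_nt"], r["cdr3_nt"], int(r["read_count"])
        )
        for r in df.to_dict("records")
    ]


def provenance(inputs: dict, config: dict, seed: int | None = None) -> dict:
    """Provenance block embedded in every machine-readable output."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "tool": "tcrumi",
        "version": __version__,
        "inputs": inputs,
        "config_sha1": hashlib.sha1(blob).hexdigest(),
        "seed": seed,
    }


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
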