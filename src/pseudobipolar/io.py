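"""Readers, writers and run manifests.

Tabular dialect: tab-separated, UTF-8, header row, ``NA`` for missing
values.  FASTA goes through Bio.SeqIO; tables through pandas behind
schema-validating wrappers that report offending line numbers.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .meiosis import HET, MISSING, P1, P2, MarkerMap

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_tsv_table",
    "write_tsv_table",
    "read_marker_map",
    "write_marker_map",
    "read_progeny_table",
    "write_progeny_table",
    "write_manifest",
]

_PROGENY_CALLS = {P1, P2, HET, MISSING}


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> sequence map."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq)
    if not records:
        warnings.warn(f"{path}: empty FASTA, no sequences read", stacklevel=2)
    return records


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


def read_tsv_table(path, required_columns: Sequence[str]) -> pd.DataFrame:
    """Read a TSV table and check the declared schema."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required_columns if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return table


def write_tsv_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_marker_map(path) -> MarkerMap:
    table = read_tsv_table(path, MarkerMap.COLUMNS)
    try:
        table["position_kb"] = table["position_kb"].astype(float)
    except ValueError as err:
        raise ValueError(f"{path}: non-numeric position_kb ({err})") from None
    return MarkerMap(table)


def write_marker_map(path, marker_map: MarkerMap) -> None:
    write_tsv_table(path, marker_map.table)


def read_progeny_table(path) -> pd.DataFrame:
    """Read a progeny table of P1/P2/HET/NA origin calls, naming bad lines."""
    table = read_tsv_table(path, ["teliospore", "colony"])
    markers = [c for c in table.columns if c not in ("teliospore", "colony")]
    for marker in markers:
        bad = ~table[marker].isin(_PROGENY_CALLS)
        if bad.any():
            # +2: header line plus 1-based numbering
            lines = [int(i) + 2 for i in table.index[bad]]
            value = table.loc[bad, marker].iloc[0]
            raise ValueError(
                f"{path}: unknown call {value!r} for marker {marker!r} on line(s) {lines}"
            )
    return table


def write_progeny_table(path, table: pd.DataFrame) -> None:
    write_tsv_table(path, table)


def write_manifest(out_dir, config: Mapping, seed: Optional[int] = None) -> Path:
    """Write a reproducibility manifest (config + seed + config hash)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"config": _jsonable(config), "seed": seed}
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode("utf-8")
    ).hexdigest()
    payload["config_sha256"] = digest
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)
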