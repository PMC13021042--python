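"""Trial-table I/O, schema validation, and run manifests."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd

from .exceptions import InvalidParameterError
from .simulate import TABLE_COLUMNS

__all__ = [
    "read_trial_table",
    "sha256_file",
    "validate_trial_table",
    "write_manifest",
    "write_trial_table",
]

_ANGLE_COLUMNS = ["S_M", "probe1_sim", "probe1_dis", "probe2_sim", "probe2_dis", "response"]


def validate_trial_table(table: pd.DataFrame) -> None:
    """Raise with a row/column diagnostic if the table violates the schema.

    Angles must lie in [0, 360); confidence in {1, 2, 3}; all schema columns
    must be present.
    """
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidParameterError(f"missing columns: {missing}")
    for col in _ANGLE_COLUMNS:
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[(vals < 0) | (vals >= 360)].tolist()
        if bad:
            raise InvalidParameterError(
                f"column {col!r} out of [0, 360) at rows {bad[:10]}"
            )
    conf = table["confidence"]
    bad = table.index[~conf.isin([1, 2, 3])].tolist()
    if bad:
        raise InvalidParameterError(f"confidence not in {{1,2,3}} at rows {bad[:10]}")


def write_trial_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_trial_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-table CSV (same schema for synthetic or real data)."""
    table = pd.read_csv(path)
    validate_trial_table(table)
    return table


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path, config: dict, artifacts: list[str | Path]
) -> Path:
    """Write a run manifest: config hash plus a checksum for every output file."""
    out_dir = Path(out_dir)
    cfg_text = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "created_unix": int(time.time()),
        "artifacts": {
            str(Path(p).name): sha256_file(p) for p in artifacts
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
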