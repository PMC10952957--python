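"""File schemas, configuration and run manifests.

Participant tables travel as CSV with a versioned schema comment line;
readers reject unknown versions. Configurations (cohort spec, unit costs,
voucher schedule, lifetime parameters) are YAML. Every command writes a run
manifest recording the command, config hashes, seed, package version,
timestamps and output files, so a run is reproducible from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import pandas as pd
import yaml

SCHEMA_VERSION = "cohort-v1"
_SCHEMA_PREFIX = "# schema: "


def write_cohort(table: pd.DataFrame, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{_SCHEMA_PREFIX}{SCHEMA_VERSION}\n")
        table.to_csv(fh, index=False)


def read_cohort(path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith(_SCHEMA_PREFIX):
            raise ValueError(f"{path}: missing schema version line")
        version = first[len(_SCHEMA_PREFIX):]
        if version != SCHEMA_VERSION:
            raise ValueError(f"{path}: unknown schema version {version!r}")
        table = pd.read_csv(fh)
    for col in ("quit_4wk", "quit_12wk", "quit_late", "quit_late_selfreport", "quit_postpartum"):
        if col in table.columns:
            table[col] = table[col].fillna("missing")
    return table


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_config(obj, path) -> None:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def _hash_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def write_manifest(
    out_dir, command: str, seed: int, configs=(), outputs=(), extra=None
) -> Path:
    from . import __version__

    manifest = {
        "command": command,
        "seed": int(seed),
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "configs": {str(p): _hash_file(p) for p in configs},
        "outputs": [str(p) for p in outputs],
    }
    if extra:
        manifest.update(extra)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
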