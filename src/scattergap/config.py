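"""Run configuration, component-scoped seeding and output manifests.

Every random operation in a pipeline run consumes a child seed derived
from the global seed and a stable component label, so adding a stage never
perturbs another stage's randomness.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = ["child_seed", "child_rng", "load_config", "write_manifest", "PACKAGE_VERSION"]

PACKAGE_VERSION = "0.1.0"


def child_seed(seed: int, label: str) -> int:
    """Derive a stable component-scoped seed (< 2**31) from a global seed."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def child_rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, label))


def load_config(path: str | Path) -> dict:
    """Read a YAML run configuration; an empty file yields an empty dict."""
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return asdict(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON-serializable: {type(obj).__name__}")


def write_manifest(
    out_dir: str | Path, subcommand: str, config: dict, seed: int, inputs: dict | None = None
) -> Path:
    """Write a reproducibility manifest next to a stage's outputs.

    Records the subcommand, the full configuration and its hash, the global
    seed and digests of any input files, so the stage can be re-run from
    the manifest alone.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config, sort_keys=True, default=_jsonable)
    digests = {}
    for name, path in (inputs or {}).items():
        h = hashlib.sha256()
        with open(path, "rb") as f:
            for chunk in iter(lambda: f.read(1 << 20), b""):
                h.update(chunk)
        digests[name] = h.hexdigest()
    manifest = {
        "subcommand": subcommand,
        "package_version": PACKAGE_VERSION,
        "seed": int(seed),
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "input_sha256": digests,
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
        f.write("\n")
    return path
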