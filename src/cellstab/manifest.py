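"""Reproducibility manifests written next to every CLI artifact."""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

from . import __version__

__all__ = ["write_manifest", "file_digest"]


def file_digest(path) -> str:
    """SHA-256 of a file, or of the concatenated sorted files of a directory."""
    path = Path(path)
    h = hashlib.sha256()
    files = sorted(p for p in path.rglob("*") if p.is_file()) if path.is_dir() else [path]
    for f in files:
        h.update(f.name.encode())
        h.update(f.read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir, command: str, parameters: dict, inputs=(), master_seed=None
) -> Path:
    """JSON manifest: command, parameters, seed, input digests, version, time.

    Together with the input files this is sufficient to re-execute the run
    identically (all randomness is seed-derived).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "parameters": {k: _jsonable(v) for k, v in parameters.items()},
        "master_seed": master_seed,
        "inputs": {str(p): file_digest(p) for p in inputs if Path(p).exists()},
        "tool": "cellstab",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path = out_dir / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def _jsonable(value):
    if isinstance(value, Path):
        return str(value)
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value
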