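"""Flat key-value run configuration and reproducibility manifests.

Config files are plain text, one ``dotted.key = value`` per line,
``#`` comments allowed. CLI flags always override file values. Every CLI
run writes a JSON run-manifest next to its primary output recording the
fully resolved configuration, SHA-256 digests of the inputs, the output
paths and the package version — enough to reproduce or audit the run.
Manifests contain no timestamps, so identical inputs and seeds yield
byte-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from . import __version__

__all__ = ["load_config", "resolve", "write_run_manifest", "sha256_file"]


def load_config(path: str | Path | None) -> dict[str, str]:
    """Parse a flat dotted-key config file into a string-valued dict."""
    if path is None:
        return {}
    config: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {lineno}: expected 'key = value'")
        key, value = line.split("=", 1)
        key = key.strip()
        if not key:
            raise ValueError(f"{path}: line {lineno}: empty key")
        config[key] = value.strip()
    return config


def resolve(config: dict[str, str], key: str, cli_value, cast=str, default=None):
    """CLI flag > config file > default."""
    if cli_value is not None:
        return cli_value
    if key in config:
        raw = config[key]
        if cast is bool:
            return raw.lower() in ("1", "true", "yes", "on")
        return cast(raw)
    return default


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_manifest(
    out_path: str | Path,
    subcommand: str,
    resolved_config: dict,
    inputs: dict[str, str | Path],
    outputs: list[str | Path],
) -> Path:
    manifest = {
        "tool": "coreselect",
        "version": __version__,
        "subcommand": subcommand,
        "config": resolved_config,
        "inputs": {
            name: {"path": str(p), "sha256": sha256_file(p)}
            for name, p in inputs.items()
        },
        "outputs": [str(p) for p in outputs],
    }
    path = Path(str(out_path) + ".run.json")
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
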