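"""Report assembly helpers: rounding, manifests, summary tables.

Percentages in assembled reports are rounded half-up to whole percent,
the convention used for headline shares such as 6405/23849 -> 27%.
"""

from __future__ import annotations

import hashlib
import json
import math
import platform
from datetime import datetime, timezone
from pathlib import Path

__all__ = [
    "round_half_up",
    "percent",
    "config_digest",
    "write_manifest",
    "read_manifest",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero upward."""
    return math.floor(x + 0.5)


def percent(numerator: float, denominator: float) -> int:
    """Whole-number percentage, rounded half-up."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator)


def config_digest(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(
    outdir: str | Path, files: dict[str, str], config: dict
) -> Path:
    """Write a run manifest listing outputs, config hash, and run metadata.

    Every listed file must exist and be non-empty. The ``metadata`` block
    (timestamp, versions) is informational; the data files themselves are
    deterministic for fixed inputs and seed.
    """
    from . import __version__

    outdir = Path(outdir)
    for key, rel in files.items():
        path = outdir / rel
        if not path.exists() or path.stat().st_size == 0:
            raise ValueError(f"manifest entry {key!r} missing or empty: {path}")
    manifest = {
        "config_digest": config_digest(config),
        "config": config,
        "files": files,
        "metadata": {
            "nadkit_version": __version__,
            "python": platform.python_version(),
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path


def read_manifest(outdir: str | Path) -> dict:
    path = Path(outdir) / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"no manifest at {path}")
    return json.loads(path.read_text())
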