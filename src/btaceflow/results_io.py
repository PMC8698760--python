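"""Result serialization: CSV tables plus a JSON run manifest.

Outputs are deterministic: identical inputs produce byte-identical CSVs
(rows sorted, floats written with repr-level precision).  The manifest
records the provenance a reader needs to re-run the computation: config
path, every resolved parameter, seed (when randomness was involved),
package version and a timestamp.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .analysis import SweepCurve
from .config import LoadedRun, resolved_parameters
from .hydraulics import FlowSolution

__all__ = ["write_manifest", "write_solution", "write_sweep"]


def _write_csv(frame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")


def write_manifest(
    out_dir: str | Path,
    run: LoadedRun | None = None,
    config_path: str | Path | None = None,
    seed: int | None = None,
    extra: dict | None = None,
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "software": "btaceflow",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config_path": str(config_path) if config_path else None,
        "seed": seed,
        "parameters": resolved_parameters(run) if run is not None else None,
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def write_solution(solution: FlowSolution, out_dir: str | Path) -> list[Path]:
    """node_pressures.csv (Pa and mmHg) + branch_flows.csv (m3/s and mL/min)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nodes, branches = solution.to_frames()
    node_path = out_dir / "node_pressures.csv"
    branch_path = out_dir / "branch_flows.csv"
    _write_csv(nodes, node_path)
    _write_csv(branches, branch_path)
    return [node_path, branch_path]


def write_sweep(curve: SweepCurve, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "sweep.csv"
    _write_csv(curve.to_frame(), path)
    return path
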