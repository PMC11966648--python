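"""Result serialization: CSV for tables, NPZ + JSON sidecar for fields,
and a manifest that makes every artifact reproducible from config + seed
+ package version."""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import OutcomeReport
from .pde import PDESolution

__all__ = ["write_manifest", "write_table", "save_solution", "load_solution",
           "write_report"]


def _version() -> str:
    from . import __version__
    return __version__


def write_manifest(out_dir: Path, command: str, config: dict,
                   seed: int | None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{command}_manifest.json"
    payload = {
        "command": command,
        "config": config,
        "seed": seed,
        "package_version": _version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path


def write_table(df: pd.DataFrame, path: Path) -> Path:
    """CSV with '.' decimal separator and deterministic float formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def save_solution(sol: PDESolution, stem: Path) -> tuple[Path, Path]:
    """Write a PDE solution as ``<stem>.npz`` plus ``<stem>.json`` sidecar."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    npz = stem.with_suffix(".npz")
    np.savez_compressed(
        npz, x=sol.x, t=sol.t, u=sol.u, v=sol.v,
        l2_dudt=sol.diagnostics.get("l2_dudt", np.array([])),
        l2_dvdt=sol.diagnostics.get("l2_dvdt", np.array([])),
    )
    c = sol.config
    sidecar = {
        "params": {f"a{i}": getattr(c.p, f"a{i}") for i in range(1, 9)},
        "spatial": {"d": c.cfg.d, "gamma": c.cfg.gamma, "L": c.cfg.L},
        "ic": {"kind": c.ic.kind, "base": [[b.u, b.v] for b in c.ic.base],
               "eps": c.ic.eps, "modes": list(c.ic.modes),
               "split": c.ic.split},
        "Nx": c.Nx, "t_end": c.t_end, "n_save": c.n_save,
        "rtol": c.rtol, "atol": c.atol, "seed": c.seed,
        "package_version": _version(),
    }
    js = stem.with_suffix(".json")
    js.write_text(json.dumps(sidecar, indent=2) + "\n")
    return npz, js


def load_solution(stem: Path) -> PDESolution:
    """Reload a solution written by :func:`save_solution`."""
    from .model import NondimParams, StatePoint
    from .pde import ICSpec, PDEConfig
    from .turing import SpatialConfig

    stem = Path(stem)
    data = np.load(stem.with_suffix(".npz"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    ic = ICSpec(kind=meta["ic"]["kind"],
                base=tuple(StatePoint(u=b[0], v=b[1]) for b in meta["ic"]["base"]),
                eps=meta["ic"]["eps"], modes=tuple(meta["ic"]["modes"]),
                split=meta["ic"]["split"])
    config = PDEConfig(
        p=NondimParams(**meta["params"]),
        cfg=SpatialConfig(**meta["spatial"]),
        ic=ic, seed=meta["seed"], Nx=meta["Nx"], t_end=meta["t_end"],
        n_save=meta["n_save"], rtol=meta["rtol"], atol=meta["atol"])
    return PDESolution(
        x=data["x"], t=data["t"], u=data["u"], v=data["v"], config=config,
        diagnostics={"l2_dudt": data["l2_dudt"], "l2_dvdt": data["l2_dvdt"]})


def write_report(report: OutcomeReport, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "outcome": report.outcome,
        "dominant_mode": report.dominant_mode,
        "period": report.period,
        "amplitude": report.amplitude,
        "front_speed": report.front_speed,
        "front_direction": report.front_direction,
        "front_r2": report.front_r2,
        "notes": report.notes,
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path
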