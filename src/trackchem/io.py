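"""Plain-text interchange formats.

* 1 ps snapshot CSV (``event,species,x_nm,y_nm,z_nm``) — the chemical
  stage's standalone input;
* phase-space CSV (``event,time_ps,kind,x_nm,y_nm,z_nm,value``) for
  physics-stage deposits and activations;
* G-value results CSV (``species,t_ps,G_mean,G_sd,n_events``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .chem import MoleculeSet
from .physics import Box, PhysicsEvent
from .registry import Registry, default_registry

SNAPSHOT_COLUMNS = ["event", "species", "x_nm", "y_nm", "z_nm"]
PHASESPACE_COLUMNS = ["event", "time_ps", "kind", "x_nm", "y_nm", "z_nm", "value"]


def snapshot_frame(populations: list[MoleculeSet]) -> pd.DataFrame:
    rows = []
    for event, m in enumerate(populations):
        reg = m.registry
        for idx in np.flatnonzero(m.alive):
            x, y, z = m.positions[idx]
            rows.append(
                {
                    "event": event,
                    "species": reg.species[m.species_ids[idx]].name,
                    "x_nm": x,
                    "y_nm": y,
                    "z_nm": z,
                }
            )
    return pd.DataFrame(rows, columns=SNAPSHOT_COLUMNS)


def write_snapshot(populations: list[MoleculeSet], path: str | Path) -> None:
    snapshot_frame(populations).to_csv(path, index=False)


def read_snapshot(
    path: str | Path,
    registry: Registry | None = None,
    box: Box | None = None,
) -> list[MoleculeSet]:
    """Load per-event 1 ps populations from a snapshot CSV."""
    registry = registry or default_registry()
    df = pd.read_csv(path)
    missing = set(SNAPSHOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"snapshot is missing columns {sorted(missing)}")
    out = []
    for _, g in df.groupby("event", sort=True):
        out.append(
            MoleculeSet.from_names(
                g["species"].tolist(),
                g[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float),
                registry,
                t=registry.constants.chem_t_start_ps,
                box=box,
            )
        )
    return out


def phasespace_frame(events: list[PhysicsEvent]) -> pd.DataFrame:
    rows = []
    for i, ev in enumerate(events):
        for d in ev.deposits:
            rows.append(
                {
                    "event": i,
                    "time_ps": 0.0,
                    "kind": f"deposit:{d.process}",
                    "x_nm": d.position[0],
                    "y_nm": d.position[1],
                    "z_nm": d.position[2],
                    "value": d.amount,
                }
            )
        for a in ev.activations:
            rows.append(
                {
                    "event": i,
                    "time_ps": a.time,
                    "kind": f"activation:{a.state}",
                    "x_nm": a.position[0],
                    "y_nm": a.position[1],
                    "z_nm": a.position[2],
                    "value": a.potential_energy,
                }
            )
        for c in ev.solvation_candidates:
            rows.append(
                {
                    "event": i,
                    "time_ps": c.time,
                    "kind": "solvation_candidate",
                    "x_nm": c.position[0],
                    "y_nm": c.position[1],
                    "z_nm": c.position[2],
                    "value": c.residual_energy,
                }
            )
    return pd.DataFrame(rows, columns=PHASESPACE_COLUMNS)
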