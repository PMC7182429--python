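"""Tabular and trajectory I/O.

Phase grids travel as tidy CSV (one row per cell), trajectories as
extended XYZ with the orientation vector in three extra columns; both
round-trip losslessly at the stated precision.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .bd import SimulationState
from .phase import PhaseGrid
from .theory import Structure

__all__ = [
    "GRID_COLUMNS",
    "write_phase_grid",
    "read_phase_grid",
    "write_trajectory",
    "read_trajectory",
]

GRID_COLUMNS = ["lam", "dmu", "gamma", "winner", "dg_winner",
                "x_opt", "r_opt", "n_def"]


def grid_to_frame(grid: PhaseGrid) -> pd.DataFrame:
    rows = []
    for i, lam in enumerate(grid.lam_axis):
        for j, dmu in enumerate(grid.dmu_axis):
            rows.append({
                "lam": lam, "dmu": dmu, "gamma": grid.gamma,
                "winner": grid.labels[i, j].value,
                "dg_winner": grid.dg[i, j] if grid.dg is not None else np.nan,
                "x_opt": grid.x_opt[i, j] if grid.x_opt is not None else np.nan,
                "r_opt": grid.r_opt[i, j] if grid.r_opt is not None else np.nan,
                "n_def": int(grid.n_def[i, j]) if grid.n_def is not None else 0,
            })
    return pd.DataFrame(rows, columns=GRID_COLUMNS)


def write_phase_grid(grid: PhaseGrid, path) -> None:
    """Write a phase grid as tidy CSV, floats to 12 significant digits."""
    grid_to_frame(grid).to_csv(path, index=False, float_format="%.12g")


def read_phase_grid(path) -> PhaseGrid:
    """Read a tidy phase-grid CSV back into a :class:`PhaseGrid`."""
    df = pd.read_csv(path)
    missing = [c for c in GRID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phase-grid CSV {path} line 1: missing column(s) "
                         + ", ".join(missing))
    lam_axis = np.unique(df["lam"].to_numpy())
    dmu_axis = np.unique(df["dmu"].to_numpy())
    gammas = df["gamma"].unique()
    if len(gammas) != 1:
        raise ValueError("phase-grid CSV must hold a single gamma")
    nl, nd = len(lam_axis), len(dmu_axis)
    labels = np.empty((nl, nd), dtype=object)
    dg = np.full((nl, nd), np.nan)
    x_opt = np.full((nl, nd), np.nan)
    r_opt = np.full((nl, nd), np.nan)
    n_def = np.zeros((nl, nd), dtype=int)
    li = {v: k for k, v in enumerate(lam_axis)}
    dj = {v: k for k, v in enumerate(dmu_axis)}
    for row in df.itertuples(index=False):
        i, j = li[row.lam], dj[row.dmu]
        labels[i, j] = Structure(row.winner)
        dg[i, j] = row.dg_winner
        x_opt[i, j] = row.x_opt
        r_opt[i, j] = row.r_opt
        n_def[i, j] = int(row.n_def)
    return PhaseGrid(lam_axis=lam_axis, dmu_axis=dmu_axis,
                     gamma=float(gammas[0]), labels=labels, dg=dg,
                     x_opt=x_opt, r_opt=r_opt, n_def=n_def)


# --------------------------------------------------------------------------
# extended XYZ trajectories
# --------------------------------------------------------------------------

def write_trajectory(states, path) -> None:
    """Write states as extended XYZ: symbol x y z ox oy oz per record."""
    if isinstance(states, SimulationState):
        states = [states]
    with open(path, "w") as fh:
        for st in states:
            n = len(st.positions)
            fh.write(f"{n}\n")
            fh.write(f"step={st.step_count} box={st.box:.12g} "
                     f"dt={st.time_step:.12g} seed={st.rng_seed}\n")
            for p, o in zip(st.positions, st.orientations):
                fh.write("C " + " ".join(f"{v:.12g}" for v in (*p, *o)) + "\n")


def _parse_comment(line):
    out = {}
    for tok in line.split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            out[k] = v
    return out


def read_trajectory(path):
    """Read an extended XYZ trajectory back into SimulationState frames.

    Orientations that are not unit vectors are renormalized with a warning;
    an empty file yields an empty list.
    """
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        n = int(lines[k].strip())
        meta = _parse_comment(lines[k + 1])
        pos = np.empty((n, 3))
        ori = np.empty((n, 3))
        for irow in range(n):
            parts = lines[k + 2 + irow].split()
            if len(parts) != 7:
                raise ValueError(
                    f"{path}: record line {k + 3 + irow} has {len(parts)} "
                    "fields, expected 7 (symbol x y z ox oy oz)")
            pos[irow] = [float(v) for v in parts[1:4]]
            ori[irow] = [float(v) for v in parts[4:7]]
        norms = np.linalg.norm(ori, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            warnings.warn(f"{path}: non-unit orientation vectors "
                          "renormalized on read", stacklevel=2)
        ori /= np.where(norms > 0, norms, 1.0)[:, None]
        frames.append(SimulationState(
            positions=pos, orientations=ori,
            box=float(meta.get("box", 0.0)),
            time_step=float(meta.get("dt", 0.0)),
            rng_seed=int(meta.get("seed", 0)),
            step_count=int(meta.get("step", 0))))
        k += 2 + n
    return frames
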