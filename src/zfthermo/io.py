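"""File I/O: CSV dialects, the chelator-constants registry, PDB and XYZ.

CSV layouts (UTF-8, header row, decimal point):
  titration:    ph,absorbance
  competition:  pzn,ellipticity
  ITC:          volume_ul,heat_ucal
  channels:     frame,force,rc

Structures use standard PDB; trajectories multi-frame XYZ.  Both are read
through MDAnalysis when available (it is an optional runtime dependency of
this layer only).
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mdpost import Trajectory
from .speciation import Chelator
from .titration import CompetitionSeries, PhTitrationCurve

__all__ = [
    "read_titration_csv",
    "write_titration_csv",
    "read_competition_csv",
    "write_competition_csv",
    "read_itc_csv",
    "write_itc_csv",
    "load_chelators",
    "get_chelator",
    "read_pdb_coords",
    "write_pdb",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "read_channels_csv",
    "write_channels_csv",
]


def read_titration_csv(path, peptide_id: str | None = None,
                       wavelength: float = 218.0) -> PhTitrationCurve:
    df = pd.read_csv(path)
    return PhTitrationCurve(peptide_id or Path(path).stem,
                            df["ph"].to_numpy(), df["absorbance"].to_numpy(),
                            wavelength)


def write_titration_csv(curve: PhTitrationCurve, path) -> None:
    pd.DataFrame({"ph": curve.ph, "absorbance": curve.absorbance}).to_csv(
        path, index=False)


def read_competition_csv(path, peptide_id: str | None = None,
                         wavelength: float = 220.0) -> CompetitionSeries:
    df = pd.read_csv(path)
    return CompetitionSeries(peptide_id or Path(path).stem,
                             df["pzn"].to_numpy(), df["ellipticity"].to_numpy(),
                             wavelength)


def write_competition_csv(series: CompetitionSeries, path) -> None:
    pd.DataFrame({"pzn": series.pzn,
                  "ellipticity": series.ellipticity}).to_csv(path, index=False)


def read_itc_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Injection table -> (volumes uL, heats ucal)."""
    df = pd.read_csv(path)
    return df["volume_ul"].to_numpy(float), df["heat_ucal"].to_numpy(float)


def write_itc_csv(volumes_ul, heats_ucal, path) -> None:
    pd.DataFrame({"volume_ul": volumes_ul,
                  "heat_ucal": heats_ucal}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# chelator registry
# ---------------------------------------------------------------------------


def load_chelators(path=None) -> dict[str, Chelator]:
    """Chelator constants from a YAML registry (bundled file by default)."""
    if path is None:
        ref = importlib.resources.files("zfthermo").joinpath("data/chelators.yaml")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    out = {}
    for name, rec in raw["chelators"].items():
        out[name] = Chelator(
            name=name,
            log_protonation_constants=rec["log_protonation_constants"],
            log_beta_znl=rec["log_beta_znl"],
            log_beta_znhl=rec.get("log_beta_znhl"),
            reference=rec.get("reference", ""),
        )
    return out


def get_chelator(name: str, path=None) -> Chelator:
    reg = load_chelators(path)
    try:
        return reg[name]
    except KeyError:
        raise KeyError(
            f"unknown chelator {name!r}; available: {sorted(reg)}") from None


# ---------------------------------------------------------------------------
# structures and trajectories
# ---------------------------------------------------------------------------


def read_pdb_coords(path) -> dict[str, np.ndarray]:
    """Atom-name -> coordinates (A) from a PDB file via MDAnalysis."""
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    return {name: pos.copy() for name, pos in
            zip(u.atoms.names, u.atoms.positions)}


def write_pdb(coords: dict, path) -> None:
    """Write named atoms as HETATM records (element from the name's letters)."""
    import MDAnalysis as mda

    names = list(coords)
    n = len(names)
    u = mda.Universe.empty(n, trajectory=True)
    u.add_TopologyAttr("names", names)
    elements = ["".join(c for c in nm if c.isalpha())[:2] or "X" for nm in names]
    u.add_TopologyAttr("elements", elements)
    u.atoms.positions = np.array([coords[nm] for nm in names], dtype=float)
    u.atoms.write(str(path))


def read_xyz_trajectory(path, channels_csv=None) -> Trajectory:
    """Multi-frame XYZ (plus optional frame,force,rc CSV) -> Trajectory."""
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    atom_ids = list(u.atoms.names)
    coords = np.array([u.atoms.positions.copy() for _ in u.trajectory])
    force = rc = None
    if channels_csv is not None:
        force, rc = read_channels_csv(channels_csv)
    return Trajectory(atom_ids, coords, pulling_force=force,
                      reaction_coordinate=rc)


def write_xyz_trajectory(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        for frame in traj.coords:
            fh.write(f"{len(traj.atom_ids)}\n\n")
            for name, (x, y, z) in zip(traj.atom_ids, frame):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def read_channels_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["force"].to_numpy(float), df["rc"].to_numpy(float)


def write_channels_csv(traj: Trajectory, path) -> None:
    pd.DataFrame({
        "frame": np.arange(traj.n_frames),
        "force": traj.pulling_force,
        "rc": traj.reaction_coordinate,
    }).to_csv(path, index=False)
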