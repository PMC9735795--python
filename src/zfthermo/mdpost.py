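"""Post-analysis of (steered) MD trajectories of the Zn(II) site.

The Zn(Cys2His2) coordination is tracked through a smooth contact number
built from the rational switching function

    s(r) = (1 - (r/r0)^n) / (1 - (r/r0)^m),   n=8, m=12, r0=2.8 A

(removable singularity at r = r0 evaluated as n/m).  During constant-speed
pulling, each ligand's contact number drops from ~1 to 0 as its Zn-L bond
ruptures; the ordered drops define the dissociation pathway through the
ZnL3/ZnL2/ZnL1 intermediates.  The module also provides rupture-force and
pulling-work statistics, geometric hydrogen-bond detection, RMSD/RMSF, and
probability-based free-energy surfaces over projected coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Trajectory",
    "SwitchingParams",
    "ContactSeries",
    "DissociationPathway",
    "RuptureStats",
    "HBond",
    "Fes2D",
    "MdAnalysisError",
    "SelectionError",
    "switching_value",
    "contact_number",
    "contact_series",
    "classify_pathway",
    "pathway_census",
    "rupture_statistics",
    "detect_hbonds",
    "rmsd",
    "rmsf",
    "free_energy_surface",
]

R_KCAL = 1.9872e-3  # kcal/(mol K)


class MdAnalysisError(ValueError):
    pass


class SelectionError(MdAnalysisError):
    pass


@dataclass
class Trajectory:
    """Frames of named-atom coordinates plus optional pulling channels.

    coords: (n_frames, n_atoms, 3) in Angstrom; atom_ids name the columns.
    pulling_force in kcal/(mol A); reaction_coordinate in Angstrom.
    """

    atom_ids: Sequence[str]
    coords: np.ndarray
    pulling_force: Optional[np.ndarray] = None
    reaction_coordinate: Optional[np.ndarray] = None
    timestep_ps: float = 1.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise MdAnalysisError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != len(self.atom_ids):
            raise MdAnalysisError("atom_ids must match the coordinate columns")
        for name in ("pulling_force", "reaction_coordinate"):
            ch = getattr(self, name)
            if ch is not None:
                ch = np.asarray(ch, float)
                if ch.shape[0] != self.coords.shape[0]:
                    raise MdAnalysisError(f"{name} length must equal frame count")
                setattr(self, name, ch)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def index(self, atom_id: str) -> int:
        try:
            return list(self.atom_ids).index(atom_id)
        except ValueError:
            raise SelectionError(f"atom {atom_id!r} not in trajectory") from None


@dataclass(frozen=True)
class SwitchingParams:
    r0: float = 2.8
    n_exp: int = 8
    m_exp: int = 12

    def __post_init__(self):
        if not (0 < self.n_exp < self.m_exp):
            raise MdAnalysisError("require 0 < n < m")
        if self.r0 <= 0:
            raise MdAnalysisError("r0 must be positive")


@dataclass
class ContactSeries:
    """Per-ligand contact-number time series (same frame axis for all)."""

    series: dict  # ligand id -> np.ndarray of CN per frame

    def __post_init__(self):
        lengths = {len(v) for v in self.series.values()}
        if len(lengths) > 1:
            raise MdAnalysisError("all ligand series must share the frame axis")

    @property
    def n_frames(self) -> int:
        return next(iter(map(len, self.series.values())), 0)


@dataclass
class DissociationPathway:
    """Ordered ligand-release events; signature is the release sequence."""

    release_order: list  # [(ligand id, frame index), ...] strictly increasing
    intermediate_labels: list = field(default_factory=list)
    pre_dissociated: list = field(default_factory=list)

    @property
    def signature(self) -> tuple:
        return tuple(lig for lig, _ in self.release_order)


@dataclass
class RuptureStats:
    rupture_force: float  # global max pulling force of the replica
    per_event_force: dict  # ligand id -> max force in its release window
    per_cn_level_force: dict  # ligands-bound-before-event -> force
    total_work: float  # kcal/mol


@dataclass
class HBond:
    donor: str
    hydrogen: str
    acceptor: str
    distance: float  # donor-acceptor heavy-atom distance, A
    angle: float  # deviation from D-H...A linearity, degrees


@dataclass
class Fes2D:
    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray  # kcal/mol, min-shifted to 0; empty cells +inf
    minima: list  # [(i, j), ...] local minima on the grid


# ---------------------------------------------------------------------------
# switching function / contact numbers
# ---------------------------------------------------------------------------


def switching_value(r, params: SwitchingParams = SwitchingParams()):
    """Rational switching s(r) = (1 - (r/r0)^n) / (1 - (r/r0)^m).

    s(0) = 1, strictly decreasing, s -> 0 as r -> inf; the removable
    singularity at r = r0 is evaluated as its limit n/m.
    """
    r = np.asarray(r, float)
    if np.any(r < 0):
        raise MdAnalysisError("distance must be nonnegative")
    x = r / params.r0
    n, m = params.n_exp, params.m_exp
    near_one = np.abs(x - 1.0) < 1e-7
    xs = np.where(near_one, 0.5, x)  # safe placeholder, overwritten below
    with np.errstate(over="ignore"):
        val = (1.0 - xs**n) / (1.0 - xs**m)
    val = np.where(near_one, n / m, val)
    # large-x overflow -> limit x^(n-m) -> 0
    val = np.where(np.isfinite(val), val, 0.0)
    return float(val) if val.ndim == 0 else val


def contact_number(
    frame: np.ndarray,
    zn_index: int,
    ligand_indices: Sequence[int],
    params: SwitchingParams = SwitchingParams(),
) -> float:
    """Smooth Zn-ligand contact count: sum of s(r) over ligand atoms."""
    frame = np.asarray(frame, float)
    if zn_index >= frame.shape[0] or max(ligand_indices) >= frame.shape[0]:
        raise SelectionError("atom index outside frame")
    d = np.linalg.norm(frame[list(ligand_indices)] - frame[zn_index], axis=1)
    return float(np.sum(switching_value(d, params)))


def contact_series(
    traj: Trajectory,
    zn_id: str,
    ligand_atom_ids: dict,
    params: SwitchingParams = SwitchingParams(),
) -> ContactSeries:
    """Per-ligand CN time series; ligand_atom_ids maps ligand -> atom id list."""
    zn = traj.index(zn_id)
    series = {}
    for ligand, atoms in ligand_atom_ids.items():
        idx = [traj.index(a) for a in atoms]
        d = np.linalg.norm(traj.coords[:, idx, :] - traj.coords[:, [zn], :],
                           axis=2)
        series[ligand] = np.sum(switching_value(d, params), axis=1)
    return ContactSeries(series)


# ---------------------------------------------------------------------------
# dissociation pathways
# ---------------------------------------------------------------------------


def _release_frame(cn: np.ndarray, threshold: float, persistence: int):
    """First frame from which CN stays below threshold for >= persistence frames."""
    below = cn < threshold
    run = 0
    start = None
    for i, b in enumerate(below):
        if b:
            if start is None:
                start = i
            run += 1
            if run >= persistence:
                return start
        else:
            run = 0
            start = None
    return None


def classify_pathway(
    series: ContactSeries,
    bound_threshold: float = 0.5,
    persistence: int = 50,
) -> DissociationPathway:
    """Order the Zn-ligand release events from the contact-number traces.

    A ligand is released at the first frame after which its CN stays below
    bound_threshold for at least `persistence` consecutive frames (brief
    rebinding excursions shorter than that are tolerated).  Ligands already
    below threshold at frame 0 are flagged pre-dissociated, not released.
    """
    events = []
    pre = []
    for ligand, cn in series.series.items():
        if cn[0] < bound_threshold:
            pre.append(ligand)
            continue
        f = _release_frame(cn, bound_threshold, persistence)
        if f is not None:
            events.append((ligand, f))
    events.sort(key=lambda e: e[1])
    n_start = len(series.series) - len(pre)
    labels = [f"ZnL{n_start - k}" for k in range(len(events) + 1)]
    return DissociationPathway(release_order=events,
                               intermediate_labels=labels,
                               pre_dissociated=pre)


def pathway_census(pathways: Sequence[DissociationPathway]) -> dict:
    """Count pathway signatures; fractions sum to 1 over the replicas."""
    if len(pathways) == 0:
        raise MdAnalysisError("no pathways to tally")
    counts: dict = {}
    for p in pathways:
        counts[p.signature] = counts.get(p.signature, 0) + 1
    total = len(pathways)
    return {sig: (c, c / total) for sig, c in counts.items()}


def rupture_statistics(
    traj: Trajectory,
    series: ContactSeries,
    pathway: DissociationPathway,
) -> RuptureStats:
    """Rupture forces per release event and pulling work of the replica.

    Per-event force: maximum pulling force in the window between the
    preceding release (or frame 0) and the event frame.  The replica's
    rupture force is the global maximum over the run.  Work is the
    trapezoidal integral of force over the reaction coordinate.
    """
    if traj.pulling_force is None:
        raise MdAnalysisError("trajectory has no pulling-force channel")
    force = traj.pulling_force
    per_event = {}
    per_level = {}
    prev = 0
    bound = len(series.series) - len(pathway.pre_dissociated)
    for ligand, frame in pathway.release_order:
        window = force[prev:frame + 1]
        f = float(window.max()) if window.size else 0.0
        per_event[ligand] = f
        per_level[f"ZnL{bound}"] = f
        bound -= 1
        prev = frame
    if traj.reaction_coordinate is None:
        raise MdAnalysisError("trajectory has no reaction-coordinate channel")
    work = float(np.trapezoid(force, traj.reaction_coordinate))
    return RuptureStats(
        rupture_force=float(force.max()),
        per_event_force=per_event,
        per_cn_level_force=per_level,
        total_work=work,
    )


def mean_rupture_force(stats: Sequence[RuptureStats]) -> float:
    """Arithmetic mean of the per-replica rupture forces."""
    return float(np.mean([s.rupture_force for s in stats]))


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------


def detect_hbonds(
    coords: dict,
    donor_hydrogen_pairs: Sequence[tuple],
    acceptors: Sequence[str],
    d_max: float = 3.0,
    angle_max: float = 20.0,
) -> list[HBond]:
    """Geometric hydrogen bonds among named atoms.

    A bond is emitted when the donor-acceptor heavy-atom distance is below
    d_max (A) and the D-H...A axis deviates from linearity by less than
    angle_max degrees (deviation = 180 deg minus the D-H-A angle at H).
    """
    out = []
    for donor, hydrogen in donor_hydrogen_pairs:
        if donor not in coords or hydrogen not in coords:
            raise SelectionError(f"donor pair ({donor}, {hydrogen}) not in structure")
        d_xyz = np.asarray(coords[donor], float)
        h_xyz = np.asarray(coords[hydrogen], float)
        for acc in acceptors:
            if acc == donor or acc == hydrogen:
                continue
            if acc not in coords:
                raise SelectionError(f"acceptor {acc} not in structure")
            a_xyz = np.asarray(coords[acc], float)
            dist = float(np.linalg.norm(a_xyz - d_xyz))
            if dist >= d_max:
                continue
            v1 = d_xyz - h_xyz
            v2 = a_xyz - h_xyz
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            dha = math.degrees(math.acos(float(np.clip(cosang, -1.0, 1.0))))
            deviation = 180.0 - dha
            if deviation < angle_max:
                out.append(HBond(donor, hydrogen, acc, dist, deviation))
    return out


# ---------------------------------------------------------------------------
# RMSD / RMSF
# ---------------------------------------------------------------------------


def _superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal least-squares rigid alignment (Kabsch) of mobile onto reference."""
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(rc, mc)
    return rot.apply(mc) + reference.mean(axis=0)


def rmsd(
    frame: np.ndarray,
    reference: np.ndarray,
    selection: Optional[Sequence[int]] = None,
    superpose: bool = False,
) -> float:
    """Root-mean-square deviation between two frames over a selection."""
    frame = np.asarray(frame, float)
    reference = np.asarray(reference, float)
    if selection is not None:
        frame = frame[list(selection)]
        reference = reference[list(selection)]
    if frame.shape != reference.shape:
        raise SelectionError("mismatched atom counts")
    if superpose:
        frame = _superpose(frame, reference)
    return float(np.sqrt(np.mean(np.sum((frame - reference) ** 2, axis=1))))


def rmsf(traj: Trajectory, selection: Optional[Sequence[int]] = None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the mean structure."""
    coords = traj.coords
    if selection is not None:
        coords = coords[:, list(selection), :]
    mean = coords.mean(axis=0)
    return np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))


# ---------------------------------------------------------------------------
# free-energy surface
# ---------------------------------------------------------------------------


def free_energy_surface(
    xy_samples: np.ndarray,
    bins: int | Sequence[int] = 30,
    temperature: float = 298.15,
) -> Fes2D:
    """FES over two projected coordinates from state probabilities.

    F(cell) = -RT ln(p(cell)/p_max), minimum shifted to zero; unvisited
    cells are +inf.  Local minima are grid cells not exceeded by any of
    their 8 neighbours.
    """
    xy = np.asarray(xy_samples, float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise MdAnalysisError("xy_samples must be (n, 2)")
    if xy.shape[0] < 100:
        raise MdAnalysisError("need at least 100 samples")
    counts, xe, ye = np.histogram2d(xy[:, 0], xy[:, 1], bins=bins)
    p = counts / counts.sum()
    pmax = p.max()
    with np.errstate(divide="ignore"):
        fes = -R_KCAL * temperature * np.log(p / pmax)
    fes[p == 0] = np.inf

    minima = []
    nx, ny = fes.shape
    for i in range(nx):
        for j in range(ny):
            if not np.isfinite(fes[i, j]):
                continue
            neigh = fes[max(i - 1, 0):i + 2, max(j - 1, 0):j + 2]
            if fes[i, j] <= neigh.min():
                minima.append((i, j))
    return Fes2D(xe, ye, fes, minima)
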