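"""Synthetic-data generators with recorded ground truth.

Every input the analysis consumes — pH-titration traces, competition
ellipticity series, ITC isotherms, pulling trajectories with scripted
bond-rupture order, and hydrogen-bond test structures — can be generated
here under a fixed seed, so the whole pipeline is testable end to end
without instrument or simulation output.  Defaults mirror the regime the
analysis is designed for: femtomolar-range Zn(II) affinities
(-logKd 12.3-14.5), exothermic isotherms (dH_ITC -17 to -21 kcal/mol),
thiol pKa near 7.5-9, and four-ligand Zn(Cys2His2) release trajectories.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .itc import ItcExperiment, simulate_isotherm
from .mdpost import Trajectory
from .titration import (
    CompetitionSeries,
    HillFit,
    PhTitrationCurve,
    PkaFit,
    _eval_hill,
    _eval_titration,
)

__all__ = [
    "gen_ph_titration",
    "gen_competition_series",
    "gen_itc_isotherm",
    "gen_smd_trajectory",
    "gen_hbond_structure",
    "default_itc_design",
    "LIGAND_IDS",
]

LIGAND_IDS = ("Cys3", "Cys6", "His19", "His23")


def gen_ph_titration(
    pk1: float = 7.6,
    pk2: float = 8.8,
    a0: float = 0.05,
    a1: float = 0.45,
    a2: float = 0.85,
    ph_grid: Optional[np.ndarray] = None,
    noise_sd: float = 0.002,
    seed: int = 0,
    peptide_id: str = "synthetic",
) -> tuple[PhTitrationCurve, PkaFit]:
    """Two-proton titration curve plus its ground-truth parameters.

    Default grid pH 3..8 in 0.1 steps (51 points), the NaOH-titration window
    used for thiol pKa determination; additive Gaussian absorbance noise.
    """
    if pk1 > pk2:
        raise ValueError("require pk1 <= pk2")
    if ph_grid is None:
        ph_grid = np.round(np.arange(3.0, 8.0 + 1e-9, 0.1), 10)
    truth = PkaFit(pk1, pk2, a0, a1, a2)
    a = _eval_titration(pk1, pk2, a0, a1, a2, ph_grid)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, size=ph_grid.shape)
    return PhTitrationCurve(peptide_id, ph_grid, a), truth


def gen_competition_series(
    kd: float = 5.0e-13,
    hill_n: float = 1.0,
    theta_min: float = -10000.0,
    theta_max: float = -4000.0,
    pzn_grid: Optional[np.ndarray] = None,
    noise_frac: float = 0.01,
    seed: int = 0,
    peptide_id: str = "synthetic",
) -> tuple[CompetitionSeries, HillFit]:
    """Hill competition series (ellipticity vs pZn) plus ground truth.

    Default grid spans -log10(kd) +/- 2.25 pZn units; noise is Gaussian
    with sd = noise_frac times the signal range.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    if pzn_grid is None:
        center = -math.log10(kd)
        pzn_grid = np.linspace(center - 2.25, center + 2.25, 19)
    truth = HillFit(theta_min, theta_max, hill_n, kd)
    theta = _eval_hill(theta_min, theta_max, hill_n, kd, 10.0 ** (-pzn_grid))
    rng = np.random.default_rng(seed)
    if noise_frac > 0:
        theta = theta + rng.normal(
            0.0, noise_frac * abs(theta_max - theta_min), size=pzn_grid.shape
        )
    return CompetitionSeries(peptide_id, pzn_grid, theta), truth


def default_itc_design(
    n_injections: int = 25,
    injection_volume_ul: float = 6.82,
    cell_volume_ml: float = 1.0,
    cell_concentration: float = 30e-6,
    syringe_concentration: float = 0.35e-3,
) -> ItcExperiment:
    """The standard titration schedule: 25 x 6.82 uL of 0.35 mM Zn into
    1 mL of 30 uM peptide at 298.15 K in HEPES."""
    return ItcExperiment(
        cell_volume_ml=cell_volume_ml,
        cell_concentration=cell_concentration,
        syringe_concentration=syringe_concentration,
        injection_volumes_ul=np.full(n_injections, injection_volume_ul),
        heats_ucal=np.zeros(n_injections),
    )


def gen_itc_isotherm(
    kb: float = 1e8,
    dh: float = -20.0,
    n: float = 1.0,
    design: Optional[ItcExperiment] = None,
    dilution_offset: float = 0.0,
    noise_frac: float = 0.01,
    noise_floor_ucal: float = 0.1,
    seed: int = 0,
) -> tuple[ItcExperiment, dict]:
    """Single-site ITC isotherm plus ground truth.

    Heat noise is proportional to |heat| with an absolute floor, emulating
    integration error on small saturation-tail peaks.
    """
    if design is None:
        design = default_itc_design()
    heats = simulate_isotherm(kb, dh, n, design, dilution_offset)
    rng = np.random.default_rng(seed)
    if noise_frac > 0 or noise_floor_ucal > 0:
        sd = noise_frac * np.abs(heats) + noise_floor_ucal
        heats = heats + rng.normal(0.0, 1.0, size=heats.shape) * sd
    exp = ItcExperiment(
        cell_volume_ml=design.cell_volume_ml,
        cell_concentration=design.cell_concentration,
        syringe_concentration=design.syringe_concentration,
        injection_volumes_ul=design.injection_volumes_ul.copy(),
        heats_ucal=heats,
        temperature=design.temperature,
        buffer_name=design.buffer_name,
    )
    truth = {"kb": kb, "dh": dh, "n": n, "dilution_offset": dilution_offset}
    return exp, truth


# unit vectors separating the four ligands around the Zn centre
_LIGAND_DIRECTIONS = np.array([
    [1.0, 1.0, 1.0],
    [1.0, -1.0, -1.0],
    [-1.0, 1.0, -1.0],
    [-1.0, -1.0, 1.0],
]) / math.sqrt(3.0)


def gen_smd_trajectory(
    release_order: Sequence[str] = ("Cys3", "His19", "His23", "Cys6"),
    release_frames: Optional[Sequence[int]] = None,
    frame_count: int = 700,
    bound_distance: float = 2.3,
    unbound_distance: float = 9.0,
    ramp_frames: int = 10,
    force_peaks: Optional[dict] = None,
    force_baseline: float = 20.0,
    rc_span: float = 12.0,
    noise_amplitude: float = 0.05,
    seed: int = 0,
) -> tuple[Trajectory, dict]:
    """Scripted Zn-unbinding trajectory with known release order.

    Atoms are the Zn ion and one coordinating atom per ligand (Cys S-gamma,
    His N-epsilon).  Each ligand sits at the bound distance until its
    scripted frame, then ramps to beyond the switching cutoff.  The force
    channel carries a triangular peak at each release on a constant
    baseline; the reaction coordinate grows linearly.  Coordinate jitter is
    uniform within a sphere of radius noise_amplitude.
    """
    order = list(release_order)
    if sorted(order) != sorted(LIGAND_IDS):
        raise ValueError(f"release_order must be a permutation of {LIGAND_IDS}")
    if release_frames is None:
        step = frame_count // (len(order) + 1)
        release_frames = [step * (k + 1) for k in range(len(order))]
    release_frames = list(release_frames)
    if any(b <= a for a, b in zip(release_frames, release_frames[1:])):
        raise ValueError("release_frames must be strictly increasing")
    if release_frames[-1] + ramp_frames >= frame_count:
        raise ValueError("last release too close to the end of the run")

    rng = np.random.default_rng(seed)
    atom_ids = ["Zn"] + list(LIGAND_IDS)
    coords = np.zeros((frame_count, len(atom_ids), 3))
    t = np.arange(frame_count)

    frame_of = dict(zip(order, release_frames))
    for li, ligand in enumerate(LIGAND_IDS):
        f_rel = frame_of[ligand]
        # distance profile: bound, linear ramp over ramp_frames, unbound
        dist = np.full(frame_count, float(bound_distance))
        ramp = np.clip((t - f_rel) / max(ramp_frames, 1), 0.0, 1.0)
        dist = bound_distance + (unbound_distance - bound_distance) * ramp
        direction = _LIGAND_DIRECTIONS[li]
        coords[:, li + 1, :] = dist[:, None] * direction[None, :]

    if noise_amplitude > 0:
        # uniform jitter inside a sphere, applied to ligand atoms only
        v = rng.normal(size=(frame_count, len(LIGAND_IDS), 3))
        v /= np.linalg.norm(v, axis=2, keepdims=True)
        radius = noise_amplitude * rng.random((frame_count, len(LIGAND_IDS), 1)) ** (1 / 3)
        coords[:, 1:, :] += v * radius

    if force_peaks is None:
        force_peaks = {lig: 100.0 - 15.0 * k for k, lig in enumerate(order)}
    force = np.full(frame_count, force_baseline, float)
    half_width = max(ramp_frames, 5)
    for ligand, f_rel in frame_of.items():
        tri = np.clip(1.0 - np.abs(t - f_rel) / half_width, 0.0, 1.0)
        force = np.maximum(force, force_baseline + (force_peaks[ligand] - force_baseline) * tri)
    rc = np.linspace(0.0, rc_span, frame_count)

    traj = Trajectory(atom_ids, coords, pulling_force=force,
                      reaction_coordinate=rc)
    truth = {
        "release_order": order,
        "release_frames": release_frames,
        "force_peaks": force_peaks,
        "ligand_atoms": {lig: [lig] for lig in LIGAND_IDS},
    }
    return traj, truth


def gen_hbond_structure(
    specs: Sequence[tuple],
) -> tuple[dict, list]:
    """Place D, H, A triplets at exact requested geometry.

    Each spec is (d_a_distance, linearity_deviation_deg, should_pass).
    The donor sits at the triplet origin with its hydrogen 1.0 A along +x;
    the acceptor is placed so the donor-acceptor distance and the deviation
    of D-H...A from linearity are exactly as requested.  Triplets are
    spaced 50 A apart so only intra-triplet pairs can qualify.  Returns
    (coords dict, expected records), where each record carries the atom
    names and the expected pass/fail label.
    """
    coords: dict = {}
    expected = []
    for k, (d_a, dev_deg, should_pass) in enumerate(specs):
        if d_a <= 1.0:
            raise ValueError("donor-acceptor distance must exceed the D-H bond")
        dev = math.radians(dev_deg)
        # acceptor at H + t*u with u at angle dev off the D->H axis:
        # |A - D|^2 = (1 + t cos dev)^2 + (t sin dev)^2 = d_a^2
        t = -math.cos(dev) + math.sqrt(math.cos(dev) ** 2 - 1.0 + d_a**2)
        origin = np.array([50.0 * k, 0.0, 0.0])
        d_xyz = origin
        h_xyz = origin + np.array([1.0, 0.0, 0.0])
        a_xyz = h_xyz + t * np.array([math.cos(dev), math.sin(dev), 0.0])
        names = (f"D{k}", f"H{k}", f"A{k}")
        coords[names[0]] = d_xyz
        coords[names[1]] = h_xyz
        coords[names[2]] = a_xyz
        expected.append({
            "donor": names[0], "hydrogen": names[1], "acceptor": names[2],
            "d_a_distance": d_a, "deviation_deg": dev_deg,
            "should_pass": bool(should_pass),
        })
    return coords, expected
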