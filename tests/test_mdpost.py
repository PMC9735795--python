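"""Switching function, pathway classification, rupture/work, h-bonds, FES."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zfthermo.mdpost import (
    ContactSeries,
    MdAnalysisError,
    SelectionError,
    SwitchingParams,
    Trajectory,
    classify_pathway,
    contact_number,
    contact_series,
    detect_hbonds,
    free_energy_surface,
    mean_rupture_force,
    pathway_census,
    rmsd,
    rmsf,
    rupture_statistics,
    switching_value,
)
from zfthermo.synth import LIGAND_IDS, gen_hbond_structure, gen_smd_trajectory

R_KCAL = 1.9872e-3


class TestSwitchingFunction:
    def test_known_values(self):
        assert switching_value(0.0) == 1.0
        assert switching_value(2.8) == pytest.approx(8 / 12)
        assert switching_value(5.6) == pytest.approx(255 / 4095, rel=1e-12)
        assert switching_value(2.0) == pytest.approx(
            (1 - (2 / 2.8) ** 8) / (1 - (2 / 2.8) ** 12), rel=1e-12)

    def test_continuous_at_r0(self):
        for r in (2.8 - 1e-9, 2.8 + 1e-9):
            assert abs(switching_value(r) - 8 / 12) < 1e-6

    @given(
        r0=st.floats(1.0, 5.0),
        n=st.integers(2, 10),
        extra=st.integers(1, 8),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_strictly_decreasing(self, r0, n, extra):
        params = SwitchingParams(r0=r0, n_exp=n, m_exp=n + extra)
        r = np.linspace(0.0, 4 * r0, 400)
        s = switching_value(r, params)
        assert np.all(s > 0) and np.all(s <= 1.0)
        assert np.all(np.diff(s) < 1e-12)

    def test_far_limit(self):
        assert switching_value(100.0) < 1e-6


class TestContactNumber:
    def test_single_atom(self):
        frame = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        cn = contact_number(frame, 0, [1])
        x = 2.0 / 2.8
        assert cn == pytest.approx((1 - x**8) / (1 - x**12), rel=1e-12)

    def test_additivity(self):
        frame = np.array([[0.0, 0, 0], [2.5, 0, 0], [0, 2.5, 0]])
        assert contact_number(frame, 0, [1, 2]) == pytest.approx(
            2 * switching_value(2.5), rel=1e-12)

    def test_distant_atoms(self):
        # rational tail decays as (r/r0)^(n-m) = (r/r0)^-4
        frame = np.array([[0.0, 0, 0], [20.0, 0, 0]])
        assert contact_number(frame, 0, [1]) == pytest.approx(
            (20.0 / 2.8) ** -4, rel=1e-2)
        far = np.array([[0.0, 0, 0], [1000.0, 0, 0]])
        assert contact_number(far, 0, [1]) < 1e-6

    def test_missing_atom(self):
        with pytest.raises(SelectionError):
            contact_number(np.zeros((2, 3)), 0, [5])


class TestPathway:
    def _series(self, traj):
        return contact_series(traj, "Zn", {l: [l] for l in LIGAND_IDS})

    def test_scripted_order_recovered(self):
        order = ("Cys3", "His19", "His23", "Cys6")
        traj, _ = gen_smd_trajectory(release_order=order, seed=5)
        p = classify_pathway(self._series(traj))
        assert p.signature == order
        assert p.intermediate_labels == ["ZnL4", "ZnL3", "ZnL2", "ZnL1", "ZnL0"]
        frames = [f for _, f in p.release_order]
        assert frames == sorted(frames)

    def test_recovery_over_random_scripts(self):
        """All 50 random scripted replicas classify to their scripted order."""
        rng = np.random.default_rng(123)
        perms = list(itertools.permutations(LIGAND_IDS))
        for seed in range(50):
            order = perms[rng.integers(len(perms))]
            traj, truth = gen_smd_trajectory(release_order=order, seed=seed)
            p = classify_pathway(self._series(traj))
            assert list(p.signature) == truth["release_order"]

    def test_never_released(self):
        cn = {l: np.ones(200) for l in LIGAND_IDS}
        p = classify_pathway(ContactSeries(cn))
        assert p.release_order == []
        assert p.intermediate_labels == ["ZnL4"]

    def test_brief_dip_tolerated(self):
        cn = np.ones(300)
        cn[100:120] = 0.1  # 20 frames < persistence 50
        series = ContactSeries({"Cys3": cn, "Cys6": np.ones(300),
                                "His19": np.ones(300), "His23": np.ones(300)})
        assert classify_pathway(series).release_order == []

    def test_pre_dissociated_flag(self):
        series = ContactSeries({"Cys3": np.zeros(100), "Cys6": np.ones(100),
                                "His19": np.ones(100), "His23": np.ones(100)})
        p = classify_pathway(series)
        assert p.pre_dissociated == ["Cys3"]


class TestCensus:
    def test_dominant_fraction(self):
        dominant = ("Cys3", "His19", "His23", "Cys6")
        minor = ("Cys3", "His23", "His19", "Cys6")
        paths = []
        for seed in range(40):
            order = dominant if seed < 35 else minor
            traj, _ = gen_smd_trajectory(release_order=order, seed=seed)
            series = contact_series(traj, "Zn", {l: [l] for l in LIGAND_IDS})
            paths.append(classify_pathway(series))
        census = pathway_census(paths)
        assert census[dominant][1] == pytest.approx(0.875)
        assert sum(frac for _, frac in census.values()) == pytest.approx(1.0)

    def test_permutation_invariance_and_sum(self):
        traj_a, _ = gen_smd_trajectory(seed=0)
        traj_b, _ = gen_smd_trajectory(
            release_order=("Cys6", "His19", "His23", "Cys3"), seed=1)
        lig = {l: [l] for l in LIGAND_IDS}
        pa = classify_pathway(contact_series(traj_a, "Zn", lig))
        pb = classify_pathway(contact_series(traj_b, "Zn", lig))
        c1 = pathway_census([pa, pb])
        c2 = pathway_census([pb, pa])
        assert c1 == c2
        assert all(frac == 0.5 for _, frac in c1.values())

    def test_empty_rejected(self):
        with pytest.raises(MdAnalysisError):
            pathway_census([])


class TestRupture:
    def test_constant_force_work(self):
        traj = Trajectory(["Zn"], np.zeros((100, 1, 3)),
                          pulling_force=np.full(100, 5.0),
                          reaction_coordinate=np.linspace(0, 10, 100))
        series = ContactSeries({"Cys3": np.ones(100)})
        stats = rupture_statistics(traj, series, classify_pathway(series))
        assert stats.total_work == pytest.approx(50.0)
        assert stats.per_event_force == {}

    def test_scripted_peak_assigned_to_first_event(self):
        traj, truth = gen_smd_trajectory(seed=9, noise_amplitude=0.0)
        series = contact_series(traj, "Zn", {l: [l] for l in LIGAND_IDS})
        pathway = classify_pathway(series)
        stats = rupture_statistics(traj, series, pathway)
        first = truth["release_order"][0]
        assert stats.per_event_force[first] == pytest.approx(
            truth["force_peaks"][first], rel=1e-6)
        assert stats.rupture_force == pytest.approx(
            max(truth["force_peaks"].values()), rel=1e-6)
        assert set(stats.per_cn_level_force) == {"ZnL4", "ZnL3", "ZnL2", "ZnL1"}

    def test_zero_force(self):
        traj, _ = gen_smd_trajectory(seed=2)
        traj.pulling_force = np.zeros(traj.n_frames)
        series = contact_series(traj, "Zn", {l: [l] for l in LIGAND_IDS})
        stats = rupture_statistics(traj, series, classify_pathway(series))
        assert stats.total_work == 0.0
        assert all(v == 0.0 for v in stats.per_event_force.values())

    def test_missing_channel(self):
        traj = Trajectory(["Zn"], np.zeros((10, 1, 3)))
        series = ContactSeries({"Cys3": np.ones(10)})
        with pytest.raises(MdAnalysisError):
            rupture_statistics(traj, series, classify_pathway(series))

    def test_work_stride_invariance(self):
        """Trapezoidal work stable within 1% under 2x frame-stride refinement."""
        for n in (350, 700):
            t = np.linspace(0, 1, n)
            force = 50 + 40 * np.sin(2 * np.pi * t) ** 2
            rc = 12 * t
            traj = Trajectory(["Zn"], np.zeros((n, 1, 3)),
                              pulling_force=force, reaction_coordinate=rc)
            series = ContactSeries({"Cys3": np.ones(n)})
            w = rupture_statistics(traj, series,
                                   classify_pathway(series)).total_work
            if n == 350:
                w_coarse = w
        assert w == pytest.approx(w_coarse, rel=0.01)

    def test_mean_over_replicas(self):
        forces = []
        stats = []
        lig = {l: [l] for l in LIGAND_IDS}
        for seed in range(3):
            traj, truth = gen_smd_trajectory(seed=seed)
            series = contact_series(traj, "Zn", lig)
            s = rupture_statistics(traj, series, classify_pathway(series))
            stats.append(s)
            forces.append(s.rupture_force)
        assert mean_rupture_force(stats) == pytest.approx(np.mean(forces))


def brute_force_hbonds(coords, pairs, acceptors, d_max=3.0, angle_max=20.0):
    """O(N^2) reference: direct geometry per candidate triple."""
    found = []
    for (d, h) in pairs:
        for a in acceptors:
            if a in (d, h):
                continue
            dd = np.linalg.norm(np.asarray(coords[a]) - np.asarray(coords[d]))
            v1 = np.asarray(coords[d]) - np.asarray(coords[h])
            v2 = np.asarray(coords[a]) - np.asarray(coords[h])
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            dev = 180.0 - math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if dd < d_max and dev < angle_max:
                found.append((d, h, a))
    return found


class TestHBonds:
    def test_boundary_geometries(self):
        specs = [
            (2.9, 0.0, True),
            (3.2, 0.0, False),
            (2.8, 25.0, False),
            (2.8, 15.0, True),
            (2.8, 19.9, True),
            (2.8, 20.1, False),
        ]
        coords, expected = gen_hbond_structure(specs)
        pairs = [(e["donor"], e["hydrogen"]) for e in expected]
        acceptors = [e["acceptor"] for e in expected]
        bonds = detect_hbonds(coords, pairs, acceptors)
        got = {(b.donor, b.hydrogen, b.acceptor) for b in bonds}
        want = {(e["donor"], e["hydrogen"], e["acceptor"])
                for e in expected if e["should_pass"]}
        assert got == want
        for b in bonds:
            assert b.distance < 3.0 and b.angle < 20.0

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(7)
        specs = [(float(rng.uniform(2.2, 3.5)), float(rng.uniform(0, 40)), None)
                 for _ in range(25)]
        specs = [(d, a, True) for d, a, _ in specs]
        coords, expected = gen_hbond_structure(specs)
        pairs = [(e["donor"], e["hydrogen"]) for e in expected]
        acceptors = [e["acceptor"] for e in expected]
        got = {(b.donor, b.hydrogen, b.acceptor)
               for b in detect_hbonds(coords, pairs, acceptors)}
        assert got == set(brute_force_hbonds(coords, pairs, acceptors))

    def test_missing_donor_raises(self):
        with pytest.raises(SelectionError):
            detect_hbonds({"A0": np.zeros(3)}, [("D0", "H0")], ["A0"])


class TestRmsdRmsf:
    def test_identical_frames(self):
        f = np.random.default_rng(0).normal(size=(10, 3))
        assert rmsd(f, f) == 0.0

    def test_translation_pythagorean(self):
        f = np.random.default_rng(1).normal(size=(10, 3))
        g = f + np.array([3.0, 4.0, 0.0])
        assert rmsd(g, f) == pytest.approx(5.0, rel=1e-12)
        assert rmsd(g, f, superpose=True) == pytest.approx(0.0, abs=1e-8)

    def test_rotation_removed_by_superposition(self):
        from scipy.spatial.transform import Rotation
        f = np.random.default_rng(2).normal(size=(20, 3))
        rot = Rotation.from_euler("xyz", [30, -20, 45], degrees=True)
        g = rot.apply(f) + np.array([1.0, -2.0, 0.5])
        assert rmsd(g, f, superpose=True) == pytest.approx(0.0, abs=1e-8)

    def test_mismatched_selection(self):
        with pytest.raises(SelectionError):
            rmsd(np.zeros((5, 3)), np.zeros((6, 3)))

    def test_rmsf_static_is_zero(self):
        coords = np.tile(np.random.default_rng(3).normal(size=(1, 8, 3)), (50, 1, 1))
        traj = Trajectory([f"a{i}" for i in range(8)], coords)
        assert np.allclose(rmsf(traj), 0.0)

    def test_rmsf_known_oscillation(self):
        # one atom oscillating +/-1 A along x: rmsf = sqrt(mean(x^2)) = 1
        n = 1000
        coords = np.zeros((n, 2, 3))
        coords[:, 1, 0] = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        traj = Trajectory(["a", "b"], coords)
        assert rmsf(traj)[1] == pytest.approx(1.0, rel=1e-12)
        assert rmsf(traj)[0] == 0.0


class TestFes:
    def test_two_cluster_free_energy_gap(self):
        """9:1 occupancy -> dF = RT ln 9 ~ 1.30 kcal/mol at 298.15 K."""
        rng = np.random.default_rng(17)
        a = rng.normal(0.0, 0.1, size=(900, 2))
        b = rng.normal(5.0, 0.1, size=(100, 2))
        xy = np.vstack([a, b])
        surf = free_energy_surface(xy, bins=8)
        finite = surf.free_energy[np.isfinite(surf.free_energy)]
        gap = R_KCAL * 298.15 * math.log(9.0)
        # deepest two basins: 0 and ~gap
        vals = np.sort(np.unique(np.round(finite, 3)))
        assert vals[0] == 0.0
        assert np.min(np.abs(finite[finite > 0.5] - gap)) < 0.15

    def test_uniform_two_cells(self):
        rng = np.random.default_rng(5)
        x = np.where(rng.random(4000) < 0.5, 0.25, 0.75)
        y = np.full(4000, 0.5)
        xy = np.column_stack([x + rng.normal(0, 0.01, 4000), y])
        surf = free_energy_surface(xy, bins=2)
        finite = surf.free_energy[np.isfinite(surf.free_energy)]
        assert np.all(finite < 0.05)

    def test_single_cluster_single_minimum(self):
        xy = np.random.default_rng(9).normal(0, 0.01, size=(200, 2))
        surf = free_energy_surface(xy, bins=3)
        assert len(surf.minima) >= 1
        i, j = surf.minima[0]
        assert surf.free_energy[i, j] == 0.0

    def test_too_few_samples(self):
        with pytest.raises(MdAnalysisError):
            free_energy_surface(np.zeros((50, 2)))
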