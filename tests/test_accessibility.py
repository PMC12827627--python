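"""Large-probe ASA, domain widths, nearest-obstruction distances and the
simultaneous-binding probability, checked against closed forms and
independent brute-force recounts."""

import numpy as np
import pytest

from avidkit import (
    BeadStructure,
    DomainMap,
    Ensemble,
    ToyIgMParams,
    asa_timeseries,
    binding_accessibility,
    compute_asa,
    domain_widths,
    generate_toy_igm,
    nearest_obstruction_distance,
)
from conftest import make_structure


def beads_at(positions, radii=None):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return BeadStructure(
        positions=positions,
        radii=np.full(n, 0.235) if radii is None else np.asarray(radii, float),
        chain_ids=np.full(n, "A"),
        residue_indices=np.arange(1, n + 1),
        residue_names=np.full(n, "UNK"),
        bead_names=np.full(n, "BB"),
    )


class TestASA:
    def test_isolated_bead_closed_form(self):
        """One bead, r = 0.235 nm, probe 3.5 nm: area = 4π(3.735)² = 175.30 nm²."""
        s = beads_at([[0, 0, 0]])
        res = compute_asa(s, [0], probe_radius=3.5, n_sphere_points=960)
        expected = 4 * np.pi * 3.735**2
        assert res.total_area == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(175.30, abs=0.01)

    def test_full_occlusion_by_engulfing_bead(self):
        s = beads_at([[0, 0, 0], [0.01, 0, 0]], radii=[0.1, 5.0])
        res = compute_asa(s, [0], probe_radius=1.0)
        assert res.per_bead_area[0] == 0.0

    def test_two_sphere_spherical_cap_analytic(self):
        """Two equal beads r=0.5, probe 1.0, d=1.5: exposed = 2πρ(2ρ − h), h = ρ − d/2."""
        rho, d = 1.5, 1.5
        s = beads_at([[0, 0, 0], [d, 0, 0]], radii=[0.5, 0.5])
        res = compute_asa(s, [0, 1], probe_radius=1.0, n_sphere_points=4096)
        h = rho - d / 2
        analytic = 2 * np.pi * rho * (2 * rho - h)
        assert res.per_bead_area[0] == pytest.approx(analytic, rel=0.01)
        assert res.per_bead_area[1] == pytest.approx(analytic, rel=0.01)
        # independent dense-point brute force with a different (seeded random) point set
        rng = np.random.default_rng(99)
        pts = rng.normal(size=(200_000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        surf = s.positions[0] + rho * pts
        exposed = np.linalg.norm(surf - s.positions[1], axis=1) >= rho
        brute = exposed.mean() * 4 * np.pi * rho**2
        assert res.per_bead_area[0] == pytest.approx(brute, rel=0.01)

    def test_monotone_under_added_occluders(self):
        base = beads_at([[0, 0, 0]])
        area0 = compute_asa(base, [0], 1.0).total_area
        areas = [area0]
        positions = [[0.0, 0, 0]]
        for k in range(1, 4):
            positions.append([0.5 * k, 0.3, 0.0])
            s = beads_at(positions)
            areas.append(compute_asa(s, [0], 1.0).per_bead_area[0])
        assert all(a <= b + 1e-12 for a, b in zip(areas[1:], areas[:-1]))

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation

        s = make_structure(30, seed=6, scale=2.0)
        sel = np.arange(5)
        a1 = compute_asa(s, sel, 1.5).total_area
        # translation is exactly invariant (lattice moves with each bead)
        s_t = s.with_positions(s.positions + np.array([3.0, -2.0, 9.0]))
        assert compute_asa(s_t, sel, 1.5).total_area == pytest.approx(a1, rel=1e-12)
        # rotation is invariant up to lattice discretisation
        rot = Rotation.from_rotvec([0.3, -1.2, 0.7]).as_matrix()
        s_r = s.with_positions(s.positions @ rot.T)
        assert compute_asa(s_r, sel, 1.5).total_area == pytest.approx(a1, rel=0.02)

    def test_point_density_convergence(self):
        """Doubling the sphere lattice changes the total by < 0.5%."""
        s = make_structure(40, seed=7, scale=1.5)
        sel = np.arange(10)
        a1 = compute_asa(s, sel, 1.0, n_sphere_points=960).total_area
        a2 = compute_asa(s, sel, 1.0, n_sphere_points=1920).total_area
        assert abs(a1 - a2) / a2 < 0.005

    def test_empty_selection_and_negative_probe_raise(self):
        s = beads_at([[0, 0, 0]])
        with pytest.raises(ValueError):
            compute_asa(s, [], 1.0)
        with pytest.raises(ValueError):
            compute_asa(s, [0], -0.5)

    def test_timeseries_decomposes_per_frame(self, small_toy):
        ens, dmap = small_toy
        sub = Ensemble(ens.topology, ens.frames[:4], ens.frame_spacing)
        series = asa_timeseries(sub, dmap, "CDR_1", probe_radius=2.0, n_sphere_points=128)
        for f in range(4):
            frame_struct = ens.topology.with_positions(ens.frames[f])
            direct = compute_asa(frame_struct, dmap["CDR_1"], 2.0, 128).total_area
            assert series[f] == pytest.approx(direct, rel=1e-12)

    def test_timeseries_constant_on_static_ensemble(self, frozen_toy):
        ens, dmap = frozen_toy
        sub = Ensemble(ens.topology, ens.frames[:3], ens.frame_spacing)
        series = asa_timeseries(sub, dmap, "CDR_2", probe_radius=2.0, n_sphere_points=64)
        assert np.ptp(series) == 0.0


class TestDomainWidths:
    def test_two_beads(self):
        s = beads_at([[0, 0, 0], [2.0, 0, 0]])
        max_w, _ = domain_widths(s, [0, 1])
        assert max_w == pytest.approx(2.0)

    def test_matches_brute_force_on_random_cloud(self):
        s = make_structure(200, seed=10, scale=4.0)
        sel = np.arange(200)
        max_w, min_w = domain_widths(s, sel)
        # O(N²) pairwise maximum
        pts = s.positions
        brute_max = 0.0
        for i in range(200):
            d = np.linalg.norm(pts - pts[i], axis=1).max()
            brute_max = max(brute_max, d)
        assert max_w == pytest.approx(brute_max, abs=1e-12)
        # independent eigendecomposition of the covariance
        c = pts - pts.mean(axis=0)
        vals, vecs = np.linalg.eigh(c.T @ c / len(c))
        extents = [(c @ vecs[:, k]).max() - (c @ vecs[:, k]).min() for k in range(3)]
        assert min_w == pytest.approx(min(extents), abs=1e-12)

    def test_single_bead_raises(self):
        s = beads_at([[0, 0, 0]])
        with pytest.raises(ValueError):
            domain_widths(s, [0])


def two_fab_map():
    """Hand-built frame: CDR_1 COM at origin, Fab_2 beads at 1.0/2.5/3.0 nm."""
    frame = np.array(
        [
            [0.0, 0.0, 0.0],   # Fab_1 / CDR_1
            [-1.0, 0.0, 0.0],  # Fab_1 stem
            [1.0, 0.0, 0.0],   # Fab_2
            [2.5, 0.0, 0.0],
            [3.0, 0.0, 0.0],
        ]
    )
    dmap = DomainMap(
        domains={
            "Fab_1": [0, 1],
            "CDR_1": [0],
            "Fab_2": [2, 3, 4],
            "CDR_2": [2],
        },
        fab_ids=["Fab_1", "Fab_2"],
        cdr_of={"Fab_1": "CDR_1", "Fab_2": "CDR_2"},
    )
    return frame, dmap


class TestNearestObstruction:
    def test_hand_checkable_minimum(self):
        frame, dmap = two_fab_map()
        assert nearest_obstruction_distance(frame, dmap, "Fab_1") == pytest.approx(1.0)

    def test_no_obstructions_gives_infinity(self):
        frame = np.zeros((2, 3))
        frame[1, 0] = 1.0
        dmap = DomainMap(
            domains={"Fab_1": [0, 1], "CDR_1": [0]},
            fab_ids=["Fab_1"],
            cdr_of={"Fab_1": "CDR_1"},
        )
        assert nearest_obstruction_distance(frame, dmap, "Fab_1") == np.inf

    def test_unknown_fab_raises(self):
        frame, dmap = two_fab_map()
        with pytest.raises(KeyError):
            nearest_obstruction_distance(frame, dmap, "Fab_9")

    def test_matches_exhaustive_loop_on_toy_frames(self, small_toy):
        ens, dmap = small_toy
        for f in (0, 7, 19):
            frame = ens.frames[f]
            for fab in dmap.fab_ids[:4]:
                got = nearest_obstruction_distance(frame, dmap, fab)
                # exhaustive recount over all non-excluded beads
                cdr = dmap.cdr_of[fab]
                com = frame[dmap[cdr]].mean(axis=0)
                fab_beads = set(dmap[fab].tolist())
                best = np.inf
                for name, idx in dmap.domains.items():
                    if name == fab or name == cdr:
                        continue
                    for i in idx:
                        if int(i) in fab_beads:
                            continue
                        best = min(best, float(np.linalg.norm(frame[int(i)] - com)))
                assert got == pytest.approx(best, abs=1e-12)

    def test_residue_com_mode(self):
        """Residue mode measures to residue centres of mass, not bead centres."""
        # Fab_2's first residue has two beads at x = 1.0 and 2.0: residue COM 1.5
        frame = np.array(
            [[0.0, 0, 0], [-1.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [5.0, 0, 0]]
        )
        topo = BeadStructure(
            positions=frame,
            radii=np.full(5, 0.235),
            chain_ids=np.full(5, "A"),
            residue_indices=[1, 2, 3, 3, 4],
            residue_names=np.full(5, "UNK"),
            bead_names=["BB", "BB", "BB", "SC", "BB"],
        )
        dmap = DomainMap(
            domains={"Fab_1": [0, 1], "CDR_1": [0], "Fab_2": [2, 3, 4], "CDR_2": [4]},
            fab_ids=["Fab_1", "Fab_2"],
            cdr_of={"Fab_1": "CDR_1", "Fab_2": "CDR_2"},
        )
        assert nearest_obstruction_distance(frame, dmap, "Fab_1") == pytest.approx(1.0)
        d_res = nearest_obstruction_distance(
            frame, dmap, "Fab_1", obstruction_mode="residue", topology=topo
        )
        assert d_res == pytest.approx(1.5)
        ens = Ensemble(topo, frame[None])
        res = binding_accessibility(ens, dmap, threshold=1.2, obstruction_mode="residue")
        assert res.per_fab_probability["Fab_1"] == 1.0

    def test_rigid_motion_invariance(self, small_toy):
        from scipy.spatial.transform import Rotation

        ens, dmap = small_toy
        frame = ens.frames[0]
        rot = Rotation.from_rotvec([1.0, 0.2, -0.5]).as_matrix()
        moved = frame @ rot.T + np.array([5.0, 5.0, 5.0])
        for fab in ("Fab_1", "Fab_6"):
            d1 = nearest_obstruction_distance(frame, dmap, fab)
            d2 = nearest_obstruction_distance(moved, dmap, fab)
            assert d1 == pytest.approx(d2, rel=1e-10)


class TestBindingAccessibility:
    def test_widely_separated_arms_give_probability_one(self, frozen_toy):
        ens, dmap = frozen_toy
        res = binding_accessibility(ens, dmap, threshold=1.8)
        assert res.overall_probability == 1.0

    def test_pinned_fab_probability_zero(self):
        frame, dmap = two_fab_map()
        frame = frame.copy()
        frame[2] = [0.5, 0.0, 0.0]  # obstruction 0.5 nm from CDR_1 COM
        topo = beads_at(frame)
        ens = Ensemble(topo, np.stack([frame] * 4))
        res = binding_accessibility(ens, dmap, threshold=1.8)
        assert res.per_fab_probability["Fab_1"] == 0.0

    def test_threshold_tie_counts_accessible(self):
        frame, dmap = two_fab_map()
        topo = beads_at(frame)
        ens = Ensemble(topo, frame[None])
        res = binding_accessibility(ens, dmap, threshold=1.0)
        assert res.per_fab_probability["Fab_1"] == 1.0

    def test_matches_brute_force_recount(self, small_toy):
        ens, dmap = small_toy
        res = binding_accessibility(ens, dmap, threshold=1.8)
        n_acc = 0
        total = 0
        for f in range(ens.n_frames):
            for fab in dmap.fab_ids:
                d = nearest_obstruction_distance(ens.frames[f], dmap, fab)
                n_acc += d >= 1.8
                total += 1
        assert res.n_configurations == total == ens.n_frames * 10
        assert res.overall_probability == pytest.approx(n_acc / total, abs=0)

    def test_frame_order_and_concatenation_invariance(self, small_toy):
        ens, dmap = small_toy
        rng = np.random.default_rng(0)
        perm = rng.permutation(ens.n_frames)
        shuffled = Ensemble(ens.topology, ens.frames[perm], ens.frame_spacing)
        a = binding_accessibility(ens, dmap)
        b = binding_accessibility(shuffled, dmap)
        assert a.overall_probability == b.overall_probability
        half = ens.n_frames // 2
        e1 = Ensemble(ens.topology, ens.frames[:half], ens.frame_spacing)
        e2 = Ensemble(ens.topology, ens.frames[half:], ens.frame_spacing)
        c = binding_accessibility([e1, e2], dmap)
        d = binding_accessibility([e2, e1], dmap)
        assert c.overall_probability == d.overall_probability == a.overall_probability

    def test_overall_is_mean_of_per_fab_at_equal_counts(self, small_toy):
        ens, dmap = small_toy
        res = binding_accessibility(ens, dmap)
        assert res.overall_probability == pytest.approx(
            np.mean(list(res.per_fab_probability.values())), abs=1e-12
        )

    def test_missing_fab_ids_raises(self, small_toy):
        ens, dmap = small_toy
        empty = DomainMap(domains=dict(dmap.domains), fab_ids=[], cdr_of={})
        with pytest.raises(ValueError, match="Fab"):
            binding_accessibility(ens, empty)
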