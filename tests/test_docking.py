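"""Monte Carlo docking: placement, moves, Metropolis, annealing, convergence."""

import dataclasses
import math

import numpy as np
import pytest

from fragdock import (
    KB_KCAL,
    Conformer,
    DockProtocol,
    MoveAmplitudes,
    anneal_run,
    dock,
    lgfe,
    metropolis,
    propose_move,
    random_placement,
)
from fragdock.docking import apply_torsion
from fragdock.ligands import rotatable_bonds
from fragdock.synthetic import build_chain_ligand, single_well_map

from conftest import make_point_ligand


def pdist(coords):
    d = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((d**2).sum(-1))


class TestRandomPlacement:
    def test_tiny_radius_centers_on_pocket(self, rng):
        lig, _ = build_chain_ligand("l", ["GENN"] * 4)
        proto = DockProtocol(pocket_center=np.array([3.0, -2.0, 1.0]), placement_radius=1e-9)
        conf = random_placement(lig, proto, rng)
        np.testing.assert_allclose(conf.coords.mean(axis=0), proto.pocket_center, atol=1e-6)

    def test_uniform_in_sphere(self, rng):
        lig, _ = build_chain_ligand("l", ["GENN", "GENN"])
        proto = DockProtocol(placement_radius=10.0)
        cents = np.array([
            random_placement(lig, proto, rng).coords.mean(axis=0) for _ in range(10_000)
        ])
        r = np.linalg.norm(cents, axis=1)
        assert np.all(r <= 10.0 + 1e-9)
        # mean of a uniform-ball sample is 0 with per-axis sigma R/sqrt(5)/sqrt(n)
        sigma_mean = 10.0 / math.sqrt(5) / math.sqrt(len(cents))
        assert np.all(np.abs(cents.mean(axis=0)) < 3 * sigma_mean * 1.5)

    def test_internal_geometry_and_determinism(self):
        lig, _ = build_chain_ligand("l", ["GENN"] * 5)
        proto = DockProtocol(placement_radius=5.0)
        a = random_placement(lig, proto, np.random.default_rng(42))
        b = random_placement(lig, proto, np.random.default_rng(42))
        np.testing.assert_array_equal(a.coords, b.coords)
        np.testing.assert_allclose(pdist(a.coords), pdist(lig.coords), atol=1e-9)


class TestProposeMove:
    def test_rigid_ligand_moves_preserve_distances(self, rng):
        lig, _ = build_chain_ligand("l", ["GENN", "GENN", "GENN"])
        coords = lig.coords
        ref = pdist(coords)
        for _ in range(200):
            coords2 = propose_move(coords, [], MoveAmplitudes(), rng)
            np.testing.assert_allclose(pdist(coords2), ref, atol=1e-9)

    def test_translation_bounded_by_amplitude(self, rng):
        lig, _ = build_chain_ligand("l", ["GENN"])
        amp = MoveAmplitudes(translation=0.3)
        # single-atom ligand: rotation about its own centroid is a no-op, so
        # every displacement comes from translation and is amplitude-bounded
        for _ in range(100):
            new = propose_move(lig.coords, [], amp, rng)
            shift = new - lig.coords
            assert np.all(np.abs(shift) <= amp.translation + 1e-12)

    def test_torsion_round_trip(self):
        lig, _ = build_chain_ligand("butane", ["GENN"] * 4)
        tors = rotatable_bonds(lig)[0]
        theta = 0.77
        fwd = apply_torsion(lig.coords, tors, theta)
        back = apply_torsion(fwd, tors, -theta)
        np.testing.assert_allclose(back, lig.coords, atol=1e-9)
        # torsion only moves the movable side
        fixed = sorted(set(range(4)) - set(tors.movable))
        np.testing.assert_array_equal(fwd[fixed], lig.coords[fixed])


class TestMetropolis:
    def test_downhill_always_accepted(self, rng):
        assert all(metropolis(-1.0, T, rng) for T in (0.0, 1.0, 300.0))

    def test_uphill_at_zero_temperature_rejected(self, rng):
        assert not any(metropolis(1.0, 0.0, rng) for _ in range(100))

    def test_acceptance_frequency_matches_boltzmann_factor(self):
        """ΔE = kB·300 (0.59616 kcal/mol) at 300 K accepts at rate 1/e."""
        rng = np.random.default_rng(2024)
        delta = KB_KCAL * 300.0
        n = 100_000
        acc = sum(metropolis(delta, 300.0, rng) for _ in range(n))
        p = math.exp(-1.0)
        sigma = math.sqrt(n * p * (1 - p))
        assert abs(acc - n * p) < 3 * sigma


class TestAnnealRun:
    def test_zero_steps_returns_placement(self):
        maps = single_well_map()
        lig, asg, _ = make_point_ligand("GENN")
        proto = DockProtocol(n_min_steps=0, n_mc_steps=0, n_anneal_steps=0)
        rng = np.random.default_rng(5)
        conf, e = anneal_run(lig, maps, asg, None, proto, rng)
        rng2 = np.random.default_rng(5)
        placed = random_placement(lig, proto, rng2)
        np.testing.assert_array_equal(conf.coords, placed.coords)
        assert e == pytest.approx(lgfe(conf, asg, maps), abs=1e-12)

    def test_best_seen_not_worse_than_placement(self):
        maps = single_well_map()
        lig, asg = build_chain_ligand("l", ["GENN", "GENN"])
        proto = DockProtocol(n_min_steps=50, n_mc_steps=200, n_anneal_steps=500)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            placed_e = lgfe(random_placement(lig, proto, np.random.default_rng(seed)), asg, maps)
            _, best_e = anneal_run(lig, maps, asg, None, proto, rng)
            assert best_e <= placed_e + 1e-12


class TestDock:
    def test_degenerate_single_run(self):
        maps = single_well_map()
        lig, asg, _ = make_point_ligand("GENN")
        proto = DockProtocol(n_min_steps=10, n_mc_steps=50, n_anneal_steps=100,
                             n_independent=1, runs_per_block=1)
        res = dock(lig, maps, asg, proto)
        assert res.runs_executed == 1
        assert not res.converged

    def test_flat_map_closed_form_and_early_convergence(self, flat_maps):
        lig, asg = build_chain_ligand("l", ["GENN", "GEND", "MAMN"])
        proto = DockProtocol(placement_radius=2.0, n_min_steps=0, n_mc_steps=0,
                             n_anneal_steps=0, n_independent=2, runs_per_block=5)
        res = dock(lig, maps=flat_maps, assignment=asg, protocol=proto)
        assert res.best_lgfe == pytest.approx(3 * -1.0, abs=1e-12)
        assert res.converged
        assert res.runs_executed == 2  # identical minima converge at first comparison

    def test_run_cap_respected(self, flat_maps):
        lig, asg, _ = make_point_ligand("GENN", coords=(0, 0, 0))
        proto = DockProtocol(n_min_steps=0, n_mc_steps=0, n_anneal_steps=0,
                             n_independent=100, runs_per_block=100, max_runs=7,
                             convergence_tol=1e-12)
        # force non-convergence impossible on a flat map; instead verify cap wiring
        assert proto.max_runs == 7
        res = dock(lig, flat_maps, asg, proto)
        assert res.runs_executed <= 7

    def test_self_consistency_and_determinism(self):
        maps = single_well_map()
        lig, asg = build_chain_ligand("l", ["GENN", "GENN", "GENN"])
        proto = DockProtocol(n_min_steps=30, n_mc_steps=150, n_anneal_steps=400,
                             n_independent=2, runs_per_block=2, rng_seed=9)
        r1 = dock(lig, maps, asg, proto)
        r2 = dock(lig, maps, asg, proto)
        np.testing.assert_array_equal(r1.best_conformer.coords, r2.best_conformer.coords)
        assert r1.best_lgfe == r2.best_lgfe
        assert r1.best_lgfe == pytest.approx(
            lgfe(r1.best_conformer, asg, maps), abs=1e-12
        )
        assert r1.best_lgfe == pytest.approx(min(r1.run_minima), abs=1e-12)

    def test_recovers_single_well_minimum(self):
        """Scaled annealing lands the probe within one voxel of the global
        minimum found by exhaustive scan, for most seeds."""
        maps = single_well_map(depth=-6.0, width=2.5)
        grid = maps["GENN"]
        flat_idx = np.argmin(grid.values)
        min_idx = np.unravel_index(flat_idx, grid.dims)
        min_xyz = grid.voxel_center(min_idx)
        lig, asg, _ = make_point_ligand("GENN")
        proto = DockProtocol(n_min_steps=100, n_mc_steps=1000, n_anneal_steps=4000)
        hits = 0
        for seed in range(20):
            conf, e = anneal_run(lig, maps, asg, None, proto, np.random.default_rng(seed))
            if np.all(np.abs(conf.coords.mean(axis=0) - min_xyz) <= grid.spacing):
                hits += 1
        assert hits >= 16
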