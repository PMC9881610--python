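"""FragMap weight optimization: flat-bottom penalty, objective, MCSA, redock."""

import numpy as np
import pytest

from fragdock import (
    AtomicGFETable,
    BMLConfig,
    Conformer,
    DockProtocol,
    WeightVector,
    atomic_gfes,
    bml_objective,
    flat_bottom_penalty,
    load_weights,
    mcsa_optimize,
    redock_evaluate,
    save_weights,
)
from fragdock.bml import RedockReport
from fragdock.metrics import pearson_r
from fragdock.synthetic import SyntheticSpec, build_chain_ligand, make_bml_dataset, make_fragmaps


@pytest.fixture
def noiseless_table():
    spec = SyntheticSpec(n_ligands=40, noise_sigma=0.0, rng_seed=11)
    return make_bml_dataset(spec)


class TestFlatBottomPenalty:
    def test_interior_is_exactly_zero(self):
        cfg = BMLConfig()
        w = WeightVector({"GENN": 0.05, "GEND": 2.0, "GENA": 1.0})
        assert flat_bottom_penalty(w, cfg) == 0.0

    def test_closed_form_above_upper(self):
        cfg = BMLConfig()
        assert flat_bottom_penalty(WeightVector({"GENN": 2.5}), cfg) == pytest.approx(
            5000.0 * 0.5**2, abs=1e-12
        )

    def test_closed_form_below_lower(self):
        cfg = BMLConfig()
        assert flat_bottom_penalty(WeightVector({"GENN": 0.04}), cfg) == pytest.approx(
            5000.0 * 0.01**2, abs=1e-12
        )

    def test_penalties_sum_over_types(self):
        cfg = BMLConfig()
        w = WeightVector({"A": 2.5, "B": 0.04, "C": 1.0})
        assert flat_bottom_penalty(w, cfg) == pytest.approx(1250.0 + 0.5, abs=1e-12)


class TestObjective:
    def test_true_weights_on_noiseless_table(self, noiseless_table):
        table, w_star = noiseless_table
        loss = bml_objective(WeightVector(w_star), table, BMLConfig())
        assert loss == pytest.approx(-1.0, abs=1e-9)

    def test_zero_weights_degenerate_guard(self, noiseless_table):
        table, _ = noiseless_table
        w0 = WeightVector({t: 0.0 for t in table.map_types})
        with pytest.warns(UserWarning, match="zero-variance"):
            loss = bml_objective(w0, table, BMLConfig())
        assert loss == pytest.approx(flat_bottom_penalty(w0, BMLConfig()), abs=1e-12)

    def test_matches_independent_recomputation(self, noiseless_table, rng):
        table, _ = noiseless_table
        cfg = BMLConfig()
        for _ in range(5):
            w = WeightVector({t: rng.uniform(0.0, 2.5) for t in table.map_types})
            pred = table.predicted_pic50(w)
            # independent Pearson via the definitional formula
            x, y = pred - pred.mean(), table.exp_pic50 - table.exp_pic50.mean()
            r = float((x * y).sum() / np.sqrt((x**2).sum() * (y**2).sum()))
            expected = -r + flat_bottom_penalty(w, cfg)
            assert bml_objective(w, table, cfg) == pytest.approx(expected, abs=1e-12)

    def test_too_few_ligands_for_pearson(self):
        table = AtomicGFETable(["a", "b"], ["GENN"], np.array([[-1.0], [-2.0]]),
                               np.array([5.0, 6.0]))
        with pytest.raises(ValueError, match="at least 3"):
            bml_objective(WeightVector({"GENN": 1.0}), table, BMLConfig())


class TestMcsa:
    def test_zero_steps_returns_unit_weights(self, noiseless_table):
        table, _ = noiseless_table
        w = mcsa_optimize(table, BMLConfig(n_mcsa_steps=0))
        assert all(w[t] == 1.0 for t in table.map_types)

    def test_noiseless_recovery_reaches_perfect_correlation(self, noiseless_table):
        table, _ = noiseless_table
        w = mcsa_optimize(table, BMLConfig(n_mcsa_steps=20_000, rng_seed=3))
        assert pearson_r(table.predicted_pic50(w), table.exp_pic50) >= 0.999

    def test_noisy_recovery_and_bounds(self):
        """σ = 0.3 pIC50 noise: training R ≥ 0.9, weights inside the flat bottom."""
        cfg = BMLConfig(n_mcsa_steps=15_000)
        ok = 0
        for seed in range(3):
            table, _ = make_bml_dataset(SyntheticSpec(n_ligands=50, noise_sigma=0.3, rng_seed=seed))
            w = mcsa_optimize(table, BMLConfig(n_mcsa_steps=cfg.n_mcsa_steps, rng_seed=seed))
            r = pearson_r(table.predicted_pic50(w), table.exp_pic50)
            if r >= 0.9:
                ok += 1
            assert all(cfg.lower - 1e-6 <= w[t] <= cfg.upper + 1e-6 for t in table.map_types)
        assert ok == 3

    def test_scale_degeneracy_preserves_predictions(self, noiseless_table):
        """Doubling g and halving w leaves the predicted pIC50 unchanged."""
        table, w_star = noiseless_table
        halved = WeightVector({t: v / 2 for t, v in w_star.items()})
        doubled = AtomicGFETable(table.ligand_ids, table.map_types, 2 * table.g, table.exp_pic50)
        np.testing.assert_allclose(
            doubled.predicted_pic50(halved), table.predicted_pic50(WeightVector(w_star)),
            atol=1e-10,
        )


class TestTableAndWeightsIO:
    def test_csv_round_trip(self, tmp_path, noiseless_table):
        table, _ = noiseless_table
        p = tmp_path / "table.csv"
        table.to_csv(p)
        back = AtomicGFETable.from_csv(p)
        assert back.ligand_ids == table.ligand_ids
        assert back.map_types == table.map_types
        np.testing.assert_allclose(back.g, table.g, atol=1e-12)
        np.testing.assert_allclose(back.exp_pic50, table.exp_pic50, atol=1e-12)

    def test_weights_yaml_round_trip(self, tmp_path):
        w = WeightVector({"GENN": 0.8, "MAMN": 1.2})
        p = tmp_path / "w.yaml"
        save_weights(w, p)
        back = load_weights(p)
        assert dict(back) == dict(w)

    def test_table_linearity_matches_pose_scores(self, rng):
        """LGFE from the table equals re-scoring the source poses, exactly."""
        maps = make_fragmaps(SyntheticSpec())
        lig, asg = build_chain_ligand("x", ["GENN", "GEND", "MAMN", "GENN"])
        conf = Conformer(lig, rng.uniform(-5, 5, size=(4, 3)))
        bd = atomic_gfes(conf, asg, maps)  # unit weights

        class FakeResult:
            breakdown = bd

        table = AtomicGFETable.from_dock_results(
            {"x": FakeResult()}, {"x": 5.0}, maps.map_types
        )
        w = WeightVector({t: rng.uniform(0.05, 2.0) for t in maps.map_types})
        weighted = atomic_gfes(conf, asg, maps, w).total
        assert table.lgfe(w)[0] == pytest.approx(weighted, abs=1e-12)


class TestRedockEvaluate:
    def test_unit_weights_reproduce_baseline_and_schema(self):
        maps = make_fragmaps(SyntheticSpec())
        proto = DockProtocol(n_min_steps=20, n_mc_steps=100, n_anneal_steps=300,
                             n_independent=1, runs_per_block=2, rng_seed=4)
        ligands, assignments, exp = {}, {}, {}
        for i, labels in enumerate([["GENN", "GENN"], ["GEND", "GENN"], ["MAMN", "GENN", "GENN"]]):
            lig, asg = build_chain_ligand(f"m{i}", labels)
            ligands[lig.name], assignments[lig.name], exp[lig.name] = lig, asg, 5.0 + i
        rep = redock_evaluate(WeightVector(), ligands, assignments, maps, proto, exp)
        assert isinstance(rep, RedockReport)
        d = rep.to_dict()
        assert set(d["metrics"]) == {"mue", "r", "pi", "pc", "n"}
        assert set(d["predicted_pic50"]) == set(ligands)
        # identical protocol and seeds → identical scores on a second call
        rep2 = redock_evaluate(WeightVector(), ligands, assignments, maps, proto, exp)
        assert rep2.lgfe == rep.lgfe

    def test_pose_shift_diagnostic_reported(self):
        maps = make_fragmaps(SyntheticSpec())
        proto = DockProtocol(n_min_steps=10, n_mc_steps=50, n_anneal_steps=100,
                             n_independent=1, runs_per_block=1, rng_seed=1)
        ligands, assignments, exp = {}, {}, {}
        for i, labels in enumerate([["GENN", "GENN"], ["GEND", "GENN"], ["MAMN", "GENN"]]):
            lig, asg = build_chain_ligand(f"m{i}", labels)
            ligands[lig.name], assignments[lig.name], exp[lig.name] = lig, asg, 5.0 + i
        refs = {"m0": ligands["m0"].coords}
        rep = redock_evaluate(WeightVector(), ligands, assignments, maps, proto, exp,
                              reference_poses=refs)
        assert "m0" in rep.pose_shift and rep.pose_shift["m0"] >= 0.0
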