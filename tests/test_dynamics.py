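"""Intrinsic dynamics, exploration primitives, and full simulation runs."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

import exploradapt as ea
from exploradapt.dynamics import (
    fully_converged_genes,
    sample_distance,
    state_space_cohort,
)
from exploradapt.phenotype import ExpressionCohort


class TestInteractionWeights:
    def test_matches_pearson_formula_entry_by_entry(self):
        rng = np.random.default_rng(5)
        vals = pd.DataFrame(
            rng.normal(size=(3, 4)), index=["TF0", "g1", "g2"],
            columns=["s0", "s1", "s2", "s3"],
        )
        cohort = ExpressionCohort(vals, pd.Series({c: "L" for c in vals.columns}))
        net = ea.RegulatoryNetwork.from_edges(
            ["TF0", "g1", "g2"], [("TF0", "g1"), ("TF0", "g2")]
        )
        J = ea.interaction_weights(cohort, "L", net).J
        for tgt in (1, 2):
            x, y = vals.iloc[0], vals.iloc[tgt]
            want = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
            assert J[tgt, 0] == pytest.approx(want, abs=1e-12)

    def test_identical_expression_gives_weight_one(self):
        row = np.arange(4.0)
        vals = pd.DataFrame([row, row], index=["TF0", "g1"], columns=list("abcd"))
        cohort = ExpressionCohort(vals, pd.Series({c: "L" for c in "abcd"}))
        net = ea.RegulatoryNetwork.from_edges(["TF0", "g1"], [("TF0", "g1")])
        assert ea.interaction_weights(cohort, "L", net).J[1, 0] == pytest.approx(1.0)

    def test_constant_gene_gets_zero_weights(self):
        vals = pd.DataFrame(
            [[1.0, 1, 1, 1], [0.5, 1.5, 0.7, 2.0]], index=["TF0", "g1"],
            columns=list("abcd"),
        )
        cohort = ExpressionCohort(vals, pd.Series({c: "L" for c in "abcd"}))
        net = ea.RegulatoryNetwork.from_edges(["TF0", "g1"], [("TF0", "g1")])
        assert ea.interaction_weights(cohort, "L", net).J[1, 0] == 0.0

    def test_too_few_samples_rejected(self):
        vals = pd.DataFrame([[1.0], [2.0]], index=["TF0", "g1"], columns=["a"])
        cohort = ExpressionCohort(vals, pd.Series({"a": "L"}))
        net = ea.RegulatoryNetwork.from_edges(["TF0", "g1"], [("TF0", "g1")])
        with pytest.raises(ValueError, match="fewer than 2"):
            ea.interaction_weights(cohort, "L", net)


class TestIntrinsicStep:
    def test_origin_is_a_fixed_point(self):
        T = np.array([[0, 1], [1, 0]])
        J = np.array([[0, 0.5], [0.3, 0]])
        assert (ea.intrinsic_step(np.zeros(2), T, J) == 0).all()

    def test_pure_decay_arithmetic(self):
        # no interactions: x' = x + 0.25 * (0 - 0.5 * 1) = 0.875
        got = ea.intrinsic_step(np.array([1.0]), np.zeros((1, 1)), np.zeros((1, 1)),
                                beta=0.5, h=0.25)
        assert got[0] == pytest.approx(0.875, abs=1e-15)

    def test_self_loop_converges_to_tanh_root(self):
        """Single gene with unit self-edge settles at the root of tanh(x)=0.5x."""
        root = brentq(lambda x: np.tanh(x) - 0.5 * x, 1.0, 3.0)
        T = np.ones((1, 1))
        J = np.ones((1, 1))
        x = np.array([1.0])
        for _ in range(2000):
            x = ea.intrinsic_step(x, T, J)
        assert x[0] == pytest.approx(root, abs=1e-9)
        assert root == pytest.approx(1.915, abs=1e-3)

    def test_nonfinite_state_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            ea.intrinsic_step(np.array([np.inf]), np.zeros((1, 1)), np.zeros((1, 1)))


class TestSampleDistance:
    def test_inside_interval_converged(self):
        pd_vec, gd, conv = sample_distance(
            np.array([0.4]), np.array([0.2]), np.array([0.6])
        )
        assert pd_vec[0] == 0 and gd == 0 and conv[0]

    def test_distance_to_nearer_bound(self):
        pd_vec, _, conv = sample_distance(
            np.array([0.7]), np.array([0.2]), np.array([0.6])
        )
        assert pd_vec[0] == pytest.approx(0.1) and not conv[0]

    def test_additivity_and_converged_count(self):
        y = np.array([0.5, 0.7, 1.4])
        lo = np.array([0.2, 0.2, 0.2])
        hi = np.array([0.6, 0.6, 1.0])
        pd_vec, gd, conv = sample_distance(y, lo, hi)
        assert pd_vec == pytest.approx([0.0, 0.1, 0.4])
        assert gd == pytest.approx(0.5)
        assert conv.sum() == 1


class TestExplorationScale:
    membership = np.array(
        [[True, True, False], [False, True, False]]
    )  # P0={g0,g1}, P1={g1}; g2 in no pathway

    def test_damping_applies_to_fully_converged_genes_only(self):
        D = np.full((3, 3), 0.1)
        # P0 converged, P1 not: g0 fully converged, g1 not (member of P1), g2 untouched
        D2 = ea.update_exploration_scale(D, np.array([True, False]), self.membership)
        assert D2[0, 1] == pytest.approx(0.095)
        assert D2[0, 0] == pytest.approx(0.1 * 0.95**2)  # row and column of g0
        assert D2[1, 2] == pytest.approx(0.1)
        assert D2[2, 2] == pytest.approx(0.1)

    def test_geometric_decay_over_repeated_steps(self):
        D = np.full((3, 3), 0.1)
        for _ in range(5):
            D = ea.update_exploration_scale(D, np.array([True, True]), self.membership)
        assert D[0, 2] == pytest.approx(0.1 * 0.95**5)
        assert D[0, 1] == pytest.approx(0.1 * 0.95**10)  # both endpoints converged
        assert D[2, 2] == pytest.approx(0.1)  # pathway-free gene never damped

    def test_fully_converged_gene_mask(self):
        mask = fully_converged_genes(np.array([True, False]), self.membership)
        assert mask.tolist() == [True, False, False]


class TestPerturbWeights:
    def test_zero_scale_is_identity(self):
        J = np.arange(9.0).reshape(3, 3)
        out = ea.perturb_weights(J, np.zeros((3, 3)), np.random.default_rng(0))
        assert (out == J).all()

    def test_non_edges_unchanged(self):
        rng = np.random.default_rng(1)
        T = np.zeros((4, 4), dtype=int)
        T[1, 0] = T[2, 0] = 1
        J = np.zeros((4, 4))
        out = ea.perturb_weights(J, np.full((4, 4), 0.5), rng, T=T)
        assert out[3, 3] == 0 and out[0, 1] == 0
        assert out[1, 0] != 0 and out[2, 0] != 0

    def test_increment_variance_matches_scale(self):
        rng = np.random.default_rng(2)
        n = 150  # 22500 entries >= 1e4
        J = np.zeros((n, n))
        out = ea.perturb_weights(J, np.full((n, n), 0.1), rng)
        assert out.var() == pytest.approx(0.1, rel=0.05)

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ea.perturb_weights(np.zeros((2, 2)), np.full((2, 2), -0.1),
                               np.random.default_rng(0))


class TestSimulate:
    def _setup(self, tiny_system):
        _, network, pmap, cohort, ctx = tiny_system
        x0 = ctx.initial_state(cohort.samples_of("src")[0])
        return network, pmap, ctx, x0

    def test_zero_noise_exploratory_equals_intrinsic(self, tiny_system):
        network, pmap, ctx, x0 = self._setup(tiny_system)
        kw = dict(targets=ctx.targets_of("tgt"), pathway_map=pmap, t_max=20, seed=3)
        a = ea.simulate(x0, network, ctx.weights_of("src"), mode="intrinsic", **kw)
        b = ea.simulate(x0, network, ctx.weights_of("src"), mode="exploratory", D0=0.0, **kw)
        assert np.array_equal(a.gd, b.gd)
        assert np.array_equal(a.phenotypes, b.phenotypes)

    def test_record_length_without_early_convergence(self, tiny_system):
        network, pmap, ctx, x0 = self._setup(tiny_system)
        rec = ea.simulate(
            x0, network, ctx.weights_of("src"), ctx.targets_of("tgt"), pmap,
            mode="intrinsic", t_max=10, stop_early=False,
        )
        assert rec.n_steps == 11

    def test_intrinsic_runs_are_bit_identical(self, tiny_system):
        network, pmap, ctx, x0 = self._setup(tiny_system)
        kw = dict(targets=ctx.targets_of("tgt"), pathway_map=pmap,
                  mode="intrinsic", t_max=15)
        a = ea.simulate(x0, network, ctx.weights_of("src"), **kw)
        b = ea.simulate(x0, network, ctx.weights_of("src"), **kw)
        assert np.array_equal(a.final_state, b.final_state)
        assert np.array_equal(a.gd, b.gd)

    def test_record_internal_consistency(self, tiny_system):
        network, pmap, ctx, x0 = self._setup(tiny_system)
        rec = ea.simulate(
            x0, network, ctx.weights_of("src"), ctx.targets_of("tgt"), pmap,
            mode="exploratory", D0=0.1, t_max=30, seed=4,
        )
        assert rec.gd == pytest.approx(rec.pd.sum(axis=1), abs=1e-12)
        assert (rec.converged_count == (rec.pd == 0).sum(axis=1)).all()
        assert (rec.final_D <= 0.1 + 1e-15).all()

    def test_intrinsic_state_stays_within_gain_bound(self, tiny_system):
        """|x_i| is eventually bounded by (row sum of |T*J|)/beta since |tanh|<=1."""
        network, pmap, ctx, x0 = self._setup(tiny_system)
        rec = ea.simulate(
            x0, network, ctx.weights_of("src"), ctx.targets_of("tgt"), pmap,
            mode="intrinsic", t_max=50, stop_early=False,
        )
        W = network.T * ctx.weights_of("src").J
        bound = np.abs(W).sum(axis=1) / 0.5
        assert (np.abs(rec.final_state) <= bound + 1e-9).all()

    def test_divergent_state_raises_with_step(self, tiny_system):
        network, pmap, ctx, _ = self._setup(tiny_system)
        bad = np.full(network.n, np.inf)
        with pytest.raises(ea.SimulationDiverged) as err:
            ea.simulate(bad, network, ctx.weights_of("src"),
                        ctx.targets_of("tgt"), pmap, mode="intrinsic", t_max=5)
        assert err.value.t == 0

    def test_adapted_state_reverts_closer_than_forward_run(self, asymmetric_context):
        """After adapting toward a narrow, hard target, the adapted state
        replayed with dJ=0 toward its wide source band ends nearer the source
        than the forward run ended to its target (plasticity is retained)."""
        ctx = asymmetric_context
        x0 = ctx.initial_state(ctx.cohort.samples_of("A")[0])
        fwd = ea.simulate(
            x0, ctx.network, ctx.weights_of("A"), ctx.targets_of("B"),
            ctx.pathway_map, mode="exploratory", D0=0.1, t_max=100, seed=1,
        )
        back = ea.simulate(
            fwd.final_state, ctx.network, fwd.final_J, ctx.targets_of("A"),
            ctx.pathway_map, mode="intrinsic", t_max=100,
        )
        assert back.final_gd < fwd.final_gd


class TestStateSpace:
    def test_values_lie_in_open_unit_interval(self, demo_data):
        _, _, _, cohort = demo_data
        vals = state_space_cohort(cohort).values.to_numpy()
        assert (np.abs(vals) < 1).all()

    def test_zero_variance_gene_maps_to_zero(self):
        vals = pd.DataFrame(
            [[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]], index=["g1", "g2"],
            columns=["a", "b", "c"],
        )
        cohort = ExpressionCohort(vals, pd.Series({c: "L" for c in "abc"}))
        out = state_space_cohort(cohort).values
        assert (out.loc["g1"] == 0).all()
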