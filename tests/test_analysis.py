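"""Transition experiments, reversal, plasticity, vector fields, ablation."""

import numpy as np
import pandas as pd
import pytest

import exploradapt as ea
from exploradapt.analysis import AngleDistribution, _closest_samples
from exploradapt.dynamics import sample_distance
from exploradapt.phenotype import ExpressionCohort


class TestTransitionExperiment:
    def test_self_phenotype_mostly_inside_own_band_at_start(self, demo_context):
        """A sample's phenotype sits inside its own location's 10-90 band for
        roughly 80% of pathways (by construction of the percentile band)."""
        ctx = demo_context
        targets = ctx.targets_of("A")
        order = list(targets.pathway_ids)
        cover = [
            sample_distance(
                ctx.phenotypes.loc[order, sid].to_numpy(float), targets
            )[2].mean()
            for sid in ctx.cohort.samples_of("A")
        ]
        assert 0.7 <= np.mean(cover) <= 0.9

    def test_zero_noise_matches_intrinsic_summary(self, tiny_system):
        _, _, _, _, ctx = tiny_system
        kw = dict(t_max=15, seeds=[1, 2], max_samples=3)
        a = ea.transition_experiment(ctx, "src", "tgt", mode="intrinsic", **kw)
        b = ea.transition_experiment(ctx, "src", "tgt", mode="exploratory", D0=0.0, **kw)
        assert np.array_equal(a.final_gd, b.final_gd)
        assert np.array_equal(a.final_converged_pct, b.final_converged_pct)

    def test_exploration_flag_true_only_for_genuinely_new_target(self, demo_context):
        """Exploration helps reach a shifted target location but does not beat
        intrinsic dynamics at staying in the familiar (source) environment."""
        ctx = demo_context
        kw = dict(t_max=100, seeds=[1, 2, 3, 4, 5, 6], max_samples=6)
        for target, expected in (("A", False), ("B", True)):
            intr = ea.transition_experiment(ctx, "A", target, mode="intrinsic", **kw)
            expl = ea.transition_experiment(
                ctx, "A", target, mode="exploratory", D0=0.1, **kw
            )
            assert ea.exploration_necessary(expl, intr) is expected

    def test_empty_location_rejected(self, tiny_system):
        _, _, _, _, ctx = tiny_system
        with pytest.raises(KeyError):
            ea.transition_experiment(ctx, "nowhere", "tgt", t_max=2)


class TestReversalRatios:
    def _summary(self, src, tgt, gd, conv):
        return ea.TransitionSummary(
            source=src, target=tgt, mode="exploratory",
            final_gd=np.asarray(gd, float),
            final_converged_pct=np.asarray(conv, float),
            sample_ids=[f"s{i}" for i in range(len(gd))], seeds=[0] * len(gd),
        )

    def test_identical_summaries_give_unit_ratios(self):
        f = self._summary("A", "B", [2.0, 4.0], [50.0, 70.0])
        r = self._summary("B", "A", [2.0, 4.0], [50.0, 70.0])
        rr = ea.reversal_ratios(f, r)
        assert rr.gd_ratio == 1.0 and rr.converged_ratio == 1.0

    def test_mismatched_directions_rejected(self):
        f = self._summary("A", "B", [1.0], [10.0])
        with pytest.raises(ValueError, match="mirror"):
            ea.reversal_ratios(f, f)

    def test_zero_forward_distance_reported_undefined(self):
        f = self._summary("A", "B", [0.0, 0.0], [100.0, 100.0])
        r = self._summary("B", "A", [1.0, 1.0], [50.0, 50.0])
        with pytest.warns(UserWarning, match="undefined"):
            rr = ea.reversal_ratios(f, r)
        assert np.isnan(rr.gd_ratio)


class TestPlasticityRanking:
    def test_degenerate_cohort_all_tied_at_zero_drift(self):
        # every sample identical -> z-scores 0 -> X(0)=0, the fixed point
        vals = pd.DataFrame(
            np.tile([[3.0], [1.0], [2.0]], 4), index=["TF0", "g1", "g2"],
            columns=["a", "b", "c", "d"],
        )
        labels = pd.Series({"a": "L1", "b": "L1", "c": "L2", "d": "L2"})
        cohort = ExpressionCohort(vals, labels)
        net = ea.RegulatoryNetwork.from_edges(
            ["TF0", "g1", "g2"], [("TF0", "g1"), ("TF0", "g2")]
        )
        pmap = ea.GenePathwayMap({"P1": {"g1"}, "P2": {"g2"}},
                                 universe=frozenset(["TF0", "g1", "g2"]))
        ctx = ea.SimulationContext(cohort, net, pmap)
        ranking = ea.intrinsic_plasticity_ranking(ctx, t_max=10)
        assert (ranking["mean_drift"] == 0).all()

    def test_ranking_orders_by_independently_recomputed_drift(self, demo_context):
        """The rigid-to-plastic ordering must agree with a direct per-sample
        recomputation of the L1 phenotype drift via the simulator."""
        ctx = demo_context
        ranking = ea.intrinsic_plasticity_ranking(ctx, t_max=30, max_samples=4)
        drift = {}
        for loc in ctx.cohort.locations:
            per_sample = []
            for sid in ctx.cohort.samples_of(loc)[:4]:
                rec = ea.simulate(
                    ctx.initial_state(sid), ctx.network, ctx.weights_of(loc),
                    ctx.targets_of(loc), ctx.pathway_map, mode="intrinsic",
                    t_max=30, stop_early=False,
                )
                per_sample.append(np.abs(rec.phenotypes[-1] - rec.phenotypes[0]).sum())
            drift[loc] = np.mean(per_sample)
        assert list(ranking.index) == sorted(drift, key=drift.get)
        for loc, want in drift.items():
            assert ranking.loc[loc, "mean_drift"] == pytest.approx(want, abs=1e-9)

    def test_ranking_is_deterministic(self, tiny_system):
        _, _, _, _, ctx = tiny_system
        a = ea.intrinsic_plasticity_ranking(ctx, t_max=10, max_samples=3)
        b = ea.intrinsic_plasticity_ranking(ctx, t_max=10, max_samples=3)
        pd.testing.assert_frame_equal(a, b)


class TestPcaVectorField:
    def test_identical_start_end_gives_zero_arrows(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 4))
        vf = ea.pca_vector_field(x, x.copy(), n_components=2)
        assert np.allclose(vf.arrows, 0)

    def test_pure_translation_gives_equal_arrows(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(6, 4))
        vf = ea.pca_vector_field(x, x + np.array([1.0, -2.0, 0.5, 3.0]), 2)
        assert np.allclose(vf.arrows - vf.arrows[0], 0, atol=1e-9)

    def test_embedding_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        start = rng.normal(size=(20, 2)) @ np.array([[3.0, 1.0], [0.5, 0.2]])
        end = start + rng.normal(0, 0.1, start.shape)
        vf = ea.pca_vector_field(start, end, n_components=2)
        stacked = np.vstack([start, end])
        centered = stacked - stacked.mean(axis=0)
        evals, evecs = np.linalg.eigh(centered.T @ centered)
        evecs = evecs[:, ::-1]  # descending variance
        want = np.abs(centered[: len(start)] @ evecs)
        assert np.allclose(np.abs(vf.origins), want, atol=1e-8)

    def test_excess_components_rejected(self):
        x = np.zeros((3, 2))
        with pytest.raises(ValueError, match="n_components"):
            ea.pca_vector_field(x, x, n_components=5)


class TestTrajectoryAngles:
    def test_parallel_and_antiparallel(self):
        v = np.array([[1.0, 2.0, 3.0]])
        assert ea.trajectory_angles(v, v).angles_deg[0] == pytest.approx(0.0)
        assert ea.trajectory_angles(v, -v).angles_deg[0] == pytest.approx(180.0)

    def test_matches_dot_product_oracle(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(50, 7))
        b = rng.normal(size=(50, 7))
        got = ea.trajectory_angles(a, b).angles_deg
        want = [
            np.degrees(np.arccos(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))))
            for u, v in zip(a, b)
        ]
        assert np.allclose(got, want, atol=1e-9)
        assert ((got >= 0) & (got <= 180)).all()

    def test_zero_arrows_excluded_with_warning(self):
        a = np.array([[1.0, 0.0], [0.0, 0.0]])
        b = np.array([[0.0, 1.0], [1.0, 1.0]])
        with pytest.warns(UserWarning, match="zero-length"):
            dist = ea.trajectory_angles(a, b)
        assert dist.n_excluded == 1 and len(dist.angles_deg) == 1

    def test_identical_arrow_sets_have_zero_mean_angle(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(10, 5))
        assert ea.trajectory_angles(a, a.copy()).mean == pytest.approx(0.0, abs=1e-5)


class TestAblation:
    def test_zero_removal_identical_to_baseline(self, tiny_system):
        _, _, _, _, ctx = tiny_system
        res = ea.subpopulation_ablation(
            ctx, "src", "tgt", 0, 0, strategy="closest", seeds=[1],
            t_max=10, max_samples=3,
        )
        assert res.baseline_mean_gd == res.ablated_mean_gd

    def test_closest_samples_ranked_by_distance_to_other_band(self, demo_context):
        ctx = demo_context
        picked = _closest_samples(ctx, "A", "B", 3)
        targets = ctx.targets_of("B")
        order = list(targets.pathway_ids)
        gds = {
            sid: sample_distance(
                ctx.phenotypes.loc[order, sid].to_numpy(float), targets
            )[1]
            for sid in ctx.cohort.samples_of("A")
        }
        cutoff = sorted(gds.values())[2]
        assert all(gds[s] <= cutoff for s in picked)

    def test_excess_removal_rejected(self, tiny_system):
        _, _, _, _, ctx = tiny_system
        with pytest.raises(ValueError, match="entire location"):
            ea.subpopulation_ablation(ctx, "src", "tgt", 10, 0, t_max=2)
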