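"""The clustering network: forward contracts, training behaviour,
assignment rules, risk trajectories, ablations and persistence."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from odtgc.autodiff import no_grad
from odtgc.model import (
    FittedModel,
    ModelConfig,
    TemporalGraphClusterNet,
    assign,
    fit,
    risk_trajectory,
    soft_assign,
)
from odtgc.pipeline import fit_cohort, prepare_cohort
from odtgc.synthcohort import CohortConfig


@pytest.fixture(scope="module")
def tiny_prepared():
    return prepare_cohort(cohort_config=CohortConfig(n_patients=80, seed=21))


@pytest.fixture(scope="module")
def tiny_model(tiny_prepared):
    cfg = ModelConfig(epochs=4, pretrain_epochs=2, seed=5, batch_size=40)
    return fit_cohort(tiny_prepared, cfg)


class TestConfig:
    @pytest.mark.parametrize("bad", [
        dict(K=1), dict(loss_weights=(-1, 1, 1, 1)), dict(epochs=0),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelConfig(**bad)


class TestForward:
    def test_output_shapes(self, tiny_prepared):
        data = tiny_prepared.data
        net = TemporalGraphClusterNet(
            data.X.shape[-1], ModelConfig(seed=0), np.random.default_rng(0)
        )
        with no_grad():
            out = net.forward(data.X[:7], data.A, collect_nodes=True)
        N, T, V, d = 7, data.X.shape[1], 13, 24
        assert out["y_hat"].shape == (N, T)
        assert out["z"].shape == (N, d)
        assert out["z_steps"].shape == (N, T, d)
        assert out["nodes_fused"].shape == (N, T, V, d)
        assert np.all((out["y_hat"].data > 0) & (out["y_hat"].data < 1))

    def test_seeded_forward_deterministic(self, tiny_prepared):
        data = tiny_prepared.data
        outs = []
        for _ in range(2):
            net = TemporalGraphClusterNet(
                data.X.shape[-1], ModelConfig(seed=0), np.random.default_rng(0)
            )
            with no_grad():
                outs.append(net.forward(data.X[:5], data.A)["z"].data)
        np.testing.assert_array_equal(outs[0], outs[1])


class TestFit:
    def test_composite_loss_decreases_in_joint_phase(self, tiny_model):
        joint = [row["L"] for row in tiny_model.training_log
                 if row["phase"] == "joint"]
        assert len(joint) >= 2
        assert joint[-1] < joint[0]

    def test_same_seed_identical_assignments(self, tiny_prepared):
        cfg = ModelConfig(epochs=2, pretrain_epochs=1, seed=9, batch_size=40)
        a = fit(tiny_prepared.data, tiny_prepared.y, cfg)
        b = fit(tiny_prepared.data, tiny_prepared.y, cfg)
        np.testing.assert_array_equal(assign(a, tiny_prepared.data),
                                      assign(b, tiny_prepared.data))
        np.testing.assert_array_equal(a.centroids.mu, b.centroids.mu)

    def test_planted_recovery_small_cohort(self, small_prepared, small_model):
        labels = assign(small_model, small_prepared.data)
        assert adjusted_rand_score(small_prepared.truth, labels) >= 0.8

    def test_mismatched_labels_rejected(self, tiny_prepared):
        with pytest.raises(ValueError):
            fit(tiny_prepared.data, np.zeros(3), ModelConfig(epochs=1))


class TestAssignment:
    def test_argmax_and_tie_rule(self):
        q = np.array([[0.2, 0.5, 0.3], [0.5, 0.5, 0.0]])
        # highest q wins; exact ties resolve to the lowest cluster index
        assert q.argmax(axis=1).tolist() == [1, 0]

    def test_assign_matches_soft_argmax(self, small_prepared, small_model):
        sa = small_model.soft_assignment(small_prepared.data)
        np.testing.assert_array_equal(
            assign(small_model, small_prepared.data), sa.Q.argmax(axis=1)
        )
        np.testing.assert_allclose(sa.Q.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(sa.P.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(sa.Q_G.sum(axis=1), 1.0, atol=1e-6)

    def test_assignments_stable_under_centroid_relabeling(
        self, small_prepared, small_model
    ):
        emb = small_model.embed(small_prepared.data, collect_nodes=False)
        perm = np.array([2, 0, 1])
        q_orig = soft_assign(emb.Z, small_model.centroids.mu)
        q_perm = soft_assign(emb.Z, small_model.centroids.mu[perm])
        # labels map through the same permutation; risk levels are unchanged
        np.testing.assert_array_equal(
            perm[q_perm.argmax(1)], q_orig.argmax(1)
        )
        risk = small_model.centroids.risk_order
        np.testing.assert_array_equal(
            risk[perm][q_perm.argmax(1)], risk[q_orig.argmax(1)]
        )


class TestRiskTrajectory:
    def test_length_and_levels(self, small_prepared, small_model):
        rt = risk_trajectory(small_model, small_prepared.data)
        assert rt.shape == (len(small_prepared.y), 12)
        assert set(np.unique(rt)) <= {0, 1, 2}

    def test_mortality_nondecreasing_in_final_level(
        self, small_prepared, small_model
    ):
        rt = risk_trajectory(small_model, small_prepared.data)
        final = rt[:, -1]
        rates = [
            small_prepared.y[final == lvl].mean()
            for lvl in sorted(np.unique(final))
            if np.any(final == lvl)
        ]
        assert all(a <= b + 1e-9 for a, b in zip(rates, rates[1:]))


class TestAblation:
    def test_outcome_labels_inert_when_ls_disabled(self):
        """With sigma = 0 the death labels appear in no loss term, so
        shuffling them must leave training bit-identical."""
        prep = prepare_cohort(cohort_config=CohortConfig(n_patients=60, seed=31))
        cfg = ModelConfig(epochs=2, pretrain_epochs=1, seed=2, batch_size=30,
                          use_LS=False)
        rng = np.random.default_rng(0)
        y_shuffled = rng.permutation(prep.y)
        a = fit(prep.data, prep.y, cfg)
        b = fit(prep.data, y_shuffled, cfg)
        emb_a = a.embed(prep.data, collect_nodes=False)
        emb_b = b.embed(prep.data, collect_nodes=False)
        np.testing.assert_array_equal(emb_a.Z, emb_b.Z)
        np.testing.assert_array_equal(
            soft_assign(emb_a.Z, a.centroids.mu).argmax(1),
            soft_assign(emb_b.Z, b.centroids.mu).argmax(1),
        )

    def test_cvae_ablation_trains(self):
        prep = prepare_cohort(cohort_config=CohortConfig(n_patients=50, seed=41))
        cfg = ModelConfig(epochs=2, pretrain_epochs=1, seed=2, batch_size=25,
                          use_CVAE=False)
        model = fit(prep.data, prep.y, cfg)
        assert all(np.isfinite(row["L"]) for row in model.training_log)
        assert all(row.get("LCVAE", 0.0) == 0.0 for row in model.training_log)


class TestPersistence:
    def test_checkpoint_round_trip_exact(self, tiny_prepared, tiny_model,
                                         tmp_path):
        path = str(tmp_path / "model.npz")
        tiny_model.save(path)
        loaded = FittedModel.load(path)
        np.testing.assert_array_equal(loaded.centroids.mu,
                                      tiny_model.centroids.mu)
        np.testing.assert_array_equal(loaded.centroids.risk_order,
                                      tiny_model.centroids.risk_order)
        np.testing.assert_array_equal(
            assign(loaded, tiny_prepared.data),
            assign(tiny_model, tiny_prepared.data),
        )
        emb_a = loaded.embed(tiny_prepared.data, collect_nodes=False)
        emb_b = tiny_model.embed(tiny_prepared.data, collect_nodes=False)
        np.testing.assert_array_equal(emb_a.Z, emb_b.Z)
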