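import numpy as np
import pytest

from torsiongen import boltzmann as bz
from torsiongen import circular, molgraph, molio, rotamer
from torsiongen.errors import UsageError
from torsiongen.molio import Conformation


class TestSampleLatent:
    def test_deterministic(self):
        spec = bz.LatentSpec(kind="gaussian", dim=3)
        a = bz.sample_latent(spec, 10, 42)
        b = bz.sample_latent(spec, 10, 42)
        np.testing.assert_array_equal(a, b)

    def test_gaussian_moments(self):
        spec = bz.LatentSpec(kind="gaussian", dim=2)
        z = bz.sample_latent(spec, 10_000, 7)
        assert np.abs(z.mean(axis=0)).max() < 4 / np.sqrt(10_000)

    def test_sum_of_gaussians_mixture_balance(self):
        spec = bz.LatentSpec(kind="sum_of_gaussians", dim=1,
                             centers=[[-5.0], [5.0]])
        z = bz.sample_latent(spec, 10_000, 11).ravel()
        frac = np.mean(z > 0)
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_uniform_bounds(self):
        spec = bz.LatentSpec(kind="uniform", dim=4, low=-2.0, high=3.0)
        z = bz.sample_latent(spec, 1000, 1)
        assert z.min() >= -2.0 and z.max() <= 3.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(UsageError):
            bz.LatentSpec(kind="cauchy", dim=2)


class TestLosses:
    def test_pretrain_loss_zero_for_ideal_pairs(self):
        pairs = np.tile([1.0, 0.0], (5, 1))
        assert bz.pretrain_loss(pairs, eps_xy=1.0) == pytest.approx(0.0)

    def test_pretrain_loss_quarter_turn(self):
        pairs = np.array([[0.0, 1.0]])
        assert bz.pretrain_loss(pairs, eps_xy=0.0) == pytest.approx(np.pi**2 / 4)

    def test_pretrain_loss_additive_modulus(self):
        base = bz.pretrain_loss(np.array([[0.0, 1.0]]), eps_xy=1.0)
        both = bz.pretrain_loss(np.array([[0.0, 1.0], [2.0, 0.0]]), eps_xy=1.0)
        assert both == pytest.approx(base + 9.0)

    def test_energy_only_loss(self):
        assert bz.energy_only_loss(5.0, 1.0) == 6.0
        assert bz.energy_only_loss(0.0, 0.0) == 0.0

    @pytest.mark.parametrize(
        "U,S,T,expected",
        [(10.0, 2.0, 2.0, 3.0), (10.0, 2.0, 0.5, 9.0)],
    )
    def test_boltzmann_loss_branches(self, U, S, T, expected):
        assert bz.boltzmann_loss(U, S, 0.0, T) == pytest.approx(expected)

    def test_boltzmann_loss_continuous_at_one(self):
        for U, S, L in [(10.0, 2.0, 0.0), (-3.0, 1.5, 0.2)]:
            lo = bz.boltzmann_loss(U, S, L, 1.0 - 1e-12)
            hi = bz.boltzmann_loss(U, S, L, 1.0)
            assert lo == pytest.approx(hi, abs=1e-9)
            assert hi == pytest.approx(U - S + L)


class TestAnalyticTargets:
    def test_body_temperature(self):
        assert round(bz.temperature_from_kelvin(310.0), 2) == 2.58

    def test_zero_kelvin(self):
        assert bz.temperature_from_kelvin(0.0) == 0.0

    def test_inverse_gas_constant(self):
        from torsiongen.constants import GAS_CONSTANT

        assert bz.temperature_from_kelvin(1.0 / GAS_CONSTANT) == pytest.approx(1.0)

    @pytest.mark.parametrize("n,expected", [(596, 3_196_944), (1, 9), (10, 900)])
    def test_invertible_bound(self, n, expected):
        assert bz.invertible_param_lower_bound(n) == expected


class TestGeneratorModel:
    def test_output_shape_and_param_count(self):
        model = bz.GeneratorModel(latent_dim=4, n_dihedrals=3, n_layers=4,
                                  hidden=16, seed=0)
        out = model.forward(np.zeros((5, 4)))
        assert out.shape == (5, 3, 2)
        expected = 4 * 16 + 16 + 16 * 16 + 16 + 16 * 16 + 16 + 16 * 6 + 6
        assert model.parameter_count == expected

    def test_backward_matches_fd(self):
        model = bz.GeneratorModel(latent_dim=3, n_dihedrals=2, n_layers=3,
                                  hidden=8, seed=1)
        rng = np.random.default_rng(0)
        z = rng.normal(size=(4, 3))
        w = rng.normal(size=(4, 2, 2))  # arbitrary linear loss weights

        def loss():
            return float(np.sum(model.forward(z) * w))

        loss()
        gW, gb = model.backward(w)
        h = 1e-6
        W0 = model.weights[0]
        for idx in [(0, 0), (1, 3), (2, 7)]:
            orig = W0[idx]
            W0[idx] = orig + h
            up = loss()
            W0[idx] = orig - h
            down = loss()
            W0[idx] = orig
            assert gW[0][idx] == pytest.approx((up - down) / (2 * h), abs=1e-5)


@pytest.fixture(scope="module")
def butane_setup():
    system = molio.make_fixture("chain", 4, seed=1)
    topo = molgraph.prepare_rotamer_metadata(system)
    return system, topo


@pytest.fixture(scope="module")
def trained_identity_model(butane_setup):
    system, topo = butane_setup
    cfg = bz.TrainingConfig(n_pre=200, seed=7)
    model = bz.GeneratorModel(cfg.latent.dim, topo.M, seed=7)
    bz.pretrain(model, system, topo, cfg)
    return system, topo, model


class TestTraining:

    def test_pretrain_drives_angles_to_zero(self, butane_setup):
        system, topo = butane_setup
        cfg = bz.TrainingConfig(n_pre=200, seed=7)
        model = bz.GeneratorModel(cfg.latent.dim, topo.M, seed=7)
        bz.pretrain(model, system, topo, cfg)
        z = bz.sample_latent(cfg.latent, 256, 999)
        theta = circular.angles_from_pairs(model.forward(z))
        assert np.mean(np.abs(theta)) < 0.05

    def test_pretrain_skipped_with_warning(self, butane_setup, caplog):
        system, topo = butane_setup
        cfg = bz.TrainingConfig(n_pre=0, seed=1)
        model = bz.GeneratorModel(cfg.latent.dim, topo.M, seed=1)
        import logging

        with caplog.at_level(logging.WARNING):
            bz.pretrain(model, system, topo, cfg)
        assert any("pre-training skipped" in r.message for r in caplog.records)

    def test_training_lowers_energy_from_displaced_start(self, butane_setup):
        system, topo = butane_setup
        conf0 = rotamer.sample_rotamers(
            Conformation(system.positions()), topo, [0.8]
        )
        cfg = bz.TrainingConfig(t_nn=0.1, n_pre=150, n_train=300, seed=3)
        model = bz.GeneratorModel(cfg.latent.dim, topo.M, seed=3)
        bz.pretrain(model, system, topo, cfg)
        model, report = bz.train(model, system, topo, cfg, conf0=conf0)
        assert (
            report.epochs.median_energy.iloc[-1]
            <= report.epochs.median_energy.iloc[0]
        )

    def test_energy_calls_equal_batch_size_per_epoch(self, butane_setup):
        system, topo = butane_setup
        cfg = bz.TrainingConfig(n_pre=20, n_train=15, batch_size=8, seed=1)
        model = bz.GeneratorModel(cfg.latent.dim, topo.M, seed=1)
        bz.pretrain(model, system, topo, cfg)
        model, report = bz.train(model, system, topo, cfg)
        assert report.energy_calls == cfg.n_train * cfg.batch_size

    def test_entropy_term_broadens_distribution(self, butane_setup):
        system, topo = butane_setup
        gains = []
        for seed in range(5):
            ent = {}
            for use_entropy in (True, False):
                cfg = bz.TrainingConfig(
                    t_nn=2.58, n_pre=150, n_train=200, seed=seed,
                    use_entropy=use_entropy,
                )
                model = bz.GeneratorModel(cfg.latent.dim, topo.M, seed=seed)
                bz.pretrain(model, system, topo, cfg)
                model, _ = bz.train(model, system, topo, cfg)
                z = bz.sample_latent(cfg.latent, 256, 999)
                theta = circular.angles_from_pairs(model.forward(z))
                ent[use_entropy] = circular.nn_entropy(theta)
            gains.append(ent[True] - ent[False])
        assert np.median(gains) > 0

    def test_training_deterministic(self, butane_setup):
        system, topo = butane_setup
        reports = []
        for _ in range(2):
            cfg = bz.TrainingConfig(n_pre=30, n_train=10, seed=5)
            model = bz.GeneratorModel(cfg.latent.dim, topo.M, seed=5)
            bz.pretrain(model, system, topo, cfg)
            model, report = bz.train(model, system, topo, cfg)
            reports.append(report.epochs)
        np.testing.assert_array_equal(
            reports[0].to_numpy(), reports[1].to_numpy()
        )


class TestEnsembleAndRmsf:
    @pytest.fixture
    def trained(self, trained_identity_model):
        return trained_identity_model

    def test_single_frame(self, trained):
        system, topo, model = trained
        ens = bz.generate_ensemble(model, system, topo, 1, seed=3)
        assert len(ens.frames) == 1

    def test_seeded_reproducibility(self, trained):
        system, topo, model = trained
        a = bz.generate_ensemble(model, system, topo, 5, seed=3)
        b = bz.generate_ensemble(model, system, topo, 5, seed=3)
        for fa, fb in zip(a.frames, b.frames):
            np.testing.assert_array_equal(fa.positions, fb.positions)

    def test_pretrained_model_stays_near_native(self, trained):
        system, topo, model = trained
        ens = bz.generate_ensemble(model, system, topo, 10, seed=3)
        ref = system.positions()
        from torsiongen.align import rmsd

        for f in ens.frames:
            assert rmsd(f.positions, ref) < 0.05

    def test_rmsf_identical_frames_zero(self, trained):
        system, topo, model = trained
        conf = Conformation(system.positions())
        ens = molio.EnsembleTrajectory(system, [conf, conf, conf])
        np.testing.assert_allclose(bz.rmsf(ens), 0.0, atol=1e-12)

    def test_rmsf_two_frame_displacement(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(6, 3))
        moved = base.copy()
        moved[5] += np.array([0.2, 0.0, 0.0])
        system = molio.make_fixture("chain", 6, seed=1)
        ens = molio.EnsembleTrajectory(
            system, [Conformation(base), Conformation(moved)]
        )
        vals = bz.rmsf(ens, selection=np.arange(5))
        assert vals[5] == pytest.approx(0.1, abs=1e-9)  # sqrt of two-point variance
        assert np.abs(vals[:5]).max() < 1e-9

    def test_rmsf_invariant_under_global_motion(self, trained, rng):
        system, topo, model = trained
        ens = bz.generate_ensemble(model, system, topo, 6, seed=4)
        base = bz.rmsf(ens)
        from torsiongen.align import quaternion_to_rotation

        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        R = quaternion_to_rotation(q)
        moved = molio.EnsembleTrajectory(
            system,
            [Conformation(f.positions @ R.T + 1.0) for f in ens.frames],
        )
        np.testing.assert_allclose(bz.rmsf(moved), base, atol=1e-9)

    def test_rmsf_needs_two_frames(self, trained):
        system, topo, model = trained
        ens = bz.generate_ensemble(model, system, topo, 1, seed=3)
        with pytest.raises(UsageError):
            bz.rmsf(ens)
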