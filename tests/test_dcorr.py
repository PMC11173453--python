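"""Δ-learning: residual labelling, closed-form fit, recovery, guards."""

import warnings

import numpy as np
import pytest

from protonfes.dcorr import (
    ExtrapolationWarning,
    corrected_surface,
    default_descriptor_pairs,
    make_training_set,
    train,
)
from protonfes.modelsys import build_gt_toy
from protonfes.sampling import Schedule, UmbrellaWindow, run_windows

from _numeric import fd_gradient


@pytest.fixture(scope="module")
def gt_training(gt_mod):
    """Frames sampled on the base surface along the wGT basin + transfer axis."""
    system, reference, base = gt_mod
    from protonfes.modelsys import gt_reaction_coordinates

    rc = gt_reaction_coordinates()
    centers = [(-0.8 + 0.2 * i, -0.8) for i in range(9)]  # along the H3 transfer
    windows = [UmbrellaWindow(c, 100.0, window_id=i) for i, c in enumerate(centers)]
    sched = Schedule(equil_time=250.0, prod_time=2500.0, dt=0.5, stride=10.0)
    samples = run_windows(system, base, rc, windows, sched, seed=5,
                          extra_observables={"pos": lambda x: x})
    trajs = [s.extras["pos"] for s in samples]
    ts = make_training_set(trajs, base, reference, stride=1,
                           provenance=[f"w{i}" for i in range(len(trajs))])
    return system, reference, base, rc, ts


@pytest.fixture(scope="module")
def gt_mod(gt):
    return gt


class TestTrainingSet:
    def test_identical_surfaces_give_zero_residuals(self, gt_mod, rng):
        system, reference, _ = gt_mod
        frames = system.named_states["wGT"] + 0.05 * rng.standard_normal((60, 8, 2))
        ts = make_training_set([frames], reference, reference)
        np.testing.assert_allclose(ts.denergy, 0.0, atol=1e-12)
        np.testing.assert_allclose(ts.dforces, 0.0, atol=1e-12)

    def test_residuals_equal_truth_correction(self, gt_mod, rng):
        """E_ref - E_base equals the Gaussian truth correction by construction."""
        system, reference, base = gt_mod
        from protonfes.modelsys import gt_reaction_coordinates

        rc = gt_reaction_coordinates()
        frames = system.named_states["wGT"] + 0.08 * rng.standard_normal((80, 8, 2))
        ts = make_training_set([frames], base, reference)
        corr = base.inner.correction.value(rc.values(frames))
        np.testing.assert_allclose(ts.denergy, corr, atol=1e-10)

    def test_force_residuals_match_energy_residual_gradient(self, gt_mod, rng):
        system, reference, base = gt_mod
        x = system.named_states["GT*"] + 0.05 * rng.standard_normal((8, 2))
        ts = make_training_set([x[None]], base, reference)
        fd = fd_gradient(lambda y: reference.energy(y) - base.energy(y), x)
        np.testing.assert_allclose(ts.dforces[0], -fd, atol=1e-5)

    def test_provenance_recorded(self, gt_mod, rng):
        system, reference, base = gt_mod
        frames = system.named_states["wGT"] + 0.01 * rng.standard_normal((10, 8, 2))
        ts = make_training_set([frames, frames], base, reference,
                               provenance=["alpha", "beta"])
        assert set(ts.provenance) == {"alpha", "beta"}

    def test_mismatched_surfaces_rejected(self, gt_mod):
        from protonfes.modelsys import HarmonicSurface

        _, reference, _ = gt_mod
        with pytest.raises(ValueError):
            make_training_set([np.zeros((5, 8, 2))], reference, HarmonicSurface(1.0, 0.1))


class TestTrain:
    def test_zero_residuals_give_zero_model(self, gt_mod, gt_training, rng):
        system, reference, _, rc, _ = gt_training
        frames = system.named_states["wGT"] + 0.05 * rng.standard_normal((120, 8, 2))
        ts = make_training_set([frames], reference, reference)
        model = train(ts, system, rc, seed=0, n_centers=60)
        e = model.predict_energy(frames)
        assert float(np.sqrt(np.mean(e**2))) < 1e-8

    def test_recovery_of_gaussian_truth(self, gt_training):
        """Dense sampling of a smooth residual: held-out RMSE < 0.1 kcal/mol."""
        system, reference, base, rc, ts = gt_training
        model = train(ts, system, rc, seed=0)
        assert model.fit_report["val_energy_rmse"] < 0.1

    def test_shuffled_labels_destroy_fit(self, gt_training):
        """Negative control: permuted labels leave ~label-sized validation error."""
        system, _, _, rc, ts = gt_training
        rng = np.random.default_rng(99)
        shuffled = type(ts)(ts.positions, rng.permutation(ts.denergy),
                            ts.dforces * 0.0, list(ts.provenance))
        model = train(shuffled, system, rc, seed=0, w_force=0.0)
        label_sd = float(np.std(ts.denergy))
        assert model.fit_report["val_energy_rmse"] > 0.5 * label_sd

    def test_too_few_frames_rejected(self, gt_mod, rng):
        system, reference, base = gt_mod
        from protonfes.modelsys import gt_reaction_coordinates

        frames = system.named_states["wGT"] + 0.01 * rng.standard_normal((20, 8, 2))
        ts = make_training_set([frames], base, reference)
        with pytest.raises(ValueError):
            train(ts, system, gt_reaction_coordinates(), seed=0)

    def test_deterministic_given_seed(self, gt_training):
        system, _, _, rc, ts = gt_training
        m1 = train(ts, system, rc, seed=3, n_centers=80)
        m2 = train(ts, system, rc, seed=3, n_centers=80)
        np.testing.assert_array_equal(m1.weights, m2.weights)


class TestCorrectionModel:
    def test_energy_force_consistency(self, gt_training, rng):
        """Predicted force is the exact analytic gradient of predicted energy."""
        system, _, _, rc, ts = gt_training
        model = train(ts, system, rc, seed=0, n_centers=100)
        x = ts.positions[17]
        _, g = model.predict_energy_gradient(x)
        fd = fd_gradient(lambda y: model.predict_energy(y), x)
        scale = max(1.0, np.max(np.abs(fd)))
        np.testing.assert_allclose(g, fd, atol=2e-6 * scale)

    def test_extrapolation_guard_flags_outside_points(self, gt_training):
        system, _, base, rc, ts = gt_training
        model = train(ts, system, rc, seed=0, n_centers=60)
        inside = ts.positions[0]
        assert model.in_domain(inside)
        outside = inside * 3.0  # blown-up cluster: descriptors far out of range
        assert not model.in_domain(outside)
        surf = corrected_surface(base, model, guard=True)
        with pytest.warns(ExtrapolationWarning):
            surf.energy(outside)

    def test_corrected_surface_recovers_reference_energies(self, gt_training, rng):
        """corrected = base + model ~ reference on the training region."""
        system, reference, base, rc, ts = gt_training
        model = train(ts, system, rc, seed=0)
        surf = corrected_surface(base, model, guard=False)
        idx = rng.choice(ts.n_frames, 200, replace=False)
        x = ts.positions[idx]
        err = surf.energy(x) - reference.energy(x)
        assert float(np.sqrt(np.mean(err**2))) < 0.05
        base_err = base.energy(x) - reference.energy(x)
        assert np.sqrt(np.mean(err**2)) < 0.2 * np.sqrt(np.mean(base_err**2))

    def test_model_json_roundtrip_fields(self, gt_training):
        import json

        system, _, _, rc, ts = gt_training
        model = train(ts, system, rc, seed=0, n_centers=40)
        doc = json.loads(model.to_json())
        assert doc["fit_report"]["seed"] == 0
        assert len(doc["weights"]) == 40


def test_default_descriptor_pairs_cover_protons(gt_mod):
    system, _, _ = gt_mod
    pairs = default_descriptor_pairs(system)
    assert len(pairs) == 6  # 3 pairs per transferable proton
    flat = {i for p in pairs for i in p}
    assert system.index("H3") in flat and system.index("H1") in flat
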