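"""Phase extraction: windowing, training contract, smoothing, calibration."""

import numpy as np
import pytest

from repanom.features import fit_sphere_rotation, project_sequence
from repanom.phase import (
    PhaseHyperparams,
    PhaseNetwork,
    PhaseSequence,
    _relational_grads,
    build_window_pairs,
    build_windows,
    calibrate_direction,
    circular_correlation,
    extract_phase,
    smooth_phase,
    train_fallback_extractor,
    train_phase_network,
)
from repanom.simulate import SimConfig, generate_session

TWO_PI = 2 * np.pi


def _identity_extractor(D=2, w=1):
    """A hand-built linear extractor passing the first two dims through."""
    proj = np.zeros((2, w * D))
    proj[0, 0] = 1.0
    proj[1, 1] = 1.0
    return PhaseNetwork(
        kind="pca",
        window_len=w,
        feat_mean=np.zeros(D),
        feat_sd=np.ones(D),
        pca_mean=np.zeros(w * D),
        pca_proj=proj,
    )


class TestWindows:
    def test_window_counts_and_overlap(self, rng):
        X = rng.standard_normal((20, 3))
        W = build_windows(X, 7)
        assert W.shape == (14, 21)
        a, b = build_window_pairs(X, 7)
        assert a.shape[0] == 20 - 7  # L - w pairs
        # consecutive windows overlap by w-1 samples
        np.testing.assert_array_equal(a[0][3:], b[0][:-3])

    def test_constant_signal_identical_windows(self):
        W = build_windows(np.ones((10, 2)), 4)
        assert np.ptp(W) == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            build_window_pairs(np.zeros((7, 2)), 7)


class TestExtraction:
    def test_output_normalized_and_angles(self):
        net = _identity_extractor()
        X = np.array([[2.0, 0.0], [0.0, -5.0], [1.0, 1.0]])
        seq = extract_phase(net, X)
        np.testing.assert_allclose(np.linalg.norm(seq.circle, axis=1), 1.0, atol=1e-12)
        assert seq.angles[0] == pytest.approx(0.0)
        assert seq.angles[1] == pytest.approx(3 * np.pi / 2)  # atan2(-1, 0) mod 2pi
        assert seq.angles[2] == pytest.approx(np.pi / 4)

    def test_output_length_matches_input(self, rng):
        net = _identity_extractor(D=2, w=5)
        X = rng.standard_normal((30, 2))
        assert len(extract_phase(net, X)) == 30

    def test_schema_mismatch_rejected(self, rng):
        net = _identity_extractor(D=2)
        with pytest.raises(ValueError, match="dimension"):
            extract_phase(net, rng.standard_normal((10, 5)))


class TestSmoothing:
    def test_constant_sequence_unchanged(self):
        seq = PhaseSequence(np.tile([0.6, 0.8], (12, 1)))
        out = smooth_phase(seq, 7)
        np.testing.assert_allclose(out.circle, seq.circle, atol=1e-12)

    def test_window_one_is_identity(self, rng):
        c = rng.standard_normal((15, 2))
        c /= np.linalg.norm(c, axis=1, keepdims=True)
        out = smooth_phase(PhaseSequence(c), 1)
        np.testing.assert_allclose(out.circle, c, atol=1e-12)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_phase(PhaseSequence(np.ones((5, 2))), 4)

    def test_outlier_pulled_toward_neighbors(self):
        c = np.tile([1.0, 0.0], (13, 1))
        c[6] = [-1.0, 0.0]  # single flipped sample
        out = smooth_phase(PhaseSequence(c), 7)
        # average of 6 copies of (1,0) and one (-1,0) is (5/7, 0) -> renormalizes to (1,0)
        np.testing.assert_allclose(out.circle[6], [1.0, 0.0], atol=1e-12)

    def test_never_leaves_unit_circle(self, rng):
        c = rng.standard_normal((40, 2))
        c /= np.linalg.norm(c, axis=1, keepdims=True)
        out = smooth_phase(PhaseSequence(c), 7)
        np.testing.assert_allclose(np.linalg.norm(out.circle, axis=1), 1.0, atol=1e-9)

    def test_antipodal_cancellation_keeps_previous(self):
        c = np.array([[1.0, 0], [1.0, 0], [-1.0, 0]] * 3)
        out = smooth_phase(PhaseSequence(c), 3)
        np.testing.assert_allclose(np.linalg.norm(out.circle, axis=1), 1.0, atol=1e-9)


class TestRelationalObjective:
    def test_analytic_gradients_match_finite_differences(self, rng):
        hp = PhaseHyperparams()
        O1 = rng.standard_normal((6, 2))
        O2 = rng.standard_normal((6, 2))
        loss, d1, d2 = _relational_grads(O1, O2, hp)
        eps = 1e-6
        for O, dO in ((O1, d1), (O2, d2)):
            for i in range(O.shape[0]):
                for j in range(2):
                    O[i, j] += eps
                    lp = _relational_grads(O1, O2, hp)[0]
                    O[i, j] -= 2 * eps
                    lm = _relational_grads(O1, O2, hp)[0]
                    O[i, j] += eps
                    assert dO[i, j] == pytest.approx((lp - lm) / (2 * eps), abs=1e-4)


@pytest.fixture(scope="module")
def small_training_setup():
    cfg = SimConfig(pause_probability=0.0, noise_sd=0.01)
    sessions = [generate_session(cfg, f"S{i}", i) for i in range(3)]
    projs = {
        ch.name: fit_sphere_rotation(
            np.concatenate([s.features.channel(ch.name) for s in sessions])
        )
        for ch in cfg.schema.sphere_channels
    }
    flats = [project_sequence(s.features, projs) for s in sessions]
    fresh = generate_session(cfg, "F", 777)
    fresh_flat = project_sequence(fresh.features, projs)
    return flats, fresh, fresh_flat


class TestTrainingContract:
    def test_fallback_meets_phase_contract(self, small_training_setup):
        flats, fresh, fresh_flat = small_training_setup
        net = train_fallback_extractor(flats, seed=0)
        net = calibrate_direction(net, np.concatenate(flats))
        cc = circular_correlation(extract_phase(net, fresh_flat).angles, fresh.true_phase)
        assert cc >= 0.9

    def test_network_meets_phase_contract(self, small_training_setup):
        flats, fresh, fresh_flat = small_training_setup
        net = train_phase_network(flats, PhaseHyperparams(), seed=0)
        net = calibrate_direction(net, np.concatenate(flats))
        ang = extract_phase(net, fresh_flat).angles
        assert circular_correlation(ang, fresh.true_phase) >= 0.9

    def test_noiseless_sinusoids_give_monotone_phase(self, rng):
        # multi-channel sinusoids driven by a variable-rate cycle, no noise:
        # the extracted phase must advance forward almost everywhere
        rate = np.repeat(rng.uniform(0.08, 0.2, 30), rng.integers(30, 60))
        phi = np.cumsum(rate)
        X = np.stack(
            [np.sin(phi), np.cos(phi), np.sin(phi + 0.5), 0.5 * np.cos(phi + 1.0)],
            axis=1,
        )
        hp = PhaseHyperparams(pretrain_iters=400, finetune_iters=100)
        net = calibrate_direction(train_phase_network([X], hp, seed=0), X)
        ang = extract_phase(net, X).angles
        inc = np.mod(np.diff(ang) + np.pi, TWO_PI) - np.pi
        assert (inc >= 0).mean() >= 0.99
        assert circular_correlation(ang, np.mod(phi, TWO_PI)) >= 0.9

    def test_training_deterministic_under_seed(self, small_training_setup):
        flats, _, _ = small_training_setup
        hp = PhaseHyperparams(pretrain_iters=50, finetune_iters=20)
        a = train_phase_network(flats, hp, seed=3)
        b = train_phase_network(flats, hp, seed=3)
        for Wa, Wb in zip(a.mlp.W + a.mlp.b, b.mlp.W + b.mlp.b):
            np.testing.assert_array_equal(Wa, Wb)

    def test_calibration_fixes_reversed_extractor(self, small_training_setup):
        flats, _, _ = small_training_setup
        ref = np.concatenate(flats)
        net = train_fallback_extractor(flats, seed=0)
        net = calibrate_direction(net, ref)
        from dataclasses import replace

        reversed_net = replace(net, flip=not net.flip)
        fixed = calibrate_direction(reversed_net, ref)
        ang = extract_phase(fixed, ref).angles
        inc = np.mod(np.diff(ang) + np.pi, TWO_PI) - np.pi
        assert np.median(inc) > 0
        # an already-forward extractor is left unchanged
        assert calibrate_direction(net, ref).flip == net.flip


class TestCircularCorrelation:
    def test_self_and_offset(self, rng):
        a = rng.uniform(0, TWO_PI, 300)
        assert circular_correlation(a, a) == pytest.approx(1.0, abs=1e-9)
        assert circular_correlation(a, np.mod(a + 2.0, TWO_PI)) == pytest.approx(1.0, abs=1e-9)

    def test_reversal_and_independence(self, rng):
        a = rng.uniform(0, TWO_PI, 300)
        assert circular_correlation(a, -a) == pytest.approx(-1.0, abs=1e-9)
        b = rng.uniform(0, TWO_PI, 300)
        assert abs(circular_correlation(a, b)) < 0.2
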