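"""Localizer: loss identities, network contract, training behavior, read-out."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ogmap import (
    GroundTruthLabels,
    LocalizerConfig,
    LocalizerOutput,
    SimulationConfig,
    bce,
    build_localizer,
    dice_loss,
    load_localizer,
    localization_loss,
    localize,
    match_labels,
    occupancy_loss,
    peak_finder_localize,
    render_image,
    save_localizer,
    total_loss,
    train_localizer,
)
from ogmap.localizer import CLAMP_EPS, predict


class TestBce:
    def test_confident_correct_is_zero_after_clamping(self):
        assert bce(1.0, 1.0) <= -np.log(1 - CLAMP_EPS) + 1e-12

    def test_half_prediction_is_log_two(self):
        assert bce(0.0, 0.5) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_quarter_prediction(self):
        assert bce(1.0, 0.25) == pytest.approx(-np.log(0.25), abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bce(1.5, 0.5)
        with pytest.raises(ValueError):
            bce(0.5, -0.1)


class TestDiceLoss:
    def test_exact_binary_match_is_zero(self):
        assert dice_loss([1, 0, 1], [1, 0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_complete_miss(self):
        expected = 1.0 - 1e-5 / (1e-5 + 1.0)
        assert dice_loss([0, 0, 0], [1, 0, 0]) == pytest.approx(expected, abs=1e-12)

    def test_half_overlap(self):
        expected = 1.0 - (1e-5 + 1.0) / (1e-5 + 2.0)
        assert dice_loss([0.5, 0.5], [1, 0]) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss([1, 0], [1, 0, 1])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_range_and_permutation_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 30))
        p = rng.random(n)
        t = (rng.random(n) < 0.2).astype(float)
        val = dice_loss(p, t)
        assert 0.0 <= val <= 1.0
        perm = rng.permutation(n)
        assert dice_loss(p[perm], t[perm]) == pytest.approx(val, abs=1e-12)


class TestOccupancyLoss:
    def test_perfect_binary_match_near_zero(self):
        assert occupancy_loss([1, 0, 1], [1, 0, 1]) == pytest.approx(0.0, abs=1e-5)

    def test_single_pixel_sum_of_terms(self):
        expected = dice_loss([0.5], [1.0]) + bce(1.0, 0.5)
        assert occupancy_loss([0.5], [1.0]) == pytest.approx(expected, abs=1e-12)

    def test_empty_vectors_vacuous(self):
        assert occupancy_loss([], []) == pytest.approx(0.0, abs=1e-12)


class TestLocalizationLoss:
    def test_fully_masked_when_no_emitters(self):
        assert localization_loss([0.3, 0.9], [0.5, 0.5], [0, 0]) == 0.0

    def test_matching_half_position_is_log_two(self):
        """bce is a proper score: its minimum over y at x=0.5 is ln 2, not 0."""
        assert localization_loss([0.5], [0.5], [1]) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_boundary_position_zero_after_clamping(self):
        assert localization_loss([1.0], [1.0], [1]) == pytest.approx(0.0, abs=1e-5)

    def test_minimized_at_true_position(self):
        for target in (0.2, 0.5, 0.8):
            at_truth = localization_loss([target], [target], [1])
            for y in np.linspace(0.01, 0.99, 33):
                assert at_truth <= localization_loss([y], [target], [1]) + 1e-12


class TestTotalLoss:
    def test_zero_at_clamped_perfect_prediction_with_binary_rel(self):
        truth = GroundTruthLabels(
            np.array([1.0, 3.0]),
            np.array([0.0, 1.0, 0.0, 1.0]),
            np.array([0.0, 0.0, 0.0, 0.0]),
        )
        out = LocalizerOutput(truth.occupancy.copy(), truth.rel_position.copy())
        assert total_loss(out, truth) == pytest.approx(0.0, abs=1e-4)

    def test_dominates_localization_term(self):
        rng = np.random.default_rng(0)
        occ = (rng.random(20) < 0.2).astype(float)
        rel = rng.random(20) * occ
        truth = GroundTruthLabels(np.array([]), occ, rel)
        out = LocalizerOutput(rng.random(20), rng.random(20))
        assert total_loss(out, truth) >= localization_loss(out.rel_position, rel, occ) >= 0

    def test_single_pixel_matches_scalar_arithmetic(self):
        truth = GroundTruthLabels(np.array([0.3]), np.array([1.0]), np.array([0.3]))
        out = LocalizerOutput(np.array([0.9]), np.array([0.3]))
        expected = dice_loss([0.9], [1.0]) + bce(1.0, 0.9) + bce(0.3, 0.3)
        assert total_loss(out, truth) == pytest.approx(expected, abs=1e-12)


class TestNetworkContract:
    CFG = LocalizerConfig(base_channels=4, training_steps=0, batch_size=2, seed=3)

    def test_output_shape_and_range(self):
        model = build_localizer(self.CFG)
        for L in (100, 1000):
            img = np.random.default_rng(0).normal(size=(5, L))
            out = predict(img, model)
            assert out.occupancy.shape == (L,)
            assert ((out.occupancy >= 0) & (out.occupancy <= 1)).all()
            assert ((out.rel_position >= 0) & (out.rel_position <= 1)).all()

    def test_same_seed_identical_parameters(self):
        w1 = build_localizer(self.CFG).get_weights()
        w2 = build_localizer(self.CFG).get_weights()
        for a, b in zip(w1, w2):
            np.testing.assert_array_equal(a, b)

    def test_wrong_row_count_rejected(self):
        model = build_localizer(self.CFG)
        with pytest.raises(ValueError):
            predict(np.zeros((4, 100)), model)

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            LocalizerConfig(depth=0)
        with pytest.raises(ValueError):
            LocalizerConfig(occupancy_threshold=1.5)

    def test_save_load_round_trip(self, tmp_path):
        model = build_localizer(self.CFG)
        path = tmp_path / "model.npz"
        save_localizer(model, path)
        loaded = load_localizer(path)
        img = np.random.default_rng(1).normal(size=(5, 120))
        a, b = predict(img, model), predict(img, loaded)
        np.testing.assert_allclose(a.occupancy, b.occupancy, atol=1e-7)


class TestTraining:
    SIM = SimulationConfig(length_range_px=(100, 200))

    def test_zero_steps_leaves_model_unchanged(self):
        cfg = LocalizerConfig(base_channels=4, training_steps=0, batch_size=2, seed=5)
        model = build_localizer(cfg)
        before = [w.copy() for w in model.get_weights()]
        model, history = train_localizer(model, self.SIM, cfg)
        assert history == []
        for a, b in zip(before, model.get_weights()):
            np.testing.assert_array_equal(a, b)

    def test_short_run_reduces_loss(self):
        cfg = LocalizerConfig(base_channels=4, training_steps=60, batch_size=8, seed=5)
        model = build_localizer(cfg)
        model, history = train_localizer(model, self.SIM, cfg)
        assert len(history) == 60
        assert np.mean(history[-10:]) < np.mean(history[:10])

    def test_loss_log_written(self, tmp_path):
        cfg = LocalizerConfig(base_channels=4, training_steps=5, batch_size=2, seed=5)
        model = build_localizer(cfg)
        log = tmp_path / "loss.log"
        train_localizer(model, self.SIM, cfg, log_path=log, log_every=1)
        lines = log.read_text().strip().splitlines()
        assert len(lines) == 5
        step, loss = lines[2].split("\t")
        assert int(step) == 2 and float(loss) > 0


class TestReadout:
    def test_localize_threshold_validation(self):
        model = build_localizer(LocalizerConfig(base_channels=4, seed=1))
        img = np.zeros((5, 100))
        with pytest.raises(ValueError):
            localize(img, model, threshold=1.5)

    def test_run_suppression_keeps_single_peak(self, monkeypatch):
        """Consecutive super-threshold pixels collapse to the max-occupancy one."""
        model = build_localizer(LocalizerConfig(base_channels=4, seed=1))
        occ = np.zeros(100)
        rel = np.zeros(100)
        occ[[40, 41, 42]] = [0.7, 0.95, 0.8]
        rel[41] = 0.25
        occ[70] = 0.9
        rel[70] = 0.5
        fake = LocalizerOutput(occ, rel)
        monkeypatch.setattr("ogmap.localizer.predict", lambda img, m: fake)
        qm = localize(np.zeros((5, 100)), model, threshold=0.5)
        np.testing.assert_allclose(qm.positions_px, [41.25, 70.5])


class TestMatching:
    def test_greedy_matching_counts(self):
        res = match_labels(np.array([10.2, 20.0, 35.0]), np.array([10.0, 20.4]))
        assert res["n_matched"] == 2
        assert res["precision"] == pytest.approx(2 / 3)
        assert res["recall"] == pytest.approx(1.0)
        assert res["rmse_px"] == pytest.approx(np.sqrt((0.2**2 + 0.4**2) / 2))

    def test_radius_respected(self):
        res = match_labels(np.array([10.0]), np.array([12.0]), radius=1.0)
        assert res["n_matched"] == 0


def test_peak_finder_merges_close_pair():
    """The classical baseline reports one label for a sub-diffraction pair."""
    cfg = SimulationConfig()
    labels = GroundTruthLabels.from_positions(np.array([50.0, 52.0]), 100)
    img = render_image(labels, 100, cfg, np.random.default_rng(0), noise=True)
    qm = peak_finder_localize(img)
    near = qm.positions_px[(qm.positions_px > 46) & (qm.positions_px < 56)]
    assert len(near) <= 1
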