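"""EF/NRMSE metrics, baselines, interpretation exports, ablations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from deepcrop.evaluation import (
    ablation_run,
    attention_to_frame,
    evaluate_simulation,
    export_hidden,
    extract_attention,
    mean_baseline,
    modeling_efficiency,
    nrmse,
)
from deepcrop.growth_records import WindowDataset, window_samples
from deepcrop.env_features import feature_tensor


def brute_force_ef(y, p):
    y = np.asarray(y, float)
    p = np.asarray(p, float)
    num = sum((yi - pi) ** 2 for yi, pi in zip(y, p))
    den = sum((yi - y.mean()) ** 2 for yi in y)
    return 1 - num / den


def brute_force_nrmse(y, p):
    y = np.asarray(y, float)
    p = np.asarray(p, float)
    rmse = (sum((yi - pi) ** 2 for yi, pi in zip(y, p)) / len(y)) ** 0.5
    return rmse / (max(y) - min(y))


class TestModelingEfficiency:
    def test_perfect_match_is_one(self):
        y = [1.0, 2.0, 3.0, 4.0]
        assert modeling_efficiency(y, y) == 1.0

    def test_mean_predictor_is_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert modeling_efficiency(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_hand_evaluated_example(self):
        # y=[0,1,2], p=[0,0,0]: residual SS 5, variance SS 2 -> 1 - 5/2
        assert modeling_efficiency([0, 1, 2], [0, 0, 0]) == pytest.approx(-1.5)

    def test_constant_observations_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            modeling_efficiency([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        y, p = rng.normal(size=50), rng.normal(size=50)
        assert modeling_efficiency(y, p) == pytest.approx(
            modeling_efficiency(y + 7.3, p + 7.3), rel=1e-9
        )

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_brute_force_formula(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 30)
        y = rng.normal(size=n)
        p = rng.normal(size=n)
        assert modeling_efficiency(y, p) == pytest.approx(
            brute_force_ef(y, p), abs=1e-10
        )
        assert nrmse(y, p) == pytest.approx(brute_force_nrmse(y, p), abs=1e-10)


class TestNrmse:
    def test_perfect_is_zero(self):
        assert nrmse([0.0, 2.0, 5.0], [0.0, 2.0, 5.0]) == 0.0

    def test_hand_evaluated_example(self):
        assert nrmse([0.0, 2.0], [1.0, 1.0]) == pytest.approx(0.5)

    def test_positive_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        y, p = rng.normal(size=30), rng.normal(size=30)
        assert nrmse(3.7 * y, 3.7 * p) == pytest.approx(nrmse(y, p), rel=1e-12)

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            nrmse([1.0, 1.0], [0.0, 2.0])


class TestBaselineAndReport:
    def test_baseline_ef_zero_on_its_own_data(self):
        index = pd.RangeIndex(5)
        labels = pd.DataFrame({"a": [1.0, 2, 3, 4, 5]}, index=index)
        base = mean_baseline(labels, index)
        assert (base["a"] == 3.0).all()
        assert modeling_efficiency(labels["a"], base["a"]) == pytest.approx(0.0)

    def test_baseline_nrmse_matches_hand_computation(self):
        y = np.array([0.0, 1.0, 2.0])
        base = np.full(3, 1.0)
        expected = np.sqrt(2.0 / 3.0) / 2.0
        assert nrmse(y, base) == pytest.approx(expected)

    def test_truth_against_itself_is_perfect(self, small_cultivation):
        truth = small_cultivation.truth
        report = evaluate_simulation(truth, truth, ["leaf_dw_g", "harvest_fw_g"])
        assert (report.per_factor["ef"] == 1.0).all()
        assert (report.per_factor["nrmse"] == 0.0).all()

    def test_restricting_to_observation_days_changes_n(self, small_cultivation):
        truth = small_cultivation.truth
        obs_days = truth.index[::10]
        report = evaluate_simulation(truth, truth.loc[obs_days], ["leaf_dw_g"])
        assert report.per_factor.loc["leaf_dw_g", "n"] == len(obs_days)

    def test_aggregate_is_mean_of_factor_efs(self):
        index = pd.RangeIndex(4)
        labels = pd.DataFrame(
            {"a": [0.0, 1, 2, 3], "b": [1.0, 3, 5, 7]}, index=index
        )
        pred = labels.copy()
        pred["a"] += 0.5
        report = evaluate_simulation(pred, labels, ["a", "b"])
        expected = (report.per_factor.loc["a", "ef"] + report.per_factor.loc["b", "ef"]) / 2
        assert report.aggregate_ef == pytest.approx(expected)

    def test_constant_label_factor_skipped_with_warning(self):
        index = pd.RangeIndex(4)
        labels = pd.DataFrame({"a": [0.0, 1, 2, 3], "b": 0.0}, index=index)
        with pytest.warns(UserWarning, match="constant-label factor 'b'"):
            report = evaluate_simulation(labels, labels, ["a", "b"])
        assert list(report.per_factor.index) == ["a"]
        with pytest.raises(ValueError, match="no scoreable factors"):
            evaluate_simulation(labels, labels, ["b"])

    def test_disjoint_days_rejected(self, small_cultivation):
        truth = small_cultivation.truth
        shifted = truth.copy()
        shifted.index = truth.index + pd.Timedelta(days=1000)
        with pytest.raises(ValueError, match="overlap"):
            evaluate_simulation(shifted, truth)


@pytest.fixture(scope="module")
def sample(tiny_result):
    cult = tiny_result.cultivations["c2"]
    feats, _, _ = feature_tensor(cult.env)
    return window_samples(
        feats, cult.truth.to_numpy()[None, ...],
        tiny_result.trained.cfg.memory_length, "c2",
    )


class TestInterpretationExports:
    def test_attention_rows_sum_to_one(self, tiny_result, sample):
        maps = extract_attention(
            tiny_result.trained, sample[0].features, sample[0].prev_growth
        )
        assert maps
        for m in maps:
            np.testing.assert_allclose(m.weights.sum(axis=-1), 1.0, atol=1e-5)

    def test_cross_attention_shape_heads_L_24L(self, tiny_result, sample):
        cfg = tiny_result.trained.cfg
        maps = extract_attention(
            tiny_result.trained, sample[0].features, sample[0].prev_growth,
            ["leaf"], day_tag=20,
        )
        cross = [m for m in maps if m.kind == "cross"]
        assert cross
        for m in cross:
            assert m.weights.shape == (
                1, cfg.n_heads, cfg.memory_length, 24 * cfg.memory_length
            )
            assert m.day_tag == 20

    def test_decoder_self_attention_upper_triangle_zero(self, tiny_result, sample):
        maps = extract_attention(
            tiny_result.trained, sample[0].features, sample[0].prev_growth
        )
        for m in maps:
            if m.kind == "self" and m.decoder:
                L = m.weights.shape[-1]
                upper = np.triu_indices(L, k=1)
                assert (m.weights[..., upper[0], upper[1]] == 0).all()

    def test_unknown_decoder_rejected(self, tiny_result, sample):
        with pytest.raises(ValueError, match="unknown"):
            extract_attention(
                tiny_result.trained, sample[0].features, sample[0].prev_growth,
                ["root"],
            )

    def test_attention_frame_is_long_format(self, tiny_result, sample):
        maps = extract_attention(
            tiny_result.trained, sample[0].features, sample[0].prev_growth, ["leaf"]
        )
        frame = attention_to_frame(maps[0])
        assert set(frame.columns) >= {"head", "query_day", "key_pos", "weight"}
        assert len(frame) == int(np.prod(maps[0].weights.shape[1:]))

    def test_hidden_export_rows_and_determinism(self, tiny_result, sample):
        dataset = WindowDataset.from_samples(sample[:5])
        hidden, meta = export_hidden(tiny_result.trained, dataset, decoder="leaf")
        L = tiny_result.trained.cfg.memory_length
        assert hidden.shape == (5 * L, tiny_result.trained.cfg.d_model)
        assert len(meta) == len(hidden)
        assert set(meta["decoder"]) == {"leaf"}
        hidden2, _ = export_hidden(tiny_result.trained, dataset, decoder="leaf")
        np.testing.assert_array_equal(hidden, hidden2)


class TestAblation:
    def test_removing_all_decoders_rejected_before_training(self, tiny_config):
        with pytest.raises(ValueError, match="at least one decoder"):
            ablation_run(tiny_config, "structure", ["no_decoders"])

    def test_invalid_axis_and_variant_rejected(self, tiny_config):
        with pytest.raises(ValueError, match="axis"):
            ablation_run(tiny_config, "bogus", ["x"])
        with pytest.raises(ValueError, match="loss variant"):
            ablation_run(tiny_config, "loss", ["bogus"])
        with pytest.raises(ValueError, match="unknown input features"):
            ablation_run(tiny_config, "input", [["not_a_feature"]])

    def test_loss_axis_variants_scored_on_shared_dataset(self, tiny_config):
        cfg = tiny_config.copy()
        cfg.training.epochs = 1
        cfg.n_augment_draws = 1
        table = ablation_run(cfg, "loss", ["single", "multitask"])
        assert list(table["variant"]) == ["single", "multitask"]
        assert list(table["n_loss_terms"]) == [1, 8]
        assert np.isfinite(table["aggregate_ef"]).all()

    def test_memory_length_axis_changes_model(self, tiny_config):
        cfg = tiny_config.copy()
        cfg.training.epochs = 1
        cfg.n_augment_draws = 1
        table = ablation_run(cfg, "memory_length", [2, 4])
        assert len(table) == 2
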