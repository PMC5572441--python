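"""Benchmark metrics, end-to-end runs, sweeps and the efficiency measure."""

import numpy as np
import pytest

from binam import (
    ExperimentConfig,
    IntegratorConfig,
    energy_efficiency,
    evaluate_metrics,
    recall_matrix,
    run_benchmark,
    score_recall,
    sweep_1d,
    sweep_2d,
    train,
)
from binam.bench import results_to_frame
from binam.codec import EncodingSpec, SpikeTrainSet, encode
from binam.presets import REFERENCE_SETS, benchmark_config


@pytest.fixture(scope="module")
def tiny_config():
    return ExperimentConfig(
        m=12, n=12, c=3, d=3, N=8, s=1, omega=1,
        neuron=REFERENCE_SETS["a"].replace(v_th=-76.0),  # 3-of-4 scaling: c=3
        sigma_t=0.0,
    )


# --- metric normalisation ---------------------------------------------------


def test_ideal_recall_scores_perfectly(small_dataset, small_memory):
    ideal = recall_matrix(small_memory, small_dataset.X)
    r = evaluate_metrics(ideal, small_dataset)
    assert r.I_n == pytest.approx(1.0)
    assert r.alpha_n == pytest.approx(0.0)
    assert r.beta_n == pytest.approx(0.0)
    assert r.alpha_bar > 0  # this workload does produce false positives


def test_all_zero_recall_scores_zero_information(small_dataset):
    r = evaluate_metrics(np.zeros_like(small_dataset.Y), small_dataset)
    assert r.I_n == pytest.approx(0.0, abs=1e-12)
    assert r.beta_n == 1.0
    assert r.alpha_n == -1.0  # complete false-positive shortage


def test_all_ones_recall_saturates_alpha(small_dataset):
    r = evaluate_metrics(np.ones_like(small_dataset.Y), small_dataset)
    assert r.alpha_n == pytest.approx(1.0)
    assert r.beta_n == 0.0


def test_exact_stored_values_give_negative_alpha_n(small_dataset):
    # returning exactly the stored patterns suppresses the expected false
    # positives entirely: a shortage, mapped to alpha_n = -1
    r = evaluate_metrics(small_dataset.Y, small_dataset)
    assert r.alpha_n == pytest.approx(-1.0)
    assert r.beta_n == 0.0
    assert r.I_n > 1.0  # more information than the theoretical memory


def test_metric_shape_mismatch_rejected(small_dataset):
    with pytest.raises(ValueError, match="shape"):
        evaluate_metrics(np.zeros((3, 3)), small_dataset)


def test_normalised_metrics_stay_in_range(small_dataset, rng):
    for _ in range(10):
        noisy = (rng.random(small_dataset.Y.shape) < 0.3).astype(np.uint8)
        r = evaluate_metrics(noisy, small_dataset)
        assert -1.0 <= r.alpha_n <= 1.0
        assert 0.0 <= r.beta_n <= 1.0
        assert r.I_n >= 0.0


# --- end-to-end runs --------------------------------------------------------


def test_benchmark_run_is_deterministic(tiny_config):
    a = run_benchmark(tiny_config)
    b = run_benchmark(tiny_config)
    assert a.I_n == b.I_n
    assert a.alpha_bar == b.alpha_bar
    assert np.array_equal(a.alphas, b.alphas)


def test_benchmark_rejects_empty_workload(tiny_config):
    with pytest.raises(ValueError, match="at least one sample"):
        run_benchmark(tiny_config.replace(N=0))


def test_automatic_sample_count_resolution(tiny_config):
    from binam import optimal_sample_count

    cfg = tiny_config.replace(N=None)
    assert cfg.resolve_N() == optimal_sample_count(12, 12, 3, 3)


def test_identical_input_repetitions_average_identically(tiny_config):
    r = run_benchmark(tiny_config.replace(repetitions=3, repeat_mode="input"))
    assert len(r.runs) == 3
    assert r.runs[0].I_n == r.runs[1].I_n == r.runs[2].I_n == r.I_n


def test_seed_repetitions_vary_the_workload(tiny_config):
    r = run_benchmark(
        tiny_config.replace(repetitions=3, repeat_mode="seed", sigma_t=2.0)
    )
    assert len(r.runs) == 3
    assert len({run.I for run in r.runs}) > 1


def test_config_round_trip_and_hash(tiny_config):
    doc = tiny_config.to_dict()
    back = ExperimentConfig.from_dict(doc)
    assert back == tiny_config
    assert back.config_hash == tiny_config.config_hash
    assert back.replace(m=13).config_hash != tiny_config.config_hash


def test_external_scoring_path_matches_builtin(tmp_path, small_dataset, small_memory):
    # write the builtin substrate's output to CSV and score it back in —
    # the black-box path any hardware recording would take
    from binam import build_network, run_backend

    net = build_network(small_memory, params=REFERENCE_SETS["a"])
    sp = encode(small_dataset.X, EncodingSpec(s=1, sigma_t=0.0))
    out, _ = run_backend(net, sp)
    path = tmp_path / "out.csv"
    out.to_csv(path)
    back = SpikeTrainSet.from_csv(path, n_channels=16, duration=sp.duration)
    r = score_recall(back, small_dataset)
    assert r.I_n == pytest.approx(1.0)


# --- sweeps -----------------------------------------------------------------


def test_sweep_1d_empty_values_yield_empty_table(tiny_config):
    table = sweep_1d(tiny_config, "c", [])
    assert len(table) == 0


def test_sweep_1d_survives_infeasible_points(tiny_config):
    table = sweep_1d(tiny_config, "c", [3, 40])
    assert list(table["status"]) == ["ok", "failed"]
    assert table.loc[0, "I_n"] == pytest.approx(1.0)


def test_sweep_1d_peak_at_tuned_input_weight(tiny_config):
    # neuron tuned for c=3 here: fewer active inputs miss stored bits, more
    # fire spuriously; the normalised information peaks at the tuned c
    table = sweep_1d(tiny_config.replace(sigma_t=0.0), "c", [2, 3, 4])
    ok = table[table.status == "ok"]
    assert ok["I_n"].idxmax() == 1


def test_sweep_2d_shapes_and_zero_weight_column(tiny_config):
    grids = sweep_2d(tiny_config, [-76.0, -70.0], [0.05, tiny_config.neuron.w])
    assert grids["I_n"].shape == (2, 2)
    # near-zero weight: no output spikes at all
    assert grids["beta_n"][0, 0] == pytest.approx(1.0)
    assert grids["I_n"][0, 0] == pytest.approx(0.0, abs=1e-12)
    # tuned point recalls perfectly
    assert grids["I_n"][0, 1] == pytest.approx(1.0)


def test_sweep_2d_rejects_empty_grids(tiny_config):
    with pytest.raises(ValueError):
        sweep_2d(tiny_config, [], [1.0])


def test_results_frame_has_standard_columns(tiny_config):
    r = run_benchmark(tiny_config)
    frame = results_to_frame([(tiny_config, r)])
    for col in ("config_hash", "m", "n", "N", "s", "omega", "backend",
                "integrator", "dt", "I_bits", "I_n", "alpha_n", "beta_n",
                "t_per_sample_ms", "seed"):
        assert col in frame.columns


# --- energy efficiency ------------------------------------------------------


def test_efficiency_from_published_energy_per_sample():
    # I_n = 0.917 at 112.9 mJ per sample: 8.1 recalled samples per joule
    N = 113648
    res = energy_efficiency(0.917, N, energy_j=N * 112.9e-3)
    assert res.E_eff == pytest.approx(8.1, abs=0.4)
    assert res.E_per_sample == pytest.approx(0.1129)


def test_efficiency_scales_inversely_with_power():
    a = energy_efficiency(0.5, 100, power_w=1.0, t_s=10.0)
    b = energy_efficiency(0.5, 100, power_w=2.0, t_s=10.0)
    assert a.E == pytest.approx(10.0)
    assert b.E_eff == pytest.approx(a.E_eff / 2)
    assert energy_efficiency(0.0, 100, power_w=1.0, t_s=10.0).E_eff == 0.0


def test_efficiency_rejects_non_positive_inputs():
    with pytest.raises(ValueError):
        energy_efficiency(1.0, 10, power_w=0.0, t_s=1.0)
    with pytest.raises(ValueError):
        energy_efficiency(1.0, 10, energy_j=-1.0)
    with pytest.raises(ValueError):
        energy_efficiency(1.0, 10)


# --- published-size configurations ------------------------------------------


def test_benchmark_config_lookup():
    cfg = benchmark_config("b")
    assert (cfg.m, cfg.n, cfg.N) == (28, 32, 54)
    assert (cfg.s, cfg.omega) == (1, 4)
    with pytest.raises(KeyError):
        benchmark_config("e")
    with pytest.raises(KeyError):
        benchmark_config("a", "spinnaker")
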