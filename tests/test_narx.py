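"""Tapped-delay NARX model: embedding, LM training, open/closed-loop prediction."""

import numpy as np
import pytest

from pepnarx.narx import (
    NarxConfig,
    _split_rows,
    fit_narx,
    make_regression_matrix,
    predict_closed_loop,
    predict_open_loop,
)
from pepnarx.series import SeriesGroup, build_series


def linear_arx(n, seed=0, u_low=-2.0, u_high=2.0):
    """Exact recursion y(t) = 0.5 y(t-1) + 0.3 u(t-1) + 0.1 — the oracle."""
    rng = np.random.default_rng(seed)
    u = rng.uniform(u_low, u_high, n)
    y = np.zeros(n)
    for t in range(1, n):
        y[t] = 0.5 * y[t - 1] + 0.3 * u[t - 1] + 0.1
    return y, u


def test_presets_match_the_two_series():
    assert (NarxConfig.for_group(SeriesGroup.BY_CODE).ny,
            NarxConfig.for_group(SeriesGroup.BY_CODE).nu) == (3, 3)
    assert (NarxConfig.for_group(SeriesGroup.BY_ACTIVITY).ny,
            NarxConfig.for_group(SeriesGroup.BY_ACTIVITY).nu) == (2, 2)
    cfg = NarxConfig()
    assert cfg.hidden_units == 10
    assert cfg.split == (0.7, 0.15, 0.15)


def test_regression_matrix_unrolling():
    X, t = make_regression_matrix([1.0, 2, 3, 4], [5.0, 6, 7, 8], NarxConfig(ny=1, nu=1))
    assert X.shape == (3, 2)
    assert X[0].tolist() == [1.0, 5.0]
    assert t.tolist() == [2.0, 3.0, 4.0]


def test_regression_matrix_row_and_column_counts():
    X, t = make_regression_matrix(np.arange(4.0), np.arange(4.0), NarxConfig(ny=3, nu=3))
    assert X.shape == (1, 6)
    X, _ = make_regression_matrix(np.arange(10.0), np.arange(10.0), NarxConfig(ny=2, nu=3))
    assert X.shape[1] == 5
    with pytest.raises(ValueError):
        make_regression_matrix(np.arange(3.0), np.arange(3.0), NarxConfig(ny=3, nu=3))


def test_lag_ordering_in_features():
    y = np.array([10.0, 20, 30, 40, 50])
    u = np.array([1.0, 2, 3, 4, 5])
    X, t = make_regression_matrix(y, u, NarxConfig(ny=2, nu=2))
    # targets are y[2:]; the last row predicts y(4)=50 (0-based) from
    # features [y(3), y(2), u(3), u(2)] — most recent lag first
    assert t.tolist() == [30.0, 40.0, 50.0]
    assert X[2].tolist() == [40.0, 30.0, 4.0, 3.0]
    assert X[0].tolist() == [20.0, 10.0, 2.0, 1.0]


def test_fit_recovers_noiseless_linear_system():
    y, u = linear_arx(500, seed=0, u_low=-8, u_high=8)
    model = fit_narx(y, u, NarxConfig(ny=1, nu=1, seed=3))
    assert model.test_mse < 1e-4
    # closed-form oracle: 0.5*2 + 0.3*6 + 0.1 = 2.9
    assert predict_open_loop(model, [2.0], [6.0]) == pytest.approx(2.9, abs=0.05)


def test_fit_constant_target():
    rng = np.random.default_rng(1)
    y = np.full(60, 3.25)
    u = rng.standard_normal(60)
    model = fit_narx(y, u, NarxConfig(ny=1, nu=1, seed=0))
    assert model.test_mse == pytest.approx(0.0, abs=1e-6)
    assert predict_open_loop(model, [3.25], [0.0]) == pytest.approx(3.25, abs=1e-3)


def test_fit_pure_noise_hits_irreducible_floor():
    rng = np.random.default_rng(2)
    y = rng.standard_normal(500)
    u = rng.standard_normal(500)
    model = fit_narx(y, u, NarxConfig(ny=1, nu=1, seed=0))
    assert model.test_mse == pytest.approx(1.0, abs=0.2)


def test_open_loop_is_deterministic_and_validates_history():
    y, u = linear_arx(200, seed=3)
    model = fit_narx(y, u, NarxConfig(ny=2, nu=2, seed=1))
    a = predict_open_loop(model, [0.1, 0.2], [0.3, 0.4])
    b = predict_open_loop(model, [0.1, 0.2], [0.3, 0.4])
    assert a == b
    with pytest.raises(ValueError):
        predict_open_loop(model, [0.1], [0.3, 0.4])


def test_closed_loop_single_step_matches_open_loop():
    y, u = linear_arx(300, seed=4)
    model = fit_narx(y, u, NarxConfig(ny=1, nu=1, seed=2))
    one = predict_closed_loop(model, y[:10], u[9:10], steps=1)
    assert one[0] == pytest.approx(predict_open_loop(model, y[:10], u[9:10]))
    assert predict_closed_loop(model, y[:10], u[9:30], steps=0).size == 0


def test_closed_loop_tracks_stable_recursion():
    y, u = linear_arx(400, seed=5)
    model = fit_narx(y, u, NarxConfig(ny=1, nu=1, seed=2))
    steps = 20
    pred = predict_closed_loop(model, y[:10], u[9 : 9 + steps], steps=steps)
    exact = np.empty(steps)
    prev = y[9]
    for s in range(steps):
        exact[s] = 0.5 * prev + 0.3 * u[9 + s] + 0.1
        prev = exact[s]
    assert np.max(np.abs(pred - exact)) < 0.1


@pytest.mark.parametrize("random_split", [True, False])
def test_split_partitions_are_disjoint_and_cover(random_split):
    tr, val, te = _split_rows(100, (0.7, 0.15, 0.15), random_split, seed=0)
    all_idx = np.concatenate([tr, val, te])
    assert sorted(all_idx.tolist()) == list(range(100))
    assert (len(tr), len(val), len(te)) == (70, 15, 15)


def test_seeded_fit_is_bitwise_reproducible():
    y, u = linear_arx(200, seed=6)
    cfg = NarxConfig(ny=2, nu=2, seed=11)
    a = fit_narx(y, u, cfg)
    b = fit_narx(y, u, cfg)
    assert np.array_equal(a.theta, b.theta)
    assert (a.train_mse, a.validation_mse, a.test_mse) == (
        b.train_mse,
        b.validation_mse,
        b.test_mse,
    )


def test_sorted_series_model_is_much_more_accurate(fbm_records):
    """On the same records the activity-sorted NARX must beat the
    code-sorted NARX by an order of magnitude in test MSE."""
    by_code = build_series(fbm_records, SeriesGroup.BY_CODE)
    by_act = build_series(fbm_records, SeriesGroup.BY_ACTIVITY)
    mc = fit_narx(by_code.y, by_code.u, NarxConfig.for_group(SeriesGroup.BY_CODE, seed=1))
    ma = fit_narx(by_act.y, by_act.u, NarxConfig.for_group(SeriesGroup.BY_ACTIVITY, seed=1))
    assert mc.test_mse > 10 * ma.test_mse


def test_rejects_bad_inputs():
    with pytest.raises(ValueError):
        fit_narx(np.array([1.0, np.nan, 2.0] * 20), np.ones(60), NarxConfig(ny=1, nu=1))
    with pytest.raises(ValueError):
        NarxConfig(split=(0.5, 0.2, 0.2))
    with pytest.raises(ValueError):
        NarxConfig(ny=0)


def test_model_json_roundtrip():
    from pepnarx.narx import NarxModel

    y, u = linear_arx(150, seed=8)
    model = fit_narx(y, u, NarxConfig(ny=1, nu=1, seed=4))
    clone = NarxModel.from_dict(model.to_dict())
    probe_y, probe_u = [0.4], [0.2]
    assert predict_open_loop(clone, probe_y, probe_u) == pytest.approx(
        predict_open_loop(model, probe_y, probe_u)
    )
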