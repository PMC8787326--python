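"""Nonlinear autoregressive modeling with exogenous input (NARX).

The activity series is modeled as

    y(t) = f[ y(t-1), ..., y(t-ny), u(t-1), ..., u(t-nu) ]

where ``y`` is ln(EC50) along one of the two constructed orderings and
``u`` is ln(sequence code).  ``f`` is a one-hidden-layer network (sigmoid
hidden units, linear output) trained in open-loop (series-parallel) form by
Levenberg-Marquardt on mean squared error, with validation-based early
stopping.  Two presets mirror the two series: lags 1..3 for the code-sorted
series and 1..2 for the activity-sorted series, 10 hidden units each, and a
0.7:0.15:0.15 train/validation/test division.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special

from .series import SeriesGroup, SeriesPair

__all__ = [
    "NarxConfig",
    "NarxModel",
    "make_regression_matrix",
    "fit_narx",
    "predict_open_loop",
    "predict_closed_loop",
]


@dataclass(frozen=True)
class NarxConfig:
    """Delay, architecture and training configuration of a NARX fit."""

    ny: int = 3
    nu: int = 3
    hidden_units: int = 10
    split: tuple[float, float, float] = (0.7, 0.15, 0.15)
    max_epochs: int = 200
    seed: int = 0
    #: seeded random (interleaved) division by default, as in the network
    #: toolbox this architecture comes from; False divides contiguously in
    #: time, which on a sorted series makes the test partition an
    #: extrapolation region.
    random_split: bool = True
    activation: str = "tanh"

    def __post_init__(self) -> None:
        if self.ny < 1 or self.nu < 1:
            raise ValueError("ny and nu must be >= 1")
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if abs(sum(self.split) - 1.0) > 1e-9 or any(f < 0 for f in self.split):
            raise ValueError("split fractions must be nonnegative and sum to 1")

    @classmethod
    def for_group(cls, group: SeriesGroup, **overrides) -> "NarxConfig":
        """The two presets: BY_CODE uses lags 1..3, BY_ACTIVITY lags 1..2."""
        if group is SeriesGroup.BY_CODE:
            cfg = cls(ny=3, nu=3)
        else:
            cfg = cls(ny=2, nu=2)
        return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# small MLP + Levenberg-Marquardt trainer (shared with the BPNN baseline)
# ---------------------------------------------------------------------------


def _act(z: np.ndarray, kind: str) -> tuple[np.ndarray, np.ndarray]:
    """Activation value and derivative."""
    if kind == "tanh":
        a = np.tanh(z)
        return a, 1.0 - a**2
    if kind == "logsig":
        a = special.expit(z)
        return a, a * (1.0 - a)
    raise ValueError(f"unknown activation {kind!r}")


def _init_theta(d: int, h: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.uniform(-0.5, 0.5, size=h * d + h + h + 1)


def _unpack(theta: np.ndarray, d: int, h: int):
    w1 = theta[: h * d].reshape(h, d)
    b1 = theta[h * d : h * d + h]
    w2 = theta[h * d + h : h * d + 2 * h]
    b2 = theta[-1]
    return w1, b1, w2, b2


def _forward(theta: np.ndarray, X: np.ndarray, h: int, kind: str) -> np.ndarray:
    w1, b1, w2, b2 = _unpack(theta, X.shape[1], h)
    a, _ = _act(X @ w1.T + b1, kind)
    return a @ w2 + b2


def _jacobian(theta: np.ndarray, X: np.ndarray, h: int, kind: str):
    """Predictions and d(prediction)/d(theta), shape (n, n_params)."""
    n, d = X.shape
    w1, b1, w2, b2 = _unpack(theta, d, h)
    a, ap = _act(X @ w1.T + b1, kind)  # (n, h)
    yhat = a @ w2 + b2
    g = ap * w2  # (n, h): dyhat/d(preactivation_j)
    J = np.empty((n, len(theta)))
    J[:, : h * d] = (g[:, :, None] * X[:, None, :]).reshape(n, h * d)
    J[:, h * d : h * d + h] = g
    J[:, h * d + h : h * d + 2 * h] = a
    J[:, -1] = 1.0
    return yhat, J


def fit_mlp_lm(
    X: np.ndarray,
    y: np.ndarray,
    hidden: int,
    seed: int,
    activation: str = "tanh",
    max_epochs: int = 200,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    patience: int = 6,
    goal_mse: float = 0.0,
    mu0: float = 1e-3,
    mu_max: float = 1e10,
) -> tuple[np.ndarray, dict]:
    """Train a one-hidden-layer regressor by Levenberg-Marquardt.

    Damped Gauss-Newton on the residual Jacobian: solve
    (J'J + mu*I) step = -J'r, decreasing mu tenfold on an accepted step and
    increasing it tenfold on a rejected one.  Ill-conditioned normal
    equations fall back to a least-squares (pseudo-inverse) solve.  Training
    stops on the MSE goal, a vanishing gradient, mu overflow, ``max_epochs``
    or ``patience`` consecutive validation-error increases (best-validation
    weights are restored).
    """
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in training data")
    theta = _init_theta(X.shape[1], hidden, seed)
    mu = mu0
    use_val = X_val is not None and len(X_val) > 0
    yhat, J = _jacobian(theta, X, hidden, activation)
    r = yhat - y
    mse = float(np.mean(r**2))
    initial_mse = mse
    best_val = np.inf
    best_theta = theta.copy()
    val_increases = 0
    eye = np.eye(len(theta))
    n_epochs = 0
    stop = "max_epochs"
    for _ in range(max_epochs):
        n_epochs += 1
        if mse <= goal_mse:
            stop = "goal"
            break
        grad = J.T @ r
        if np.max(np.abs(grad)) < 1e-12:
            stop = "gradient"
            break
        JtJ = J.T @ J
        accepted = False
        while mu <= mu_max:
            A = JtJ + mu * eye
            try:
                step = np.linalg.solve(A, -grad)
                if not np.all(np.isfinite(step)):
                    raise np.linalg.LinAlgError
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(A, -grad, rcond=None)[0]
            cand = theta + step
            cand_hat = _forward(cand, X, hidden, activation)
            cand_mse = float(np.mean((cand_hat - y) ** 2))
            if cand_mse < mse:
                theta, mse = cand, cand_mse
                mu = max(mu / 10.0, 1e-12)
                accepted = True
                break
            mu *= 10.0
        if not accepted:
            stop = "mu_overflow"
            break
        yhat, J = _jacobian(theta, X, hidden, activation)
        r = yhat - y
        if use_val:
            val_hat = _forward(theta, X_val, hidden, activation)
            val_mse = float(np.mean((val_hat - y_val) ** 2))
            if val_mse < best_val:
                best_val = val_mse
                best_theta = theta.copy()
                val_increases = 0
            else:
                val_increases += 1
                if val_increases >= patience:
                    stop = "early_stopping"
                    break
    if use_val and np.isfinite(best_val):
        theta = best_theta
    final_mse = float(np.mean((_forward(theta, X, hidden, activation) - y) ** 2))
    info = {
        "epochs": n_epochs,
        "stop": stop,
        "train_mse": final_mse,
        "converged": final_mse < initial_mse,
    }
    return theta, info


# ---------------------------------------------------------------------------
# NARX surface
# ---------------------------------------------------------------------------


def make_regression_matrix(
    y: np.ndarray, u: np.ndarray, config: NarxConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Tapped-delay embedding: row t = [y(t-1)..y(t-ny), u(t-1)..u(t-nu)].

    Targets run from t = max(ny, nu) + 1 to n, so the row count is
    n - max(ny, nu).
    """
    yv = np.asarray(y, dtype=float)
    uv = np.asarray(u, dtype=float)
    if len(yv) != len(uv):
        raise ValueError("y and u must have equal length")
    m = max(config.ny, config.nu)
    n = len(yv)
    if n <= m:
        raise ValueError(f"series of length {n} too short for max delay {m}")
    rows = n - m
    X = np.empty((rows, config.ny + config.nu))
    for i, t in enumerate(range(m, n)):
        X[i, : config.ny] = yv[t - np.arange(1, config.ny + 1)]
        X[i, config.ny :] = uv[t - np.arange(1, config.nu + 1)]
    return X, yv[m:]


def _split_rows(n_rows: int, split: tuple[float, float, float], random_split: bool, seed: int):
    n_tr = int(round(split[0] * n_rows))
    n_val = int(round(split[1] * n_rows))
    n_tr = max(1, min(n_tr, n_rows - 2))
    n_val = max(1, min(n_val, n_rows - n_tr - 1))
    n_te = n_rows - n_tr - n_val
    if n_te < 1:
        raise ValueError(f"{n_rows} rows cannot be split into three nonempty partitions")
    idx = np.arange(n_rows)
    if random_split:
        idx = np.random.default_rng(seed).permutation(n_rows)
    return idx[:n_tr], idx[n_tr : n_tr + n_val], idx[n_tr + n_val :]


@dataclass(frozen=True)
class NarxModel:
    """A fitted NARX regressor with its scalers and split errors.

    Errors are MSE on the raw ln scale; inputs and target are standardized
    internally on the training partition only.
    """

    config: NarxConfig
    theta: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    train_mse: float
    validation_mse: float
    test_mse: float
    fit_info: dict = field(default_factory=dict)

    def predict_features(self, X: np.ndarray) -> np.ndarray:
        """Predict targets (raw ln scale) from raw tapped-delay features."""
        Xs = (np.atleast_2d(X) - self.x_mean) / self.x_std
        ys = _forward(self.theta, Xs, self.config.hidden_units, self.config.activation)
        return ys * self.y_std + self.y_mean

    def to_dict(self) -> dict:
        return {
            "config": {
                "ny": self.config.ny,
                "nu": self.config.nu,
                "hidden_units": self.config.hidden_units,
                "split": list(self.config.split),
                "max_epochs": self.config.max_epochs,
                "seed": self.config.seed,
                "random_split": self.config.random_split,
                "activation": self.config.activation,
            },
            "theta": self.theta.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "errors": {
                "train_mse": self.train_mse,
                "validation_mse": self.validation_mse,
                "test_mse": self.test_mse,
            },
            "fit_info": self.fit_info,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NarxModel":
        cfg = NarxConfig(
            ny=d["config"]["ny"],
            nu=d["config"]["nu"],
            hidden_units=d["config"]["hidden_units"],
            split=tuple(d["config"]["split"]),
            max_epochs=d["config"]["max_epochs"],
            seed=d["config"]["seed"],
            random_split=d["config"]["random_split"],
            activation=d["config"]["activation"],
        )
        return cls(
            config=cfg,
            theta=np.asarray(d["theta"]),
            x_mean=np.asarray(d["x_mean"]),
            x_std=np.asarray(d["x_std"]),
            y_mean=d["y_mean"],
            y_std=d["y_std"],
            train_mse=d["errors"]["train_mse"],
            validation_mse=d["errors"]["validation_mse"],
            test_mse=d["errors"]["test_mse"],
            fit_info=d.get("fit_info", {}),
        )


def fit_narx(y: np.ndarray, u: np.ndarray, config: NarxConfig) -> NarxModel:
    """Fit the NARX network on a (y, u) series pair.

    The tapped-delay rows are divided into train/validation/test by a
    seeded shuffle (default) or contiguously in time when
    ``config.random_split`` is False; features and target are standardized
    on the training partition.
    """
    X, t = make_regression_matrix(y, u, config)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(t)):
        raise ValueError("non-finite values in series")
    tr, val, te = _split_rows(len(t), config.split, config.random_split, config.seed)
    x_mean = X[tr].mean(axis=0)
    x_std = X[tr].std(axis=0)
    x_std = np.where(x_std > 0, x_std, 1.0)
    y_mean = float(t[tr].mean())
    y_std = float(t[tr].std())
    if y_std == 0.0:
        y_std = 1.0
    Xs = (X - x_mean) / x_std
    ts = (t - y_mean) / y_std
    theta, info = fit_mlp_lm(
        Xs[tr],
        ts[tr],
        hidden=config.hidden_units,
        seed=config.seed,
        activation=config.activation,
        max_epochs=config.max_epochs,
        X_val=Xs[val],
        y_val=ts[val],
    )

    def raw_mse(idx: np.ndarray) -> float:
        pred = _forward(theta, Xs[idx], config.hidden_units, config.activation) * y_std + y_mean
        return float(np.mean((pred - t[idx]) ** 2))

    return NarxModel(
        config=config,
        theta=theta,
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        y_std=y_std,
        train_mse=raw_mse(tr),
        validation_mse=raw_mse(val),
        test_mse=raw_mse(te),
        fit_info=info,
    )


def fit_series(pair: SeriesPair, **overrides) -> NarxModel:
    """Fit the preset NARX for a constructed series pair."""
    config = NarxConfig.for_group(pair.group, **overrides)
    return fit_narx(pair.y, pair.u, config)


def _lag_features(model: NarxModel, y_hist: np.ndarray, u_hist: np.ndarray) -> np.ndarray:
    ny, nu = model.config.ny, model.config.nu
    yh = np.asarray(y_hist, dtype=float)
    uh = np.asarray(u_hist, dtype=float)
    if len(yh) < ny or len(uh) < nu:
        raise ValueError(f"histories too short: need >= {ny} y values and {nu} u values")
    return np.concatenate([yh[-1 : -1 - ny : -1] if ny > 0 else [], uh[-1 : -1 - nu : -1]])


def predict_open_loop(model: NarxModel, y_hist: np.ndarray, u_hist: np.ndarray) -> float:
    """One-step-ahead (series-parallel) prediction from measured lags.

    ``y_hist``/``u_hist`` are in time order; the last element is the most
    recent observation, i.e. lag 1.
    """
    feats = _lag_features(model, y_hist, u_hist)
    return float(model.predict_features(feats)[0])


def predict_closed_loop(
    model: NarxModel, y_seed: np.ndarray, u_future: np.ndarray, steps: int
) -> np.ndarray:
    """Multi-step prediction feeding outputs back as lagged targets.

    ``u_future`` must hold the exogenous values covering the forecast:
    entries u(T-nu+1) .. u(T+steps-1) in time order, where T is the time of
    the last seeded target.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    ny, nu = model.config.ny, model.config.nu
    y_work = list(np.asarray(y_seed, dtype=float))
    if len(y_work) < ny:
        raise ValueError(f"seed history of length {len(y_work)} shorter than ny={ny}")
    uf = np.asarray(u_future, dtype=float)
    if len(uf) < nu + steps - 1 and steps > 0:
        raise ValueError("u_future too short for the requested horizon")
    out = np.empty(steps)
    for s in range(steps):
        u_hist = uf[s : s + nu]
        out[s] = predict_open_loop(model, np.array(y_work), u_hist)
        y_work.append(out[s])
    return out
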