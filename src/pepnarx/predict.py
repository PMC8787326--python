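"""Two-stage EC50 prediction and the backpropagation baseline.

An unseen sequence is predicted in two stages.  First the classifier gives
its activity segment (the "rough location" on the sorted series), and the
code-sorted NARX — evaluated at the query's insertion point in the
code-sorted series — gives a coarse ln(EC50) estimate.  Second, the two
reference peptides whose activities bracket the coarse estimate inside the
predicted segment anchor a one-step forecast of the activity-sorted NARX,
which emits the refined estimate.  A plain 3-10-1 feedforward network
(digit-mean, ln code and length as inputs) serves as the regression
baseline the two-stage method is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .classify import SegmentScheme, featurize_records
from .codec import PeptideRecord, encode_sequence
from .narx import NarxConfig, NarxModel, fit_narx, fit_mlp_lm, predict_open_loop, _forward
from .series import SeriesGroup, SeriesPair, build_series

__all__ = [
    "PredictionResult",
    "BpnnConfig",
    "predict_ec50",
    "evaluate_method",
    "fit_bpnn_baseline",
]


@dataclass(frozen=True)
class PredictionResult:
    query_sequence: str
    predicted_class: int
    coarse_estimate: float
    refined_estimate: float
    #: (id, ln EC50, ln code) of the two anchor records (empty on fallback).
    neighbors_used: tuple[tuple[str, float, float], ...]
    predicted_ec50: float
    warnings: tuple[str, ...] = field(default_factory=tuple)


def _coarse_estimate(model: NarxModel, by_code: SeriesPair, q_log_code: float) -> float:
    """Evaluate the code-sorted NARX at the query's insertion point."""
    m = max(model.config.ny, model.config.nu)
    p = int(np.searchsorted(by_code.u, q_log_code))
    p = min(max(p, m), by_code.n)
    y_hist = by_code.y[p - model.config.ny : p]
    u_hist = by_code.u[p - model.config.nu : p]
    return predict_open_loop(model, y_hist, u_hist)


def predict_ec50(
    query: str,
    reference: list[PeptideRecord],
    models: tuple[NarxModel, NarxModel],
    classify_fn: Callable[[str], int],
    scheme: SegmentScheme,
) -> PredictionResult:
    """Predict ln(EC50) (and EC50) of an unseen sequence.

    ``models`` is the pair (code-sorted NARX, activity-sorted NARX) trained
    on ``reference``; ``classify_fn`` maps a sequence to a segment label
    under ``scheme``.  A segment holding fewer than two reference records
    degrades to the coarse estimate with a recorded warning.
    """
    model_code, model_act = models
    enc = encode_sequence(query)
    label = int(classify_fn(query))
    if not (0 <= label < scheme.k):
        raise ValueError(f"classifier produced label {label} outside 0..{scheme.k - 1}")
    by_code = build_series(reference, SeriesGroup.BY_CODE)
    by_act = build_series(reference, SeriesGroup.BY_ACTIVITY)
    warnings: list[str] = []

    coarse = _coarse_estimate(model_code, by_code, enc.log_code)

    member_idx = np.flatnonzero(scheme.assign(by_act.y) == label)
    coarse_label = int(scheme.assign(coarse))
    if coarse_label != label:
        warnings.append(
            f"coarse estimate {coarse:.3f} falls in segment {coarse_label}, "
            f"classifier chose {label}; trusting the classifier"
        )
    if len(member_idx) < 2:
        warnings.append(
            f"segment {label} holds {len(member_idx)} reference record(s); "
            "falling back to the coarse estimate"
        )
        return PredictionResult(
            query_sequence=enc.sequence,
            predicted_class=label,
            coarse_estimate=coarse,
            refined_estimate=coarse,
            neighbors_used=(),
            predicted_ec50=float(np.exp(coarse)),
            warnings=tuple(warnings),
        )

    seg_y = by_act.y[member_idx]  # ascending (series is sorted on y)
    below = member_idx[seg_y <= coarse]
    above = member_idx[seg_y > coarse]
    if len(below) and len(above):
        anchors = (int(below[-1]), int(above[0]))
    elif len(above):
        anchors = (int(above[0]), int(above[1]))
    else:
        anchors = (int(below[-2]), int(below[-1]))
    lo, hi = sorted(anchors, key=lambda i: by_act.y[i])

    ny, nu = model_act.config.ny, model_act.config.nu
    # anchor activities as the most recent lags of the sorted series,
    # padded with earlier segment members if the model uses deeper lags
    hist = [by_act.y[lo], by_act.y[hi]]
    pad = list(by_act.y[member_idx[member_idx < lo]][::-1][: max(0, ny - 2)])
    y_hist = np.array((pad[::-1] + hist)[-ny:] if ny >= 2 else hist[-ny:])
    if len(y_hist) < ny:
        y_hist = np.concatenate([np.full(ny - len(y_hist), by_act.y[lo]), y_hist])
    u_hist = np.full(nu, enc.log_code)
    refined = predict_open_loop(model_act, y_hist, u_hist)

    # keep the refinement inside the anchor segment (± one typical step)
    step = float(np.mean(np.abs(np.diff(seg_y)))) if len(seg_y) > 1 else 0.0
    refined = float(np.clip(refined, seg_y[0] - step, seg_y[-1] + step))

    neighbors = tuple(
        (by_act.ids[i], float(by_act.y[i]), float(by_act.u[i])) for i in (lo, hi)
    )
    return PredictionResult(
        query_sequence=enc.sequence,
        predicted_class=label,
        coarse_estimate=coarse,
        refined_estimate=refined,
        neighbors_used=neighbors,
        predicted_ec50=float(np.exp(refined)),
        warnings=tuple(warnings),
    )


def _make_classifier(
    mode: str,
    train_records: list[PeptideRecord],
    test_records: list[PeptideRecord],
    scheme: SegmentScheme,
    seed: int,
) -> Callable[[str], int]:
    if mode == "oracle":
        truth = {r.sequence: int(scheme.assign(r.ln_ec50)) for r in test_records}
        truth.update({r.sequence: int(scheme.assign(r.ln_ec50)) for r in train_records})
        return lambda seq: truth[seq.upper()]
    if mode == "svm":
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        X = featurize_records(train_records)
        y = scheme.assign(np.array([r.ln_ec50 for r in train_records])).astype(int)
        clf = Pipeline(
            [("scale", StandardScaler()), ("svm", SVC(kernel="rbf", random_state=seed))]
        )
        clf.fit(X, y)
        from .classify import featurize

        return lambda seq: int(clf.predict(featurize(seq)[None, :])[0])
    if mode == "random":
        rng = np.random.default_rng(seed)
        return lambda seq: int(rng.integers(0, scheme.k))
    raise ValueError(f"unknown classification mode {mode!r}")


def evaluate_method(
    records: list[PeptideRecord],
    n_train: int,
    classification: str = "oracle",
    seeds: list[int] | None = None,
    k: int = 3,
) -> dict:
    """Benchmark the two-stage predictor on a train/test split in code order.

    The first ``n_train`` records of the code-sorted ordering train both
    NARX models (and the scheme/classifier); the remainder are queried one
    by one.  ``classification`` is 'oracle' (assume the segment is correct,
    the reference verification protocol), 'svm' or 'random'.  Reports ln-
    scale MSE per seed and the median across seeds.
    """
    if seeds is None:
        seeds = [0]
    order = build_series(records, SeriesGroup.BY_CODE).order
    ordered = [records[i] for i in order]
    if not (0 < n_train < len(ordered)):
        raise ValueError("n_train must leave at least one test record")
    train_recs = ordered[:n_train]
    test_recs = ordered[n_train:]
    scheme = SegmentScheme.from_records(train_recs, k=k)
    by_code = build_series(train_recs, SeriesGroup.BY_CODE)
    by_act = build_series(train_recs, SeriesGroup.BY_ACTIVITY)

    per_seed: list[float] = []
    for seed in seeds:
        model_code = fit_narx(
            by_code.y, by_code.u, NarxConfig.for_group(SeriesGroup.BY_CODE, seed=seed)
        )
        model_act = fit_narx(
            by_act.y, by_act.u, NarxConfig.for_group(SeriesGroup.BY_ACTIVITY, seed=seed)
        )
        classify_fn = _make_classifier(classification, train_recs, test_recs, scheme, seed)
        sq_errors = []
        for rec in test_recs:
            res = predict_ec50(
                rec.sequence, train_recs, (model_code, model_act), classify_fn, scheme
            )
            sq_errors.append((res.refined_estimate - rec.ln_ec50) ** 2)
        per_seed.append(float(np.mean(sq_errors)))
    return {
        "classification": classification,
        "k": k,
        "n_train": n_train,
        "n_test": len(test_recs),
        "seeds": list(seeds),
        "mse_per_seed": per_seed,
        "median_mse": float(np.median(per_seed)),
        "scale": "ln",
    }


@dataclass(frozen=True)
class BpnnConfig:
    """The fixed 3-10-1 baseline network configuration.

    Log-sigmoid hidden layer, linear output, Levenberg-Marquardt training.
    ``learning_rate`` is recorded for completeness but plays no role in the
    LM update (as in the reference environment's trainer).
    """

    hidden_units: int = 10
    max_iterations: int = 1000
    learning_rate: float = 0.1
    goal_mse: float = 1e-5
    seed: int = 0


def _bpnn_features(records: list[PeptideRecord]) -> np.ndarray:
    out = np.empty((len(records), 3))
    for i, r in enumerate(records):
        enc = encode_sequence(r.sequence)
        out[i] = (float(np.mean(enc.digits)), enc.log_code, float(len(enc.digits)))
    return out


def fit_bpnn_baseline(
    records: list[PeptideRecord],
    config: BpnnConfig = BpnnConfig(),
    n_resamples: int = 100,
    n_test: int | None = None,
) -> dict:
    """Test-MSE distribution of the 3-10-1 baseline over random splits.

    Inputs are digit-mean, ln code and length (sequence-only, matched to
    the 3-input architecture); the target is ln(EC50).  Each resample draws
    a fresh seeded test set, trains by LM toward ``goal_mse`` and records
    raw ln-scale test MSE; non-convergent resamples are recorded, not fatal.
    """
    if len(records) < 10:
        raise ValueError("need at least 10 records")
    if n_test is None:
        n_test = max(1, round(len(records) * 31 / 231))
    if not (0 < n_test < len(records)):
        raise ValueError("n_test must leave a nonempty training set")
    X = _bpnn_features(records)
    y = np.array([r.ln_ec50 for r in records])
    mses: list[float] = []
    non_convergent = 0
    for r in range(n_resamples):
        rng = np.random.default_rng([config.seed, r])
        idx = rng.permutation(len(records))
        te, tr = idx[:n_test], idx[n_test:]
        mu = X[tr].mean(axis=0)
        sd = np.where(X[tr].std(axis=0) > 0, X[tr].std(axis=0), 1.0)
        ymu, ysd = y[tr].mean(), max(y[tr].std(), 1e-12)
        theta, info = fit_mlp_lm(
            (X[tr] - mu) / sd,
            (y[tr] - ymu) / ysd,
            hidden=config.hidden_units,
            seed=int(rng.integers(0, 2**31 - 1)),
            activation="logsig",
            max_epochs=config.max_iterations,
            goal_mse=config.goal_mse,
        )
        if not info["converged"]:
            non_convergent += 1
        pred = _forward(theta, (X[te] - mu) / sd, config.hidden_units, "logsig") * ysd + ymu
        mses.append(float(np.mean((pred - y[te]) ** 2)))
    return {
        "n_resamples": n_resamples,
        "n_test": n_test,
        "mse_per_resample": mses,
        "median_mse": float(np.median(mses)),
        "mean_mse": float(np.mean(mses)),
        "non_convergent": non_convergent,
        "scale": "ln",
    }
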