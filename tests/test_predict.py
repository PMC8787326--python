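"""Two-stage EC50 prediction and the BPNN regression baseline."""

import numpy as np
import pytest

from pepnarx.classify import SegmentScheme
from pepnarx.codec import PeptideRecord
from pepnarx.narx import NarxConfig, fit_narx
from pepnarx.predict import (
    BpnnConfig,
    _make_classifier,
    evaluate_method,
    fit_bpnn_baseline,
    predict_ec50,
)
from pepnarx.series import SeriesGroup, build_series
from pepnarx.simulate import SyntheticSpec, generate


def _trained_setup(records, seed=1, k=3):
    by_code = build_series(records, SeriesGroup.BY_CODE)
    by_act = build_series(records, SeriesGroup.BY_ACTIVITY)
    mc = fit_narx(by_code.y, by_code.u, NarxConfig.for_group(SeriesGroup.BY_CODE, seed=seed))
    ma = fit_narx(by_act.y, by_act.u, NarxConfig.for_group(SeriesGroup.BY_ACTIVITY, seed=seed))
    scheme = SegmentScheme.from_records(records, k=k)
    oracle = _make_classifier("oracle", records, [], scheme, seed)
    return (mc, ma), scheme, oracle


def test_self_query_consistency():
    """Querying a sequence that is itself in the reference set must land
    near that record's measured activity."""
    records = generate(SyntheticSpec(seed=3, link="monotone_code", noise_sd=0.1))
    models, scheme, oracle = _trained_setup(records)
    for rec in records[::40]:
        res = predict_ec50(rec.sequence, records, models, oracle, scheme)
        assert abs(res.refined_estimate - rec.ln_ec50) < 0.5
        assert res.predicted_ec50 == pytest.approx(np.exp(res.refined_estimate))


def test_interior_noiseless_queries_are_recovered():
    """With a noiseless monotone sequence-activity mapping and correct
    classification, interpolative queries are recovered almost exactly."""
    records = generate(SyntheticSpec(seed=3, link="monotone_code", noise_sd=0.0))
    order = build_series(records, SeriesGroup.BY_CODE).order
    ordered = [records[i] for i in order]
    held_out = ordered[10:221:7]
    held_ids = {r.id for r in held_out}
    reference = [r for r in ordered if r.id not in held_ids]
    models, scheme, _ = _trained_setup(reference)
    truth = {r.sequence: int(scheme.assign(r.ln_ec50)) for r in ordered}
    sq = [
        (predict_ec50(r.sequence, reference, models, lambda s: truth[s], scheme).refined_estimate
         - r.ln_ec50) ** 2
        for r in held_out
    ]
    assert np.mean(sq) < 0.05


def test_two_member_segment_forces_those_anchors():
    # ln EC50 values: one below 0, two in (0, median), three above -- the
    # middle segment [0, median of ln EC50) then holds exactly c and d
    records = [
        PeptideRecord(id="a", sequence="AA", ec50=float(np.exp(-1.0))),
        PeptideRecord(id="c", sequence="DC", ec50=float(np.exp(0.2))),
        PeptideRecord(id="d", sequence="ED", ec50=float(np.exp(0.4))),
        PeptideRecord(id="e", sequence="FE", ec50=20.0),
        PeptideRecord(id="f", sequence="GF", ec50=30.0),
        PeptideRecord(id="g", sequence="HG", ec50=45.0),
    ]
    models, scheme, _ = _trained_setup(records, k=3)
    assert [int(scheme.assign(r.ln_ec50)) for r in records] == [0, 1, 1, 2, 2, 2]
    res = predict_ec50("DD", records, models, lambda s: 1, scheme)
    assert {n[0] for n in res.neighbors_used} == {"c", "d"}


def test_sparse_segment_falls_back_to_coarse():
    records = [
        PeptideRecord(id=f"p{i}", sequence=s, ec50=e)
        for i, (s, e) in enumerate(
            [("AA", 0.1), ("CA", 0.2), ("DA", 0.3), ("EA", 5.0), ("FA", 6.0), ("GA", 7.0)]
        )
    ]
    scheme = SegmentScheme(k=3, boundaries=(0.0, 100.0), labels=(0, 1, 2))
    by_code = build_series(records, SeriesGroup.BY_CODE)
    by_act = build_series(records, SeriesGroup.BY_ACTIVITY)
    mc = fit_narx(by_code.y, by_code.u, NarxConfig.for_group(SeriesGroup.BY_CODE, seed=0))
    ma = fit_narx(by_act.y, by_act.u, NarxConfig.for_group(SeriesGroup.BY_ACTIVITY, seed=0))
    res = predict_ec50("HA", records, (mc, ma), lambda s: 2, scheme)  # empty segment
    assert res.refined_estimate == res.coarse_estimate
    assert res.neighbors_used == ()
    assert any("falling back" in w for w in res.warnings)


def test_anchors_belong_to_predicted_segment(fbm_records):
    reference = fbm_records[:200]
    models, scheme, _ = _trained_setup(reference)
    # oracle over all records, including the held-out queries
    truth = {r.sequence: int(scheme.assign(r.ln_ec50)) for r in fbm_records}
    oracle = lambda seq: truth[seq]
    for rec in fbm_records[200:210]:
        res = predict_ec50(rec.sequence, reference, models, oracle, scheme)
        if not res.neighbors_used:
            continue
        for _, ln_ec50, _ in res.neighbors_used:
            assert scheme.assign(ln_ec50) == res.predicted_class


def test_classifier_label_out_of_range_rejected(fbm_records):
    models, scheme, _ = _trained_setup(fbm_records[:100])
    with pytest.raises(ValueError):
        predict_ec50("AC", fbm_records[:100], models, lambda s: 7, scheme)


def test_evaluate_oracle_beats_random_classification(monotone_records):
    seeds = [1, 2, 3, 4, 5]
    oracle = evaluate_method(monotone_records, 200, "oracle", seeds=seeds)
    rand = evaluate_method(monotone_records, 200, "random", seeds=seeds)
    assert oracle["median_mse"] < rand["median_mse"]


def test_evaluate_degradation_monotonicity(monotone_records):
    """Better segment information can only help: oracle <= SVM <= random
    (medians over seeds, classifiable regime)."""
    seeds = [1, 2, 3, 4, 5]
    oracle = evaluate_method(monotone_records, 200, "oracle", seeds=seeds)["median_mse"]
    svm = evaluate_method(monotone_records, 200, "svm", seeds=seeds)["median_mse"]
    rand = evaluate_method(monotone_records, 200, "random", seeds=seeds)["median_mse"]
    assert oracle <= svm <= rand


def test_evaluate_single_test_point_runs(fbm_records):
    report = evaluate_method(fbm_records, len(fbm_records) - 1, "oracle", seeds=[1])
    assert report["n_test"] == 1
    assert np.isfinite(report["median_mse"])
    with pytest.raises(ValueError):
        evaluate_method(fbm_records, len(fbm_records), "oracle")


def test_bpnn_constant_target_is_learned_exactly():
    records = [
        PeptideRecord(id=f"p{i}", sequence=s, ec50=2.5)
        for i, s in enumerate(["AA", "AC", "AD", "AE", "CA", "CC", "CD", "CE", "DA", "DC", "DD", "DE"])
    ]
    report = fit_bpnn_baseline(records, BpnnConfig(seed=0), n_resamples=100, n_test=3)
    assert len(report["mse_per_resample"]) == 100
    assert report["median_mse"] == pytest.approx(0.0, abs=1e-4)


def test_bpnn_pure_noise_cannot_beat_the_variance_floor():
    """When the target carries no sequence signal, no resample can do
    substantially better than predicting the mean (MSE = target variance);
    a flexible net typically does worse through overfitting."""
    records = generate(SyntheticSpec(n=200, seed=5, link="independent", noise_sd=0.0))
    target_var = np.var([r.ln_ec50 for r in records])
    report = fit_bpnn_baseline(records, BpnnConfig(seed=1), n_resamples=10)
    assert np.all(np.isfinite(report["mse_per_resample"]))
    assert report["median_mse"] >= 0.9 * target_var


def test_bpnn_validation():
    records = generate(SyntheticSpec(n=20, seed=1))
    with pytest.raises(ValueError):
        fit_bpnn_baseline(records[:5])
    with pytest.raises(ValueError):
        fit_bpnn_baseline(records, n_test=20)
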