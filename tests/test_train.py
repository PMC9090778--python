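"""Loss, initialization, fold splitting, early stopping."""

import numpy as np
import pytest

import spindleseg as sg
from spindleseg import nn
from spindleseg.model import ModelConfig, build_model
from spindleseg.preprocess import EEGSegment
from spindleseg.events import EventList
from spindleseg.train import (
    TrainConfig,
    generalized_dice_grad,
    generalized_dice_loss,
    init_params,
    kfold_by_subject,
    steps_per_epoch,
    train_fold,
)


def one_hot(indicator: np.ndarray) -> np.ndarray:
    y = np.zeros((1, 2, len(indicator)))
    y[0, 1] = indicator
    y[0, 0] = 1 - indicator
    return y


def gdl_by_direct_substitution(probs, targets):
    """Independent oracle: literal evaluation of the weighted dice formula."""
    num = den = 0.0
    for c in range(2):
        r = targets[:, c, :].ravel()
        p = probs[:, c, :].ravel()
        w = 1.0 / max(r.sum() ** 2, 1e-8)
        num += w * (r * p).sum()
        den += w * (r + p).sum()
    return 1.0 - 2.0 * num / den


def test_loss_zero_at_perfect_prediction():
    y = one_hot(np.array([1, 1, 0, 0, 1, 0]))
    assert generalized_dice_loss(y, y) == pytest.approx(0.0, abs=1e-12)


def test_loss_hand_computed_uniform_prediction():
    # 4-sample batch, targets [1,1,0,0], uniform 0.5/0.5 prediction.
    y = one_hot(np.array([1, 1, 0, 0]))
    p = np.full_like(y, 0.5)
    # By direct substitution: w both 1/4, num = 2*(1/4), den = 2*(1/4)*4 = 2
    assert generalized_dice_loss(p, y) == pytest.approx(0.5)
    assert generalized_dice_loss(p, y) == pytest.approx(gdl_by_direct_substitution(p, y))


def test_loss_symmetric_under_class_swap():
    rng = np.random.default_rng(0)
    y = one_hot((rng.random(30) < 0.3).astype(float))
    ps = rng.random((1, 1, 30))
    p = np.concatenate([1 - ps, ps], axis=1)
    swapped_y = y[:, ::-1, :]
    swapped_p = p[:, ::-1, :]
    assert generalized_dice_loss(p, y) == pytest.approx(
        generalized_dice_loss(swapped_p, swapped_y)
    )


def test_loss_bounded_and_matches_oracle_on_random_batches():
    rng = np.random.default_rng(1)
    for _ in range(20):
        y = np.zeros((3, 2, 40))
        ind = rng.random((3, 40)) < rng.uniform(0.05, 0.5)
        y[:, 1] = ind
        y[:, 0] = 1 - ind
        ps = rng.random((3, 1, 40))
        p = np.concatenate([1 - ps, ps], axis=1)
        loss = generalized_dice_loss(p, y)
        assert 0.0 <= loss <= 1.0
        assert loss == pytest.approx(gdl_by_direct_substitution(p, y))


def test_loss_gradient_matches_finite_differences():
    rng = np.random.default_rng(2)
    y = one_hot((rng.random(12) < 0.4).astype(float))
    ps = rng.uniform(0.1, 0.9, (1, 1, 12))
    p = np.concatenate([1 - ps, ps], axis=1)
    g = generalized_dice_grad(p, y)
    eps = 1e-7
    for c in range(2):
        for t in range(12):
            pp = p.copy()
            pp[0, c, t] += eps
            pm = p.copy()
            pm[0, c, t] -= eps
            fd = (generalized_dice_loss(pp, y) - generalized_dice_loss(pm, y)) / (2 * eps)
            assert g[0, c, t] == pytest.approx(fd, rel=1e-5, abs=1e-9)


def test_init_params_deterministic_and_bounded():
    cfg = ModelConfig(filters_per_level=[4, 8, 16])
    n1 = init_params(build_model(cfg), seed=7)
    n2 = init_params(build_model(cfg), seed=7)
    n3 = init_params(build_model(cfg), seed=8)
    s1, s2, s3 = (nn.state_dict(n) for n in (n1, n2, n3))
    for k in s1:
        np.testing.assert_array_equal(s1[k], s2[k])
    assert any(not np.array_equal(s1[k], s3[k]) for k in s1)
    for layer in nn.iter_layers(n1):
        if isinstance(layer, nn.Conv1d):
            bound = np.sqrt(6.0 / layer.fan_in)
            w = layer.params["W"]
            assert np.all(np.abs(w) <= bound)
            assert np.max(np.abs(w)) > 0.5 * bound  # actually fills the range


def make_records(n_ten: int, n_three: int):
    recs = [
        {"subject_id": f"t{i:03d}", "cohort": "younger", "n_segments": 10}
        for i in range(n_ten)
    ]
    recs += [
        {"subject_id": f"r{i:03d}", "cohort": "older", "n_segments": 3}
        for i in range(n_three)
    ]
    return recs


def test_kfold_balances_ten_segment_subjects():
    """144 subjects (30 ten-segment, 114 three-segment): folds of 24
    subjects, 5 ten-segment subjects and 107 segments each."""
    recs = make_records(30, 114)
    split = kfold_by_subject(recs, k=6, seed=1)
    seg_count = {r["subject_id"]: r["n_segments"] for r in recs}
    for fold in range(6):
        subjects = split.fold_subjects(fold)
        assert len(subjects) == 24
        assert sum(s.startswith("t") for s in subjects) == 5
        assert sum(seg_count[s] for s in subjects) == 107


def test_kfold_singletons_and_errors():
    recs = make_records(0, 6)
    split = kfold_by_subject(recs, k=6, seed=0)
    assert sorted(len(split.fold_subjects(f)) for f in range(6)) == [1] * 6
    with pytest.raises(ValueError, match="folds"):
        kfold_by_subject(make_records(0, 3), k=6)


def test_kfold_keeps_subjects_whole():
    recs = make_records(4, 20)
    split = kfold_by_subject(recs, k=4, seed=3)
    # one fold per subject id: definitional, but guards against accidental
    # per-segment splitting in refactors
    assert set(split.assignments) == {r["subject_id"] for r in recs}
    assert all(isinstance(f, int) for f in split.assignments.values())


def test_steps_per_epoch_matches_training_set_size():
    # 535 training segments at minibatch 12 -> 45 steps.
    assert steps_per_epoch(535, 12) == 45
    assert steps_per_epoch(12, 12) == 1
    assert steps_per_epoch(13, 12) == 2


def _tiny_samples(n, seed=0, length=200):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        x = rng.standard_normal(length)
        seg = EEGSegment(sg.zscore(x), 100.0, subject_id=f"s{i}")
        out.append((seg, EventList([(0.2, 0.3)])))
    return out


def test_early_stopping_contract(monkeypatch):
    """With patience 1 and a never-improving metric, training stops after
    the second epoch."""
    calls = []

    def flat_metric(network, samples, model_config, batch_size, metric="f1_bar"):
        calls.append(1)
        return 0.0

    monkeypatch.setattr("spindleseg.train.validation_metric", flat_metric)
    cfg = ModelConfig(levels=2, filters_per_level=[2, 4], conv_kernel=3, pool_widths=[2])
    tc = TrainConfig(batch_size=4, patience=1, max_epochs=50)
    _, history = train_fold(_tiny_samples(4), _tiny_samples(2, seed=1), cfg, tc, seed=0)
    assert len(history) == 2
    assert len(calls) == 2


def test_train_fold_rejects_empty_sets():
    cfg = ModelConfig(levels=2, filters_per_level=[2, 4], conv_kernel=3, pool_widths=[2])
    with pytest.raises(ValueError, match="non-empty"):
        train_fold([], _tiny_samples(2), cfg, TrainConfig())


def test_best_metric_non_decreasing_and_best_kept(recovery_run):
    history = recovery_run["history"]
    running_best = history["val_metric"].cummax()
    assert (running_best.diff().dropna() >= 0).all()
    # returned parameters correspond to the best epoch, so re-scoring the
    # returned network cannot fall below any earlier epoch's value
    from spindleseg.train import validation_metric

    final = validation_metric(
        recovery_run["network"],
        recovery_run["val_samples"],
        recovery_run["model_config"],
        batch_size=12,
    )
    assert final == pytest.approx(history["val_metric"].max(), abs=1e-9)


@pytest.fixture(scope="module")
def cv_result():
    """Scaled-down six-fold cross-validation on high-SNR synthetic data:
    12 subjects with 30 s segments and a narrow model, enough for the
    stability properties without a full-scale run."""
    cfg = sg.SynthConfig(snr=10.0, segment_length_s=30.0)
    rng = np.random.default_rng(42)
    subjects = [
        sg.generate_subject(cfg, 3, rng, subject_id=f"s{i:02d}", cohort="younger")
        for i in range(12)
    ]
    samples_by_subject = {
        s.subject_id: list(zip(s.segments, s.annotations)) for s in subjects
    }
    records = [
        {"subject_id": s.subject_id, "cohort": s.cohort, "n_segments": 3}
        for s in subjects
    ]
    model_cfg = ModelConfig(filters_per_level=[4, 8, 16])
    train_cfg = TrainConfig(max_epochs=15, patience=15, folds=6)
    return sg.cross_validate(
        samples_by_subject, records, model_cfg, train_cfg, seed=5
    )


def test_cross_validate_reports_six_folds(cv_result):
    assert len(cv_result["models"]) == 6
    assert len(cv_result["fold_metrics"]) == 6  # SD over exactly 6 values
    assert cv_result["sd_metric"] == pytest.approx(
        np.std(cv_result["fold_metrics"], ddof=1)
    )


def test_cross_validate_stable_across_folds(cv_result):
    """At high SNR the fold-to-fold spread of F1-bar stays small."""
    assert cv_result["sd_metric"] < 0.1
    assert cv_result["mean_metric"] > 0.5


def test_cross_validate_deterministic_given_seed():
    cfg = sg.SynthConfig(snr=10.0, segment_length_s=30.0)

    def run():
        rng = np.random.default_rng(9)
        subjects = [
            sg.generate_subject(cfg, 2, rng, subject_id=f"s{i}", cohort="older")
            for i in range(4)
        ]
        samples = {s.subject_id: list(zip(s.segments, s.annotations)) for s in subjects}
        records = [
            {"subject_id": s.subject_id, "cohort": s.cohort, "n_segments": 2}
            for s in subjects
        ]
        model_cfg = ModelConfig(
            levels=2, filters_per_level=[4, 8], conv_kernel=5, pool_widths=[4]
        )
        train_cfg = TrainConfig(max_epochs=2, patience=2, folds=2, batch_size=4)
        return sg.cross_validate(samples, records, model_cfg, train_cfg, seed=17)

    r1, r2 = run(), run()
    for h1, h2 in zip(r1["histories"], r2["histories"]):
        np.testing.assert_array_equal(h1["loss"].values, h2["loss"].values)
        np.testing.assert_array_equal(h1["val_metric"].values, h2["val_metric"].values)


def test_config_invariants():
    with pytest.raises(ValueError, match="batch"):
        TrainConfig(batch_size=0)
    with pytest.raises(ValueError, match="patience"):
        TrainConfig(patience=100, max_epochs=50)
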