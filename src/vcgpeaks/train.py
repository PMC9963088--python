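"""Training loop and experiment protocols.

Training minimizes per-sample binary cross-entropy with Adam (learning
rate 0.001, batch size 64 by default) and stops early when the epoch-mean
training loss has not improved by more than 1e-6 for ``patience``
consecutive epochs (no validation split is used; the monitored quantity
is the training loss). The weights attaining the best monitored loss are
restored at the end.

Protocols: leave-one-out (train on all records but one, score the held-out
record, average across folds) and cross-database (one model trained on all
training windows, scored on every test record, pooled report).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .detect import detect
from .metrics import (aggregate, compute_metrics, match_peaks,
                      restrict_to_annotated_span)
from .model import ModelConfig, SegmentationModel, build_model
from .nn import Adam, bce_with_logits
from .windows import SegmentSet, make_training_set


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    max_epochs: int = 500
    patience: int = 10
    batch_size: int = 64
    random_seed: int = 0
    min_improvement: float = 1e-6
    optimizer: str = "adam"     # fixed; documented for the run manifest
    loss: str = "bce"


def train(model: SegmentationModel, data: SegmentSet,
          config: TrainConfig | None = None, loss_schedule=None):
    """Train ``model`` on a SegmentSet with masks.

    Returns ``(model, loss_history)`` where the history holds one
    epoch-mean loss per completed epoch. ``loss_schedule`` is a test hook:
    a callable replacing the epoch loss (the optimization step still runs)
    to exercise the early-stopping rule with scripted losses.
    """
    config = config or TrainConfig()
    if data.masks is None or len(data) == 0:
        raise ValueError("training requires a non-empty SegmentSet with masks")
    x = np.asarray(data.data, dtype=np.float64)
    y = np.asarray(data.masks, dtype=np.float64)
    rng = np.random.default_rng(config.random_seed)
    opt = Adam(model.layers(), lr=config.learning_rate)

    best_loss = np.inf
    best_state = model.get_weights()
    since_improve = 0
    history = []
    n = len(data)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            sel = order[start: start + config.batch_size]
            z = model.forward_logits(x[sel], training=True)
            loss, dz = bce_with_logits(z, y[sel])
            model.backward(dz)
            opt.step()
            epoch_losses.append(loss * sel.size)
        epoch_loss = float(np.sum(epoch_losses) / n)
        if loss_schedule is not None:
            epoch_loss = float(loss_schedule(epoch))
        history.append(epoch_loss)
        if epoch_loss < best_loss - config.min_improvement:
            best_loss = epoch_loss
            best_state = model.get_weights()
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.patience:
                break
    model.set_weights(best_state)
    return model, history


def _score_record(model, vcg, ann):
    det = detect(model, vcg)
    if len(ann) == 0:
        return None
    det = restrict_to_annotated_span(det, ann, vcg.sampling_rate)
    return compute_metrics(match_peaks(det, ann, vcg.sampling_rate))


def _pool_training_windows(records, window_length):
    sets = [make_training_set(vcg, ann, window_length=window_length)
            for vcg, ann in records]
    sets = [s for s in sets if len(s)]
    if not sets:
        raise ValueError("no training windows: all records shorter than one window")
    return SegmentSet(
        window_length=window_length,
        stride=window_length,
        starts=np.concatenate([s.starts for s in sets]),
        data=np.concatenate([s.data for s in sets]),
        masks=np.concatenate([s.masks for s in sets]),
    )


def run_leave_one_out(records, config: TrainConfig | None = None,
                      model_config: ModelConfig | None = None):
    """Leave-one-out protocol over (VCGRecord, BeatAnnotations) pairs.

    Returns ``(per_record_reports, macro_report, pooled_report)``. Records
    without annotations are excluded from the averages with a warning.
    """
    if len(records) < 2:
        raise ValueError("leave-one-out needs at least 2 records")
    config = config or TrainConfig()
    model_config = model_config or ModelConfig()
    reports = []
    for i, (vcg, ann) in enumerate(records):
        train_recs = [r for j, r in enumerate(records) if j != i]
        data = _pool_training_windows(train_recs, model_config.input_length)
        model = build_model(model_config, seed=config.random_seed)
        train(model, data, config)
        rep = _score_record(model, vcg, ann)
        if rep is None:
            warnings.warn(
                f"record {vcg.record_id!r} has no annotations; excluded")
            continue
        reports.append(rep)
    return reports, aggregate(reports, "macro"), aggregate(reports, "pooled")


def run_cross_database(train_records, test_records,
                       config: TrainConfig | None = None,
                       model_config: ModelConfig | None = None):
    """Cross-database protocol: one model, disjoint record sets.

    Returns ``(pooled_report, per_record_reports, model)``.
    """
    if not test_records:
        raise ValueError("test set must not be empty")
    train_ids = {vcg.record_id for vcg, _ in train_records}
    test_ids = {vcg.record_id for vcg, _ in test_records}
    overlap = train_ids & test_ids
    if overlap:
        raise ValueError(f"train/test record sets overlap: {sorted(overlap)}")
    config = config or TrainConfig()
    model_config = model_config or ModelConfig()
    data = _pool_training_windows(train_records, model_config.input_length)
    model = build_model(model_config, seed=config.random_seed)
    train(model, data, config)
    reports = []
    for vcg, ann in test_records:
        rep = _score_record(model, vcg, ann)
        if rep is None:
            warnings.warn(
                f"record {vcg.record_id!r} has no annotations; excluded")
            continue
        reports.append(rep)
    return aggregate(reports, "pooled"), reports, model
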