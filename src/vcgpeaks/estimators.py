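"""Scikit-learn style estimator facades over the detection pipeline.

``RPeakUNet`` wraps windowing, training and consensus peak extraction as a
fit/predict estimator; ``PanTompkins`` exposes the classical baseline with
the same predict surface. Both cooperate with ``sklearn.base`` cloning and
``get_params``/``set_params``. Inputs are lists of records rather than a
feature matrix, so these estimators compose with sklearn model selection
only through custom splitters; the value of the interface here is uniform
parameter handling and the shared ``predict``/``score`` contract.
"""

from __future__ import annotations

from sklearn.base import BaseEstimator

from .detect import detect
from .kors import kors_transform
from .metrics import compute_metrics, match_peaks, restrict_to_annotated_span
from .model import ModelConfig, build_model
from .pantompkins import PTConfig, pt_detect
from .records import ECGRecord, VCGRecord
from .train import TrainConfig, train, _pool_training_windows


def _as_vcg(record):
    if isinstance(record, VCGRecord):
        return record
    if isinstance(record, ECGRecord):
        return kors_transform(record)
    raise TypeError(f"expected ECGRecord or VCGRecord, got {type(record)!r}")


class RPeakUNet(BaseEstimator):
    """R-peak detector: Kors VCG + 1D U-Net segmentation + consensus rule.

    Parameters mirror the published training setup (Adam, learning rate
    0.001, batch 64, early stopping with patience 10) and the detection
    rule (probability threshold 0.5, minimum consensus support 5).

    Attributes (after fit)
    ----------------------
    model_ : SegmentationModel
        The trained network.
    loss_history_ : list of float
        Epoch-mean training loss per completed epoch.
    n_parameters_ : int
        Trainable parameter count of the fitted network.
    """

    def __init__(self, input_length=2048, in_channels=3, learning_rate=0.001,
                 batch_size=64, max_epochs=500, patience=10, threshold=0.5,
                 min_support=5, random_state=0):
        self.input_length = input_length
        self.in_channels = in_channels
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.threshold = threshold
        self.min_support = min_support
        self.random_state = random_state

    def _configs(self):
        return (ModelConfig(input_length=self.input_length,
                            in_channels=self.in_channels),
                TrainConfig(learning_rate=self.learning_rate,
                            batch_size=self.batch_size,
                            max_epochs=self.max_epochs,
                            patience=self.patience,
                            random_seed=self.random_state))

    def fit(self, records, annotations):
        """Fit on parallel lists of records and BeatAnnotations."""
        if len(records) != len(annotations):
            raise ValueError("records and annotations differ in length")
        model_cfg, train_cfg = self._configs()
        pairs = [(_as_vcg(r), a) for r, a in zip(records, annotations)]
        data = _pool_training_windows(pairs, model_cfg.input_length)
        model = build_model(model_cfg, seed=train_cfg.random_seed)
        from .model import count_trainable_parameters
        model, history = train(model, data, train_cfg)
        self.model_ = model
        self.loss_history_ = history
        self.n_parameters_ = count_trainable_parameters(model)
        return self

    def predict(self, record):
        """Detected R-peak sample indices for one record."""
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted; call fit first")
        peaks = detect(self.model_, _as_vcg(record),
                       threshold=self.threshold,
                       min_support=self.min_support)
        return peaks.sample_indices

    def score(self, records, annotations):
        """Pooled F1 (fraction in [0, 1]) over records."""
        tp = fn = fp = 0
        for rec, ann in zip(records, annotations):
            vcg = _as_vcg(rec)
            det = detect(self.model_, vcg, threshold=self.threshold,
                         min_support=self.min_support)
            det = restrict_to_annotated_span(det, ann, vcg.sampling_rate)
            m = match_peaks(det, ann, vcg.sampling_rate)
            tp, fn, fp = tp + m.tp, fn + m.fn, fp + m.fp
        rep = compute_metrics((tp, fn, fp))
        return (rep.f1 or 0.0) / 100.0


class PanTompkins(BaseEstimator):
    """Classical single-lead baseline with the estimator surface.

    ``fit`` is a no-op (the algorithm is fully adaptive); ``predict``
    takes an ECGRecord and runs detection on ``lead``.
    """

    def __init__(self, lead="II", band_low=5.0, band_high=15.0,
                 integration_ms=150.0, refractory_ms=200.0):
        self.lead = lead
        self.band_low = band_low
        self.band_high = band_high
        self.integration_ms = integration_ms
        self.refractory_ms = refractory_ms

    def fit(self, records=None, annotations=None):
        self.config_ = PTConfig(band_low=self.band_low,
                                band_high=self.band_high,
                                integration_ms=self.integration_ms,
                                refractory_ms=self.refractory_ms)
        return self

    def predict(self, record: ECGRecord):
        if not hasattr(self, "config_"):
            self.fit()
        sig = record.select_leads([self.lead]).signal[:, 0]
        return pt_detect(sig, record.sampling_rate, self.config_).sample_indices
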