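"""Conv-LSTM sequence model for time-resolved strip readout.

The learnable core: a small per-frame convolutional encoder feeding an LSTM
whose final hidden state is mapped by a fully connected head to either a
scalar concentration score (regression, trained with mean absolute error) or
two class logits (binary positive/negative, obtained by swapping the head
and fine-tuning with cross-entropy).

The regression target is the color-chart level (0-8): higher concentrations
get larger numbers, so thresholding the score gives a binary call and
rounding gives the chart level.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
from skimage.color import rgb2hsv
from skimage.transform import resize
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin

from ._nn import Adam, SeqNet
from .dataset import FrameSequence

__all__ = [
    "ModelConfig",
    "ScoreBatch",
    "ClassProbBatch",
    "TrainReport",
    "mae_loss",
    "ce_loss",
    "hsv_augment",
    "StripSequenceRegressor",
    "StripBinaryClassifier",
    "build_model",
    "train_regressor",
    "fine_tune_binary",
    "predict_score",
    "save_checkpoint",
    "load_checkpoint",
]

_CE_EPS = 1e-12
# the network regresses level/8 internally; predictions are rescaled to the
# 0-8 chart scale, keeping Adam step sizes commensurate with the output range
_SCORE_SCALE = 8.0


@dataclass
class ModelConfig:
    """Hyperparameters of the sequence model and its training loop."""

    input_size_px: tuple = (16, 16)
    encoder_channels: tuple = (8, 16)
    feature_dim: int = 16
    recurrent_hidden: int = 24
    recurrent_layers: int = 1
    output_dim: int = 1
    seed: int = 0
    epochs: int = 150
    batch_size: int = 8
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        self.input_size_px = tuple(int(v) for v in self.input_size_px)
        self.encoder_channels = tuple(int(v) for v in self.encoder_channels)
        if self.output_dim not in (1, 2):
            raise ValueError("output_dim must be 1 (regression) or 2 (binary)")
        if min(self.feature_dim, self.recurrent_hidden, self.recurrent_layers,
               self.epochs, self.batch_size, *self.input_size_px,
               *self.encoder_channels) < 1:
            raise ValueError("all dimensions/counts must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class ScoreBatch:
    """Regression batch: N targets y_i and predictions y_hat_i."""

    y: tuple
    y_hat: tuple

    def __post_init__(self) -> None:
        if len(self.y) != len(self.y_hat):
            raise ValueError("y and y_hat must have equal length")
        if len(self.y) < 1:
            raise ValueError("empty batch")
        object.__setattr__(self, "y", tuple(float(v) for v in self.y))
        object.__setattr__(self, "y_hat", tuple(float(v) for v in self.y_hat))

    @property
    def N(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class ClassProbBatch:
    """Binary batch: one-hot truth vectors and predicted 2-class probabilities."""

    y_onehot: tuple
    p_hat: tuple

    def __post_init__(self) -> None:
        y = tuple(tuple(float(v) for v in row) for row in self.y_onehot)
        p = tuple(tuple(float(v) for v in row) for row in self.p_hat)
        if len(y) != len(p) or len(y) < 1:
            raise ValueError("batch must be non-empty with matching lengths")
        for row in y:
            if len(row) != 2 or sorted(row) != [0.0, 1.0]:
                raise ValueError("y_onehot rows must be 2-class one-hot")
        for row in p:
            if len(row) != 2 or abs(sum(row) - 1.0) > 1e-6:
                raise ValueError("p_hat rows must sum to 1")
        object.__setattr__(self, "y_onehot", y)
        object.__setattr__(self, "p_hat", p)


@dataclass
class TrainReport:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    final_epoch: int = 0
    seed: int = 0
    config: dict = field(default_factory=dict)


def mae_loss(batch: ScoreBatch) -> float:
    """Mean absolute error (1/N) * sum |y_i - y_hat_i|."""
    y = np.asarray(batch.y)
    y_hat = np.asarray(batch.y_hat)
    return float(np.mean(np.abs(y - y_hat)))


def ce_loss(batch: ClassProbBatch) -> float:
    """Mean two-class cross-entropy -sum_i y_i log p_hat_i (natural log).

    Predicted probabilities are clamped to [1e-12, 1] before the log, so the
    loss stays finite even for a confidently wrong prediction.
    """
    y = np.asarray(batch.y_onehot)
    p = np.clip(np.asarray(batch.p_hat), _CE_EPS, 1.0)
    return float(np.mean(-np.sum(y * np.log(p), axis=1)))


def hsv_augment(sample: FrameSequence) -> list:
    """Return [original, HSV-re-embedded] versions of a cropped sequence.

    Each frame of the second sample is its HSV transform scaled back to an
    8-bit 3-channel image (H, S, V each in 0-255), doubling the training set
    with a color-space view of the same strip.
    """
    frames = np.asarray(sample.frames)
    if frames.ndim != 4 or frames.shape[-1] != 3:
        raise ValueError("RGB frame sequence required")
    hsv = np.stack([
        np.clip(np.rint(rgb2hsv(f) * 255.0), 0, 255).astype(np.uint8)
        for f in frames
    ])
    return [sample, FrameSequence(hsv, sample.timestamps_s)]


# ---------------------------------------------------------------------------
# estimators


def _prepare(X, input_size_px) -> list:
    """Resize ROI-cropped sequences to the model input size, scale to [0, 1].

    Accepts FrameSequence objects or arrays of shape (T, H, W, 3); returns a
    list of float arrays (T, 3, h, w).
    """
    out = []
    for sample in X:
        frames = sample.frames if isinstance(sample, FrameSequence) else sample
        frames = np.asarray(frames)
        if frames.ndim != 4 or frames.shape[-1] != 3 or len(frames) < 1:
            raise ValueError("each sample must be a (T, H, W, 3) sequence "
                             "with at least one frame")
        scaled = np.stack([
            resize(f.astype(np.float64) / 255.0, input_size_px,
                   preserve_range=True, anti_aliasing=True)
            for f in frames
        ])
        out.append(np.ascontiguousarray(scaled.transpose(0, 3, 1, 2)))
    return out


class _ConvLstmBase(BaseEstimator):
    def __init__(self, input_size_px=(16, 16), encoder_channels=(8, 16),
                 feature_dim=16, recurrent_hidden=24, recurrent_layers=1,
                 seed=0, epochs=150, batch_size=8, learning_rate=1e-3):
        self.input_size_px = input_size_px
        self.encoder_channels = encoder_channels
        self.feature_dim = feature_dim
        self.recurrent_hidden = recurrent_hidden
        self.recurrent_layers = recurrent_layers
        self.seed = seed
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate

    _output_dim = 1

    def _config(self) -> ModelConfig:
        return ModelConfig(
            input_size_px=tuple(self.input_size_px),
            encoder_channels=tuple(self.encoder_channels),
            feature_dim=self.feature_dim,
            recurrent_hidden=self.recurrent_hidden,
            recurrent_layers=self.recurrent_layers,
            output_dim=self._output_dim,
            seed=self.seed, epochs=self.epochs,
            batch_size=self.batch_size, learning_rate=self.learning_rate,
        )

    def _build_net(self, rng) -> SeqNet:
        cfg = self._config()
        return SeqNet(cfg.input_size_px, 3, cfg.encoder_channels,
                      cfg.feature_dim, cfg.recurrent_hidden,
                      cfg.recurrent_layers, cfg.output_dim, rng)

    def _forward_sets(self, prepared):
        """Forward variable-length samples grouped by frame count."""
        n = len(prepared)
        out = np.empty((n, self.net_.out_dim))
        by_len: dict[int, list] = {}
        for i, s in enumerate(prepared):
            by_len.setdefault(len(s), []).append(i)
        for idx in by_len.values():
            batch = np.stack([prepared[i] for i in idx])
            out[idx] = self.net_.forward(batch)
        return out

    def _fit_loop(self, prepared, targets, val_prepared, val_targets,
                  loss_and_grad):
        cfg = self._config()
        rng = np.random.default_rng(cfg.seed)
        if not hasattr(self, "net_") or self.net_ is None:
            self.net_ = self._build_net(rng)
        opt = Adam(self.net_.params, lr=cfg.learning_rate)
        report = TrainReport(seed=cfg.seed, config=asdict(cfg))

        lengths = {len(p) for p in prepared}
        groups = {L: [i for i, p in enumerate(prepared) if len(p) == L]
                  for L in lengths}
        for epoch in range(cfg.epochs):
            batch_losses = []
            batches = []
            for L, idx in groups.items():
                idx = list(idx)
                rng.shuffle(idx)
                for s in range(0, len(idx), cfg.batch_size):
                    batches.append(idx[s:s + cfg.batch_size])
            rng.shuffle(batches)
            for bidx in batches:
                xb = np.stack([prepared[i] for i in bidx])
                tb = targets[bidx]
                out = self.net_.forward(xb, train=True)
                loss, dout = loss_and_grad(out, tb)
                self.net_.backward(dout)
                opt.step(self.net_.params, self.net_.grads)
                batch_losses.append(loss)
            report.train_loss.append(float(np.mean(batch_losses)))
            if val_prepared:
                vout = self._forward_sets(val_prepared)
                vloss, _ = loss_and_grad(vout, val_targets)
                report.val_loss.append(float(vloss))
        report.final_epoch = cfg.epochs
        self.train_report_ = report
        return report


class StripSequenceRegressor(_ConvLstmBase, RegressorMixin):
    """Conv-LSTM regressor of the color-chart level from an ROI sequence.

    fit(X, y): X is a list of ROI-cropped frame sequences (FrameSequence or
    (T, H, W, 3) uint8 arrays, variable T allowed), y the level targets on
    the 0-8 scale.  Trained with mean absolute error and Adam; fully
    reproducible for a fixed ``seed``.
    """

    _output_dim = 1

    def fit(self, X, y, X_val=None, y_val=None):
        y = np.asarray(y, dtype=float)
        if len(X) != len(y) or len(y) == 0:
            raise ValueError("X and y must be non-empty with equal length")
        prepared = _prepare(X, tuple(self.input_size_px))
        val_prepared = _prepare(X_val, tuple(self.input_size_px)) if X_val else []
        val_targets = (np.asarray(y_val, dtype=float)
                       if y_val is not None else None)

        def loss_and_grad(out, targets):
            pred = out[:, 0] * _SCORE_SCALE
            resid = pred - targets
            loss = float(np.mean(np.abs(resid)))  # MAE on the level scale
            dout = (_SCORE_SCALE * np.sign(resid) / len(resid))[:, None]
            return loss, dout

        self.net_ = None
        self._fit_loop(prepared, y, val_prepared, val_targets, loss_and_grad)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "net_") or self.net_ is None:
            raise RuntimeError("model is not fitted")
        prepared = _prepare(X, tuple(self.input_size_px))
        return self._forward_sets(prepared)[:, 0] * _SCORE_SCALE


class StripBinaryClassifier(_ConvLstmBase, ClassifierMixin):
    """Binary positive/negative classifier sharing the regressor backbone.

    Normally produced by :func:`fine_tune_binary`, which transplants a
    trained regressor's encoder and LSTM and re-initializes the 2-way head;
    it can also be trained from scratch.  Trained with cross-entropy on
    softmax probabilities.
    """

    _output_dim = 2
    classes_ = np.array([0, 1])  # 0 = negative, 1 = positive

    def fit(self, X, y, X_val=None, y_val=None):
        y = np.asarray(y, dtype=int)
        if len(X) != len(y) or len(y) == 0:
            raise ValueError("X and y must be non-empty with equal length")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("binary labels must be 0 (negative) / 1 (positive)")
        prepared = _prepare(X, tuple(self.input_size_px))
        val_prepared = _prepare(X_val, tuple(self.input_size_px)) if X_val else []
        val_targets = np.asarray(y_val, dtype=int) if y_val is not None else None

        def loss_and_grad(out, targets):
            p = _softmax(out)
            onehot = np.zeros_like(p)
            onehot[np.arange(len(targets)), targets] = 1.0
            loss = float(np.mean(
                -np.sum(onehot * np.log(np.clip(p, _CE_EPS, 1.0)), axis=1)))
            dout = (p - onehot) / len(targets)
            return loss, dout

        self._fit_loop(prepared, y, val_prepared, val_targets, loss_and_grad)
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "net_") or self.net_ is None:
            raise RuntimeError("model is not fitted")
        prepared = _prepare(X, tuple(self.input_size_px))
        return _softmax(self._forward_sets(prepared))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# spec-shaped functional surface


def build_model(config: ModelConfig):
    """Instantiate an unfitted estimator from a config (seeded parameters)."""
    cls = (StripSequenceRegressor if config.output_dim == 1
           else StripBinaryClassifier)
    est = cls(
        input_size_px=config.input_size_px,
        encoder_channels=config.encoder_channels,
        feature_dim=config.feature_dim,
        recurrent_hidden=config.recurrent_hidden,
        recurrent_layers=config.recurrent_layers,
        seed=config.seed, epochs=config.epochs,
        batch_size=config.batch_size, learning_rate=config.learning_rate,
    )
    est.net_ = est._build_net(np.random.default_rng(config.seed))
    return est


def train_regressor(model: StripSequenceRegressor, X, y,
                    X_val=None, y_val=None) -> TrainReport:
    """Train an MAE regressor in place; returns the per-epoch TrainReport."""
    model.fit(X, y, X_val=X_val, y_val=y_val)
    return model.train_report_


def fine_tune_binary(model: StripSequenceRegressor, X, y, *,
                     epochs: int | None = None, seed: int | None = None,
                     learning_rate: float | None = None
                     ) -> StripBinaryClassifier:
    """Swap the 1-d regression head for a fresh 2-d head and fine-tune.

    All encoder, projection and LSTM parameters are carried over unchanged
    at hand-off; only the final fully connected layer is re-initialized.
    Fine-tuning minimizes cross-entropy on binary labels (1 = positive).
    """
    if not isinstance(model, StripSequenceRegressor):
        raise ValueError("model already binary (or not a trained regressor)")
    if not hasattr(model, "net_") or model.net_ is None:
        raise ValueError("regressor must be fitted before fine-tuning")
    clf = StripBinaryClassifier(**model.get_params())
    if seed is not None:
        clf.seed = seed
    if epochs is not None:
        clf.epochs = epochs
    if learning_rate is not None:
        clf.learning_rate = learning_rate
    rng = np.random.default_rng(clf.seed)
    clf.net_ = clf._build_net(rng)
    state = model.net_.state_dict()
    for k in list(state):
        if k.startswith("head_"):
            del state[k]  # head is re-initialized, not transplanted
    for k, v in state.items():
        clf.net_.params[k] = v.copy()
    clf.fit(X, y)
    return clf


def predict_score(model: StripSequenceRegressor, sample) -> float:
    """Scalar level score for one preprocessed (ROI-cropped) sequence."""
    score = float(model.predict([sample])[0])
    if not math.isfinite(score):
        raise ValueError("non-finite prediction")
    return score


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model, path) -> None:
    """Save estimator config + parameters to a single .npz archive."""
    if not hasattr(model, "net_") or model.net_ is None:
        raise ValueError("cannot checkpoint an unfitted model")
    meta = {
        "kind": type(model).__name__,
        "params": model.get_params(),
    }
    arrays = {f"param/{k}": v for k, v in model.net_.state_dict().items()}
    np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path):
    """Restore an estimator saved by :func:`save_checkpoint`."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k.split("/", 1)[1]: data[k]
                 for k in data.files if k.startswith("param/")}
    cls = {"StripSequenceRegressor": StripSequenceRegressor,
           "StripBinaryClassifier": StripBinaryClassifier}[meta["kind"]]
    params = meta["params"]
    for key in ("input_size_px", "encoder_channels"):
        params[key] = tuple(params[key])
    est = cls(**params)
    est.net_ = est._build_net(np.random.default_rng(est.seed))
    est.net_.load_state_dict(state)
    return est
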