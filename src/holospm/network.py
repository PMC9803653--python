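"""Holo-SpeckleNet: dense autoencoder feature extraction plus regression.

A deep autoencoder (DAE) compresses each flattened 70 x 70 speckle segment
(4900 pixels on the unit interval) through a 512-256-128-64 encoder and a
mirrored decoder, trained with Adam to minimize the RMSE between input and
reconstruction; sigmoid activations throughout.  The 64 latent features then
feed a 256-256-1 regression head trained with plain stochastic gradient
descent on the mean absolute error against the mass-concentration labels
(rectified-linear hidden units, linear output).

The networks are implemented directly in numpy: seeded fan-in-scaled
initialization, mini-batch training, and single-threaded determinism, so a
fixed seed reproduces the training history bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import PreprocParams, SegmentSet, run_preproc_chain

__all__ = [
    "TrainingHyper",
    "NetworkSpec",
    "DAEModel",
    "RegressorModel",
    "HoloSpeckleNet",
    "PredictionRecord",
    "train_dae",
    "encode",
    "reconstruct",
    "train_regressor",
    "train_specklenet",
    "predict_concentration",
    "rmse",
    "mae",
    "percent_error",
]


@dataclass(frozen=True)
class TrainingHyper:
    optimizer: str  # "adam" | "sgd"
    loss: str       # "rmse" | "mae"
    batch_size: int
    epochs: int
    learning_rate: float
    activation: str  # "sigmoid" | "relu"

    def __post_init__(self) -> None:
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be adam|sgd")
        if self.loss not in ("rmse", "mae"):
            raise ValueError("loss must be rmse|mae")
        if min(self.batch_size, self.epochs) < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size/epochs/learning_rate must be positive")


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture + training recipe of both network stages.

    Defaults are the full-scale recipe (4900-512-256-128-64 encoder, Adam /
    RMSE / batch 4096 / 5000 epochs / lr 1e-3; 64-256-256-1 regressor, SGD /
    MAE / batch 8192 / 10000 epochs / lr 1e-7).  :meth:`test_profile` gives
    a reduced desk-scale variant that trains in minutes on one CPU.
    """

    encoder_widths: tuple[int, ...] = (4900, 512, 256, 128, 64)
    decoder_widths: tuple[int, ...] | None = None
    regressor_widths: tuple[int, ...] = (64, 256, 256, 1)
    dae_hyper: TrainingHyper = TrainingHyper("adam", "rmse", 4096, 5000,
                                             1e-3, "sigmoid")
    reg_hyper: TrainingHyper = TrainingHyper("sgd", "mae", 8192, 10_000,
                                             1e-7, "relu")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decoder_widths is None:
            object.__setattr__(self, "decoder_widths",
                               tuple(reversed(self.encoder_widths)))
        if any(w <= 0 for w in (*self.encoder_widths, *self.decoder_widths,
                                *self.regressor_widths)):
            raise ValueError("all layer widths must be positive")
        if self.encoder_widths[-1] != self.regressor_widths[0]:
            raise ValueError("latent width must equal regressor input width")
        if self.decoder_widths[0] != self.encoder_widths[-1]:
            raise ValueError("decoder must start at the latent width")

    @property
    def latent_width(self) -> int:
        return self.encoder_widths[-1]

    @property
    def input_width(self) -> int:
        return self.encoder_widths[0]

    @classmethod
    def test_profile(cls, tile_size: int = 70, seed: int = 0) -> "NetworkSpec":
        """Reduced widths/epochs for single-CPU runs (same algorithm)."""
        return cls(
            encoder_widths=(tile_size**2, 256, 64),
            regressor_widths=(64, 64, 64, 1),
            dae_hyper=TrainingHyper("adam", "rmse", 256, 150, 1e-3, "sigmoid"),
            reg_hyper=TrainingHyper("sgd", "mae", 8192, 4000, 1e-2, "relu"),
            seed=seed,
        )


# ---------------------------------------------------------------------------
# minimal dense network machinery


def _act(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sigmoid":
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        return out
    if kind == "relu":
        return np.maximum(x, 0.0)
    return x  # linear


def _act_grad(a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sigmoid":
        return a * (1.0 - a)
    if kind == "relu":
        return (a > 0).astype(a.dtype)
    return np.ones_like(a)


class _MLP:
    """Fully connected stack with per-layer activations."""

    def __init__(self, widths: tuple[int, ...], activations: list[str],
                 rng: np.random.Generator):
        assert len(activations) == len(widths) - 1
        self.activations = activations
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(widths, widths[1:]):
            bound = 1.0 / np.sqrt(fan_in)
            self.weights.append(rng.uniform(-bound, bound, (fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self.widths = tuple(widths)

    def forward(self, x: np.ndarray, upto: int | None = None) -> np.ndarray:
        n_layers = len(self.weights) if upto is None else upto
        a = x
        for w, b, act in zip(self.weights[:n_layers], self.biases[:n_layers],
                             self.activations[:n_layers]):
            a = _act(a @ w + b, act)
        return a

    def forward_cached(self, x: np.ndarray) -> list[np.ndarray]:
        acts = [x]
        for w, b, act in zip(self.weights, self.biases, self.activations):
            acts.append(_act(acts[-1] @ w + b, act))
        return acts

    def backward(self, acts: list[np.ndarray], grad_out: np.ndarray
                 ) -> list[tuple[np.ndarray, np.ndarray]]:
        """Parameter gradients given dL/d(final activation)."""
        grads: list[tuple[np.ndarray, np.ndarray]] = []
        delta = grad_out
        for i in reversed(range(len(self.weights))):
            delta = delta * _act_grad(acts[i + 1], self.activations[i])
            grads.append((acts[i].T @ delta, delta.sum(axis=0)))
            if i > 0:
                delta = delta @ self.weights[i].T
        grads.reverse()
        return grads


class _Optimizer:
    def __init__(self, mlp: _MLP, hyper: TrainingHyper):
        self.kind = hyper.optimizer
        self.lr = hyper.learning_rate
        if self.kind == "adam":
            self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
            self.t = 0
            self.m = [(np.zeros_like(w), np.zeros_like(b))
                      for w, b in zip(mlp.weights, mlp.biases)]
            self.v = [(np.zeros_like(w), np.zeros_like(b))
                      for w, b in zip(mlp.weights, mlp.biases)]

    def step(self, mlp: _MLP, grads) -> None:
        if self.kind == "sgd":
            for i, (gw, gb) in enumerate(grads):
                mlp.weights[i] -= self.lr * gw
                mlp.biases[i] -= self.lr * gb
            return
        self.t += 1
        corr1 = 1 - self.beta1**self.t
        corr2 = 1 - self.beta2**self.t
        for i, (gw, gb) in enumerate(grads):
            mw, mb = self.m[i]
            vw, vb = self.v[i]
            mw[:] = self.beta1 * mw + (1 - self.beta1) * gw
            mb[:] = self.beta1 * mb + (1 - self.beta1) * gb
            vw[:] = self.beta2 * vw + (1 - self.beta2) * gw**2
            vb[:] = self.beta2 * vb + (1 - self.beta2) * gb**2
            mlp.weights[i] -= self.lr * (mw / corr1) / (np.sqrt(vw / corr2) + self.eps)
            mlp.biases[i] -= self.lr * (mb / corr1) / (np.sqrt(vb / corr2) + self.eps)


def _loss_and_grad(pred: np.ndarray, target: np.ndarray, kind: str
                   ) -> tuple[float, np.ndarray]:
    resid = pred - target
    n = resid.size
    if kind == "rmse":
        value = float(np.sqrt(np.mean(resid**2)))
        grad = resid / (n * value) if value > 0 else np.zeros_like(resid)
        return value, grad
    value = float(np.mean(np.abs(resid)))
    return value, np.sign(resid) / n


def _train_mlp(mlp: _MLP, x: np.ndarray, y: np.ndarray, hyper: TrainingHyper,
               rng: np.random.Generator, autoencode: bool = False,
               corruption_sd: float = 0.0) -> list[float]:
    n = x.shape[0]
    batch = min(hyper.batch_size, n)
    opt = _Optimizer(mlp, hyper)
    history: list[float] = []
    for epoch in range(hyper.epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, batch):
            idx = perm[start:start + batch]
            xb = x[idx]
            if autoencode and corruption_sd > 0:
                xb = xb + rng.normal(0.0, corruption_sd, xb.shape)
            acts = mlp.forward_cached(xb)
            loss, grad = _loss_and_grad(acts[-1], y[idx], hyper.loss)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite {hyper.loss} at epoch {epoch}: training "
                    "diverged (lower the learning rate)")
            opt.step(mlp, mlp.backward(acts, grad))
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history


# ---------------------------------------------------------------------------
# model containers and training entry points


@dataclass
class DAEModel:
    mlp: _MLP
    n_encoder_layers: int
    spec: NetworkSpec
    history: list[float]
    branch: str = ""


@dataclass
class RegressorModel:
    mlp: _MLP
    spec: NetworkSpec
    history: list[float]
    feature_mean: np.ndarray | None = None
    feature_sd: np.ndarray | None = None
    branch: str = ""


@dataclass
class HoloSpeckleNet:
    """Trained encoder + regression head for one branch (fine or coarse)."""

    dae: DAEModel
    regressor: RegressorModel
    branch: str = ""

    def predict_segments(self, x: np.ndarray) -> np.ndarray:
        return predict_features(self.regressor, encode(self.dae, x))


@dataclass
class PredictionRecord:
    """Per-segment, per-frame and class-level predictions for one stack."""

    segment_predictions: np.ndarray  # (n_frames, segments_per_frame)
    frame_means: np.ndarray
    class_mean: float
    truth: tuple[float, float] | None
    branch: str


def _segments_matrix(segments) -> np.ndarray:
    if isinstance(segments, SegmentSet):
        return segments.as_matrix()
    return np.asarray(segments, dtype=float)


def train_dae(segments, spec: NetworkSpec,
              corruption_sd: float = 0.0) -> DAEModel:
    """Train the autoencoder to reconstruct unit-interval segments.

    Minimizes the per-batch RMSE between each segment and its
    reconstruction by mini-batch gradient steps (Adam by default).  With
    ``corruption_sd > 0`` the inputs (not the targets) are perturbed with
    Gaussian noise each batch — denoising-style regularization that pushes
    the latent code toward texture statistics rather than the exact pixel
    layout of individual training segments.
    """
    x = _segments_matrix(segments)
    if x.shape[1] != spec.input_width:
        raise ValueError(
            f"segment width {x.shape[1]} != encoder input {spec.input_width}")
    rng = np.random.default_rng(spec.seed)
    widths = (*spec.encoder_widths, *spec.decoder_widths[1:])
    act = spec.dae_hyper.activation
    mlp = _MLP(widths, [act] * (len(widths) - 1), rng)
    history = _train_mlp(mlp, x, x, spec.dae_hyper, rng, autoencode=True,
                         corruption_sd=corruption_sd)
    return DAEModel(mlp=mlp, n_encoder_layers=len(spec.encoder_widths) - 1,
                    spec=spec, history=history)


def encode(model: DAEModel, segments) -> np.ndarray:
    """Latent features (one row of ``latent_width`` values per segment)."""
    x = _segments_matrix(segments)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != model.spec.input_width:
        raise ValueError("segment width does not match the encoder input")
    z = model.mlp.forward(x, upto=model.n_encoder_layers)
    return z[0] if single else z


def reconstruct(model: DAEModel, segments) -> np.ndarray:
    return model.mlp.forward(_segments_matrix(segments))


def train_regressor(features: np.ndarray, labels: np.ndarray,
                    spec: NetworkSpec) -> RegressorModel:
    """Train the regression head on latent features vs concentration labels.

    Hidden layers use the rectifier; the scalar output is linear.  Features
    are standardized internally (stored with the model) so the plain-SGD /
    MAE recipe is well-conditioned regardless of latent scale.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=float).reshape(-1, 1)
    if features.shape[0] != labels.shape[0]:
        raise ValueError("one label per feature vector required")
    if np.unique(labels).size < 2:
        raise ValueError("need >= 2 distinct labels for regression")
    if features.shape[1] != spec.regressor_widths[0]:
        raise ValueError("feature width does not match the regressor input")
    mu = features.mean(axis=0)
    sd = features.std(axis=0)
    sd[sd == 0] = 1.0
    z = (features - mu) / sd
    rng = np.random.default_rng(spec.seed + 1)
    widths = spec.regressor_widths
    acts = [spec.reg_hyper.activation] * (len(widths) - 2) + ["linear"]
    mlp = _MLP(widths, acts, rng)
    # start the output bias at the label mean so SGD refines, not bootstraps
    mlp.biases[-1][:] = labels.mean()
    history = _train_mlp(mlp, z, labels, spec.reg_hyper, rng)
    return RegressorModel(mlp=mlp, spec=spec, history=history,
                          feature_mean=mu, feature_sd=sd)


def predict_features(model: RegressorModel, features: np.ndarray) -> np.ndarray:
    features = np.asarray(features, dtype=float)
    single = features.ndim == 1
    if single:
        features = features[None, :]
    z = (features - model.feature_mean) / model.feature_sd
    out = model.mlp.forward(z)[:, 0]
    return float(out[0]) if single else out


def train_specklenet(segments, labels: np.ndarray, spec: NetworkSpec,
                     branch: str = "") -> HoloSpeckleNet:
    """Convenience two-stage training: DAE, then regressor on its latents."""
    dae = train_dae(segments, spec)
    feats = encode(dae, segments)
    reg = train_regressor(feats, labels, spec)
    dae.branch = reg.branch = branch
    return HoloSpeckleNet(dae=dae, regressor=reg, branch=branch)


def predict_concentration(net: HoloSpeckleNet, frames,
                          params: PreprocParams | None = None,
                          background=None) -> PredictionRecord:
    """Predict one class's concentration from a stack of raw frames.

    Each frame is preprocessed with the branch parameters and tiled; the
    per-frame prediction is the mean over its segments and the class value
    is the mean of the frame means.
    """
    if len(frames) == 0:
        raise ValueError("empty frame set")
    seg = run_preproc_chain(frames, params=params,
                            branch=net.branch or None, background=background)
    per_frame = len(seg) // len(frames)
    preds = net.predict_segments(seg.as_matrix()).reshape(len(frames), per_frame)
    frame_means = preds.mean(axis=1)
    return PredictionRecord(
        segment_predictions=preds, frame_means=frame_means,
        class_mean=float(frame_means.mean()), truth=frames[0].labels,
        branch=net.branch)


# ---------------------------------------------------------------------------
# error metrics


def rmse(pred, truth) -> float:
    """Root mean square of the residuals."""
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    if pred.shape != truth.shape:
        raise ValueError("pred/truth length mismatch")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def mae(pred, truth) -> float:
    """Mean absolute residual."""
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    if pred.shape != truth.shape:
        raise ValueError("pred/truth length mismatch")
    return float(np.mean(np.abs(pred - truth)))


def percent_error(pred, truth) -> tuple[float, float]:
    """Per-class absolute percent errors aggregated as (mean, sd)."""
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    if pred.shape != truth.shape:
        raise ValueError("pred/truth length mismatch")
    if np.any(truth == 0):
        raise ValueError("percent error undefined for zero truth")
    errs = 100.0 * np.abs(pred - truth) / np.abs(truth)
    return float(errs.mean()), float(errs.std())
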