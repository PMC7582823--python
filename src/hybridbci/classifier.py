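"""Four-layer convolutional network decoder for STFT power maps.

Architecture (fixed topology, configurable widths):

    input (25 × 500 normalized power map)
      → 2×2 valid convolution, K kernels, bias, ReLU
      → 2×2 max-pooling, stride 2
      → fully connected (fc1 units), ReLU
      → fully connected (8 class scores)

Training minimizes the mean-squared error against one-hot targets,

    J(w, b) = (1/m) Σ_i ½ ‖y⁽ⁱ⁾ − h_{w,b}(x⁽ⁱ⁾)‖²,

by plain mini-batch gradient descent (no momentum, no adaptive rates),
with gradients from backpropagation.  Accuracy is reported as
(1 − ε) × 100 % where ε is the fraction of wrongly classified test
samples.

Everything is implemented directly in numpy: the forward pass, the
backward pass, and the update rule, so the arithmetic is fully
inspectable and checkable against finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split

from .features import STFTFeaturizer
from .preprocess import Epoch, analysis_bandpass

__all__ = ["CNNClassifier", "TrainConfig", "TrainResult", "EvalReport",
           "conv2d_valid", "max_pool_2x2", "forward", "train", "evaluate",
           "predict_epoch", "make_decoder"]


# ---------------------------------------------------------------------------
# numerical primitives

def conv2d_valid(X: np.ndarray, kernels: np.ndarray,
                 bias: np.ndarray) -> np.ndarray:
    """Valid 2-D convolution (correlation) of a batch with 2×2 kernels.

    X : (B, H, W); kernels : (K, kh, kw); bias : (K,)
    returns (B, K, H-kh+1, W-kw+1)
    """
    B, H, W = X.shape
    K, kh, kw = kernels.shape
    U, V = H - kh + 1, W - kw + 1
    out = np.zeros((B, K, U, V), dtype=X.dtype)
    for di in range(kh):
        for dj in range(kw):
            patch = X[:, di:di + U, dj:dj + V]
            out += kernels[:, di, dj][None, :, None, None] * patch[:, None]
    return out + bias[None, :, None, None]


def max_pool_2x2(A: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """2×2 max-pool with stride 2; odd trailing rows/columns are dropped.

    Returns the pooled array and the boolean mask of argmax positions
    (over the cropped region) used for gradient routing.
    """
    B, K, U, V = A.shape
    Uc, Vc = (U // 2) * 2, (V // 2) * 2
    crop = A[:, :, :Uc, :Vc]
    blocks = crop.reshape(B, K, Uc // 2, 2, Vc // 2, 2)
    pooled = blocks.max(axis=(3, 5))
    mask = crop == np.repeat(np.repeat(pooled, 2, axis=2), 2, axis=3)
    return pooled, mask


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0)


def _forward_pass(params: Dict[str, np.ndarray], X: np.ndarray,
                  want_cache: bool = False):
    """Scores for a batch of maps X (B, H, W); optionally the backprop cache."""
    z1 = conv2d_valid(X, params["conv_kernels"], params["conv_bias"])
    a1 = _relu(z1)
    p, mask = max_pool_2x2(a1)
    f = p.reshape(p.shape[0], -1)
    z2 = f @ params["fc1_weights"] + params["fc1_bias"]
    a2 = _relu(z2)
    scores = a2 @ params["fc2_weights"] + params["fc2_bias"]
    if not want_cache:
        return scores
    return scores, {"X": X, "z1": z1, "mask": mask, "pshape": p.shape,
                    "f": f, "z2": z2, "a2": a2}


def _backward_pass(params: Dict[str, np.ndarray], cache: dict,
                   dscores: np.ndarray) -> Dict[str, np.ndarray]:
    """Gradients of the batch loss w.r.t. every parameter."""
    grads: Dict[str, np.ndarray] = {}
    a2, f, z2 = cache["a2"], cache["f"], cache["z2"]
    grads["fc2_weights"] = a2.T @ dscores
    grads["fc2_bias"] = dscores.sum(axis=0)
    dz2 = (dscores @ params["fc2_weights"].T) * (z2 > 0)
    grads["fc1_weights"] = f.T @ dz2
    grads["fc1_bias"] = dz2.sum(axis=0)
    df = dz2 @ params["fc1_weights"].T
    dp = df.reshape(cache["pshape"])
    # route pooled gradients back to the argmax positions
    da1 = np.repeat(np.repeat(dp, 2, axis=2), 2, axis=3) * cache["mask"]
    z1 = cache["z1"]
    B, K, U, V = z1.shape
    dz1 = np.zeros_like(z1)
    dz1[:, :, :da1.shape[2], :da1.shape[3]] = da1
    dz1 *= z1 > 0
    X = cache["X"]
    kh, kw = params["conv_kernels"].shape[1:]
    dk = np.zeros_like(params["conv_kernels"])
    for di in range(kh):
        for dj in range(kw):
            patch = X[:, di:di + U, dj:dj + V]
            dk[:, di, dj] = np.tensordot(dz1, patch, axes=([0, 2, 3], [0, 1, 2]))
    grads["conv_kernels"] = dk
    grads["conv_bias"] = dz1.sum(axis=(0, 2, 3))
    return grads


def mse_loss_and_grad(scores: np.ndarray,
                      targets: np.ndarray) -> Tuple[float, np.ndarray]:
    """Batch loss (1/m) Σ ½‖y − h‖² and its gradient w.r.t. the scores."""
    m = scores.shape[0]
    diff = scores - targets
    loss = 0.5 * float(np.sum(diff * diff)) / m
    return loss, diff / m


# ---------------------------------------------------------------------------
# estimator

class CNNClassifier(BaseEstimator, ClassifierMixin):
    """Small CNN for 8-class SSVEP / blink decoding from power maps.

    Parameters
    ----------
    n_kernels : int
        Number of 2×2 convolution kernels.
    fc1_units : int
        Width of the first fully connected layer.
    learning_rate : float
        Gradient-descent step size α.
    n_epochs : int
        Passes over the training set.
    batch_size : int
        Mini-batch size.
    random_state : int
        Seeds weight initialization and batch shuffling.
    dtype : str
        Parameter/computation dtype ("float32" is ample for training;
        use "float64" for finite-difference gradient checks).

    Attributes
    ----------
    conv_kernels_, conv_bias_, fc1_weights_, fc1_bias_, fc2_weights_,
    fc2_bias_ : ndarray
        Learned parameters.
    classes_ : ndarray
        Sorted class labels.
    loss_history_ : list of float
        Mean per-batch training loss per epoch.
    input_shape_ : tuple
        (n_freq_rows, n_frames) the model was fitted on.
    """

    _PARAM_KEYS = ("conv_kernels", "conv_bias", "fc1_weights", "fc1_bias",
                   "fc2_weights", "fc2_bias")

    def __init__(self, n_kernels: int = 8, fc1_units: int = 64,
                 learning_rate: float = 0.01, n_epochs: int = 50,
                 batch_size: int = 32, random_state: int = 0,
                 dtype: str = "float32"):
        self.n_kernels = n_kernels
        self.fc1_units = fc1_units
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.random_state = random_state
        self.dtype = dtype

    # -- parameter plumbing -------------------------------------------------
    def _params(self) -> Dict[str, np.ndarray]:
        return {k: getattr(self, k + "_") for k in self._PARAM_KEYS}

    def _set_params_arrays(self, params: Dict[str, np.ndarray]) -> None:
        for k in self._PARAM_KEYS:
            setattr(self, k + "_", params[k])

    def _init_params(self, input_shape: Tuple[int, int],
                     n_classes: int) -> Dict[str, np.ndarray]:
        rng = np.random.default_rng(self.random_state)
        H, W = input_shape
        U, V = H - 1, W - 1
        flat = self.n_kernels * (U // 2) * (V // 2)
        dt = np.dtype(self.dtype)

        def uniform(shape, fan_in):
            a = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-a, a, size=shape).astype(dt)

        return {
            "conv_kernels": uniform((self.n_kernels, 2, 2), 4),
            "conv_bias": np.zeros(self.n_kernels, dtype=dt),
            "fc1_weights": uniform((flat, self.fc1_units), flat),
            "fc1_bias": np.zeros(self.fc1_units, dtype=dt),
            "fc2_weights": uniform((self.fc1_units, n_classes), self.fc1_units),
            "fc2_bias": np.zeros(n_classes, dtype=dt),
        }

    def initialize(self, input_shape: Tuple[int, int],
                   classes: Sequence) -> "CNNClassifier":
        """Set seeded random-init weights without training.

        An initialized-but-untrained model is a valid (if useless)
        decoder: it maps any conforming epoch to some label in its class
        space rather than erroring.
        """
        self.classes_ = np.asarray(classes)
        self.input_shape_ = tuple(input_shape)
        self.n_classes_ = int(self.classes_.size)
        self._set_params_arrays(
            self._init_params(self.input_shape_, self.n_classes_))
        self.loss_history_ = []
        return self

    # -- sklearn surface ----------------------------------------------------
    def _validate_X(self, X: np.ndarray, fitted: bool) -> np.ndarray:
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3:
            raise ValueError(f"expected (n, H, W) map stack, got shape {X.shape}")
        if fitted and X.shape[1:] != self.input_shape_:
            raise ValueError(
                f"map shape mismatch: expected {self.input_shape_}, "
                f"got {X.shape[1:]}"
            )
        return X

    def fit(self, X: np.ndarray, y: Sequence) -> "CNNClassifier":
        X = self._validate_X(X, fitted=False)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError(f"{X.shape[0]} maps but {y.shape[0]} labels")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes to train")
        self.input_shape_ = X.shape[1:]
        self.n_classes_ = int(self.classes_.size)
        params = self._init_params(self.input_shape_, self.n_classes_)
        targets = np.eye(self.n_classes_, dtype=self.dtype)[y_idx]
        rng = np.random.default_rng(self.random_state + 1)
        n = X.shape[0]
        self.loss_history_ = []
        for _ in range(self.n_epochs):
            order = rng.permutation(n)
            batch_losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                scores, cache = _forward_pass(params, X[idx], want_cache=True)
                loss, dscores = mse_loss_and_grad(scores, targets[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss ({loss}) at epoch "
                        f"{len(self.loss_history_)}; lower the learning rate"
                    )
                grads = _backward_pass(params, cache, dscores)
                for k in self._PARAM_KEYS:
                    params[k] = params[k] - self.learning_rate * grads[k]
                batch_losses.append(loss)
            self.loss_history_.append(float(np.mean(batch_losses)))
        self._set_params_arrays(params)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = self._validate_X(X, fitted=True)
        return _forward_pass(self._params(), X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]


# ---------------------------------------------------------------------------
# spec-level operations

@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters: α, epochs, batch size, split, seed."""

    learning_rate: float = 0.01
    epochs: int = 50
    batch_size: int = 32
    train_fraction: float = 0.8
    seed: int = 0
    n_kernels: int = 8
    fc1_units: int = 64

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TrainResult:
    model: CNNClassifier
    loss_history: List[float]
    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray


@dataclass
class EvalReport:
    """Test-set error rate ε, accuracy = (1 − ε) × 100 %, and confusion."""

    error_rate: float
    accuracy: float
    confusion: np.ndarray
    classes: np.ndarray
    per_class_accuracy: Dict[str, float]
    n_test: int


def train(maps: np.ndarray, labels: Sequence,
          config: TrainConfig = TrainConfig()) -> TrainResult:
    """Stratified train/test split, then mini-batch gradient descent.

    ``maps`` is an (n, H, W) stack of normalized feature maps.  The split
    is stratified by label with ``config.train_fraction`` (default 80/20)
    and seeded by ``config.seed``; the held-out portion is returned for
    :func:`evaluate`.
    """
    maps = np.asarray(maps)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least two classes to train")
    X_tr, X_te, y_tr, y_te = train_test_split(
        maps, labels, train_size=config.train_fraction,
        stratify=labels, random_state=config.seed)
    model = CNNClassifier(
        n_kernels=config.n_kernels, fc1_units=config.fc1_units,
        learning_rate=config.learning_rate, n_epochs=config.epochs,
        batch_size=config.batch_size, random_state=config.seed)
    model.fit(X_tr, y_tr)
    return TrainResult(model, model.loss_history_, X_tr, y_tr, X_te, y_te)


def evaluate(model: CNNClassifier, X_test: np.ndarray,
             y_test: Sequence) -> EvalReport:
    """Error rate, accuracy, and confusion matrix on a held-out set."""
    y_test = np.asarray(y_test)
    if y_test.size == 0:
        raise ValueError("test set is empty")
    unknown = set(y_test.tolist()) - set(model.classes_.tolist())
    if unknown:
        raise ValueError(f"test labels outside the model's classes: {unknown}")
    pred = model.predict(X_test)
    eps = float(np.mean(pred != y_test))
    conf = confusion_matrix(y_test, pred, labels=model.classes_)
    per_class = {}
    for i, c in enumerate(model.classes_):
        row = conf[i].sum()
        per_class[str(c)] = float(conf[i, i] / row) if row else float("nan")
    return EvalReport(error_rate=eps, accuracy=(1.0 - eps) * 100.0,
                      confusion=conf, classes=model.classes_,
                      per_class_accuracy=per_class, n_test=int(y_test.size))


def forward(model: CNNClassifier, fmap) -> np.ndarray:
    """Raw class-score vector for one feature map (array or FeatureMap)."""
    power = getattr(fmap, "power", fmap)
    return model.decision_function(np.asarray(power)[None])[0]


def make_decoder(model: CNNClassifier, fs: float = 500.0,
                 band: Tuple[float, float] = (5.0, 30.0)):
    """Bind the end-to-end epoch → label pipeline to a trained model.

    Returns a callable ``decoder(epoch) -> label`` performing
    5–30 Hz band-pass → STFT → min-max normalization → CNN argmax.
    """
    featurizer = STFTFeaturizer(fs=fs, band=band)

    def decoder(epoch: Epoch) -> str:
        filtered = analysis_bandpass(epoch, band[0], band[1])
        fmap = featurizer.transform_one(filtered.samples)
        scores = forward(model, fmap)
        return str(model.classes_[int(np.argmax(scores))])

    return decoder


def predict_epoch(model: CNNClassifier, epoch: Epoch) -> str:
    """End-to-end label for one raw epoch (the decoder handed to control)."""
    return make_decoder(model, fs=epoch.fs)(epoch)
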