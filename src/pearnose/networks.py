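"""The four e-nose classifiers: BPNN, ELM, RBF network, and hybrid BP-ELM.

All four consume stable-value feature rows (10 sensor readings) and emit a
browning grade.  They share a tiny dense-layer engine trained with the
package's own Adam implementation on cross-entropy with an L2 weight
penalty:

* :class:`BPNNClassifier` - fully trained multilayer perceptron, default
  hidden widths (21, 43, 87), ReLU hidden units, softmax output.
* :class:`ELMClassifier` - extreme learning machine: one random, fixed
  sigmoid hidden layer (default 500 units) whose output weights ``beta``
  are solved in closed form, ``beta = pinv(H) @ T``.
* :class:`RBFNetClassifier` - Gaussian radial-basis hidden layer with
  k-means centres (default k = 3) and a shared width derived from the
  maximum centre distance; linear + softmax output trained by Adam.
* :class:`BPELMClassifier` - the hybrid: two ReLU layers are pre-trained
  by backprop (through a temporary softmax head), then feed a frozen
  random sigmoid layer whose output weights are solved like an ELM's.
  The learned layers hand the random-feature head a representation in
  which the grades are (nearly) linearly separable, combining backprop's
  feature extraction with the ELM's one-shot convex output fit.

Ties in ``predict`` go to the lowest grade index.  Everything is
deterministic given ``random_state``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .adam import AdamState, adam_step
from .errors import ClusteringError, ConvergenceError
from .data import FeatureTable

__all__ = [
    "Dense", "LayeredNetParams", "TrainConfig",
    "BPNNClassifier", "ELMClassifier", "RBFNetClassifier", "BPELMClassifier",
    "cross_entropy_l2_loss", "rbf_select_k",
    "bpnn_train", "elm_fit", "rbf_fit", "bpelm_train", "net_predict",
    "save_model", "load_model",
]

_ACTIVATIONS = ("relu", "sigmoid", "linear", "softmax")


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _activate(z: np.ndarray, tag: str) -> np.ndarray:
    if tag == "relu":
        return np.maximum(z, 0.0)
    if tag == "sigmoid":
        return expit(z)
    if tag == "linear":
        return z
    if tag == "softmax":
        return softmax(z)
    raise ValueError(f"unknown activation {tag!r}")


def _activation_grad(a: np.ndarray, tag: str) -> np.ndarray:
    """d activation / d pre-activation, expressed through the output a."""
    if tag == "relu":
        return (a > 0).astype(float)
    if tag == "sigmoid":
        return a * (1.0 - a)
    if tag == "linear":
        return np.ones_like(a)
    raise ValueError(f"activation {tag!r} not supported in hidden position")


@dataclass
class Dense:
    """One dense layer: output = activation(X @ W + b)."""

    W: np.ndarray
    b: np.ndarray
    activation: str
    trainable: bool = True

    def __post_init__(self) -> None:
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)


@dataclass
class LayeredNetParams:
    """A stack of dense layers; softmax may only sit at the output."""

    layers: list[Dense] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, (a, b) in enumerate(zip(self.layers, self.layers[1:])):
            if a.W.shape[1] != b.W.shape[0]:
                raise ValueError(
                    f"layer {i} outputs {a.W.shape[1]} units but layer "
                    f"{i + 1} expects {b.W.shape[0]}"
                )
        for layer in self.layers[:-1]:
            if layer.activation == "softmax":
                raise ValueError("softmax is only allowed at the output layer")

    def forward(self, X: np.ndarray) -> list[np.ndarray]:
        """All layer outputs, starting with X itself."""
        acts = [np.asarray(X, dtype=float)]
        for layer in self.layers:
            acts.append(_activate(acts[-1] @ layer.W + layer.b, layer.activation))
        return acts

    def output(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[-1]


def cross_entropy_l2_loss(probs, onehot_labels, weights=None,
                          alpha_r: float = 0.0) -> float:
    """Mean cross-entropy over the batch plus ``alpha_r * sum ||W||_F^2``.

    ``probs`` rows must already be on the probability simplex (to 1e-9);
    probabilities are clipped away from zero so a confident mistake yields
    a large but finite loss.
    """
    probs = np.asarray(probs, dtype=float)
    onehot = np.asarray(onehot_labels, dtype=float)
    if probs.shape != onehot.shape:
        raise ValueError(
            f"probs {probs.shape} and labels {onehot.shape} differ in shape"
        )
    if alpha_r < 0:
        raise ValueError("alpha_r must be >= 0")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("probability rows must sum to 1 (within 1e-9)")
    ce = -(onehot * np.log(np.clip(probs, 1e-12, 1.0))).sum(axis=1).mean()
    penalty = 0.0
    if weights is not None and alpha_r > 0:
        ws = [weights] if isinstance(weights, np.ndarray) else list(weights)
        penalty = alpha_r * float(sum((np.asarray(W) ** 2).sum() for W in ws))
    return float(ce + penalty)


# ---------------------------------------------------------------------------
# dense-net engine


def _init_dense(rng: np.random.Generator, n_in: int, n_out: int,
                activation: str, trainable: bool = True) -> Dense:
    # He init for ReLU, Glorot otherwise
    if activation == "relu":
        scale = np.sqrt(2.0 / n_in)
    else:
        scale = np.sqrt(2.0 / (n_in + n_out))
    return Dense(
        W=rng.normal(0.0, scale, size=(n_in, n_out)),
        b=np.zeros(n_out),
        activation=activation,
        trainable=trainable,
    )


def _backward(layers: list[Dense], acts: list[np.ndarray],
              onehot: np.ndarray, alpha: float) -> list[tuple]:
    """Gradients of CE+L2 w.r.t. every layer's (W, b); output is softmax."""
    n = len(onehot)
    grads: list[tuple] = [None] * len(layers)
    delta = (acts[-1] - onehot) / n  # softmax + cross-entropy
    for i in range(len(layers) - 1, -1, -1):
        gW = acts[i].T @ delta
        if layers[i].trainable and alpha > 0:
            gW = gW + 2.0 * alpha * layers[i].W
        grads[i] = (gW, delta.sum(axis=0))
        if i > 0:
            delta = (delta @ layers[i].W.T) * _activation_grad(
                acts[i], layers[i - 1].activation
            )
    return grads


def _train_layers(layers: list[Dense], X: np.ndarray, Y: np.ndarray, *,
                  epochs: int, batch_size: int | None, alpha: float,
                  lr: float, beta_1: float, beta_2: float, eps: float,
                  rng: np.random.Generator) -> list[float]:
    """Adam-train the trainable layers in place; returns the loss curve."""
    net = LayeredNetParams(layers)  # validates chaining
    t_idx = [i for i, l in enumerate(layers) if l.trainable]
    params = []
    names = []
    for i in t_idx:
        params += [layers[i].W, layers[i].b]
        names += [f"layer {i} weights", f"layer {i} bias"]
    state = AdamState.init(params, lr=lr, beta_1=beta_1, beta_2=beta_2, eps=eps)
    n = len(X)
    loss_curve: list[float] = []
    penalty_ws = lambda: [layers[i].W for i in t_idx]
    for epoch in range(epochs):
        if batch_size is None or batch_size >= n:
            batches = [np.arange(n)]
        else:
            order = rng.permutation(n)
            batches = [order[s:s + batch_size] for s in range(0, n, batch_size)]
        epoch_ce = 0.0
        for idx in batches:
            acts = net.forward(X[idx])
            epoch_ce += -(Y[idx] * np.log(np.clip(acts[-1], 1e-12, 1.0))
                          ).sum() / n
            grads = _backward(layers, acts, Y[idx], alpha)
            flat_g = []
            for i in t_idx:
                flat_g += list(grads[i])
            params, state = adam_step(state, params, flat_g, names)
            for j, i in enumerate(t_idx):
                layers[i].W = params[2 * j]
                layers[i].b = params[2 * j + 1]
        with np.errstate(over="ignore"):  # overflow -> inf -> divergence error
            loss = epoch_ce + (alpha * sum((W ** 2).sum() for W in penalty_ws())
                               if alpha > 0 else 0.0)
        if not np.isfinite(loss):
            raise ConvergenceError(f"non-finite training loss at epoch {epoch}")
        loss_curve.append(float(loss))
    return loss_curve


def _solve_output_weights(H: np.ndarray, T: np.ndarray,
                          ridge: float = 0.0) -> np.ndarray:
    """Least-squares output weights: pinv(H) @ T, or a ridge solve."""
    if ridge > 0:
        k = H.shape[1]
        return np.linalg.solve(H.T @ H + ridge * np.eye(k), H.T @ T)
    return np.linalg.pinv(H) @ T


def _onehot(y_idx: np.ndarray, n_classes: int) -> np.ndarray:
    T = np.zeros((len(y_idx), n_classes))
    T[np.arange(len(y_idx)), y_idx] = 1.0
    return T


# ---------------------------------------------------------------------------
# estimators


class _BaseNetClassifier(ClassifierMixin, BaseEstimator):
    """Shared predict surface: subclasses implement ``_scores``."""

    def _scores(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _prep_fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        self.n_features_in_ = X.shape[1]
        return X.astype(float), y_idx, _onehot(y_idx, len(self.classes_))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = check_array(X)
        # np.argmax resolves ties toward the lowest class index
        return self.classes_[np.argmax(self._scores(X), axis=1)]

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = check_array(X)
        s = self._scores(X)
        if np.allclose(s.sum(axis=1), 1.0, atol=1e-6) and s.min() >= 0:
            return s
        return softmax(s)  # analytic heads emit scores, not probabilities


class BPNNClassifier(_BaseNetClassifier):
    """Backprop multilayer perceptron trained with Adam on CE + L2.

    Defaults mirror the comparator network of the pear study: hidden
    widths (21, 43, 87), ReLU hidden units, softmax output, 8000 epochs of
    full-batch Adam.  Set ``batch_size``/``max_epochs`` down for desk-scale
    runs.
    """

    def __init__(self, hidden_layer_sizes=(21, 43, 87), alpha: float = 1e-4,
                 learning_rate: float = 1e-3, beta_1: float = 0.9,
                 beta_2: float = 0.999, epsilon: float = 1e-8,
                 max_epochs: int = 8000, batch_size: int | None = None,
                 random_state: int | None = None):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.alpha = alpha
        self.learning_rate = learning_rate
        self.beta_1 = beta_1
        self.beta_2 = beta_2
        self.epsilon = epsilon
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def fit(self, X, y) -> "BPNNClassifier":
        X, _, Y = self._prep_fit(X, y)
        rng = np.random.default_rng(self.random_state)
        sizes = [self.n_features_in_, *self.hidden_layer_sizes, Y.shape[1]]
        self.layers_ = [
            _init_dense(rng, sizes[i], sizes[i + 1],
                        "relu" if i < len(sizes) - 2 else "softmax")
            for i in range(len(sizes) - 1)
        ]
        self.loss_curve_ = _train_layers(
            self.layers_, X, Y, epochs=self.max_epochs,
            batch_size=self.batch_size, alpha=self.alpha,
            lr=self.learning_rate, beta_1=self.beta_1, beta_2=self.beta_2,
            eps=self.epsilon, rng=rng,
        )
        self.n_iter_ = self.max_epochs
        return self

    @property
    def net_(self) -> LayeredNetParams:
        check_is_fitted(self)
        return LayeredNetParams(self.layers_)

    def _scores(self, X):
        return self.net_.output(X)


class ELMClassifier(_BaseNetClassifier):
    """Extreme learning machine: random sigmoid hidden layer, analytic head.

    Hidden weights and biases are drawn once from U(-1, 1) and never
    updated; the output weights solve ``min_beta ||H beta - T||_F`` via the
    Moore-Penrose pseudoinverse (or a ridge-regularised normal-equation
    solve when ``ridge > 0``).  Default width 500 sigmoid units.
    """

    def __init__(self, n_hidden: int = 500, ridge: float = 0.0,
                 random_state: int | None = None):
        self.n_hidden = n_hidden
        self.ridge = ridge
        self.random_state = random_state

    def fit(self, X, y) -> "ELMClassifier":
        X, _, T = self._prep_fit(X, y)
        if len(X) < T.shape[1]:
            raise ValueError(
                f"need at least {T.shape[1]} rows (one per class); got {len(X)}"
            )
        rng = np.random.default_rng(self.random_state)
        self.hidden_weights_ = rng.uniform(-1, 1, (self.n_features_in_, self.n_hidden))
        self.hidden_bias_ = rng.uniform(-1, 1, self.n_hidden)
        H = expit(X @ self.hidden_weights_ + self.hidden_bias_)
        if np.any(H.std(axis=0) < 1e-12):
            warnings.warn(
                "hidden layer has constant columns; least-squares solution "
                "may be ill-conditioned", RuntimeWarning,
            )
        self.beta_ = _solve_output_weights(H, T, self.ridge)
        return self

    def _scores(self, X):
        return expit(X @ self.hidden_weights_ + self.hidden_bias_) @ self.beta_


def rbf_select_k(X, k_max: int, seed: int | None = None,
                 n_init: int = 10) -> tuple[int, np.ndarray]:
    """k-means SSE curve for k = 1..k_max plus the elbow choice.

    SSE(k) is the within-cluster sum of squared distances to the cluster
    means.  The elbow is the k whose relative drop SSE(k-1)/SSE(k) is
    largest - past the true cluster count the curve flattens, so the
    largest ratio sits at the knee.  A degenerate all-identical input has
    SSE identically zero and returns k = 1.
    """
    X = check_array(X)
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    n_distinct = len(np.unique(X, axis=0))
    if n_distinct == 1:
        return 1, np.zeros(k_max)
    if n_distinct < k_max:
        raise ClusteringError(
            f"only {n_distinct} distinct points; cannot form up to {k_max} clusters"
        )
    sse = np.empty(k_max)
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        sse[k - 1] = km.inertia_
    floor = 1e-12 * max(sse[0], 1.0)
    ratios = sse[:-1] / np.maximum(sse[1:], floor)
    elbow = int(np.argmax(ratios)) + 2  # ratios[j] compares k=j+1 -> k=j+2
    return elbow, sse


class RBFNetClassifier(_BaseNetClassifier):
    """Gaussian RBF network with k-means centres.

    Hidden unit i computes ``exp(-||x - c_i||^2 / (2 width^2))``.  The
    shared width comes from the maximum centre distance mu_max:
    ``mu_max / sqrt(2k)`` (classical heuristic, default) or ``mu_max / k``
    (``width_mode="paper"``).  With a single centre mu_max is undefined and
    an explicit ``width`` is required.  The linear + softmax output layer
    is Adam-trained on cross-entropy (``output_solver="lstsq"`` swaps in a
    one-shot least-squares fit).
    """

    def __init__(self, n_centers: int = 3, width: float | None = None,
                 width_mode: str = "classical", output_solver: str = "adam",
                 alpha: float = 1e-4, learning_rate: float = 1e-3,
                 max_epochs: int = 8000, batch_size: int | None = None,
                 random_state: int | None = None):
        self.n_centers = n_centers
        self.width = width
        self.width_mode = width_mode
        self.output_solver = output_solver
        self.alpha = alpha
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        d2 = cdist(X, self.centers_, "sqeuclidean")
        return np.exp(-d2 / (2.0 * self.width_ ** 2))

    def fit(self, X, y) -> "RBFNetClassifier":
        if self.width_mode not in ("classical", "paper"):
            raise ValueError("width_mode must be 'classical' or 'paper'")
        X, _, Y = self._prep_fit(X, y)
        k = self.n_centers
        if k < 1:
            raise ValueError("n_centers must be >= 1")
        if len(np.unique(X, axis=0)) < k:
            raise ClusteringError(
                f"fewer than {k} distinct points; cannot place {k} centres"
            )
        km = KMeans(n_clusters=k, n_init=10, random_state=self.random_state).fit(X)
        self.centers_ = km.cluster_centers_
        if self.width is not None:
            self.width_ = float(self.width)
        elif k == 1:
            raise ValueError(
                "with a single centre the maximum centre distance is "
                "undefined; pass an explicit width"
            )
        else:
            mu_max = float(pdist(self.centers_).max())
            self.width_ = (mu_max / np.sqrt(2.0 * k)
                           if self.width_mode == "classical" else mu_max / k)
        if self.width_ <= 0:
            raise ValueError("width must be > 0")

        Phi = self._hidden(X)
        rng = np.random.default_rng(self.random_state)
        if self.output_solver == "adam":
            self.output_layers_ = [_init_dense(rng, k, Y.shape[1], "softmax")]
            self.loss_curve_ = _train_layers(
                self.output_layers_, Phi, Y, epochs=self.max_epochs,
                batch_size=self.batch_size, alpha=self.alpha,
                lr=self.learning_rate, beta_1=0.9, beta_2=0.999, eps=1e-8,
                rng=rng,
            )
        elif self.output_solver == "lstsq":
            beta = _solve_output_weights(Phi, Y)
            self.output_layers_ = [Dense(beta, np.zeros(Y.shape[1]), "softmax")]
            self.loss_curve_ = []
        else:
            raise ValueError("output_solver must be 'adam' or 'lstsq'")
        return self

    def _scores(self, X):
        return LayeredNetParams(self.output_layers_).output(self._hidden(X))


class BPELMClassifier(_BaseNetClassifier):
    """Hybrid backprop + ELM classifier.

    Training proceeds in four steps: (1) two ReLU layers plus a temporary
    softmax head are trained by Adam on CE + L2; (2) the head is discarded
    and a frozen random sigmoid layer (U(-1, 1) weights, default 500
    units) is appended; (3) the output weights ``beta`` are solved by
    least squares on that layer's training output; (4) prediction is
    ``argmax(O_dense3 @ beta)``.  ``pretrain_mode="through-frozen"``
    instead creates the frozen layer first and backpropagates through it
    during step 1.
    """

    def __init__(self, hidden_layer_sizes=(43, 87), n_random_hidden: int = 500,
                 alpha: float = 1e-4, learning_rate: float = 1e-3,
                 beta_1: float = 0.9, beta_2: float = 0.999,
                 epsilon: float = 1e-8, max_epochs: int = 8000,
                 batch_size: int | None = None, ridge: float = 0.0,
                 pretrain_mode: str = "softmax-head",
                 random_state: int | None = None):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.n_random_hidden = n_random_hidden
        self.alpha = alpha
        self.learning_rate = learning_rate
        self.beta_1 = beta_1
        self.beta_2 = beta_2
        self.epsilon = epsilon
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.ridge = ridge
        self.pretrain_mode = pretrain_mode
        self.random_state = random_state

    def fit(self, X, y) -> "BPELMClassifier":
        if self.pretrain_mode not in ("softmax-head", "through-frozen"):
            raise ValueError(
                "pretrain_mode must be 'softmax-head' or 'through-frozen'"
            )
        X, _, T = self._prep_fit(X, y)
        rng = np.random.default_rng(self.random_state)
        n_classes = T.shape[1]
        sizes = [self.n_features_in_, *self.hidden_layer_sizes]
        bp_layers = [_init_dense(rng, sizes[i], sizes[i + 1], "relu")
                     for i in range(len(sizes) - 1)]
        h_out = sizes[-1]

        def make_random_layer() -> Dense:
            return Dense(
                W=rng.uniform(-1, 1, (h_out, self.n_random_hidden)),
                b=rng.uniform(-1, 1, self.n_random_hidden),
                activation="sigmoid",
                trainable=False,
            )

        if self.pretrain_mode == "softmax-head":
            head = _init_dense(rng, h_out, n_classes, "softmax")
            stack = [*bp_layers, head]
            random_layer = None
        else:
            random_layer = make_random_layer()
            head = _init_dense(rng, self.n_random_hidden, n_classes, "softmax")
            stack = [*bp_layers, random_layer, head]
        self.loss_curve_ = _train_layers(
            stack, X, T, epochs=self.max_epochs, batch_size=self.batch_size,
            alpha=self.alpha, lr=self.learning_rate, beta_1=self.beta_1,
            beta_2=self.beta_2, eps=self.epsilon, rng=rng,
        )
        if random_layer is None:
            random_layer = make_random_layer()
        self.random_hidden_init_ = (random_layer.W.copy(), random_layer.b.copy())
        self.layers_ = [*bp_layers, random_layer]
        O3 = LayeredNetParams(self.layers_).output(X)
        self.beta_ = _solve_output_weights(O3, T, self.ridge)
        self.n_iter_ = self.max_epochs
        return self

    def _scores(self, X):
        return LayeredNetParams(self.layers_).output(X) @ self.beta_


# ---------------------------------------------------------------------------
# functional wrappers


@dataclass
class TrainConfig:
    """Gradient-training knobs shared by the trained networks.

    ``epochs`` defaults to the study's 8000; desk-scale runs override it.
    ``l2`` is the regularisation coefficient of the loss; ``hidden_layer_sizes``
    drives the BPNN, ``bp_hidden_sizes``/``n_random_hidden`` the hybrid.
    """

    epochs: int = 8000
    batch_size: int | None = None
    l2: float = 1e-4
    learning_rate: float = 1e-3
    beta_1: float = 0.9
    beta_2: float = 0.999
    epsilon: float = 1e-8
    seed: int = 0
    hidden_layer_sizes: tuple[int, ...] = (21, 43, 87)
    bp_hidden_sizes: tuple[int, ...] = (43, 87)
    n_random_hidden: int = 500
    ridge: float = 0.0
    pretrain_mode: str = "softmax-head"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.l2 < 0:
            raise ValueError("l2 must be >= 0")
        if any(s < 1 for s in (*self.hidden_layer_sizes, *self.bp_hidden_sizes,
                               self.n_random_hidden)):
            raise ValueError("layer sizes must be positive")


def bpnn_train(table: FeatureTable, config: TrainConfig) -> BPNNClassifier:
    return BPNNClassifier(
        hidden_layer_sizes=config.hidden_layer_sizes, alpha=config.l2,
        learning_rate=config.learning_rate, beta_1=config.beta_1,
        beta_2=config.beta_2, epsilon=config.epsilon,
        max_epochs=config.epochs, batch_size=config.batch_size,
        random_state=config.seed,
    ).fit(table.X, table.y)


def bpelm_train(table: FeatureTable, config: TrainConfig) -> BPELMClassifier:
    return BPELMClassifier(
        hidden_layer_sizes=config.bp_hidden_sizes,
        n_random_hidden=config.n_random_hidden, alpha=config.l2,
        learning_rate=config.learning_rate, beta_1=config.beta_1,
        beta_2=config.beta_2, epsilon=config.epsilon,
        max_epochs=config.epochs, batch_size=config.batch_size,
        ridge=config.ridge, pretrain_mode=config.pretrain_mode,
        random_state=config.seed,
    ).fit(table.X, table.y)


def elm_fit(X, labels, n_hidden: int = 500, seed: int | None = None,
            ridge: float = 0.0) -> ELMClassifier:
    return ELMClassifier(n_hidden=n_hidden, ridge=ridge,
                         random_state=seed).fit(X, labels)


def rbf_fit(X, labels, k: int = 3, seed: int | None = None,
            **kwargs) -> RBFNetClassifier:
    return RBFNetClassifier(n_centers=k, random_state=seed, **kwargs).fit(X, labels)


def net_predict(model, X) -> tuple[np.ndarray, np.ndarray]:
    """Labels and class probabilities from any fitted classifier."""
    return model.predict(X), model.predict_proba(X)


# ---------------------------------------------------------------------------
# JSON serialisation (CLI model files)

_MODEL_CLASSES: dict[str, type] = {}


def _register(cls):
    _MODEL_CLASSES[cls.__name__] = cls
    return cls


for _c in (BPNNClassifier, ELMClassifier, RBFNetClassifier, BPELMClassifier):
    _register(_c)


def _layer_state(layer: Dense) -> dict:
    return {"W": layer.W.tolist(), "b": layer.b.tolist(),
            "activation": layer.activation, "trainable": layer.trainable}


def _layer_from_state(d: dict) -> Dense:
    return Dense(W=np.asarray(d["W"]), b=np.asarray(d["b"]),
                 activation=d["activation"], trainable=d["trainable"])


def save_model(model, path) -> None:
    """Serialise a fitted classifier (architecture + weights) to JSON."""
    check_is_fitted(model)
    params = {}
    for key, val in model.get_params().items():
        params[key] = list(val) if isinstance(val, tuple) else val
    fitted: dict = {
        "classes_": model.classes_.tolist(),
        "n_features_in_": int(model.n_features_in_),
    }
    for name in ("layers_", "output_layers_"):
        if hasattr(model, name):
            fitted[name] = [_layer_state(l) for l in getattr(model, name)]
    for name in ("hidden_weights_", "hidden_bias_", "beta_", "centers_"):
        if hasattr(model, name):
            fitted[name] = getattr(model, name).tolist()
    for name in ("width_", "loss_curve_"):
        if hasattr(model, name):
            fitted[name] = getattr(model, name)
    state = {"model": type(model).__name__, "params": params, "fitted": fitted}
    with open(path, "w") as fh:
        json.dump(state, fh, sort_keys=True)


def load_model(path):
    """Rebuild a classifier saved by :func:`save_model`."""
    with open(path) as fh:
        state = json.load(fh)
    cls = _MODEL_CLASSES.get(state.get("model"))
    if cls is None:
        raise ValueError(f"unknown model class {state.get('model')!r}")
    params = {
        k: tuple(v) if isinstance(v, list) else v
        for k, v in state["params"].items()
    }
    model = cls(**params)
    fitted = state["fitted"]
    model.classes_ = np.asarray(fitted["classes_"])
    model.n_features_in_ = fitted["n_features_in_"]
    for name in ("layers_", "output_layers_"):
        if name in fitted:
            setattr(model, name, [_layer_from_state(d) for d in fitted[name]])
    for name in ("hidden_weights_", "hidden_bias_", "beta_", "centers_"):
        if name in fitted:
            setattr(model, name, np.asarray(fitted[name], dtype=float))
    for name in ("width_", "loss_curve_"):
        if name in fitted:
            setattr(model, name, fitted[name])
    return model
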