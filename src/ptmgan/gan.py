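"""Class-conditional generative augmentation for imbalanced tabular data.

Two conditional adversarial generators balance the modification classes by
synthesizing feature rows for the minority classes up to the majority count:

* ``cgan`` — conditional GAN: discriminator with a sigmoid output trained on
  the log-loss, Adam optimizer.
* ``cwgan`` — conditional Wasserstein GAN: the critic's output sigmoid is
  removed and the logarithms dropped, the loss becomes the difference of
  critic expectations between real and generated rows, every critic weight is
  clipped to ``[-c, c]`` after each critic update, the optimizer is RMSProp,
  and the critic takes ``n_critic`` steps per generator step.

Both condition the generator and the discriminator/critic on the class label
as a one-hot vector appended to their inputs. Features are min-max scaled to
``[-1, 1]`` (fitted on the real rows) so a tanh generator output covers the
data range; generated rows are inverse-scaled back to feature space.

The networks are small fully-connected NumPy models with hand-written
backpropagation and optimizers, which keeps the package dependency-light and
the training loop transparent for testing (e.g. the clip bound is asserted
after every critic step).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


def _leaky_relu(a: np.ndarray, slope: float = 0.2) -> np.ndarray:
    return np.where(a > 0, a, slope * a)


def _leaky_relu_grad(a: np.ndarray, slope: float = 0.2) -> np.ndarray:
    return np.where(a > 0, 1.0, slope)


def _softplus(t: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, t)


def _sigmoid(t: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * t))


class _MLP:
    """Fully-connected net, leaky-ReLU hidden layers, configurable output."""

    def __init__(self, sizes: Sequence[int], out_activation: Optional[str], rng):
        self.out_activation = out_activation
        self.W = []
        self.b = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            bound = np.sqrt(2.0 / fan_in)
            self.W.append(rng.normal(0.0, bound, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self._cache = None

    @property
    def params(self) -> list:
        return self.W + self.b

    def forward(self, x: np.ndarray) -> np.ndarray:
        acts = [x]
        pre = []
        h = x
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            a = h @ W + b
            pre.append(a)
            if i < len(self.W) - 1:
                h = _leaky_relu(a)
            elif self.out_activation == "tanh":
                h = np.tanh(a)
            else:  # linear output; sigmoid losses work on the raw logit
                h = a
            acts.append(h)
        self._cache = (acts, pre)
        return h

    def backward(self, dout: np.ndarray):
        """Backprop ``dL/d(output)``; returns (param gradients, dL/d(input))."""
        acts, pre = self._cache
        grads_W = [None] * len(self.W)
        grads_b = [None] * len(self.b)
        delta = dout
        for i in reversed(range(len(self.W))):
            if i < len(self.W) - 1:
                delta = delta * _leaky_relu_grad(pre[i])
            elif self.out_activation == "tanh":
                delta = delta * (1.0 - np.tanh(pre[i]) ** 2)
            grads_W[i] = acts[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            delta = delta @ self.W[i].T
        return grads_W + grads_b, delta

    def clip_(self, c: float) -> None:
        for p in self.params:
            np.clip(p, -c, c, out=p)

    def max_abs_weight(self) -> float:
        return max(float(np.abs(p).max()) for p in self.params)


class _Adam:
    def __init__(self, params, lr, beta1=0.5, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _RMSProp:
    def __init__(self, params, lr, decay=0.9, eps=1e-8):
        self.lr, self.decay, self.eps = lr, decay, eps
        self.cache = [np.zeros_like(p) for p in params]

    def step(self, params, grads):
        for p, g, c in zip(params, grads, self.cache):
            c *= self.decay
            c += (1 - self.decay) * g * g
            p -= self.lr * g / (np.sqrt(c) + self.eps)


@dataclass
class GanConfig:
    """Training configuration shared by the CGAN and CWGAN trainers.

    Defaults follow common practice for weight-clipped Wasserstein training
    (clip 0.01, RMSProp at 5e-5, five critic steps per generator step); the
    production iteration count is 50,000 but toy runs use far fewer.
    """

    noise_dim: int = 100
    gen_hidden: tuple = (256, 512)
    critic_hidden: tuple = (512, 256)
    learning_rate: Optional[float] = None  # method default: Adam 2e-4 / RMSProp 5e-5
    clip: float = 0.01
    n_critic: int = 5
    iterations: int = 50_000
    batch_size: int = 64
    per_class: bool = False
    balanced_batches: bool = True
    seed: int = 0
    critic_callback: Optional[object] = None  # called with the critic after each update

    def __post_init__(self):
        if self.clip <= 0:
            raise ValueError("clip bound must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class LossTrace:
    """Per-iteration generator (Gloss) and discriminator/critic (Dloss) losses."""

    g_loss: np.ndarray
    d_loss: np.ndarray

    def __post_init__(self):
        self.g_loss = np.asarray(self.g_loss, dtype=float)
        self.d_loss = np.asarray(self.d_loss, dtype=float)
        if self.g_loss.shape != self.d_loss.shape:
            raise ValueError("loss traces must have equal length")

    def __len__(self) -> int:
        return len(self.g_loss)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"iteration": np.arange(1, len(self) + 1), "Gloss": self.g_loss, "Dloss": self.d_loss}
        ).to_csv(path, index=False)


@dataclass
class _MinMaxScaler:
    """Min-max map of each feature onto [-1, 1]; constant columns map to 0."""

    lo: np.ndarray
    span: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "_MinMaxScaler":
        lo = X.min(axis=0)
        span = X.max(axis=0) - lo
        span[span == 0] = 1.0  # constant column: transforms to -1... see transform
        return cls(lo, span)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return 2.0 * (X - self.lo) / self.span - 1.0

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return (Z + 1.0) * self.span / 2.0 + self.lo


@dataclass
class GanModelPair:
    """Trained conditional generator + discriminator/critic with context."""

    method: str
    generator: _MLP
    discriminator: _MLP
    config: GanConfig
    classes: np.ndarray
    scaler: _MinMaxScaler
    trace: LossTrace
    n_features: int

    def one_hot(self, labels: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.classes, labels)
        if (idx >= len(self.classes)).any() or not np.array_equal(
            self.classes[idx], labels
        ):
            raise ValueError("unknown class label")
        out = np.zeros((len(labels), len(self.classes)))
        out[np.arange(len(labels)), idx] = 1.0
        return out


@dataclass
class SyntheticBatch:
    """Generated feature rows, all flagged synthetic."""

    X: np.ndarray
    label: int
    synthetic: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.synthetic is None:
            self.synthetic = np.ones(len(self.X), dtype=bool)


def compute_deficits(counts: Sequence[int]) -> np.ndarray:
    """Per-class shortfall relative to the largest class."""
    counts = np.asarray(counts, dtype=int)
    if (counts < 1).any():
        raise ValueError("class counts must be >= 1")
    return counts.max() - counts


def _train(X, labels, config: GanConfig, method: str) -> GanModelPair:
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    K = len(classes)
    n, d = X.shape
    rng = np.random.default_rng(config.seed)
    scaler = _MinMaxScaler.fit(X)
    Z = scaler.transform(X)
    onehot = np.zeros((n, K))
    onehot[np.arange(n), np.searchsorted(classes, labels)] = 1.0

    gen = _MLP((config.noise_dim + K, *config.gen_hidden, d), "tanh", rng)
    wgan = method == "cwgan"
    disc = _MLP((d + K, *config.critic_hidden, 1), None, rng)
    lr = config.learning_rate or (5e-5 if wgan else 2e-4)
    if wgan:
        opt_d: object = _RMSProp(disc.params, lr)
        opt_g: object = _RMSProp(gen.params, lr)
    else:
        opt_d = _Adam(disc.params, lr)
        opt_g = _Adam(gen.params, lr)

    bs = min(config.batch_size, n)
    g_trace = np.empty(config.iterations)
    d_trace = np.empty(config.iterations)

    class_rows = [np.flatnonzero(labels == c) for c in classes]

    def real_batch():
        if config.balanced_batches:
            # draw the conditioning class uniformly so minority conditionals
            # receive as much generator/critic exposure as the majority
            cls_draw = rng.integers(0, K, size=bs)
            idx = np.array(
                [class_rows[c][rng.integers(0, len(class_rows[c]))] for c in cls_draw]
            )
        else:
            idx = rng.integers(0, n, size=bs)
        return Z[idx], onehot[idx]

    n_critic = config.n_critic if wgan else 1
    for it in range(config.iterations):
        for _ in range(n_critic):
            xr, yr = real_batch()
            z = rng.standard_normal((bs, config.noise_dim))
            xf = gen.forward(np.hstack([z, yr]))
            t_real = disc.forward(np.hstack([xr, yr]))
            if wgan:
                d_real_grad = -np.ones_like(t_real) / bs
            else:
                d_real_grad = (_sigmoid(t_real) - 1.0) / bs
            g_real, _ = disc.backward(d_real_grad)
            t_fake = disc.forward(np.hstack([xf, yr]))
            if wgan:
                d_fake_grad = np.ones_like(t_fake) / bs
                d_loss = float(t_fake.mean() - t_real.mean())
            else:
                d_fake_grad = _sigmoid(t_fake) / bs
                d_loss = float(
                    _softplus(-t_real).mean() + _softplus(t_fake).mean()
                )
            g_fake, _ = disc.backward(d_fake_grad)
            opt_d.step(disc.params, [a + b for a, b in zip(g_real, g_fake)])
            if wgan:
                disc.clip_(config.clip)
            if config.critic_callback is not None:
                config.critic_callback(disc)
        # generator step
        _, yr = real_batch()
        z = rng.standard_normal((bs, config.noise_dim))
        gen_in = np.hstack([z, yr])
        xf = gen.forward(gen_in)
        t_fake = disc.forward(np.hstack([xf, yr]))
        if wgan:
            g_loss = float(-t_fake.mean())
            dL_dt = -np.ones_like(t_fake) / bs
        else:
            # minimize log(1 - D(G(z|y)))
            g_loss = float(-_softplus(t_fake).mean())
            dL_dt = -_sigmoid(t_fake) / bs
        _, dx = disc.backward(dL_dt)
        gen_grads, _ = gen.backward(dx[:, :xf.shape[1]])
        opt_g.step(gen.params, gen_grads)
        if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
            raise RuntimeError(
                f"non-finite loss at iteration {it + 1} "
                f"(Gloss={g_loss}, Dloss={d_loss}); lower the learning rate"
            )
        g_trace[it] = g_loss
        d_trace[it] = d_loss

    return GanModelPair(
        method, gen, disc, config, classes, scaler, LossTrace(g_trace, d_trace), d
    )


def train_cgan(X, labels, config: Optional[GanConfig] = None) -> GanModelPair:
    """Train a conditional GAN (sigmoid discriminator, log-loss, Adam)."""
    return _train(X, labels, config or GanConfig(), "cgan")


def train_cwgan(X, labels, config: Optional[GanConfig] = None) -> GanModelPair:
    """Train a conditional Wasserstein GAN (clipped linear critic, RMSProp)."""
    return _train(X, labels, config or GanConfig(), "cwgan")


def generate(model: GanModelPair, class_label, n: int, seed: int = 0) -> SyntheticBatch:
    """Sample ``n`` rows of a class from the trained generator."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return SyntheticBatch(np.empty((0, model.n_features)), class_label)
    rng = np.random.default_rng(seed)
    y = model.one_hot(np.repeat(class_label, n))
    z = rng.standard_normal((n, model.config.noise_dim))
    out = model.generator.forward(np.hstack([z, y]))
    return SyntheticBatch(model.scaler.inverse(out), class_label)


def augment_dataset(
    X,
    labels,
    method: str = "cwgan",
    config: Optional[GanConfig] = None,
):
    """Balance all classes up to the majority count with synthetic rows.

    Returns ``(X_aug, labels_aug, synthetic_mask, model)`` where the first
    ``len(X)`` rows are the untouched real rows; ``model`` is None when the
    input was already balanced (nothing is trained).
    """
    if method not in ("cgan", "cwgan"):
        raise ValueError(f"unknown augmentation method {method!r}")
    config = config or GanConfig()
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("augmentation needs at least two classes")
    deficits = compute_deficits(counts)
    if not deficits.any():
        return X.copy(), labels.copy(), np.zeros(len(X), dtype=bool), None

    trainer = train_cwgan if method == "cwgan" else train_cgan
    if config.per_class:
        models = {}
        for cls, deficit in zip(classes, deficits):
            if deficit:
                sub = labels == cls
                models[cls] = trainer(X[sub], labels[sub], config)
        model = None
    else:
        model = trainer(X, labels, config)

    parts_X, parts_y = [X], [labels]
    for j, (cls, deficit) in enumerate(zip(classes, deficits)):
        if deficit == 0:
            continue
        src = models[cls] if config.per_class else model
        batch = generate(src, cls, int(deficit), seed=config.seed + 1 + j)
        parts_X.append(batch.X)
        parts_y.append(np.repeat(cls, deficit))
    X_aug = np.vstack(parts_X)
    labels_aug = np.concatenate(parts_y)
    synthetic = np.zeros(len(X_aug), dtype=bool)
    synthetic[len(X):] = True
    return X_aug, labels_aug, synthetic, model


def mean_distance(real_rows: np.ndarray, synthetic_rows: np.ndarray) -> float:
    """Euclidean distance between the column-mean of real and synthetic rows."""
    real_rows = np.asarray(real_rows, dtype=float)
    synthetic_rows = np.asarray(synthetic_rows, dtype=float)
    if real_rows.size == 0 or synthetic_rows.size == 0:
        raise ValueError("both row sets must be non-empty")
    if real_rows.shape[1] != synthetic_rows.shape[1]:
        raise ValueError("feature widths differ")
    return float(
        np.linalg.norm(real_rows.mean(axis=0) - synthetic_rows.mean(axis=0))
    )
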