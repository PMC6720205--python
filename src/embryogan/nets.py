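"""Dense generator/discriminator networks and their primitives.

Both networks are fully connected and written directly in NumPy with
analytic gradients, so every building block — LeakyReLU, batch
normalization with running statistics, sigmoid/tanh heads, binary
cross-entropy — is an explicit, testable function rather than a
framework call.

Discriminator (6 layers): flatten -> dense -> LeakyReLU(0.2) -> dense
-> LeakyReLU(0.2) -> dense(1) + sigmoid, emitting the probability that
the input frame is real.  Generator (11 layers): a 100-value latent
vector -> [dense -> LeakyReLU(0.2) -> batch-norm(momentum 0.8)] x3 ->
dense(side^2) with a tanh head -> reshape to a side x side frame in
[-1, 1].  Layer widths default to the canonical dense-GAN ladder
(256/512/1024 up, 512/256 down) and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "leaky_relu",
    "leaky_relu_grad",
    "sigmoid",
    "bce_loss",
    "BatchNormState",
    "batch_norm_forward",
    "batch_norm_backward",
    "DiscriminatorSpec",
    "GeneratorSpec",
    "Discriminator",
    "Generator",
    "discriminator_forward",
    "generator_forward",
    "BCE_EPS",
]

#: Probability clipping floor inside the cross-entropy (Keras convention).
BCE_EPS = 1e-7

WEIGHT_INIT_STD = 0.02  # DCGAN-style normal(0, 0.02) initialization


def leaky_relu(x, alpha: float = 0.2):
    """max(x, 0) + alpha * min(x, 0), elementwise."""
    x = np.asarray(x, dtype=np.float64)
    return np.maximum(x, 0.0) + alpha * np.minimum(x, 0.0)


def leaky_relu_grad(x, alpha: float = 0.2):
    """Derivative of :func:`leaky_relu`; the subgradient at 0 is taken as alpha."""
    x = np.asarray(x, dtype=np.float64)
    return np.where(x > 0.0, 1.0, alpha)


def sigmoid(x):
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_loss(y, y_hat, eps: float = BCE_EPS) -> float:
    """Mean binary cross-entropy -(1/N) sum[y log p + (1-y) log(1-p)].

    Probabilities are clipped to [eps, 1-eps] before the logs, so the loss
    is finite for saturated predictions.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    p = np.asarray(y_hat, dtype=np.float64).ravel()
    if y.size == 0:
        raise ValueError("empty input")
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {p.shape}")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


# ---------------------------------------------------------------------------
# batch normalization
# ---------------------------------------------------------------------------

@dataclass
class BatchNormState:
    """Learned scale/shift plus running statistics for one batch-norm layer.

    In training mode the layer standardizes with the current batch mean and
    (biased) variance and folds those statistics into the running averages,
    ``running <- momentum * running + (1 - momentum) * batch``; inference
    mode standardizes with the running averages.  Scale and shift start at
    identity, so at initialization the forward map is plain standardization.
    """

    gamma: np.ndarray
    beta: np.ndarray
    running_mean: np.ndarray
    running_var: np.ndarray
    momentum: float = 0.8
    eps: float = 1e-5

    @classmethod
    def initial(cls, width: int, momentum: float = 0.8, eps: float = 1e-5) -> "BatchNormState":
        if not 0.0 <= momentum <= 1.0:
            raise ValueError("momentum must lie in [0, 1]")
        if eps <= 0:
            raise ValueError("eps must be positive")
        return cls(
            gamma=np.ones(width), beta=np.zeros(width),
            running_mean=np.zeros(width), running_var=np.ones(width),
            momentum=momentum, eps=eps,
        )


def batch_norm_forward(batch: np.ndarray, state: BatchNormState, training: bool):
    """Normalize a (N, width) batch of activations.

    Returns ``(out, cache)``; the cache holds what the backward pass needs
    and is ``None`` in inference mode.  Training mode requires N >= 2 and
    updates the running statistics in place.
    """
    x = np.asarray(batch, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError(f"expected (N, width) activations, got shape {x.shape}")
    if training:
        if x.shape[0] < 2:
            raise ValueError("training-mode batch norm needs batch size >= 2")
        mu = x.mean(axis=0)
        var = x.var(axis=0)  # biased, matches the per-batch standardization
        inv_std = 1.0 / np.sqrt(var + state.eps)
        x_hat = (x - mu) * inv_std
        m = state.momentum
        state.running_mean[...] = m * state.running_mean + (1.0 - m) * mu
        state.running_var[...] = m * state.running_var + (1.0 - m) * var
        cache = (x_hat, inv_std, state.gamma.copy())
    else:
        inv_std = 1.0 / np.sqrt(state.running_var + state.eps)
        x_hat = (x - state.running_mean) * inv_std
        cache = None
    return state.gamma * x_hat + state.beta, cache


def batch_norm_backward(dout: np.ndarray, cache):
    """Gradients of the training-mode forward pass: returns (dx, dgamma, dbeta)."""
    x_hat, inv_std, gamma = cache
    n = x_hat.shape[0]
    dgamma = (dout * x_hat).sum(axis=0)
    dbeta = dout.sum(axis=0)
    dxhat = dout * gamma
    dx = inv_std * (dxhat - dxhat.mean(axis=0) - x_hat * (dxhat * x_hat).mean(axis=0))
    # the mean/var terms contribute the two subtracted means; n>=2 guaranteed
    assert n >= 2
    return dx, dgamma, dbeta


# ---------------------------------------------------------------------------
# network specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscriminatorSpec:
    """Layer stack of the real/fake classifier."""

    input_side: int = 200
    widths: tuple[int, ...] = (512, 256)
    alpha: float = 0.2

    @property
    def input_dim(self) -> int:
        return self.input_side * self.input_side

    def layer_dims(self) -> list[tuple[int, int]]:
        dims = [self.input_dim, *self.widths, 1]
        return list(zip(dims[:-1], dims[1:]))

    def param_count(self) -> int:
        return sum(din * dout + dout for din, dout in self.layer_dims())

    def describe(self) -> list[str]:
        layers = ["flatten"]
        for w in self.widths:
            layers += [f"dense({w})", f"leaky_relu({self.alpha})"]
        layers += ["dense(1, sigmoid)"]
        return layers


@dataclass(frozen=True)
class GeneratorSpec:
    """Layer stack of the latent-to-image network."""

    latent_dim: int = 100
    widths: tuple[int, ...] = (256, 512, 1024)
    output_side: int = 200
    alpha: float = 0.2
    bn_momentum: float = 0.8
    bn_eps: float = 1e-5
    output_activation: str = "tanh"  # or "sigmoid", paired with [0,1] scaling

    @property
    def output_dim(self) -> int:
        return self.output_side * self.output_side

    def layer_dims(self) -> list[tuple[int, int]]:
        dims = [self.latent_dim, *self.widths, self.output_dim]
        return list(zip(dims[:-1], dims[1:]))

    def param_count(self) -> int:
        dense = sum(din * dout + dout for din, dout in self.layer_dims())
        bn = sum(2 * w for w in self.widths)  # scale + shift per hidden layer
        return dense + bn

    def describe(self) -> list[str]:
        layers = [f"input({self.latent_dim})"]
        for w in self.widths:
            layers += [f"dense({w})", f"leaky_relu({self.alpha})", f"batch_norm({self.bn_momentum})"]
        layers += [f"dense({self.output_dim}, {self.output_activation})",
                   f"reshape({self.output_side}x{self.output_side})"]
        return layers


def _init_dense(rng: np.random.Generator, dims) -> dict[str, np.ndarray]:
    params = {}
    for i, (din, dout) in enumerate(dims):
        params[f"W{i}"] = rng.normal(0.0, WEIGHT_INIT_STD, size=(din, dout))
        params[f"b{i}"] = np.zeros(dout)
    return params


# ---------------------------------------------------------------------------
# discriminator
# ---------------------------------------------------------------------------

class Discriminator:
    """Fully connected real-vs-fake classifier over flattened frames."""

    def __init__(self, spec: DiscriminatorSpec = DiscriminatorSpec(),
                 rng: np.random.Generator | None = None,
                 params: dict[str, np.ndarray] | None = None):
        self.spec = spec
        if params is not None:
            self.params = params
        else:
            rng = rng or np.random.default_rng(0)
            self.params = _init_dense(rng, spec.layer_dims())

    def _as_batch(self, img: np.ndarray) -> tuple[np.ndarray, bool]:
        x = np.asarray(img, dtype=np.float64)
        single = x.ndim == 2 and x.shape == (self.spec.input_side, self.spec.input_side)
        if single:
            x = x.reshape(1, -1)
        elif x.ndim == 3:
            if x.shape[1:] != (self.spec.input_side, self.spec.input_side):
                raise ValueError(f"expected {self.spec.input_side}x{self.spec.input_side} "
                                 f"frames, got {x.shape[1:]}")
            x = x.reshape(x.shape[0], -1)
        elif x.ndim == 2 and x.shape[1] == self.spec.input_dim:
            pass
        else:
            raise ValueError(f"bad input shape {x.shape} for side {self.spec.input_side}")
        return x, single

    def forward(self, img: np.ndarray) -> np.ndarray | float:
        """Probability-of-real for one frame (float) or a batch (vector)."""
        x, single = self._as_batch(img)
        p, _ = self.forward_cache(x)
        return float(p[0]) if single else p

    def forward_cache(self, x: np.ndarray):
        """Forward on a flattened (N, D) batch, caching pre-activations."""
        n_hidden = len(self.spec.widths)
        cache = {"x": x, "a": [], "h": []}
        h = x
        for i in range(n_hidden):
            a = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            h = leaky_relu(a, self.spec.alpha)
            cache["a"].append(a)
            cache["h"].append(h)
        logits = h @ self.params[f"W{n_hidden}"] + self.params[f"b{n_hidden}"]
        p = sigmoid(logits).ravel()
        cache["p"] = p
        return p, cache

    def backward(self, cache, dlogit: np.ndarray):
        """Backprop from d(loss)/d(logit); returns (grads, dx).

        For sigmoid + cross-entropy against labels y, dlogit = (p - y)/N.
        ``dx`` (gradient with respect to the input frames) is what the
        generator update chains through.
        """
        n_hidden = len(self.spec.widths)
        grads: dict[str, np.ndarray] = {}
        d = np.asarray(dlogit, dtype=np.float64).reshape(-1, 1)
        grads[f"W{n_hidden}"] = cache["h"][-1].T @ d
        grads[f"b{n_hidden}"] = d.sum(axis=0)
        dh = d @ self.params[f"W{n_hidden}"].T
        for i in range(n_hidden - 1, -1, -1):
            da = dh * leaky_relu_grad(cache["a"][i], self.spec.alpha)
            prev = cache["h"][i - 1] if i > 0 else cache["x"]
            grads[f"W{i}"] = prev.T @ da
            grads[f"b{i}"] = da.sum(axis=0)
            dh = da @ self.params[f"W{i}"].T
        return grads, dh


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

class Generator:
    """Latent-to-frame network with batch-normalized hidden layers."""

    def __init__(self, spec: GeneratorSpec = GeneratorSpec(),
                 rng: np.random.Generator | None = None,
                 params: dict[str, np.ndarray] | None = None,
                 bn_states: list[BatchNormState] | None = None):
        self.spec = spec
        if params is not None:
            self.params = params
        else:
            rng = rng or np.random.default_rng(0)
            self.params = _init_dense(rng, spec.layer_dims())
            for i, w in enumerate(spec.widths):
                self.params[f"gamma{i}"] = np.ones(w)
                self.params[f"beta{i}"] = np.zeros(w)
        if bn_states is not None:
            self.bn_states = bn_states
        else:
            self.bn_states = [
                BatchNormState.initial(w, spec.bn_momentum, spec.bn_eps)
                for w in spec.widths
            ]
        # keep the learnable scale/shift shared between params and BN state
        for i, st in enumerate(self.bn_states):
            st.gamma = self.params[f"gamma{i}"]
            st.beta = self.params[f"beta{i}"]

    def forward(self, z: np.ndarray, training: bool = False) -> np.ndarray:
        """Map latents (N, latent_dim) or a single latent to side x side frames."""
        z = np.asarray(z, dtype=np.float64)
        single = z.ndim == 1
        if single:
            z = z.reshape(1, -1)
        out, _ = self.forward_cache(z, training=training)
        imgs = out.reshape(-1, self.spec.output_side, self.spec.output_side)
        return imgs[0] if single else imgs

    def forward_cache(self, z: np.ndarray, training: bool):
        if z.ndim != 2 or z.shape[1] != self.spec.latent_dim:
            raise ValueError(f"latent batch must be (N, {self.spec.latent_dim}), got {z.shape}")
        cache = {"z": z, "a": [], "h": [], "bn": [], "hn": []}
        h = z
        for i in range(len(self.spec.widths)):
            a = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            act = leaky_relu(a, self.spec.alpha)
            hn, bn_cache = batch_norm_forward(act, self.bn_states[i], training=training)
            cache["a"].append(a)
            cache["h"].append(act)
            cache["bn"].append(bn_cache)
            cache["hn"].append(hn)
            h = hn
        n_hidden = len(self.spec.widths)
        a_out = h @ self.params[f"W{n_hidden}"] + self.params[f"b{n_hidden}"]
        if self.spec.output_activation == "tanh":
            out = np.tanh(a_out)
        elif self.spec.output_activation == "sigmoid":
            out = sigmoid(a_out)
        else:
            raise ValueError(f"unknown output activation {self.spec.output_activation!r}")
        cache["out"] = out
        return out, cache

    def backward(self, cache, dout: np.ndarray):
        """Backprop from d(loss)/d(output frame), flattened (N, side^2)."""
        n_hidden = len(self.spec.widths)
        out = cache["out"]
        if self.spec.output_activation == "tanh":
            da = dout * (1.0 - out * out)
        else:
            da = dout * out * (1.0 - out)
        grads: dict[str, np.ndarray] = {}
        grads[f"W{n_hidden}"] = cache["hn"][-1].T @ da
        grads[f"b{n_hidden}"] = da.sum(axis=0)
        dh = da @ self.params[f"W{n_hidden}"].T
        for i in range(n_hidden - 1, -1, -1):
            dact, dgamma, dbeta = batch_norm_backward(dh, cache["bn"][i])
            grads[f"gamma{i}"] = dgamma
            grads[f"beta{i}"] = dbeta
            da_i = dact * leaky_relu_grad(cache["a"][i], self.spec.alpha)
            prev = cache["hn"][i - 1] if i > 0 else cache["z"]
            grads[f"W{i}"] = prev.T @ da_i
            grads[f"b{i}"] = da_i.sum(axis=0)
            dh = da_i @ self.params[f"W{i}"].T
        return grads


def discriminator_forward(img: np.ndarray, params: dict[str, np.ndarray],
                          spec: DiscriminatorSpec = DiscriminatorSpec()):
    """Functional wrapper: probability that ``img`` is real."""
    return Discriminator(spec, params=params).forward(img)


def generator_forward(z: np.ndarray, params: dict[str, np.ndarray],
                      spec: GeneratorSpec = GeneratorSpec(),
                      training: bool = False,
                      bn_states: list[BatchNormState] | None = None):
    """Functional wrapper: frame(s) generated from latent vector(s)."""
    return Generator(spec, params=params, bn_states=bn_states).forward(z, training=training)
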