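"""Adversarial training loop with loss logging and checkpoints.

One unconditional generator is trained over all classes at once.  Each
iteration draws one real batch and one generated batch, applies a single
combined discriminator update toward hard labels (real = 1, fake = 0),
then one generator update.  The generator objective defaults to the
non-saturating surrogate — cross-entropy of D(G(z)) against the label 1
— which gives usable gradients early in training when the discriminator
wins easily; the original saturating objective (minimize log(1 - D(G(z))))
is available via ``TrainConfig.saturating``.

Determinism contract: every random draw at iteration t comes from a
stream derived from (seed, t), so two runs with the same config are
bit-identical, and resuming from a checkpoint at iteration t reproduces
the single-run history exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imageset import LabeledImageSet, denormalize, normalize
from .nets import (BatchNormState, Discriminator, DiscriminatorSpec, Generator,
                   GeneratorSpec, bce_loss)
from .optim import AdamState, adam_step

__all__ = ["TrainConfig", "LossHistory", "TrainState", "train_gan",
           "sample_generator", "mode_collapse_score",
           "save_checkpoint", "load_checkpoint"]

CHECKPOINT_MAGIC = "EMBRYOGAN-CKPT-1"

# spawn-key streams: 0 = G init, 1 = D init, 2 = batch pick, 3 = latents
_STREAM_G_INIT, _STREAM_D_INIT, _STREAM_BATCH, _STREAM_LATENT = range(4)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass(frozen=True)
class TrainConfig:
    """Training schedule and network hyperparameters.

    Defaults are the full-scale recipe (200k iterations, batch 256,
    checkpoints every 25k, learning rate 2e-5, beta1 0.7); ``image_side``
    and the layer widths can be reduced for desk-scale runs.
    """

    iterations: int = 200_000
    batch_size: int = 256
    checkpoint_every: int = 25_000
    learning_rate: float = 2e-5
    beta1: float = 0.7
    beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0
    image_side: int = 200
    latent_dim: int = 100
    g_widths: tuple[int, ...] = (256, 512, 1024)
    d_widths: tuple[int, ...] = (512, 256)
    saturating: bool = False

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValueError("iterations must be non-negative")
        for name in ("batch_size", "checkpoint_every", "image_side", "latent_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.iterations and self.checkpoint_every > self.iterations:
            raise ValueError("checkpoint_every must not exceed iterations")


@dataclass
class LossHistory:
    """Per-iteration generator and discriminator (real/fake) losses."""

    g_loss: list[float] = field(default_factory=list)
    d_loss_real: list[float] = field(default_factory=list)
    d_loss_fake: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.g_loss)

    def append(self, g: float, d_real: float, d_fake: float) -> None:
        self.g_loss.append(g)
        self.d_loss_real.append(d_real)
        self.d_loss_fake.append(d_fake)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({
            "iteration": np.arange(1, len(self) + 1),
            "g_loss": self.g_loss,
            "d_loss_real": self.d_loss_real,
            "d_loss_fake": self.d_loss_fake,
        }).to_csv(path, index=False)


@dataclass
class TrainState:
    """Everything needed to continue or sample from a training run."""

    generator: Generator
    discriminator: Discriminator
    adam_g: AdamState
    adam_d: AdamState
    iteration: int
    history: LossHistory
    config: TrainConfig


def _init_state(cfg: TrainConfig) -> TrainState:
    g_spec = GeneratorSpec(latent_dim=cfg.latent_dim, widths=cfg.g_widths,
                           output_side=cfg.image_side)
    d_spec = DiscriminatorSpec(input_side=cfg.image_side, widths=cfg.d_widths)
    gen = Generator(g_spec, rng=_rng(cfg.seed, _STREAM_G_INIT))
    disc = Discriminator(d_spec, rng=_rng(cfg.seed, _STREAM_D_INIT))
    kw = dict(lr=cfg.learning_rate, beta1=cfg.beta1, beta2=cfg.beta2, eps=cfg.adam_eps)
    return TrainState(
        generator=gen, discriminator=disc,
        adam_g=AdamState.for_params(gen.params, **kw),
        adam_d=AdamState.for_params(disc.params, **kw),
        iteration=0, history=LossHistory(), config=cfg,
    )


def train_gan(data: LabeledImageSet, cfg: TrainConfig,
              out_dir: str | Path | None = None,
              state: TrainState | None = None) -> TrainState:
    """Run the adversarial loop for ``cfg.iterations`` total iterations.

    ``data`` must be non-empty with frames already at ``cfg.image_side``.
    Pass a loaded ``state`` to resume; the run continues from
    ``state.iteration`` and reproduces the single-run loss history.
    Checkpoints (parameters, optimizer state, sample grid, loss CSV) are
    written to ``out_dir`` every ``cfg.checkpoint_every`` iterations.
    A non-finite loss aborts with a diagnostic state dump.
    """
    if len(data) == 0 and cfg.iterations > 0:
        raise ValueError("training data is empty")
    for img in data.images[:1]:
        if img.shape != (cfg.image_side, cfg.image_side):
            raise ValueError(
                f"data frames are {img.shape}, expected "
                f"({cfg.image_side}, {cfg.image_side}); resize first"
            )

    st = state or _init_state(cfg)
    gen, disc = st.generator, st.discriminator
    b = cfg.batch_size
    real_flat = (
        normalize(np.stack(data.images)).reshape(len(data), -1)
        if len(data) else np.empty((0, cfg.image_side ** 2))
    )
    n_real = real_flat.shape[0]
    out_path = Path(out_dir) if out_dir is not None else None

    for t in range(st.iteration, cfg.iterations):
        idx = _rng(cfg.seed, _STREAM_BATCH, t).integers(0, n_real, size=b)
        real = real_flat[idx]
        z = _rng(cfg.seed, _STREAM_LATENT, t).standard_normal((b, cfg.latent_dim))

        fake, g_cache = gen.forward_cache(z, training=True)

        # --- discriminator step: one combined real+fake batch, hard labels
        x = np.concatenate([real, fake])
        y = np.concatenate([np.ones(b), np.zeros(b)])
        p, d_cache = disc.forward_cache(x)
        d_loss_real = bce_loss(np.ones(b), p[:b])
        d_loss_fake = bce_loss(np.zeros(b), p[b:])
        d_grads, _ = disc.backward(d_cache, (p - y) / (2 * b))
        adam_step(disc.params, d_grads, st.adam_d)

        # --- generator step against the updated discriminator
        p_fake, d_cache2 = disc.forward_cache(fake)
        g_loss = bce_loss(np.ones(b), p_fake)
        if cfg.saturating:
            dlogit = -p_fake / b          # d/dlogit of mean log(1 - D(G(z)))
        else:
            dlogit = (p_fake - 1.0) / b   # d/dlogit of BCE against label 1
        _, dx = disc.backward(d_cache2, dlogit)
        g_grads = gen.backward(g_cache, dx)
        adam_step(gen.params, g_grads, st.adam_g)

        if not (np.isfinite(g_loss) and np.isfinite(d_loss_real) and np.isfinite(d_loss_fake)):
            diag = {
                "iteration": t + 1, "g_loss": g_loss,
                "d_loss_real": d_loss_real, "d_loss_fake": d_loss_fake,
                "p_fake_range": [float(p_fake.min()), float(p_fake.max())],
            }
            if out_path is not None:
                out_path.mkdir(parents=True, exist_ok=True)
                save_checkpoint(out_path / "diagnostic_state.npz", st)
                (out_path / "diagnostic.json").write_text(json.dumps(diag, indent=2))
            raise RuntimeError(f"non-finite loss at iteration {t + 1}: {diag}")

        st.history.append(g_loss, d_loss_real, d_loss_fake)
        st.iteration = t + 1

        if out_path is not None and (t + 1) % cfg.checkpoint_every == 0:
            out_path.mkdir(parents=True, exist_ok=True)
            save_checkpoint(out_path / f"checkpoint_{t + 1:08d}.npz", st)
            _write_sample_grid(out_path / f"samples_{t + 1:08d}.png", gen, cfg, t + 1)
            st.history.to_csv(out_path / "loss_history.csv")

    return st


def _write_sample_grid(path: Path, gen: Generator, cfg: TrainConfig,
                       iteration: int, grid: int = 4) -> None:
    from PIL import Image

    z = _rng(cfg.seed, 4, iteration).standard_normal((grid * grid, cfg.latent_dim))
    frames = denormalize(gen.forward(z, training=False))
    side = cfg.image_side
    canvas = frames.reshape(grid, grid, side, side).transpose(0, 2, 1, 3).reshape(
        grid * side, grid * side)
    Image.fromarray(canvas, mode="L").save(path)


def sample_generator(gen: Generator, n: int, seed: int = 0,
                     label: int = 0) -> LabeledImageSet:
    """Draw ``n`` frames from the generator, denormalized to 8-bit storage.

    The unconditional network carries no class input, so samples get the
    placeholder label 0 unless the caller assigns one (e.g. for a
    generator trained on a single class).
    """
    if n == 0:
        return LabeledImageSet(provenance="generated")
    z = np.random.default_rng(seed).standard_normal((n, gen.spec.latent_dim))
    frames = denormalize(gen.forward(z, training=False))
    return LabeledImageSet(images=list(frames), labels=[label] * n, provenance="generated")


def mode_collapse_score(samples: LabeledImageSet) -> float:
    """Mean pairwise normalized L2 distance between samples; 0 iff identical.

    Frames are scaled to [0, 1] and distances divided by sqrt(H*W), so two
    frames differing by full range at a single pixel are 1/sqrt(H*W) apart
    and the score lies in [0, 1].  A score near 0 signals mode collapse —
    the generator emitting (near-)copies of one frame.
    """
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 samples")
    x = np.stack(samples.images).astype(np.float64) / 255.0
    flat = x.reshape(n, -1)
    npix = flat.shape[1]
    total = 0.0
    for i in range(n - 1):
        d = flat[i + 1:] - flat[i]
        total += float(np.sqrt((d * d).sum(axis=1)).sum())
    return total / (n * (n - 1) / 2) / np.sqrt(npix)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, state: TrainState) -> None:
    """Write parameters, BN running stats, Adam state and history to one file.

    Container: NumPy .npz with a JSON header under ``meta`` and flat arrays
    under prefixed keys; the ``magic`` entry versions the format.
    """
    cfg = state.config
    meta = {
        "magic": CHECKPOINT_MAGIC,
        "iteration": state.iteration,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(cfg).items()},
        "g_spec": {"latent_dim": cfg.latent_dim, "widths": list(cfg.g_widths),
                   "output_side": cfg.image_side},
        "d_spec": {"input_side": cfg.image_side, "widths": list(cfg.d_widths)},
    }
    arrays: dict[str, np.ndarray] = {}
    for k, v in state.generator.params.items():
        arrays[f"g_param_{k}"] = v
    for k, v in state.discriminator.params.items():
        arrays[f"d_param_{k}"] = v
    for i, bn in enumerate(state.generator.bn_states):
        arrays[f"g_bn{i}_mean"] = bn.running_mean
        arrays[f"g_bn{i}_var"] = bn.running_var
    for net, adam in (("g", state.adam_g), ("d", state.adam_d)):
        for k, v in adam.m.items():
            arrays[f"{net}_adam_m_{k}"] = v
        for k, v in adam.v.items():
            arrays[f"{net}_adam_v_{k}"] = v
        arrays[f"{net}_adam_t"] = np.array(adam.t)
    arrays["hist"] = np.array([state.history.g_loss, state.history.d_loss_real,
                               state.history.d_loss_fake])
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path: str | Path) -> TrainState:
    """Rebuild a :class:`TrainState` from :func:`save_checkpoint` output."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta.get("magic") != CHECKPOINT_MAGIC:
            raise ValueError(f"not an embryogan checkpoint: {path}")
        cfg_dict = meta["config"]
        for key in ("g_widths", "d_widths"):
            cfg_dict[key] = tuple(cfg_dict[key])
        cfg = TrainConfig(**cfg_dict)

        g_params = {k[len("g_param_"):]: data[k] for k in data.files
                    if k.startswith("g_param_")}
        d_params = {k[len("d_param_"):]: data[k] for k in data.files
                    if k.startswith("d_param_")}
        g_spec = GeneratorSpec(**meta["g_spec"])
        d_spec = DiscriminatorSpec(**meta["d_spec"])
        bn_states = []
        for i, w in enumerate(g_spec.widths):
            st = BatchNormState.initial(w, g_spec.bn_momentum, g_spec.bn_eps)
            st.running_mean = data[f"g_bn{i}_mean"].copy()
            st.running_var = data[f"g_bn{i}_var"].copy()
            bn_states.append(st)
        gen = Generator(g_spec, params=g_params, bn_states=bn_states)
        disc = Discriminator(d_spec, params=d_params)

        def _adam(prefix: str, params: dict[str, np.ndarray]) -> AdamState:
            st = AdamState.for_params(params, lr=cfg.learning_rate, beta1=cfg.beta1,
                                      beta2=cfg.beta2, eps=cfg.adam_eps)
            st.m = {k: data[f"{prefix}_adam_m_{k}"].copy() for k in params}
            st.v = {k: data[f"{prefix}_adam_v_{k}"].copy() for k in params}
            st.t = int(data[f"{prefix}_adam_t"])
            return st

        hist_arr = data["hist"]
        history = LossHistory(
            g_loss=list(hist_arr[0]), d_loss_real=list(hist_arr[1]),
            d_loss_fake=list(hist_arr[2]),
        )
        return TrainState(
            generator=gen, discriminator=disc,
            adam_g=_adam("g", g_params), adam_d=_adam("d", d_params),
            iteration=int(meta["iteration"]), history=history, config=cfg,
        )
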