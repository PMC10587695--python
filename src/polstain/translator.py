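"""Unpaired cycle-consistent translation between polarimetric encodings and
bright-field stain contrast.

Two ResNet-style generators map between the domains (G: polarimetric -> RGB
bright-field, F: the inverse) and two 70x70 PatchGAN discriminators judge
realism.  Training minimizes the adversarial terms of both directions plus
an L1 cycle-consistency penalty weighted by ``lambda_cyc``:

    L = L_GAN(G, D_Y) + L_GAN(F, D_X)
        + lambda * ( E_x ||F(G(x)) - x||_1 + E_y ||G(F(y)) - y||_1 )

No paired examples are required; pairing only enters evaluation.

The generator follows the classic residual translation design: a 7x7 stem
at ``base_width`` channels, two stride-2 downsampling convolutions, nine
residual blocks at quarter resolution, mirrored transposed-convolution
upsampling back to ``base_width`` at full resolution, and a 7x7 tanh
projection to the output channels.  A strict variant with three strided
downsampling steps is available behind ``strict_strided``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import (
    Adam,
    Conv2d,
    ConvTranspose2d,
    InstanceNorm2d,
    LeakyReLU,
    Network,
    ReflectPad2d,
    ReLU,
    ResidualBlock,
    Sequential,
    Tanh,
    sigmoid,
)

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "TrainConfig",
    "ModelPair",
    "TrainingHistory",
    "build_generator",
    "build_discriminator",
    "discriminator_output_size",
    "receptive_field",
    "adversarial_loss",
    "cycle_loss",
    "total_objective",
    "learning_rate",
    "train",
    "translate",
    "transfer_init",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class GeneratorSpec:
    in_channels: int = 3
    out_channels: int = 3
    base_width: int = 64
    n_down_steps: int = 3
    n_res_blocks: int = 9
    norm: str = "instance"
    final_activation: str = "tanh"
    #: If True, use three stride-2 convolutions after the stem instead of
    #: the default stem + two strided reading of "three steps".
    strict_strided: bool = False

    def __post_init__(self) -> None:
        if self.in_channels not in (1, 3):
            raise ValueError(f"in_channels must be 1 or 3, got {self.in_channels}")
        if self.out_channels not in (1, 3):
            raise ValueError(f"out_channels must be 1 or 3, got {self.out_channels}")


@dataclass(frozen=True)
class DiscriminatorSpec:
    in_channels: int = 3
    kernel: int = 4
    widths: tuple[int, ...] = (64, 128, 256, 512, 1)
    strides: tuple[int, ...] = (2, 2, 2, 1, 1)
    leaky_slope: float = 0.2


@dataclass
class TrainConfig:
    epochs: int = 100
    flat_epochs: int = 50
    batch_size: int = 4
    lr0: float = 2e-4
    lambda_cyc: float = 10.0
    gan_mode: str = "log"  # log (as in the adversarial objective) | least_squares
    seed: int = 0
    fake_pool_size: int = 50
    beta1: float = 0.5
    beta2: float = 0.999
    identity_weight: float = 0.0
    checkpoint_dir: str | None = None

    def __post_init__(self) -> None:
        if self.flat_epochs > self.epochs:
            raise ValueError("flat_epochs must not exceed epochs")
        if self.gan_mode not in ("log", "least_squares"):
            raise ValueError(f"unknown gan_mode {self.gan_mode!r}")


@dataclass
class TrainingHistory:
    """Per-epoch means of the four loss terms plus the lr schedule, and the
    raw per-iteration cycle losses (useful for convergence comparisons)."""

    epochs: list[dict] = field(default_factory=list)
    iterations: list[dict] = field(default_factory=list)


@dataclass
class ModelPair:
    g: Network  # X -> Y
    f: Network  # Y -> X
    d_x: Network
    d_y: Network
    g_spec: GeneratorSpec
    f_spec: GeneratorSpec
    d_spec: DiscriminatorSpec
    history: TrainingHistory = field(default_factory=TrainingHistory)


def build_generator(spec: GeneratorSpec, rng: np.random.Generator | None = None) -> Network:
    """Residual translation generator; output spatial size equals input."""
    rng = rng or np.random.default_rng()
    w = spec.base_width
    n_strided = 3 if spec.strict_strided else 2
    layers: list = [
        ReflectPad2d(3),
        Conv2d(spec.in_channels, w, 7, rng=rng, bias=False),
        InstanceNorm2d(),
        ReLU(),
    ]
    width = w
    for _ in range(n_strided):
        layers += [
            Conv2d(width, width * 2, 3, stride=2, pad=1, rng=rng, bias=False),
            InstanceNorm2d(),
            ReLU(),
        ]
        width *= 2
    layers += [ResidualBlock(width, rng=rng) for _ in range(spec.n_res_blocks)]
    for _ in range(n_strided):
        layers += [
            ConvTranspose2d(width, width // 2, rng=rng, bias=False),
            InstanceNorm2d(),
            ReLU(),
        ]
        width //= 2
    assert width == w  # last upsampling feature map has base_width channels
    layers += [ReflectPad2d(3), Conv2d(w, spec.out_channels, 7, rng=rng), Tanh()]
    return Network(layers)


def build_discriminator(spec: DiscriminatorSpec, rng: np.random.Generator | None = None) -> Network:
    """Fully convolutional PatchGAN: one realism logit per receptive patch."""
    rng = rng or np.random.default_rng()
    layers: list = []
    c_in = spec.in_channels
    n = len(spec.widths)
    for i, (width, stride) in enumerate(zip(spec.widths, spec.strides)):
        has_norm = 0 < i < n - 1  # instance norm on middle layers only
        layers.append(
            Conv2d(c_in, width, spec.kernel, stride=stride, pad=1, rng=rng, bias=not has_norm)
        )
        if has_norm:
            layers.append(InstanceNorm2d())
        if i < n - 1:  # final layer is the raw prediction map
            layers.append(LeakyReLU(spec.leaky_slope))
        c_in = width
    return Network(layers)


def discriminator_output_size(spec: DiscriminatorSpec, input_size: int) -> int:
    """Closed-form output map side: ``floor((n + 2 - k)/s) + 1`` per layer."""
    n = input_size
    for s in spec.strides:
        n = (n + 2 - spec.kernel) // s + 1
    return n


def receptive_field(spec: DiscriminatorSpec) -> int:
    """Receptive field of one output unit via the backward recursion
    ``rf <- rf * s + (k - s)`` over the layers in reverse."""
    rf = 1
    for s in reversed(spec.strides):
        rf = rf * s + (spec.kernel - s)
    return rf


# ---------------------------------------------------------------------------
# Losses


def _d_map(d: Network, batch: np.ndarray, mode: str) -> np.ndarray:
    raw, _ = d.forward(batch)
    return sigmoid(raw) if mode == "log" else raw


def adversarial_loss(d: Network, real_batch: np.ndarray, fake_batch: np.ndarray, mode: str = "log") -> float:
    """Adversarial objective value over a real and a fake batch.

    ``log`` mode is the printed minimax form
    ``E[log D(real)] + E[log(1 - D(fake))]`` averaged over the patch map
    (D outputs probabilities via a sigmoid); ``least_squares`` is the
    squared-error variant against labels 1/0 (lower is better for D).
    """
    if real_batch.shape != fake_batch.shape:
        raise ValueError(f"batch shape mismatch: {real_batch.shape} vs {fake_batch.shape}")
    p_real = _d_map(d, real_batch, mode)
    p_fake = _d_map(d, fake_batch, mode)
    if mode == "log":
        eps = 1e-12
        return float(np.mean(np.log(p_real + eps)) + np.mean(np.log(1.0 - p_fake + eps)))
    return float(np.mean((p_real - 1.0) ** 2) + np.mean(p_fake**2))


def cycle_loss(g: Network, f: Network, batch_x: np.ndarray) -> float:
    """Cycle-consistency reconstruction error ``E ||F(G(x)) - x||_1``."""
    y, _ = g.forward(batch_x)
    rec, _ = f.forward(y)
    return float(np.mean(np.abs(rec - batch_x)))


def total_objective(losses: dict, lambda_cyc: float) -> float:
    """Overall objective: both adversarial terms plus lambda times both
    cycle terms."""
    return float(
        losses["adv_g"]
        + losses["adv_f"]
        + lambda_cyc * (losses["cyc_forward"] + losses["cyc_backward"])
    )


def learning_rate(cfg: TrainConfig, epoch: int) -> float:
    """Schedule: constant ``lr0`` for ``flat_epochs`` (1-indexed), then
    linear decay reaching zero at ``epochs``."""
    if epoch <= cfg.flat_epochs:
        return cfg.lr0
    frac = (epoch - cfg.flat_epochs) / (cfg.epochs - cfg.flat_epochs)
    return cfg.lr0 * max(0.0, 1.0 - frac)


# ---------------------------------------------------------------------------
# Training


class _ImagePool:
    """Replay buffer of past generated images used for discriminator
    updates; returning stale fakes stabilizes adversarial training."""

    def __init__(self, size: int, rng: np.random.Generator):
        self.size = size
        self.rng = rng
        self.images: list[np.ndarray] = []

    def query(self, batch: np.ndarray) -> np.ndarray:
        if self.size == 0:
            return batch
        out = []
        for img in batch:
            if len(self.images) < self.size:
                self.images.append(img.copy())
                out.append(img)
            elif self.rng.random() < 0.5:
                j = int(self.rng.integers(len(self.images)))
                out.append(self.images[j].copy())
                self.images[j] = img.copy()
            else:
                out.append(img)
        return np.stack(out)


def _to_nchw(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 4:
        raise ValueError(f"expected (N, H, W, C) data, got shape {data.shape}")
    return np.ascontiguousarray(data.transpose(0, 3, 1, 2))


def _gen_adv_grad(raw: np.ndarray, mode: str) -> tuple[float, np.ndarray]:
    """Generator-side adversarial loss on D's raw map for a fake batch and
    its gradient w.r.t. the raw map."""
    n = raw.size
    if mode == "log":
        # minimize log(1 - D(fake)) (printed minimax form)
        p = sigmoid(raw)
        loss = float(np.mean(np.log(1.0 - p + 1e-12)))
        grad = -p / n
    else:
        loss = float(np.mean((raw - 1.0) ** 2))
        grad = 2.0 * (raw - 1.0) / n
    return loss, grad


def _disc_loss_grads(
    raw_real: np.ndarray, raw_fake: np.ndarray, mode: str
) -> tuple[float, np.ndarray, np.ndarray]:
    """Discriminator loss (to minimize, with the conventional 0.5 factor)
    and gradients w.r.t. both raw maps."""
    nr, nf = raw_real.size, raw_fake.size
    if mode == "log":
        pr, pf = sigmoid(raw_real), sigmoid(raw_fake)
        loss = -0.5 * (
            float(np.mean(np.log(pr + 1e-12))) + float(np.mean(np.log(1.0 - pf + 1e-12)))
        )
        g_real = -0.5 * (1.0 - pr) / nr
        g_fake = 0.5 * pf / nf
    else:
        loss = 0.5 * (float(np.mean((raw_real - 1.0) ** 2)) + float(np.mean(raw_fake**2)))
        g_real = (raw_real - 1.0) / nr
        g_fake = raw_fake / nf
    return loss, g_real, g_fake


def _l1_grad(pred: np.ndarray, target: np.ndarray, weight: float) -> tuple[float, np.ndarray]:
    diff = pred - target
    loss = float(np.mean(np.abs(diff)))
    return loss, weight * np.sign(diff, dtype=np.float32) / diff.size


def train(
    data_x: np.ndarray,
    data_y: np.ndarray,
    cfg: TrainConfig,
    g_spec: GeneratorSpec | None = None,
    d_spec: DiscriminatorSpec | None = None,
    init_from: "ModelPair | str | Path | None" = None,
) -> ModelPair:
    """Train the translation pair on two unpaired image collections.

    Parameters
    ----------
    data_x : (Nx, H, W, Cx) array in [-1, 1]
        Polarimetric-domain encodings.
    data_y : (Ny, H, W, Cy) array in [-1, 1]
        Bright-field-domain encodings.  Nx and Ny need not match and no
        pairing is assumed.
    init_from : ModelPair or checkpoint path, optional
        Transfer-learning donor; weights are copied before training and
        optimizer state starts fresh.

    Returns
    -------
    ModelPair with trained weights and the full training history; the run
    is reproducible bit-for-bit from ``cfg.seed``.
    """
    if len(data_x) == 0 or len(data_y) == 0:
        raise ValueError("empty training dataset")
    x_all, y_all = _to_nchw(data_x), _to_nchw(data_y)
    cx, cy = x_all.shape[1], y_all.shape[1]
    g_spec = g_spec or GeneratorSpec(in_channels=cx, out_channels=cy)
    if g_spec.in_channels != cx or g_spec.out_channels != cy:
        raise ValueError(
            f"generator spec channels ({g_spec.in_channels}->{g_spec.out_channels}) "
            f"do not match data ({cx}->{cy})"
        )
    f_spec = GeneratorSpec(
        in_channels=cy,
        out_channels=cx,
        base_width=g_spec.base_width,
        n_down_steps=g_spec.n_down_steps,
        n_res_blocks=g_spec.n_res_blocks,
        strict_strided=g_spec.strict_strided,
    )
    d_spec = d_spec or DiscriminatorSpec()
    rng = np.random.default_rng(cfg.seed)
    pair = ModelPair(
        g=build_generator(g_spec, rng),
        f=build_generator(f_spec, rng),
        d_x=build_discriminator(
            DiscriminatorSpec(in_channels=cx, kernel=d_spec.kernel, widths=d_spec.widths,
                              strides=d_spec.strides, leaky_slope=d_spec.leaky_slope), rng),
        d_y=build_discriminator(
            DiscriminatorSpec(in_channels=cy, kernel=d_spec.kernel, widths=d_spec.widths,
                              strides=d_spec.strides, leaky_slope=d_spec.leaky_slope), rng),
        g_spec=g_spec,
        f_spec=f_spec,
        d_spec=d_spec,
    )
    if init_from is not None:
        donor = load_checkpoint(init_from) if isinstance(init_from, (str, Path)) else init_from
        transfer_init(pair, donor)

    gen_params = pair.g.params() + pair.f.params()
    dis_params = pair.d_x.params() + pair.d_y.params()
    opt_g = Adam(gen_params, cfg.lr0, cfg.beta1, cfg.beta2)
    opt_d = Adam(dis_params, cfg.lr0, cfg.beta1, cfg.beta2)
    pool_x = _ImagePool(cfg.fake_pool_size, rng)
    pool_y = _ImagePool(cfg.fake_pool_size, rng)

    n_iter = max(len(x_all), len(y_all)) // cfg.batch_size or 1
    it_global = 0
    for epoch in range(1, cfg.epochs + 1):
        lr = learning_rate(cfg, epoch)
        opt_g.lr = opt_d.lr = lr
        perm_x = rng.permutation(len(x_all))
        perm_y = rng.permutation(len(y_all))
        ep = {"adv_g": 0.0, "adv_f": 0.0, "cyc_forward": 0.0, "cyc_backward": 0.0, "d": 0.0}
        for it in range(n_iter):
            bx = x_all[[perm_x[(it * cfg.batch_size + j) % len(x_all)] for j in range(cfg.batch_size)]]
            by = y_all[[perm_y[(it * cfg.batch_size + j) % len(y_all)] for j in range(cfg.batch_size)]]

            # --- generator update (D weights frozen: grads discarded) ---
            fake_y, tg1 = pair.g.forward(bx)
            rec_x, tf1 = pair.f.forward(fake_y)
            fake_x, tf2 = pair.f.forward(by)
            rec_y, tg2 = pair.g.forward(fake_x)
            raw_fy, tdy = pair.d_y.forward(fake_y)
            raw_fx, tdx = pair.d_x.forward(fake_x)

            adv_g, g_raw_fy = _gen_adv_grad(raw_fy, cfg.gan_mode)
            adv_f, g_raw_fx = _gen_adv_grad(raw_fx, cfg.gan_mode)
            cyc_f, g_rec_x = _l1_grad(rec_x, bx, cfg.lambda_cyc)
            cyc_b, g_rec_y = _l1_grad(rec_y, by, cfg.lambda_cyc)

            g_fake_y = pair.d_y.backward(tdy, g_raw_fy) + pair.f.backward(tf1, g_rec_x)
            g_fake_x = pair.d_x.backward(tdx, g_raw_fx) + pair.g.backward(tg2, g_rec_y)
            if cfg.identity_weight > 0 and cx == cy:
                idt_y, tgi = pair.g.forward(by)
                _, g_idt = _l1_grad(idt_y, by, cfg.identity_weight * cfg.lambda_cyc)
                pair.g.backward(tgi, g_idt)
                idt_x, tfi = pair.f.forward(bx)
                _, g_idtx = _l1_grad(idt_x, bx, cfg.identity_weight * cfg.lambda_cyc)
                pair.f.backward(tfi, g_idtx)
            pair.g.backward(tg1, g_fake_y)
            pair.f.backward(tf2, g_fake_x)
            opt_g.step()
            opt_g.zero_grad()
            pair.d_x.zero_grad()
            pair.d_y.zero_grad()

            # --- discriminator updates on real + replayed fakes ---
            d_total = 0.0
            for d_net, real, fake, pool in (
                (pair.d_y, by, fake_y, pool_y),
                (pair.d_x, bx, fake_x, pool_x),
            ):
                fake_b = pool.query(fake)
                raw_r, tr = d_net.forward(real)
                raw_f, tf = d_net.forward(fake_b)
                d_loss, g_r, g_f = _disc_loss_grads(raw_r, raw_f, cfg.gan_mode)
                d_net.backward(tr, g_r)
                d_net.backward(tf, g_f)
                d_total += d_loss
            opt_d.step()
            opt_d.zero_grad()
            pair.g.zero_grad()
            pair.f.zero_grad()

            it_global += 1
            pair.history.iterations.append(
                {"iteration": it_global, "epoch": epoch, "cyc_forward": cyc_f, "cyc_backward": cyc_b}
            )
            for k, v in (("adv_g", adv_g), ("adv_f", adv_f), ("cyc_forward", cyc_f),
                         ("cyc_backward", cyc_b), ("d", d_total)):
                ep[k] += v / n_iter
        pair.history.epochs.append({"epoch": epoch, "lr": lr, **ep})
        if cfg.checkpoint_dir is not None:
            save_checkpoint(pair, Path(cfg.checkpoint_dir) / "latest.npz", cfg=cfg, epoch=epoch)
    return pair


def translate(g: Network, encoded) -> np.ndarray:
    """Run a trained generator on an encoded image.

    Accepts an :class:`~polstain.preprocess.EncodedImage` or a plain
    (H, W, C) array in [-1, 1]; H and W must be divisible by 4.  Returns a
    uint8 image mapped by ``(tanh_output + 1) * 127.5``.
    """
    data = getattr(encoded, "data", encoded)
    data = np.asarray(data, dtype=np.float32)
    if data.ndim == 2:
        data = data[..., None]
    h, w, c = data.shape
    first_conv = next(l for l in g.net.layers if isinstance(l, Conv2d))
    if c != first_conv.c_in:
        raise ValueError(f"input has {c} channels but generator expects {first_conv.c_in}")
    if h % 4 or w % 4:
        raise ValueError(f"spatial size {h}x{w} must be divisible by 4")
    out, _ = g.forward(data.transpose(2, 0, 1)[None])
    img = np.clip(np.rint((out[0].transpose(1, 2, 0) + 1.0) * 127.5), 0, 255)
    return img.astype(np.uint8)


def transfer_init(pair: ModelPair, donor: ModelPair) -> ModelPair:
    """Copy all donor weights into ``pair`` (transfer-learning warm start).

    Optimizer state is not carried over — training after a transfer starts
    with fresh Adam moments.  Architectures must match exactly; a mismatch
    raises listing the offending tensor shapes.
    """
    for name in ("g", "f", "d_x", "d_y"):
        try:
            getattr(pair, name).set_weights(getattr(donor, name).get_weights())
        except ValueError as e:
            raise ValueError(f"transfer_init: network {name!r} incompatible: {e}") from None
    return pair


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(pair: ModelPair, path, cfg: TrainConfig | None = None, epoch: int | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for name in ("g", "f", "d_x", "d_y"):
        for i, wgt in enumerate(getattr(pair, name).get_weights()):
            arrays[f"{name}__{i}"] = wgt
    meta = {
        "g_spec": asdict(pair.g_spec),
        "f_spec": asdict(pair.f_spec),
        "d_spec": asdict(pair.d_spec),
        "cfg": asdict(cfg) if cfg else None,
        "epoch": epoch,
        "history": {"epochs": pair.history.epochs, "iterations": pair.history.iterations},
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> ModelPair:
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        g_spec = GeneratorSpec(**meta["g_spec"])
        f_spec = GeneratorSpec(**meta["f_spec"])
        d_kwargs = dict(meta["d_spec"])
        d_kwargs["widths"] = tuple(d_kwargs["widths"])
        d_kwargs["strides"] = tuple(d_kwargs["strides"])
        d_spec = DiscriminatorSpec(**d_kwargs)
        rng = np.random.default_rng(0)
        pair = ModelPair(
            g=build_generator(g_spec, rng),
            f=build_generator(f_spec, rng),
            d_x=build_discriminator(
                DiscriminatorSpec(**{**d_kwargs, "in_channels": g_spec.in_channels}), rng),
            d_y=build_discriminator(
                DiscriminatorSpec(**{**d_kwargs, "in_channels": g_spec.out_channels}), rng),
            g_spec=g_spec,
            f_spec=f_spec,
            d_spec=d_spec,
        )
        for name in ("g", "f", "d_x", "d_y"):
            n_par = len(getattr(pair, name).params())
            getattr(pair, name).set_weights([z[f"{name}__{i}"] for i in range(n_par)])
        pair.history = TrainingHistory(meta["history"]["epochs"], meta["history"]["iterations"])
    return pair


def history_to_csv(history: TrainingHistory) -> str:
    """Per-epoch training history as CSV (epoch, lr, four losses)."""
    lines = ["epoch,lr,adv_g,adv_f,cyc_forward,cyc_backward"]
    for e in history.epochs:
        lines.append(
            f"{e['epoch']},{e['lr']:.8g},{e['adv_g']:.8g},{e['adv_f']:.8g},"
            f"{e['cyc_forward']:.8g},{e['cyc_backward']:.8g}"
        )
    return "\n".join(lines) + "\n"
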