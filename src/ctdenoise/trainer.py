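"""Unpaired training loop: two generators, two multi-scale discriminator
banks, Adam with a fixed learning rate, Xavier-uniform initialization,
checkpointing, and inference.

Each optimizer step updates the discriminators first (on detached fakes),
then both generators jointly under the weighted adversarial + cycle +
identity objective.  Batching is unpaired: the two domains are shuffled
independently each epoch and zipped per step, with the shorter domain
wrapping around.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, no_grad
from .ct_io import CTImage, ConstantImageError, DomainTag, denormalize, minmax_normalize
from .discriminator import (
    DiscriminatorBank,
    DiscriminatorConfig,
    multiscale_inputs_tensor,
)
from .generator import Generator, GeneratorConfig, generator_forward
from .layers import Adam, Module, xavier_uniform_
from .losses import (
    LossBreakdown,
    LossWeights,
    adversarial_loss,
    generator_adversarial_loss,
    joint_loss,
)
from .phantom import UnpairedDataset

__all__ = [
    "TrainConfig",
    "CycleGANState",
    "init_weights",
    "build_state",
    "train_step",
    "fit",
    "denoise",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 1
    epochs: int = 10               # full-scale protocol uses 5000
    input_size: int = 64           # full-scale protocol uses 512
    seed: int = 0
    checkpoint_every: int = 0      # epochs; 0 disables periodic checkpoints
    gan_mode: str = "non_saturating"
    dtype: str = "float32"         # network arithmetic precision
    weights: LossWeights = field(default_factory=LossWeights)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    discriminator: DiscriminatorConfig = field(default_factory=DiscriminatorConfig)

    def __post_init__(self):
        if self.lr < 0:
            raise ValueError("lr must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class CycleGANState:
    cfg: TrainConfig
    G: Generator                  # low-dose -> standard-dose
    F: Generator                  # standard-dose -> low-dose
    D_Y: DiscriminatorBank        # judges standard-dose realism
    D_X: DiscriminatorBank        # judges low-dose realism
    opt_G: Adam
    opt_D: Adam
    rng: np.random.Generator
    epoch: int = 0
    step: int = 0

    def networks(self) -> dict[str, Module]:
        return {"G": self.G, "F": self.F, "D_Y": self.D_Y, "D_X": self.D_X}


def init_weights(network: Module, rng: np.random.Generator,
                 method: str = "xavier_uniform") -> Module:
    """Xavier-uniform conv weights, zero biases, reproducible given the rng."""
    if method != "xavier_uniform":
        raise ValueError(f"unknown init method {method!r}")
    return xavier_uniform_(network, rng)


def build_state(cfg: TrainConfig) -> CycleGANState:
    rng = np.random.default_rng(cfg.seed)
    G = Generator(cfg.generator)
    F = Generator(cfg.generator)
    D_Y = DiscriminatorBank(cfg.discriminator)
    D_X = DiscriminatorBank(cfg.discriminator)
    for net in (G, F, D_Y, D_X):
        init_weights(net, rng)
        net.astype(cfg.dtype)
    for net in (G, F):
        if cfg.generator.zero_init_hfs_fuse:
            for mod in net.hfs_modules:
                mod.zero_init_fuse()
        if cfg.generator.tail_init_scale != 1.0:
            w = net.tail.conv.weight
            w.data = w.data * cfg.generator.tail_init_scale
    opt_G = Adam(G.parameters() + F.parameters(), lr=cfg.lr,
                 betas=(cfg.beta1, cfg.beta2))
    opt_D = Adam(D_Y.parameters() + D_X.parameters(), lr=cfg.lr,
                 betas=(cfg.beta1, cfg.beta2))
    return CycleGANState(cfg=cfg, G=G, F=F, D_Y=D_Y, D_X=D_X,
                         opt_G=opt_G, opt_D=opt_D, rng=rng)


def _as_batch(a, dtype="float64") -> Tensor:
    if isinstance(a, Tensor):
        return a
    a = np.asarray(a, dtype=dtype)
    if a.ndim == 2:
        a = a.reshape(1, 1, *a.shape)
    return Tensor(a)


def _bank_scores(bank: DiscriminatorBank, x: Tensor,
                 rng: np.random.Generator) -> list[Tensor]:
    return bank(multiscale_inputs_tensor(x, bank.cfg, rng))


def train_step(x, y, state: CycleGANState) -> LossBreakdown:
    """One discriminator update followed by one generator update.

    ``x`` (low-dose) and ``y`` (standard-dose) are normalized images at the
    configured size, as 2D arrays or NCHW tensors.
    """
    cfg = state.cfg
    x, y = _as_batch(x, cfg.dtype), _as_batch(y, cfg.dtype)
    rng = state.rng

    # -- discriminator update (fakes detached) ------------------------------
    with no_grad():
        fake_y = state.G(x).detach()
        fake_x = state.F(y).detach()

    d_losses = []
    state.opt_D.zero_grad()
    for bank, real, fake in ((state.D_Y, y, fake_y), (state.D_X, x, fake_x)):
        objective = adversarial_loss(_bank_scores(bank, real, rng),
                                     _bank_scores(bank, fake, rng))
        d_loss = -objective  # D maximizes the printed objective
        if not np.isfinite(d_loss.item()):
            raise FloatingPointError(f"non-finite discriminator loss: {d_loss.item()}")
        d_loss.backward()
        d_losses.append(d_loss.item())
    state.opt_D.step()

    # -- generator update ----------------------------------------------------
    state.opt_G.zero_grad()
    fake_y = state.G(x)
    fake_x = state.F(y)
    adv_G = generator_adversarial_loss(_bank_scores(state.D_Y, fake_y, rng),
                                       mode=cfg.gan_mode)
    adv_F = generator_adversarial_loss(_bank_scores(state.D_X, fake_x, rng),
                                       mode=cfg.gan_mode)
    # reuse fake_x / fake_y: cyc = |G(F(y)) - y| + |F(G(x)) - x|
    cyc = (state.G(fake_x) - y).abs().mean() + (state.F(fake_y) - x).abs().mean()
    idt = (state.G(y) - y).abs().mean() + (state.F(x) - x).abs().mean()
    total, breakdown = joint_loss(adv_G, adv_F, cyc, idt, cfg.weights,
                                  d_losses=tuple(d_losses))
    if not np.isfinite(total.item()):
        raise FloatingPointError(f"non-finite generator loss: {total.item()}")
    total.backward()
    state.opt_G.step()
    state.step += 1
    return breakdown


def _normalized_pixels(img: CTImage, size: int) -> np.ndarray:
    norm = img if img.normalized else minmax_normalize(img)
    p = norm.pixels
    if p.shape != (size, size):
        raise ValueError(f"image shape {p.shape} != configured size {size}")
    return p


def fit(dataset: UnpairedDataset, cfg: TrainConfig,
        out_dir: str | Path | None = None,
        max_steps: int | None = None,
        log_callback=None) -> tuple[CycleGANState, list[LossBreakdown]]:
    """Train on an unpaired dataset; returns the final state and loss log.

    The paired evaluation set is never touched: only the two unpaired
    training lists are read, and their source disjointness is re-asserted.
    """
    if not dataset.low_dose or not dataset.standard_dose:
        raise ValueError("empty training dataset")
    low_ids, std_ids = dataset.training_source_ids()
    if low_ids & std_ids:
        raise ValueError("training domains share source phantoms (paired data)")
    eval_ids = {c.source_id.split("@")[0] for c, _ in dataset.paired_eval}
    if eval_ids & (low_ids | std_ids):
        raise ValueError("paired evaluation set leaks into training")

    state = build_state(cfg)
    xs = [_normalized_pixels(img, cfg.input_size) for img in dataset.low_dose]
    ys = [_normalized_pixels(img, cfg.input_size) for img in dataset.standard_dose]

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    log: list[LossBreakdown] = []
    log_path = out_dir / "loss_log.jsonl" if out_dir is not None else None

    shuffle_rng = np.random.default_rng(cfg.seed + 1)
    steps_per_epoch = max(len(xs), len(ys))
    done = False
    for epoch in range(cfg.epochs):
        order_x = shuffle_rng.permutation(len(xs))
        order_y = shuffle_rng.permutation(len(ys))
        for s in range(steps_per_epoch):
            x = xs[order_x[s % len(xs)]]
            y = ys[order_y[s % len(ys)]]
            breakdown = train_step(x, y, state)
            log.append(breakdown)
            if log_path is not None:
                with log_path.open("a") as fh:
                    fh.write(json.dumps({
                        "epoch": epoch, "step": state.step,
                        **{k: getattr(breakdown, k)
                           for k in ("adv_G", "adv_F", "cyc", "idt", "total")},
                        "d_losses": list(breakdown.d_losses),
                    }) + "\n")
            if log_callback is not None:
                log_callback(epoch, state.step, breakdown)
            if max_steps is not None and state.step >= max_steps:
                done = True
                break
        state.epoch = epoch + 1
        if out_dir is not None and cfg.checkpoint_every and \
                (epoch + 1) % cfg.checkpoint_every == 0:
            save_checkpoint(state, out_dir / f"checkpoint_ep{epoch + 1:05d}.npz")
        if done:
            break
    if out_dir is not None:
        save_checkpoint(state, out_dir / "checkpoint_final.npz")
    return state, log


def denoise(state: CycleGANState, img: CTImage) -> CTImage:
    """Translate a raw low-dose slice toward the standard-dose domain.

    Pipeline: min-max normalize -> generator -> denormalize with the input's
    own intensity range.  A constant input violates the normalization
    precondition and raises.
    """
    if img.normalized:
        norm = img
    else:
        try:
            norm = minmax_normalize(img)
        except ConstantImageError:
            raise
    out = generator_forward(state.G, norm)
    if img.normalized:
        return out
    result = denormalize(out, norm.norm_min, norm.norm_max)
    result.source_id = f"{img.source_id}|denoised:{state.cfg.config_hash()}"
    return result


# -- checkpointing -----------------------------------------------------------


def save_checkpoint(state: CycleGANState, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    for net_name, net in state.networks().items():
        for key, value in net.state_dict().items():
            arrays[f"{net_name}/{key}"] = value
    for opt_name, opt in (("opt_G", state.opt_G), ("opt_D", state.opt_D)):
        sd = opt.state_dict()
        arrays[f"{opt_name}/t"] = np.asarray(sd["t"])
        for i, m in enumerate(sd["m"]):
            arrays[f"{opt_name}/m/{i}"] = m
        for i, v in enumerate(sd["v"]):
            arrays[f"{opt_name}/v/{i}"] = v
    meta = {
        "epoch": state.epoch,
        "step": state.step,
        "config_hash": state.cfg.config_hash(),
        "config": asdict(state.cfg),
        "rng_state": state.rng.bit_generator.state,
    }
    arrays["meta"] = np.frombuffer(
        json.dumps(meta, default=str).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def _config_from_dict(d: dict) -> TrainConfig:
    d = dict(d)
    d["weights"] = LossWeights(**d["weights"])
    d["generator"] = GeneratorConfig(**d["generator"])
    d["discriminator"] = DiscriminatorConfig(
        **{k: tuple(v) if isinstance(v, list) else v
           for k, v in d["discriminator"].items()}
    )
    for key in ("lr", "beta1", "beta2"):
        d[key] = float(d[key])
    return TrainConfig(**d)


def load_checkpoint(path: str | Path) -> CycleGANState:
    path = Path(path)
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        cfg = _config_from_dict(meta["config"])
        state = build_state(cfg)
        for net_name, net in state.networks().items():
            prefix = f"{net_name}/"
            sd = {k[len(prefix):]: data[k] for k in data.files
                  if k.startswith(prefix)}
            net.load_state_dict(sd)
        for opt_name, opt in (("opt_G", state.opt_G), ("opt_D", state.opt_D)):
            n = len(opt.params)
            opt.load_state_dict({
                "t": int(data[f"{opt_name}/t"]),
                "m": [data[f"{opt_name}/m/{i}"] for i in range(n)],
                "v": [data[f"{opt_name}/v/{i}"] for i in range(n)],
            })
    state.epoch = int(meta["epoch"])
    state.step = int(meta["step"])
    rng = np.random.default_rng()
    rng_state = meta["rng_state"]
    # json stringifies large ints inside the bit generator state; restore them
    def _restore(obj):
        if isinstance(obj, dict):
            return {k: _restore(v) for k, v in obj.items()}
        if isinstance(obj, str) and obj.isdigit():
            return int(obj)
        return obj

    rng.bit_generator.state = _restore(rng_state)
    state.rng = rng
    return state
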