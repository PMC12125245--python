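"""Loss, patch pipeline and optimization loop for the bridge denoiser.

The training objective draws a uniform timestep per pair (uniform weighting
``gamma_t = 1``), forms the noisy state by direct forward sampling and
regresses the network output on the forward error::

    L = E_{(x0,y), t, eps} || m_t (y - x0) + sqrt(delta_t) eps
                              - eps_theta(x_t, t) ||^2

averaged over pixels, channels and batch.  The shallow dimension-matching
network and the denoiser are optimized jointly with AdamW (constant
learning rate by default, optional cosine decay).

Normalization convention: autofluorescence patches are mapped to zero mean
and unit variance per channel; targets are mapped affinely from [0, 255]
to [-1, 1], which is inverted at inference (stored in the model's
``normalization_spec``).
"""

from __future__ import annotations

import csv
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import AdamW, Tensor
from .network import DenoiserConfig, DenoiserModel, build_denoiser
from .schedule import BridgeSchedule, make_schedule

__all__ = [
    "TrainConfig",
    "normalize_af_stack",
    "normalize_target",
    "make_patches",
    "bb_loss",
    "train_model",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (defaults follow the full-scale recipe; pass
    smaller batch/patch values for desk-scale runs)."""

    T: int = 1000
    learning_rate: float = 1e-4
    batch_size: int = 16
    patch_size: int = 192
    max_steps: int = 2000
    seed: int = 0
    weight_decay: float = 0.01
    lr_schedule: str = "constant"      # "constant" | "cosine"
    augment: bool = True
    recrop_each_epoch: bool = True     # random offsets per epoch vs fixed grid
    ema_decay: float | None = 0.995    # EMA of weights used for inference
    init_checkpoint: str | None = None

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.patch_size % 8:
            raise ValueError("patch_size must be divisible by 8")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")


def normalize_af_stack(y0: np.ndarray) -> np.ndarray:
    """Zero-mean unit-variance per channel over the spatial axes."""
    y0 = np.asarray(y0, dtype=np.float32)
    mean = y0.mean(axis=(-2, -1), keepdims=True)
    std = y0.std(axis=(-2, -1), keepdims=True)
    return (y0 - mean) / np.maximum(std, 1e-6)


def normalize_target(he: np.ndarray) -> np.ndarray:
    """Affine map of an 8-bit RGB target to [-1, 1]."""
    return (np.asarray(he, dtype=np.float32) - 127.5) / 127.5


def make_patches(pair, patch_size: int, rng: np.random.Generator,
                 augment: bool = True, random_offset: bool = False):
    """Aligned, normalized, augmented patch pairs from one registered FOV.

    Tiles the target into non-overlapping ``patch_size`` squares (with a
    random common offset when ``random_offset``), crops the matching
    autofluorescence windows of side ``patch_size / N``, normalizes both
    members and applies the same random flip / 90-degree rotation to each
    pair.  Returns a list of (x0, y0) with x0 (3, p, p) in [-1, 1] and y0
    (af_channels, p/N, p/N) standardized.
    """
    N = pair.factor
    if patch_size % N:
        raise ValueError(f"patch_size {patch_size} not divisible by factor {N}")
    _, H, W = pair.he.shape
    if patch_size > H or patch_size > W:
        raise ValueError(f"patch_size {patch_size} exceeds image {H}x{W}")
    oy = ox = 0
    if random_offset and H > patch_size:
        oy = int(rng.integers(0, (H - patch_size) % patch_size + 1))
        ox = int(rng.integers(0, (W - patch_size) % patch_size + 1))
        oy -= oy % N
        ox -= ox % N
    patches = []
    for i in range(oy, H - patch_size + 1, patch_size):
        for j in range(ox, W - patch_size + 1, patch_size):
            x0 = normalize_target(pair.he[:, i:i + patch_size,
                                          j:j + patch_size])
            y0 = normalize_af_stack(
                pair.af[:, i // N:(i + patch_size) // N,
                        j // N:(j + patch_size) // N])
            if augment:
                k = int(rng.integers(0, 4))
                flip = bool(rng.integers(0, 2))
                x0 = np.rot90(x0, k, axes=(1, 2))
                y0 = np.rot90(y0, k, axes=(1, 2))
                if flip:
                    x0 = x0[:, :, ::-1]
                    y0 = y0[:, :, ::-1]
            patches.append((np.ascontiguousarray(x0),
                            np.ascontiguousarray(y0)))
    return patches


def bb_loss(batch, model: DenoiserModel, schedule: BridgeSchedule,
            rng: np.random.Generator) -> Tensor:
    """Training loss of one batch of normalized (x0, y0) pairs.

    Draws t uniformly from 1..T and eps ~ N(0, I) per pair; gradients flow
    into both the denoiser and the dimension-matching network (through the
    condition image y, the noisy state and the regression target).
    """
    if len(batch) == 0:
        raise ValueError("empty batch")
    x0 = np.stack([b[0] for b in batch]).transpose(0, 2, 3, 1)  # NHWC
    y0 = np.stack([b[1] for b in batch]).transpose(0, 2, 3, 1)
    B = x0.shape[0]
    t = rng.integers(1, schedule.T + 1, size=B)
    eps = rng.standard_normal(x0.shape).astype(np.float32)
    m_t = schedule.m[t].astype(np.float32)[:, None, None, None]
    sd_t = np.sqrt(schedule.delta[t]).astype(np.float32)[:, None, None, None]

    y = model.dimension_match_t(Tensor(y0))
    x0_t, eps_t = Tensor(x0), Tensor(eps)
    drift = ad.mul(ad.sub(y, x0_t), Tensor(m_t))          # m_t (y - x0)
    noise = ad.mul(eps_t, Tensor(sd_t))
    x_t = ad.add(x0_t, ad.add(drift, noise))              # forward sample
    target = ad.sub(x_t, x0_t)            # == m_t (y - x0) + sqrt(d) eps
    pred = model.unet_t(ad.concat_last(x_t, y), t)
    diff = ad.sub(target, pred)
    return ad.scale(ad.sum_sq(diff), 1.0 / diff.data.size)


def train_model(dataset, config: TrainConfig,
                denoiser_config: DenoiserConfig | None = None,
                out_path: str | Path | None = None,
                log_path: str | Path | None = None,
                callback=None) -> DenoiserModel:
    """Joint optimization of f_c and eps_theta on registered pairs.

    All pairs must share one super-resolution factor, which must match the
    denoiser configuration.  With ``init_checkpoint`` the parameters start
    from a previous model (transfer learning); otherwise they are built
    fresh from ``denoiser_config`` with the run seed.
    """
    if not dataset:
        raise ValueError("empty dataset")
    factors = {p.factor for p in dataset}
    if len(factors) != 1:
        raise ValueError(f"mixed super-resolution factors {factors}")
    factor = factors.pop()

    if config.init_checkpoint:
        model = DenoiserModel.load(config.init_checkpoint)
    else:
        if denoiser_config is None:
            from .network import default_toy_config
            denoiser_config = default_toy_config(sr_factor=factor)
        model = build_denoiser(denoiser_config, seed=config.seed)
    if model.config.sr_factor != factor:
        raise ValueError(
            f"dataset factor {factor} does not match model factor "
            f"{model.config.sr_factor}")
    model.t_max = config.T
    model.seed_lineage = tuple(model.seed_lineage) + (int(config.seed),)

    schedule = make_schedule(config.T)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    opt = AdamW(model.params, lr=config.learning_rate,
                weight_decay=config.weight_decay)
    ema = None
    if config.ema_decay:
        ema = {k: p.data.copy() for k, p in model.params.items()}
    log_rows = []
    step = 0
    t_start = time.time()
    while step < config.max_steps:
        patches = []
        for pair in dataset:
            patches.extend(make_patches(
                pair, config.patch_size, rng, augment=config.augment,
                random_offset=config.recrop_each_epoch))
        order = rng.permutation(len(patches))
        for s in range(0, len(order), config.batch_size):
            idx = order[s:s + config.batch_size]
            if len(idx) < config.batch_size and len(order) >= config.batch_size:
                continue  # drop ragged tail batch
            batch = [patches[i] for i in idx]
            if config.lr_schedule == "cosine":
                opt.lr = config.learning_rate * 0.5 * (
                    1 + np.cos(np.pi * step / config.max_steps))
            opt.zero_grad()
            loss = bb_loss(batch, model, schedule, rng)
            loss.backward()
            opt.step()
            if ema is not None:
                d = config.ema_decay
                for k, p in model.params.items():
                    ema[k] += (1.0 - d) * (p.data - ema[k])
            log_rows.append((step, float(loss.data),
                             time.time() - t_start))
            if callback is not None:
                callback(step, float(loss.data))
            step += 1
            if step >= config.max_steps:
                break

    if ema is not None and step > 0:
        for k, p in model.params.items():
            p.data = ema[k]
    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["step", "loss", "elapsed_s"])
            w.writerows(log_rows)
    model.loss_log = log_rows
    if out_path is not None:
        model.save(out_path)
    return model
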