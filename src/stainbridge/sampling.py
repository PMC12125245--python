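"""Engineered reverse-sampling strategies for the Brownian-bridge model.

Three strategies generate a virtual stain from the condition image
``y`` (all start at ``x_T = y`` and share identical stochastic stepping
above the exit point ``t_e``):

* ``vanilla`` — ancestral sampling: every step draws posterior noise with
  variance ``delta_tilde_t`` (the final step t = 1 is noiseless because
  ``delta_tilde_1 = 0``).
* ``mean`` — for ``t <= t_e`` the step takes the posterior mean only,
  suppressing the noise re-injection that makes repeated inferences differ.
* ``skip`` — at ``t = t_e`` the stain is estimated in one shot as
  ``x_te - eps_theta(x_te, t_e)`` and the chain stops.

Post-sampling averaging runs a strategy ``n_avg`` times on independent
noise streams and averages pixel-wise in continuous intensity space;
quantization to 8-bit happens once, after averaging.

Reproducibility contract: the noise of run ``r`` at step ``t`` comes from a
counter-based generator keyed by ``(base_seed, r, t)``, so outputs depend
only on ``(base_seed, run_index)`` and are independent across runs
regardless of execution order or batching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import DenoiserModel
from .schedule import BridgeSchedule
from .training import normalize_af_stack

__all__ = [
    "SamplingConfig",
    "rng_for",
    "vanilla_step",
    "mean_step",
    "skip_exit",
    "run_reverse",
    "run_reverse_batch",
    "average_inferences",
    "repeat_inferences",
]

_STRATEGIES = ("vanilla", "mean", "skip")


@dataclass(frozen=True)
class SamplingConfig:
    """Strategy, exit point, averaging count and seed of one inference."""

    strategy: str = "mean"
    t_e: int = 50
    n_avg: int = 1
    base_seed: int = 0

    def __post_init__(self):
        if self.strategy not in _STRATEGIES:
            raise ValueError(
                f"strategy {self.strategy!r} not in {_STRATEGIES}")
        if self.n_avg < 1:
            raise ValueError("n_avg must be >= 1")
        if self.t_e < 1:
            raise ValueError("t_e must be >= 1")

    def validate_against(self, schedule: BridgeSchedule) -> None:
        # vanilla sampling ignores the exit point
        if self.strategy != "vanilla" and self.t_e > schedule.T:
            raise ValueError(
                f"exit point t_e={self.t_e} exceeds T={schedule.T}")


def rng_for(base_seed: int, run_index: int, t: int) -> np.random.Generator:
    """Counter-based noise stream for (run, step); independent by keying."""
    return np.random.Generator(
        np.random.Philox(np.random.SeedSequence([base_seed, run_index, t])))


def _posterior_mean(x_t, y, t, eps_hat, schedule):
    c_x, c_y, c_eps = schedule.posterior_coefficients(t)
    return c_x * x_t + c_y * y - c_eps * eps_hat


def vanilla_step(x_t, y, t: int, model: DenoiserModel,
                 schedule: BridgeSchedule, rng: np.random.Generator):
    """One stochastic reverse step x_t -> x_{t-1} (Gaussian transition)."""
    if t < 1:
        raise ValueError("no reverse step below t = 1")
    eps_hat = model.predict_error(x_t, y, t)
    mean = _posterior_mean(x_t, y, t, eps_hat, schedule)
    var = schedule.step_noise_var(t)
    if var > 0.0:
        mean = mean + np.sqrt(var) * rng.standard_normal(
            mean.shape).astype(np.float32)
    return mean.astype(np.float32)


def mean_step(x_t, y, t: int, model: DenoiserModel,
              schedule: BridgeSchedule):
    """One noiseless reverse step: the posterior mean, no added variance."""
    if t < 1:
        raise ValueError("no reverse step below t = 1")
    eps_hat = model.predict_error(x_t, y, t)
    return _posterior_mean(x_t, y, t, eps_hat, schedule).astype(np.float32)


def skip_exit(x_te, t_e: int, y, model: DenoiserModel):
    """One-shot estimate of the stain at the exit point:
    ``x0_hat = x_te - eps_theta(x_te, t_e)``."""
    if t_e < 1:
        raise ValueError("t_e must be >= 1")
    return (np.asarray(x_te, dtype=np.float32)
            - model.predict_error(x_te, y, t_e))


def _denormalize(x: np.ndarray, spec: dict) -> np.ndarray:
    return x * float(spec["target_scale"]) + float(spec["target_offset"])


def _to_uint8(x: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(x), 0, 255).astype(np.uint8)


def _trajectories(y: np.ndarray, model: DenoiserModel,
                  schedule: BridgeSchedule, config: SamplingConfig,
                  run_indices) -> np.ndarray:
    """Run one reverse trajectory per batch element (element i uses noise
    stream (base_seed, run_indices[i], t)); returns x_0 in normalized
    intensity units, shape (B, 3, H, W)."""
    config.validate_against(schedule)
    T = schedule.T
    # vanilla steps stochastically all the way down; mean/skip only above t_e
    t_e = 0 if config.strategy == "vanilla" else config.t_e
    x = y.copy()
    B = x.shape[0]
    for t in range(T, t_e, -1):  # shared stochastic (vanilla) segment
        eps_hat = model.predict_error(x, y, t)
        x = _posterior_mean(x, y, t, eps_hat, schedule).astype(np.float32)
        var = schedule.step_noise_var(t)
        if var > 0.0:
            sd = np.sqrt(var)
            for i in range(B):
                rng = rng_for(config.base_seed, int(run_indices[i]), t)
                x[i] += (sd * rng.standard_normal(x.shape[1:])).astype(
                    np.float32)
    if config.strategy == "skip":
        return skip_exit(x, t_e, y, model)
    if config.strategy == "vanilla":
        return x
    for t in range(t_e, 0, -1):  # noiseless posterior-mean segment
        eps_hat = model.predict_error(x, y, t)
        x = _posterior_mean(x, y, t, eps_hat, schedule).astype(np.float32)
    return x


def run_reverse_batch(y0, model: DenoiserModel, schedule: BridgeSchedule,
                      config: SamplingConfig, run_indices) -> np.ndarray:
    """Float virtual stains (B, 3, H, W) on the 8-bit intensity scale, one
    trajectory per run index; ``y0`` is a single AF stack shared by all
    runs or a batch of stacks (one per run)."""
    y0 = np.asarray(y0, dtype=np.float32)
    run_indices = np.asarray(run_indices, dtype=np.int64)
    if y0.ndim == 3:
        y0 = y0[None]
    if y0.shape[0] == 1 and len(run_indices) > 1:
        y0 = np.broadcast_to(y0, (len(run_indices),) + y0.shape[1:])
    if y0.shape[0] != len(run_indices):
        raise ValueError("one AF stack (or one per run) required")
    y = model.dimension_match(normalize_af_stack(y0))
    x0 = _trajectories(y, model, schedule, config, run_indices)
    return _denormalize(x0, model.normalization_spec)


def run_reverse(y0, model: DenoiserModel, schedule: BridgeSchedule,
                config: SamplingConfig, run_index: int = 1) -> np.ndarray:
    """Single virtually stained image as 8-bit RGB (3, H, W)."""
    out = run_reverse_batch(y0, model, schedule, config, [run_index])
    return _to_uint8(out[0])


def average_inferences(y0, model: DenoiserModel, schedule: BridgeSchedule,
                       config: SamplingConfig) -> np.ndarray:
    """Pixel-wise mean of ``n_avg`` independent runs (run_index 1..n_avg),
    quantized to 8-bit RGB only after averaging."""
    out = run_reverse_batch(
        y0, model, schedule, config, np.arange(1, config.n_avg + 1))
    return _to_uint8(out.mean(axis=0))


def repeat_inferences(y0, model: DenoiserModel, schedule: BridgeSchedule,
                      config: SamplingConfig, n_repeats: int) -> np.ndarray:
    """``n_repeats`` independent ``n_avg``-averaged stains of one FOV
    (uint8, shape (n_repeats, 3, H, W)) for output-consistency analysis.

    Repeat i consumes the run-index block i*n_avg+1 .. (i+1)*n_avg, so all
    n_repeats * n_avg trajectories are mutually independent; they are run
    as one batch.
    """
    k = config.n_avg
    runs = np.arange(1, n_repeats * k + 1)
    out = run_reverse_batch(y0, model, schedule, config, runs)
    out = out.reshape(n_repeats, k, *out.shape[1:]).mean(axis=1)
    return np.stack([_to_uint8(o) for o in out])
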