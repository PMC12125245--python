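"""Closed-form quantities of the discrete Brownian-bridge diffusion process.

The forward process pins a target image ``x_0`` at step 0 and a
dimension-matched condition image ``y`` at step ``T``::

    x_t = x_0 + m_t (y - x_0) + sqrt(delta_t) * eps,   eps ~ N(0, I)

with the linear mixing schedule ``m_t = t / T`` and marginal variance
``delta_t = 2 t (T - t) / T^2`` (normalized-intensity units squared), so the
variance vanishes at both ends and peaks at ``T/2``.

Because the process is a Gaussian bridge, the reverse-time transition
``p(x_{t-1} | x_t, x_0, y)`` is Gaussian with a mean that is linear in
``x_t``, ``y`` and the forward error ``eps_theta ~ x_t - x_0``::

    mu'_t = c_x[t] * x_t + c_y[t] * y - c_eps[t] * eps_theta

and variance ``delta_tilde_t = delta_step_t * delta_{t-1} / delta_t`` where
``delta_step_t = delta_t - delta_{t-1} ((1-m_t)/(1-m_{t-1}))^2`` is the
one-step transition variance.  All arrays are precomputed once in double
precision at construction.

The first reverse step (t = T) is degenerate because ``delta_T = 0``; the
posterior given ``x_T = y`` collapses onto the forward marginal at ``T-1``
around the current estimate of ``x_0``.  ``posterior_coefficients`` and
``step_noise_var`` encode that resolution: at ``t = T`` the coefficients are
``(1 - m_{T-1}, m_{T-1}, 1 - m_{T-1})`` and the step noise variance is
``delta_{T-1}`` instead of the (0/0) ``delta_tilde_T``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BridgeSchedule",
    "make_schedule",
    "forward_sample",
    "training_target",
    "derive_posterior_coefficients",
]


@dataclass(frozen=True)
class BridgeSchedule:
    """Precomputed schedule arrays, index-aligned on t = 0..T.

    Coefficient arrays (``c_x``, ``c_y``, ``c_eps``) are defined for
    t = 1..T; their entry 0 is unused and set to 0.  ``delta_tilde[T]``
    stores the effective noise variance of the degenerate first reverse
    step, ``delta_{T-1}``.
    """

    T: int
    m: np.ndarray
    delta: np.ndarray
    delta_step: np.ndarray
    delta_tilde: np.ndarray
    c_x: np.ndarray
    c_y: np.ndarray
    c_eps: np.ndarray
    noiseless: bool = field(default=False)

    def posterior_coefficients(self, t: int) -> tuple[float, float, float]:
        """(c_x, c_y, c_eps) of the reverse-step mean at integer step t."""
        if not 1 <= t <= self.T:
            raise ValueError(f"reverse step t={t} outside 1..{self.T}")
        return float(self.c_x[t]), float(self.c_y[t]), float(self.c_eps[t])

    def step_noise_var(self, t: int) -> float:
        """Variance of the noise added by a stochastic reverse step at t."""
        if not 1 <= t <= self.T:
            raise ValueError(f"reverse step t={t} outside 1..{self.T}")
        if self.noiseless:
            return 0.0
        return float(self.delta_tilde[t])

    def without_noise(self) -> "BridgeSchedule":
        """Copy whose stochastic reverse steps add no noise (for the
        strategy-equivalence identity: vanilla with zeroed step noise must
        match noiseless posterior-mean stepping bit for bit)."""
        return BridgeSchedule(self.T, self.m, self.delta, self.delta_step,
                              self.delta_tilde, self.c_x, self.c_y,
                              self.c_eps, noiseless=True)


def make_schedule(T: int) -> BridgeSchedule:
    """Build the full schedule for ``T`` total diffusion steps (T >= 2)."""
    if not isinstance(T, (int, np.integer)) or T < 2:
        raise ValueError(f"T must be an integer >= 2, got {T!r}")
    T = int(T)
    t = np.arange(T + 1, dtype=np.float64)
    m = t / T
    delta = 2.0 * t * (T - t) / T**2

    # transition variance delta_{t|t-1}; ratio a_t = (1-m_t)/(1-m_{t-1})
    a = np.zeros(T + 1)
    a[1:] = (1.0 - m[1:]) / (1.0 - m[:-1])
    b = np.zeros(T + 1)
    b[1:] = m[1:] - m[:-1] * a[1:]
    delta_step = np.zeros(T + 1)
    delta_step[1:] = delta[1:] - delta[:-1] * a[1:] ** 2

    delta_tilde = np.zeros(T + 1)
    delta_tilde[1:T] = delta_step[1:T] * delta[:T - 1] / delta[1:T]
    delta_tilde[T] = delta[T - 1]  # degenerate first reverse step

    c_x = np.zeros(T + 1)
    c_y = np.zeros(T + 1)
    c_eps = np.zeros(T + 1)
    ts = slice(1, T)
    c_eps[ts] = (1.0 - m[:T - 1]) * delta_step[ts] / delta[ts]
    c_x[ts] = c_eps[ts] + a[ts] * delta[:T - 1] / delta[ts]
    c_y[ts] = (m[:T - 1] * delta_step[ts]
               - a[ts] * b[ts] * delta[:T - 1]) / delta[ts]
    # t = T: x_{T-1} = (1-m_{T-1}) x0_hat + m_{T-1} y with x0_hat = x_T - eps
    c_x[T] = 1.0 - m[T - 1]
    c_eps[T] = 1.0 - m[T - 1]
    c_y[T] = m[T - 1]

    for name, arr in (("m", m), ("delta", delta), ("delta_step", delta_step),
                      ("delta_tilde", delta_tilde), ("c_x", c_x),
                      ("c_y", c_y), ("c_eps", c_eps)):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(f"schedule array {name} not finite")

    return BridgeSchedule(T, m, delta, delta_step, delta_tilde,
                          c_x, c_y, c_eps)


def _check_step(schedule: BridgeSchedule, t: int) -> None:
    if not 0 <= t <= schedule.T:
        raise ValueError(f"step t={t} outside 0..{schedule.T}")


def forward_sample(x0, y, t: int, eps, schedule: BridgeSchedule):
    """Direct forward draw ``x_t = x_0 + m_t (y - x_0) + sqrt(delta_t) eps``.

    ``x0``, ``y`` and ``eps`` must share a shape; ``eps`` is a standard
    normal field supplied by the caller so the draw is reproducible.
    """
    x0, y, eps = np.asarray(x0), np.asarray(y), np.asarray(eps)
    if not (x0.shape == y.shape == eps.shape):
        raise ValueError(
            f"shape mismatch: x0 {x0.shape}, y {y.shape}, eps {eps.shape}")
    _check_step(schedule, t)
    m_t = schedule.m[t]
    # (1 - m) x0 + m y: algebraically x0 + m (y - x0), but exactly pinned
    # to x0 at t = 0 and to y at t = T in floating point
    return (1.0 - m_t) * x0 + m_t * y + np.sqrt(schedule.delta[t]) * eps


def training_target(x0, y, t: int, eps, schedule: BridgeSchedule):
    """The field the denoiser regresses on: ``m_t (y - x_0) + sqrt(delta_t) eps``.

    Identically equals ``forward_sample(...) - x0``.
    """
    x0 = np.asarray(x0)
    # bit-identical to forward_sample(...) - x0 by construction
    return forward_sample(x0, y, t, eps, schedule) - x0


def derive_posterior_coefficients(schedule: BridgeSchedule,
                                  t: int) -> tuple[float, float, float]:
    """Coefficients (c_x, c_y, c_eps) of the reverse-step posterior mean."""
    return schedule.posterior_coefficients(t)
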