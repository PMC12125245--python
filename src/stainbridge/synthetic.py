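"""Synthetic paired data with the statistical structure the method assumes.

Two families of fixtures:

* Histology-like image pairs — H&E-style RGB targets (purplish-blue
  elliptical nuclei over a pink stroma texture with white lumen patches)
  and pseudo-autofluorescence stacks derived from them by Beer-Lambert
  style optical-density conversion, linear channel mixing, Gaussian
  blurring, N x N mean binning and additive Gaussian noise.  Mixing in
  density space makes nuclei bright in the DAPI-like channel, as in real
  autofluorescence of unstained tissue.

* Analytic Gaussian toys — small jointly Gaussian (x_0, y) problems with a
  closed-form conditional law and an oracle denoiser, used to validate the
  bridge mathematics and the sampling strategies against exact answers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .schedule import BridgeSchedule, make_schedule

__all__ = [
    "SyntheticConfig",
    "ImagePair",
    "generate_stained_image",
    "derive_af_stack",
    "generate_pair",
    "generate_dataset",
    "GaussianToy",
    "generate_gaussian_toy",
]

# density-space mixing (rows: DAPI, TxRed, FITC, Cy5; columns: OD of R,G,B).
# Row 1 weights the red/green optical densities that are high inside
# hematoxylin-stained nuclei, so the DAPI-like plane is nucleus-bright.
DEFAULT_MIXING = np.array([
    [1.0, 0.5, 0.0],
    [0.0, 0.9, 0.4],
    [0.1, 0.4, 0.9],
    [0.4, 0.0, 0.7],
], dtype=np.float64)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults emulate a 2x super-resolution task."""

    image_size: int = 256
    sr_factor: int = 2
    nuclei_density: float = 6.0   # expected nuclei per 64x64 tile
    psf_sigma: float = 1.0        # px of Gaussian blur before binning
    noise_sigma: float = 0.02     # additive noise, normalized units
    af_channels: int = 4
    mixing_matrix: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.image_size % 8 or self.image_size % self.sr_factor:
            raise ValueError("image_size must be divisible by 8 and by "
                             "the super-resolution factor")
        if self.nuclei_density <= 0:
            raise ValueError("nuclei_density must be > 0")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")
        if not 1 <= self.af_channels <= 4:
            raise ValueError("af_channels must be 1..4")
        mix = self.mixing_matrix
        if not mix:
            mix = tuple(map(tuple, DEFAULT_MIXING[:self.af_channels]))
        mix_arr = np.asarray(mix, dtype=np.float64)
        if mix_arr.shape != (self.af_channels, 3) or np.any(mix_arr < 0):
            raise ValueError("mixing_matrix must be non-negative with "
                             "shape (af_channels, 3)")
        object.__setattr__(self, "mixing_matrix", tuple(map(tuple, mix_arr)))

    @property
    def mixing(self) -> np.ndarray:
        return np.asarray(self.mixing_matrix, dtype=np.float64)

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ImagePair:
    """Registered (autofluorescence stack, H&E target) pair."""

    af: np.ndarray        # (af_channels, H/N, W/N) float32
    he: np.ndarray        # (3, H, W) uint8
    factor: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.he.shape[1] != self.af.shape[1] * self.factor or \
                self.he.shape[2] != self.af.shape[2] * self.factor:
            raise ValueError("spatial ratio of pair must equal the factor")


def _ellipse_mask(h, w, cy, cx, a, b, theta):
    yy, xx = np.mgrid[0:h, 0:w]
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_stained_image(config: SyntheticConfig, seed: int) -> np.ndarray:
    """H&E-like 8-bit RGB target (3, H, W): Poisson-placed purplish-blue
    elliptical nuclei over pink stroma with white lumen regions."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    H = W = config.image_size

    # pink stroma with smooth eosin texture
    tex = gaussian_filter(rng.standard_normal((H, W)), 6.0)
    tex = (tex - tex.mean()) / max(tex.std(), 1e-9)
    img = np.empty((H, W, 3), dtype=np.float64)
    img[..., 0] = 232 + 10 * tex
    img[..., 1] = 170 + 22 * tex
    img[..., 2] = 200 + 14 * tex

    # white lumen patches where a second smooth field is high
    lum = gaussian_filter(rng.standard_normal((H, W)), 12.0)
    lum_mask = lum > np.quantile(lum, 0.88)
    img[lum_mask] = 246.0

    # nuclei: Poisson count over 64x64 tiles, overlap-avoiding placement
    n_tiles = (H / 64.0) * (W / 64.0)
    count = rng.poisson(config.nuclei_density * n_tiles)
    centers: list[tuple[float, float, float]] = []
    for _ in range(count):
        a = rng.uniform(3.0, 8.0)
        b = rng.uniform(3.0, 8.0)
        theta = rng.uniform(0.0, np.pi)
        for _attempt in range(40):
            cy = rng.uniform(0, H - 1)
            cx = rng.uniform(0, W - 1)
            r = max(a, b)
            if all((cy - py) ** 2 + (cx - px) ** 2 > (r + pr + 2.0) ** 2
                   for py, px, pr in centers):
                break
        centers.append((cy, cx, max(a, b)))
        mask = _ellipse_mask(H, W, cy, cx, a, b, theta)
        color = np.array([100.0, 82.0, 168.0]) + rng.normal(0, 1, 3) * (
            12.0, 9.0, 14.0)
        shade = 1.0 + 0.08 * tex[mask][:, None]
        img[mask] = color * shade

    return np.clip(np.rint(img), 0, 255).astype(np.uint8).transpose(2, 0, 1)


def derive_af_stack(he: np.ndarray, config: SyntheticConfig,
                    seed: int) -> np.ndarray:
    """Pseudo-autofluorescence stack from an H&E target: optical-density
    conversion, channel mixing, blur, N x N mean binning, additive noise."""
    he = np.asarray(he)
    N = config.sr_factor
    if he.shape[0] != 3:
        raise ValueError("he must be channel-first RGB")
    if he.shape[1] % N or he.shape[2] % N:
        raise ValueError(f"spatial dims {he.shape[1:]} not divisible by "
                         f"factor {N}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    od = -np.log10((he.astype(np.float64) + 1.0) / 256.0)  # Beer-Lambert
    planes = np.einsum("kc,chw->khw", config.mixing, od)
    if config.psf_sigma > 0:
        planes = np.stack(
            [gaussian_filter(p, config.psf_sigma) for p in planes])
    h, w = planes.shape[1] // N, planes.shape[2] // N
    planes = planes.reshape(-1, h, N, w, N).mean(axis=(2, 4))
    if config.noise_sigma > 0:
        planes = planes + rng.normal(0, config.noise_sigma, planes.shape)
    return planes.astype(np.float32)


def generate_pair(config: SyntheticConfig, seed: int) -> ImagePair:
    he = generate_stained_image(config, seed)
    af = derive_af_stack(he, config, seed)
    return ImagePair(af=af, he=he, factor=config.sr_factor,
                     meta={"seed": int(seed),
                           "config_hash": config.content_hash()})


def generate_dataset(config: SyntheticConfig, n_pairs: int,
                     n_holdout: int = 0,
                     out_dir: str | Path | None = None):
    """Seeded sequence of pairs, optionally written to disk.

    The first ``n_pairs - n_holdout`` pairs form the training split and the
    remainder the held-out split (disjoint by construction).  When
    ``out_dir`` is given, writes one float32 multi-plane TIFF and one 8-bit
    PNG per pair plus a JSON manifest carrying config and per-pair seeds.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if not 0 <= n_holdout < n_pairs:
        raise ValueError("n_holdout must be in [0, n_pairs)")
    pairs, records = [], []
    for i in range(n_pairs):
        pair_seed = int(
            np.random.SeedSequence([config.seed, i]).generate_state(1)[0]
            % (2 ** 31))
        pair = generate_pair(config, pair_seed)
        pair.meta["split"] = "train" if i < n_pairs - n_holdout else "holdout"
        pair.meta["index"] = i
        pairs.append(pair)
        records.append({"index": i, "seed": pair_seed,
                        "split": pair.meta["split"]})
    manifest = {"config": asdict(config), "n_pairs": n_pairs,
                "n_holdout": n_holdout, "pairs": records}
    if out_dir is not None:
        from . import io as sbio
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, pair in enumerate(pairs):
            af_name, he_name = f"pair{i:04d}_af.tiff", f"pair{i:04d}_he.png"
            sbio.write_af_stack(out_dir / af_name, pair.af, force=True)
            sbio.write_rgb(out_dir / he_name, pair.he, force=True)
            records[i]["af_file"] = af_name
            records[i]["he_file"] = he_name
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2))
    return pairs, manifest


# --------------------------------------------------------------- Gaussian toy

class GaussianToy:
    """Jointly Gaussian (x_0, y) with an exact oracle denoiser.

    x_0 ~ N(mu0, S0), y = A x_0 + b + eta with eta ~ N(0, Sn); all
    conditional laws are then closed-form, which makes the toy an
    independent ground truth for the reverse-sampling machinery.
    """

    def __init__(self, T: int, mu0, S0, A, b, Sn, seed: int):
        self.schedule: BridgeSchedule = make_schedule(T)
        self.mu0 = np.asarray(mu0, dtype=np.float64)
        self.S0 = np.asarray(S0, dtype=np.float64)
        self.A = np.asarray(A, dtype=np.float64)
        self.b = np.asarray(b, dtype=np.float64)
        self.Sn = np.asarray(Sn, dtype=np.float64)
        self.seed = int(seed)
        self.dims = self.mu0.shape[0]
        self.mu_y = self.A @ self.mu0 + self.b
        self.Sxy = self.S0 @ self.A.T                    # Cov(x0, y)
        self.Syy = self.A @ self.S0 @ self.A.T + self.Sn

    # ------------------------------------------------------------- sampling
    def sample_pairs(self, n: int, rng: np.random.Generator):
        x0 = rng.multivariate_normal(self.mu0, self.S0, size=n,
                                     method="svd")
        eta = rng.multivariate_normal(np.zeros(self.dims), self.Sn,
                                      size=n, method="svd")
        y = x0 @ self.A.T + self.b + eta
        return x0, y

    # ------------------------------------------------------- conditionals
    def posterior_x0_given_y(self, y):
        """Closed-form law of x_0 | y: (mean, covariance)."""
        y = np.asarray(y, dtype=np.float64)
        K = np.linalg.solve(self.Syy.T, self.Sxy.T).T   # Sxy Syy^-1
        mean = self.mu0 + (y - self.mu_y) @ K.T
        cov = self.S0 - K @ self.Sxy.T
        return mean, cov

    def _joint_xt(self, t: int):
        """Mean map and covariance blocks of (x_0, x_t, y) at step t."""
        m = self.schedule.m[t]
        d = self.schedule.delta[t]
        I = np.eye(self.dims)
        # x_t = (1-m) x0 + m y + sqrt(d) eps
        S00 = self.S0
        S0y = self.Sxy
        Syy = self.Syy
        S0t = (1 - m) * S00 + m * S0y
        Sty = (1 - m) * S0y + m * Syy
        Stt = ((1 - m) ** 2 * S00 + m ** 2 * Syy
               + m * (1 - m) * (S0y + S0y.T) + d * I)
        return m, S0t, Sty, Stt

    def oracle_eps(self, x_t, y, t: int):
        """Exact E[x_t - x_0 | x_t, y], the ideal denoiser output.

        Vectorized over leading axes of x_t / y.
        """
        x_t = np.asarray(x_t, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        m, S0t, Sty, Stt = self._joint_xt(t)
        # condition x_0 on z = (x_t, y)
        Szz = np.block([[Stt, Sty], [Sty.T, self.Syy]])
        S0z = np.concatenate([S0t, self.Sxy], axis=1)
        # pseudo-inverse: at t = T the state duplicates y and Szz is singular
        K = S0z @ np.linalg.pinv(Szz, hermitian=True, rcond=1e-12)
        mu_t = (1 - m) * self.mu0 + m * self.mu_y
        dz = np.concatenate(
            [x_t - mu_t, y - self.mu_y], axis=-1)
        x0_hat = self.mu0 + dz @ K.T
        return x_t - x0_hat

    # -------------------------------------------------- vectorized sampler
    def sample_reverse(self, y, n_runs: int, strategy: str = "vanilla",
                       t_e: int | None = None, seed: int | None = None):
        """Run ``n_runs`` reverse trajectories conditioned on a fixed ``y``
        with the oracle denoiser, vectorized over runs (per-step noise
        streams keyed by (seed, t)); returns samples of x_0, shape
        (n_runs, dims)."""
        sch = self.schedule
        T = sch.T
        seed = self.seed if seed is None else int(seed)
        t_exit = 0 if strategy == "vanilla" else int(t_e)
        y = np.asarray(y, dtype=np.float64)
        yb = np.broadcast_to(y, (n_runs, self.dims)).copy()
        x = yb.copy()
        for t in range(T, t_exit, -1):
            c_x, c_y, c_eps = sch.posterior_coefficients(t)
            x = c_x * x + c_y * yb - c_eps * self.oracle_eps(x, yb, t)
            var = sch.step_noise_var(t)
            if var > 0:
                rng = np.random.Generator(np.random.Philox(
                    np.random.SeedSequence([seed, t])))
                x = x + np.sqrt(var) * rng.standard_normal(x.shape)
        if strategy == "skip":
            return x - self.oracle_eps(x, yb, t_exit)
        for t in range(t_exit, 0, -1):
            c_x, c_y, c_eps = sch.posterior_coefficients(t)
            x = c_x * x + c_y * yb - c_eps * self.oracle_eps(x, yb, t)
        return x


def generate_gaussian_toy(T: int, dims: int, seed: int,
                          deterministic: bool = False) -> GaussianToy:
    """Random (but seeded) small Gaussian toy; ``dims <= 16``.

    With ``deterministic=True`` the condition determines the target exactly
    (y = A x_0 with invertible A and no observation noise), so every
    sampling strategy must recover x_0 to numerical precision.
    """
    if dims > 16:
        raise ValueError("toy problems are capped at dims <= 16")
    rng = np.random.default_rng(seed)
    mu0 = rng.normal(0, 1, dims)
    L = rng.normal(0, 0.6, (dims, dims))
    S0 = L @ L.T + 0.3 * np.eye(dims)
    A = np.eye(dims) + 0.3 * rng.normal(0, 1, (dims, dims))
    b = rng.normal(0, 0.5, dims)
    if deterministic:
        Sn = np.zeros((dims, dims))
    else:
        Ln = rng.normal(0, 0.3, (dims, dims))
        Sn = Ln @ Ln.T + 0.1 * np.eye(dims)
    return GaussianToy(T, mu0, S0, A, b, Sn, seed)
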