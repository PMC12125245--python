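"""Quantitative evaluation of virtual stains.

Implements the full evaluation battery: windowed SSIM, PSNR referenced to
the ground-truth image maximum, a pluggable perceptual (LPIPS-style)
distance, pixel-wise coefficient-of-variation analysis over YCbCr,
radially averaged power spectra, paired two-sided t-tests, and exit-point
sweeps.

Conventions (stated to the digit):

* SSIM uses the standard reference configuration — 11x11 Gaussian window
  with sigma 1.5, K1 = 0.01, K2 = 0.03, L = data range — averaged over
  channels for color images; a global-statistics variant is available via
  ``windowed=False``.
* YCbCr is BT.601 full range: Y = 0.299 R + 0.587 G + 0.114 B,
  Cb = 128 - 0.168736 R - 0.331264 G + 0.5 B,
  Cr = 128 + 0.5 R - 0.418688 G - 0.081312 B.
* CV uses the sample standard deviation (n-1); Cb/Cr keep their +128
  offset so denominators are well-behaved; zero-mean pixels are excluded
  and counted.
* PSNR = 10 log10(max(A)^2 / MSE) with max(A) the maximum pixel value of
  the reference image (not a fixed dynamic range); MSE = 0 maps to the
  +inf sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage.metrics import structural_similarity
from skimage.transform import resize

from .sampling import SamplingConfig, average_inferences

__all__ = [
    "ssim",
    "psnr",
    "mse",
    "lpips",
    "identity_extractor",
    "rgb_to_ycbcr",
    "cv_analysis",
    "CVResult",
    "radial_power_spectrum",
    "paired_t_test",
    "TTestResult",
    "exit_point_sweep",
    "MetricsReport",
]


# ------------------------------------------------------------------- SSIM

def _ssim_global(a, b, data_range):
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    cov = ((a - mu_a) * (b - mu_b)).sum() / (a.size - 1)
    return ((2 * mu_a * mu_b + c1) * (2 * cov + c2)
            / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)))


def ssim(a: np.ndarray, b: np.ndarray, data_range: float | None = None,
         windowed: bool = True) -> float:
    """Structural similarity between two images.

    Color inputs (channel-first (3, H, W) or (H, W, 3)) are scored per
    channel and averaged.  ``data_range`` defaults to 255 for 8-bit input
    and to the joint value range otherwise.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if data_range is None:
        if a.dtype == np.uint8 and b.dtype == np.uint8:
            data_range = 255.0
        else:
            lo = min(a.min(), b.min())
            hi = max(a.max(), b.max())
            data_range = float(hi - lo) or 1.0
    a = a.astype(np.float64)
    b = b.astype(np.float64)
    if a.ndim == 3:  # per-channel average
        axis = 0 if a.shape[0] in (3, 4) else 2
        chans = np.moveaxis(a, axis, 0), np.moveaxis(b, axis, 0)
        return float(np.mean([
            ssim(ca, cb, data_range=data_range, windowed=windowed)
            for ca, cb in zip(*chans)]))
    if not windowed:
        return float(_ssim_global(a, b, data_range))
    return float(structural_similarity(
        a, b, data_range=data_range, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03))


# ------------------------------------------------------------------- PSNR

def mse(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def psnr(reference: np.ndarray, estimate: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB, peak taken from the reference
    image's own maximum; returns +inf for identical images."""
    err = mse(reference, estimate)
    if err == 0.0:
        return float("inf")
    peak = float(np.asarray(reference, dtype=np.float64).max())
    return float(10.0 * np.log10(peak**2 / err))


# ------------------------------------------------------------------ LPIPS

def identity_extractor(img: np.ndarray) -> list[np.ndarray]:
    """Trivial single-layer feature extractor (the image itself), used to
    exercise the perceptual-distance formula without pretrained weights."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 2:
        img = img[None]
    return [img]


def lpips(m: np.ndarray, m0: np.ndarray, feature_extractor=None) -> float:
    """Perceptual distance: sum over layers of the spatial mean of squared
    differences of channel-unit-normalized feature maps.

    ``feature_extractor`` maps an image to a list of (C, H, W) feature
    stacks (e.g. a pretrained VGG backbone supplied by the caller; weights
    are not bundled).
    """
    if feature_extractor is None:
        raise ValueError(
            "perceptual backend not configured: pass feature_extractor "
            "(e.g. a pretrained VGG feature stack, or identity_extractor "
            "for a weight-free check)")
    total = 0.0
    for fa, fb in zip(feature_extractor(np.asarray(m)),
                      feature_extractor(np.asarray(m0))):
        na = fa / np.maximum(
            np.sqrt((fa**2).sum(axis=0, keepdims=True)), 1e-10)
        nb = fb / np.maximum(
            np.sqrt((fb**2).sum(axis=0, keepdims=True)), 1e-10)
        total += float(((na - nb) ** 2).sum(axis=0).mean())
    return total


# ------------------------------------------------------------------ YCbCr

_YCBCR = np.array([
    [0.299, 0.587, 0.114],
    [-0.168736, -0.331264, 0.5],
    [0.5, -0.418688, -0.081312],
])
_YCBCR_OFFSET = np.array([0.0, 128.0, 128.0])


def rgb_to_ycbcr(rgb: np.ndarray) -> np.ndarray:
    """BT.601 full-range conversion of a channel-first 8-bit RGB image."""
    rgb = np.asarray(rgb, dtype=np.float64)
    return (np.einsum("kc,chw->khw", _YCBCR, rgb)
            + _YCBCR_OFFSET[:, None, None])


@dataclass
class CVResult:
    cv_maps: np.ndarray          # (3, H, W) in %, nan where excluded
    mean_cv: dict                # channel -> mean CV in %
    excluded: dict               # channel -> count of zero-mean pixels


def cv_analysis(stack: np.ndarray) -> CVResult:
    """Pixel-wise coefficient of variation across k repeated inferences.

    ``stack`` holds k >= 2 8-bit RGB images (k, 3, H, W) of one FOV.  Each
    image is converted to YCbCr; per pixel and channel the sample standard
    deviation (ddof 1) is divided by the mean over the k repeats.  Pixels
    with zero mean are excluded and counted.
    """
    stack = np.asarray(stack)
    if stack.ndim != 4 or stack.shape[1] != 3:
        raise ValueError("stack must be (k, 3, H, W)")
    if stack.shape[0] < 2:
        raise ValueError("CV needs at least 2 repeated inferences")
    ycc = np.stack([rgb_to_ycbcr(img) for img in stack])  # (k, 3, H, W)
    mean = ycc.mean(axis=0)
    sd = ycc.std(axis=0, ddof=1)
    # pixels identical across repeats have exactly zero spread (guard the
    # rounding of the two-pass variance on identical floats)
    sd[np.ptp(ycc, axis=0) == 0] = 0.0
    valid = mean != 0
    cv = np.full(mean.shape, np.nan)
    cv[valid] = sd[valid] / mean[valid] * 100.0
    names = ("Y", "Cb", "Cr")
    mean_cv = {n: float(np.nanmean(cv[i])) for i, n in enumerate(names)}
    excluded = {n: int((~valid[i]).sum()) for i, n in enumerate(names)}
    return CVResult(cv_maps=cv, mean_cv=mean_cv, excluded=excluded)


# --------------------------------------------------------------- spectrum

def radial_power_spectrum(img: np.ndarray,
                          upsample_factor: int = 1) -> np.ndarray:
    """Radially averaged power spectrum of a square grayscale image.

    Low-resolution inputs are first bilinearly upsampled by
    ``upsample_factor`` to the reference sampling grid.  Returns the mean
    squared DFT magnitude over integer-radius annuli from the spectrum
    center (index = radius in cycles per frame).
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image (Y channel)")
    if img.shape[0] != img.shape[1]:
        raise ValueError(f"non-square input {img.shape}")
    if upsample_factor > 1:
        img = resize(img, (img.shape[0] * upsample_factor,) * 2,
                     order=1, anti_aliasing=False, preserve_range=True)
    F = np.fft.fftshift(np.fft.fft2(img))
    power = np.abs(F) ** 2
    n = img.shape[0]
    cy = cx = n // 2
    yy, xx = np.ogrid[0:n, 0:n]
    r = np.rint(np.hypot(yy - cy, xx - cx)).astype(int)
    n_r = r.max() + 1
    sums = np.bincount(r.ravel(), weights=power.ravel(), minlength=n_r)
    counts = np.bincount(r.ravel(), minlength=n_r)
    return sums / counts


# ---------------------------------------------------------------- t-tests

@dataclass
class TTestResult:
    t: float
    p: float
    dof: int
    degenerate: bool = False


def paired_t_test(metric_a, metric_b) -> TTestResult:
    """Classical paired two-sided t-test on per-FOV metric values.

    Degenerate case (all paired differences exactly zero) is flagged
    instead of fabricating a statistic.  Significance convention for
    downstream use: alpha = 0.05, p-values unadjusted.
    """
    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length vectors")
    if a.size < 2:
        raise ValueError("need at least 2 paired values")
    d = a - b
    if np.all(d == 0.0):
        return TTestResult(t=np.nan, p=np.nan, dof=a.size - 1,
                           degenerate=True)
    res = stats.ttest_rel(a, b)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue),
                       dof=int(a.size - 1))


# ------------------------------------------------------------------ sweep

def exit_point_sweep(model, schedule, dataset, strategy: str, points,
                     base_seed: int = 0, n_avg: int = 1,
                     feature_extractor=None) -> list[dict]:
    """SSIM (and optionally perceptual distance) per exit point.

    Runs ``strategy`` over the held-out pairs at each exit point in
    ``points`` with fixed counter-based seeds; one result row per t_e.
    The paper-scale grid spans nine points from 10 to 500.
    """
    points = list(points)
    if not points:
        raise ValueError("empty exit-point grid")
    if any(not 1 <= p <= schedule.T for p in points):
        raise ValueError(f"exit points must lie in 1..{schedule.T}")
    rows = []
    for t_e in points:
        cfg = SamplingConfig(strategy=strategy, t_e=int(t_e),
                             n_avg=n_avg, base_seed=base_seed)
        ssims, lps = [], []
        for pair in dataset:
            out = average_inferences(pair.af, model, schedule, cfg)
            ssims.append(ssim(out, pair.he))
            if feature_extractor is not None:
                lps.append(lpips(out, pair.he, feature_extractor))
        row = {"t_e": int(t_e), "ssim": float(np.mean(ssims))}
        if lps:
            row["lpips"] = float(np.mean(lps))
        rows.append(row)
    return rows


DEFAULT_EXIT_POINTS = (10, 25, 50, 100, 150, 200, 300, 400, 500)


@dataclass
class MetricsReport:
    """Container of per-FOV metrics plus aggregate statistics."""

    per_fov: list = field(default_factory=list)   # dicts per FOV
    cv: dict = field(default_factory=dict)        # channel -> mean CV (%)
    spectra: dict = field(default_factory=dict)
    tests: dict = field(default_factory=dict)     # name -> TTestResult

    def summary(self) -> dict:
        out = {}
        if self.per_fov:
            keys = [k for k in self.per_fov[0] if k != "fov"]
            for k in keys:
                vals = [row[k] for row in self.per_fov
                        if np.isfinite(row[k])]
                if vals:
                    out[f"mean_{k}"] = float(np.mean(vals))
        out.update({f"cv_{k}": v for k, v in self.cv.items()})
        return out
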