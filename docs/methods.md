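# Methods

## Model

`stainbridge` treats virtual staining as conditional image-to-image
translation through a pinned diffusion process.  Let `x_0` be the
histochemically stained RGB target (normalized to `[-1, 1]`) and `y_0` the
registered multi-channel autofluorescence (AF) stack of the same
label-free field of view, acquired at `1/N` of the target's lateral
sampling (pixel super-resolution factor `N`).  A shallow two-convolution
network with a pixel-shuffle of upscale `N`, `f_c`, lifts `y_0` to a
3-channel condition image `y = f_c(y_0)` on the target grid, so a single
model performs resolution enhancement and staining jointly.

The forward process is a discrete Brownian bridge pinned at both ends,

    x_t = (1 - m_t) x_0 + m_t y + sqrt(delta_t) eps,
    m_t = t / T,   delta_t = 2 t (T - t) / T^2,   t = 0 .. T,

with `T = 1000`.  The marginal variance vanishes at both ends and peaks at
`T/2`; `x_T = y` exactly.  A U-Net `eps_theta(x_t, y, t)` is trained to
regress the forward error `x_t - x_0 = m_t (y - x_0) + sqrt(delta_t) eps`
under uniform timestep weighting (`gamma_t = 1`):

    L = E || (x_t - x_0) - eps_theta(concat(x_t, y), t) ||^2 .

### Reverse-step coefficients

Because the bridge is Gaussian and Markov, the reverse transition given
`(x_t, x_0, y)` is Gaussian with variance
`delta_tilde_t = delta_step_t * delta_{t-1} / delta_t`, where
`delta_step_t = delta_t - delta_{t-1} a_t^2` and
`a_t = (1 - m_t)/(1 - m_{t-1})`.  Substituting the network's error
estimate for `x_t - x_0` gives the posterior-mean parameterization

    mu'_t = c_x[t] x_t + c_y[t] y - c_eps[t] eps_theta,
    c_eps[t] = (1 - m_{t-1}) delta_step_t / delta_t,
    c_x[t]   = c_eps[t] + a_t delta_{t-1} / delta_t,
    c_y[t]   = (m_{t-1} delta_step_t - a_t b_t delta_{t-1}) / delta_t,

with `b_t = (m_t - m_{t-1}) / (1 - m_{t-1})`.  These closed forms were
derived by standard Gaussian conditioning of the jointly normal
`(x_{t-1}, x_t)` given `(x_0, y)` and are verified in the test suite
against an independent brute-force conditioning oracle (agreement to
1e-10 on a `T = 10` scalar schedule) and by the telescoping identity that
noiseless stepping with the exact error recovers `x_0`.

Two degenerate indices need care.  `delta_tilde_1 = 0` (forced by
`delta_0 = 0`), so the final reverse step is always noiseless.  At
`t = T`, `delta_T = 0` makes the generic expression 0/0; the posterior
given `x_T = y` collapses onto the forward marginal at `T - 1` around the
current estimate of the target, so the first reverse step draws

    x_{T-1} = (1 - m_{T-1}) (x_T - eps_theta) + m_{T-1} y
              + sqrt(delta_{T-1}) z .

This is the standard resolution for bridges pinned at the terminal state.

### Sampling strategies

All strategies start at `x_T = y` and share identical stochastic
(`vanilla`) stepping above the exit point `t_e` (default 50):

* **vanilla** — ancestral sampling with noise variance `delta_tilde_t` at
  every step;
* **mean** — for `t <= t_e` the transition noise is dropped and the chain
  follows the posterior mean only;
* **skip** — at `t_e` the output is estimated in one shot as
  `x_{t_e} - eps_theta(x_{t_e}, t_e)` and the chain stops.

Post-sampling averaging runs a strategy `n_avg` times on independent
noise streams and averages pixel-wise in continuous intensity space;
quantization to 8 bits happens once, after averaging, to avoid rounding
bias in consistency measurements.  When `k` repeated averaged outputs are
produced (the consistency experiment), repeat `i` consumes run indices
`i*n_avg+1 .. (i+1)*n_avg`, so all `k * n_avg` trajectories are mutually
independent.

Reproducibility contract: the noise of run `r` at step `t` comes from a
counter-based Philox stream keyed by `(base_seed, r, t)`; outputs depend
only on `(base_seed, run_index)`, independent of execution order and
batching.

## Network

The denoiser is a U-Net with one down-sampling and one up-sampling path
joined by skip concatenations; adjacent levels are connected by 2x2
average pooling (down) and 2x2 nearest-neighbour interpolation (up); the
middle block is residual / multi-head attention / residual.  Residual
blocks use group normalization and SiLU; the timestep enters through
interleaved sin/cos positional features followed by a linear layer, then
per block through SiLU + linear, added to the block input as a channel
bias.  Inference is a pure function of parameters and inputs (no
stochastic layers), which the bit-reproducibility tests rely on.

The network is implemented on a compact tape-based reverse-mode autodiff
engine (`stainbridge.autodiff`) carrying exactly the operator set the
model needs; convolutions run as shift-and-accumulate matrix products in
NHWC layout.  Optimization is AdamW (constant learning rate by default,
cosine decay optional); inference uses an exponential moving average of
the weights (decay 0.995, disableable), the usual stabilizer for
short-schedule diffusion training.

Full-fidelity layout: four levels per path, attention in every level.
Desk-scale default (`default_toy_config`): base width 6 with channel
multipliers (1, 2, 3, 4), single-convolution residual blocks, attention
at the lowest-resolution level and the middle block, 2 heads.  The
reduced width and block depth keep a full `T = 1000` reverse trajectory
batch tractable on one CPU core; both layouts are plain configuration.

Initialization is seeded He-normal; output-facing convolutions (residual
second conv, attention projection, final conv) start at a tenth of the He
scale so the untrained network is near the identity on its skip
connections while every branch still receives gradient (the suite checks
that no parameter has a dead gradient path).

## Normalization

AF patches are standardized to zero mean and unit variance per channel
(per patch at training time, per image at inference).  Targets are mapped
affinely from `[0, 255]` to `[-1, 1]`; the inverse map is stored in the
checkpoint's `normalization_spec` and applied before quantization.
Patches are cut on a non-overlapping grid whose offset can be
re-randomized each epoch; paired flips and 90-degree rotations are
applied identically to both members.  Patch size must be divisible by 8
(three poolings) and by `N` (AF alignment); at `N = 5` this means
patch sizes like 200 rather than 192.

## Synthetic data

The generator emulates the statistical structure the method assumes —
nothing more.  H&E-like targets place Poisson-distributed purplish-blue
elliptical nuclei (axes 3-8 px, random orientation, slight color jitter,
overlap-avoiding placement) over a pink stroma texture (smoothed Gaussian
field) with white lumen patches.  Pseudo-AF stacks are derived from the
target by Beer-Lambert optical-density conversion, a non-negative 3->4
channel mixing whose first row is nucleus-weighted (DAPI-like), Gaussian
blur (`psf_sigma = 1` px), `N x N` mean binning and additive Gaussian
noise (`sigma = 0.02` normalized units).  Defaults: 6 nuclei per 64x64
tile, the density used throughout the tests.

What this emulates: informative, nearly invertible AF-to-stain structure,
channel-wise informativeness (nuclei bright in channel 1), band-limiting
from binning.  What it does not: registration artifacts (out of scope),
multimodal stain ambiguity, scanner color profiles, tissue-scale
morphology.  Passing tests therefore demonstrate the correctness of the
machinery and the variance behaviour of the samplers, not clinical-grade
staining fidelity.

The analytic Gaussian toys define jointly normal `(x_0, y)` with a
closed-form conditional law and an exact oracle denoiser
`E[x_t - x_0 | x_t, y]`; they are the ground truth for the sampling
tests.

## Numerical choices and tolerances

* Schedule arrays are precomputed once in double precision; network
  arithmetic is float32.
* Monte-Carlo checks use 3-standard-error bands at their stated draw
  counts.
* Ancestral sampling with the learned-transition variance
  `delta_tilde_t` omits the `c_eps^2 Var(x_0 | x_t, y)` term of the exact
  reverse conditional, a deficit that vanishes as the schedule is
  refined.  On the 2-D Gaussian toy the output-variance deficit is ~5% at
  `T = 1000` — outside a 3-SE band at 10^4 runs — and ~1% at `T = 4000`;
  the distribution-match test therefore runs the toy at `T = 4000`, where
  stepping bias is negligible against the Monte-Carlo band.  The image
  pipeline keeps `T = 1000`.
* On the Gaussian toy, the output variance of the mean strategy is
  non-increasing in the exit point `t_e`: raising `t_e` replaces
  stochastic steps by posterior-mean steps, which can only remove
  injected noise.  At `t_e = T` the trajectory is fully deterministic.
* SSIM follows the standard reference configuration (11x11 Gaussian
  window, sigma 1.5, K1 = 0.01, K2 = 0.03, L = data range), per channel
  and averaged for color; a global-statistics variant is exposed behind a
  flag.  PSNR references the ground-truth image's own maximum, not a
  fixed dynamic range, and returns `+inf` for identical images.
* YCbCr uses BT.601 full-range coefficients (0.299/0.587/0.114;
  Cb = 128 - 0.168736 R - 0.331264 G + 0.5 B;
  Cr = 128 + 0.5 R - 0.418688 G - 0.081312 B).  CV uses the sample
  standard deviation (n-1); Cb/Cr keep the +128 offset so denominators
  are well-behaved; zero-mean pixels are excluded and counted.
* The perceptual distance implements the unit-normalized feature-map
  formulation with a caller-supplied extractor; pretrained VGG weights
  are not bundled, and a trivial identity extractor exercises the formula
  in tests.
* Paired comparisons use the classical two-sided paired t-test
  (significance convention 0.05, p-values unadjusted); the all-zero
  difference case returns a degenerate flag rather than a statistic.

## Desk-scale problem sizes

The packaged experiments are sized for a single CPU core.  The
consistency experiment (`scripts/acceptance.py`) generates 46 paired
64x64 FOVs at factor 1 (40 train / 6 held out), trains the desk-scale
network for 2000 AdamW steps (batch 16, 32-pixel patches, learning rate
2e-3 — the short-schedule, small-network analogue of the full-scale
recipe of batch 16 at rate 1e-4), then produces five 5-average
mean-sampling outputs per held-out FOV (t_e = 50, T = 1000; 150 full
reverse trajectories in total) and reports the mean pixel-wise CV of the
chroma channels.  The test suite repeats the same protocol at reduced
size from a session-scoped trained fixture.

## Known limitations

* The numpy engine is single-threaded and memory-bandwidth bound; the
  full-fidelity configuration (base width 32+, attention at every level,
  192-pixel patches) is expressible but not practical without a GPU
  backend.
* The universal cross-factor model and accelerated samplers (DDIM/PLMS
  step subsampling) are out of scope.
* `make_patches` requires the patch size to be an integer multiple of
  `N`, so the AF crop is pixel-aligned; fractional alignments would
  require resampling, which the registration-free synthetic setting
  deliberately avoids.
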