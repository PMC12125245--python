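# stainbridge

Pixel super-resolved **virtual staining** of label-free tissue with a
**Brownian-bridge diffusion model**.

Histochemical staining (e.g. hematoxylin & eosin, H&E) is the workhorse of
diagnostic pathology but is slow, destructive and chemically variable.
Virtual staining replaces it computationally: multi-channel
autofluorescence (AF) images of the unstained section (DAPI, TxRed, FITC,
Cy5 filter channels) are translated into brightfield H&E-like images.
`stainbridge` implements a conditional diffusion approach in which the AF
stack may be acquired at `1/N` of the target lateral sampling; the model
simultaneously virtually stains and raises the space-bandwidth product by
`N^2` (up to 25x at `N = 5`).

The package is aimed at method developers: every mathematical component —
the bridge schedule, the reverse-step coefficients, the engineered
sampling strategies, and the evaluation battery — is exposed, tested
against closed-form oracles, and exercisable end-to-end on synthetic
paired data at desk scale on a single CPU.

## Model

With `x_0` the stained target and `y = f_c(y_0)` the dimension-matched
condition image (a shallow CNN with a pixel shuffle lifts the AF stack
`y_0` to the target grid), the forward process is a Brownian bridge
pinned at both ends,

    x_t = (1 - m_t) x_0 + m_t y + sqrt(delta_t) eps_t,
    m_t = t/T,  delta_t = 2 t (T - t) / T^2,  T = 1000,

and a U-Net `eps_theta` is trained with the uniform-weight objective

    L = E || m_t (y - x_0) + sqrt(delta_t) eps_t - eps_theta(x_t, t) ||^2.

The reverse transition is Gaussian with mean
`mu'_t = c_x x_t + c_y y - c_eps eps_theta` and variance
`delta_tilde_t`; the closed-form coefficients are derived and verified in
`stainbridge.schedule` (see `docs/methods.md`).  Three reverse-sampling
strategies are provided — **vanilla** (fully stochastic), **mean**
(noiseless posterior-mean steps below an exit point `t_e`, default 50)
and **skip** (one-shot exit at `t_e`) — plus pixel-wise averaging of
repeated runs.  Mean sampling with 5-times averaging is the
recommended operating point: it suppresses the run-to-run variance of
diffusion inference to sub-percent coefficients of variation while
preserving image quality.

## Worked example

```bash
# 1. synthesize a paired dataset: H&E-like targets + pseudo-AF stacks
stainbridge simulate --n 12 --size 64 --factor 1 --holdout 2 --seed 11 \
    --out data/

# 2. train the desk-scale model (a few minutes on one core)
cat > train.yaml <<EOF
T: 1000
max_steps: 800
batch_size: 8
patch_size: 32
learning_rate: 0.002
EOF
stainbridge train --data data/ --factor 1 --config train.yaml \
    --out model.npz

# 3. virtually stain a held-out AF stack (mean sampling, 5x averaging)
stainbridge infer --input data/pair0010_af.tiff --checkpoint model.npz \
    --strategy mean --t-exit 50 --n-avg 5 --seed 7 --output stain.png

# 4. score against the ground-truth target
mkdir -p pred truth
cp stain.png pred/pair0010.png
cp data/pair0010_he.png truth/pair0010.png
stainbridge evaluate --pred pred/ --truth truth/ --metrics ssim,psnr \
    --report report.json
```

The evaluate step prints the per-FOV summary, e.g.

```json
{
  "mean_ssim": 0.793,
  "mean_psnr": 18.73
}
```

meaning the virtual stain reaches SSIM 0.79 and PSNR 18.7 dB against the
held-out histochemical target after 800 training steps — a deliberately
small run; the consistency experiment below trains longer.  Inference
writes a provenance JSON (config hash, seed, package version) next to
every artifact, and rerunning any command with the same seeds reproduces
outputs bit for bit.

Python API equivalents live in `stainbridge` (`generate_dataset`,
`train_model`, `run_reverse`, `average_inferences`,
`metrics.cv_analysis`, ...); see `docs/methods.md` for the science.

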