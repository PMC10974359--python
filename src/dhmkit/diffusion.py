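"""Desk-scale conditional denoising diffusion (DDPM/IDDPM machinery).

The forward process corrupts a clean profile x₀ through T Gaussian steps

    q(x_t | x_{t−1}) = N(x_t; sqrt(1−β_t)·x_{t−1}, β_t·I)

whose marginal admits direct sampling with ᾱ_t = Π_{s≤t}(1−β_s):

    q(x_t | x₀)      = N(x_t; sqrt(ᾱ_t)·x₀, (1−ᾱ_t)·I)

A network predicts the injected noise ε from (x_t, t) plus a conditioning
channel (the noisy profile to be cleaned); the predicted noise inverts the
marginal to an x₀ estimate, and ancestral reverse sampling walks x_T ~ N(0,I)
back to a denoised profile.  Training minimizes the reweighted objective
L_simple = E‖ε − ε̂‖² plus a small variational (KL) term, the hybrid
L_MSE + λ·L_KL objective.

Everything here is sized for a single CPU: small images, short schedules and
a compact convolutional predictor (:mod:`dhmkit._net`).  The full-scale
training configuration used for real microscope data (2000 images at
875×656, 80 000 Adam iterations, batch 8) is preserved as a preset but is far
beyond desk scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from dhmkit._net import Adam, ConvDenoiserNet
from dhmkit.height import HeightMap

__all__ = [
    "NoiseSchedule",
    "DiffusionConfig",
    "DenoiserModel",
    "LossReport",
    "HeightScaler",
    "build_schedule",
    "q_sample",
    "q_step",
    "predict_x0",
    "posterior_mean",
    "kl_gaussian",
    "losses",
    "train_conditional_denoiser",
    "denoise_profile",
    "reverse_sample",
    "save_model",
    "load_model",
    "FULL_SCALE_PRESET",
]

#: training settings used at full scale on real microscope data; kept as a
#: reference preset, not exercised on a desk CPU
FULL_SCALE_PRESET = {
    "n_images": 2000,
    "image_resolution": (875, 656),
    "optimizer": "Adam",
    "iterations": 80_000,
    "batch_size": 8,
}


@dataclass(frozen=True)
class NoiseSchedule:
    """β_t, α_t = 1−β_t and ᾱ_t = Π α_s for t = 1..T (index 0 ⇔ t = 1)."""

    betas: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.betas, dtype=float)
        if b.ndim != 1 or b.size < 1:
            raise ValueError("schedule needs at least one step")
        if np.any(b <= 0) or np.any(b >= 1):
            raise ValueError("all betas must lie in the open interval (0, 1)")
        object.__setattr__(self, "betas", b)

    @property
    def T(self) -> int:
        return self.betas.size

    @property
    def alphas(self) -> np.ndarray:
        return 1.0 - self.betas

    @property
    def alpha_bars(self) -> np.ndarray:
        return np.cumprod(self.alphas)

    def alpha_bar(self, t: int | np.ndarray) -> np.ndarray:
        """ᾱ_t with the convention ᾱ_0 = 1."""
        t = np.asarray(t)
        ab = np.concatenate([[1.0], self.alpha_bars])
        return ab[t]


def build_schedule(
    T: int,
    kind: str = "cosine",
    beta_min: float = 1e-4,
    beta_max: float = 0.02,
) -> NoiseSchedule:
    """Noise schedule of T steps.

    ``linear``: β_t linearly spaced from beta_min to beta_max (the original
    DDPM choice, appropriate for T in the hundreds).  ``cosine``: ᾱ_t follows
    a squared cosine, which keeps ᾱ_T near zero even for short schedules and
    is the default here (betas clipped to ≤ 0.999).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if kind == "linear":
        if not (0.0 < beta_min <= beta_max < 1.0):
            raise ValueError(f"need 0 < beta_min <= beta_max < 1, got ({beta_min}, {beta_max})")
        betas = np.linspace(beta_min, beta_max, T)
    elif kind == "cosine":
        s = 0.008
        t = np.arange(T + 1)
        f = np.cos(((t / T + s) / (1 + s)) * math.pi / 2.0) ** 2
        alpha_bar = f / f[0]
        betas = np.clip(1.0 - alpha_bar[1:] / alpha_bar[:-1], 1e-8, 0.999)
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")
    return NoiseSchedule(betas=betas)


def _check_t(t: int, T: int) -> None:
    if not (1 <= t <= T):
        raise ValueError(f"step t={t} out of range 1..{T}")


def q_sample(x0: np.ndarray, t: int, schedule: NoiseSchedule, eps: np.ndarray) -> np.ndarray:
    """Sample the forward marginal: x_t = sqrt(ᾱ_t)·x₀ + sqrt(1−ᾱ_t)·ε."""
    _check_t(t, schedule.T)
    ab = schedule.alpha_bars[t - 1]
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps


def q_step(x_prev: np.ndarray, t: int, schedule: NoiseSchedule, eps: np.ndarray) -> np.ndarray:
    """One forward step: x_t = sqrt(1−β_t)·x_{t−1} + sqrt(β_t)·ε."""
    _check_t(t, schedule.T)
    beta = schedule.betas[t - 1]
    return np.sqrt(1.0 - beta) * x_prev + np.sqrt(beta) * eps


def predict_x0(x_t: np.ndarray, t: int, eps_hat: np.ndarray, schedule: NoiseSchedule) -> np.ndarray:
    """Invert the forward marginal: x̂₀ = (x_t − sqrt(1−ᾱ_t)·ε̂)/sqrt(ᾱ_t).

    Exact round trip with :func:`q_sample` when ε̂ equals the true ε.
    """
    _check_t(t, schedule.T)
    ab = schedule.alpha_bars[t - 1]
    if ab == 0:
        raise ValueError("alpha_bar is zero at this step; x0 is unrecoverable")
    return (x_t - np.sqrt(1.0 - ab) * eps_hat) / np.sqrt(ab)


def posterior_mean(x_t: np.ndarray, x0: np.ndarray, t: int, schedule: NoiseSchedule) -> np.ndarray:
    """Mean of the true reverse posterior q(x_{t−1} | x_t, x₀)."""
    _check_t(t, schedule.T)
    beta = schedule.betas[t - 1]
    alpha = schedule.alphas[t - 1]
    ab_t = schedule.alpha_bars[t - 1]
    ab_prev = schedule.alpha_bar(t - 1)
    coef0 = np.sqrt(ab_prev) * beta / (1.0 - ab_t)
    coeft = np.sqrt(alpha) * (1.0 - ab_prev) / (1.0 - ab_t)
    return coef0 * x0 + coeft * x_t


def kl_gaussian(mean1, var1, mean2, var2) -> float:
    """Closed-form KL(N(mean1, var1·I) ‖ N(mean2, var2·I)), summed over elements."""
    m1, m2 = np.asarray(mean1, float), np.asarray(mean2, float)
    v1, v2 = np.asarray(var1, float), np.asarray(var2, float)
    if np.any(v1 <= 0) or np.any(v2 <= 0):
        raise ValueError("variances must be positive")
    kl = 0.5 * (np.log(v2 / v1) + (v1 + (m1 - m2) ** 2) / v2 - 1.0)
    return float(np.sum(kl))


@dataclass
class LossReport:
    """Per-batch loss terms: the reweighted MSE, the VLB pieces and the hybrid."""

    l_simple: float
    l_terminal: float              # L_T = KL(q(x_T|x0) ‖ N(0, I)), per pixel
    l_vlb_term: float              # L_{t−1} KL term (or L0 NLL when t == 1), per pixel
    term_name: str                 # "L0" or "L_{t-1}"
    lambda_kl: float
    hybrid: float


def losses(
    x0: np.ndarray,
    t: int,
    eps: np.ndarray,
    eps_hat: np.ndarray,
    schedule: NoiseSchedule,
    lambda_kl: float = 1e-3,
) -> LossReport:
    """Evaluate the training objective pieces for one (x₀, t, ε, ε̂) draw.

    ``l_simple`` is mean((ε − ε̂)²).  The variational term compares the true
    reverse posterior against the model's reverse kernel p_θ (mean from ε̂,
    variance fixed to β_t); at t = 1 it is the Gaussian negative
    log-likelihood of x₀ instead.  ``l_terminal`` is the prior-matching term,
    which vanishes as ᾱ_T → 0.  All KL/NLL terms are reported per pixel; the
    hybrid objective is l_simple + λ·l_vlb_term.
    """
    x0 = np.asarray(x0, float)
    if x0.shape != np.shape(eps) or np.shape(eps) != np.shape(eps_hat):
        raise ValueError("x0, eps and eps_hat must share a shape")
    _check_t(t, schedule.T)
    n = x0.size

    l_simple = float(np.mean((eps - eps_hat) ** 2))

    ab_T = schedule.alpha_bars[-1]
    l_terminal = kl_gaussian(np.sqrt(ab_T) * x0, 1.0 - ab_T, 0.0, 1.0) / n

    x_t = q_sample(x0, t, schedule, eps)
    beta = schedule.betas[t - 1]
    x0_hat = predict_x0(x_t, t, eps_hat, schedule)
    mu_theta = posterior_mean(x_t, x0_hat, t, schedule)
    if t == 1:
        # L0: continuous Gaussian decoder NLL of x0 under N(mu_theta, beta_1)
        nll = 0.5 * np.log(2 * math.pi * beta) + (x0 - mu_theta) ** 2 / (2 * beta)
        l_vlb = float(np.mean(nll))
        name = "L0"
    else:
        ab_t = schedule.alpha_bars[t - 1]
        ab_prev = schedule.alpha_bar(t - 1)
        var_q = (1.0 - ab_prev) / (1.0 - ab_t) * beta
        mu_q = posterior_mean(x_t, x0, t, schedule)
        l_vlb = kl_gaussian(mu_q, var_q, mu_theta, beta) / n
        name = "L_{t-1}"

    return LossReport(
        l_simple=l_simple,
        l_terminal=l_terminal,
        l_vlb_term=l_vlb,
        term_name=name,
        lambda_kl=lambda_kl,
        hybrid=l_simple + lambda_kl * l_vlb,
    )


# --------------------------------------------------------------------------
# conditional training and sampling
# --------------------------------------------------------------------------


@dataclass
class HeightScaler:
    """Affine map of height maps onto [−1, 1] by dataset min/max, invertible."""

    vmin: float
    vmax: float

    @classmethod
    def fit(cls, arrays) -> "HeightScaler":
        vmin = min(float(np.min(a)) for a in arrays)
        vmax = max(float(np.max(a)) for a in arrays)
        if vmax <= vmin:
            raise ValueError("degenerate data range")
        return cls(vmin=vmin, vmax=vmax)

    def transform(self, a: np.ndarray) -> np.ndarray:
        return 2.0 * (np.asarray(a, float) - self.vmin) / (self.vmax - self.vmin) - 1.0

    def inverse(self, a: np.ndarray) -> np.ndarray:
        return (np.asarray(a, float) + 1.0) / 2.0 * (self.vmax - self.vmin) + self.vmin


@dataclass(frozen=True)
class DiffusionConfig:
    """Desk-scale training configuration for the conditional denoiser."""

    T: int = 50
    schedule_kind: str = "cosine"
    iterations: int = 300
    batch_size: int = 8
    learning_rate: float = 2e-3
    channels: int = 32
    emb_dim: int = 32
    lambda_kl: float = 1e-3


@dataclass
class DenoiserModel:
    """Trained conditional ε-predictor plus everything needed to sample."""

    net: ConvDenoiserNet
    schedule: NoiseSchedule
    config: DiffusionConfig
    scaler: HeightScaler | None = None
    loss_history: list = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return self.net.n_params


def _as_array(x) -> np.ndarray:
    return x.values if isinstance(x, HeightMap) else np.asarray(x, dtype=float)


def train_conditional_denoiser(
    pairs,
    config: DiffusionConfig = DiffusionConfig(),
    seed: int = 0,
    scaler: HeightScaler | None = None,
) -> DenoiserModel:
    """Train ε̂_θ(x_t, t, condition) on (noisy, clean) profile pairs.

    The noisy profile is channel-concatenated with x_t as the conditional
    input; the clean profile plays x₀.  Inputs must already be normalized to
    [−1, 1] (use :class:`HeightScaler`; pass it in so sampling can invert the
    normalization).  Fully seeded: the same seed reproduces the same model.
    With ``config.iterations == 0`` the freshly initialized model is returned
    unchanged.
    """
    data = [(_as_array(nz), _as_array(cl)) for nz, cl in pairs]
    if len(data) < 1:
        raise ValueError("need at least one training pair")
    for nz, cl in data:
        if nz.shape != cl.shape:
            raise ValueError("noisy/clean shapes differ")
        for a in (nz, cl):
            if a.min() < -1.0 - 1e-9 or a.max() > 1.0 + 1e-9:
                raise ValueError(
                    "training images must be normalized to [-1, 1]; "
                    "use HeightScaler before training"
                )

    rng = np.random.default_rng(seed)
    schedule = build_schedule(config.T, kind=config.schedule_kind)
    net = ConvDenoiserNet(
        channels=config.channels, emb_dim=config.emb_dim,
        t_max=config.T, seed=int(rng.integers(2**31)),
    )
    model = DenoiserModel(net=net, schedule=schedule, config=config, scaler=scaler)
    if config.iterations == 0:
        return model

    opt = Adam(net.params, lr=config.learning_rate)
    noisy = np.stack([nz for nz, _ in data])
    clean = np.stack([cl for _, cl in data])
    n = len(data)
    betas = schedule.betas
    alphas = schedule.alphas
    abars = schedule.alpha_bars

    for _ in range(config.iterations):
        idx = rng.integers(0, n, size=config.batch_size)
        t = rng.integers(1, config.T + 1, size=config.batch_size)
        x0 = clean[idx]
        cond = noisy[idx]
        eps = rng.standard_normal(x0.shape)
        ab = abars[t - 1][:, None, None]
        x_t = np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps

        inp = np.stack([x_t, cond], axis=1)  # (B, 2, H, W)
        eps_hat, cache = net.forward(inp, t, want_cache=True)
        eps_hat = eps_hat[:, 0]
        resid = eps_hat - eps

        # hybrid objective: mean((ε̂−ε)²) + λ · per-sample KL weight w_t ·
        # mean((ε̂−ε)²); the KL between equal-variance Gaussians reduces to a
        # reweighted MSE on ε̂ since μ_θ − μ̃ ∝ (ε̂ − ε)
        w_t = betas[t - 1] / (2.0 * alphas[t - 1] * (1.0 - abars[t - 1]))
        batch_px = resid.size
        loss = float(np.mean(resid**2) + config.lambda_kl * np.mean(w_t * np.mean(resid**2, axis=(1, 2))))
        dres = 2.0 * resid / batch_px
        dres += (config.lambda_kl * 2.0 * w_t[:, None, None] * resid) / batch_px
        grads = net.backward(dres[:, None], cache)
        opt.step(net.params, grads)
        model.loss_history.append(loss)
    return model


def reverse_sample(
    cond: np.ndarray,
    model: DenoiserModel,
    rng: np.random.Generator,
    eps_fn=None,
    stochastic: bool = True,
) -> np.ndarray:
    """Ancestral reverse sampling conditioned on ``cond`` (normalized scale).

    ``eps_fn(x_t, t)`` overrides the network prediction (used by oracle
    tests); ``stochastic=False`` walks the posterior means deterministically.
    Injected noise uses the fixed variances β_t.
    """
    schedule = model.schedule
    x = rng.standard_normal(cond.shape)
    for t in range(schedule.T, 0, -1):
        if eps_fn is not None:
            eps_hat = eps_fn(x, t)
        else:
            inp = np.stack([x, cond], axis=0)[None]
            eps_hat = model.net.forward(inp, np.array([t]))[0, 0]
        x0_hat = np.clip(predict_x0(x, t, eps_hat, schedule), -1.0, 1.0)
        mean = posterior_mean(x, x0_hat, t, schedule)
        if t > 1 and stochastic:
            x = mean + np.sqrt(schedule.betas[t - 1]) * rng.standard_normal(cond.shape)
        else:
            x = mean
    return x


def save_model(path, model: DenoiserModel) -> None:
    """Persist a trained denoiser (parameters, schedule, scaler, config) as NPZ."""
    import dataclasses

    payload = {f"param_{k}": v for k, v in model.net.params.items()}
    payload["betas"] = model.schedule.betas
    payload["config"] = np.array(
        [model.config.T, model.config.channels, model.config.emb_dim], dtype=int
    )
    cfg = dataclasses.asdict(model.config)
    payload["config_json"] = np.frombuffer(
        __import__("json").dumps(cfg).encode(), dtype=np.uint8
    )
    if model.scaler is not None:
        payload["scaler"] = np.array([model.scaler.vmin, model.scaler.vmax])
    np.savez(path, **payload)


def load_model(path) -> DenoiserModel:
    import json

    with np.load(path) as data:
        cfg = DiffusionConfig(**json.loads(bytes(data["config_json"]).decode()))
        schedule = NoiseSchedule(betas=data["betas"])
        net = ConvDenoiserNet(channels=cfg.channels, emb_dim=cfg.emb_dim, t_max=cfg.T)
        net.params = {k[len("param_"):]: data[k] for k in data.files if k.startswith("param_")}
        scaler = None
        if "scaler" in data.files:
            vmin, vmax = data["scaler"]
            scaler = HeightScaler(vmin=float(vmin), vmax=float(vmax))
    return DenoiserModel(net=net, schedule=schedule, config=cfg, scaler=scaler)


def denoise_profile(
    noisy: HeightMap | np.ndarray,
    model: DenoiserModel,
    schedule: NoiseSchedule | None = None,
    seed: int = 0,
    n_samples: int = 4,
) -> HeightMap:
    """Denoise a height profile with the trained conditional diffusion model.

    The noisy profile is normalized with the model's training scaler, used as
    the conditioning channel for ancestral reverse sampling from x_T ~ N(0,I),
    and the result mapped back to micrometres.  ``n_samples`` independent
    chains are averaged (a posterior-mean estimate); deterministic for a
    fixed seed.
    """
    if schedule is None:
        schedule = model.schedule
    if schedule.T != model.schedule.T or not np.allclose(schedule.betas, model.schedule.betas):
        raise ValueError("schedule does not match the one the model was trained with")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    arr = _as_array(noisy)
    if model.scaler is not None:
        cond = np.clip(model.scaler.transform(arr), -1.0, 1.0)
    else:
        cond = arr
        if cond.min() < -1.0 - 1e-9 or cond.max() > 1.0 + 1e-9:
            raise ValueError("input not normalized and the model has no scaler")

    rng = np.random.default_rng(seed)
    out = np.mean([reverse_sample(cond, model, rng) for _ in range(n_samples)], axis=0)
    if model.scaler is not None:
        out = model.scaler.inverse(out)
    constants = noisy.constants if isinstance(noisy, HeightMap) else None
    return HeightMap(values=out, constants=constants)
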