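"""Denoising-diffusion machinery over the embedded angle manifold.

The diffusion state is the (L, 12) unit-circle embedding of the residue
angle table.  The forward process is the standard DDPM Gaussian chain
with closed-form marginals

    x_t = sqrt(abar_t) * x_0 + sqrt(1 - abar_t) * eps,

and the reverse sampler is the epsilon-prediction DDPM update with
sigma_t = sqrt(beta_t).  Two variance-schedule families are provided:
a linear ramp of beta from 0.001 to 0.02 (the training default) and the
squared-cosine abar profile with offset s = 0.008.  Time indexing is
1-based: t = 0 is data, t = T is (approximately) white noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .internal_coords import (
    AngleEmbedding,
    GeometryConstants,
    IDEAL_GEOMETRY,
    ResidueAngleTable,
    unembed_angles,
)

__all__ = [
    "NoiseSchedule",
    "DiffusionState",
    "make_schedule",
    "forward_sample",
    "invert_forward",
    "reverse_step",
    "sample_trajectory",
]

DEFAULT_BETA_START = 0.001
DEFAULT_BETA_END = 0.02
DEFAULT_T = 1000
COSINE_OFFSET = 0.008


@dataclass(frozen=True)
class NoiseSchedule:
    """Precomputed beta/alpha/abar/sigma arrays for a schedule family.

    Arrays are length T and indexed by ``t - 1`` for time step t in 1..T.
    """

    family: str
    T: int
    beta: np.ndarray
    alpha: np.ndarray
    alpha_bar: np.ndarray
    sigma: np.ndarray

    def check_t(self, t: int) -> None:
        if not (1 <= t <= self.T):
            raise ValueError(f"time step {t} outside 1..{self.T}")

    def as_dict(self) -> dict:
        return {
            "family": self.family,
            "T": self.T,
            "beta_start": float(self.beta[0]),
            "beta_end": float(self.beta[-1]),
        }


@dataclass
class DiffusionState:
    """A noised embedding at step ``t`` (kept mainly for bookkeeping)."""

    x: np.ndarray
    t: int

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)


def make_schedule(
    family: str = "linear",
    T: int = DEFAULT_T,
    beta_start: float = DEFAULT_BETA_START,
    beta_end: float = DEFAULT_BETA_END,
) -> NoiseSchedule:
    """Build a variance schedule.

    linear: beta_t ramps affinely from ``beta_start`` at t=1 to
    ``beta_end`` at t=T (T=1 degenerates to beta_start alone).
    cosine: abar_t follows the squared-cosine profile with offset 0.008;
    the implied beta is clipped to at most 0.999; beta_start/beta_end are
    ignored for this family.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if family == "linear":
        if not (0 < beta_start <= beta_end < 1):
            raise ValueError("need 0 < beta_start <= beta_end < 1")
        if T == 1:
            beta = np.array([beta_start])
        else:
            beta = beta_start + (np.arange(T) / (T - 1)) * (beta_end - beta_start)
    elif family == "cosine":
        s = COSINE_OFFSET
        def f(u: np.ndarray) -> np.ndarray:
            return np.cos((u / T + s) / (1 + s) * np.pi / 2) ** 2
        steps = np.arange(T + 1)
        abar = f(steps) / f(np.array(0))
        beta = np.clip(1.0 - abar[1:] / abar[:-1], 0.0, 0.999)
    else:
        raise ValueError(f"unknown schedule family {family!r}")
    alpha = 1.0 - beta
    alpha_bar = np.cumprod(alpha)
    sigma = np.sqrt(beta)
    return NoiseSchedule(family=family, T=T, beta=beta, alpha=alpha,
                         alpha_bar=alpha_bar, sigma=sigma)


def forward_sample(
    x0: np.ndarray,
    t: int,
    schedule: NoiseSchedule,
    noise: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> DiffusionState:
    """Closed-form forward draw of x_t given the clean embedding x0."""
    schedule.check_t(t)
    x0 = np.asarray(x0, dtype=float)
    if noise is None:
        rng = rng if rng is not None else np.random.default_rng()
        noise = rng.standard_normal(x0.shape)
    ab = schedule.alpha_bar[t - 1]
    xt = np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * noise
    return DiffusionState(x=xt, t=t)


def invert_forward(
    x_t: np.ndarray, eps: np.ndarray, t: int, schedule: NoiseSchedule
) -> np.ndarray:
    """Algebraic inverse of the forward closed form given the true noise."""
    schedule.check_t(t)
    ab = schedule.alpha_bar[t - 1]
    return (np.asarray(x_t, float) - np.sqrt(1.0 - ab) * np.asarray(eps, float)) / np.sqrt(ab)


def reverse_step(
    x_t: np.ndarray,
    eps_pred: np.ndarray,
    t: int,
    schedule: NoiseSchedule,
    z: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One DDPM reverse update x_t -> x_{t-1}.

    The injected noise z is forced to zero at t = 1 so the returned
    conformation is deterministic given the final noise prediction.
    """
    schedule.check_t(t)
    x_t = np.asarray(x_t, dtype=float)
    eps_pred = np.asarray(eps_pred, dtype=float)
    if x_t.shape != eps_pred.shape:
        raise ValueError(f"shape mismatch: x_t {x_t.shape} vs eps_pred {eps_pred.shape}")
    a = schedule.alpha[t - 1]
    ab = schedule.alpha_bar[t - 1]
    mean = (x_t - ((1.0 - a) / np.sqrt(1.0 - ab)) * eps_pred) / np.sqrt(a)
    if t == 1:
        return mean
    if z is None:
        rng = rng if rng is not None else np.random.default_rng()
        z = rng.standard_normal(x_t.shape)
    return mean + schedule.sigma[t - 1] * z


def sample_trajectory(
    denoiser: Callable[[np.ndarray, int], np.ndarray],
    L: int,
    schedule: NoiseSchedule,
    seed: int,
    constants: GeometryConstants = IDEAL_GEOMETRY,
) -> ResidueAngleTable:
    """Run the full reverse chain and return the generated angle table.

    ``denoiser(x_t, t)`` must return the predicted noise for the current
    step; conditioning on the target context is closed over by the
    caller.  Fully reproducible given ``seed``.
    """
    if L < 2:
        raise ValueError("binder length must be >= 2")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((L, 12))
    for t in range(schedule.T, 0, -1):
        eps = denoiser(x, t)
        x = reverse_step(x, eps, t, schedule, rng=rng)
    return unembed_angles(AngleEmbedding(x), constants)
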