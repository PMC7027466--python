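"""Stochastic drivers: autocorrelated environmental noise and demographic sampling.

Environmental fluctuations are modelled as a first-order autoregressive
(AR(1)) process

    sigma_t = a * sigma_{t-1} + b * phi_t,    phi_t ~ Normal(0, 1),  sigma_0 = 0,

with the innovation scale tied to the autocorrelation, b = sqrt(1 - a**2).
This choice makes the stationary variance b**2 / (1 - a**2) = 1 for every
|a| < 1, so red noise (a > 0), white noise (a = 0) and blue noise (a < 0)
series are directly comparable in magnitude.  Demographic stochasticity is
Poisson sampling of integer abundances around a deterministic expectation,
so the conditional mean and variance of the draw both equal the expectation.

All randomness in the package flows through :func:`seed_stream`: every
logical stream (per-species noise, demographic draws, per-replicate
parameter draws) is a pure function of the root seed and a small integer
tag path, which makes ensembles reproducible and lets scenario runners
share random numbers across model variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "NoiseSeries",
    "generate_ar1",
    "demographic_draw",
    "seed_stream",
    "NOISE_STREAM",
    "DEMOGRAPHIC_STREAM",
    "PARAMETER_STREAM",
]

SeedLike = "int | np.random.SeedSequence"

# Stream tags used as the first element of a SeedSequence spawn key.
NOISE_STREAM = 0
DEMOGRAPHIC_STREAM = 1
PARAMETER_STREAM = 2


def seed_stream(seed, *key) -> np.random.SeedSequence:
    """Deterministic child :class:`~numpy.random.SeedSequence` for a tagged stream.

    Unlike ``SeedSequence.spawn`` (which is stateful), this is a pure function
    of ``seed`` and ``key``, so the same (seed, key) pair always names the same
    stream.

    Parameters
    ----------
    seed
        Root integer seed (non-negative) or an existing ``SeedSequence``.
    *key
        Integer tag path appended to the spawn key.
    """
    if isinstance(seed, np.random.SeedSequence):
        if not key:
            return seed
        return np.random.SeedSequence(
            entropy=seed.entropy, spawn_key=tuple(seed.spawn_key) + tuple(key)
        )
    seed = int(seed)
    if seed < 0:
        raise ValueError(f"seed must be non-negative, got {seed}")
    return np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))


@dataclass
class NoiseSeries:
    """A realised AR(1) environmental driver.

    Attributes
    ----------
    a : float
        Autocorrelation coefficient in [-1, 1].
    b : float
        Innovation scale, ``sqrt(1 - a**2)`` (recomputable from ``a``).
    sigma : numpy.ndarray
        Realised values ``sigma_0 .. sigma_T`` (length T + 1, ``sigma[0] == 0``).
    innovations : numpy.ndarray
        Standard-normal innovations ``phi_1 .. phi_T`` (length T).
    seed
        Seed (integer or SeedSequence) the series was generated from.
    """

    a: float
    b: float
    sigma: np.ndarray
    innovations: np.ndarray
    seed: object = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.sigma)

    def to_frame(self) -> pd.DataFrame:
        """Two-column tidy representation (t, sigma)."""
        return pd.DataFrame({"t": np.arange(len(self.sigma)), "sigma": self.sigma})


def generate_ar1(a: float, T: int, seed) -> NoiseSeries:
    """Generate an AR(1) environmental noise series of horizon ``T``.

    Returns ``sigma_0 .. sigma_T`` with ``sigma_0 = 0`` and
    ``sigma_t = a * sigma_{t-1} + b * phi_t`` where ``b = sqrt(1 - a**2)``.
    At ``a = +-1`` the innovation scale is zero, so the series is
    identically zero.

    Parameters
    ----------
    a : float
        Autocorrelation in [-1, 1].
    T : int
        Number of steps; the returned series has ``T + 1`` values.
    seed
        Integer seed or ``SeedSequence``; equal seeds give bitwise-identical
        series.
    """
    a = float(a)
    if not -1.0 <= a <= 1.0:
        raise ValueError(f"autocorrelation a must be in [-1, 1], got {a}")
    T = int(T)
    if T < 1:
        raise ValueError(f"horizon T must be >= 1, got {T}")
    b = math.sqrt(max(1.0 - a * a, 0.0))
    rng = np.random.default_rng(seed_stream(seed))
    phi = rng.standard_normal(T)
    sigma = np.empty(T + 1)
    sigma[0] = 0.0
    # sigma_t = a sigma_{t-1} + b phi_t is exactly the IIR filter b / (1 - a z^-1).
    sigma[1:] = lfilter([b], [1.0, -a], phi)
    return NoiseSeries(a=a, b=b, sigma=sigma, innovations=phi, seed=seed)


def demographic_draw(expected, rng: np.random.Generator):
    """One Poisson draw (per element) around an expected abundance.

    Negative expectations — which arise when a strongly negative
    environmental term is added to the density-dependent expectation — are
    clamped to zero before sampling (total reproductive failure), keeping
    abundances non-negative.

    Parameters
    ----------
    expected
        Scalar or array of finite expected abundances.
    rng : numpy.random.Generator
        Source of randomness.

    Returns
    -------
    int or numpy.ndarray
        Poisson(max(expected, 0)) variate(s), matching the input shape.
    """
    arr = np.asarray(expected, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("expected abundance must be finite")
    lam = np.maximum(arr, 0.0)
    draw = rng.poisson(lam)
    if np.isscalar(expected) or arr.ndim == 0:
        return int(draw)
    return draw
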