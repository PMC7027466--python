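"""Single-species stochastic dynamics built on the Beverton-Holt map.

The deterministic skeleton is the compensatory Beverton-Holt model

    N_{t+1} = R N_t / (1 + alpha N_t),

with density-independent growth rate R and intraspecific competition
coefficient alpha; its positive fixed point (carrying capacity) is
K = (R - 1) / alpha.  Four stochastic variants are supported:

``deterministic``
    the bare map;
``demographic``
    N_{t+1} ~ Poisson(R N_t / (1 + alpha N_t));
``environmental``
    N_{t+1} = R N_t / (1 + alpha N_t) + N_t * zeta * sigma_t, with sigma an
    AR(1) driver (white to red noise);
``both``
    Poisson sampling of the environmental expectation, clamped at zero.

An overcompensatory alternative, the fixed-point-matched Ricker map
N exp(r (1 - N/K)) with r = ln R, is available through
``density_form="ricker"`` so compensatory and overcompensatory density
dependence can be compared at the same carrying capacity.

In all variants a population dropping below one individual is set to zero
and stays there (absorbing extinction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VARIANTS",
    "DENSITY_FORMS",
    "PopulationParams",
    "Trajectory",
    "bh_step",
    "ricker_step",
    "simulate_population",
]

VARIANTS = ("deterministic", "demographic", "environmental", "both")
DENSITY_FORMS = ("beverton_holt", "ricker")

#: Abundance below which a population is considered extinct (one individual).
EXTINCTION_THRESHOLD = 1.0


@dataclass
class PopulationParams:
    """Parameters of the single-species model.

    Attributes
    ----------
    R : float
        Density-independent growth rate per step (> 0).
    alpha : float
        Intraspecific competition coefficient per individual (> 0).
    zeta : float
        Environmental-sensitivity magnitude (>= 0).
    a : float
        Noise autocorrelation in [-1, 1].
    variant : str
        One of ``deterministic``, ``demographic``, ``environmental``, ``both``.
    density_form : str
        ``beverton_holt`` (compensatory) or ``ricker`` (overcompensatory).
    """

    R: float
    alpha: float
    zeta: float = 0.0
    a: float = 0.0
    variant: str = "deterministic"
    density_form: str = "beverton_holt"

    def __post_init__(self):
        if self.R <= 0:
            raise ValueError(f"R must be > 0, got {self.R}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.zeta < 0:
            raise ValueError(f"zeta must be >= 0, got {self.zeta}")
        if not -1.0 <= self.a <= 1.0:
            raise ValueError(f"a must be in [-1, 1], got {self.a}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.density_form not in DENSITY_FORMS:
            raise ValueError(
                f"unknown density_form {self.density_form!r}; expected one of {DENSITY_FORMS}"
            )
        if self.density_form == "ricker" and self.R <= 1:
            raise ValueError("ricker density form requires R > 1 (K = (R-1)/alpha > 0)")

    @property
    def carrying_capacity(self) -> float:
        """Deterministic fixed point (R - 1) / alpha."""
        return (self.R - 1.0) / self.alpha


@dataclass
class Trajectory:
    """Abundance-through-time record for one or more species.

    ``abundances`` has shape ``(T + 1, S)``; row ``t`` is the state at time
    ``t`` (row 0 is the initial state).  Abundances are non-negative, and
    integer-valued whenever demographic (Poisson) sampling is active.
    ``extinction_times[i]`` is the first time species ``i`` fell below one
    individual, or ``None`` if it survived the whole horizon (censored).
    """

    abundances: np.ndarray
    variant: str
    seed: object = field(default=None, repr=False)
    extinction_times: list = None
    model: str = "beverton_holt"

    def __post_init__(self):
        self.abundances = np.atleast_2d(np.asarray(self.abundances, dtype=float))
        if self.extinction_times is None:
            self.extinction_times = _extinction_times(self.abundances)

    @property
    def n_steps(self) -> int:
        return self.abundances.shape[0] - 1

    @property
    def n_species(self) -> int:
        return self.abundances.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.abundances.shape[0])

    def species(self, i: int = 0) -> np.ndarray:
        """Abundance column of species ``i``."""
        return self.abundances[:, i]

    def to_frame(self) -> pd.DataFrame:
        """Tidy representation with columns (t, species, abundance)."""
        T1, S = self.abundances.shape
        return pd.DataFrame(
            {
                "t": np.repeat(np.arange(T1), S),
                "species": np.tile(np.arange(S), T1),
                "abundance": self.abundances.ravel(),
            }
        )


def _extinction_times(abundances: np.ndarray) -> list:
    """First time each species drops below one individual (None = censored)."""
    out = []
    for col in abundances.T:
        below = col < EXTINCTION_THRESHOLD
        out.append(int(np.argmax(below)) if below.any() else None)
    return out


def bh_step(N, R: float, alpha: float):
    """Expected next abundance under the Beverton-Holt map R N / (1 + alpha N).

    Accepts scalars or arrays; N must be non-negative.
    """
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("abundance N must be non-negative")
    out = R * N / (1.0 + alpha * N)
    return float(out) if out.ndim == 0 else out


def ricker_step(N, R: float, alpha: float):
    """Expected next abundance under a Ricker map matched to the BH fixed point.

    Uses N exp(r (1 - N / K)) with r = ln(R) and K = (R - 1) / alpha, so the
    fixed point coincides with the Beverton-Holt model sharing (R, alpha) and
    comparisons between the two isolate the compensation type.  Requires
    R > 1 so K > 0.
    """
    if R <= 1:
        raise ValueError("ricker_step requires R > 1 so that K = (R-1)/alpha > 0")
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("abundance N must be non-negative")
    r = math.log(R)
    K = (R - 1.0) / alpha
    out = N * np.exp(r * (1.0 - N / K))
    return float(out) if out.ndim == 0 else out


def simulate_population(params: PopulationParams, n0=None, T: int = 100, seed=None) -> Trajectory:
    """Simulate a single population for ``T`` steps.

    Delegates to the community engine with S = 1 so that single-species and
    community runs share one code path (and one RNG-stream derivation).

    Parameters
    ----------
    params : PopulationParams
    n0 : float, optional
        Initial abundance; defaults to the deterministic carrying capacity
        (R - 1) / alpha rounded to the nearest integer.
    T : int
        Number of steps (>= 1).
    seed
        Root seed; required for any stochastic variant, ignored by the
        deterministic one.
    """
    from .community import CommunityParams, simulate_community

    if n0 is None:
        n0 = round(params.carrying_capacity)
    cp = CommunityParams(
        R=[params.R],
        alpha=[[params.alpha]],
        zeta=[params.zeta],
        a=params.a,
        variant=params.variant,
        density_form=params.density_form,
    )
    return simulate_community(cp, [n0], T, seed=seed)
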