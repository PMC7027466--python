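"""Transient predator-prey dynamics: noise-sustained quasi-cycles.

A Rosenzweig-MacArthur consumer-resource system with logistic prey growth
and a Holling type-II functional response:

    dN/dt = r N (1 - N/K) - c N P / (h + N)
    dP/dt = e c N P / (h + N) - m P

with attack rate c, half-saturation constant h, conversion efficiency e and
predator mortality m.  In the parameter regime where the coexistence
equilibrium is a stable focus, deterministic trajectories show damped
(transient) oscillations and settle onto the point equilibrium.
Environmental stochasticity on the prey growth rate — r multiplied by
(1 + zeta sigma_t), with sigma an AR(1) driver held constant over each unit
time interval — continually re-excites the damped oscillation, producing
sustained quasi-cycles and pushing trajectories toward otherwise invisible
unstable equilibria (the prey-only saddle in particular).

The deterministic skeleton is integrated with fixed-step RK4; the
stochastic mode uses the same integrator with the noise-perturbed growth
rate frozen within each step, so zeta = 0 reproduces the deterministic
trajectory bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .drivers import NOISE_STREAM, generate_ar1, seed_stream
from .population import Trajectory

__all__ = [
    "PredPreyParams",
    "Equilibrium",
    "simulate_pred_prey",
    "simulate_pred_prey_ensemble",
    "find_equilibria",
]


@dataclass
class PredPreyParams:
    """Rosenzweig-MacArthur parameters (continuous time).

    Attributes
    ----------
    r : float
        Prey intrinsic growth rate (per unit time).
    K : float
        Prey carrying capacity.
    attack : float
        Predator attack rate c.
    conversion : float
        Conversion efficiency e of consumed prey into predators.
    mortality : float
        Predator per-capita mortality m.
    half_sat : float
        Half-saturation prey density h of the type-II response.
    zeta : float
        Environmental-noise magnitude on the prey growth rate.
    a : float
        AR(1) autocorrelation of the noise (per unit time).
    dt : float
        Fixed RK4 step size, in time units; must divide 1 evenly so noise
        can be held constant over unit intervals.
    """

    r: float = 1.0
    K: float = 10.0
    attack: float = 1.0
    conversion: float = 0.5
    mortality: float = 0.34
    half_sat: float = 2.0
    zeta: float = 0.0
    a: float = 0.0
    dt: float = 0.01

    def __post_init__(self):
        for name in ("r", "K", "attack", "conversion", "mortality", "half_sat"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.zeta < 0:
            raise ValueError(f"zeta must be >= 0, got {self.zeta}")
        if not -1.0 <= self.a <= 1.0:
            raise ValueError(f"a must be in [-1, 1], got {self.a}")
        if self.dt <= 0 or self.dt > 1:
            raise ValueError(f"dt must be in (0, 1], got {self.dt}")
        if abs(round(1.0 / self.dt) - 1.0 / self.dt) > 1e-9:
            raise ValueError(f"1/dt must be an integer so noise spans unit intervals, got dt={self.dt}")


@dataclass
class Equilibrium:
    """An equilibrium state with its local stability classification."""

    state: np.ndarray
    eigenvalues: np.ndarray
    stable: bool
    label: str  # "extinction", "prey_only", or "coexistence"

    def __post_init__(self):
        self.state = np.asarray(self.state, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues)


def _rhs(N, P, r_eff, p: PredPreyParams):
    """Vector field; r_eff may be an array (vectorised over replicates)."""
    pred = p.attack * N * P / (p.half_sat + N)
    dN = r_eff * N * (1.0 - N / p.K) - pred
    dP = p.conversion * pred - p.mortality * P
    return dN, dP


def _jacobian(N, P, p: PredPreyParams) -> np.ndarray:
    h = p.half_sat
    dfdN = p.r * (1.0 - 2.0 * N / p.K) - p.attack * P * h / (h + N) ** 2
    dfdP = -p.attack * N / (h + N)
    dgdN = p.conversion * p.attack * P * h / (h + N) ** 2
    dgdP = p.conversion * p.attack * N / (h + N) - p.mortality
    return np.array([[dfdN, dfdP], [dgdN, dgdP]])


def find_equilibria(params: PredPreyParams) -> list[Equilibrium]:
    """Closed-form equilibria with Jacobian-eigenvalue stability labels.

    Always returns the extinction state (0, 0) and the prey-only state
    (K, 0); the interior coexistence equilibrium
    N* = m h / (e c - m),  P* = r (1 - N*/K) (h + N*) / c
    is included when it is feasible (positive).
    """
    out = []
    for state, label in (((0.0, 0.0), "extinction"), ((params.K, 0.0), "prey_only")):
        eig = np.linalg.eigvals(_jacobian(*state, params))
        out.append(Equilibrium(state, eig, bool(np.all(eig.real < 0)), label))
    denom = params.conversion * params.attack - params.mortality
    if denom > 0:
        n_star = params.mortality * params.half_sat / denom
        if n_star < params.K:
            p_star = params.r * (1.0 - n_star / params.K) * (params.half_sat + n_star) / params.attack
            eig = np.linalg.eigvals(_jacobian(n_star, p_star, params))
            out.append(Equilibrium((n_star, p_star), eig, bool(np.all(eig.real < 0)), "coexistence"))
    return out


def _integrate(params: PredPreyParams, n0, p0, T: int, sigma: np.ndarray) -> np.ndarray:
    """RK4 over T unit intervals; states sampled at unit times, shape (T+1, n, 2).

    ``sigma`` has shape (T, n): one noise value per unit interval per
    replicate, frozen within the interval (the environment varies more
    slowly than the integration step).
    """
    n = sigma.shape[1]
    substeps = round(1.0 / params.dt)
    dt = params.dt
    N = np.full(n, float(n0))
    P = np.full(n, float(p0))
    out = np.empty((T + 1, n, 2))
    out[0, :, 0] = N
    out[0, :, 1] = P
    for t in range(T):
        r_eff = params.r * (1.0 + params.zeta * sigma[t])
        for _ in range(substeps):
            k1N, k1P = _rhs(N, P, r_eff, params)
            k2N, k2P = _rhs(N + 0.5 * dt * k1N, P + 0.5 * dt * k1P, r_eff, params)
            k3N, k3P = _rhs(N + 0.5 * dt * k2N, P + 0.5 * dt * k2P, r_eff, params)
            k4N, k4P = _rhs(N + dt * k3N, P + dt * k3P, r_eff, params)
            N = N + dt / 6.0 * (k1N + 2.0 * k2N + 2.0 * k3N + k4N)
            P = P + dt / 6.0 * (k1P + 2.0 * k2P + 2.0 * k3P + k4P)
            N = np.maximum(N, 0.0)
            P = np.maximum(P, 0.0)
        out[t + 1, :, 0] = N
        out[t + 1, :, 1] = P
    return out


def simulate_pred_prey(
    params: PredPreyParams, n0: float, p0: float, T: int, seed=None, stochastic: bool = False
) -> Trajectory:
    """Integrate the predator-prey system over ``T`` unit time intervals.

    The returned trajectory samples the state at unit times; column 0 is
    prey, column 1 predator.  In stochastic mode the prey growth rate is
    multiplied by (1 + zeta sigma_t) with sigma an AR(1) series (one value
    per unit interval).  With zeta = 0 the stochastic trajectory is bitwise
    identical to the deterministic one.

    Parameters
    ----------
    params : PredPreyParams
    n0, p0 : float
        Initial prey and predator densities (> 0).
    T : int
        Horizon in time units (>= 1).
    seed
        Required when ``stochastic`` is true.
    stochastic : bool
        Inject environmental noise into the prey growth rate.
    """
    if n0 <= 0 or p0 <= 0:
        raise ValueError("initial prey and predator densities must be > 0")
    T = int(T)
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if stochastic:
        if seed is None:
            raise ValueError("stochastic mode requires a seed")
        sigma = generate_ar1(params.a, T, seed_stream(seed, NOISE_STREAM, 0)).sigma[:T, None]
    else:
        sigma = np.zeros((T, 1))
    states = _integrate(params, n0, p0, T, sigma)
    variant = "environmental" if stochastic else "deterministic"
    return Trajectory(
        abundances=states[:, 0, :],
        variant=variant,
        seed=seed if stochastic else None,
        extinction_times=[None, None],
        model="rosenzweig_macarthur",
    )


def simulate_pred_prey_ensemble(
    params: PredPreyParams, n0: float, p0: float, T: int, seeds
) -> np.ndarray:
    """Vectorised stochastic ensemble over many seeds.

    Returns an array of shape (n_seeds, T + 1, 2).  Each seed's noise series
    matches what :func:`simulate_pred_prey` would draw for that seed, so the
    ensemble is just the batched version of the single-trajectory call.
    """
    if n0 <= 0 or p0 <= 0:
        raise ValueError("initial prey and predator densities must be > 0")
    seeds = list(seeds)
    sigma = np.column_stack(
        [generate_ar1(params.a, T, seed_stream(s, NOISE_STREAM, 0)).sigma[:T] for s in seeds]
    )
    states = _integrate(params, n0, p0, int(T), sigma)
    return np.moveaxis(states, 1, 0)
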