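"""Multispecies competitive dynamics and the seed-banking annual-plant model.

The community skeleton adds pairwise competition to the Beverton-Holt map:

    N_{i,t+1} = R_i N_{i,t} / (1 + sum_j alpha_ij N_{j,t}),

where alpha_ij is the per-capita effect of species j on species i
(alpha_ii intraspecific).  Demographic stochasticity draws each species'
next abundance from an independent Poisson conditioned on the full
community state; environmental stochasticity adds N_i zeta_i sigma_{i,t}
with an independent AR(1) driver per species (species respond to different
underlying environmental variables); the combined variant Poisson-samples
the clamped sum.  All species update synchronously from the time-t state,
and the below-one-individual extinction rule is absorbing per species.

The seed-bank extension models an annual plant whose population is counted
as seeds at the start of each growing season:

    N_{i,t+1} = N_{i,t} s_i (1 - g_{i,t})
                + g_{i,t} R_i N_{i,t} / (1 + sum_j alpha_ij N_{j,t}),

with seed survival s_i, germination fraction g_{i,t} = g_i (deterministic)
or clip(g_i + zeta_i sigma_{i,t}, 0, 1) (environmental).  Ungerminated
seeds "store" the population through bad years — the classic setting for
the storage effect.  Competition acts on total seed abundance N_j, not on
the germinated density g_j N_j; see the methods note for discussion of
this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .drivers import (
    DEMOGRAPHIC_STREAM,
    NOISE_STREAM,
    demographic_draw,
    generate_ar1,
    seed_stream,
)
from .population import (
    DENSITY_FORMS,
    EXTINCTION_THRESHOLD,
    VARIANTS,
    Trajectory,
    bh_step,
    ricker_step,
)

__all__ = [
    "SeedBank",
    "CommunityParams",
    "community_step_expected",
    "simulate_community",
    "simulate_seedbank_community",
]


@dataclass
class SeedBank:
    """Seed-bank block: survival of ungerminated seeds and mean germination.

    Both are fractions in [0, 1], scalar or per-species arrays.
    """

    s: np.ndarray
    g: np.ndarray

    def __post_init__(self):
        self.s = np.atleast_1d(np.asarray(self.s, dtype=float))
        self.g = np.atleast_1d(np.asarray(self.g, dtype=float))
        for name, arr in (("s", self.s), ("g", self.g)):
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"seed-bank {name} must lie in [0, 1]")


@dataclass
class CommunityParams:
    """Parameters of the S-species community model.

    Attributes
    ----------
    R : array (S,)
        Per-species growth rates (> 0).
    alpha : array (S, S)
        Competition matrix; diagonal intraspecific (> 0), off-diagonal
        interspecific (>= 0).
    zeta : float or array (S,)
        Environmental sensitivities (>= 0).
    a : float
        Shared noise autocorrelation in [-1, 1].
    variant : str
        As in :class:`~stochcomm.population.PopulationParams`.
    seedbank : SeedBank, optional
        Present only for the annual-plant model.
    rho : float
        Optional uniform cross-species correlation of environmental noise
        (default 0: independent drivers per species).
    density_form : str
        ``beverton_holt`` or ``ricker`` (the latter only for S = 1).
    """

    R: np.ndarray
    alpha: np.ndarray
    zeta: object = 0.0
    a: float = 0.0
    variant: str = "deterministic"
    seedbank: SeedBank | None = None
    rho: float = 0.0
    density_form: str = "beverton_holt"

    def __post_init__(self):
        self.R = np.atleast_1d(np.asarray(self.R, dtype=float))
        self.alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        S = self.R.shape[0]
        if self.alpha.shape != (S, S):
            raise ValueError(f"alpha must have shape ({S}, {S}), got {self.alpha.shape}")
        self.zeta = np.broadcast_to(np.asarray(self.zeta, dtype=float), (S,)).copy()
        if np.any(self.R <= 0):
            raise ValueError("all growth rates R must be > 0")
        if np.any(np.diag(self.alpha) <= 0):
            raise ValueError("intraspecific competition alpha_ii must be > 0")
        if np.any(self.alpha < 0):
            raise ValueError("competition coefficients must be >= 0")
        if np.any(self.zeta < 0):
            raise ValueError("zeta must be >= 0")
        if not -1.0 <= self.a <= 1.0:
            raise ValueError(f"a must be in [-1, 1], got {self.a}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.density_form not in DENSITY_FORMS:
            raise ValueError(f"unknown density_form {self.density_form!r}")
        if self.density_form == "ricker" and S > 1:
            raise ValueError("ricker density form is only defined for S = 1")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"cross-species noise correlation rho must be in [0, 1], got {self.rho}")
        if self.seedbank is not None:
            for name, arr in (("s", self.seedbank.s), ("g", self.seedbank.g)):
                if arr.shape[0] == 1 and S > 1:
                    setattr(self.seedbank, name, np.repeat(arr, S))
                elif arr.shape[0] != S:
                    raise ValueError(f"seed-bank {name} must have length {S}")

    @property
    def S(self) -> int:
        return self.R.shape[0]

    def equilibrium(self) -> np.ndarray:
        """Interior equilibrium N* solving sum_j alpha_ij N*_j = R_i - 1."""
        return np.linalg.solve(self.alpha, self.R - 1.0)


def community_step_expected(N, params: CommunityParams) -> np.ndarray:
    """Expected next abundance vector R_i N_i / (1 + sum_j alpha_ij N_j)."""
    N = np.asarray(N, dtype=float)
    if N.shape != (params.S,):
        raise ValueError(f"N must have shape ({params.S},), got {N.shape}")
    if np.any(N < 0):
        raise ValueError("abundances must be non-negative")
    if params.density_form == "ricker":
        return np.atleast_1d(ricker_step(N, params.R[0], params.alpha[0, 0]))
    return params.R * N / (1.0 + params.alpha @ N)


def _species_noise(params: CommunityParams, T: int, seed) -> np.ndarray:
    """Per-species AR(1) noise matrix, shape (T + 1, S).

    Species i draws from stream (NOISE_STREAM, i).  With rho > 0 a common
    series (stream (NOISE_STREAM, S)) is mixed in as
    sqrt(rho) * common + sqrt(1 - rho) * independent, which preserves the
    AR(1) structure and unit stationary variance.
    """
    S = params.S
    cols = [generate_ar1(params.a, T, seed_stream(seed, NOISE_STREAM, i)).sigma for i in range(S)]
    sigma = np.column_stack(cols)
    if params.rho > 0:
        common = generate_ar1(params.a, T, seed_stream(seed, NOISE_STREAM, S)).sigma
        sigma = np.sqrt(params.rho) * common[:, None] + np.sqrt(1.0 - params.rho) * sigma
    return sigma


def _simulate(params: CommunityParams, n0, T: int, seed, seedbank: bool) -> Trajectory:
    T = int(T)
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    S = params.S
    N = np.asarray(n0, dtype=float).reshape(-1).copy()
    if N.shape != (S,):
        raise ValueError(f"initial abundances must have shape ({S},), got {N.shape}")
    if np.any(N < 0):
        raise ValueError("initial abundances must be non-negative")

    env = params.variant in ("environmental", "both") or (
        seedbank and params.variant == "environmental"
    )
    demo = params.variant in ("demographic", "both")
    if (env or demo) and seed is None:
        raise ValueError(f"variant {params.variant!r} requires a seed")

    sigma = _species_noise(params, T, seed) if env else None
    rng = np.random.default_rng(seed_stream(seed, DEMOGRAPHIC_STREAM)) if demo else None

    if seedbank:
        sb = params.seedbank
        if sb is None:
            raise ValueError("seed-bank simulation requires params.seedbank")
        if demo:
            raise ValueError(
                "the seed-bank model supports only deterministic and environmental variants"
            )

    out = np.empty((T + 1, S))
    N[N < EXTINCTION_THRESHOLD] = 0.0  # extinction rule applies to the initial state too
    out[0] = N
    for t in range(T):
        if seedbank:
            g_t = sb.g if not env else np.clip(sb.g + params.zeta * sigma[t], 0.0, 1.0)
            growth = params.R * N / (1.0 + params.alpha @ N)
            expected = N * sb.s * (1.0 - g_t) + g_t * growth
        else:
            expected = community_step_expected(N, params)
            if env:
                expected = expected + N * params.zeta * sigma[t]
        if demo:
            N = demographic_draw(np.maximum(expected, 0.0), rng).astype(float)
        else:
            N = np.maximum(expected, 0.0)
        N[N < EXTINCTION_THRESHOLD] = 0.0
        out[t + 1] = N

    model = "seedbank" if seedbank else params.density_form
    traj_seed = seed if (env or demo) else None
    return Trajectory(abundances=out, variant=params.variant, seed=traj_seed, model=model)


def simulate_community(params: CommunityParams, n0, T: int, seed=None) -> Trajectory:
    """Simulate an S-species community for ``T`` steps.

    Variant semantics parallel :func:`~stochcomm.population.simulate_population`
    exactly; with S = 1 the output is bitwise identical to the population
    engine under the same seed.

    Parameters
    ----------
    params : CommunityParams
    n0 : array (S,)
        Initial abundances.
    T : int
        Number of steps.
    seed
        Root seed (int or SeedSequence); required for stochastic variants.
    """
    return _simulate(params, n0, T, seed, seedbank=False)


def simulate_seedbank_community(params: CommunityParams, n0, T: int, seed=None) -> Trajectory:
    """Simulate the seed-banking annual-plant community for ``T`` steps.

    Requires ``params.seedbank``; supports the deterministic and
    environmental variants (the model is defined without Poisson sampling).
    With g_i = 1 and no noise the dynamics reduce to the plain community
    model (no seed carries over).
    """
    if params.seedbank is None:
        raise ValueError("simulate_seedbank_community requires params.seedbank")
    return _simulate(params, n0, T, seed, seedbank=True)
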