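"""Summary statistics for trajectories and replicate ensembles.

Covers the quantities used to read the simulations: alpha diversity
(species richness at the one-individual extinction cutoff, so continuous
and integer-valued state variables are comparable), persistence time
(first passage below one individual, censored at the horizon), lag-1
temporal correlation of abundance, the coefficient of variation of
aggregate community abundance (a stability measure), ensemble
distributions of any of these at a snapshot time, and a minimal
observation-error hook (none / Gaussian / Poisson resampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drivers import seed_stream
from .population import EXTINCTION_THRESHOLD, Trajectory

__all__ = [
    "Ensemble",
    "MetricResult",
    "alpha_diversity",
    "persistence_time",
    "lag1_correlation",
    "ensemble_distribution",
    "trajectory_metric_distribution",
    "aggregate_cv",
    "observe",
]

#: Metrics evaluated on the community state at a snapshot time.
SNAPSHOT_METRICS = ("alpha_diversity", "total_abundance")
#: Metrics evaluated on a whole trajectory.
TRAJECTORY_METRICS = ("lag1_correlation", "persistence_time", "aggregate_cv")


@dataclass
class Ensemble:
    """A set of replicate trajectories simulated under one scenario."""

    scenario: str
    trajectories: list
    seeds: list = field(default_factory=list)

    def __post_init__(self):
        if not self.trajectories:
            raise ValueError("ensemble must contain at least one trajectory")
        t0 = self.trajectories[0]
        for tr in self.trajectories[1:]:
            if tr.abundances.shape != t0.abundances.shape or tr.variant != t0.variant:
                raise ValueError("all trajectories in an ensemble must share T, S and variant")

    @property
    def n(self) -> int:
        return len(self.trajectories)

    @property
    def variant(self) -> str:
        return self.trajectories[0].variant

    def to_frame(self) -> pd.DataFrame:
        """Tidy representation with columns (replicate, t, species, abundance)."""
        frames = []
        for rep, tr in enumerate(self.trajectories):
            df = tr.to_frame()
            df.insert(0, "replicate", rep)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


@dataclass
class MetricResult:
    """Per-replicate metric values with their first two moments and histogram.

    ``variance`` is the sample variance (ddof = 1) and is NaN for a single
    replicate.  Censored persistence times appear as NaN in ``values``.
    """

    name: str
    values: np.ndarray
    mean: float
    variance: float
    bin_edges: np.ndarray | None = None
    counts: np.ndarray | None = None

    @classmethod
    def from_values(cls, name: str, values) -> "MetricResult":
        values = np.asarray(values, dtype=float)
        finite = values[np.isfinite(values)]
        mean = float(np.mean(finite)) if finite.size else float("nan")
        variance = float(np.var(finite, ddof=1)) if finite.size > 1 else float("nan")
        if finite.size:
            counts, edges = np.histogram(finite, bins="auto")
        else:
            counts, edges = None, None
        return cls(name=name, values=values, mean=mean, variance=variance,
                   bin_edges=edges, counts=counts)

    def histogram_frame(self) -> pd.DataFrame:
        """Histogram as (bin_left, bin_right, count) rows."""
        if self.bin_edges is None:
            raise ValueError("no histogram available")
        return pd.DataFrame(
            {"bin_left": self.bin_edges[:-1], "bin_right": self.bin_edges[1:], "count": self.counts}
        )


def alpha_diversity(state, threshold: float = EXTINCTION_THRESHOLD) -> int:
    """Species richness: count of species at or above ``threshold``.

    The default threshold is the one-individual extinction cutoff, so
    richness is consistent between real-valued and Poisson-sampled state
    variables.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    state = np.asarray(state, dtype=float)
    if np.any(state < 0):
        raise ValueError("abundances must be non-negative")
    return int(np.count_nonzero(state >= threshold))


def persistence_time(column, T: int | None = None):
    """First time t with abundance < 1, or None if censored at the horizon.

    t = 0 (the initial state) counts: a population starting below one
    individual has persistence time 0.
    """
    column = np.asarray(column, dtype=float)
    below = column < EXTINCTION_THRESHOLD
    if below.any():
        return int(np.argmax(below))
    return None


def lag1_correlation(column, burn_in: int = 100) -> float:
    """Pearson correlation between N_t and N_{t+1} after a burn-in window.

    Raises on constant series (undefined correlation) rather than silently
    returning 0.
    """
    column = np.asarray(column, dtype=float)
    x = column[burn_in:]
    if x.size < 3:
        raise ValueError("need at least 3 post-burn-in points")
    if np.ptp(x[:-1]) == 0 or np.ptp(x[1:]) == 0:
        raise ValueError("lag-1 correlation undefined for a constant series")
    return float(np.corrcoef(x[:-1], x[1:])[0, 1])


def aggregate_cv(trajectory: Trajectory, burn_in: int = 100) -> float:
    """Coefficient of variation (sd/mean) of total community abundance.

    A community-stability measure: statistical averaging across species can
    make the aggregate less volatile than any single population.
    """
    total = trajectory.abundances.sum(axis=1)[burn_in:]
    if total.size < 2:
        raise ValueError("need at least 2 post-burn-in points")
    mean = float(np.mean(total))
    if mean <= 0:
        raise ValueError("aggregate CV undefined: post-burn-in mean abundance is zero")
    return float(np.std(total, ddof=1) / mean)


def ensemble_distribution(ensemble: Ensemble, metric: str, t_star: int,
                          threshold: float = EXTINCTION_THRESHOLD) -> MetricResult:
    """Distribution of a snapshot metric across replicates at time ``t_star``.

    Supported metrics: ``alpha_diversity`` (richness at the extinction
    cutoff) and ``total_abundance``.
    """
    if metric not in SNAPSHOT_METRICS:
        raise ValueError(f"unknown snapshot metric {metric!r}; expected one of {SNAPSHOT_METRICS}")
    T = ensemble.trajectories[0].n_steps
    if not 0 <= t_star <= T:
        raise ValueError(f"t_star must be in [0, {T}], got {t_star}")
    if metric == "alpha_diversity":
        values = [alpha_diversity(tr.abundances[t_star], threshold) for tr in ensemble.trajectories]
    else:
        values = [tr.abundances[t_star].sum() for tr in ensemble.trajectories]
    return MetricResult.from_values(metric, values)


def trajectory_metric_distribution(ensemble: Ensemble, metric: str, burn_in: int = 100,
                                   species: int = 0) -> MetricResult:
    """Distribution of a whole-trajectory metric across replicates.

    Supported metrics: ``lag1_correlation`` and ``persistence_time`` (on one
    species' column) and ``aggregate_cv``.  Replicates where the metric is
    undefined — censored persistence times, or correlations of series that
    are constant after burn-in (e.g. already extinct) — become NaN in the
    per-replicate vector and are excluded from the moments.
    """
    if metric not in TRAJECTORY_METRICS:
        raise ValueError(
            f"unknown trajectory metric {metric!r}; expected one of {TRAJECTORY_METRICS}"
        )
    values = []
    for tr in ensemble.trajectories:
        if metric == "lag1_correlation":
            try:
                values.append(lag1_correlation(tr.species(species), burn_in))
            except ValueError:
                values.append(float("nan"))
        elif metric == "persistence_time":
            pt = persistence_time(tr.species(species))
            values.append(float("nan") if pt is None else pt)
        else:
            values.append(aggregate_cv(tr, burn_in))
    return MetricResult.from_values(metric, values)


def observe(trajectory: Trajectory, error_model: str = "none", sd: float = 1.0,
            seed=None) -> Trajectory:
    """Apply an observation-error model to a trajectory.

    ``none`` returns the input unchanged; ``gaussian`` adds mean-zero noise
    with standard deviation ``sd``, floored at 0; ``poisson`` resamples each
    value as Poisson(value).  Observation error overlays the record of the
    process without feeding back into the dynamics.
    """
    if error_model == "none":
        return trajectory
    if error_model not in ("gaussian", "poisson"):
        raise ValueError(f"unknown error model {error_model!r}")
    if error_model == "gaussian" and sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    if seed is None:
        raise ValueError(f"error model {error_model!r} requires a seed")
    rng = np.random.default_rng(seed_stream(seed))
    if error_model == "gaussian":
        observed = np.maximum(trajectory.abundances + rng.normal(0.0, sd, trajectory.abundances.shape), 0.0) if sd > 0 else trajectory.abundances.copy()
    else:
        observed = rng.poisson(trajectory.abundances).astype(float)
    return Trajectory(
        abundances=observed,
        variant=trajectory.variant,
        seed=trajectory.seed,
        model=trajectory.model,
    )
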