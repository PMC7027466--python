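"""Named, config-driven simulation scenarios mirroring the reference figures.

A :class:`ScenarioSpec` fully describes an ensemble experiment: which model
engine to run (population / community / seed-bank / predator-prey), which
stochasticity variants, parameter values (scalars or per-replicate
distribution draws written ``"uniform:lo,hi"``), community size, horizon,
replicate count and snapshot time.  Specs round-trip through YAML, so every
scenario can be launched from a config file or the CLI.

Replicate seeds derive deterministically from one root seed.  Scenario
parameters with distribution specs are realised once per root seed (one
fixed community per ensemble) and each replicate varies only in its
environmental-noise and demographic streams, so the ensemble distribution
isolates stochastic dynamics rather than parameter uncertainty.  All
variants of a scenario share both the parameter draw and the per-replicate
noise streams (common random numbers): distributional differences between
variants reflect model structure, not sampling luck.

Built-in scenarios (``builtin_scenarios`` / ``list_scenarios``) reproduce
the reference parameterizations: ``fig3`` (all four variants of a
20-species community), ``fig4_population`` (demographic extinction at small
vs large carrying capacity), ``fig4_community`` (niche vs neutral diversity
drift), ``fig5_population`` (white vs red noise tracking),
``fig5_seedbank`` (storage-effect community under white vs red noise) and
``fig6_predprey`` (noise-sustained transient cycles).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .drivers import PARAMETER_STREAM, seed_stream
from .population import VARIANTS, PopulationParams, simulate_population
from .community import CommunityParams, SeedBank, simulate_community, simulate_seedbank_community
from .predprey import PredPreyParams, simulate_pred_prey
from .metrics import (
    SNAPSHOT_METRICS,
    TRAJECTORY_METRICS,
    Ensemble,
    MetricResult,
    ensemble_distribution,
    trajectory_metric_distribution,
)

__all__ = [
    "ScenarioSpec",
    "ScenarioRun",
    "run_scenario",
    "builtin_scenarios",
    "list_scenarios",
    "parse_param",
    "draw_scenario_params",
    "replicate_seeds",
]

MODELS = ("population", "community", "seedbank", "predprey")


def parse_param(value):
    """Parse a parameter spec: a number passes through, ``"uniform:lo,hi"``
    becomes a ("uniform", lo, hi) draw descriptor."""
    if isinstance(value, (int, float)) or value is None:
        return value
    if isinstance(value, str):
        kind, _, args = value.partition(":")
        if kind != "uniform":
            raise ValueError(f"unknown distribution {kind!r} in parameter spec {value!r}")
        try:
            lo, hi = (float(x) for x in args.split(","))
        except ValueError as exc:
            raise ValueError(f"malformed parameter spec {value!r}") from exc
        if hi < lo:
            raise ValueError(f"empty uniform range in parameter spec {value!r}")
        return ("uniform", lo, hi)
    raise ValueError(f"unsupported parameter spec {value!r}")


def _resolve(value, rng: np.random.Generator, size=None):
    """Realise a parsed parameter: scalars broadcast, descriptors draw."""
    parsed = parse_param(value)
    if isinstance(parsed, tuple):
        _, lo, hi = parsed
        draw = rng.uniform(lo, hi, size=size)
        return float(draw) if size is None else draw
    if size is None:
        return parsed
    return np.full(size, float(parsed))


@dataclass
class ScenarioSpec:
    """Complete description of one ensemble experiment.

    ``params`` holds base parameter specs; each entry of ``arms`` overrides
    a subset of them, naming a comparison arm (e.g. white vs red noise).
    Every (arm, variant) pair is run with the same replicate seeds.
    """

    name: str
    model: str
    variants: tuple = ("deterministic",)
    params: dict = field(default_factory=dict)
    arms: dict = field(default_factory=lambda: {"default": {}})
    S: int = 1
    T: int = 100
    n_reps: int = 200
    t_star: int | None = None
    burn_in: int = 100
    n0: float | None = None
    metrics: tuple = ()
    seed: int | None = None
    description: str = ""

    def __post_init__(self):
        self.variants = tuple(self.variants)
        self.metrics = tuple(self.metrics)

    def validate(self) -> None:
        """Raise on any invalid field before a simulation starts."""
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        for v in self.variants:
            if v not in VARIANTS:
                raise ValueError(f"unknown variant {v!r}; expected one of {VARIANTS}")
        if not self.variants:
            raise ValueError("scenario needs at least one variant")
        if self.S < 1 or self.T < 1 or self.n_reps < 1:
            raise ValueError("S, T and n_reps must all be >= 1")
        if self.t_star is not None and not 0 <= self.t_star <= self.T:
            raise ValueError(f"t_star must be in [0, {self.T}], got {self.t_star}")
        for m in self.metrics:
            if m not in SNAPSHOT_METRICS + TRAJECTORY_METRICS:
                raise ValueError(f"unknown metric {m!r}")
        if any(m in SNAPSHOT_METRICS for m in self.metrics) and self.t_star is None:
            raise ValueError("snapshot metrics require t_star")
        if not self.arms:
            raise ValueError("scenario needs at least one arm")
        for arm, overrides in self.arms.items():
            merged = {**self.params, **overrides}
            for key, value in merged.items():
                parse_param(value)
            if self.model == "seedbank":
                for key in ("s", "g"):
                    if key not in merged:
                        raise ValueError(f"seed-bank scenario arm {arm!r} is missing {key!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["variants"] = list(self.variants)
        d["metrics"] = list(self.metrics)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ScenarioSpec":
        return cls.from_dict(yaml.safe_load(text))


def replicate_seeds(root_seed: int, n_reps: int) -> list[int]:
    """Deterministic per-replicate integer seeds derived from the root seed."""
    words = np.random.SeedSequence(int(root_seed)).generate_state(n_reps)
    return [int(w) for w in words]


def draw_scenario_params(spec: ScenarioSpec, arm: str, root_seed: int) -> dict:
    """Realise an arm's parameters from the scenario's root seed.

    Distribution specs are drawn once per (arm, root seed) — the realised
    community is fixed across replicates and variants, so ensemble spread
    reflects stochastic dynamics only, and every variant sees identical
    draws (common random numbers).  Community-level distribution specs draw
    one value per species (growth rates, sensitivities) or per ordered pair
    (interspecific competition), in a fixed order.
    """
    merged = {**spec.params, **spec.arms[arm]}
    rng = np.random.default_rng(seed_stream(root_seed, PARAMETER_STREAM))
    out = {}
    if spec.model in ("community", "seedbank"):
        S = spec.S
        # Fixed draw order keeps replicate streams reproducible.
        out["R"] = _resolve(merged["R"], rng, size=S)
        inter = _resolve(merged.get("alpha_inter", 0.0), rng, size=(S, S))
        alpha = np.asarray(inter, dtype=float).copy()
        np.fill_diagonal(alpha, _resolve(merged["alpha_intra"], rng, size=S))
        out["alpha"] = alpha
        out["zeta"] = _resolve(merged.get("zeta", 0.0), rng, size=S)
        out["a"] = _resolve(merged.get("a", 0.0), rng)
        if spec.model == "seedbank":
            out["s"] = _resolve(merged["s"], rng, size=S)
            out["g"] = _resolve(merged["g"], rng, size=S)
    elif spec.model == "population":
        for key in ("R", "alpha", "zeta", "a"):
            out[key] = _resolve(merged.get(key, 0.0), rng)
    else:  # predprey
        for key in ("r", "K", "attack", "conversion", "mortality", "half_sat",
                    "zeta", "a", "dt", "p0"):
            if key in merged:
                out[key] = _resolve(merged[key], rng)
    return out


@dataclass
class ScenarioRun:
    """Result of one (arm, variant) cell: the ensemble, the realised
    parameters, and the requested metric distributions."""

    arm: str
    variant: str
    ensemble: Ensemble
    drawn_params: dict
    metrics: dict


def _simulate_cell(spec: ScenarioSpec, arm: str, variant: str, root_seed: int,
                   rep_seeds: list[int]) -> ScenarioRun:
    drawn = draw_scenario_params(spec, arm, root_seed)
    trajectories = []
    for rep_seed in rep_seeds:
        if spec.model == "population":
            p = PopulationParams(R=drawn["R"], alpha=drawn["alpha"], zeta=drawn["zeta"],
                                 a=drawn["a"], variant=variant)
            tr = simulate_population(p, n0=spec.n0, T=spec.T, seed=rep_seed)
        elif spec.model in ("community", "seedbank"):
            seedbank = SeedBank(s=drawn["s"], g=drawn["g"]) if spec.model == "seedbank" else None
            p = CommunityParams(R=drawn["R"], alpha=drawn["alpha"], zeta=drawn["zeta"],
                                a=drawn["a"], variant=variant, seedbank=seedbank)
            n0 = np.full(spec.S, 50.0 if spec.n0 is None else float(spec.n0))
            sim = simulate_seedbank_community if spec.model == "seedbank" else simulate_community
            tr = sim(p, n0, spec.T, seed=rep_seed)
        else:  # predprey
            drawn_pp = dict(drawn)
            p0 = drawn_pp.pop("p0")
            p = PredPreyParams(**drawn_pp)
            tr = simulate_pred_prey(p, n0=spec.n0, p0=p0, T=spec.T, seed=rep_seed,
                                    stochastic=(variant != "deterministic"))
        trajectories.append(tr)
    ensemble = Ensemble(scenario=f"{spec.name}:{arm}:{variant}", trajectories=trajectories,
                        seeds=list(rep_seeds))
    metric_results = {}
    for m in spec.metrics:
        if m in SNAPSHOT_METRICS:
            metric_results[m] = ensemble_distribution(ensemble, m, spec.t_star)
        else:
            metric_results[m] = trajectory_metric_distribution(ensemble, m, burn_in=spec.burn_in)
    return ScenarioRun(arm=arm, variant=variant, ensemble=ensemble,
                       drawn_params=drawn, metrics=metric_results)


def run_scenario(spec: ScenarioSpec, seed: int | None = None, outdir=None,
                 n_reps: int | None = None) -> dict:
    """Execute a scenario: every (arm, variant) cell over a common set of
    replicate seeds.

    Parameters
    ----------
    spec : ScenarioSpec
    seed : int, optional
        Root seed; overrides ``spec.seed``.  Required by stochastic variants.
    outdir : path-like, optional
        If given, writes per-cell trajectory CSVs, a combined metrics CSV
        and a YAML run manifest sufficient to reproduce the outputs.
    n_reps : int, optional
        Override the spec's replicate count (e.g. to match the reference
        ensemble size).

    Returns
    -------
    dict
        Maps ``(arm, variant)`` to :class:`ScenarioRun`.
    """
    spec.validate()
    root_seed = spec.seed if seed is None else seed
    if root_seed is None:
        raise ValueError("scenario needs a root seed (spec.seed or the seed argument)")
    reps = spec.n_reps if n_reps is None else int(n_reps)
    rep_seeds = replicate_seeds(root_seed, reps)

    results = {}
    for arm in spec.arms:
        for variant in spec.variants:
            results[(arm, variant)] = _simulate_cell(spec, arm, variant, root_seed, rep_seeds)

    if outdir is not None:
        _write_outputs(spec, results, root_seed, rep_seeds, Path(outdir))
    return results


def _write_outputs(spec, results, root_seed, rep_seeds, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    metric_rows = []
    files = []
    for (arm, variant), run in results.items():
        path = outdir / f"{spec.name}__{arm}__{variant}.trajectories.csv"
        run.ensemble.to_frame().to_csv(path, index=False)
        files.append(path.name)
        for mname, mres in run.metrics.items():
            for rep, value in enumerate(mres.values):
                metric_rows.append({"scenario": spec.name, "arm": arm, "variant": variant,
                                    "replicate": rep, "metric": mname, "value": value})
    if metric_rows:
        pd.DataFrame(metric_rows).to_csv(outdir / f"{spec.name}.metrics.csv", index=False)
        files.append(f"{spec.name}.metrics.csv")
    manifest = {
        "spec": spec.to_dict(),
        "root_seed": int(root_seed),
        "replicate_seeds": rep_seeds,
        "stochcomm_version": __version__,
        "outputs": files,
    }
    (outdir / f"{spec.name}.manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))


def builtin_scenarios() -> dict:
    """The built-in figure scenarios, keyed by name.

    Replicate counts default to 200 for desk-scale runtime; pass
    ``n_reps`` to :func:`run_scenario` to match the reference ensembles
    (1,000 runs).
    """
    specs = [
        ScenarioSpec(
            name="fig3",
            description="Fig. 3: 20-species community under none/demographic/environmental/"
                        "both stochasticity; alpha-diversity distributions at t=40.",
            model="community",
            variants=("deterministic", "demographic", "environmental", "both"),
            params={"R": "uniform:2,2.5", "alpha_inter": "uniform:0.005,0.01",
                    "alpha_intra": 0.03, "zeta": 0.35, "a": 0.0},
            S=20, T=40, t_star=40, n0=50, metrics=("alpha_diversity",),
        ),
        ScenarioSpec(
            name="fig4_population",
            description="Fig. 4B,C: demographic extinction risk at small (K=6) vs "
                        "large (K=30) carrying capacity, R=1.6.",
            model="population",
            variants=("demographic",),
            params={"R": 1.6, "zeta": 0.0, "a": 0.0},
            arms={"K30": {"alpha": 0.02}, "K6": {"alpha": 0.1}},
            T=500, metrics=("persistence_time",),
        ),
        ScenarioSpec(
            name="fig4_community",
            description="Fig. 4D,E: alpha-diversity drift under demographic stochasticity, "
                        "niche-stabilized vs neutral 20-species communities.",
            model="community",
            variants=("demographic",),
            params={"zeta": 0.0, "a": 0.0, "alpha_intra": 0.03},
            arms={
                "niche": {"R": "uniform:2.0,2.5", "alpha_inter": "uniform:0.002,0.005"},
                "neutral": {"R": 2.25, "alpha_inter": 0.0035, "alpha_intra": 0.0035},
            },
            S=20, T=100, t_star=100, n0=50, metrics=("alpha_diversity",),
        ),
        ScenarioSpec(
            name="fig5_population",
            description="Fig. 5B,C: lag-1 abundance correlation of a compensatory population "
                        "under white (a=0) vs red (a=0.75) environmental noise.",
            model="population",
            variants=("environmental",),
            params={"R": 1.5, "alpha": 0.05, "zeta": 0.25},
            arms={"white": {"a": 0.0}, "red": {"a": 0.75}},
            T=600, burn_in=100, n0=10, metrics=("lag1_correlation",),
        ),
        ScenarioSpec(
            name="fig5_seedbank",
            description="Fig. 5D,E: seed-bank annual-plant community; alpha diversity under "
                        "white vs red germination noise (storage effect).",
            model="seedbank",
            variants=("environmental",),
            params={"s": 0.8, "g": 0.5, "zeta": 0.2, "R": "uniform:1.1,1.5",
                    "alpha_inter": "uniform:0.001,0.005", "alpha_intra": 0.007},
            arms={"white": {"a": 0.0}, "red": {"a": 0.75}},
            S=20, T=200, t_star=200, n0=50, metrics=("alpha_diversity",),
        ),
        ScenarioSpec(
            name="fig6_predprey",
            description="Fig. 6: Rosenzweig-MacArthur transient cycles, damped "
                        "deterministically but sustained by prey-growth noise.",
            model="predprey",
            variants=("deterministic", "environmental"),
            params={"r": 1.0, "K": 10.0, "attack": 1.0, "conversion": 0.5,
                    "mortality": 0.34, "half_sat": 2.0, "zeta": 0.2, "a": 0.0,
                    "dt": 0.01, "p0": 5.0},
            T=400, n_reps=10, n0=7.0,
        ),
    ]
    return {s.name: s for s in specs}


def list_scenarios() -> dict:
    """Names and one-line descriptions of the built-in scenarios."""
    return {name: spec.description for name, spec in builtin_scenarios().items()}
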