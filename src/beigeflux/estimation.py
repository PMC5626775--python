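"""χ²-based model fitting, rejection, parameter ensembles and prediction bands.

The agreement between model and data is the weighted sum of squared residuals

    cost = Σ_i ((y_data,i − y_sim,i) / SEM_i)²

summed over every fitted time point of every experiment.  A hypothesis is
*rejected* when even its best fit exceeds the χ² quantile at significance
``alpha`` with degrees of freedom equal to the number of fitted points.  All
non-rejected parameter vectors found around the optimum form an *acceptable
ensemble*; simulating every member yields a pointwise prediction envelope (the
"gray area" band) that expresses what the data do and do not pin down.

Shared kinetic parameters are common to all conditions; per-condition beige
modifiers obey the active hypothesis's constraints.  Optimization is
multi-start trust-region least squares in log10 parameter space.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import chi2 as chi2_dist
from scipy.stats import qmc

from .config import RunConfig
from .io import OCRTrace
from .model import (
    FREE_SHARED_PARAMETERS,
    ConditionModifiers,
    ModelParameters,
    SimulationError,
    SteadyStateError,
    simulate_protocol,
)
from .protocols import Protocol

__all__ = [
    "Dataset",
    "Experiment",
    "FitResult",
    "ParameterEnsemble",
    "PredictionBand",
    "AlignmentError",
    "DataError",
    "ConstraintError",
    "chi2_cost",
    "chi2_threshold",
    "fit_hypothesis",
    "collect_ensemble",
    "prediction_band",
]

CONDITION_ORDER = ("control", "rosi", "bmp4")


class AlignmentError(ValueError):
    """Simulation and data are not on the same time grid."""


class DataError(ValueError):
    """Data violate the weighting contract (e.g. non-positive SEM)."""


class ConstraintError(ValueError):
    """A hypothesis admits no feasible parameters."""


# ---------------------------------------------------------------------------
# dataset

@dataclass
class Experiment:
    trace: OCRTrace
    protocol: Protocol
    condition_id: str

    def __post_init__(self):
        mt = np.asarray(self.protocol.measurement_times, dtype=float)
        idx = np.searchsorted(mt, self.trace.time_min)
        ok = (idx < len(mt)) & np.isclose(
            mt[np.minimum(idx, len(mt) - 1)], self.trace.time_min
        )
        if not ok.all():
            raise AlignmentError(
                f"{self.trace.experiment_id}: trace times are not a subset of "
                f"protocol {self.protocol.protocol_id} measurement times"
            )
        self.grid_index = idx


@dataclass
class Dataset:
    """A collection of (trace, protocol, condition) experiments to fit."""

    experiments: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def add(self, experiment: Experiment) -> None:
        self.experiments[experiment.trace.experiment_id] = experiment

    def __len__(self) -> int:
        return len(self.experiments)

    @property
    def n_points(self) -> int:
        return sum(len(e.trace) for e in self.experiments.values())

    @property
    def conditions(self) -> list[str]:
        seen = {e.condition_id for e in self.experiments.values()}
        return [c for c in CONDITION_ORDER if c in seen] + sorted(
            seen - set(CONDITION_ORDER)
        )

    def subset(self, ids) -> "Dataset":
        return Dataset(
            experiments={i: self.experiments[i] for i in ids},
            provenance=dict(self.provenance),
        )

    def merged(self, other: "Dataset") -> "Dataset":
        exps = dict(self.experiments)
        exps.update(other.experiments)
        return Dataset(experiments=exps, provenance=dict(self.provenance))


# ---------------------------------------------------------------------------
# χ² machinery

def chi2_cost(sim: OCRTrace, data: OCRTrace) -> float:
    """Weighted sum of squared residuals between a simulation and data.

    Requires identical time grids and strictly positive SEM; zero iff the
    simulation reproduces the data exactly, additive over points.
    """
    if len(sim) != len(data) or not np.allclose(sim.time_min, data.time_min):
        raise AlignmentError(
            f"time grids differ between {sim.experiment_id} and {data.experiment_id}"
        )
    if np.any(data.ocr_sem <= 0):
        raise DataError(f"{data.experiment_id}: SEM must be > 0 at every fitted point")
    r = (data.ocr_mean - sim.ocr_mean) / data.ocr_sem
    return float(np.dot(r, r))


def chi2_threshold(df: int, alpha: float = 0.05) -> float:
    """Inverse χ² CDF at 1 − alpha with ``df`` degrees of freedom."""
    if int(df) != df or df < 1:
        raise ValueError(f"df must be a positive integer, got {df!r}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha!r}")
    return float(chi2_dist.ppf(1.0 - alpha, int(df)))


# ---------------------------------------------------------------------------
# parameter space

#: shared parameters whose fit bounds are absolute, not relative to defaults
_ABS_BOUNDS = {"n_alt": (1.0, 4.0), "tau_drug": (0.2, 5.0)}
_REL_BOUND_DECADES = 6.0  # others: default × 10^±6

#: per-condition modifier bounds (fitted in log10 space).  Content scales are
#: kept within a few-fold of control: measured mitochondrial-protein and lipid
#: content differences between these treatments are of that order, and the
#: scales are otherwise weakly identified from OCR alone.  Expression-like
#: levels (u_ucp1, u_alt) get a wide range.
MODIFIER_BOUNDS = {
    "u_ucp1": (1e-2, 1e2),
    "m_mito": (0.2, 5.0),
    "f_ffa": (0.5, 3.0),
    "u_alt": (1e-2, 1e2),
}
MODIFIER_STARTS = {"u_ucp1": 1.0, "m_mito": 1.0, "f_ffa": 1.0, "u_alt": 1.0}
_THETA_BOUNDS = (1e-3, 1.0)  # detection-limit fraction multiplier for H2


@dataclass
class _Entry:
    kind: str          # "shared" | "mod" | "theta"
    name: str
    cond: str | None
    lo: float          # log10 bounds
    hi: float
    start: float       # log10 start value


class ParameterSpace:
    """Mapping between the fit vector (log10) and model parameter objects."""

    def __init__(self, hypothesis, conditions, defaults: ModelParameters):
        self.hypothesis = hypothesis
        self.conditions = [c for c in CONDITION_ORDER if c in conditions]
        self.defaults = defaults
        self.entries: list[_Entry] = []
        self._fixed: dict = {c: {} for c in self.conditions}
        for name in FREE_SHARED_PARAMETERS:
            v = getattr(defaults, name)
            if name in _ABS_BOUNDS:
                lo, hi = _ABS_BOUNDS[name]
            else:
                lo, hi = v * 10.0 ** -_REL_BOUND_DECADES, v * 10.0 ** _REL_BOUND_DECADES
            self.entries.append(
                _Entry("shared", name, None, np.log10(lo), np.log10(hi), np.log10(v))
            )
        for cond in self.conditions:
            cons = hypothesis.constraints.get(cond, {})
            for fname in ("u_ucp1", "m_mito", "f_ffa", "u_alt"):
                spec = cons.get(fname, ("fix", 1.0 if fname in ("m_mito", "f_ffa") else 0.0))
                if spec[0] == "fix":
                    self._fixed[cond][fname] = float(spec[1])
                elif spec[0] == "free":
                    lo, hi = (spec[1], spec[2]) if len(spec) == 3 else MODIFIER_BOUNDS[fname]
                    if lo <= 0 or hi <= lo:
                        raise ConstraintError(
                            f"{hypothesis.hypothesis_id}: infeasible bounds for "
                            f"{cond}.{fname}: ({lo}, {hi})"
                        )
                    self.entries.append(
                        _Entry(
                            "mod", fname, cond, np.log10(lo), np.log10(hi),
                            np.log10(np.clip(MODIFIER_STARTS[fname], lo, hi)),
                        )
                    )
                elif spec[0] == "detect":
                    # u_ucp1(cond) = theta * frac * u_ucp1(rosi), theta in (0, 1]
                    self._fixed[cond][fname] = ("detect", float(spec[1]))
                    self.entries.append(
                        _Entry(
                            "theta", fname, cond,
                            np.log10(_THETA_BOUNDS[0]), np.log10(_THETA_BOUNDS[1]), 0.0,
                        )
                    )
                else:  # pragma: no cover - defensive
                    raise ConstraintError(f"unknown constraint kind {spec[0]!r}")

    @property
    def dim(self) -> int:
        return len(self.entries)

    @property
    def bounds(self):
        return (
            np.array([e.lo for e in self.entries]),
            np.array([e.hi for e in self.entries]),
        )

    @property
    def x0(self) -> np.ndarray:
        return np.array([e.start for e in self.entries])

    def decode(self, x):
        vals = 10.0 ** np.asarray(x, dtype=float)
        shared = {}
        mods_raw = {c: dict() for c in self.conditions}
        thetas = {}
        for e, v in zip(self.entries, vals):
            if e.kind == "shared":
                shared[e.name] = v
            elif e.kind == "mod":
                mods_raw[e.cond][e.name] = v
            else:
                thetas[(e.cond, e.name)] = v
        params = ModelParameters(**shared)
        mods = {}
        for cond in self.conditions:
            d = dict(mods_raw[cond])
            for fname, spec in self._fixed[cond].items():
                if isinstance(spec, tuple) and spec[0] == "detect":
                    ref = mods.get("rosi")
                    if ref is None:
                        raise ConstraintError(
                            "detection-limit constraint needs a rosi condition"
                        )
                    d[fname] = thetas[(cond, fname)] * spec[1] * ref.u_ucp1
                else:
                    d[fname] = spec
            mods[cond] = ConditionModifiers(condition_id=cond, **d)
        return params, mods


# ---------------------------------------------------------------------------
# fitting

@dataclass
class FitResult:
    hypothesis_id: str
    best_params: ModelParameters
    best_mods: dict
    best_cost: float
    n_points: int
    threshold: float
    rejected: bool
    meta: dict = field(default_factory=dict)
    x_best: np.ndarray | None = None
    space: ParameterSpace | None = None

    def to_dict(self) -> dict:
        return {
            "hypothesis_id": self.hypothesis_id,
            "best_cost": self.best_cost,
            "n_points": self.n_points,
            "threshold": self.threshold,
            "rejected": self.rejected,
            "best_params": self.best_params.to_dict(),
            "best_mods": {c: m.to_dict() for c, m in self.best_mods.items()},
            "meta": {
                k: (list(v) if isinstance(v, (tuple, np.ndarray)) else v)
                for k, v in self.meta.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _residual_builder(dataset: Dataset, space: ParameterSpace, config: RunConfig):
    exps = [dataset.experiments[k] for k in sorted(dataset.experiments)]
    sems = [
        np.maximum(
            e.trace.ocr_sem,
            np.maximum(config.sem_floor, config.sem_floor_rel * np.abs(e.trace.ocr_mean)),
        )
        for e in exps
    ]
    n = sum(len(e.trace) for e in exps)

    def residuals(x):
        try:
            params, mods = space.decode(x)
        except (ValueError, ConstraintError):
            return np.full(n, 1e3)
        out = []
        for e, sem in zip(exps, sems):
            try:
                sim = simulate_protocol(
                    params, mods[e.condition_id], e.protocol,
                    rtol=config.rtol, atol=config.atol,
                )
            except (SimulationError, SteadyStateError, ValueError):
                out.append(np.full(len(e.trace), 1e3))
                continue
            out.append((e.trace.ocr_mean - sim.ocr_mean[e.grid_index]) / sem)
        return np.concatenate(out)

    return residuals


def _starts(space: ParameterSpace, config: RunConfig) -> list[np.ndarray]:
    xs = [space.x0]
    if config.n_starts > 1:
        sampler = qmc.LatinHypercube(d=space.dim, seed=config.seed)
        lo, hi = space.bounds
        u = sampler.random(config.n_starts - 1)
        lo_s = np.maximum(space.x0 - config.start_spread_decades, lo)
        hi_s = np.minimum(space.x0 + config.start_spread_decades, hi)
        for row in u:
            xs.append(lo_s + row * (hi_s - lo_s))
    return xs


def fit_hypothesis(dataset: Dataset, hypothesis, config: RunConfig | None = None) -> FitResult:
    """Fit one uncoupling hypothesis to all experiments simultaneously.

    Shared kinetic parameters are common across conditions ("basic
    mitochondrial functions are the same regardless of treatment"); the
    per-condition beige modifiers obey the hypothesis's constraints.  The fit
    is multi-start (deterministic given config.seed); the rejection flag
    compares the best cost with the χ² bound at ``alpha`` and df = number of
    fitted points.
    """
    config = config or RunConfig()
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    space = ParameterSpace(hypothesis, dataset.conditions, ModelParameters.default())
    residuals = _residual_builder(dataset, space, config)
    lo, hi = space.bounds
    best = None
    start_costs = []
    exhausted = False
    for x0 in _starts(space, config):
        sol = least_squares(
            residuals,
            np.clip(x0, lo, hi),
            bounds=(lo, hi),
            method="trf",
            ftol=config.ftol,
            xtol=1e-10,
            diff_step=config.diff_step,
            max_nfev=config.max_nfev,
        )
        cost = float(2.0 * sol.cost)  # least_squares cost = 0.5 * sum r^2
        start_costs.append(cost)
        exhausted = exhausted or sol.status == 0
        if best is None or cost < best[1]:
            best = (sol.x, cost)
    x_best, best_cost = best
    params, mods = space.decode(x_best)
    n = dataset.n_points
    threshold = chi2_threshold(n, config.alpha)
    return FitResult(
        hypothesis_id=hypothesis.hypothesis_id,
        best_params=params,
        best_mods=mods,
        best_cost=best_cost,
        n_points=n,
        threshold=threshold,
        rejected=best_cost > threshold,
        meta={
            "seed": config.seed,
            "n_starts": config.n_starts,
            "start_costs": start_costs,
            "alpha": config.alpha,
            "budget_exhausted": exhausted,
            "config_digest": config.digest(),
        },
        x_best=np.asarray(x_best),
        space=space,
    )


# ---------------------------------------------------------------------------
# ensembles and bands

@dataclass
class ParameterEnsemble:
    """Acceptable parameter vectors (cost ≤ threshold) around the best fit."""

    hypothesis_id: str
    members: list            # list of (x (log10 vector), cost)
    threshold: float
    space: ParameterSpace | None = None
    flag_undersized: bool = False
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def decoded(self):
        for x, cost in self.members:
            yield self.space.decode(x) + (cost,)

    def to_dict(self) -> dict:
        return {
            "hypothesis_id": self.hypothesis_id,
            "threshold": self.threshold,
            "n_members": len(self.members),
            "flag_undersized": self.flag_undersized,
            "costs": [float(c) for _, c in self.members],
            "meta": dict(self.meta),
        }


def collect_ensemble(
    dataset: Dataset, hypothesis, fit: FitResult, config: RunConfig | None = None
) -> ParameterEnsemble:
    """Sample acceptable parameters by perturb-and-accept around the best fit.

    Every member re-satisfies cost ≤ threshold by direct evaluation; the best
    fit is always a member.  A rejected fit yields an empty, flagged ensemble.
    """
    config = config or RunConfig()
    if fit.rejected:
        return ParameterEnsemble(
            hypothesis_id=fit.hypothesis_id,
            members=[],
            threshold=fit.threshold,
            space=fit.space,
            flag_undersized=True,
            meta={"reason": "rejected fit", "seed": config.seed},
        )
    space = fit.space
    residuals = _residual_builder(dataset, space, config)
    lo, hi = space.bounds
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))
    members = [(np.asarray(fit.x_best), fit.best_cost)]
    steps = list(config.ensemble_steps) or [0.1]
    # random walk over the acceptable region: proposals start from a random
    # existing member; global jitter alternates with single-axis excursions,
    # which trace out the weakly identified directions that give the band its
    # width.  Any sampler is admissible as long as every member re-satisfies
    # cost <= threshold, which is checked by direct evaluation here.
    for i in range(config.ensemble_n_proposals):
        base = members[int(rng.integers(len(members)))][0]
        if i % 2 == 0:
            sigma = steps[(i // 2) % len(steps)]
            x = base + rng.normal(0.0, sigma, size=space.dim)
        else:
            x = base + rng.normal(0.0, 0.01, size=space.dim)
            j = int(rng.integers(space.dim))
            x[j] = base[j] + rng.uniform(-1.0, 1.0)
        x = np.clip(x, lo, hi)
        r = residuals(x)
        cost = float(np.dot(r, r))
        if cost <= fit.threshold:
            members.append((x, cost))
    return ParameterEnsemble(
        hypothesis_id=fit.hypothesis_id,
        members=members,
        threshold=fit.threshold,
        space=space,
        flag_undersized=len(members) < config.ensemble_min_members,
        meta={"seed": config.seed, "n_proposals": config.ensemble_n_proposals},
    )


@dataclass
class PredictionBand:
    """Pointwise simulation envelope of an acceptable-parameter ensemble."""

    protocol_id: str
    condition_id: str
    times: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    best: np.ndarray

    def __post_init__(self):
        if np.any(self.lower > self.upper + 1e-12):
            raise ValueError("prediction band has lower > upper")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "protocol_id": self.protocol_id,
                "condition_id": self.condition_id,
                "time_min": self.times,
                "ocr_lower": self.lower,
                "ocr_best": self.best,
                "ocr_upper": self.upper,
            }
        )


def prediction_band(
    ensemble: ParameterEnsemble,
    condition_id: str,
    protocol: Protocol,
    config: RunConfig | None = None,
) -> PredictionBand:
    """Simulate every ensemble member under ``protocol`` and envelope the
    trajectories pointwise (min/max); ``best`` is the best-fit member's
    simulation."""
    config = config or RunConfig()
    if len(ensemble) == 0:
        raise ValueError("cannot build a prediction band from an empty ensemble")
    sims = []
    for params, mods, _cost in ensemble.decoded():
        if condition_id not in mods:
            raise ValueError(f"ensemble carries no condition {condition_id!r}")
        tr = simulate_protocol(
            params, mods[condition_id], protocol, rtol=config.rtol, atol=config.atol
        )
        sims.append(tr.ocr_mean)
    arr = np.vstack(sims)
    best_idx = int(np.argmin([c for _, c in ensemble.members]))
    return PredictionBand(
        protocol_id=protocol.protocol_id,
        condition_id=condition_id,
        times=np.asarray(protocol.measurement_times, dtype=float),
        lower=arr.min(axis=0),
        upper=arr.max(axis=0),
        best=arr[best_idx],
    )
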