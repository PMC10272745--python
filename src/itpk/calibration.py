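"""Parameter calibration against concentration–time data, and synthetic data.

Free parameters are addressed by dotted paths into :class:`ModelParameters`:

* ``transport.dispersion_D``
* ``transport.clearance_k.3``           (compartment index 1–6)
* ``exchange.exchange_U.1-2``           (pair "i-j")
* ``exchange.stickiness_beta.4-5``

Fitting is bounded nonlinear least squares (scipy.optimize.least_squares) on
residuals in log10-concentration space above a quantification floor — drug
levels span several decades, so log residuals weight all phases of the curve.
Positive parameters are optimised on a log10 scale.  Partition coefficients
have a dedicated closed-form estimator (:func:`fit_partition`) that enforces
the simplex constraint by projection.

A synthetic-data generator (:func:`generate_synthetic`) produces noisy
observations from known ground truth, with multiplicative lognormal noise of
a chosen coefficient of variation, for parameter-recovery studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .infusion import DoseSchedule
from .model_core import (
    BrainPartitionSpec,
    ConfigurationError,
    ModelParameters,
)
from .observables import extract_observable
from .solver import SolverSettings, simulate

__all__ = [
    "PKDataset",
    "FreeParameter",
    "FitSpec",
    "FitResult",
    "generate_synthetic",
    "objective",
    "fit",
    "fit_partition",
    "get_parameter",
    "set_parameter",
]

_PENALTY_RESIDUAL = 1.0e3  # per-record residual charged when a candidate fails


# --------------------------------------------------------------------------
# parameter addressing
# --------------------------------------------------------------------------

def _parse_path(path: str):
    parts = path.split(".")
    if len(parts) == 2 and parts == ["transport", "dispersion_D"]:
        return ("transport", "dispersion_D", None)
    if len(parts) == 3 and parts[0] == "transport" and parts[1] == "clearance_k":
        return ("transport", "clearance_k", int(parts[2]))
    if len(parts) == 3 and parts[0] == "exchange" and \
            parts[1] in ("exchange_U", "stickiness_beta"):
        i, _, j = parts[2].partition("-")
        return ("exchange", parts[1], (int(i), int(j)))
    raise ConfigurationError(f"unknown parameter path {path!r}")


def get_parameter(params: ModelParameters, path: str) -> float:
    group, attr, key = _parse_path(path)
    obj = getattr(getattr(params, group), attr)
    return float(obj) if key is None else float(obj[key])


def set_parameter(params: ModelParameters, path: str, value: float) -> ModelParameters:
    """Return a copy of ``params`` with one scalar parameter replaced."""
    group, attr, key = _parse_path(path)
    sub = getattr(params, group)
    if key is None:
        new_sub = sub.__class__(**{**_fields(sub), attr: float(value)})
    else:
        mapping = dict(getattr(sub, attr))
        mapping[key] = float(value)
        new_sub = sub.__class__(**{**_fields(sub), attr: mapping})
    return params.with_updates(**{group: new_sub})


def _fields(obj) -> dict:
    return {k: getattr(obj, k) for k in obj.__dataclass_fields__}


# --------------------------------------------------------------------------
# datasets
# --------------------------------------------------------------------------

@dataclass
class PKDataset:
    """Observed (or synthetic) concentration–time records.

    ``data`` columns: time_min, observable, concentration_ug_ml, noise_cv.
    ``provenance`` records where the records came from (file path, or the
    generating seed/parameters for synthetic data).
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    REQUIRED = ("time_min", "observable", "concentration_ug_ml")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ConfigurationError(f"PKDataset missing columns {missing}")
        if "noise_cv" not in self.data.columns:
            self.data = self.data.assign(noise_cv=0.0)
        if (self.data.time_min < 0).any():
            raise ConfigurationError("PKDataset times must be >= 0")
        if (self.data.concentration_ug_ml < 0).any():
            raise ConfigurationError("PKDataset concentrations must be >= 0")

    @property
    def observables(self) -> list[str]:
        return sorted(self.data.observable.unique())

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# itpk PKDataset v1; provenance: {json.dumps(self.provenance)}\n")
            self.data.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "PKDataset":
        provenance = {"source": str(path)}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                _, _, tail = first.partition("provenance:")
                if tail.strip():
                    try:
                        provenance = json.loads(tail.strip())
                    except json.JSONDecodeError:
                        pass
                df = pd.read_csv(fh)
            else:
                fh.seek(0)
                df = pd.read_csv(fh)
        return cls(data=df, provenance=provenance)


def lognormal_noise_factors(rng: np.random.Generator, noise_cv: float,
                            size: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal factors with the given CV.

    With σ² = ln(1 + CV²) and mean −σ²/2, the factors have expectation 1 and
    coefficient of variation exactly ``noise_cv``.
    """
    if noise_cv == 0:
        return np.ones(size)
    sigma = float(np.sqrt(np.log1p(noise_cv ** 2)))
    return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=size)


def generate_synthetic(params: ModelParameters, schedule: DoseSchedule,
                       design: dict, noise_cv: float = 0.0,
                       seed: int | None = 0,
                       settings: SolverSettings | None = None,
                       truth: dict | None = None) -> PKDataset:
    """Simulate and sample noisy observations with known ground truth.

    ``design`` maps observable labels to arrays of sampling times (min).
    Noise is multiplicative lognormal with coefficient of variation
    ``noise_cv`` and unit mean (``noise_cv = 0`` reproduces the model output
    exactly).  The seed and any supplied ``truth`` parameter values are
    recorded in the dataset provenance.
    """
    if noise_cv < 0:
        raise ConfigurationError("noise_cv must be >= 0")
    if not design:
        raise ConfigurationError("design must name at least one observable")
    all_times = sorted({float(t) for ts in design.values() for t in ts})
    t_end = max(all_times[-1], schedule.last_event_end)
    res = simulate(params, schedule, t_end, output_times=all_times,
                   settings=settings)
    rng = np.random.default_rng(seed)
    rows = []
    for label, times in design.items():
        series = extract_observable(res, label)
        factors = lognormal_noise_factors(rng, noise_cv, len(times))
        for t, factor in zip(times, factors):
            c = float(series[res.time_index(float(t))]) * float(factor)
            rows.append({"time_min": float(t), "observable": label,
                         "concentration_ug_ml": c, "noise_cv": noise_cv})
    return PKDataset(
        data=pd.DataFrame(rows),
        provenance={"synthetic": True, "seed": seed, "noise_cv": noise_cv,
                    "truth": truth or {}},
    )


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FreeParameter:
    path: str
    lower: float
    upper: float
    log_scale: bool = True

    def violations(self) -> list[str]:
        out = []
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)
                and self.lower < self.upper):
            out.append(f"{self.path}: bounds must be finite with lower < upper")
        if self.log_scale and self.lower <= 0:
            out.append(f"{self.path}: log-scale bounds must be positive")
        return out


@dataclass
class FitSpec:
    """What to fit and how."""

    free: list[FreeParameter]
    fixed_overrides: dict = field(default_factory=dict)     #: path -> value
    quantification_floor: float = 1e-9                      #: µg/mL
    dataset_weights: list[float] | None = None
    max_nfev: int = 200
    xtol: float = 1e-12
    seed: int = 0                                           #: multistart RNG

    def violations(self) -> list[str]:
        out = []
        if not self.free:
            out.append("fitspec has no free parameters")
        for fp in self.free:
            out += fp.violations()
        return out

    def _encode(self, values: np.ndarray) -> np.ndarray:
        return np.array([np.log10(v) if fp.log_scale else v
                         for fp, v in zip(self.free, values)])

    def _decode(self, x: np.ndarray) -> np.ndarray:
        return np.array([10.0 ** xi if fp.log_scale else xi
                         for fp, xi in zip(self.free, x)])

    def _bounds(self):
        lo = [np.log10(fp.lower) if fp.log_scale else fp.lower for fp in self.free]
        hi = [np.log10(fp.upper) if fp.log_scale else fp.upper for fp in self.free]
        return np.array(lo), np.array(hi)


def _normalize_datasets(datasets):
    """Accept a (dataset, schedule) pair or a list of such pairs."""
    if isinstance(datasets, tuple) and len(datasets) == 2 \
            and isinstance(datasets[0], PKDataset):
        return [datasets]
    return list(datasets)


def _apply_candidate(base: ModelParameters, fitspec: FitSpec,
                     values: np.ndarray) -> ModelParameters:
    p = base
    for path, v in fitspec.fixed_overrides.items():
        p = set_parameter(p, path, v)
    for fp, v in zip(fitspec.free, values):
        p = set_parameter(p, fp.path, float(v))
    return p


def _residuals(fitspec: FitSpec, values: np.ndarray, datasets,
               base_params: ModelParameters,
               settings: SolverSettings | None) -> np.ndarray:
    floor = fitspec.quantification_floor
    weights = fitspec.dataset_weights or [1.0] * len(datasets)
    out = []
    try:
        candidate = _apply_candidate(base_params, fitspec, values)
        for (ds, schedule), w in zip(datasets, weights):
            kept = ds.data[ds.data.concentration_ug_ml >= floor]
            design_times = sorted(kept.time_min.unique())
            t_end = max(max(design_times), schedule.last_event_end)
            res = simulate(candidate, schedule, t_end,
                           output_times=design_times, settings=settings)
            cache = {}
            for rec in kept.itertuples():
                if rec.observable not in cache:
                    cache[rec.observable] = extract_observable(res, rec.observable)
                model_c = max(float(cache[rec.observable][res.time_index(rec.time_min)]),
                              floor)
                out.append(np.sqrt(w) * (np.log10(model_c)
                                         - np.log10(max(rec.concentration_ug_ml, floor))))
    except Exception:   # noqa: BLE001 - infeasible candidate: finite penalty
        n = sum(len(ds.data) for ds, _ in datasets)
        return np.full(max(n, 1), _PENALTY_RESIDUAL)
    return np.asarray(out)


def objective(fitspec: FitSpec, candidate_values, datasets,
              base_params: ModelParameters,
              settings: SolverSettings | None = None) -> float:
    """Sum of squared log10 residuals over all datasets (deterministic).

    A candidate whose simulation fails is charged a large finite penalty
    rather than raising, so optimisers can route around infeasible corners.
    """
    datasets = _normalize_datasets(datasets)
    r = _residuals(fitspec, np.asarray(candidate_values, float), datasets,
                   base_params, settings)
    return float(np.sum(r ** 2))


@dataclass
class FitResult:
    values: dict                 #: path -> fitted value
    params: ModelParameters      #: base parameters with the fit applied
    cost: float                  #: 0.5 * sum of squared residuals (scipy)
    success: bool
    message: str
    nfev: int
    residuals: pd.DataFrame
    covariance: np.ndarray | None
    recovery: dict               #: path -> relative error vs truth, if known

    def report(self) -> dict:
        return {
            "values": self.values,
            "cost": self.cost,
            "success": self.success,
            "message": self.message,
            "nfev": self.nfev,
            "recovery_relative_error": self.recovery,
        }


def fit(fitspec: FitSpec, datasets, base_params: ModelParameters,
        initial_guess: dict | None = None, n_multistart: int = 1,
        settings: SolverSettings | None = None) -> FitResult:
    """Bounded least squares over the free parameters.

    ``initial_guess`` maps parameter paths to starting values; missing entries
    start at the geometric (or arithmetic) midpoint of their bounds.  With
    ``n_multistart`` > 1, additional seeded random starts are drawn uniformly
    in the transformed space and the best solution wins.  Non-convergence is
    flagged in the result, never silently ignored.
    """
    errs = fitspec.violations()
    if errs:
        raise ConfigurationError("; ".join(errs))
    datasets = _normalize_datasets(datasets)
    n_records = sum(len(ds.data) for ds, _ in datasets)
    if n_records < len(fitspec.free):
        raise ConfigurationError(
            f"{n_records} records cannot identify {len(fitspec.free)} parameters")

    lo, hi = fitspec._bounds()
    starts = []
    x0 = 0.5 * (lo + hi)
    if initial_guess:
        guess = np.array([
            initial_guess.get(fp.path, None) for fp in fitspec.free], dtype=object)
        enc = x0.copy()
        for i, (fp, g) in enumerate(zip(fitspec.free, guess)):
            if g is not None:
                enc[i] = np.log10(g) if fp.log_scale else float(g)
        x0 = enc
    starts.append(np.clip(x0, lo, hi))
    rng = np.random.default_rng(fitspec.seed)
    for _ in range(n_multistart - 1):
        starts.append(rng.uniform(lo, hi))

    def fun(x):
        return _residuals(fitspec, fitspec._decode(x), datasets,
                          base_params, settings)

    best = None
    total_nfev = 0
    for x_start in starts:
        sol = least_squares(fun, x_start, bounds=(lo, hi),
                            xtol=fitspec.xtol, max_nfev=fitspec.max_nfev)
        total_nfev += sol.nfev
        if best is None or sol.cost < best.cost:
            best = sol

    values_arr = fitspec._decode(best.x)
    values = {fp.path: float(v) for fp, v in zip(fitspec.free, values_arr)}
    fitted_params = _apply_candidate(base_params, fitspec, values_arr)

    # covariance proxy from the Jacobian at the solution
    cov = None
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.pinv(jtj) * (2.0 * best.cost
                                     / max(len(best.fun) - len(best.x), 1))
    except Exception:   # noqa: BLE001
        cov = None

    rows = []
    k = 0
    for ds, _sched in datasets:
        kept = ds.data[ds.data.concentration_ug_ml >= fitspec.quantification_floor]
        for rec in kept.itertuples():
            rows.append({"time_min": rec.time_min, "observable": rec.observable,
                         "observed_ug_ml": rec.concentration_ug_ml,
                         "log10_residual": float(best.fun[k])})
            k += 1
    residuals = pd.DataFrame(rows)

    recovery = {}
    for ds, _sched in datasets:
        truth = ds.provenance.get("truth") or {}
        for path, true_v in truth.items():
            if path in values and true_v:
                recovery[path] = abs(values[path] - true_v) / abs(true_v)

    return FitResult(values=values, params=fitted_params, cost=float(best.cost),
                     success=bool(best.success), message=str(best.message),
                     nfev=total_nfev, residuals=residuals, covariance=cov,
                     recovery=recovery)


def fit_partition(region_datasets: dict, c4_times, c4_concentrations,
                  spec: BrainPartitionSpec,
                  v4: float | None = None) -> dict[str, float]:
    """Estimate brain partition coefficients from region data.

    Under the volumetric partition rule each region's series is proportional
    to C4, so φ_i = C_i V_i / (V4 C4) pointwise; the estimator takes the
    median over time points with informative C4 and projects the result onto
    the probability simplex (φ ≥ 0, Σφ = 1).

    ``region_datasets`` maps region name -> (times, concentrations) sampled on
    the same grid as the supplied C4 trajectory.
    """
    missing = [r for r in spec.region_names if r not in region_datasets]
    if missing:
        raise ConfigurationError(f"missing region data for {missing}")
    v4 = v4 if v4 is not None else float(np.sum(spec.region_volume_Vi))
    c4_t = np.asarray(c4_times, float)
    c4_c = np.asarray(c4_concentrations, float)
    if not np.any(c4_c > 0):
        raise ConfigurationError("degenerate fit: C4 trajectory is identically zero")
    raw = []
    for name, vi in zip(spec.region_names, spec.region_volume_Vi):
        t_i, c_i = region_datasets[name]
        t_i = np.asarray(t_i, float)
        c_i = np.asarray(c_i, float)
        c4_here = np.interp(t_i, c4_t, c4_c)
        ok = c4_here > 0
        if not np.any(ok):
            raise ConfigurationError(f"no informative points for region {name!r}")
        raw.append(float(np.median(c_i[ok] * vi / (v4 * c4_here[ok]))))
    phi = _project_simplex(np.asarray(raw))
    return {name: float(p) for name, p in zip(spec.region_names, phi)}


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto {x : x >= 0, sum x = 1}."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    rho = np.nonzero(u + (1.0 - css) / (np.arange(v.size) + 1) > 0)[0][-1]
    theta = (1.0 - css[rho]) / (rho + 1.0)
    return np.maximum(v + theta, 0.0)
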