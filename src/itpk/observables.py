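"""Derived quantities: regional samples, brain trajectories, PK metrics, sweeps.

Observable labels used across the package (and by the calibration module):

* ``spinal_csf:<landmark>`` / ``spinal_tissue:<landmark>`` — the cell
  containing a named axial landmark (lumbar, thoracic, cervical by default);
* ``cranial_csf``, ``cranial_tissue``, ``blood``, ``peripheral`` — lumped;
* ``brain:<region>`` — a brain sub-region under the volumetric partition rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .infusion import InfusionEvent, DoseSchedule
from .model_core import (
    ConfigurationError,
    ModelParameters,
    brain_region_concentrations,
)
from .solver import SimulationResult, SolverSettings, simulate

__all__ = [
    "sample_region",
    "brain_trajectories",
    "extract_observable",
    "exposure_fraction",
    "pk_metrics",
    "regimen_sweep",
    "regimen_grid",
]

_LUMPED = {"cranial_csf": 3, "cranial_tissue": 4, "blood": 5, "peripheral": 6}


def sample_region(result: SimulationResult, compartment: str, landmark: str,
                  window_cells: int = 1) -> np.ndarray:
    """Concentration–time series of the cell containing a named landmark.

    ``window_cells`` > 1 returns the mean over a centered window of that many
    cells (clipped at the domain ends).
    """
    if compartment not in ("spinal_csf", "spinal_tissue"):
        raise ConfigurationError(
            f"compartment must be spinal_csf or spinal_tissue, got {compartment!r}")
    x = result.params.landmark_x(landmark)
    L = result.params.geometry.length_L
    if not (0.0 < x <= L):
        raise ConfigurationError(f"landmark {landmark!r} at {x} cm outside (0, {L}]")
    i = result.grid.cell_index(x)
    half = max(int(window_cells) // 2, 0)
    lo, hi = max(i - half, 0), min(i + half + 1, result.n)
    block = result.c1 if compartment == "spinal_csf" else result.c2
    return block[:, lo:hi].mean(axis=1)


def brain_trajectories(result: SimulationResult,
                       spec=None) -> pd.DataFrame:
    """Per-region brain concentration series (columns = region names)."""
    spec = spec or result.params.partition
    c4 = result.lumped(4)
    v4 = result.params.volumes.cranial_tissue
    cols = {name: np.empty_like(c4) for name in spec.region_names}
    for k, c in enumerate(c4):
        regional = brain_region_concentrations(float(c), spec, v4)
        for name, val in regional.items():
            cols[name][k] = val
    return pd.DataFrame(cols, index=pd.Index(result.times, name="time_min"))


def extract_observable(result: SimulationResult, label: str) -> np.ndarray:
    """Series for one observable label (see module docstring for the set)."""
    if label in _LUMPED:
        return result.lumped(_LUMPED[label])
    if ":" in label:
        kind, _, sub = label.partition(":")
        if kind in ("spinal_csf", "spinal_tissue"):
            return sample_region(result, kind, sub)
        if kind == "brain":
            traj = brain_trajectories(result)
            if sub not in traj.columns:
                raise ConfigurationError(f"unknown brain region {sub!r}")
            return traj[sub].to_numpy()
    raise ConfigurationError(f"unknown observable {label!r}")


def exposure_fraction(result: SimulationResult, threshold: float,
                      at_time: float, compartment: str = "spinal_tissue") -> float:
    """Fraction of spinal length whose concentration ≥ threshold at a time.

    The threshold defining a "significant" exposure is drug- and
    assay-specific, so it is a required explicit argument.
    """
    if threshold < 0:
        raise ConfigurationError("threshold must be >= 0")
    if compartment not in ("spinal_tissue", "spinal_csf"):
        raise ConfigurationError(
            f"compartment must be spinal_csf or spinal_tissue, got {compartment!r}")
    i = result.time_index(at_time)
    profile = (result.c2 if compartment == "spinal_tissue" else result.c1)[i]
    return float(np.mean(profile >= threshold))


def pk_metrics(times, concentrations) -> dict[str, float]:
    """Standard summaries of one concentration–time series.

    Cmax/Tmax are read off the sampled grid; AUC(0→t_last) is trapezoidal.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.size == 0:
        raise ConfigurationError("series must be non-empty")
    imax = int(np.argmax(c))
    auc = float(np.trapezoid(c, t)) if t.size > 1 else 0.0
    return {"cmax": float(c[imax]), "tmax": float(t[imax]), "auc": auc}


_DEFAULT_METRICS = ("cranial_tissue", "spinal_tissue:thoracic")


def _single_regimen_row(params, dose_ug, volume_ml, duration_min, site_cm,
                        t_end, output_times, metric_observables, settings):
    event = InfusionEvent.create(start_time=0.0, volume_ml=volume_ml,
                                 duration_min=duration_min, dose_ug=dose_ug,
                                 site_cm=site_cm)
    schedule = DoseSchedule(events=(event,), horizon=t_end)
    res = simulate(params, schedule, t_end, output_times=output_times,
                   settings=settings)
    row = {}
    for label in metric_observables:
        series = extract_observable(res, label)
        m = pk_metrics(res.times, series)
        key = label.replace(":", "_")
        row[f"{key}_cmax"] = m["cmax"]
        row[f"{key}_auc"] = m["auc"]
        row[f"{key}_final"] = float(series[-1])
    return row


def regimen_sweep(params: ModelParameters, dose_ug: float,
                  volume_range=(1.0, 5.0), duration_range=(0.1, 100.0),
                  n_samples: int = 100, seed: int = 0,
                  site_cm: float = 3.0, t_end: float = 10080.0,
                  n_output: int = 60,
                  metric_observables=_DEFAULT_METRICS,
                  settings: SolverSettings | None = None) -> pd.DataFrame:
    """Randomised infusion-regimen sweep at fixed dose.

    Volumes are sampled uniformly over ``volume_range`` (mL); durations
    log-uniformly over ``duration_range`` (min), since the regimen space of
    interest spans three decades of infusion time.  One simulation per sample;
    per-sample failures are recorded in the ``status`` column and the sweep
    continues.  Fully determined by (seed, n_samples, ranges, params).
    """
    if n_samples < 1:
        raise ConfigurationError("n_samples must be >= 1")
    lo_v, hi_v = volume_range
    lo_d, hi_d = duration_range
    if lo_v <= 0 or hi_v < lo_v or lo_d <= 0 or hi_d < lo_d:
        raise ConfigurationError("ranges must be positive and ordered")
    rng = np.random.default_rng(seed)
    volumes = rng.uniform(lo_v, hi_v, size=n_samples)
    durations = np.exp(rng.uniform(np.log(lo_d), np.log(hi_d), size=n_samples))
    output_times = np.linspace(0.0, t_end, n_output)
    rows = []
    for v, d in zip(volumes, durations):
        row = {"volume_ml": float(v), "duration_min": float(d)}
        try:
            row.update(_single_regimen_row(params, dose_ug, float(v), float(d),
                                           site_cm, t_end, output_times,
                                           metric_observables, settings))
            row["status"] = "ok"
        except Exception as exc:  # noqa: BLE001 - per-row failures are recorded
            row["status"] = f"failed: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


def regimen_grid(params: ModelParameters, dose_ug: float,
                 volumes_ml, durations_min, site_cm: float = 3.0,
                 t_end: float = 10080.0, n_output: int = 60,
                 metric_observables=_DEFAULT_METRICS,
                 settings: SolverSettings | None = None) -> pd.DataFrame:
    """Deterministic volume × duration grid (same metrics as regimen_sweep)."""
    output_times = np.linspace(0.0, t_end, n_output)
    rows = []
    for v in volumes_ml:
        for d in durations_min:
            row = {"volume_ml": float(v), "duration_min": float(d)}
            row.update(_single_regimen_row(params, dose_ug, float(v), float(d),
                                           site_cm, t_end, output_times,
                                           metric_observables, settings))
            row["status"] = "ok"
            rows.append(row)
    return pd.DataFrame(rows)
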