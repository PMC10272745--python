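"""Finite-volume discretization and time integration of the coupled system.

The spinal CSF channel (C1) obeys the advection–dispersion–reaction PDE

    ∂C1/∂t = −∂(u C1)/∂x + D ∂²C1/∂x² − k1 C1 − (m12 + m15)/V_cell + source,

with a reflecting (zero-flux) condition at the closed sacral end and exchange
with cranial CSF across the cervical end.  The spinal tissue rod (C2) carries
no axial transport.  Discretizing both rods into N uniform volume elements and
appending the four lumped compartments yields a linear system of 2N + 4 ODEs,

    dy/dt = M y + s(t),

where M and s are constant between infusion-event boundaries (each event runs
at a constant rate).  The integrator therefore splits [0, t_end] at event
start/end times and integrates each segment with a stiff-capable adaptive
method (scipy's BDF by default) using the exact Jacobian M.

Numerical scheme:

* advection — first-order upwind on the face velocities (flow is rostral only,
  u ≥ 0), positivity-preserving and monotone;
* dispersion — central second difference, zero-flux at x = 0 and x = L (the
  cervical coupling to C3 is a separate boundary exchange term, not part of
  the stencil);
* cervical boundary — m13 = U13 (C1(L) − C3) always; the advective outflow
  u(L) A C1(L) is delivered to C3 while an infusion runs (configurable via
  ``ModelParameters.cervical_advection``) so that volume and mass balance
  close;
* infusion source — exact per-cell integrals of the point-spread kernel, so
  the delivered mass matches the nominal dose to round-off.

All exchange terms are assembled as amount-fluxes divided by the receiving
volume, which makes them internally conservative: with all clearances zero
the total amount in the system equals the total dosed mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .infusion import DoseSchedule
from .model_core import (
    COMPARTMENT_NAMES,
    ConfigurationError,
    ModelParameters,
    StateVector,
    validate_parameters,
)

__all__ = [
    "Grid",
    "SimulationResult",
    "SolverError",
    "SolverSettings",
    "build_grid",
    "assemble_rhs",
    "system_matrices",
    "simulate",
    "total_mass",
    "convergence_study",
]


class SolverError(RuntimeError):
    """Integration failure; carries the last valid state and time."""

    def __init__(self, message: str, t_last: float | None = None,
                 state_last: np.ndarray | None = None):
        super().__init__(message)
        self.t_last = t_last
        self.state_last = state_last


@dataclass(frozen=True)
class Grid:
    """Cell-centered uniform axial grid over [0, L]."""

    x_centers: np.ndarray      #: cell centers, cm
    dx: float                  #: cell width, cm
    csf_cell_volume: float     #: A·Δx, mL
    tissue_cell_volume: float  #: A_t·Δx, mL

    @property
    def n(self) -> int:
        return self.x_centers.size

    @property
    def x_faces(self) -> np.ndarray:
        return np.linspace(self.x_centers[0] - self.dx / 2.0,
                           self.x_centers[-1] + self.dx / 2.0, self.n + 1)

    def cell_index(self, x: float) -> int:
        """Index of the cell containing position x (cm)."""
        n = self.n
        i = int(np.floor(x / self.dx))
        return min(max(i, 0), n - 1)


@dataclass(frozen=True)
class SolverSettings:
    """Integrator configuration (scipy.integrate.solve_ivp)."""

    method: str = "BDF"
    rtol: float = 1e-8
    atol: float = 1e-11
    max_step: float = np.inf


@dataclass
class SimulationResult:
    """Time grid × full state trajectory plus bookkeeping."""

    times: np.ndarray                    #: output times, min (strictly increasing)
    states: np.ndarray                   #: (T, 2N+4) concentrations, µg/mL
    grid: Grid
    params: ModelParameters
    schedule: DoseSchedule
    settings: SolverSettings
    mass_ledger: list[dict] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.grid.n

    @property
    def c1(self) -> np.ndarray:
        """(T, N) spinal CSF concentration profiles."""
        return self.states[:, : self.n]

    @property
    def c2(self) -> np.ndarray:
        """(T, N) spinal tissue concentration profiles."""
        return self.states[:, self.n: 2 * self.n]

    def lumped(self, compartment: int) -> np.ndarray:
        """(T,) series of a lumped compartment C3–C6."""
        if compartment not in (3, 4, 5, 6):
            raise ConfigurationError(f"compartment {compartment} is not lumped")
        return self.states[:, 2 * self.n + compartment - 3]

    def state_at(self, index: int) -> StateVector:
        return StateVector.unpack(self.states[index], self.n)

    def time_index(self, t: float, rtol: float = 1e-9) -> int:
        """Index of output time t; errors if t was not an output time."""
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > rtol * max(1.0, abs(t)) + 1e-9:
            raise ValueError(f"time {t} min is not on the output grid")
        return i

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy long table: time_min, compartment, position_cm, concentration."""
        frames = []
        for comp, block in ((1, self.c1), (2, self.c2)):
            name = COMPARTMENT_NAMES[comp]
            for j, x in enumerate(self.grid.x_centers):
                frames.append(pd.DataFrame({
                    "time_min": self.times,
                    "compartment": name,
                    "position_cm": x,
                    "concentration_ug_ml": block[:, j],
                }))
        for comp in (3, 4, 5, 6):
            frames.append(pd.DataFrame({
                "time_min": self.times,
                "compartment": COMPARTMENT_NAMES[comp],
                "position_cm": np.nan,
                "concentration_ug_ml": self.lumped(comp),
            }))
        return pd.concat(frames, ignore_index=True)


def build_grid(geometry) -> Grid:
    """Uniform cell-centered grid; CSF cell volumes tile A·L exactly."""
    errs = geometry.violations()
    if errs:
        raise ConfigurationError("; ".join(errs))
    n = geometry.n_elements_N
    dx = geometry.length_L / n
    centers = (np.arange(n) + 0.5) * dx
    return Grid(x_centers=centers, dx=dx,
                csf_cell_volume=geometry.area_csf_A * dx,
                tissue_cell_volume=geometry.area_tissue * dx)


def _face_velocities(t: float, grid: Grid, schedule: DoseSchedule,
                     params: ModelParameters) -> np.ndarray:
    from .infusion import bulk_velocity
    return bulk_velocity(t, grid.x_faces, schedule, params.geometry)


def system_matrices(params: ModelParameters, grid: Grid,
                    t: float, schedule: DoseSchedule):
    """Assemble (M, s) of dy/dt = M y + s for the event configuration at time t.

    Both are constant on any interval over which the set of active events does
    not change, because each event infuses at a constant rate.
    """
    n = grid.n
    dim = 2 * n + 4
    dx = grid.dx
    vc = grid.csf_cell_volume
    vt = grid.tissue_cell_volume
    tr = params.transport
    ex = params.exchange
    vol = params.volumes
    i3, i4, i5, i6 = 2 * n, 2 * n + 1, 2 * n + 2, 2 * n + 3

    M = np.zeros((dim, dim))
    s = np.zeros(dim)

    # --- C1: dispersion (reflecting at both ends of the stencil) ---
    d = tr.dispersion_D / dx ** 2
    idx = np.arange(n)
    M[idx, idx] += -2.0 * d
    M[idx[:-1], idx[:-1] + 1] += d
    M[idx[1:], idx[1:] - 1] += d
    M[0, 0] += d       # ghost-cell reflection at x = 0
    M[n - 1, n - 1] += d   # and at x = L (cervical exchange handled below)

    # --- C1: upwind advection on face velocities (u >= 0, rostral) ---
    u_face = _face_velocities(t, grid, schedule, params)
    if np.any(u_face > 0):
        M[idx, idx] += -u_face[1:] / dx
        M[idx[1:], idx[1:] - 1] += u_face[1:-1] / dx
        if params.cervical_advection:
            # advected outflow u(L)·A·C1(L) enters cranial CSF
            M[i3, n - 1] += u_face[-1] * params.geometry.area_csf_A / vol.cranial_csf

    # --- clearances ---
    k = tr.clearance_k
    M[idx, idx] += -k[1]
    M[n + idx, n + idx] += -k[2]
    for comp, ii in ((3, i3), (4, i4), (5, i5), (6, i6)):
        M[ii, ii] += -k[comp]

    # --- distributed exchanges (per-cell coefficient U/N, amounts/volume) ---
    u12 = ex.exchange_U[(1, 2)] / n
    b12 = ex.stickiness_beta[(1, 2)]
    M[idx, idx] += -u12 / vc
    M[idx, n + idx] += u12 * b12 / vc
    M[n + idx, idx] += u12 / vt
    M[n + idx, n + idx] += -u12 * b12 / vt

    u15 = ex.exchange_U[(1, 5)] / n
    b15 = ex.stickiness_beta[(1, 5)]
    M[idx, idx] += -u15 / vc
    M[idx, i5] += u15 * b15 / vc
    M[i5, idx] += u15 / vol.blood
    M[i5, i5] += -n * u15 * b15 / vol.blood

    u25 = ex.exchange_U[(2, 5)] / n
    b25 = ex.stickiness_beta[(2, 5)]
    M[n + idx, n + idx] += -u25 / vt
    M[n + idx, i5] += u25 * b25 / vt
    M[i5, n + idx] += u25 / vol.blood
    M[i5, i5] += -n * u25 * b25 / vol.blood

    # --- cervical boundary exchange with cranial CSF ---
    u13 = ex.exchange_U[(1, 3)]
    M[n - 1, n - 1] += -u13 / vc
    M[n - 1, i3] += u13 / vc
    M[i3, n - 1] += u13 / vol.cranial_csf
    M[i3, i3] += -u13 / vol.cranial_csf

    # --- lumped exchanges ---
    u34 = ex.exchange_U[(3, 4)]
    b34 = ex.stickiness_beta[(3, 4)]
    M[i3, i3] += -u34 / vol.cranial_csf
    M[i3, i4] += u34 * b34 / vol.cranial_csf
    M[i4, i3] += u34 / vol.cranial_tissue
    M[i4, i4] += -u34 * b34 / vol.cranial_tissue

    u45 = ex.exchange_U[(4, 5)]
    b45 = ex.stickiness_beta[(4, 5)]
    # m45 = U45 (b45 C4 - C5): leaves C4, enters C5 (asymmetric form)
    M[i4, i4] += -u45 * b45 / vol.cranial_tissue
    M[i4, i5] += u45 / vol.cranial_tissue
    M[i5, i4] += u45 * b45 / vol.blood
    M[i5, i5] += -u45 / vol.blood

    u56 = ex.exchange_U[(5, 6)]
    b56 = ex.stickiness_beta[(5, 6)]
    M[i5, i5] += -u56 / vol.blood
    M[i5, i6] += u56 * b56 / vol.blood
    M[i6, i5] += u56 / vol.peripheral
    M[i6, i6] += -u56 * b56 / vol.peripheral

    # --- infusion source into C1 (exact per-cell kernel integrals) ---
    L = params.geometry.length_L
    faces = grid.x_faces
    for e in schedule.active_events(t):
        if e.dose_mass <= 0:
            continue
        cell_int = np.diff(e.kernel_cdf(faces, L))
        s[:n] += e.rate * e.infusate_concentration * cell_int / vc
    return M, s


def assemble_rhs(t: float, state, params: ModelParameters,
                 schedule: DoseSchedule, grid: Grid | None = None) -> np.ndarray:
    """Time derivative of the packed state vector (2N+4,) at time t."""
    if grid is None:
        grid = build_grid(params.geometry)
    y = state.pack() if isinstance(state, StateVector) else np.asarray(state, float)
    if not np.all(np.isfinite(y)):
        raise SolverError("non-finite state passed to assemble_rhs", t_last=t,
                          state_last=y)
    M, s = system_matrices(params, grid, t, schedule)
    return M @ y + s


def simulate(params: ModelParameters, schedule: DoseSchedule,
             t_end: float, output_times=None,
             initial_state: StateVector | None = None,
             settings: SolverSettings | None = None) -> SimulationResult:
    """Integrate the 2N+4 system over [0, t_end].

    Event start/end times are used as integration breakpoints (M and s are
    constant within each segment), so short boluses are never stepped over.
    Small negative concentrations within the solver tolerance are clamped to
    zero; anything materially below zero aborts with a :class:`SolverError`.
    """
    report = validate_parameters(params)
    if not report.ok:
        raise ConfigurationError(str(report))
    errs = schedule.violations(params.geometry.length_L)
    if errs:
        raise ConfigurationError("; ".join(errs))
    if schedule.events and t_end < schedule.last_event_end:
        raise ConfigurationError(
            f"t_end = {t_end} min precedes the end of the last infusion "
            f"({schedule.last_event_end} min)")
    settings = settings or SolverSettings()
    grid = build_grid(params.geometry)
    n = grid.n

    if output_times is None:
        output_times = np.linspace(0.0, t_end, 201)
    output_times = np.asarray(sorted(set(float(t) for t in output_times)))
    if output_times.size and (output_times[0] < 0 or output_times[-1] > t_end):
        raise ConfigurationError("output_times must lie within [0, t_end]")

    y = (initial_state.pack() if initial_state is not None
         else np.zeros(2 * n + 4))
    if y.shape != (2 * n + 4,):
        raise ConfigurationError("initial_state has the wrong number of elements")

    breaks = [b for b in schedule.breakpoints() if 0.0 < b < t_end]
    seg_edges = [0.0] + breaks + [t_end]

    times_out: list[float] = []
    states_out: list[np.ndarray] = []
    if output_times.size and output_times[0] == 0.0:
        times_out.append(0.0)
        states_out.append(y.copy())
    nfev = 0
    for ta, tb in zip(seg_edges[:-1], seg_edges[1:]):
        if tb <= ta:
            continue
        tmid = 0.5 * (ta + tb)
        M, s = system_matrices(params, grid, tmid, schedule)

        def rhs(t, yy, M=M, s=s):
            return M @ yy + s

        def jac(t, yy, M=M):
            return M

        t_eval = output_times[(output_times > ta) & (output_times <= tb)]
        want_tb = t_eval.size == 0 or t_eval[-1] != tb
        te_abs = np.concatenate([t_eval, [tb]]) if want_tb else t_eval
        # M and s are constant on the segment, so integrate in local time
        # (avoids step-size underflow at large absolute times)
        sol = solve_ivp(rhs, (0.0, tb - ta), y, method=settings.method,
                        jac=jac, rtol=settings.rtol, atol=settings.atol,
                        max_step=settings.max_step, t_eval=te_abs - ta)
        if not sol.success:
            t_last = ta + (float(sol.t[-1]) if len(sol.t) else 0.0)
            raise SolverError(f"integrator failed on [{ta}, {tb}]: {sol.message}",
                              t_last=t_last,
                              state_last=sol.y[:, -1] if len(sol.t) else y)
        nfev += sol.nfev
        n_report = len(t_eval)  # the trailing tb sample may be bookkeeping only
        for tt, yy in zip(te_abs[:n_report], sol.y.T[:n_report]):
            times_out.append(float(tt))
            states_out.append(yy.copy())
        y = sol.y[:, -1].copy()

    times = np.asarray(times_out)
    states = np.asarray(states_out) if states_out else np.zeros((0, 2 * n + 4))

    # negative-concentration policy
    if states.size:
        peak = float(np.max(np.abs(states))) if np.max(np.abs(states)) > 0 else 0.0
        floor = -max(10.0 * settings.atol, 1e-9 * peak)
        worst = float(states.min(initial=0.0))
        if worst < floor:
            raise SolverError(
                f"concentration fell to {worst:.3e} µg/mL, below the tolerance "
                f"floor {floor:.3e}", t_last=float(times[-1]), state_last=states[-1])
        np.clip(states, 0.0, None, out=states)

    ledger = [{
        "start_min": e.start_time,
        "duration_min": e.duration,
        "volume_ml": e.infusate_volume_Vinj,
        "dose_ug": e.dose_mass,
    } for e in schedule.events]
    return SimulationResult(
        times=times, states=states, grid=grid, params=params,
        schedule=schedule, settings=settings, mass_ledger=ledger,
        diagnostics={"nfev": int(nfev), "n_segments": len(seg_edges) - 1,
                     "rtol": settings.rtol, "atol": settings.atol},
    )


def total_mass(state, params: ModelParameters, grid: Grid | None = None) -> float:
    """Total drug amount (µg) in all compartments of one state."""
    if grid is None:
        grid = build_grid(params.geometry)
    sv = state if isinstance(state, StateVector) else StateVector.unpack(
        np.asarray(state, float), grid.n)
    vol = params.volumes
    return (float(np.sum(sv.c1)) * grid.csf_cell_volume
            + float(np.sum(sv.c2)) * grid.tissue_cell_volume
            + sv.c3 * vol.cranial_csf + sv.c4 * vol.cranial_tissue
            + sv.c5 * vol.blood + sv.c6 * vol.peripheral)


def _restrict(profile: np.ndarray, n_coarse: int) -> np.ndarray:
    """Conservative restriction of a fine cell-centered profile to n_coarse cells."""
    n_fine = profile.size
    if n_fine % n_coarse:
        raise ValueError("fine grid must be an integer refinement of the coarse one")
    r = n_fine // n_coarse
    return profile.reshape(n_coarse, r).mean(axis=1)


def convergence_study(params: ModelParameters, schedule: DoseSchedule,
                      N_list, t_end: float, at_time: float | None = None,
                      settings: SolverSettings | None = None,
                      reference: str = "finest") -> pd.DataFrame:
    """Grid-refinement study of the C1 profile.

    Runs the same problem on each N in ``N_list`` (must be increasing and
    nested), measures the L² error of the final C1 profile against the finest
    grid (restricted conservatively), and reports the observed order between
    successive refinements.  Expected: ≈2 for smooth diffusion-dominated
    problems, ≈1 when upwind advection dominates.
    """
    N_list = list(N_list)
    if any(b <= a for a, b in zip(N_list[:-1], N_list[1:])):
        raise ConfigurationError("N_list must be strictly increasing")
    at_time = t_end if at_time is None else at_time
    profiles = {}
    for n in N_list:
        p = params.with_updates(
            geometry=params.geometry.__class__(
                length_L=params.geometry.length_L,
                area_csf_A=params.geometry.area_csf_A,
                area_tissue=params.geometry.area_tissue,
                n_elements_N=n))
        res = simulate(p, schedule, t_end, output_times=[at_time],
                       settings=settings)
        profiles[n] = res.c1[res.time_index(at_time)]
    n_ref = N_list[-1]
    ref = profiles[n_ref]
    rows = []
    L = params.geometry.length_L
    for n in N_list[:-1]:
        diff = profiles[n] - _restrict(ref, n)
        err = float(np.sqrt(np.sum(diff ** 2) * (L / n)))
        rows.append({"N": n, "dx_cm": L / n, "l2_error": err})
    df = pd.DataFrame(rows)
    orders = [np.nan]
    for i in range(1, len(df)):
        orders.append(float(np.log2(df.l2_error[i - 1] / df.l2_error[i])))
    df["observed_order"] = orders
    return df
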