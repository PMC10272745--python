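"""Dose schedules and the distributed infusion flux.

An infusion event pushes ``infusate_volume_Vinj`` mL of solution (carrying
``dose_mass`` µg of drug, or nothing for a flush) into the spinal CSF channel
at a lumbar/thoracic site over a finite duration.  Rather than a point (Dirac)
source, the inflow is spread by a compactly supported point-spread kernel that
decays symmetrically to zero within ``spread_halfwidth`` (default 2 cm) of the
injection site — a catheter mixes the infusate over a small but finite zone.

The local volumetric flux density f(t, x) (mL/min/cm) satisfies the volume
identity  V_inj = ∫∫ f dx dt  over the event window, and drives an axially
uniform plug flow.  With the sacral end closed and the fluid incompressible,

    u(x, t) = (1/A) ∫_0^x f(t, x') dx' ,

so u rises from 0 across the kernel support to F(t)/A rostral of it and
vanishes whenever no infusion is active.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .model_core import ConfigurationError, SpinalGeometry

__all__ = [
    "InfusionEvent",
    "DoseSchedule",
    "build_schedule",
    "psf_kernel",
    "infusion_flux",
    "bulk_velocity",
]


@dataclass(frozen=True)
class InfusionEvent:
    """One infusion (drug bolus or drug-free flush).

    Exactly one of ``duration_min``/``rate_ml_min`` may be supplied at build
    time via :meth:`create`; the stored event always carries the duration,
    with the rate derived as volume/duration.
    """

    start_time: float               #: min
    infusate_volume_Vinj: float     #: mL
    duration: float                 #: min
    dose_mass: float = 0.0          #: µg; 0 for a flush
    injection_site_xbar: float = 3.0  #: cm from the sacral end
    spread_halfwidth: float = 2.0   #: cm

    @classmethod
    def create(cls, *, start_time: float = 0.0, volume_ml: float,
               duration_min: float | None = None, rate_ml_min: float | None = None,
               dose_ug: float = 0.0, site_cm: float = 3.0,
               halfwidth_cm: float = 2.0) -> "InfusionEvent":
        if (duration_min is None) == (rate_ml_min is None):
            raise ConfigurationError(
                "specify exactly one of duration_min or rate_ml_min")
        if volume_ml <= 0:
            raise ConfigurationError(f"infusate volume must be > 0 (got {volume_ml})")
        if duration_min is None:
            if rate_ml_min <= 0:
                raise ConfigurationError(f"rate must be > 0 (got {rate_ml_min})")
            duration_min = volume_ml / rate_ml_min
        if duration_min <= 0:
            raise ConfigurationError(f"duration must be > 0 (got {duration_min})")
        return cls(start_time=start_time, infusate_volume_Vinj=volume_ml,
                   duration=duration_min, dose_mass=dose_ug,
                   injection_site_xbar=site_cm, spread_halfwidth=halfwidth_cm)

    @property
    def rate(self) -> float:
        """Volumetric infusion rate F (mL/min)."""
        return self.infusate_volume_Vinj / self.duration

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    @property
    def infusate_concentration(self) -> float:
        """Drug concentration of the infusate stream (µg/mL)."""
        return self.dose_mass / self.infusate_volume_Vinj

    def is_active(self, t: float) -> bool:
        return self.start_time <= t < self.end_time

    def violations(self, length_L: float | None = None) -> list[str]:
        out = []
        if self.infusate_volume_Vinj <= 0:
            out.append(f"event volume must be > 0 (got {self.infusate_volume_Vinj})")
        if self.duration <= 0:
            out.append(f"event duration must be > 0 (got {self.duration})")
        if self.dose_mass < 0:
            out.append(f"event dose_mass must be >= 0 (got {self.dose_mass})")
        if self.spread_halfwidth <= 0:
            out.append(f"event spread_halfwidth must be > 0 (got {self.spread_halfwidth})")
        if abs(self.rate * self.duration - self.infusate_volume_Vinj) \
                > 1e-12 * max(self.infusate_volume_Vinj, 1.0):
            out.append("event rate*duration must equal infusate volume")
        if length_L is not None and not (0.0 < self.injection_site_xbar < length_L):
            out.append(f"injection site {self.injection_site_xbar} cm outside "
                       f"(0, {length_L}) cm")
        return out

    # ---- point-spread kernel (raised-cosine bump, clipped to [0, L]) ----

    def _cdf_unclipped(self, x) -> np.ndarray:
        """Integral of the unit Hann bump from −∞ to x (before clipping)."""
        x = np.asarray(x, dtype=float)
        z = np.clip((x - self.injection_site_xbar) / self.spread_halfwidth, -1.0, 1.0)
        return 0.5 * (z + np.sin(np.pi * z) / np.pi) + 0.5

    def _norm(self, length_L: float) -> float:
        # mass of the bump remaining after clipping the support to [0, L]
        return float(self._cdf_unclipped(length_L) - self._cdf_unclipped(0.0))

    def kernel(self, x, length_L: float) -> np.ndarray:
        """Point-spread density (1/cm): symmetric, zero beyond the halfwidth,
        unit integral over [0, L] (renormalised if clipped by a boundary)."""
        x = np.asarray(x, dtype=float)
        h = self.spread_halfwidth
        d = x - self.injection_site_xbar
        inside = (np.abs(d) < h) & (x >= 0.0) & (x <= length_L)
        k = np.where(inside, (1.0 + np.cos(np.pi * d / h)) / (2.0 * h), 0.0)
        return k / self._norm(length_L)

    def kernel_cdf(self, x, length_L: float) -> np.ndarray:
        """∫_0^x kernel dx' — exact, used for cell integrals and plug flow."""
        lo = self._cdf_unclipped(0.0)
        return (self._cdf_unclipped(np.clip(x, 0.0, length_L)) - lo) / self._norm(length_L)


@dataclass(frozen=True)
class DoseSchedule:
    """Time-ordered program of infusion events; overlapping flow rates add."""

    events: tuple[InfusionEvent, ...] = ()
    horizon: float | None = None    #: min; None = open-ended

    def __post_init__(self):
        object.__setattr__(self, "events",
                           tuple(sorted(self.events, key=lambda e: e.start_time)))

    @property
    def last_event_end(self) -> float:
        return max((e.end_time for e in self.events), default=0.0)

    @property
    def total_dose(self) -> float:
        return sum(e.dose_mass for e in self.events)

    def active_events(self, t: float) -> list[InfusionEvent]:
        return [e for e in self.events if e.is_active(t)]

    def breakpoints(self) -> list[float]:
        """Event start/end times, for use as integration segment boundaries."""
        pts = set()
        for e in self.events:
            pts.add(e.start_time)
            pts.add(e.end_time)
        return sorted(pts)

    def violations(self, length_L: float | None = None) -> list[str]:
        out = []
        for i, e in enumerate(self.events):
            out += [f"event {i}: {v}" for v in e.violations(length_L)]
        if self.horizon is not None and self.events and self.horizon < self.last_event_end:
            out.append("schedule horizon ends before the last event")
        return out


def build_schedule(doses, repeat_interval: float = 0.0, n_repeats: int = 1,
                   flush: dict | None = None,
                   horizon: float | None = None) -> DoseSchedule:
    """Assemble a repeat-dose schedule.

    Parameters
    ----------
    doses
        List of dicts accepted by :meth:`InfusionEvent.create` (keys
        ``dose_ug``, ``volume_ml``, ``duration_min`` or ``rate_ml_min``,
        ``site_cm``, optional ``halfwidth_cm``).  Within one cycle the doses
        run back to back starting at the cycle origin.
    repeat_interval
        Minutes between cycle starts (e.g. 2 weeks = 20160 min).
    n_repeats
        Number of cycles (each containing every dose plus the flush).
    flush
        Optional drug-free event appended immediately after the last dose of
        each cycle (``volume_ml``, ``duration_min``/``rate_ml_min``; site and
        halfwidth default to the last dose's).
    """
    if n_repeats < 1:
        raise ConfigurationError("n_repeats must be >= 1")
    if n_repeats > 1 and repeat_interval <= 0:
        raise ConfigurationError("repeat_interval must be > 0 for repeated doses")
    events = []
    for r in range(n_repeats):
        t = r * repeat_interval
        last = None
        for spec in doses:
            ev = InfusionEvent.create(start_time=t, **spec)
            events.append(ev)
            t = ev.end_time
            last = ev
        if flush is not None:
            fspec = dict(flush)
            fspec.setdefault("site_cm",
                             last.injection_site_xbar if last else 3.0)
            fspec.setdefault("halfwidth_cm",
                             last.spread_halfwidth if last else 2.0)
            fspec["dose_ug"] = 0.0
            events.append(InfusionEvent.create(start_time=t, **fspec))
    return DoseSchedule(events=tuple(events), horizon=horizon)


def psf_kernel(x, event: InfusionEvent, length_L: float = 20.0) -> np.ndarray:
    """Point-spread flux-density weight (1/cm) of one event at position(s) x."""
    return event.kernel(x, length_L)


def infusion_flux(t: float, x, schedule: DoseSchedule,
                  length_L: float = 20.0) -> np.ndarray:
    """Local volumetric infusion flux density f(t, x) in mL/min/cm.

    Superposition of rate·kernel over all events active at t; the double
    integral over an event's window and the domain recovers its V_inj.
    """
    x = np.asarray(x, dtype=float)
    f = np.zeros_like(x)
    for e in schedule.active_events(t):
        f += e.rate * e.kernel(x, length_L)
    return f


def bulk_velocity(t: float, x, schedule: DoseSchedule,
                  geometry: SpinalGeometry) -> np.ndarray:
    """Plug-flow velocity u(x, t) = (1/A) ∫_0^x f(t, x') dx' in cm/min.

    Zero at the closed sacral end, non-decreasing in x, equal to F(t)/A
    rostral of every active kernel's support, identically zero when no
    infusion is running.
    """
    x = np.asarray(x, dtype=float)
    u = np.zeros_like(x)
    for e in schedule.active_events(t):
        u += e.rate * e.kernel_cdf(x, geometry.length_L)
    return u / geometry.area_csf_A
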