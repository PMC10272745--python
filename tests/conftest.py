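import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import itpk
from itpk.model_core import (
    EXCHANGE_PAIRS,
    STICKY_PAIRS,
    ExchangeParams,
    SpinalGeometry,
    TransportParams,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


ZERO_U = {p: 0.0 for p in EXCHANGE_PAIRS}
ZERO_BETA = {p: 0.0 for p in STICKY_PAIRS}
ZERO_K = {i: 0.0 for i in range(1, 7)}


@pytest.fixture(scope="session")
def reference():
    """Shipped NHP reference parameters + single-dose protocol."""
    return itpk.reference_config()


@pytest.fixture(scope="session")
def ref_params(reference):
    return reference[0]


@pytest.fixture(scope="session")
def ref_schedule(reference):
    return reference[1]


def stripped_params(base, *, D=0.0, k=None, U=None, beta=None, n_elements=None):
    """Reference parameters with transport/exchange switched off except as given."""
    geometry = base.geometry if n_elements is None else SpinalGeometry(
        length_L=base.geometry.length_L,
        area_csf_A=base.geometry.area_csf_A,
        area_tissue=base.geometry.area_tissue,
        n_elements_N=n_elements,
    )
    return base.with_updates(
        geometry=geometry,
        transport=TransportParams(dispersion_D=D,
                                  clearance_k={**ZERO_K, **(k or {})}),
        exchange=ExchangeParams(exchange_U={**ZERO_U, **(U or {})},
                                stickiness_beta={**ZERO_BETA, **(beta or {})}),
    )


@pytest.fixture()
def small_fast_params(ref_params):
    """Coarse grid for quick calibration-style tests."""
    return ref_params.with_updates(geometry=SpinalGeometry(
        length_L=20.0, area_csf_A=0.5, area_tissue=0.3, n_elements_N=30))


def single_dose_schedule(dose_ug=12000.0, volume_ml=1.0, duration_min=1.0,
                         site_cm=3.0, flush=False):
    events = [itpk.InfusionEvent.create(
        start_time=0.0, volume_ml=volume_ml, duration_min=duration_min,
        dose_ug=dose_ug, site_cm=site_cm)]
    if flush:
        events.append(itpk.InfusionEvent.create(
            start_time=events[0].end_time, volume_ml=0.25, duration_min=1.0,
            dose_ug=0.0, site_cm=site_cm))
    return itpk.DoseSchedule(events=tuple(events))
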