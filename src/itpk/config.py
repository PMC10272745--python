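"""Structured-text configuration: loading, validation, serialization, manifests.

One YAML dialect with flat keys mirroring the domain types, units spelled out
in the key names.  ``load_config`` either returns fully validated objects or
raises a :class:`ConfigError` carrying *every* violation, not just the first.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import yaml

from . import __version__
from .infusion import DoseSchedule, InfusionEvent
from .model_core import (
    BrainPartitionSpec,
    CompartmentVolumes,
    ExchangeParams,
    ModelParameters,
    SpinalGeometry,
    TransportParams,
    ValidationReport,
    validate_parameters,
)

__all__ = [
    "ConfigError",
    "load_config",
    "loads_config",
    "save_config",
    "dumps_config",
    "reference_config",
    "run_manifest",
]

_COMPARTMENT_KEYS = {1: "spinal_csf", 2: "spinal_tissue", 3: "cranial_csf",
                     4: "cranial_tissue", 5: "blood", 6: "peripheral"}
_KEY_TO_COMPARTMENT = {v: k for k, v in _COMPARTMENT_KEYS.items()}


class ConfigError(ValueError):
    """Invalid configuration; ``report`` lists every violation found."""

    def __init__(self, report: ValidationReport):
        super().__init__(str(report))
        self.report = report


def _pair_key(pair: tuple[int, int]) -> str:
    return f"{pair[0]}-{pair[1]}"


def _parse_pair(key: str) -> tuple[int, int]:
    i, _, j = str(key).partition("-")
    return (int(i), int(j))


def _build_params(doc: dict, errors: list[str]) -> ModelParameters:
    m = doc.get("model", {})
    geo = m.get("geometry", {})
    geometry = SpinalGeometry(
        length_L=float(geo.get("length_cm", 20.0)),
        area_csf_A=float(geo.get("csf_area_cm2", 0.5)),
        area_tissue=float(geo.get("tissue_area_cm2", 0.3)),
        n_elements_N=int(geo.get("n_elements", 100)),
    )
    tr = m.get("transport", {})
    clearance = {_KEY_TO_COMPARTMENT[k]: float(v)
                 for k, v in tr.get("clearance_per_min", {}).items()
                 if k in _KEY_TO_COMPARTMENT}
    for k in tr.get("clearance_per_min", {}):
        if k not in _KEY_TO_COMPARTMENT:
            errors.append(f"transport.clearance_per_min: unknown compartment {k!r}")
    transport = TransportParams(
        dispersion_D=float(tr.get("dispersion_cm2_min", 0.1)),
        clearance_k={i: clearance.get(i, 0.0) for i in range(1, 7)},
    )
    ex = m.get("exchange", {})
    exchange = ExchangeParams(
        exchange_U={_parse_pair(k): float(v)
                    for k, v in ex.get("U_ml_min", {}).items()},
        stickiness_beta={_parse_pair(k): float(v)
                         for k, v in ex.get("beta", {}).items()},
    )
    vo = m.get("volumes_ml", {})
    volumes = CompartmentVolumes(
        cranial_csf=float(vo.get("cranial_csf", 8.0)),
        cranial_tissue=float(vo.get("cranial_tissue", 72.0)),
        blood=float(vo.get("blood", 150.0)),
        peripheral=float(vo.get("peripheral", 2000.0)),
    )
    pa = m.get("brain_partition", {})
    partition = BrainPartitionSpec(
        region_names=tuple(pa.get("regions",
                                  ("pons", "hippocampus", "cerebellum", "cortex"))),
        region_volume_Vi=tuple(float(v) for v in pa.get("volumes_ml",
                                                        (1.8, 1.2, 6.0, 63.0))),
        partition_phi=tuple(float(v) for v in pa.get("phi",
                                                     (0.08, 0.07, 0.15, 0.70))),
    )
    landmarks = {str(k): float(v) for k, v in m.get(
        "landmarks_fraction_of_L",
        {"lumbar": 0.15, "thoracic": 0.50, "cervical": 0.90}).items()}
    return ModelParameters(
        geometry=geometry, transport=transport, exchange=exchange,
        volumes=volumes, partition=partition, landmark_positions=landmarks,
        cervical_advection=bool(m.get("cervical_advection", True)),
    )


def _build_schedule(doc: dict, errors: list[str]) -> DoseSchedule:
    s = doc.get("schedule", {})
    events = []
    for i, ev in enumerate(s.get("events", [])):
        try:
            events.append(InfusionEvent.create(
                start_time=float(ev.get("start_min", 0.0)),
                volume_ml=float(ev["volume_ml"]),
                duration_min=(float(ev["duration_min"])
                              if "duration_min" in ev else None),
                rate_ml_min=(float(ev["rate_ml_min"])
                             if "rate_ml_min" in ev else None),
                dose_ug=float(ev.get("dose_ug", 0.0)),
                site_cm=float(ev.get("site_cm", 3.0)),
                halfwidth_cm=float(ev.get("halfwidth_cm", 2.0)),
            ))
        except (KeyError, ValueError) as exc:
            errors.append(f"schedule.events[{i}]: {exc}")
    horizon = s.get("horizon_min")
    return DoseSchedule(events=tuple(events),
                        horizon=float(horizon) if horizon is not None else None)


def loads_config(text: str) -> tuple[ModelParameters, DoseSchedule]:
    """Parse a config document; raise ConfigError with all violations."""
    try:
        doc = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(ValidationReport(
            ok=False, errors=(f"YAML parse error: {exc}",))) from exc
    errors: list[str] = []
    params = _build_params(doc, errors)
    schedule = _build_schedule(doc, errors)
    report = validate_parameters(params)
    errors = list(report.errors) + errors
    errors += schedule.violations(params.geometry.length_L)
    if errors:
        raise ConfigError(ValidationReport(ok=False, errors=tuple(errors)))
    return params, schedule


def load_config(path) -> tuple[ModelParameters, DoseSchedule]:
    with open(path) as fh:
        return loads_config(fh.read())


def dumps_config(params: ModelParameters, schedule: DoseSchedule) -> str:
    doc = {
        "model": {
            "geometry": {
                "length_cm": params.geometry.length_L,
                "csf_area_cm2": params.geometry.area_csf_A,
                "tissue_area_cm2": params.geometry.area_tissue,
                "n_elements": params.geometry.n_elements_N,
            },
            "transport": {
                "dispersion_cm2_min": params.transport.dispersion_D,
                "clearance_per_min": {
                    _COMPARTMENT_KEYS[i]: params.transport.clearance_k[i]
                    for i in range(1, 7)},
            },
            "exchange": {
                "U_ml_min": {_pair_key(p): v
                             for p, v in sorted(params.exchange.exchange_U.items())},
                "beta": {_pair_key(p): v
                         for p, v in sorted(params.exchange.stickiness_beta.items())},
            },
            "volumes_ml": {
                "cranial_csf": params.volumes.cranial_csf,
                "cranial_tissue": params.volumes.cranial_tissue,
                "blood": params.volumes.blood,
                "peripheral": params.volumes.peripheral,
            },
            "brain_partition": {
                "regions": list(params.partition.region_names),
                "volumes_ml": list(params.partition.region_volume_Vi),
                "phi": list(params.partition.partition_phi),
            },
            "landmarks_fraction_of_L": dict(params.landmark_positions),
            "cervical_advection": params.cervical_advection,
        },
        "schedule": {
            "horizon_min": schedule.horizon,
            "events": [{
                "start_min": e.start_time,
                "dose_ug": e.dose_mass,
                "volume_ml": e.infusate_volume_Vinj,
                "duration_min": e.duration,
                "site_cm": e.injection_site_xbar,
                "halfwidth_cm": e.spread_halfwidth,
            } for e in schedule.events],
        },
    }
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=None)


def save_config(params: ModelParameters, schedule: DoseSchedule, path) -> None:
    with open(path, "w") as fh:
        fh.write(dumps_config(params, schedule))


def reference_config() -> tuple[ModelParameters, DoseSchedule]:
    """The shipped NHP reference parameter set and single-dose protocol.

    Only the effective dispersion (0.1 cm²/min) is anchored to reported NHP
    calibration; the remaining values are documented stand-ins in
    physiological NHP ranges, meant to be overridden per drug/subject.
    """
    text = resources.files("itpk").joinpath("data/reference_nhp.yaml").read_text()
    return loads_config(text)


def run_manifest(command: str, seed: int | None = None,
                 config_text: str | None = None, **extra) -> dict:
    """JSON-able record sufficient to re-execute a deterministic run."""
    manifest = {
        "tool": "itpk",
        "version": __version__,
        "command": command,
        "seed": seed,
    }
    if config_text is not None:
        manifest["config_sha256"] = hashlib.sha256(
            config_text.encode()).hexdigest()
    manifest.update(extra)
    return manifest


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
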