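"""Domain types, unit conventions and algebraic flux laws.

The model describes intrathecal (IT) drug delivery along the neuraxis with six
coupled compartments:

* C1 — spinal CSF, a one-dimensional flow channel of uniform cross-section,
  spatially resolved along the spine (x = 0 at the closed sacral end,
  x = L at the cervical end);
* C2 — spinal tissue, a rod of uniform cross-section resolved on the same axis;
* C3 — cranial CSF (well mixed);
* C4 — cranial tissue / brain parenchyma (well mixed), partitioned
  volumetrically into pons, hippocampus, cerebellum and cortex;
* C5 — blood plasma / systemic circulation;
* C6 — peripheral organs and tissue.

Units convention used throughout the package:

==============  =========
quantity        unit
==============  =========
length          cm
time            min
volume          mL
amount          µg
concentration   µg/mL
exchange U      mL/min
clearance k     1/min
dispersion D    cm²/min
==============  =========

Exchange between connected compartments is reversible and driven by the local
concentration difference, with a "stickiness" (trapping) coefficient
``0 ≤ β ≤ 1`` that biases the flux toward slow tissue release:

    m12 = U12 (C1 − β12 C2)        spinal CSF ↔ spinal tissue
    m15 = U15 (C1 − β15 C5)        spinal CSF ↔ blood
    m25 = U25 (C2 − β25 C5)        spinal tissue ↔ blood
    m13 = U13 (C1(L) − C3)         cervical boundary ↔ cranial CSF
    m34 = U34 (C3 − β34 C4)        cranial CSF ↔ brain
    m45 = U45 (β45 C4 − C5)        brain ↔ blood (asymmetric, as modelled)
    m56 = U56 (C5 − β56 C6)        blood ↔ peripheral

All fluxes are amounts per minute (µg/min); each concentration ODE divides by
the receiving volume, which is what makes the exchange terms conservative.
The exchange coefficient U absorbs the interface area (U·A lumped, mL/min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "SpinalGeometry",
    "TransportParams",
    "ExchangeParams",
    "CompartmentVolumes",
    "BrainPartitionSpec",
    "ModelParameters",
    "StateVector",
    "ValidationReport",
    "COMPARTMENT_NAMES",
    "EXCHANGE_PAIRS",
    "STICKY_PAIRS",
    "exchange_flux",
    "clearance_rate",
    "brain_region_concentrations",
    "validate_parameters",
    "ug_per_ml_to_nM",
]

#: compartment index -> human-readable name
COMPARTMENT_NAMES: dict[int, str] = {
    1: "spinal_csf",
    2: "spinal_tissue",
    3: "cranial_csf",
    4: "cranial_tissue",
    5: "blood",
    6: "peripheral",
}

#: connected pairs carrying an exchange coefficient U (mL/min)
EXCHANGE_PAIRS: tuple[tuple[int, int], ...] = (
    (1, 2), (1, 5), (2, 5), (1, 3), (3, 4), (4, 5), (5, 6),
)

#: pairs carrying a stickiness/trapping coefficient beta in [0, 1]
#: (the cervical boundary flux (1,3) has none)
STICKY_PAIRS: tuple[tuple[int, int], ...] = (
    (1, 2), (1, 5), (2, 5), (3, 4), (4, 5), (5, 6),
)


def ug_per_ml_to_nM(concentration_ug_ml: float, molecular_weight_g_mol: float) -> float:
    """Convert a mass concentration (µg/mL) to a molar one (nmol/L).

    The molecular weight is drug-specific configuration; it is not part of the
    shipped parameter set.
    """
    if molecular_weight_g_mol <= 0:
        raise ValueError("molecular weight must be positive")
    return concentration_ug_ml * 1.0e6 / molecular_weight_g_mol


@dataclass(frozen=True)
class SpinalGeometry:
    """Geometry of the 1-D spinal CSF channel and tissue rod."""

    length_L: float = 20.0          #: channel length, cm (sacral -> cervical)
    area_csf_A: float = 0.5         #: CSF channel cross-section, cm²
    area_tissue: float = 0.3        #: tissue rod cross-section, cm²
    n_elements_N: int = 100         #: axial finite-volume elements per rod

    @property
    def dx(self) -> float:
        """Uniform element width, cm."""
        return self.length_L / self.n_elements_N

    @property
    def csf_volume(self) -> float:
        """Total spinal CSF volume A·L, mL."""
        return self.area_csf_A * self.length_L

    @property
    def tissue_volume(self) -> float:
        """Total spinal tissue volume, mL."""
        return self.area_tissue * self.length_L

    def violations(self) -> list[str]:
        out = []
        if not self.length_L > 0:
            out.append(f"geometry.length_L must be > 0 (got {self.length_L})")
        if not self.area_csf_A > 0:
            out.append(f"geometry.area_csf_A must be > 0 (got {self.area_csf_A})")
        if not self.area_tissue > 0:
            out.append(f"geometry.area_tissue must be > 0 (got {self.area_tissue})")
        if not (isinstance(self.n_elements_N, (int, np.integer)) and self.n_elements_N >= 2):
            out.append(f"geometry.n_elements_N must be an integer >= 2 (got {self.n_elements_N})")
        return out


@dataclass(frozen=True)
class TransportParams:
    """Axial dispersion and first-order clearances.

    ``dispersion_D`` is the *effective* dispersion coefficient of the drug in
    spinal CSF: an apparent diffusivity, orders of magnitude above molecular
    diffusion, standing in for mixing by natural CSF pulsations in this
    coarse-grained 1-D description.
    """

    dispersion_D: float = 0.1                      #: cm²/min
    clearance_k: Mapping[int, float] = field(
        default_factory=lambda: {i: 0.0 for i in range(1, 7)}
    )                                              #: 1/min per compartment

    def violations(self) -> list[str]:
        out = []
        if not self.dispersion_D >= 0:
            out.append(f"transport.dispersion_D must be >= 0 (got {self.dispersion_D})")
        for i in range(1, 7):
            if i not in self.clearance_k:
                out.append(f"transport.clearance_k missing compartment {i}")
            elif not self.clearance_k[i] >= 0:
                out.append(
                    f"transport.clearance_k[{i}] must be >= 0 (got {self.clearance_k[i]})"
                )
        return out


@dataclass(frozen=True)
class ExchangeParams:
    """Lumped exchange coefficients U (mL/min) and trapping coefficients β."""

    exchange_U: Mapping[tuple[int, int], float] = field(default_factory=dict)
    stickiness_beta: Mapping[tuple[int, int], float] = field(default_factory=dict)

    def violations(self) -> list[str]:
        out = []
        for pair in EXCHANGE_PAIRS:
            if pair not in self.exchange_U:
                out.append(f"exchange.exchange_U missing pair {pair}")
            elif not self.exchange_U[pair] >= 0:
                out.append(f"exchange.exchange_U[{pair}] must be >= 0 "
                           f"(got {self.exchange_U[pair]})")
        for pair in STICKY_PAIRS:
            if pair not in self.stickiness_beta:
                out.append(f"exchange.stickiness_beta missing pair {pair}")
            else:
                b = self.stickiness_beta[pair]
                if not (0.0 <= b <= 1.0):
                    out.append(
                        f"exchange.stickiness_beta[{pair}] violates 0 <= beta <= 1 (got {b})"
                    )
        for pair in self.exchange_U:
            if pair not in EXCHANGE_PAIRS:
                out.append(f"exchange.exchange_U has unknown pair {pair}")
        for pair in self.stickiness_beta:
            if pair not in STICKY_PAIRS:
                out.append(f"exchange.stickiness_beta has unknown pair {pair}")
        return out


@dataclass(frozen=True)
class CompartmentVolumes:
    """Volumes (mL) of the lumped compartments C3–C6.

    Element volumes for the distributed C1/C2 follow from the geometry
    (A·Δx per element); these four are needed to convert amount-fluxes into
    concentration rates in the lumped ODEs.
    """

    cranial_csf: float = 8.0
    cranial_tissue: float = 72.0
    blood: float = 150.0
    peripheral: float = 2000.0

    def volume(self, compartment: int) -> float:
        return {3: self.cranial_csf, 4: self.cranial_tissue,
                5: self.blood, 6: self.peripheral}[compartment]

    def violations(self) -> list[str]:
        out = []
        for name in ("cranial_csf", "cranial_tissue", "blood", "peripheral"):
            v = getattr(self, name)
            if not v > 0:
                out.append(f"volumes.{name} must be > 0 (got {v})")
        return out


@dataclass(frozen=True)
class BrainPartitionSpec:
    """Volumetric partition of cranial-tissue drug into brain sub-regions.

    The amount in C4 is split so that region i holds the fraction φ_i of the
    total cranial-tissue amount:  C_i = φ_i V4 C4 / V_i,  with Σφ_i = 1 and
    ΣV_i = V4, which conserves amount exactly.
    """

    region_names: tuple[str, ...] = ("pons", "hippocampus", "cerebellum", "cortex")
    region_volume_Vi: tuple[float, ...] = (1.8, 1.2, 6.0, 63.0)
    partition_phi: tuple[float, ...] = (0.08, 0.07, 0.15, 0.70)

    def violations(self, v4: float | None = None) -> list[str]:
        out = []
        n = len(self.region_names)
        if len(self.region_volume_Vi) != n or len(self.partition_phi) != n:
            out.append("partition: region_names, region_volume_Vi and partition_phi "
                       "must have equal length")
            return out
        if any(v <= 0 for v in self.region_volume_Vi):
            out.append("partition.region_volume_Vi entries must be > 0")
        if any(p < 0 for p in self.partition_phi):
            out.append("partition.partition_phi entries must be >= 0")
        s = math.fsum(self.partition_phi)
        if abs(s - 1.0) > 1e-12:
            out.append(f"partition.partition_phi must sum to 1 "
                       f"(normalization sum(phi) = 1; got {s!r})")
        if v4 is not None:
            vs = math.fsum(self.region_volume_Vi)
            if abs(vs - v4) > 1e-9 * max(abs(v4), 1.0):
                out.append(
                    f"partition.region_volume_Vi must sum to the cranial tissue volume "
                    f"V4 = {v4} (got {vs})"
                )
        return out


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameterisation of the six-compartment model."""

    geometry: SpinalGeometry = field(default_factory=SpinalGeometry)
    transport: TransportParams = field(default_factory=TransportParams)
    exchange: ExchangeParams = field(default_factory=ExchangeParams)
    volumes: CompartmentVolumes = field(default_factory=CompartmentVolumes)
    partition: BrainPartitionSpec = field(default_factory=BrainPartitionSpec)
    #: named axial landmarks as fractions of L in (0, 1]
    landmark_positions: Mapping[str, float] = field(
        default_factory=lambda: {"lumbar": 0.15, "thoracic": 0.50, "cervical": 0.90}
    )
    #: carry infused volume out of the cervical end into cranial CSF by
    #: advection (keeps the simulator mass-conservative during infusion);
    #: switch off to match a purely diffusive boundary coupling
    cervical_advection: bool = True

    def landmark_x(self, landmark: str) -> float:
        """Absolute axial position (cm) of a named landmark."""
        try:
            frac = self.landmark_positions[landmark]
        except KeyError:
            raise KeyError(
                f"unknown landmark {landmark!r}; known: {sorted(self.landmark_positions)}"
            ) from None
        return frac * self.geometry.length_L

    def with_updates(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    errors: tuple[str, ...] = ()

    def __str__(self) -> str:
        if self.ok:
            return "parameters valid"
        return "parameter validation failed:\n" + "\n".join(f"  - {e}" for e in self.errors)


@dataclass
class StateVector:
    """Concentrations of the full system at one instant.

    ``c1`` and ``c2`` are profiles over the N axial elements (µg/mL);
    ``c3``–``c6`` are the lumped compartment concentrations.
    """

    c1: np.ndarray
    c2: np.ndarray
    c3: float = 0.0
    c4: float = 0.0
    c5: float = 0.0
    c6: float = 0.0

    @classmethod
    def zeros(cls, n: int) -> "StateVector":
        return cls(c1=np.zeros(n), c2=np.zeros(n))

    @classmethod
    def unpack(cls, y: np.ndarray, n: int) -> "StateVector":
        y = np.asarray(y, dtype=float)
        if y.shape != (2 * n + 4,):
            raise ValueError(f"state vector must have length 2N+4 = {2 * n + 4}")
        return cls(c1=y[:n].copy(), c2=y[n:2 * n].copy(),
                   c3=float(y[2 * n]), c4=float(y[2 * n + 1]),
                   c5=float(y[2 * n + 2]), c6=float(y[2 * n + 3]))

    def pack(self) -> np.ndarray:
        return np.concatenate([
            np.asarray(self.c1, dtype=float),
            np.asarray(self.c2, dtype=float),
            [self.c3, self.c4, self.c5, self.c6],
        ])


class ConfigurationError(ValueError):
    """Raised for invalid model/schedule configuration."""


def _check_pair(pair: tuple[int, int]) -> None:
    if tuple(pair) not in EXCHANGE_PAIRS:
        raise ConfigurationError(
            f"unknown compartment pair {tuple(pair)}; connected pairs are {EXCHANGE_PAIRS}"
        )


def exchange_flux(pair: tuple[int, int], c_from: float, c_to: float,
                  params: ExchangeParams) -> float:
    """Reversible inter-compartment mass-transfer rate (µg/min).

    Positive return means net transfer from the first to the second member of
    ``pair``.  The flux laws are listed in the module docstring; note the
    (4,5) brain→blood flux is asymmetric, with β multiplying the *source*
    concentration: m45 = U45 (β45 C4 − C5).
    """
    pair = tuple(pair)
    _check_pair(pair)
    u = params.exchange_U[pair]
    if pair == (1, 3):
        return u * (c_from - c_to)
    beta = params.stickiness_beta[pair]
    if pair == (4, 5):
        return u * (beta * c_from - c_to)
    return u * (c_from - beta * c_to)


def clearance_rate(compartment: int, c: float, params: TransportParams) -> float:
    """First-order elimination rate k_i·c (concentration/min, to be subtracted)."""
    if compartment not in COMPARTMENT_NAMES:
        raise ConfigurationError(f"unknown compartment index {compartment}")
    return params.clearance_k[compartment] * c


def brain_region_concentrations(c4: float, spec: BrainPartitionSpec,
                                v4: float | None = None) -> dict[str, float]:
    """Distribute the cranial-tissue concentration over brain sub-regions.

    Applies the volumetric partition rule C_i = φ_i V4 C4 / V_i.  When ``v4``
    is not given it is taken as ΣV_i (the partition spec must tile C4).
    Conserves amount: Σ C_i V_i = V4 C4 to round-off.
    """
    errs = spec.violations(v4)
    if errs:
        raise ConfigurationError("; ".join(errs))
    v4 = math.fsum(spec.region_volume_Vi) if v4 is None else v4
    return {
        name: phi * v4 * c4 / vi
        for name, vi, phi in zip(spec.region_names, spec.region_volume_Vi,
                                 spec.partition_phi)
    }


def validate_parameters(params: ModelParameters) -> ValidationReport:
    """Check every type invariant; never raises, reports all violations."""
    errors: list[str] = []
    errors += params.geometry.violations()
    errors += params.transport.violations()
    errors += params.exchange.violations()
    errors += params.volumes.violations()
    errors += params.partition.violations(params.volumes.cranial_tissue)
    marks = sorted(params.landmark_positions.items(), key=lambda kv: kv[1])
    for name, frac in params.landmark_positions.items():
        if not (0.0 < frac <= 1.0):
            errors.append(f"landmark_positions[{name!r}] must lie in (0, 1] (got {frac})")
    if len({f for _, f in marks}) != len(marks):
        errors.append("landmark_positions fractions must be strictly increasing/distinct")
    return ValidationReport(ok=not errors, errors=tuple(errors))
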