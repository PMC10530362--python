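"""Closed-form steady-state models of voltage-dependent open-channel block.

A charged blocker binding at fractional electrical depth ``delta_b`` inside
the transmembrane field has a voltage-dependent dissociation constant

    K_d(V) = K_b * exp(z * delta_b * V / (RT/F)),

so hyperpolarization (negative V, cationic blocker) deepens the block
(Woodhull model).  Two extensions cover the phenomenology of glutamate
receptor channels:

* a *permeant* blocker can be pushed through the open channel at strong
  negative voltages, relieving block; the permeation barrier at depth
  ``delta_p`` contributes a second term
  ``K_p * exp(-z * delta_p * V / (RT/F))`` to the effective K_d;
* an *independent voltage-insensitive site* with affinity ``K_vin``
  multiplies the pore factor by ``1 / (1 + C / K_vin)`` and leaves a
  residual inhibition at depolarized potentials.

All ratios are I_drug / I_control, 1 meaning no inhibition.  Concentrations
are in uM, voltages in mV (membrane potential, inside minus outside).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "FARADAY",
    "ThermoContext",
    "BlockParams",
    "HillParams",
    "IlluminationState",
    "CompoundSpec",
    "NoReliefError",
    "thermal_voltage",
    "effective_kd",
    "ratio_eq1",
    "ratio_eq2",
    "ratio_eq3",
    "hill_ratio",
    "relief_voltage",
    "kb_from_anchor",
]

#: Molar gas constant R, J mol^-1 K^-1 (CODATA 2018, exact).
GAS_CONSTANT = 8.31446261815324
#: Faraday constant F, C mol^-1 (CODATA 2018, exact).
FARADAY = 96485.33212

_T_MIN, _T_MAX = 273.0, 320.0


def thermal_voltage(temperature: float) -> float:
    """RT/F in millivolts at ``temperature`` (kelvin).

    About 25.5 mV at the 296 K room temperature of a typical patch-clamp
    rig.  Raises ``ValueError`` outside the physiological [273, 320] K range.
    """
    if not (_T_MIN <= temperature <= _T_MAX):
        raise ValueError(
            f"temperature {temperature!r} K outside supported range "
            f"[{_T_MIN}, {_T_MAX}] K"
        )
    return 1e3 * GAS_CONSTANT * temperature / FARADAY


@dataclass(frozen=True)
class ThermoContext:
    """Temperature context; exposes the thermal voltage RT/F in mV."""

    temperature: float = 296.0

    def __post_init__(self) -> None:
        thermal_voltage(self.temperature)  # validates the range

    @property
    def vt_mV(self) -> float:
        return thermal_voltage(self.temperature)


class NoReliefError(ValueError):
    """Raised when a parameter set admits no relief-from-block voltage."""


@dataclass(frozen=True)
class BlockParams:
    """Parameter vector of the pore-block models.

    K_b : uM
        Dissociation constant of the pore site extrapolated to 0 mV.
    delta_b : dimensionless in [0, 1]
        Electrical depth of the binding site.
    K_p : uM, >= 0
        Permeation-term coefficient; 0 disables permeation.
    delta_p : dimensionless in [0, 1]
        Electrical depth of the permeation barrier.
    K_vin : uM or None
        Affinity of the independent voltage-insensitive site; None means
        no such site (infinite K_vin).
    z : int >= 1
        Elementary charge of the blocker (QAQ +2, AAQ +1).

    delta_b and delta_p are treated as independent empirical quantities;
    their sum may exceed 1.
    """

    K_b: float
    delta_b: float
    K_p: float = 0.0
    delta_p: float = 0.0
    K_vin: float | None = None
    z: int = 1

    def __post_init__(self) -> None:
        if not self.K_b > 0:
            raise ValueError(f"K_b must be positive, got {self.K_b}")
        if self.K_p < 0:
            raise ValueError(f"K_p must be >= 0, got {self.K_p}")
        if self.K_vin is not None and not self.K_vin > 0:
            raise ValueError(f"K_vin must be positive or None, got {self.K_vin}")
        for name in ("delta_b", "delta_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.z < 1:
            raise ValueError(f"z must be a positive integer charge, got {self.z}")

    def to_dict(self) -> dict:
        return {
            "K_b_uM": self.K_b,
            "delta_b": self.delta_b,
            "K_p_uM": self.K_p,
            "delta_p": self.delta_p,
            "K_vin_uM": self.K_vin,
            "z": self.z,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BlockParams":
        return cls(
            K_b=d["K_b_uM"],
            delta_b=d["delta_b"],
            K_p=d.get("K_p_uM", 0.0),
            delta_p=d.get("delta_p", 0.0),
            K_vin=d.get("K_vin_uM"),
            z=d.get("z", 1),
        )


@dataclass(frozen=True)
class HillParams:
    """Concentration-response (Hill) parameters: IC50 in uM, Hill slope."""

    ic50: float
    hill_n: float = 1.0

    def __post_init__(self) -> None:
        if not self.ic50 > 0:
            raise ValueError(f"ic50 must be positive, got {self.ic50}")
        if not self.hill_n > 0:
            raise ValueError(f"hill_n must be positive, got {self.hill_n}")


class Illumination(str, enum.Enum):
    DARK = "dark"
    ILLUMINATED = "illuminated"


@dataclass(frozen=True)
class IlluminationState:
    """Discrete optical condition: dark, or illuminated at a wavelength.

    Photoisomerization is modelled as selecting a parameter set, not as a
    photochemical process; the wavelength is metadata (380 nm is the
    empirically best photoswitching wavelength for these compounds).
    """

    label: Illumination = Illumination.DARK
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        if self.label is Illumination.ILLUMINATED:
            if self.wavelength_nm is None:
                raise ValueError("illuminated state requires a wavelength")
            if not 330.0 <= self.wavelength_nm <= 500.0:
                raise ValueError(
                    f"wavelength {self.wavelength_nm} nm outside [330, 500] nm"
                )
        elif self.wavelength_nm is not None:
            raise ValueError("dark state carries no wavelength")


DARK = IlluminationState(Illumination.DARK)
UV380 = IlluminationState(Illumination.ILLUMINATED, 380.0)


@dataclass(frozen=True)
class CompoundSpec:
    """A photoswitchable compound: charge plus per-illumination parameters."""

    name: str
    charge_z: int
    block_params: dict[IlluminationState, BlockParams] = field(default_factory=dict)
    hill_params: dict[IlluminationState, HillParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in self.block_params.values():
            if p.z != self.charge_z:
                raise ValueError(
                    f"{self.name}: BlockParams z={p.z} inconsistent with "
                    f"charge_z={self.charge_z}"
                )
        states = set(self.block_params) | set(self.hill_params)
        labels = {s.label for s in states}
        if states and labels != {Illumination.DARK, Illumination.ILLUMINATED}:
            raise ValueError(
                f"{self.name}: a photoswitch needs both dark and illuminated "
                f"parameter sets, got labels {sorted(l.value for l in labels)}"
            )


def _pore_exponents(V, params: BlockParams, thermo: ThermoContext):
    v = np.asarray(V, dtype=float) / thermo.vt_mV
    bind = params.K_b * np.exp(params.z * params.delta_b * v)
    perm = params.K_p * np.exp(-params.z * params.delta_p * v)
    return bind, perm


def effective_kd(V, params: BlockParams, thermo: ThermoContext = ThermoContext()):
    """Effective voltage-dependent dissociation constant of the pore site, uM.

    K_d,eff(V) = K_b e^{z delta_b V / Vt} + K_p e^{-z delta_p V / Vt}.
    Convex in V; with all four pore parameters positive it has a unique
    minimum at :func:`relief_voltage`.
    """
    bind, perm = _pore_exponents(V, params, thermo)
    return bind + perm


def ratio_eq1(C, V, params: BlockParams, thermo: ThermoContext = ThermoContext()):
    """Single-site impermeant block: 1 / (1 + C / (K_b e^{z delta_b V/Vt})).

    The K_p and K_vin entries of ``params`` are ignored (this is the
    reduction of the permeant model at K_p = 0 and no second site).
    Strictly increasing in V for a cationic blocker with delta_b > 0.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentration must be >= 0")
    bind, _ = _pore_exponents(V, params, thermo)
    return 1.0 / (1.0 + C / bind)


def ratio_eq2(C, V, params: BlockParams, thermo: ThermoContext = ThermoContext()):
    """Permeant single-site block: 1 / (1 + C / K_d,eff(V)).

    Non-monotonic in V when K_p > 0: block is relieved both by
    depolarization (unbinding toward the outside) and by strong
    hyperpolarization (blocker swept through the channel).
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentration must be >= 0")
    return 1.0 / (1.0 + C / effective_kd(V, params, thermo))


def ratio_eq3(C, V, params: BlockParams, thermo: ThermoContext = ThermoContext()):
    """Permeant pore site plus an independent voltage-insensitive site.

    1 / (1 + C/K_deff + C/K_vin + C^2/(K_deff K_vin)); factorizes exactly as
    ratio_eq2(C, V) * 1/(1 + C/K_vin) (independent binding).  As V -> +inf
    the pore empties and the ratio tends to the residual 1/(1 + C/K_vin).
    """
    if params.K_vin is None:
        raise ValueError("ratio_eq3 requires a finite K_vin")
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentration must be >= 0")
    kd = effective_kd(V, params, thermo)
    kv = params.K_vin
    return 1.0 / (1.0 + C / kd + C / kv + C**2 / (kd * kv))


def hill_ratio(C, params: HillParams):
    """Concentration-response ratio 1 / (1 + (C / IC50)^n); decreasing in C."""
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentration must be >= 0")
    return 1.0 / (1.0 + (C / params.ic50) ** params.hill_n)


def relief_voltage(params: BlockParams, thermo: ThermoContext = ThermoContext()) -> float:
    """Voltage of maximal block (minimum of the effective K_d), mV.

    V* = (RT/F) / (z (delta_b + delta_p)) * ln(K_p delta_p / (K_b delta_b)).
    Block is relieved at potentials more negative than V*.  Raises
    :class:`NoReliefError` when K_p or delta_p (or delta_b) is zero, i.e.
    for an impermeant blocker whose block deepens monotonically.
    """
    if params.K_p <= 0 or params.delta_p <= 0 or params.delta_b <= 0:
        raise NoReliefError(
            "no relief voltage: permeation term absent "
            f"(K_p={params.K_p}, delta_p={params.delta_p}, delta_b={params.delta_b})"
        )
    num = params.K_p * params.delta_p
    den = params.K_b * params.delta_b
    return thermo.vt_mV / (params.z * (params.delta_b + params.delta_p)) * math.log(num / den)


def kb_from_anchor(
    C: float,
    V: float,
    ratio: float,
    delta_b: float,
    z: int,
    thermo: ThermoContext = ThermoContext(),
) -> float:
    """K_b (uM) such that the single-site model passes through one point.

    Exact inversion of the impermeant model at a single observed
    (C, V, ratio): K_b = C / ((1/ratio - 1) e^{z delta_b V / Vt}).
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"anchor ratio must lie in (0, 1), got {ratio}")
    B = 1.0 / ratio - 1.0
    return C / (B * math.exp(z * delta_b * V / thermo.vt_mV))


def params_to_json(
    params: BlockParams,
    *,
    compound: str,
    receptor: str,
    illumination: str,
    temperature: float = 296.0,
) -> str:
    """Serialize a labelled parameter set to the interchange JSON schema."""
    d = {"compound": compound, "receptor": receptor, "illumination": illumination}
    d.update(params.to_dict())
    d["T_K"] = temperature
    return json.dumps(d, indent=2)


def params_from_json(text: str) -> tuple[BlockParams, dict]:
    """Inverse of :func:`params_to_json`; returns (params, metadata)."""
    d = json.loads(text)
    params = BlockParams.from_dict(d)
    meta = {k: d[k] for k in ("compound", "receptor", "illumination", "T_K") if k in d}
    return params, meta
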