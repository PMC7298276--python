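"""Hemodynamic <-> electrical unit conversions and auxiliary vessel physics.

The analog maps pressure to voltage (1 mmHg = 0.1 V, so a 120 mmHg aortic
pressure becomes 12 V) and volumetric flow to current (1 L/min = 1 mA).
Vascular resistance in mmHg·min/L then maps to ohms through the derived
scale pressure/flow: 1 mmHg·min/L = 100 Ω.

Also provided: Laplace wall tension T = P·R and the Poiseuille resistance
scaling, where vessel resistance varies with the inverse 4th power of the
radius (an electrical wire varies with the inverse square).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ConversionFactors",
    "VesselGeometry",
    "pressure_to_voltage",
    "voltage_to_pressure",
    "flow_to_current",
    "current_to_flow",
    "hemo_resistance_to_ohms",
    "laplace_wall_tension",
    "poiseuille_resistance_ratio",
]


@dataclass(frozen=True)
class ConversionFactors:
    """Linear mapping between hemodynamic and electrical quantities."""

    volts_per_mmhg: float = 0.1
    milliamps_per_liter_min: float = 1.0

    def __post_init__(self) -> None:
        if self.volts_per_mmhg <= 0 or self.milliamps_per_liter_min <= 0:
            raise ValueError("conversion factors must be positive")

    @property
    def ohms_per_hemo_resistance(self) -> float:
        """Ohms per (mmHg·min/L); derived, never stored independently."""
        return self.volts_per_mmhg / (self.milliamps_per_liter_min * 1e-3)


DEFAULT_FACTORS = ConversionFactors()


@dataclass(frozen=True)
class VesselGeometry:
    """Vessel radius/length relative to a reference state; all positive."""

    radius: float
    reference_radius: float
    length: float = 1.0

    def __post_init__(self) -> None:
        if min(self.radius, self.reference_radius, self.length) <= 0:
            raise ValueError("vessel dimensions must be positive")


def pressure_to_voltage(p_mmhg: float,
                        f: ConversionFactors = DEFAULT_FACTORS) -> float:
    """Arterial pressure (mmHg) to volts."""
    if p_mmhg < 0:
        raise ValueError("negative pressure outside arterial scope")
    return p_mmhg * f.volts_per_mmhg


def voltage_to_pressure(v: float,
                        f: ConversionFactors = DEFAULT_FACTORS) -> float:
    return v / f.volts_per_mmhg


def flow_to_current(q_l_min: float,
                    f: ConversionFactors = DEFAULT_FACTORS) -> float:
    """Blood flow (L/min) to milliamperes."""
    if q_l_min < 0:
        raise ValueError("negative flow rate")
    return q_l_min * f.milliamps_per_liter_min


def current_to_flow(i_ma: float,
                    f: ConversionFactors = DEFAULT_FACTORS) -> float:
    return i_ma / f.milliamps_per_liter_min


def hemo_resistance_to_ohms(p_mmhg: float, q_l_min: float,
                            f: ConversionFactors = DEFAULT_FACTORS,
                            rounded: bool = False) -> float:
    """Vascular resistance pressure/flow expressed in ohms.

    Example: a 10 mmHg portal gradient at 0.86 L/min gives
    1 V / 0.86 mA = 1163 Ω (rounded).
    """
    if q_l_min <= 0:
        raise ZeroDivisionError(
            "flow rate must be > 0 to define a resistance (pressure/flow)")
    r = pressure_to_voltage(p_mmhg, f) / (flow_to_current(q_l_min, f) * 1e-3)
    return round(r) if rounded else r


def laplace_wall_tension(pressure_mmhg: float,
                         geometry: VesselGeometry) -> float:
    """Wall tension T = P·R (mmHg · length units).

    An increased intravascular pressure raises wall tension at fixed
    radius, predisposing to aneurysmal dilation; conversely a pressure
    drop lowers tension and can let an already-compressed vessel collapse.
    """
    if pressure_mmhg < 0:
        raise ValueError("negative pressure outside arterial scope")
    return pressure_mmhg * geometry.radius


def poiseuille_resistance_ratio(geometry: VesselGeometry,
                                exponent: int = 4) -> float:
    """Multiplicative resistance factor (r_ref / r) ** exponent.

    ``exponent=4`` is the vascular (Poiseuille) law; ``exponent=2`` the
    electrical-wire analogue.  Equals 1 at the reference radius and
    decreases strictly as the radius grows (dilation lowers resistance).
    """
    if exponent not in (2, 4):
        raise ValueError(f"exponent must be 2 or 4, got {exponent}")
    return (geometry.reference_radius / geometry.radius) ** exponent
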