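"""The reduced splanchnic circuit: celiac stenosis vs. PDA aneurysm.

The splanchnic arterial tree is lumped into a two-branch current divider
fed by a 12 V DC source (120 mmHg aortic pressure):

* branch 1 — the celiac artery (CA): a series stenosis potentiometer plus
  a fixed 3.3 kΩ vessel resistor;
* branch 2 — the pancreaticoduodenal arcade (PDA block): a fixed 3.3 kΩ
  vessel resistor in parallel with an aneurysm/collateral potentiometer;
* downstream, both branches feed the 12 kΩ pancreas+liver bed returning
  to ground.

Raising the stenosis potentiometer towards 50 kΩ throttles the CA and
diverts flow into the PDA (favouring aneurysm formation); lowering the
aneurysm potentiometer towards 0 Ω shorts the PDA block and steals the
CA flow completely, regardless of the stenosis — the steal phenomenon.
The measured "PDA flow" is the total current entering the PDA block
(vessel resistor plus aneurysm path), which equals 0.455 mA in the
normal state.

``steady_flows`` is an exact closed-form series/parallel evaluation and
serves as the analytic counterpart of solving the built circuit with the
nodal solver; the two must agree to well below reporting precision.
"""

from __future__ import annotations

from dataclasses import dataclass

from .circuit import (Circuit, CircuitError, Potentiometer, Resistor,
                      VoltageSource, solve_dc)
from .units import ConversionFactors, DEFAULT_FACTORS, pressure_to_voltage

__all__ = [
    "SplanchnicParameters",
    "ModelState",
    "FlowPair",
    "ParameterDerivation",
    "derive_parameters",
    "build_reduced_circuit",
    "steady_flows",
    "flows_from_solution",
    "FULL_NETWORK_EDGES",
    "build_full_network",
]

# Node names in the reduced circuit
AORTA = "aorta"          # source + terminal / divider input
_CA_MID = "ca_mid"       # between stenosis pot and CA resistor
PORTAL = "portal"        # divider output, feeds pancreas+liver bed
GROUND = "ground"        # systemic venous return / source -


@dataclass(frozen=True)
class SplanchnicParameters:
    """Electrical parameterization of the reduced splanchnic circuit.

    Defaults: 12 V source; 3.3 kΩ CA and PDA vessel resistors (two 1.3 kΩ
    segments rounded up to the available part); 12 kΩ pancreas+liver bed;
    0–50 kΩ potentiometers for stenosis and aneurysm.
    """

    source_voltage: float = 12.0
    r_ca: float = 3300.0
    r_pda: float = 3300.0
    r_pancreas_liver: float = 12000.0
    pot_min: float = 0.0
    pot_max: float = 50000.0

    def __post_init__(self) -> None:
        if min(self.source_voltage, self.r_ca, self.r_pda,
               self.r_pancreas_liver) <= 0:
            raise ValueError("voltage and fixed resistances must be positive")
        if not 0 <= self.pot_min < self.pot_max:
            raise ValueError("need 0 <= pot_min < pot_max")


@dataclass(frozen=True)
class ModelState:
    """Potentiometer settings: stenosis severity and aneurysm/collateral
    conductance (lower resistance = bigger aneurysm)."""

    r_stenosis: float
    r_aneurysm: float

    def check(self, params: SplanchnicParameters) -> None:
        for label, r in (("r_stenosis", self.r_stenosis),
                         ("r_aneurysm", self.r_aneurysm)):
            if not params.pot_min <= r <= params.pot_max:
                raise ValueError(
                    f"{label} = {r} Ω outside potentiometer range "
                    f"[{params.pot_min}, {params.pot_max}] Ω")


@dataclass(frozen=True)
class FlowPair:
    """CA flow, PDA-block flow and total load current, in mA (>= 0)."""

    i_ca: float
    i_pda: float

    @property
    def i_total(self) -> float:
        return self.i_ca + self.i_pda

    def rounded(self, ndigits: int = 3) -> "FlowPair":
        return FlowPair(round(self.i_ca, ndigits), round(self.i_pda, ndigits))


def _parallel(a: float, b: float) -> float:
    if a == 0 or b == 0:
        return 0.0
    return a * b / (a + b)


def steady_flows(params: SplanchnicParameters, state: ModelState) -> FlowPair:
    """Closed-form steady CA/PDA flows by series/parallel reduction.

    R_block = r_pda ∥ r_aneurysm (0 when the aneurysm pot is an exact
    short); R_ca = r_ca + r_stenosis; the divider splits the total load
    current V / (r_pancreas_liver + R_ca ∥ R_block) in proportion to the
    opposite branch resistance.
    """
    state.check(params)
    r_branch_ca = params.r_ca + state.r_stenosis
    r_block = _parallel(params.r_pda, state.r_aneurysm)
    r_par = _parallel(r_branch_ca, r_block)
    i_total = params.source_voltage / (params.r_pancreas_liver + r_par)  # A
    i_ca = i_total * r_block / (r_branch_ca + r_block)
    return FlowPair(i_ca=i_ca * 1e3, i_pda=(i_total - i_ca) * 1e3)


def build_reduced_circuit(params: SplanchnicParameters,
                          state: ModelState) -> Circuit:
    """Assemble the reduced splanchnic circuit at the given state.

    Element names: ``stenosis_pot``, ``r_ca`` (branch 1), ``r_pda``,
    ``aneurysm_pot`` (branch 2), ``r_pancreas_liver`` (load), ``source``.
    CA flow is the ``r_ca`` branch current; PDA flow is the sum of the
    ``r_pda`` and ``aneurysm_pot`` currents.
    """
    state.check(params)
    c = Circuit(nodes={AORTA, _CA_MID, PORTAL, GROUND}, ground=GROUND)
    c.add(VoltageSource("source", AORTA, GROUND, params.source_voltage))
    c.add(Potentiometer("stenosis_pot", AORTA, _CA_MID,
                        params.pot_min, params.pot_max, state.r_stenosis))
    c.add(Resistor("r_ca", _CA_MID, PORTAL, params.r_ca))
    c.add(Resistor("r_pda", AORTA, PORTAL, params.r_pda))
    c.add(Potentiometer("aneurysm_pot", AORTA, PORTAL,
                        params.pot_min, params.pot_max, state.r_aneurysm))
    c.add(Resistor("r_pancreas_liver", PORTAL, GROUND,
                   params.r_pancreas_liver))
    return c


def flows_from_solution(solution) -> FlowPair:
    """Extract the (CA, PDA-block) flow pair from a solved reduced circuit.

    Flow tracings are unsigned, so magnitudes are reported.
    """
    i_ca = abs(solution.branch_currents["r_ca"])
    i_pda = abs(solution.branch_currents["r_pda"]
                + solution.branch_currents["aneurysm_pot"])
    return FlowPair(i_ca=i_ca, i_pda=i_pda)


def solve_reduced(params: SplanchnicParameters, state: ModelState) -> FlowPair:
    """Build and solve the reduced circuit; numerical twin of
    :func:`steady_flows`."""
    return flows_from_solution(solve_dc(build_reduced_circuit(params, state)))


# ---------------------------------------------------------------------------
# Parameter derivation arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterDerivation:
    """How the component values follow from physiology.

    Starting from a 0.86 L/min portal flow and a 120 mmHg aortic pressure:
    each vessel segment contributes 1.3 kΩ, two in series give 2.6 kΩ,
    rounded up to the available 3.3 kΩ part; half that branch resistance
    carrying the full portal current drops ~1.4 V, and the remaining
    voltage over the portal current sets the pancreas+liver bed at
    ~12.3 kΩ, rounded to the available 12 kΩ part.
    """

    portal_resistance_ohm: float      # portal gradient / portal flow
    r_vessel_exact_ohm: float         # 2 x 1.3 kΩ segments
    r_vessel_chosen_ohm: float        # available part
    v_drop_vessel: float              # volts across half the chosen branch
    r_pancreas_liver_exact_ohm: float
    r_pancreas_liver_chosen_ohm: float


def derive_parameters(portal_flow_l_min: float = 0.86,
                      portal_gradient_mmhg: float = 10.0,
                      aortic_pressure_mmhg: float = 120.0,
                      segment_resistance_ohm: float = 1300.0,
                      chosen_vessel_ohm: float = 3300.0,
                      chosen_load_ohm: float = 12000.0,
                      f: ConversionFactors = DEFAULT_FACTORS,
                      ) -> ParameterDerivation:
    """Reproduce the component-value arithmetic from physiological inputs."""
    from .units import hemo_resistance_to_ohms

    i_portal_a = portal_flow_l_min * f.milliamps_per_liter_min * 1e-3
    v_source = pressure_to_voltage(aortic_pressure_mmhg, f)
    v_drop = (chosen_vessel_ohm / 2.0) * i_portal_a
    return ParameterDerivation(
        portal_resistance_ohm=hemo_resistance_to_ohms(
            portal_gradient_mmhg, portal_flow_l_min, f),
        r_vessel_exact_ohm=2 * segment_resistance_ohm,
        r_vessel_chosen_ohm=chosen_vessel_ohm,
        v_drop_vessel=v_drop,
        r_pancreas_liver_exact_ohm=(v_source - v_drop) / i_portal_a,
        r_pancreas_liver_chosen_ohm=chosen_load_ohm,
    )


# ---------------------------------------------------------------------------
# Full splanchnic network (topology template; resistances user-supplied)
# ---------------------------------------------------------------------------

#: edge name -> (node_a, node_b) in the full splanchnic graph.
#: Arteries: CA/SMA/IMA off the aorta, PHA from the celiac hub to the
#: liver; collaterals: PDA (celiac<->SMA hub), AoR arc of Riolan
#: (SMA<->IMA hub); venous return: SMV/IMV to the portal confluence, PV
#: to the liver, HV to the IVC, IVC to the systemic return (ground).
FULL_NETWORK_EDGES: dict[str, tuple[str, str]] = {
    "CA": ("aorta", "celiac_hub"),
    "SMA": ("aorta", "sma_hub"),
    "IMA": ("aorta", "ima_hub"),
    "PDA": ("celiac_hub", "sma_hub"),
    "AoR": ("sma_hub", "ima_hub"),
    "PHA": ("celiac_hub", "liver"),
    "SMV": ("sma_hub", "portal_confluence"),
    "IMV": ("ima_hub", "portal_confluence"),
    "PV": ("portal_confluence", "liver"),
    "HV": ("liver", "ivc"),
    "IVC": ("ivc", "systemic_return"),
}


def build_full_network(resistance_table: dict[str, float],
                       source_voltage: float = 12.0) -> Circuit:
    """Full splanchnic circuit from a per-edge resistance table (ohms).

    Every edge in :data:`FULL_NETWORK_EDGES` must be given a positive
    resistance; missing names raise with the list of absent edges.  The
    source spans aorta -> systemic return (ground).
    """
    missing = sorted(set(FULL_NETWORK_EDGES) - set(resistance_table))
    if missing:
        raise CircuitError(
            f"missing resistance values for edges: {', '.join(missing)}")
    bad = sorted(name for name in FULL_NETWORK_EDGES
                 if not resistance_table[name] > 0)
    if bad:
        raise CircuitError(
            f"edge resistances must be positive: {', '.join(bad)}")
    nodes = {n for ab in FULL_NETWORK_EDGES.values() for n in ab}
    c = Circuit(nodes=nodes, ground="systemic_return")
    for name, (a, b) in FULL_NETWORK_EDGES.items():
        c.add(Resistor(name, a, b, float(resistance_table[name])))
    c.add(VoltageSource("source", "aorta", "systemic_return", source_voltage))
    return c
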