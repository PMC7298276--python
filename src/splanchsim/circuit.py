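"""General DC resistor-network representation and steady-state solver.

Circuits are node/element graphs of resistors, potentiometers and a single
ideal voltage source, with one designated ground node (reference potential
0 V).  The solver uses conductance-matrix nodal analysis extended with the
source current as an unknown (modified nodal analysis), which is exact for
the purely resistive, single-source networks in scope.

Zero-resistance elements (a potentiometer dialled to exactly 0 Ω) are
handled by merging their endpoint nodes into one supernode before assembly,
so short circuits are exact rather than approximated by a small epsilon.
Currents through the shorted elements themselves are recovered afterwards
from Kirchhoff's current law on the short subgraph.

Sign convention: branch current is positive for conventional current
flowing from ``node_a`` to ``node_b`` (for the source, from ``node_plus``
through the external network to ``node_minus``, i.e. the current delivered
by the source).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Union

import numpy as np

__all__ = [
    "Resistor",
    "Potentiometer",
    "VoltageSource",
    "Circuit",
    "DCSolution",
    "CircuitError",
    "SingularCircuitError",
    "solve_dc",
    "equivalent_resistance",
    "branch_current",
    "kcl_residuals",
    "generate_random_network",
]


class CircuitError(ValueError):
    """Structural problem with a circuit (missing ground, disconnected graph,
    duplicate element names, unknown nodes)."""


class SingularCircuitError(CircuitError):
    """The circuit admits no unique DC solution, e.g. the voltage source is
    shorted by an all-zero-resistance loop."""


@dataclass(frozen=True)
class Resistor:
    """Two-terminal ohmic element.

    Parameters
    ----------
    name : str
        Unique element identifier within the circuit.
    node_a, node_b : str
        Endpoint node labels; must differ.
    resistance : float
        Resistance in ohms, finite and >= 0.  A value of exactly 0 is an
        ideal short.
    """

    name: str
    node_a: str
    node_b: str
    resistance: float

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise CircuitError(f"element {self.name!r}: endpoints must differ")
        if not np.isfinite(self.resistance) or self.resistance < 0:
            raise CircuitError(
                f"element {self.name!r}: resistance must be finite and >= 0, "
                f"got {self.resistance!r}"
            )


@dataclass(frozen=True)
class Potentiometer:
    """Variable resistor constrained to ``[r_min, r_max]``.

    Models an adjustable vascular resistance: a series potentiometer raised
    towards ``r_max`` represents a stenosis, a parallel potentiometer lowered
    towards 0 Ω an aneurysm or collateral bed.
    """

    name: str
    node_a: str
    node_b: str
    r_min: float
    r_max: float
    value: float

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise CircuitError(f"element {self.name!r}: endpoints must differ")
        if not 0 <= self.r_min <= self.value <= self.r_max:
            raise CircuitError(
                f"element {self.name!r}: need 0 <= r_min <= value <= r_max, "
                f"got ({self.r_min}, {self.value}, {self.r_max})"
            )

    def with_value(self, value: float) -> "Potentiometer":
        """Return a copy dialled to ``value`` ohms."""
        return Potentiometer(self.name, self.node_a, self.node_b,
                             self.r_min, self.r_max, value)

    @property
    def resistance(self) -> float:
        return self.value


@dataclass(frozen=True)
class VoltageSource:
    """Ideal DC voltage source; ``node_plus`` is held ``voltage`` volts above
    ``node_minus``."""

    name: str
    node_plus: str
    node_minus: str
    voltage: float

    def __post_init__(self) -> None:
        if self.node_plus == self.node_minus:
            raise CircuitError(f"source {self.name!r}: terminals must differ")
        if self.voltage <= 0:
            raise CircuitError(f"source {self.name!r}: voltage must be > 0")


Element = Union[Resistor, Potentiometer, VoltageSource]


@dataclass
class Circuit:
    """A DC circuit: declared nodes, elements and one ground node.

    Invariants checked at solve time: the graph is connected, ground is a
    declared node, every element endpoint is declared, element names are
    unique, and at most one voltage source is present.
    """

    nodes: set[str]
    elements: list[Element] = field(default_factory=list)
    ground: str | None = None

    # -- construction helpers -------------------------------------------------

    def add(self, element: Element) -> None:
        for n in _endpoints(element):
            self.nodes.add(n)
        self.elements.append(element)

    def element(self, name: str) -> Element:
        for el in self.elements:
            if el.name == name:
                return el
        raise KeyError(f"no element named {name!r}")

    def set_potentiometer(self, name: str, value: float) -> None:
        """Dial the named potentiometer to ``value`` ohms in place."""
        for i, el in enumerate(self.elements):
            if el.name == name:
                if not isinstance(el, Potentiometer):
                    raise CircuitError(f"{name!r} is not a potentiometer")
                self.elements[i] = el.with_value(value)
                return
        raise KeyError(f"no element named {name!r}")

    # -- validation -----------------------------------------------------------

    def validate(self) -> None:
        if self.ground is None:
            raise CircuitError("circuit has no ground node designated")
        if self.ground not in self.nodes:
            raise CircuitError(f"ground node {self.ground!r} is not declared")
        names = [el.name for el in self.elements]
        if len(names) != len(set(names)):
            raise CircuitError("element names must be unique")
        for el in self.elements:
            for n in _endpoints(el):
                if n not in self.nodes:
                    raise CircuitError(
                        f"element {el.name!r} references undeclared node {n!r}")
        n_src = sum(isinstance(el, VoltageSource) for el in self.elements)
        if n_src > 1:
            raise CircuitError("at most one voltage source is supported")
        if not self._connected():
            raise CircuitError("circuit graph is not connected")

    def _connected(self) -> bool:
        if not self.nodes:
            return False
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for el in self.elements:
            a, b = _endpoints(el)
            adj[a].add(b)
            adj[b].add(a)
        seen = {next(iter(self.nodes))}
        stack = list(seen)
        while stack:
            for m in adj[stack.pop()]:
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        return seen == self.nodes

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        elems = []
        for el in self.elements:
            d = {"kind": type(el).__name__.lower(), **el.__dict__}
            elems.append(d)
        return {"nodes": sorted(self.nodes), "ground": self.ground,
                "elements": elems}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "Circuit":
        kinds = {"resistor": Resistor, "potentiometer": Potentiometer,
                 "voltagesource": VoltageSource}
        elements: list[Element] = []
        for e in d["elements"]:
            e = dict(e)
            kind = e.pop("kind")
            try:
                elements.append(kinds[kind](**e))
            except KeyError:
                raise CircuitError(f"unknown element kind {kind!r}") from None
        return cls(nodes=set(d["nodes"]), elements=elements, ground=d["ground"])

    @classmethod
    def from_json(cls, s: str) -> "Circuit":
        return cls.from_dict(json.loads(s))


@dataclass
class DCSolution:
    """Steady-state solution: node potentials (V, ground = 0) and signed
    branch currents (mA, positive node_a -> node_b)."""

    node_potentials: dict[str, float]
    branch_currents: dict[str, float]


def _endpoints(el: Element) -> tuple[str, str]:
    if isinstance(el, VoltageSource):
        return el.node_plus, el.node_minus
    return el.node_a, el.node_b


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def solve_dc(circuit: Circuit) -> DCSolution:
    """Solve a resistive DC circuit for node potentials and branch currents.

    Zero-resistance elements are collapsed into supernodes (exact shorts);
    the remaining network is solved by nodal analysis with the voltage
    source current as an extra unknown.  Currents through the shorted
    elements are then recovered by KCL within each supernode.

    Raises
    ------
    CircuitError
        For structural defects (no ground, disconnected graph, ...).
    SingularCircuitError
        If the source is shorted by a zero-resistance loop or the system
        is otherwise singular.
    """
    circuit.validate()

    uf = _UnionFind(circuit.nodes)
    shorts: list[Element] = []
    for el in circuit.elements:
        if not isinstance(el, VoltageSource) and el.resistance == 0:
            uf.union(el.node_a, el.node_b)
            shorts.append(el)

    rep = {n: uf.find(n) for n in circuit.nodes}
    supernodes = sorted(set(rep.values()))
    gnd = rep[circuit.ground]
    unknown = [s for s in supernodes if s != gnd]
    index = {s: i for i, s in enumerate(unknown)}
    n = len(unknown)

    source = next((el for el in circuit.elements
                   if isinstance(el, VoltageSource)), None)
    if source is not None and rep[source.node_plus] == rep[source.node_minus]:
        raise SingularCircuitError(
            "voltage source is short-circuited by a zero-resistance loop")

    dim = n + (1 if source is not None else 0)
    A = np.zeros((dim, dim))
    b = np.zeros(dim)

    for el in circuit.elements:
        if isinstance(el, VoltageSource) or el.resistance == 0:
            continue
        g = 1.0 / el.resistance
        ia = index.get(rep[el.node_a])
        ib = index.get(rep[el.node_b])
        if ia is not None:
            A[ia, ia] += g
        if ib is not None:
            A[ib, ib] += g
        if ia is not None and ib is not None:
            A[ia, ib] -= g
            A[ib, ia] -= g

    if source is not None:
        # MNA branch row/column: V(+) - V(-) = E; the unknown at dim-1 is
        # the internal plus->minus current, i.e. MINUS the current the
        # source delivers into the network at its plus terminal.
        k = dim - 1
        ip = index.get(rep[source.node_plus])
        im = index.get(rep[source.node_minus])
        if ip is not None:
            A[ip, k] += 1.0
            A[k, ip] += 1.0
        if im is not None:
            A[im, k] -= 1.0
            A[k, im] -= 1.0
        b[k] = source.voltage

    try:
        x = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise SingularCircuitError(f"singular circuit: {exc}") from exc
    if not np.all(np.isfinite(x)):
        raise SingularCircuitError("non-finite solution")

    potentials = {node: (0.0 if rep[node] == gnd else float(x[index[rep[node]]]))
                  for node in circuit.nodes}

    currents: dict[str, float] = {}
    for el in circuit.elements:
        if isinstance(el, VoltageSource):
            currents[el.name] = -float(x[dim - 1]) * 1e3
        elif el.resistance > 0:
            i = (potentials[el.node_a] - potentials[el.node_b]) / el.resistance
            currents[el.name] = i * 1e3
    if shorts:
        _recover_short_currents(circuit, source, shorts, currents, x, dim)

    return DCSolution(node_potentials=potentials, branch_currents=currents)


def _recover_short_currents(circuit: Circuit, source: VoltageSource | None,
                            shorts: list[Element],
                            currents: dict[str, float],
                            x: np.ndarray, dim: int) -> None:
    """Determine currents through 0 Ω elements from KCL at the original
    (pre-merge) nodes.

    Let c_k be the unknown current of short k (positive node_a -> node_b).
    At every original node, injected current from resistive elements and
    the source plus the signed sum of short currents must vanish.  Shorts
    forming a forest give a uniquely determined system; a cycle of shorts
    is physically indeterminate and the minimum-norm split is returned.
    """
    nodes = sorted(circuit.nodes)
    nidx = {m: i for i, m in enumerate(nodes)}
    inj = np.zeros(len(nodes))  # known current INTO each node, in mA
    for el in circuit.elements:
        if isinstance(el, VoltageSource):
            # the source element delivers its current INTO node_plus
            i_src = currents[el.name]
            inj[nidx[el.node_plus]] += i_src
            inj[nidx[el.node_minus]] -= i_src
        elif el.resistance > 0:
            i = currents[el.name]
            inj[nidx[el.node_a]] -= i
            inj[nidx[el.node_b]] += i
    M = np.zeros((len(nodes), len(shorts)))
    for k, el in enumerate(shorts):
        M[nidx[el.node_a], k] = -1.0
        M[nidx[el.node_b], k] = 1.0
    # KCL: inj + M @ c = 0
    c, *_ = np.linalg.lstsq(M, -inj, rcond=None)
    for k, el in enumerate(shorts):
        currents[el.name] = float(c[k])


def branch_current(solution: DCSolution, element_name: str) -> float:
    """Signed current (mA) through the named element; positive from
    ``node_a`` to ``node_b``."""
    try:
        return solution.branch_currents[element_name]
    except KeyError:
        raise KeyError(f"no element named {element_name!r} in solution") from None


def kcl_residuals(circuit: Circuit, solution: DCSolution) -> dict[str, float]:
    """Net current (mA) flowing into each node; ~0 everywhere for a valid
    solution (the ground/source nodes balance too, by conservation)."""
    res = {n: 0.0 for n in circuit.nodes}
    for el in circuit.elements:
        i = solution.branch_currents[el.name]
        a, b = _endpoints(el)
        if isinstance(el, VoltageSource):
            # through the source element the current arrives AT node_plus
            res[a] += i
            res[b] -= i
        else:
            res[a] -= i
            res[b] += i
    return res


def equivalent_resistance(circuit: Circuit, terminal_a: str,
                          terminal_b: str) -> float:
    """Two-terminal equivalent resistance in ohms.

    Voltage sources are disabled by removal (open circuit); a 1 V test
    source is applied between the terminals and the resistance read as
    V/I.  Returns ``math.inf`` when the terminals lie in disconnected
    components.  Equals recursive series/parallel reduction wherever the
    network is series-parallel.
    """
    if terminal_a == terminal_b:
        raise CircuitError("terminals must differ")
    if terminal_a not in circuit.nodes or terminal_b not in circuit.nodes:
        raise CircuitError("both terminals must be declared nodes")

    passive = [el for el in circuit.elements
               if not isinstance(el, VoltageSource)]
    # keep only the component reachable from terminal_a through passive
    # elements; an unreachable terminal_b means infinite resistance
    adj: dict[str, set[str]] = {n: set() for n in circuit.nodes}
    for el in passive:
        adj[el.node_a].add(el.node_b)
        adj[el.node_b].add(el.node_a)
    seen = {terminal_a}
    stack = [terminal_a]
    while stack:
        for m in adj[stack.pop()]:
            if m not in seen:
                seen.add(m)
                stack.append(m)
    if terminal_b not in seen:
        return float("inf")

    sub = Circuit(nodes=set(seen),
                  elements=[el for el in passive
                            if el.node_a in seen and el.node_b in seen],
                  ground=terminal_b)
    sub.add(VoltageSource("__test__", terminal_a, terminal_b, 1.0))
    try:
        sol = solve_dc(sub)
    except SingularCircuitError:
        return 0.0  # terminals joined by a zero-resistance path
    i_ma = sol.branch_currents["__test__"]
    if i_ma == 0:
        return float("inf")
    return 1.0 / (i_ma * 1e-3)


def generate_random_network(n_nodes: int, n_resistors: int,
                            seed: int) -> Circuit:
    """Reproducible random connected resistor network with one 12 V source.

    A random spanning tree guarantees connectivity; remaining resistors are
    placed on uniformly chosen node pairs (parallel edges allowed).
    Resistances are log-uniform in [100 Ω, 10 kΩ].  Node ``n0`` is ground
    and carries the source negative terminal.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if n_resistors < n_nodes - 1:
        raise ValueError(
            f"need at least n_nodes - 1 = {n_nodes - 1} resistors for a "
            f"connected network, got {n_resistors}")
    rng = np.random.default_rng(seed)
    nodes = [f"n{i}" for i in range(n_nodes)]
    circuit = Circuit(nodes=set(nodes), ground="n0")

    def r() -> float:
        return float(10 ** rng.uniform(2, 4))

    k = 0
    for i in range(1, n_nodes):
        j = int(rng.integers(0, i))
        circuit.add(Resistor(f"R{k}", nodes[j], nodes[i], r()))
        k += 1
    while k < n_resistors:
        a, b = rng.choice(n_nodes, size=2, replace=False)
        circuit.add(Resistor(f"R{k}", nodes[int(a)], nodes[int(b)], r()))
        k += 1
    plus = nodes[int(rng.integers(1, n_nodes))]
    circuit.add(VoltageSource("V1", plus, "n0", 12.0))
    return circuit
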