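"""Shared fixtures and independent oracles.

The series/parallel generator below builds random two-terminal networks
whose exact equivalent resistance is known by construction (recursive
composition tracked in exact rational arithmetic).  It is deliberately
independent of the nodal solver it is used to check.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest

from splanchsim import Circuit, ModelState, Resistor, SplanchnicParameters


@pytest.fixture
def params() -> SplanchnicParameters:
    return SplanchnicParameters()


@pytest.fixture
def normal_state() -> ModelState:
    return ModelState(r_stenosis=0.0, r_aneurysm=50000.0)


def make_series_parallel(seed: int, depth: int = 4):
    """Random series-parallel two-terminal network with exact resistance.

    Returns ``(circuit, terminal_a, terminal_b, resistance)`` where
    ``resistance`` is a :class:`fractions.Fraction` computed purely from
    the series/parallel composition rules (never from a linear solve).
    """
    rng = np.random.default_rng(seed)
    counter = [0]

    def fresh() -> str:
        counter[0] += 1
        return f"m{counter[0]}"

    elements: list[Resistor] = []

    def build(a: str, b: str, d: int) -> Fraction:
        if d == 0 or rng.random() < 0.3:
            r = int(rng.integers(10, 100_000))
            elements.append(Resistor(f"R{len(elements)}", a, b, float(r)))
            return Fraction(r)
        if rng.random() < 0.5:  # series split
            mid = fresh()
            return build(a, mid, d - 1) + build(mid, b, d - 1)
        r1 = build(a, b, d - 1)  # parallel
        r2 = build(a, b, d - 1)
        return r1 * r2 / (r1 + r2)

    total = build("ta", "tb", depth)
    nodes = {"ta", "tb"} | {el.node_a for el in elements} \
        | {el.node_b for el in elements}
    return Circuit(nodes=nodes, elements=list(elements), ground="tb"), \
        "ta", "tb", total
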