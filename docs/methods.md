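# Methods

## Model and assumptions

`splanchsim` treats steady splanchnic blood flow as direct current in a
lumped resistor network. The analogy holds because both are linear flow
systems: pressure differences drive flow through resistive conduits
exactly as voltage differences drive current (Ohm's law), and flow is
conserved at junctions (Kirchhoff's current law). The mapping is

| hemodynamic | electrical | scale |
|---|---|---|
| pressure (mmHg) | voltage (V) | 1 mmHg = 0.1 V |
| flow (L/min) | current (mA) | 1 L/min = 1 mA |
| resistance (mmHg·min/L) | resistance (Ω) | derived: 100 Ω per unit |

Assumptions inherited from the analogy:

* **Steady, non-pulsatile flow.** The source is DC; the conclusions
  concern resistance/flow relationships, which are independent of
  pulsatility, but no pressure-wave phenomena are represented.
* **Linear (Poiseuille) resistances.** Turbulence in an aneurysm sac is
  neglected; computational-fluid-dynamics evidence indicates the net
  pressure drop across an aneurysm falls as it dilates, so a dilated
  segment is modelled as a *reduced* resistance.
* **Quasi-static dynamics.** The network has no capacitors or inductors,
  so every instant of a time-varying scenario is an independent
  steady-state solve. Vessel-wall remodelling (months) is vastly slower
  than flow equilibration (seconds), so the quasi-static limit is the
  physiologically relevant one.
* **One pressure source.** The aorta is an ideal source; venous return
  is ground. Current sensing is ideal (0 Ω), consistent with all the
  flow values the model reproduces.

## The reduced circuit

The two-branch divider (see README) uses: 12 V source; 3.3 kΩ fixed CA
and PDA resistances (two 1.3 kΩ vessel segments ≈ 2.6 kΩ, rounded to the
nearest standard part); a 12 kΩ pancreas+liver outflow bed (the exact
derivation gives (12 V − 1.4 V) / 0.86 mA = 12.3 kΩ, again rounded to a
standard part); and two 0–50 kΩ potentiometers. The stenosis
potentiometer sits in series with the CA resistor; the aneurysm
potentiometer in parallel with the PDA resistor.

Two conventions matter and are fixed here:

* **"PDA flow" is the total current entering the PDA block** (vessel
  resistor plus aneurysm/collateral path). Measuring the PDA resistor
  alone would read 0.427 mA in the normal state instead of the correct
  0.455 mA, because part of the arcade flow passes through the
  collateral path even normally.
* **The aneurysm potentiometer is placed across the PDA resistor.** An
  electrically equivalent variant wires it as a sibling branch of the
  divider; both yield identical terminal behaviour and identical
  measurands, so the choice is presentational. The closed form treats
  the pair as one block `R_b = R_PDA ∥ R_aneu` either way.

## Solver

`solve_dc` implements modified nodal analysis: node conductance matrix
plus one extra unknown for the source current, solved in double
precision with `numpy.linalg.solve`. Design points:

* **Exact shorts.** A potentiometer at exactly 0 Ω merges its endpoint
  nodes (union-find) before assembly rather than being replaced by a
  small epsilon, so the total-steal state yields CA flow exactly 0.000
  mA, not merely a small number. Currents *through* shorted elements are
  recovered afterwards from KCL on the short subgraph within each merged
  supernode (least squares; exact whenever the shorts form a forest,
  which holds in every shipped circuit — a cycle of ideal shorts has no
  determinate current split and gets the minimum-norm one).
* **Degenerate inputs.** A missing ground, a disconnected graph or an
  undeclared endpoint raises a structural error before any algebra; a
  zero-resistance loop across the source raises a singular-circuit
  error.
* **Sign convention.** Branch current is positive from `node_a` to
  `node_b`; flow outputs report magnitudes, since flow tracings are
  unsigned.
* **Equivalent resistance** between two terminals is measured by opening
  (removing) all voltage sources, applying a 1 V test source and reading
  the current. Disconnected terminals report infinity; terminals joined
  by a short report 0.

`steady_flows` evaluates the reduced circuit in closed form
(series/parallel reduction and the current-divider rule). The pair
(closed form, nodal solve) is used as a mutual oracle: the test suite
requires agreement below 1e-9 mA across a 50×50 grid of potentiometer
states, and checks the solver separately against exact-rational
series/parallel reduction and against graph-Laplacian effective
resistance (`networkx.resistance_distance`) on random networks.

## Scenarios

A scenario is a pair of piecewise-linear potentiometer signals plus
labelled clinical zones. The built-ins are two 7 s chronologies with 1 s
manipulations and 1 s holds:

| zone | scenario 1 (stenosis-first) | scenario 2 (aneurysm-first) |
|---|---|---|
| 0–1 s | normal (0 Ω, 50 kΩ) | normal (0 Ω, 50 kΩ) |
| 2–3 s | stenosis only (50 kΩ, 50 kΩ) | aneurysm only (0 Ω, 0 Ω) |
| 4–5 s | preop: total steal (50 kΩ, 0 Ω) | preop (50 kΩ, 0 Ω) |
| 6–7 s | postop (50 kΩ, 50 kΩ) | postop (50 kΩ, 50 kΩ) |

(even seconds are the connecting 1 s ramps). Manipulations ramp linearly
— matching the straight resistance segments in the tracings they emulate;
step changes are equally expressible via breakpoints and would alter
only transition samples, never hold-zone values. The combined 14 s
timeline concatenates the two with scenario 2 offset by +7 s; the reset
to the normal state between them is a near-instant ramp ending exactly
at t = 7 s.

Numerical choices, all presentation-level:

* default sampling step dt = 1 ms (7001 samples per scenario; any
  dt ≤ 0.1 s gives identical hold-zone values, which the suite checks by
  refinement);
* zones are half-open `[start, end)`, the final sample belonging to the
  last zone; zone summary values are read at zone midpoints to avoid
  boundary ambiguity;
* currents are reported to 3 decimals in mA (the reporting precision of
  the values being reproduced); trace CSVs store 6 significant digits;
* the steal threshold (0.0005 mA — anything that rounds to 0.000) and
  the LED-brightness class boundaries (off < 2%, dim < 50%, normal
  ≤ 110% of the normal-state current, else bright) are heuristics for
  qualitative description, not model quantities.

`detect_reconstitution` flags the clinically telling pattern: preop CA
flow below the steal threshold, postop CA flow above it but still below
normal — flow has *reappeared* without the stenosis being relieved.
`scenario_equivalence` compares normal/preop/postop flows between two
summaries at 1e-6 mA, the testable form of the path-independence
argument.

## Full-network template

Beyond the reduced circuit, `build_full_network` ships a topology-only
template of the whole splanchnic loop — aorta → {CA, SMA, IMA} hubs,
collaterals PDA (celiac↔SMA) and arc of Riolan (SMA↔IMA), hepatic artery
to the liver, venous return SMV/IMV → portal confluence → portal vein →
liver → hepatic vein → IVC → ground. Branch resistances are deliberately
**not** defaulted: no published per-vessel values back them, so the
caller must supply a complete positive resistance table (missing edges
are listed in the error). With the collateral path set to the reduced
parameters and all other branches effectively open, the full graph
reproduces the two-branch flows to < 1e-6 mA (tested).

## Synthetic fixtures

`generate_random_network` builds seeded random connected resistor
networks (spanning tree + extra edges, log-uniform resistances in
100 Ω–10 kΩ, one 12 V source) used to exercise the solver's conservation
and reciprocity properties. These fixtures emulate arbitrary vascular
meshes only in the abstract — they carry no physiological scaling — so
passing them demonstrates solver correctness, not anatomical fidelity.
The tests' series-parallel fixtures track their exact equivalent
resistance in rational arithmetic by construction, independent of any
linear solve.

## Known limitations

* No pulsatility, compliance (Windkessel) or inertance; no wave
  reflection. Only resistive steady states.
* Aneurysm wall mechanics enter only through Laplace's T = P·R as an
  auxiliary formula; rupture risk and remodelling dynamics are out of
  scope.
* The full-network template fixes a plausible topology but no
  physiological resistance values; conclusions from it depend entirely
  on the user's table.
* Absolute vessel radii are never used: the Poiseuille helper operates
  on radius *ratios* relative to a reference state.
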