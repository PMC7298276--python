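# splanchsim

Lumped-parameter, electrical-analog simulation of the splanchnic arterial
circulation, built to analyse the interplay between **celiac artery (CA)
stenosis** and **pancreaticoduodenal artery (PDA) aneurysm**.

These two rare conditions co-occur far more often than chance allows, and
it is usually assumed the stenosis comes first: throttled CA flow is
diverted through the pancreaticoduodenal arcade, and the chronically
overloaded collateral dilates into an aneurysm. Because neither disease
can be provoked in patients or animals, the question of which condition
causes which is well suited to a circuit model: steady blood flow through
a vascular bed obeys the same linear relations as direct current through
a resistor network (pressure ↔ voltage, flow ↔ current, vascular
resistance ↔ electrical resistance). `splanchsim` is for vascular
physiologists, surgeons and modellers who want that analysis as
reproducible code rather than a bench circuit.

## The model

The splanchnic tree is reduced to a two-branch current divider fed by a
12 V DC source (120 mmHg aortic pressure, using 1 mmHg = 0.1 V and
1 L/min = 1 mA):

```
aorta ──┬── R_sten (0–50 kΩ) ── R_CA (3.3 kΩ) ──┬── R_panc+liver (12 kΩ) ── ground
        │                                       │
        ├────────────── R_PDA (3.3 kΩ) ─────────┤
        └────────────── R_aneu (0–50 kΩ) ───────┘
```

* a **series potentiometer** `R_sten` raised towards 50 kΩ is a stenosis
  (a narrowing can only add resistance);
* a **parallel potentiometer** `R_aneu` lowered towards 0 Ω is an
  aneurysm with its collaterals (a dilated, multiplying pathway can only
  lower resistance — by Poiseuille, resistance falls with the 4th power
  of the radius);
* CA flow is the current in the series branch, PDA flow the total
  current entering the parallel block.

Solving the divider (closed form, or by modified nodal analysis on the
assembled circuit — the package does both and cross-checks them) gives
for the aneurysm block resistance `R_b = R_PDA ∥ R_aneu`:

```
I_total = V / (R_load + (R_CA + R_sten) ∥ R_b)
I_CA    = I_total · R_b / (R_CA + R_sten + R_b),   I_PDA = I_total − I_CA
```

Because the network is purely resistive, flows depend only on the
*instantaneous* state, never on the order in which it was reached. That
is the scientific point: the stenosis-first and aneurysm-first
chronologies arrive at identical normal, preoperative and postoperative
flows, so *either* condition can plausibly precede and provoke the
other — the steal phenomenon runs both ways. The model also reproduces
postoperative **reconstitution**: correcting only the aneurysm revives
the collapsed CA at 44 mL/min even though the stenosis stays in place.

## Worked example

Steady flows with a severe stenosis (50 kΩ) and no aneurysm:

```
$ splanchsim solve 50000 50000
CA flow:  0.044 mA (44 mL/min)
PDA flow: 0.760 mA (760 mL/min)
```

The CA flow has collapsed from its normal 0.427 mA to 0.044 mA while the
PDA arcade has risen from 0.455 mA to 0.760 mA — the diverted flow that
would chronically overload the collateral. Running both chronologies
back-to-back on one 14 s timeline (each manipulation is a 1 s linear
ramp, sampled quasi-statically at 1 ms):

```
$ splanchsim run --scenario both --summary summary.json
INFO scenario 'combined', 14001 samples (dt = 0.001 s)
INFO   [ 0.0,  1.0) normal        i_ca = 0.427 mA  i_pda = 0.455 mA
INFO   [ 2.0,  3.0) stenosis_only i_ca = 0.044 mA  i_pda = 0.760 mA
INFO   [ 4.0,  5.0) preop         i_ca = 0.000 mA  i_pda = 1.000 mA
INFO   [ 6.0,  7.0) postop        i_ca = 0.044 mA  i_pda = 0.760 mA
INFO   [ 7.0,  8.0) normal        i_ca = 0.427 mA  i_pda = 0.455 mA
INFO   [ 9.0, 10.0) aneurysm_only i_ca = 0.000 mA  i_pda = 1.000 mA
INFO   [11.0, 12.0) preop         i_ca = 0.000 mA  i_pda = 1.000 mA
INFO   [13.0, 14.0) postop        i_ca = 0.044 mA  i_pda = 0.760 mA
INFO steal = True, reconstitution = True
INFO scenario equivalence (normal/preop/postop): True
```

(transition zones elided). Reading the zones: the aneurysm-only state at
9–10 s already steals the *entire* CA flow with no stenosis present;
both chronologies reach the same preoperative total-steal state
(0.000 / 1.000 mA) and the same postoperative state, where the CA is
reconstituted at 0.044 mA = 44 mL/min. Unit conversions are exposed too:

```
$ splanchsim convert resistance 10 0.86
10 mmHg / 0.86 L/min = 1163 ohm
```

i.e. a 10 mmHg portal gradient at 0.86 L/min portal flow maps to 1163 Ω,
the scale from which the component values above were derived. The same
functionality is available as a library (`splanchsim.steady_flows`,
`run_scenario`, `solve_dc`, ...), including a general DC nodal solver,
two-terminal equivalent resistance, and a full splanchnic network
template accepting user resistance tables.

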