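# btaceflow

A lumped-parameter (0D) hydraulic simulator of **balloon-occluded transarterial
chemoembolization (B-TACE)** in a bench model of the hepatic artery.

B-TACE treats liver cancer by infusing chemoembolic agents distal to a
temporarily inflated microballoon in a hepatic artery. Whether the treatment
targets the tumour depends on where the balloon sits relative to the liver's
collateral arteries: after occlusion the upstream and downstream compartments
stay connected through collaterals such as the communicating arcade (CA)
between the right and left hepatic arteries, and the pressure just distal to
the balloon — the *balloon-occluded arterial stump pressure* (BOASP) — decides
between two regimes. If the BOASP stays high, pump-driven flow persists through
a collateral detour and the agent spreads to healthy territories; if it falls
below the normal-tissue pressure, the *pressure-gradient effect* (PGE)
redistributes flow from normal to tumour territories and the injection is
tumour-selective.

`btaceflow` reproduces this physics as a resistive flow network, mirroring a
physical bench rig: a constant-head pump feeds a symmetric bifurcating
arterial phantom (PHA → RHA/LHA → 4 sectional → 8 Couinaud segmental outlets
S2–S8, plus CA / sectional / segmental collaterals); each outlet drains through
a three-way stopcock to an upper reservoir (normal-tissue pressure, head
`z_UR`) or a lower reservoir (tumour pressure, `z_LR < z_UR`).

## Model

Every tube is a Hagen–Poiseuille resistor and every reservoir/pump an ideal
constant-pressure source (fluid–electric analogy, steady laminar Newtonian
flow):

```
Δp = R q,     R = 128 μ l / (π d⁴),     p_reservoir = ρ g z,   p_pump = ρ g H
```

Kirchhoff's current law at every interior node yields a linear system in the
unknown interior pressures, solved by nodal analysis (`solve_flow`). An
independent least-squares solver over the full redundant constraint set
(`oracle_solve`) cross-checks it in the tests. On top of the solver:

* **BOASP** — stump-node pressure before/after occlusion (`compute_boasp`);
* **PGE detection** — `LRP < BOASP < URP`, cross-validated against flow
  reversal in normal-segment outlet tubes (`detect_pge`);
* **injectate tracing** — passive-tracer reachability along flow directions,
  using the vanishing-injection limit on stagnant branches
  (`trace_injectate`);
* **outcome** — successful iff the tracer reaches only tumour-bearing
  segments (`classify_outcome`);
* **site sweeps** over the nine balloon positions 'a'–'i' along the
  PHA→RHA→right-posterior→S7 path (`occlusion_sweep`);
* **sizing** — checks/searches the seven bench design parameters
  (outlet tube l/d to each reservoir, `z_LR`, `z_UR`, `H_pump`)
  against the conceptual-design criteria (`check_design_criteria`,
  `search_sizing`).

## Worked example

Sweep the physically testable balloon sites with a tumour in segment S7
(catheter location 1 = site `c`, distal to the CA; location 2 = site `b`,
between the CA pathways):

```
btace-flow sweep --tumors S7 --sites b,c,e,f,h --out results/
```

`results/sweep.csv`:

```
site  p_before_mmHg  boasp_mmHg  IP_mmHg  URP_mmHg  LRP_mmHg   pge     reached      outcome
   b         12.592      11.947   12.957     8.086      5.88 False S5+S6+S7+S8 unsuccessful
   c         12.495       7.534   12.957     8.086      5.88  True          S7   successful
   e         12.197      11.285   12.957     8.086      5.88 False       S6+S7 unsuccessful
   f         12.041       6.983   12.957     8.086      5.88  True          S7   successful
   h         11.427      10.286   12.957     8.086      5.88 False          S7   successful
```

Reading it: baseline pressure falls steadily from proximal to distal sites
(12.6 → 11.4 mmHg) between the inlet pressure (IP) and the reservoir heads.
Occluding at `b` leaves the BOASP above the upper-reservoir pressure (URP,
the in-model PGE threshold): flow detours through the arcade and the whole
right lobe — healthy and tumour tissue alike — receives injectate. At `c`
and `f` the BOASP drops between URP and LRP, PGE develops (upper reservoir
feeds the artery, outlet flows at S5/S6/S8 reverse), and the agent lands in
S7 only. Site `h` succeeds *without* PGE because the stump sees a smaller
resistance towards S7 than towards S6. With water as working fluid the
absolute pressures are bench-scale (≈13 mmHg at the inlet), far below the
~90 mmHg hepatic artery; the `blood_mimic` fluid preset raises the operating
point.

Other entry points: `btace-flow solve` (node-pressure/branch-flow tables),
`btace-flow size` (design check), `btace-flow describe` (tree outline), all
configurable via YAML (see `examples/ivm.yaml`).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole pipeline from scratch on the shipped defaults: baseline
flow distributions and the full nine-site occlusion sweeps for both cancer
scenarios (tumours in S7; in S5+S7), the sizing check on the bench default
parameters, and a seeded solver-vs-oracle cross-check, printing the headline
numbers and writing the target report to `--out`.
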