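# Methods

## The model

The simulator is a steady-state lumped-parameter (0D) flow network. Three
assumptions make the reduction exact rather than approximate within its own
terms: flow is steady (no pulsatility, no compliance), laminar and Newtonian,
so each straight tube obeys the Hagen–Poiseuille law `Δp = R q` with
`R = 128 μ l / (π d⁴)`; and the pump and reservoirs hold constant heads, so
they are ideal pressure sources `p = ρ g z` (an overflow drain in the
physical rig keeps the free surfaces fixed, which is what licenses the
constant-source idealization). Pressures are gauge, with the datum at the
pump reservoir. The arterial phantom lies horizontal, so gravity enters the
equations only through the reservoir and pump heads, never along a branch.

Kirchhoff's current law at every interior node, with branch conductances
`1/R`, gives a grounded-Laplacian linear system in the unknown interior
pressures; boundary pressures fold into the right-hand side. `solve_flow`
solves it densely (networks here have < 100 nodes) and back-substitutes
branch flows. With all resistances positive and at least one boundary node
per connected component the system is symmetric positive definite, which is
exactly the solvability condition `FlowNetwork.check_solvable` enforces —
violating it raises `SingularNetworkError` naming the offending component,
never NaNs.

An occluded branch is removed from the system (flow reported as exactly
zero) rather than assigned a huge resistance, to keep the matrix well
conditioned; a regression test confirms removal matches an `R × 10¹²`
penalization to 1e-6 relative.

`oracle_solve` exists only as an independent cross-check: it stacks the full
redundant constraint set (one branch law per branch, scaled by `1/R`; one
conservation row per interior node; `q = 0` per blocked branch) and solves
it by column-equilibrated least squares with no nodal elimination. Tests
require agreement with `solve_flow` to 1e-8 relative over seeded random
networks.

## Geometry and its provenance

The bench circuit is: pump source (`ρ g H_pump`) → inflow tube → arterial
tree → per-segment outlet tube → reservoir source (`ρ g z_UR` or `ρ g z_LR`
according to the stopcock routing of the cancer scenario).

The seven sized bench parameters are used as published defaults: outlet
tubes 40 mm × 1.2 mm to both reservoirs, `z_LR` = 80 mm, `z_UR` = 110 mm,
`H_pump` = 200 mm. (The source text contains one internally inconsistent
inequality for the height ordering; the sized values and the accompanying
prose imply `z_LR < z_HA < z_UR`, which is what `IVMConfig` validates.)

The artery tree dimensions are *not* published; the shipped defaults are
calibration values chosen once to be anatomically plausible for a
real-scale adult hepatic artery (PHA 30 mm × 4.0 mm, lobar 30 mm × 3.0 mm,
sectional 25 mm × 2.2 mm, segmental 25 mm × 1.6 mm) with collaterals
thinner than the main branches of their generation (CA 15 mm × 2.0 mm,
sectional 12 mm × 1.5 mm, segmental 10 mm × 1.2 mm). Their only contract is
reproducing the bench behaviour the acceptance tests assert (all outlets
fed at baseline with tumour preference; PGE exactly at sites c and f;
effective injections exactly at c, f, h among the tested sites; strictly
decreasing proximal-to-distal baseline pressure). Every value is
overridable in configuration, and the tree is left-right symmetric by
construction — a property the mirror-symmetry test exploits exactly.

Collateral attachments split each host branch into thirds, and the balloon
site map names the three sub-segments of each path level: a/b/c on the RHA
(proximal to / between / distal to the two CA stations), d/e/f on the right
posterior sectional artery, g/h/i on the S7 segmental artery. The exact
positions of d–i are this package's reconstruction of the level-by-level
layout (the source figure cannot be read to that precision); b and c are
anchored by the published catheter locations 2 and 1 respectively.

Working fluid defaults to water (`μ` = 1.0e-3 Pa·s, `ρ` = 1000 kg/m³ —
water's viscosity is a standard value, not printed in the source); a
`blood_mimic` preset (1050 kg/m³, 3.5e-3 Pa·s) reproduces the proposed
water–glycol mixture. With water the absolute pressures are bench-scale
(inlet ≈ 13 mmHg), far below physiological arterial pressure: a green test
establishes the *redistribution logic*, not clinical pressure magnitudes.

## Occlusion assessment

**BOASP** is the pressure at the node immediately distal to the blocked
sub-branch, read from the occluded solve; the same node's baseline pressure
is reported as the pre-occlusion pressure.

**PGE** uses the strict pressure window `LRP < BOASP < URP` (equalities are
measure-zero and map to False). Because the same physics can be read from
the flows, the detector also computes the set of normal-segment outlet
tubes with reversed (reservoir → artery) flow and *requires* the two
criteria to agree; disagreement raises `PGEConsistencyError`, treating it as
a geometry/configuration defect rather than a rounding issue. The URP plays
the role of the clinical stump-pressure threshold (64 mmHg in the
literature); the package never asserts that number — it is bench-external.

**Injectate tracing** treats the agent as a passive tracer at an
infinitesimal infusion rate. Branches carrying ambient flow above an
absolute floor of 1e-12 m³/s are traversed only along that flow. On
ambient-stagnant branches the direction is taken from the
vanishing-injection limit: the response field of a unit volume source at the
stump node, obtained from the same nodal matrix by superposition (boundary
pressures grounded). This limit never perturbs the reported flow field, and
it matters in exactly one configuration class: when the stump is a perfect
stagnation point, as happens with two tumours (S5+S7) and the balloon distal
to the CA, where the anterior and posterior subtrees are hydraulically
identical and the tracer must still split toward both tumour sinks. Passing
`infinitesimal_injection=False` recovers pure flow-direction reachability
(which reports an empty, stagnant set in that case).

**Outcome** is the strict definition: successful iff the reached set is
non-empty and contains only tumour segments. At site `h` this matters: the
stump feeds S7 exclusively because the resistance toward S7 is smaller than
back toward S6, so `h` succeeds with PGE = False. Whether "effective"
should instead mean merely *preferential* delivery is an open reading; the
strict form is implemented and tested.

**Sweeps** assess any ordered subset of the nine sites against one shared
baseline solve and report IP (baseline inlet pressure), URP and LRP as
reference lines, with a flag marking the physically testable subset
{b, c, e, f, h} (the real microballoon cannot sit at a, d, g).

## Sizing

`check_design_criteria` evaluates a seven-parameter vector over both cancer
scenarios and three catheter states (none, location 1 = c, location 2 = b):
baseline all-outlets-fed, tumour-preference, PGE at c, no PGE at b, and
optional absolute flow bounds (e.g. the 0–500 mL/min pump envelope; off by
default because the conceptual design quantifies no magnitudes). Invalid or
unsolvable configurations yield failing results with diagnostics, not
exceptions. `search_sizing` enumerates a finite grid deterministically and
ranks passing vectors by the margin `URP − BOASP` at the PGE site (larger =
more robust PGE demonstration); the ranking rule is this package's own
choice, since the original sizing was manual.

## Numerical choices

* Solver: dense `numpy.linalg.solve` on the grounded Laplacian; unknown
  ordering is the sorted interior node ids, so solutions are bit-reproducible.
* Residual verification: branch law `|Δp − Rq| ≤ tol·max(|Δp|, R|q|, ε_p)`
  and conservation `|Σq| ≤ tol·(Σ|q| + ε_q)` at tol = 1e-9, where the floors
  are the machine-epsilon pressure scale (and the flow it induces through the
  smallest resistance) divided by tol — so dead-end nodes and equal-pressure
  networks, whose true values are exactly zero, are not flagged for pure
  roundoff.
* Tracing flow floor: 1e-12 m³/s absolute (≈ 5 orders below the smallest
  meaningful outlet flow); injection-limit floor: 1e-9 of the injection
  field's own maximum.
* Per-branch Reynolds numbers (`4ρ|q|/(πμd)`) are reported as a diagnostic
  wherever tube geometry is known; the bench defaults stay laminar
  (Re < 2300) but no check is enforced.
* Units: SI internally; reporting converts by 133.322 Pa/mmHg and
  6×10⁷ (m³/s → mL/min).

## Limitations

No pulsatility, compliance or inertance (RC/RLC), no non-Newtonian
rheology, no minor losses or turbulence; the pump is an ideal source (no
pump curve/working point); no embolic/lipiodol transport or deposition —
the tracer model says where the agent *can* go, not how much accumulates;
single anatomy (the most common branching variant), two pressure levels
only (all tumours share one intratumoral pressure); reservoir refill
dynamics ignored. The random-network generator exercises the solver, not
the anatomy: it makes no attempt at vascular realism.
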