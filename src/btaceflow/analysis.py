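"""Occlusion assessment: BOASP, pressure-gradient effect, injectate tracing.

After the balloon inflates, the pressure at the stump node immediately
distal to it — the balloon-occluded arterial stump pressure (BOASP) — tells
the two post-occlusion regimes apart.  If the BOASP stays above the
upper-reservoir pressure (URP) the pump-generated flow persists through a
collateral detour and both reservoirs keep being fed.  If the BOASP falls
strictly between the URP and the lower-reservoir pressure (LRP), the distal
compartment can no longer push water into the upper reservoir: instead the
upper reservoir feeds the artery and a gravity-driven flow runs from normal
(upper) to tumour (lower) territories through the collaterals.  That second
regime is the pressure-gradient effect (PGE), and the URP plays the role of
the clinical 64 mmHg stump-pressure threshold.

The injected agent is treated as a passive tracer: starting from the stump
node it can reach exactly the outlets connected by branches traversed in
the direction of their computed flow.  A treatment is successful when the
reached set is non-empty and contains only tumour-bearing segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

import numpy as np

from .artery import SITE_LABELS, SEGMENTS
from .hydraulics import (
    FlowNetwork,
    FlowSolution,
    NetworkError,
    assemble_nodal_system,
    solve_flow,
)
from .ivm import (
    CancerScenario,
    IVMConfig,
    OcclusionState,
    apply_occlusion,
    build_ivm_network,
    outlet_tube_id,
)
from .units import pa_to_mmhg

__all__ = [
    "Q_FLOOR",
    "PGEConsistencyError",
    "OcclusionAssessment",
    "SweepCurve",
    "compute_boasp",
    "detect_pge",
    "injection_field",
    "trace_injectate",
    "classify_outcome",
    "assess_occlusion",
    "occlusion_sweep",
    "PHYSICAL_SITES",
]

#: Absolute flow floor (m**3/s) below which a branch counts as stagnant.
Q_FLOOR = 1e-12

#: Balloon positions reachable by the physical microballoon on the bench
#: (the device length rules out 'a', 'd' and 'g'; 'i' is past the last
#: collateral station).  Purely an annotation — all nine sites simulate.
PHYSICAL_SITES = frozenset({"b", "c", "e", "f", "h"})


class PGEConsistencyError(NetworkError):
    """Pressure-window and flow-reversal PGE criteria disagree.

    Both must identify the same regime on any consistent geometry; a
    disagreement signals a configuration or geometry inconsistency, not a
    borderline rounding issue.
    """


@dataclass(frozen=True)
class OcclusionAssessment:
    """Everything the bench read-out reports for one balloon position."""

    site: str
    pressure_before: float  # Pa at the stump node, baseline solve
    boasp: float  # Pa at the stump node, occluded solve
    pge: bool
    reached_outlets: frozenset[str]
    outcome: str  # "successful" | "unsuccessful"
    reversed_normal_outlets: frozenset[str]
    injection_node: str
    stagnant: bool = False

    @property
    def boasp_mmhg(self) -> float:
        return pa_to_mmhg(self.boasp)


def compute_boasp(
    baseline: FlowSolution, occluded: FlowSolution, distal_node: str, site: str | None
) -> tuple[float, float]:
    """Pressure at the stump node before and after inflating the balloon."""
    if site is None:
        raise NetworkError("BOASP is undefined without an occlusion site")
    before = baseline.pressure(distal_node)
    boasp = occluded.pressure(distal_node)
    return before, boasp


def detect_pge(
    boasp: float,
    urp: float,
    lrp: float,
    occluded: FlowSolution,
    scenario: CancerScenario,
    q_floor: float = Q_FLOOR,
) -> tuple[bool, frozenset[str]]:
    """PGE flag plus the set of normal outlets with reversed (reservoir->artery) flow.

    Pressure criterion: LRP < BOASP < URP, strict on both sides (equality is
    a measure-zero boundary and maps to False).  Flow criterion: at least
    one normal-segment outlet tube carries reversed flow.  The two must
    agree; otherwise :class:`PGEConsistencyError` is raised.
    """
    pge_pressure = lrp < boasp < urp
    reversed_normal = frozenset(
        seg
        for seg in scenario.normal_segments()
        if occluded.flow(outlet_tube_id(seg)) < -q_floor
    )
    pge_flow = bool(reversed_normal)
    if pge_pressure != pge_flow:
        raise PGEConsistencyError(
            f"PGE criteria disagree: pressure window says {pge_pressure} "
            f"(BOASP={boasp:.6g} Pa, URP={urp:.6g}, LRP={lrp:.6g}) but reversed "
            f"normal outlets are {sorted(reversed_normal)}"
        )
    return pge_pressure, reversed_normal


def injection_field(network: FlowNetwork, injection_node: str) -> dict[str, float]:
    """Branch flows of a unit volumetric source placed at ``injection_node``.

    By superposition this is the response to the injection alone (boundary
    pressures grounded): the same nodal system is solved with a unit
    current-source right-hand side.  Only the flow signs are meaningful.
    """
    a, _, order = assemble_nodal_system(network)
    if injection_node not in order:
        raise NetworkError(
            f"injection node {injection_node!r} must be an interior node of the network"
        )
    rhs = np.zeros(len(order))
    rhs[order.index(injection_node)] = 1.0
    p = dict(zip(order, np.linalg.solve(a, rhs)))
    flows = {}
    for br in network.unblocked_branches():
        flows[br.id] = (p.get(br.tail, 0.0) - p.get(br.head, 0.0)) / br.resistance
    return flows


def trace_injectate(
    network: FlowNetwork,
    occluded: FlowSolution,
    injection_node: str,
    q_floor: float = Q_FLOOR,
    infinitesimal_injection: bool = True,
) -> frozenset[str]:
    """Outlets a passive tracer released at ``injection_node`` can reach.

    Branches carrying ambient flow (|q| > ``q_floor``) are traversed only in
    the direction of that flow.  On ambient-stagnant branches the tracer is
    carried by the injection itself: with ``infinitesimal_injection`` (the
    default) their direction is taken from the vanishing-rate injection
    limit — the unit-source field of :func:`injection_field`, which never
    perturbs the reported ambient solution.  Disabling it reproduces a pure
    flow-direction reachability where stagnant branches are never traversed.
    Returns segment labels; an empty set means no outlet is reachable.
    """
    if injection_node not in network.nodes:
        raise NetworkError(f"unknown injection node {injection_node!r}")
    if infinitesimal_injection:
        inj = injection_field(network, injection_node)
        inj_scale = max(abs(v) for v in inj.values()) if inj else 0.0
        inj_floor = 1e-9 * inj_scale
    downstream: dict[str, list[str]] = {n: [] for n in network.nodes}
    for br in network.unblocked_branches():
        q = occluded.flow(br.id)
        if abs(q) <= q_floor and infinitesimal_injection:
            q = inj[br.id] if abs(inj[br.id]) > inj_floor else 0.0
            if q > 0.0:
                downstream[br.tail].append(br.head)
            elif q < 0.0:
                downstream[br.head].append(br.tail)
        elif q > q_floor:
            downstream[br.tail].append(br.head)
        elif q < -q_floor:
            downstream[br.head].append(br.tail)
    seen = {injection_node}
    stack = [injection_node]
    while stack:
        node = stack.pop()
        if network.nodes[node].kind == "boundary":
            continue  # a reservoir is a sink; the tracer pools there
        for nxt in downstream[node]:
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return frozenset(seg for seg in SEGMENTS if f"o_{seg}" in seen)


def classify_outcome(reached_outlets: frozenset[str], scenario: CancerScenario) -> str:
    """Successful iff the tracer reaches at least one outlet and only tumour ones."""
    ok = bool(reached_outlets) and reached_outlets <= scenario.tumor_segments
    return "successful" if ok else "unsuccessful"


def assess_occlusion(
    config: IVMConfig,
    scenario: CancerScenario,
    site: str,
    baseline: FlowSolution | None = None,
    network: FlowNetwork | None = None,
) -> OcclusionAssessment:
    """Solve baseline and occluded states for one balloon site and assess.

    ``baseline``/``network`` may be passed in to avoid re-solving the
    unoccluded circuit across a sweep; the network is restored to its
    unoccluded state before returning.
    """
    if network is None:
        network = build_ivm_network(config, scenario)
    if baseline is None:
        apply_occlusion(network, OcclusionState(None))
        baseline = solve_flow(network)
    apply_occlusion(network, OcclusionState(site))
    occluded = solve_flow(network)
    stump = network.meta["occlusion"]["distal_node"]
    before, boasp = compute_boasp(baseline, occluded, stump, site)
    pge, reversed_normal = detect_pge(boasp, config.urp, config.lrp, occluded, scenario)
    reached = trace_injectate(network, occluded, stump)
    ambient_stagnant = all(
        abs(occluded.flow(br.id)) <= Q_FLOOR
        for br in network.unblocked_branches()
        if stump in (br.tail, br.head)
    )
    apply_occlusion(network, OcclusionState(None))
    return OcclusionAssessment(
        site=site,
        pressure_before=before,
        boasp=boasp,
        pge=pge,
        reached_outlets=reached,
        outcome=classify_outcome(reached, scenario),
        reversed_normal_outlets=reversed_normal,
        injection_node=stump,
        stagnant=ambient_stagnant,
    )


@dataclass(frozen=True)
class SweepCurve:
    """Pressure-versus-occlusion-site curve with its reference pressures.

    ``ip`` is the baseline pressure at the artery inlet; ``urp``/``lrp`` are
    the reservoir heads.  Sites are ordered proximal to distal.
    """

    sites: tuple[str, ...]
    assessments: dict[str, OcclusionAssessment]
    ip: float
    urp: float
    lrp: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label in self.sites:
            a = self.assessments[label]
            rows.append(
                {
                    "site": label,
                    "physically_tested": label in PHYSICAL_SITES,
                    "p_before_mmHg": pa_to_mmhg(a.pressure_before),
                    "boasp_mmHg": pa_to_mmhg(a.boasp),
                    "IP_mmHg": pa_to_mmhg(self.ip),
                    "URP_mmHg": pa_to_mmhg(self.urp),
                    "LRP_mmHg": pa_to_mmhg(self.lrp),
                    "pge": a.pge,
                    "reached": "+".join(sorted(a.reached_outlets)),
                    "outcome": a.outcome,
                }
            )
        return pd.DataFrame(rows)

    def plot(self, ax=None):
        """Pressure-occlusion-site chart: baseline and BOASP curves over the
        IP/URP/LRP reference lines."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        frame = self.to_frame()
        ax.plot(frame["site"], frame["p_before_mmHg"], "o-", label="before occlusion")
        ax.plot(frame["site"], frame["boasp_mmHg"], "s-", label="BOASP")
        for name, value, style in (
            ("IP", self.ip, ":"),
            ("URP", self.urp, "--"),
            ("LRP", self.lrp, "-."),
        ):
            ax.axhline(pa_to_mmhg(value), linestyle=style, linewidth=1, label=name)
        ax.set_xlabel("occlusion site (proximal → distal)")
        ax.set_ylabel("pressure (mmHg)")
        ax.legend(fontsize=8)
        return ax


def occlusion_sweep(
    config: IVMConfig,
    scenario: CancerScenario,
    sites: tuple[str, ...] | list[str] | None = None,
) -> SweepCurve:
    """Assess every requested balloon site (default: all nine, 'a'..'i').

    The baseline circuit is solved once and shared.  An unsolvable occlusion
    propagates as an error carrying its site label.
    """
    labels = tuple(sites) if sites is not None else SITE_LABELS
    network = build_ivm_network(config, scenario)
    baseline = solve_flow(network)
    assessments = {}
    for label in labels:
        try:
            assessments[label] = assess_occlusion(
                config, scenario, label, baseline=baseline, network=network
            )
        except NetworkError as exc:
            raise NetworkError(f"occlusion at site {label!r} failed: {exc}") from exc
    return SweepCurve(
        sites=labels,
        assessments=assessments,
        ip=baseline.pressure("n_inlet"),
        urp=config.urp,
        lrp=config.lrp,
    )
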