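"""Steady-state resistive flow networks (the 0D hydraulic core).

A vascular or bench circuit is reduced to a graph of nodes joined by
resistive branches, following the classical fluid-electric analogy: tubes
are resistors (Hagen-Poiseuille law for laminar, steady, Newtonian flow),
while the pump and the constant-level reservoirs are ideal constant-pressure
sources.  On every unblocked branch the pressure drop obeys

    dp = R * q,          R = 128 * mu * l / (pi * d**4)

and at every interior node the signed flows sum to zero (Kirchhoff's current
law).  Fixing the boundary pressures turns the network into a linear system
in the unknown interior pressures, which ``solve_flow`` assembles and solves
by nodal analysis.  ``oracle_solve`` solves the full redundant constraint
set (one branch law per branch plus one conservation relation per interior
node) by linear least squares with no nodal elimination; it exists purely as
an independent cross-check for tests.

Pressures are gauge pressures in Pa; flows are signed m**3/s, positive in
the branch's tail-to-head direction.  Gravity enters only through the
source-pressure formula p = rho*g*z for reservoir/pump heads; branches
themselves are treated as horizontal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .units import m3s_to_mlmin, pa_to_mmhg

__all__ = [
    "NetworkError",
    "InvalidGeometryError",
    "SingularNetworkError",
    "IncompleteSolutionError",
    "FluidProperties",
    "TubeSpec",
    "Node",
    "Branch",
    "FlowNetwork",
    "FlowSolution",
    "SolutionReport",
    "WATER",
    "BLOOD_MIMIC",
    "poiseuille_resistance",
    "source_pressure",
    "assemble_nodal_system",
    "solve_flow",
    "oracle_solve",
    "verify_solution",
]


class NetworkError(ValueError):
    """Base class for flow-network construction and solution errors."""


class InvalidGeometryError(NetworkError):
    """A tube or fluid parameter is outside its physical domain."""


class SingularNetworkError(NetworkError):
    """A connected component with interior nodes has no pressure boundary."""

    def __init__(self, message: str, component: frozenset[str] = frozenset()):
        super().__init__(message)
        self.component = component


class IncompleteSolutionError(NetworkError):
    """A solution object does not cover every node/branch of the network."""


@dataclass(frozen=True)
class FluidProperties:
    """Working fluid: density (kg/m**3), dynamic viscosity (Pa*s), g (m/s**2)."""

    density: float
    viscosity: float
    gravity: float = 9.8

    def __post_init__(self) -> None:
        for name in ("density", "viscosity", "gravity"):
            if not getattr(self, name) > 0.0:
                raise InvalidGeometryError(f"fluid {name} must be strictly positive")


#: Water at roughly 20 degC (the bench working fluid).
WATER = FluidProperties(density=1000.0, viscosity=1.0e-3)
#: Water-glycol blood mimic (density 1050 kg/m**3, viscosity 0.0035 Pa*s).
BLOOD_MIMIC = FluidProperties(density=1050.0, viscosity=3.5e-3)


@dataclass(frozen=True)
class TubeSpec:
    """Straight circular tube: length and inner diameter, both in metres."""

    length: float
    diameter: float

    def __post_init__(self) -> None:
        if self.length < 0.0:
            raise InvalidGeometryError("tube length must be >= 0")
        if not self.diameter > 0.0:
            raise InvalidGeometryError("tube diameter must be strictly positive")

    def cross_section(self) -> float:
        return math.pi * self.diameter**2 / 4.0


def poiseuille_resistance(fluid: FluidProperties, tube: TubeSpec) -> float:
    """Hagen-Poiseuille hydraulic resistance, 128*mu*l/(pi*d**4), in Pa*s/m**3."""
    return 128.0 * fluid.viscosity * tube.length / (math.pi * tube.diameter**4)


def source_pressure(fluid: FluidProperties, height: float) -> float:
    """Hydrostatic gauge pressure rho*g*z of a free surface (or pump head) at ``height``."""
    return fluid.density * fluid.gravity * height


@dataclass(frozen=True)
class Node:
    id: str
    kind: str = "interior"  # "interior" | "boundary"
    pressure: float | None = None  # Pa, boundary nodes only
    elevation: float = 0.0  # informational; gravity enters via source_pressure

    def __post_init__(self) -> None:
        if self.kind not in ("interior", "boundary"):
            raise NetworkError(f"node {self.id!r}: unknown kind {self.kind!r}")
        if self.kind == "boundary" and self.pressure is None:
            raise NetworkError(f"boundary node {self.id!r} needs a fixed pressure")
        if self.kind == "interior" and self.pressure is not None:
            raise NetworkError(f"interior node {self.id!r} must not fix a pressure")


@dataclass(frozen=True)
class Branch:
    id: str
    tail: str
    head: str
    resistance: float  # Pa*s/m**3
    blocked: bool = False
    tube: TubeSpec | None = None  # retained for diagnostics (Reynolds number)

    def __post_init__(self) -> None:
        if not self.resistance > 0.0:
            raise NetworkError(f"branch {self.id!r}: resistance must be > 0")
        if self.tail == self.head:
            raise NetworkError(f"branch {self.id!r}: self-loops are not allowed")


class FlowNetwork:
    """Mutable container of nodes and resistive branches.

    Multiple parallel branches between the same node pair are allowed (they
    are physically parallel tubes).  ``meta`` is a free-form dict used by
    higher layers (scenario, occlusion bookkeeping); it never affects the
    hydraulics.
    """

    def __init__(self, fluid: FluidProperties = WATER):
        self.fluid = fluid
        self.nodes: dict[str, Node] = {}
        self.branches: dict[str, Branch] = {}
        self.meta: dict = {}

    # -- construction -----------------------------------------------------
    def add_interior(self, node_id: str, elevation: float = 0.0) -> None:
        self._add_node(Node(node_id, "interior", None, elevation))

    def add_boundary(self, node_id: str, pressure: float, elevation: float = 0.0) -> None:
        self._add_node(Node(node_id, "boundary", float(pressure), elevation))

    def _add_node(self, node: Node) -> None:
        if node.id in self.nodes:
            raise NetworkError(f"duplicate node id {node.id!r}")
        self.nodes[node.id] = node

    def add_branch(
        self,
        branch_id: str,
        tail: str,
        head: str,
        *,
        resistance: float | None = None,
        tube: TubeSpec | None = None,
        blocked: bool = False,
    ) -> None:
        """Add a branch, given either an explicit resistance or a tube spec."""
        if branch_id in self.branches:
            raise NetworkError(f"duplicate branch id {branch_id!r}")
        for end in (tail, head):
            if end not in self.nodes:
                raise NetworkError(f"branch {branch_id!r}: unknown endpoint {end!r}")
        if resistance is None:
            if tube is None:
                raise NetworkError(f"branch {branch_id!r}: need resistance or tube")
            resistance = poiseuille_resistance(self.fluid, tube)
            if resistance == 0.0:
                raise InvalidGeometryError(
                    f"branch {branch_id!r}: zero-length tube has zero resistance"
                )
        self.branches[branch_id] = Branch(branch_id, tail, head, float(resistance), blocked, tube)

    def remove_branch(self, branch_id: str) -> Branch:
        return self.branches.pop(branch_id)

    def set_boundary_pressure(self, node_id: str, pressure: float) -> None:
        node = self.nodes[node_id]
        if node.kind != "boundary":
            raise NetworkError(f"node {node_id!r} is not a boundary node")
        self.nodes[node_id] = replace(node, pressure=float(pressure))

    def block(self, branch_id: str, blocked: bool = True) -> None:
        self.branches[branch_id] = replace(self.branches[branch_id], blocked=blocked)

    def copy(self) -> "FlowNetwork":
        out = FlowNetwork(self.fluid)
        out.nodes = dict(self.nodes)
        out.branches = dict(self.branches)
        out.meta = dict(self.meta)
        return out

    # -- queries ----------------------------------------------------------
    def interior_ids(self) -> list[str]:
        return sorted(n.id for n in self.nodes.values() if n.kind == "interior")

    def boundary_ids(self) -> list[str]:
        return sorted(n.id for n in self.nodes.values() if n.kind == "boundary")

    def unblocked_branches(self) -> list[Branch]:
        return [b for b in self.branches.values() if not b.blocked]

    def graph(self, include_blocked: bool = False) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self.nodes)
        for b in self.branches.values():
            if include_blocked or not b.blocked:
                g.add_edge(b.tail, b.head, key=b.id)
        return g

    def check_solvable(self) -> None:
        """Every component holding an interior node must hold a boundary node."""
        for comp in nx.connected_components(self.graph()):
            kinds = {self.nodes[n].kind for n in comp}
            if "interior" in kinds and "boundary" not in kinds:
                names = ", ".join(sorted(comp))
                raise SingularNetworkError(
                    f"component with no pressure boundary: {{{names}}}",
                    component=frozenset(comp),
                )


@dataclass
class FlowSolution:
    """Node pressures (Pa) and signed branch flows (m**3/s, tail->head positive)."""

    node_pressures: dict[str, float]
    branch_flows: dict[str, float]

    def pressure(self, node_id: str) -> float:
        return self.node_pressures[node_id]

    def flow(self, branch_id: str) -> float:
        return self.branch_flows[branch_id]

    def to_frames(self):
        """Return (node table, branch table) as tidy pandas DataFrames."""
        import pandas as pd

        nodes = pd.DataFrame(
            {
                "node": sorted(self.node_pressures),
                "pressure_pa": [self.node_pressures[n] for n in sorted(self.node_pressures)],
            }
        )
        nodes["pressure_mmhg"] = nodes["pressure_pa"].map(pa_to_mmhg)
        branches = pd.DataFrame(
            {
                "branch": sorted(self.branch_flows),
                "flow_m3_per_s": [self.branch_flows[b] for b in sorted(self.branch_flows)],
            }
        )
        branches["flow_ml_per_min"] = branches["flow_m3_per_s"].map(m3s_to_mlmin)
        return nodes, branches


def assemble_nodal_system(network: FlowNetwork):
    """Assemble the nodal (grounded-Laplacian) system ``A p = b``.

    One flow-conservation equation per interior node, written in the unknown
    interior pressures with branch conductances 1/R; boundary pressures are
    folded into the right-hand side.  Blocked branches are excluded from the
    system altogether.  Returns ``(A, b, order)`` where ``order`` is the
    sorted list of interior node ids defining the unknown ordering.
    """
    network.check_solvable()
    order = network.interior_ids()
    index = {nid: i for i, nid in enumerate(order)}
    n = len(order)
    a = np.zeros((n, n))
    b = np.zeros(n)
    for br in network.unblocked_branches():
        g = 1.0 / br.resistance
        for this, other in ((br.tail, br.head), (br.head, br.tail)):
            if this not in index:
                continue
            i = index[this]
            a[i, i] += g
            if other in index:
                a[i, index[other]] -= g
            else:
                b[i] += g * network.nodes[other].pressure  # type: ignore[operator]
    return a, b, order


def solve_flow(network: FlowNetwork) -> FlowSolution:
    """Solve for interior pressures by nodal analysis, then back out branch flows.

    Blocked branches are reported with a flow of exactly zero.  Raises
    :class:`SingularNetworkError` on a network that has a boundary-free
    component (never returns silent NaNs).
    """
    a, b, order = assemble_nodal_system(network)
    if len(order):
        try:
            p_int = np.linalg.solve(a, b)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by check_solvable
            raise SingularNetworkError(f"singular nodal system: {exc}") from exc
        if not np.all(np.isfinite(p_int)):  # pragma: no cover
            raise SingularNetworkError("non-finite pressures in nodal solution")
    else:
        p_int = np.zeros(0)
    pressures = {nid: network.nodes[nid].pressure for nid in network.boundary_ids()}
    pressures.update(zip(order, p_int.tolist()))
    flows = {}
    for br in network.branches.values():
        if br.blocked:
            flows[br.id] = 0.0
        else:
            flows[br.id] = (pressures[br.tail] - pressures[br.head]) / br.resistance
    return FlowSolution(dict(pressures), flows)  # type: ignore[arg-type]


def oracle_solve(network: FlowNetwork) -> FlowSolution:
    """Independent least-squares solve of the full redundant constraint set.

    Unknowns are all interior pressures and all branch flows.  Rows: one
    branch law per unblocked branch (scaled by 1/R so all rows are flow-
    sized), one q=0 row per blocked branch, and one conservation row per
    interior node.  Columns are equilibrated before the ``lstsq`` call.
    Intended for small test networks only; it shares no assembly code with
    :func:`solve_flow`.
    """
    network.check_solvable()
    interior = network.interior_ids()
    branch_ids = sorted(network.branches)
    p_index = {nid: i for i, nid in enumerate(interior)}
    q_index = {bid: len(interior) + j for j, bid in enumerate(branch_ids)}
    n_unknown = len(interior) + len(branch_ids)

    rows: list[np.ndarray] = []
    rhs: list[float] = []

    def boundary_pressure(nid: str) -> float | None:
        node = network.nodes[nid]
        return node.pressure if node.kind == "boundary" else None

    for bid in branch_ids:
        br = network.branches[bid]
        row = np.zeros(n_unknown)
        if br.blocked:
            row[q_index[bid]] = 1.0
            rows.append(row)
            rhs.append(0.0)
            continue
        # (p_tail - p_head)/R - q = 0
        b_val = 0.0
        for nid, sign in ((br.tail, 1.0), (br.head, -1.0)):
            fixed = boundary_pressure(nid)
            if fixed is None:
                row[p_index[nid]] += sign / br.resistance
            else:
                b_val -= sign * fixed / br.resistance
        row[q_index[bid]] = -1.0
        rows.append(row)
        rhs.append(b_val)

    for nid in interior:
        row = np.zeros(n_unknown)
        for bid in branch_ids:
            br = network.branches[bid]
            if br.blocked:
                continue
            if br.tail == nid:
                row[q_index[bid]] -= 1.0  # flow leaving the node
            if br.head == nid:
                row[q_index[bid]] += 1.0
        rows.append(row)
        rhs.append(0.0)

    a = np.array(rows)
    b = np.array(rhs)
    scale = np.linalg.norm(a, axis=0)
    scale[scale == 0.0] = 1.0
    x_scaled, *_ = np.linalg.lstsq(a / scale, b, rcond=None)
    x = x_scaled / scale

    pressures = {nid: network.nodes[nid].pressure for nid in network.boundary_ids()}
    pressures.update({nid: float(x[p_index[nid]]) for nid in interior})
    flows = {
        bid: (0.0 if network.branches[bid].blocked else float(x[q_index[bid]]))
        for bid in branch_ids
    }
    return FlowSolution(dict(pressures), flows)  # type: ignore[arg-type]


@dataclass
class SolutionReport:
    """Residual report from :func:`verify_solution`."""

    max_branch_residual: float
    max_node_residual: float
    worst_branch: str | None
    worst_node: str | None
    tolerance: float
    passed: bool
    failing_branches: list[str] = field(default_factory=list)
    failing_nodes: list[str] = field(default_factory=list)
    reynolds: dict[str, float] = field(default_factory=dict)


def _reynolds(network: FlowNetwork, branch: Branch, q: float) -> float | None:
    # Re = rho*v*d/mu with v = q/A and A = pi d^2/4  ->  Re = 4 rho |q| / (pi mu d)
    if branch.tube is None:
        return None
    f = network.fluid
    return 4.0 * f.density * abs(q) / (math.pi * f.viscosity * branch.tube.diameter)


def verify_solution(
    network: FlowNetwork, solution: FlowSolution, tolerance: float = 1e-9
) -> SolutionReport:
    """Check the branch law and node conservation, both as relative residuals.

    Branch law: |dp - R q| <= tol * max(|dp|, R|q|, eps_p).
    Conservation: |sum q| <= tol * (sum |q| + eps_q).

    The floors eps_p/eps_q absorb pure floating-point roundoff where the true
    values are zero (dead-end nodes, equal boundary pressures): they are the
    machine-epsilon pressure scale — and the flow it induces through the
    smallest resistance — divided by the tolerance, so the allowed absolute
    error never drops below roundoff itself.
    """
    p_scale = max((abs(p) for p in solution.node_pressures.values()), default=1.0) or 1.0
    r_min = min((b.resistance for b in network.unblocked_branches()), default=1.0)
    eps_mach = 64.0 * np.finfo(float).eps
    eps_p = eps_mach * max(p_scale, 1.0) / tolerance
    eps_q = eps_p / r_min
    missing_nodes = set(network.nodes) - set(solution.node_pressures)
    missing_branches = set(network.branches) - set(solution.branch_flows)
    if missing_nodes or missing_branches:
        raise IncompleteSolutionError(
            f"solution misses nodes {sorted(missing_nodes)} / branches {sorted(missing_branches)}"
        )

    max_br, worst_br = 0.0, None
    failing_branches = []
    reynolds = {}
    for br in network.branches.values():
        q = solution.branch_flows[br.id]
        re = _reynolds(network, br, q)
        if re is not None:
            reynolds[br.id] = re
        if br.blocked:
            if q != 0.0:
                failing_branches.append(br.id)
                max_br, worst_br = max(max_br, 1.0), br.id
            continue
        dp = solution.node_pressures[br.tail] - solution.node_pressures[br.head]
        res = abs(dp - br.resistance * q) / max(abs(dp), br.resistance * abs(q), eps_p)
        if res > max_br:
            max_br, worst_br = res, br.id
        if res > tolerance:
            failing_branches.append(br.id)

    max_nd, worst_nd = 0.0, None
    failing_nodes = []
    for nid in network.interior_ids():
        total, magnitude = 0.0, 0.0
        for br in network.unblocked_branches():
            q = solution.branch_flows[br.id]
            if br.head == nid:
                total += q
                magnitude += abs(q)
            if br.tail == nid:
                total -= q
                magnitude += abs(q)
        res = abs(total) / (magnitude + eps_q)
        if res > max_nd:
            max_nd, worst_nd = res, nid
        if res > tolerance:
            failing_nodes.append(nid)

    return SolutionReport(
        max_branch_residual=max_br,
        max_node_residual=max_nd,
        worst_branch=worst_br,
        worst_node=worst_nd,
        tolerance=tolerance,
        passed=not failing_branches and not failing_nodes,
        failing_branches=failing_branches,
        failing_nodes=failing_nodes,
        reynolds=reynolds,
    )
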