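"""Symmetric bifurcating hepatic artery with collateral pathways.

The arterial phantom is the most common hepatic arterial morphology: the
proper hepatic artery (PHA) bifurcates into right and left hepatic arteries
(RHA, LHA); each lobar artery bifurcates into two sectional arteries, and
each sectional artery into two segmental arteries, until the eight Couinaud
segmental outlets S2, S3, S4a, S4b (left lobe) and S5, S6, S7, S8 (right
lobe) are generated — a full binary tree of 15 main branches.

Collateral pathways ride on top of the tree:

* the communicating arcade (CA): two thin pathways joining the RHA to the
  LHA at matching stations along each lobar artery;
* same-generation connections at the sectional level (right posterior <->
  right anterior, mirrored on the left), standing in for hilar-plexus /
  watershed connections;
* same-generation connections at the segmental level (S7 <-> S6, mirrored
  as S2 <-> S3).

Attaching a collateral splits the host branch into thirds, creating the
junction nodes ``n_<base>_c1`` / ``n_<base>_c2``.  The microballoon site map
'a'..'i' then names the three sub-segments of each branch on the
PHA -> RHA -> right-posterior -> S7 path: 'a'/'b'/'c' on the RHA (proximal
to / between / distal to the CA stations), 'd'/'e'/'f' on the right
posterior sectional artery, 'g'/'h'/'i' on the S7 segmental artery.
Site 'c' is the classical "distal to the CA" balloon position (location 1)
and 'b' the "between the CA pathways" position (location 2).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx

from .hydraulics import FluidProperties, FlowNetwork, NetworkError, TubeSpec, WATER

__all__ = [
    "SEGMENTS",
    "RIGHT_SEGMENTS",
    "LEFT_SEGMENTS",
    "SITE_LABELS",
    "ArteryTreeSpec",
    "CollateralSpec",
    "BalloonSite",
    "BalloonSiteMap",
    "DEFAULT_TREE",
    "DEFAULT_COLLATERALS",
    "build_hepatic_tree",
    "attach_collaterals",
    "build_artery",
    "map_balloon_sites",
    "mirror_id",
    "describe_tree",
]

#: Couinaud segmental outlets, left lobe first.
SEGMENTS = ("S2", "S3", "S4a", "S4b", "S5", "S6", "S7", "S8")
LEFT_SEGMENTS = ("S2", "S3", "S4a", "S4b")
RIGHT_SEGMENTS = ("S5", "S6", "S7", "S8")
SITE_LABELS = ("a", "b", "c", "d", "e", "f", "g", "h", "i")

#: (branch id, tail node, head node, generation) for the 15 main branches.
_MAIN_TREE = (
    ("b_pha", "n_inlet", "n_pha", "pha"),
    ("b_lha", "n_pha", "n_lha", "lobar"),
    ("b_rha", "n_pha", "n_rha", "lobar"),
    ("b_l_lat", "n_lha", "n_l_lat", "sectional"),
    ("b_l_med", "n_lha", "n_l_med", "sectional"),
    ("b_r_ant", "n_rha", "n_r_ant", "sectional"),
    ("b_r_post", "n_rha", "n_r_post", "sectional"),
    ("b_S2", "n_l_lat", "o_S2", "segmental"),
    ("b_S3", "n_l_lat", "o_S3", "segmental"),
    ("b_S4a", "n_l_med", "o_S4a", "segmental"),
    ("b_S4b", "n_l_med", "o_S4b", "segmental"),
    ("b_S5", "n_r_ant", "o_S5", "segmental"),
    ("b_S8", "n_r_ant", "o_S8", "segmental"),
    ("b_S6", "n_r_post", "o_S6", "segmental"),
    ("b_S7", "n_r_post", "o_S7", "segmental"),
)

_GENERATION_ORDER = ("pha", "lobar", "sectional", "segmental")


@dataclass(frozen=True)
class ArteryTreeSpec:
    """Per-generation tube dimensions of the main bifurcating tree.

    Defaults are calibration values: a ~4 mm PHA tapering to 1.6 mm
    segmental arteries, real-scale for an adult hepatic artery.  Their only
    contract is reproducing the qualitative bench behaviour (flow to every
    segment at baseline, collateral redistribution under occlusion); every
    value can be overridden in configuration.
    """

    pha: TubeSpec = TubeSpec(0.030, 0.0040)
    lobar: TubeSpec = TubeSpec(0.030, 0.0030)
    sectional: TubeSpec = TubeSpec(0.025, 0.0022)
    segmental: TubeSpec = TubeSpec(0.025, 0.0016)

    def __post_init__(self) -> None:
        diameters = [getattr(self, g).diameter for g in _GENERATION_ORDER]
        if any(d_next > d for d, d_next in zip(diameters, diameters[1:])):
            raise NetworkError("artery diameters must be non-increasing with generation")

    def tube(self, generation: str) -> TubeSpec:
        return getattr(self, generation)


@dataclass(frozen=True)
class CollateralSpec:
    """Collateral tube dimensions per level; ``None`` omits that level.

    Collaterals are thinner than the main branches of the same generation
    (higher resistance), so they carry little flow until an occlusion makes
    them the only route.  ``attach_fractions`` places the two junction nodes
    along each host branch (default: at one and two thirds of its length).
    """

    ca: TubeSpec | None = TubeSpec(0.015, 0.0020)
    sectional: TubeSpec | None = TubeSpec(0.012, 0.0015)
    segmental: TubeSpec | None = TubeSpec(0.010, 0.0012)
    attach_fractions: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)

    def __post_init__(self) -> None:
        f1, f2 = self.attach_fractions
        if not 0.0 < f1 < f2 < 1.0:
            raise NetworkError("attach_fractions must satisfy 0 < f1 < f2 < 1")

    @property
    def empty(self) -> bool:
        return self.ca is None and self.sectional is None and self.segmental is None


DEFAULT_TREE = ArteryTreeSpec()
DEFAULT_COLLATERALS = CollateralSpec()


def build_hepatic_tree(
    spec: ArteryTreeSpec = DEFAULT_TREE, fluid: FluidProperties = WATER
) -> FlowNetwork:
    """Build the 15-branch main tree as a network fragment (all nodes interior).

    The fragment has one inlet node ``n_inlet`` and eight outlet nodes
    ``o_<segment>``; resistances follow the Hagen-Poiseuille law for the
    per-generation tubes.  Node and branch ids are deterministic.
    """
    net = FlowNetwork(fluid)
    for node_id in dict.fromkeys(n for _, t, h, _ in _MAIN_TREE for n in (t, h)):
        net.add_interior(node_id)
    for branch_id, tail, head, generation in _MAIN_TREE:
        net.add_branch(branch_id, tail, head, tube=spec.tube(generation))
    outlets = {b[2] for b in _MAIN_TREE if b[2].startswith("o_")}
    if outlets != {f"o_{s}" for s in SEGMENTS}:  # pragma: no cover - structural guard
        raise NetworkError("tree must expose exactly the eight Couinaud outlets")
    net.meta["artery_spec"] = spec
    return net


def _split_branch(net: FlowNetwork, branch_id: str, fractions: tuple[float, float]) -> None:
    """Replace ``branch_id`` by three sub-branches with junction nodes in between."""
    br = net.remove_branch(branch_id)
    if br.tube is None:  # pragma: no cover - all main branches carry tubes
        raise NetworkError(f"cannot split branch {branch_id!r} without tube geometry")
    base = branch_id.removeprefix("b_")
    n1, n2 = f"n_{base}_c1", f"n_{base}_c2"
    net.add_interior(n1)
    net.add_interior(n2)
    f1, f2 = fractions
    pieces = (
        (f"{branch_id}_1", br.tail, n1, f1),
        (f"{branch_id}_2", n1, n2, f2 - f1),
        (f"{branch_id}_3", n2, br.head, 1.0 - f2),
    )
    for piece_id, tail, head, frac in pieces:
        net.add_branch(
            piece_id, tail, head, tube=TubeSpec(br.tube.length * frac, br.tube.diameter)
        )


_CA_HOSTS = ("b_rha", "b_lha")
_SECTIONAL_HOSTS = ("b_r_post", "b_r_ant", "b_l_lat", "b_l_med")
_SEGMENTAL_HOSTS = ("b_S7", "b_S6", "b_S2", "b_S3")

#: Collateral edges per level: (edge base id, host A base, host B base).
_COLLATERAL_EDGES = {
    "ca": (("c_ca", "rha", "lha"),),
    "sectional": (("c_r_post_r_ant", "r_post", "r_ant"), ("c_l_lat_l_med", "l_lat", "l_med")),
    "segmental": (("c_S7_S6", "S7", "S6"), ("c_S2_S3", "S2", "S3")),
}


def attach_collaterals(
    net: FlowNetwork,
    collaterals: CollateralSpec = DEFAULT_COLLATERALS,
    fluid: FluidProperties | None = None,
) -> FlowNetwork:
    """Split host branches and add the collateral edges, in place.

    Returns the same network for chaining.  An empty spec leaves the
    fragment untouched.  With the default symmetric spec the left and right
    lobes remain exact mirror images.
    """
    del fluid  # resistances come from net.fluid; kept for interface parity
    if collaterals.empty:
        return net
    level_hosts = {"ca": _CA_HOSTS, "sectional": _SECTIONAL_HOSTS, "segmental": _SEGMENTAL_HOSTS}
    for level, hosts in level_hosts.items():
        tube = getattr(collaterals, level)
        if tube is None:
            continue
        for host in hosts:
            if host not in net.branches:
                raise NetworkError(f"collateral attachment: no such branch {host!r}")
            _split_branch(net, host, collaterals.attach_fractions)
        for edge_base, base_a, base_b in _COLLATERAL_EDGES[level]:
            for station in (1, 2):
                net.add_branch(
                    f"{edge_base}_{station}",
                    f"n_{base_a}_c{station}",
                    f"n_{base_b}_c{station}",
                    tube=tube,
                )
    net.meta["collateral_spec"] = collaterals
    return net


def build_artery(
    spec: ArteryTreeSpec = DEFAULT_TREE,
    collaterals: CollateralSpec = DEFAULT_COLLATERALS,
    fluid: FluidProperties = WATER,
) -> FlowNetwork:
    """Convenience: main tree plus collaterals."""
    return attach_collaterals(build_hepatic_tree(spec, fluid), collaterals)


@dataclass(frozen=True)
class BalloonSite:
    label: str
    branch: str
    distal_node: str


@dataclass(frozen=True)
class BalloonSiteMap:
    """Ordered microballoon sites 'a'..'i' along the PHA -> S7 path."""

    sites: tuple[BalloonSite, ...] = field(default_factory=tuple)

    def __getitem__(self, label: str) -> BalloonSite:
        for site in self.sites:
            if site.label == label:
                return site
        raise KeyError(f"unknown balloon site {label!r}; expected one of {SITE_LABELS}")

    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.sites)


_SITE_TABLE = (
    ("a", "b_rha_1", "n_rha_c1"),
    ("b", "b_rha_2", "n_rha_c2"),
    ("c", "b_rha_3", "n_rha"),
    ("d", "b_r_post_1", "n_r_post_c1"),
    ("e", "b_r_post_2", "n_r_post_c2"),
    ("f", "b_r_post_3", "n_r_post"),
    ("g", "b_S7_1", "n_S7_c1"),
    ("h", "b_S7_2", "n_S7_c2"),
    ("i", "b_S7_3", "o_S7"),
)


def map_balloon_sites(net: FlowNetwork) -> BalloonSiteMap:
    """Resolve the nine balloon sites on a default-topology artery.

    Requires the full default collateral layout (every site's sub-branch
    must exist); a non-default topology must supply an explicit site list in
    its configuration instead.
    """
    missing = [row[1] for row in _SITE_TABLE if row[1] not in net.branches]
    if missing:
        raise NetworkError(
            "balloon sites are defined only for the default collateral topology; "
            f"missing branches {missing} — provide an explicit site list in the config"
        )
    return BalloonSiteMap(tuple(BalloonSite(*row) for row in _SITE_TABLE))


_MIRROR_TOKENS = {
    "rha": "lha",
    "r_post": "l_lat",
    "r_ant": "l_med",
    "S7": "S2",
    "S6": "S3",
    "S5": "S4b",
    "S8": "S4a",
}
_MIRROR = {**_MIRROR_TOKENS, **{v: k for k, v in _MIRROR_TOKENS.items()}}
_MIRROR_RE = re.compile(
    "|".join(sorted(map(re.escape, _MIRROR), key=len, reverse=True))
)
#: Collateral edge ids whose endpoints swap under mirroring (id maps to itself
#: up to endpoint order); canonicalized after token replacement.
_CANONICAL = {
    "c_lha_rha": "c_ca",
    "c_l_lat_l_med": "c_l_lat_l_med",
    "c_l_med_l_lat": "c_l_lat_l_med",
    "c_r_post_r_ant": "c_r_post_r_ant",
    "c_r_ant_r_post": "c_r_post_r_ant",
    "c_S2_S3": "c_S2_S3",
    "c_S3_S2": "c_S2_S3",
    "c_S7_S6": "c_S7_S6",
    "c_S6_S7": "c_S7_S6",
}


def mirror_id(identifier: str) -> str:
    """Map a node/branch id to its left<->right mirror image.

    The PHA spine and the CA edges (which join the two sides) map to
    themselves; everything else swaps lobe.
    """
    out = _MIRROR_RE.sub(lambda m: _MIRROR[m.group(0)], identifier)
    for prefix, canonical in _CANONICAL.items():
        if out.startswith(prefix):
            return canonical + out[len(prefix):]
    return out


def describe_tree(net: FlowNetwork) -> str:
    """Indented text outline of the artery graph, inlet downward."""
    g = net.graph(include_blocked=True)
    lines: list[str] = []
    seen: set[str] = set()

    def visit(node: str, depth: int) -> None:
        seen.add(node)
        lines.append("  " * depth + node)
        for _, nbr, key in sorted(g.edges(node, keys=True), key=lambda e: e[2]):
            if nbr not in seen:
                lines.append("  " * depth + f"|- {key}")
                visit(nbr, depth + 1)
    root = "n_inlet" if "n_inlet" in net.nodes else sorted(net.nodes)[0]
    visit(root, 0)
    stray = sorted(set(net.nodes) - seen)
    for node in stray:
        lines.append(f"(disconnected) {node}")
    return "\n".join(lines)
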