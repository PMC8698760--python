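"""Assembly of the full bench circuit (pump, artery, stopcocks, reservoirs).

The bench rig drives water from a pump (an ideal constant-pressure source of
head ``H_pump``) through an inflow tube into the arterial phantom.  Each of
the eight segmental outlets passes through a three-way stopcock that routes
it either to the upper reservoir (free surface at ``z_UR``, modelling
normal-tissue pressure) or to the lower reservoir (``z_LR`` < ``z_UR``,
modelling tumour-tissue pressure).  Reservoir free-surface levels are held
constant by an overflow drain, so both reservoirs are ideal pressure sources
``rho*g*z``.  A cancer scenario is exactly a stopcock routing: tumour-bearing
segments drain low, normal segments drain high.

A microballoon occlusion marks one sub-branch of the artery as blocked and
records the node immediately distal to the balloon — the stump node whose
pressure is the balloon-occluded arterial stump pressure (BOASP) and where
the injectate enters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .artery import (
    DEFAULT_COLLATERALS,
    DEFAULT_TREE,
    SEGMENTS,
    ArteryTreeSpec,
    BalloonSiteMap,
    CollateralSpec,
    build_artery,
    map_balloon_sites,
)
from .hydraulics import (
    FluidProperties,
    FlowNetwork,
    NetworkError,
    TubeSpec,
    WATER,
    source_pressure,
)

__all__ = [
    "IVMConfig",
    "CancerScenario",
    "OcclusionState",
    "CASE_1",
    "CASE_2",
    "build_ivm_network",
    "set_stopcocks",
    "apply_occlusion",
    "outlet_tube_id",
    "reservoir_id",
]


@dataclass(frozen=True)
class IVMConfig:
    """Complete parameterization of the bench circuit.

    Heights are measured from the pump-reservoir datum (z = 0); the sized
    bench values are 40 mm x 1.2 mm outlet tubes to either reservoir,
    z_LR = 80 mm, z_UR = 110 mm and H_pump = 200 mm.  The inflow tube
    stands in for the celiac / common hepatic / proper hepatic access route
    (300 mm x 4 mm calibration default; not printed on the bench sheet).
    """

    fluid: FluidProperties = WATER
    tree: ArteryTreeSpec = DEFAULT_TREE
    collaterals: CollateralSpec = DEFAULT_COLLATERALS
    outlet_tube_lr: TubeSpec = TubeSpec(0.040, 0.0012)
    outlet_tube_ur: TubeSpec = TubeSpec(0.040, 0.0012)
    z_lr: float = 0.080
    z_ur: float = 0.110
    h_pump: float = 0.200
    inflow_tube: TubeSpec = TubeSpec(0.300, 0.0040)
    z_artery: float = 0.095  # informational only: the phantom lies horizontal

    def __post_init__(self) -> None:
        if not self.z_ur > self.z_lr:
            raise NetworkError(
                "upper reservoir free surface must sit above the lower one (z_ur > z_lr)"
            )
        if not self.h_pump > self.z_ur:
            raise NetworkError("pump head must exceed the upper reservoir level (h_pump > z_ur)")

    @property
    def pump_pressure(self) -> float:
        return source_pressure(self.fluid, self.h_pump)

    @property
    def urp(self) -> float:
        """Upper-reservoir pressure rho*g*z_UR (the in-model PGE threshold)."""
        return source_pressure(self.fluid, self.z_ur)

    @property
    def lrp(self) -> float:
        return source_pressure(self.fluid, self.z_lr)


@dataclass(frozen=True)
class CancerScenario:
    """Which Couinaud segments bear tumours (routed to the lower reservoir)."""

    tumor_segments: frozenset[str]

    def __init__(self, tumor_segments) -> None:
        segs = frozenset(tumor_segments)
        unknown = segs - set(SEGMENTS)
        if unknown:
            raise NetworkError(f"unknown segment label(s) {sorted(unknown)}; valid: {SEGMENTS}")
        object.__setattr__(self, "tumor_segments", segs)

    def is_tumor(self, segment: str) -> bool:
        return segment in self.tumor_segments

    def normal_segments(self) -> frozenset[str]:
        return frozenset(SEGMENTS) - self.tumor_segments


#: The two bench test scenarios: tumours in S7, and tumours in S5 + S7.
CASE_1 = CancerScenario({"S7"})
CASE_2 = CancerScenario({"S5", "S7"})


@dataclass(frozen=True)
class OcclusionState:
    """Microballoon position: a site label 'a'..'i', or None for no balloon."""

    site: str | None = None


def outlet_tube_id(segment: str) -> str:
    return f"t_{segment}"


def reservoir_id(segment: str) -> str:
    return f"res_{segment}"


def build_ivm_network(config: IVMConfig, scenario: CancerScenario) -> FlowNetwork:
    """Assemble the solvable circuit: pump -> inflow tube -> artery -> outlet
    tubes -> reservoir boundary nodes.

    Every artery node is interior; the pump and the per-outlet reservoir
    connections are the only boundary (fixed-pressure) nodes.
    """
    net = build_artery(config.tree, config.collaterals, config.fluid)
    net.add_boundary("src_pump", config.pump_pressure, elevation=0.0)
    net.add_branch("b_inflow", "src_pump", "n_inlet", tube=config.inflow_tube)
    for segment in SEGMENTS:
        # placeholder pressure/tube; set_stopcocks routes them per scenario
        net.add_boundary(reservoir_id(segment), config.urp, elevation=config.z_ur)
        net.add_branch(
            outlet_tube_id(segment),
            f"o_{segment}",
            reservoir_id(segment),
            tube=config.outlet_tube_ur,
        )
    net.meta["config"] = config
    net.meta["site_map"] = map_balloon_sites(net)
    return set_stopcocks(net, scenario)


def set_stopcocks(net: FlowNetwork, scenario: CancerScenario) -> FlowNetwork:
    """Route each outlet to the reservoir its scenario demands, in place.

    Idempotent; switching a scenario back restores the original network
    (boundary pressure and outlet-tube resistance per segment).
    """
    config: IVMConfig = net.meta["config"]
    for segment in SEGMENTS:
        tumor = scenario.is_tumor(segment)
        pressure = config.lrp if tumor else config.urp
        tube = config.outlet_tube_lr if tumor else config.outlet_tube_ur
        net.set_boundary_pressure(reservoir_id(segment), pressure)
        tube_id = outlet_tube_id(segment)
        old = net.remove_branch(tube_id)
        net.add_branch(tube_id, old.tail, old.head, tube=tube, blocked=old.blocked)
    net.meta["scenario"] = scenario
    return net


def apply_occlusion(net: FlowNetwork, state: OcclusionState) -> FlowNetwork:
    """Inflate the microballoon at ``state.site``, in place.

    Marks the site's sub-branch as blocked (the branch is excluded from the
    linear system, not given a large finite resistance) and records the
    distal stump node in ``net.meta['occlusion']``.  ``site=None`` clears
    any occlusion and leaves the hydraulics untouched.
    """
    previous = net.meta.pop("occlusion", None)
    if previous is not None:
        net.block(previous["branch"], False)
    if state.site is None:
        return net
    site_map: BalloonSiteMap = net.meta["site_map"]
    site = site_map[state.site]  # raises KeyError on an unknown label
    net.block(site.branch)
    net.meta["occlusion"] = {
        "site": site.label,
        "branch": site.branch,
        "distal_node": site.distal_node,
    }
    return net
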