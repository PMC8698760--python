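"""Design-parameter sizing checks for the bench circuit.

Seven parameters fix the hydraulic operating point of the rig: the outlet
tube dimensions to each reservoir (l_LR, d_LR, l_UR, d_UR), the two
reservoir free-surface heights (z_LR, z_UR) and the pump head (H_pump).
The sizing contract mirrors the conceptual design: at baseline every outlet
must be fed and tumour outlets preferentially so; a balloon distal to the
communicating-arcade stations (site 'c', catheter location 1) must develop
the pressure-gradient effect, while a balloon between the stations (site
'b', location 2) must not.  Each criterion is evaluated for both bench
cancer scenarios (tumours in S7; tumours in S5+S7), i.e. two cases times
three catheter states.

``check_design_criteria`` validates one parameter vector; ``search_sizing``
exhaustively evaluates a parameter grid and ranks the passing vectors by
how far the PGE-site stump pressure sits below the upper-reservoir
threshold (a larger margin means a more robust demonstration).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

from .analysis import assess_occlusion
from .hydraulics import NetworkError, TubeSpec, solve_flow
from .ivm import CASE_1, CASE_2, IVMConfig, build_ivm_network, outlet_tube_id
from .units import m3s_to_mlmin

__all__ = [
    "SizingParams",
    "SizingCriteria",
    "SizingResult",
    "check_design_criteria",
    "search_sizing",
]


@dataclass(frozen=True)
class SizingParams:
    """The seven sized quantities, SI units (m)."""

    l_lr: float = 0.040
    d_lr: float = 0.0012
    l_ur: float = 0.040
    d_ur: float = 0.0012
    z_lr: float = 0.080
    z_ur: float = 0.110
    h_pump: float = 0.200

    def as_config(self, base: IVMConfig | None = None) -> IVMConfig:
        base = base if base is not None else IVMConfig()
        return replace(
            base,
            outlet_tube_lr=TubeSpec(self.l_lr, self.d_lr),
            outlet_tube_ur=TubeSpec(self.l_ur, self.d_ur),
            z_lr=self.z_lr,
            z_ur=self.z_ur,
            h_pump=self.h_pump,
        )


@dataclass(frozen=True)
class SizingCriteria:
    """Pass/fail conditions evaluated per cancer scenario.

    ``flow_bounds_mlmin`` optionally constrains every baseline outlet flow
    into a (min, max) window in mL/min — e.g. (0, 500) keeps the total
    within the bench pump's delivery envelope.  Disabled by default because
    the conceptual design quantifies no flow magnitudes.
    """

    require_baseline_all_fed: bool = True
    require_tumor_preference: bool = True
    require_pge_at: str = "c"
    require_no_pge_at: str = "b"
    flow_bounds_mlmin: tuple[float, float] | None = None


@dataclass(frozen=True)
class SizingResult:
    params: SizingParams
    checks: dict[str, bool]
    diagnostics: dict[str, str] = field(default_factory=dict)
    pge_margin: float = float("nan")  # URP - BOASP at the PGE site (Pa), min over cases
    baseline_flows_mlmin: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return bool(self.checks) and all(self.checks.values())


def check_design_criteria(
    params: SizingParams,
    criteria: SizingCriteria = SizingCriteria(),
    base_config: IVMConfig | None = None,
) -> SizingResult:
    """Evaluate one parameter vector against the sizing criteria.

    An unsolvable or physically invalid configuration yields a failing
    result with a diagnostic message rather than an exception.
    """
    checks: dict[str, bool] = {}
    diagnostics: dict[str, str] = {}
    margins: list[float] = []
    baseline_flows: dict[str, dict[str, float]] = {}

    try:
        config = params.as_config(base_config)
    except NetworkError as exc:
        return SizingResult(params, {"valid_configuration": False}, {"valid_configuration": str(exc)})
    checks["valid_configuration"] = True

    for case_name, scenario in (("case1", CASE_1), ("case2", CASE_2)):
        try:
            network = build_ivm_network(config, scenario)
            baseline = solve_flow(network)
            flows = {
                seg: m3s_to_mlmin(baseline.flow(outlet_tube_id(seg)))
                for seg in sorted(scenario.tumor_segments | scenario.normal_segments())
            }
            baseline_flows[case_name] = flows
            if criteria.require_baseline_all_fed:
                checks[f"{case_name}:baseline_all_fed"] = all(q > 0.0 for q in flows.values())
            if criteria.require_tumor_preference:
                tumor_min = min(flows[s] for s in scenario.tumor_segments)
                normal_max = max(flows[s] for s in scenario.normal_segments())
                checks[f"{case_name}:tumor_preference"] = tumor_min > normal_max
            if criteria.flow_bounds_mlmin is not None:
                lo, hi = criteria.flow_bounds_mlmin
                checks[f"{case_name}:flow_bounds"] = all(lo <= q <= hi for q in flows.values())

            for label, want_pge, key in (
                (criteria.require_pge_at, True, "pge_at"),
                (criteria.require_no_pge_at, False, "no_pge_at"),
            ):
                assessment = assess_occlusion(
                    config, scenario, label, baseline=baseline, network=network
                )
                check_name = f"{case_name}:{key}_{label}"
                checks[check_name] = assessment.pge is want_pge
                if want_pge:
                    margins.append(config.urp - assessment.boasp)
        except NetworkError as exc:
            checks[f"{case_name}:solvable"] = False
            diagnostics[f"{case_name}:solvable"] = str(exc)

    margin = min(margins) if margins else float("nan")
    return SizingResult(params, checks, diagnostics, margin, baseline_flows)


def search_sizing(
    grid: dict[str, list[float]],
    criteria: SizingCriteria = SizingCriteria(),
    base_config: IVMConfig | None = None,
) -> list[SizingResult]:
    """Exhaustive, deterministic grid search over the seven parameters.

    ``grid`` maps parameter names (any subset of the ``SizingParams``
    fields; omitted ones keep their defaults) to candidate value lists.
    Returns the passing results sorted by decreasing PGE margin, ties broken
    by the parameter vector itself so the ordering is reproducible and
    independent of enumeration order.
    """
    if not grid:
        raise NetworkError("empty sizing grid")
    names = sorted(grid)
    unknown = set(names) - set(SizingParams.__dataclass_fields__)
    if unknown:
        raise NetworkError(f"unknown sizing parameter(s): {sorted(unknown)}")
    for name in names:
        if not grid[name]:
            raise NetworkError(f"empty candidate list for parameter {name!r}")
    passing = []
    for values in itertools.product(*(grid[name] for name in names)):
        params = replace(SizingParams(), **dict(zip(names, values)))
        result = check_design_criteria(params, criteria, base_config)
        if result.passed:
            passing.append(result)
    passing.sort(key=lambda r: (-r.pge_margin, tuple(sorted(vars(r.params).items()))))
    return passing
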