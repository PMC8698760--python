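import pytest

from btaceflow import (
    CASE_1,
    CASE_2,
    FlowNetwork,
    IVMConfig,
    WATER,
    build_ivm_network,
    solve_flow,
)


@pytest.fixture(scope="session")
def config() -> IVMConfig:
    return IVMConfig()


@pytest.fixture(scope="session")
def case1():
    return CASE_1


@pytest.fixture(scope="session")
def case2():
    return CASE_2


@pytest.fixture()
def ivm_case1(config, case1) -> FlowNetwork:
    return build_ivm_network(config, case1)


@pytest.fixture(scope="session")
def baseline_case1(config, case1):
    """Unoccluded Case-1 circuit and its solution (read-only)."""
    net = build_ivm_network(config, case1)
    return net, solve_flow(net)


@pytest.fixture()
def y_network() -> FlowNetwork:
    """Pump at 1960 Pa through R=1e8 to a junction, two identical R=2e8 legs to 0 Pa."""
    net = FlowNetwork(WATER)
    net.add_boundary("src", 1960.0)
    net.add_interior("junction")
    net.add_boundary("sink_a", 0.0)
    net.add_boundary("sink_b", 0.0)
    net.add_branch("feed", "src", "junction", resistance=1.0e8)
    net.add_branch("leg_a", "junction", "sink_a", resistance=2.0e8)
    net.add_branch("leg_b", "junction", "sink_b", resistance=2.0e8)
    return net
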