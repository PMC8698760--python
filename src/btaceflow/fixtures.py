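"""Seeded random network generation (test-oracle support).

Generates small, always-solvable resistive networks: a random spanning tree
guarantees connectivity, extra chords add cycles, resistances are
log-uniform over [1e7, 1e10] Pa*s/m**3 (the range the bench circuit spans)
and boundary pressures uniform over [0, 2000] Pa (pump-head scale).
"""

from __future__ import annotations

import numpy as np

from .hydraulics import FlowNetwork, NetworkError, WATER

__all__ = ["random_network_fixture"]


def random_network_fixture(
    seed: int,
    n_nodes: int = 10,
    n_boundary: int = 3,
    extra_edges: int | None = None,
) -> FlowNetwork:
    """Reproducible random solvable network with ``n_nodes`` nodes.

    The first ``n_boundary`` nodes are fixed-pressure boundaries; the rest
    are interior.  ``extra_edges`` chords (default: n_nodes // 2) are added
    on top of a random spanning tree, so parallel branches can occur.
    """
    if n_boundary < 1:
        raise NetworkError("need at least one boundary node for solvability")
    if n_nodes < 2 or n_boundary > n_nodes:
        raise NetworkError(f"infeasible sizes: n_nodes={n_nodes}, n_boundary={n_boundary}")
    rng = np.random.default_rng(seed)
    net = FlowNetwork(WATER)
    names = [f"v{i:02d}" for i in range(n_nodes)]
    for i, name in enumerate(names):
        if i < n_boundary:
            net.add_boundary(name, float(rng.uniform(0.0, 2000.0)))
        else:
            net.add_interior(name)

    def resistance() -> float:
        return float(10.0 ** rng.uniform(7.0, 10.0))

    order = rng.permutation(n_nodes)
    for k, idx in enumerate(order[1:], start=1):
        attach = order[int(rng.integers(0, k))]
        net.add_branch(f"e{len(net.branches):03d}", names[idx], names[attach], resistance=resistance())
    n_extra = extra_edges if extra_edges is not None else n_nodes // 2
    for _ in range(n_extra):
        i, j = rng.choice(n_nodes, size=2, replace=False)
        net.add_branch(f"e{len(net.branches):03d}", names[i], names[j], resistance=resistance())
    net.check_solvable()
    return net
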