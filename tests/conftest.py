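"""Shared fixtures: small hand-built networks and generator shortcuts."""

from __future__ import annotations

import numpy as np
import pytest

from tissuenet import GeneratorParams, RegulatoryNetwork, generate_expression, generate_reference


def make_network(roles: dict[str, str], arcs, label: str = "") -> RegulatoryNetwork:
    return RegulatoryNetwork(roles=dict(roles), arcs=set(arcs), label=label)


def random_network(
    seed: int, n: int = 20, n_arcs: int = 60, p_tf: float = 0.4, p_mirna: float = 0.2
) -> RegulatoryNetwork:
    """Small random role-valid network for oracle comparisons."""
    rng = np.random.default_rng(seed)
    roles = {}
    for i in range(n):
        u = rng.random()
        roles[f"g{i:02d}"] = "TF" if u < p_tf else "miRNA" if u < p_tf + p_mirna else "nonTF"
    roles["g00"] = "TF"  # at least one regulator
    regs = [g for g, r in roles.items() if r != "nonTF"]
    genes = list(roles)
    arcs = set()
    for _ in range(n_arcs * 3):
        if len(arcs) >= n_arcs:
            break
        a = regs[int(rng.integers(len(regs)))]
        b = genes[int(rng.integers(n))]
        if a != b:
            arcs.add((a, b))
    return RegulatoryNetwork(roles=roles, arcs=arcs, label=f"rand{seed}")


@pytest.fixture
def small_params() -> GeneratorParams:
    return GeneratorParams(seed=11, n_tf=40, n_mirna=20, n_nontf=140, n_tissues=4)


@pytest.fixture
def small_reference(small_params):
    return generate_reference(small_params)


@pytest.fixture
def small_profile(small_params, small_reference):
    return generate_expression(small_params, small_reference)
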