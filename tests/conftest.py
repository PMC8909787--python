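"""Shared fixtures: small planted datasets and a fitted hierarchy."""

import numpy as np
import pytest

from mosbm import (
    MultipartiteNetwork,
    PlantedModel,
    build_network,
    fit_blockmodel,
    generate_layers,
)


@pytest.fixture(scope="session")
def small_model() -> PlantedModel:
    """Two clusters, two branches of two topics each: fast but nontrivial."""
    return PlantedModel(
        n_samples=20,
        cluster_sizes=(10, 10),
        branches={"genes": (5, 5), "mirna": (4, 4)},
        hazard_multipliers=(1.0, 4.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_data(small_model):
    layers, truth = generate_layers(small_model, seed=11)
    return layers, truth


@pytest.fixture(scope="session")
def small_network(small_data) -> MultipartiteNetwork:
    layers, _ = small_data
    return build_network(layers)


@pytest.fixture(scope="session")
def small_fit(small_network):
    return fit_blockmodel(small_network, n_init=5, seed=11)


@pytest.fixture()
def toy_bipartite() -> MultipartiteNetwork:
    """Two disconnected (samples + features) islands: planted optimum obvious."""
    ids = ["s0", "s1", "s2", "s3", "g0", "g1", "g2", "g3"]
    kinds = ["sample"] * 4 + ["genes"] * 4
    edges = []
    for s in (0, 1):
        for g in (4, 5):
            edges.append((s, g, 6))
    for s in (2, 3):
        for g in (6, 7):
            edges.append((s, g, 6))
    return MultipartiteNetwork(ids, kinds, np.asarray(edges), ["genes"])


def random_tiny_network(rng: np.random.Generator) -> MultipartiteNetwork:
    """Random small two-branch star network for exhaustive-oracle checks."""
    n_s = int(rng.integers(3, 5))
    n_f1 = int(rng.integers(2, 4))
    n_f2 = int(rng.integers(2, 4))
    ids = (
        [f"s{i}" for i in range(n_s)]
        + [f"a{i}" for i in range(n_f1)]
        + [f"b{i}" for i in range(n_f2)]
    )
    kinds = ["sample"] * n_s + ["A"] * n_f1 + ["B"] * n_f2
    edges = []
    for f in range(n_f1):
        for s in range(n_s):
            m = int(rng.integers(0, 5))
            if m:
                edges.append((s, n_s + f, m))
    for f in range(n_f2):
        for s in range(n_s):
            m = int(rng.integers(0, 5))
            if m:
                edges.append((s, n_s + n_f1 + f, m))
    if not edges:  # regenerate on the (vanishingly unlikely) empty draw
        return random_tiny_network(rng)
    return MultipartiteNetwork(ids, kinds, np.asarray(edges), ["A", "B"])


def set_partitions(items: list):
    """All partitions of a list into nonempty blocks (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part
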