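import warnings

import numpy as np
import pytest

import hostscope as hs

warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
warnings.filterwarnings("ignore", message=".*stratum.*")


@pytest.fixture(scope="session")
def tiny_frame() -> hs.HostFrame:
    """Three-leaf frame with hand-checkable patristic distances."""
    newick = "((A:1,B:2):1,C:4);"
    lineage = "\n".join([
        "A\td__D;p__P;c__C;o__O;f__F;g__gAB;s__sA",
        "B\td__D;p__P;c__C;o__O;f__F;g__gAB;s__sB",
        "C\td__D;p__P;c__C;o__O;f__F2;g__gC;s__sC",
    ])
    return hs.HostFrame.from_strings(newick, lineage)


@pytest.fixture(scope="session")
def small_world() -> hs.World:
    return hs.simulate_world(hs.WorldConfig(
        n_genera=12, genomes_per_genus=(2, 3), n_viruses=100, seed=11))


@pytest.fixture(scope="session")
def fast_fit_config() -> hs.FitConfig:
    return hs.FitConfig(n_trials=1, combined_n_trials=4, n_target_pairs=800)


@pytest.fixture(scope="session")
def fitted_small(small_world, fast_fit_config):
    """Fitted predictor on the small world, with its virus splits."""
    train, cal, test = hs.split_viruses(small_world, seed=5)
    model = hs.HostPredictor(small_world.frame, small_world.hit_tables,
                             truth=small_world.truth,
                             phage_predictions=small_world.phage_predictions,
                             label_tallies=small_world.label_tallies,
                             config=fast_fit_config)
    results = model.fit(seed=5, train_viruses=train, calibration_viruses=cal)
    return small_world, results, (train, cal, test)


def random_edge_tree(rng: np.random.Generator, n_leaves: int):
    """Random rooted binary tree as (newick, edge list with lengths).

    Built directly as an edge list so tests can compute path sums with an
    independent graph traversal rather than through the tree library.
    """
    nodes = [f"L{i}" for i in range(n_leaves)]
    newicks = {n: n for n in nodes}
    edges = []
    counter = 0
    active = list(nodes)
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        b = active.pop(j)
        a = active.pop(i)
        parent = f"N{counter}"
        counter += 1
        la, lb = rng.uniform(0.1, 3.0, size=2).round(4)
        edges.append((parent, a, la))
        edges.append((parent, b, lb))
        newicks[parent] = f"({newicks[a]}:{la},{newicks[b]}:{lb})"
        active.append(parent)
    return newicks[active[0]] + ";", edges, nodes


def path_distance(edges, a: str, b: str) -> float:
    """Independent oracle: shortest weighted path over the undirected tree."""
    adj: dict[str, list[tuple[str, float]]] = {}
    for u, v, w in edges:
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    stack = [(a, 0.0, None)]
    while stack:
        node, dist, prev = stack.pop()
        if node == b:
            return dist
        for nxt, w in adj.get(node, []):
            if nxt != prev:
                stack.append((nxt, dist + w, node))
    raise AssertionError(f"no path {a}..{b}")
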