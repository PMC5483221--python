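import numpy as np
import pandas as pd
import pytest

from prxfam import (
    ExpressionMatrix,
    MotifLibrary,
    SynthConfig,
    gen_motif_library,
)


@pytest.fixture(scope="session")
def default_config() -> SynthConfig:
    return SynthConfig(seed=11)


@pytest.fixture(scope="session")
def library() -> MotifLibrary:
    return gen_motif_library(n_decoys=0, seed=0)


@pytest.fixture(scope="session")
def library_with_decoys() -> MotifLibrary:
    return gen_motif_library(n_decoys=10, seed=0)


@pytest.fixture()
def small_matrix() -> ExpressionMatrix:
    """3 genes x 6 samples, two tissues, hand-checkable values."""
    samples = ["leaf_r1", "leaf_r2", "root_r1", "root_r2", "seed_r1", "seed_r2"]
    values = pd.DataFrame(
        np.array(
            [
                [8.0, 10.0, 7.0, 9.0, 12.0, 12.0],
                [12.0, 12.0, 12.0, 12.0, 12.0, 12.0],
                [5.0, 5.2, 5.1, 5.3, 5.2, 5.0],
            ]
        ),
        index=["gA", "gB", "gC"],
        columns=samples,
    )
    tissues = pd.Series(
        ["leaf", "leaf", "root", "root", "seed", "seed"], index=samples
    )
    return ExpressionMatrix(values=values, tissue_map=tissues)


def random_additive_tree_distances(rng: np.random.Generator, n_taxa: int):
    """Random binary tree with positive branch lengths and its exact
    path-length (additive) distance matrix. Independent of the NJ code:
    distances come from all-pairs path sums on an explicit edge list.
    """
    # start from 3-leaf star, repeatedly attach a new leaf to a random edge
    next_internal = [0]
    edges: dict[tuple[str, str], float] = {}

    def new_internal() -> str:
        next_internal[0] += 1
        return f"I{next_internal[0]}"

    def bl() -> float:
        return float(rng.uniform(0.5, 3.0))

    center = new_internal()
    leaves = [f"T{i}" for i in range(n_taxa)]
    for leaf in leaves[:3]:
        edges[(center, leaf)] = bl()
    for leaf in leaves[3:]:
        u, v = list(edges)[int(rng.integers(len(edges)))]
        w = edges.pop((u, v))
        mid = new_internal()
        split = float(rng.uniform(0.2, 0.8)) * w
        edges[(u, mid)] = split
        edges[(mid, v)] = w - split
        edges[(mid, leaf)] = bl()
    # all-pairs shortest path lengths via simple BFS over the tree
    adj: dict[str, list[tuple[str, float]]] = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    def dist_from(src: str) -> dict[str, float]:
        out = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nxt, w in adj[node]:
                if nxt not in out:
                    out[nxt] = out[node] + w
                    stack.append(nxt)
        return out

    d = pd.DataFrame(0.0, index=leaves, columns=leaves)
    for a in leaves:
        da = dist_from(a)
        for b in leaves:
            d.loc[a, b] = da[b]
    return d
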