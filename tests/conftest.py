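"""Shared fixtures and oracle helpers for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from barcode_audit import BarcodeLibrary, BarcodeRecord, DistanceMatrix


def make_library(seq_by_id: dict[str, str], species: dict[str, str] | None = None,
                 genus: str = "Genus", family: str = "Family") -> BarcodeLibrary:
    """Build a library quickly; species defaults to one species per specimen."""
    records = []
    for sid, seq in seq_by_id.items():
        sp = species[sid] if species else f"Genus {sid}"
        records.append(BarcodeRecord(sid, sp, genus, family, seq))
    return BarcodeLibrary(records)


def dm_from_array(d, ids=None, min_overlap: int = 1) -> DistanceMatrix:
    """Wrap a plain symmetric array (proportions) as a DistanceMatrix."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    ids = list(ids) if ids is not None else [f"s{i:02d}" for i in range(n)]
    overlap = np.full((n, n), 658, dtype=np.int64)
    return DistanceMatrix(ids, d, overlap, min_overlap)


def naive_k2p(seq_a: str, seq_b: str, min_overlap: int) -> float:
    """Independent per-pair K2P reference (pure Python, from first principles)."""
    purines = {"A", "G"}
    L = ts = tv = 0
    for x, y in zip(seq_a, seq_b):
        if x in "ACGT" and y in "ACGT":
            L += 1
            if x != y:
                if (x in purines) == (y in purines):
                    ts += 1
                else:
                    tv += 1
    if L < min_overlap:
        return float("nan")
    P, Q = ts / L, tv / L
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return float("nan")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """Random unrooted binary tree with positive branch lengths.

    Returns (leaf names, pairwise path-length matrix).  Built by repeatedly
    subdividing a uniformly chosen edge and hanging the next leaf off the
    new internal node; path lengths are read off the explicit graph so the
    matrix is additive by construction.
    """
    import networkx as nx

    names = [f"L{i:02d}" for i in range(n_leaves)]
    g = nx.Graph()
    g.add_edge(names[0], names[1], weight=float(rng.uniform(0.05, 1.0)))
    next_internal = 0
    for k in range(2, n_leaves):
        u, v = list(g.edges())[int(rng.integers(g.number_of_edges()))]
        length = g.edges[u, v]["weight"]
        split = float(rng.uniform(0.1, 0.9)) * length
        w = f"I{next_internal}"
        next_internal += 1
        g.remove_edge(u, v)
        g.add_edge(u, w, weight=split)
        g.add_edge(w, v, weight=length - split)
        g.add_edge(w, names[k], weight=float(rng.uniform(0.05, 1.0)))
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    d = np.array([[dist[a][b] for b in names] for a in names])
    d = (d + d.T) / 2.0  # remove float asymmetry from per-direction sums
    np.fill_diagonal(d, 0.0)
    return names, d


@pytest.fixture(scope="session")
def presets():
    from barcode_audit import preset_scenarios

    return preset_scenarios()
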