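"""Neighbour-joining trees, bootstrap supports, monophyly audit and
single-linkage threshold clustering.

The tree work answers one question per species: do its specimens form an
exclusive clade on the K2P neighbour-joining tree?  Threshold clustering at
2.2% is the documented stand-in for database-assigned barcode OTUs: every
report produced from it states that it is a single-linkage proxy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from skbio.tree import TreeNode

from .distances import DEFAULT_MIN_OVERLAP, DistanceMatrix, _k2p_from_code_matrix
from .library import BarcodeLibrary

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# neighbour joining


def _drop_for_complete(m: DistanceMatrix) -> list[str]:
    """Greedily drop the ids with the most undefined cells until the
    remaining matrix is complete; returns the retained ids."""
    d = m.d.copy()
    keep = list(range(m.n))
    while True:
        sub = d[np.ix_(keep, keep)]
        undef = np.isnan(sub).sum(axis=1)
        if undef.max(initial=0) == 0:
            break
        worst = keep[int(np.argmax(undef))]
        keep.remove(worst)
        logger.warning(
            "dropping %s: %d undefined distances", m.ids[worst], int(undef.max())
        )
    return [m.ids[i] for i in keep]


def _pick_min_pair(q: np.ndarray, keys: list[str]) -> tuple[int, int]:
    """Index pair minimising Q; exact ties broken by the lexicographically
    smallest (sorted) key pair."""
    n = q.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = q[iu, ju]
    qmin = vals.min()
    best = None
    for k in np.flatnonzero(vals == qmin):
        i, j = int(iu[k]), int(ju[k])
        pair_key = tuple(sorted((keys[i], keys[j])))
        if best is None or pair_key < best[0]:
            best = (pair_key, i, j)
    return best[1], best[2]


def _pick_zero_pair(d: np.ndarray, keys: list[str]) -> tuple[int, int] | None:
    """First zero-distance pair under the lexicographic tie rule, if any.

    Nodes at distance <= 0 are joined before the Q criterion is consulted:
    for any additive completion of the matrix such nodes are co-located,
    so making them sisters is always consistent, whereas Q ties between
    identical rows would otherwise be resolved by float noise from the
    rest of the matrix.
    """
    n = d.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    hits = np.flatnonzero(d[iu, ju] <= 0.0)
    if hits.size == 0:
        return None
    best = None
    for k in hits:
        i, j = int(iu[k]), int(ju[k])
        pair_key = tuple(sorted((keys[i], keys[j])))
        if best is None or pair_key < best[0]:
            best = (pair_key, i, j)
    return best[1], best[2]


def nj_tree(m: DistanceMatrix, clamp_negative: bool = True) -> TreeNode:
    """Saitou–Nei neighbour joining, deterministic under the stated tie rules.

    Undefined cells are resolved by greedily dropping the offending
    specimens (with a warning).  Nodes at zero distance are joined first
    (see :func:`_pick_zero_pair`); otherwise the pair minimising Q is
    joined, exact ties broken lexicographically.  Negative limb estimates
    are clamped to zero with the deficit transferred to the sister limb so
    cherry path lengths are preserved where possible;
    ``clamp_negative=False`` keeps raw estimates.  Returns an unrooted
    tree as a trifurcating :class:`skbio.TreeNode`.
    """
    ids = _drop_for_complete(m)
    if len(ids) < 3:
        raise ValueError("neighbour joining needs at least 3 specimens")
    sub = m.submatrix(ids)
    d = sub.d.copy()
    nodes = [TreeNode(name=i) for i in ids]
    # tie-break key of an internal node = smallest leaf id beneath it
    keys = list(ids)

    while len(nodes) > 3:
        r = len(nodes)
        sums = d.sum(axis=1)
        zero = _pick_zero_pair(d, keys)
        if zero is not None:
            i, j = zero
        else:
            q = (r - 2) * d - sums[:, None] - sums[None, :]
            np.fill_diagonal(q, np.inf)
            i, j = _pick_min_pair(q, keys)
        li = d[i, j] / 2 + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        if clamp_negative:
            if li < 0:
                li, lj = 0.0, max(d[i, j], 0.0)
            elif lj < 0:
                li, lj = max(d[i, j], 0.0), 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = float(li)
        child_j.length = float(lj)
        new = TreeNode(children=[child_i, child_j])
        dn = (d[i, :] + d[j, :] - d[i, j]) / 2

        keep = [k for k in range(r) if k not in (i, j)]
        d_new = np.empty((r - 1, r - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = dn[keep]
        d_new[:-1, -1] = dn[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        nodes = [nodes[k] for k in keep] + [new]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    # final trifurcation
    (a, b, c) = nodes
    la = (d[0, 1] + d[0, 2] - d[1, 2]) / 2
    lb = (d[0, 1] + d[1, 2] - d[0, 2]) / 2
    lc = (d[0, 2] + d[1, 2] - d[0, 1]) / 2
    if clamp_negative:
        la, lb, lc = max(la, 0.0), max(lb, 0.0), max(lc, 0.0)
    a.length, b.length, c.length = float(la), float(lb), float(lc)
    return TreeNode(children=[a, b, c])


# ---------------------------------------------------------------------------
# bipartitions, monophyly


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, each canonicalised to
    the side *not* containing the alphabetically first leaf."""
    leaves = sorted(t.name for t in tree.tips())
    all_set = frozenset(leaves)
    ref = leaves[0]
    out: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_set - side
        if 2 <= len(side) <= len(all_set) - 2:
            out.add(side)
    return out


def _canonical(side: frozenset, all_set: frozenset, ref: str) -> frozenset:
    return all_set - side if ref in side else side


MONOPHYLETIC = "monophyletic"
NON_MONOPHYLETIC = "non-monophyletic"
TRIVIAL = "trivial"


def monophyly_report(tree: TreeNode, labels: dict[str, str]) -> pd.DataFrame:
    """Per-species monophyly status on an unrooted tree.

    A species with n>=2 specimens is monophyletic iff some edge bipartition
    isolates exactly its leaf set; singletons are 'trivial'.  For
    non-monophyletic species the other species found inside the smallest
    clade spanning its specimens are listed as conflicting.
    """
    leaves = sorted(t.name for t in tree.tips())
    unlabelled = [s for s in leaves if s not in labels]
    if unlabelled:
        raise ValueError(f"leaves without species label: {unlabelled}")
    all_set = frozenset(leaves)
    ref = leaves[0]
    biparts = bipartitions(tree)
    by_species: dict[str, set] = {}
    for leaf in leaves:
        by_species.setdefault(labels[leaf], set()).add(leaf)

    rows = []
    for species in sorted(by_species):
        members = frozenset(by_species[species])
        if len(members) == 1:
            rows.append({"species": species, "status": TRIVIAL, "conflicting": ""})
            continue
        if len(members) >= len(all_set) - 1:
            mono = True  # complement is empty or a single pendant leaf
        else:
            mono = _canonical(members, all_set, ref) in biparts
        conflicting = ""
        if not mono:
            lca = tree.lca([tree.find(m) for m in members])
            inside = {t.name for t in lca.tips()}
            conflicting = ";".join(
                sorted({labels[t] for t in inside} - {species})
            )
        rows.append(
            {
                "species": species,
                "status": MONOPHYLETIC if mono else NON_MONOPHYLETIC,
                "conflicting": conflicting,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_supports(
    lib: BarcodeLibrary,
    n_replicates: int = 1000,
    seed: int | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    clamp_negative: bool = True,
) -> tuple[TreeNode, dict[frozenset, float]]:
    """Non-parametric bootstrap supports for the K2P neighbour-joining tree.

    Alignment columns are resampled with replacement, the K2P matrix and NJ
    tree are recomputed per replicate, and support is the percentage of
    retained replicates whose tree contains each original internal
    bipartition.  One root seed spawns independent per-replicate streams.
    Returns the original tree with supports attached as internal node
    names, plus the support map.
    """
    if seed is None:
        raise ValueError("bootstrap requires an explicit seed")
    from .distances import pairwise_matrix

    m = pairwise_matrix(lib, min_overlap)
    tree = nj_tree(m, clamp_negative)
    ids = sorted(t.name for t in tree.tips())
    sub = lib.subset(ids)
    order = sub.ids
    codes = sub.encoded()
    n_cols = codes.shape[1]

    orig = bipartitions(tree)
    counts = {bp: 0 for bp in orig}
    kept = 0
    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    for stream in streams:
        rng = np.random.default_rng(stream)
        cols = rng.integers(0, n_cols, n_cols)
        d, overlap = _k2p_from_code_matrix(codes[:, cols], min_overlap)
        if np.isnan(d).any():
            logger.info("bootstrap replicate dropped: undefined distances")
            continue
        rep_tree = nj_tree(
            DistanceMatrix(order, d, overlap, min_overlap), clamp_negative
        )
        rep_biparts = bipartitions(rep_tree)
        kept += 1
        for bp in counts:
            if bp in rep_biparts:
                counts[bp] += 1
    if kept == 0:
        raise RuntimeError("all bootstrap replicates were dropped")
    supports = {bp: 100.0 * c / kept for bp, c in counts.items()}

    all_set = frozenset(ids)
    ref = min(ids)
    for node in tree.non_tips(include_self=False):
        side = _canonical(
            frozenset(t.name for t in node.tips()), all_set, ref
        )
        if side in supports:
            node.name = f"{supports[side]:.0f}"
    return tree, supports


# ---------------------------------------------------------------------------
# threshold clustering (single-linkage OTU proxy)


@dataclass
class ClusterAssignment:
    """Single-linkage clusters of the sub-threshold distance graph.

    This is a documented proxy for database-assigned barcode OTUs ("BINs"):
    specimens joined whenever some chain of pairs stays below the
    threshold.
    """

    assignments: dict[str, str]
    threshold: float
    note: str = field(
        default="single-linkage proxy for barcode OTUs (not the original RESL/BIN algorithm)"
    )

    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, lab in self.assignments.items():
            out.setdefault(lab, []).append(sid)
        return out

    def n_clusters_of(self, specimen_ids) -> int:
        return len({self.assignments[s] for s in specimen_ids})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s, c) for s, c in self.assignments.items()],
            columns=["specimen_id", "cluster"],
        )


def threshold_clusters(m: DistanceMatrix, threshold: float = 2.2) -> ClusterAssignment:
    """Connected components of the graph joining pairs with d < threshold (%).

    Undefined pairs contribute no edge.  Cluster labels are assigned in
    order of each cluster's first specimen in the input ordering.
    """
    t = threshold / 100.0
    adj = np.nan_to_num(m.d, nan=np.inf) < t
    np.fill_diagonal(adj, True)
    _, comp = connected_components(csr_matrix(adj), directed=False)
    label_of_comp: dict[int, str] = {}
    assignments: dict[str, str] = {}
    for idx, sid in enumerate(m.ids):
        c = comp[idx]
        if c not in label_of_comp:
            label_of_comp[c] = f"C{len(label_of_comp) + 1:04d}"
        assignments[sid] = label_of_comp[c]
    return ClusterAssignment(assignments, threshold)
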