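"""Statistical parsimony haplotype networks.

Specimens are collapsed into haplotypes, haplotype pairs are connected in
order of increasing mutational difference — inserting one inferred
("missing") node per intermediate step — and connections are refused
beyond a *connection limit*: the largest number of steps for which a
parsimonious (homoplasy-free) connection is still probable at the chosen
confidence (95% by default).  Haplotype pairs that cannot be connected
within the limit end up in separate subnetworks; a deep split inside a
nominal species therefore shows up as two unconnected subnetworks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._seq import BASES, IUPAC_SETS
from .library import BarcodeLibrary

# character -> set of compatible bases; gap treated like N (missing data)
_CHARSET = {c: set(s) for c, s in IUPAC_SETS.items()}
_CHARSET["-"] = set(BASES)


@dataclass
class Haplotype:
    haplotype_id: str
    sequence: str
    members: list[str]
    species_counts: dict[str, int]

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeTable:
    """Specimens collapsed to haplotypes, numbered h1, h2, ... by
    descending frequency then first occurrence."""

    haplotypes: list[Haplotype]
    alignment_length: int

    def __len__(self) -> int:
        return len(self.haplotypes)

    def get(self, haplotype_id: str) -> Haplotype:
        for h in self.haplotypes:
            if h.haplotype_id == haplotype_id:
                return h
        raise KeyError(haplotype_id)

    def members_union(self) -> set[str]:
        out: set[str] = set()
        for h in self.haplotypes:
            out.update(h.members)
        return out

    def mutational_difference(self, id_a: str, id_b: str) -> int:
        """Number of differing sites where both representatives are
        unambiguous bases (gaps/ambiguities skipped, matching pairwise
        deletion)."""
        a = self.get(id_a).sequence
        b = self.get(id_b).sequence
        return sum(
            1
            for x, y in zip(a, b)
            if x in BASES and y in BASES and x != y
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "haplotype_id": h.haplotype_id,
                    "n_specimens": h.n,
                    "members": ";".join(h.members),
                    "species_counts": ";".join(
                        f"{s}:{c}" for s, c in sorted(h.species_counts.items())
                    ),
                }
                for h in self.haplotypes
            ]
        )


def _compatible(seq_a: str, seq_b: str) -> bool:
    for x, y in zip(seq_a, seq_b):
        if x in BASES and y in BASES:
            if x != y:
                return False
        elif not (_CHARSET[x] & _CHARSET[y]):
            return False
    return True


def _refine(rep: str, member: str) -> str:
    # keep the more specific character at each position
    out = []
    for x, y in zip(rep, member):
        if x in BASES:
            out.append(x)
        elif y in BASES or len(_CHARSET[y]) < len(_CHARSET[x]):
            out.append(y)
        else:
            out.append(x)
    return "".join(out)


def collapse_haplotypes(lib: BarcodeLibrary, strict: bool = False) -> HaplotypeTable:
    """Collapse specimens into haplotypes.

    By default two sequences merge when they agree at every site where both
    are unambiguous ("ambiguity-compatible": an N is compatible with any
    base), which tolerates the unequal read quality typical of barcode
    libraries.  ``strict=True`` requires byte-identical sequences.
    Specimens are processed in input order and join the first compatible
    haplotype; the representative is refined with the member's unambiguous
    bases as it grows.
    """
    groups: list[dict] = []  # {"rep": str, "members": [...], "species": {...}}
    for rec in lib.records:
        placed = False
        for g in groups:
            if (rec.sequence == g["rep"]) if strict else _compatible(
                rec.sequence, g["rep"]
            ):
                g["members"].append(rec.specimen_id)
                g["species"][rec.species] = g["species"].get(rec.species, 0) + 1
                if not strict:
                    g["rep"] = _refine(g["rep"], rec.sequence)
                placed = True
                break
        if not placed:
            groups.append(
                {
                    "rep": rec.sequence,
                    "members": [rec.specimen_id],
                    "species": {rec.species: 1},
                    "first": len(groups),
                }
            )
    order = sorted(
        range(len(groups)), key=lambda k: (-len(groups[k]["members"]), k)
    )
    haplotypes = [
        Haplotype(
            haplotype_id=f"h{rank + 1}",
            sequence=groups[k]["rep"],
            members=list(groups[k]["members"]),
            species_counts=dict(groups[k]["species"]),
        )
        for rank, k in enumerate(order)
    ]
    return HaplotypeTable(haplotypes, lib.alignment_length)


# ---------------------------------------------------------------------------
# parsimony probability / connection limit


def parsimony_probability(n_steps: int, seq_length: int) -> float:
    """Probability that ``n_steps`` observed differences over ``seq_length``
    sites reflect a fully parsimonious (homoplasy-free) connection.

    Model: substitutions hit sites as independent Poisson events with a
    common per-site rate; under a Jukes–Cantor-style state walk a site with
    ``k`` hits shows a difference with probability ``3/4 (1 - (-1/3)^k)``.
    The rate is fitted so the expected number of visible differences equals
    the observed count, and the connection is parsimonious when every
    differing site was hit exactly once and every identical site not at
    all.  The probability is monotone decreasing in the step count and
    increasing in sequence length.
    """
    if n_steps < 0 or seq_length < 1:
        raise ValueError("need n_steps >= 0 and seq_length >= 1")
    if n_steps == 0:
        return 1.0
    m = float(seq_length)
    j = float(n_steps)
    if j >= 0.75 * m:
        return 0.0

    def expected_diff(lam: float) -> float:
        return m * 0.75 * (1.0 - math.exp(-4.0 * lam / 3.0)) - j

    lam = brentq(expected_diff, 1e-12, 50.0)
    p_diff = 0.75 * (1.0 - math.exp(-4.0 * lam / 3.0))
    p_one_hit = lam * math.exp(-lam)
    p_same = 0.25 + 0.75 * math.exp(-4.0 * lam / 3.0)
    p_zero_hit = math.exp(-lam)
    log_p = j * (math.log(p_one_hit) - math.log(p_diff)) + (m - j) * (
        math.log(p_zero_hit) - math.log(p_same)
    )
    return math.exp(log_p)


def connection_limit(seq_length: int, confidence: float = 0.95) -> int:
    """Largest number of mutational steps whose parsimony probability is
    still >= ``confidence``; 0 if even a single step fails the bound."""
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    limit = 0
    j = 1
    while j < seq_length:
        if parsimony_probability(j, seq_length) >= confidence:
            limit = j
            j += 1
        else:
            break
    return limit


# ---------------------------------------------------------------------------
# network assembly


@dataclass
class ParsimonyNetwork:
    """Haplotypes plus inferred intermediates, every edge one mutation.

    ``subnetworks`` lists the real haplotype ids of each connected
    component; ``equal_length_alternatives`` records same-length
    connections that would create reticulations (reported, not drawn, to
    keep the canonical output a forest of unique paths).
    """

    graph: nx.Graph
    connection_limit: int
    subnetworks: list[list[str]]
    equal_length_alternatives: list[tuple[str, str, int]] = field(
        default_factory=list
    )

    def n_subnetworks(self) -> int:
        return len(self.subnetworks)

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            {"node_1": u, "node_2": v}
            for u, v in sorted(self.graph.edges())
        ]
        return pd.DataFrame(rows, columns=["node_1", "node_2"])

    def to_node_frame(self) -> pd.DataFrame:
        rows = []
        for node, attrs in sorted(self.graph.nodes(data=True)):
            rows.append(
                {
                    "node": node,
                    "kind": attrs.get("kind", "inferred"),
                    "n_specimens": attrs.get("n", 0),
                    "species_counts": attrs.get("species", ""),
                }
            )
        return pd.DataFrame(rows, columns=["node", "kind", "n_specimens", "species_counts"])


def _hap_rank(hid: str) -> int:
    return int(hid[1:])


def build_network(table: HaplotypeTable, limit: int) -> ParsimonyNetwork:
    """Assemble the statistical parsimony network at a given step limit.

    Haplotype pairs are processed in order of increasing mutational
    difference (ties: higher combined specimen count first, then haplotype
    numbering).  A pair in different components is connected through
    ``difference - 1`` inferred intermediate nodes when within the limit; a
    pair already connected gets a direct path only if it is strictly
    shorter than the current graph path (equal-length alternatives are
    recorded, not added).
    """
    g = nx.Graph()
    for h in table.haplotypes:
        g.add_node(
            h.haplotype_id,
            kind="real",
            n=h.n,
            species=";".join(f"{s}:{c}" for s, c in sorted(h.species_counts.items())),
        )
    pairs = []
    ids = [h.haplotype_id for h in table.haplotypes]
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            diff = table.mutational_difference(a, b)
            freq = table.get(a).n + table.get(b).n
            pairs.append((diff, -freq, _hap_rank(a), _hap_rank(b), a, b))
    pairs.sort()

    inferred_counter = 0
    alternatives: list[tuple[str, str, int]] = []
    for diff, _negfreq, _ra, _rb, a, b in pairs:
        if diff == 0 or diff > limit:
            continue
        connected = nx.has_path(g, a, b)
        if connected:
            current = nx.shortest_path_length(g, a, b)
            if diff > current:
                continue
            if diff == current:
                alternatives.append((a, b, diff))
                continue
        # add a path of `diff` single-mutation edges
        prev = a
        for _ in range(diff - 1):
            inferred_counter += 1
            node = f"m{inferred_counter}"
            g.add_node(node, kind="inferred", n=0, species="")
            g.add_edge(prev, node)
            prev = node
        g.add_edge(prev, b)

    comps = []
    for comp in nx.connected_components(g):
        real = sorted((h for h in comp if g.nodes[h]["kind"] == "real"), key=_hap_rank)
        comps.append(real)
    comps.sort(key=lambda real: (-sum(table.get(h).n for h in real), _hap_rank(real[0])))
    return ParsimonyNetwork(g, limit, comps, alternatives)


def subnetwork_gap(net: ParsimonyNetwork, table: HaplotypeTable) -> pd.DataFrame:
    """Minimum mutational steps between each pair of subnetworks.

    Empty when the network is connected; the gap of a deep split equals the
    planted/observed step count between the closest haplotypes of the two
    subnetworks.
    """
    rows = []
    subs = net.subnetworks
    for i in range(len(subs)):
        for j in range(i + 1, len(subs)):
            steps = min(
                table.mutational_difference(a, b)
                for a in subs[i]
                for b in subs[j]
            )
            rows.append({"subnetwork_1": i + 1, "subnetwork_2": j + 1, "min_steps": steps})
    return pd.DataFrame(rows, columns=["subnetwork_1", "subnetwork_2", "min_steps"])
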