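"""Pairwise Kimura 2-parameter distances and the species-level summaries.

The K2P model corrects observed differences for multiple substitutions
while distinguishing transitions (A<->G, C<->T) from transversions.  With
``P`` the transition and ``Q`` the transversion proportion over the sites
retained after pairwise deletion,

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Sites where either sequence carries a gap, an N or any partial ambiguity
code are deleted pairwise.  A pair is *undefined* (NaN) when fewer than
``min_overlap`` sites remain or when the logarithm's argument is not
positive (saturation); undefined pairs are skipped, never clamped.

Distances are stored as proportions; report tables convert to percent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import encode
from .library import BarcodeLibrary

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 300

# reasons recorded for undefined cells
UNDEF_OVERLAP = "overlap"
UNDEF_SATURATED = "saturated"


@dataclass
class DistanceMatrix:
    """Symmetric K2P distance matrix with per-pair overlap site counts.

    ``d`` holds proportions with NaN for undefined pairs; ``overlap`` holds
    the number of sites retained after pairwise deletion.
    """

    ids: list[str]
    d: np.ndarray
    overlap: np.ndarray
    min_overlap: int = DEFAULT_MIN_OVERLAP

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.overlap.shape != (n, n):
            raise ValueError("matrix shape does not match id list")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, specimen_id: str) -> int:
        return self.ids.index(specimen_id)

    def undefined_pairs(self) -> list[tuple[str, str, str]]:
        """(id1, id2, reason) for every undefined off-diagonal pair."""
        out = []
        iu, ju = np.triu_indices(self.n, k=1)
        for i, j in zip(iu, ju):
            if np.isnan(self.d[i, j]):
                reason = (
                    UNDEF_OVERLAP
                    if self.overlap[i, j] < self.min_overlap
                    else UNDEF_SATURATED
                )
                out.append((self.ids[i], self.ids[j], reason))
        return out

    def submatrix(self, specimen_ids) -> "DistanceMatrix":
        idx = [self.ids.index(s) for s in specimen_ids]
        return DistanceMatrix(
            [self.ids[i] for i in idx],
            self.d[np.ix_(idx, idx)].copy(),
            self.overlap[np.ix_(idx, idx)].copy(),
            self.min_overlap,
        )

    def to_square_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def to_long_frame(self) -> pd.DataFrame:
        iu, ju = np.triu_indices(self.n, k=1)
        return pd.DataFrame(
            {
                "id1": [self.ids[i] for i in iu],
                "id2": [self.ids[j] for j in ju],
                "distance": self.d[iu, ju],
                "overlap": self.overlap[iu, ju],
            }
        )


def _k2p_from_counts(L: int, ts: int, tv: int, min_overlap: int) -> float:
    if L < min_overlap:
        return np.nan
    P = ts / L
    Q = tv / L
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return np.nan
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def k2p_distance(
    seq_a: str, seq_b: str, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> float:
    """K2P distance between two aligned sequences (NaN when undefined)."""
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"aligned sequences differ in length ({len(seq_a)} vs {len(seq_b)})"
        )
    a = encode(seq_a)
    b = encode(seq_b)
    both = (a < 4) & (b < 4)
    L = int(both.sum())
    if L == 0:
        return np.nan
    diff = both & (a != b)
    # transitions: both purines (0,2) or both pyrimidines (1,3) => same parity
    purine_a = (a == 0) | (a == 2)
    purine_b = (b == 0) | (b == 2)
    ts = int((diff & (purine_a == purine_b)).sum())
    tv = int(diff.sum()) - ts
    return _k2p_from_counts(L, ts, tv, min_overlap)


def _k2p_from_code_matrix(
    codes: np.ndarray, min_overlap: int
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs K2P on an ``(n, L)`` uint8 code matrix.

    Returns ``(d, overlap)`` with NaN marking undefined pairs.  Pattern
    counts are accumulated with float32 matrix products (exact for counts
    below 2**24, far above any alignment length here).
    """
    valid = (codes < 4).astype(np.float32)
    onehot = [(codes == c).astype(np.float32) for c in range(4)]

    overlap = valid @ valid.T
    match = sum(h @ h.T for h in onehot)
    # transition pairs: A/G in either orientation plus C/T in either orientation
    ts = (
        onehot[0] @ onehot[2].T
        + onehot[2] @ onehot[0].T
        + onehot[1] @ onehot[3].T
        + onehot[3] @ onehot[1].T
    )
    mismatch = overlap - match
    tv = mismatch - ts

    L = overlap.astype(np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(L > 0, ts / np.maximum(L, 1), 0.0)
        Q = np.where(L > 0, tv / np.maximum(L, 1), 0.0)
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    d = np.asarray(d, dtype=np.float64)
    d[(w1 <= 0) | (w2 <= 0) | (L < min_overlap)] = np.nan
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0 + 0.0  # exact symmetry; +0.0 normalises -0.0
    return d, L


def pairwise_matrix(
    lib: BarcodeLibrary, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> DistanceMatrix:
    """All-pairs K2P distance matrix for a library (vectorised)."""
    if len(lib) < 2:
        raise ValueError("distance analysis needs at least 2 records")
    d, L = _k2p_from_code_matrix(lib.encoded(), min_overlap)
    m = DistanceMatrix(lib.ids, d, L, min_overlap)
    n_undef = len(m.undefined_pairs())
    if n_undef:
        logger.info("pairwise_matrix: %d undefined pairs skipped", n_undef)
    return m


def species_summaries(m: DistanceMatrix, labels: dict[str, str]) -> pd.DataFrame:
    """Per-species distance summary (percent scale).

    Columns: species, n_specimens, mean_intra, max_intra, nn_species,
    nn_distance.  Intraspecific statistics are NaN for singletons and for
    species whose intraspecific pairs are all undefined (the latter are
    logged).  The nearest neighbour is the species attaining the minimum
    defined interspecific distance.
    """
    unlabelled = [s for s in m.ids if s not in labels]
    if unlabelled:
        raise ValueError(f"ids without species label: {unlabelled}")
    sp = np.array([labels[s] for s in m.ids])
    species = sorted(set(sp))
    rows = []
    for s in species:
        mask = sp == s
        n = int(mask.sum())
        block = m.d[np.ix_(mask, mask)]
        iu, ju = np.triu_indices(n, k=1)
        intra = block[iu, ju]
        intra = intra[~np.isnan(intra)]
        if n >= 2 and intra.size == 0:
            logger.warning("species %s: all intraspecific pairs undefined", s)
        mean_intra = float(np.mean(intra)) * 100 if intra.size else np.nan
        max_intra = float(np.max(intra)) * 100 if intra.size else np.nan

        inter = m.d[np.ix_(mask, ~mask)]
        other = sp[~mask]
        nn_species, nn_distance = "", np.nan
        if inter.size:
            col_min = np.full(inter.shape[1], np.nan)
            finite = ~np.isnan(inter)
            has = finite.any(axis=0)
            col_min[has] = np.nanmin(np.where(finite, inter, np.inf), axis=0)[has]
            if has.any():
                best = np.nanmin(col_min)
                # among species attaining the minimum, tie-break by name
                cands = sorted(set(other[col_min == best]))
                nn_species = cands[0]
                nn_distance = float(best) * 100
        rows.append(
            {
                "species": s,
                "n_specimens": n,
                "mean_intra": mean_intra,
                "max_intra": max_intra,
                "nn_species": nn_species,
                "nn_distance": nn_distance,
            }
        )
    return pd.DataFrame(rows)


def _min_interspecific_table(m: DistanceMatrix, labels: dict[str, str]) -> pd.DataFrame:
    sp = np.array([labels[s] for s in m.ids])
    species = sorted(set(sp))
    rows = []
    for a_i, s1 in enumerate(species):
        for s2 in species[a_i + 1 :]:
            block = m.d[np.ix_(sp == s1, sp == s2)]
            finite = block[~np.isnan(block)]
            if finite.size:
                rows.append((s1, s2, float(finite.min()) * 100))
    return pd.DataFrame(rows, columns=["species_1", "species_2", "min_distance"])


def low_divergence_pairs(
    m: DistanceMatrix, labels: dict[str, str], threshold: float = 2.2
) -> pd.DataFrame:
    """Species pairs whose minimum interspecific K2P distance is < threshold (%).

    Ascending by distance, ties broken alphabetically; the analogue of the
    "species pairs with low nucleotide variability" table.
    """
    if len(set(labels[s] for s in m.ids)) < 2:
        raise ValueError("low_divergence_pairs needs at least 2 species")
    tab = _min_interspecific_table(m, labels)
    tab = tab[tab["min_distance"] < threshold]
    return tab.sort_values(
        ["min_distance", "species_1", "species_2"], kind="mergesort"
    ).reset_index(drop=True)


def deep_divergence_species(
    summaries: pd.DataFrame, threshold: float = 2.2
) -> pd.DataFrame:
    """Species with maximum intraspecific distance (MPD) above threshold (%).

    Sorted ascending by MPD, mirroring the deep-divergence tables.
    """
    tab = summaries[summaries["max_intra"] > threshold]
    cols = ["species", "n_specimens", "mean_intra", "max_intra"]
    return tab[cols].sort_values(
        ["max_intra", "species"], kind="mergesort"
    ).reset_index(drop=True)


def write_square_tsv(m: DistanceMatrix, path) -> None:
    m.to_square_frame().to_csv(path, sep="\t", index_label="specimen_id")


def write_long_tsv(m: DistanceMatrix, path) -> None:
    m.to_long_frame().to_csv(path, sep="\t", index=False)
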