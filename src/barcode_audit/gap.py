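"""Recursive barcode-gap partitioning and the two-parameter sweep.

The partitioner sorts all pairwise K2P distances, looks for the first
*significant* gap above a prior ceiling on intraspecific divergence, splits
the data at that gap into single-linkage groups, and recurses within each
group until no significant gap remains.  A gap between consecutive sorted
distances is significant when its width exceeds ``X`` times the local
average gap width over a sliding rank window (the candidate gap itself is
excluded from its own local scale).

The sweep re-runs the partitioner over a grid of the two parameters — the
intraspecific prior ``P`` (geometric grid, default 0.001..0.1 in 100
steps) and the relative gap width ``X`` (linear grid, default 0.1..10 in
100 steps) — and classifies each species per cell as *lumped* (all its
specimens in one group) or *split*.  The per-species intraspecific
divergence estimator ``P`` is the smallest grid prior at which the species
is lumped at a fixed gap width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix

FLAG_TOO_FEW = "too_few"


@dataclass
class Partition:
    """Group assignment produced by one (prior, gap width) setting."""

    groups: dict[str, int]
    prior: float
    gap_width: float
    depth: int
    flags: tuple[str, ...] = ()

    @property
    def n_groups(self) -> int:
        return len(set(self.groups.values()))

    def group_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for sid, g in self.groups.items():
            out.setdefault(g, []).append(sid)
        return out

    def is_lumped(self, specimen_ids) -> bool:
        return len({self.groups[s] for s in specimen_ids}) == 1


def _window_size(n_distances: int, window: int | None) -> int:
    if window is not None:
        return window
    return max(10, math.ceil(0.05 * n_distances))


class _GapSearcher:
    """Pre-computed sorted distances, gaps and local scales for one group."""

    def __init__(self, dsorted: np.ndarray, window: int | None = None):
        self.dsorted = dsorted
        self.gaps = np.diff(dsorted)
        n = len(self.gaps)
        w = _window_size(len(dsorted), window)
        if n == 0:
            self.scales = np.empty(0)
            return
        half = w // 2
        lo = np.maximum(np.arange(n) - half, 0)
        hi = np.minimum(np.arange(n) + half, n - 1)
        csum = np.concatenate([[0.0], np.cumsum(self.gaps)])
        win_sum = csum[hi + 1] - csum[lo]
        win_cnt = hi - lo + 1
        # exclude the candidate gap itself from its local scale
        with np.errstate(invalid="ignore", divide="ignore"):
            self.scales = np.where(
                win_cnt > 1, (win_sum - self.gaps) / (win_cnt - 1), 0.0
            )

    def first_gap_threshold(self, prior: float, gap_width: float) -> float | None:
        """Distance value at the left edge of the first significant gap, or
        None.  The partition links pairs with d <= that value."""
        if len(self.gaps) == 0:
            return None
        significant = (
            (self.gaps > 0)
            & (self.dsorted[1:] >= prior)
            & (self.gaps > gap_width * self.scales)
        )
        idx = np.flatnonzero(significant)
        if idx.size == 0:
            return None
        return float(self.dsorted[idx[0]])


def _components(sub: np.ndarray, threshold: float) -> list[np.ndarray]:
    adj = sub <= threshold
    np.fill_diagonal(adj, True)
    n_comp, lab = connected_components(csr_matrix(adj), directed=False)
    return [np.flatnonzero(lab == c) for c in range(n_comp)]


class _RecursivePartitioner:
    """Shared caches for repeated partitioning of one distance matrix."""

    def __init__(self, m: DistanceMatrix, window: int | None = None):
        if np.isnan(m.d).any():
            raise ValueError(
                "gap partitioning requires defined distances for all pairs; "
                "drop or repair undefined pairs first"
            )
        self.m = m
        self.window = window
        self._searchers: dict[tuple, _GapSearcher] = {}
        self._components: dict[tuple, tuple] = {}

    def _searcher(self, idx: tuple) -> _GapSearcher:
        s = self._searchers.get(idx)
        if s is None:
            ind = np.array(idx)
            sub = self.m.d[np.ix_(ind, ind)]
            iu, ju = np.triu_indices(len(ind), k=1)
            s = _GapSearcher(np.sort(sub[iu, ju]), self.window)
            self._searchers[idx] = s
        return s

    def _split_once(self, idx: tuple, threshold: float) -> tuple:
        key = (idx, threshold)
        comps = self._components.get(key)
        if comps is None:
            ind = np.array(idx)
            sub = self.m.d[np.ix_(ind, ind)]
            comps = tuple(
                tuple(ind[c]) for c in _components(sub, threshold)
            )
            self._components[key] = comps
        return comps

    def partition(self, prior: float, gap_width: float) -> Partition:
        n = self.m.n
        flags: tuple[str, ...] = ()
        if n < 3:
            flags = (FLAG_TOO_FEW,)
            groups = {sid: 0 for sid in self.m.ids}
            return Partition(groups, prior, gap_width, 0, flags)

        max_depth = 0
        final: list[tuple] = []

        def recurse(idx: tuple, depth: int) -> None:
            nonlocal max_depth
            max_depth = max(max_depth, depth)
            if len(idx) < 3:
                final.append(idx)
                return
            thr = self._searcher(idx).first_gap_threshold(prior, gap_width)
            if thr is None:
                final.append(idx)
                return
            comps = self._split_once(idx, thr)
            if len(comps) == 1:
                final.append(idx)
                return
            for c in comps:
                recurse(c, depth + 1)

        recurse(tuple(range(n)), 0)
        # number groups by first specimen appearance
        final.sort(key=lambda c: min(c))
        groups: dict[str, int] = {}
        for g, comp in enumerate(final):
            for i in comp:
                groups[self.m.ids[i]] = g
        return Partition(groups, prior, gap_width, max_depth, flags)


def abgd_partition(
    m: DistanceMatrix,
    prior_P: float,
    gap_width_X: float,
    window: int | None = None,
) -> Partition:
    """Single recursive barcode-gap partition at one parameter setting.

    ``prior_P`` is the intraspecific-divergence ceiling (proportion, in
    (0, 1)); only gaps whose right edge lies at or above it are candidate
    splits.  ``gap_width_X`` scales the local significance criterion.
    Fewer than 3 specimens cannot be partitioned: a single flagged group is
    returned.
    """
    if not (0.0 < prior_P < 1.0):
        raise ValueError("prior_P must be in (0, 1)")
    if gap_width_X <= 0:
        raise ValueError("gap_width_X must be > 0")
    return _RecursivePartitioner(m, window).partition(prior_P, gap_width_X)


@dataclass
class SweepResult:
    """Partition grid over (prior P, gap width X) with per-species calls.

    ``group_counts[i, k]`` is the number of groups at gap width ``i`` and
    prior ``k``; ``lumped[species][i, k]`` is True when all specimens of
    the species share one group in that cell.
    """

    priors: np.ndarray
    gap_widths: np.ndarray
    group_counts: np.ndarray
    lumped: dict[str, np.ndarray]
    depths: np.ndarray

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for species in sorted(self.lumped):
            grid = self.lumped[species]
            for i, x in enumerate(self.gap_widths):
                for k, p in enumerate(self.priors):
                    rows.append(
                        {
                            "species": species,
                            "prior_percent": p * 100,
                            "gap_width": x,
                            "classification": "lumped" if grid[i, k] else "split",
                            "n_groups": int(self.group_counts[i, k]),
                        }
                    )
        return pd.DataFrame(rows)

    def width_index(self, gap_width: float) -> int:
        i = int(np.argmin(np.abs(self.gap_widths - gap_width)))
        if not np.isclose(self.gap_widths[i], gap_width, rtol=1e-9, atol=1e-12):
            raise ValueError(
                f"gap width {gap_width} is not on the sweep grid"
            )
        return i


def geometric_priors(p_min: float, p_max: float, n_steps: int) -> np.ndarray:
    """Equal-log-step prior grid (the priors span two orders of magnitude)."""
    return np.geomspace(p_min, p_max, n_steps)


def ape_sweep(
    m: DistanceMatrix,
    labels: dict[str, str],
    p_min: float = 0.001,
    p_max: float = 0.1,
    n_steps: int = 100,
    x_min: float = 0.1,
    x_max: float = 10.0,
    n_x: int = 100,
    window: int | None = None,
) -> SweepResult:
    """Run the partitioner over the full (prior, gap width) grid.

    Deterministic; cells inherit the partitioner's too-few flag silently
    (a <3-specimen dataset is a single group everywhere).
    """
    unlabelled = [s for s in m.ids if s not in labels]
    if unlabelled:
        raise ValueError(f"ids without species label: {unlabelled}")
    priors = geometric_priors(p_min, p_max, n_steps)
    widths = np.linspace(x_min, x_max, n_x) if n_x > 1 else np.array([x_min])
    part = _RecursivePartitioner(m, window)
    species_members: dict[str, list[str]] = {}
    for sid in m.ids:
        species_members.setdefault(labels[sid], []).append(sid)

    group_counts = np.zeros((len(widths), len(priors)), dtype=int)
    depths = np.zeros((len(widths), len(priors)), dtype=int)
    lumped = {
        sp: np.zeros((len(widths), len(priors)), dtype=bool)
        for sp in species_members
    }
    for i, x in enumerate(widths):
        for k, p in enumerate(priors):
            cell = part.partition(float(p), float(x))
            group_counts[i, k] = cell.n_groups
            depths[i, k] = cell.depth
            for sp, members in species_members.items():
                lumped[sp][i, k] = cell.is_lumped(members)
    return SweepResult(priors, widths, group_counts, lumped, depths)


@dataclass
class PEstimate:
    """Smallest grid prior (in percent) lumping a species, or a censored flag."""

    species: str
    estimator_P: float | None
    censored: str | None  # "<0.1" when lumped at the smallest prior, ">10" when never
    gap_width: float

    @property
    def label(self) -> str:
        if self.censored:
            return self.censored
        return f"{self.estimator_P:.2f}"


def estimate_P(
    sweep: SweepResult, species: str, gap_width: float = 0.1
) -> PEstimate:
    """Read the intraspecific divergence estimator off a sweep column."""
    if species not in sweep.lumped:
        raise KeyError(f"species {species!r} not present in the sweep")
    i = sweep.width_index(gap_width)
    row = sweep.lumped[species][i]
    idx = np.flatnonzero(row)
    lo_pct = sweep.priors[0] * 100
    hi_pct = sweep.priors[-1] * 100
    if idx.size == 0:
        return PEstimate(species, None, f">{hi_pct:g}", gap_width)
    first = int(idx[0])
    if first == 0:
        return PEstimate(species, None, f"<{lo_pct:g}", gap_width)
    return PEstimate(species, float(sweep.priors[first] * 100), None, gap_width)


def render_sweep_matrix(
    sweep: SweepResult, gap_width: float | None = None
) -> dict[float, pd.DataFrame]:
    """Lumped/split matrices (rows = species, columns = priors in %), one
    per gap width; mirrors the red/blue sweep image plots as text."""
    if gap_width is not None:
        indices = [sweep.width_index(gap_width)]
    else:
        indices = range(len(sweep.gap_widths))
    out = {}
    for i in indices:
        cols = [f"{p * 100:.4g}" for p in sweep.priors]
        data = {
            sp: ["lumped" if v else "split" for v in sweep.lumped[sp][i]]
            for sp in sorted(sweep.lumped)
        }
        out[float(sweep.gap_widths[i])] = pd.DataFrame.from_dict(
            data, orient="index", columns=cols
        )
    return out


def save_sweep_raster(sweep: SweepResult, gap_width: float, path) -> None:
    """Optional raster image of one sweep column set (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = render_sweep_matrix(sweep, gap_width)[
        float(sweep.gap_widths[sweep.width_index(gap_width)])
    ]
    grid = (mat == "lumped").to_numpy().astype(int)
    fig, ax = plt.subplots(figsize=(8, max(2, 0.25 * grid.shape[0])))
    ax.imshow(grid, aspect="auto", cmap="bwr_r", vmin=0, vmax=1)
    ax.set_yticks(range(grid.shape[0]), mat.index, fontsize=6)
    ax.set_xlabel("intraspecific divergence prior (%)")
    ax.set_title(f"gap width X = {gap_width:g} (red = lumped, blue = split)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
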