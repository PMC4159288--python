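"""Seeded synthetic barcode libraries with planted structure.

The generator emulates the statistical regimes of a real COI barcode
library: per-species haplotype clusters with low intraspecific divergence,
interspecific divergences up to ~26%, species groups sharing identical
haplotypes (recent speciation / hybridization), and single species split
into deep lineages (cryptic-species candidates).  Substitution *counts*
are planted, not branch times, because pairwise distances are the
observable every downstream stage consumes: each evolve call places its
substitutions at distinct sites, so every truth-critical divergence sits
on a single branch and its step count is exact.

Sequence evolution follows a K80-style process: substitutions choose a
transition over a transversion with odds ``kappa : 1`` (default 4, typical
for insect mitochondrial COI).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._seq import BASES, TRANSITION, TRANSVERSIONS
from .library import BarcodeLibrary, BarcodeRecord
from .tree import MONOPHYLETIC, NON_MONOPHYLETIC, TRIVIAL


@dataclass(frozen=True)
class SpeciesSpec:
    """Planted structure for one species.

    ``intra_divergence`` is the target maximum within-lineage K2P distance
    (percent).  ``split_divergence`` plants a deep split: two lineages at
    that K2P distance (percent); ``split_steps`` plants the split as an
    exact mutational step count instead.  ``root_divergence`` places the
    species ancestor that far (percent) from the library root, spacing the
    species from the rest.  ``sharing_group`` makes the species carry a
    haplotype identical to every other member of the group;
    ``anchor_species``/``anchor_steps`` derive the ancestor from an earlier
    species' ancestor at an exact step count (low-divergence pairs).
    """

    name: str
    genus: str
    family: str
    n_specimens: int
    n_haplotypes: int = 1
    intra_divergence: float = 0.0
    split_divergence: float | None = None
    split_steps: int | None = None
    root_divergence: float = 8.0
    sharing_group: str | None = None
    anchor_species: str | None = None
    anchor_steps: int = 0


@dataclass(frozen=True)
class ScenarioConfig:
    """A full synthetic-library scenario; the seed is mandatory."""

    name: str
    species: tuple[SpeciesSpec, ...]
    seed: int
    alignment_length: int = 658
    kappa: float = 4.0
    short_fraction: float = 0.0
    ambiguous_fraction: float = 0.0

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=seed)

    def sharing_groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sp in self.species:
            if sp.sharing_group:
                out.setdefault(sp.sharing_group, []).append(sp.name)
        return out


@dataclass
class TruthTable:
    """Ground truth for every planted feature of an emitted library."""

    specimen_species: dict[str, str]
    specimen_lineage: dict[str, str]
    lineage_divergences: dict[str, dict]  # species -> {percent, steps} or {}
    sharing_groups: dict[str, list[str]]
    expected_monophyly: dict[str, str]
    expected_clusters: dict[str, int]
    expected_shared_cluster: dict[str, bool]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sid, sp in self.specimen_species.items():
            split = self.lineage_divergences.get(sp) or {}
            rows.append(
                {
                    "specimen_id": sid,
                    "species": sp,
                    "lineage": self.specimen_lineage[sid],
                    "split_percent": split.get("percent", np.nan),
                    "split_steps": split.get("steps", 0),
                    "expected_monophyly": self.expected_monophyly[sp],
                    "expected_clusters": self.expected_clusters[sp],
                    "expected_shared_cluster": self.expected_shared_cluster[sp],
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "specimen_species": self.specimen_species,
            "specimen_lineage": self.specimen_lineage,
            "lineage_divergences": self.lineage_divergences,
            "sharing_groups": self.sharing_groups,
            "expected_monophyly": self.expected_monophyly,
            "expected_clusters": self.expected_clusters,
            "expected_shared_cluster": self.expected_shared_cluster,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def evolve_sequence(
    ancestor: str, n_substitutions: int, kappa: float, rng: np.random.Generator
) -> str:
    """Apply exactly ``n_substitutions`` changes at distinct uniform sites.

    Each event is a transition with odds ``kappa : 1`` over a transversion;
    a transversion picks either alternative base uniformly.  Distinct sites
    keep the realized Hamming distance equal to the planted count.
    """
    if n_substitutions < 0:
        raise ValueError("n_substitutions must be >= 0")
    if n_substitutions > len(ancestor):
        raise ValueError(
            f"cannot place {n_substitutions} substitutions on "
            f"{len(ancestor)} sites"
        )
    if any(c not in BASES for c in ancestor):
        raise ValueError("ancestor must be over A/C/G/T only")
    if n_substitutions == 0:
        return ancestor
    seq = list(ancestor)
    sites = rng.choice(len(seq), size=n_substitutions, replace=False)
    p_transition = kappa / (kappa + 1.0)
    for site in sites:
        base = seq[site]
        if rng.random() < p_transition:
            seq[site] = TRANSITION[base]
        else:
            seq[site] = TRANSVERSIONS[base][rng.integers(2)]
    return "".join(seq)


def k2p_of_steps(steps: int, length: int, kappa: float) -> float:
    """Expected K2P distance (proportion) of ``steps`` single-hit
    substitutions on ``length`` sites at transition odds ``kappa``."""
    p = steps / length
    f = kappa / (kappa + 1.0)
    w1 = 1.0 - (1.0 + f) * p
    w2 = 1.0 - 2.0 * (1.0 - f) * p
    if w1 <= 0 or w2 <= 0:
        raise ValueError("step count saturates the K2P correction")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def steps_for_divergence(target_percent: float, length: int, kappa: float) -> int:
    """Substitution count whose expected K2P distance matches a target (%).

    Raises when the target cannot be reached on the given length (the K2P
    logarithm saturates first).
    """
    if target_percent < 0:
        raise ValueError("divergence targets must be >= 0")
    if target_percent == 0:
        return 0
    t = target_percent / 100.0
    f = kappa / (kappa + 1.0)
    p_max = 1.0 / (1.0 + f)

    def g(p: float) -> float:
        return (
            -0.5 * math.log(1.0 - (1.0 + f) * p)
            - 0.25 * math.log(1.0 - 2.0 * (1.0 - f) * p)
            - t
        )

    hi = p_max * (1.0 - 1e-9)
    try:
        p = brentq(g, 1e-12, hi)
    except ValueError as exc:  # pragma: no cover - defensive
        raise ValueError(
            f"divergence target {target_percent}% unsatisfiable at "
            f"length {length}"
        ) from exc
    steps = max(1, round(p * length))
    if steps > length:
        raise ValueError(
            f"divergence target {target_percent}% needs {steps} substitutions "
            f"but only {length} sites exist"
        )
    return steps


def _satellite_steps(s_max: int, n_satellites: int) -> list[int]:
    """Step counts for satellite haplotypes so the largest within-lineage
    pairwise distance stays near ``s_max`` (satellite-satellite paths pass
    through the central haplotype)."""
    if n_satellites == 0:
        return []
    if n_satellites == 1:
        return [max(1, s_max)]
    cap = max(1, s_max // 2)
    return [max(1, round(i * cap / n_satellites)) for i in range(1, n_satellites + 1)]


def _abbrev(name: str) -> str:
    parts = name.split()
    genus = parts[0][:4].upper()
    epithet = parts[1] if len(parts) > 1 else "sp"
    digits = "".join(c for c in epithet if c.isdigit())
    return f"{genus}{epithet[:4].upper()}{digits}"


def _random_ancestor(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, length))


def generate_library(cfg: ScenarioConfig) -> tuple[BarcodeLibrary, TruthTable]:
    """Emit a library plus its truth table; deterministic per seed."""
    if cfg.seed is None:
        raise ValueError("ScenarioConfig.seed is mandatory")
    names = [sp.name for sp in cfg.species]
    if len(set(names)) != len(names):
        raise ValueError("duplicate species names in scenario")
    for sp in cfg.species:
        if sp.n_haplotypes > sp.n_specimens:
            raise ValueError(f"{sp.name}: more haplotypes than specimens")
        if min(sp.intra_divergence, sp.root_divergence) < 0:
            raise ValueError(f"{sp.name}: divergence targets must be >= 0")
        if sp.anchor_species is not None:
            if sp.anchor_species not in names:
                raise ValueError(f"{sp.name}: unknown anchor {sp.anchor_species!r}")
            target = next(t for t in cfg.species if t.name == sp.anchor_species)
            # An anchored species attaches at the target's central haplotype.
            # If the target also has satellite haplotypes (and is not already
            # expected non-monophyletic through a sharing group) that central
            # node becomes an exact star polytomy whose tree resolution is
            # arbitrary, so the planted monophyly truth would be undefined.
            if target.n_haplotypes > 1 and target.sharing_group is None:
                raise ValueError(
                    f"{sp.name}: anchor target {target.name!r} must have a "
                    "single haplotype (or a sharing group) so its planted "
                    "monophyly expectation is implied by the geometry"
                )
        if (
            sp.split_divergence is not None or sp.split_steps is not None
        ) and sp.n_specimens < 2:
            raise ValueError(f"{sp.name}: a lineage split needs >= 2 specimens")

    L = cfg.alignment_length
    kappa = cfg.kappa
    rng = np.random.default_rng(cfg.seed)
    root = _random_ancestor(L, rng)

    group_anc: dict[str, str] = {}
    species_anc: dict[str, str] = {}
    records: list[BarcodeRecord] = []
    specimen_species: dict[str, str] = {}
    specimen_lineage: dict[str, str] = {}
    lineage_div: dict[str, dict] = {}

    for sp in cfg.species:
        # --- species ancestor
        if sp.sharing_group is not None:
            if sp.sharing_group not in group_anc:
                group_anc[sp.sharing_group] = evolve_sequence(
                    root, steps_for_divergence(sp.root_divergence, L, kappa), kappa, rng
                )
            anc = group_anc[sp.sharing_group]
        elif sp.anchor_species is not None:
            anc = evolve_sequence(
                species_anc[sp.anchor_species], sp.anchor_steps, kappa, rng
            )
        else:
            anc = evolve_sequence(
                root, steps_for_divergence(sp.root_divergence, L, kappa), kappa, rng
            )
        species_anc[sp.name] = anc

        # --- lineages
        if sp.split_steps is not None or sp.split_divergence is not None:
            steps = (
                sp.split_steps
                if sp.split_steps is not None
                else steps_for_divergence(sp.split_divergence, L, kappa)
            )
            lineages = [("A", anc), ("B", evolve_sequence(anc, steps, kappa, rng))]
            lineage_div[sp.name] = {
                "percent": k2p_of_steps(steps, L, kappa) * 100,
                "steps": steps,
            }
            n_lin = [math.ceil(sp.n_specimens / 2), sp.n_specimens // 2]
            h_lin = [math.ceil(sp.n_haplotypes / 2), sp.n_haplotypes // 2]
            h_lin = [max(1, h) for h in h_lin]
        else:
            lineages = [("A", anc)]
            lineage_div[sp.name] = {}
            n_lin = [sp.n_specimens]
            h_lin = [sp.n_haplotypes]

        # --- haplotypes and specimens
        abbrev = _abbrev(sp.name)
        counter = 0
        s_max = steps_for_divergence(sp.intra_divergence, L, kappa) if sp.intra_divergence else 0
        for (lin_name, lin_anc), n_spec, n_hap in zip(lineages, n_lin, h_lin):
            n_hap = min(n_hap, n_spec)
            sat_steps = _satellite_steps(s_max, n_hap - 1) if s_max else [1] * (n_hap - 1)
            haps = [lin_anc] + [
                evolve_sequence(lin_anc, s, kappa, rng) for s in sat_steps
            ]
            # central haplotype dominates; each satellite gets one specimen
            assignment = [0] * (n_spec - (n_hap - 1)) + list(range(1, n_hap))
            for hap_idx in assignment:
                counter += 1
                sid = f"{abbrev}{counter:02d}"
                records.append(
                    BarcodeRecord(sid, sp.name, sp.genus, sp.family, haps[hap_idx])
                )
                specimen_species[sid] = sp.name
                specimen_lineage[sid] = lin_name

    # --- quality degradation: Ns then truncation to >= 402 informative bases.
    # Truncation is applied only to structureless background species so the
    # planted step counts of sharing/anchor/split regimes survive pairwise
    # deletion exactly.
    if cfg.ambiguous_fraction > 0 or cfg.short_fraction > 0:
        structured = {
            sp.name
            for sp in cfg.species
            if sp.sharing_group
            or sp.anchor_species
            or sp.split_divergence is not None
            or sp.split_steps is not None
        }
        eligible = [
            i for i, rec in enumerate(records) if rec.species not in structured
        ]
        n_short = round(cfg.short_fraction * len(records))
        n_short = min(n_short, len(eligible))
        short_idx = set(
            (np.array(eligible)[rng.choice(len(eligible), size=n_short, replace=False)]).tolist()
        ) if n_short else set()
        for i, rec in enumerate(records):
            seq = list(rec.sequence)
            if cfg.ambiguous_fraction > 0:
                n_amb = round(cfg.ambiguous_fraction * L)
                for site in rng.choice(L, size=n_amb, replace=False):
                    seq[site] = "N"
            if i in short_idx:
                informative = sum(1 for c in seq if c not in "-N")
                target = int(rng.integers(402, max(informative, 403)))
                cut = 0
                while informative > target and cut < L:
                    if seq[cut] not in "-N":
                        informative -= 1
                    seq[cut] = "-"
                    cut += 1
            new_seq = "".join(seq)
            if new_seq != rec.sequence:
                records[i] = BarcodeRecord(
                    rec.specimen_id, rec.species, rec.genus, rec.family, new_seq
                )

    lib = BarcodeLibrary(records, L)

    # --- expectations
    sharing = cfg.sharing_groups()
    in_sharing = {name for members in sharing.values() for name in members}
    threshold_steps = steps_for_divergence(2.2, L, kappa)
    expected_monophyly: dict[str, str] = {}
    expected_clusters: dict[str, int] = {}
    expected_shared: dict[str, bool] = {}
    for sp in cfg.species:
        if sp.n_specimens == 1:
            expected_monophyly[sp.name] = TRIVIAL
        elif sp.name in in_sharing:
            expected_monophyly[sp.name] = NON_MONOPHYLETIC
        else:
            expected_monophyly[sp.name] = MONOPHYLETIC
        split = lineage_div[sp.name]
        expected_clusters[sp.name] = (
            2 if split and split["percent"] > 2.2 else 1
        )
        expected_shared[sp.name] = sp.name in in_sharing or (
            sp.anchor_species is not None and sp.anchor_steps < threshold_steps
        )
        # the anchor target also shares a cluster with the anchored species
        if sp.anchor_species is not None and sp.anchor_steps < threshold_steps:
            expected_shared[sp.anchor_species] = True

    truth = TruthTable(
        specimen_species=specimen_species,
        specimen_lineage=specimen_lineage,
        lineage_divergences=lineage_div,
        sharing_groups=sharing,
        expected_monophyly=expected_monophyly,
        expected_clusters=expected_clusters,
        expected_shared_cluster=expected_shared,
    )
    return lib, truth


# ---------------------------------------------------------------------------
# presets


def _clean_species(
    i: int, n_specimens: int = 3, intra: float = 0.5
) -> SpeciesSpec:
    genus = f"Genus{chr(ord('A') + i % 8)}"
    return SpeciesSpec(
        name=f"{genus} species{i + 1:02d}",
        genus=genus,
        family=f"Family{chr(ord('A') + i % 4)}",
        n_specimens=n_specimens,
        n_haplotypes=min(2, n_specimens),
        intra_divergence=intra,
        root_divergence=3.0 + (i % 11),
    )


def _sharing_quartet() -> list[SpeciesSpec]:
    """Four congeners: three share one dominant haplotype, the fourth sits
    one mutational step away (the classic hybridizing-quartet pattern)."""
    fam = dict(genus="Nabimorpha", family="FamilyS")
    return [
        SpeciesSpec("Nabimorpha brevicula", n_specimens=5, n_haplotypes=2,
                    intra_divergence=0.3, root_divergence=9.0,
                    sharing_group="quartet", **fam),
        SpeciesSpec("Nabimorpha ericina", n_specimens=4, n_haplotypes=2,
                    intra_divergence=0.3, root_divergence=9.0,
                    sharing_group="quartet", **fam),
        SpeciesSpec("Nabimorpha rugata", n_specimens=4, n_haplotypes=2,
                    intra_divergence=0.3, root_divergence=9.0,
                    sharing_group="quartet", **fam),
        SpeciesSpec("Nabimorpha pseudina", n_specimens=3, n_haplotypes=1,
                    anchor_species="Nabimorpha brevicula", anchor_steps=1, **fam),
    ]


def _deep_split_species(percent: float | None, steps: int | None = None,
                        n: int = 10) -> SpeciesSpec:
    tag = f"{percent:g}".replace(".", "p") if percent is not None else f"s{steps}"
    return SpeciesSpec(
        name=f"Cryptica profunda{tag}",
        genus="Cryptica",
        family="FamilyD",
        n_specimens=n,
        n_haplotypes=min(5, n),
        intra_divergence=0.3,
        split_divergence=percent,
        split_steps=steps,
        root_divergence=10.0,
    )


def preset_scenarios() -> dict[str, ScenarioConfig]:
    """Named scenario set covering every planted regime.

    ``clean_library``: well-separated species only.  ``haplotype_sharing``:
    the hybridizing quartet plus context species.  ``deep_split_5/8/23``:
    one species split into two lineages at 5/8/23% K2P.
    ``orius_two_lineages``: a split planted as exactly 29 mutational steps.
    ``mixed_full``: ~40 species / 150 specimens combining all regimes.
    """
    presets: dict[str, ScenarioConfig] = {}

    presets["clean_library"] = ScenarioConfig(
        name="clean_library",
        species=tuple(_clean_species(i, 3 + i % 3) for i in range(12)),
        seed=20140909,
    )

    presets["haplotype_sharing"] = ScenarioConfig(
        name="haplotype_sharing",
        species=tuple(_sharing_quartet() + [_clean_species(9, 4)]),
        seed=20140909,
    )

    for pct in (5.0, 8.0, 23.0):
        presets[f"deep_split_{pct:g}"] = ScenarioConfig(
            name=f"deep_split_{pct:g}",
            species=(_deep_split_species(pct), _clean_species(3, 3)),
            seed=20140909,
        )

    presets["orius_two_lineages"] = ScenarioConfig(
        name="orius_two_lineages",
        species=(_deep_split_species(None, steps=29, n=10),),
        seed=20140909,
    )

    mixed: list[SpeciesSpec] = [
        _clean_species(i, 3 + (i % 2), intra=0.2 + 0.1 * (i % 5))
        for i in range(33)
    ]
    mixed += _sharing_quartet()
    mixed += [
        SpeciesSpec("Parallelus primus", genus="Parallelus", family="FamilyP",
                    n_specimens=3, n_haplotypes=1,
                    root_divergence=12.0),
        SpeciesSpec("Parallelus secundus", genus="Parallelus", family="FamilyP",
                    n_specimens=3, n_haplotypes=1,
                    anchor_species="Parallelus primus", anchor_steps=4),
        _deep_split_species(8.0, n=8),
        _deep_split_species(23.0, n=7),
        _deep_split_species(None, steps=29, n=10),
    ]
    presets["mixed_full"] = ScenarioConfig(
        name="mixed_full",
        species=tuple(mixed),
        seed=20140909,
        short_fraction=0.1,
    )
    return presets
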