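"""Synthetic library generator: determinism, planted structure, properties."""

import math

import numpy as np
import pytest

from barcode_audit import (
    ScenarioConfig,
    SpeciesSpec,
    evolve_sequence,
    generate_library,
    pairwise_matrix,
    steps_for_divergence,
)
from barcode_audit.simulate import _satellite_steps, k2p_of_steps
from barcode_audit.tree import MONOPHYLETIC, NON_MONOPHYLETIC, TRIVIAL


def hamming(a, b):
    return sum(1 for x, y in zip(a, b) if x != y)


class TestEvolveSequence:
    def test_zero_steps_identity(self):
        rng = np.random.default_rng(0)
        assert evolve_sequence("ACGT" * 10, 0, 4.0, rng) == "ACGT" * 10

    def test_exact_hamming_distance(self):
        rng = np.random.default_rng(1)
        anc = "ACGT" * 50
        for k in (1, 5, 25, 120):
            assert hamming(anc, evolve_sequence(anc, k, 4.0, rng)) == k

    def test_huge_kappa_gives_only_transitions(self):
        rng = np.random.default_rng(2)
        anc = "ACGT" * 50
        out = evolve_sequence(anc, 100, 1e12, rng)
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        for x, y in zip(anc, out):
            if x != y:
                assert (x, y) in transitions

    def test_transition_fraction_near_kappa_odds(self):
        rng = np.random.default_rng(3)
        anc = "ACGT" * 250  # 1000 sites
        out = evolve_sequence(anc, 800, 4.0, rng)
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        ts = sum(
            1 for x, y in zip(anc, out) if x != y and (x, y) in transitions
        )
        assert ts / 800 == pytest.approx(0.8, abs=0.05)

    def test_invalid_inputs(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            evolve_sequence("ACGT", -1, 4.0, rng)
        with pytest.raises(ValueError):
            evolve_sequence("ACGT", 5, 4.0, rng)
        with pytest.raises(ValueError):
            evolve_sequence("ACNT", 1, 4.0, rng)


class TestStepsForDivergence:
    def test_round_trip_within_quantisation(self):
        for pct in (0.5, 2.2, 5.0, 8.0, 15.0, 23.0):
            steps = steps_for_divergence(pct, 658, 4.0)
            realised = k2p_of_steps(steps, 658, 4.0) * 100
            # off by at most the half-step quantisation
            neighbour = k2p_of_steps(steps + 1, 658, 4.0) * 100
            assert abs(realised - pct) <= (neighbour - realised)

    def test_zero_target(self):
        assert steps_for_divergence(0.0, 658, 4.0) == 0

    def test_monotone_in_target(self):
        steps = [steps_for_divergence(p, 658, 4.0) for p in (1, 3, 8, 15, 23)]
        assert steps == sorted(steps)
        assert steps[0] >= 1

    def test_negative_target_raises(self):
        with pytest.raises(ValueError):
            steps_for_divergence(-1.0, 658, 4.0)

    def test_extreme_target_stays_below_saturation(self):
        # the K2P correction diverges before the step count can exceed the
        # sequence length, so even huge targets yield a legal count
        steps = steps_for_divergence(300.0, 658, 4.0)
        assert 0 < steps <= 658
        assert k2p_of_steps(steps, 658, 4.0) * 100 > 100.0

    def test_satellite_steps_cap(self):
        assert _satellite_steps(10, 1) == [10]
        assert max(_satellite_steps(10, 4)) <= 5
        assert _satellite_steps(0, 0) == []


def tiny_scenario(seed=1, **overrides):
    spec = dict(
        name="Testus alpha", genus="Testus", family="FamT",
        n_specimens=4, n_haplotypes=2, intra_divergence=0.5,
    )
    spec.update(overrides)
    return ScenarioConfig(
        name="tiny",
        species=(
            SpeciesSpec(**spec),
            SpeciesSpec(name="Testus beta", genus="Testus", family="FamT",
                        n_specimens=3, root_divergence=12.0),
        ),
        seed=seed,
    )


class TestGenerateLibrary:
    def test_seed_determinism_byte_identical(self):
        lib1, truth1 = generate_library(tiny_scenario())
        lib2, truth2 = generate_library(tiny_scenario())
        assert [r.sequence for r in lib1.records] == [
            r.sequence for r in lib2.records
        ]
        assert truth1.to_json() == truth2.to_json()

    def test_different_seed_different_sequences(self):
        lib1, _ = generate_library(tiny_scenario(seed=1))
        lib2, _ = generate_library(tiny_scenario(seed=2))
        assert [r.sequence for r in lib1.records] != [
            r.sequence for r in lib2.records
        ]

    def test_counts_and_labels(self):
        lib, truth = generate_library(tiny_scenario())
        assert len(lib) == 7
        assert set(truth.specimen_species.values()) == {
            "Testus alpha", "Testus beta"
        }
        assert truth.expected_monophyly["Testus alpha"] == MONOPHYLETIC

    def test_validation_errors(self):
        with pytest.raises(ValueError, match="haplotypes"):
            generate_library(tiny_scenario(n_haplotypes=9))
        with pytest.raises(ValueError, match="anchor"):
            generate_library(tiny_scenario(anchor_species="Testus ghost"))
        with pytest.raises(ValueError, match="2 specimens"):
            generate_library(
                tiny_scenario(n_specimens=1, n_haplotypes=1, split_divergence=8.0)
            )

    def test_anchor_target_with_satellites_rejected(self):
        # anchoring to a multi-haplotype species creates a star polytomy
        # whose monophyly truth would be arbitrary
        cfg = tiny_scenario()
        extra = SpeciesSpec(
            name="Testus gamma", genus="Testus", family="FamT",
            n_specimens=2, anchor_species="Testus alpha", anchor_steps=3,
        )
        cfg = ScenarioConfig("bad", cfg.species + (extra,), seed=1)
        with pytest.raises(ValueError, match="single haplotype"):
            generate_library(cfg)

    def test_duplicate_species_rejected(self):
        cfg = tiny_scenario()
        cfg = ScenarioConfig("dup", (cfg.species[0], cfg.species[0]), seed=1)
        with pytest.raises(ValueError, match="duplicate"):
            generate_library(cfg)


class TestPlantedStructure:
    def test_deep_split_realised_divergence(self, presets):
        for scen, pct in (("deep_split_5", 5.0), ("deep_split_8", 8.0),
                          ("deep_split_23", 23.0)):
            lib, truth = generate_library(presets[scen])
            m = pairwise_matrix(lib)
            sp = next(s for s in truth.lineage_divergences if truth.lineage_divergences[s])
            ids = [sid for sid, s in truth.specimen_species.items() if s == sp]
            idx = [m.index_of(i) for i in ids]
            block = m.d[np.ix_(idx, idx)]
            max_intra = np.nanmax(block) * 100
            planted = truth.lineage_divergences[sp]["percent"]
            assert abs(max_intra - planted) / planted < 0.15
            assert abs(planted - pct) / pct < 0.05

    def test_sharing_group_distance_zero(self, presets):
        lib, truth = generate_library(presets["haplotype_sharing"])
        m = pairwise_matrix(lib)
        group = truth.sharing_groups["quartet"]
        # every pair of sharing species attains an interspecific distance of 0
        for a in group:
            for b in group:
                if a >= b:
                    continue
                ia = [m.index_of(s) for s, sp in truth.specimen_species.items() if sp == a]
                ib = [m.index_of(s) for s, sp in truth.specimen_species.items() if sp == b]
                assert np.nanmin(m.d[np.ix_(ia, ib)]) == 0.0

    def test_anchored_species_exact_steps(self, presets):
        lib, truth = generate_library(presets["haplotype_sharing"])
        seqs = {r.specimen_id: r.sequence for r in lib.records}
        anchored = [s for s, sp in truth.specimen_species.items()
                    if sp == "Nabimorpha pseudina"]
        shared = [s for s, sp in truth.specimen_species.items()
                  if sp == "Nabimorpha brevicula"]
        min_h = min(hamming(seqs[a], seqs[b]) for a in anchored for b in shared)
        assert min_h == 1  # the planted anchor offset

    def test_lineage_assignment_matches_distances(self, presets):
        lib, truth = generate_library(presets["deep_split_8"])
        m = pairwise_matrix(lib)
        sp = next(s for s in truth.lineage_divergences if truth.lineage_divergences[s])
        ids = [sid for sid, s in truth.specimen_species.items() if s == sp]
        for a in ids:
            for b in ids:
                if a >= b:
                    continue
                d = m.d[m.index_of(a), m.index_of(b)]
                same = truth.specimen_lineage[a] == truth.specimen_lineage[b]
                assert (d < 0.022) == same

    def test_truth_expectations_consistent(self, presets):
        _, truth = generate_library(presets["mixed_full"])
        for sp, status in truth.expected_monophyly.items():
            assert status in (MONOPHYLETIC, NON_MONOPHYLETIC, TRIVIAL)
        for sp in truth.sharing_groups.get("quartet", []):
            assert truth.expected_monophyly[sp] == NON_MONOPHYLETIC
            assert truth.expected_shared_cluster[sp]
        for sp, div in truth.lineage_divergences.items():
            if div:
                expected = 2 if div["percent"] > 2.2 else 1
                assert truth.expected_clusters[sp] == expected

    def test_short_fraction_respects_min_length_and_structure(self, presets):
        lib, truth = generate_library(presets["mixed_full"])
        structured = set(truth.sharing_groups.get("quartet", []))
        structured |= {s for s, d in truth.lineage_divergences.items() if d}
        for rec in lib.records:
            informative = sum(1 for c in rec.sequence if c not in "-N")
            assert informative >= 402
            if rec.species in structured:
                assert informative == lib.alignment_length

    def test_mixed_full_has_no_undefined_pairs(self, presets):
        lib, _ = generate_library(presets["mixed_full"])
        m = pairwise_matrix(lib)
        assert m.undefined_pairs() == []
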