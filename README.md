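# barcode-audit

A toolkit for auditing DNA barcode reference libraries — aligned
mitochondrial COI sequences (typically 658 bp) labelled with species,
genus and family. A reference library only supports specimen
identification when each species' barcodes are distinct from every other
species' and cohesive among themselves; this package measures both
properties with the standard battery of barcoding analyses and reports
every specimen or species that breaks them.

## What it does

Given a FASTA alignment and a metadata table, `barcode-audit`:

- **Validates and filters** the library: metadata/sequence consistency,
  alignment-length checks, a >400-informative-bases inclusion rule, and a
  base-composition summary (mean per-sequence frequencies, AT content).
- **Computes Kimura 2-parameter distances** with pairwise deletion of
  non-ACGT sites. Saturated or low-overlap pairs are reported as
  *undefined*, never silently clamped.
- **Screens with the 2.2% threshold**: species pairs whose minimum
  interspecific distance falls below it (haplotype sharing, very recent
  divergence, or misidentification candidates) and species whose maximum
  intraspecific distance exceeds it (deep splits, cryptic-lineage
  candidates). Single-linkage clustering at the same threshold acts as a
  barcode-OTU proxy and separates deep splits that fracture into multiple
  clusters from those that do not.
- **Builds a bootstrapped neighbour-joining tree** (deterministic
  tie-breaking, seeded column resampling) and audits per-species
  monophyly on the unrooted topology.
- **Draws statistical parsimony networks** per species or genus:
  haplotype collapsing, a 95% connection limit (8 steps at 658 bp), and
  subnetwork gaps in mutational steps.
- **Runs a two-parameter barcode-gap sweep**: a recursive gap
  partitioner evaluated over a grid of prior intraspecific ceilings *P*
  (0.1–10%, log-spaced) × relative gap widths *X* (0.1–10). Reading the
  narrow-gap column from small *P* upward yields a per-species estimator
  of intraspecific divergence, censored as `<0.1` / `>10` at the grid
  edges.
- **Generates synthetic libraries with planted structure** — shared
  haplotypes, anchored near-neighbour species, deep two-lineage splits,
  truncated fragments — together with a truth table, so every audit
  finding can be checked against what was planted.
- **Orchestrates the full audit** (`run_audit` / `barcode-audit run`)
  and writes deterministic report tables, including the headline
  *identification rate*: the share of species that are monophyletic and
  share no threshold cluster with another species.

## Worked example

```python
from barcode_audit import (
    AuditConfig, compare_to_truth, generate_library, preset_scenarios, run_audit,
)

lib, truth = generate_library(preset_scenarios()["mixed_full"])
report = run_audit(lib, AuditConfig(seed=20140909))
```

On the `mixed_full` preset (162 specimens, 42 species, every planted
anomaly at once) this prints, via `examples/06_full_audit.py`:

```
42 species, 162 specimens
identification rate: 85.71%
low-divergence species pairs (< 2.2%): 7
deep-divergence species: 0 single-cluster, 3 multi-cluster

multi-cluster deep splits (cryptic-lineage candidates):
 family              species  n_specimens  mean_intra  max_intra  n_clusters estimator_P
FamilyD  Cryptica profunda23            7   13.212752  23.130593           2         >10
FamilyD   Cryptica profunda8            8    4.693612   8.500570           2        8.29
FamilyD Cryptica profundas29           10    2.669531   5.068155           2        4.71

discrepancies against the planted truth table: 0
```

The seven low-divergence pairs are exactly the planted quartet sharing a
haplotype (all six pairwise combinations at 0.00–0.15%) plus one anchored
species pair at 0.61%; the three deep splits were planted at 7.95%,
22.90% and 4.58% — the estimator recovers 8.29, `>10` (off-grid, honest
censoring) and 4.71.

The scripts in `examples/` walk through each capability in order:
library I/O and composition, distance screening, tree + monophyly, the
parsimony network (including the two-subnetwork split of a planted deep
lineage and its reconnection at a relaxed confidence), the gap sweep, and
the full audit.

## Command line

Every analysis is also exposed as a subcommand:

```sh
barcode-audit simulate --scenario mixed_full -o demo
barcode-audit validate -f demo/library.fasta -m demo/metadata.tsv
barcode-audit distances -f demo/library.fasta -m demo/metadata.tsv -o d.tsv --long
barcode-audit clusters  -f demo/library.fasta -m demo/metadata.tsv -o clusters.tsv
barcode-audit tree      -f demo/library.fasta -m demo/metadata.tsv --seed 1 -o tree.nwk
barcode-audit network   -f demo/library.fasta -m demo/metadata.tsv --group Cryptica --genus -o net
barcode-audit sweep     -f demo/library.fasta -m demo/metadata.tsv -o sweep
barcode-audit run       -f demo/library.fasta -m demo/metadata.tsv --seed 1 -o audit_out
```

`run` writes `species_overview.tsv`, `low_divergence_pairs.tsv`, both
deep-divergence tables, `monophyly.tsv`, `clusters.tsv`, `networks.tsv`,
`tree.nwk`, `run_metadata.json` and `audit.log`. Everything except the
timing log is byte-identical across re-runs with the same seed.

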