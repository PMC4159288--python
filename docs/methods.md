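# Methods and numerical decisions

This document records the models behind each analysis, the default
parameters and why they are what they are, and the deliberate numerical
choices a re-implementer would otherwise have to reverse-engineer.

## Input model

A library is an aligned FASTA of equal-length DNA barcode sequences
(canonical length 658 bp) plus a tab-separated metadata table mapping
every specimen id to species, genus and family. Sequences may contain
IUPAC ambiguity codes, `N` and alignment gaps `-`; all of these are
treated as *missing* for distance purposes, while ambiguity codes other
than `N` still count as *informative* for the length rule.

Inclusion rule: a record participates in analyses only if it has **more
than 400 informative bases** (`min_bases = 401`). The composition
summary reports mean per-sequence base frequencies over unambiguous
bases (not pooled counts, so short sequences are not under-weighted).

## Kimura 2-parameter distances

For each pair, sites where either sequence is non-ACGT are deleted
(pairwise deletion). With transition proportion *P* and transversion
proportion *Q* over the *n* retained sites,

d = −½ ln((1 − 2P − Q) √(1 − 2Q)).

A pair is **undefined** (reported as NaN with a reason, never clamped)
when fewer than `min_overlap = 300` sites remain, or when a logarithm
argument is ≤ 0 (distance saturation). Downstream stages treat undefined
pairs explicitly: no clustering edge, greedy specimen removal before
tree building, replicate dropping in the bootstrap.

Implementation: sequences are encoded as one-hot float32 matrices and
all P/Q counts obtained by matrix products, then finished in float64.
The matrix is symmetrised as `(d + dᵀ)/2 + 0.0`; the trailing `+ 0.0`
normalises IEEE −0.0 cells so report files are byte-stable. The per-pair
scalar path and the vectorised path agree to ≤ 1e-12, and both agree
with an independent R implementation (`ape::dist.dna`, model K80,
pairwise deletion) to ≤ 1e-9 (exercised in the test suite when `Rscript`
is available).

## Threshold screening at 2.2%

Three screens share one threshold (default 2.2%):

- **Low-divergence pairs**: species pairs whose *minimum* interspecific
  distance is below the threshold.
- **Deep-divergence species**: species whose *maximum* intraspecific
  distance exceeds it.
- **Threshold clusters**: connected components of the graph with an edge
  wherever `d < threshold`. Single linkage is a deliberate, documented
  proxy for barcode-OTU algorithms (it is not RESL/BIN); it has the
  right qualitative behaviour — chains merge, coarsening is monotone in
  the threshold — and is exactly reproducible.

The cut is strict (`<`). Note that `2.2 / 100` is
`0.022000000000000002` in binary floating point, so behaviour *exactly
at* the boundary is float-dependent; tests probe either side of the
boundary rather than the boundary itself.

## Neighbour joining

Standard NJ on the K2P matrix with the Q criterion, producing an
unrooted, trifurcating tree. Two deterministic tie rules:

1. **Zero-distance pre-joining**: if any pair has `d ≤ 0` it is joined
   first (lexicographically smallest such pair). Identical sequences
   therefore always form a zero-length clade; without this rule, exact Q
   ties among duplicates are resolved by float noise and can interleave
   other taxa between identical specimens.
2. **Exact Q ties** are broken by the lexicographically smallest pair of
   node keys (an internal node's key is its smallest leaf id).

Negative limb estimates are clamped to zero with the deficit moved to
the sister limb, floored at `max(d[i,j], 0)` so a negative working
distance cannot reintroduce a negative branch. Clamping preserves the
cherry's internal path length. On additive matrices the unclamped tree
reproduces all pairwise path lengths to ≤ 1e-8 and the topology matches
scikit-bio's NJ.

## Bootstrap and monophyly

Bootstrap replicates resample alignment columns with replacement;
replicate seeds come from `SeedSequence(seed).spawn(n)`, so results are
reproducible. Replicates whose resampled matrix has undefined pairs are
dropped; support is the percentage of *kept* replicates containing each
original bipartition. Bipartitions are canonicalised as the side not
containing the alphabetically first leaf. Supports are attached as
internal node names.

Monophyly is assessed on the unrooted topology: a species is
monophyletic if its leaf set (or its complement) is a bipartition;
singletons are reported as `trivial`; failures list the species found
inside the smallest covering clade.

## Statistical parsimony networks

Specimens collapse to haplotypes; two sequences match if they are equal
at every site informative in both (so `N`/gaps/ambiguities are
wildcards; `strict=True` requires literal identity). Ambiguity-wildcard
merging canonicalises to the most-informative member.

The **connection limit** is the largest step count *j* whose parsimony
probability is ≥ the confidence level. The probability model is: given
two sequences of length *L* separated by a Poisson(λ) number of
substitutions under a Jukes–Cantor site model, a site hit *k* times
shows a visible difference with probability ¾(1 − (−⅓)ᵏ); conditioning
on an *observed* difference of *j* sites, the parsimony probability is
the posterior probability that no extra (superimposed) changes occurred,
with λ calibrated so the expected observed difference equals *j*. The
implementation is validated against a Monte-Carlo simulation of that
exact process in the test suite. Frozen reference values:
`connection_limit(658, 0.95) = 8`, `(658, 0.90) = 11`,
`(360, 0.95) = 6`, `parsimony_probability(8, 658) = 0.952088…`.

The network joins haplotypes in increasing mutational distance while the
distance is within the limit, keeping a forest of unique shortest
connections; equal-length alternative connections are recorded in
`equal_length_alternatives` rather than drawn, so the canonical output
has no reticulations. Pairs beyond the limit are refused, which is what
splits deep intraspecific lineages into separate subnetworks;
`subnetwork_gap` reports the minimum steps between subnetworks.

## Barcode-gap partitioner and sweep

One partition step sorts all defined pairwise distances and looks for
the **first significant gap**: consecutive sorted values whose
difference is positive, whose right edge is at or above the prior
ceiling *P*, and whose width exceeds *X* times the mean of a local
sliding window of differences (the candidate itself excluded from its
window; default window size scales with the number of pairs). If a gap
is found, single-linkage components below the gap become candidate
groups and each group is re-partitioned recursively; groups of fewer
than 3 specimens are flagged rather than split.

The **sweep** evaluates the partitioner over `geomspace(0.001, 0.1, 100)`
priors × `linspace(0.1, 10, 100)` gap widths (adjacent priors differ by
a factor ≈ 1.048, i.e. ~4.8% grid resolution). Results are cached per
recursion subproblem, which is what makes the 100 × 100 grid cheap.
Group counts are empirically monotone non-increasing in the prior
(asserted over the grid in the acceptance tests).

The per-species **estimator P** reads the narrow-gap column
(*X* = 0.1): the smallest grid prior at which the species' specimens are
lumped into one group, in percent. Species lumped already at the
smallest prior are censored `<0.1`; species never lumped are censored
`>10`. On planted two-lineage splits the estimator recovers the planted
divergence within one grid step in ≥ 90% of seeds, and a planted 23%
split is censored `>10` in 100% of seeds (both measured, not tuned).

## Synthetic libraries and ground truth

The generator evolves each species from a random ancestor using exact
substitution counts under a K80-style model with transition/transversion
bias κ = 4: `evolve_sequence(seq, n_steps)` applies exactly *n* single
site changes; `steps_for_divergence` inverts the K2P expectation by root
finding so a planted split realises its target percent divergence.
Planted regimes:

- background species with a few satellite haplotypes (1–3 steps);
- **sharing groups**: several species emitted from one shared haplotype
  (plus optional private satellites) — non-monophyly and zero distances;
- **anchored species**: a species placed a fixed small step count from
  another species' haplotype — sub-threshold interspecific distance;
- **deep splits**: one species carrying two lineages at a target percent
  divergence — deep intraspecific variation, two threshold clusters, a
  broken parsimony network;
- **truncation**: a fraction of records shortened (missing leading/
  trailing data) down to a floor above the inclusion rule.

Two soundness rules keep the planted truth well-defined:

- truncation is applied **only to structureless background species**, so
  it cannot erode a planted distance or sharing pattern;
- an anchored species' target must have a **single haplotype** (unless
  it is in a sharing group). Otherwise the anchor attaches at the centre
  of the target's star of satellites, the true tree contains a polytomy
  there, and the planted monophyly expectation would depend on how NJ
  happens to resolve it. The generator rejects such configurations.

The truth table records, per species, the planted lineage divergence,
expected monophyly status, expected threshold-cluster count and expected
cluster sharing. `compare_to_truth` joins it against an audit report and
returns the discrepancies (empty on all presets).

The preset scenarios' parameters (seeds included) are fixed study
conditions; analysis code is never adjusted to them.

## Audit orchestration

`run_audit` chains: length filter → composition → K2P matrix →
threshold screens and clusters → bootstrap NJ + monophyly → per-genus
parsimony networks → gap sweep + estimators. The **identification
rate** is the percentage of species that are monophyletic (or trivial)
*and* share no threshold cluster with another species. Defaults:
seed required, 1000 bootstrap replicates, 95% network confidence,
100 × 100 sweep. All report files are byte-identical across re-runs
with the same seed except `audit.log` (wall-clock stage timings);
`run_metadata.json` deliberately contains no timestamps.

## Limitations

- Single-linkage threshold clustering is a proxy, not the original
  barcode-OTU algorithms; cluster counts can differ on borderline data.
- The parsimony-probability model uses a Jukes–Cantor site process for
  the superimposed-change correction even though distances use K2P; the
  frozen limits match the conventional values, but intermediate
  probabilities are model-dependent.
- The gap partitioner's prior-monotonicity is an empirical property of
  the rule on these data, asserted but not proven.
- The simulator evolves sites independently (no rate heterogeneity,
  codon structure or indels) and plants at most two lineages per
  species.
- NJ is the only tree method; no likelihood or Bayesian cross-check is
  provided.
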