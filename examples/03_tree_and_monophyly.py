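"""Bootstrap a neighbour-joining tree and audit species monophyly.

A reference library works for identification when each species' specimens
form an exclusive clade.  This example builds the K2P NJ tree for the
haplotype-sharing scenario, attaches bootstrap supports, and reports which
species fail the monophyly check — by construction, the quartet sharing a
haplotype must fail, the rest must pass.
"""

from barcode_audit import (
    bootstrap_supports,
    generate_library,
    monophyly_report,
    preset_scenarios,
)

lib, truth = generate_library(preset_scenarios()["haplotype_sharing"])

tree, supports = bootstrap_supports(lib, n_replicates=200, seed=20140909)
print(f"{len(lib)} specimens; {len(supports)} internal bipartitions")
strong = sum(1 for v in supports.values() if v >= 95)
print(f"{strong} bipartitions with bootstrap support >= 95%")

report = monophyly_report(tree, lib.species_labels)
print("\nmonophyly report:")
print(report.to_string(index=False))

print("\nplanted expectation:")
for sp, status in sorted(truth.expected_monophyly.items()):
    print(f"  {sp}: {status}")

newick = str(tree)
print(f"\nNewick string is {len(newick)} characters; first 120:\n{newick[:120]}...")
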