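"""Windowed topology discordance on a simulated five-species alignment.

Loci are simulated under the MSC (0.5-unit internal branches, no gene
flow), concatenated into a reference-anchored alignment, windowed, filtered
(aligned length, missing rate, mean bootstrap — all strict), and each
window's NJ tree is classified by the position of the focal clade.
"""

from discordpan import (
    WindowFilterConfig,
    build_window_records,
    parse_tree,
    simulate_loci_alignment,
    topology_spectrum,
)

stree = parse_tree("((((A:0.5,B:0.5):0.5,C:1.0):0.5,D:1.5):0.5,O:2.0);")
aln = simulate_loci_alignment(stree, n_loci=100, locus_length=2000,
                              mutation_scale=0.05, seed=1)
cfg = WindowFilterConfig(window_size=2000, min_aligned=1000,
                         max_missing=0.20, min_mean_bootstrap=80)
groups = {"A": "PET", "B": "PET", "C": "ETB", "D": "LYC", "O": "OUT"}
records = build_window_records(aln, cfg, groups=groups, bootstrap=50, seed=1)
spec = topology_spectrum(records)

print(f"windows total/passed : {spec.n_windows_total}/{spec.n_windows_passed}")
print(f"distinct topologies  : {spec.n_distinct_topologies}")
for cls, frac in sorted(spec.class_fractions.items()):
    print(f"  {cls:28s} {frac:6.1%}")

print(
    "\nEven without gene flow a sizeable fraction of windows disagrees with\n"
    "the species tree — pure incomplete lineage sorting on short branches."
)
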