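"""Theta from matched trees, and the per-site ILS fraction.

Theta for an internal branch is its mutation-unit length (substitutions per
site, e.g. from a concatenation ML tree) divided by its coalescent-unit
length (e.g. from an ASTRAL tree) — a proxy for the effective population
size along that branch. The ILS fraction scores discordant derived-allele
sharing against the total segregating-site count.
"""

from discordpan import SitePatternCounts, estimate_theta, ils_fraction, parse_tree

mut = parse_tree("(((A:0.01,B:0.01):0.02,C:0.03):0.01,D:0.04);")
coal = parse_tree("(((A:1.0,B:1.0):0.5,C:1.5):1.0,D:2.5);")
for est in estimate_theta(mut, coal):
    print(
        f"branch {sorted(est.branch)}: mutation={est.mutation_units}"
        f"  coalescent={est.coalescent_units}  theta={est.theta}"
    )

counts = SitePatternCounts(c_baaa=2, c_abaa=2, c_aaba=2, c_bbaa=4, c_abba=3, c_baba=3)
print(f"\nILS fraction for the worked counts: {ils_fraction(counts):.4f}")
print("(= (3+3) / [(2+2+2 + 2*(4+3+3)) / 3] = 18/26)")
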