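"""Classify pan-gene clusters by occupancy and build accumulation curves.

A synthetic 45-accession presence/absence matrix is generated with the
published category proportions, classified (core = all 45, soft-core =
42-44, shell = 2-41, specific = 1) and summarized with a totally-random
pan/core accumulation curve.
"""

from discordpan import accumulation_curve, classify_clusters
from discordpan.simulate import simulate_presence_absence

mat, truth = simulate_presence_absence(45, 5000, (0.255, 0.112, 0.554, 0.079), seed=1)
cls = classify_clusters(mat)
print("category     count  fraction")
for cat in ("core", "soft_core", "shell", "specific"):
    print(f"{cat:10s} {cls.counts[cat]:7d}  {cls.fractions[cat]:7.1%}")
print(f"labels recovered exactly: {cls.labels == truth}")

curve = accumulation_curve(mat, n_combinations=100, replications=5, seed=1)
for k in (1, 5, 15, 30, 45):
    ki = k - 1
    print(
        f"k={k:2d}  pan={curve.pan_mean[ki]:8.1f}  core={curve.core_mean[ki]:8.1f}"
    )

print(
    "\nThe pan curve rises toward the full cluster count while the core curve\n"
    "falls toward the strict-core count as more genomes are added."
)
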