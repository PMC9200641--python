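"""Nei-Gojobori (1986) Ka/Ks on codon-aligned CDS pairs.

The classic hand-checkable example: TTT (Phe) vs TTA (Leu) has 2.5
nonsynonymous and 0.5 synonymous sites per codon pair, one nonsynonymous
difference, and Ka = -(3/4) ln(1 - (4/3) * 0.4) ~ 0.572.
"""

from discordpan import ng86_kaks

res = ng86_kaks("TTT", "TTA")
print(f"TTT vs TTA : N={res.N_sites}  S={res.S_sites}  Nd={res.Nd}  Sd={res.Sd}")
print(f"             Ka={res.Ka:.4f}  Ks={res.Ks:.4f}")

# a purely synonymous Gly change diluted over a few codons so pS < 3/4
res2 = ng86_kaks("AAAAAAGGT", "AAAAAAGGC")
print(f"...GGT vs ...GGC : Ka={res2.Ka:.4f}  Ks={res2.Ks:.4f}  (synonymous only)")

pair = ("ATGGCTAAGTTTGGA", "ATGGGTAGGTTAGGC")
res3 = ng86_kaks(*pair)
ratio = "undefined" if res3.ratio is None else f"{res3.ratio:.3f}"
print(f"5-codon toy: Ka={res3.Ka:.4f}  Ks={res3.Ks:.4f}  Ka/Ks={ratio}")

print("\nKa/Ks < 1 indicates purifying selection; ~1 is neutral evolution.")
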