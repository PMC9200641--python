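# Methods

## The multispecies coalescent simulator

Gene trees are drawn under the standard MSC on a rooted species tree whose
branch lengths are in coalescent units (one unit = 2N generations, the
ASTRAL convention). Within each species-tree branch, k lineages coalesce
with exponential waiting times at rate k(k−1)/2; lineages that fail to
coalesce pass to the parent branch, and the process continues above the
root until a single ancestor remains. Node ages are computed with all
leaves at time 0; the species tree is assumed ultrametric in coalescent
units (a non-ultrametric input is not rejected, but branch durations are
then taken from node ages, not edge lengths). When two species-tree nodes
share an age (a zero-length internal branch), merges process children
before parents, so the t → 0 limit yields the correct 1/3:1/3:1/3 quartet
distribution.

Introgression is a single discrete pulse: at time `t_m` each lineage
currently in the recipient branch relocates to the donor branch
independently with probability γ, per locus. This is the simplest model
under which the f4-ratio has expectation γ; `t_m` must fall inside both
branches' time spans, and γ = 0 reproduces the scenario-free run
bit-for-bit under the same seed. Random streams are split per locus from
the master seed (`default_rng([seed, locus])`), so increasing `n_loci`
extends a run without perturbing earlier loci.

The closed-form MSC quartet probabilities — concordant `1 − (2/3)e^(−t)`,
each discordant `(1/3)e^(−t)` for an internal branch of t units — serve as
the independent oracle for the simulator; the tests check all three at
t ∈ {0.1, 0.5, 2.0} within three binomial standard errors at 20,000 loci.

## Sequence evolution

Alignments evolve along gene trees under JC69: a uniform root sequence, and
per branch a per-site change probability `(3/4)(1 − e^(−4d/3))` where
`d = branch length × mutation_scale` is in expected substitutions/site; a
changed site picks one of the other three bases uniformly. This is the
exact JC69 transition kernel, not a Poisson approximation, so the pairwise
divergence matches the closed form `p = (3/4)(1 − e^(−4d/3))` at any d.
`mutation_scale` plays the role of a per-coalescent-unit θ-like factor;
0.01 is used for the 500-bp D-statistic loci (a realistic nuclear
diversity scale for the study system) and 0.05 for the 2-kb window loci,
where a little extra signal keeps per-window NJ inference reliable without
approaching saturation.

## Site-pattern statistics

Counting is frequency-weighted (Patterson/Dsuite style): per usable site
the outgroup consensus defines the ancestral allele; sites with a
polymorphic or missing outgroup, more than two alleles, or an empty group
are skipped; group derived-allele frequencies p1, p2, p3 then contribute
products such as `(1−p1)·p2·p3` to ABBA and `p1·(1−p2)·p3` to BABA. With
one haploid sample per group this reduces exactly to integer pattern
counting; a strict integer mode (group-consensus rounding, ties skipped)
is available behind a flag. `n_sites_used` counts usable segregating
sites, so with haploid single samples the six accumulators total at most
`n_sites_used` (the BBBA-type patterns are not tallied).

Uncertainty comes from a delete-one block jackknife: by default 20
contiguous equal-count blocks of usable sites, or BED-defined blocks when
supplied. The pseudo-statistic for each deleted block is recomputed on the
pooled remaining accumulators, `SE² = ((n−1)/n)·Σ(D₋ᵢ − mean)²`, and
`Z = D/SE`. If every block is identical the SE is zero: Z is reported as 0
when D = 0 and flagged undefined otherwise.

`f4(W,X;Y,Z)` is the mean over usable sites of `(pW − pX)(pY − pZ)`
(invariant to which allele's frequency is used). The f4-ratio α divides
two f4s over the same block structure and jackknifes the ratio directly;
the denominator must be significantly non-zero (|Z| ≥ 3 by default). The
shipped Patterson configuration for a recipient X, sister B, reference A,
donor C and outgroup O is `α = f4(A,O;X,B)/f4(A,O;C,B)`, whose expectation
is the pulse fraction γ.

The ILS fraction applies the printed per-site formula to pooled per-block
counts; a genome-fraction summary (share of blocks whose ILS value exceeds
a configurable cutoff) is provided but is explicitly a stand-in
aggregation — the genome-wide per cent in the original analysis was
produced by an unspecified per-SNP aggregation and is not reproducible at
desk scale.

## Window trees

Windows are anchored to multiples of the window size in reference
coordinates (0-based half-open everywhere; VCF's 1-based positions are
converted at the boundary). "Fully aligned length" counts columns with no
missing character in any retained taxon; the missing rate is missing cells
over all cells, with gap and N treated alike. All three filters are strict
inequalities, exactly as stated (> 10 kb, < 20%, > 80), so boundary values
fail. Trailing partial windows are retained but flagged and excluded from
the spectrum.

Per-window inference is neighbor joining on Jukes–Cantor distances rather
than per-window maximum likelihood — a deliberate design choice: the
discordance summary depends only on topology classes, and NJ is exact on
additive matrices, fast, and deterministic under a seed. Q-criterion ties
break by the lexicographic order of the joined clusters' smallest leaf
labels. Saturated pairs (p ≥ 3/4) receive a large-distance sentinel (10
substitutions/site) with a warning. Bootstrap supports are the percentage
of site-resampled replicates containing each internal bipartition. The NJ
oracle tests cover every unrooted 4- and 5-taxon shape, with the 5-taxon
result cross-checked against an exhaustive least-squares search over all
15 topologies and against scikit-bio's NJ on a noisy matrix.

Topology classification roots on the outgroup and requires each focal
group to be monophyletic; the class names the sister of the ETB-like
group, with everything else (including any non-monophyletic group) binned
as "other". The spectrum reports both the number of retained windows and
the number of distinct canonical topologies, since either reading of a
"distinct topologies" count may be wanted.

## Quartet-frequency comparison and theta

Induced quartets are resolved by the four-point condition on topological
(edge-count) leaf distances; ties (hard polytomies) are tallied as
unresolved and excluded from per-subset normalization. Observed and
simulated tables are compared by Pearson correlation over all
subset × topology pairs. θ per internal branch is the mutation-unit length
divided by the coalescent-unit length of the matched bipartition; zero
coalescent lengths are flagged rather than divided.

## Pan-genome

Classification uses occupancy bands that partition 1..n: core = n,
soft-core = [ceil(0.933·n), n−1] (equal to 42–44 at n = 45), specific = 1,
shell = the remainder. Matrices with fewer than five accessions are
rejected as degenerate. The synthetic generator assigns true categories by
largest-remainder apportionment of the requested proportions (defaults are
the published 25.5/11.2/55.4/7.9% split), draws occupancy uniformly within
each band, and places presences uniformly — by construction the classifier
recovers its labels exactly, which the tests assert.

Accumulation curves follow the totally-random design (500 subset draws per
genome count, 30 replications); when C(n,k) is within the budget all
distinct subsets are enumerated instead, which makes the toy-matrix means
exactly equal the exhaustive enumeration and the k = n point exactly
variance-free.

Ka/Ks implements NG86 only (the original analysis averaged 15 estimators
from a calculator suite; one fully specified method keeps the testable
surface identical while avoiding bulk): synonymous-site fractions from
each codon's nine single-nucleotide neighbors (mutations to stops count as
nonsynonymous), sites averaged between the two sequences, differences
averaged over all minimal mutational pathways with stop-crossing pathways
skipped and the remainder renormalized, then `pN = Nd/N`, `pS = Sd/S` and
the Jukes–Cantor correction. Proportions ≥ 3/4 are flagged saturated;
Ks = 0 flags the ratio undefined. Terminal stop codons are skipped;
internal stops are an error naming the codon.

## Problem sizes and numerical choices

The calibration studies use the scales stated with the design: 50
replicates of 2,000 loci × 500 bp for the D-statistic null and the γ = 0.3
pulse; 20,000 loci for the closed-form quartet checks. The end-to-end
self-consistency design uses 300 windows of 2 kb on a five-species tree
with 0.5-unit internal branches and `mutation_scale` 0.05 — sizes chosen
once as realistic desk-scale values giving reliable per-window inference.
All simulations are deterministic under their seed; seeds derived from a
master seed stay below 2³¹.

## Known limitations

- One haploid sample per species is the simulator default (multi-sample is
  supported); no recombination within loci, demographic size changes, or
  continuous migration.
- The JC69 generator does not emulate alignment error, indel structure, or
  base-composition bias, so passing tests demonstrate statistical
  correctness of the estimators, not robustness to real-data artefacts.
- The genome-fraction ILS summary is a labelled stand-in aggregation (see
  above).
- Species-tree inference itself (super-matrix ML, ASTRAL) and orthology
  clustering are out of scope; trees and presence/absence matrices are
  inputs.
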