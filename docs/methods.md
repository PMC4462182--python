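# Methods

This note documents the models, conventions and numerical choices
behind `rieskeq`, in the order the pipeline uses them.

## Sequence model and oligo metrics

Sequences are upper-case IUPAC nucleotide strings; `U` maps to `T` on
ingest. Gaps are legal only inside alignments — an oligo with a gap is
an error, not a warning. Matching between IUPAC codes is *set
intersection*: code X matches code Y iff the nucleotide sets they
denote overlap. Internally this is a 4-bit mask per position
(A=1, C=2, G=4, T=8), which lets the in-silico PCR matcher vectorize
over target positions.

**GC content.** The default convention counts only literal `G`/`C`
characters; ambiguity codes contribute nothing, including `S` (G or C).
This convention reproduces the printed GC values of the reference
primer panel. An alternate `mode="expected"` weighs each code by the
G/C fraction of its set (`S`→1, `Y`→0.5, …) for users who prefer an
expectation over a count. Two printed values in the reference panel
(the naphthalene-clade forward primer, printed 44 vs. computed 50, and
one reverse primer off by one point) cannot be reproduced under any
counting convention we tried and are treated as typographical errata;
the convention was not tuned to fit them.

**Degeneracy.** `n_degenerate` counts non-ACGT characters; `expansion`
is the product of per-position code cardinalities, i.e. the number of
distinct oligos in the synthesis mixture. A brute-force enumeration
oracle (explicit expansion of all variants) backs this in the tests.

## Distances and trees

Three pairwise distance models are provided. Sites where either
sequence carries a gap or ambiguity are excluded *pairwise* (pairwise
deletion), matching how distances on a gappy family alignment are
normally computed. The Tamura–Nei (TN93) closed form uses base
frequencies pooled over the whole alignment — a composite estimate —
and per-pair transition/transversion proportions. This approximates
the "maximum composite likelihood" distances produced by common GUI
phylogeny software; exact reproduction of any particular program is not
promised, and p-distance/JC69 are provided for testable closed forms.
All three models agree with `ape::dist.dna` (R) to 10 decimal places on
a frozen reference pair.

Saturated pairs (logarithm argument ≤ 0) are undefined. `pairwise_distance`
returns `nan`; `distance_matrix` substitutes a ceiling (default 5.0
substitutions/site) with a warning and lists the affected pairs, so
neighbour joining remains runnable on difficult inputs.

**Neighbour joining** is the standard Saitou–Nei algorithm with the
canonical limb-length formulas. On additive (tree-metric) input it
recovers the generating topology and branch lengths exactly; the test
suite verifies this on random trees against a tree→matrix oracle, and
cross-checks topologies against scikit-bio's independent NJ
implementation. Negative branch-length estimates are clamped to zero
and the clamped deficit is recorded in the tree metadata. Ties in the
Q criterion are broken lexicographically by index so output is
deterministic.

**Bootstrap.** Columns are resampled with replacement per replicate
(seeded NumPy generator); the support of each internal edge of the
reference tree is the percentage of replicates whose NJ tree contains
the same bipartition. Replicates containing an undefined distance are
dropped and counted; the effective replicate count is reported. The
production default is 2000 replicates; tests use 100 for desk scale,
which is ample for the clean splits they assert on.

**Clade PD.** Both the mean and the maximum pairwise distance among
clade members are reported; design *eligibility* uses the mean
(`pd_mean < 0.29` by default), since the threshold describes the
typical relatedness of a clade rather than its worst pair. Singleton
clades have PD 0 and are trivially eligible.

## Primer design

Candidates are windows of 16–20 alignment columns. Each column is
collapsed to the minimal IUPAC code covering every residue observed in
the clade, so every member matches every candidate with zero mismatches
*by construction* — this is asserted, and it is what makes the
100 %-coverage guarantee structural rather than empirical. Windows
containing a gap in any member are invalid. An optional mode ignores
residues below a frequency cutoff (5 % is a reasonable choice for noisy
large clades); in that mode coverage is computed, not guaranteed, and
filtered against the required level.

Filters, in evaluation order (cheap first):

* **degeneracy** ≤ 3 ambiguous positions (expansion consequently ≤ 64);
* **GC** ≤ 60 %, *soft*: violators are kept but penalized in ranking,
  because the reference panel itself contains 63–65 % GC primers —
  practice overrides the stated rule;
* **self-complementarity**: the longest complementary run between the
  oligo and itself (any offset, IUPAC intersection as match) must be
  < 4 nt, and any run touching the 3′ terminus < 3 nt — dimers that
  can extend are the dangerous ones;
* **Tm**: nearest-neighbour estimate (Biopython's SantaLucia
  parameters) at 50 mM monovalent salt and 250 nM oligo, mean over all
  expansions of a degenerate oligo, required to fall in 55–70 °C.
  A Wallace-rule (2AT+4GC) estimator is available for quick checks.
  Published annealing temperatures are empirically optimized values
  and are treated as data, never as a Tm oracle.

Coordinates are 1-based on the ungapped model reference sequence of the
clade (first alignment record by default). A reverse candidate is
stored as the synthesized oligo (reverse complement of the sense
window); its `start` is the sense coordinate of its 5′ base — the
3′-most template position it covers — so a pair's expected amplicon is
the inclusive span `reverse.start − forward.start + 1`. Printed
position/amplicon arithmetic in the reference panel is internally
inconsistent for some rows; where they conflict, the printed amplicon
sizes are taken as authoritative. Pairs are accepted for amplicons in
[60, 300) bp and ranked lexicographically by (total expansion, amplicon
length, |Tm_F − Tm_R|, GC violations), making output deterministic.

## In-silico PCR

`find_binding_sites` reports every position on both strands where the
mismatch count (IUPAC-intersection semantics) is within budget **and**
the 3′-terminal bases (default 2) match exactly. Site positions are the
1-based leftmost sense-strand coordinate of the footprint. The matcher
is verified against a naive sliding-window oracle on random targets.

Default mismatch budgets: **0** for coverage claims (the coverage
guarantee is a perfect-match property) and **2** for off-target risk
scanning. These are engineering defaults — wet-lab specificity checks
have no single in-silico equivalent — and reports state the budget
used. A primer set is *specific* iff its target-clade coverage reaches
the required level (default 100 %) and every non-target clade shows
zero amplifiable sequences.

## qPCR mathematics

Standard curves regress Ct on log10(copies) — slope ≈ −3.32 at 100 %
efficiency — by ordinary least squares; the QC window is efficiency in
[90, 110] % with r² > 0.99. Copy numbers of plasmid standards follow
from the construct mass at 660 Da per base pair (default vector
3973 bp plus insert). Quantification inverts the curve,
`copies = 10^((Ct − b)/a)`, scales by the template dilution factor and
normalizes per gram (or ml) of matrix; estimates outside the standards'
span are flagged rather than truncated.

Melt peaks are called on −dF/dT (central differences) smoothed with a
3-sample moving average; the prominence threshold defaults to 5 % of
the profile maximum. Both values are conventional rather than
principled and are exposed as parameters.

**Spike calibration.** The forward model is a weighted least-squares
fit of measured on true log10 abundance (weights 1/sd²; a zero SD is
floored to the smallest positive SD present so its weight stays
finite), giving `LogC_m = a·LogC_real − b`. The correction is the
algebraic inverse `LogC_real = (LogC_m + b)/a`, so round-tripping is
exact by construction, and the reported SEs of (a, b) propagate to the
corrected value to first order. Fitting the forward direction and
inverting — rather than regressing true on measured — keeps the
coefficient uncertainties attached to the line that was actually
measured. Ct determination from raw fluorescence is out of scope:
instruments define their own thresholds, and the toolkit consumes Ct
tables.

## Synthetic data

`simulate_clades` generates a root sequence, clade ancestors at
`between/2` substitutions/site from the root, and members at
`within/2` from their ancestor, under a uniform (Jukes–Cantor-like)
substitution process: per site, the probability of differing after a
branch of length *t* is `(3/4)(1 − e^(−4t/3))`. Defaults — 10 clades ×
5 members, 1400 bp, within-clade divergence 0.10, between-clade 0.90 —
put within-clade PD well under the 0.29 design threshold and
between-clade p-distances near saturation, the regime in which
clade-specific design is realistic for this gene family. Divergence
targets above 3 substitutions/site are rejected as saturated.

Two short "pinned" blocks (24 bp at positions 200 and 400 by default)
are exempt from *within-clade* mutation, emulating the functionally
constrained motifs (such as the Rieske-centre coding region) that real
primer design exploits; the blocks still mutate on the root→ancestor
branches, so they carry clade identity and do not compromise
specificity. Their root composition is drawn at 60 % GC so conserved
windows have primer-like melting temperatures. What the simulator does
**not** model: indels, rate heterogeneity, codon structure, base
composition bias, or chimeric sequences — so passing tests demonstrate
the correctness and internal consistency of the algorithms, not
recall/precision on real gene libraries.

The qPCR generators draw Ct values and spike measurements directly from
the linear models plus Gaussian noise, at the designs the analysis
expects (nine-decade dilution series; three spike levels at 10^7–10^9
with 12 replicates, σ = 0.05 log units).

All generators, the bootstrap, and every stochastic test are seeded;
identical seeds give byte-identical output files.

## Problem sizes and limitations

Tests and the acceptance checks run at desk scale: bootstrap at 100
replicates, NJ oracle on 4–8-taxon trees, design on 10 clades × 5
members × 1400 bp (a few seconds end to end). The candidate scan is
O(alignment length × lengths × members) per clade and comfortably
handles full-gene alignments; the all-pairs distance matrix is
O(n²·L) and is the practical bound for libraries beyond a few thousand
sequences. Known limitations: no thermodynamic (ΔG) off-target
ranking, no multiplex compatibility scoring, no probe design, no
maximum-likelihood tree inference, and no remote-database screening —
the in-silico specificity screen is only as good as the library it is
given.
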