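# Methods

This note records the models, parameter choices and numerical policies
behind `amoebascan`, and what the synthetic-data experiments do and do
not demonstrate.

## Alien Index

The Alien Index of a gene is

    AI = ln(bbh_recipient + c) − ln(bbh_donor + c)

where `bbh_recipient` is the best (lowest) e-value among hits to the
recipient group (default: Eukaryota) and `bbh_donor` the best e-value
among hits to the donor group (default: Bacteria ∪ Archaea ∪ Viruses).
Published applications of the index state the threshold (AI ≥ 45) but
not the logarithm base, pseudo-count, or missing-hit convention, so
these are fixed here as explicit defaults and written to every run
manifest: natural logarithms, pseudo-count `c = 1e-200` (keeps AI
finite when BLAST prints an e-value of exactly 0), and a default
e-value of 1.0 for a side with no hit. E-values above 1 are clamped to
1, which gives the exact bound `|AI| ≤ 200·ln 10 + ln(1 + c)` attained
at (1.0, 0.0). The threshold comparator is `≥` and configurable; the
candidate set is monotone non-increasing in the threshold. A
self-lineage exclusion (e.g. dropping Amoebozoa hits from the recipient
side) exists but is off by default.

Group membership tests every lineage rank, not just the superkingdom,
so donor groups can be defined at any granularity. Donor attribution
takes the single best donor-side hit (minimum e-value, ties broken by
bitscore then subject id) and reports the lineage rank immediately
below the superkingdom as the donor phylum.

Numerical accuracy: the double-precision evaluation agrees with
50-digit decimal arithmetic to better than 1e-9 relative error over
e-values down to ~1e-150. Differences between two e-values that are
*both* far below the pseudo-count (≪ 1e-200) are not resolvable in
double precision; such inputs do not occur for clamped BLAST output.

## Contamination screening

A scaffold is a contaminant only under the conjunction of three
criteria: (1) taxonomy call ≠ eukaryote (including no-hit), (2)
|gc − gc_center| > gc_delta, (3) coverage < 10. The taxonomy call uses
the superkingdom holding the majority of summed bitscore among hits at
e ≤ 1e-3 ("bestsum"; a single-best-hit rule is available), with ties
resolved toward eukaryote because the screen is meant to err toward
retaining host genes. The GC band is a design choice — the criterion
"low or high GC" needs a number — and defaults to a symmetric
`gc_delta = 0.08` around the assembly-wide length-weighted GC; both are
recorded in the manifest. Missing coverage leaves the coverage
criterion undefined and retains the scaffold with a warning. A
whitelist file substitutes for curation steps (e.g. ortholog-informed
rescue) that are out of scope.

N50 is the length of the smallest scaffold in the minimal
descending-length prefix whose cumulative length reaches half the
total; it is validated against a brute-force scan on random multisets.

## Taxonomic partition

Best hit = minimum e-value among hits with e < 1e-3 (strict, per the
printed inequality; configurable), ties broken by maximum bitscore then
lexicographic subject id, making classification order-independent. No
qualifying hit ⇒ ORFan. The partition is exhaustive and exclusive, and
raising the cutoff can only move genes out of, never into, the ORFan
class.

## Alignment, SSU divergence, NJ corroboration

Global alignment is Needleman–Wunsch with a linear gap penalty
(defaults +1/−1/−2) and deterministic traceback preferring diagonal
over up over left; the row recurrence is vectorized by rewriting the
left-gap chain as a running maximum. Affine gaps (separate open/extend)
delegate to Biopython's `PairwiseAligner`. Divergence is
1 − matches/columns with terminal gap columns excluded and internal gap
columns counted as differences — a p-distance convention chosen because
the source analyses never define theirs; both policies are options and
are manifest-logged. Scores are cross-checked in tests against
exhaustive alignment enumeration, Biopython, and edlib edit distances.

The SSU report computes the full pairwise divergence matrix and passes
when the maximum stays below 3%, the conventional species-level bound
for intragenomic SSU variation.

Neighbor joining (scikit-bio's implementation behind this package's
surface) replaces maximum-likelihood tree inference as the LGT
corroboration engine — a deliberate simplification: deterministic,
fast, and consistent on additive matrices, but without model-based
branch support; every corroboration output carries a disclaimer field.
Negative NJ branch lengths are clamped to zero unless requested
otherwise. Before the nesting check, internal branches of length ≤
1e-9 are collapsed into polytomies so that arbitrary resolutions of
ties cannot masquerade as clades; the candidate is `nested_in_donor`
(or `_in_recipient`) when the smallest bipartition side containing it
holds only donor (or only recipient) companions, and `unresolved`
otherwise, including when minimal sides disagree.

## Toolkit inventory and detection

Genome *presence* (≥ 1 distinct gene-model subject at e ≤ 1e-15 for a
query protein) and transcript *detection* (sample value ≥ 1 unit) are
deliberately separate outputs: a gene can be genome-present yet
undetected in every sample, as the data show for one SPO11 copy.
"Detected" has no published quantitative definition, so the
threshold-in-one-sample rule is this package's explicit default. The
meiosis-toolkit completeness flag requires all 12 canonical genes
(SPO11, DMC1, HOP1, HOP2, MER3, MND1, MSH4, MSH5, ZIP1, PCH2, REC8,
ZIP4).

## Synthetic-data generator

The generator emulates the statistical structure of the real study and
plants ground truth for every downstream stage. Defaults:

| parameter | default | origin |
|---|---|---|
| host GC | 0.3769 | assembly GC of the emulated genome |
| contaminant GC offsets | ±0.15 | places contaminants well outside the 0.08 band |
| host coverage | Normal(50, 8), floor 12 | comfortably above the 10× cutoff |
| contaminant coverage | Uniform(1, 8) | below the cutoff |
| category proportions | 0.476/0.265/0.190/0.009/0.057 | published partition (normalized from a 0.997 rounded sum) |
| bacterial LGT fraction | 0.1047 | 546 of 5210 bacteria-matching genes |
| archaeal / viral LGT fraction | 0.077 / 0.73 | 19 archaeal candidates; 73% of viral genes above threshold |
| bacterial donor mix | Proteobacteria 26%, Terrabacteria 28%, FCB 18%, PVC 11.5%, other 16.5% | published donor distribution |
| viral donor mix | Mimiviridae 98% (Harvfovirus 37, Hyperionvirus 17, Klosneuvirinae 15, Tupanvirus 12, other 19), unclassified dsDNA 2% | published giant-virus mix |
| viral LGT intron fraction | 0.40 | published intron content |
| exon/intron sizes | means 7.7 exons, 154.3 bp exons, 75.4 bp introns | published gene-structure means |
| SSU copies | 22, max divergence 0.029 | published copy count, under the 3% bound |
| sample design | YT42–44 small, YT45–47 medium, YT48–49 large | published single-cell design |
| detection probabilities | small 0.15, medium 0.65, large 0.75 | reproduces the medium/large-skewed detection pattern |
| toolkit | SPO11/ZIP4/BIK1 two copies, GEX1 absent, placeholder presence 0.82 | published copy numbers; yields ~87% of 95 queries found |

The e-value separation laws are invented (the real analysis gives only
the threshold): a gene's true-origin side draws log10 e ~ U(−180, −60)
and the opposite side is absent or weak (log10 e ~ U(−3, 0)), so every
planted LGT has AI ≥ 3·ln 10 − (−60·ln 10) ≈ 131 ≫ 45 and every
non-LGT foreign-category gene has its donor hit undercutting the
recipient hit by at most 10 decades (AI ≤ 23 ≪ 45). Recovery is
therefore unambiguous by construction — the planted-truth tests
validate the *machinery* (grouping, clamping, thresholding, joins), not
the discriminative power of the index on borderline real data. ORFans
receive nothing below e = 2e-3. Contaminant scaffolds receive bacterial
scaffold-level hits (plus an occasional weak spurious eukaryote hit);
host scaffolds receive amoebozoan hits.

One global seed is split into named per-stage streams (assembly, genes,
hits, toolkit, ssu) via `numpy.random.SeedSequence.spawn`, making all
outputs byte-identical under a repeated seed while letting stages be
regenerated independently. SSU copies are substitution-only mutants of
one ancestor, each holding at most `L·d/2` substitutions so all
pairwise divergences respect the bound exactly; an indel-free design
keeps the divergence oracle closed-form. Scaffold lengths are lognormal
with a 6 kb median and a 1 kb floor — far below real scaffold scale, a
size chosen to keep simulated assemblies small while leaving GC and
coverage laws untouched. Detection values are Bernoulli per condition
with a planted-pattern override used to reproduce specific published
rows.

What the generator does **not** emulate: amplification bias, chimeras
and real coverage heterogeneity of single-cell assemblies; homology
structure within lineages (hits are drawn independently per gene);
expression levels beyond presence/absence; indels and rate variation
in SSU copies. Green planted-truth tests therefore say nothing about
detection power on data that violate these simplifications.

## Problem sizes and determinism

The shared test bundle uses 30 scaffolds and 800 genes; planted-truth
recovery runs 50 bundles at 2,000 genes; partition convergence uses
10,000 genes (±2 points); the acceptance script reports a 27,369-gene
run with 200 scaffolds. All randomized tests use fixed seeds or
derandomized property-based settings. The assembly-statistics check
against the deposited accession requires downloading ~70 Mb from
GenBank and is the only network-dependent test.
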