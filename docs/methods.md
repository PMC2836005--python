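# Methods

This note records how each stage works, the parameters that matter, and
the design decisions taken where the problem was genuinely open. It is
the place to look before changing a default.

## Synthetic genomes (`synthdata`)

The generator is the package's ground-truth instrument: it plants
elements with the structure the annotation stages assume and emits their
exact coordinates, TSDs and gene models.

**Element architecture.** An element is `TIR5 + interior +
revcomp(TIR5)`. The 5′ arm begins with a concrete realisation of the
TGTNR terminal motif; the interior carries a transposase CDS
(`M + peptide + TAA`, codons drawn uniformly among synonyms) optionally
split by introns written as `GT…AG` (GC-AG or GT-TG only on request),
padded with random sequence to the requested element length. One
template is built per family spec and every copy is an insertion of that
template plus independent per-site substitutions at `copy_divergence` —
so copies are genuine copies, families cluster as families, and a
consensus rebuilt from them converges on the template.

**Insertion.** Ginger1-type: the 4-mer at the target site is rewritten
to a draw from the TSD profile (default CCGG 0.75, CCGT 0.12, ACGG 0.12,
other 0.01 — the composition table used for the group's logo) and
duplicated on both flanks. This rewriting, rather than searching for
pre-existing CCGG sites, gives exact control of composition at any n.
Ginger2-type: the site is rewritten to a realisation of RTATAY and its
central 4-mer (TATA-like) is the duplication, flanked by the R and Y
context bases. Sites are placed non-overlapping with ≥30 bp spacing and
away from contig edges.

**Synthetic proteins.** The transposase peptides are synthetic: explicit
motif blocks (YPYY; H-x3-H…C-x3-C; D-x60-D-x30-E; GPY near the integrase
C-terminus; OTU/Ulp1/PHD-style tails) joined by filler drawn from an
alphabet that deliberately excludes the residues the motif patterns
anchor on (C, D, E, G, H, N, P, Q, F, Y). Each pattern therefore occurs
exactly where planted. The Ginger2 peptide carries the zinc finger and
DDE blocks but neither YPYY nor GPY/F — the group's defining absence.
The RT/RNase-H panel peptides are random synthetic stand-ins (they only
need to be findable by the homology scan, not realistic).

**What the generator does not emulate.** Background is i.i.d. with a GC
dial — no repeat landscape, no nesting, no excision footprints, no
indels (divergence is substitution-only, which is also why divergence is
measured under pairwise deletion). Flanks are never mutated, so TSDs are
always exact in truth; in real genomes old TSDs decay. A "decoy inverted
repeat" option exists for stress-testing the TIR detector. Passing tests
therefore demonstrate correctness of the method's logic under its own
model, not performance on real assemblies.

## Discovery (`discovery`)

Six-frame translation (standard code, stops as `*`) plus Smith–Waterman
(BLOSUM62, gap open −11 / extend −1, via Biopython's PairwiseAligner)
of a query panel against 2-kb windows with 50% overlap. A window is only
aligned when one of its frame translations shares an exact 5-residue
word with the panel — the BLAST-style word seed that keeps a
multi-megabase scan at a few seconds. The default score threshold is a
raw 60; at that threshold a weak chance hit appears roughly once per few
hundred kb of random sequence, which downstream stages tolerate (such
hits have no TIRs and classify as vestiges or are absorbed into real
elements). Overlapping or near-adjacent hits (≤300 bp, i.e. a short
intron) merge keeping the best score; the gap is deliberately small so
neighboring elements are never fused.

## Boundary refinement (`structure`)

Given a transposase hit, candidate 5′ termini are TGTNR matches upstream
and candidate 3′ termini are YNACA matches downstream (within
`search_radius`, default 10 kb). A candidate pair must carry an exact
flanking duplication (longest k in 3..6; exact match only — allowing
mismatches would flood 4-mers with chance TSDs) and a TIR arm alignment
(match +1 / mismatch −1 / gap −2, arms anchored within 5 bp of the
termini, identity ≥0.8, arm ≥25 bp). In parallel, one local
inverted-repeat alignment of ≤5-kb segments flanking the hit proposes
arm ends directly; its candidates rescue elements whose terminal motif
mutated away — without it, a chance TGTNR *inside* the left arm (whose
mirror-image YNACA necessarily sits inside the right arm) anchors a
shrunk, weaker-armed candidate.

**Selection.** Rank by TSD presence (boolean — ranking by TSD *length*
lets a chance longer flank k-mer drag a boundary off the true terminus),
then by arm score + 25 per matched terminal motif; within a 20-point
band, the minimal span bracketing the hit wins. The band absorbs
arm-score noise between a true element and a candidate spanning it plus
a same-template neighbor (whose arms align exactly as well, because the
copies are copies). Residual ambiguity exists: if a terminus mutates
*and* a chance duplication sits within a few bp of the true end, the
detector can legitimately settle 1–2 bp off with a different TSD length;
this is rare (order 1 in 10² elements at 1% divergence) and irreducible
from structure alone.

The pipeline adds one resolution layer: annotations from all hits are
accepted minimal-span-first; a hit whose annotation overlaps an accepted
one is re-refined with the accepted territory excluded. This handles the
case where a hit's own 3′ motif is dead and its best per-hit candidate
spans into the neighbor.

`find_tirs` itself reports the maximal-scoring arm pair; at zero
divergence a planted arm can gain a few chance-matching bases of inward
extension, so recovered arm lengths can exceed the planted length by
O(1) bp on some backgrounds. Arms longer than `max_len` are reported
whole with a flag (published length ranges are descriptive, not
algorithmic), enlarging the alignment window as needed.

## Classification (`classify`)

Ordered rules; the retroelement veto first (if a 5-kb flank encodes RT
or RNase H, the integrase is read as part of an LTR element): then
TIR + 4-bp TSD with GPY/F or YPYY → Ginger1; without both → Ginger2;
TIR + 5-bp TSD → Ginger2_Tdd5like; transposase without TIRs →
vestige; else unclassified. The rules are exhaustive and mutually
exclusive by construction (property-tested over the feature lattice).
TSD composition (GC-rich vs AT-rich context) is recorded as evidence
only — composition is a tendency with exceptions, motif content is the
discriminator. Motif content comes from the *reconstructed* transposase
protein (spliced alignment against the panel homolog), not from raw
six-frame translations: GP[YF] is three residues and matches non-coding
frames by chance often enough to flip labels.

## Families (`family`)

Single-linkage clustering on global pairwise identity (threshold 0.80, a
conventional family cutoff), deterministic numbering by leftmost member.
Consensus is per-column majority over aligned copies; columns ≥50%
gapped are dropped; ties become IUPAC codes. Divergence is
100 × mismatches / compared columns with columns gapped in either
sequence excluded (pairwise deletion) — indels are not counted.
Length-identical copies (the generator's substitution-only regime) are
consumed as already aligned; otherwise the progressive aligner runs,
subsampling deterministically above 20 copies.

## Gene models (`genemodel`)

`reconstruct_cds` is a spliced alignment: a DP over (genome position,
homolog residue) in which each residue is emitted by a codon whose
bases may be interrupted by an intron after 0, 1 or 2 bases — so intron
phase falls out of the optimisation rather than being enumerated.
Introns must start GT and end AG (GC-AG and GT-TG admitted behind
`allow_noncanonical`), respect a 30-bp minimum, and cost a flat penalty
(−5) so splicing is only invoked when it pays. Codons are scored with
BLOSUM62; stops are prohibitive. The full homolog must be accounted for,
and the result is rejected below 0.5 × the homolog's self-score. No
protein gaps are modelled: this is homology-guided prediction for cases
where homology is strong (family copies, domesticated descendants), not
a general gene finder. The stop codon is not part of the model, so
reconstructed CDS ends 3 bp short of a planted CDS that includes it.

Intron comparison convention: an intron's position is the MSA column of
the last full codon before the splice; its phase is the number of bases
of the split codon on the 5′ exon. Conserved means same column *and*
same phase in every model.

Motif patterns are plain regexes with configurable spacing windows
(`[YF]P[YF][YF]`; `H.{2,6}H.{15,40}C.{2,6}C`; `D.{50,130}D.{25,50}E`;
`GP[YF]` restricted to the C-terminal third of the integrase region).
The OTU/Ulp1/PHD defaults are synthetic Cys–His–Asp protease-style
signatures that the generator plants verbatim; for real proteins they
should be replaced with alignment-derived patterns — they are stand-ins,
not curated profiles, and are exposed for exactly that reason.

## Phylogenetics (`phylo`)

p-distances use pairwise deletion by default (complete deletion
available); Poisson correction d = −ln(1−p); gamma correction
d = a((1−p)^(−1/a) − 1) with shape a = 2 by default (a config value, not
estimated). p = 1 raises an explicit error rather than silently emitting
infinity; bootstrap replicates that hit it are skipped and the support
denominator adjusted.

NJ is Saitou–Nei with the Q-criterion, ties broken toward the smallest
node-index pair, negative branch estimates clamped to zero (logged).
ME refits OLS branch lengths per topology and hill-climbs over NNI
moves. The ME criterion is the **sum of the raw OLS estimates**;
negative estimates are clamped only in the reported tree. Clamping
inside the criterion would reward topologies that generate negative
estimates — on additive data a wrong quartet fits a negative internal
branch, and its clamped total can undercut the true tree's. NNI-only
search is an approximation to coarser neighborhood schemes; it is exact
on additive matrices (verified against exhaustive topology enumeration
at ≤6 taxa).

Bootstrap resamples alignment columns, rebuilds per replicate, and maps
bipartition frequencies onto the full-data tree (not a majority-rule
consensus) — supports annotate the tree actually reported. Newick output
carries branch lengths and integer supports as internal labels;
round-trips are verified against dendropy.

The progressive aligner builds a guide order from p-distance NJ over
pairwise global alignments and merges profiles by global DP with
sum-of-pairs scoring (BLOSUM62 + linear gap −4 for proteins; +1/−1,
gap −2 for nucleotides), traceback ties diagonal > up > left. It is a
deliberately simple MUSCLE stand-in: adequate for the short, similar
sequences the pipeline aligns, not a general MSA tool.

## Logos (`logo`)

Column frequencies over equal-length TSDs; information content
IC = 2 − H with H in bits and 0·log0 ≡ 0; the optional small-sample
correction subtracts e(n) = 3/(2·ln2·n) (4-letter alphabet), floored at
zero. Off by default. PNG rendering sits behind a flag.

## Problem sizes

The bundled structural-recovery runs use 1–3-Mb genomes with 64–112
planted elements — large enough that composition percentages have
meaningful binomial error bars and adjacency effects between elements
actually occur, small enough to run on a laptop in minutes. The
conserved-intron and geometry checks are single-fixture and run in
seconds.

## Known limitations

- The generator's idealisations listed above; in particular, recovery
  rates on real assemblies (nested insertions, decayed TSDs, large
  introns) will be lower than on synthetic genomes.
- Discovery has no E-value calibration; the raw-score threshold is
  scale-dependent in principle.
- `shared_introns` assumes plus-strand gene models (all bundled fixtures
  are plus-strand); minus-strand models should be mapped through their
  plus-strand equivalents first.
- The ME search is NNI-only and can in principle stop in a local
  optimum on non-additive data.
- Classification follows the published decision rules exactly; an
  element whose extracted duplication is 3 or 6 bp long (possible by
  chance context around a genuine 4-bp TSD) is left unclassified rather
  than forced into a group.
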