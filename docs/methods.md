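# Methods notes

This note documents the models, defaults and design choices behind
`barcodiag`, and what the synthetic benchmarks do and do not demonstrate.

## Sequence handling

Sequences are DNA over the full IUPAC alphabet; ambiguity codes compare by
base-set intersection and the gap character never matches anything (gaps
are handled explicitly by alignment-aware code, not by the matcher).
Bidirectional Sanger reads of one amplicon are merged ungapped over their
best suffix/prefix overlap (default `min_overlap=20`,
`max_mismatch_frac=0.05`; chromatogram pairs rarely need indels).  Without
quality data there is no principled way to arbitrate a discordant overlap
position, so disagreeing bases become `N` and compatible ambiguity codes
collapse to their intersection.

## Alignment and trimming

The built-in aligner is a deterministic progressive scheme: k-mer (k = 6)
distances, UPGMA guide tree, profile–profile Needleman–Wunsch with affine
gaps (defaults match +1 / mismatch −1 / open −6 / extend −0.5, ties resolved
diagonal-first).  It is adequate for the low divergence of intra-genus
barcode sets and keeps the pipeline free of external binaries; for
production work alignments from MUSCLE/MAFFT are imported verbatim via
`import_alignment`, which is also how every ground-truth alignment enters
the test suite.

Trimming to the primer interior locates both universal primers on the
column-wise majority consensus — individual rows with sequencing errors
therefore cannot shift the trim coordinates — and keeps the columns
strictly between the two primer intervals.  All-gap columns created by
trimming are retained and counted; the trim report carries both the
gap-inclusive and gap-free widths because published column counts do not
always state which convention they use.  Coordinates are 1-based inclusive
throughout.

## Distances, neighbour joining, bootstrap

`pairwise_distance` supports p-distance, JC69 and K2P (the default; the
model choice does not move the well-separated splits these datasets
produce).  All ambiguity codes — not only gaps and `N` — are treated as
missing data, under pairwise or complete deletion.  Saturated corrected
distances (logarithm of a non-positive number) are flagged as infinite and
can be escalated to an error.

Neighbour joining follows Saitou–Nei with the standard Q-criterion.  Two
numerical conventions make the output reproducible and well-formed:
Q-ties are broken by the lexicographically smallest pair of cluster labels
(a cluster is labelled by its smallest leaf id), and negative branch
lengths are clamped to zero with the deficit moved to the sister edge, so
exported Newick is valid downstream.  On additive distances the algorithm
is exact; the suite verifies topology and branch lengths to 1e-9 on random
5–8 leaf trees.

Bootstrap replicates resample alignment columns with replacement; support
is the percentage of replicates whose NJ tree contains the same
bipartition, reported as integer percentages on the internal edges of the
point-estimate tree.  Rows are visited in id order during resampling, so
supports are invariant to input leaf order for a fixed seed.  A two-block
alignment with conflicting quartet signals calibrates to ~50% (ties in the
resampled column counts resolve deterministically, adding the tie
probability — a few percent at 200 columns — to one side).  Outgroup
rooting requires the outgroup to be monophyletic and splits the subtending
edge at its midpoint.

## Diagnostic sites and feasibility

The SNP scanner reports columns where the target rows are fixed for one
unambiguous base, the non-target rows carry bases from a disjoint set, and
no participating row has a gap; gap-containing columns belong to the indel
scanner, keeping SNP and INDEL calls disjoint.  `STRICT` (default)
disqualifies any ambiguity code; `COMPATIBLE` accepts codes whose base set
is consistent with the alleles established by the unambiguous rows of
their own group.  UNKNOWN-role rows (commercial samples) and OUTGROUP rows
never participate in discovery.  The grouping can also be given as a
species name or id set, which is how surrogate-private indels (e.g. a 9-bp
insertion in one species) are queried.

Site context is summarised as the GC fraction of the column-majority
consensus in a centred window (default 41 columns ≈ a primer footprint
plus margin).  The ARMS context screen enumerates every candidate primer
footprint with its 3′ end anchored on the site (both orientations, lengths
18–28) and declares the site infeasible only if *all* of them exceed the
AT threshold or melt too low — so relaxing `max_at` or `min_tm` can only
make sites feasible (monotone screen).  Defaults `max_at = 0.75`,
`min_tm = 55 °C` encode common primer-design practice: above ~3/4 AT there
is too little pairing energy left for a discriminating 3′ end.  The RFLP
screen compares target- and non-target-allele consensus sequences for
recognition-site gain/loss (both strands) over a built-in, user-extensible
table of 22 common 6-cutters.

## ARMS design and melting temperatures

The diagnostic primer is copied from the consensus of the group it must
amplify, 3′-terminal base exactly on the site column (reverse-complemented
for minus-strand primers).  "Third position from the 3′ end" counts the
terminal base as position 1.  The destabiliser base must pair with neither
group's template at that column; among the remaining candidates the one
forming the weakest mispair wins, using a fixed stability ranking of
mismatched pairs (G·T wobble strongest … C·C weakest), ties broken
alphabetically.  Primer length grows from the minimum until the
nearest-neighbour Tm enters the target range (default 55–68 °C), making
the design fully deterministic; the assay builder falls back to the
opposite orientation when a locally AT-poor footprint cannot reach the
range.  Designed primers satisfy two invariants checked by the tests:
exactly one mismatch against the intended template (the engineered one)
and at least two mismatches within the 3′-terminal three bases against
every other allele.

Melting temperatures: the Wallace rule 2(A+T)+4(G+C) (ambiguity codes
contribute their base-set midpoint) and a nearest-neighbour model with the
unified dinucleotide ΔH/ΔS parameters, entropic salt correction
0.368·(N−1)·ln[Na⁺] and duplex term R·ln(CT) with the primer assumed in
excess (defaults 50 mM Na⁺, 250 nM primer).  The implementation is
cross-checked in the tests against an independent ΔH/ΔS evaluation and
against Biopython's nearest-neighbour routine at matched settings
(agreement < 0.1 °C).  Published primer-datasheet Tm values computed under
unknown conventions are treated as descriptive metadata, not calibration
targets.

## In-silico PCR and verdicts

Annealing is ungapped with IUPAC-aware mismatch counting on both strands.
The ARMS abolition rule is encoded as: extension is blocked iff the
3′-terminal base mismatches, or ≥2 mismatches fall within the 3′-terminal
three bases.  Universal primers therefore anneal under a strict terminal
rule; the diagnostic primer is budgeted one 3′-window mismatch (its own
engineered destabiliser).  Every convergent forward/reverse site pair
within `max_amplicon` (default 3000 bp) yields an amplicon whose length
includes both primer footprints; bands within `size_tolerance` (default
10%, gel-level precision) of an expected size are labelled CONTROL or
DIAGNOSTIC, anything else OFF_TARGET.  Duplex patterns from the two
complementary assays combine into the verdict table shown in the README;
absence of the control band in both assays is reported as assay failure,
never as species absence.  Templates shorter than the shortest primer are
an error by default; fragmentation workflows pass `on_short="empty"` to
treat them as yielding no product.

## Synthetic genera: what they emulate and what they do not

The generator draws an ancestral sequence from a per-segment GC profile,
evolves it down a small species tree under Jukes–Cantor substitutions
(expected substitutions/site per branch), adds per-accession noise
(default 0.002), then deterministically overwrites the planted features:
universal-primer flanks at both ends, private SNPs, and lineage-private
insertions.  Around each planted SNP a ±34-column *guard window* is frozen
to the ancestral sequence in every row, so primer footprints are conserved
across species — emulating the empirically conserved context of usable
diagnostic sites and making ARMS discrimination deterministic.  A repair
pass reverts any *accidental* fixed target/non-target difference produced
by the background substitutions (one non-target row is set back to the
target allele), so the planted ledger is provably the exact set of
diagnostic features; the scanner itself is validated independently against
a naive per-column oracle, keeping that guarantee non-circular.  In the
default tree the target species sits on a zero-length terminal branch
(its accessions differ only by accession noise), which removes the main
source of accidental target-private substitutions.

Two default geometries mirror the two marker situations the toolkit is
built for.  The *coding-marker* genus (950 bp, GC ≈ 0.45) plants
target-private SNPs so the diagnostic amplicons land near 650 bp and
800 bp next to the 950-bp control, an AT-rich decoy SNP inside a 10%-GC
segment that must fail the context screen, and a 9-bp insertion private to
one surrogate.  The *spacer-marker* genus (450 bp ancestral length,
GC ≈ 0.27 with a 12%-GC segment spanning the informative region, realised
mean AT ≈ 75%) plants two target-private substitutions at positions 320
and 381 in AT-rich context (both fail the ARMS screen), a ~100-bp segment
private to one regional clade (median amplicon lengths ≈ 550 vs 450 bp)
and a 9-bp surrogate-private insertion.  Commercial "products" are copies
of target accessions with UNKNOWN role; fragmentation cuts each template
at uniform breakpoints into `round(len/mean)` pieces, so a 200-bp mean
guarantees loss of the long control amplicon.

Passing on these data shows the pipeline's logic is sound under its own
assumptions — fixed diagnostic sites with conserved context, no
chimeras or heteroplasmy, substitution-only background, error-free reads.
It does not demonstrate robustness to misassigned reference labels,
within-species polymorphism at the diagnostic site, mixtures of species in
one product, or polymerase-specific extension behaviour; mixtures in
particular are expected to produce AMBIGUOUS verdicts by design.

## Problem sizes

The test suite and acceptance script run at desk scale by choice: genera
of 5 species / 16 sequences × ~1 kb, 100 random trees and alignments for
the oracle-equivalence checks, 50 seeded genera for ground-truth recovery,
10 seeds for the end-to-end round trip, and 1000 bootstrap replicates
(matching standard practice) for support values.
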