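# Methods

## Scope and data model

`plastodeg` analyses annotated plastomes (GenBank flat files, or FASTA plus
annotation transfer) for structural architecture and per-gene degradation.
Internally everything is 0-based half-open with strand in `{+,-}`; GenBank's
1-based inclusive coordinates are converted only at the I/O boundary.
Multi-exon and *trans*-spliced genes are ordered part lists in transcription
order, so the spliced sequence is a concatenation; features crossing the
circular origin are stored as two parts.

## Quadripartite structure

**Repeat finding.** The core primitive enumerates *maximal inverted repeat
pairs*: maximal exact matches between the sequence and its reverse
complement, reported as arc pairs `(A, B)` with non-overlapping arms.
Implementation is k-mer seeding (k = min(21, min_len)) with per-diagonal
extension skipping; the test suite proves exact equivalence with an
O(n²) brute-force oracle on random strings ≤ 300 bp.  IUPAC ambiguity
codes never match.  Circularity is handled by doubling the sequence and
deduplicating modulo the length.

Plastome-scale defaults are `min_len = 10,000` and
`max_mismatch_frac = 0.005` (typical orchid IRs are 24–27 kb).  With a
mismatch tolerance, exact pairs ≥ 500 bp are chained across gaps ≤ 2 kb
when the merged identity stays above threshold.  This is what resolves an
IR carrying a one-sided insertion (e.g. a trnV-GAC duplicated within only
one repeat copy): the two exact pieces merge into one composite IR whose
identity is < 1.  A consequence is that the two IR hulls may then differ in
length by the inserted block; the reported Table-2-style "IR length" is the
IRA hull.  Since a plugin-default repeat finder is not reproducible, these
pinned parameters are this package's own, documented substitute.

**Partition.** The dominant pair defines the regions: SSC is the shorter
single-copy arc, LSC the longer; IRA is the copy adjacent to the SSC→LSC
transition.  Errors are explicit: no repeat ⇒ "no quadripartite structure";
two disjoint candidates within 80% of each other's length ⇒ ambiguity
error listing both.  The partition is invariant under rotation and under
reverse complement (up to the IRA/IRB label swap).

**Junctions.** A junction at position p belongs to the feature containing p
(half-open); otherwise the nearest flanking features are reported.  The
functional ycf1's overlap with the IR is measured on the full-length CDS
feature, not the fragment.  The IRB/SSC **boundary-shift flag** fires when
(i) ndhF has no locatable feature (or an optional call row says lost),
(ii) the junction lies in a spacer whose nearest SSC-side gene is rpl32,
and (iii) a ycf1 fragment is present at the IR side.

## Degradation classification

**Evidence.** Each reference exon is aligned (edlib, infix mode) against
both strands of the doubled genome.  Exons shorter than 50 bp are placed in
a window predicted from the catalog's intron-length hints relative to the
longest exon, preferring the co-optimal hit closest to the predicted
position — small splice-flanking exons (petB/petD/rpl16 exon 1) are
otherwise unplaceable by sequence alone.  A hit whose edit distance exceeds
80% of the exon length is treated as absent.

Reference bases count as *identified* when they lie in confident match
blocks: runs of ≥ 12 exactly matching columns, merged across gaps of ≤ 30
reference bases.  This keeps junk alignment smeared over deleted regions
from inflating coverage (a random alignment of length L contains an exact
12-run with probability ≈ L/4¹²), while point substitutions inside intact
sequence stay identified.  Codons are read off the aligned target at the
reference frame; when an aligner expresses a multi-substitution codon as a
net-zero indel combination, the codon is reconstructed from the target
between the nearest aligned anchors.  Indels are reported only inside
blocks; indels within 10 bp of each other are one event, and the frame is
preserved when every such cluster's net shift is a multiple of 3 (distant
compensating indels do *not* rescue the frame).

**Disruption.** `D = (deleted + inserted + 3·stops) / reference length`,
capped at 1, where deleted = reference length − identified-and-aligned
bases (so truncations and unrecovered internal segments count as deleted).
D is lesion-extent, not downstream-extent: a gene with one internal stop is
moderately pseudogenised, which matches how severities are reported in
comparative plastome studies (severe cases show large truncations, not
single stops).  A downstream-extent variant is available behind
`ThresholdConfig.downstream_extent` but is not the default.

**Categories.** lost ⇔ no evidence or coverage < 0.30 (coverage exactly
0.30 is *not* lost); else, for a CDS, functional requires an allowed start
codon (ATG, plus ACG where the catalog flags it — ndhD), no internal stop,
preserved frame, terminal stop, and D < 0.10; else moderate if D < 0.10,
severe otherwise (D exactly 0.10 is severe — the verbal rules "<10%" and
">10%" leave the boundary undefined, so it is pinned here).  RNA genes:
functional iff coverage ≥ 0.90 and identity ≥ 0.90; otherwise severity by
coverage.  For IR-duplicated genes the best hit per exon is evaluated,
which is the best-preserved copy — exactly the sample-level call wanted;
per-copy placements for the summary counts come from annotations.

**Annotation transfer** places each catalog gene's best non-overlapping
hits (up to expected copies + 1, so triplications are caught) as features
when block identity ≥ 0.90; hits recovering < 30% of the reference are
annotated as fragments.  Classification itself never reads annotations, so
it is identical whether a record carries planted truth or transferred
features.

## Synthetic plastomes

The generator emulates a ~150 kb circular orchid-type plastome: 79 CDS,
30 tRNA, 4 rRNA; rRNAs, 7 CDS (incl. the rps12 3' exons and ndhB) and 8
tRNAs duplicated in the IRs; rps12 trans-spliced with its 5' exon in the
LSC; the ndhC–ndhK–ndhJ operon adjacent in the LSC (12 bp spacers); the
SSC-resident ndh genes; ycf1 spanning the SSC/IRA junction with 500 bp
inside the IR and the corresponding fragment at the IRB end; psbA next to
the IRA/LSC junction.  Reference gene sequences are deterministic
pseudo-random stand-ins (fixed internal seed) with realistic lengths;
ndhB codon 68 is pinned to TTA on the minus strand so the classic
single-A→C stop lesion is reproducible, and ndhD starts with ACG.

Intergenic spacers are i.i.d. nucleotides; sizes are drawn from a seeded
lognormal with region-specific scale (LSC 420, SSC 200, IR 160 bp median)
and rescaled to hit the target length exactly.  Base composition (CDS
~38% GC, rRNA/tRNA ~52%, spacers 27%) was chosen so the whole genome lands
near the ~37% GC typical of orchid plastomes.  No repeats are injected
other than the IR itself, so repeat detection on fixtures is unambiguous.

**Events** edit the genome through the feature map: premature stops
(minimal substitution to TGA/TAA/TAG), frame-breaking and in-frame indels
(mid-exon), 3' truncations and whole-gene deletions (contiguous genomic
cuts), partial retention, plus structural ops.  Events on IR-duplicated
genes apply identically to both copies by default, preserving
IRA = revcomp(IRB).  The **boundary shift** is modeled as deletion-driven:
ndhF plus the residual spacer are removed so the IRB/SSC junction lands in
the rpl32-adjacent spacer next to the ycf1 fragment — the affected real
plastomes do not have longer IRs, and duplicative IR growth would disrupt
the functional ycf1 at the mirrored junction.  **Triplication** inserts an
extra tRNA copy 30 bp from the IRA copy, deliberately one-sided.

**Truth labels are computed, not asserted**: each gene's event list is
converted to the analytic `AlignmentEvidence` it implies and passed through
the same `classify_gene` the pipeline uses, so generator and classifier
share one source of threshold truth.  Unless an event is a declared
boundary probe, disruption avoids [0.08, 0.12] and coverage avoids
[0.25, 0.35], guaranteeing a margin around the category thresholds; the
parameter-recovery test then demands 100% category agreement.

The `dipodium_like` profile hard-codes the genus-wide observation that all
11 ndh genes are non-functional in every sample, with per-gene category
weights shaped like the observed pattern (ndhG almost always lost, ndhB/
ndhD/ndhJ never lost, ndhF severely truncated or — with the boundary
shift — fully deleted, occasional trnV-GAC triplication).

**What the fixtures do not model:** sequencing reads or assembly error,
evolutionary divergence of intergenic spacers, paralogy or organelle
transfer homology, codon-split splice sites, RNA secondary structure.
Passing on fixtures therefore demonstrates the *rules* are implemented
correctly, not that annotation transfer is robust to real interspecific
divergence.

## Reporting

The degradation matrix defaults to the 11 ndh genes in catalog order, rows
ordered by ladderized post-order tree traversal when a tree is given.  The
canonical output is a text grid (`F`, `P~`, `P!`, `L`) that parses back
losslessly; PNG rendering is optional.  Summary counts follow the
total-(unique) convention: totals count IR copies, uniques collapse each
IR pair to one (an extra copy beyond the pair still counts, so a
triplicated tRNA raises both).  A separate `functional_genes` column counts
distinct functional gene names; with pseudogene and lost counts it
partitions the catalog exactly.

## Problem sizes

The shipped study runs 24 simulated samples of 150 kb with all 113 catalog
genes classified per sample (~2,700 gene calls), and verifies the repeat
finder on 200 random strings; on one CPU the whole acceptance run takes a
few minutes.

## Known limitations

* Identity-gated annotation transfer on deeply diverged real samples may
  under-place genes; the 90% default matches common transfer settings.
* The per-cent-disruption formula is a pinned operationalization; published
  studies state the threshold but not the formula.
* The "lost" rule implements the mapping-detectability arm only (70%
  unidentifiable); absence from de novo assemblies is assembly-level
  evidence outside this package's inputs.
* tRNA pseudogenisation is diagnosed by coverage/identity, not structure.
* Exon placement of < 50 bp exons relies on intron-length hints from the
  reference; without hints such exons fall back to global search.
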