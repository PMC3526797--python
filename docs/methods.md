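# Methods

## The data-generating model

CRAC libraries are short (here 20–50 nt) strand-specific cDNA reads from RNA
fragments crosslinked to a protein of interest.  Three read-level signals
carry the biology this package quantifies:

1. **Microdeletions.**  Reverse transcriptase frequently skips the
   crosslinked nucleotide, leaving a 1–2 nt deletion in the cDNA.  Deletion
   positions therefore map binding sites at near-nucleotide resolution.
2. **Non-templated oligo(A) tails.**  The TRAMP complex adds short A tails to
   RNAs slated for exosome degradation.  A read whose 3′ end carries ≥ 2
   adenosines not present in the reference is called A-tailed; filtering
   tracks and tables on this flag separates surveillance intermediates from
   bulk binding.
3. **Junction reads.**  A read crossing an exon–exon junction can only come
   from spliced mRNA; one crossing an intron–exon boundary can only come from
   unspliced precursor (or the excised intron, which is indistinguishable).
   Their ratio (IE/EE), the intron-mapped fraction, and coverage around the
   two splice sites summarize precursor binding.

## The synthetic-data generator

`forge_genome` embeds non-overlapping features in a random chromosome:
intron-containing mRNAs with a bimodal intron-length mix (defaults ~80–120 nt
vs ~350–450 nt), intronless mRNAs, tRNAs with and without introns, snoRNAs,
snRNAs plus a U6 gene (`snR6`, the one Pol III snRNA), a desk-scale 35S rDNA
unit, 5S, CUTs, SUTs and scR1.  Features alternate strands so both
orientations are exercised.

`simulate_reads` draws each read by: class (configured weights) → feature
(uniform within class, with per-feature multipliers for condition contrasts)
→ template (precursor with probability `pre_mature_ratio`, else spliced
mature; precursors carry a 10 nt flanking extension so leader/trailer reads
exist) → start position (mixture of uniform and a Gaussian peak at the
crosslink site, default weight 0.6, sd 8 nt) → substitution errors → with
probability δ a 1-nt (p = 0.8) or 2-nt (p = 0.2) deletion at a covered
crosslink site → with class probability π_A an oligo(A) tail of length
2 + Geometric(0.5) − 1 → adapter fill to the 50 nt cycle length.  Every
event is written to a JSONL manifest keyed by read id; one integer seed
reproduces FASTQ and manifest byte-for-byte.

Default study conditions: class weights 30% 35S, 30% mRNA, 14% tRNA, 8%
snoRNA, 5% snRNA, 5% CUT, 4% SUT, 2% 5S, 2% scR1 — a plausible
nuclear-surveillance mixture with all three polymerases visible; π_A between
0.05 (mRNA) and 0.30 (tRNA); δ = 0.3 at one crosslink site per feature.

**Idealisations the simulator makes (and what tests therefore show).**

* *Crosslink sites sit in locally non-repetitive sequence.*  Inside a
  homopolymer or period-2 repeat the deleted base is mathematically
  unidentifiable from the read, so deletion mapping there is ambiguous for
  any method.  The generator rejects such positions; recovery tests measure
  the informative case, not repeat resolution.
* *The default adapter contains no adenosine.*  With an A-containing adapter
  a read can spell genomic bases + tail + adapter-fill that exactly equals an
  adapter prefix, an irreducible tail/adapter ambiguity.  Real small-RNA
  adapters do contain A; on real data a small fraction of tails adjacent to
  short adapter remnants would be lost.
* No PCR bias, paired ends, quality-score structure, or antisense
  transcription (antisense contamination is a config knob defaulting to 0).
  Passing tests show the analysis recovers the planted signal structure; they
  do not certify behaviour under amplification artifacts or repeat-family
  multi-mapping (tRNA families in real genomes).

## Read preparation and alignment

Duplicate reads are collapsed by full sequence identity (CRAC has no UMIs);
the multiplicity is retained and **all downstream counting weights each
unique insert by its multiplicity**, so every sequenced read contributes one
unit.  (Unit-weight counting is available by resetting `count`; on real,
PCR-amplified libraries it is the conservative choice, but on simulated data
multiplicity weighting is the faithful measurement.)

Adapter trimming removes the leftmost read suffix matching an adapter prefix,
allowing mismatches at a 10% rate of the overlap (exact below 10 nt, one
mismatch from 10 nt) and trimming sub-overlap run-ins (1–4 nt) only on exact
match.  Inserts shorter than 15 nt are discarded.

The built-in aligner anchors the read's 5′-most k-mer (default k = 12) by
exact hash lookup over both strands of the genome **and** the exon–exon
junction library, then extends 3′-ward with a small dynamic program: match
+1, mismatch −2, deletion −3 per deleted reference base, total deletion
budget 6 nt, no insertions.  Whatever suffix does not improve the score is
soft-clipped — that is where non-templated tails survive.  Ties break to the
lowest (reference, coordinate); reads with more than one distinct best locus
are flagged multi and excluded from counting.  A junction-entry placement
that stays on one side of the junction is canonicalised to its genomic locus
so it does not masquerade as a second locus.  The junction flank defaults to
60 nt (> max read length + deletion budget) so any junction-spanning read
fits an entry.  This is a desk-scale tool: real libraries should be aligned
externally and imported via SAM (`=`/`X` normalised to M; hard clips
rejected).

Against an exhaustive dynamic program over every placement (same scoring),
the aligner recovers the optimal score for effectively all lesion-free reads;
its one structural blind spot is a deletion inside the 5′ seed k-mer, which
costs ~2–4% of deletion-carrying reads at δ = 0.3 and is the reason mapped
fractions fall as lesion/error rates rise.

## Tail calling and deletion extraction

The 3′ soft-clip is never trusted directly: it is first re-extended base by
base against the reference downstream of the aligned 3′ end (in transcript
orientation); any matching prefix is templated.  The remaining suffix is the
candidate tail, called A-tailed iff ≥ 2 nt and all-A (a `tail_purity` option
relaxes composition).  A genomic A immediately downstream therefore absorbs
tail bases — deliberate, conservative, measurable on the simulator.
Deletion positions are read off the CIGAR, one event per deleted reference
base (matching per-base deletion-track rendering; per-read counting is a
one-line change at the call site).

## Attribution and normalization

Reads attribute to same-strand overlapping features; overlaps resolve by
class priority (rRNA_35S > rRNA_5S > tRNA > snRNA > snoRNA > scR1/other-PolIII
> CUT > SUT > mRNA > other — specific classes beat the mRNAs that host them),
then by greatest overlap, then lexicographic id.  Reads within ±50 nt of a
feature attribute to it as 5′/3′-flank, capturing precursor leaders and
trailers.  Everything else is intergenic, which stays in the hpm denominator:
hpm = 10⁶ × units / total mapped units, so every column of the per-RNA
matrix sums to exactly one million.

## Profiles and metagenes

Hit tracks add weight to M-covered reference bases, deletion tracks to
D-skipped bases; N gaps (spliced junction reads) cover nothing.  Filtered
(A-tailed) tracks keep the full-library denominator so they are pointwise ≤
the total track.  The pre-mRNA metagene anchors each spliced gene at its 3′
splice site (first intron for multi-intron genes — configurable), orders rows
by intron length, and reports raw hpm so expression differences stay visible;
a per-row-normalized export exists for display.  tRNA profiles anchor at the
mature 5′ end, rank by precursor length (intron included) and retain ±30 nt
of flanking coverage.

## Splicing statistics

A read counts toward a junction only if it covers the boundary with ≥
`min_overhang` aligned nt on each side (default 1, the most permissive rule;
the pipeline emits the counts so a {1,3,5} sensitivity sweep is a loop).  EE
requires an N gap exactly matching an annotated intron; IE requires
contiguous alignment across the boundary.  Ratios are computed per replicate
and averaged, SE = SD/√r; with one replicate the SE comes from a seeded
bootstrap over genes (1,000 resamples).  The 3′SS/5′SS ratio sums hit
coverage in ±10 nt windows around each splice site.

## Clustering and enrichment

Profiles are log₁₀(1 + hpm)-transformed before Pearson correlation; a
zero-variance row gets r = 0 (distance 1) with a warning.  Complete linkage
is implemented in-package so the tie-break is deterministic (smallest leaf
index pair); scipy's implementation is an independent cross-check in the
tests.  Both axes (mRNAs and experiments) are clustered, since either view is
informative.  Cluster × gene-set 2×2 tables use the closed-form chi-square
with 1 df and no continuity correction, switching to Fisher's exact test
(flagged) when any expected cell < 5; p-values are reported raw, with
Benjamini–Hochberg available as an option.  The number of clusters k is a
user choice (default 2); no automatic cut criterion is imposed.

## Problem sizes and numerical choices

Validation runs use 10,000 reads (tail exactness), 50,000 reads (class
recovery, crosslink recovery, each point of the five-point precursor-fraction
grid, each of eight clustering libraries) and 10,000 reads per experiment for
the double-run determinism check — sizes at which binomial noise is far below
the tested margins while a complete validation pass stays in the minutes
range on one CPU.  Genomes are ~10–16 kb with 18–31 features (≤ 5 kb with
intronless features only for the aligner-oracle comparison, where the oracle
is O(genome × read × deletions) per read).  Distance matrices are clipped to
[−1, 1] before 1 − r; bootstrap and linkage tie-breaks are seeded or
deterministic throughout, and the pipeline writes SHA-256 checksums of every
output so determinism is checkable byte-for-byte.

## Known limitations

No insertions in the built-in aligner; multi-gene families collapse to
multi-mappers and are dropped by default; non-A tails (e.g. CUCU) are out of
scope; deletion-in-seed reads are lost rather than rescued; IE/EE cannot
separate excised-intron binding from pre-mRNA binding — the intron statistic
inherits that ambiguity deliberately.
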