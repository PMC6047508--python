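# Methods

This note documents the algorithms, their assumptions, the tunable
parameters, and the limits of what the simulated-data tests can show.

## Coordinates, formats, alphabets

All coordinates are 0-based half-open in memory and converted to 1-based
only when SAM or VCF text is written. FASTQ is Phred+33 only (modern
Illumina); raw reads may contain `N` but no other ambiguity code, while
reference and consensus sequences use the full IUPAC alphabet. Alignments
are exchanged as SAM 1.6 text (optionally gzipped) rather than BAM:
byte-exact text output makes determinism checkable with a file compare,
and `samtools` converts losslessly when a binary file is wanted. Variant
sites go to a minimal VCF 4.2 with `DP` and allele-depth `AD` in INFO.

## Read cleaning

Trimming applies, in order: adapter clip → LEADING → TRAILING →
sliding window → minimum length. The adapter clip takes the *leftmost*
semi-global match of any adapter whose overlap with the read's 3' end is
at least `adapter_min_overlap` (default 5) and whose mismatch rate is at
most `adapter_max_mismatch_rate` (default 0.1), and truncates the read
at the match start. Overlaps shorter than the minimum are by construction
unclippable; a read whose insert happens to end in bases resembling an
adapter prefix is clipped early — an inherent false-positive mode of
overlap-based trimming, shared with the standard tools.

The sliding window (default 4 bases, mean quality 20) truncates at the
first window whose mean drops below the threshold, but retains leading
bases of that window that are individually at or above the threshold.

A pair survives only if both mates survive; surviving singletons go to an
unpaired file that downstream stages also consume.

The QC battery is a reduced, fully specified set of seven tests (per-base
quality quartiles, per-read mean-quality mode, per-base N fraction,
length uniformity, duplication level, adapter k-mer content by position,
per-position GC deviation from the file mean), each mapped to
pass / warning / fail at fixed thresholds. It is deliberately not a
re-implementation of any existing QC tool's internals; the thresholds are
stated in `cleaning.qc_battery`'s docstring and tested directly.

## De novo assembly

A single-k de Bruijn assembler over canonical k-mers (a k-mer and its
reverse complement count as one; capture reads come from both strands).
Defaults: `k = 31`, `min_kmer_count = 2`, `min_contig_length = 100`.

Graph cleanup alternates two operations to a fixed point (at most six
rounds):

- **Tip removal.** Dead-end unitigs shorter than `tip_length_factor × k`
  (default 4k = 124 bp at k = 31) are removed *only if every junction
  they attach to has an alternative edge on that side* — a tip must
  compete with another path. The bound covers one read length because the
  longest artifact a PCR-duplicated erroneous read can plant (its k-mers
  pass `min_kmer_count` twice over) is about one read. The competition
  condition protects real fragments stranded between a k-mer coverage
  hole and a branch point, which have no alternative.
- **Bubble popping by branch walking.** From every node with two or more
  successors, each branch is walked along its unique-successor chain (up
  to 3k nodes) until the walks reconverge. Equal-length branch pairs
  differing by at most ⌈k/10⌉ substitutions collapse onto the
  higher-coverage branch (ties break lexicographically). Walking ignores
  in-degree, so an error stub merging into a haplotype branch cannot mask
  the bubble; the orphaned stub becomes a tip for the next round.
  Indel bubbles (unequal branch lengths) are left alone — the default
  simulation model plants substitutions only, and collapsing unequal
  branches risks chimeric joins.

Contigs are maximal non-branching paths, orientation-normalized to the
lexicographically smaller of sequence/reverse-complement, sorted by
descending length then sequence, which makes assembly output
byte-deterministic. Paired-end information is not used (no scaffolding):
downstream stages need contig-level sequence only.

## Target-contig selection

Local alignment: exact affine-gap Smith–Waterman (match 1, mismatch −2,
gap open −5, gap extend −1; the first gap base costs the open penalty)
for sequence pairs up to 5 kb, seed-and-extend (exact 15-mers, merged
diagonal bands of width 31, exact SW inside the band window) above.
Both strands are tried; identity is matching columns over alignment
columns.

Hits have two tiers sharing the identity threshold (preset: 0.75 / 0.85 /
0.95):

- a **full hit** spans ≥ `min_coverage_of_locus` (default 0.5) of the
  locus and is required to *assign* a contig to a locus;
- an **evidence hit** spans ≥ `paralog_evidence_coverage` (default 0.25)
  and counts toward paralogy flagging.

A locus is excluded as potentially paralogous when two *distinct* contigs
have evidence hits whose reference intervals overlap by at least half of
the shorter interval. The overlap condition separates the two ways a
locus can attract several contigs: duplicate gene copies align to the
same stretch (paralogy), whereas complementary fragments of one broken
assembly tile the locus side by side (not paralogy). The lower evidence
tier matters because gene duplicates only a few percent diverged share
enough k-mers that a single-k de Bruijn graph fragments both copies —
their partial matches are precisely the duplication signal.

A contig with full hits on two or more loci (a long contig spanning
adjacent exons and their introns) is flagged multi-locus; when kept
(default) its *whole* sequence, introns included, is assigned to each of
its loci, since the interspersed introns carry most of the phylogenetic
signal. Multi-locus contigs excluded by the flag are removed before the
paralogy count, so a locus whose only other hit came from such a contig
counts as singly hit.

## Multiple sequence alignment and consensus

Per-locus MSAs are built progressively: all pairwise global alignments
(match 1, mismatch −1, open −3, extend −1) give a 1 − identity distance
matrix; a hand-rolled UPGMA (ties in joining broken by the
lexicographically smallest member id, making the guide tree
deterministic) orders profile–profile merges scored by expected
sum-of-pairs over column base frequencies. IUPAC codes spread uniformly
over the bases they cover; gaps contribute nothing to a profile column.
A locus is aligned only when recovered in ≥ `min_samples` (default 3)
distinct samples. No flank trimming or iterative refinement is performed.

Alignment consensus: columns where gaps hold a strict majority are
omitted (`skip` rule). Majority mode emits the most frequent base if its
non-gap fraction reaches `min_base_fraction` (default 0.5), else `N`;
ambiguity mode emits the minimal IUPAC code over all bases at fraction
≥ 0.25 — a quarter share admits one allele of a heterozygote in a
four-row alignment without letting sequencing noise in. Base ties break
alphabetically.

## Reference-based assembly

Reference libraries come in three modes: per-locus ambiguity consensus
of the contig MSAs (the default inside `automate-all`); sample-specific
(each sample's own ungapped MSA row); or a user FASTA passed through.

The mapper is seed-and-extend: exact 19-mer seeds over the forward
library strand vote for (locus, strand, diagonal) candidates using the
read and its reverse complement; the top candidates are verified by
banded edit-distance alignment (band from the `max_edit_rate` budget;
reference IUPAC codes match any base they cover at zero cost). A read
maps if its edit distance is ≤ `max_edit_rate × read length`
(preset: 0.15 / 0.10 / 0.05). Terminal read bases falling outside the
locus are soft-clipped and do not count as edits; at least half the read
must remain. Tied best placements leave the read unmapped — assigning
ambiguous reads risks exactly the chimeric consensus the pipeline exists
to avoid — with one exception: ties across *duplicate reference entries*
(identical sequence, same offset; the inevitable result of keeping
multi-locus contigs whole, which puts one identical consensus under each
of a gene's exon ids) carry no distinguishing information and go to the
lexicographically first locus. A corollary is that read depth for a
multi-exon gene concentrates on its first exon's reference entry; the
other entries show zero coverage in the matrices.

Duplicates: fragments sharing (locus, strand, leftmost position — and
the mate's leftmost position for pairs mapped to the same locus) form a
group; the member with the highest summed base quality survives.
Coincidental position collisions are indistinguishable from PCR
duplicates at high depth, so flagged rates slightly exceed planted rates
on dense simulations.

Pileups tally bases with quality ≥ 20; a site is a variant when ≥ 2 base
alleles each reach depth ≥ 3 and ≥ 0.2 of the site's base depth, and
heterozygous when exactly two pass. The per-locus consensus writes `N`
below depth 3 (echoing the three-read reporting floor used for coverage
summaries), the IUPAC code of the two alleles at het sites, the majority
base elsewhere, omits deletion-majority positions, and trims leading and
trailing `N` runs. Locus selection ranks loci by the cross-sample mean of
per-sample mean depths (absent samples count zero; zero-depth positions
included), ties by locus id.

## Allele phasing

Heterozygous sites are nodes; fragments (read pairs share a fragment id,
so mates link sites jointly) connect the sites they co-cover. Per
connected component, phases are assigned greedily in breadth-first order
from the highest-depth site, each new site oriented to maximize
agreement with co-observation counts; then any single-site flip that
lowers the minimum-error-correction (MEC) count is applied until no flip
helps. Refinement never worsens the greedy MEC; on small instances the
test suite checks the result against exhaustive search over all phase
vectors. Fragments go to the haplotype they conflict with least; ties
(including all fragments covering no het site) stay unassigned and are
written to both per-allele SAM files. Haplotype sequences substitute the
phased alleles into the unphased consensus at het positions, so h0 and
h1 differ only there. Each phase block is canonicalized so h0 carries
the alphabetically smaller allele at the block's first site; no phase is
claimed across blocks. Sites where more than two alleles pass the
variant thresholds set an excess-haplotype flag — such loci are still
phased as the best two-haplotype fit but should be read critically
(possible paralogy or polyploidy). Polyploid phasing is out of scope.

## Simulator

The generator emulates a within-genus exon-capture experiment: genes of
1–3 exons (120–300 bp) joined by introns (80–200 bp), 300 bp flanking
sequence on each side (sheared fragments extend beyond targeted exons,
so real coverage does not fall to zero inside terminal exons), a bait
reference containing the ancestral exons only, per-sample divergence
0.01 from the ancestor (the closely-related regime the conservative
preset documents; cross-genus scenarios override it upward, e.g. the
preset-monotonicity test plants 0.12), heterozygosity 0.005, paired
100 bp reads with insert 220 ± 40 drawn from alternating haplotypes,
base qualities decaying 38 → 25 with noise, error rate 0.001, 10%
adapter read-through pairs, 5% exact-copy PCR duplicates, and optionally
a fraction of genes duplicated with five-fold divergence (paralogs).
Every read's provenance (sample, gene, haplotype, fragment position) and
every planted het site is recorded, and a fixed seed makes the output
byte-identical across runs.

What the simulator does *not* model — and what passing tests therefore
do not demonstrate: capture-efficiency bias between loci, GC bias,
platform-specific error spectra, indels (plantable but off by default;
the consensus and phasing treat indels conservatively), contamination,
and polyploidy. Results on real data will be worse than planted-truth
recovery rates in proportion to how far these effects dominate.

## Problem sizes and determinism

The shipped tests and the acceptance script run the full pipeline on 20
exon loci × 6 samples at 10–30× coverage (a few thousand read pairs per
sample), 50 assembler plants of 300–800 bp, and 100 phasing loci — sizes
chosen so the whole battery completes in minutes on one core while every
stage still sees the failure modes it must handle (het bubbles, adapter
read-through, duplicates, coverage holes, paralogs). All randomness
flows from explicit seeds; two runs with the same seed produce
byte-identical FASTA/SAM/VCF/TSV outputs, which the test suite asserts
file by file.

## Known limitations

- Single-k assembly cannot separate duplicates less than ~3% diverged
  (shared k-mers merge the copies) nor assemble through k-mer coverage
  holes; the paralog filter is deliberately conservative instead.
- The mapper has no insert-size model; mates map independently.
- Allele calling is threshold-based, not a genotype-likelihood model —
  adequate for consensus building, not for population genetics.
- The duplicate-reference tie rule concentrates multi-exon-gene coverage
  on one reference entry; per-exon coverage for such genes is only
  meaningful at the gene level.
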