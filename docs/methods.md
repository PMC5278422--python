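# Methods

`allelecut` implements two connected analyses for allele-specific
CRISPR/Cas9 genome editing in crosses of sequenced strains: genome-wide
discovery of candidate target sites whose protospacer or PAM contains a
strain-distinguishing SNV, and quantification of editing outcomes per
parental allele from amplicon deep-sequencing reads of heterozygous
animals.

## Site discovery

A candidate SpCas9 site is any 23-nt window of the form N20-NGG. Every
GG dinucleotide on either strand anchors one candidate, provided 21 nt
of 5' flanking sequence exist on that strand; overlapping anchors (a
GGG run) yield independent sites. Windows containing an ambiguous base
(N) are undesignable and dropped by default (`drop_n=False` keeps
them). Minus-strand sites are reported in forward coordinates with
strand-oriented protospacer and PAM strings, so the invariant
`protospacer + pam == strand_oriented(genome[start:end])` always holds.

A site is *strain-specific* with respect to a biallelic SNV when the
variant falls in the 20-nt protospacer or in either G of the PAM. A
variant at the PAM N position is excluded: N pairs with any base, so it
cannot discriminate alleles. `distance_from_pam` runs from 20 (5'-most
protospacer base) to 1 (PAM-proximal base), with 0 for hits inside the
PAM GG; mismatch tolerance of Cas9 decreases toward the PAM, so this
distance is the natural ordering for downstream interpretation. The
record is symmetric in the two strains; which allele a given guide
perfectly matches is decided by the guide sequence downstream.

Guide activity scoring is deliberately pluggable. Published scoring
heuristics are numerous, tool-specific and trained on particular
screens; the package ships a documented uniform scorer (every
designable window scores 1.0) and accepts any callable mapping a 23-nt
window to [0, 1].

Annotation counts sites against gene models: unique coding exons
overlapped by at least one strain-specific site window, unique genes
with such an exon, unique genes with any overlap (exonic or intronic),
and genes with at least one coding exon *flanked* — one site entirely
5' and one entirely 3' of the exon, both windows inside the gene span
on the same chromosome. The flanking definition targets the in-cis
excision use case (two cuts on the same chromosome removing an exon),
which is why both flanks must be intragenic.

## Read processing

Trimming follows Trimmomatic's rule order and semantics with the
defaults LEADING:5, TRAILING:5, SLIDINGWINDOW:10:30, MINLEN:75: clip
optional adapters (simplified suffix-overlap matching, at most one
mismatch per 10 matched bases), drop leading then trailing bases below
quality 5, scan 10-base windows from the 5' end and cut at the first
window whose mean quality falls below 30 (keeping leading bases of that
window that individually reach the threshold), and discard reads
shorter than 75 nt. Quality encoding is fixed to Phred+33; scores that
decode above 62 are rejected as likely Phred+64 data.

Merging follows the usearch defaults used for amplicon consensus
building: both mates are truncated at the first base with quality <= 3,
then the longest ungapped overlap between mate 1 and the reverse
complement of mate 2 with zero mismatches and length >= 50 is taken.
The consensus keeps the higher-quality base at disagreeing positions
(only reachable when `max_diffs > 0`). Pairs that fail to merge are
dropped and counted; with zero allowed mismatches this means surviving
merged reads are error-free across their overlap, which concentrates
residual sequencing error in the single-covered flanks.

Alignment is *glocal*: global in the read, free end gaps on the
reference, affine gap costs (match +2, mismatch -4, gap open -6, gap
extend -1 per additional base). The implementation drives Biopython's
`PairwiseAligner` and converts the optimal path into an explicit op
list (match/mismatch/insertion/deletion with reference offsets); indels
are then shifted to their leftmost score-equivalent placement so
reported positions are deterministic, matching VCF-style normalisation.
An exact-substring fast path covers unedited error-free reads.
Reads longer than the reference on either end are represented as
end insertions (penalised); unaligned reference overhangs cost nothing.
Pre-aligned SAM is accepted as an alternative entry point: CIGAR
strings are re-expressed as op lists, M blocks are split into
match/mismatch runs against the amplicon reference, soft-clipped bases
are stripped, and unmapped/secondary/supplementary records are skipped
with counts.

## Outcome classification

Each aligned read receives a verdict with four components.

**Allele.** The read base aligned at the diagnostic SNP offset decides
the parental allele. A read is *indeterminate* when (checked in order):
the base at the loxP-specific SNP equals the donor base (the read
derives from the repair template and carries no parental information);
the read does not cover the SNP; the SNP base is deleted; an indel in
the read could equally optimally be placed over the SNP (below); or the
base matches neither strain (sequencing error).

The fourth rule deserves explanation. An indel inside a repeat slides
between score-equivalent placements, and an indel directly adjacent to
the diagnostic base can trade places with it against a substitution at
equal score. In both situations different co-optimal alignments put
different bases (or a gap) at the SNP column, so the allele call would
be an artefact of the aligner's tie-breaking. `allelecut` computes the
indel's slide range on the reference plus a one-base adjacency margin
and refuses to call an allele when that region touches the SNP. This is
a conservative, deterministic approximation of full co-optimality
analysis; it errs on the side of indeterminate, the same class the
published accounting used for uncategorisable reads.

**Edited.** A read is edited iff at least one insertion or deletion
overlaps the edit window, which defaults to the protospacer plus PAM
(23 nt) and is configurable per target. Substitutions never count —
they are indistinguishable from sequencing error at amplicon depths.
The indel inventory records kind, length and left-aligned position of
window-overlapping indels.

**loxP.** A read is loxP-positive iff it contains any 10-mer of the
34-nt loxP sequence (forward orientation by default; a both-strands
switch exists). Note the loxP arms are 13-bp inverted repeats, so only
10-mers spanning the asymmetric spacer distinguish orientations.

**Junction.** For two-cut deletion assays the amplicon reference is the
junction sequence (upstream of cut 1 fused to downstream of cut 2); a
read supports the deletion iff it has >= 10 matched bases on each side
of the fusion coordinate (configurable), which guards against spurious
end alignments.

Per-locus summaries follow the published accounting conventions:
`strain_a + strain_b + indeterminate == total` always; edited% per
allele is over that allele's reads; loxP% and junction% per strain are
over total reads. Percentages are reported to one decimal place; full
precision is kept internally. Allele bias is tested by Pearson's
chi-squared on the edited/unedited x allele table (no continuity
correction by default, exposed as a flag); Fisher's exact test (exact
hypergeometric conditioning, two-sided by the probability-<=-observed
rule) covers small or zero-margin tables such as phenotype frequencies.

## Synthetic data

The generator emulates a MiSeq amplicon experiment on embryos from a
cross of two sequenced strains. Defaults: a ~260-nt amplicon with an
embedded N20-NGG site, one heterozygous diagnostic SNP in the
protospacer, allele ratio 0.5, per-allele indel rates 0.30 (guide
perfectly matched) and 0.05 (one mismatch), indel lengths geometric
(p = 0.5) truncated at 20 with random-base insertions, edits planted at
the blunt-cut position between protospacer bases 17 and 18 (3 bp 5' of
the PAM), per-base substitution error 0.001 (post-filter MiSeq scale),
180-nt mates reading the fragment from both ends, and uniform base
quality 37. loxP knock-ins insert the 34-mer at the cut and convert the
diagnostic position to a third, donor-specific base, mirroring oligo
designs with 33-nt homology arms spanning the strain SNP. Junction
amplicons treat every fragment as a deletion product (the assay only
amplifies deleted chromosomes) with the chromosome bias set by the
allele ratio.

Every read appears once in a ground-truth manifest: source allele,
planted indel (kind, length, left-aligned position), loxP and junction
flags, and `snp_assignable` — whether classifying the *error-free*
fragment recovers the source allele. This operational definition is
needed because indel/SNP interactions (above) make some edited reads
intrinsically unassignable; planted edit rates are therefore recovered
over SNP-assignable reads, the same conditioning the classifier (and
the published read accounting) applies. On error-free data the
pipeline's verdicts match the manifest exactly; property tests assert
this, along with bit-reproducibility under a fixed seed.

What the generator does not model: platform quality profiles (uniform
Q37 instead), PCR duplicates and chimeras, microhomology-biased repair
spectra, partial HDR conversion tracts (donor reads always carry the
loxP SNP, so per-strain loxP attribution is exercised only through the
read-level rules), and multi-locus amplicon mixtures with primer
artefacts. Passing tests therefore demonstrate correctness of the
accounting and robustness to uniform substitution error, not
performance under every real library pathology.

Two degenerate assay geometries are excluded from the simulated locus
panels used in validation: a diagnostic SNP at, or immediately 5' of,
the blunt-cut position. With every simulated indel anchored exactly at
the cut, such loci produce zero assignable edited reads — the
edited-read margin of the contingency table is empty and no method
could detect bias. Real assay panels avoid placing the diagnostic base
where every edit destroys it, for the same reason.

## Numerical and design choices

* Coordinates are 0-based half-open internally; VCF positions convert
  at parse; BED output is 0-based.
* Merge tie-breaking takes the longest qualifying overlap.
* Alignment tie-breaking is resolved by left-aligning indels after the
  optimum is found; scores are exact small integers so no floating
  tolerance is involved.
* Empty genome scan input yields an empty result; an empty
  classification list is an explicit error (an empty summary would
  silently hide upstream failure).
* All mapped reads are counted; no minimum mapping-quality or
  read-support filter is applied by default.
* Simulation sizes used in the validation suite — 10 loci x 10,000
  read pairs for bias recovery, 1,000 sequences (up to 10 kb) for
  scanner/oracle equivalence, 500 instances for alignment/oracle
  equivalence, all 46,375 tables with total <= 30 for Fisher exactness —
  were chosen to give three-standard-error resolution on the planted
  rates while keeping the default suite fast on one CPU.

## Known limitations

* The aligner assumes amplicon-scale references (tested to ~100 kb);
  it is not a genome mapper.
* Allele assignment is conservative near indels by design; loci whose
  diagnostic SNP sits within an indel slide region of the cut lose a
  fraction of edited reads to the indeterminate class, reducing power.
* Guide scoring is a placeholder interface, not a trained model.
* Only the NGG PAM is scanned; merging handles the standard
  forward/reverse overlap geometry, not staggered read-through pairs.
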