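# Methods

## The model

splicejudge treats alternative splicing as a junction-level phenomenon: the
unit of evidence is a read spanning an exon–exon boundary, and every
downstream quantity — regulation calls, PTC status, event classes, PSI — is
derived from junction read counts. This sidesteps full-transcript
quantification (no EM, no isoform deconvolution) at the cost of assuming
that junction reads are an unbiased proxy for isoform abundance; that
assumption holds for uniformly sampled short single-end reads and degrades
with strong positional bias.

### Coordinates and the junction database

All internal coordinates are 0-based half-open (BED convention); GTF
(1-based closed) is converted at the boundary, which keeps interval
arithmetic free of fencepost cases. A gene's exon union keeps exons that
differ in *either* boundary as distinct members — this is what makes
alternative donor/acceptor variants representable. The combinatorial
database joins every ordered pair of distinct, non-overlapping union exons
of a gene. Overlapping exons never pair: they are boundary variants of the
same exonic region and joining them would fabricate a junction no splicing
reaction can produce. Combinatorics are intra-gene; inter-gene or
intergenic junctions enter only through import of externally discovered
junction BED files. Junction identity is the genome-wide key
(chrom, strand, donor, acceptor); the first assigned gene wins on key
collisions. A `max_exons` guard exists for pathologically exon-rich genes
but no cap is applied by default.

Junction flank length defaults to 70 nt = read length 75 − minimum anchor 5,
so that every read that spans a boundary with at least the anchor on each
side fits inside a single junction window. Flanks of exons shorter than the
window are truncated and flagged.

### Mapping

The internal mapper is exact-match by design: with error-free or quality-
trimmed reads it is deterministic and auditable against exhaustive substring
search, and mismatch tolerance is delegated to external aligners (SAM/BAM
import, including decoding of N-gapped genome alignments and of hits to the
exported junction index via the `gene|chrom|strand|donor|acceptor` header
grammar). Matching uses a 20-mer seed index over both strands of the genome
and junction windows followed by full-read verification. Policies:

* a junction hit requires ≥ `anchor_min` (default 5) nt on each side of the
  boundary; otherwise the read is equivalent to an exonic hit;
* categories are mutually exclusive with junction > exonic > intronic >
  intergenic precedence;
* a read matching two distinct junctions, or two genome loci, is left
  unmapped (unique-mapping policy).

Reads unmapped at full length are trimmed from the 3′ end (the end where
sequencing quality decays) in 10 bp steps and remapped after each trim,
stopping at the first success or below `trunc_min_len` (default 35 nt ≥
2 × anchor + seed). This rescues reads that span three exons — they cross
two junctions and match no single junction window until the distal overhang
is removed.

### Quantification and regulation

Junction RPKM uses the constant feature length 2 × flank, so junction RPKM
is a depth-normalized count up to a constant. Cross-sample factors come
from upper-quartile (75th percentile of nonzero counts) or TMM (trimmed
mean of M values, 30%/5% two-sided trims on M and A, precision-weighted,
first sample as reference, library-size scaled); `tests/` cross-checks the
TMM implementation against edgeR's `calcNormFactors`. A junction is called
regulated between WT and KO when either sample has ≥ 3 raw reads
(`min_reads`, the artifact-suppression cutoff) and the normalized fold
change with pseudocount 0.5 crosses 2-fold (up) or 0.5-fold (down). The
pseudocount makes KO-only junctions upregulated by construction and keeps
zero-denominator fold changes finite; fold changes use normalized counts
rather than RPKM (equivalent up to a constant for junctions).

### PTC prediction

For each junction the reference backbone — the gene's longest isoform with
an annotated CDS, ties broken by smallest id — is re-spliced: exonic
sequence between donor and acceptor is removed, flanking exons are clipped,
exons wholly inside the spliced-out region are dropped, and a junction
whose donor or acceptor exon is absent from the backbone splices that exon
in and continues with the backbone exons beyond it (novel-exon
splice-through). The annotated start codon is carried over only while the
spliced transcript's 5′ sequence is identical to the reference through the
start codon; otherwise the reading frame is unresolvable and the call is
NA (this covers alternative-first-exon junctions upstream of the start
codon, where promoter choice could move the start). The first in-frame
stop (TAA/TAG/TGA scanned on DNA; reports print the RNA spelling) is a PTC
iff its distance to the last exon–exon junction, measured from the 3′ end
of the stop codon, is ≥ `ptc_min_dist` (default 50, inclusive — "at least
50 nucleotides") and it is not the reference's own annotated stop. Stops in
the last exon always have negative distance and are never premature. Only
the positional rule is modeled; poly(A)-binding-protein proximity effects,
selenocysteine read-through and uORFs are out of scope.

### Event classes and PSI

Events are motifs on the per-gene graph of expressed junctions (≥ 1 read in
any sample by default), using the exon-union 5′→3′ rank order:

* **SES** — skip i→k coexpressed with i→j, j→k for one intervening exon;
* **MES** — skip spanning ≥ 2 *consecutive* union exons whose inclusion
  chain is fully expressed (consecutiveness keeps chains that a transcript
  could actually contain);
* **A5SS / A3SS** — two junctions sharing an acceptor (donor) whose donor
  (acceptor) exons overlap; the junction with the shorter intron is the
  inclusion side (it retains more exonic sequence);
* **MXE** — i→j, j→m, i→k, k→m all expressed and the direct j→k junction
  *not* expressed; a single read on j→k voids the call, which is precisely
  how aberrant double inclusion of a mutually exclusive pair is exposed;
* **AFE / ALE** — two non-overlapping terminal exons converging on one
  acceptor (diverging from one donor), where terminal means the exon never
  appears downstream (upstream) of any expressed junction.

PSI is `100 · I / (I + E)` where I and E are the *mean* counts over the
inclusion and exclusion junction sets — the mean, not the sum, so an
SES inclusion path with two junctions is not double-weighted against the
single skip junction. ΔPSI = PSI(KO) − PSI(WT); directional calls require
|ΔPSI| > 20 percentage points and ≥ `min_event_reads` (default 10) summed
reads per sample, an order of magnitude consistent with the 5–10-read
minima used elsewhere in the analysis. Complex regions may match several
motifs and are reported once per class.

### Conservation analyses

Tracks are fixed-/variable-step WIG or bedGraph text; missing positions are
NaN and are excluded from means, never imputed as zero. The skipped-exon
meta-profile concatenates six strand-aware segments: last 25 nt of the
upstream exon, 75 nt of upstream intron, first/last 25 nt of the cassette,
75 nt of downstream intron, first 25 nt of the downstream exon. Intron
windows are anchored at the cassette's boundaries (where splice-regulatory
elements concentrate) and exon windows at their intron-facing boundaries;
segments shorter than the window contribute their available positions.
Per-position means divide by the number of anchors with data at that
position (positions are weighted, not events).

The PTC profile is a ±100 nt window centered on the first base of the stop,
clipped at the containing exon's boundaries, minus the mean profile of a
seeded random sample (default n = 4000, seed 1729) of expressed exons
windowed around random in-exon positions with the same clipping. The
stop-identity analysis samples genomic trinucleotides uniformly (default
10⁵ positions; all three frames arise from uniform position sampling),
bins them exonic/intronic/intergenic, and compares TAA/TAG/TGA usage of
predicted PTCs against the exonic background and annotated stops with a
two-sided Fisher's exact test — scipy's hypergeometric test for 2×2, exact
margin enumeration for 2×3 up to 500 total observations and a seeded Monte
Carlo estimate above. The PTC+/PTC− ratio by expression uses 1-RPKM bins
with no read cutoff, since the low-expression end is exactly where splice
errors accumulate.

## The synthetic study design

The generator emulates the assay the package is built for: two pooled
75 bp single-end libraries, one wild type and one completely NMD-deficient.
Each gene carries one designed event. PTC semantics are enforced at the
sequence level:

* all exon sequence is generated with **no stop trinucleotide in any
  frame** (a single left-to-right pass replacing offending middle bases
  with C, which can never create a stop since stops are spelled from
  {T, A, G} alone);
* the two bases before every donor boundary are forced non-T, so no
  junction-spanning triplet can spell a stop;
* stops are then planted explicitly: a normal stop in the last exon of the
  clean isoform's frame, plus — for poison-exon designs — an in-frame stop
  in the alternative region ≥ 50 nt upstream of a downstream junction, or —
  for frame-shift designs — an alternative region with length ≢ 0 (mod 3)
  and a stop planted in the shifted frame of the next exon;
* every designed isoform is re-verified by direct translation before
  emission, so designed labels are exact by construction.

Defaults are the study conditions: 50 genes spread over the seven classes,
4× stabilization of PTC+ isoforms in the KO (renormalized per gene),
a 12.5% wild-type molar fraction for the PTC+ isoform (giving designed
junction fold changes near 2.8 and ΔPSI near ±24), 4000 reads per gene and
condition (≈ 60-fold junction coverage on the minor isoform, enough for the
2-fold screen to operate far from its noise floor), uniform read starts,
error-free bases (the exact-match mapper is then sufficient; a substitution
error mode is not modeled — use an external aligner plus SAM import for
error-tolerant runs), and a 0.3 per-gene rate of low-abundance spurious
junctions emulating splice errors (suppressed for MXE/AFE/ALE genes, where
a random junction into a terminal exon would corrupt the designed motif
itself rather than add background). Reads are drawn per isoform with
molar-abundance × effective-length weights, which makes the expected
junction-level PSI equal the molar inclusion fraction exactly and gives the
ground truth a closed form. The conservation track is a constant 0.3
baseline with 0.9 planted in the 75 nt intron windows flanking regulated
cassettes. CDS records are written only for isoforms whose translation is
clean — mirroring the repository bias against NMD targets that motivates
the combinatorial database in the first place.

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate about real data: sequencing errors and quality decay,
fragment-length/GC bias, positional coverage bias, paired ends, biological
replicates and dispersion, overlapping genes, repeats (so real ambiguous
mapping rates are higher), intron retention, and genes with more than one
event.

## Numerical and degenerate-input choices

* Upper-quartile factors use numpy's linear-interpolation percentile on
  nonzero counts; all-zero samples are an error.
* TMM falls back to a unit ratio when no feature is positive in both
  samples, and to the untrimmed weighted mean when trimming empties the
  set.
* PSI is undefined (None, event flagged unsupported) when I + E = 0.
* Ties in backbone selection and longest-isoform selection break by
  lexicographically smallest isoform id.
* `per_gene_slopes` regresses through the origin (a gene with zero
  junctions has zero AS/PTC junctions by definition); fewer than three
  genes is an error.
* The canonical-isoform expression correction
  `gene_fc · (1 − ptc_frac_KO)/(1 − ptc_frac_WT)` is flagged unreliable
  above 0.9 PTC fraction and undefined at 1.0.
* Reads shorter than max(2 × anchor, seed k) are unmapped; truncation
  stops before the read would drop below `trunc_min_len`.
* Browser junction tracks export every junction with ≥ 1 read (no cutoff);
  BED scores are capped at 1000 per the UCSC track format.

## Known limitations

* PTC calls are per junction against a single backbone; compound isoforms
  that differ from the backbone at several places at once are only assessed
  through the one junction being spliced in (the novel-exon splice-through
  policy makes the minimal consistent transcript).
* The internal mapper is exact-match and single-end; indels and paired-end
  logic are out of scope by design.
* Event detection reports motif instances, not a parsimonious transcript
  set; complex loci can yield several overlapping events.
* 2×k Fisher enumeration is exponential in k; only k ≤ 3 is used here, with
  Monte Carlo above 500 observations.
* The conservation module consumes text tracks; bigWig input would need
  conversion upstream.
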