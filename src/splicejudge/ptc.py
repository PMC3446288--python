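"""Premature-termination-codon prediction under the 50-nt rule.

A stop codon is predicted to trigger nonsense-mediated decay when it lies
at least ``ptc_min_dist`` (default 50) nucleotides upstream of the last
exon-exon junction of the transcript it terminates; stops in the last exon
and the reference's own annotated stop are never premature.  For each
junction, the junction is spliced into a reference backbone isoform (the
longest isoform with an annotated CDS), the resulting transcript is scanned
for the first in-frame stop, and the distance criterion is applied.

Only the positional 50-nt rule is modeled; poly(A)-binding-protein
proximity effects and other NMD-efficiency modifiers are out of scope, as
are selenocysteine recoding and uORFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotation import Exon, GeneModel, Isoform, spliced_sequence, transcript_to_genomic
from .junctiondb import Junction

__all__ = [
    "SplicedTranscript",
    "PtcCall",
    "reference_backbone",
    "splice_in_junction",
    "find_first_stop",
    "call_ptc",
    "classify_inclusion_exclusion",
    "DEFAULT_PTC_MIN_DIST",
    "STOP_CODONS",
    "rna_codon",
]

DEFAULT_PTC_MIN_DIST = 50
STOP_CODONS = ("TAA", "TAG", "TGA")
_RNA = {"TAA": "UAA", "TAG": "UAG", "TGA": "UGA", None: "none"}


def rna_codon(dna: str | None) -> str:
    """Report-facing RNA spelling of a DNA stop codon."""
    return _RNA.get(dna, "none")


@dataclass
class SplicedTranscript:
    """An exon chain (possibly with clipped boundary exons) plus its spliced
    sequence, transcript-relative junction offsets and CDS start."""

    exon_chain: list[Exon]
    seq: str
    junction_offsets: list[int]
    cds_start: int | None

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def strand(self) -> str:
        return self.exon_chain[0].strand

    def genomic_position(self, tpos: int) -> int:
        return transcript_to_genomic(self.exon_chain, self.strand, tpos)


@dataclass
class PtcCall:
    junction: Junction
    is_ptc: bool
    stop_pos: int | None          # transcript offset of the first in-frame stop
    stop_codon: str | None        # DNA alphabet; use rna_codon() for reports
    dist_to_last_junction: int | None
    flags: set[str] = field(default_factory=set)

    @property
    def status(self) -> str:
        if "na" in self.flags:
            return "NA"
        return "PTC+" if self.is_ptc else "PTC-"


class JunctionOutsideReference(ValueError):
    pass


def reference_backbone(g: GeneModel, genome=None) -> Isoform:
    """Longest CDS-bearing isoform; ties broken by smallest id.

    When no isoform carries an annotated CDS and a genome is supplied, the
    longest isoform gets an ORF-inferred start, flagged as inferred.
    """
    with_cds = [i for i in g.isoforms if i.cds_start is not None]
    if with_cds:
        return min(with_cds, key=lambda i: (-i.length, i.id))
    from .annotation import infer_cds_start, longest_isoform

    iso = longest_isoform(g)
    if genome is not None:
        cds = infer_cds_start(iso, genome)
        if cds is not None:
            iso = Isoform(iso.id, iso.exons, cds_start=cds, cds_inferred=True)
    return iso


# ---------------------------------------------------------------------------
# splicing a junction into the backbone


def _tx_cmp(strand: str):
    """Key mapping genomic coords to a transcription-direction axis."""
    return (lambda x: x) if strand == "+" else (lambda x: -x)


def splice_in_junction(ref: Isoform, j: Junction, genome) -> SplicedTranscript:
    """Apply one junction to the reference exon chain.

    Exonic sequence between the junction's donor and acceptor is removed,
    the flanking exons are clipped to the junction boundaries, and exons of
    the reference wholly inside the spliced-out region are dropped.  When
    the junction's donor or acceptor exon is not part of the reference
    (a novel or variant exon), that exon is spliced in and the chain
    continues with the reference exons downstream of it.
    """
    strand = ref.strand
    if j.strand != strand or j.chrom != ref.chrom:
        raise JunctionOutsideReference("junction on a different chrom/strand than reference")
    ax = _tx_cmp(strand)
    # transcription-axis positions of the junction boundaries
    d_ax, a_ax = ax(j.donor), ax(j.acceptor)
    ref_exons = ref.exons  # transcription order
    ref_start_ax = ax(j_boundary_5p(ref_exons[0], strand))
    ref_end_ax = ax(j_boundary_3p(ref_exons[-1], strand))
    if a_ax <= ref_start_ax or d_ax >= ref_end_ax:
        raise JunctionOutsideReference(
            f"junction {j.key} entirely outside reference {ref.id}"
        )

    chain5 = _upstream_chain(ref_exons, j, strand)
    chain3 = _downstream_chain(ref_exons, j, strand)
    chain = chain5 + chain3
    if not chain5 or not chain3:
        raise JunctionOutsideReference(
            f"junction {j.key} leaves no exons on one side of reference {ref.id}"
        )
    seq = spliced_sequence(chain, strand, genome)
    offsets = []
    off = 0
    for e in chain[:-1]:
        off += e.length
        offsets.append(off)
    cds = _carried_cds_start(ref, chain, strand)
    return SplicedTranscript(chain, seq, offsets, cds)


def j_boundary_5p(e: Exon, strand: str) -> int:
    """Genomic coordinate of an exon's transcription-sense 5' boundary."""
    return e.start if strand == "+" else e.end


def j_boundary_3p(e: Exon, strand: str) -> int:
    return e.end if strand == "+" else e.start


def _clip_3p(e: Exon, strand: str, donor: int) -> Exon:
    """Clip an exon so its transcription-sense 3' end is at ``donor``."""
    if strand == "+":
        return Exon(e.chrom, e.start, donor, strand)
    return Exon(e.chrom, donor, e.end, strand)


def _clip_5p(e: Exon, strand: str, acceptor: int) -> Exon:
    if strand == "+":
        return Exon(e.chrom, acceptor, e.end, strand)
    return Exon(e.chrom, e.start, acceptor, strand)


def _upstream_chain(ref_exons: list[Exon], j: Junction, strand: str) -> list[Exon]:
    ax = _tx_cmp(strand)
    d_ax = ax(j.donor)
    # a reference exon "contains" the donor when it spans it internally or
    # ends exactly at it
    for idx, e in enumerate(ref_exons):
        s_ax, t_ax = ax(j_boundary_5p(e, strand)), ax(j_boundary_3p(e, strand))
        if s_ax < d_ax <= t_ax:
            return ref_exons[:idx] + [_clip_3p(e, strand, j.donor)]
    # novel/variant donor exon: keep reference exons wholly upstream of it,
    # then the donor exon clipped at the donor
    de = j.donor_exon
    if de is None:
        raise JunctionOutsideReference(f"donor {j.donor} not on reference and no donor exon")
    keep = [
        e for e in ref_exons
        if ax(j_boundary_3p(e, strand)) <= ax(j_boundary_5p(de, strand))
    ]
    return keep + [_clip_3p(de, strand, j.donor)]


def _downstream_chain(ref_exons: list[Exon], j: Junction, strand: str) -> list[Exon]:
    ax = _tx_cmp(strand)
    a_ax = ax(j.acceptor)
    for idx, e in enumerate(ref_exons):
        s_ax, t_ax = ax(j_boundary_5p(e, strand)), ax(j_boundary_3p(e, strand))
        if s_ax <= a_ax < t_ax:
            return [_clip_5p(e, strand, j.acceptor)] + ref_exons[idx + 1:]
    ae = j.acceptor_exon
    if ae is None:
        raise JunctionOutsideReference(f"acceptor {j.acceptor} not on reference and no acceptor exon")
    keep = [
        e for e in ref_exons
        if ax(j_boundary_5p(e, strand)) >= ax(j_boundary_3p(ae, strand))
    ]
    return [_clip_5p(ae, strand, j.acceptor)] + keep


def _carried_cds_start(ref: Isoform, chain: list[Exon], strand: str) -> int | None:
    """Carry the reference cds_start over when the spliced transcript's 5'
    prefix is unchanged through the start codon, else None (frame
    unresolvable)."""
    if ref.cds_start is None:
        return None
    shared = 0
    for re_, ce in zip(ref.exons, chain):
        if re_ == ce:
            shared += re_.length
            continue
        if j_boundary_5p(re_, strand) == j_boundary_5p(ce, strand):
            shared += min(re_.length, ce.length)
        break
    if ref.cds_start + 3 <= shared:
        return ref.cds_start
    return None


# ---------------------------------------------------------------------------
# stop scanning and the 50-nt rule


def find_first_stop(t: SplicedTranscript) -> tuple[int | None, str | None]:
    """First in-frame stop from cds_start, scanning DNA triplets."""
    if t.cds_start is None:
        raise ValueError("transcript has no cds_start")
    seq = t.seq.upper()
    for i in range(t.cds_start, len(seq) - 2, 3):
        cod = seq[i : i + 3]
        if cod in STOP_CODONS:
            return i, cod
    return None, None


def call_ptc(
    ref: Isoform,
    j: Junction,
    genome,
    ptc_min_dist: int = DEFAULT_PTC_MIN_DIST,
    annotated_stop_pos: int | None = None,
) -> PtcCall:
    """PTC status of splicing junction ``j`` into backbone ``ref``.

    ``annotated_stop_pos`` is the genomic position (first stop base) of the
    reference's own termination codon; a recovered stop at that position is
    the normal stop and never premature.  Junctions producing a transcript
    with unresolvable reading frame (no CDS carried over) are flagged "na".
    """
    flags: set[str] = set()
    t = splice_in_junction(ref, j, genome)
    if ref.cds_inferred:
        flags.add("uses_inferred_cds")
    if t.cds_start is None:
        flags.add("na")
        return PtcCall(j, False, None, None, None, flags)
    stop_pos, codon = find_first_stop(t)
    if stop_pos is None:
        flags.add("no_stop_found")
        return PtcCall(j, False, None, None, None, flags)
    last_j = t.junction_offsets[-1] if t.junction_offsets else 0
    dist = last_j - (stop_pos + 3)
    if annotated_stop_pos is None and ref.cds_start is not None:
        annotated_stop_pos = reference_stop_genomic(ref, genome)
    is_annotated = (
        annotated_stop_pos is not None
        and t.genomic_position(stop_pos) == annotated_stop_pos
    )
    if is_annotated:
        flags.add("annotated_stop")
    is_ptc = dist >= ptc_min_dist and not is_annotated
    return PtcCall(j, is_ptc, stop_pos, codon, dist, flags)


def reference_stop_genomic(ref: Isoform, genome) -> int | None:
    """Genomic position of the first base of the reference's own stop."""
    seq = spliced_sequence(ref.exons, ref.strand, genome).upper()
    for i in range(ref.cds_start, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return transcript_to_genomic(ref.exons, ref.strand, i)
    return None


# ---------------------------------------------------------------------------
# event-level inclusion/exclusion semantics


def classify_inclusion_exclusion(event, calls: dict) -> str:
    """Label an event's PTC semantics from per-junction PTC calls.

    ``calls`` maps junction keys to PtcCall.  A path (inclusion or
    exclusion junction set) is PTC+ when any of its junctions is PTC+.
    Returns one of ptc_on_inclusion / ptc_on_exclusion / ptc_free /
    both_ptc / na (na for events outside the coding taxonomy, e.g.
    alternative last exons).
    """
    if event.cls == "ALE":
        return "na"
    path_calls = []
    for path in (event.inclusion_junctions, event.exclusion_junctions):
        cs = [calls.get(j.key) for j in path]
        if any(c is None or "na" in c.flags for c in cs):
            return "na"
        path_calls.append(any(c.is_ptc for c in cs))
    inc_ptc, exc_ptc = path_calls
    if inc_ptc and exc_ptc:
        return "both_ptc"
    if inc_ptc:
        return "ptc_on_inclusion"
    if exc_ptc:
        return "ptc_on_exclusion"
    return "ptc_free"
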