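"""Read-to-junction assignment.

Two routes are supported: an internal exact-match mapper built on a k-mer
seed index over the junction flank sequences and the genome (deterministic,
desk-scale), and import of external SAM/BAM alignments produced against the
genome and/or the exported junction-index FASTA.  Reads left unmapped at
full length can be rescued by iterative 3'-end truncation in fixed steps —
reads spanning three or more exons cross two junctions and match no single
junction window until the distal overhang is trimmed away.

Assignment categories are mutually exclusive: a read is junction, exonic,
intronic, intergenic or unmapped, with junction taking precedence over
genomic hits and ambiguous (multi-target) reads left unmapped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pysam
from Bio.Seq import reverse_complement

from .annotation import GeneModel
from .junctiondb import Junction, JunctionDB, parse_junction_header

log = logging.getLogger(__name__)

__all__ = [
    "MappingParams",
    "ReadAssignment",
    "MapperIndex",
    "map_reads",
    "truncate_and_rescue",
    "map_with_rescue",
    "import_sam",
    "category_counts",
    "read_fastx",
]

CATEGORIES = ("junction", "genome_exonic", "genome_intronic", "genome_intergenic", "unmapped")


@dataclass(frozen=True)
class MappingParams:
    anchor_min: int = 5          # nt required on each side of a junction
    trunc_step: int = 10         # nt trimmed from the 3' end per rescue round
    trunc_min_len: int = 35      # stop trimming below this read length
    max_mismatches: int = 0      # internal mapper is exact-match
    seed_k: int = 20             # k-mer seed length for the internal index

    def __post_init__(self) -> None:
        if self.trunc_step <= 0:
            raise ValueError("trunc_step must be positive")
        if self.trunc_min_len < 2 * self.anchor_min:
            raise ValueError("trunc_min_len must be >= 2 * anchor_min")
        if self.max_mismatches != 0:
            raise NotImplementedError(
                "the internal mapper is exact-match; use an external aligner "
                "plus import_sam for mismatch-tolerant mapping"
            )


@dataclass
class ReadAssignment:
    read_id: str
    category: str                 # one of CATEGORIES
    junction: Junction | None = None
    gene_id: str | None = None    # for exonic/intronic hits
    chrom: str | None = None
    pos: int | None = None        # genome hit position (0-based)
    mapped_length: int | None = None
    truncation_rounds: int = 0
    reverse: bool = False


class MapperIndex:
    """Exact-match seed index over junction sequences and the genome.

    Both strands of the junction windows and the genome are indexed so that
    reads sequenced from either strand resolve to the same target.
    """

    def __init__(self, db: JunctionDB, genome, models: list[GeneModel],
                 params: MappingParams | None = None):
        self.params = params or MappingParams()
        self.db = db
        k = self.params.seed_k
        # reference sequences: ("J", key) -> junction window, ("G", chrom) -> genome
        self.refs: dict[tuple, str] = {}
        self.boundaries: dict[tuple, int] = {}
        for key, js in db.seqs.items():
            self.refs[("J", key)] = js.seq.upper()
            self.boundaries[("J", key)] = js.boundary
        chrom_names = set()
        for g in models:
            chrom_names.add(g.chrom)
        try:
            names = list(genome.keys())
        except AttributeError:
            names = sorted(chrom_names)
        for chrom in names:
            self.refs[("G", str(chrom))] = str(genome[str(chrom)][:]).upper()

        self.seeds: dict[str, list[tuple[tuple, int]]] = {}
        for rid, seq in self.refs.items():
            for i in range(len(seq) - k + 1):
                self.seeds.setdefault(seq[i : i + k], []).append((rid, i))

        # genome annotation lookup for category calls
        self._exonic: dict[str, list[tuple[int, int, str]]] = {}
        self._spans: dict[str, list[tuple[int, int, str]]] = {}
        for g in models:
            for e in g.exon_union:
                self._exonic.setdefault(g.chrom, []).append((e.start, e.end, g.gene_id))
            self._spans.setdefault(g.chrom, []).append((*g.span, g.gene_id))
        for d in (self._exonic, self._spans):
            for v in d.values():
                v.sort()

    # -- genomic category ---------------------------------------------------

    def categorize_genomic(self, chrom: str, start: int, end: int) -> tuple[str, str | None]:
        """(category, gene_id) for a genome interval: exonic when overlapping
        any union exon, intronic when inside a gene span, else intergenic."""
        for s, t, gid in self._exonic.get(chrom, []):
            if s >= end:
                break
            if start < t:
                return "genome_exonic", gid
        for s, t, gid in self._spans.get(chrom, []):
            if s >= end:
                break
            if start < t:
                return "genome_intronic", gid
        return "genome_intergenic", None

    def junction_for_gap(self, chrom: str, gap_left: int, gap_right: int) -> Junction | None:
        """DB junction whose intron matches a genomic gap, either strand."""
        for strand, donor, acceptor in (
            ("+", gap_left, gap_right),
            ("-", gap_right, gap_left),
        ):
            j = self.db.get((chrom, strand, donor, acceptor))
            if j is not None:
                return j
        return None

    # -- exact-match lookup -------------------------------------------------

    def _hits(self, seq: str) -> list[tuple[tuple, int]]:
        k = self.params.seed_k
        if len(seq) < k:
            return []
        out = []
        for rid, pos in self.seeds.get(seq[:k], ()):
            ref = self.refs[rid]
            if ref[pos : pos + len(seq)] == seq:
                out.append((rid, pos))
        return out

    def match(self, read_id: str, seq: str) -> ReadAssignment:
        """Assign one read (exact match, unique-mapping policy)."""
        p = self.params
        seq = seq.upper()
        if len(seq) < max(2 * p.anchor_min, p.seed_k):
            return ReadAssignment(read_id, "unmapped")
        j_hits: dict[tuple, tuple[int, bool]] = {}
        g_hits: dict[tuple[str, int], bool] = {}
        for fwd_seq, rev in ((seq, False), (reverse_complement(seq), True)):
            for (kind, name), pos in self._hits(fwd_seq):
                if kind == "J":
                    b = self.boundaries[("J", name)]
                    # read must straddle the boundary with anchor_min each side
                    if pos <= b - p.anchor_min and pos + len(seq) >= b + p.anchor_min:
                        j_hits.setdefault(name, (pos, rev))
                else:
                    g_hits.setdefault((name, pos), rev)
        if j_hits:
            if len(j_hits) > 1:
                return ReadAssignment(read_id, "unmapped")  # ambiguous
            key, (pos, rev) = next(iter(j_hits.items()))
            return ReadAssignment(
                read_id, "junction", junction=self.db.get(key),
                gene_id=self.db.get(key).gene_id,
                mapped_length=len(seq), reverse=rev,
            )
        if g_hits:
            if len(g_hits) > 1:
                return ReadAssignment(read_id, "unmapped")
            (chrom, pos), rev = next(iter(g_hits.items()))
            cat, gid = self.categorize_genomic(chrom, pos, pos + len(seq))
            return ReadAssignment(read_id, cat, gene_id=gid, chrom=chrom,
                                  pos=pos, mapped_length=len(seq), reverse=rev)
        return ReadAssignment(read_id, "unmapped")


def map_reads(reads, index: MapperIndex, params: MappingParams | None = None):
    """Map (read_id, seq) pairs; every read yields exactly one assignment."""
    if params is not None and params is not index.params:
        raise ValueError("params must match the ones the index was built with")
    return [index.match(rid, seq) for rid, seq in reads]


def truncate_and_rescue(unmapped, index: MapperIndex):
    """Iteratively trim 3' ends of previously unmapped reads and remap.

    Trimming proceeds in ``trunc_step`` decrements, stopping at the first
    successful (re)assignment or once the next trim would drop the read
    below ``trunc_min_len``; ``truncation_rounds`` records trims used.
    """
    p = index.params
    out = []
    for rid, seq in unmapped:
        rounds = 0
        cur = seq
        asn = ReadAssignment(rid, "unmapped")
        while len(cur) - p.trunc_step >= p.trunc_min_len:
            cur = cur[: -p.trunc_step]
            rounds += 1
            asn = index.match(rid, cur)
            if asn.category != "unmapped":
                break
        asn.truncation_rounds = rounds
        out.append(asn)
    return out


def map_with_rescue(reads, index: MapperIndex):
    """Full-length pass plus truncation rescue of the unmapped remainder."""
    reads = list(reads)
    first = map_reads(reads, index)
    seq_by_id = dict(reads)
    rescued = truncate_and_rescue(
        [(a.read_id, seq_by_id[a.read_id]) for a in first if a.category == "unmapped"],
        index,
    )
    res_by_id = {a.read_id: a for a in rescued}
    return [res_by_id.get(a.read_id, a) if a.category == "unmapped" else a for a in first]


# ---------------------------------------------------------------------------
# SAM/BAM import


def import_sam(path: str, index: MapperIndex) -> list[ReadAssignment]:
    """Decode external alignments into read assignments.

    Reference names following the junction-index grammar
    (``gene|chrom|strand|donor|acceptor``) are resolved to DB junctions
    (subject to the anchor requirement); genome alignments with a single
    N-CIGAR gap matching a DB junction become junction assignments, other
    genome hits are categorized by overlap.  Secondary and supplementary
    records are ignored; unknown reference names are skipped and counted.
    """
    out: list[ReadAssignment] = []
    skipped = 0
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as af:
        for rec in af:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_unmapped:
                out.append(ReadAssignment(rec.query_name, "unmapped"))
                continue
            rname = rec.reference_name
            try:
                gid, chrom, strand, donor, acceptor = parse_junction_header(rname)
            except ValueError:
                gid = None
            if gid is not None:
                j = index.db.get((chrom, strand, donor, acceptor))
                js = index.db.seqs.get((chrom, strand, donor, acceptor))
                if j is None:
                    skipped += 1
                    continue
                p = index.params
                start = rec.reference_start
                end = rec.reference_end or (start + (rec.query_length or 0))
                if js is not None and not (
                    start <= js.boundary - p.anchor_min and end >= js.boundary + p.anchor_min
                ):
                    # within one flank only: equivalent to an exonic hit
                    cat, hit_gid = "genome_exonic", j.gene_id
                    out.append(ReadAssignment(rec.query_name, cat, gene_id=hit_gid,
                                              mapped_length=end - start,
                                              reverse=rec.is_reverse))
                    continue
                out.append(ReadAssignment(rec.query_name, "junction", junction=j,
                                          gene_id=j.gene_id, mapped_length=end - start,
                                          reverse=rec.is_reverse))
                continue
            if ("G", rname) not in index.refs:
                skipped += 1
                continue
            gaps = [
                (pos, pos + length)
                for pos, length in _n_gaps(rec)
            ]
            if len(gaps) == 1:
                j = index.junction_for_gap(rname, gaps[0][0], gaps[0][1])
                if j is not None:
                    out.append(ReadAssignment(rec.query_name, "junction", junction=j,
                                              gene_id=j.gene_id, chrom=rname,
                                              pos=rec.reference_start,
                                              mapped_length=rec.query_length,
                                              reverse=rec.is_reverse))
                    continue
            cat, gid2 = index.categorize_genomic(
                rname, rec.reference_start, rec.reference_end or rec.reference_start + 1
            )
            out.append(ReadAssignment(rec.query_name, cat, gene_id=gid2, chrom=rname,
                                      pos=rec.reference_start,
                                      mapped_length=rec.query_length,
                                      reverse=rec.is_reverse))
    if skipped:
        log.warning("import_sam: %d records with unknown reference names skipped", skipped)
    return out


def _n_gaps(rec) -> list[tuple[int, int]]:
    """(gap_start, gap_length) genomic pairs for N CIGAR operations."""
    gaps = []
    pos = rec.reference_start
    for op, length in rec.cigartuples or ():
        if op == 3:  # N
            gaps.append((pos, length))
        if op in (0, 2, 3, 7, 8):  # consume reference
            pos += length
    return gaps


# ---------------------------------------------------------------------------
# reporting and IO


def category_counts(assignments) -> dict[str, int]:
    counts = {c: 0 for c in CATEGORIES}
    for a in assignments:
        counts[a.category] += 1
    counts["total"] = len(assignments)
    counts["mapped"] = counts["total"] - counts["unmapped"]
    return counts


def read_fastx(path: str):
    """Yield (read_id, sequence) from FASTA or FASTQ."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        with open(path) as fh:
            for title, seq, _q in FastqGeneralIterator(fh):
                yield title.split()[0], seq
    else:
        from Bio import SeqIO

        for rec in SeqIO.parse(path, "fasta"):
            yield rec.id, str(rec.seq)
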