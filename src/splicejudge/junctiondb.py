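"""Combinatorial exon-exon junction database.

For every gene, every ordered pair of distinct, non-overlapping exons from
the gene's exon union forms a candidate junction — both the annotated
(consecutive) junctions of each isoform and every in-silico skip or
alternative pairing.  Junction flanking sequences are exported as a FASTA
"index" against which short reads (or an external aligner) can be matched.

Overlapping exons never form a junction with each other: they are
alternative boundary variants of the same exonic region, and joining them
would fabricate self-ligation artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Seq import reverse_complement

from .annotation import Exon, GeneModel

log = logging.getLogger(__name__)

__all__ = [
    "Junction",
    "JunctionSeq",
    "JunctionDB",
    "build_combinatorial_db",
    "import_denovo_junctions",
    "write_junction_fasta",
    "parse_junction_header",
    "read_junction_bed",
    "write_junction_bed",
    "fetch",
    "DEFAULT_FLANK_LEN",
]

DEFAULT_FLANK_LEN = 70  # read_length 75 minus anchor_min 5


def fetch(genome, chrom: str, start: int, end: int, strand: str = "+") -> str:
    """Extract genome sequence, strand-corrected, from a pyfaidx.Fasta or a
    plain dict of chromosome strings."""
    try:
        seq = str(genome[chrom][start:end])
    except KeyError as exc:
        raise KeyError(f"chromosome {chrom!r} not in genome") from exc
    seq = seq.upper()
    if len(seq) < end - start:
        raise ValueError(
            f"interval {chrom}:{start}-{end} extends beyond chromosome end"
        )
    return seq if strand == "+" else reverse_complement(seq)


@dataclass(frozen=True)
class Junction:
    """A donor/acceptor coordinate pair.

    ``donor`` is the genomic coordinate of the 5' exon's transcription-sense
    3' boundary and ``acceptor`` the 3' exon's 5' boundary.  On the + strand
    the donor is an exclusive end (donor <= acceptor); on the - strand the
    roles mirror genomically (donor >= acceptor, donor = upstream exon
    start, acceptor = downstream exon end).
    """

    gene_id: str
    chrom: str
    strand: str
    donor: int
    acceptor: int
    donor_exon: Exon | None = None
    acceptor_exon: Exon | None = None
    source: str = "combinatorial"

    def __post_init__(self) -> None:
        if self.strand == "+" and self.donor > self.acceptor:
            raise ValueError(f"+-strand junction with donor > acceptor: {self}")
        if self.strand == "-" and self.donor < self.acceptor:
            raise ValueError(f"--strand junction with donor < acceptor: {self}")

    @property
    def key(self) -> tuple[str, str, int, int]:
        """Genome-wide identity key (gene-independent)."""
        return (self.chrom, self.strand, self.donor, self.acceptor)

    @property
    def intron_bounds(self) -> tuple[int, int]:
        """Genomic [start, end) of the spliced-out region."""
        return (min(self.donor, self.acceptor), max(self.donor, self.acceptor))

    def __hash__(self) -> int:
        return hash(self.key)

    def __eq__(self, other) -> bool:
        return isinstance(other, Junction) and self.key == other.key


@dataclass
class JunctionSeq:
    """A junction plus its mappable flanking sequence.

    ``seq`` is ``flank_len`` bases ending at the donor followed by
    ``flank_len`` bases starting at the acceptor, in transcript-strand
    orientation.  ``boundary`` is the position of the junction within
    ``seq`` (== length of the donor-side flank); flanks are truncated, and
    flagged, when an exon is shorter than ``flank_len``.
    """

    junction: Junction
    seq: str
    boundary: int
    truncated: bool = False

    @property
    def header(self) -> str:
        j = self.junction
        return f"{j.gene_id}|{j.chrom}|{j.strand}|{j.donor}|{j.acceptor}"


def _tx_ordered(strand: str, a: Exon, b: Exon) -> bool:
    """True if a is transcriptionally strictly upstream of b (non-overlapping)."""
    if strand == "+":
        return a.end <= b.start
    return b.end <= a.start


def junction_between(gene_id: str, strand: str, up: Exon, down: Exon,
                     source: str = "combinatorial") -> Junction:
    """The junction joining two exons (up transcriptionally upstream)."""
    if strand == "+":
        donor, acceptor = up.end, down.start
    else:
        donor, acceptor = up.start, down.end
    return Junction(gene_id, up.chrom, strand, donor, acceptor,
                    donor_exon=up, acceptor_exon=down, source=source)


def extract_junction_seq(j: Junction, genome, flank_len: int) -> JunctionSeq:
    up, down = j.donor_exon, j.acceptor_exon
    if up is None or down is None:
        raise ValueError("junction lacks exon references; cannot extract sequence")
    up_len = min(flank_len, up.length)
    down_len = min(flank_len, down.length)
    if j.strand == "+":
        upseq = fetch(genome, j.chrom, j.donor - up_len, j.donor, "+")
        downseq = fetch(genome, j.chrom, j.acceptor, j.acceptor + down_len, "+")
    else:
        upseq = fetch(genome, j.chrom, j.donor, j.donor + up_len, "-")
        downseq = fetch(genome, j.chrom, j.acceptor - down_len, j.acceptor, "-")
    return JunctionSeq(
        junction=j,
        seq=upseq + downseq,
        boundary=up_len,
        truncated=(up_len < flank_len or down_len < flank_len),
    )


class JunctionDB:
    """Container for junctions with unique (chrom, strand, donor, acceptor)
    keys; the first assigned gene wins on collision."""

    def __init__(self, flank_len: int = DEFAULT_FLANK_LEN):
        self.flank_len = flank_len
        self._by_key: dict[tuple, Junction] = {}
        self.seqs: dict[tuple, JunctionSeq] = {}

    def __len__(self) -> int:
        return len(self._by_key)

    def __contains__(self, j: Junction) -> bool:
        return j.key in self._by_key

    def __iter__(self):
        return iter(self._by_key.values())

    def get(self, key) -> Junction | None:
        return self._by_key.get(key)

    def add(self, j: Junction, genome=None) -> bool:
        """Add a junction; returns False when the key already exists."""
        if j.key in self._by_key:
            return False
        self._by_key[j.key] = j
        if genome is not None and j.donor_exon is not None:
            self.seqs[j.key] = extract_junction_seq(j, genome, self.flank_len)
        return True

    def junctions_of_gene(self, gene_id: str) -> list[Junction]:
        return [j for j in self._by_key.values() if j.gene_id == gene_id]


def build_combinatorial_db(
    models: list[GeneModel],
    genome,
    flank_len: int = DEFAULT_FLANK_LEN,
    max_exons: int | None = None,
) -> JunctionDB:
    """All ordered pairs of distinct non-overlapping union exons per gene.

    ``max_exons`` is a guard for pathologically exon-rich genes: genes with
    more union exons are skipped with a warning rather than exploding the
    pair count.
    """
    db = JunctionDB(flank_len=flank_len)
    for g in models:
        exons = g.exon_union  # already 5'->3'
        if max_exons is not None and len(exons) > max_exons:
            log.warning(
                "gene %s has %d union exons (> max_exons=%d); skipped",
                g.gene_id, len(exons), max_exons,
            )
            continue
        for i, up in enumerate(exons):
            for down in exons[i + 1:]:
                if up.overlaps(down):
                    continue
                if not _tx_ordered(g.strand, up, down):
                    continue
                db.add(junction_between(g.gene_id, g.strand, up, down), genome)
    return db


# ---------------------------------------------------------------------------
# FASTA index export / header grammar


def write_junction_fasta(db: JunctionDB, path: str) -> None:
    with open(path, "w") as fh:
        for key, js in sorted(db.seqs.items()):
            fh.write(f">{js.header}\n{js.seq}\n")


def parse_junction_header(name: str) -> tuple[str, str, str, int, int]:
    """Decode ``gene|chrom|strand|donor|acceptor``."""
    parts = name.split("|")
    if len(parts) != 5 or parts[2] not in ("+", "-"):
        raise ValueError(f"not a junction index name: {name!r}")
    return parts[0], parts[1], parts[2], int(parts[3]), int(parts[4])


# ---------------------------------------------------------------------------
# junction BED (TopHat junctions.bed dialect: blocks flank the gap)


def read_junction_bed(path: str) -> list[tuple[str, str, int, int, int]]:
    """Yield (chrom, strand, gap_left, gap_right, score) per junction line.

    Accepts BED12 (blocks flank the gap) and 6-column junction BED where
    start/end directly delimit the gap.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) >= 12:
                cstart = int(f[1])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                if len(sizes) < 2:
                    log.warning("%s:%d: junction line with < 2 blocks skipped", path, lineno)
                    continue
                gap_left = cstart + starts[0] + sizes[0]
                gap_right = cstart + starts[1]
            elif len(f) >= 6:
                gap_left, gap_right = int(f[1]), int(f[2])
            else:
                raise ValueError(f"{path}:{lineno}: junction BED needs >= 6 fields")
            strand = f[5] if len(f) >= 6 else "+"
            score = int(float(f[4])) if len(f) >= 5 and f[4] not in (".", "") else 0
            out.append((f[0], strand, gap_left, gap_right, score))
    return out


def write_junction_bed(path: str, junction_counts: dict[Junction, int],
                       track_name: str = "junctions") -> None:
    """BED12 junction track, score = read count (all junctions >= 1 read)."""
    with open(path, "w") as fh:
        fh.write(f'track name="{track_name}" description="splice junctions"\n')
        for j, count in sorted(junction_counts.items(), key=lambda kv: kv[0].key):
            if count < 1:
                continue
            lo, hi = j.intron_bounds
            up, down = j.donor_exon, j.acceptor_exon
            b1 = min(25, up.length) if up is not None else 25
            b2 = min(25, down.length) if down is not None else 25
            start, end = lo - b1, hi + b2
            fh.write(
                f"{j.chrom}\t{start}\t{end}\t{j.gene_id}\t{min(count, 1000)}\t"
                f"{j.strand}\t{start}\t{end}\t0\t2\t{b1},{b2}\t0,{hi - start}\n"
            )


def import_denovo_junctions(
    path: str, models: list[GeneModel], db: JunctionDB
) -> list[Junction]:
    """Add junctions from an external junction BED to the database.

    Each imported junction is assigned to the gene whose span contains it on
    the matching strand; junctions overlapping two genes are flagged
    ambiguous and assigned to neither, and junctions in no gene get
    gene_id "intergenic".  Junctions already present are ignored.
    """
    added: list[Junction] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in models:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, strand, gap_left, gap_right, _score in read_junction_bed(path):
        hosts = [
            g for g in by_chrom.get(chrom, [])
            if g.strand == strand and g.span[0] <= gap_left and gap_right <= g.span[1]
        ]
        if len(hosts) > 1:
            log.warning(
                "junction %s:%d-%d spans genes %s; flagged ambiguous",
                chrom, gap_left, gap_right, ",".join(g.gene_id for g in hosts),
            )
            continue
        gene = hosts[0] if hosts else None
        gid = gene.gene_id if gene else "intergenic"
        if strand == "+":
            donor, acceptor = gap_left, gap_right
        else:
            donor, acceptor = gap_right, gap_left
        d_exon = a_exon = None
        if gene is not None:
            for e in gene.exon_union:
                d_boundary = e.end if strand == "+" else e.start
                a_boundary = e.start if strand == "+" else e.end
                if d_boundary == donor:
                    d_exon = e
                if a_boundary == acceptor:
                    a_exon = e
        j = Junction(gid, chrom, strand, donor, acceptor,
                     donor_exon=d_exon, acceptor_exon=a_exon,
                     source="denovo_import")
        if db.add(j):
            added.append(j)
    return added
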