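"""Gene-model ingestion and merging.

Reads transcript annotations from GTF, BED12 or refFlat files, converts them
to a single internal representation (0-based half-open coordinates, exons in
transcription order) and merges exon models from multiple repositories into
per-gene non-redundant exon sets.  Exons differing in *either* boundary are
kept as distinct members of the union, which is what makes alternative
5'/3' splice-site variants representable downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gffutils

log = logging.getLogger(__name__)

__all__ = [
    "Exon",
    "Isoform",
    "GeneModel",
    "AnnotationError",
    "load_gene_models",
    "merge_repositories",
    "longest_isoform",
    "write_gtf",
    "infer_cds_start",
]


class AnnotationError(ValueError):
    """Raised for malformed annotation records (message names the line)."""


@dataclass(frozen=True, order=True)
class Exon:
    """A genomic exon interval, 0-based half-open, with strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise AnnotationError(f"exon start must be < end: {self}")
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"exon strand must be + or -: {self}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Exon") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class Isoform:
    """One transcript: exons in transcription order plus optional CDS start.

    ``cds_start`` is the transcript-relative, 0-based offset of the first
    base of the annotated start codon.  ``cds_inferred`` marks offsets that
    were recovered by ORF scanning rather than read from CDS records.
    """

    id: str
    exons: list[Exon]
    cds_start: int | None = None
    cds_inferred: bool = False

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    def junction_pairs(self) -> list[tuple[Exon, Exon]]:
        """Consecutive (upstream, downstream) exon pairs, transcription order."""
        return list(zip(self.exons, self.exons[1:]))

    def validate(self) -> None:
        if not self.exons:
            raise AnnotationError(f"isoform {self.id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"isoform {self.id} has exons on mixed chromosomes/strands"
            )
        starts = [e.start for e in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if not ordered:
            raise AnnotationError(f"isoform {self.id}: exon order inconsistent with strand")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise AnnotationError(f"isoform {self.id} has overlapping exons")
        if self.cds_start is not None and not (0 <= self.cds_start < self.length - 2):
            raise AnnotationError(
                f"isoform {self.id}: cds_start {self.cds_start} outside transcript"
            )


def _tx_sort_key(strand: str):
    """Sort key placing exons in transcription (5'->3') order."""
    if strand == "+":
        return lambda e: (e.start, e.end)
    return lambda e: (-e.end, -e.start)


@dataclass
class GeneModel:
    """All isoforms of one gene plus the deduplicated union of their exons."""

    gene_id: str
    chrom: str
    strand: str
    isoforms: list[Isoform]
    exon_union: list[Exon] = field(default_factory=list)
    # provenance: (start, end) -> set of source labels
    exon_sources: dict[tuple[int, int], set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exon_union:
            self.rebuild_union()

    def rebuild_union(self, source: str | None = None) -> None:
        seen: dict[tuple[int, int], Exon] = {}
        for iso in self.isoforms:
            for e in iso.exons:
                seen.setdefault(e.interval(), e)
        self.exon_union = sorted(seen.values(), key=_tx_sort_key(self.strand))
        if source is not None:
            for iv in seen:
                self.exon_sources.setdefault(iv, set()).add(source)

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(e.start for e in self.exon_union),
            max(e.end for e in self.exon_union),
        )

    def exon_rank(self, exon: Exon) -> int:
        """Index of an exon in the 5'->3' sorted union."""
        return self.exon_union.index(exon)


# ---------------------------------------------------------------------------
# readers


def load_gene_models(path: str, dialect: str = "gtf") -> list[GeneModel]:
    """Load gene models from an annotation file.

    dialect: one of ``gtf`` (1-based closed, Ensembl/UCSC attribute styles),
    ``bed12`` or ``refflat``.  Coordinates are converted to the internal
    0-based half-open convention; the CDS start is recorded when the dialect
    provides it (GTF CDS records, BED12 thickStart/thickEnd, refFlat
    cdsStart/cdsEnd).
    """
    if dialect == "gtf":
        return _load_gtf(path)
    if dialect == "bed12":
        return _load_bed12(path)
    if dialect == "refflat":
        return _load_refflat(path)
    raise ValueError(f"unknown annotation dialect: {dialect!r}")


def _assemble_genes(
    per_transcript: dict[str, dict],
) -> list[GeneModel]:
    """Group validated transcripts into GeneModels, rejecting bad records."""
    genes: dict[str, list[Isoform]] = {}
    for tid, rec in per_transcript.items():
        exons = rec["exons"]
        if not exons:
            continue
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) > 1 or len(strands) > 1:
            log.warning("transcript %s has exons on mixed strands/chromosomes; rejected", tid)
            continue
        strand = exons[0].strand
        exons = sorted(set(exons), key=_tx_sort_key(strand))
        iso = Isoform(id=tid, exons=exons, cds_start=rec.get("cds_start"))
        try:
            iso.validate()
        except AnnotationError as exc:
            log.warning("transcript %s rejected: %s", tid, exc)
            continue
        genes.setdefault(rec["gene_id"], []).append(iso)
    out = []
    for gid, isoforms in genes.items():
        isoforms.sort(key=lambda i: i.id)
        out.append(
            GeneModel(
                gene_id=gid,
                chrom=isoforms[0].chrom,
                strand=isoforms[0].strand,
                isoforms=isoforms,
            )
        )
    out.sort(key=lambda g: (g.chrom, g.span[0], g.gene_id))
    return out


def _load_gtf(path: str) -> list[GeneModel]:
    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils wraps line info in its message
        raise AnnotationError(f"failed to parse GTF {path}: {exc}") from exc

    per_tx: dict[str, dict] = {}
    cds_bounds: dict[str, list[tuple[int, int]]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        try:
            gid = feat.attributes["gene_id"][0]
            tid = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise AnnotationError(
                f"GTF record missing {exc} attribute: {feat}"
            ) from exc
        # GTF is 1-based closed; gffutils keeps that convention in .start/.end
        start, end = feat.start - 1, feat.end
        rec = per_tx.setdefault(tid, {"gene_id": gid, "exons": [], "cds_start": None})
        if feat.featuretype == "exon":
            rec["exons"].append(Exon(feat.seqid, start, end, feat.strand))
        else:
            cds_bounds.setdefault(tid, []).append((start, end))

    for tid, bounds in cds_bounds.items():
        rec = per_tx.get(tid)
        if rec is None or not rec["exons"]:
            continue
        strand = rec["exons"][0].strand
        # genomic position of the first base of the start codon
        g = min(b[0] for b in bounds) if strand == "+" else max(b[1] for b in bounds) - 1
        rec["cds_start"] = _genomic_to_transcript(rec["exons"], strand, g)
    return _assemble_genes(per_tx)


def _genomic_to_transcript(exons: list[Exon], strand: str, gpos: int) -> int | None:
    """Transcript-relative offset of genomic position ``gpos`` (0-based)."""
    off = 0
    for e in sorted(exons, key=_tx_sort_key(strand)):
        if e.start <= gpos < e.end:
            return off + (gpos - e.start if strand == "+" else e.end - 1 - gpos)
        off += e.length
    return None


def transcript_to_genomic(exons: list[Exon], strand: str, tpos: int) -> int:
    """Genomic coordinate of transcript offset ``tpos`` (0-based)."""
    off = 0
    for e in sorted(exons, key=_tx_sort_key(strand)):
        if tpos < off + e.length:
            within = tpos - off
            return e.start + within if strand == "+" else e.end - 1 - within
        off += e.length
    raise ValueError(f"transcript offset {tpos} beyond transcript end")


def _load_bed12(path: str) -> list[GeneModel]:
    per_tx: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise AnnotationError(f"{path}:{lineno}: BED12 needs 12 fields, got {len(f)}")
            try:
                chrom, cstart = f[0], int(f[1])
                name, strand = f[3], f[5]
                thick_start, thick_end = int(f[6]), int(f[7])
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise AnnotationError(f"{path}:{lineno}: blockCount disagrees with block lists")
            exons = [
                Exon(chrom, cstart + bs, cstart + bs + sz, strand)
                for bs, sz in zip(starts, sizes)
            ]
            exons.sort(key=_tx_sort_key(strand))
            cds_start = None
            if thick_start < thick_end:
                g = thick_start if strand == "+" else thick_end - 1
                cds_start = _genomic_to_transcript(exons, strand, g)
            tid = name if name not in per_tx else f"{name}.{lineno}"
            per_tx[tid] = {"gene_id": name, "exons": exons, "cds_start": cds_start}
    return _assemble_genes(per_tx)


def _load_refflat(path: str) -> list[GeneModel]:
    per_tx: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 11:
                raise AnnotationError(f"{path}:{lineno}: refFlat needs 11 fields, got {len(f)}")
            gene_name, tx_name, chrom, strand = f[0], f[1], f[2], f[3]
            try:
                cds_s, cds_e = int(f[6]), int(f[7])
                n = int(f[8])
                estarts = [int(x) for x in f[9].rstrip(",").split(",")]
                eends = [int(x) for x in f[10].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            if len(estarts) != n or len(eends) != n:
                raise AnnotationError(f"{path}:{lineno}: exonCount disagrees with exon lists")
            exons = [Exon(chrom, s, e, strand) for s, e in zip(estarts, eends)]
            exons.sort(key=_tx_sort_key(strand))
            cds_start = None
            if cds_s < cds_e:
                g = cds_s if strand == "+" else cds_e - 1
                cds_start = _genomic_to_transcript(exons, strand, g)
            tid = tx_name if tx_name not in per_tx else f"{tx_name}.{lineno}"
            per_tx[tid] = {"gene_id": gene_name, "exons": exons, "cds_start": cds_start}
    return _assemble_genes(per_tx)


# ---------------------------------------------------------------------------
# writer


def write_gtf(models: list[GeneModel], path: str, source: str = "splicejudge") -> None:
    """Write gene models as GTF (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for g in models:
            for iso in g.isoforms:
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{iso.id}";'
                for e in sorted(iso.exons, key=lambda e: e.start):
                    fh.write(
                        f"{g.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{g.strand}\t.\t{attrs}\n"
                    )
                if iso.cds_start is not None and not iso.cds_inferred:
                    for cs, ce in _cds_genomic_blocks(iso):
                        fh.write(
                            f"{g.chrom}\t{source}\tCDS\t{cs + 1}\t{ce}\t.\t"
                            f"{g.strand}\t.\t{attrs}\n"
                        )


def _cds_genomic_blocks(iso: Isoform) -> list[tuple[int, int]]:
    """Genomic blocks from cds_start to transcript end (no stop annotation
    needed for round-tripping the start-codon offset)."""
    blocks = []
    off = 0
    for e in iso.exons:  # transcription order
        lo = max(iso.cds_start - off, 0)
        if lo < e.length:
            if iso.strand == "+":
                blocks.append((e.start + lo, e.end))
            else:
                blocks.append((e.start, e.end - lo))
        off += e.length
    return sorted(blocks)


# ---------------------------------------------------------------------------
# merging and selection


def merge_repositories(
    model_sets: list[list[GeneModel]], labels: list[str] | None = None
) -> list[GeneModel]:
    """Merge gene models from several repositories.

    Gene identity is resolved by exact gene_id match first, then by
    single-linkage clustering of genes with >= 1 bp exonic overlap on the
    same strand.  The merged exon_union is the set union of exact exon
    intervals from all sources, with per-exon source provenance retained.
    Overlapping genes on opposite strands are kept separate.
    """
    if labels is None:
        labels = [f"source{i}" for i in range(len(model_sets))]
    entries: list[tuple[str, GeneModel]] = [
        (lab, g) for lab, ms in zip(labels, model_sets) for g in ms
    ]
    n = len(entries)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    by_id: dict[str, list[int]] = {}
    for i, (_, g) in enumerate(entries):
        by_id.setdefault(g.gene_id, []).append(i)
    for idxs in by_id.values():
        for j in idxs[1:]:
            union(idxs[0], j)

    # single-linkage by exonic overlap on same chrom+strand
    order = sorted(range(n), key=lambda i: (entries[i][1].chrom, entries[i][1].span[0]))
    for a_pos, i in enumerate(order):
        gi = entries[i][1]
        for j in order[a_pos + 1:]:
            gj = entries[j][1]
            if (gj.chrom, gj.span[0]) > (gi.chrom, gi.span[1]):
                break
            if gi.strand != gj.strand:
                if gi.span[0] < gj.span[1] and gj.span[0] < gi.span[1]:
                    log.warning(
                        "overlapping genes on opposite strands kept separate: %s / %s",
                        gi.gene_id, gj.gene_id,
                    )
                continue
            if _exonic_overlap(gi, gj):
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    merged: list[GeneModel] = []
    for idxs in groups.values():
        members = [entries[i] for i in idxs]
        gid = sorted(m[1].gene_id for m in members)[0]
        chrom, strand = members[0][1].chrom, members[0][1].strand
        isoforms: dict[str, Isoform] = {}
        sources: dict[tuple[int, int], set[str]] = {}
        for lab, g in members:
            for iso in g.isoforms:
                key = iso.id
                if key in isoforms and isoforms[key].exons != iso.exons:
                    key = f"{iso.id}@{lab}"
                isoforms.setdefault(key, replace(iso, id=key))
            for e in g.exon_union:
                labs = sources.setdefault(e.interval(), set())
                labs.add(lab)
                labs |= g.exon_sources.get(e.interval(), set())
        gm = GeneModel(
            gene_id=gid,
            chrom=chrom,
            strand=strand,
            isoforms=sorted(isoforms.values(), key=lambda i: i.id),
            exon_sources=sources,
        )
        merged.append(gm)
    merged.sort(key=lambda g: (g.chrom, g.span[0], g.gene_id))
    return merged


def _exonic_overlap(a: GeneModel, b: GeneModel) -> bool:
    if a.chrom != b.chrom:
        return False
    bx = sorted(e.interval() for e in b.exon_union)
    for e in a.exon_union:
        for s, t in bx:
            if s >= e.end:
                break
            if e.start < t and s < e.end:
                return True
    return False


def longest_isoform(g: GeneModel) -> Isoform:
    """Isoform with maximal summed exon length; ties -> smallest id."""
    if not g.isoforms:
        raise ValueError(f"gene {g.gene_id} has no isoforms")
    return min(g.isoforms, key=lambda i: (-i.length, i.id))


# ---------------------------------------------------------------------------
# CDS inference

_STOPS = ("TAA", "TAG", "TGA")


def spliced_sequence(exons: list[Exon], strand: str, genome) -> str:
    """Spliced transcript sequence (transcription orientation).

    ``genome`` is a mapping-style accessor: ``genome[chrom][start:end]``
    returning sequence (a pyfaidx.Fasta or a plain dict of strings).
    """
    from .junctiondb import fetch  # local import to avoid cycle

    parts = []
    for e in sorted(exons, key=_tx_sort_key(strand)):
        parts.append(fetch(genome, e.chrom, e.start, e.end, strand))
    return "".join(parts)


def infer_cds_start(iso: Isoform, genome) -> int | None:
    """Offset of the start codon of the longest ORF (ATG..stop), or None."""
    seq = spliced_sequence(iso.exons, iso.strand, genome).upper()
    best = None  # (orf_len, start)
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            cod = seq[i : i + 3]
            if cod == "ATG" and start is None:
                start = i
            elif cod in _STOPS and start is not None:
                cand = (i + 3 - start, -start)
                if best is None or cand > best:
                    best = cand
                start = None
    if best is None:
        return None
    return -best[1]
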