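"""Synthetic genomes, annotations, conservation tracks and WT/KO read sets.

The generator emulates the study design the package targets: two pooled
single-end 75 bp libraries from a wild-type and an NMD-deficient condition,
where transcript isoforms carrying a premature termination codon (PTC) are
stabilized in the knock-out by a constant factor.  Genes are designed
around one alternative-splicing event each (SES, MES, A5SS, A3SS, MXE, AFE
or ALE) with fully controlled PTC semantics:

* poison-exon designs place an in-frame stop inside the alternative region,
  at least 50 nt upstream of a downstream junction (PTC upon inclusion);
* frame-shifting designs give the alternative region a length not divisible
  by three, with a stop planted in the shifted frame of a downstream exon
  (PTC upon exclusion);
* in-frame, stop-free alternative regions are PTC-free.

All exon sequence is generated free of stop trinucleotides in every frame
(planted stops excepted), and the two bases preceding every donor boundary
are forced to 'C' so that no junction-spanning stop can arise by accident;
designed isoforms are re-verified by direct translation before emission.
Reads are drawn uniformly along each isoform with molar-abundance x
effective-length weighting, so that the expected junction-level percent
spliced in equals the molar inclusion fraction exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import Exon, GeneModel, Isoform, write_gtf
from .junctiondb import junction_between

__all__ = [
    "SimConfig",
    "DesignedEvent",
    "GroundTruth",
    "Simulation",
    "ReadRecord",
    "simulate_genome_and_models",
    "simulate_reads",
    "write_fastq",
    "double_junction_reads",
]

STOPS = ("TAA", "TAG", "TGA")
_BASES = np.array(list("ACGT"))

DEFAULT_EVENT_MIX = {"SES": 12, "MES": 7, "A5SS": 7, "A3SS": 7, "MXE": 6, "AFE": 6, "ALE": 5}
DEFAULT_PTC_MIX = {
    "SES": {"ptc_on_inclusion": 1 / 3, "ptc_on_exclusion": 1 / 3, "ptc_free": 1 / 3},
    "MES": {"ptc_on_inclusion": 1 / 3, "ptc_on_exclusion": 1 / 3, "ptc_free": 1 / 3},
    "A5SS": {"ptc_on_inclusion": 0.4, "ptc_on_exclusion": 0.3, "ptc_free": 0.3},
    "A3SS": {"ptc_on_inclusion": 0.4, "ptc_on_exclusion": 0.3, "ptc_free": 0.3},
    "MXE": {"ptc_free": 1.0},
    "AFE": {"ptc_free": 1.0},
    "ALE": {"ptc_free": 1.0},
}


@dataclass
class SimConfig:
    """Study-design parameters for the simulator.

    ``ptc_minor_frac_wt`` is the molar fraction of the PTC+ isoform in the
    wild type; the knock-out multiplies it by ``stabilization_factor`` and
    renormalizes, mirroring complete loss of NMD-mediated degradation.
    ``reads_per_gene`` is the sequenced depth per gene and condition.
    """

    event_mix: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_EVENT_MIX))
    ptc_mix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PTC_MIX.items()}
    )
    read_length: int = 75
    reads_per_gene: int = 4000
    stabilization_factor: float = 4.0
    ptc_minor_frac_wt: float = 0.125
    inclusion_psi_wt: float | None = None   # override for ptc_free two-path events (%)
    inclusion_psi_ko: float | None = None
    splice_noise_rate: float = 0.3          # per-gene chance of one spurious junction
    noise_reads: int = 2
    ptc_tga_bias: float = 0.6               # P(planted premature stop is TGA)
    exon_len_range: tuple[int, int] = (120, 180)
    cassette_len_range: tuple[int, int] = (90, 150)
    intron_len_range: tuple[int, int] = (150, 300)
    intergenic_len: int = 800
    anchor_min: int = 5                     # for ground-truth junction-span bookkeeping
    boundary_dist: int | None = None        # pin SES poison-exon stop at this exact
                                            # distance from the last junction (edge designs)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stabilization_factor < 1:
            raise ValueError("stabilization_factor must be >= 1")
        if not 0 <= self.splice_noise_rate <= 1:
            raise ValueError("splice_noise_rate must be in [0, 1]")
        for name in ("exon_len_range", "cassette_len_range", "intron_len_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid {name}: ({lo}, {hi})")
        for cls, n in self.event_mix.items():
            if cls not in DEFAULT_EVENT_MIX:
                raise ValueError(f"unknown event class in event_mix: {cls}")
            if cls in ("MXE",) and n > 0 and self.exon_len_range[1] < 3:
                raise ValueError("MXE requested with degenerate exon lengths")


@dataclass
class DesignedEvent:
    gene_id: str
    cls: str
    semantics: str                       # ptc_on_inclusion | ptc_on_exclusion | ptc_free
    inclusion_junctions: list[tuple]     # junction keys (chrom, strand, donor, acceptor)
    exclusion_junctions: list[tuple]
    constitutive_junctions: list[tuple]  # shared by both isoforms (designed PTC-)
    ptc_junctions: list[tuple]           # designed PTC+ junction keys
    psi_wt: float                        # molar inclusion %, WT
    psi_ko: float
    cassette_triple: tuple[Exon, Exon, Exon] | None = None  # SES conservation anchor
    ptc_genomic: tuple[str, str, int, Exon] | None = None   # (chrom, strand, stop pos, exon)
    ptc_codon: str | None = None
    regulated: bool = False              # |designed delta PSI| > 20


@dataclass
class ReadRecord:
    read_id: str
    gene_id: str
    isoform_id: str
    start: int
    spanned_junctions: tuple[tuple, ...]


@dataclass
class GroundTruth:
    events: list[DesignedEvent]
    # (gene_id, isoform_id) -> {"wt": molar fraction, "ko": molar fraction}
    abundances: dict[tuple[str, str], dict[str, float]]
    # condition -> junction key -> expected read count
    expected_counts: dict[str, dict[tuple, float]]

    def designed_ptc_junctions(self) -> set[tuple]:
        return {k for ev in self.events for k in ev.ptc_junctions}

    def constitutive_junctions(self) -> set[tuple]:
        return {k for ev in self.events for k in ev.constitutive_junctions}


@dataclass
class Simulation:
    cfg: SimConfig
    genome: dict[str, str]
    models: list[GeneModel]
    truth: GroundTruth
    regulated_windows: list[tuple[str, int, int]]  # planted high-conservation intervals

    def write_genome(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    def write_gtf(self, path: str) -> None:
        write_gtf(self.models, path)

    def write_track(self, path: str, baseline: float = 0.3, planted: float = 0.9) -> None:
        """Fixed-step WIG: constant baseline, with planted elevated scores in
        the intron windows flanking regulated cassette exons."""
        with open(path, "w") as fh:
            for chrom in sorted(self.genome):
                scores = np.full(len(self.genome[chrom]), baseline)
                for c, s, e in self.regulated_windows:
                    if c == chrom:
                        scores[s:e] = planted
                fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
                fh.write("\n".join(f"{v:g}" for v in scores) + "\n")

    def isoform_sequence(self, gene_id: str, isoform_id: str) -> str:
        gene = next(g for g in self.models if g.gene_id == gene_id)
        iso = next(i for i in gene.isoforms if i.id == isoform_id)
        from .annotation import spliced_sequence

        return spliced_sequence(iso.exons, iso.strand, self.genome)


# ---------------------------------------------------------------------------
# sequence utilities


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(_BASES[rng.integers(0, 4, size=n)])


def _stop_free(rng: np.random.Generator, n: int) -> list[str]:
    """Random DNA with no stop trinucleotide at any offset.

    A single left-to-right pass replacing the middle base of each stop with
    'C' suffices: stops are spelled from {T, A, G} only, so a 'C' can never
    create a new one.
    """
    seq = _random_seq(rng, n)
    for i in range(n - 2):
        if "".join(seq[i : i + 3]) in STOPS:
            seq[i + 1] = "C"
    return seq


def _guard_donor(seq: list[str], boundary: int | None = None) -> None:
    """Force the two bases before a donor boundary (default: exon end) to be
    non-T ('C'), so no junction-spanning trinucleotide can spell a stop."""
    end = len(seq) if boundary is None else boundary
    for k in (end - 2, end - 1):
        if 0 <= k < len(seq) and seq[k] == "T":
            seq[k] = "C"


def _plant(seq: list[str], pos: int, codon: str) -> None:
    seq[pos : pos + 3] = list(codon)


def _draw_stop(rng: np.random.Generator, tga_bias: float | None = None) -> str:
    if tga_bias is None:
        return STOPS[int(rng.integers(0, 3))]
    r = rng.random()
    if r < tga_bias:
        return "TGA"
    return "TAA" if r < tga_bias + (1 - tga_bias) / 2 else "TAG"


def _rlen(rng: np.random.Generator, lo: int, hi: int, mod3: int | None = None) -> int:
    n = int(rng.integers(lo, hi + 1))
    if mod3 is not None:
        n += (mod3 - n) % 3
    return n


# ---------------------------------------------------------------------------
# per-gene designs

CDS_OFF = 30  # start-codon offset inside the first coding exon


@dataclass
class _GeneDesign:
    """A gene in transcript-strand gene coordinates, before genome placement."""

    gene_id: str
    cls: str
    semantics: str
    regions: list[tuple[str, list[str]]]          # (name, seq) exons+introns in order
    exon_bounds: dict[str, tuple[int, int]]       # exon name -> gene-coordinate interval
    isoforms: dict[str, tuple[list[str], bool]]   # iso id -> (exon names, has_cds)
    cds_gene_off: dict[str, int]                  # iso id -> cds offset within first coding exon
    ptc_exon: str | None = None                   # exon holding the planted premature stop
    ptc_off: int | None = None                    # offset of the stop inside that exon
    ptc_codon: str | None = None
    cassette_names: tuple[str, str, str] | None = None
    ptc_isoform: str | None = None                # isoform carrying the PTC


def _frame_align(off: int, frame_base: int) -> int:
    """Smallest offset >= off whose distance to frame_base is 0 mod 3."""
    return off + (frame_base - off) % 3


def _design_skip(gene_id: str, cls: str, semantics: str, cfg: SimConfig,
                 rng: np.random.Generator, n_cassettes: int,
                 boundary_dist: int | None = None) -> _GeneDesign:
    """SES (one cassette) or MES (>= 2 cassettes) gene.

    Structure: e1 - [cassettes] - e3 - e4, alternative isoform skips all
    cassettes at once.  ``boundary_dist`` pins the premature stop at an
    exact distance from the last junction (used for 49/50 nt edge designs).
    """
    elo, ehi = cfg.exon_len_range
    clo, chi = cfg.cassette_len_range
    ilo, ihi = cfg.intron_len_range
    a = _rlen(rng, elo, ehi)
    mod = 0 if semantics in ("ptc_on_inclusion", "ptc_free") else 1
    if n_cassettes == 1:
        m = [_rlen(rng, clo, chi, mod3=mod)]
    else:
        m = [_rlen(rng, clo, chi, mod3=0) for _ in range(n_cassettes - 1)]
        m.append(_rlen(rng, clo, chi, mod3=mod))
    b = _rlen(rng, elo, ehi)
    c = _rlen(rng, elo, ehi)

    seqs = {
        "e1": _stop_free(rng, a),
        **{f"c{i+1}": _stop_free(rng, mi) for i, mi in enumerate(m)},
        "e3": _stop_free(rng, b),
        "e4": _stop_free(rng, c),
    }
    cass = [f"c{i+1}" for i in range(len(m))]
    inc_order = ["e1", *cass, "e3", "e4"]

    ptc_exon = ptc_off = ptc_codon = None
    if semantics == "ptc_on_inclusion":
        # in-frame stop in the (last) cassette, >= 50 nt + e3 upstream of e3|e4
        tgt = cass[-1]
        upstream = a + sum(m[:-1])  # transcript offset where the cassette begins
        if boundary_dist is None:
            p = _frame_align(m[-1] // 2, CDS_OFF - upstream)
        else:
            # distance = (m - p - 3) + b  =>  choose p near the cassette end
            p = _frame_align(m[-1] - 9, CDS_OFF - upstream)
            while p > m[-1] - 6:
                p -= 3
            b = boundary_dist - (m[-1] - p - 3)
            if b < 10:
                raise ValueError("boundary_dist too small for this cassette length")
            seqs["e3"] = _stop_free(rng, b)
        assert 3 <= p <= m[-1] - 6
        ptc_exon, ptc_off = tgt, p
        ptc_codon = _draw_stop(rng, cfg.ptc_tga_bias)
        _plant(seqs[tgt], p, ptc_codon)
    elif semantics == "ptc_on_exclusion":
        # stop in e3 in the frame of the cassette-skipping isoform
        q = _frame_align(max(3, b // 2 - 30), CDS_OFF - a)
        if q > b - 56:
            q = _frame_align(3, CDS_OFF - a)
        assert q <= b - 56, "e3 too short for a 50-nt-rule stop"
        ptc_exon, ptc_off = "e3", q
        ptc_codon = _draw_stop(rng, cfg.ptc_tga_bias)
        _plant(seqs["e3"], q, ptc_codon)

    # normal stop in the last exon, in the clean isoform's frame
    clean_upstream = a + (sum(m) if semantics != "ptc_on_inclusion" else 0) + b
    k = _frame_align(21, (CDS_OFF - clean_upstream) % 3)
    assert k + 43 <= c
    _plant(seqs["e4"], k, _draw_stop(rng))

    for name in ("e1", *cass, "e3"):
        _guard_donor(seqs[name])

    regions: list[tuple[str, list[str]]] = [("e1", seqs["e1"])]
    for i, name in enumerate(cass):
        regions.append((f"i{i+1}", _intron(rng, ilo, ihi)))
        regions.append((name, seqs[name]))
    regions.append((f"i{len(cass)+1}", _intron(rng, ilo, ihi)))
    regions.append(("e3", seqs["e3"]))
    regions.append((f"i{len(cass)+2}", _intron(rng, ilo, ihi)))
    regions.append(("e4", seqs["e4"]))

    has_cds_inc = semantics != "ptc_on_inclusion"
    has_cds_exc = semantics != "ptc_on_exclusion"
    ptc_isoform = (f"{gene_id}.T1" if semantics == "ptc_on_inclusion"
                   else f"{gene_id}.T2" if semantics == "ptc_on_exclusion" else None)
    if boundary_dist is not None and boundary_dist < 50:
        # the planted stop deliberately misses the rule: not a PTC
        ptc_isoform = None
    d = _GeneDesign(
        gene_id=gene_id, cls=cls, semantics=semantics,
        regions=regions, exon_bounds={},
        isoforms={
            f"{gene_id}.T1": (inc_order, has_cds_inc),
            f"{gene_id}.T2": (["e1", "e3", "e4"], has_cds_exc),
        },
        cds_gene_off={f"{gene_id}.T1": CDS_OFF, f"{gene_id}.T2": CDS_OFF},
        ptc_exon=ptc_exon, ptc_off=ptc_off, ptc_codon=ptc_codon,
        cassette_names=("e1", cass[0], "e3") if n_cassettes == 1 else None,
        ptc_isoform=ptc_isoform,
    )
    return d


def _design_alt_ss(gene_id: str, cls: str, semantics: str, cfg: SimConfig,
                   rng: np.random.Generator) -> _GeneDesign:
    """A5SS or A3SS gene: e1 - e2(short/long variants) - e3 - e4.

    For A5SS the long variant extends the donor (3') side of e2; for A3SS
    the acceptor (5') side.  Inclusion = the extended variant.
    """
    elo, ehi = cfg.exon_len_range
    ilo, ihi = cfg.intron_len_range
    a = _rlen(rng, elo, ehi)
    m = _rlen(rng, elo, ehi, mod3=0)
    ext = _rlen(rng, 60, 90, mod3=0 if semantics in ("ptc_on_inclusion", "ptc_free") else 1)
    b = _rlen(rng, elo, ehi)
    c = _rlen(rng, elo, ehi)

    e1 = _stop_free(rng, a)
    e2 = _stop_free(rng, m + ext)  # full variant region
    e3 = _stop_free(rng, b)
    e4 = _stop_free(rng, c)

    if cls == "A5SS":
        short_bounds, long_bounds = (0, m), (0, m + ext)
        ext_lo = m  # extension occupies the donor side
    else:
        short_bounds, long_bounds = (ext, m + ext), (0, m + ext)
        ext_lo = 0

    ptc_exon = ptc_off = ptc_codon = None
    # positions inside the long e2 sit at transcript offset a + p
    if semantics == "ptc_on_inclusion":
        p = _frame_align(ext_lo + 6, CDS_OFF - a)
        assert p + 3 <= ext_lo + ext
        assert (m + ext - p - 3) + b >= 50  # distance rule via e3|e4 junction
        ptc_exon, ptc_off = "e2", p
        ptc_codon = _draw_stop(rng, cfg.ptc_tga_bias)
        _plant(e2, p, ptc_codon)
        clean_upstream = a + m + b          # short variant reaches e4
    elif semantics == "ptc_on_exclusion":
        # short variant shifts frame downstream; stop planted in e3 in its frame
        q = _frame_align(max(3, b // 2 - 30), CDS_OFF - (a + m))
        if q > b - 56:
            q = _frame_align(3, CDS_OFF - (a + m))
        assert q <= b - 56
        ptc_exon, ptc_off = "e3", q
        ptc_codon = _draw_stop(rng, cfg.ptc_tga_bias)
        _plant(e3, q, ptc_codon)
        clean_upstream = a + m + ext + b    # long variant reaches e4
    else:
        clean_upstream = a + m + b          # same frame either way (ext % 3 == 0)

    k = _frame_align(21, (CDS_OFF - clean_upstream) % 3)
    assert k + 43 <= c
    _plant(e4, k, _draw_stop(rng))

    _guard_donor(e1)
    _guard_donor(e3)
    _guard_donor(e2)                        # long donor boundary
    if cls == "A5SS":
        _guard_donor(e2, boundary=m)        # short donor boundary

    regions = [
        ("e1", e1), ("i1", _intron(rng, ilo, ihi)),
        ("e2", e2), ("i2", _intron(rng, ilo, ihi)),
        ("e3", e3), ("i3", _intron(rng, ilo, ihi)),
        ("e4", e4),
    ]
    has_cds_long = semantics != "ptc_on_inclusion"
    has_cds_short = semantics != "ptc_on_exclusion"
    d = _GeneDesign(
        gene_id=gene_id, cls=cls, semantics=semantics,
        regions=regions, exon_bounds={},
        isoforms={
            f"{gene_id}.T1": (["e1", "e2long", "e3", "e4"], has_cds_long),
            f"{gene_id}.T2": (["e1", "e2short", "e3", "e4"], has_cds_short),
        },
        cds_gene_off={f"{gene_id}.T1": CDS_OFF, f"{gene_id}.T2": CDS_OFF},
        ptc_exon=ptc_exon, ptc_off=ptc_off, ptc_codon=ptc_codon,
        ptc_isoform=(f"{gene_id}.T1" if semantics == "ptc_on_inclusion"
                     else f"{gene_id}.T2" if semantics == "ptc_on_exclusion" else None),
    )
    d.exon_bounds["__variant__"] = (short_bounds, long_bounds)  # resolved at placement
    return d


def _design_mxe(gene_id: str, cfg: SimConfig, rng: np.random.Generator) -> _GeneDesign:
    elo, ehi = cfg.exon_len_range
    ilo, ihi = cfg.intron_len_range
    a = _rlen(rng, elo, ehi)
    ma = _rlen(rng, cfg.cassette_len_range[0], cfg.cassette_len_range[1], mod3=0)
    mb = _rlen(rng, cfg.cassette_len_range[0], cfg.cassette_len_range[1], mod3=0)
    c = _rlen(rng, elo, ehi)
    e1, ea, eb, e4 = (_stop_free(rng, n) for n in (a, ma, mb, c))
    # same frame in e4 regardless of which cassette is used (ma, mb % 3 == 0)
    k = _frame_align(21, (CDS_OFF - (a + ma)) % 3)
    assert k + 43 <= c
    _plant(e4, k, _draw_stop(rng))
    for s in (e1, ea, eb):
        _guard_donor(s)
    regions = [
        ("e1", e1), ("i1", _intron(rng, ilo, ihi)),
        ("eA", ea), ("i2", _intron(rng, ilo, ihi)),
        ("eB", eb), ("i3", _intron(rng, ilo, ihi)),
        ("e4", e4),
    ]
    return _GeneDesign(
        gene_id=gene_id, cls="MXE", semantics="ptc_free",
        regions=regions, exon_bounds={},
        isoforms={
            f"{gene_id}.T1": (["e1", "eA", "e4"], True),
            f"{gene_id}.T2": (["e1", "eB", "e4"], True),
        },
        cds_gene_off={f"{gene_id}.T1": CDS_OFF, f"{gene_id}.T2": CDS_OFF},
    )


def _design_afe(gene_id: str, cfg: SimConfig, rng: np.random.Generator) -> _GeneDesign:
    elo, ehi = cfg.exon_len_range
    ilo, ihi = cfg.intron_len_range
    fa = _rlen(rng, elo, ehi)
    fb = _rlen(rng, elo, ehi)
    b = _rlen(rng, elo, ehi)
    c = _rlen(rng, elo, ehi)
    f1a, f1b, e2, e3 = (_stop_free(rng, n) for n in (fa, fb, b, c))
    # first exons are untranslated; CDS starts inside the shared e2
    k = _frame_align(21, (CDS_OFF - b) % 3)
    assert k + 43 <= c
    _plant(e3, k, _draw_stop(rng))
    for s in (f1a, f1b, e2):
        _guard_donor(s)
    regions = [
        ("f1a", f1a), ("i1", _intron(rng, ilo, ihi)),
        ("f1b", f1b), ("i2", _intron(rng, ilo, ihi)),
        ("e2", e2), ("i3", _intron(rng, ilo, ihi)),
        ("e3", e3),
    ]
    return _GeneDesign(
        gene_id=gene_id, cls="AFE", semantics="ptc_free",
        regions=regions, exon_bounds={},
        isoforms={
            f"{gene_id}.T1": (["f1a", "e2", "e3"], True),
            f"{gene_id}.T2": (["f1b", "e2", "e3"], True),
        },
        cds_gene_off={f"{gene_id}.T1": CDS_OFF, f"{gene_id}.T2": CDS_OFF},
    )


def _design_ale(gene_id: str, cfg: SimConfig, rng: np.random.Generator) -> _GeneDesign:
    elo, ehi = cfg.exon_len_range
    ilo, ihi = cfg.intron_len_range
    a = _rlen(rng, elo, ehi)
    b = _rlen(rng, elo, ehi, mod3=0)
    ca = _rlen(rng, elo, ehi)
    cb = _rlen(rng, elo, ehi)
    e1, e2, t3a, t3b = (_stop_free(rng, n) for n in (a, b, ca, cb))
    k = _frame_align(21, (CDS_OFF - (a + b)) % 3)
    assert k + 43 <= min(ca, cb)
    stop = _draw_stop(rng)
    _plant(t3a, k, stop)
    _plant(t3b, k, _draw_stop(rng))
    for s in (e1, e2):
        _guard_donor(s)
    regions = [
        ("e1", e1), ("i1", _intron(rng, ilo, ihi)),
        ("e2", e2), ("i2", _intron(rng, ilo, ihi)),
        ("t3a", t3a), ("i3", _intron(rng, ilo, ihi)),
        ("t3b", t3b),
    ]
    return _GeneDesign(
        gene_id=gene_id, cls="ALE", semantics="ptc_free",
        regions=regions, exon_bounds={},
        isoforms={
            f"{gene_id}.T1": (["e1", "e2", "t3a"], True),
            f"{gene_id}.T2": (["e1", "e2", "t3b"], True),
        },
        cds_gene_off={f"{gene_id}.T1": CDS_OFF, f"{gene_id}.T2": CDS_OFF},
    )


def _intron(rng: np.random.Generator, lo: int, hi: int) -> list[str]:
    n = int(rng.integers(lo, hi + 1))
    seq = _random_seq(rng, n)
    seq[:2] = ["G", "T"]   # advisory GT..AG splice-site dinucleotides
    seq[-2:] = ["A", "G"]
    return seq


_BUILDERS = {
    "SES": lambda gid, sem, cfg, rng: _design_skip(
        gid, "SES", sem, cfg, rng, 1,
        boundary_dist=cfg.boundary_dist if sem == "ptc_on_inclusion" else None,
    ),
    "MES": lambda gid, sem, cfg, rng: _design_skip(gid, "MES", sem, cfg, rng, 2),
    "A5SS": lambda gid, sem, cfg, rng: _design_alt_ss(gid, "A5SS", sem, cfg, rng),
    "A3SS": lambda gid, sem, cfg, rng: _design_alt_ss(gid, "A3SS", sem, cfg, rng),
    "MXE": lambda gid, sem, cfg, rng: _design_mxe(gid, cfg, rng),
    "AFE": lambda gid, sem, cfg, rng: _design_afe(gid, cfg, rng),
    "ALE": lambda gid, sem, cfg, rng: _design_ale(gid, cfg, rng),
}


# ---------------------------------------------------------------------------
# genome placement and ground truth


def _place_gene(design: _GeneDesign, chrom: str, offset: int, strand: str):
    """Resolve a design into genomic Exon objects and a genomic sequence."""
    gene_seq: list[str] = []
    bounds: dict[str, tuple[int, int]] = {}
    pos = 0
    for name, seq in design.regions:
        if not name.startswith("i"):
            bounds[name] = (pos, pos + len(seq))
        gene_seq.extend(seq)
        pos += len(seq)
    glen = pos

    variant = design.exon_bounds.get("__variant__")
    if variant is not None:
        (slo, shi), (llo, lhi) = variant
        r0 = bounds["e2"][0]
        bounds["e2short"] = (r0 + slo, r0 + shi)
        bounds["e2long"] = (r0 + llo, r0 + lhi)
        del bounds["e2"]

    def to_genomic(t0: int, t1: int) -> tuple[int, int]:
        if strand == "+":
            return offset + t0, offset + t1
        return offset + glen - t1, offset + glen - t0

    exons = {
        name: Exon(chrom, *to_genomic(t0, t1), strand)
        for name, (t0, t1) in bounds.items()
    }
    seq = "".join(gene_seq)
    if strand == "-":
        from Bio.Seq import reverse_complement

        seq = reverse_complement(seq)
    return exons, seq, bounds


def _verify_design(design: _GeneDesign, iso_seqs: dict[str, str],
                   cds_offsets: dict[str, int], bounds) -> None:
    """Re-check designed PTC semantics by direct translation."""
    for iso_id, seq in iso_seqs.items():
        cds = cds_offsets[iso_id]
        first = None
        for i in range(cds, len(seq) - 2, 3):
            if seq[i : i + 3] in STOPS:
                first = i
                break
        assert first is not None, f"{iso_id}: no stop reached"
        names = design.isoforms[iso_id][0]
        lens = [bounds[n][1] - bounds[n][0] for n in names]
        last_junction = sum(lens[:-1])
        dist = last_junction - (first + 3)
        is_ptc = dist >= 50
        expect_ptc = iso_id == design.ptc_isoform
        assert is_ptc == expect_ptc, (
            f"{design.gene_id}/{iso_id}: designed PTC semantics not realized "
            f"(dist={dist}, expected ptc={expect_ptc})"
        )


def simulate_genome_and_models(cfg: SimConfig) -> Simulation:
    """Generate the genome FASTA content, gene models and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    chrom = "chr1"
    genome_parts: list[str] = []
    cursor = 0
    models: list[GeneModel] = []
    events: list[DesignedEvent] = []
    abundances: dict[tuple[str, str], dict[str, float]] = {}
    regulated_windows: list[tuple[str, int, int]] = []

    gene_no = 0
    S = cfg.stabilization_factor
    for cls in sorted(cfg.event_mix):
        n_cls = cfg.event_mix[cls]
        sem_fracs = cfg.ptc_mix.get(cls, {"ptc_free": 1.0})
        sem_names = sorted(sem_fracs)
        counts = _apportion(n_cls, [sem_fracs[s] for s in sem_names])
        for sem, n_sem in zip(sem_names, counts):
            for _ in range(n_sem):
                gene_no += 1
                gid = f"g{gene_no:03d}"
                strand = "+" if gene_no % 2 else "-"
                design = _BUILDERS[cls](gid, sem, cfg, rng)
                gap = _random_seq(rng, cfg.intergenic_len)
                genome_parts.append("".join(gap))
                cursor += cfg.intergenic_len
                exons, gseq, bounds = _place_gene(design, chrom, cursor, strand)
                genome_parts.append(gseq)
                gene_start = cursor
                cursor += len(gseq)

                iso_objs = []
                iso_seqs = {}
                cds_offsets = {}
                for iso_id, (names, has_cds) in sorted(design.isoforms.items()):
                    ex_list = [exons[n] for n in names]
                    cds_offsets[iso_id] = _iso_cds_start(design, names, bounds)
                    iso_objs.append(
                        Isoform(iso_id, ex_list,
                                cds_start=cds_offsets[iso_id] if has_cds else None)
                    )
                    iso_seqs[iso_id] = _iso_gene_seq(design, names, bounds)
                _verify_design(design, iso_seqs, cds_offsets, bounds)
                gene = GeneModel(gid, chrom, strand, iso_objs)
                models.append(gene)

                ev = _ground_truth_event(design, gene, exons, cfg, S)
                events.append(ev)
                for iso_id in design.isoforms:
                    frac_inc = ev.psi_wt / 100.0
                    frac_inc_ko = ev.psi_ko / 100.0
                    is_inc = iso_id.endswith(".T1")
                    abundances[(gid, iso_id)] = {
                        "wt": frac_inc if is_inc else 1 - frac_inc,
                        "ko": frac_inc_ko if is_inc else 1 - frac_inc_ko,
                    }
                if ev.regulated and ev.cassette_triple is not None:
                    _, cas, _ = ev.cassette_triple
                    regulated_windows.append((chrom, cas.start - 75, cas.start))
                    regulated_windows.append((chrom, cas.end, cas.end + 75))

    genome_parts.append("".join(_random_seq(rng, cfg.intergenic_len)))
    genome = {chrom: "".join(genome_parts)}
    truth = GroundTruth(events, abundances, {})
    truth.expected_counts = _expected_counts(models, truth, cfg)
    return Simulation(cfg, genome, models, truth, regulated_windows)


def _iso_gene_seq(design: _GeneDesign, names: list[str], bounds) -> str:
    gene_seq = "".join("".join(s) for _, s in design.regions)
    return "".join(gene_seq[bounds[n][0] : bounds[n][1]] for n in names)


def _iso_cds_start(design: _GeneDesign, names: list[str], bounds) -> int:
    """Transcript offset of the start codon: CDS_OFF inside the first coding
    exon (for AFE genes the first exon is untranslated)."""
    if design.cls == "AFE":
        first_len = bounds[names[0]][1] - bounds[names[0]][0]
        return first_len + CDS_OFF
    return CDS_OFF


def _apportion(total: int, weights: list[float]) -> list[int]:
    """Largest-remainder integer split of ``total`` by ``weights``."""
    if total == 0 or not weights:
        return [0] * len(weights)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    raw = w * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return base.tolist()


def _ground_truth_event(design: _GeneDesign, gene: GeneModel, exons, cfg: SimConfig,
                        S: float) -> DesignedEvent:
    strand = gene.strand

    def jkey(u: str, v: str) -> tuple:
        return junction_between(gene.gene_id, strand, exons[u], exons[v]).key

    sem = design.semantics
    if sem != "ptc_free" and design.ptc_isoform is None:
        sem = "ptc_free"  # edge designs whose planted stop misses the rule
    cls = design.cls
    if cls in ("SES", "MES"):
        cass = sorted(n for n, _ in design.regions if n.startswith("c") and not n.startswith("i"))
        chain = ["e1", *cass, "e3"]
        inc = [jkey(u, v) for u, v in zip(chain, chain[1:])]
        exc = [jkey("e1", "e3")]
        cons = [jkey("e3", "e4")]
        triple = (exons["e1"], exons[cass[0]], exons["e3"]) if cls == "SES" else None
    elif cls in ("A5SS", "A3SS"):
        inc = [jkey("e2long", "e3") if cls == "A5SS" else jkey("e1", "e2long")]
        exc = [jkey("e2short", "e3") if cls == "A5SS" else jkey("e1", "e2short")]
        cons = [jkey("e3", "e4")]
        triple = None
    elif cls == "MXE":
        inc = [jkey("e1", "eA"), jkey("eA", "e4")]
        exc = [jkey("e1", "eB"), jkey("eB", "e4")]
        cons = []
        triple = None
    elif cls == "AFE":
        inc = [jkey("f1a", "e2")]
        exc = [jkey("f1b", "e2")]
        cons = [jkey("e2", "e3")]
        triple = None
    else:  # ALE
        inc = [jkey("e2", "t3a")]
        exc = [jkey("e2", "t3b")]
        cons = [jkey("e1", "e2")]
        triple = None

    if sem == "ptc_on_inclusion":
        psi_wt = cfg.ptc_minor_frac_wt * 100
        # junction-level PTC+ status holds only for junctions that splice the
        # stop-carrying (last) cassette into the backbone on their own
        ptc_j = inc[-2:] if cls in ("SES", "MES") else inc
    elif sem == "ptc_on_exclusion":
        psi_wt = (1 - cfg.ptc_minor_frac_wt) * 100
        ptc_j = exc
    else:
        psi_wt = cfg.inclusion_psi_wt if cfg.inclusion_psi_wt is not None else 50.0
        ptc_j = []

    if sem == "ptc_free":
        psi_ko = cfg.inclusion_psi_ko if cfg.inclusion_psi_ko is not None else psi_wt
    else:
        f = cfg.ptc_minor_frac_wt
        f_ko = f * S / (f * S + (1 - f))
        psi_ko = f_ko * 100 if sem == "ptc_on_inclusion" else (1 - f_ko) * 100

    ptc_genomic = None
    if design.ptc_exon is not None:
        # "e2" offsets are in full variant-region coordinates = e2long's frame
        name = "e2long" if design.ptc_exon == "e2" else design.ptc_exon
        e = exons[name]
        off = design.ptc_off
        gpos = e.start + off if strand == "+" else e.end - 1 - off
        ptc_genomic = (gene.chrom, strand, gpos, e)

    return DesignedEvent(
        gene_id=gene.gene_id, cls=cls, semantics=sem,
        inclusion_junctions=inc, exclusion_junctions=exc,
        constitutive_junctions=cons, ptc_junctions=ptc_j,
        psi_wt=psi_wt, psi_ko=psi_ko,
        cassette_triple=triple, ptc_genomic=ptc_genomic,
        ptc_codon=design.ptc_codon,
        regulated=abs(psi_ko - psi_wt) > 20,
    )


def _expected_counts(models, truth: GroundTruth, cfg: SimConfig):
    """Closed-form expected junction read counts per condition."""
    rl, anchor = cfg.read_length, cfg.anchor_min
    w = rl - 2 * anchor + 1
    out = {"wt": {}, "ko": {}}
    for g in models:
        for cond in ("wt", "ko"):
            denom = 0.0
            per_iso = {}
            for iso in g.isoforms:
                a = truth.abundances[(g.gene_id, iso.id)][cond]
                eff = max(iso.length - rl + 1, 0)
                per_iso[iso.id] = a * eff
                denom += a * eff
            for iso in g.isoforms:
                if denom == 0:
                    continue
                n_iso = cfg.reads_per_gene * per_iso[iso.id] / denom
                eff = max(iso.length - rl + 1, 1)
                for up, down in iso.junction_pairs():
                    key = junction_between(g.gene_id, g.strand, up, down).key
                    out[cond][key] = out[cond].get(key, 0.0) + n_iso * w / eff
    return out


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(sim: Simulation, condition: str,
                   rng: np.random.Generator | None = None):
    """Draw reads for one condition; returns (reads, provenance records).

    Reads start uniformly along each isoform, with isoforms weighted by
    molar abundance x effective length; the knock-out's PTC+ isoform
    abundances are already stabilized and renormalized in the ground truth.
    Per-gene spurious "splice-error" junction reads are added at low
    abundance for eligible genes.
    """
    cfg = sim.cfg
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 1 if condition == "wt" else 2])
    rl, anchor = cfg.read_length, cfg.anchor_min
    reads: list[tuple[str, str]] = []
    records: list[ReadRecord] = []
    for g in sim.models:
        iso_seqs = {i.id: sim.isoform_sequence(g.gene_id, i.id) for i in g.isoforms}
        iso_juncs = {}
        for iso in g.isoforms:
            offs = []
            off = 0
            keys = []
            for up, down in iso.junction_pairs():
                off += up.length
                offs.append(off)
                keys.append(junction_between(g.gene_id, g.strand, up, down).key)
            iso_juncs[iso.id] = (offs, keys)
        weights = []
        iso_ids = [i.id for i in g.isoforms]
        for iso in g.isoforms:
            a = sim.truth.abundances[(g.gene_id, iso.id)][condition]
            weights.append(a * max(iso.length - rl + 1, 0))
        weights = np.asarray(weights)
        if weights.sum() == 0:
            continue
        p = weights / weights.sum()
        choices = rng.choice(len(iso_ids), size=cfg.reads_per_gene, p=p)
        for n, ci in enumerate(choices):
            iso_id = iso_ids[ci]
            seq = iso_seqs[iso_id]
            start = int(rng.integers(0, len(seq) - rl + 1))
            rid = f"{condition}:{g.gene_id}:{n}"
            reads.append((rid, seq[start : start + rl]))
            offs, keys = iso_juncs[iso_id]
            spanned = tuple(
                k for o, k in zip(offs, keys)
                if start <= o - anchor and start + rl >= o + anchor
            )
            records.append(ReadRecord(rid, g.gene_id, iso_id, start, spanned))
        _add_noise_reads(sim, g, condition, rng, reads, records)
    return reads, records


def _add_noise_reads(sim, g, condition, rng, reads, records) -> None:
    cfg = sim.cfg
    truth = sim.truth
    ev = next((e for e in truth.events if e.gene_id == g.gene_id), None)
    if ev is None or ev.cls in ("MXE", "AFE", "ALE"):
        return  # noise into terminal/forbidden exons would corrupt motifs
    if rng.random() >= cfg.splice_noise_rate:
        return
    designed = set(ev.inclusion_junctions) | set(ev.exclusion_junctions) | set(ev.constitutive_junctions)
    exons = g.exon_union
    candidates = []
    for i, up in enumerate(exons):
        for down in exons[i + 1:]:
            if up.overlaps(down):
                continue
            j = junction_between(g.gene_id, g.strand, up, down)
            if j.key not in designed:
                candidates.append(j)
    if not candidates:
        return
    j = candidates[int(rng.integers(0, len(candidates)))]
    from .annotation import spliced_sequence

    up, down = j.donor_exon, j.acceptor_exon
    useq = spliced_sequence([up], g.strand, sim.genome)
    dseq = spliced_sequence([down], g.strand, sim.genome)
    rl = cfg.read_length
    for n in range(cfg.noise_reads):
        take_up = rl // 2 + int(rng.integers(-5, 6))
        frag = useq[-take_up:] + dseq[: rl - take_up]
        if len(frag) < rl:
            continue
        rid = f"{condition}:{g.gene_id}:noise{n}"
        reads.append((rid, frag))
        records.append(ReadRecord(rid, g.gene_id, "noise", -1, (j.key,)))


def double_junction_reads(sim: Simulation, gene_id: str, n: int = 10,
                          overhang: int = 5, rng=None):
    """75-mers from an inclusion isoform spanning two junctions, with only
    ``overhang`` bases past the second junction — unmappable at full length
    but rescued by one 3' trim when overhang < trunc_step."""
    cfg = sim.cfg
    gene = next(g for g in sim.models if g.gene_id == gene_id)
    iso = next(i for i in gene.isoforms if i.id.endswith(".T1"))
    seq = sim.isoform_sequence(gene_id, iso.id)
    offs = []
    off = 0
    for e in iso.exons[:-1]:
        off += e.length
        offs.append(off)
    out = []
    rl = cfg.read_length
    for i in range(len(offs) - 1):
        o1, o2 = offs[i], offs[i + 1]
        start = o2 + overhang - rl
        if start <= o1 - cfg.anchor_min and start >= 0:
            for k in range(n):
                out.append((f"dj:{gene_id}:{i}:{k}", seq[start : start + rl]))
    return out


def write_fastq(reads, path: str) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
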