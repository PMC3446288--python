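"""Alternative-splicing event inference and PSI quantification.

Seven event classes are detected as motifs on the graph of expressed
junctions of each gene (exons = nodes, junctions = directed edges in
transcription order):

* SES  — skip junction i->k coexpressed with inclusion junctions i->j, j->k
         for a single intervening exon j;
* MES  — skip junction spanning >= 2 consecutive intervening exons, each
         linked by an expressed inclusion chain i->j1->...->jn->k;
* A5SS — two junctions sharing an acceptor whose donor exons overlap
         (alternative donor boundaries of the same exonic region);
* A3SS — the mirror image (shared donor, overlapping acceptor exons);
* MXE  — exons j, k (j upstream, non-overlapping) with i->j, j->m, i->k,
         k->m all expressed and the j->k junction *not* expressed (the
         stringent criterion: a read on j->k destroys the call, revealing
         double inclusion instead);
* AFE  — junctions from two non-overlapping 5'-terminal exons converging on
         one acceptor;
* ALE  — junctions from one donor diverging to two non-overlapping
         3'-terminal exons.

Percent spliced in (PSI) is the ratio of junction evidence supporting the
inclusion path versus the reciprocal exclusion path, using the mean count
over multi-junction sides so that a two-junction inclusion path is not
double-weighted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .annotation import Exon, GeneModel
from .junctiondb import Junction

__all__ = [
    "SpliceEvent",
    "PsiRecord",
    "classify_events",
    "compute_psi",
    "compute_delta_psi",
    "EVENT_CLASSES",
    "DEFAULT_DPSI_THRESHOLD",
    "DEFAULT_MIN_EVENT_READS",
]

EVENT_CLASSES = ("SES", "MES", "A5SS", "A3SS", "MXE", "AFE", "ALE")
DEFAULT_DPSI_THRESHOLD = 20.0
DEFAULT_MIN_EVENT_READS = 10


@dataclass
class SpliceEvent:
    event_id: str
    gene_id: str
    cls: str
    inclusion_junctions: list[Junction]
    exclusion_junctions: list[Junction]
    affected_exons: list[Exon]

    def __post_init__(self) -> None:
        if self.cls not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.cls!r}")
        inc = {j.key for j in self.inclusion_junctions}
        exc = {j.key for j in self.exclusion_junctions}
        if not inc or not exc or inc & exc:
            raise ValueError("inclusion/exclusion junction sets must be disjoint and nonempty")

    @property
    def junctions(self) -> list[Junction]:
        return self.inclusion_junctions + self.exclusion_junctions


@dataclass
class PsiRecord:
    event: SpliceEvent
    psi_wt: float | None
    psi_ko: float | None
    delta_psi: float | None
    supported: bool
    direction: str  # increased-inclusion | increased-exclusion | no-call


def classify_events(
    junction_counts: dict[Junction, dict[str, int] | int],
    models: list[GeneModel],
    min_reads_expressed: int = 1,
) -> list[SpliceEvent]:
    """Detect event motifs on expressed junctions, gene by gene.

    ``junction_counts`` maps each junction to either a per-sample count
    mapping or a plain count; a junction is expressed when any sample has
    >= ``min_reads_expressed`` reads.  Only junctions with resolved exon
    references participate (imported junctions acquire them when their
    boundaries coincide with union-exon boundaries).
    """

    def total(v) -> int:
        return max(v.values()) if isinstance(v, dict) else int(v)

    by_gene: dict[str, list[Junction]] = {}
    for j, v in junction_counts.items():
        if total(v) >= min_reads_expressed and j.donor_exon is not None and j.acceptor_exon is not None:
            by_gene.setdefault(j.gene_id, []).append(j)

    models_by_id = {g.gene_id: g for g in models}
    events: list[SpliceEvent] = []
    for gid in sorted(by_gene):
        gene = models_by_id.get(gid)
        if gene is None:
            continue
        events.extend(_gene_events(gene, by_gene[gid]))
    for n, ev in enumerate(events):
        ev.event_id = f"{ev.gene_id}:{ev.cls}:{n}"
    return events


def _gene_events(gene: GeneModel, junctions: list[Junction]) -> list[SpliceEvent]:
    exons = gene.exon_union  # 5'->3' transcription order
    rank = {e.interval(): i for i, e in enumerate(exons)}

    def rk(e: Exon) -> int | None:
        return rank.get(e.interval())

    # edges between union exons, by rank pair
    edges: dict[tuple[int, int], Junction] = {}
    for j in junctions:
        u, v = rk(j.donor_exon), rk(j.acceptor_exon)
        if u is None or v is None or u >= v:
            continue
        edges.setdefault((u, v), j)

    out_edges: dict[int, list[int]] = {}
    in_edges: dict[int, list[int]] = {}
    for (u, v) in edges:
        out_edges.setdefault(u, []).append(v)
        in_edges.setdefault(v, []).append(u)

    overlap = [[exons[a].overlaps(exons[b]) for b in range(len(exons))] for a in range(len(exons))]
    has_in = set(in_edges)    # exons with an expressed upstream junction
    has_out = set(out_edges)  # exons with an expressed downstream junction

    events: list[SpliceEvent] = []

    def ev(cls, inc, exc, affected):
        events.append(SpliceEvent("", gene.gene_id, cls, inc, exc, affected))

    # SES / MES: skip edge (i,k) plus an expressed chain through >=1
    # intervening exon(s); MES chains run through consecutive union exons.
    for (i, k), skip in sorted(edges.items()):
        # single intervening exon
        for jx in range(i + 1, k):
            if (i, jx) in edges and (jx, k) in edges:
                ev("SES", [edges[(i, jx)], edges[(jx, k)]], [skip], [exons[jx]])
        # consecutive chains of length >= 2
        inner = [jx for jx in range(i + 1, k)
                 if not overlap[jx][i] and not overlap[jx][k]]
        for chain in _consecutive_chains(inner):
            if len(chain) < 2:
                continue
            path = [(i, chain[0])] + list(zip(chain, chain[1:])) + [(chain[-1], k)]
            if all(p in edges for p in path):
                ev("MES", [edges[p] for p in path], [skip], [exons[c] for c in chain])

    # A5SS / A3SS: shared boundary, overlapping variant exons on the other side
    by_acceptor: dict[tuple, list[tuple[int, int]]] = {}
    by_donor: dict[tuple, list[tuple[int, int]]] = {}
    for (u, v), j in edges.items():
        by_acceptor.setdefault((j.acceptor, v), []).append((u, v))
        by_donor.setdefault((j.donor, u), []).append((u, v))
    for pairs in by_acceptor.values():
        for (u1, v), (u2, _) in itertools.combinations(sorted(pairs), 2):
            if u1 != u2 and overlap[u1][u2]:
                j1, j2 = edges[(u1, v)], edges[(u2, v)]
                inc, exc = _variant_order(j1, j2)
                ev("A5SS", [inc], [exc], sorted({inc.donor_exon, exc.donor_exon},
                                                key=lambda e: e.start))
    for pairs in by_donor.values():
        for (u, v1), (_, v2) in itertools.combinations(sorted(pairs), 2):
            if v1 != v2 and overlap[v1][v2]:
                j1, j2 = edges[(u, v1)], edges[(u, v2)]
                inc, exc = _variant_order(j1, j2)
                ev("A3SS", [inc], [exc], sorted({inc.acceptor_exon, exc.acceptor_exon},
                                                key=lambda e: e.start))

    # MXE: i->j, j->m, i->k, k->m expressed, j->k NOT expressed
    for jx, kx in itertools.combinations(range(len(exons)), 2):
        if overlap[jx][kx] or (jx, kx) in edges:
            continue
        ups = set(in_edges.get(jx, ())) & set(in_edges.get(kx, ()))
        downs = set(out_edges.get(jx, ())) & set(out_edges.get(kx, ()))
        for i in sorted(ups):
            for m in sorted(downs):
                if i < jx < kx < m and not overlap[i][jx] and not overlap[kx][m]:
                    ev("MXE",
                       [edges[(i, jx)], edges[(jx, m)]],
                       [edges[(i, kx)], edges[(kx, m)]],
                       [exons[jx], exons[kx]])

    # AFE: two non-overlapping 5'-terminal exons converging on one acceptor
    for pairs in by_acceptor.values():
        for (u1, v), (u2, _) in itertools.combinations(sorted(pairs), 2):
            if u1 == u2 or overlap[u1][u2]:
                continue
            if u1 in has_in or u2 in has_in:
                continue
            j1, j2 = edges[(u1, v)], edges[(u2, v)]
            ev("AFE", [j1], [j2], [exons[u1], exons[u2]])

    # ALE: one donor diverging to two non-overlapping 3'-terminal exons
    for pairs in by_donor.values():
        for (u, v1), (_, v2) in itertools.combinations(sorted(pairs), 2):
            if v1 == v2 or overlap[v1][v2]:
                continue
            if v1 in has_out or v2 in has_out:
                continue
            j1, j2 = edges[(u, v1)], edges[(u, v2)]
            ev("ALE", [j1], [j2], [exons[v1], exons[v2]])

    return events


def _consecutive_chains(inner: list[int]) -> list[list[int]]:
    """Maximal runs of consecutive union-exon ranks, plus all sub-runs."""
    runs: list[list[int]] = []
    cur: list[int] = []
    for x in inner:
        if cur and x == cur[-1] + 1:
            cur.append(x)
        else:
            if cur:
                runs.append(cur)
            cur = [x]
    if cur:
        runs.append(cur)
    out = []
    for run in runs:
        for a in range(len(run)):
            for b in range(a + 1, len(run) + 1):
                out.append(run[a:b])
    return out


def _variant_order(j1: Junction, j2: Junction) -> tuple[Junction, Junction]:
    """(inclusion, exclusion) for alternative-splice-site junction pairs:
    the junction with the shorter intron includes more exonic sequence."""
    l1 = j1.intron_bounds[1] - j1.intron_bounds[0]
    l2 = j2.intron_bounds[1] - j2.intron_bounds[0]
    return (j1, j2) if l1 <= l2 else (j2, j1)


# ---------------------------------------------------------------------------
# PSI


def _mean_count(junctions: list[Junction], counts, sample) -> float:
    vals = []
    for j in junctions:
        v = counts.get(j, 0)
        if isinstance(v, dict):
            v = v.get(sample, 0)
        vals.append(v)
    return sum(vals) / len(vals)


def compute_psi(event: SpliceEvent, counts, sample=None) -> float | None:
    """100 * I / (I + E) with I, E the mean counts over the inclusion and
    exclusion junction sets; None (undefined) when I + E == 0."""
    i = _mean_count(event.inclusion_junctions, counts, sample)
    e = _mean_count(event.exclusion_junctions, counts, sample)
    if i + e == 0:
        return None
    return 100.0 * i / (i + e)


def _total_event_reads(event: SpliceEvent, counts, sample) -> float:
    tot = 0.0
    for j in event.junctions:
        v = counts.get(j, 0)
        if isinstance(v, dict):
            v = v.get(sample, 0)
        tot += v
    return tot


def compute_delta_psi(
    event: SpliceEvent,
    counts_wt,
    counts_ko,
    threshold: float = DEFAULT_DPSI_THRESHOLD,
    min_event_reads: int = DEFAULT_MIN_EVENT_READS,
) -> PsiRecord:
    """PSI(KO) - PSI(WT) in percentage points, with a per-sample summed-read
    support requirement; events crossing +-threshold are directional calls."""
    psi_wt = compute_psi(event, counts_wt)
    psi_ko = compute_psi(event, counts_ko)
    supported = (
        psi_wt is not None
        and psi_ko is not None
        and _total_event_reads(event, counts_wt, None) >= min_event_reads
        and _total_event_reads(event, counts_ko, None) >= min_event_reads
    )
    if psi_wt is None or psi_ko is None:
        return PsiRecord(event, psi_wt, psi_ko, None, False, "no-call")
    delta = psi_ko - psi_wt
    if not supported:
        direction = "no-call"
    elif delta > threshold:
        direction = "increased-inclusion"
    elif delta < -threshold:
        direction = "increased-exclusion"
    else:
        direction = "no-call"
    return PsiRecord(event, psi_wt, psi_ko, delta, supported, direction)
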