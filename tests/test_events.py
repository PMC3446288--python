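import numpy as np
import pytest

from splicejudge.annotation import Exon
from splicejudge.events import (
    SpliceEvent,
    classify_events,
    compute_delta_psi,
    compute_psi,
)
from splicejudge.junctiondb import Junction, junction_between

from conftest import make_gene
import oracles


def _gene_from_intervals(intervals, strand="+", gene_id="g"):
    """GeneModel whose exon_union is exactly ``intervals`` (one isoform per
    exon pair chain is unnecessary; a single isoform through all
    non-overlapping exons plus variant singletons suffices)."""
    groups = []
    used = set()
    for i, iv in enumerate(intervals):
        if i in used:
            continue
        chain = [iv]
        used.add(i)
        for j in range(i + 1, len(intervals)):
            if j in used:
                continue
            if all(not (c[0] < intervals[j][1] and intervals[j][0] < c[1]) for c in chain):
                chain.append(intervals[j])
                used.add(j)
        groups.append(chain)
    iso_specs = {f"t{k}": chain for k, chain in enumerate(groups)}
    return make_gene(gene_id, "chr1", strand, iso_specs)


def _counts_for(gene, pairs, count=10):
    """Junction->count map for expressed rank pairs of gene.exon_union."""
    exons = gene.exon_union
    return {
        junction_between(gene.gene_id, gene.strand, exons[u], exons[v]): count
        for u, v in pairs
    }


def test_toy_ses_motif():
    g = _gene_from_intervals([(0, 100), (200, 300), (400, 500)])
    counts = _counts_for(g, [(0, 1), (1, 2), (0, 2)])
    evs = classify_events(counts, [g])
    assert [e.cls for e in evs] == ["SES"]
    assert evs[0].affected_exons[0].interval() == (200, 300)


def test_mxe_motif_and_forbidden_junction():
    """i->j, j->m, i->k, k->m with no j->k is an MXE; one read on j->k
    destroys the call and exposes the double-inclusion pattern instead."""
    g = _gene_from_intervals([(0, 100), (200, 300), (400, 500), (600, 700)])
    counts = _counts_for(g, [(0, 1), (1, 3), (0, 2), (2, 3)])
    evs = classify_events(counts, [g])
    assert [e.cls for e in evs] == ["MXE"]
    assert {e.interval() for e in evs[0].affected_exons} == {(200, 300), (400, 500)}
    # add the forbidden junction
    counts2 = dict(counts)
    counts2.update(_counts_for(g, [(1, 2)], count=1))
    evs2 = classify_events(counts2, [g])
    assert all(e.cls != "MXE" for e in evs2)
    # the double-inclusion chain now supports MES through both exons
    assert any(e.cls == "MES" for e in evs2) is False  # no skip junction i->m
    counts3 = dict(counts2)
    counts3.update(_counts_for(g, [(0, 3)], count=1))
    assert any(e.cls == "MES" for e in classify_events(counts3, [g]))


def test_ses_plus_a3ss_combination():
    """Junctions 1->2, 2->3, 1->3 plus 2->3' (overlapping acceptor variant)
    give one SES and one A3SS."""
    g = _gene_from_intervals([(0, 100), (200, 300), (400, 500), (430, 500)])
    # ranks: 0=(0,100), 1=(200,300), 2=(400,500), 3=(430,500)
    counts = _counts_for(g, [(0, 1), (1, 2), (0, 2), (1, 3)])
    evs = classify_events(counts, [g])
    classes = sorted(e.cls for e in evs)
    assert classes == ["A3SS", "SES"]
    a3 = next(e for e in evs if e.cls == "A3SS")
    # inclusion junction is the one with the shorter intron (more exon)
    assert a3.inclusion_junctions[0].acceptor == 400


def test_afe_ale_motifs():
    g = _gene_from_intervals([(0, 100), (200, 300), (400, 500)])
    # two 5'-terminal exons converging on rank 2
    counts = _counts_for(g, [(0, 2), (1, 2)])
    evs = classify_events(counts, [g])
    assert [e.cls for e in evs] == ["AFE"]
    # one donor diverging to two 3'-terminal exons
    counts2 = _counts_for(g, [(0, 1), (0, 2)])
    evs2 = classify_events(counts2, [g])
    assert [e.cls for e in evs2] == ["ALE"]


def test_events_match_brute_force_enumeration():
    """On random junction graphs over <= 8 exons, classification equals
    exhaustive motif enumeration, including the MXE forbidden-junction rule."""
    rng = np.random.default_rng(41)
    for trial in range(150):
        n = int(rng.integers(3, 9))
        intervals, pos = [], 0
        for _ in range(n):
            ln = int(rng.integers(40, 90))
            intervals.append((pos, pos + ln))
            pos += ln + int(rng.integers(30, 80))
            if rng.random() < 0.25 and len(intervals) < n:
                # overlapping boundary variant of the previous exon
                s, e = intervals[-1]
                intervals.append((s + int(rng.integers(10, ln // 2 + 10)), e))
        intervals = intervals[:n]
        strand = "+" if trial % 2 else "-"
        if strand == "-":
            # mirror the intervals so ranks still run 5'->3'
            m = pos + 50
            g_intervals = [(m - e, m - s) for s, e in intervals]
        else:
            g_intervals = intervals
        gene = _gene_from_intervals(g_intervals, strand=strand)
        exons = gene.exon_union
        # exon_union rank order must match interval construction order
        rank_iv = [e.interval() for e in exons]

        def ok(u, v):
            a, b = rank_iv[u], rank_iv[v]
            return not (a[0] < b[1] and b[0] < a[1])

        all_pairs = [(u, v) for u in range(len(exons)) for v in range(u + 1, len(exons)) if ok(u, v)]
        chosen = [p for p in all_pairs if rng.random() < 0.5]
        # exon variants sharing a boundary yield the same junction key; such
        # pairs are indistinguishable at junction level, so keep one each
        seen_keys, dedup = set(), []
        for u, v in chosen:
            key = junction_between(gene.gene_id, gene.strand, exons[u], exons[v]).key
            if key not in seen_keys:
                seen_keys.add(key)
                dedup.append((u, v))
        chosen = dedup
        counts = _counts_for(gene, chosen)
        got = classify_events(counts, [gene])
        # normalize: compare per-class instance counts keyed by exon ranks
        tx_iv = [
            (iv if strand == "+" else iv)
            for iv in rank_iv
        ]
        expected = oracles.enumerate_motifs(tx_iv, set(chosen))
        got_set = set()
        idx = {e.interval(): i for i, e in enumerate(exons)}
        for ev in got:
            if ev.cls == "SES":
                i = idx[ev.exclusion_junctions[0].donor_exon.interval()]
                k = idx[ev.exclusion_junctions[0].acceptor_exon.interval()]
                j = idx[ev.affected_exons[0].interval()]
                got_set.add(("SES", (i, j, k)))
            elif ev.cls == "MES":
                i = idx[ev.exclusion_junctions[0].donor_exon.interval()]
                k = idx[ev.exclusion_junctions[0].acceptor_exon.interval()]
                mids = tuple(idx[e.interval()] for e in ev.affected_exons)
                got_set.add(("MES", (i,) + mids + (k,)))
            elif ev.cls == "A5SS":
                u = tuple(sorted(idx[e.interval()] for e in ev.affected_exons))
                v = idx[ev.inclusion_junctions[0].acceptor_exon.interval()]
                got_set.add(("A5SS", u + (v,)))
            elif ev.cls == "A3SS":
                u = idx[ev.inclusion_junctions[0].donor_exon.interval()]
                v = tuple(sorted(idx[e.interval()] for e in ev.affected_exons))
                got_set.add(("A3SS", (u,) + v))
            elif ev.cls == "AFE":
                u = tuple(sorted(idx[e.interval()] for e in ev.affected_exons))
                v = idx[ev.inclusion_junctions[0].acceptor_exon.interval()]
                got_set.add(("AFE", u + (v,)))
            elif ev.cls == "ALE":
                u = idx[ev.inclusion_junctions[0].donor_exon.interval()]
                v = tuple(sorted(idx[e.interval()] for e in ev.affected_exons))
                got_set.add(("ALE", (u,) + v))
            elif ev.cls == "MXE":
                i = idx[ev.inclusion_junctions[0].donor_exon.interval()]
                j = idx[ev.inclusion_junctions[0].acceptor_exon.interval()]
                k = idx[ev.exclusion_junctions[0].acceptor_exon.interval()]
                m = idx[ev.inclusion_junctions[1].acceptor_exon.interval()]
                got_set.add(("MXE", (i, j, k, m)))
        assert got_set == expected, (trial, sorted(got_set ^ expected))


# ---------------------------------------------------------------------------
# PSI


def _two_path_event(inc_counts, exc_counts):
    incs = [Junction("g", "chr1", "+", 100 + 10 * i, 200 + 10 * i) for i in range(len(inc_counts))]
    excs = [Junction("g", "chr1", "+", 500 + 10 * i, 600 + 10 * i) for i in range(len(exc_counts))]
    ev = SpliceEvent("e", "g", "SES" if len(incs) == 2 else "A5SS",
                     incs, excs, [Exon("chr1", 150, 180, "+")])
    counts = {j: c for j, c in zip(incs, inc_counts)}
    counts.update({j: c for j, c in zip(excs, exc_counts)})
    return ev, counts


def test_psi_values():
    ev, counts = _two_path_event([30, 30], [10])
    assert compute_psi(ev, counts) == pytest.approx(75.0)
    ev0, c0 = _two_path_event([0, 0], [10])
    assert compute_psi(ev0, c0) == 0.0
    ev5, c5 = _two_path_event([7], [7])
    assert compute_psi(ev5, c5) == pytest.approx(50.0)
    evn, cn = _two_path_event([0, 0], [0])
    assert compute_psi(evn, cn) is None


def test_psi_complementarity():
    ev, counts = _two_path_event([30, 30], [10])
    flipped = SpliceEvent("e", "g", ev.cls, ev.exclusion_junctions,
                          ev.inclusion_junctions, ev.affected_exons)
    assert compute_psi(ev, counts) + compute_psi(flipped, counts) == pytest.approx(100.0)


def test_delta_psi_and_direction():
    ev, wt = _two_path_event([70, 70], [30])
    _, ko = _two_path_event([9, 9], [91])
    rec = compute_delta_psi(ev, wt, ko)
    assert rec.psi_wt == pytest.approx(70.0)
    assert rec.psi_ko == pytest.approx(9.0)
    assert rec.delta_psi == pytest.approx(-61.0)
    assert rec.direction == "increased-exclusion"


def test_delta_psi_antisymmetry_and_support():
    ev, wt = _two_path_event([40, 40], [20])
    _, ko = _two_path_event([10, 10], [50])
    fwd = compute_delta_psi(ev, wt, ko)
    rev = compute_delta_psi(ev, ko, wt)
    assert fwd.delta_psi == -rev.delta_psi
    same = compute_delta_psi(ev, wt, wt)
    assert same.delta_psi == 0.0 and same.direction == "no-call"
    # below the summed-read support threshold -> no call
    ev2, low_wt = _two_path_event([2, 2], [1])
    _, low_ko = _two_path_event([1, 1], [4])
    rec = compute_delta_psi(ev2, low_wt, low_ko, min_event_reads=10)
    assert not rec.supported and rec.direction == "no-call"


def test_designed_psi_recovered(small_sim, small_sim_db, small_sim_counts):
    """Estimated PSI tracks the generator's molar-fraction ground truth."""
    per_j = {}
    for cond, cmap in small_sim_counts.items():
        for j, c in cmap.items():
            per_j.setdefault(j, {})[cond] = c
    evs = classify_events(per_j, small_sim.models)
    errors = []
    for t_ev in small_sim.truth.events:
        match = [
            e for e in evs
            if e.gene_id == t_ev.gene_id and e.cls == t_ev.cls
            and {j.key for j in e.inclusion_junctions} == set(t_ev.inclusion_junctions)
            and {j.key for j in e.exclusion_junctions} == set(t_ev.exclusion_junctions)
        ]
        assert match, (t_ev.gene_id, t_ev.cls)
        psi = compute_psi(match[0], small_sim_counts["wt"])
        errors.append(abs(psi - t_ev.psi_wt))
    assert np.mean(errors) < 5.0
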