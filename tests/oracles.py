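"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the library's own code paths: transcripts are
assembled by direct genome slicing with Biopython, stops are found by
translation, splice-event motifs are enumerated with plain nested loops
over exon index combinations, and mapping is exhaustive substring search.
"""

from __future__ import annotations

import itertools
import math

from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# PTC oracle: full-isoform construction + translation + the 50-nt rule


def _slice(genome, chrom, start, end, strand):
    s = str(genome[chrom][start:end]).upper()
    return s if strand == "+" else str(Seq(s).reverse_complement())


def _ax(strand):
    return (lambda x: x) if strand == "+" else (lambda x: -x)


def brute_force_ptc(ref, junction, genome, min_dist=50):
    """(is_ptc, dist or None): splice the junction into the reference by the
    documented policy, translate, and apply the distance rule directly.

    Returns None when the reading frame is unresolvable (call is "NA").
    """
    strand = ref.strand
    ax = _ax(strand)
    donor, acceptor = junction.donor, junction.acceptor

    def b5(e):
        return e.start if strand == "+" else e.end

    def b3(e):
        return e.end if strand == "+" else e.start

    if ax(acceptor) <= ax(b5(ref.exons[0])) or ax(donor) >= ax(b3(ref.exons[-1])):
        return "outside"

    def iv(e):
        return (e.start, e.end)

    # 5' side
    chain = []
    found = False
    for idx, e in enumerate(ref.exons):
        if ax(b5(e)) < ax(donor) <= ax(b3(e)):
            chain = [iv(x) for x in ref.exons[:idx]] + [_clip(e, strand, three_prime=donor)]
            found = True
            break
    if not found:
        de = junction.donor_exon
        if de is None:
            return "outside"
        chain = [iv(e) for e in ref.exons if ax(b3(e)) <= ax(b5(de))]
        chain.append(_clip(de, strand, three_prime=donor))
    # 3' side
    found = False
    for idx, e in enumerate(ref.exons):
        if ax(b5(e)) <= ax(acceptor) < ax(b3(e)):
            chain = chain + [_clip(e, strand, five_prime=acceptor)] + [iv(x) for x in ref.exons[idx + 1:]]
            found = True
            break
    if not found:
        ae = junction.acceptor_exon
        if ae is None:
            return "outside"
        tail = [iv(e) for e in ref.exons if ax(b5(e)) >= ax(b3(ae))]
        chain = chain + [_clip(ae, strand, five_prime=acceptor)] + tail

    if len(chain) < 2:
        return "outside"

    # shared 5' prefix with the reference decides whether cds_start carries
    shared = 0
    for re_, ce in zip(ref.exons, chain):
        if (re_.start, re_.end) == (ce[0], ce[1]):
            shared += re_.end - re_.start
            continue
        if b5(re_) == (ce[0] if strand == "+" else ce[1]):
            shared += min(re_.end - re_.start, ce[1] - ce[0])
        break
    if ref.cds_start is None or ref.cds_start + 3 > shared:
        return "na"

    pieces = [_slice(genome, ref.chrom, s, t, strand) for s, t in chain]
    seq = "".join(pieces)
    cds = seq[ref.cds_start:]
    prot = str(Seq(cds[: len(cds) // 3 * 3]).translate())
    stop_aa = prot.find("*")
    if stop_aa == -1:
        return (False, None)
    stop_pos = ref.cds_start + 3 * stop_aa
    last_junction = sum(len(p) for p in pieces[:-1])
    dist = last_junction - (stop_pos + 3)
    # the reference's own termination codon is never premature
    ref_seq = "".join(_slice(genome, ref.chrom, e.start, e.end, strand) for e in ref.exons)
    ref_cds = ref_seq[ref.cds_start:]
    ref_prot = str(Seq(ref_cds[: len(ref_cds) // 3 * 3]).translate())
    annotated = None
    if "*" in ref_prot:
        annotated = _tx2genomic(ref.exons, strand, ref.cds_start + 3 * ref_prot.find("*"))
    here = _chain2genomic(chain, strand, stop_pos)
    is_annotated = annotated is not None and here == annotated
    return (dist >= min_dist and not is_annotated, dist)


def _clip(e, strand, three_prime=None, five_prime=None):
    s, t = e.start, e.end
    if three_prime is not None:
        if strand == "+":
            t = three_prime
        else:
            s = three_prime
    if five_prime is not None:
        if strand == "+":
            s = five_prime
        else:
            t = five_prime
    return (s, t)


def _tx2genomic(exons, strand, tpos):
    off = 0
    for e in exons:
        ln = e.end - e.start
        if tpos < off + ln:
            w = tpos - off
            return e.start + w if strand == "+" else e.end - 1 - w
        off += ln
    raise ValueError


def _chain2genomic(chain, strand, tpos):
    off = 0
    for s, t in chain:
        ln = t - s
        if tpos < off + ln:
            w = tpos - off
            return s + w if strand == "+" else t - 1 - w
        off += ln
    raise ValueError


# ---------------------------------------------------------------------------
# splice-event motif enumeration


def enumerate_motifs(exons, edges):
    """All event motifs on a toy junction graph.

    ``exons`` are (start, end) intervals in transcription order (index ==
    rank); ``edges`` is the set of expressed (u, v) rank pairs, u < v.
    Returns a set of (cls, frozen-description) tuples.
    """

    def overlaps(a, b):
        return exons[a][0] < exons[b][1] and exons[b][0] < exons[a][1]

    n = len(exons)
    has_in = {v for _, v in edges}
    has_out = {u for u, _ in edges}
    found = set()

    for (i, k) in edges:
        for j in range(i + 1, k):
            if (i, j) in edges and (j, k) in edges:
                found.add(("SES", (i, j, k)))
        inner = [j for j in range(i + 1, k) if not overlaps(j, i) and not overlaps(j, k)]
        for size in range(2, len(inner) + 1):
            for combo in itertools.combinations(inner, size):
                if any(combo[x + 1] != combo[x] + 1 for x in range(len(combo) - 1)):
                    continue  # must be consecutive ranks
                path = [(i, combo[0])] + list(zip(combo, combo[1:])) + [(combo[-1], k)]
                if all(p in edges for p in path):
                    found.add(("MES", (i,) + combo + (k,)))

    for (u1, v1), (u2, v2) in itertools.combinations(sorted(edges), 2):
        # shared acceptor exon, overlapping donors -> A5SS
        if v1 == v2 and u1 != u2 and overlaps(u1, u2):
            found.add(("A5SS", tuple(sorted((u1, u2))) + (v1,)))
        if u1 == u2 and v1 != v2 and overlaps(v1, v2):
            found.add(("A3SS", (u1,) + tuple(sorted((v1, v2)))))
        # AFE / ALE with non-overlapping terminal exons
        if v1 == v2 and u1 != u2 and not overlaps(u1, u2):
            if u1 not in has_in and u2 not in has_in:
                found.add(("AFE", tuple(sorted((u1, u2))) + (v1,)))
        if u1 == u2 and v1 != v2 and not overlaps(v1, v2):
            if v1 not in has_out and v2 not in has_out:
                found.add(("ALE", (u1,) + tuple(sorted((v1, v2)))))

    for j, k in itertools.combinations(range(n), 2):
        if overlaps(j, k) or (j, k) in edges:
            continue
        for i in range(j):
            for m in range(k + 1, n):
                if ((i, j) in edges and (j, m) in edges and (i, k) in edges
                        and (k, m) in edges and not overlaps(i, j) and not overlaps(k, m)):
                    found.add(("MXE", (i, j, k, m)))
    return found


# ---------------------------------------------------------------------------
# exhaustive mapping


def brute_force_map(seq, junction_seqs, genome, anchor):
    """(kind, ids): exhaustive substring search with the unique-mapping and
    junction-precedence policy; returns ('junction', key) / ('genome', pos) /
    ('unmapped', None) / ('ambiguous', None)."""
    rc = str(Seq(seq).reverse_complement())
    j_hits = set()
    for key, (jseq, boundary) in junction_seqs.items():
        for s in (seq, rc):
            start = jseq.find(s)
            while start != -1:
                if start <= boundary - anchor and start + len(s) >= boundary + anchor:
                    j_hits.add(key)
                start = jseq.find(s, start + 1)
    if len(j_hits) == 1:
        return ("junction", next(iter(j_hits)))
    if len(j_hits) > 1:
        return ("ambiguous", None)
    g_hits = set()
    for chrom, cseq in genome.items():
        for s in (seq, rc):
            start = cseq.find(s)
            while start != -1:
                g_hits.add((chrom, start))
                start = cseq.find(s, start + 1)
    if len(g_hits) == 1:
        return ("genome", next(iter(g_hits)))
    if len(g_hits) > 1:
        return ("ambiguous", None)
    return ("unmapped", None)


# ---------------------------------------------------------------------------
# statistics


def fisher_2x2_enum(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def upper_quartile_brute(values):
    """75th percentile of nonzero counts, linear interpolation (matches
    numpy's default), computed from first principles."""
    nz = sorted(v for v in values if v > 0)
    if not nz:
        raise ValueError("no nonzero values")
    k = 0.75 * (len(nz) - 1)
    lo = int(math.floor(k))
    hi = int(math.ceil(k))
    return nz[lo] + (nz[hi] - nz[lo]) * (k - lo)
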