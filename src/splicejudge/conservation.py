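"""Conservation meta-profiles and stop-codon identity analysis.

Per-base conservation scores (phastCons-style, values in [0, 1]) are read
from fixed-step WIG or bedGraph text.  Meta-profiles average scores over an
anchor set in strand-aware windows; missing positions are excluded from the
means rather than imputed as zero.  The stop-codon identity analysis
tabulates TAA/TAG/TGA usage of predicted premature stops against genomic
backgrounds and annotated stops, tested with Fisher's exact test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .annotation import Exon, GeneModel

log = logging.getLogger(__name__)

__all__ = [
    "ConservationTrack",
    "ConservationProfile",
    "read_track",
    "profile_ses",
    "profile_ptc",
    "stop_identity_table",
    "fisher_exact_table",
    "ptc_fraction_by_expression",
    "SES_EXON_FLANK",
    "SES_INTRON_FLANK",
]

SES_EXON_FLANK = 25
SES_INTRON_FLANK = 75
STOPS = ("TAA", "TAG", "TGA")


class ConservationTrack:
    """Per-chromosome per-base scores with NaN for missing positions."""

    def __init__(self) -> None:
        self._chroms: dict[str, np.ndarray] = {}

    def set(self, chrom: str, start: int, values: np.ndarray) -> None:
        arr = self._chroms.get(chrom)
        end = start + len(values)
        if arr is None or len(arr) < end:
            new = np.full(max(end, 0 if arr is None else len(arr)), np.nan)
            if arr is not None:
                new[: len(arr)] = arr
            self._chroms[chrom] = arr = new
        arr[start:end] = values

    def query(self, chrom: str, start: int, end: int, strand: str = "+") -> np.ndarray:
        """Scores for [start, end); positions beyond the track are NaN
        (missing), never 0.  On the minus strand the vector is reversed so
        index 0 is the transcription-sense 5' end of the window."""
        n = end - start
        out = np.full(n, np.nan)
        arr = self._chroms.get(chrom)
        if arr is not None:
            lo, hi = max(start, 0), min(end, len(arr))
            if lo < hi:
                out[lo - start : hi - start] = arr[lo:hi]
        return out[::-1] if strand == "-" else out


def read_track(path: str) -> ConservationTrack:
    """Parse fixed-step/variable-step WIG or bedGraph text."""
    track = ConservationTrack()
    chrom, pos, step = None, 0, 1
    mode = "bedgraph"
    buf: list[float] = []
    buf_start = 0

    def flush():
        nonlocal buf
        if buf and chrom is not None:
            track.set(chrom, buf_start, np.asarray(buf))
        buf = []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                flush()
                kv = dict(p.split("=") for p in line.split()[1:])
                chrom = kv["chrom"]
                pos = int(kv["start"]) - 1  # WIG is 1-based
                step = int(kv.get("step", 1))
                mode = "fixed"
                buf_start = pos
                continue
            if line.startswith("variableStep"):
                flush()
                kv = dict(p.split("=") for p in line.split()[1:])
                chrom = kv["chrom"]
                mode = "variable"
                continue
            f = line.split()
            if mode == "fixed":
                val = float(f[0])
                if step == 1:
                    buf.append(val)
                else:
                    flush()
                    track.set(chrom, pos, np.asarray([val]))
                    buf_start = pos + step
                pos += step
            elif mode == "variable":
                track.set(chrom, int(f[0]) - 1, np.asarray([float(f[1])]))
            else:  # bedGraph: chrom start end value (0-based half-open)
                c, s, e, v = f[0], int(f[1]), int(f[2]), float(f[3])
                track.set(c, s, np.full(e - s, v))
    flush()
    return track


@dataclass
class ConservationProfile:
    anchor_set_label: str
    n_anchors: int
    mean_score: np.ndarray
    n_per_position: np.ndarray
    baseline_subtracted: bool = False
    segments: tuple | None = None  # (label, length) pairs describing layout


def _stack_mean(windows: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    mat = np.vstack(windows)
    n = np.sum(~np.isnan(mat), axis=0)
    total = np.nansum(mat, axis=0)
    mean = np.divide(total, n, out=np.full(n.shape, np.nan), where=n > 0)
    return mean, n


# ---------------------------------------------------------------------------
# cassette-exon (SES) meta-profiles


def _ses_window(track: ConservationTrack, up: Exon, cassette: Exon, down: Exon,
                exon_flank: int, intron_flank: int) -> np.ndarray:
    """Strand-aware window around one skipped exon.

    Layout (transcription order): last ``exon_flank`` nt of the upstream
    exon | ``intron_flank`` nt of upstream intron adjacent to the cassette
    | first and last ``exon_flank`` nt of the cassette | ``intron_flank``
    nt of downstream intron adjacent to the cassette | first ``exon_flank``
    nt of the downstream exon.  Exon segments shorter than the window
    contribute their available positions (rest NaN), anchored at the
    boundary the segment abuts.
    """
    strand = cassette.strand
    chrom = cassette.chrom

    def seg_exon_3p(e: Exon, n: int) -> np.ndarray:
        # last n nt of an exon (transcription sense), right-aligned at its 3' end
        out = np.full(n, np.nan)
        take = min(n, e.length)
        if strand == "+":
            vals = track.query(chrom, e.end - take, e.end, "+")
        else:
            vals = track.query(chrom, e.start, e.start + take, "-")
        out[n - take:] = vals
        return out

    def seg_exon_5p(e: Exon, n: int) -> np.ndarray:
        out = np.full(n, np.nan)
        take = min(n, e.length)
        if strand == "+":
            vals = track.query(chrom, e.start, e.start + take, "+")
        else:
            vals = track.query(chrom, e.end - take, e.end, "-")
        out[:take] = vals
        return out

    def seg_intron(a_end: int, b_start: int, n: int, anchor: str) -> np.ndarray:
        """Intron between genomic a_end..b_start; ``anchor`` says which end
        of the window (transcription sense) the n positions hug."""
        out = np.full(n, np.nan)
        ilen = b_start - a_end
        take = min(n, ilen)
        if strand == "+":
            if anchor == "3p":  # nearest the downstream feature
                vals = track.query(chrom, b_start - take, b_start, "+")
                out[n - take:] = vals
            else:
                vals = track.query(chrom, a_end, a_end + take, "+")
                out[:take] = vals
        else:
            if anchor == "3p":
                vals = track.query(chrom, a_end, a_end + take, "-")
                out[n - take:] = vals
            else:
                vals = track.query(chrom, b_start - take, b_start, "-")
                out[:take] = vals
        return out

    if strand == "+":
        up_intron = (up.end, cassette.start)
        down_intron = (cassette.end, down.start)
    else:
        up_intron = (cassette.end, up.start)
        down_intron = (down.end, cassette.start)

    parts = [
        seg_exon_3p(up, exon_flank),
        seg_intron(*up_intron, intron_flank, anchor="3p"),
        seg_exon_5p(cassette, exon_flank),
        seg_exon_3p(cassette, exon_flank),
        seg_intron(*down_intron, intron_flank, anchor="5p"),
        seg_exon_5p(down, exon_flank),
    ]
    return np.concatenate(parts)


def profile_ses(
    anchor_sets: dict[str, list[tuple[Exon, Exon, Exon]]],
    track: ConservationTrack,
    exon_flank: int = SES_EXON_FLANK,
    intron_flank: int = SES_INTRON_FLANK,
) -> dict[str, ConservationProfile]:
    """Mean per-position profiles around skipped exons, one per anchor set.

    Each anchor is an (upstream exon, cassette exon, downstream exon)
    triple; each position averages over the anchors with non-missing data
    there.
    """
    segments = (
        ("upstream_exon", exon_flank), ("upstream_intron", intron_flank),
        ("cassette_5p", exon_flank), ("cassette_3p", exon_flank),
        ("downstream_intron", intron_flank), ("downstream_exon", exon_flank),
    )
    out = {}
    for label, anchors in anchor_sets.items():
        if not anchors:
            raise ValueError(f"anchor set {label!r} is empty")
        windows = [
            _ses_window(track, up, cas, down, exon_flank, intron_flank)
            for up, cas, down in anchors
        ]
        mean, n = _stack_mean(windows)
        out[label] = ConservationProfile(label, len(anchors), mean, n, segments=segments)
    return out


# ---------------------------------------------------------------------------
# PTC-centered profiles


def _centered_window(track: ConservationTrack, chrom: str, strand: str,
                     center: int, exon: Exon, halfwin: int) -> np.ndarray:
    """+-halfwin window centered on a genomic position, clipped at the exon
    boundaries (scores never extend into introns), transcription sense."""
    out = np.full(2 * halfwin + 1, np.nan)
    lo = max(exon.start, center - halfwin)
    hi = min(exon.end, center + halfwin + 1)
    if lo >= hi:
        return out
    vals = track.query(chrom, lo, hi, "+")
    out[lo - (center - halfwin): hi - (center - halfwin)] = vals
    return out[::-1] if strand == "-" else out


def profile_ptc(
    anchors: list[tuple[str, str, int, Exon]],
    track: ConservationTrack,
    baseline_exons: list[Exon],
    n_baseline: int = 4000,
    halfwin: int = 100,
    seed: int = 1729,
) -> ConservationProfile:
    """Baseline-subtracted conservation around premature stops.

    ``anchors`` are (chrom, strand, genomic position of the stop's first
    base, containing exon).  The baseline is the mean profile of a seeded
    random sample of expressed exons, windowed around random in-exon
    positions with the same exon-boundary clipping, subtracted position by
    position.  Anchors whose window has no in-exon positions are skipped
    and counted out of ``n_anchors``.
    """
    windows = []
    for chrom, strand, center, exon in anchors:
        w = _centered_window(track, chrom, strand, center, exon, halfwin)
        if np.all(np.isnan(w)):
            log.warning("PTC anchor %s:%d has no in-exon positions; skipped", chrom, center)
            continue
        windows.append(w)
    if not windows:
        raise ValueError("no usable PTC anchors")
    mean, n = _stack_mean(windows)

    rng = np.random.default_rng(seed)
    base_windows = []
    take = min(n_baseline, len(baseline_exons))
    idx = rng.choice(len(baseline_exons), size=take, replace=n_baseline > len(baseline_exons))
    for i in idx:
        e = baseline_exons[i]
        center = int(rng.integers(e.start, e.end))
        base_windows.append(_centered_window(track, e.chrom, e.strand, center, e, halfwin))
    base_mean, _ = _stack_mean(base_windows)
    return ConservationProfile(
        "ptc_centered", len(windows), mean - base_mean, n, baseline_subtracted=True,
    )


# ---------------------------------------------------------------------------
# stop-codon identity


def fisher_exact_table(table: np.ndarray, simulate_above: int = 500,
                       n_sim: int = 20000, seed: int = 1729) -> float:
    """Two-sided Fisher's exact test for a 2 x k contingency table.

    2 x 2 tables use the hypergeometric test directly; wider tables are
    tested exactly by enumerating all tables with the observed margins and
    summing the probabilities of tables no more probable than the observed
    one.  Tables with total count above ``simulate_above`` use a seeded
    Monte Carlo estimate instead of full enumeration.
    """
    t = np.asarray(table, dtype=int)
    if t.shape[0] != 2:
        raise ValueError("expected a 2 x k table")
    if t.shape[1] == 2:
        return float(stats.fisher_exact(t)[1])
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = int(t.sum())
    if n == 0:
        return 1.0

    def log_prob(top: np.ndarray) -> float:
        # multivariate hypergeometric pmf of the top row given margins
        lp = -math.lgamma(n + 1) + math.lgamma(row[0] + 1) + math.lgamma(row[1] + 1)
        for c, x in zip(col, top):
            lp += math.lgamma(c + 1) - math.lgamma(x + 1) - math.lgamma(c - x + 1)
        return lp

    obs_lp = log_prob(t[0])
    if n <= simulate_above:
        total = 0.0
        tol = 1e-9
        def rec(ci: int, remaining: int, acc: list[int], lp_acc: float):
            nonlocal total
            if ci == len(col) - 1:
                x = remaining
                if 0 <= x <= col[ci]:
                    lp = log_prob(np.array(acc + [x]))
                    if lp <= obs_lp + tol:
                        total += math.exp(lp)
                return
            for x in range(0, min(col[ci], remaining) + 1):
                rec(ci + 1, remaining - x, acc + [x], 0.0)
        rec(0, int(row[0]), [], 0.0)
        return float(min(total, 1.0))
    # Monte Carlo: permute category labels, compare table probabilities
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(col)), col)
    hits = 0
    for _ in range(n_sim):
        rng.shuffle(labels)
        top = np.bincount(labels[: row[0]], minlength=len(col))
        if log_prob(top) <= obs_lp + 1e-9:
            hits += 1
    return float((hits + 1) / (n_sim + 1))


def stop_identity_table(
    ptc_codons: list[str],
    refseq_stop_codons: list[str],
    genome,
    models: list[GeneModel],
    n_samples: int = 100_000,
    seed: int = 1729,
) -> tuple[dict[str, dict[str, int]], dict[str, float]]:
    """Stop-identity distributions and Fisher tests.

    Samples ``n_samples`` genomic trinucleotide positions per background
    category (exonic, intronic, intergenic; all three reading frames arise
    naturally from uniform position sampling), keeps the ones spelling a
    stop codon, and tabulates TAA/TAG/TGA frequencies alongside the
    predicted-PTC and annotated-stop sets.  Returns the table and two-sided
    Fisher p-values for PTC vs exonic background and PTC vs annotated stops.
    """
    from .junctiondb import fetch

    rng = np.random.default_rng(seed)
    chroms = [(str(name), len(genome[str(name)][:])) for name in genome.keys()]
    total_len = sum(l for _, l in chroms)

    exonic: list[tuple[int, int, str]] = []
    spans: dict[str, list[tuple[int, int]]] = {}
    ex_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in models:
        spans.setdefault(g.chrom, []).append(g.span)
        for e in g.exon_union:
            ex_by_chrom.setdefault(g.chrom, []).append((e.start, e.end))
    for d in (spans, ex_by_chrom):
        for v in d.values():
            v.sort()

    def category(chrom: str, pos: int) -> str:
        for s, t in ex_by_chrom.get(chrom, []):
            if s > pos:
                break
            if pos < t:
                return "exonic"
        for s, t in spans.get(chrom, []):
            if s > pos:
                break
            if pos < t:
                return "intronic"
        return "intergenic"

    table: dict[str, dict[str, int]] = {
        cat: dict.fromkeys(STOPS, 0)
        for cat in ("exonic", "intronic", "intergenic", "refseq_stops", "ptc")
    }
    for cod in ptc_codons:
        if cod in STOPS:
            table["ptc"][cod] += 1
    for cod in refseq_stop_codons:
        if cod in STOPS:
            table["refseq_stops"][cod] += 1

    weights = np.array([l for _, l in chroms], dtype=float) / total_len
    picks = rng.choice(len(chroms), size=n_samples, p=weights)
    offs = rng.random(n_samples)
    for ci, u in zip(picks, offs):
        chrom, clen = chroms[ci]
        pos = int(u * (clen - 3))
        tri = fetch(genome, chrom, pos, pos + 3, "+")
        if tri in STOPS:
            table[category(chrom, pos)][tri] += 1

    for cat in list(table):
        if sum(table[cat].values()) == 0:
            log.warning("stop-identity category %s has zero stops; excluded", cat)
            del table[cat]

    tests = {}
    for other, name in (("exonic", "ptc_vs_exonic"), ("refseq_stops", "ptc_vs_refseq")):
        if "ptc" in table and other in table:
            t = np.array([
                [table["ptc"][s] for s in STOPS],
                [table[other][s] for s in STOPS],
            ])
            tests[name] = fisher_exact_table(t)
    return table, tests


# ---------------------------------------------------------------------------
# PTC fraction by expression


def ptc_fraction_by_expression(
    is_ptc: list[bool], rpkm_values: list[float], bin_width: float = 1.0
) -> list[tuple[float, float | None, int, int]]:
    """(bin_start, PTC+/PTC- ratio or None, n_ptc, n_non) per occupied
    expression bin; no minimum read cutoff is applied."""
    bins: dict[int, list[int]] = {}
    for flag, r in zip(is_ptc, rpkm_values):
        k = int(math.floor(r / bin_width))
        b = bins.setdefault(k, [0, 0])
        b[0 if flag else 1] += 1
    out = []
    for k in sorted(bins):
        n_ptc, n_non = bins[k]
        ratio = (n_ptc / n_non) if n_non > 0 else None
        out.append((k * bin_width, ratio, n_ptc, n_non))
    return out
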