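import numpy as np
import pytest

from splicejudge.annotation import Exon
from splicejudge.conservation import (
    ConservationTrack,
    fisher_exact_table,
    profile_ptc,
    profile_ses,
    ptc_fraction_by_expression,
    read_track,
    stop_identity_table,
)

import oracles


def _constant_track(length=5000, value=0.5, chrom="chr1"):
    t = ConservationTrack()
    t.set(chrom, 0, np.full(length, value))
    return t


def test_wig_fixedstep_and_bedgraph_equivalent(tmp_path):
    vals = [0.1, 0.2, 0.3, 0.4]
    wig = tmp_path / "a.wig"
    wig.write_text("fixedStep chrom=chr1 start=11 step=1\n" + "\n".join(map(str, vals)) + "\n")
    bg = tmp_path / "a.bedgraph"
    bg.write_text("".join(f"chr1\t{10 + i}\t{11 + i}\t{v}\n" for i, v in enumerate(vals)))
    t1, t2 = read_track(str(wig)), read_track(str(bg))
    np.testing.assert_allclose(t1.query("chr1", 10, 14), vals)
    np.testing.assert_allclose(t2.query("chr1", 10, 14), vals)
    # beyond the track -> missing (NaN), never 0
    assert np.isnan(t1.query("chr1", 0, 5)).all()
    assert np.isnan(t1.query("chr2", 0, 5)).all()


def test_minus_strand_query_reversed():
    t = ConservationTrack()
    t.set("chr1", 0, np.arange(10, dtype=float))
    np.testing.assert_allclose(t.query("chr1", 2, 6, "-"), [5, 4, 3, 2])


def _ses_anchor(chrom="chr1", strand="+", base=1000):
    up = Exon(chrom, base, base + 200, strand)
    cas = Exon(chrom, base + 400, base + 520, strand)
    down = Exon(chrom, base + 800, base + 950, strand)
    if strand == "-":
        return (down, cas, up)
    return (up, cas, down)


def test_constant_track_gives_flat_profile():
    track = _constant_track()
    anchors = [_ses_anchor(base=b) for b in (500, 1500, 2500)]
    profs = profile_ses({"any": anchors}, track)
    p = profs["any"]
    assert p.n_anchors == 3
    np.testing.assert_allclose(p.mean_score, 0.5)
    assert len(p.mean_score) == 25 + 75 + 25 + 25 + 75 + 25


def test_single_anchor_profile_is_raw_scores():
    rng = np.random.default_rng(51)
    track = ConservationTrack()
    track.set("chr1", 0, rng.random(3000))
    anchor = _ses_anchor(base=1000)
    up, cas, down = anchor
    p = profile_ses({"one": [anchor]}, track)["one"]
    # upstream-exon segment: last 25 nt of the upstream exon
    np.testing.assert_allclose(p.mean_score[:25], track.query("chr1", up.end - 25, up.end))
    # cassette 5' segment
    np.testing.assert_allclose(p.mean_score[100:125], track.query("chr1", cas.start, cas.start + 25))


def test_strand_mirror_symmetry():
    """A minus-strand anchor over mirrored scores yields the same profile as
    its plus-strand image."""
    rng = np.random.default_rng(52)
    scores = rng.random(4000)
    t_fwd = ConservationTrack()
    t_fwd.set("chr1", 0, scores)
    t_rev = ConservationTrack()
    t_rev.set("chr1", 0, scores[::-1])
    plus = profile_ses({"s": [_ses_anchor(strand="+", base=1000)]}, t_fwd)["s"]
    # mirrored coordinates: interval (a, b) -> (4000 - b, 4000 - a)
    up = Exon("chr1", 4000 - 1200, 4000 - 1000, "-")
    cas = Exon("chr1", 4000 - 1520, 4000 - 1400, "-")
    down = Exon("chr1", 4000 - 1950, 4000 - 1800, "-")
    minus = profile_ses({"s": [(up, cas, down)]}, t_rev)["s"]
    np.testing.assert_allclose(minus.mean_score, plus.mean_score)


def test_profile_permutation_invariance():
    rng = np.random.default_rng(53)
    track = ConservationTrack()
    track.set("chr1", 0, rng.random(9000))
    anchors = [_ses_anchor(base=b) for b in (500, 2500, 4500, 6500)]
    p1 = profile_ses({"s": anchors}, track)["s"]
    p2 = profile_ses({"s": anchors[::-1]}, track)["s"]
    np.testing.assert_allclose(p1.mean_score, p2.mean_score)


def test_short_exons_contribute_available_positions():
    track = _constant_track()
    up = Exon("chr1", 1000, 1010, "+")  # 10 nt < 25 nt window
    cas = Exon("chr1", 1200, 1320, "+")
    down = Exon("chr1", 1500, 1600, "+")
    p = profile_ses({"s": [(up, cas, down)]}, track)["s"]
    seg = p.mean_score[:25]
    assert np.isnan(seg[:15]).all() and np.isfinite(seg[15:]).all()


def test_empty_anchor_set_errors():
    with pytest.raises(ValueError):
        profile_ses({"empty": []}, _constant_track())


# ---------------------------------------------------------------------------
# PTC-centered profiles


def test_ptc_profile_self_subtraction_zero():
    """With a uniform track the baseline equals the signal: the subtracted
    profile is identically zero wherever defined."""
    track = _constant_track(10_000, 0.7)
    exons = [Exon("chr1", 1000 * i + 100, 1000 * i + 400, "+") for i in range(1, 9)]
    anchors = [("chr1", "+", e.start + 150, e) for e in exons[:4]]
    p = profile_ptc(anchors, track, exons, n_baseline=100, seed=1)
    assert p.baseline_subtracted
    defined = np.isfinite(p.mean_score)
    assert defined.any()
    np.testing.assert_allclose(p.mean_score[defined], 0.0, atol=1e-12)
    assert p.n_anchors == 4


def test_ptc_profile_planted_signal_recovered():
    """Elevated scores +-10 nt around the stops appear in the subtracted
    profile exactly there."""
    track = _constant_track(20_000, 0.4)
    exons = [Exon("chr1", 1000 * i, 1000 * i + 500, "+") for i in range(1, 19)]
    anchors = []
    for e in exons[:6]:
        center = e.start + 250
        track.set("chr1", center - 10, np.full(21, 0.9))
        anchors.append(("chr1", "+", center, e))
    p = profile_ptc(anchors, track, exons[6:], n_baseline=200, seed=2, halfwin=100)
    mid = 100
    np.testing.assert_allclose(p.mean_score[mid - 10 : mid + 11], 0.5, atol=1e-9)
    np.testing.assert_allclose(p.mean_score[: mid - 10], 0.0, atol=1e-9)


def test_ptc_window_clipped_at_exon_boundary():
    track = _constant_track()
    e = Exon("chr1", 1000, 1060, "+")
    p = profile_ptc([("chr1", "+", 1030, e)], track, [e], n_baseline=5, seed=3)
    # only positions within the 60 nt exon carry signal
    assert (p.n_per_position > 0).sum() == 60


# ---------------------------------------------------------------------------
# Fisher's exact test and stop identity


def test_fisher_2x2_matches_enumeration_exhaustive():
    """scipy-backed 2x2 path equals exhaustive hypergeometric enumeration on
    all small tables and a seeded sample of tables with margins <= 30."""
    for a in range(6):
        for b in range(6):
            for c in range(6):
                for d in range(6):
                    if a + b + c + d == 0:
                        continue
                    p = fisher_exact_table(np.array([[a, b], [c, d]]))
                    q = oracles.fisher_2x2_enum(a, b, c, d)
                    assert p == pytest.approx(q, abs=1e-9), (a, b, c, d)
    rng = np.random.default_rng(54)
    for _ in range(300):
        a, b, c, d = rng.integers(0, 16, size=4)
        if a + b + c + d == 0 or max(a + b, c + d, a + c, b + d) > 30:
            continue
        p = fisher_exact_table(np.array([[a, b], [c, d]]))
        q = oracles.fisher_2x2_enum(int(a), int(b), int(c), int(d))
        assert p == pytest.approx(q, abs=1e-9)


def test_fisher_2x2_worked_example():
    assert fisher_exact_table(np.array([[8, 2], [1, 9]])) == pytest.approx(0.005477, abs=5e-5)
    assert fisher_exact_table(np.array([[8, 2], [1, 9]])) == pytest.approx(
        oracles.fisher_2x2_enum(8, 2, 1, 9))


def test_fisher_2x3_identical_rows_not_significant():
    p = fisher_exact_table(np.array([[10, 10, 10], [10, 10, 10]]))
    assert p > 0.5


def test_fisher_2x3_detects_tga_bias():
    """A 70% TGA-biased PTC set against a uniform background is rejected at
    alpha = 0.01 for n = 200 per group."""
    biased = np.array([140, 30, 30])
    uniform = np.array([67, 67, 66])
    p = fisher_exact_table(np.vstack([biased, uniform]))
    assert p < 0.01


def test_fisher_2x3_exact_vs_montecarlo():
    t = np.array([[12, 5, 9], [4, 11, 7]])
    exact = fisher_exact_table(t, simulate_above=1000)
    mc = fisher_exact_table(t, simulate_above=10, n_sim=40000, seed=9)
    assert mc == pytest.approx(exact, abs=0.02)


def test_stop_identity_table(small_sim):
    ptc_codons = ["TGA"] * 14 + ["TAA"] * 3 + ["TAG"] * 3
    ref_codons = ["TAA"] * 10 + ["TAG"] * 8 + ["TGA"] * 12
    table, tests = stop_identity_table(
        ptc_codons, ref_codons, small_sim.genome, small_sim.models,
        n_samples=20_000, seed=5,
    )
    assert table["ptc"] == {"TAA": 3, "TAG": 3, "TGA": 14}
    assert set(tests) == {"ptc_vs_exonic", "ptc_vs_refseq"}
    for cat in ("exonic", "intronic", "intergenic"):
        assert cat in table and sum(table[cat].values()) > 0
    assert all(0 <= p <= 1 for p in tests.values())


# ---------------------------------------------------------------------------
# PTC fraction by expression


def test_ptc_fraction_bins():
    flags = [True] * 3 + [False] * 6
    rpkms = [0.5] * 9
    (row,) = ptc_fraction_by_expression(flags, rpkms)
    assert row == (0.0, 0.5, 3, 6)
    rows = ptc_fraction_by_expression([False, False], [0.1, 3.7])
    assert [r[1] for r in rows] == [0.0, 0.0]
    # zero PTC- bin -> undefined ratio
    (r,) = ptc_fraction_by_expression([True], [2.2])
    assert r[1] is None and r[0] == 2.0


def test_ptc_fraction_low_expression_enrichment():
    """A planted enrichment of PTC+ junctions at low expression produces a
    decreasing ratio across bins."""
    rng = np.random.default_rng(55)
    flags, rpkms = [], []
    for k in range(6):
        n = 300
        p_ptc = 0.5 / (k + 1)
        flags += list(rng.random(n) < p_ptc)
        rpkms += list(k + rng.random(n))
    rows = ptc_fraction_by_expression(flags, rpkms)
    ratios = np.array([r[1] for r in rows])
    slope = np.polyfit(np.arange(len(ratios)), ratios, 1)[0]
    assert slope < 0
    assert ratios[0] > 2 * ratios[-1]
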