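"""Junction and gene quantification, normalization and regulation calls.

Counts reads per junction and per gene, converts counts to RPKM (reads per
kilobase of feature per million mapped reads), derives cross-sample scale
factors (upper-quartile or trimmed-mean-of-M, TMM) and classifies each
junction as up-/down-/unregulated between two conditions using a minimum
read cutoff and a two-fold change threshold on normalized counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .junctiondb import Junction, JunctionDB
from .mapping import ReadAssignment

__all__ = [
    "count_junctions",
    "counts_matrix",
    "rpkm",
    "junction_rpkm_table",
    "normalize",
    "RegulationCall",
    "call_regulation",
    "regulation_table",
    "gene_expression",
]

PSEUDOCOUNT = 0.5


def count_junctions(assignments: list[ReadAssignment],
                    db: JunctionDB | None = None) -> dict[Junction, int]:
    """Reads per junction for one sample; DB junctions with zero reads are
    retained with count 0 when the database is supplied."""
    counts: dict[Junction, int] = {}
    if db is not None:
        for j in db:
            counts[j] = 0
    for a in assignments:
        if a.category == "junction" and a.junction is not None:
            counts[a.junction] = counts.get(a.junction, 0) + 1
    return counts


def counts_matrix(per_sample: dict[str, dict[Junction, int]]) -> pd.DataFrame:
    """Junction x sample integer count matrix (missing -> 0)."""
    all_j: dict[tuple, Junction] = {}
    for counts in per_sample.values():
        for j in counts:
            all_j.setdefault(j.key, j)
    keys = sorted(all_j)
    labels = [f"{c}:{s}:{d}-{a}" for c, s, d, a in keys]
    data = {
        s: [counts.get(all_j[k], 0) for k in keys]
        for s, counts in per_sample.items()
    }
    df = pd.DataFrame(data, index=pd.Index(labels, name="junction_key"))
    df.attrs["junctions"] = {lab: all_j[k] for lab, k in zip(labels, keys)}
    return df


def rpkm(count: float, feature_len: int, mapped_reads: int) -> float:
    """count / (feature_len/1e3) / (mapped_reads/1e6)."""
    if feature_len <= 0:
        raise ValueError("feature_len must be positive")
    if mapped_reads <= 0:
        raise ValueError("mapped_reads must be positive")
    return count / (feature_len / 1_000) / (mapped_reads / 1_000_000)


def junction_rpkm_table(counts: dict[Junction, int], flank_len: int,
                        mapped_reads: int) -> dict[Junction, float]:
    """Per-junction RPKM with the constant feature length 2 x flank_len, so
    junction RPKM ranks identically to depth-normalized counts."""
    return {j: rpkm(c, 2 * flank_len, mapped_reads) for j, c in counts.items()}


# ---------------------------------------------------------------------------
# cross-sample normalization


def normalize(counts: pd.DataFrame, method: str = "upper_quartile") -> pd.Series:
    """Per-sample scale factors that multiply raw counts before comparison.

    ``upper_quartile``: factors equalize the 75th percentile of nonzero
    feature counts to the first (reference) sample.  ``tmm``: factors from
    the trimmed mean of log expression ratios against the first sample
    (trim 30% of M and 5% of A from each tail, precision-weighted), scaled
    by library size so that a pure depth difference is removed exactly.
    ``none``: all ones.
    """
    if counts.shape[1] < 2:
        raise ValueError("normalization needs at least two samples")
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    samples = list(counts.columns)
    if method == "none":
        return pd.Series(1.0, index=samples)
    if method == "upper_quartile":
        uq = {}
        for s in samples:
            col = counts[s].to_numpy(dtype=float)
            nz = col[col > 0]
            if nz.size == 0:
                raise ValueError(f"sample {s} has no nonzero features")
            uq[s] = np.percentile(nz, 75)
        ref = uq[samples[0]]
        return pd.Series({s: ref / uq[s] for s in samples})
    if method == "tmm":
        ref = counts[samples[0]].to_numpy(dtype=float)
        n_ref = ref.sum()
        factors = {}
        for s in samples:
            obs = counts[s].to_numpy(dtype=float)
            factors[s] = 1.0 / (_tmm_ratio(obs, ref, obs.sum(), n_ref) * (obs.sum() / n_ref))
        return pd.Series(factors)
    raise ValueError(f"unknown normalization method: {method!r}")


def _tmm_ratio(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
               m_trim: float = 0.30, a_trim: float = 0.05) -> float:
    """2**TMM: residual expression ratio of obs vs ref after depth scaling."""
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 1.0
    o, r = obs[keep], ref[keep]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # binomial delta-method precision weights, as in the TMM method
    w = 1.0 / ((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r))
    n = m.size
    lo_m, hi_m = np.floor(n * m_trim), np.ceil(n * (1 - m_trim))
    lo_a, hi_a = np.floor(n * a_trim), np.ceil(n * (1 - a_trim))
    rank_m = np.argsort(np.argsort(m, kind="stable"), kind="stable")
    rank_a = np.argsort(np.argsort(a, kind="stable"), kind="stable")
    sel = (rank_m >= lo_m) & (rank_m < hi_m) & (rank_a >= lo_a) & (rank_a < hi_a)
    if not sel.any():
        sel = np.ones_like(m, dtype=bool)
    return float(2 ** (np.sum(w[sel] * m[sel]) / np.sum(w[sel])))


# ---------------------------------------------------------------------------
# regulation calls


@dataclass
class RegulationCall:
    junction: Junction
    status: str           # upregulated | downregulated | unregulated | below_cutoff
    fold_change: float | None
    wt_count: int
    ko_count: int


def call_regulation(
    junction: Junction,
    wt_count: int,
    ko_count: int,
    wt_factor: float = 1.0,
    ko_factor: float = 1.0,
    min_reads: int = 3,
    fold_threshold: float = 2.0,
    pseudocount: float = PSEUDOCOUNT,
) -> RegulationCall:
    """Classify one junction's change between WT and KO.

    The minimum read requirement is satisfied when *either* sample reaches
    ``min_reads`` raw reads; the fold change is computed on normalized
    counts with a pseudocount so that KO>0/WT=0 junctions are upregulated
    by construction.
    """
    if max(wt_count, ko_count) < min_reads:
        return RegulationCall(junction, "below_cutoff", None, wt_count, ko_count)
    fc = (ko_count * ko_factor + pseudocount) / (wt_count * wt_factor + pseudocount)
    if fc >= fold_threshold:
        status = "upregulated"
    elif fc <= 1.0 / fold_threshold:
        status = "downregulated"
    else:
        status = "unregulated"
    return RegulationCall(junction, status, fc, wt_count, ko_count)


def regulation_table(
    counts_wt: dict[Junction, int],
    counts_ko: dict[Junction, int],
    wt_factor: float = 1.0,
    ko_factor: float = 1.0,
    min_reads: int = 3,
) -> dict[Junction, RegulationCall]:
    out = {}
    for j in set(counts_wt) | set(counts_ko):
        out[j] = call_regulation(
            j, counts_wt.get(j, 0), counts_ko.get(j, 0),
            wt_factor, ko_factor, min_reads=min_reads,
        )
    return out


# ---------------------------------------------------------------------------
# gene expression


def gene_expression(assignments: list[ReadAssignment], models,
                    mapped_reads: int | None = None) -> pd.DataFrame:
    """Per-gene read counts (exonic + junction reads of the gene) and RPKM
    using the union-exon model length."""
    lengths = {g.gene_id: sum(e.length for e in g.exon_union) for g in models}
    counts = dict.fromkeys(lengths, 0)
    for a in assignments:
        if a.gene_id in counts and a.category in ("junction", "genome_exonic"):
            counts[a.gene_id] += 1
    if mapped_reads is None:
        mapped_reads = sum(1 for a in assignments if a.category != "unmapped")
    rows = {
        gid: {
            "count": counts[gid],
            "length": lengths[gid],
            "rpkm": rpkm(counts[gid], lengths[gid], mapped_reads) if mapped_reads else 0.0,
        }
        for gid in sorted(lengths)
    }
    return pd.DataFrame.from_dict(rows, orient="index")
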