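"""End-to-end orchestration: annotate -> junction DB -> map -> quantify ->
PTC -> events -> (conservation), plus summary tables, per-gene splicing
slopes, browser-track export and the canonical-isoform correction."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import annotation, conservation, events, junctiondb, mapping, ptc, quantify
from .junctiondb import DEFAULT_FLANK_LEN

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "SummaryReport",
    "RunResult",
    "run",
    "per_gene_slopes",
    "export_browser_tracks",
    "splice_factor_canonical_correction",
    "subsample_assignments",
]


@dataclass
class RunConfig:
    gtf: str
    genome: str
    wt_reads: str | None = None
    ko_reads: str | None = None
    wt_sam: str | None = None
    ko_sam: str | None = None
    track: str | None = None
    out_dir: str = "splicejudge_out"
    flank_len: int = DEFAULT_FLANK_LEN
    anchor_min: int = 5
    trunc_step: int = 10
    trunc_min_len: int = 35
    min_reads: int = 3
    norm_method: str = "tmm"
    dpsi_threshold: float = 20.0
    min_event_reads: int = 10
    ptc_min_dist: int = 50
    seed: int = 1729

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate(self) -> None:
        for cond in ("wt", "ko"):
            reads = getattr(self, f"{cond}_reads")
            sam = getattr(self, f"{cond}_sam")
            if reads is None and sam is None:
                raise ValueError(f"config must name a {cond.upper()} sample (reads or SAM)")
        for name in ("gtf", "genome", "wt_reads", "ko_reads", "wt_sam", "ko_sam", "track"):
            p = getattr(self, name)
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(f"{name}: {p}")


@dataclass
class SummaryReport:
    mapping_tallies: dict[str, dict[str, int]]
    regulation_tallies: dict[str, dict[str, int]]         # all | ptc_plus
    as_vs_canonical: dict[str, dict[str, int]]
    event_class_table: pd.DataFrame
    slopes: dict[str, float]

    def to_json(self) -> str:
        d = {
            "mapping": self.mapping_tallies,
            "regulation": self.regulation_tallies,
            "as_vs_canonical": self.as_vs_canonical,
            "event_classes": self.event_class_table.to_dict(orient="index"),
            "slopes": self.slopes,
        }
        return json.dumps(d, indent=2, default=int)


@dataclass
class RunResult:
    config: RunConfig
    models: list
    db: junctiondb.JunctionDB
    assignments: dict[str, list]
    counts: dict[str, dict]
    factors: dict[str, float]
    regulation: dict
    ptc_calls: dict
    event_list: list
    psi_records: list
    report: SummaryReport
    conservation_profiles: dict = field(default_factory=dict)


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline; any stage failure aborts with the stage
    name while keeping the upstream outputs already written."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    stage = "annotate"
    try:
        models = annotation.load_gene_models(config.gtf, "gtf")
        genome = _load_genome(config.genome)

        stage = "junctiondb"
        db = junctiondb.build_combinatorial_db(models, genome, config.flank_len)

        stage = "map"
        params = mapping.MappingParams(
            anchor_min=config.anchor_min,
            trunc_step=config.trunc_step,
            trunc_min_len=config.trunc_min_len,
        )
        index = mapping.MapperIndex(db, genome, models, params)
        assignments = {}
        for cond in ("wt", "ko"):
            sam = getattr(config, f"{cond}_sam")
            if sam is not None:
                assignments[cond] = mapping.import_sam(sam, index)
            else:
                reads = mapping.read_fastx(getattr(config, f"{cond}_reads"))
                assignments[cond] = mapping.map_with_rescue(reads, index)

        stage = "quantify"
        counts = {c: quantify.count_junctions(assignments[c], db) for c in assignments}
        mat = quantify.counts_matrix(counts)
        factors = quantify.normalize(mat, config.norm_method).to_dict()
        regulation = quantify.regulation_table(
            counts["wt"], counts["ko"], factors["wt"], factors["ko"],
            min_reads=config.min_reads,
        )

        stage = "ptc"
        ptc_calls = {}
        backbones = {}
        for g in models:
            ref = ptc.reference_backbone(g, genome)
            if ref.cds_start is None:
                continue
            backbones[g.gene_id] = ref
            stop_pos = ptc.reference_stop_genomic(ref, genome)
            for j in db.junctions_of_gene(g.gene_id):
                try:
                    ptc_calls[j.key] = ptc.call_ptc(
                        ref, j, genome, config.ptc_min_dist, annotated_stop_pos=stop_pos
                    )
                except ptc.JunctionOutsideReference:
                    continue

        stage = "events"
        per_j = {}
        for cond in counts:
            for j, c in counts[cond].items():
                per_j.setdefault(j, {})[cond] = c
        event_list = events.classify_events(per_j, models)
        psi_records = [
            events.compute_delta_psi(ev, counts["wt"], counts["ko"],
                                     config.dpsi_threshold, config.min_event_reads)
            for ev in event_list
        ]

        stage = "summary"
        report = _summarize(models, db, assignments, counts, regulation,
                            ptc_calls, event_list, psi_records, backbones)
        _write_outputs(config, db, counts, regulation, ptc_calls, psi_records, report)

        result = RunResult(config, models, db, assignments, counts, factors,
                           regulation, ptc_calls, event_list, psi_records, report)

        if config.track is not None:
            stage = "conservation"
            result.conservation_profiles = _conservation_stage(
                config, models, ptc_calls, regulation, event_list, psi_records)
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _load_genome(path: str):
    import pyfaidx

    return pyfaidx.Fasta(path, sequence_always_upper=True)


def canonical_junction_keys(models, genome=None) -> set:
    """Junctions between consecutive exons of each gene's longest isoform."""
    keys = set()
    for g in models:
        iso = annotation.longest_isoform(g)
        for up, down in iso.junction_pairs():
            keys.add(junctiondb.junction_between(g.gene_id, g.strand, up, down).key)
    return keys


def _summarize(models, db, assignments, counts, regulation, ptc_calls,
               event_list, psi_records, backbones) -> SummaryReport:
    mapping_tallies = {c: mapping.category_counts(a) for c, a in assignments.items()}

    def reg_tally(keys=None):
        tally = {"upregulated": 0, "downregulated": 0, "unregulated": 0, "below_cutoff": 0}
        for j, call in regulation.items():
            if keys is not None and j.key not in keys:
                continue
            tally[call.status] += 1
        return tally

    ptc_plus = {k for k, c in ptc_calls.items() if c.is_ptc}
    regulation_tallies = {"all": reg_tally(), "ptc_plus": reg_tally(ptc_plus)}

    canonical = canonical_junction_keys(models)
    expressed = {j.key for j, c in regulation.items() if max(c.wt_count, c.ko_count) > 0}
    as_keys = expressed - canonical
    as_vs_canonical = {
        "canonical": {"n": len(expressed & canonical)},
        "alternative": {
            "n": len(as_keys),
            "ptc_plus": len(as_keys & ptc_plus),
        },
    }

    rows = {}
    for cls in events.EVENT_CLASSES:
        evs = [r for r in psi_records if r.event.cls == cls]
        called = [r for r in evs if r.direction != "no-call"]
        from .ptc import classify_inclusion_exclusion

        sem = [classify_inclusion_exclusion(r.event, ptc_calls) for r in called]
        rows[cls] = {
            "total_events": len(called),
            "ptc_events": sum(s in ("ptc_on_inclusion", "ptc_on_exclusion", "both_ptc") for s in sem),
            "inclusion_events": sum(r.direction == "increased-inclusion" for r in called),
            "exclusion_events": sum(r.direction == "increased-exclusion" for r in called),
            "ptc_upon_inclusion": sum(s == "ptc_on_inclusion" for s in sem),
            "ptc_upon_exclusion": sum(s == "ptc_on_exclusion" for s in sem),
        }
    event_table = pd.DataFrame.from_dict(rows, orient="index")

    slopes = {}
    try:
        tallies = per_gene_junction_tallies(models, counts, ptc_calls, canonical)
        for cond in counts:
            slopes[f"as_{cond}"] = per_gene_slopes(
                tallies[cond]["n_junctions"], tallies[cond]["n_as"])
            slopes[f"ptc_{cond}"] = per_gene_slopes(
                tallies[cond]["n_junctions"], tallies[cond]["n_ptc"])
    except ValueError:
        pass
    return SummaryReport(mapping_tallies, regulation_tallies, as_vs_canonical,
                         event_table, slopes)


def per_gene_junction_tallies(models, counts, ptc_calls, canonical=None):
    """Per-condition DataFrames of expressed / AS / PTC+ junctions per gene."""
    if canonical is None:
        canonical = canonical_junction_keys(models)
    ptc_plus = {k for k, c in ptc_calls.items() if c.is_ptc}
    out = {}
    for cond, cmap in counts.items():
        rows = {}
        for j, c in cmap.items():
            if c <= 0:
                continue
            r = rows.setdefault(j.gene_id, {"n_junctions": 0, "n_as": 0, "n_ptc": 0})
            r["n_junctions"] += 1
            if j.key not in canonical:
                r["n_as"] += 1
            if j.key in ptc_plus:
                r["n_ptc"] += 1
        out[cond] = pd.DataFrame.from_dict(rows, orient="index").fillna(0)
    return out


def per_gene_slopes(x, y) -> float:
    """Least-squares slope through the origin of y against x.

    A gene with zero junctions necessarily has zero alternative or PTC+
    junctions, so the fit is constrained through (0, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 genes for a slope estimate")
    denom = float(np.sum(x * x))
    if denom == 0:
        return 0.0
    return float(np.sum(x * y) / denom)


def subsample_assignments(assignments, fraction: float, seed: int = 1729):
    """Stochastically drop reads to normalize library sizes between samples."""
    rng = np.random.default_rng(seed)
    keep = rng.random(len(assignments)) < fraction
    return [a for a, k in zip(assignments, keep) if k]


def export_browser_tracks(result: RunResult, out_dir: str) -> None:
    """UCSC-style junction BED (score = read count, no minimum cutoff) and
    exon-coverage bedGraph per sample."""
    os.makedirs(out_dir, exist_ok=True)
    for cond, cmap in result.counts.items():
        junctiondb.write_junction_bed(
            os.path.join(out_dir, f"junctions_{cond}.bed"), cmap,
            track_name=f"junctions_{cond}",
        )
        cov: dict[str, dict[int, int]] = {}
        for a in result.assignments[cond]:
            if a.category == "genome_exonic" and a.chrom is not None:
                d = cov.setdefault(a.chrom, {})
                for p in range(a.pos, a.pos + (a.mapped_length or 0)):
                    d[p] = d.get(p, 0) + 1
        path = os.path.join(out_dir, f"coverage_{cond}.bedgraph")
        with open(path, "w") as fh:
            fh.write(f'track type=bedGraph name="coverage_{cond}"\n')
            for chrom in sorted(cov):
                positions = sorted(cov[chrom])
                i = 0
                while i < len(positions):
                    j = i
                    while (j + 1 < len(positions)
                           and positions[j + 1] == positions[j] + 1
                           and cov[chrom][positions[j + 1]] == cov[chrom][positions[i]]):
                        j += 1
                    fh.write(f"{chrom}\t{positions[i]}\t{positions[j] + 1}\t"
                             f"{cov[chrom][positions[i]]}\n")
                    i = j + 1


def splice_factor_canonical_correction(
    gene_fc: float, ptc_fraction_wt: float, ptc_fraction_ko: float
) -> tuple[float | None, list[str]]:
    """Canonical-isoform fold change after removing the PTC+ contribution:
    gene_fc * (1 - ptc_fraction_ko) / (1 - ptc_fraction_wt)."""
    flags = []
    if ptc_fraction_wt >= 1.0 or ptc_fraction_ko >= 1.0:
        return None, ["undefined"]
    if ptc_fraction_wt > 0.9 or ptc_fraction_ko > 0.9:
        flags.append("unreliable")
    return gene_fc * (1 - ptc_fraction_ko) / (1 - ptc_fraction_wt), flags


def _write_outputs(config, db, counts, regulation, ptc_calls, psi_records, report):
    out = config.out_dir
    rows = []
    for j in db:
        call = regulation.get(j)
        pcall = ptc_calls.get(j.key)
        rows.append({
            "gene_id": j.gene_id, "chrom": j.chrom, "strand": j.strand,
            "donor": j.donor, "acceptor": j.acceptor, "source": j.source,
            "wt_count": counts["wt"].get(j, 0), "ko_count": counts["ko"].get(j, 0),
            "status": call.status if call else "NA",
            "fold_change": call.fold_change if call else None,
            "ptc": pcall.status if pcall else "NA",
            "stop_codon": ptc.rna_codon(pcall.stop_codon) if pcall else "none",
            "dist_to_last_junction": pcall.dist_to_last_junction if pcall else None,
        })
    pd.DataFrame(rows).to_csv(os.path.join(out, "junctions.tsv"), sep="\t", index=False)

    ev_rows = [{
        "event_id": r.event.event_id, "gene_id": r.event.gene_id, "class": r.event.cls,
        "psi_wt": r.psi_wt, "psi_ko": r.psi_ko, "delta_psi": r.delta_psi,
        "direction": r.direction, "supported": r.supported,
    } for r in psi_records]
    pd.DataFrame(ev_rows).to_csv(os.path.join(out, "events.tsv"), sep="\t", index=False)
    with open(os.path.join(out, "summary.json"), "w") as fh:
        fh.write(report.to_json())


def _conservation_stage(config, models, ptc_calls, regulation, event_list, psi_records):
    track = conservation.read_track(config.track)
    profiles = {}
    # SES profile sets, grouped by regulation direction and PTC semantics
    sets: dict[str, list] = {"regulated": [], "unregulated": []}
    for r in psi_records:
        if r.event.cls != "SES" or r.psi_wt is None:
            continue
        skip = r.event.exclusion_junctions[0]
        anchor = (skip.donor_exon, r.event.affected_exons[0], skip.acceptor_exon)
        key = "regulated" if r.direction != "no-call" else "unregulated"
        sets[key].append(anchor)
    sets = {k: v for k, v in sets.items() if v}
    if sets:
        profiles["ses"] = conservation.profile_ses(sets, track)
    return profiles
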