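import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from splicejudge import junctiondb, mapping, quantify
from splicejudge.annotation import Exon, GeneModel, Isoform
from splicejudge.synthetic import SimConfig, simulate_genome_and_models, simulate_reads


def make_gene(gene_id, chrom, strand, iso_specs, cds=None):
    """Build a GeneModel from {iso_id: [(start, end), ...]} genomic intervals.

    ``cds``: {iso_id: transcript-relative start-codon offset}.
    """
    isoforms = []
    for iso_id, intervals in iso_specs.items():
        exons = [Exon(chrom, s, e, strand) for s, e in intervals]
        exons.sort(key=lambda e: e.start, reverse=(strand == "-"))
        isoforms.append(Isoform(iso_id, exons, cds_start=(cds or {}).get(iso_id)))
    return GeneModel(gene_id, chrom, strand, isoforms)


def random_genome(rng, length, chrom="chr1"):
    return {chrom: "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])}


@pytest.fixture(scope="session")
def small_sim():
    """A small noise-free simulation shared by several test modules."""
    cfg = SimConfig(
        seed=7,
        reads_per_gene=600,
        splice_noise_rate=0.0,
        event_mix={"SES": 4, "MES": 2, "A5SS": 2, "A3SS": 2, "MXE": 2, "AFE": 1, "ALE": 1},
    )
    return simulate_genome_and_models(cfg)


@pytest.fixture(scope="session")
def small_sim_db(small_sim):
    return junctiondb.build_combinatorial_db(small_sim.models, small_sim.genome)


@pytest.fixture(scope="session")
def small_sim_index(small_sim, small_sim_db):
    return mapping.MapperIndex(small_sim_db, small_sim.genome, small_sim.models)


@pytest.fixture(scope="session")
def small_sim_mapped(small_sim, small_sim_index):
    out = {}
    for cond in ("wt", "ko"):
        reads, records = simulate_reads(small_sim, cond)
        out[cond] = {
            "reads": reads,
            "records": records,
            "assignments": mapping.map_with_rescue(reads, small_sim_index),
        }
    return out


@pytest.fixture(scope="session")
def small_sim_counts(small_sim_db, small_sim_mapped):
    return {
        cond: quantify.count_junctions(d["assignments"], small_sim_db)
        for cond, d in small_sim_mapped.items()
    }
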