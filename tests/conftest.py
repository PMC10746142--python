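import numpy as np
import pytest

from hadalcomp.models import FOCAL, REFERENCE, DepthTrack, GeneModel
from hadalcomp.simulate import SimulationConfig, simulate_depth_cohort, simulate_genome_annotation


def make_gene(gene_id="g1", contig="chr1", strand="+", intervals=((0, 100),)):
    return GeneModel(
        gene_id=gene_id, contig=contig, strand=strand, cds_intervals=tuple(intervals)
    )


def make_track(individual_id, species_label, depths_by_contig):
    arrays = {
        contig: np.asarray(values, dtype=np.int64)
        for contig, values in depths_by_contig.items()
    }
    return DepthTrack(individual_id=individual_id, species_label=species_label, depths=arrays)


@pytest.fixture(scope="session")
def planted_world():
    """A 20-gene cohort with one planted event of each type."""
    cfg = SimulationConfig(
        n_genes=20,
        gene_length_range=(300, 600),
        n_focal_individuals=3,
        n_reference_individuals=2,
        planted_losses=frozenset({"g0001"}),
        planted_duplications={"g0002": 3.0},
        planted_pseudogenes={"g0003": (82, (22,))},
        planted_indels={"g0004": -11, "g0005": 4},
        planted_denovo=frozenset({"g0006"}),
        planted_consistent_up=frozenset({"g0007"}),
        rng_seed=11,
    )
    annotated = simulate_genome_annotation(cfg)
    tracks = simulate_depth_cohort(cfg, annotated)
    return cfg, annotated, tracks
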