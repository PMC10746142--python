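import filecmp
import os

import numpy as np
import pytest
from Bio.Seq import Seq

from hadalcomp import io_formats
from hadalcomp.models import FOCAL, REFERENCE
from hadalcomp.simulate import (
    ConfigurationError,
    FOCAL_SPECIES,
    SimulationConfig,
    build_truth,
    read_truth,
    simulate_cds_alignments,
    simulate_depth_cohort,
    simulate_genome_annotation,
    simulate_protein_msa,
    write_fixture_bundle,
    write_truth,
)

STOPS = {"TAA", "TAG", "TGA"}


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"n_genes": 0}, "n_genes"),
            ({"gene_length_range": (6, 300)}, "gene_length_range"),
            ({"n_focal_individuals": 0}, "n_focal_individuals"),
            ({"mean_depth": 0.0}, "mean_depth"),
            ({"planted_losses": frozenset({"nope"})}, "planted_losses"),
            ({"n_tissues": 1}, "n_tissues"),
            ({"planted_indels": {"g0001": 0}}, "planted_indels"),
        ],
    )
    def test_errors_name_the_field(self, kwargs, field):
        with pytest.raises(ConfigurationError, match=field):
            SimulationConfig(n_genes=10, **kwargs) if "n_genes" not in kwargs else SimulationConfig(**kwargs)

    def test_planted_sets_must_be_disjoint(self):
        with pytest.raises(ConfigurationError, match="already planted"):
            SimulationConfig(
                n_genes=10,
                planted_losses=frozenset({"g0001"}),
                planted_duplications={"g0001": 2.0},
            )


class TestGenomeAnnotation:
    def test_every_gene_is_a_complete_orf(self):
        cfg = SimulationConfig(n_genes=10, rng_seed=1)
        annotated = simulate_genome_annotation(cfg)
        assert len(annotated.genes) == 10
        for gene in annotated.genes:
            cds = annotated.cds[gene.gene_id]
            assert len(cds) % 3 == 0
            assert cds[:3] == "ATG"
            assert cds[-3:] in STOPS
            for i in range(0, len(cds) - 3, 3):
                assert cds[i : i + 3] not in STOPS

    def test_gff_coordinates_consistent_with_fasta(self):
        """Extracting each gene's CDS from the genome reproduces the ORF."""
        cfg = SimulationConfig(n_genes=15, rng_seed=4)
        annotated = simulate_genome_annotation(cfg)
        for gene in annotated.genes:
            assert io_formats.extract_cds(annotated.genome, gene) == annotated.cds[gene.gene_id]

    def test_gff_round_trips_through_reader(self, tmp_path):
        cfg = SimulationConfig(n_genes=8, rng_seed=2)
        annotated = simulate_genome_annotation(cfg)
        path = tmp_path / "sim.gff3"
        path.write_text(annotated.gff3())
        back = io_formats.read_gff3(path)
        assert [(g.gene_id, g.strand, g.cds_intervals) for g in back] == [
            (g.gene_id, g.strand, g.cds_intervals) for g in annotated.genes
        ]

    def test_seed_determinism_byte_identical(self):
        cfg = SimulationConfig(n_genes=10, rng_seed=7)
        a = simulate_genome_annotation(cfg)
        b = simulate_genome_annotation(cfg)
        assert a.fasta() == b.fasta()
        assert a.gff3() == b.gff3()

    def test_truth_marks_planted_pseudogene(self):
        cfg = SimulationConfig(n_genes=5, planted_pseudogenes={"g0003": (82, (22,))}, rng_seed=1)
        truth = build_truth(cfg)
        row = truth.set_index("gene_id").loc["g0003"]
        assert row["event"] == "pseudogene"
        assert "deletions=22" in row["param"]
        assert "substitutions=82" in row["param"]


def test_truth_round_trip(tmp_path):
    cfg = SimulationConfig(
        n_genes=6, planted_losses=frozenset({"g0002"}), planted_duplications={"g0004": 2.5}, rng_seed=1
    )
    truth = build_truth(cfg)
    path = tmp_path / "truth.tsv"
    write_truth(truth, path)
    back = read_truth(path)
    assert back.equals(truth.astype(str))


@pytest.fixture(scope="module")
def world():
    cfg = SimulationConfig(
        n_genes=30,
        n_focal_individuals=4,
        n_reference_individuals=3,
        planted_losses=frozenset({"g0001"}),
        planted_duplications={"g0002": 14 / 3},
        rng_seed=5,
    )
    annotated = simulate_genome_annotation(cfg)
    return cfg, annotated, simulate_depth_cohort(cfg, annotated)


class TestDepthCohort:
    def test_loss_gene_capped_below_three(self, world):
        cfg, annotated, tracks = world
        gene = next(g for g in annotated.genes if g.gene_id == "g0001")
        for track in tracks:
            depths = track.gene_depths(gene)
            if track.species_label == FOCAL:
                assert depths.max() <= 2
            else:
                assert depths.mean() > 20  # reference unaffected

    def test_duplication_scales_focal_depth(self, world):
        """Planted factor 14/3: focal mean ~ 4.67x the reference mean."""
        cfg, annotated, tracks = world
        gene = next(g for g in annotated.genes if g.gene_id == "g0002")
        focal_mean = np.mean(
            [track.gene_depths(gene).mean() for track in tracks if track.species_label == FOCAL]
        )
        ref_mean = np.mean(
            [track.gene_depths(gene).mean() for track in tracks if track.species_label == REFERENCE]
        )
        assert focal_mean / ref_mean == pytest.approx(14 / 3, rel=0.05)

    def test_neutral_gene_ratio_near_one(self, world):
        cfg, annotated, tracks = world
        gene = next(g for g in annotated.genes if g.gene_id == "g0010")
        focal_mean = np.mean(
            [track.gene_depths(gene).mean() for track in tracks if track.species_label == FOCAL]
        )
        ref_mean = np.mean(
            [track.gene_depths(gene).mean() for track in tracks if track.species_label == REFERENCE]
        )
        assert focal_mean / ref_mean == pytest.approx(1.0, rel=0.1)

    def test_simulated_mean_near_configured(self, world):
        from hadalcomp.depth_profiles import individual_mean_depth

        cfg, annotated, tracks = world
        neutral = [g for g in annotated.genes if g.gene_id not in {"g0001", "g0002"}]
        for track in tracks[:2]:
            assert 28 <= individual_mean_depth(track, neutral) <= 32


class TestProteinMsa:
    def test_planted_deletion_gap_only_in_focal(self):
        cfg = SimulationConfig(n_genes=3, planted_indels={"g0001": -11}, rng_seed=6)
        annotated = simulate_genome_annotation(cfg)
        msa = simulate_protein_msa(cfg, annotated)["g0001"]
        focal = msa[FOCAL_SPECIES]
        assert focal.count("-") == 11
        gap_start = focal.index("-")
        assert focal[gap_start : gap_start + 11] == "-" * 11
        for name, row in msa.items():
            if name != FOCAL_SPECIES:
                assert "-" not in row

    def test_planted_insertion_gaps_every_nonfocal_row(self):
        cfg = SimulationConfig(n_genes=3, planted_indels={"g0002": 4}, rng_seed=6)
        annotated = simulate_genome_annotation(cfg)
        msa = simulate_protein_msa(cfg, annotated)["g0002"]
        assert "-" not in msa[FOCAL_SPECIES]
        for name, row in msa.items():
            if name != FOCAL_SPECIES:
                assert row.count("-") == 4


class TestCdsAlignments:
    def test_planted_recipe_applied(self):
        cfg = SimulationConfig(n_genes=4, planted_pseudogenes={"g0002": (82, (22,))}, rng_seed=8)
        annotated = simulate_genome_annotation(cfg)
        aln = simulate_cds_alignments(cfg, annotated)
        orth, focal = aln["g0002"]
        assert orth == annotated.cds["g0002"]
        assert focal.count("-") == 22
        diffs = sum(1 for a, b in zip(orth, focal) if b != "-" and a != b)
        assert diffs == 82
        orth2, focal2 = aln["g0001"]  # neutral gene: identical rows
        assert orth2 == focal2


def test_fixture_bundle_byte_identical(tmp_path):
    cfg = SimulationConfig(
        n_genes=8,
        n_focal_individuals=2,
        n_reference_individuals=2,
        planted_losses=frozenset({"g0001"}),
        planted_indels={"g0002": -5},
        rng_seed=12,
    )
    out1, out2 = tmp_path / "a", tmp_path / "b"
    write_fixture_bundle(cfg, out1)
    write_fixture_bundle(cfg, out2)
    for root, _, files in os.walk(out1):
        for name in files:
            p1 = os.path.join(root, name)
            p2 = p1.replace(str(out1), str(out2))
            assert filecmp.cmp(p1, p2, shallow=False), f"{name} differs between runs"
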