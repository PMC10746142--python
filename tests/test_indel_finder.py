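import numpy as np
import pytest

from hadalcomp import indel_finder
from hadalcomp.simulate import FOCAL_SPECIES, SimulationConfig, simulate_genome_annotation, simulate_protein_msa

FOCAL = "focal"


def build_msa(n_species=6, length=40, focal_patch=None, patch_cols=None, base_char="A"):
    """Conserved alignment; optionally overwrite focal columns with a patch."""
    base = base_char * length
    msa = {f"sp{i}": base for i in range(n_species)}
    focal_row = list(base)
    if focal_patch is not None:
        for col, char in zip(patch_cols, focal_patch):
            focal_row[col] = char
    msa[FOCAL] = "".join(focal_row)
    return msa


class TestFindRegions:
    def test_focal_deletion_run(self):
        cols = range(10, 21)  # 11 columns
        msa = build_msa(focal_patch="-" * 11, patch_cols=cols)
        (region,) = indel_finder.find_lineage_specific_regions("g", msa, FOCAL)
        assert (region.start_col, region.end_col) == (10, 21)
        assert region.kind == "deletion"
        assert region.length == 11

    def test_focal_insertion_run(self):
        # insertion: non-focal rows gapped, focal has residues
        msa = {f"sp{i}": "AAAAA----AAAAA" for i in range(5)}
        msa[FOCAL] = "AAAAAWWWWAAAAA"
        (region,) = indel_finder.find_lineage_specific_regions("g", msa, FOCAL)
        assert region.kind == "insertion"
        assert region.length == 4

    def test_substitution_run(self):
        msa = build_msa(focal_patch="WWW", patch_cols=range(15, 18))
        (region,) = indel_finder.find_lineage_specific_regions("g", msa, FOCAL)
        assert region.kind == "substitution_run"
        assert region.length == 3

    @pytest.mark.parametrize("run_len, strict, n_found", [(2, False, 0), (3, False, 1), (3, True, 0), (4, True, 1)])
    def test_minimum_length_rule(self, run_len, strict, n_found):
        msa = build_msa(focal_patch="W" * run_len, patch_cols=range(15, 15 + run_len))
        regions = indel_finder.find_lineage_specific_regions(
            "g", msa, FOCAL, strict_greater=strict
        )
        assert len(regions) == n_found

    def test_nonfocal_disagreement_breaks_specificity(self):
        msa = build_msa(focal_patch="WWW", patch_cols=range(15, 18))
        rows = dict(msa)
        rows["sp0"] = rows["sp0"][:16] + "C" + rows["sp0"][17:]  # middle column disagrees
        regions = indel_finder.find_lineage_specific_regions("g", rows, FOCAL)
        assert regions == []  # run split into 1+1 columns, below minimum

    def test_species_order_invariance(self):
        msa = build_msa(focal_patch="-" * 5, patch_cols=range(12, 17))
        shuffled = dict(reversed(list(msa.items())))
        a = indel_finder.find_lineage_specific_regions("g", msa, FOCAL)
        b = indel_finder.find_lineage_specific_regions("g", shuffled, FOCAL)
        assert a == b

    def test_regions_are_maximal_and_disjoint(self):
        msa = build_msa(
            length=60,
            focal_patch="WWW" + "WWWW",
            patch_cols=list(range(10, 13)) + list(range(30, 34)),
        )
        regions = indel_finder.find_lineage_specific_regions("g", msa, FOCAL)
        assert [(r.start_col, r.end_col) for r in regions] == [(10, 13), (30, 34)]
        for r1, r2 in zip(regions, regions[1:]):
            assert r2.start_col > r1.end_col  # no adjacency or overlap

    def test_quorum_enforced(self):
        msa = build_msa(n_species=3)
        with pytest.raises(ValueError, match="non-focal species"):
            indel_finder.find_lineage_specific_regions("g", msa, FOCAL)

    def test_ragged_alignment_rejected(self):
        msa = build_msa()
        msa["sp0"] = msa["sp0"][:-1]
        with pytest.raises(ValueError, match="ragged"):
            indel_finder.find_lineage_specific_regions("g", msa, FOCAL)

    def test_focal_individual_consistency_flag(self):
        msa = build_msa(focal_patch="-" * 4, patch_cols=range(12, 16))
        consistent_rows = {"ind1": msa[FOCAL], "ind2": msa[FOCAL]}
        (region,) = indel_finder.find_lineage_specific_regions(
            "g", msa, FOCAL, focal_individual_rows=consistent_rows
        )
        assert region.focal_consistent is True
        split_row = msa[FOCAL][:12] + "AAAA" + msa[FOCAL][16:]
        (region,) = indel_finder.find_lineage_specific_regions(
            "g", msa, FOCAL, focal_individual_rows={"ind1": msa[FOCAL], "ind2": split_row}
        )
        assert region.focal_consistent is False


class TestFlanks:
    def test_perfect_flanks_pass(self):
        msa = build_msa(focal_patch="-" * 5, patch_cols=range(12, 17))
        ok, left, right = indel_finder.validate_flanks(12, 17, msa)
        assert ok and left == 1.0 and right == 1.0

    def test_degraded_flank_fails(self):
        # 6 rows: pairwise identity with 3 of 6 rows altered over the whole
        # left window drops to 0.6 < 0.9
        msa = build_msa(n_species=5, focal_patch="-" * 5, patch_cols=range(12, 17))
        for name in ["sp0", "sp1", "sp2"]:
            row = list(msa[name])
            for col in range(7, 12):
                row[col] = "C"
            msa[name] = "".join(row)
        ok, left, right = indel_finder.validate_flanks(12, 17, msa)
        assert not ok
        assert left == pytest.approx(1 - (3 * 3) / 15)  # 9 of 15 pairs mismatch
        assert right == 1.0
        regions = indel_finder.find_lineage_specific_regions("g", msa, FOCAL)
        assert regions == []  # finder applies the flank gate

    def test_region_at_alignment_edge_fails(self):
        msa = build_msa(focal_patch="-" * 4, patch_cols=range(3, 7))  # 3-col left flank
        ok, *_ = indel_finder.validate_flanks(3, 7, msa)
        assert not ok
        assert indel_finder.find_lineage_specific_regions("g", msa, FOCAL) == []


class TestPlantedRecovery:
    def test_noise_free_exact_boundaries(self):
        cfg = SimulationConfig(
            n_genes=6,
            gene_length_range=(450, 600),
            planted_indels={"g0001": -3, "g0002": -5, "g0003": -11, "g0004": 4},
            rng_seed=3,
        )
        annotated = simulate_genome_annotation(cfg)
        msa = simulate_protein_msa(cfg, annotated)
        for gid, delta in cfg.planted_indels.items():
            (region,) = indel_finder.find_lineage_specific_regions(
                gid, msa[gid], FOCAL_SPECIES
            )
            assert region.length == abs(delta)
            assert region.kind == ("deletion" if delta < 0 else "insertion")
        for gid in ("g0005", "g0006"):  # neutral genes stay silent
            assert indel_finder.find_lineage_specific_regions(gid, msa[gid], FOCAL_SPECIES) == []
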