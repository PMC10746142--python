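import pytest
from Bio.Seq import Seq

from hadalcomp import io_formats, pseudogene_caller
from conftest import make_gene

# 100-codon CDS engineered so a 22-nt deletion at position 90 shifts the
# frame (+1) and the shifted frame reads TAA downstream (via CTA ACT).
ENGINEERED_CDS = "ATG" + "GCT" * 29 + "AAT" * 30 + "CTAACT" + "GCT" * 37 + "TAA"
assert len(ENGINEERED_CDS) == 300


def oracle_stop_positions(focal_gapped: str) -> list[int]:
    """Independent oracle: translate the ungapped focal sequence directly."""
    seq = focal_gapped.replace("-", "")
    protein = str(Seq(seq[: len(seq) // 3 * 3]).translate())
    internal = protein[:-1]
    return [i + 1 for i, aa in enumerate(internal) if aa == "*"]


class TestAlignmentCoverage:
    MAF = """##maf version=1
a score=0.0
s ref.chr1 10 10 + 1000 ACGTACGTAC
s tanaka.chrA 5 8 + 500 ACGT--GTAC

"""

    def test_partial_coverage(self, tmp_path):
        path = tmp_path / "a.maf"
        path.write_text(self.MAF)
        blocks = io_formats.read_maf(path)
        gene = make_gene("g", intervals=((10, 20),))
        cov = pseudogene_caller.alignment_coverage(blocks, gene, "tanaka", "ref")
        assert cov == pytest.approx(0.8)  # 2 gap columns of 10
        assert pseudogene_caller.alignment_coverage(blocks, gene, "ref", "ref") == 1.0

    def test_unaligned_contig_is_zero(self, tmp_path):
        path = tmp_path / "a.maf"
        path.write_text(self.MAF)
        blocks = io_formats.read_maf(path)
        gene = make_gene("g", contig="chr99", intervals=((0, 10),))
        assert pseudogene_caller.alignment_coverage(blocks, gene, "tanaka", "ref") == 0.0

    def test_minus_strand_anchor_projection(self, tmp_path):
        """A minus-strand anchor row maps column i to srcSize-1-(start+i)."""
        maf = (
            "##maf version=1\n"
            "a score=0.0\n"
            "s ref.chr1 10 10 - 100 ACGTACGTAC\n"
            "s tanaka.chrA 5 10 + 500 ACGTACGTAC\n\n"
        )
        path = tmp_path / "m.maf"
        path.write_text(maf)
        blocks = io_formats.read_maf(path)
        # anchor covers + strand positions 89 down to 80
        covered = make_gene("g", intervals=((80, 90),))
        outside = make_gene("g2", intervals=((10, 20),))
        assert pseudogene_caller.alignment_coverage(blocks, covered, "tanaka", "ref") == 1.0
        assert pseudogene_caller.alignment_coverage(blocks, outside, "tanaka", "ref") == 0.0

    def test_pairwise_coverage(self):
        rows = {"ref": "AAAAAAAAAA", "focal": "AAAAAAA---"}
        cov = pseudogene_caller.alignment_coverage_pairwise(rows, "ref", "focal")
        assert cov == pytest.approx(0.7)


class TestCallUnitaryCandidates:
    @pytest.mark.parametrize(
        "ref_cov, focal_cov, expected",
        [
            (0.85, 0.05, True),
            (0.70, 0.30, True),  # boundaries are inclusive
            (0.85, 0.95, False),
            (0.69, 0.05, False),  # fails the reference presence gate
            (0.60, 0.00, False),
        ],
    )
    def test_gate(self, ref_cov, focal_cov, expected):
        coverages = {"g": {"stickleback": ref_cov, "hadal": focal_cov}}
        out = pseudogene_caller.call_unitary_candidates(coverages, ["stickleback"], "hadal")
        assert (out == ["g"]) is expected


class TestDetectDisruptions:
    def test_22nt_deletion_frameshift_and_downstream_stop(self):
        focal = ENGINEERED_CDS[:90] + "-" * 22 + ENGINEERED_CDS[112:]
        report = pseudogene_caller.detect_disruptions("g", ENGINEERED_CDS, focal)
        kinds = {e.kind for e in report.events}
        assert "frameshift_indel" in kinds  # 22 mod 3 == 1
        stops = [e.position for e in report.events if e.kind == "premature_stop"]
        assert stops == oracle_stop_positions(focal)
        assert stops and stops[0] < 100
        assert report.verdict == "pseudogene_candidate"

    def test_in_frame_deletion_is_intact(self):
        focal = ENGINEERED_CDS[:90] + "---" + ENGINEERED_CDS[93:]
        report = pseudogene_caller.detect_disruptions("g", ENGINEERED_CDS, focal)
        assert report.events == ()
        assert report.verdict == "intact"
        assert report.intact_fraction == 1.0

    def test_premature_stop_position_and_intact_fraction(self):
        # TAA substituted at codon 10 of the 100-codon gene
        focal = ENGINEERED_CDS[:27] + "TAA" + ENGINEERED_CDS[30:]
        report = pseudogene_caller.detect_disruptions("g", ENGINEERED_CDS, focal)
        (event,) = report.events
        assert (event.kind, event.position) == ("premature_stop", 10)
        assert report.intact_fraction == pytest.approx(0.10)

    def test_identical_sequence_is_intact(self):
        report = pseudogene_caller.detect_disruptions("g", ENGINEERED_CDS, ENGINEERED_CDS)
        assert report.verdict == "intact"

    def test_start_and_stop_loss(self):
        no_start = "CTG" + ENGINEERED_CDS[3:]
        kinds = {
            e.kind
            for e in pseudogene_caller.detect_disruptions("g", ENGINEERED_CDS, no_start).events
        }
        assert kinds == {"start_loss"}
        no_stop = ENGINEERED_CDS[:-3] + "GCT"
        kinds = {
            e.kind
            for e in pseudogene_caller.detect_disruptions("g", ENGINEERED_CDS, no_stop).events
        }
        assert kinds == {"stop_loss"}

    def test_compensating_indels_restore_frame(self):
        """A +1 insertion cancelled by a -1 deletion leaves no shifted tail."""
        orth = "-" + ENGINEERED_CDS
        focal = "A" + ENGINEERED_CDS[:90] + "-" + ENGINEERED_CDS[91:]
        report = pseudogene_caller.detect_disruptions("g", orth, focal)
        frameshifts = [e for e in report.events if e.kind == "frameshift_indel"]
        assert len(frameshifts) == 2  # each 1-nt indel is its own event
        stops = [e.position for e in report.events if e.kind == "premature_stop"]
        # frame restored downstream of the deletion: no spurious stops
        assert stops == oracle_stop_positions(focal) == []

    def test_ortholog_with_internal_stop_rejected(self):
        bad = ENGINEERED_CDS[:30] + "TGA" + ENGINEERED_CDS[33:]
        with pytest.raises(ValueError, match="internal stop"):
            pseudogene_caller.detect_disruptions("g", bad, bad)

    def test_reverse_strand_gene_reports_identically(self):
        """Strand handling lives in CDS extraction; reports must match."""
        cds = ENGINEERED_CDS
        rc = str(Seq(cds).reverse_complement())
        genome_plus = {"chr1": "CC" + cds + "GG"}
        genome_minus = {"chr1": "CC" + rc + "GG"}
        gene_plus = make_gene("g", strand="+", intervals=((2, 2 + len(cds)),))
        gene_minus = make_gene("g", strand="-", intervals=((2, 2 + len(cds)),))
        extracted_plus = io_formats.extract_cds(genome_plus, gene_plus)
        extracted_minus = io_formats.extract_cds(genome_minus, gene_minus)
        assert extracted_plus == extracted_minus == cds
        focal = cds[:27] + "TAA" + cds[30:]
        rep_plus = pseudogene_caller.detect_disruptions("g", extracted_plus, focal)
        rep_minus = pseudogene_caller.detect_disruptions("g", extracted_minus, focal)
        assert rep_plus == rep_minus
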