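"""Screen for de novo-originated genes.

A focal-genome gene is a de novo candidate when (i) its locus is
depth-absent (>50% of coding sites with depth < 10) in every
reference-species individual mapped onto the focal genome, (ii) no
outgroup genome covers 40% or more of its CDS by local homology,
(iii) it is expressed somewhere (max tissue TPM >= 1), and (iv) its ORF
is complete (start codon through stop codon).

The four filters are independent predicates; the candidate set does not
depend on their order. The canonical order (depth -> homology ->
expression -> ORF) only determines which failure is reported as the
primary rejection reason.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import DeNovoCall, DepthTrack, GeneModel
from .pseudogene_caller import START_CODON, STOP_CODONS

DEFAULT_DELETION_DEPTH = 10
DEFAULT_MIN_DELETION_FRACTION = 0.50
DEFAULT_MAX_HOMOLOGY_FRACTION = 0.40
DEFAULT_MIN_TPM = 1.0

FILTER_ORDER = ("depth_absence", "homology", "expression", "orf")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def flag_deletion_loci(
    track: DepthTrack, gene: GeneModel, deletion_depth: int = DEFAULT_DELETION_DEPTH
) -> np.ndarray:
    """Boolean mask over a gene's coding sites: True where depth < threshold."""
    return track.gene_depths(gene) < deletion_depth


def deletion_fractions(
    tracks: Sequence[DepthTrack],
    genes: Sequence[GeneModel],
    deletion_depth: int = DEFAULT_DELETION_DEPTH,
) -> dict[str, dict[str, float]]:
    """gene -> individual -> fraction of coding sites flagged as deleted."""
    out: dict[str, dict[str, float]] = {}
    for gene in genes:
        out[gene.gene_id] = {
            t.individual_id: float(flag_deletion_loci(t, gene, deletion_depth).mean())
            for t in tracks
        }
    return out


def call_candidate_novel_genes(
    fractions: Mapping[str, Mapping[str, float]],
    min_deletion_fraction: float = DEFAULT_MIN_DELETION_FRACTION,
) -> list[str]:
    """Genes depth-absent (fraction strictly > threshold) in every individual."""
    return sorted(
        gene_id
        for gene_id, per_ind in fractions.items()
        if per_ind and all(f > min_deletion_fraction for f in per_ind.values())
    )


# ---------------------------------------------------------------------------
# Homology fraction


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def homology_fraction(cds: str, target_genome: Mapping[str, str] | str, k: int = 15) -> float:
    """Fraction of CDS positions covered by exact k-mer matches to a genome.

    A lightweight stand-in for a local aligner: every CDS k-mer found in the
    target (either strand) marks its k positions as covered; the fraction is
    the covered union over the CDS length. Exact copies score ~1, unrelated
    sequence ~0. Real-data hit tables can be supplied instead via
    :func:`homology_fraction_from_hits`.
    """
    if not cds:
        raise ValueError("empty CDS")
    cds = cds.upper()
    if len(cds) < k:
        return 0.0
    if isinstance(target_genome, str):
        target_genome = {"seq": target_genome}
    target_kmers: set[str] = set()
    for seq in target_genome.values():
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            target_kmers.add(seq[i : i + k])
    covered = np.zeros(len(cds), dtype=bool)
    rc = _revcomp(cds)
    for i in range(len(cds) - k + 1):
        if cds[i : i + k] in target_kmers:
            covered[i : i + k] = True
    for i in range(len(rc) - k + 1):
        if rc[i : i + k] in target_kmers:
            j = len(cds) - (i + k)
            covered[j : j + k] = True
    return float(covered.mean())


def homology_fraction_from_hits(hits: pd.DataFrame, gene_id: str, cds_length: int) -> float:
    """Coverage from an imported hit table (query, target, qstart, qend, identity).

    qstart/qend are 1-based inclusive on the query CDS.
    """
    covered = np.zeros(cds_length, dtype=bool)
    sub = hits[hits["query"] == gene_id]
    for _, row in sub.iterrows():
        covered[int(row["qstart"]) - 1 : int(row["qend"])] = True
    return float(covered.mean())


def filter_by_homology_fraction(
    cds: str,
    outgroup_genomes: Mapping[str, Mapping[str, str] | str],
    max_fraction: float = DEFAULT_MAX_HOMOLOGY_FRACTION,
    k: int = 15,
) -> tuple[float, bool]:
    """Max homology fraction across outgroups and whether it passes (< 0.4)."""
    best = max(
        (homology_fraction(cds, genome, k=k) for genome in outgroup_genomes.values()),
        default=0.0,
    )
    return best, best < max_fraction


# ---------------------------------------------------------------------------
# Expression and ORF completeness


def orf_complete(cds: str) -> bool:
    cds = cds.upper()
    return (
        len(cds) >= 6
        and len(cds) % 3 == 0
        and cds[:3] == START_CODON
        and cds[-3:] in STOP_CODONS
    )


def filter_by_expression_and_orf(
    gene_id: str,
    tpm: pd.DataFrame,
    cds: str,
    min_tpm: float = DEFAULT_MIN_TPM,
) -> tuple[bool, str | None, float]:
    """(passed, rejection reason, max TPM) for the expression + ORF filters."""
    if gene_id not in tpm.index:
        return False, "no_expression_data", float("nan")
    max_tpm = float(tpm.loc[gene_id].max())
    if max_tpm < min_tpm:
        return False, "low_expression", max_tpm
    if not orf_complete(cds):
        return False, "incomplete_orf", max_tpm
    return True, None, max_tpm


# ---------------------------------------------------------------------------
# Full screen


def screen_de_novo(
    genes: Sequence[GeneModel],
    reference_tracks: Sequence[DepthTrack],
    cds_sequences: Mapping[str, str],
    outgroup_genomes: Mapping[str, Mapping[str, str] | str],
    tpm: pd.DataFrame,
    deletion_depth: int = DEFAULT_DELETION_DEPTH,
    min_deletion_fraction: float = DEFAULT_MIN_DELETION_FRACTION,
    max_homology_fraction: float = DEFAULT_MAX_HOMOLOGY_FRACTION,
    min_tpm: float = DEFAULT_MIN_TPM,
    k: int = 15,
) -> list[DeNovoCall]:
    """Apply all four filters to every gene and report the predicate vector."""
    fractions = deletion_fractions(reference_tracks, genes, deletion_depth)
    calls: list[DeNovoCall] = []
    for gene in sorted(genes, key=lambda g: g.gene_id):
        per_ind = fractions[gene.gene_id]
        cds = cds_sequences[gene.gene_id]
        depth_pass = bool(per_ind) and all(
            f > min_deletion_fraction for f in per_ind.values()
        )
        hom_frac, hom_pass = filter_by_homology_fraction(
            cds, outgroup_genomes, max_homology_fraction, k=k
        )
        if gene.gene_id in tpm.index:
            max_tpm = float(tpm.loc[gene.gene_id].max())
            expr_pass = max_tpm >= min_tpm
        else:
            max_tpm = float("nan")
            expr_pass = False
        orf_pass = orf_complete(cds)
        passed = {
            "depth_absence": depth_pass,
            "homology": hom_pass,
            "expression": expr_pass,
            "orf": orf_pass,
        }
        if all(passed.values()):
            status, reason = "candidate", None
        else:
            status = "rejected"
            reason = next(name for name in FILTER_ORDER if not passed[name])
            if reason == "expression" and gene.gene_id not in tpm.index:
                reason = "no_expression_data"
            elif reason == "expression":
                reason = "low_expression"
            elif reason == "orf":
                reason = "incomplete_orf"
        calls.append(
            DeNovoCall(
                gene_id=gene.gene_id,
                deletion_fractions=per_ind,
                max_homology_fraction=hom_frac,
                max_tpm=max_tpm,
                orf_complete=orf_pass,
                passed=passed,
                status=status,
                reason=reason,
            )
        )
    return calls


def de_novo_table(calls: Sequence[DeNovoCall]):
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "min_deletion_fraction": [
                min(c.deletion_fractions.values()) if c.deletion_fractions else float("nan")
                for c in calls
            ],
            "max_homology_fraction": [c.max_homology_fraction for c in calls],
            "max_tpm": [c.max_tpm for c in calls],
            "orf_complete": [c.orf_complete for c in calls],
            "status": [c.status for c in calls],
            "reason": [c.reason or "" for c in calls],
        }
    )
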