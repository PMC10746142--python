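"""Unitary pseudogene detection.

Two stages mirror how decayed genes are recognized: (1) the locus must be
present in the cross-species alignment for the intact reference lineage
(at least 70% of the coding sequence aligned) while (largely) absent for
the focal lineage; (2) the focal coding sequence, read through a pairwise
alignment against an intact ortholog, must carry open-reading-frame
disruptions — premature stop codons, frameshifting indels, loss of the
start or the stop.

Frameshift state is tracked as the cumulative indel phase along the
alignment walk, so a pair of compensating indels that restores the frame
does not leave a shifted tail.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import GAP, MafBlock
from .models import DisruptionEvent, DisruptionReport, GeneModel

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"

DEFAULT_REFERENCE_MIN_COVERAGE = 0.70
DEFAULT_FOCAL_MAX_COVERAGE = 0.30


# ---------------------------------------------------------------------------
# Alignment coverage


def alignment_coverage(
    blocks: Sequence[MafBlock],
    gene: GeneModel,
    species: str,
    coord_species: str,
) -> float:
    """Fraction of a gene's CDS covered by non-gap columns of ``species``.

    ``coord_species`` is the species on whose genome the gene is annotated;
    its rows define the genome coordinates of each alignment column. A gene
    on an unaligned contig simply has coverage 0.
    """
    cds_positions: set[int] = set()
    for start, end in gene.cds_intervals:
        cds_positions.update(range(start, end))
    covered: set[int] = set()
    for block in blocks:
        anchor = None
        for row in block.rows:
            if row.species == coord_species and row.contig == gene.contig:
                anchor = row
                break
        if anchor is None:
            continue
        other = block.row_for(species)
        if other is None:
            continue
        pos = anchor.start
        for col, char in enumerate(anchor.text):
            if char == GAP:
                continue
            genome_pos = (
                pos if anchor.strand == "+" else anchor.src_size - 1 - pos
            )
            if genome_pos in cds_positions and other.text[col] != GAP:
                covered.add(genome_pos)
            pos += 1
    return len(covered) / gene.cds_length


def alignment_coverage_pairwise(rows: Mapping[str, str], ref_name: str, species: str) -> float:
    """Coverage from a per-gene aligned FASTA: fraction of the reference
    row's non-gap columns at which ``species`` is also non-gap."""
    ref = rows[ref_name]
    other = rows.get(species)
    ref_len = sum(1 for c in ref if c != GAP)
    if ref_len == 0:
        raise ValueError(f"{ref_name}: reference row is all gaps")
    if other is None:
        return 0.0
    covered = sum(1 for r, o in zip(ref, other) if r != GAP and o != GAP)
    return covered / ref_len


def call_unitary_candidates(
    coverages: Mapping[str, Mapping[str, float]],
    reference_species: Sequence[str],
    focal_species: str,
    reference_min_coverage: float = DEFAULT_REFERENCE_MIN_COVERAGE,
    focal_max_coverage: float = DEFAULT_FOCAL_MAX_COVERAGE,
) -> list[str]:
    """Genes whose locus aligns for a reference species but not for the focal.

    ``coverages`` maps gene -> species -> CDS coverage fraction. The gate is
    coverage >= ``reference_min_coverage`` for at least one reference species
    and <= ``focal_max_coverage`` for the focal species.
    """
    candidates = []
    for gene_id in sorted(coverages):
        cov = coverages[gene_id]
        ref_ok = any(cov.get(sp, 0.0) >= reference_min_coverage for sp in reference_species)
        focal_absent = cov.get(focal_species, 0.0) <= focal_max_coverage
        if ref_ok and focal_absent:
            candidates.append(gene_id)
    return candidates


# ---------------------------------------------------------------------------
# ORF disruption detection


def _ungap(seq: str) -> str:
    return seq.replace(GAP, "")


def detect_disruptions(
    gene_id: str,
    ortholog_row: str,
    focal_row: str,
) -> DisruptionReport:
    """Annotate ORF disruptions in a focal CDS aligned to an intact ortholog.

    Both rows are gapped nucleotide sequences of equal length; the ortholog
    must be a complete CDS (length divisible by 3, no internal stop codon).
    Events: maximal indel runs whose length is not a multiple of 3
    (``frameshift_indel``), internal stop codons in the focal reading frame
    (``premature_stop``, 1-based codon position), ``start_loss`` and
    ``stop_loss``. Verdict is ``pseudogene_candidate`` iff any event exists.
    """
    if len(ortholog_row) != len(focal_row):
        raise ValueError(f"{gene_id}: aligned rows differ in length")
    orth = _ungap(ortholog_row).upper()
    focal = _ungap(focal_row).upper()
    if len(orth) % 3 != 0:
        raise ValueError(f"{gene_id}: ortholog CDS length {len(orth)} not divisible by 3")
    n_codons = len(orth) // 3
    for i in range(0, len(orth) - 3, 3):
        if orth[i : i + 3] in STOP_CODONS:
            raise ValueError(
                f"{gene_id}: intact ortholog carries an internal stop at codon {i // 3 + 1}"
            )

    events: list[DisruptionEvent] = []

    # --- indel runs along the alignment walk
    orth_consumed = 0  # ortholog bases seen so far (CDS nt coordinate)
    col = 0
    width = len(ortholog_row)
    orow, frow = ortholog_row.upper(), focal_row.upper()
    while col < width:
        o_gap = orow[col] == GAP
        f_gap = frow[col] == GAP
        if o_gap == f_gap:  # match column or double gap
            if not o_gap:
                orth_consumed += 1
            col += 1
            continue
        run_start_nt = orth_consumed + 1  # 1-based ortholog CDS position
        run_len = 0
        kind_is_deletion = f_gap
        while col < width and (orow[col] == GAP) != (frow[col] == GAP) and (
            (frow[col] == GAP) == kind_is_deletion
        ):
            if orow[col] != GAP:
                orth_consumed += 1
            run_len += 1
            col += 1
        if run_len % 3 != 0:
            events.append(
                DisruptionEvent(kind="frameshift_indel", position=run_start_nt, length=run_len)
            )

    # --- start / internal stops / terminal stop, on the focal sequence itself
    if len(focal) >= 3 and focal[:3] != START_CODON:
        events.append(DisruptionEvent(kind="start_loss", position=1, length=3))
    n_focal_codons = len(focal) // 3
    for i in range(n_focal_codons):
        codon = focal[3 * i : 3 * i + 3]
        if codon in STOP_CODONS and i < n_focal_codons - 1:
            events.append(
                DisruptionEvent(kind="premature_stop", position=i + 1, length=3)
            )
    if len(focal) % 3 == 0 and n_focal_codons > 0:
        if focal[-3:] not in STOP_CODONS and orth[-3:] in STOP_CODONS:
            events.append(
                DisruptionEvent(kind="stop_loss", position=n_focal_codons, length=3)
            )

    if events:
        first_codon = min(_event_codon(e) for e in events)
        intact = min(1.0, max(0.0, first_codon / n_codons))
        verdict = "pseudogene_candidate"
    else:
        intact = 1.0
        verdict = "intact"
    return DisruptionReport(
        gene_id=gene_id,
        events=tuple(sorted(events, key=_event_codon)),
        intact_fraction=intact,
        verdict=verdict,
    )


def _event_codon(event: DisruptionEvent) -> int:
    if event.kind == "frameshift_indel":
        return (event.position + 2) // 3  # nt position -> codon, 1-based
    return event.position


def disruption_table(reports: Sequence[DisruptionReport]):
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in reports],
            "events": [
                ";".join(f"{e.kind}:{e.position}:{e.length}" for e in r.events)
                for r in reports
            ],
            "intact_fraction": [r.intact_fraction for r in reports],
            "verdict": [r.verdict for r in reports],
        }
    )
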