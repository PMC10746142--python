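"""High-copy sites (HCS), candidate duplications, and copy-number estimates.

A coding site is an HCS when the mean (library-size normalized) depth of
the focal individuals exceeds 1.5x the mean of the reference individuals.
Genes with HCS over at least 50% of their coding length are candidate
duplications, and the integer copy number is the reference copy count
scaled by the gene-level depth ratio.

Normalizing per-individual depths by each individual's coding mean before
the 1.5x comparison makes the calls invariant to sequencing depth
differences between libraries; the raw-average comparison used on matched
~30x cohorts is available with ``normalize=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .depth_profiles import individual_mean_depth
from .models import FOCAL, REFERENCE, DepthTrack, DuplicationCall, GeneModel

DEFAULT_RATIO = 1.5
DEFAULT_MIN_HCS_FRACTION = 0.50


@dataclass(frozen=True)
class GeneDepthComparison:
    """Per-gene site-level focal vs reference depth comparison."""

    gene_id: str
    hcs_mask: np.ndarray  # True where focal mean > ratio * reference mean
    excluded_mask: np.ndarray  # reference mean == 0 at these sites
    mean_depth_ratio: float  # gene-level focal/reference mean depth ratio


def call_hcs(
    tracks: Sequence[DepthTrack],
    genes: Sequence[GeneModel],
    ratio: float = DEFAULT_RATIO,
    normalize: bool = True,
) -> dict[str, GeneDepthComparison]:
    """Site-level HCS masks and gene-level depth ratios for every gene.

    Sites where the reference mean depth is zero cannot enter the ratio
    rule; they are excluded from the HCS mask and counted separately.
    """
    focal = [t for t in tracks if t.species_label == FOCAL]
    reference = [t for t in tracks if t.species_label == REFERENCE]
    if not focal or not reference:
        raise ValueError("need at least one focal and one reference individual")

    scale: dict[str, float] = {}
    for track in focal + reference:
        scale[track.individual_id] = (
            individual_mean_depth(track, genes) if normalize else 1.0
        )
        if scale[track.individual_id] == 0:
            raise ValueError(f"{track.individual_id}: zero mean depth")

    out: dict[str, GeneDepthComparison] = {}
    for gene in genes:
        focal_mean = np.mean(
            [t.gene_depths(gene) / scale[t.individual_id] for t in focal], axis=0
        )
        ref_mean = np.mean(
            [t.gene_depths(gene) / scale[t.individual_id] for t in reference], axis=0
        )
        excluded = ref_mean == 0
        hcs = ~excluded & (focal_mean > ratio * ref_mean)
        ref_total = float(ref_mean.sum())
        gene_ratio = float(focal_mean.sum()) / ref_total if ref_total > 0 else math.inf
        out[gene.gene_id] = GeneDepthComparison(
            gene_id=gene.gene_id,
            hcs_mask=hcs,
            excluded_mask=excluded,
            mean_depth_ratio=gene_ratio,
        )
    return out


def estimate_copy_number(mean_depth_ratio: float, reference_copies: int) -> int:
    """round(reference_copies * ratio), half away from zero, floored at 1."""
    if reference_copies < 1:
        raise ValueError("reference_copies must be >= 1")
    if not math.isfinite(mean_depth_ratio):
        raise ValueError("depth ratio is not finite; cannot estimate copy number")
    return max(1, int(math.floor(reference_copies * mean_depth_ratio + 0.5)))


def call_duplications(
    comparisons: Mapping[str, GeneDepthComparison],
    genes: Sequence[GeneModel],
    min_hcs_fraction: float = DEFAULT_MIN_HCS_FRACTION,
    reference_copies: Mapping[str, int] | int = 1,
) -> list[DuplicationCall]:
    """Candidate duplication calls, ordered by descending depth ratio.

    ``reference_copies`` is the known copy number in the reference lineage,
    either one integer for all genes or a per-gene mapping (default 1).
    """
    by_gene = {g.gene_id: g for g in genes}
    calls: list[DuplicationCall] = []
    for gene_id in sorted(comparisons):
        comp = comparisons[gene_id]
        gene = by_gene[gene_id]
        n_hcs = int(comp.hcs_mask.sum())
        fraction = n_hcs / gene.cds_length
        ref_copies = (
            reference_copies if isinstance(reference_copies, int)
            else reference_copies.get(gene_id, 1)
        )
        est = (
            estimate_copy_number(comp.mean_depth_ratio, ref_copies)
            if math.isfinite(comp.mean_depth_ratio)
            else ref_copies
        )
        calls.append(
            DuplicationCall(
                gene_id=gene_id,
                cds_length=gene.cds_length,
                n_hcs_sites=n_hcs,
                n_excluded_sites=int(comp.excluded_mask.sum()),
                hcs_fraction=fraction,
                mean_depth_ratio=comp.mean_depth_ratio,
                reference_copies=ref_copies,
                estimated_copies=est,
                status=(
                    "candidate_duplication" if fraction >= min_hcs_fraction else "neutral"
                ),
            )
        )
    calls.sort(key=lambda c: (-c.mean_depth_ratio, c.gene_id))
    return calls


def duplications_table(calls: list[DuplicationCall]):
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "hcs_fraction": [c.hcs_fraction for c in calls],
            "mean_ratio": [c.mean_depth_ratio for c in calls],
            "reference_copies": [c.reference_copies for c in calls],
            "estimated_copies": [c.estimated_copies for c in calls],
            "status": [c.status for c in calls],
        }
    )
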