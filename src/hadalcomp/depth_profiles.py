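"""Per-site depth classification over coding regions.

Each coding site of each individual is classified as HIGH (depth greater
than half that individual's mean coding depth), LOW (depth below 3 reads),
or MID (everything else). When the mean is below 6 a site can satisfy both
rules; LOW takes precedence, because absence of reads is the stronger
signal for the loss caller downstream.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np

from .models import FOCAL, HIGH, LOW, MID, REFERENCE, DepthTrack, GeneModel, SiteClassMatrix

logger = logging.getLogger(__name__)

DEFAULT_LOW_DEPTH = 3.0
DEFAULT_HIGH_FRACTION = 0.5


def individual_mean_depth(track: DepthTrack, genes: Sequence[GeneModel]) -> float:
    """Arithmetic mean depth over all annotated coding sites of one individual."""
    total = 0
    n_sites = 0
    for gene in genes:
        d = track.gene_depths(gene)
        total += int(d.sum())
        n_sites += d.size
    if n_sites == 0:
        raise ValueError(f"{track.individual_id}: no coding sites to average over")
    return total / n_sites


def classify_depths(
    depths: np.ndarray,
    mean_depth: float,
    low_depth: float = DEFAULT_LOW_DEPTH,
    high_fraction: float = DEFAULT_HIGH_FRACTION,
) -> np.ndarray:
    """Vectorized HIGH/MID/LOW codes for one individual's site depths."""
    cls = np.full(depths.shape, MID, dtype=np.int8)
    cls[depths > high_fraction * mean_depth] = HIGH
    cls[depths < low_depth] = LOW  # LOW wins where both rules apply
    return cls


def classify_sites(
    tracks: Sequence[DepthTrack],
    genes: Sequence[GeneModel],
    low_depth: float = DEFAULT_LOW_DEPTH,
    high_fraction: float = DEFAULT_HIGH_FRACTION,
) -> SiteClassMatrix:
    """Classify every coding site of every individual.

    Individuals whose coding mean depth is 0 carry no information and are
    excluded with a warning.
    """
    usable: list[DepthTrack] = []
    means: dict[str, float] = {}
    for track in tracks:
        mean = individual_mean_depth(track, genes)
        if mean == 0:
            logger.warning(
                "individual %s has zero mean coding depth; excluded from classification",
                track.individual_id,
            )
            continue
        usable.append(track)
        means[track.individual_id] = mean
    if not usable:
        raise ValueError("no usable individuals (all zero mean depth)")

    individuals = [t.individual_id for t in usable]
    species = {t.individual_id: t.species_label for t in usable}
    classes: dict[str, np.ndarray] = {}
    for gene in genes:
        mat = np.empty((gene.cds_length, len(usable)), dtype=np.int8)
        for j, track in enumerate(usable):
            mat[:, j] = classify_depths(
                track.gene_depths(gene), means[track.individual_id], low_depth, high_fraction
            )
        classes[gene.gene_id] = mat
    return SiteClassMatrix(
        individuals=individuals,
        species=species,
        mean_depth=means,
        classes=classes,
        genes={g.gene_id: g for g in genes},
    )


def normalized_gene_depth(
    track: DepthTrack, gene: GeneModel, mean_depth: float | None = None,
    genes: Sequence[GeneModel] | None = None,
) -> float:
    """Mean coding depth of one gene divided by the individual's overall mean.

    Pass either a precomputed ``mean_depth`` or the full gene set to compute
    it. Cancels library-size differences between individuals.
    """
    if mean_depth is None:
        if genes is None:
            raise ValueError("need mean_depth or the gene set to compute it")
        mean_depth = individual_mean_depth(track, genes)
    if mean_depth == 0:
        raise ValueError(f"{track.individual_id}: zero mean depth, ratio undefined")
    return float(track.gene_depths(gene).mean()) / mean_depth


def normalized_site_depths(
    track: DepthTrack, gene: GeneModel, mean_depth: float
) -> np.ndarray:
    """Per-site depths of a gene scaled by the individual's coding mean."""
    if mean_depth == 0:
        raise ValueError(f"{track.individual_id}: zero mean depth, ratio undefined")
    return track.gene_depths(gene).astype(float) / mean_depth
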