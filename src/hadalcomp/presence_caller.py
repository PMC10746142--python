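"""Species-specific lost sites (SLS) and candidate gene-loss calling.

A coding site is an SLS when it is HIGH in the reference-species
individuals and LOW in the focal-species individuals. Genes whose SLS
sites cover at least 40% of the coding length are candidate losses.
The all-individuals quantifier is the default; a fraction-based
relaxation is available for noisy cohorts.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .models import FOCAL, HIGH, LOW, REFERENCE, LossCall, SiteClassMatrix

DEFAULT_MIN_SLS_FRACTION = 0.40


def call_sls(
    matrix: SiteClassMatrix,
    min_reference_high: float = 1.0,
    min_focal_low: float = 1.0,
) -> dict[str, np.ndarray]:
    """Boolean SLS mask per gene.

    ``min_reference_high`` / ``min_focal_low`` are the fractions of
    individuals that must show HIGH (reference) and LOW (focal) for a site
    to qualify; 1.0 means every individual (the default, strict rule).
    """
    ref_cols = matrix.columns(REFERENCE)
    focal_cols = matrix.columns(FOCAL)
    if ref_cols.size == 0:
        raise ValueError("no reference individuals in the site-class matrix")
    if focal_cols.size == 0:
        raise ValueError("no focal individuals in the site-class matrix")
    masks: dict[str, np.ndarray] = {}
    for gene_id, cls in matrix.classes.items():
        ref_high = (cls[:, ref_cols] == HIGH).mean(axis=1)
        focal_low = (cls[:, focal_cols] == LOW).mean(axis=1)
        masks[gene_id] = (ref_high >= min_reference_high) & (focal_low >= min_focal_low)
    return masks


def call_gene_losses(
    sls_masks: Mapping[str, np.ndarray],
    matrix: SiteClassMatrix,
    min_sls_fraction: float = DEFAULT_MIN_SLS_FRACTION,
) -> list[LossCall]:
    """Candidate loss calls, sorted by descending SLS fraction then gene id."""
    focal_cols = matrix.columns(FOCAL)
    calls: list[LossCall] = []
    for gene_id in sorted(sls_masks):
        mask = sls_masks[gene_id]
        gene = matrix.genes[gene_id]
        n_sls = int(mask.sum())
        fraction = n_sls / gene.cds_length
        cls = matrix.classes[gene_id]
        per_ind = {
            matrix.individuals[j]: float((cls[:, j] == LOW).mean()) for j in focal_cols
        }
        calls.append(
            LossCall(
                gene_id=gene_id,
                cds_length=gene.cds_length,
                n_sls_sites=n_sls,
                sls_fraction=fraction,
                per_individual_low_fraction=per_ind,
                status="candidate_loss" if fraction >= min_sls_fraction else "retained",
            )
        )
    calls.sort(key=lambda c: (-c.sls_fraction, c.gene_id))
    return calls


def losses_table(calls: list[LossCall]):
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "cds_length": [c.cds_length for c in calls],
            "n_sls": [c.n_sls_sites for c in calls],
            "sls_fraction": [c.sls_fraction for c in calls],
            "status": [c.status for c in calls],
        }
    )
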