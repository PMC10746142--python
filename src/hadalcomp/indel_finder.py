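"""Scan protein alignments for focal-lineage-specific variant regions.

A column is *specific* when every non-focal row carries the same character
and the focal row differs from it (a different residue, or a gap on one
side only). Maximal runs of specific columns at least ``min_length``
residues long are reported, classified by their gap pattern (deletion:
focal gapped; insertion: non-focal gapped; otherwise a substitution run),
and kept only when the 5-column windows on both sides are conserved
(mean pairwise identity >= 90%). Windows truncated by the alignment edge
fail the flank check, so regions hanging off alignment ends are never
reported.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .io_formats import GAP
from .models import IndelRegion

DEFAULT_MIN_LENGTH = 3
DEFAULT_FLANK = 5
DEFAULT_FLANK_IDENTITY = 0.90
DEFAULT_MIN_SPECIES = 4


def _alignment_matrix(msa: Mapping[str, str], order: Sequence[str]) -> np.ndarray:
    widths = {len(msa[name]) for name in order}
    if len(widths) != 1:
        raise ValueError(f"ragged alignment (row lengths {sorted(widths)})")
    return np.array([list(msa[name]) for name in order])


def mean_pairwise_identity(window: np.ndarray) -> float:
    """Mean over all row pairs and columns of the character-match indicator."""
    n_rows = window.shape[0]
    matches = 0
    pairs = 0
    for i in range(n_rows):
        for j in range(i + 1, n_rows):
            matches += int((window[i] == window[j]).sum())
            pairs += window.shape[1]
    return matches / pairs if pairs else 1.0


def validate_flanks(
    start_col: int,
    end_col: int,
    msa: Mapping[str, str],
    flank: int = DEFAULT_FLANK,
    min_identity: float = DEFAULT_FLANK_IDENTITY,
    include_focal: bool = True,
    focal_species: str | None = None,
) -> tuple[bool, float, float]:
    """Check the flank-conservation rule for a candidate region.

    Returns (ok, left identity, right identity). A flank shorter than
    ``flank`` columns (region at the alignment edge) fails. With
    ``include_focal=False`` the focal row is left out of the identity
    computation (requires ``focal_species``).
    """
    names = sorted(msa)
    if not include_focal:
        if focal_species is None:
            raise ValueError("focal_species required when include_focal=False")
        names = [n for n in names if n != focal_species]
    mat = _alignment_matrix(msa, names)
    width = mat.shape[1]
    if start_col - flank < 0 or end_col + flank > width:
        return False, 0.0, 0.0
    left = mean_pairwise_identity(mat[:, start_col - flank : start_col])
    right = mean_pairwise_identity(mat[:, end_col : end_col + flank])
    return (left >= min_identity and right >= min_identity), left, right


def find_lineage_specific_regions(
    gene_id: str,
    msa: Mapping[str, str],
    focal_species: str,
    min_length: int = DEFAULT_MIN_LENGTH,
    strict_greater: bool = False,
    flank: int = DEFAULT_FLANK,
    flank_identity: float = DEFAULT_FLANK_IDENTITY,
    min_species: int = DEFAULT_MIN_SPECIES,
    include_focal_in_flanks: bool = True,
    focal_individual_rows: Mapping[str, str] | None = None,
) -> list[IndelRegion]:
    """Maximal focal-specific runs with conserved flanks.

    ``min_length`` is in residues, compared inclusively (>=) by default;
    ``strict_greater=True`` switches to a strict > rule. When
    ``focal_individual_rows`` (aligned sequences of individual focal
    animals) is given, each region's ``focal_consistent`` flag records
    whether all individuals agree with the focal row over the region.
    """
    if focal_species not in msa:
        raise ValueError(f"{gene_id}: focal species {focal_species!r} not in alignment")
    non_focal = sorted(n for n in msa if n != focal_species)
    if len(non_focal) < min_species:
        raise ValueError(
            f"{gene_id}: need >= {min_species} non-focal species, have {len(non_focal)}"
        )
    mat = _alignment_matrix(msa, non_focal)
    focal = np.array(list(msa[focal_species]))
    if focal.size != mat.shape[1]:
        raise ValueError(f"{gene_id}: ragged alignment")

    agree = (mat == mat[0]).all(axis=0)
    specific = agree & (focal != mat[0])

    regions: list[IndelRegion] = []
    width = specific.size
    col = 0
    while col < width:
        if not specific[col]:
            col += 1
            continue
        start = col
        while col < width and specific[col]:
            col += 1
        end = col
        length = end - start
        long_enough = length > min_length if strict_greater else length >= min_length
        if not long_enough:
            continue
        ok, left, right = validate_flanks(
            start,
            end,
            msa,
            flank=flank,
            min_identity=flank_identity,
            include_focal=include_focal_in_flanks,
            focal_species=focal_species,
        )
        if not ok:
            continue
        focal_slice = focal[start:end]
        other_slice = mat[0, start:end]
        if (focal_slice == GAP).all():
            kind = "deletion"
        elif (other_slice == GAP).all():
            kind = "insertion"
        else:
            kind = "substitution_run"
        consistent: bool | None = None
        if focal_individual_rows is not None:
            region_str = "".join(focal_slice)
            consistent = all(
                row[start:end] == region_str for row in focal_individual_rows.values()
            )
        regions.append(
            IndelRegion(
                gene_id=gene_id,
                start_col=start,
                end_col=end,
                length=length,
                kind=kind,
                flank_identity_left=left,
                flank_identity_right=right,
                focal_consistent=consistent,
            )
        )
    return regions


def regions_table(regions: Sequence[IndelRegion]):
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in regions],
            "start_col": [r.start_col for r in regions],
            "end_col": [r.end_col for r in regions],
            "length": [r.length for r in regions],
            "kind": [r.kind for r in regions],
            "flank_identity_left": [r.flank_identity_left for r in regions],
            "flank_identity_right": [r.flank_identity_right for r in regions],
        }
    )
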