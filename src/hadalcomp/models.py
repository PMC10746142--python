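"""Core domain types shared across the pipeline.

Coordinate convention: everything in memory is 0-based, half-open.
GFF3 (1-based inclusive) is converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

# Per-site depth classes. LOW must sort below MID below HIGH so that
# monotonicity in depth can be asserted on the integer codes.
LOW, MID, HIGH = 0, 1, 2
CLASS_NAMES = {LOW: "LOW", MID: "MID", HIGH: "HIGH"}

FOCAL = "focal"
REFERENCE = "reference"


@dataclass(frozen=True)
class GeneModel:
    """A gene's coding structure on one contig.

    ``cds_intervals`` are 0-based half-open, sorted, non-overlapping.
    For minus-strand genes the intervals are still in ascending genome
    order; strand only matters when extracting sequence.
    """

    gene_id: str
    contig: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.cds_intervals:
            raise ValueError(f"{self.gene_id}: gene has no CDS intervals")
        prev_end = -1
        for start, end in self.cds_intervals:
            if start >= end:
                raise ValueError(f"{self.gene_id}: empty/inverted CDS interval ({start}, {end})")
            if start < prev_end:
                raise ValueError(f"{self.gene_id}: CDS intervals overlap or are unsorted")
            prev_end = end

    @property
    def cds_length(self) -> int:
        return sum(end - start for start, end in self.cds_intervals)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]

    def coding_positions(self) -> np.ndarray:
        """All coding genome positions, ascending (strand-independent)."""
        return np.concatenate(
            [np.arange(start, end) for start, end in self.cds_intervals]
        )


@dataclass
class DepthTrack:
    """Per-site read depth for one sequenced individual.

    ``depths`` maps contig -> dense int array starting at position 0;
    positions beyond the array (or absent from the input file) are depth 0.
    """

    individual_id: str
    species_label: str  # FOCAL or REFERENCE
    depths: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.species_label not in (FOCAL, REFERENCE):
            raise ValueError(
                f"species_label must be {FOCAL!r} or {REFERENCE!r}, got {self.species_label!r}"
            )
        for contig, arr in self.depths.items():
            if arr.size and arr.min() < 0:
                raise ValueError(f"{self.individual_id}/{contig}: negative depth")

    def depth_at(self, contig: str, positions: np.ndarray) -> np.ndarray:
        """Depths at 0-based positions; absent contigs/positions are 0."""
        arr = self.depths.get(contig)
        if arr is None:
            return np.zeros(len(positions), dtype=np.int64)
        out = np.zeros(len(positions), dtype=np.int64)
        inside = positions < arr.size
        out[inside] = arr[positions[inside]]
        return out

    def gene_depths(self, gene: GeneModel) -> np.ndarray:
        return self.depth_at(gene.contig, gene.coding_positions())


@dataclass
class SiteClassMatrix:
    """HIGH/MID/LOW class per coding site per individual.

    ``classes[gene_id]`` has shape (cds_length, n_individuals), int8 codes
    from :data:`LOW`/:data:`MID`/:data:`HIGH`, columns ordered as
    ``individuals``.
    """

    individuals: list[str]
    species: dict[str, str]  # individual -> FOCAL | REFERENCE
    mean_depth: dict[str, float]
    classes: dict[str, np.ndarray]
    genes: dict[str, "GeneModel"]

    def columns(self, label: str) -> np.ndarray:
        """Column indices of individuals with the given species label."""
        return np.array(
            [i for i, ind in enumerate(self.individuals) if self.species[ind] == label],
            dtype=int,
        )

    def to_frame(self):
        """Tidy (gene, site, individual, class) table, mainly for export."""
        import pandas as pd

        records = []
        for gene_id in sorted(self.classes):
            cls = self.classes[gene_id]
            for j, ind in enumerate(self.individuals):
                records.append(
                    pd.DataFrame(
                        {
                            "gene_id": gene_id,
                            "site": np.arange(cls.shape[0]),
                            "individual": ind,
                            "class": [CLASS_NAMES[c] for c in cls[:, j]],
                        }
                    )
                )
        return pd.concat(records, ignore_index=True)


@dataclass(frozen=True)
class LossCall:
    gene_id: str
    cds_length: int
    n_sls_sites: int
    sls_fraction: float
    per_individual_low_fraction: Mapping[str, float]
    status: str  # "candidate_loss" | "retained"


@dataclass(frozen=True)
class DuplicationCall:
    gene_id: str
    cds_length: int
    n_hcs_sites: int
    n_excluded_sites: int  # reference normalized mean 0 at these sites
    hcs_fraction: float
    mean_depth_ratio: float
    reference_copies: int
    estimated_copies: int
    status: str  # "candidate_duplication" | "neutral"


@dataclass(frozen=True)
class DisruptionEvent:
    kind: str  # premature_stop | frameshift_indel | start_loss | stop_loss
    position: int  # 1-based codon index (stops) or CDS nt offset (indels)
    length: int


@dataclass(frozen=True)
class DisruptionReport:
    gene_id: str
    events: tuple[DisruptionEvent, ...]
    intact_fraction: float
    verdict: str  # "intact" | "pseudogene_candidate"


@dataclass(frozen=True)
class DeNovoCall:
    gene_id: str
    deletion_fractions: Mapping[str, float]  # per reference individual
    max_homology_fraction: float
    max_tpm: float
    orf_complete: bool
    passed: Mapping[str, bool]  # predicate vector keyed by filter name
    status: str  # "candidate" | "rejected"
    reason: str | None  # first failing filter in canonical order


@dataclass(frozen=True)
class IndelRegion:
    gene_id: str
    start_col: int  # 0-based, half-open alignment columns
    end_col: int
    length: int  # residues
    kind: str  # insertion | deletion | substitution_run
    flank_identity_left: float
    flank_identity_right: float
    focal_consistent: bool | None = None

    @property
    def columns(self) -> tuple[int, int]:
        return (self.start_col, self.end_col)


@dataclass(frozen=True)
class ConsistencyResult:
    direction: str  # "up" | "down"
    genes: tuple[str, ...]
    statistic: int
    p_value: float
    n_permutations: int
    per_tissue_counts: Mapping[str, int]
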