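"""Cross-tissue differential-expression consistency.

Per-tissue DE tables (gene, log2 fold-change, BH-adjusted p) are reduced
to ternary indicators (+1 up, -1 down, 0 not DE) at the |log2FC| >= 1,
adjusted p < 0.05 thresholds, intersected across tissues, and the
observed count of all-tissue-consistent genes is compared against a
column-permutation null. Permuting each tissue's indicator column
independently preserves every tissue's DE rate while destroying any
cross-organ dependence, so the test addresses exactly the question of
whether DE status in one organ is informative about DE status in another.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import ConsistencyResult

logger = logging.getLogger(__name__)

DEFAULT_LFC_THRESHOLD = 1.0
DEFAULT_P_THRESHOLD = 0.05

_DIRECTION_VALUE = {"up": 1, "down": -1}


def call_de(
    table: pd.DataFrame,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.Series:
    """Ternary DE indicator per gene from a (gene_id, log2fc, padj) table."""
    if lfc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    lfc = pd.to_numeric(table["log2fc"], errors="coerce")
    padj = pd.to_numeric(table["padj"], errors="coerce")
    missing = lfc.isna() | padj.isna()
    if missing.any():
        logger.warning("%d rows with missing DE values set to indicator 0", int(missing.sum()))
    sig = (padj < p_threshold) & ~missing
    indicator = np.zeros(len(table), dtype=np.int8)
    indicator[(lfc >= lfc_threshold) & sig] = 1
    indicator[(lfc <= -lfc_threshold) & sig] = -1
    return pd.Series(indicator, index=table["gene_id"].to_numpy(), name="indicator")


def indicator_matrix(indicators: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Gene x tissue indicator matrix; genes missing from a tissue are 0."""
    if any(len(s) == 0 for s in indicators.values()):
        empty = [t for t, s in indicators.items() if len(s) == 0]
        raise ValueError(f"tissue(s) with no genes: {empty}")
    df = pd.DataFrame(indicators).fillna(0).astype(np.int8)
    return df.sort_index()


def cross_tissue_consistent_genes(
    indicators: Mapping[str, pd.Series], direction: str = "up"
) -> list[str]:
    """Genes DE in the stated direction in every tissue (intersection)."""
    if direction not in _DIRECTION_VALUE:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if len(indicators) < 2:
        raise ValueError("need at least 2 tissues")
    mat = indicator_matrix(indicators)
    value = _DIRECTION_VALUE[direction]
    consistent = (mat == value).all(axis=1)
    return sorted(mat.index[consistent])


def independence_permutation_test(
    matrix: pd.DataFrame,
    direction: str = "up",
    n_permutations: int = 1000,
    seed: int = 0,
) -> ConsistencyResult:
    """Test cross-organ independence of DE status by column permutation.

    Statistic: the observed number of genes DE in ``direction`` in every
    tissue. Null: each tissue's indicator column permuted independently.
    One-sided p-value with add-one correction,
    ``p = (1 + #{null >= observed}) / (n_permutations + 1)``.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    value = _DIRECTION_VALUE[direction]
    hits = (matrix.to_numpy() == value)  # genes x tissues boolean
    n_genes, n_tissues = hits.shape
    observed = int(hits.all(axis=1).sum())
    per_tissue = {t: int(hits[:, j].sum()) for j, t in enumerate(matrix.columns)}

    if not hits.any():
        logger.warning("degenerate indicator matrix (no DE genes); p = 1")
        return ConsistencyResult(
            direction=direction,
            genes=tuple(sorted(matrix.index[hits.all(axis=1)])),
            statistic=observed,
            p_value=1.0,
            n_permutations=n_permutations,
            per_tissue_counts=per_tissue,
        )

    rng = np.random.default_rng(seed)
    acc = np.ones((n_permutations, n_genes), dtype=bool)
    for j in range(n_tissues):
        col = np.broadcast_to(hits[:, j], (n_permutations, n_genes))
        acc &= rng.permuted(col, axis=1)
    null_counts = acc.sum(axis=1)
    p = (1 + int((null_counts >= observed).sum())) / (n_permutations + 1)
    return ConsistencyResult(
        direction=direction,
        genes=tuple(sorted(matrix.index[hits.all(axis=1)])),
        statistic=observed,
        p_value=p,
        n_permutations=n_permutations,
        per_tissue_counts=per_tissue,
    )
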