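"""Normalization of expression matrices prior to feature selection.

Two normalizers for the two major assay families:

* **UMI downsampling** for count data: cells are filtered on minimum genes
  observed and minimum total UMI, then each surviving cell's transcript pool
  is sampled without replacement down to a common depth (default 95% of the
  total-UMI cutoff). Every cell ends at exactly the same sequencing depth,
  removing the order-of-magnitude depth differences that otherwise distort
  cell-cell distances.
* **Truncated quantile normalization** for full-length / TPM-like data: per
  cell, keep the top ``g`` expressed genes, shift the whole vector down by
  the (g+1)-th highest value (so the retained tail meets zero without an
  artificial gap), clamp at zero, and quantile-normalize the retained values
  across cells. After normalization every cell carries exactly ``g``
  positive genes with an identical multiset of values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DownsampleConfig",
    "TqnConfig",
    "downsample_cells",
    "truncated_quantile_normalize",
]

log = logging.getLogger(__name__)


@dataclass
class DownsampleConfig:
    """Cell filters and target depth for UMI downsampling.

    ``target_umi`` defaults to ``floor(0.95 * min_total_umi)`` — e.g. a
    3162-count cutoff gives a 3003-count target.
    """

    min_genes_observed: int = 0
    min_total_umi: int = 1
    target_umi: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_total_umi < 1:
            raise ValueError("min_total_umi must be at least 1")
        if self.target_umi is None:
            self.target_umi = int(np.floor(0.95 * self.min_total_umi))
        if self.target_umi < 1:
            raise ValueError("target_umi must be at least 1")
        if self.target_umi > self.min_total_umi:
            raise ValueError(
                f"target_umi ({self.target_umi}) exceeds min_total_umi "
                f"({self.min_total_umi}): filtered cells could not reach it"
            )


@dataclass
class TqnConfig:
    """Number of retained expressed genes per cell for truncated QN."""

    g: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g < 1:
            raise ValueError("g must be at least 1")


def downsample_cells(
    counts: np.ndarray, cfg: DownsampleConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Filter cells and downsample each to exactly ``cfg.target_umi`` counts.

    Parameters
    ----------
    counts
        Integer genes x cells matrix.
    cfg
        Filters, target depth and seed.

    Returns
    -------
    (downsampled, kept) where ``downsampled`` is genes x kept-cells with all
    column sums equal to ``cfg.target_umi`` and ``kept`` is the boolean mask
    of surviving input cells.

    Sampling is without replacement from the cell's expanded transcript pool
    (each UMI one element, gene identity repeated by its count), realized as
    a multivariate hypergeometric draw per cell — distributionally identical
    and far cheaper than materializing the pool.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integers")
        counts = counts.astype(np.int64)
    totals = counts.sum(axis=0)
    genes_observed = (counts > 0).sum(axis=0)
    fail_umi = totals < cfg.min_total_umi
    fail_genes = genes_observed < cfg.min_genes_observed
    kept = ~(fail_umi | fail_genes)
    log.info(
        "downsample_cells: %d/%d cells kept (%d failed total-UMI >= %d, "
        "%d failed genes-observed >= %d); target depth %d",
        int(kept.sum()), counts.shape[1], int(fail_umi.sum()),
        cfg.min_total_umi, int(fail_genes.sum()), cfg.min_genes_observed,
        cfg.target_umi,
    )
    if not kept.any():
        raise ValueError(
            f"no cell passed the filters ({int(fail_umi.sum())} below "
            f"min_total_umi={cfg.min_total_umi}, {int(fail_genes.sum())} below "
            f"min_genes_observed={cfg.min_genes_observed})"
        )
    sub = counts[:, kept]
    rng = np.random.default_rng(cfg.seed)
    out = np.empty_like(sub)
    sub_totals = totals[kept]
    for j in range(sub.shape[1]):
        if sub_totals[j] == cfg.target_umi:
            out[:, j] = sub[:, j]
        else:
            out[:, j] = rng.multivariate_hypergeometric(sub[:, j], cfg.target_umi)
    return out, kept


def truncated_quantile_normalize(
    expr: np.ndarray, cfg: TqnConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Truncate each cell to its top ``g`` genes and quantile-normalize them.

    Steps per cell: (1) cells with fewer than ``g + 1`` expressed (> 0) genes
    are removed; (2) the (g+1)-th highest expression value is subtracted from
    the whole cell vector and negatives clamped to zero, so exactly the top
    ``g`` genes stay positive with no artificial gap above zero; ties at the
    g-th expression level are broken uniformly at random (seeded) so the
    retained set has exactly size ``g``; (3) the retained values are quantile
    normalized across cells against the mean-of-sorted-vectors reference, so
    afterwards the multiset of positive values is identical in every cell.

    Returns ``(normalized, kept)`` with ``kept`` the surviving-cell mask.
    """
    expr = np.asarray(expr, dtype=np.float64)
    n_genes, _ = expr.shape
    if np.any(expr < 0):
        raise ValueError("expression values must be non-negative")
    if cfg.g >= n_genes:
        raise ValueError(f"g={cfg.g} must be smaller than n_genes={n_genes}")
    expressed = (expr > 0).sum(axis=0)
    kept = expressed >= cfg.g + 1
    log.info(
        "truncated_quantile_normalize: %d/%d cells kept (need >= %d expressed "
        "genes)", int(kept.sum()), expr.shape[1], cfg.g + 1,
    )
    if not kept.any():
        raise ValueError(
            f"no cell has at least {cfg.g + 1} expressed genes "
            f"({int((~kept).sum())} cells failed)"
        )
    sub = expr[:, kept]
    n_cells = sub.shape[1]
    rng = np.random.default_rng(cfg.seed)

    # per cell: pick the retained top-g set (boundary ties broken randomly)
    # and record the retained genes ordered ascending by (value, tiebreak).
    order_idx = np.empty((cfg.g, n_cells), dtype=np.int64)  # gene of rank r
    truncated = np.zeros_like(sub)
    for j in range(n_cells):
        col = sub[:, j]
        tiebreak = rng.random(n_genes)
        order = np.lexsort((tiebreak, -col))  # descending value, random in ties
        top = order[: cfg.g]
        gap_value = col[order[cfg.g]]  # (g+1)-th highest under the tiebreak
        vals = np.maximum(col[top] - gap_value, 0.0)
        truncated[top, j] = vals
        # ascending rank within the retained set: reverse of the descending order
        order_idx[:, j] = top[::-1]

    # quantile normalization of the retained values: reference distribution is
    # the mean of the per-cell ascending value vectors.
    sorted_vals = np.empty((cfg.g, n_cells))
    for j in range(n_cells):
        sorted_vals[:, j] = truncated[order_idx[:, j], j]
    reference = sorted_vals.mean(axis=1)
    out = np.zeros_like(sub)
    for j in range(n_cells):
        out[order_idx[:, j], j] = reference
    return out, kept
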