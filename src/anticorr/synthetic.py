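"""Synthetic scRNA-seq count matrices with known ground truth.

Two generative regimes are provided, mirroring the standard simulation
paradigms used to benchmark feature selection:

* a *null* single-population matrix — every gene i.i.d. negative-binomial
  across cells with a gene-specific mean drawn log-normally and a shared
  dispersion (a minimal Splatter-like null);
* a *clustered* matrix in which each cluster owns a block of marker genes
  whose negative-binomial mean is multiplied by an effect size inside the
  owning cluster and left at baseline elsewhere, on top of
  cluster-independent negative-binomial background genes (a SERGIO-like
  master-regulator block structure: mutually exclusive marker blocks induce
  negative cross-block correlations).

These are deliberately *not* re-implementations of Splatter or SERGIO: no
library-size factors, dropout layers or dynamical GRN simulation. The
selection algorithm only sees the resulting count/correlation structure, and
a mean shift reproduces exactly that.

The negative binomial is parameterized by mean ``mu`` and dispersion ``r``
(number of failures), so ``variance = mu + mu^2 / r``; smaller ``r`` means
more overdispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

__all__ = [
    "SyntheticDataset",
    "simulate_null_counts",
    "simulate_clustered_counts",
    "downsample_to_min",
    "simulate_simpsons_pair",
]


@dataclass
class SyntheticDataset:
    """Count matrix plus ground truth.

    ``counts`` is genes x cells (integer). ``labels`` holds one cluster id
    per cell. ``true_deg`` marks genes designed to be differential;
    ``detectable_deg`` is filled in post hoc by
    :func:`anticorr.metrics.detectable_degs` and is ``None`` until then.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    labels: np.ndarray
    true_deg: np.ndarray
    detectable_deg: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.cell_ids) != n_cells:
            raise ValueError("id lengths do not match the counts matrix")
        if self.labels.shape != (n_cells,):
            raise ValueError("labels must have one entry per cell")
        if self.true_deg.shape != (n_genes,):
            raise ValueError("true_deg must have one entry per gene")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


def _check_positive(name: str, value) -> None:
    if value <= 0:
        raise ValueError(f"{name} must be positive, got {value}")


def _draw_gene_means(
    n_genes: int, rng: np.random.Generator, mean_log: float, sd_log: float
) -> np.ndarray:
    return rng.lognormal(mean=mean_log, sigma=sd_log, size=n_genes)


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB counts for a genes x cells mean matrix, shared dispersion."""
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p)


def simulate_null_counts(
    n_cells: int,
    n_genes: int,
    mean_log: float = 0.0,
    sd_log: float = 1.0,
    nb_dispersion: float = 2.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Single-population negative-binomial count matrix (no structure).

    Gene means are log-normal(``mean_log``, ``sd_log``) — median one count
    per cell with a heavy right tail, the typical shape of scRNA-seq mean
    expression — and every gene is i.i.d. across cells, so any feature a
    selection method reports on this matrix is a false discovery.
    """
    if n_cells < 2 or n_genes < 2:
        raise ValueError("n_cells and n_genes must both be at least 2")
    _check_positive("nb_dispersion", nb_dispersion)
    _check_positive("sd_log", sd_log)
    rng = np.random.default_rng(seed)
    means = _draw_gene_means(n_genes, rng, mean_log, sd_log)
    counts = _nb_draw(rng, np.repeat(means[:, None], n_cells, axis=1), nb_dispersion)
    return SyntheticDataset(
        counts=counts.astype(np.int64),
        gene_ids=[f"gene_{i}" for i in range(n_genes)],
        cell_ids=[f"cell_{j}" for j in range(n_cells)],
        labels=np.zeros(n_cells, dtype=np.int64),
        true_deg=np.zeros(n_genes, dtype=bool),
        params={
            "generator": "null",
            "n_cells": n_cells,
            "n_genes": n_genes,
            "mean_log": mean_log,
            "sd_log": sd_log,
            "nb_dispersion": nb_dispersion,
            "seed": seed,
            "gene_means": means,
        },
    )


def simulate_clustered_counts(
    n_clusters: int,
    n_cells: int,
    n_genes: int,
    n_deg: int,
    effect_size: float = 8.0,
    mean_log: float = 0.0,
    sd_log: float = 1.0,
    nb_dispersion: float = 2.0,
    cluster_proportions: np.ndarray | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Multi-cluster counts with per-cluster marker blocks.

    The ``n_deg`` marker genes are partitioned across clusters (evenly, with
    any remainder assigned round-robin); marker means are multiplied by
    ``effect_size`` in the owning cluster only. The remaining genes are
    cluster-independent NB noise. When ``n_deg=0`` the output is identical in
    law to :func:`simulate_null_counts` with the same noise parameters.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be at least 2")
    if n_cells < n_clusters or n_genes < 2:
        raise ValueError("n_cells/n_genes too small for the requested design")
    if n_deg > n_genes:
        raise ValueError(f"n_deg={n_deg} exceeds n_genes={n_genes}")
    if n_deg < 0:
        raise ValueError("n_deg must be non-negative")
    _check_positive("effect_size", effect_size)
    _check_positive("nb_dispersion", nb_dispersion)

    if cluster_proportions is None:
        sizes = np.full(n_clusters, n_cells // n_clusters, dtype=np.int64)
        sizes[: n_cells % n_clusters] += 1
    else:
        cluster_proportions = np.asarray(cluster_proportions, dtype=np.float64)
        if cluster_proportions.shape != (n_clusters,) or np.any(
            cluster_proportions <= 0
        ):
            raise ValueError("cluster_proportions must be positive, one per cluster")
        frac = cluster_proportions / cluster_proportions.sum()
        sizes = np.maximum(1, np.floor(frac * n_cells).astype(np.int64))
        while sizes.sum() < n_cells:
            sizes[np.argmax(frac * n_cells - sizes)] += 1
        while sizes.sum() > n_cells:
            sizes[np.argmax(sizes)] -= 1
    labels = np.repeat(np.arange(n_clusters), sizes)

    rng = np.random.default_rng(seed)
    means = _draw_gene_means(n_genes, rng, mean_log, sd_log)
    true_deg = np.zeros(n_genes, dtype=bool)
    true_deg[:n_deg] = True
    # markers 0..n_deg-1 assigned to clusters round-robin
    marker_owner = np.arange(n_deg) % n_clusters

    mu = np.repeat(means[:, None], n_cells, axis=1)
    for g in range(n_deg):
        mu[g, labels == marker_owner[g]] *= effect_size
    counts = _nb_draw(rng, mu, nb_dispersion)
    return SyntheticDataset(
        counts=counts.astype(np.int64),
        gene_ids=[f"gene_{i}" for i in range(n_genes)],
        cell_ids=[f"cell_{j}" for j in range(n_cells)],
        labels=labels,
        true_deg=true_deg,
        params={
            "generator": "clustered",
            "n_clusters": n_clusters,
            "n_cells": n_cells,
            "n_genes": n_genes,
            "n_deg": n_deg,
            "effect_size": effect_size,
            "mean_log": mean_log,
            "sd_log": sd_log,
            "nb_dispersion": nb_dispersion,
            "seed": seed,
            "marker_owner": marker_owner,
            "gene_means": means,
        },
    )


def downsample_to_min(
    ds: SyntheticDataset, fraction: float = 0.95, seed: int = 0
) -> SyntheticDataset:
    """Downsample every cell to ``floor(fraction * minimum cell total)``.

    Sampling is without replacement from each cell's transcript pool
    (multivariate hypergeometric per cell), so no count can exceed its
    pre-downsampling value and all column sums land exactly on the target.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    totals = ds.counts.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("all cells must have positive total counts")
    target = int(np.floor(fraction * totals.min()))
    rng = np.random.default_rng(seed)
    out = np.empty_like(ds.counts)
    for j in range(ds.counts.shape[1]):
        if totals[j] == target:
            out[:, j] = ds.counts[:, j]
        else:
            out[:, j] = rng.multivariate_hypergeometric(
                ds.counts[:, j], target
            )
    params = dict(ds.params)
    params.update({"downsampled_to": target, "downsample_fraction": fraction,
                   "downsample_seed": seed})
    return SyntheticDataset(
        counts=out,
        gene_ids=list(ds.gene_ids),
        cell_ids=list(ds.cell_ids),
        labels=ds.labels.copy(),
        true_deg=ds.true_deg.copy(),
        detectable_deg=None if ds.detectable_deg is None else ds.detectable_deg.copy(),
        params=params,
    )


def simulate_simpsons_pair(
    n_cells_per_batch: int,
    within_rho: float = -0.6,
    shift: float = 6.0,
    seed: int = 0,
):
    """Two genes whose correlation flips sign when two batches are pooled.

    Within each batch the pair is drawn from a bivariate normal with negative
    correlation ``within_rho``; the second batch is shifted upward in *both*
    genes by ``shift`` standard deviations. Within-batch Spearman rho stays
    negative while the pooled rho turns positive once the batch-level shift
    dominates — the classic Simpson's-paradox hazard of mixing technologies
    or batches before measuring correlation structure. With ``shift=0`` the
    pooled rho retains the within-batch sign.

    Returns ``(batch1, batch2, combined)``, each a 2 x cells array
    (rows: gene_a, gene_b).
    """
    if n_cells_per_batch < 10:
        raise ValueError("n_cells_per_batch must be at least 10")
    if not -1.0 < within_rho < 1.0:
        raise ValueError("within_rho must be in (-1, 1)")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, within_rho], [within_rho, 1.0]])
    batch1 = rng.multivariate_normal([0.0, 0.0], cov, size=n_cells_per_batch).T
    batch2 = rng.multivariate_normal(
        [shift, shift], cov, size=n_cells_per_batch
    ).T
    combined = np.concatenate([batch1, batch2], axis=1)
    return batch1, batch2, combined


def marker_block_mean_rho(ds: SyntheticDataset, cluster_a: int, cluster_b: int,
                          max_genes: int = 50) -> float:
    """Mean pairwise Spearman rho between two clusters' marker blocks.

    Diagnostic used in tests of the planted anti-correlation structure; uses
    at most ``max_genes`` markers per block to keep it cheap.
    """
    owner = ds.params["marker_owner"]
    idx_a = np.flatnonzero(owner == cluster_a)[:max_genes]
    idx_b = np.flatnonzero(owner == cluster_b)[:max_genes]
    rho, _ = spearmanr(ds.counts[idx_a].T, ds.counts[idx_b].T)
    rho = np.atleast_2d(rho)
    cross = rho[: len(idx_a), len(idx_a):]
    return float(np.nanmean(cross))
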