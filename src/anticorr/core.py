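"""Anti-correlation-based feature selection.

The selection principle: genes whose expression separates cell populations
are high in some cells and absent in others, so markers of *different*
populations are mutually exclusive and therefore negatively correlated.
A gene is selected when it shows a statistical *excess* of strong negative
Spearman correlations relative to a permutation null, and additionally
belongs to a module of positively co-regulated genes.

Procedure
---------
1. Build a null background of gene-gene Spearman correlations by sampling
   up to ``null_sample_size`` genes and independently permuting each gene's
   values across cells (destroying all gene-gene pairing). All pairwise
   correlations over the upper triangle are split into a negative-side and a
   positive-side null distribution; the two sides are calibrated separately
   because they follow different distributions.
2. From the negative null, take the cutoff ``c_neg`` at the target
   false-positive rate: the ``floor(N * fpr)``-th most negative null rho
   (mirrored on the positive side for ``c_pos``).
3. On the original (unshuffled) matrix, count for every gene i
   ``t_i`` = number of partners with rho < 0 and ``d_i`` ("discoveries") =
   number with rho < c_neg. Under the null only ``fp_hat = t_i * fpr``
   discoveries are expected, giving a per-gene estimated FDR
   ``fdr_hat = fp_hat / d_i``.
4. Select genes with ``fdr_hat`` below the threshold (set A: excess negative
   correlation) that also have more than ``min_positive_partners`` partners
   with rho > c_pos (set M: member of a positively co-moving module). The
   final features are F = A ∩ M.

All Spearman correlations in this module use *dense* ranks (ties share one
rank, ranks consecutive). With count data ties are pervasive and ordinary
mid-ranks leave large gaps in the null distributions; dense ranks keep them
smooth.

Randomness contract (portable seeds): with ``rng = np.random.default_rng(seed)``,
the null draws ``rng.choice(candidates, size=m, replace=False)`` over the
non-constant gene indices in their original order, then permutes each sampled
gene with ``rng.permutation`` in sampled order. Any independent
re-implementation following this contract reproduces the background exactly.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

#: Correlations within this distance of zero are treated as exactly zero.
#: Rank-based rhos are rational numbers, and on continuous data a gene pair
#: can have a mathematically exact zero correlation; without a tolerance,
#: float rounding would decide arbitrarily which side of the negative/positive
#: split such a pair lands on.
ZERO_TOL = 1e-12

__all__ = [
    "AnticorConfig",
    "ZERO_TOL",
    "NullBackground",
    "dense_rank",
    "build_null_background",
    "select_cutoff",
    "summarize_gene_correlations",
    "estimate_fdr",
    "select_features",
    "get_anti_cor_genes",
    "DEFAULT_PRE_REMOVE_PATTERNS",
]

#: Default pre-removal patterns: ribosomal, mitochondrial and hemoglobin gene
#: symbols (human/mouse conventions). Matched case-insensitively against gene
#: ids when ``pre_remove_genes="default"``. Users may pass an explicit list.
DEFAULT_PRE_REMOVE_PATTERNS = (
    r"^RP[LS]\d",      # cytosolic ribosomal proteins
    r"^MRP[LS]\d",     # mitochondrial ribosomal proteins
    r"^MT-",           # mitochondrially encoded genes
    r"^HB[ABDEGMQZ]\d?$",  # hemoglobin chains
)


@dataclass
class AnticorConfig:
    """Hyperparameters of the selection algorithm.

    Defaults are the published operating point: ``fpr=0.001`` (1 false
    positive per 1000 null correlations), ``fdr_threshold=0.066`` (= 1/15,
    i.e. a >15x excess of discoveries over the null expectation),
    ``null_sample_size=5000`` genes for the permutation background and
    ``min_positive_partners=10`` (module membership requires > 10 positively
    correlated partners beyond ``c_pos``).
    """

    fpr: float = 0.001
    fdr_threshold: float = 0.066
    null_sample_size: int = 5000
    min_positive_partners: int = 10
    pre_remove_genes: list | str | None = None
    seed: int = 0
    block_size: int = 1024

    def __post_init__(self) -> None:
        if not 0.0 < self.fpr < 1.0:
            raise ValueError(f"fpr must be in (0, 1), got {self.fpr}")
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValueError(
                f"fdr_threshold must be in (0, 1), got {self.fdr_threshold}"
            )
        if self.null_sample_size < 2:
            raise ValueError("null_sample_size must be at least 2")
        if self.block_size < 1:
            raise ValueError("block_size must be positive")


@dataclass
class NullBackground:
    """Permutation null of gene-gene Spearman correlations.

    ``b_sorted`` holds the negative-side null rhos sorted ascending (most
    negative first); ``pos_sorted`` the positive side sorted descending (most
    positive first). ``c_neg``/``c_pos`` are the FPR-calibrated cutoffs, each
    an element of its vector. Exact zeros belong to neither side.
    """

    b_sorted: np.ndarray
    pos_sorted: np.ndarray
    sampled_gene_indices: np.ndarray
    c_neg: float
    c_pos: float
    fpr: float = field(default=0.001)

    def __post_init__(self) -> None:
        if self.b_sorted.size and self.b_sorted[-1] >= 0:
            raise ValueError("b_sorted must contain only negative values")
        if self.pos_sorted.size and self.pos_sorted[-1] <= 0:
            raise ValueError("pos_sorted must contain only positive values")


def dense_rank(values: np.ndarray) -> np.ndarray:
    """Dense-rank transform: tied values share a rank, ranks are 1..#distinct."""
    values = np.asarray(values)
    if values.size == 0:
        raise ValueError("cannot rank an empty vector")
    return rankdata(values, method="dense")


def _dense_rank_rows(mat: np.ndarray) -> np.ndarray:
    """Dense-rank each row of a genes x cells matrix."""
    return rankdata(mat, method="dense", axis=1).astype(np.float64)


def _standardize_rows(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score rows; constant rows become all-zero (rho 0 with every partner).

    Returns (z, constant_mask). With rows standardized, Pearson correlation of
    any two rows is ``z_i @ z_j / n_cells`` — applied to dense ranks this is
    the Spearman variant used throughout.
    """
    mean = ranks.mean(axis=1, keepdims=True)
    sd = ranks.std(axis=1, keepdims=True)
    constant = sd[:, 0] == 0.0
    sd[constant] = 1.0
    z = (ranks - mean) / sd
    z[constant] = 0.0
    return z, constant


def select_cutoff(null_values_sorted: np.ndarray, fpr: float, side: str) -> float:
    """FPR-calibrated cutoff from a sorted null vector.

    ``side="negative"``: vector ascending (most negative first); the cutoff is
    the ``floor(N * fpr)``-th most negative null rho. ``side="positive"``:
    vector descending, mirrored. A discovery downstream is *strictly* beyond
    the cutoff, so by construction at most ``floor(N * fpr)`` null values are
    at least as extreme as the cutoff.
    """
    null_values_sorted = np.asarray(null_values_sorted, dtype=np.float64)
    n = null_values_sorted.size
    if n == 0:
        raise ValueError("empty null vector")
    if side not in ("negative", "positive"):
        raise ValueError(f"side must be 'negative' or 'positive', got {side!r}")
    k = int(np.floor(n * fpr))
    if k < 1:
        warnings.warn(
            f"floor(N*fpr) = floor({n}*{fpr}) < 1; falling back to the single "
            "most extreme null value",
            stacklevel=2,
        )
        k = 1
    return float(null_values_sorted[k - 1])


def build_null_background(expr: np.ndarray, cfg: AnticorConfig) -> NullBackground:
    """Permutation null background of dense-rank Spearman correlations.

    Samples ``min(null_sample_size, #non-constant genes)`` genes without
    replacement, permutes each independently across cells (unpairing all
    gene-gene relationships), and computes all upper-triangle pairwise
    correlations block-wise. Constant genes are excluded from the candidate
    pool: their ranks are degenerate and they carry no correlation signal.
    """
    expr = np.asarray(expr)
    if expr.ndim != 2:
        raise ValueError("expr must be a 2-D genes x cells matrix")
    n_genes, n_cells = expr.shape
    candidates = np.flatnonzero(expr.min(axis=1) != expr.max(axis=1))
    if candidates.size < 2:
        raise ValueError(
            f"need at least 2 non-constant genes for the null background, "
            f"found {candidates.size}"
        )
    if candidates.size < 500:
        warnings.warn(
            f"only {candidates.size} genes available for the null background; "
            "null distributions may be unstable below ~500 genes",
            stacklevel=2,
        )
    rng = np.random.default_rng(cfg.seed)
    m = min(cfg.null_sample_size, candidates.size)
    sampled = rng.choice(candidates, size=m, replace=False)
    permuted = np.empty((m, n_cells), dtype=np.float64)
    for i in range(m):
        permuted[i] = rng.permutation(expr[sampled[i]])

    z, _ = _standardize_rows(_dense_rank_rows(permuted))
    neg_parts: list[np.ndarray] = []
    pos_parts: list[np.ndarray] = []
    bs = cfg.block_size
    for start in range(0, m, bs):
        stop = min(start + bs, m)
        block = z[start:stop]
        within = (block @ block.T) / n_cells
        rows, cols = np.triu_indices(stop - start, k=1)
        vals = within[rows, cols]
        tail = z[stop:]
        if tail.size:
            cross = (block @ tail.T) / n_cells
            vals = np.concatenate([vals, cross.ravel()])
        neg_parts.append(vals[vals < -ZERO_TOL])
        pos_parts.append(vals[vals > ZERO_TOL])
    b = np.sort(np.concatenate(neg_parts))
    pos = np.sort(np.concatenate(pos_parts))[::-1]
    if b.size == 0 or pos.size == 0:
        raise ValueError("degenerate null background: one side is empty")
    c_neg = select_cutoff(b, cfg.fpr, side="negative")
    c_pos = select_cutoff(pos, cfg.fpr, side="positive")
    return NullBackground(
        b_sorted=b,
        pos_sorted=pos,
        sampled_gene_indices=sampled,
        c_neg=c_neg,
        c_pos=c_pos,
        fpr=cfg.fpr,
    )


def summarize_gene_correlations(
    expr: np.ndarray,
    c_neg: float,
    c_pos: float,
    gene_ids: list | None = None,
    block_size: int = 1024,
) -> pd.DataFrame:
    """Per-gene correlation tallies on the original (unshuffled) matrix.

    For every gene i over all partners j != i: ``t_i`` counts rho < 0,
    ``d_i`` counts rho < c_neg (discoveries) and ``n_pos_partners`` counts
    rho > c_pos. Computed block-wise: the full gene x gene correlation matrix
    is never materialized (memory is O(block_size * n_genes)).

    Constant genes get rho = 0 against every partner — they contribute to no
    tally on either end — and are flagged in the ``constant`` column.
    """
    expr = np.asarray(expr)
    if expr.ndim != 2:
        raise ValueError("expr must be a 2-D genes x cells matrix")
    n_genes, n_cells = expr.shape
    z, constant = _standardize_rows(_dense_rank_rows(expr))
    t = np.zeros(n_genes, dtype=np.int64)
    d = np.zeros(n_genes, dtype=np.int64)
    npos = np.zeros(n_genes, dtype=np.int64)
    for start in range(0, n_genes, block_size):
        stop = min(start + block_size, n_genes)
        rho = z[start:stop] @ z.T
        np.divide(rho, n_cells, out=rho)
        # exclude self-correlations (rho = 1 for non-constant genes)
        rho[np.arange(stop - start), np.arange(start, stop)] = 0.0
        t[start:stop] = (rho < -ZERO_TOL).sum(axis=1)
        d[start:stop] = (rho < c_neg).sum(axis=1)
        npos[start:stop] = (rho > c_pos).sum(axis=1)
    table = pd.DataFrame(
        {
            "t_i": t,
            "d_i": d,
            "n_pos_partners": npos,
            "constant": constant,
        }
    )
    if gene_ids is not None:
        if len(gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match matrix rows")
        table.index = pd.Index(gene_ids, name="gene")
    else:
        table.index.name = "gene"
    return table


def estimate_fdr(table: pd.DataFrame, fpr: float) -> pd.DataFrame:
    """Per-gene expected false positives and estimated FDR.

    ``fp_hat = t_i * fpr`` is the number of discoveries expected if the gene's
    negative correlations were null; ``fdr_hat = fp_hat / d_i`` (clamped to
    [0, 1]). Genes with no discoveries get ``fdr_hat = 1`` so the selection
    rule stays total.
    """
    table = table.copy()
    fp_hat = table["t_i"].to_numpy() * fpr
    d = table["d_i"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_hat = np.where(d > 0, fp_hat / np.maximum(d, 1), 1.0)
    table["fp_hat"] = fp_hat
    table["fdr_hat"] = np.clip(fdr_hat, 0.0, 1.0)
    return table


def select_features(table: pd.DataFrame, cfg: AnticorConfig) -> pd.DataFrame:
    """Apply the two selection filters and intersect them.

    A: excess negative correlation, ``fdr_hat < fdr_threshold``.
    M: module membership, ``n_pos_partners > min_positive_partners``
    (strictly greater).  Selected features F = A ∩ M.
    """
    table = table.copy()
    table["in_A"] = table["fdr_hat"].to_numpy() < cfg.fdr_threshold
    table["in_M"] = table["n_pos_partners"].to_numpy() > cfg.min_positive_partners
    table["selected"] = table["in_A"] & table["in_M"]
    return table


def _resolve_pre_remove(gene_ids: pd.Index, genes: list | str | None) -> np.ndarray:
    """Boolean mask of genes to drop before selection."""
    if genes is None:
        return np.zeros(len(gene_ids), dtype=bool)
    if isinstance(genes, str):
        if genes != "default":
            raise ValueError("pre_remove_genes must be a list, None or 'default'")
        pattern = re.compile("|".join(DEFAULT_PRE_REMOVE_PATTERNS), re.IGNORECASE)
        return np.array([bool(pattern.search(str(g))) for g in gene_ids])
    drop = set(map(str, genes))
    return np.array([str(g) in drop for g in gene_ids])


def get_anti_cor_genes(
    expr,
    gene_ids: list | None = None,
    cfg: AnticorConfig | None = None,
) -> pd.DataFrame:
    """End-to-end anti-correlation feature selection.

    Parameters
    ----------
    expr
        Genes x cells matrix (array or DataFrame with genes as the index) of
        normalized, log-scale expression. Spearman correlations are invariant
        to any strictly monotone per-gene transform, so the scale only matters
        through tie structure.
    gene_ids
        Row identifiers; taken from the DataFrame index when ``expr`` is a
        DataFrame.
    cfg
        Hyperparameters; defaults to :class:`AnticorConfig`.

    Returns
    -------
    DataFrame indexed by gene with columns ``t_i, d_i, n_pos_partners,
    constant, fp_hat, fdr_hat, in_A, in_M, selected``. Genes removed by
    ``pre_remove_genes`` appear with all-zero tallies, ``fdr_hat = 1`` and
    ``selected = False`` so the output always covers the full input index.
    """
    if cfg is None:
        cfg = AnticorConfig()
    if isinstance(expr, pd.DataFrame):
        if gene_ids is None:
            gene_ids = list(expr.index)
        expr = expr.to_numpy()
    expr = np.asarray(expr, dtype=np.float64)
    if gene_ids is None:
        gene_ids = [f"gene_{i}" for i in range(expr.shape[0])]
    index = pd.Index(gene_ids, name="gene")
    removed = _resolve_pre_remove(index, cfg.pre_remove_genes)
    kept = ~removed
    if kept.sum() < 2:
        raise ValueError("fewer than 2 genes remain after pre-removal")

    sub = expr[kept]
    null = build_null_background(sub, cfg)
    table = summarize_gene_correlations(
        sub, null.c_neg, null.c_pos, gene_ids=list(index[kept]),
        block_size=cfg.block_size,
    )
    table = estimate_fdr(table, cfg.fpr)
    table = select_features(table, cfg)
    table.attrs["c_neg"] = null.c_neg
    table.attrs["c_pos"] = null.c_pos
    if removed.any():
        filler = pd.DataFrame(
            {
                "t_i": 0,
                "d_i": 0,
                "n_pos_partners": 0,
                "constant": False,
                "fp_hat": 0.0,
                "fdr_hat": 1.0,
                "in_A": False,
                "in_M": False,
                "selected": False,
            },
            index=index[removed],
        )
        attrs = table.attrs
        table = pd.concat([table, filler]).loc[index]
        table.attrs = attrs
    return table
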