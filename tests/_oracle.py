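"""Independent brute-force oracle for the anti-correlation selection math.

A literal, unoptimized transcription of the selection procedure: explicit
per-pair Spearman correlations via np.corrcoef on dense ranks, Python loops
over every gene pair, no blocking and no shared code with the package
implementation. Used only to verify the optimized implementation on small
matrices. It follows the package's documented randomness contract (gene
sample via rng.choice over non-constant genes, then per-gene
rng.permutation in sampled order), which is part of the interface, not of
the implementation.
"""

import math

import numpy as np

from scipy.stats import rankdata

# correlations within this distance of zero count as exactly zero: rank-based
# rhos are rational and a pair can be mathematically zero; this convention is
# part of the algorithm definition, shared with the package
ZERO_TOL = 1e-12


def _rho(x, y):
    rx = rankdata(x, method="dense")
    ry = rankdata(y, method="dense")
    if rx.max() == 1 or ry.max() == 1:  # constant vector: rho defined as 0
        return 0.0
    return float(np.corrcoef(rx, ry)[0, 1])


def oracle_feature_table(expr, fpr=0.001, fdr_threshold=0.066,
                         null_sample_size=5000, min_positive_partners=10,
                         seed=0):
    """Compute every per-gene quantity of the selection by brute force.

    Returns a dict of numpy arrays: t, d, n_pos, fp_hat, fdr_hat, in_A,
    in_M, selected, plus the cutoffs c_neg and c_pos.
    """
    expr = np.asarray(expr, dtype=np.float64)
    n_genes, n_cells = expr.shape

    # permutation null background, per the documented randomness contract
    rng = np.random.default_rng(seed)
    candidates = [i for i in range(n_genes)
                  if expr[i].min() != expr[i].max()]
    m = min(null_sample_size, len(candidates))
    sampled = rng.choice(np.array(candidates), size=m, replace=False)
    permuted = [rng.permutation(expr[g]) for g in sampled]

    null_vals = []
    for i in range(m):
        for j in range(i + 1, m):
            null_vals.append(_rho(permuted[i], permuted[j]))
    b = sorted(v for v in null_vals if v < -ZERO_TOL)
    pos = sorted((v for v in null_vals if v > ZERO_TOL), reverse=True)

    k_neg = max(1, math.floor(len(b) * fpr))
    c_neg = b[k_neg - 1]
    k_pos = max(1, math.floor(len(pos) * fpr))
    c_pos = pos[k_pos - 1]

    # tallies on the original, unshuffled matrix
    S = np.zeros((n_genes, n_genes))
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            S[i, j] = S[j, i] = _rho(expr[i], expr[j])
    t = np.zeros(n_genes, dtype=int)
    d = np.zeros(n_genes, dtype=int)
    n_pos = np.zeros(n_genes, dtype=int)
    for i in range(n_genes):
        for j in range(n_genes):
            if i == j:
                continue
            if S[i, j] < -ZERO_TOL:
                t[i] += 1
            if S[i, j] < c_neg:
                d[i] += 1
            if S[i, j] > c_pos:
                n_pos[i] += 1

    fp_hat = t * fpr
    fdr_hat = np.ones(n_genes)
    for i in range(n_genes):
        if d[i] > 0:
            fdr_hat[i] = min(fp_hat[i] / d[i], 1.0)
    in_a = fdr_hat < fdr_threshold
    in_m = n_pos > min_positive_partners
    return {
        "t": t, "d": d, "n_pos": n_pos, "fp_hat": fp_hat,
        "fdr_hat": fdr_hat, "in_A": in_a, "in_M": in_m,
        "selected": in_a & in_m, "c_neg": c_neg, "c_pos": c_pos,
    }


def oracle_confusion_metrics(selected, truth):
    """Brute-force confusion-table metrics via explicit element loops."""
    tp = fp = fn = tn = 0
    for s, t in zip(selected, truth):
        if s and t:
            tp += 1
        elif s and not t:
            fp += 1
        elif not s and t:
            fn += 1
        else:
            tn += 1
    def safe(n, dben):
        return n / dben if dben else 0.0
    out = {
        "fpr": safe(fp, fp + tn), "tnr": safe(tn, fp + tn),
        "tpr": safe(tp, tp + fn), "fnr": safe(fn, tp + fn),
        "precision": safe(tp, tp + fp), "fdr": safe(fp, tp + fp),
        "for_": safe(fn, fn + tn),
        "acc": safe(tp + tn, tp + tn + fp + fn),
        "f1": safe(2 * tp, 2 * tp + fp + fn),
    }
    out["ba"] = 0.5 * (out["tpr"] + out["tnr"])
    prod = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    out["mcc"] = ((tp * tn - fp * fn) / math.sqrt(prod)) if prod else 0.0
    return out
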