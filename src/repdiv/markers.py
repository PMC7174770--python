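"""Cluster-versus-rest differential expression with cross-sample combination.

Per sample, each gene is tested for differential expression between one
cluster and all remaining cells pooled, with a two-sided Wilcoxon
rank-sum test (midranks, tie-corrected normal approximation; exact
enumeration for tiny groups), reporting the rank-biserial AUC
U / (n_in * n_out) and a log fold-change of pseudocounted means. Per-gene
p-values from k samples are then combined with the minimum-p special case
of Wilkinson's method, P = 1 - (1 - min p)^k, the tail probability of the
minimum of k independent uniforms — a marker is "conserved" when it is
extreme in at least one sample, and the combination corrects for having
looked at k of them.

Expression input is assumed already normalized; the module operates on
any genes x cells real-valued matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

_EXACT_MAX = 8  # exact enumeration when both group sizes are at most this


def _rank_sum_vectorized(x_in: np.ndarray, x_out: np.ndarray):
    """Tie-corrected two-sided rank-sum p and AUC, vectorized over genes.

    x_in: (n_genes, n_in); x_out: (n_genes, n_out).
    """
    n_in, n_out = x_in.shape[1], x_out.shape[1]
    n = n_in + n_out
    pooled = np.concatenate([x_in, x_out], axis=1)
    ranks = stats.rankdata(pooled, axis=1)  # midranks
    r_in = ranks[:, :n_in].sum(axis=1)
    u = r_in - n_in * (n_in + 1) / 2.0
    auc = u / (n_in * n_out)

    mu = n_in * n_out / 2.0
    # tie correction: sum over tied groups of (t^3 - t)
    sorted_pooled = np.sort(pooled, axis=1)
    tie_term = np.zeros(pooled.shape[0])
    for g in range(pooled.shape[0]):
        _, counts = np.unique(sorted_pooled[g], return_counts=True)
        tie_term[g] = np.sum(counts.astype(float) ** 3 - counts)
    sigma2 = n_in * n_out / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sigma2 > 0, (u - mu) / np.sqrt(np.maximum(sigma2, 1e-300)), 0.0)
    p = np.where(sigma2 > 0, 2 * stats.norm.sf(np.abs(z)), 1.0)
    return np.minimum(p, 1.0), auc


def _rank_sum_exact(x_in: np.ndarray, x_out: np.ndarray):
    """Exact two-sided rank-sum p per gene (tiny groups, no-tie fast path)."""
    p = np.empty(x_in.shape[0])
    auc = np.empty(x_in.shape[0])
    for g in range(x_in.shape[0]):
        a, b = x_in[g], x_out[g]
        pooled = np.concatenate([a, b])
        if np.unique(pooled).size == pooled.size:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p[g] = res.pvalue
        auc[g] = res.statistic / (a.size * b.size)
    return p, auc


def wilcoxon_cluster_vs_rest(expr: pd.DataFrame, labels: dict[str, str],
                             cluster: str) -> pd.DataFrame:
    """Per-gene rank-sum test of one cluster against the pooled rest.

    ``expr`` is a genes x cells DataFrame (columns are cell barcodes that
    appear in ``labels``). Returns a DataFrame indexed by gene with
    columns p, auc, log_fc, n_in, n_out. log_fc is the difference of
    natural-log means with one pseudocount.
    """
    cells = [c for c in expr.columns if c in labels]
    in_cells = [c for c in cells if labels[c] == cluster]
    out_cells = [c for c in cells if labels[c] != cluster]
    if len(in_cells) < 2 or len(out_cells) < 2:
        raise ValueError(
            f"cluster {cluster!r} needs >=2 cells in-group and out-group "
            f"(got {len(in_cells)} vs {len(out_cells)})"
        )
    x_in = expr[in_cells].to_numpy(dtype=float)
    x_out = expr[out_cells].to_numpy(dtype=float)
    if x_in.shape[1] <= _EXACT_MAX and x_out.shape[1] <= _EXACT_MAX:
        p, auc = _rank_sum_exact(x_in, x_out)
    else:
        p, auc = _rank_sum_vectorized(x_in, x_out)
    log_fc = np.log(x_in.mean(axis=1) + 1.0) - np.log(x_out.mean(axis=1) + 1.0)
    return pd.DataFrame(
        {"p": p, "auc": auc, "log_fc": log_fc,
         "n_in": len(in_cells), "n_out": len(out_cells)},
        index=pd.Index(expr.index, name="gene"),
    )


def combine_pvalues_min(pvals) -> float:
    """Minimum-p combination (Wilkinson, r = 1): 1 - (1 - min p)^k."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("cannot combine an empty p-value list")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return float(1.0 - (1.0 - p.min()) ** p.size)


def conserved_markers(exprs: list[pd.DataFrame],
                      labels_list: list[dict[str, str]],
                      cluster: str,
                      add_qvalues: bool = True,
                      min_detect_frac: float = 0.0) -> pd.DataFrame:
    """Conserved cluster markers across samples, ranked by combined p.

    Each sample is tested independently (cluster vs pooled rest); per-gene
    p-values are combined across the k samples containing the gene with
    the minimum-p rule. Genes are ranked by ascending combined p with
    ties broken by mean |AUC - 0.5| descending (stronger separation
    first). Genes present in fewer than all samples are flagged through
    the ``n_samples`` column. ``min_detect_frac`` optionally drops genes
    detected (nonzero) in less than that fraction of cells in every
    sample; default off.
    """
    if len(exprs) != len(labels_list) or not exprs:
        raise ValueError("need one labels mapping per expression matrix")
    per_sample = []
    for i, (expr, labels) in enumerate(zip(exprs, labels_list)):
        if min_detect_frac > 0:
            frac = (expr > 0).mean(axis=1)
            expr = expr.loc[frac >= min_detect_frac]
        res = wilcoxon_cluster_vs_rest(expr, labels, cluster)
        res = res.rename(columns={c: f"{c}_s{i}" for c in res.columns})
        per_sample.append(res)
    merged = pd.concat(per_sample, axis=1, join="outer")

    k = merged[[f"p_s{i}" for i in range(len(exprs))]].notna().sum(axis=1)
    combined = [
        combine_pvalues_min(row.dropna())
        for _, row in merged[[f"p_s{i}" for i in range(len(exprs))]].iterrows()
    ]
    merged["combined_p"] = combined
    merged["n_samples"] = k.astype(int)
    auc_cols = [f"auc_s{i}" for i in range(len(exprs))]
    merged["mean_auc"] = merged[auc_cols].mean(axis=1)
    merged["auc_distance"] = (merged["mean_auc"] - 0.5).abs()
    merged = merged.sort_values(
        ["combined_p", "auc_distance"], ascending=[True, False]
    )
    merged["rank"] = np.arange(1, len(merged) + 1)
    if add_qvalues and len(merged):
        merged["q_bh"] = multipletests(merged["combined_p"], method="fdr_bh")[1]
    merged.insert(0, "cluster", cluster)
    return merged.drop(columns=["auc_distance"])
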