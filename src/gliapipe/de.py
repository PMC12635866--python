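"""Wilcoxon rank-sum differential expression.

Implements the marker-detection and genotype "pseudobulk" comparisons:
log-normalization (ln(1 + 10,000 x / library size)), gene pre-filtering
on expression fraction and log fold-change, two-sided rank-sum tests
(exact enumeration for tiny groups, otherwise normal approximation with
tie and continuity correction), and Benjamini-Hochberg adjustment over
the tested genes. Fold-changes are natural-log with a pseudocount of 1
applied to the de-logged group means.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "log_normalize",
    "wilcoxon_de",
    "find_all_markers",
    "pseudobulk_de",
    "top_n_upregulated",
    "overlap_sets",
]

SCALE_FACTOR = 10_000.0
EXACT_MAX_N = 8


def log_normalize(counts, scale_factor: float = SCALE_FACTOR):
    """Library-size normalize and log-transform a gene x cell matrix.

    Per cell: x -> ln(1 + x * s / total). Cells with zero total counts
    get all-zero expression (with a warning). Sparse input stays sparse.
    """
    if sparse.issparse(counts):
        X = counts.tocsc().astype(float)
        totals = np.asarray(X.sum(axis=0)).ravel()
        if (totals == 0).any():
            warnings.warn(f"{int((totals == 0).sum())} cells have zero counts")
        scale = np.where(totals > 0, scale_factor / np.maximum(totals, 1), 0.0)
        X = X @ sparse.diags(scale)
        X.data = np.log1p(X.data)
        return X.tocsr()
    X = np.asarray(counts, dtype=float)
    totals = X.sum(axis=0)
    if (totals == 0).any():
        warnings.warn(f"{int((totals == 0).sum())} cells have zero counts")
    scale = np.where(totals > 0, scale_factor / np.maximum(totals, 1), 0.0)
    return np.log1p(X * scale[None, :])


def _dense(expr) -> np.ndarray:
    return expr.toarray() if sparse.issparse(expr) else np.asarray(expr, dtype=float)


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    mu = n_a * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), n_a):
        w = ranks[list(comb)].sum()
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
        total += 1
    return count / total


def wilcoxon_de(
    expr,
    gene_names,
    group_a,
    group_b,
    min_pct: float = 0.10,
    lfc_min: float = 0.0,
    fdr_max: float = 0.01,
    min_pct_mode: str = "either",
    method: str = "auto",
) -> pd.DataFrame:
    """Rank-sum differential expression between two cell groups.

    ``expr`` is a log-normalized gene x cell matrix; ``group_a`` /
    ``group_b`` are column indices (or boolean masks). Genes enter the
    test when expressed (count > 0) in at least ``min_pct`` of cells in
    either group (or both, with ``min_pct_mode='both'``) and when
    |lfc| >= ``lfc_min``, where

        lfc = ln( (mean(exp(x_a) - 1) + 1) / (mean(exp(x_b) - 1) + 1) ).

    BH adjustment runs over the tested genes only; rows with
    p_adj < ``fdr_max`` are flagged significant. ``method`` selects the
    p-value computation: "auto" enumerates exactly when both groups have
    at most 8 cells (ties handled exactly) and otherwise uses the normal
    approximation with tie and continuity correction; "exact" and
    "asymptotic" force one path.
    """
    gene_names = np.asarray(gene_names, dtype=object)
    A = _dense(expr[:, np.asarray(group_a)] if not isinstance(group_a, slice) else expr[:, group_a])
    Bm = _dense(expr[:, np.asarray(group_b)] if not isinstance(group_b, slice) else expr[:, group_b])
    n_a, n_b = A.shape[1], Bm.shape[1]
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")

    pct_a = (A > 0).mean(axis=1)
    pct_b = (Bm > 0).mean(axis=1)
    mean_a = np.expm1(A).mean(axis=1)
    mean_b = np.expm1(Bm).mean(axis=1)
    lfc = np.log((mean_a + 1) / (mean_b + 1))

    if min_pct_mode == "either":
        pct_ok = (pct_a >= min_pct) | (pct_b >= min_pct)
    elif min_pct_mode == "both":
        pct_ok = (pct_a >= min_pct) & (pct_b >= min_pct)
    else:
        raise ValueError("min_pct_mode must be 'either' or 'both'")
    keep = pct_ok & (np.abs(lfc) >= lfc_min)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        return pd.DataFrame(
            columns=["gene", "lfc", "p_raw", "p_adj", "pct_a", "pct_b", "direction", "significant"]
        )

    exact = method == "exact" or (
        method == "auto" and n_a <= EXACT_MAX_N and n_b <= EXACT_MAX_N
    )
    if exact:
        p = np.array([_exact_ranksum_p(A[i], Bm[i]) for i in idx])
    else:
        res = stats.mannwhitneyu(
            A[idx], Bm[idx], axis=1, alternative="two-sided", method="asymptotic"
        )
        p = np.atleast_1d(res.pvalue)
    p_adj = multipletests(p, method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "gene": gene_names[idx],
            "lfc": lfc[idx],
            "p_raw": p,
            "p_adj": p_adj,
            "pct_a": pct_a[idx],
            "pct_b": pct_b[idx],
        }
    )
    out["direction"] = np.where(out["lfc"] > 0, "up", "down")
    out["significant"] = out["p_adj"] < fdr_max
    return out.sort_values("p_adj", kind="stable").reset_index(drop=True)


def find_all_markers(
    expr,
    gene_names,
    cluster_labels,
    lfc_min: float = 0.25,
    fdr_max: float = 0.01,
    min_pct: float = 0.10,
) -> pd.DataFrame:
    """One-vs-rest marker detection for every cluster."""
    labels = np.asarray(cluster_labels)
    clusters = pd.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    frames = []
    for c in clusters:
        in_c = labels == c
        if in_c.sum() < 2:
            warnings.warn(f"cluster {c!r} has <2 cells; skipped")
            continue
        res = wilcoxon_de(
            expr, gene_names, np.flatnonzero(in_c), np.flatnonzero(~in_c),
            min_pct=min_pct, lfc_min=lfc_min, fdr_max=fdr_max,
        )
        res.insert(0, "cluster", c)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def pseudobulk_de(
    expr,
    gene_names,
    genotype_labels,
    genotype_a: str,
    genotype_b: str,
    lfc_min: float = 0.10,
    fdr_max: float = 0.01,
    min_pct: float = 0.10,
) -> pd.DataFrame:
    """Genotype-versus-genotype comparison across all cells.

    Cell-level rank-sum with the pseudobulk cutoffs (FDR 0.01, LFC 0.10,
    10% expression); the name is kept from the source protocol even
    though the test operates on cells, not aggregated libraries.
    """
    labels = np.asarray(genotype_labels)
    return wilcoxon_de(
        expr, gene_names,
        np.flatnonzero(labels == genotype_a), np.flatnonzero(labels == genotype_b),
        min_pct=min_pct, lfc_min=lfc_min, fdr_max=fdr_max,
    )


def top_markers(markers: pd.DataFrame, n: int = 5) -> pd.DataFrame:
    """Top-n markers per cluster by log fold-change (dot-plot export)."""
    sig = markers[markers["significant"] & (markers["lfc"] > 0)]
    return (
        sig.sort_values(["cluster", "lfc"], ascending=[True, False], kind="stable")
        .groupby("cluster", sort=False)
        .head(n)
        .reset_index(drop=True)
    )


def top_n_upregulated(degs: pd.DataFrame, n: int = 30, fdr_max: float = 0.01) -> list[str]:
    """First n upregulated genes ranked by lfc (ties: smaller p_raw,
    then gene name)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    qual = degs[(degs["lfc"] > 0) & (degs["p_adj"] < fdr_max)].copy()
    qual = qual.sort_values(
        ["lfc", "p_raw", "gene"], ascending=[False, True, True], kind="stable"
    )
    if len(qual) < n:
        warnings.warn(f"only {len(qual)} genes qualify (requested {n})")
    return qual["gene"].head(n).tolist()


def overlap_sets(named_lists: dict[str, list]) -> pd.DataFrame:
    """Counts of every intersection region among named gene sets.

    A region is the subset of names an element belongs to exactly;
    region counts partition the union (inclusion-exclusion complete).
    """
    if len(named_lists) < 2:
        raise ValueError("need at least 2 lists")
    names = list(named_lists)
    sets = {k: set(v) for k, v in named_lists.items()}
    universe = set().union(*sets.values())
    region_counts: dict[tuple, int] = {}
    for el in universe:
        region = tuple(k for k in names if el in sets[k])
        region_counts[region] = region_counts.get(region, 0) + 1
    rows = []
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            rows.append({"region": "&".join(combo), "members": combo, "count": region_counts.get(combo, 0)})
    return pd.DataFrame(rows)
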