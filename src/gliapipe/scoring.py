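"""Bin-matched control-gene module scoring.

A module score is the mean expression of a gene set minus the mean of
expression-matched control genes: all genes are ranked by average
expression across cells and cut into equal-size bins; each module gene
contributes control genes drawn at random (seeded) from its own bin.
Under exchangeability of module and control genes the expected score is
zero, so positive scores indicate coordinated enrichment of the module.

Scores are compared between groups by one-way ANOVA with Tukey-HSD post
hoc tests, and binned into quartiles for projection onto embeddings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats

__all__ = ["ModuleScoreResult", "score_module", "compare_scores", "bin_quartiles"]


@dataclass
class ModuleScoreResult:
    scores: np.ndarray  # per-cell score
    module_genes: list[str]  # module genes actually used
    control_genes: list[str]
    n_bins: int
    n_ctrl: int
    seed: int


def _dense(expr) -> np.ndarray:
    return expr.toarray() if sparse.issparse(expr) else np.asarray(expr, dtype=float)


def score_module(
    expr,
    gene_names,
    module_genes,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ModuleScoreResult:
    """Per-cell module score with expression-bin-matched controls.

    Controls are drawn per module gene, without replacement within that
    gene's bin, from one seeded stream; the control set used for the
    score is the union of the draws.
    """
    gene_names = np.asarray(gene_names, dtype=object)
    name_to_row = {g: i for i, g in enumerate(gene_names)}
    present = [g for g in module_genes if g in name_to_row]
    absent = [g for g in module_genes if g not in name_to_row]
    if absent:
        warnings.warn(f"{len(absent)} module genes absent from matrix: {absent[:5]}...")
    if not present:
        raise ValueError("no module gene present in the matrix")

    X = _dense(expr)
    data_avg = X.mean(axis=1)
    order = np.argsort(data_avg, kind="stable")
    bins = np.empty(len(gene_names), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b

    rng = np.random.default_rng(seed)
    mod_set = {name_to_row[g] for g in present}
    ctrl_rows: set[int] = set()
    for g in present:
        row = name_to_row[g]
        pool = np.flatnonzero(bins == bins[row])
        # controls avoid module genes unless the module owns the whole bin
        nonmod = pool[~np.isin(pool, list(mod_set))]
        if nonmod.size > 0:
            pool = nonmod
        else:
            pool = pool[pool != row]
        if pool.size == 0:
            warnings.warn(f"no control genes available in the bin of {g!r}")
            continue
        take = min(n_ctrl, pool.size)
        ctrl_rows.update(rng.choice(pool, size=take, replace=False).tolist())
    if not ctrl_rows:
        raise ValueError("control pool is empty for every module gene")

    mod_rows = np.array([name_to_row[g] for g in present])
    ctrl_rows = np.array(sorted(ctrl_rows))
    scores = X[mod_rows].mean(axis=0) - X[ctrl_rows].mean(axis=0)
    return ModuleScoreResult(
        scores=scores,
        module_genes=present,
        control_genes=gene_names[ctrl_rows].tolist(),
        n_bins=n_bins,
        n_ctrl=n_ctrl,
        seed=seed,
    )


def compare_scores(scores, group_labels) -> dict:
    """One-way ANOVA plus Tukey-HSD pairwise table on per-cell scores.

    Returns {"F", "p", "group_means", "tukey"} where tukey is a
    DataFrame of (group_a, group_b, diff, p_adj). With two groups the
    Tukey-adjusted p equals the unadjusted two-sample result.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(group_labels)
    groups = list(pd.unique(labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = [scores[labels == g] for g in groups]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs at least 2 observations")

    if all(np.ptp(s) == 0 for s in samples) and np.ptp([s.mean() for s in samples]) == 0:
        F, p = 0.0, 1.0
        tukey_rows = [
            {"group_a": a, "group_b": b, "diff": 0.0, "p_adj": 1.0}
            for i, a in enumerate(groups)
            for b in groups[i + 1:]
        ]
        return {
            "F": F,
            "p": p,
            "group_means": {g: float(s.mean()) for g, s in zip(groups, samples)},
            "tukey": pd.DataFrame(tukey_rows),
        }

    F, p = stats.f_oneway(*samples)
    hsd = stats.tukey_hsd(*samples)
    tukey_rows = []
    for i, a in enumerate(groups):
        for j in range(i + 1, len(groups)):
            b = groups[j]
            tukey_rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "diff": float(samples[i].mean() - samples[j].mean()),
                    "p_adj": float(hsd.pvalue[i, j]),
                }
            )
    return {
        "F": float(F),
        "p": float(p),
        "group_means": {g: float(s.mean()) for g, s in zip(groups, samples)},
        "tukey": pd.DataFrame(tukey_rows),
    }


def bin_quartiles(scores) -> np.ndarray:
    """Quartile labels 1-4 of the score distribution.

    Cells are split into four bins of size differing by at most one;
    ties are broken by stable cell order.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if n < 4:
        raise ValueError("need at least 4 cells")
    order = np.argsort(scores, kind="stable")
    labels = np.empty(n, dtype=int)
    for q, chunk in enumerate(np.array_split(order, 4), start=1):
        labels[chunk] = q
    return labels
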