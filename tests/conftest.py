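"""Shared fixtures: small seeded synthetic datasets and independent
oracle implementations (exact rank-sum enumeration, brute-force BH)."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from gliapipe import de, simulate


@pytest.fixture(scope="session")
def marker_dataset():
    """One-sample dataset with 8 clusters x 300 cells and 4-fold markers."""
    cfg = simulate.SimConfig(
        n_genes=600,
        markers_per_cluster=6,
        marker_fc=4.0,
        mean_umi_per_cell=2500.0,
        seed=11,
    )
    comp = pd.DataFrame(
        [("s1", "hWT", c, 300) for c in cfg.clusters],
        columns=["sample_id", "genotype", "cluster", "cell_count"],
    )
    ds = simulate.gen_counts(comp, cfg)
    expr = de.log_normalize(ds.counts)
    return {
        "expr": expr,
        "genes": ds.gene_names,
        "cells": ds.cells,
        "markers": ds.truth["markers"],
        "config": cfg,
    }


def exact_ranksum_oracle(a, b):
    """Two-sided rank-sum p by full enumeration of group assignments.

    Independent of the package: counts assignments whose rank sum is at
    least as extreme (in |W - E[W]|) as observed.
    """
    pooled = np.concatenate([a, b])
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    mu = n_a * (len(pooled) + 1) / 2.0
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n_a):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            hits += 1
    return hits / total


def bh_oracle(pvals):
    """Brute-force Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running_min = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        k = n - rank_from_end  # 1-based rank of p[i]
        running_min = min(running_min, p[i] * n / k)
        adj[i] = running_min
    return adj
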