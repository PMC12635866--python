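"""Differential proportion analysis (DPA) of cell-state composition.

Tests whether cluster proportions differ between genotypes using a
stratified-bootstrap / log-linear-model procedure: cells are resampled
with replacement within each sample (cluster identities frozen, no
re-clustering), sample totals are normalized while preserving
within-sample proportions, a Poisson GLM

    cellCount ~ cellType * genotype   (log link)

is fit to every bootstrap replicate, and the replicate fits are pooled
with Rubin's rules (within-replicate variance W, between-replicate
variance B, total T = W + (1 + 1/m) B) with Barnard-Rubin degrees of
freedom. Coefficient-level inference uses univariate Wald tests;
pairwise genotype contrasts within each cluster are adjusted by the
single-step max-|t| (Tukey-type) method over the contrasts' estimated
correlation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CompositionTable",
    "GLMFit",
    "PooledContrast",
    "DPAResult",
    "tabulate_composition",
    "stratified_bootstrap",
    "normalize_counts",
    "fit_poisson_glm",
    "pool_rubin",
    "pairwise_contrasts",
    "run_dpa",
]

COMPOSITION_COLUMNS = ["sample_id", "genotype", "cluster", "cell_count"]

# Alias used in prose/docstrings: a CompositionTable is a DataFrame with
# COMPOSITION_COLUMNS, zero-filled over every (sample, cluster) pair.
CompositionTable = pd.DataFrame


def _rosters(comp: pd.DataFrame, clusters=None, genotypes=None):
    clusters = list(clusters) if clusters is not None else sorted(comp["cluster"].unique())
    genotypes = list(genotypes) if genotypes is not None else sorted(comp["genotype"].unique())
    return clusters, genotypes


def tabulate_composition(cells: pd.DataFrame, clusters=None, genotypes=None) -> CompositionTable:
    """Zero-filled contingency of cell counts by (sample, cluster).

    Genotype is carried from the sample metadata; a sample mapping to
    two genotypes, or a cluster label outside the roster, is an error.
    """
    geno_map = cells.groupby("sample_id")["genotype"].unique()
    bad = geno_map[geno_map.apply(len) > 1]
    if len(bad):
        raise ValueError(f"samples with more than one genotype: {list(bad.index)}")
    if clusters is not None:
        unknown = set(cells["cluster"]) - set(clusters)
        if unknown:
            raise ValueError(f"cluster labels not in roster: {sorted(unknown)}")
    clusters, genotypes = _rosters(cells.rename(columns={}), clusters, genotypes)

    counts = (
        cells.groupby(["sample_id", "cluster"], sort=False).size().rename("cell_count")
    )
    samples = cells[["sample_id", "genotype"]].drop_duplicates()
    full = pd.MultiIndex.from_product(
        [samples["sample_id"], clusters], names=["sample_id", "cluster"]
    )
    table = counts.reindex(full, fill_value=0).reset_index()
    table = table.merge(samples, on="sample_id")
    return table[COMPOSITION_COLUMNS]


def _pivot(comp: pd.DataFrame, clusters, sample_order=None):
    """(samples x clusters) count matrix plus sample metadata."""
    wide = comp.pivot_table(
        index="sample_id", columns="cluster", values="cell_count", fill_value=0, aggfunc="sum"
    )
    if sample_order is None:
        sample_order = list(dict.fromkeys(comp["sample_id"]))
    wide = wide.reindex(index=sample_order, columns=clusters, fill_value=0)
    geno = comp.drop_duplicates("sample_id").set_index("sample_id")["genotype"]
    return wide.to_numpy(dtype=np.int64), sample_order, geno.reindex(sample_order).tolist()


def _unpivot(counts: np.ndarray, samples, genotypes_per_sample, clusters) -> pd.DataFrame:
    rows = []
    for i, s in enumerate(samples):
        for j, c in enumerate(clusters):
            rows.append((s, genotypes_per_sample[i], c, int(counts[i, j])))
    return pd.DataFrame(rows, columns=COMPOSITION_COLUMNS)


def stratified_bootstrap(
    comp: CompositionTable, B: int, seed: int = 0, clusters=None
) -> list[CompositionTable]:
    """B stratified bootstrap replicates of a composition table.

    Each replicate resamples cells with replacement within each sample,
    keeping the sample's total fixed; because a cell's only attribute
    here is its frozen cluster label, this is a multinomial draw on the
    sample's observed cluster proportions.
    """
    if B < 2:
        raise ValueError("need at least B=2 bootstrap replicates")
    clusters, _ = _rosters(comp, clusters)
    S, samples, genos = _pivot(comp, clusters)
    totals = S.sum(axis=1)
    if (totals == 0).any():
        zero = [samples[i] for i in np.flatnonzero(totals == 0)]
        raise ValueError(f"samples with zero cells: {zero}")
    rng = np.random.default_rng(seed)
    out = []
    probs = S / totals[:, None]
    for _ in range(B):
        rep = np.vstack(
            [rng.multinomial(totals[i], probs[i]) for i in range(len(samples))]
        )
        out.append(_unpivot(rep, samples, genos, clusters))
    return out


def _largest_remainder(counts: np.ndarray, target: int) -> np.ndarray:
    """Integer apportionment of ``target`` proportional to ``counts``."""
    total = counts.sum()
    if total == 0:
        return np.zeros_like(counts)
    quota = counts * (target / total)
    base = np.floor(quota).astype(np.int64)
    short = int(target - base.sum())
    if short > 0:
        frac = quota - base
        order = np.argsort(-frac, kind="stable")
        base[order[:short]] += 1
    return base


def normalize_counts(comp: CompositionTable, target_total: int | str = "mean", clusters=None):
    """Rescale each sample's counts to a common total.

    Within-sample proportions are preserved up to integer rounding by
    largest-remainder apportionment, so output totals are exactly equal
    across samples and counts stay integral for the Poisson likelihood.
    """
    clusters, _ = _rosters(comp, clusters)
    S, samples, genos = _pivot(comp, clusters)
    totals = S.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("all sample totals must be positive")
    if target_total == "mean":
        target = int(round(totals.mean()))
    else:
        target = int(target_total)
    nonzero_clusters = int((S.sum(axis=0) > 0).sum())
    if target < nonzero_clusters:
        warnings.warn(
            f"target_total {target} below the number of occupied clusters {nonzero_clusters}"
        )
    out = np.vstack([_largest_remainder(S[i], target) for i in range(len(samples))])
    return _unpivot(out, samples, genos, clusters)


# ---------------------------------------------------------------------------
# Poisson log-linear model


@dataclass
class GLMFit:
    """Poisson log-linear fit with treatment coding."""

    params: np.ndarray
    cov: np.ndarray
    colnames: list[str]
    converged: bool
    deviance: float
    df_resid: int
    fitted: np.ndarray = field(repr=False, default=None)


def _design(comp: pd.DataFrame, clusters, genotypes):
    """Treatment-coded design matrix for cellCount ~ cluster * genotype.

    Reference levels are the first cluster and first genotype in roster
    order. Row order follows the composition table.
    """
    c_idx = comp["cluster"].map({c: i for i, c in enumerate(clusters)}).to_numpy()
    g_idx = comp["genotype"].map({g: i for i, g in enumerate(genotypes)}).to_numpy()
    if np.any(pd.isna(c_idx)) or np.any(pd.isna(g_idx)):
        raise ValueError("labels outside the provided rosters")
    n = len(comp)
    cols, names = [np.ones(n)], ["Intercept"]
    for i, c in enumerate(clusters[1:], start=1):
        cols.append((c_idx == i).astype(float))
        names.append(f"cluster[T.{c}]")
    for j, g in enumerate(genotypes[1:], start=1):
        cols.append((g_idx == j).astype(float))
        names.append(f"genotype[T.{g}]")
    for i, c in enumerate(clusters[1:], start=1):
        for j, g in enumerate(genotypes[1:], start=1):
            cols.append(((c_idx == i) & (g_idx == j)).astype(float))
            names.append(f"cluster[T.{c}]:genotype[T.{g}]")
    return np.column_stack(cols), names


def _fit_poisson(y: np.ndarray, X: np.ndarray, colnames) -> GLMFit:
    model = sm.GLM(y, X, family=sm.families.Poisson())
    with warnings.catch_warnings():
        # saturated designs trip benign scale/perfect-prediction warnings
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.filterwarnings("ignore", message=".*Perfect separation.*")
        res = model.fit(maxiter=50, tol=1e-8)
    return GLMFit(
        params=np.asarray(res.params),
        cov=np.asarray(res.cov_params()),
        colnames=list(colnames),
        converged=bool(getattr(res, "converged", True)),
        deviance=float(res.deviance),
        df_resid=int(res.df_resid),
        fitted=np.asarray(res.fittedvalues),
    )


def fit_poisson_glm(comp: CompositionTable, clusters=None, genotypes=None) -> GLMFit:
    """Fit cellCount ~ cellType * genotype, family poisson(log), by IRLS."""
    clusters, genotypes = _rosters(comp, clusters, genotypes)
    for c, g in itertools.product(clusters, genotypes):
        sub = comp[(comp["cluster"] == c) & (comp["genotype"] == g)]
        if len(sub) == 0:
            raise ValueError(f"design needs >=1 observation for ({c}, {g})")
    X, names = _design(comp, clusters, genotypes)
    y = comp["cell_count"].to_numpy(dtype=float)
    return _fit_poisson(y, X, names)


def contrast_vector(colnames, cluster, genotype_a, genotype_b, ref_cluster, ref_genotype):
    """Row vector L with L @ beta = log(mu[cluster, a] / mu[cluster, b])."""
    L = np.zeros(len(colnames))
    idx = {n: i for i, n in enumerate(colnames)}
    for g, sign in ((genotype_a, 1.0), (genotype_b, -1.0)):
        if g != ref_genotype:
            L[idx[f"genotype[T.{g}]"]] += sign
            if cluster != ref_cluster:
                L[idx[f"cluster[T.{cluster}]:genotype[T.{g}]"]] += sign
    return L


# ---------------------------------------------------------------------------
# Rubin-rule pooling


@dataclass
class PooledContrast:
    """Rubin-pooled estimate over m bootstrap-replicate fits."""

    target: str
    m: int
    q_bar: float
    W_bar: float
    B_between: float
    T_total: float
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float | None = None


def _barnard_rubin_df(m: int, B: float, T: float, df_com: float | None) -> float:
    if T <= 0 or B <= 0:
        return np.inf
    lam = (1 + 1 / m) * B / T
    df_old = (m - 1) / lam**2
    if df_com is None or df_com <= 0 or not np.isfinite(df_com):
        return df_old
    df_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - lam)
    return df_old * df_obs / (df_old + df_obs)


def pool_rubin(estimates, variances, target: str = "", df_com: float | None = None) -> PooledContrast:
    """Pool per-replicate estimates and their squared standard errors.

    q_bar is the mean estimate, W the mean within-replicate variance,
    B the between-replicate sample variance, T = W + (1 + 1/m) B; the
    statistic q_bar / sqrt(T) is referred to a t distribution with
    Barnard-Rubin adjusted degrees of freedom.
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    m = est.shape[0]
    if m < 2:
        raise ValueError("pooling needs at least 2 replicates")
    q_bar = float(est.mean())
    W = float(var.mean())
    B = float(est.var(ddof=1))
    T = W + (1 + 1 / m) * B
    if T <= 0:
        return PooledContrast(target, m, q_bar, W, B, T, np.nan, np.nan, np.nan)
    stat = q_bar / np.sqrt(T)
    df = _barnard_rubin_df(m, B, T, df_com)
    p = 2 * (stats.norm.sf(abs(stat)) if np.isinf(df) else stats.t.sf(abs(stat), df))
    return PooledContrast(target, m, q_bar, W, B, T, float(stat), float(df), float(p))


def _maxt_adjust(stats_abs: np.ndarray, dfs: np.ndarray, R: np.ndarray, seed: int) -> np.ndarray:
    """Single-step max-|t| adjusted p-values over correlated contrasts.

    p_adj_i = 1 - P(all |T_j| <= |t_i|) with T multivariate t (the
    contrast correlation R, the contrast's own df). Falls back to
    Bonferroni when the rectangle probability cannot be computed.
    """
    k = len(stats_abs)
    out = np.empty(k)
    rng = np.random.default_rng(seed)
    # Pairwise contrasts are linearly dependent (rank g-1 for g groups),
    # so R is singular; clip its spectrum to a small positive floor and
    # renormalize so the QMC integrator sees a positive definite matrix.
    Rs = (R + R.T) / 2.0
    vals, vecs = np.linalg.eigh(Rs)
    floor = max(vals.max(), 1.0) * 1e-6
    Rj = (vecs * np.clip(vals, floor, None)) @ vecs.T
    d = np.sqrt(np.diag(Rj))
    Rj = Rj / np.outer(d, d)
    np.fill_diagonal(Rj, 1.0)
    for i in range(k):
        t_i = stats_abs[i]
        if not np.isfinite(t_i):
            out[i] = np.nan
            continue
        lo, hi = np.full(k, -t_i), np.full(k, t_i)
        try:
            df_i = dfs[i]
            if not np.isfinite(df_i) or df_i > 1e4:
                prob = stats.multivariate_normal(cov=Rj, allow_singular=True).cdf(
                    hi, lower_limit=lo
                )
            else:
                prob = stats.multivariate_t(shape=Rj, df=df_i).cdf(
                    hi, lower_limit=lo, random_state=rng
                )
            out[i] = min(max(1.0 - prob, 0.0), 1.0)
        except Exception:  # pragma: no cover - numerical failure path
            warnings.warn("max-|t| adjustment failed; using Bonferroni")
            out[i] = min(1.0, 2 * stats.t.sf(t_i, dfs[i]) * k)
    return out


def _pool_family(q_mat: np.ndarray, w_mat: np.ndarray, W_full: np.ndarray, df_com, seed):
    """Pool a family of k correlated contrasts measured on m replicates.

    q_mat: (m, k) per-replicate contrast estimates; w_mat: (m, k)
    within-replicate variances; W_full: (k, k) mean within-replicate
    covariance of the contrasts (for the correlation used by max-|t|).
    Returns a list of PooledContrast with p_adjusted filled.
    """
    m, k = q_mat.shape
    pooled = [pool_rubin(q_mat[:, i], w_mat[:, i], df_com=df_com) for i in range(k)]
    B_full = np.cov(q_mat, rowvar=False, ddof=1).reshape(k, k)
    T_full = W_full + (1 + 1 / m) * B_full
    d = np.sqrt(np.clip(np.diag(T_full), 1e-300, None))
    R = T_full / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    if k == 1:
        for pc in pooled:
            pc.p_adjusted = pc.p_raw
        return pooled
    stats_abs = np.array([abs(pc.statistic) for pc in pooled])
    dfs = np.array([pc.df for pc in pooled])
    adj = _maxt_adjust(stats_abs, dfs, R, seed)
    for pc, a in zip(pooled, adj):
        # guard: adjustment is never below the raw p
        pc.p_adjusted = float(max(a, pc.p_raw)) if np.isfinite(a) else np.nan
    return pooled


def pairwise_contrasts(
    fits: list[GLMFit], cluster: str, clusters, genotypes, seed: int = 0
) -> list[PooledContrast]:
    """All genotype-pair contrasts within one cluster, Rubin-pooled and
    max-|t| (Tukey-type) adjusted over the pairs."""
    fits = [f for f in fits if f.converged]
    if len(fits) < 2:
        raise ValueError("need >=2 converged fits")
    pairs = list(itertools.combinations(genotypes, 2))
    colnames = fits[0].colnames
    L = np.vstack(
        [
            contrast_vector(colnames, cluster, a, b, clusters[0], genotypes[0])
            for a, b in pairs
        ]
    )
    m = len(fits)
    q = np.vstack([L @ f.params for f in fits])
    covs = [L @ f.cov @ L.T for f in fits]
    w = np.vstack([np.diag(c) for c in covs])
    W_full = np.mean(covs, axis=0)
    df_com = fits[0].df_resid
    pooled = _pool_family(q, w, W_full, df_com, seed)
    for pc, (a, b) in zip(pooled, pairs):
        pc.target = f"{cluster}: {a} - {b}"
    return pooled


# ---------------------------------------------------------------------------
# End-to-end driver


@dataclass
class DPAResult:
    contrasts: pd.DataFrame
    wald: pd.DataFrame
    proportions: pd.DataFrame
    manifest: dict


def run_dpa(
    cells: pd.DataFrame | None = None,
    composition: CompositionTable | None = None,
    clusters=None,
    genotypes=None,
    B: int = 10_000,
    seed: int = 0,
    target_total: int | str = "mean",
    normalize: str = "per_replicate",
    observation_unit: str = "sample",
    max_drop_fraction: float = 0.01,
) -> DPAResult:
    """Bootstrap differential proportion analysis.

    Composes tabulate -> stratified bootstrap -> normalize -> Poisson GLM
    -> Rubin pooling -> max-|t| pairwise contrasts. ``observation_unit``
    chooses whether the GLM sees one row per (sample, cluster) (default)
    or per (genotype, cluster) (aggregated, saturated design).
    """
    if composition is None:
        if cells is None:
            raise ValueError("provide cells or composition")
        composition = tabulate_composition(cells, clusters, genotypes)
    clusters, genotypes = _rosters(composition, clusters, genotypes)
    if len(clusters) < 2 or len(genotypes) < 2:
        raise ValueError("need at least 2 clusters and 2 genotypes")

    S, samples, genos = _pivot(composition, clusters)
    totals = S.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("samples with zero cells")
    probs = S / totals[:, None]
    if target_total == "mean":
        target = int(round(totals.mean()))
    else:
        target = int(target_total)

    if normalize == "before":
        S_base = np.vstack([_largest_remainder(S[i], target) for i in range(len(samples))])
    else:
        S_base = S

    if observation_unit not in ("sample", "genotype"):
        raise ValueError("observation_unit must be 'sample' or 'genotype'")

    # fixed design across replicates, in (sample-major, cluster-minor) order
    if observation_unit == "sample":
        rows = [(s, genos[i], c) for i, s in enumerate(samples) for c in clusters]
    else:
        uniq_g = list(dict.fromkeys(genos))
        rows = [(g, g, c) for g in uniq_g for c in clusters]
    design_df = pd.DataFrame(rows, columns=["sample_id", "genotype", "cluster"])
    X, colnames = _design(design_df, clusters, genotypes)
    p_cols = len(colnames)

    pairs = list(itertools.combinations(genotypes, 2))
    n_pairs = len(pairs)
    L_by_cluster = {
        c: np.vstack(
            [contrast_vector(colnames, c, a, b, clusters[0], genotypes[0]) for a, b in pairs]
        )
        for c in clusters
    }

    rng = np.random.default_rng(seed)
    m_used = 0
    dropped = 0
    df_com = None
    coef_q = []
    coef_w = []
    fam_q = {c: [] for c in clusters}
    fam_w = {c: [] for c in clusters}
    fam_W_full = {c: np.zeros((n_pairs, n_pairs)) for c in clusters}
    geno_idx = {}
    for i, g in enumerate(genos):
        geno_idx.setdefault(g, []).append(i)
    prop_sums = {g: np.zeros(len(clusters)) for g in geno_idx}
    prop_sumsq = {g: np.zeros(len(clusters)) for g in geno_idx}

    for b in range(B):
        rep = np.vstack(
            [rng.multinomial(totals[i], probs[i]) for i in range(len(samples))]
        )
        if normalize == "per_replicate":
            rep = np.vstack([_largest_remainder(rep[i], target) for i in range(len(samples))])
        for g, idxs in geno_idx.items():
            gp = rep[idxs].sum(axis=0)
            gp = gp / gp.sum()
            prop_sums[g] += gp
            prop_sumsq[g] += gp**2
        if observation_unit == "genotype":
            uniq_g = list(dict.fromkeys(genos))
            agg = np.vstack([rep[geno_idx[g]].sum(axis=0) for g in uniq_g])
            y = agg.reshape(-1).astype(float)
        else:
            y = rep.reshape(-1).astype(float)
        fit = _fit_poisson(y, X, colnames)
        if not fit.converged:
            dropped += 1
            continue
        m_used += 1
        df_com = fit.df_resid
        coef_q.append(fit.params)
        coef_w.append(np.diag(fit.cov))
        for c in clusters:
            Lc = L_by_cluster[c]
            fam_q[c].append(Lc @ fit.params)
            cc = Lc @ fit.cov @ Lc.T
            fam_w[c].append(np.diag(cc))
            fam_W_full[c] += cc

    if dropped > max_drop_fraction * B:
        raise RuntimeError(f"{dropped}/{B} replicates failed to converge")
    if m_used < 2:
        raise RuntimeError("fewer than 2 converged replicates")

    coef_q = np.vstack(coef_q)
    coef_w = np.vstack(coef_w)
    wald_rows = []
    for j, name in enumerate(colnames):
        pc = pool_rubin(coef_q[:, j], coef_w[:, j], target=name, df_com=df_com)
        wald_rows.append(
            {
                "coefficient": name,
                "estimate": pc.q_bar,
                "se": np.sqrt(pc.T_total) if pc.T_total > 0 else np.nan,
                "statistic": pc.statistic,
                "df": pc.df,
                "p": pc.p_raw,
            }
        )
    wald = pd.DataFrame(wald_rows)

    contrast_rows = []
    for ci, c in enumerate(clusters):
        q_mat = np.vstack(fam_q[c])
        w_mat = np.vstack(fam_w[c])
        W_full = fam_W_full[c] / m_used
        pooled = _pool_family(q_mat, w_mat, W_full, df_com, seed=seed + 7919 * (ci + 1))
        for pc, (a, b) in zip(pooled, pairs):
            contrast_rows.append(
                {
                    "cluster": c,
                    "genotype_a": a,
                    "genotype_b": b,
                    "estimate": pc.q_bar,
                    "se": np.sqrt(pc.T_total) if pc.T_total > 0 else np.nan,
                    "statistic": pc.statistic,
                    "df": pc.df,
                    "p_raw": pc.p_raw,
                    "p_adj": pc.p_adjusted,
                    "direction": "up" if pc.q_bar > 0 else "down",
                }
            )
    contrasts = pd.DataFrame(contrast_rows)

    prop_rows = []
    for g in geno_idx:
        mean = prop_sums[g] / B
        var = prop_sumsq[g] / B - mean**2
        for j, c in enumerate(clusters):
            prop_rows.append(
                {
                    "genotype": g,
                    "cluster": c,
                    "mean_prop": mean[j],
                    "sd_prop": float(np.sqrt(max(var[j], 0.0))),
                }
            )
    proportions = pd.DataFrame(prop_rows)

    manifest = {
        "B": B,
        "m_used": m_used,
        "dropped": dropped,
        "seed": seed,
        "target_total": target,
        "normalize": normalize,
        "observation_unit": observation_unit,
        "clusters": clusters,
        "genotypes": genotypes,
    }
    return DPAResult(contrasts=contrasts, wald=wald, proportions=proportions, manifest=manifest)
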