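"""Oriented-bounding-box morphometry and pathology correlations.

Quantifies 3-D cell objects (point clouds in micrometres) by an
oriented bounding box. The default construction searches convex-hull
face normals for the minimum-volume box (each candidate aligns one axis
with a facet normal and closes the box with a rotating-calipers
minimum-area rectangle); a PCA-aligned construction is available as an
alternative. The hull search matters for elongated cells with a nearly
isotropic cross-section: there the covariance eigenplane is degenerate,
raw eigenvectors land at arbitrary in-plane angles, and even the
principal axis carries enough angular noise to leak the long dimension
into the minor extents. Lengths are reported sorted A >= B >= C.

A cell is classified as a rod when its longest box length strictly
exceeds the cutoff (default 50 um), the longest axis serving as the
proxy for maximal process length. Per-mouse rod counts, genotype
comparisons (ANOVA + Tukey, unpaired t-tests) and the Pearson
correlation matrix across histology measures complete the module.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, QhullError

from .scoring import compare_scores

__all__ = [
    "ObbResult",
    "oriented_bbox",
    "classify_rod",
    "measure_shapes",
    "count_rods",
    "correlation_matrix",
    "group_ttest",
]

ROD_CUTOFF_UM = 50.0


@dataclass
class ObbResult:
    lengths: tuple[float, float, float]  # A >= B >= C, micrometres
    axes: np.ndarray  # rows are the box axes (unit vectors)
    degenerate: bool


def _min_area_rectangle(pts2d: np.ndarray):
    """Rotating-calipers minimum-area bounding rectangle of 2-D points.

    Returns (extent_u, extent_v, axes) where axes rows are the rectangle
    directions in the plane's coordinates.
    """
    try:
        hull = ConvexHull(pts2d)
        hp = pts2d[hull.vertices]
    except (QhullError, ValueError):
        # collinear or degenerate projection: fall back to PCA directions
        centered = pts2d - pts2d.mean(axis=0)
        _, vecs = np.linalg.eigh(np.cov(centered.T) if len(pts2d) > 1 else np.eye(2))
        axes = vecs.T[::-1]
        proj = centered @ axes.T
        ext = proj.max(axis=0) - proj.min(axis=0) if len(pts2d) > 1 else np.zeros(2)
        return float(ext[0]), float(ext[1]), axes

    best = None
    edges = np.diff(np.vstack([hp, hp[:1]]), axis=0)
    for e in edges:
        norm = np.hypot(*e)
        if norm == 0:
            continue
        u = e / norm
        v = np.array([-u[1], u[0]])
        pu = hp @ u
        pv = hp @ v
        du, dv = pu.max() - pu.min(), pv.max() - pv.min()
        area = du * dv
        if best is None or area < best[0] - 1e-12:
            best = (area, du, dv, np.vstack([u, v]))
    _, du, dv, axes = best
    return float(du), float(dv), axes


def _basis_from_normal(n_vec: np.ndarray) -> np.ndarray:
    """Orthonormal basis whose last row is the given unit vector."""
    ref = np.array([1.0, 0.0, 0.0]) if abs(n_vec[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n_vec, ref)
    u /= np.linalg.norm(u)
    v = np.cross(n_vec, u)
    return np.vstack([u, v, n_vec])


def _hull_obb(centered: np.ndarray):
    """Minimum-volume box over convex-hull face normals.

    For each distinct hull facet normal, align one box axis with it and
    close the box with the rotating-calipers minimum-area rectangle of
    the projection; keep the smallest-volume candidate. Exact for point
    sets that include the vertices of a box.
    """
    hull = ConvexHull(centered)
    hp = centered[hull.vertices]
    normals = hull.equations[:, :3]
    normals = np.unique(np.round(normals, 9), axis=0)
    best = None
    for n_vec in normals:
        basis = _basis_from_normal(n_vec / np.linalg.norm(n_vec))
        proj = hp @ basis.T
        dn = proj[:, 2].max() - proj[:, 2].min()
        du, dv, axes2d = _min_area_rectangle(proj[:, :2])
        vol = dn * du * dv
        if best is None or vol < best[0] - 1e-12:
            e2 = axes2d[0] @ basis[:2]
            e3 = axes2d[1] @ basis[:2]
            best = (vol, np.vstack([e2, e3, basis[2]]))
    return best[1]


def oriented_bbox(points, method: str = "hull") -> ObbResult:
    """Oriented-bounding-box lengths (A, B, C) of a 3-D point cloud.

    ``method`` selects the axis construction:

    - "hull" (default): minimum-volume box over convex-hull face
      normals with rotating-calipers closure - deterministic, exact for
      box-vertex inputs, and robust when the cross-section is nearly
      isotropic.
    - "pca": leading covariance eigenvector for the principal axis plus
      a minimum-area rectangle in the orthogonal plane.
    - "pca_raw": raw covariance eigenvectors.

    Lengths are max - min of point projections on each axis, sorted
    descending. Degenerate inputs (< 4 points, rank-deficient
    covariance) fall back to the PCA construction, pad missing
    directions with zero extents, and are flagged.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    n = pts.shape[0]
    if n == 0:
        return ObbResult((0.0, 0.0, 0.0), np.eye(3), True)
    centered = pts - pts.mean(axis=0)
    degenerate = n < 4
    if n == 1 or np.allclose(centered, 0):
        return ObbResult((0.0, 0.0, 0.0), np.eye(3), True)

    cov = (centered.T @ centered) / max(n - 1, 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    rank = int(np.sum(vals > max(vals.max(), 1e-300) * 1e-10))
    if rank < 3:
        degenerate = True

    R = None
    if method == "hull" and rank == 3 and n >= 4:
        try:
            R = _hull_obb(centered)
        except (QhullError, ValueError):
            degenerate = True
    if R is None:
        if method == "pca_raw" or rank < 2:
            R = vecs.T
        else:
            plane = vecs[:, 1:]
            du, dv, axes2d = _min_area_rectangle(centered @ plane)
            e2 = plane @ axes2d[0]
            e3 = plane @ axes2d[1]
            R = np.vstack([vecs[:, 0], e2, e3])
    proj = centered @ R.T
    ext = proj.max(axis=0) - proj.min(axis=0)
    lengths = tuple(sorted((float(x) for x in ext), reverse=True))
    return ObbResult(lengths, R, degenerate)


def classify_rod(lengths, cutoff: float = ROD_CUTOFF_UM) -> bool:
    """True iff the longest box length strictly exceeds the cutoff."""
    a = max(lengths)
    return bool(a > cutoff)


def measure_shapes(shapes, cutoff: float = ROD_CUTOFF_UM, method: str = "hull") -> pd.DataFrame:
    """OBB lengths and rod flags for a list of shape objects.

    Accepts items with .points/.object_id/.mouse_id/.region attributes
    (e.g. simulate.ShapeObject) or plain dicts with the same keys.
    """
    rows = []
    for s in shapes:
        get = (lambda k: getattr(s, k)) if not isinstance(s, dict) else s.__getitem__
        res = oriented_bbox(get("points"), method=method)
        A, Bv, C = res.lengths
        rows.append(
            {
                "object_id": get("object_id"),
                "mouse_id": get("mouse_id"),
                "region": get("region"),
                "A": A,
                "B": Bv,
                "C": C,
                "elongation": A / Bv if Bv > 0 else np.inf,
                "is_rod": classify_rod(res.lengths, cutoff),
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(rows)


def count_rods(measured: pd.DataFrame, by=("mouse_id", "region")) -> pd.DataFrame:
    """Rod counts per mouse x region (plus objects measured)."""
    by = list(by)
    out = (
        measured.groupby(by, sort=False)
        .agg(n_objects=("is_rod", "size"), rod_count=("is_rod", "sum"))
        .reset_index()
    )
    out["rod_count"] = out["rod_count"].astype(int)
    return out


def compare_rod_counts(counts: pd.DataFrame, genotype_of_mouse: dict) -> dict:
    """One-way ANOVA + Tukey across genotypes on per-mouse rod counts."""
    g = counts["mouse_id"].map(genotype_of_mouse)
    return compare_scores(counts["rod_count"].to_numpy(float), g.to_numpy())


def correlation_matrix(measures: pd.DataFrame, alpha: float = 0.05, columns=None):
    """Pairwise-complete Pearson correlations with two-sided p-values.

    Returns (r, p, significant) DataFrames over the numeric measure
    columns. Pairs with fewer than 3 complete rows or a zero-variance
    member are reported as missing.
    """
    if columns is None:
        columns = [c for c in measures.columns if pd.api.types.is_numeric_dtype(measures[c])]
    k = len(columns)
    r = pd.DataFrame(np.eye(k), index=columns, columns=columns)
    p = pd.DataFrame(np.zeros((k, k)), index=columns, columns=columns)
    for a, b in itertools.combinations(columns, 2):
        sub = measures[[a, b]].dropna()
        if len(sub) < 3 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
            warnings.warn(f"correlation undefined for ({a}, {b})")
            r.loc[a, b] = r.loc[b, a] = np.nan
            p.loc[a, b] = p.loc[b, a] = np.nan
            continue
        res = stats.pearsonr(sub[a], sub[b])
        r.loc[a, b] = r.loc[b, a] = res.statistic
        p.loc[a, b] = p.loc[b, a] = res.pvalue
    significant = p < alpha
    return r, p, significant


def group_ttest(values_a, values_b, equal_var: bool = True) -> tuple[float, float]:
    """Unpaired two-sided t-test (equal-variance by default, Welch by flag).

    Degenerate case: zero pooled variance with equal means gives
    (t=0, p=1).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
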