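"""Seeded synthetic datasets with known ground truth.

Emulates the study design of a four-genotype chimeric-microglia cohort:
mice per genotype contribute one scRNA-seq sample each; cells fall into
eight microglial states whose proportions shift with genotype;
counts are negative-binomial with cluster-specific marker genes and
designated ribosomal/mitochondrial gene fractions; per-mouse histology
measures follow a Gaussian copula with a configurable correlation
structure; and 3-D point clouds provide rod-like and ramified cell
shapes with known oriented-bounding-box lengths.

Every generator is a pure function of (config, seed): a fixed seed
yields byte-identical outputs. Independent substreams are derived from
the master seed per generator so the stages can be regenerated
separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from . import qc

GENOTYPES = ("hWT", "h5XFAD", "hPS19", "hPS-5X")
CLUSTERS = (
    "Homeostatic",
    "MHCII",
    "IFN",
    "DAM",
    "Humanin",
    "Cytokine",
    "Degranulation",
    "Macrophage",
)

#: Baseline cluster proportions: one dominant homeostatic cluster and
#: several states an order of magnitude smaller.
BASE_PROPS = (0.58, 0.10, 0.05, 0.09, 0.04, 0.06, 0.03, 0.05)

#: Multiplicative fold-changes on cluster proportions per genotype
#: (re-normalized): the amyloid genotype expands DAM and loses MHCII,
#: the tau genotype expands the interferon state, and the combined
#: genotype loses homeostatic cells while expanding IFN, DAM and
#: cytokine/chemokine states.
DEFAULT_EFFECTS = {
    "hWT": {},
    "h5XFAD": {"MHCII": 0.7, "DAM": 2.0},
    "hPS19": {"IFN": 2.0},
    "hPS-5X": {"Homeostatic": 0.6, "IFN": 3.0, "DAM": 2.0, "Cytokine": 1.5},
}

HISTO_MEASURES = ("amylo_volume", "abeta_volume", "at8_volume", "neun_count", "rod_count")

#: Default target Pearson correlations among histology measures
#: (order: amylo, 82E1, AT8, NeuN, rod). The rod/AT8/NeuN block encodes
#: the reported pathology structure: rod-AT8 +0.85, rod-NeuN -0.88,
#: AT8-NeuN -0.81; the two plaque stains are near-duplicates of each
#: other and nearly independent of rod counts.
DEFAULT_HISTO_CORR = (
    (1.00, 0.90, 0.30, -0.20, 0.05),
    (0.90, 1.00, 0.30, -0.20, 0.05),
    (0.30, 0.30, 1.00, -0.81, 0.85),
    (-0.20, -0.20, -0.81, 1.00, -0.88),
    (0.05, 0.05, 0.85, -0.88, 1.00),
)

#: Per-genotype histology means: amyloid only in 5XFAD-carrying
#: genotypes, AT8 elevated in the tau genotype and doubled in the
#: combined genotype, neuron counts reduced and rods concentrated in the
#: combined genotype.
DEFAULT_HISTO_MEANS = {
    "hWT": (1.0e4, 8.0e3, 1.0e3, 600.0, 0.3),
    "h5XFAD": (4.0e6, 3.0e6, 2.0e4, 585.0, 0.8),
    "hPS19": (1.2e4, 9.0e3, 3.0e5, 550.0, 2.0),
    "hPS-5X": (4.5e6, 3.4e6, 6.0e5, 430.0, 20.0),
}
#: Within-genotype coefficient of variation per measure. Stain volumes
#: scatter widely (CV 0.25); regional neuron counts are tight across
#: littermates (CV 0.08).
_HISTO_SD_FRACTIONS = (0.25, 0.25, 0.25, 0.08, 0.25)
_HISTO_SD_FLOORS = (5.0e3, 4.0e3, 500.0, 10.0, 0.5)

_CANONICAL_MARKERS = {
    "Homeostatic": ["OLFML3", "VSIG4", "FOLR2", "LYVE1"],
    "MHCII": ["HLA-DRA", "HLA-DRB1", "CD74"],
    "IFN": ["IFI6", "MX1", "OAS1", "ISG15"],
    "DAM": ["CD9", "SPP1", "TREM2"],
    "Humanin": ["MTRNR2L10", "MTRNR2L8"],
    "Cytokine": ["IL1B", "CCL3", "CCL4"],
    "Degranulation": ["ARG2", "S100A8"],
    "Macrophage": ["CD163", "MRC1", "F13A1"],
}

_N_MITO = 13
_MITO_NAMES = [
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    ``effect_matrix`` holds per-genotype multiplicative fold-changes on
    the baseline cluster proportions; products are re-normalized to sum
    to one, so enriching one state depletes the others.
    ``dirichlet_concentration`` scales the Dirichlet prior
    (alpha = concentration x genotype-mean proportions) that injects
    mouse-to-mouse compositional noise; ``None`` disables it (pure
    multinomial sampling).
    """

    genotypes: tuple[str, ...] = GENOTYPES
    clusters: tuple[str, ...] = CLUSTERS
    base_props: tuple[float, ...] = BASE_PROPS
    effect_matrix: dict = field(default_factory=lambda: {g: dict(v) for g, v in DEFAULT_EFFECTS.items()})
    mice_per_genotype: int | Sequence[int] = 2
    cells_per_mouse: float = 5000.0
    cells_dispersion: float = 80.0  # NB size parameter for total cells
    n_genes: int = 2000
    markers_per_cluster: int = 10
    marker_fc: float = 4.0
    nb_dispersion: float = 2.0  # NB size parameter for gene counts
    mean_umi_per_cell: float = 2500.0
    ribo_frac: float = 0.15
    mito_frac: float = 0.05
    dirichlet_concentration: float | None = 200.0
    histo_corr: tuple = DEFAULT_HISTO_CORR
    histo_means: dict = field(default_factory=lambda: {g: tuple(v) for g, v in DEFAULT_HISTO_MEANS.items()})
    seed: int = 0

    def __post_init__(self) -> None:
        bp = np.asarray(self.base_props, dtype=float)
        if bp.shape[0] != len(self.clusters):
            raise ValueError("base_props length must match clusters")
        if abs(bp.sum() - 1.0) > 1e-12:
            raise ValueError(f"base_props must sum to 1, got {bp.sum()!r}")
        if np.any(bp <= 0):
            raise ValueError("base_props must be positive")
        for g, fc in self.effect_matrix.items():
            if g not in self.genotypes:
                raise ValueError(f"effect_matrix genotype {g!r} not in roster")
            for c, v in fc.items():
                if c not in self.clusters:
                    raise ValueError(f"effect_matrix cluster {c!r} not in roster")
                if not v > 0:
                    raise ValueError("fold-changes must be positive")
        for n in self.mice_counts():
            if n < 1:
                raise ValueError("each genotype needs at least one mouse")
        if self.markers_per_cluster * len(self.clusters) + _N_MITO + self.n_ribo_genes() > self.n_genes:
            raise ValueError("n_genes too small for markers plus ribo/mito genes")

    def mice_counts(self) -> list[int]:
        if isinstance(self.mice_per_genotype, (int, np.integer)):
            return [int(self.mice_per_genotype)] * len(self.genotypes)
        counts = [int(x) for x in self.mice_per_genotype]
        if len(counts) != len(self.genotypes):
            raise ValueError("mice_per_genotype length must match genotypes")
        return counts

    def n_ribo_genes(self) -> int:
        return max(4, self.n_genes // 20)

    def expected_props(self) -> pd.DataFrame:
        """Genotype-level expected cluster proportions after re-normalization."""
        bp = np.asarray(self.base_props, dtype=float)
        rows = {}
        for g in self.genotypes:
            fc = np.array(
                [self.effect_matrix.get(g, {}).get(c, 1.0) for c in self.clusters]
            )
            p = bp * fc
            rows[g] = p / p.sum()
        return pd.DataFrame(rows, index=list(self.clusters)).T

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class CompositionSim:
    """Per-mouse cluster cell counts plus the generating truth."""

    table: pd.DataFrame  # sample_id, genotype, cluster, cell_count
    expected_props: pd.DataFrame  # genotype x cluster
    realized_props: pd.DataFrame  # sample x cluster (Dirichlet draws)


@dataclass
class SyntheticDataset:
    counts: sparse.csr_matrix  # gene x cell
    gene_names: list[str]
    cells: pd.DataFrame
    truth: dict
    histology: pd.DataFrame | None = None
    shapes: list | None = None


def gen_composition(config: SimConfig) -> CompositionSim:
    """Draw per-mouse cluster counts.

    Total cells per mouse are negative-binomial around
    ``cells_per_mouse``; cluster allocation is Dirichlet-multinomial
    with mean equal to the genotype's re-normalized expected
    proportions. With ``dirichlet_concentration=None`` the allocation is
    plain multinomial at the expected proportions.
    """
    rng = config.rng(1)
    expected = config.expected_props()
    rows = []
    realized = []
    sample_ids = []
    for g, n_mice in zip(config.genotypes, config.mice_counts()):
        p_g = expected.loc[g].to_numpy()
        for m in range(n_mice):
            sample = f"{g}_m{m + 1}"
            size = config.cells_dispersion
            mean = config.cells_per_mouse
            total = int(rng.negative_binomial(size, size / (size + mean)))
            total = max(total, 1)
            if config.dirichlet_concentration is None:
                pi = p_g
            else:
                pi = rng.dirichlet(config.dirichlet_concentration * p_g)
            counts = rng.multinomial(total, pi)
            realized.append(pi)
            sample_ids.append(sample)
            for c, k in zip(config.clusters, counts):
                rows.append((sample, g, c, int(k)))
    table = pd.DataFrame(rows, columns=["sample_id", "genotype", "cluster", "cell_count"])
    realized_df = pd.DataFrame(realized, index=sample_ids, columns=list(config.clusters))
    return CompositionSim(table=table, expected_props=expected, realized_props=realized_df)


def make_gene_names(config: SimConfig) -> tuple[list[str], dict[str, list[str]]]:
    """Gene roster: mitochondrial (MT-), ribosomal (RPS/RPL), per-cluster
    markers (canonical symbols first, then generated), background genes."""
    n_ribo = config.n_ribo_genes()
    ribo = [f"RPS{i + 1}" if i % 2 == 0 else f"RPL{i // 2 + 1}" for i in range(n_ribo)]
    markers: dict[str, list[str]] = {}
    for ci, c in enumerate(config.clusters):
        canon = _CANONICAL_MARKERS.get(c, [])[: config.markers_per_cluster]
        extra = [
            f"{c[:3].upper()}X{j + 1}" for j in range(config.markers_per_cluster - len(canon))
        ]
        markers[c] = canon + extra
    marker_flat = [g for c in config.clusters for g in markers[c]]
    n_bg = config.n_genes - _N_MITO - n_ribo - len(marker_flat)
    background = [f"GENE{i + 1:05d}" for i in range(n_bg)]
    names = list(_MITO_NAMES) + ribo + marker_flat + background
    assert len(names) == config.n_genes
    return names, markers


def _cluster_means(config: SimConfig, gene_names: list[str], markers: dict) -> dict[str, np.ndarray]:
    """Expected per-gene counts for a cell of each cluster.

    Ribosomal and mitochondrial gene groups receive exactly their
    configured share of the expected library in expectation; markers of
    the cell's own cluster sit ``marker_fc``-fold above background.
    """
    names = np.asarray(gene_names)
    is_mito = np.array([n in set(_MITO_NAMES) for n in names])
    is_ribo = np.array([n.startswith(("RPS", "RPL")) for n in names])
    means = {}
    for c in config.clusters:
        w = np.ones(config.n_genes)
        own = set(markers[c])
        is_own = np.array([n in own for n in names])
        w[is_own] = config.marker_fc
        w[is_mito] = 0.0
        w[is_ribo] = 0.0
        other_total = w.sum()
        rest = 1.0 - config.ribo_frac - config.mito_frac
        w[is_ribo] = other_total * config.ribo_frac / rest / is_ribo.sum()
        w[is_mito] = other_total * config.mito_frac / rest / is_mito.sum()
        means[c] = config.mean_umi_per_cell * w / w.sum()
    return means


def gen_counts(composition: pd.DataFrame, config: SimConfig) -> SyntheticDataset:
    """Draw the gene x cell NB count matrix for a composition table."""
    rng = config.rng(2)
    gene_names, markers = make_gene_names(config)
    means = _cluster_means(config, gene_names, markers)
    size = config.nb_dispersion

    cell_rows = []
    blocks = []
    for _, row in composition.iterrows():
        n_cells = int(row["cell_count"])
        if n_cells == 0:
            continue
        mu = means[row["cluster"]]
        p = size / (size + mu)
        block = rng.negative_binomial(size, p[None, :], size=(n_cells, config.n_genes))
        blocks.append(sparse.csr_matrix(block))
        for i in range(n_cells):
            cell_rows.append((row["sample_id"], row["genotype"], row["cluster"]))
    X = sparse.vstack(blocks).T.tocsr()  # gene x cell
    cells = pd.DataFrame(cell_rows, columns=["sample_id", "genotype", "cluster"])
    cells.insert(0, "cell_id", [f"{s}_c{i + 1}" for i, s in enumerate(cells["sample_id"])])
    cells = qc.compute_qc_metrics(X, gene_names, cells)
    truth = {
        "markers": markers,
        "cluster_means": means,
        "config": config,
    }
    return SyntheticDataset(counts=X, gene_names=gene_names, cells=cells, truth=truth)


def gen_histology(
    config: SimConfig,
    mice_per_genotype: int | Sequence[int] | None = None,
    genotypes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-mouse histology measures from a Gaussian copula.

    Latent draws share the target correlation matrix; each measure is a
    linear rescale to the genotype's mean and SD, truncated at zero, with
    counts rounded to integers. The linear map preserves Pearson
    correlations exactly; truncation and rounding perturb them slightly.

    Returns (table, truth) where truth holds the target correlations and
    per-genotype means actually used.
    """
    R = np.asarray(config.histo_corr, dtype=float)
    if R.shape != (5, 5) or not np.allclose(R, R.T):
        raise ValueError(f"histo_corr must be a symmetric 5x5 matrix, got\n{R}")
    eigvals = np.linalg.eigvalsh(R)
    if eigvals.min() < -1e-10:
        raise ValueError(f"histo_corr is not positive semi-definite:\n{R}\neigenvalues {eigvals}")
    L = np.linalg.cholesky(R + 1e-12 * np.eye(5))

    genotypes = tuple(genotypes) if genotypes is not None else config.genotypes
    if mice_per_genotype is None:
        counts = config.mice_counts()[: len(genotypes)]
    elif isinstance(mice_per_genotype, (int, np.integer)):
        counts = [int(mice_per_genotype)] * len(genotypes)
    else:
        counts = list(mice_per_genotype)

    rng = config.rng(3)
    rows = []
    for g, n_mice in zip(genotypes, counts):
        mu = np.asarray(config.histo_means.get(g, config.histo_means["hPS-5X"]), dtype=float)
        sd = np.maximum(np.asarray(_HISTO_SD_FRACTIONS) * mu, _HISTO_SD_FLOORS)
        z = rng.standard_normal((n_mice, 5)) @ L.T
        vals = np.maximum(mu + sd * z, 0.0)
        for m in range(n_mice):
            rows.append(
                {
                    "mouse_id": f"{g}_m{m + 1}",
                    "genotype": g,
                    "amylo_volume": vals[m, 0],
                    "abeta_volume": vals[m, 1],
                    "at8_volume": vals[m, 2],
                    "neun_count": int(round(vals[m, 3])),
                    "rod_count": int(round(vals[m, 4])),
                }
            )
    table = pd.DataFrame(rows)
    truth = {"corr": R, "means": {g: config.histo_means.get(g) for g in genotypes}}
    return table, truth


@dataclass
class ShapeObject:
    object_id: str
    mouse_id: str
    region: str
    label: str  # "rod" or "ramified"
    points: np.ndarray  # (n, 3) in micrometres
    true_lengths: tuple[float, float, float]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _box_points(dims, n_points, rng) -> np.ndarray:
    half = np.asarray(dims, dtype=float) / 2.0
    corners = np.array(
        [[sx * half[0], sy * half[1], sz * half[2]] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    )
    interior = rng.uniform(-half, half, size=(max(n_points - 8, 0), 3))
    return np.vstack([corners, interior])


def gen_shapes(
    config: SimConfig,
    n_rod: int = 20,
    n_ramified: int = 40,
    n_points: int = 400,
    rod_dims: tuple[float, float, float] = (60.0, 8.0, 8.0),
    ramified_dims: tuple[float, float, float] = (30.0, 24.0, 20.0),
    region: str = "CA1",
) -> list[ShapeObject]:
    """Point clouds of rod-like (elongated, >50 um principal extent) and
    ramified (roughly isotropic, <50 um) cells at random orientations.

    The eight box corners are always included so the ground-truth axis
    lengths equal the template dimensions exactly.
    """
    rng = config.rng(4)
    shapes = []
    for i in range(n_rod + n_ramified):
        label = "rod" if i < n_rod else "ramified"
        dims = rod_dims if label == "rod" else ramified_dims
        pts = _box_points(dims, n_points, rng)
        rot = _random_rotation(rng)
        offset = rng.uniform(-200, 200, size=3)
        pts = pts @ rot.T + offset
        shapes.append(
            ShapeObject(
                object_id=f"obj{i + 1:04d}",
                mouse_id=f"sim_m{i % 4 + 1}",
                region=region,
                label=label,
                points=pts,
                true_lengths=tuple(sorted(dims, reverse=True)),
            )
        )
    return shapes
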