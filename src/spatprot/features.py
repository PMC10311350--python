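"""Per-sample featurizations of cell tables.

Spatial featurizers
    * :func:`neighborhood_matrix` — the k-NN cell-type neighborhood matrix:
      entry (i, j) is the mean, over cells of type i, of the fraction of
      their k nearest neighbors of type j; every present row sums to 1.
    * :func:`spatial_marker_features` — per-biomarker normalized
      mark-weighted L values evaluated at fixed radii (2 per biomarker).

Non-spatial featurizers
    * :func:`cell_type_proportions`
    * :func:`positivity_fractions` and :func:`neighbor_interaction_features`
      (threshold-based comparison featurization)
    * :func:`denvar_features` (expression-density clustering comparison
      featurization)

:func:`assemble_features` concatenates named feature groups into a single
samples × features matrix, imputing flagged-missing entries with 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from spatprot.datamodel import BiomarkerPanel, CellTable, CellTypeSet
from spatprot.spatial import (
    DEFAULT_FEATURE_RADII,
    PointPattern,
    Window,
    default_r_grid,
    evaluate_feature_radii,
    normalized_mark_l_multi,
)

__all__ = [
    "NeighborhoodMatrix",
    "FeatureMatrix",
    "knn_indices",
    "cell_type_proportions",
    "neighborhood_matrix",
    "spatial_marker_features",
    "positivity_fractions",
    "neighbor_interaction_features",
    "denvar_features",
    "assemble_features",
]


@dataclass
class NeighborhoodMatrix:
    """C × C k-NN neighborhood composition matrix for one sample.

    ``present[i]`` is False when no cell of type i exists in the sample; such
    rows are NaN and flagged for downstream imputation.
    """

    matrix: np.ndarray
    types: CellTypeSet
    k: int
    present: np.ndarray

    def to_vector(self) -> pd.Series:
        names = [
            f"nbr_{ti}_{tj}" for ti in self.types.names for tj in self.types.names
        ]
        return pd.Series(self.matrix.ravel(), index=names)


@dataclass
class FeatureMatrix:
    """Samples × named features, with per-group provenance and imputation log."""

    data: pd.DataFrame  # index = sample_id
    groups: dict[str, list[str]] = field(default_factory=dict)
    imputed: list[tuple[str, str]] = field(default_factory=list)  # (sample, feature)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def to_csv(self, path) -> None:
        self.data.rename_axis("sample_id").to_csv(path, float_format="%.12g")


def knn_indices(coords: np.ndarray, k: int, cell_order=None) -> np.ndarray:
    """Indices of each point's k nearest neighbors (self excluded).

    Exact distance ties are broken by position in ``cell_order`` (default:
    row order) so results are deterministic.
    """
    from scipy.spatial import cKDTree

    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} cells, got {n}")
    order = np.arange(n) if cell_order is None else np.asarray(cell_order)
    # query extra neighbors so distance ties at rank k can be re-broken
    k_query = min(n, k + 8)
    dist, idx = cKDTree(coords).query(coords, k=k_query)
    out = np.empty((n, k), dtype=int)
    for i in range(n):
        cand_d, cand_i = dist[i], idx[i]
        keep = cand_i != i
        cand_d, cand_i = cand_d[keep], cand_i[keep]
        sel = np.lexsort((order[cand_i], cand_d))[:k]
        out[i] = cand_i[sel]
    return out


def _require_typed(table: CellTable) -> np.ndarray:
    types = table.cell_types
    if types.isna().any():
        bad = table.data.loc[types.isna(), "cell_id"].iloc[0]
        raise ValueError(f"cell {bad!r} in sample {table.sample_id!r} is untyped")
    return types.to_numpy()


def cell_type_proportions(table: CellTable, types: CellTypeSet) -> pd.Series:
    """Fraction of cells of each type; sums to 1."""
    labels = _require_typed(table)
    unknown = set(labels) - set(types.names)
    if unknown:
        raise ValueError(f"labels not in cell-type set: {sorted(unknown)}")
    counts = pd.Series(labels).value_counts()
    vec = np.array([counts.get(t, 0) for t in types.names], dtype=float)
    return pd.Series(vec / vec.sum(), index=[f"prop_{t}" for t in types.names])


def neighborhood_matrix(
    table: CellTable, types: CellTypeSet, k: int = 10
) -> NeighborhoodMatrix:
    """k-NN cell-type neighborhood matrix (default k = 10).

    For each cell, its k nearest neighbors by centroid Euclidean distance are
    typed; entry (i, j) is the fraction of type-j neighbors averaged over all
    cells of type i. Rows of present types sum to 1; rows of absent types are
    NaN and flagged.
    """
    labels = _require_typed(table)
    type_idx = np.array([types.index_of(t) for t in labels])
    nbrs = knn_indices(table.coords, k)
    C = len(types)
    nbr_types = type_idx[nbrs]  # (n, k)
    # per-cell composition of its neighborhood
    comp = np.zeros((len(labels), C))
    for j in range(C):
        comp[:, j] = (nbr_types == j).mean(axis=1)
    matrix = np.full((C, C), np.nan)
    present = np.zeros(C, dtype=bool)
    for i in range(C):
        sel = type_idx == i
        if sel.any():
            present[i] = True
            matrix[i] = comp[sel].mean(axis=0)
    return NeighborhoodMatrix(matrix, types, k, present)


def spatial_marker_features(
    table: CellTable,
    panel: BiomarkerPanel | None = None,
    radii=None,
    r_grid=None,
) -> pd.Series:
    """Normalized mark-weighted L values per biomarker at fixed radii.

    Each cell centroid is a point; each biomarker's per-cell expression is
    that point's mark. For every biomarker the normalized statistic
    L̂^{w,m}(r) − L̂(r) is evaluated at the feature radii (default 80 and
    212 px), giving a 2B-length vector ordered biomarker-major. Marks with
    negative values (z-scored expression) are shifted per sample to minimum
    0 before weighting; constant marks yield exactly 0.
    """
    if panel is None:
        panel = table.panel
    if radii is None:
        radii = DEFAULT_FEATURE_RADII
    if r_grid is None:
        r_grid = default_r_grid()
    if table.n_cells < 2:
        raise ValueError("need at least 2 cells")
    expr = table.expression
    marks, constant = {}, []
    for b, name in enumerate(panel.names):
        m = expr[:, b]
        if np.ptp(m) == 0:
            constant.append(name)
            continue
        if m.min() < 0:
            m = m - m.min()
        marks[name] = m
    pattern = PointPattern(table.coords, marks=marks)
    estimates = normalized_mark_l_multi(pattern, list(marks), r_grid)
    values, names = [], []
    for name in panel.names:
        if name in constant:
            vals = np.zeros(len(radii))
        else:
            vals = evaluate_feature_radii(estimates[name], radii)
        values.extend(vals)
        names.extend(f"lwnorm_{name}_r{r:g}" for r in np.asarray(radii, dtype=float))
    return pd.Series(values, index=names)


def positivity_fractions(table: CellTable, thresholds: np.ndarray) -> pd.Series:
    """Fraction of cells whose mean expression exceeds each biomarker's
    background-derived positivity threshold."""
    thresholds = np.asarray(thresholds, dtype=float)
    frac = (table.expression > thresholds).mean(axis=0)
    return pd.Series(frac, index=[f"pos_{m}" for m in table.panel.names])


def neighbor_interaction_features(
    table: CellTable, thresholds: np.ndarray, k: int = 10
) -> pd.Series:
    """Directional biomarker co-positivity among k-NN neighbors.

    Entry (a, b): among cells positive for biomarker a, the mean fraction of
    their k nearest neighbors positive for b. NaN (flagged missing) when no
    cell is positive for a.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    positive = table.expression > thresholds  # (n, B)
    nbrs = knn_indices(table.coords, k)
    nbr_frac = positive[nbrs].mean(axis=1)  # (n, B): fraction of NNs positive per marker
    B = positive.shape[1]
    out = np.full((B, B), np.nan)
    for a in range(B):
        sel = positive[:, a]
        if sel.any():
            out[a] = nbr_frac[sel].mean(axis=0)
    names = [
        f"nbrpos_{a}_{b}" for a in table.panel.names for b in table.panel.names
    ]
    return pd.Series(out.ravel(), index=names)


# ---------------------------------------------------------------------------
# Expression-density clustering ("DenVar"-style comparison featurization)


def _density_on_grid(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Gaussian KDE (Silverman bandwidth) evaluated on a fixed grid and
    renormalized to a discrete probability vector. Degenerate (constant)
    samples become a point mass on the nearest grid point."""
    from scipy.stats import gaussian_kde

    if np.ptp(values) == 0:
        dens = np.zeros_like(grid)
        dens[np.argmin(np.abs(grid - values[0]))] = 1.0
        return dens
    dens = gaussian_kde(values, bw_method="silverman")(grid)
    total = dens.sum()
    return dens / total if total > 0 else np.full_like(grid, 1.0 / len(grid))


def denvar_features(
    tables: list[CellTable], panel: BiomarkerPanel | None = None, grid_size: int = 512
) -> pd.DataFrame:
    """Binary per-sample cluster labels from biomarker expression densities.

    Per biomarker: a kernel density estimate of the cell-level expression of
    each sample on a common grid, pairwise Jensen–Shannon distances (base-2,
    bounded by 1) between sample densities, average-linkage hierarchical
    clustering cut into 2 clusters. The cluster whose samples have the
    larger median expression is coded 1.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import jensenshannon, squareform

    if len(tables) < 2:
        raise ValueError("need at least 2 samples")
    if panel is None:
        panel = tables[0].panel
    sample_ids = [t.sample_id for t in tables]
    out = pd.DataFrame(index=sample_ids, dtype=float)
    for b, name in enumerate(panel.names):
        values = [t.expression[:, b] for t in tables]
        lo = min(v.min() for v in values)
        hi = max(v.max() for v in values)
        pad = 0.05 * (hi - lo) if hi > lo else 1.0
        grid = np.linspace(lo - pad, hi + pad, grid_size)
        dens = np.array([_density_on_grid(v, grid) for v in values])
        m = len(tables)
        dist = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                dist[i, j] = dist[j, i] = jensenshannon(dens[i], dens[j], base=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # identical densities give 0 distances
            z = linkage(squareform(dist, checks=False), method="average")
        assign = fcluster(z, t=2, criterion="maxclust")
        medians = [np.median(np.concatenate([v for v, a in zip(values, assign) if a == c]))
                   if (assign == c).any() else -np.inf for c in (1, 2)]
        high = 1 if medians[0] >= medians[1] else 2
        out[f"denvar_{name}"] = (assign == high).astype(float)
    return out


def assemble_features(groups: dict[str, pd.DataFrame], impute_value: float = 0.0) -> FeatureMatrix:
    """Concatenate named per-sample feature groups into one matrix.

    All groups must cover the same samples; duplicate feature names raise.
    Flagged-missing entries (NaN, e.g. rows for absent cell types) are
    imputed with ``impute_value`` and logged.
    """
    if not groups:
        raise ValueError("no feature groups given")
    frames, manifest = [], {}
    index = None
    for name, frame in groups.items():
        frame = frame.sort_index()
        if index is None:
            index = frame.index
        elif not frame.index.equals(index):
            raise ValueError(f"feature group {name!r} covers different samples")
        frames.append(frame)
        manifest[name] = list(frame.columns)
    data = pd.concat(frames, axis=1)
    if data.columns.duplicated().any():
        dup = data.columns[data.columns.duplicated()][0]
        raise ValueError(f"duplicate feature name {dup!r}")
    imputed = [
        (str(data.index[i]), str(data.columns[j]))
        for i, j in zip(*np.nonzero(data.isna().to_numpy()))
    ]
    return FeatureMatrix(data.fillna(impute_value), manifest, imputed)
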