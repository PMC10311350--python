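"""Core data types, delimited-text I/O, expression normalization and cell typing.

The central exchange format is the :class:`CellTable`: one segmented imaging
sample holding, per cell, a centroid in pixel coordinates (x = column,
y = row, origin top-left), an optional cell-type label, and a biomarker
expression vector over a shared :class:`BiomarkerPanel`. Clinical metadata
(patient/sample/coverslip mapping and right-censored survival outcome) lives
in a :class:`ClinicalTable`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BiomarkerPanel",
    "CellTypeSet",
    "CellTable",
    "ClinicalTable",
    "SchemaError",
    "ValidationReport",
    "read_name_list",
    "write_name_list",
    "read_cell_table",
    "write_cell_table",
    "read_clinical_table",
    "write_clinical_table",
    "normalize_expression",
    "cluster_and_type",
    "knn_label_transfer",
    "validate_dataset",
]

#: columns every cell table carries besides the biomarker block
CELL_META_COLUMNS = ("cell_id", "x", "y", "cell_type")


class SchemaError(ValueError):
    """A table does not conform to the expected schema."""


@dataclass(frozen=True)
class BiomarkerPanel:
    """Ordered, fixed set of biomarker names shared by a dataset."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(str(n) for n in self.names))
        if len(set(self.names)) != len(self.names):
            raise SchemaError("biomarker names must be unique")
        if not self.names:
            raise SchemaError("panel must contain at least one biomarker")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)


@dataclass(frozen=True)
class CellTypeSet:
    """Ordered set of cell-type names; the order fixes matrix/vector layouts."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(str(n) for n in self.names))
        if len(set(self.names)) != len(self.names):
            raise SchemaError("cell-type names must be unique")
        if not self.names:
            raise SchemaError("cell-type set must contain at least one name")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def index_of(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class CellTable:
    """One sample's cells: centroids, optional type labels, expression block.

    ``data`` holds one row per cell with columns ``cell_id, x, y, cell_type``
    followed by one column per panel biomarker, in panel order. ``cell_type``
    may contain missing values (``NaN``/``None``) for untyped cells.
    """

    sample_id: str
    data: pd.DataFrame
    panel: BiomarkerPanel

    def __post_init__(self) -> None:
        df = self.data
        for col in ("cell_id", "x", "y"):
            if col not in df.columns:
                raise SchemaError(f"cell table missing required column {col!r}")
        if "cell_type" not in df.columns:
            df = df.assign(cell_type=pd.Series([None] * len(df), dtype=object))
        missing = [m for m in self.panel.names if m not in df.columns]
        if missing:
            raise SchemaError(
                f"cell table for sample {self.sample_id!r} missing biomarker "
                f"column(s): {', '.join(missing)}"
            )
        # normalize column order: meta first, then panel order
        df = df[list(CELL_META_COLUMNS) + list(self.panel.names)].copy()
        df["cell_id"] = df["cell_id"].astype(str)
        for col in ("x", "y"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.index[vals.isna()]
            if len(bad):
                raise SchemaError(
                    f"non-numeric coordinate {col!r} at row {int(bad[0])} "
                    f"of sample {self.sample_id!r}"
                )
            df[col] = vals.astype(float)
        if not np.isfinite(df[["x", "y"]].to_numpy()).all():
            raise SchemaError(f"non-finite coordinates in sample {self.sample_id!r}")
        if df["cell_id"].duplicated().any():
            dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
            raise SchemaError(f"duplicate cell_id {dup!r} in sample {self.sample_id!r}")
        df[list(self.panel.names)] = df[list(self.panel.names)].astype(float)
        self.data = df.reset_index(drop=True)

    @property
    def n_cells(self) -> int:
        return len(self.data)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (x, y) centroids."""
        return self.data[["x", "y"]].to_numpy()

    @property
    def expression(self) -> np.ndarray:
        """(n, B) expression block in panel order."""
        return self.data[list(self.panel.names)].to_numpy()

    @property
    def cell_types(self) -> pd.Series:
        return self.data["cell_type"]

    def with_expression(self, expr: np.ndarray) -> "CellTable":
        df = self.data.copy()
        df[list(self.panel.names)] = np.asarray(expr, dtype=float)
        return CellTable(self.sample_id, df, self.panel)

    def with_cell_types(self, labels) -> "CellTable":
        df = self.data.copy()
        df["cell_type"] = list(labels)
        return CellTable(self.sample_id, df, self.panel)


@dataclass
class ClinicalTable:
    """Patient/sample/coverslip mapping plus right-censored outcomes.

    One row per sample: ``patient_id, sample_id, coverslip_id, time, event``
    and optional covariate columns (e.g. HPV status). ``event`` is 1 if the
    terminal event was observed and 0 if the observation is censored; all
    samples of a patient share the same ``(time, event)``.
    """

    data: pd.DataFrame

    REQUIRED = ("patient_id", "sample_id", "coverslip_id", "time", "event")

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise SchemaError(f"clinical table missing required column {col!r}")
        for col in ("patient_id", "sample_id", "coverslip_id"):
            df[col] = df[col].astype(str)
        df["time"] = pd.to_numeric(df["time"]).astype(float)
        df["event"] = pd.to_numeric(df["event"]).astype(int)
        if (df["time"] <= 0).any():
            raise SchemaError("survival times must be positive")
        if not df["event"].isin((0, 1)).all():
            raise SchemaError("event indicator must be 0 (censored) or 1 (event)")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise SchemaError(f"sample_id {dup!r} appears more than once")
        bad = (
            df.groupby("patient_id")[["time", "event"]].nunique().max(axis=1) > 1
        )
        if bad.any():
            pid = bad.index[bad.argmax()]
            raise SchemaError(
                f"patient {pid!r} has inconsistent (time, event) across samples"
            )
        self.data = df.reset_index(drop=True)

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.REQUIRED]

    def sample_to_patient(self) -> dict[str, str]:
        return dict(zip(self.data["sample_id"], self.data["patient_id"]))

    def sample_to_coverslip(self) -> dict[str, str]:
        return dict(zip(self.data["sample_id"], self.data["coverslip_id"]))

    def patient_outcomes(self) -> pd.DataFrame:
        """One row per patient: ``time``, ``event`` (index = patient_id)."""
        return (
            self.data.groupby("patient_id")[["time", "event"]].first().sort_index()
        )


# ---------------------------------------------------------------------------
# I/O


def _read_delimited(path) -> pd.DataFrame:
    """Read a comma- or tab-separated file with header, auto-detecting the dialect."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") > header.count(",") else ","
    return pd.read_csv(path, sep=sep, dtype={"cell_id": str, "sample_id": str})


def read_name_list(path) -> tuple[str, ...]:
    """Read a one-name-per-line text file (panel or cell-type set)."""
    with open(path, "r", encoding="utf-8") as fh:
        return tuple(line.strip() for line in fh if line.strip())


def write_name_list(names, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in names:
            fh.write(f"{name}\n")


def read_cell_table(path, panel: BiomarkerPanel, sample_id: str | None = None) -> CellTable:
    """Read a per-sample cell table from delimited text.

    The file must carry ``x``, ``y``, ``cell_id`` and one column per panel
    biomarker; ``cell_type`` and ``sample_id`` columns are optional. When the
    file has no ``sample_id`` column the caller must supply one.
    """
    df = _read_delimited(path)
    if sample_id is None:
        if "sample_id" not in df.columns:
            raise SchemaError(f"{path}: no sample_id column and none supplied")
        ids = df["sample_id"].unique()
        if len(ids) != 1:
            raise SchemaError(f"{path}: expected exactly one sample_id, found {len(ids)}")
        sample_id = str(ids[0])
    df = df.drop(columns=["sample_id"], errors="ignore")
    return CellTable(sample_id, df, panel)


def write_cell_table(table: CellTable, path) -> None:
    """Write a cell table as comma-separated UTF-8 with a ``sample_id`` column.

    Floats are written with 12 significant digits so a read/write round-trip
    is value-exact for decimal inputs at that precision.
    """
    df = table.data.copy()
    df.insert(0, "sample_id", table.sample_id)
    df.to_csv(path, index=False, float_format="%.12g")


def read_clinical_table(path) -> ClinicalTable:
    return ClinicalTable(_read_delimited(path))


def write_clinical_table(clinical: ClinicalTable, path) -> None:
    clinical.data.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Expression normalization and cell typing


def normalize_expression(
    tables: list[CellTable], scope: str = "dataset"
) -> list[CellTable]:
    """Per-biomarker z-scoring of expression values.

    scope="dataset" pools all cells of all tables for each biomarker's mean
    and standard deviation (the default: typing is trained on cells pooled
    across samples); scope="sample" standardizes each table on its own.
    The population (divide-by-n) standard deviation is used. Zero-variance
    biomarkers map to 0 with a warning.
    """
    if scope not in ("dataset", "sample"):
        raise ValueError(f"unknown scope {scope!r}")
    if not tables:
        raise ValueError("need at least one table")
    panel = tables[0].panel
    if any(t.panel != panel for t in tables):
        raise SchemaError("all tables must share the same panel")

    def _zscore(block: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
        flat = sd == 0
        if flat.any():
            names = [panel.names[i] for i in np.flatnonzero(flat)]
            warnings.warn(
                f"zero-variance biomarker(s) {names}: normalized values set to 0",
                stacklevel=3,
            )
        safe = np.where(flat, 1.0, sd)
        out = (block - mean) / safe
        out[:, flat] = 0.0
        return out

    if scope == "dataset":
        pooled = np.vstack([t.expression for t in tables])
        mean, sd = pooled.mean(axis=0), pooled.std(axis=0)
        return [t.with_expression(_zscore(t.expression, mean, sd)) for t in tables]
    out = []
    for t in tables:
        block = t.expression
        out.append(t.with_expression(_zscore(block, block.mean(axis=0), block.std(axis=0))))
    return out


def cluster_and_type(
    table: CellTable,
    n_pcs: int = 20,
    knn_k: int = 30,
    seed: int = 0,
    resolution: float = 1.0,
) -> np.ndarray:
    """Cluster cells by expression: PCA, k-NN graph, modularity community detection.

    Expression should already be normalized. Returns integer cluster labels
    (0-based, ordered by decreasing cluster size). Deterministic given seed.
    """
    import networkx as nx
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    n = table.n_cells
    if n < knn_k + 1:
        raise ValueError(f"need at least knn_k+1={knn_k + 1} cells, got {n}")
    expr = table.expression
    n_pcs = min(n_pcs, expr.shape[1], n)
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(expr)
    nn = NearestNeighbors(n_neighbors=knn_k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    graph.add_edges_from((i, j) for i in range(n) for j in idx[i, 1:])
    communities = nx.community.louvain_communities(
        graph, resolution=resolution, seed=seed
    )
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(communities):
        labels[list(members)] = lab
    return labels


def knn_label_transfer(reference, query: np.ndarray, k: int) -> np.ndarray:
    """Transfer labels from a typed reference to query cells by k-NN majority vote.

    ``reference`` is a tuple ``(expr_matrix, labels)`` in the same normalized
    expression space as ``query``. Vote ties go to the class whose voting
    neighbors have the smallest distance sum.
    """
    from sklearn.neighbors import NearestNeighbors

    ref_x, ref_labels = reference
    ref_x = np.asarray(ref_x, dtype=float)
    ref_labels = np.asarray(ref_labels)
    if ref_x.shape[0] == 0:
        raise ValueError("empty reference")
    if k > ref_x.shape[0]:
        raise ValueError(f"k={k} exceeds reference size {ref_x.shape[0]}")
    query = np.atleast_2d(np.asarray(query, dtype=float))
    nn = NearestNeighbors(n_neighbors=k).fit(ref_x)
    dist, idx = nn.kneighbors(query)
    out = np.empty(query.shape[0], dtype=ref_labels.dtype)
    for i in range(query.shape[0]):
        neigh = ref_labels[idx[i]]
        classes, counts = np.unique(neigh, return_counts=True)
        best = classes[counts == counts.max()]
        if len(best) == 1:
            out[i] = best[0]
        else:
            sums = {c: dist[i][neigh == c].sum() for c in best}
            out[i] = min(sums, key=lambda c: (sums[c], str(c)))
    return out


# ---------------------------------------------------------------------------
# Dataset validation


@dataclass
class ValidationReport:
    """Findings from a consistency check of cell tables against clinical data."""

    orphan_samples: list[str] = field(default_factory=list)
    unmatched_clinical: list[str] = field(default_factory=list)
    inconsistent_patients: list[str] = field(default_factory=list)
    empty_samples: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.orphan_samples
            or self.unmatched_clinical
            or self.inconsistent_patients
            or self.empty_samples
        )

    def findings(self) -> list[str]:
        out = []
        out += [f"sample {s!r} has no clinical row" for s in self.orphan_samples]
        out += [f"clinical row for unknown sample {s!r}" for s in self.unmatched_clinical]
        out += [
            f"patient {p!r} has inconsistent (time, event)"
            for p in self.inconsistent_patients
        ]
        out += [f"sample {s!r} has no cells" for s in self.empty_samples]
        return out


def validate_dataset(
    tables: list[CellTable],
    clinical: ClinicalTable | pd.DataFrame,
    strict: bool = False,
) -> ValidationReport:
    """Cross-check cell tables against the clinical table.

    Reports orphan samples (no clinical row), clinical rows without a cell
    table, patients whose samples disagree on (time, event), and empty
    samples. With ``strict=True`` any finding raises.

    A raw DataFrame may be passed for ``clinical`` so inconsistencies that
    :class:`ClinicalTable` itself would reject can still be reported.
    """
    df = clinical.data if isinstance(clinical, ClinicalTable) else clinical
    report = ValidationReport()
    clinical_samples = set(df["sample_id"].astype(str))
    table_samples = {t.sample_id for t in tables}
    report.orphan_samples = sorted(table_samples - clinical_samples)
    report.unmatched_clinical = sorted(clinical_samples - table_samples)
    counts = df.groupby("patient_id")[["time", "event"]].nunique().max(axis=1)
    report.inconsistent_patients = sorted(counts.index[counts > 1].astype(str))
    report.empty_samples = sorted(t.sample_id for t in tables if t.n_cells == 0)
    if strict and not report.ok:
        raise SchemaError("; ".join(report.findings()))
    return report
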