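"""Synthetic multiplexed-imaging cohorts with controlled spatial structure.

Generates datasets with the structure of a segmented CODEX-style cohort —
multiple samples per patient, coverslip batches, per-cell type labels and
biomarker expression, right-censored survival — at desk scale, with knobs
for the spatial properties every featurizer measures: the point process
(complete spatial randomness, Thomas clustering, hardcore inhibition), mark
models (independent, cluster-elevated, distance-decay), spatially mixed or
segregated cell-type layouts, and survival hazards driven by named features
such as a neighborhood-matrix entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from spatprot.datamodel import (
    BiomarkerPanel,
    CellTable,
    CellTypeSet,
    ClinicalTable,
    validate_dataset,
)
from spatprot.features import neighborhood_matrix
from spatprot.spatial import PointPattern, Window

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "sim_points",
    "sim_marks",
    "sim_cell_types",
    "sim_survival",
    "render_images",
    "generate_dataset",
]


@dataclass
class SimConfig:
    """Configuration of a synthetic cohort.

    Defaults describe the desk-scale study conditions used throughout the
    test suite: 20 patients with 2 samples each on 4 coverslips, ~300 cells
    per sample in a 1000×1000 px window, 8 biomarkers, 4 cell types, 30%
    censoring. This is roughly two orders of magnitude below a real CODEX
    cohort (hundreds of samples, thousands of cells each) but preserves its
    structure.
    """

    window_size: float = 1000.0
    n_patients: int = 20
    samples_per_patient: int = 2
    n_coverslips: int = 4
    cells_per_sample: float = 300.0  # Poisson mean
    process: str = "csr"  # csr | thomas | hardcore
    thomas_mu: float = 20.0  # mean offspring per parent
    thomas_sigma: float = 30.0  # parent-offspring displacement sd, px
    hardcore_radius: float = 10.0
    n_types: int = 4
    composition: tuple | None = None  # default: uniform over types
    mixing: float = 1.0  # 1 = iid labels; <1 = spatially segregated
    mixing_range: tuple | None = None  # per-patient U(lo, hi) overrides mixing
    n_region_seeds: int = 8
    n_biomarkers: int = 8
    type_signature_fold: float = 3.0  # expression elevation of a type's marker
    expression_sigma: float = 0.5  # lognormal shape of baseline expression
    mark_model: str = "iid"  # iid | cluster_elevated | distance_decay
    mark_fold: float = 5.0
    baseline_hazard: float = 1e-3  # events per day
    beta: dict = field(default_factory=dict)  # feature name -> log-hazard coef
    censoring_rate: float = 0.3
    render_images: bool = False
    image_size: int = 256
    cell_radius: float = 3.0
    image_background: float = 0.5
    image_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring rate must be in [0, 1)")
        if self.baseline_hazard <= 0 or self.cells_per_sample <= 0:
            raise ValueError("rates must be positive")

    @property
    def panel(self) -> BiomarkerPanel:
        return BiomarkerPanel(tuple(f"M{b:02d}" for b in range(self.n_biomarkers)))

    @property
    def types(self) -> CellTypeSet:
        return CellTypeSet(tuple(f"T{t}" for t in range(self.n_types)))

    @property
    def window(self) -> Window:
        return Window(0.0, 0.0, self.window_size, self.window_size)


# ---------------------------------------------------------------------------
# Point patterns, marks, labels


def sim_points(
    window: Window,
    n_mean: float,
    process: str = "csr",
    seed: int = 0,
    thomas_mu: float = 20.0,
    thomas_sigma: float = 30.0,
    hardcore_radius: float = 10.0,
) -> tuple[PointPattern, np.ndarray | None]:
    """Simulate a point pattern; returns (pattern, parent_centers_or_None).

    csr: Poisson(n_mean) points placed uniformly. thomas: Poisson parents
    (mean n_mean/μ) placed uniformly, each with Poisson(μ) offspring
    displaced N(0, σ²) and clipped to the window by rejection. hardcore:
    dart throwing with rejection radius until Poisson(n_mean) points are
    placed (error when packing is infeasible).
    """
    rng = np.random.default_rng(seed)
    lo = np.array([window.x_min, window.y_min])
    hi = np.array([window.x_max, window.y_max])
    if process == "csr":
        n = max(2, rng.poisson(n_mean))
        pts = rng.uniform(lo, hi, size=(n, 2))
        return PointPattern(pts, window), None
    if process == "thomas":
        n_parents = max(1, rng.poisson(n_mean / thomas_mu))
        parents = rng.uniform(lo, hi, size=(n_parents, 2))
        pts = []
        for p in parents:
            k = rng.poisson(thomas_mu)
            off = p + rng.normal(0.0, thomas_sigma, size=(k, 2))
            inside = (
                (off[:, 0] >= lo[0]) & (off[:, 0] <= hi[0])
                & (off[:, 1] >= lo[1]) & (off[:, 1] <= hi[1])
            )
            pts.append(off[inside])
        pts = np.vstack(pts) if pts else np.empty((0, 2))
        if len(pts) < 2:  # guarantee a usable pattern
            pts = np.vstack([pts, rng.uniform(lo, hi, size=(2, 2))])
        return PointPattern(pts, window), parents
    if process == "hardcore":
        n = max(2, rng.poisson(n_mean))
        placed = []
        attempts = 0
        while len(placed) < n:
            attempts += 1
            if attempts > 200 * n:
                raise RuntimeError(
                    f"hardcore packing of {n} points at radius {hardcore_radius} "
                    "infeasible in this window"
                )
            cand = rng.uniform(lo, hi, size=2)
            if not placed or (
                np.linalg.norm(np.array(placed) - cand, axis=1) >= hardcore_radius
            ).all():
                placed.append(cand)
        return PointPattern(np.array(placed), window), None
    raise ValueError(f"unknown point process {process!r}")


def sim_marks(
    pattern: PointPattern,
    mark_model: str = "iid",
    seed: int = 0,
    fold: float = 5.0,
    parents: np.ndarray | None = None,
    cluster_scale: float = 30.0,
    sigma: float = 0.5,
) -> np.ndarray:
    """Simulate non-negative marks for a pattern.

    iid: lognormal marks independent of location. cluster_elevated: iid
    baseline multiplied by ``fold`` for points within ``cluster_scale`` of
    any parent center (``fold=1`` reduces to iid). distance_decay: the
    nearest-neighbor distance rescaled to mean 1, so the mark is
    anti-correlated with local density.
    """
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=0.0, sigma=sigma, size=pattern.n)
    if mark_model == "iid":
        return base
    if mark_model == "cluster_elevated":
        if parents is None or len(parents) == 0:
            raise ValueError("cluster_elevated marks require parent centers")
        from scipy.spatial import cKDTree

        d, _ = cKDTree(parents).query(pattern.points)
        return np.where(d <= cluster_scale, fold * base, base)
    if mark_model == "distance_decay":
        from scipy.spatial import cKDTree

        d, _ = cKDTree(pattern.points).query(pattern.points, k=2)
        nn = d[:, 1]
        return nn / nn.mean()
    raise ValueError(f"unknown mark model {mark_model!r}")


def sim_cell_types(
    pattern: PointPattern,
    composition: np.ndarray,
    mixing: float = 1.0,
    seed: int = 0,
    n_region_seeds: int = 8,
) -> np.ndarray:
    """Assign cell-type indices with controllable spatial autocorrelation.

    Each cell takes an i.i.d. multinomial(composition) label with
    probability ``mixing``; otherwise it inherits the label of its nearest
    region seed (seeds placed uniformly, labeled by the composition).
    mixing = 1 gives spatially independent labels, mixing = 0 fully
    segregated regions.
    """
    composition = np.asarray(composition, dtype=float)
    if not np.isclose(composition.sum(), 1.0):
        raise ValueError("composition must sum to 1")
    rng = np.random.default_rng(seed)
    n = pattern.n
    C = len(composition)
    iid = rng.choice(C, size=n, p=composition)
    if mixing >= 1.0:
        return iid
    from scipy.spatial import cKDTree

    lo = np.array([pattern.window.x_min, pattern.window.y_min])
    hi = np.array([pattern.window.x_max, pattern.window.y_max])
    seeds = rng.uniform(lo, hi, size=(n_region_seeds, 2))
    seed_labels = rng.choice(C, size=n_region_seeds, p=composition)
    _, nearest = cKDTree(seeds).query(pattern.points)
    regional = seed_labels[nearest]
    use_iid = rng.random(n) < mixing
    return np.where(use_iid, iid, regional)


# ---------------------------------------------------------------------------
# Survival outcomes


def _censoring_horizon(hazards: np.ndarray, target_rate: float) -> float:
    """Horizon τ of uniform(0, τ) censoring giving the target expected
    censoring fraction for exponential event times with the given hazards."""
    from scipy.optimize import brentq

    def expected_rate(tau):
        # P(censored) for C ~ U(0, τ), T ~ Exp(λ): (1 - e^{-λτ}) / (λτ)
        lt = hazards * tau
        return float(np.mean((1.0 - np.exp(-lt)) / lt))

    lo, hi = 1e-9, 1.0
    while expected_rate(hi) > target_rate:
        hi *= 2.0
        if hi > 1e12:
            break
    return brentq(lambda t: expected_rate(t) - target_rate, lo, hi)


def sim_survival(
    patient_features: pd.DataFrame,
    beta: dict,
    baseline_hazard: float,
    censoring_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival times with log-linear hazards and uniform censoring.

    Hazard per patient: λ_i = λ0·exp(Σ_f β_f·(x_if − x̄_f)) (features are
    centered so λ0 is the cohort-typical hazard). Censoring times are
    uniform(0, τ) with τ chosen so the expected censoring fraction equals
    ``censoring_rate``; rate 0 disables censoring. Returns (time, event)
    per patient.
    """
    missing = [f for f in beta if f not in patient_features.columns]
    if missing:
        raise ValueError(f"beta names not in features: {missing}")
    rng = np.random.default_rng(seed)
    log_hr = np.zeros(len(patient_features))
    for name, coef in beta.items():
        x = patient_features[name].to_numpy(dtype=float)
        log_hr += coef * (x - x.mean())
    hazards = baseline_hazard * np.exp(log_hr)
    event_times = rng.exponential(1.0 / hazards)
    if censoring_rate <= 0:
        times, events = event_times, np.ones(len(hazards), dtype=int)
    else:
        tau = _censoring_horizon(hazards, censoring_rate)
        censor = rng.uniform(0.0, tau, size=len(hazards))
        times = np.minimum(event_times, censor)
        events = (event_times <= censor).astype(int)
    times = np.maximum(times, 1e-9)
    return pd.DataFrame(
        {"time": times, "event": events}, index=patient_features.index
    )


# ---------------------------------------------------------------------------
# Image rendering


def render_images(
    table: CellTable,
    image_size: int = 256,
    cell_radius: float = 3.0,
    background: float = 0.5,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a cell table as a (B, H, W) channel stack and labeled mask.

    Each cell is a disk centered at its centroid; in overlaps the
    later cell (by row order) wins. Channel intensity inside a cell is its
    expression value, the background a low constant; Gaussian noise is
    added and truncated at zero. With noise 0, per-cell quantification of
    the rendered image recovers the expression exactly.
    """
    rng = np.random.default_rng(seed)
    H = W = int(image_size)
    coords = table.coords
    if (coords < 0).any() or (coords[:, 0] >= W).any() or (coords[:, 1] >= H).any():
        raise ValueError("cell centroids must fit inside the image")
    yy, xx = np.mgrid[0:H, 0:W]
    mask = np.zeros((H, W), dtype=np.int32)
    for row_idx, (cx, cy) in enumerate(coords):
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= cell_radius**2
        mask[disk] = row_idx + 1
    expr = table.expression
    B = expr.shape[1]
    stack = np.full((B, H, W), float(background))
    inside = mask > 0
    for b in range(B):
        channel = stack[b]
        channel[inside] = expr[mask[inside] - 1, b]
    if noise > 0:
        stack = stack + rng.normal(0.0, noise, size=stack.shape)
    return np.clip(stack, 0.0, None), mask


# ---------------------------------------------------------------------------
# Full datasets


@dataclass
class SyntheticDataset:
    """A generated cohort: cell tables, clinical table, optional images,
    and the per-sample feature frame that drove the survival hazards."""

    tables: list[CellTable]
    clinical: ClinicalTable
    config: SimConfig
    hazard_features: pd.DataFrame | None = None
    images: dict | None = None


def _sample_cells(
    config: SimConfig, sample_id: str, mixing: float, seed: int
) -> CellTable:
    window = (
        Window(0, 0, config.image_size, config.image_size)
        if config.render_images
        else config.window
    )
    pattern, parents = sim_points(
        window,
        config.cells_per_sample,
        config.process,
        seed=seed,
        thomas_mu=config.thomas_mu,
        thomas_sigma=config.thomas_sigma,
        hardcore_radius=config.hardcore_radius,
    )
    composition = (
        np.asarray(config.composition, dtype=float)
        if config.composition is not None
        else np.full(config.n_types, 1.0 / config.n_types)
    )
    type_idx = sim_cell_types(
        pattern, composition, mixing, seed=seed + 1, n_region_seeds=config.n_region_seeds
    )
    rng = np.random.default_rng(seed + 2)
    B = config.n_biomarkers
    expr = rng.lognormal(0.0, config.expression_sigma, size=(pattern.n, B))
    # each type elevates its signature biomarker so expression encodes type
    for t in range(config.n_types):
        expr[type_idx == t, t % B] *= config.type_signature_fold
    if config.mark_model != "iid":
        expr[:, 0] = sim_marks(
            pattern,
            config.mark_model,
            seed=seed + 3,
            fold=config.mark_fold,
            parents=parents,
            cluster_scale=config.thomas_sigma,
        )
    types = config.types
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(pattern.n)],
            "x": pattern.points[:, 0],
            "y": pattern.points[:, 1],
            "cell_type": [types.names[t] for t in type_idx],
        }
    )
    df[list(config.panel.names)] = expr
    return CellTable(sample_id, df, config.panel)


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate a fully consistent synthetic cohort, deterministic given the
    config seed.

    Patients are assigned to coverslips round-robin; each patient's samples
    share a latent mixing level (drawn from ``mixing_range`` when set) so
    neighborhood-composition features vary at the patient level. Survival
    hazards are log-linear in the named ``beta`` features, which are
    computed from the generated samples' neighborhood matrices and averaged
    per patient.
    """
    rng = np.random.default_rng(config.seed)
    tables: list[CellTable] = []
    rows = []
    sample_feature_rows = {}
    patient_of = {}
    for p in range(config.n_patients):
        pid = f"P{p:03d}"
        slip = f"CS{p % config.n_coverslips}"
        if config.mixing_range is not None:
            mixing = float(rng.uniform(*config.mixing_range))
        else:
            mixing = config.mixing
        for s in range(config.samples_per_patient):
            sid = f"{pid}_S{s}"
            seed = int(rng.integers(2**31 - 10))
            table = _sample_cells(config, sid, mixing, seed)
            tables.append(table)
            patient_of[sid] = pid
            rows.append({"patient_id": pid, "sample_id": sid, "coverslip_id": slip})
    # features driving the hazard (neighborhood-matrix entries)
    needs_nbr = any(name.startswith("nbr_") for name in config.beta)
    hazard_features = None
    if config.beta:
        feats = {}
        for table in tables:
            vec = {}
            if needs_nbr:
                nm = neighborhood_matrix(table, config.types, k=10)
                vec.update(nm.to_vector().fillna(0.0).to_dict())
            feats[table.sample_id] = vec
        hazard_features = pd.DataFrame(feats).T
        missing = [f for f in config.beta if f not in hazard_features.columns]
        if missing:
            raise ValueError(f"beta names not computable: {missing}")
    patients = sorted({r["patient_id"] for r in rows})
    if hazard_features is not None:
        pf = hazard_features.groupby(
            hazard_features.index.map(patient_of)
        ).mean().loc[patients]
    else:
        pf = pd.DataFrame(index=patients)
    outcomes = sim_survival(
        pf,
        config.beta,
        config.baseline_hazard,
        config.censoring_rate,
        seed=config.seed + 1,
    )
    clin = pd.DataFrame(rows)
    clin["time"] = outcomes.loc[clin["patient_id"], "time"].to_numpy()
    clin["event"] = outcomes.loc[clin["patient_id"], "event"].to_numpy()
    clinical = ClinicalTable(clin)
    images = None
    if config.render_images:
        images = {
            t.sample_id: render_images(
                t,
                config.image_size,
                config.cell_radius,
                config.image_background,
                config.image_noise,
                seed=config.seed + 7 + i,
            )
            for i, t in enumerate(tables)
        }
    dataset = SyntheticDataset(tables, clinical, config, hazard_features, images)
    report = validate_dataset(tables, clinical)
    assert report.ok, f"generated dataset inconsistent: {report.findings()}"
    return dataset
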