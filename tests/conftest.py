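import numpy as np
import pandas as pd
import pytest

from spatprot.datamodel import BiomarkerPanel, CellTable, CellTypeSet
from spatprot.spatial import Window


@pytest.fixture
def panel8() -> BiomarkerPanel:
    return BiomarkerPanel(tuple(f"M{i}" for i in range(8)))


@pytest.fixture
def types4() -> CellTypeSet:
    return CellTypeSet(("T0", "T1", "T2", "T3"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


def make_cell_table(
    points: np.ndarray,
    panel: BiomarkerPanel,
    expr: np.ndarray | None = None,
    cell_types=None,
    sample_id: str = "s0",
    seed: int = 0,
) -> CellTable:
    """Build a cell table from coordinates; random lognormal expression by default."""
    n = len(points)
    if expr is None:
        expr = np.random.default_rng(seed).lognormal(0.0, 0.5, size=(n, len(panel)))
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "x": np.asarray(points)[:, 0],
            "y": np.asarray(points)[:, 1],
            "cell_type": list(cell_types) if cell_types is not None else [None] * n,
        }
    )
    df[list(panel.names)] = np.asarray(expr, dtype=float)
    return CellTable(sample_id, df, panel)


@pytest.fixture
def random_table(panel8, rng) -> CellTable:
    pts = rng.uniform(0, 500, size=(120, 2))
    types = rng.choice(["T0", "T1", "T2", "T3"], size=120)
    return make_cell_table(pts, panel8, cell_types=types, seed=1)


# ---------------------------------------------------------------------------
# Independent oracles


def arc_fraction_by_intervals(point, d: float, window: Window) -> float:
    """Inside fraction of a circle via explicit outside-interval union.

    Independent of the production inclusion–exclusion formula: builds the
    angular intervals cut off by each window edge and measures their union
    on the circle.
    """
    x, y = point
    if d == 0:
        return 1.0
    intervals = []
    for dist, center in (
        (window.x_max - x, 0.0),
        (y - window.y_min, 1.5 * np.pi),
        (x - window.x_min, np.pi),
        (window.y_max - y, 0.5 * np.pi),
    ):
        if dist < d:
            half = np.arccos(dist / d)
            intervals.append(((center - half) % (2 * np.pi), (center + half) % (2 * np.pi)))
    if not intervals:
        return 1.0
    # unwrap intervals crossing 0 and merge
    flat = []
    for a, b in intervals:
        if a <= b:
            flat.append((a, b))
        else:
            flat.append((a, 2 * np.pi))
            flat.append((0.0, b))
    flat.sort()
    total = 0.0
    cur_a, cur_b = flat[0]
    for a, b in flat[1:]:
        if a > cur_b:
            total += cur_b - cur_a
            cur_a, cur_b = a, b
        else:
            cur_b = max(cur_b, b)
    total += cur_b - cur_a
    return 1.0 - total / (2 * np.pi)


def k_oracle(
    points: np.ndarray,
    window: Window,
    r_grid: np.ndarray,
    marks: np.ndarray | None = None,
) -> np.ndarray:
    """Literal O(n²) transcription of the edge-corrected K estimator."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    K = np.zeros(len(r_grid))
    mbar = marks.mean() if marks is not None else 1.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = float(np.hypot(*(points[i] - points[j])))
            if d > r_grid[-1]:
                continue
            w = 1.0 / arc_fraction_by_intervals(points[i], d, window)
            if marks is not None:
                w *= marks[i] * marks[j] / mbar**2
            K[r_grid >= d] += w
    return window.area / (n * (n - 1)) * K


def harrell_c_oracle(times, events, risks) -> float:
    """Exhaustive pair enumeration of the concordance index."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    r = np.asarray(risks, dtype=float)
    num = den = 0.0
    for i in range(len(t)):
        for j in range(len(t)):
            if i == j or not (e[i] == 1 and t[i] < t[j]):
                continue
            den += 1
            if r[i] > r[j]:
                num += 1
            elif r[i] == r[j]:
                num += 0.5
    return num / den
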