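"""Image-derived quantities for multiplexed imaging samples.

Channel-wise pixel means over the whole image or within segmentation masks,
per-cell expression from labeled masks, background accumulation for
positivity thresholds, and the stochastic nuclear-mask dilation used to
approximate whole-cell masks from nuclear segmentations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from spatprot.datamodel import BiomarkerPanel, CellTable

__all__ = [
    "BackgroundAccumulator",
    "channel_mean_image",
    "channel_mean_in_cells",
    "per_cell_expression",
    "accumulate_background",
    "positivity_thresholds",
    "mask_dilate_stochastic",
    "propagate_labels",
    "whole_cell_mask",
    "read_channel_stack",
    "write_channel_stack",
    "read_mask",
    "write_mask",
]


def _check_stack(stack: np.ndarray) -> np.ndarray:
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("channel stack must be (B, H, W)")
    if stack.shape[1] * stack.shape[2] == 0:
        raise ValueError("empty image")
    if not np.isfinite(stack).all() or (stack < 0).any():
        raise ValueError("intensities must be finite and non-negative")
    return stack


def channel_mean_image(stack: np.ndarray) -> np.ndarray:
    """Per-channel mean intensity over all pixels ("average biomarker across image")."""
    return _check_stack(stack).mean(axis=(1, 2))


def channel_mean_in_cells(stack: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-channel mean intensity over pixels inside any cell (mask > 0)."""
    stack = _check_stack(stack)
    inside = np.asarray(mask) > 0
    if not inside.any():
        raise ValueError("mask has no cell pixels")
    return stack[:, inside].mean(axis=1)


def per_cell_expression(
    stack: np.ndarray,
    mask: np.ndarray,
    panel: BiomarkerPanel,
    sample_id: str = "sample",
    cell_ids=None,
) -> CellTable:
    """Quantify each labeled cell: mean channel intensity and pixel centroid.

    The centroid is the mean of the cell's pixel coordinates with x = column,
    y = row. ``cell_ids``, when given, maps mask labels to cell identifiers
    and every requested label must be present in the mask.
    """
    from scipy import ndimage

    import pandas as pd

    stack = _check_stack(stack)
    mask = np.asarray(mask)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if cell_ids is not None:
        requested = np.asarray(sorted(cell_ids, key=int), dtype=mask.dtype)
        missing = np.setdiff1d(requested, labels)
        if len(missing):
            raise ValueError(f"cell {missing[0]} has zero pixels in the mask")
        labels = requested
    if len(labels) == 0:
        raise ValueError("mask contains no cells")
    expr = np.column_stack(
        [ndimage.mean(stack[b], labels=mask, index=labels) for b in range(stack.shape[0])]
    )
    centroids = np.array(
        ndimage.center_of_mass(np.ones(mask.shape), labels=mask, index=labels)
    )
    df = pd.DataFrame(
        {
            "cell_id": [str(int(l)) for l in labels],
            "x": centroids[:, 1],
            "y": centroids[:, 0],
            "cell_type": [None] * len(labels),
        }
    )
    df[list(panel.names)] = expr
    return CellTable(sample_id, df, panel)


# ---------------------------------------------------------------------------
# Background statistics and positivity thresholds


@dataclass
class BackgroundAccumulator:
    """Per-biomarker background intensity sums and pixel counts across samples.

    Merging accumulators (``+``) is associative and commutative, so the
    positivity threshold — the pooled mean background intensity — does not
    depend on how pixels are partitioned into samples.
    """

    intensity_sum: np.ndarray = field(default=None)
    pixel_count: np.ndarray = field(default=None)

    @classmethod
    def empty(cls, n_channels: int) -> "BackgroundAccumulator":
        return cls(np.zeros(n_channels), np.zeros(n_channels))

    def __add__(self, other: "BackgroundAccumulator") -> "BackgroundAccumulator":
        return BackgroundAccumulator(
            self.intensity_sum + other.intensity_sum,
            self.pixel_count + other.pixel_count,
        )


def accumulate_background(
    stack: np.ndarray, mask: np.ndarray, acc: BackgroundAccumulator | None = None
) -> BackgroundAccumulator:
    """Add a sample's background pixels (mask == 0) to the accumulator."""
    stack = _check_stack(stack)
    if acc is None:
        acc = BackgroundAccumulator.empty(stack.shape[0])
    outside = np.asarray(mask) == 0
    n_bg = int(outside.sum())
    sums = stack[:, outside].sum(axis=1) if n_bg else np.zeros(stack.shape[0])
    return acc + BackgroundAccumulator(sums, np.full(stack.shape[0], float(n_bg)))


def positivity_thresholds(acc: BackgroundAccumulator) -> np.ndarray:
    """Per-biomarker positivity threshold: mean background intensity pooled
    over all accumulated samples."""
    if (acc.pixel_count <= 0).any():
        raise ValueError("no background pixels accumulated")
    return acc.intensity_sum / acc.pixel_count


# ---------------------------------------------------------------------------
# Stochastic mask dilation


def mask_dilate_stochastic(mask: np.ndarray, cycles: int = 9, seed: int = 0) -> np.ndarray:
    """Stochastically dilate a binary mask.

    Per cycle, every background pixel flips to foreground with probability
    equal to the fraction of positive pixels among its 8-connected in-image
    neighbors, evaluated synchronously from the pre-cycle state. Nine cycles
    is the convention for approximating whole cells from nuclei in CODEX
    processing. Foreground never shrinks.
    """
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    fg = np.asarray(mask) > 0
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    denom = ndimage.convolve(np.ones(fg.shape), kernel, mode="constant", cval=0.0)
    for _ in range(cycles):
        pos = ndimage.convolve(fg.astype(float), kernel, mode="constant", cval=0.0)
        prob = pos / denom
        fg = fg | ((rng.random(fg.shape) < prob) & ~fg)
    return fg


def propagate_labels(labels: np.ndarray, region: np.ndarray) -> np.ndarray:
    """Extend integer labels to every pixel of ``region`` from the nearest
    labeled pixel (exact Euclidean distance transform)."""
    from scipy import ndimage

    labels = np.asarray(labels)
    _, (ri, ci) = ndimage.distance_transform_edt(labels == 0, return_indices=True)
    out = np.where(np.asarray(region) > 0, labels[ri, ci], 0)
    out[labels > 0] = labels[labels > 0]
    return out


def whole_cell_mask(nuclear_labels: np.ndarray, cycles: int = 9, seed: int = 0) -> np.ndarray:
    """Whole-cell labeled mask from a nuclear label mask.

    The binary union of nuclei is stochastically dilated, then labels are
    propagated from the nearest nucleus pixel.
    """
    nuclear_labels = np.asarray(nuclear_labels)
    grown = mask_dilate_stochastic(nuclear_labels > 0, cycles=cycles, seed=seed)
    return propagate_labels(nuclear_labels, grown)


# ---------------------------------------------------------------------------
# TIFF I/O


def read_channel_stack(path) -> np.ndarray:
    import tifffile

    arr = tifffile.imread(path)
    return np.asarray(arr, dtype=float)


def write_channel_stack(stack: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(
        path, np.asarray(stack, dtype=np.float32), photometric="minisblack"
    )


def read_mask(path) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(path))


def write_mask(mask: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(mask, dtype=np.int32))
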