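"""Spatial-spectral imaging: electrode grid -> interpolated frame stack.

Per sub-band, the 64 channel powers are placed into the 11 x 10 scalp
topology matrix (non-electrode cells stay zero), the matrix is upsampled
by piecewise-cubic Clough-Tocher interpolation over a triangulation of
the grid cells, and the ten sub-band frames are stacked into a
110 x 100 x 10 tensor — the network's input image.

By default the zero-cells participate in the triangulation as genuine
data points, so the interpolated frame decays toward zero off the
electrode cap.  Setting ``mask_zero_cells=True`` interpolates from the
electrode cells only (extrapolated corners filled with zero), which
changes edge behavior but not the electrode-region values.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
from scipy.interpolate import CloughTocher2DInterpolator
from scipy.spatial import Delaunay

from .eeg_io import Segment
from .montage import MontageLayout, default_layout
from .spectral_features import SubBandPower, WelchConfig, segment_psd, subband_power

__all__ = [
    "TopologyMatrix",
    "FeatureTensor",
    "build_topology",
    "interpolate",
    "assemble_tensor",
    "segments_to_tensors",
    "save_features",
    "load_features",
]

DEFAULT_TARGET_SHAPE = (110, 100)


@dataclass
class TopologyMatrix:
    """One sub-band's channel powers on the scalp grid."""

    values: np.ndarray  # [rows x cols]
    band_index: int = 0


@dataclass
class FeatureTensor:
    """Stacked interpolated frames, ``values[x, y, band]``."""

    values: np.ndarray  # [110 x 100 x n_bands] at defaults

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature tensor contains non-finite values")


def build_topology(
    channel_values: np.ndarray,
    layout: MontageLayout | None = None,
    band_index: int = 0,
) -> TopologyMatrix:
    """Place per-channel values into the scalp grid (zero-cells zero)."""
    layout = layout or default_layout()
    channel_values = np.asarray(channel_values, dtype=np.float64).ravel()
    if channel_values.size != layout.n_channels:
        raise ValueError(
            f"expected {layout.n_channels} channel values, "
            f"got {channel_values.size}"
        )
    if not np.all(np.isfinite(channel_values)):
        raise ValueError("channel values must be finite")
    grid = np.zeros(layout.grid_shape)
    for ch, (r, c) in layout.placement.items():
        grid[r - 1, c - 1] = channel_values[ch - 1]
    return TopologyMatrix(values=grid, band_index=band_index)


@lru_cache(maxsize=8)
def _triangulation(rows: int, cols: int) -> tuple[Delaunay, np.ndarray]:
    rr, cc = np.meshgrid(
        np.arange(1, rows + 1), np.arange(1, cols + 1), indexing="ij"
    )
    points = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
    return Delaunay(points), points


@lru_cache(maxsize=8)
def _target_lattice(
    rows: int, cols: int, t_rows: int, t_cols: int
) -> np.ndarray:
    # Uniform lattice spanning the source extent [1, rows] x [1, cols];
    # first output axis follows source rows.
    xs = np.linspace(1, rows, t_rows)
    ys = np.linspace(1, cols, t_cols)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


def interpolate(
    matrix: TopologyMatrix | np.ndarray,
    target_shape: tuple[int, int] = DEFAULT_TARGET_SHAPE,
    mask_zero_cells: bool = False,
) -> np.ndarray:
    """Upsample a grid by Clough-Tocher piecewise-cubic interpolation.

    Returns a ``target_shape`` array evaluated on a uniform lattice over
    the source extent.  Exact for constant and planar fields.
    """
    values = matrix.values if isinstance(matrix, TopologyMatrix) else matrix
    values = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise ValueError("cannot interpolate non-finite values")
    rows, cols = values.shape
    t_rows, t_cols = target_shape
    if t_rows < rows or t_cols < cols:
        raise ValueError("target shape must not be smaller than the source")

    tri, points = _triangulation(rows, cols)
    flat = values.ravel()
    if mask_zero_cells:
        keep = flat != 0
        if keep.sum() < 3:
            return np.zeros(target_shape)
        interp = CloughTocher2DInterpolator(
            points[keep], flat[keep], fill_value=0.0, tol=1e-12, maxiter=800
        )
    else:
        # Tight gradient-estimation tolerance so linear fields reproduce
        # to ~1e-9 rather than the looser library default.
        interp = CloughTocher2DInterpolator(tri, flat, tol=1e-12, maxiter=800)
    lattice = _target_lattice(rows, cols, t_rows, t_cols)
    out = interp(lattice).reshape(target_shape)
    # Qhull can leave boundary lattice points fractionally outside the hull.
    np.nan_to_num(out, copy=False)
    return out


def assemble_tensor(
    powers: SubBandPower,
    layout: MontageLayout | None = None,
    target_shape: tuple[int, int] = DEFAULT_TARGET_SHAPE,
    mask_zero_cells: bool = False,
) -> FeatureTensor:
    """Image every sub-band and stack frames in ascending band order."""
    layout = layout or default_layout()
    if powers.power.shape[0] != layout.n_channels:
        raise ValueError(
            f"powers for {powers.power.shape[0]} channels, montage has "
            f"{layout.n_channels}"
        )
    frames = [
        interpolate(
            build_topology(powers.power[:, k], layout, band_index=k),
            target_shape,
            mask_zero_cells,
        )
        for k in range(powers.n_bands)
    ]
    return FeatureTensor(values=np.stack(frames, axis=-1))


def segments_to_tensors(
    segments: Sequence[Segment],
    band: tuple[float, float] = (10.0, 15.0),
    n_subbands: int = 10,
    layout: MontageLayout | None = None,
    welch: WelchConfig | None = None,
    target_shape: tuple[int, int] = DEFAULT_TARGET_SHAPE,
) -> tuple[np.ndarray, np.ndarray]:
    """Full feature pipeline for a trial list.

    Returns ``(tensors [n x 110 x 100 x n_subbands], labels [n])``.
    """
    layout = layout or default_layout()
    tensors, labels = [], []
    for seg in segments:
        psd = segment_psd(seg, welch)
        powers = subband_power(psd, band=band, n_subbands=n_subbands)
        tensors.append(
            assemble_tensor(powers, layout, target_shape=target_shape).values
        )
        labels.append(seg.class_label)
    return np.stack(tensors), np.asarray(labels)


def save_features(
    path: str | Path, tensors: np.ndarray, labels: np.ndarray
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("tensors", data=tensors, compression="gzip")
        f.create_dataset("labels", data=np.asarray(labels, dtype="S"))


def load_features(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    with h5py.File(path, "r") as f:
        tensors = f["tensors"][...]
        labels = np.array([x.decode() for x in f["labels"][...]])
    return tensors, labels
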