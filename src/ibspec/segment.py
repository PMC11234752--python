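"""Pixel classification: background / cell / inclusion body.

Cells are instance-segmented on the 1625 cm^-1 IR amplitude map by a
pluggable backend (any callable mapping a 2D intensity image to an
instance label map), eroded to discard membrane pixels, and discarded
when they intersect the image border.  Inside each remaining cell the
intensity histogram is thresholded with the triangle algorithm, a binary
opening removes noise-sized components, and supra-threshold pixels
outside the cell mask are dropped — so the smallest detectable IB has
the radius of the opening structuring element (2 px by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import morphology, segmentation

from .data_model import AFMIRDataset, ChannelMap

logger = logging.getLogger("ibspec.segment")

__all__ = [
    "SegmentationMaps",
    "segment_cells",
    "segment_ibs",
    "triangle_threshold",
    "fallback_cell_backend",
    "background_mask",
]

Backend = Callable[[np.ndarray], np.ndarray]


@dataclass
class SegmentationMaps:
    """Cell instance labels, IB instance labels and IB -> cell ownership.

    Invariants (checked): every IB pixel lies on a cell pixel, no cell
    touches the image border, labels are contiguous from 1.
    """

    cell_labels: np.ndarray
    ib_labels: np.ndarray
    ib_to_cell: pd.DataFrame  # columns: ib_id, cell_id

    def __post_init__(self):
        cl = np.asarray(self.cell_labels)
        il = np.asarray(self.ib_labels)
        if cl.shape != il.shape:
            raise ValueError("cell and IB label maps must share shape")
        if ((il > 0) & (cl == 0)).any():
            raise ValueError("IB pixels found outside any cell")
        border = np.zeros(cl.shape, dtype=bool)
        border[0], border[-1], border[:, 0], border[:, -1] = True, True, True, True
        if cl[border].any():
            raise ValueError("cell labels touch the image border")
        for name, lab in (("cell", cl), ("ib", il)):
            ids = np.unique(lab[lab > 0])
            if ids.size and not np.array_equal(ids, np.arange(1, ids.size + 1)):
                raise ValueError(f"{name} labels are not contiguous from 1")
        self.cell_labels = cl.astype(np.int32)
        self.ib_labels = il.astype(np.int32)

    @property
    def n_cells(self) -> int:
        return int(self.cell_labels.max())

    @property
    def n_ibs(self) -> int:
        return int(self.ib_labels.max())


def triangle_threshold(values: np.ndarray, n_bins: int = 64) -> float:
    """Triangle-algorithm threshold of a 1D intensity sample.

    A histogram of ``n_bins`` is built over [min, max]; a line is drawn
    from the histogram peak to the farthest nonempty bin (symmetric rule:
    the side is whichever nonempty bin is farther from the peak), and the
    threshold is the center of the bin with the largest perpendicular
    distance between histogram and line.  Bin index and count axes are
    normalized before measuring distance, which makes the result
    equivariant under affine rescaling of the input values.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("triangle threshold needs at least 2 values")
    vmin, vmax = float(v.min()), float(v.max())
    if vmax <= vmin:
        raise ValueError("triangle threshold undefined for constant input")
    hist, edges = np.histogram(v, bins=int(n_bins), range=(vmin, vmax))
    peak = int(np.argmax(hist))
    nonempty = np.flatnonzero(hist)
    far = int(nonempty[np.argmax(np.abs(nonempty - peak))])
    if far == peak:  # single occupied bin cannot happen for non-constant input
        raise ValueError("degenerate histogram")
    lo, hi = (peak, far) if peak < far else (far, peak)
    idx = np.arange(lo, hi + 1)
    x = (idx - peak) / (far - peak)  # 0 at the peak, 1 at the far tail bin
    y = hist[idx] / hist[peak]
    y_far = hist[far] / hist[peak]
    # perpendicular distance from (x, y) to the line (0, 1) -> (1, y_far),
    # up to the constant line-length factor
    dist = np.abs((y - 1.0) - x * (y_far - 1.0))
    best = idx[int(np.argmax(dist))]
    return float(0.5 * (edges[best] + edges[best + 1]))


def fallback_cell_backend(
    image: np.ndarray,
    smooth_sigma: float = 2.0,
    min_area_px: int = 64,
    n_bins: int = 128,
) -> np.ndarray:
    """Built-in instance segmentation: smooth, triangle threshold, watershed.

    Gaussian smoothing, a global triangle threshold separating cells
    (bright at 1625 cm^-1) from epoxy, hole filling, then a
    distance-transform watershed to split touching instances (markers are
    the interior cores where the distance transform exceeds half its
    per-component maximum).
    """
    img = np.asarray(image, dtype=float)
    sm = ndi.gaussian_filter(img, smooth_sigma)
    if sm.max() <= sm.min():
        logger.warning("fallback backend: blank image, no cells found")
        return np.zeros(img.shape, dtype=np.int32)
    thr = triangle_threshold(sm.ravel(), n_bins=n_bins)
    mask = sm > thr
    mask = ndi.binary_fill_holes(mask)
    # cut thin bridges the smoothing may have drawn between adjacent cells
    mask = morphology.opening(mask, morphology.disk(2))
    mask = morphology.remove_small_objects(mask, max_size=min_area_px - 1)
    if not mask.any():
        logger.warning("fallback backend: no component above minimum area")
        return np.zeros(img.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(mask)
    comps, n_comp = ndi.label(mask)
    cores = np.zeros(mask.shape, dtype=bool)
    for i in range(1, n_comp + 1):
        comp = comps == i
        cores |= comp & (dist > 0.5 * dist[comp].max())
    markers, _ = ndi.label(cores)
    return segmentation.watershed(-dist, markers, mask=mask).astype(np.int32)


def segment_cells(
    dataset: AFMIRDataset,
    backend: Backend | None = None,
    erosion_radius_px: int = 2,
) -> np.ndarray:
    """Instance-segment cells on the 1625 cm^-1 IR amplitude map.

    The backend's instances are each eroded by a disk of
    ``erosion_radius_px`` (membrane discard), instances touching the image
    border are removed, and the survivors are relabelled contiguously from
    1 in the backend's label order.
    """
    amp = dataset.get("IRAmplitude", "trace").data
    backend = backend or fallback_cell_backend
    raw = np.asarray(backend(amp))
    if raw.shape != amp.shape:
        raise ValueError(
            f"segmentation backend returned shape {raw.shape}, expected {amp.shape}"
        )
    selem = morphology.disk(erosion_radius_px) if erosion_radius_px > 0 else None
    border = np.zeros(amp.shape, dtype=bool)
    border[0], border[-1], border[:, 0], border[:, -1] = True, True, True, True
    out = np.zeros(amp.shape, dtype=np.int32)
    next_label = 0
    for lab in np.unique(raw[raw > 0]):
        mask = raw == lab
        if selem is not None:
            mask = morphology.erosion(mask, selem)
        if not mask.any():
            continue
        if mask[border].any():
            logger.info("segment_cells: discarding border-touching cell %d", lab)
            continue
        next_label += 1
        out[mask] = next_label
    if next_label == 0:
        logger.warning("segment_cells: no interior cells found")
    return out


def background_mask(cell_labels: np.ndarray, guard_px: int = 2) -> np.ndarray:
    """Epoxy pixels: everything at least ``guard_px`` away from any cell."""
    cells = np.asarray(cell_labels) > 0
    if guard_px > 0:
        cells = morphology.dilation(cells, morphology.disk(guard_px))
    return ~cells


def segment_ibs(
    amp_1625_registered: ChannelMap | np.ndarray,
    cell_labels: np.ndarray,
    opening_radius_px: int = 2,
    n_bins: int = 64,
    min_cell_pixels: int = 16,
    pooled_threshold: bool = False,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Detect IBs inside each cell by triangle threshold + binary opening.

    Per cell (or pooled over all cells with ``pooled_threshold``): the
    interior 1625 cm^-1 amplitudes are thresholded with the triangle
    algorithm; the supra-threshold mask is opened with a disk of
    ``opening_radius_px`` (noise-pixel discard — no surviving component can
    have an equivalent radius below the opening radius); pixels outside the
    cell mask are dropped; connected components become IB labels with
    recorded cell ownership.  Cells with fewer than ``min_cell_pixels``
    interior pixels are skipped (histogram unidentifiable).
    """
    amp = amp_1625_registered.data if isinstance(amp_1625_registered, ChannelMap) else np.asarray(
        amp_1625_registered, dtype=float
    )
    cell_labels = np.asarray(cell_labels)
    if amp.shape != cell_labels.shape:
        raise ValueError("amplitude map and cell labels have mismatched shapes")
    selem = morphology.disk(opening_radius_px) if opening_radius_px > 0 else None
    ib_labels = np.zeros(amp.shape, dtype=np.int32)
    owners: list[tuple[int, int]] = []
    next_ib = 0
    cell_ids = np.unique(cell_labels[cell_labels > 0])
    pooled_thr: float | None = None
    if pooled_threshold and cell_ids.size:
        pooled_thr = triangle_threshold(amp[cell_labels > 0], n_bins=n_bins)
    for cid in cell_ids:
        cmask = cell_labels == cid
        vals = amp[cmask]
        if vals.size < min_cell_pixels:
            logger.warning("segment_ibs: cell %d too small (%d px); skipped", cid, vals.size)
            continue
        if np.ptp(vals) == 0:
            continue
        thr = pooled_thr if pooled_thr is not None else triangle_threshold(vals, n_bins=n_bins)
        if thr <= np.median(vals):
            # IBs are a bright minority population; a threshold at or below
            # the cell median means the histogram is unimodal (no IBs) and
            # the symmetric tail rule picked the low side.
            logger.info("segment_ibs: cell %d histogram unimodal; no IBs", cid)
            continue
        mask = (amp > thr) & cmask
        if selem is not None:
            mask = morphology.opening(mask, selem)
        mask &= cmask
        if not mask.any():
            continue
        comps, n_comp = ndi.label(mask)
        for i in range(1, n_comp + 1):
            next_ib += 1
            ib_labels[comps == i] = next_ib
            owners.append((next_ib, int(cid)))
    table = pd.DataFrame(owners, columns=["ib_id", "cell_id"])
    return ib_labels, table
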