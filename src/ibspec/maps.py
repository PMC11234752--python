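"""Map-level corrections: drift registration, PLL line correction, ratio maps.

The 1625 cm^-1 dataset is acquired after the 1650 cm^-1 one; stage drift
in between shifts (and, when the drift is nonconstant, shears) the scene.
Registration maximises the normalized cross-correlation (NCC) of the two
height maps in two stages — rigid (FFT phase correlation over a coarse
rotation grid with subpixel peak interpolation) then a bounded affine
refinement — and resamples every 1625 channel through the recovered
transform with bilinear interpolation.

The PLL pulse-rate maps carry a slow per-line drift (thermal/cantilever);
it is estimated from the line-wise mean over epoxy pixels, smoothed with a
centered rolling mean, and subtracted from the whole map.  Downstream
per-IB summaries use the corrected 1650 cm^-1 PLL map (the higher IR
amplitude at 1650 makes its PLL tracking the more reliable one).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import minimize
from skimage.registration import phase_cross_correlation

from .data_model import AFMIRDataset, ChannelMap, DatasetPair

logger = logging.getLogger("ibspec.maps")

__all__ = [
    "AffineTransform2D",
    "register_pair",
    "correct_pll_map",
    "ratio_map",
]


@dataclass(frozen=True)
class AffineTransform2D:
    """3x3 affine transform acting on homogeneous pixel (row, col) vectors."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("affine matrix must be 3x3")
        if not np.allclose(m[2], [0.0, 0.0, 1.0], atol=1e-12):
            raise ValueError("last row of an affine matrix must be (0, 0, 1)")
        if abs(np.linalg.det(m[:2, :2])) < 1e-12:
            raise ValueError("affine matrix is singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(3))

    @classmethod
    def from_translation(cls, dr: float, dc: float) -> "AffineTransform2D":
        m = np.eye(3)
        m[0, 2], m[1, 2] = dr, dc
        return cls(m)

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:2, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:2, 2]

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """self after other: (self @ other) x."""
        return AffineTransform2D(self.matrix @ other.matrix)

    def inverse(self) -> "AffineTransform2D":
        return AffineTransform2D(np.linalg.inv(self.matrix))

    def apply_to_coords(self, coords: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of (row, col) coordinates."""
        c = np.asarray(coords, dtype=float)
        return c @ self.linear.T + self.translation

    def is_rigid(self, tol: float = 1e-6) -> bool:
        a = self.linear
        return bool(np.allclose(a @ a.T, np.eye(2), atol=tol))


def _map_data(m) -> np.ndarray:
    return m.data if isinstance(m, ChannelMap) else np.asarray(m, dtype=float)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float((a * b).sum() / (na * nb))


def _warp(img: np.ndarray, matrix: np.ndarray, order: int = 1, cval=np.nan) -> np.ndarray:
    return ndi.affine_transform(
        img, matrix[:2, :2], offset=matrix[:2, 2], order=order, mode="constant", cval=cval
    )


def _rotation_about_center(theta: float, shape) -> np.ndarray:
    """Rotation by theta (radians, in pixel space) about the image center."""
    c = np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])
    r = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    m = np.eye(3)
    m[:2, :2] = r
    m[:2, 2] = c - r @ c
    return m


def _params_to_matrix(p: np.ndarray) -> np.ndarray:
    """(t_r, t_c, 100*(a00-1), 100*a01, 100*a10, 100*(a11-1)) -> 3x3 matrix."""
    m = np.eye(3)
    m[0, 2], m[1, 2] = p[0], p[1]
    m[0, 0] = 1.0 + p[2] / 100.0
    m[0, 1] = p[3] / 100.0
    m[1, 0] = p[4] / 100.0
    m[1, 1] = 1.0 + p[5] / 100.0
    return m


def _matrix_to_params(m: np.ndarray) -> np.ndarray:
    return np.array(
        [
            m[0, 2],
            m[1, 2],
            100.0 * (m[0, 0] - 1.0),
            100.0 * m[0, 1],
            100.0 * m[1, 0],
            100.0 * (m[1, 1] - 1.0),
        ]
    )


def register_pair(
    pair: DatasetPair,
    *,
    max_rotation_deg: float = 3.0,
    rotation_step_deg: float = 1.0,
    max_translation_px: float = 15.0,
    shear_bound: float = 0.05,
    margin_px: int = 20,
    affine: bool = True,
) -> DatasetPair:
    """Register the 1625 dataset onto the 1650 dataset via the height maps.

    Stage 1 searches rigid transforms (translation by FFT phase correlation
    with subpixel upsampling, rotation over a coarse grid); stage 2 refines
    all six affine parameters by local optimization of the height-map NCC,
    with linear-part deviations bounded by ``shear_bound`` to prevent
    degenerate fits.  The final transform is applied to every 1625 channel
    with bilinear resampling; out-of-frame pixels are masked.  With
    ``affine=False`` only the rigid stage runs (sensitivity analyses).

    Raises ``ValueError`` when either height map is contrast-free
    (registration unidentifiable); warns when the translation estimate
    reaches the search bound.
    """
    ref = pair.ds_1650.get("Height", "trace").data.astype(float)
    mov = pair.ds_1625.get("Height", "trace").data.astype(float)
    if ref.std() < 1e-12 or mov.std() < 1e-12:
        raise ValueError("registration unidentifiable: height map has no contrast")

    m = int(margin_px)
    crop = (slice(m, ref.shape[0] - m), slice(m, ref.shape[1] - m))

    def score(matrix: np.ndarray) -> float:
        warped = _warp(mov, matrix, cval=0.0)
        return _ncc(ref[crop], warped[crop])

    # Stage 1: rigid (rotation grid x subpixel phase correlation)
    thetas = np.deg2rad(
        np.arange(-max_rotation_deg, max_rotation_deg + 1e-9, rotation_step_deg)
    )
    best_m, best_s = None, -np.inf
    for theta in thetas:
        rot = _rotation_about_center(theta, ref.shape)
        rotated = _warp(mov, rot, cval=0.0)
        shift = phase_cross_correlation(ref, rotated, upsample_factor=20)[0]
        # ndi.shift(x, s)[o] = x[o - s]; our alignment matrix samples x[M o],
        # so the translation part is -shift.
        trans = AffineTransform2D.from_translation(-shift[0], -shift[1]).matrix
        cand = trans @ rot
        s = score(cand)
        if s > best_s:
            best_m, best_s = cand, s
    if np.max(np.abs(best_m[:2, 2])) >= max_translation_px:
        warnings.warn("registration: correlation peak at translation search bound")

    # Stage 2: bounded affine refinement initialized at the rigid optimum
    if affine:
        p0 = _matrix_to_params(best_m)
        lin_bound = 100.0 * shear_bound
        bounds = [
            (-max_translation_px, max_translation_px),
            (-max_translation_px, max_translation_px),
        ] + [(-lin_bound, lin_bound)] * 4
        p0 = np.clip(p0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            lambda p: -score(_params_to_matrix(p)),
            p0,
            method="Powell",
            bounds=bounds,
            options=dict(xtol=1e-4, ftol=1e-9, maxiter=50),
        )
        refined = _params_to_matrix(res.x)
        if score(refined) >= best_s:
            best_m = refined
    logger.info("registration transform:\n%s", np.array_str(best_m, precision=4))

    transform = AffineTransform2D(best_m)
    new_channels = {}
    for key, cm in pair.ds_1625.channels.items():
        warped = _warp(cm.data, best_m, cval=np.nan)
        valid = np.isfinite(warped)
        if cm.mask is not None:
            warped_valid = _warp(cm.mask.astype(float), best_m, cval=0.0)
            valid &= warped_valid > 0.999
        new_channels[key] = ChannelMap(
            cm.channel, cm.direction, np.where(valid, warped, 0.0), cm.units, mask=valid
        )
    ds_1625 = pair.ds_1625.with_channels(new_channels)
    return DatasetPair(ds_1650=pair.ds_1650, ds_1625=ds_1625, transform=transform.matrix)


def _smooth_profile(profile: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling mean with linear-extrapolation padding at the edges.

    Plain edge handling (shrinking windows, reflection) biases the smoothed
    profile wherever the drift has a linear trend; padding by a straight-line
    fit over the edge segments keeps the correction exact for linear drift
    on every line.
    """
    if window <= 1:
        return profile.astype(float)
    pad_l = (window - 1) // 2
    pad_r = window // 2
    n = profile.size
    k = min(max(window, 4), n)
    x_left = np.arange(k)
    cl = np.polyfit(x_left, profile[:k], 1)
    left = np.polyval(cl, np.arange(-pad_l, 0))
    x_right = np.arange(n - k, n)
    cr = np.polyfit(x_right, profile[-k:], 1)
    right = np.polyval(cr, np.arange(n, n + pad_r))
    padded = np.concatenate([left, profile, right])
    return np.convolve(padded, np.ones(window) / window, mode="valid")


def correct_pll_map(
    pll: ChannelMap,
    epoxy_mask: np.ndarray,
    rolling_window_lines: int = 16,
) -> ChannelMap:
    """Subtract the smoothed line-wise epoxy PLL profile from the whole map.

    Per line, the mean PLL over epoxy pixels is computed; lines without any
    epoxy pixel are filled by linear interpolation from neighbouring lines
    (logged).  The profile is smoothed by a centered rolling mean of
    ``rolling_window_lines`` lines and subtracted from every pixel of the
    corresponding line.
    """
    if rolling_window_lines < 1:
        raise ValueError("rolling window must be at least 1 line")
    epoxy_mask = np.asarray(epoxy_mask, dtype=bool)
    if epoxy_mask.shape != pll.shape:
        raise ValueError("epoxy mask shape does not match the PLL map")
    if not epoxy_mask.any():
        raise ValueError("epoxy mask is empty; PLL line correction impossible")
    data = pll.data
    valid = pll.valid & epoxy_mask
    counts = valid.sum(axis=1)
    sums = np.where(valid, data, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    missing = counts == 0
    if missing.any():
        logger.warning(
            "PLL correction: %d line(s) without epoxy pixels; interpolated", int(missing.sum())
        )
        idx = np.arange(profile.size)
        profile[missing] = np.interp(idx[missing], idx[~missing], profile[~missing])
    smoothed = _smooth_profile(profile, int(rolling_window_lines))
    corrected = data - smoothed[:, None]
    return ChannelMap(pll.channel, pll.direction, corrected, pll.units, mask=pll.mask)


def ratio_map(
    amp_1625_registered: ChannelMap | np.ndarray,
    amp_1650: ChannelMap | np.ndarray,
    min_denominator_quantile: float = 0.05,
    epoxy_mask: np.ndarray | None = None,
) -> ChannelMap:
    """Pixelwise 1625/1650 IR amplitude ratio with a guarded denominator.

    Pixels whose 1650 amplitude falls below the ``min_denominator_quantile``
    quantile of the epoxy amplitude distribution (or of the whole map when
    no epoxy mask is given), or is non-positive, are masked rather than
    allowed to blow up the quotient.  Input masks propagate.
    """
    num = _map_data(amp_1625_registered)
    den = _map_data(amp_1650)
    if num.shape != den.shape:
        raise ValueError("ratio map inputs have mismatched shapes")
    valid = np.isfinite(num) & np.isfinite(den)
    for m in (amp_1625_registered, amp_1650):
        if isinstance(m, ChannelMap) and m.mask is not None:
            valid &= m.mask
    ref_vals = den[epoxy_mask & valid] if epoxy_mask is not None else den[valid]
    if ref_vals.size:
        thr = float(np.quantile(ref_vals, min_denominator_quantile))
    else:
        thr = 0.0
    valid &= den >= thr
    valid &= den > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        data = np.where(valid, num / np.where(valid, den, 1.0), np.nan)
    return ChannelMap(
        "Ratio1625_1650", "trace", np.where(valid, data, 0.0), units="", mask=valid
    )
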