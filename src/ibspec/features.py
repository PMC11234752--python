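"""Per-cell and per-IB quantification.

For every inclusion body the table records geometry (area, equivalent
radius, polar position along the host cell's major axis), the beta-sheet
readouts (mean 1625/1650 ratio inside the IB, in the host cytoplasm, and
their quotient — the relative beta-sheet enrichment), the stiffness
readout (corrected 1650 cm^-1 PLL frequency difference IB minus
cytoplasm), raw amplitude means, and a thickness proxy (mean height over
the IB minus the epoxy height level).

The polar position is the signed projection of the IB centroid onto the
cell's major axis, normalized to [-1, 1]; the positive pole is the one on
the right-hand side of the map (the sign itself carries no biology).
``pole_proximity = |polar_position|`` (1 = at a pole, 0 = mid-cell).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import curve_fit

from .data_model import DatasetPair
from .maps import correct_pll_map, ratio_map
from .segment import SegmentationMaps, background_mask

logger = logging.getLogger("ibspec.features")

__all__ = [
    "CellGeometry",
    "IBFeatureTable",
    "cell_geometry",
    "polar_position",
    "extract_ib_features",
    "edge_distance_profile",
    "boundary_transition_width",
]


@dataclass(frozen=True)
class CellGeometry:
    """Second-moment geometry of one cell mask.

    ``orientation`` is the major-axis angle in radians, measured
    counterclockwise from the image x axis (columns), in (-pi/2, pi/2];
    ``degenerate`` flags nearly isotropic masks whose orientation is
    meaningless.
    """

    centroid: tuple[float, float]  # (row, col)
    orientation: float
    major_length: float
    area: int
    degenerate: bool

    @property
    def axis_vector(self) -> np.ndarray:
        """Unit vector (row, col) along the major axis, x-component >= 0."""
        u = np.array([-np.sin(self.orientation), np.cos(self.orientation)])
        if u[1] < 0 or (u[1] == 0 and u[0] > 0):
            u = -u
        return u


def cell_geometry(cell_mask: np.ndarray) -> CellGeometry:
    """Centroid, orientation and major-axis extent from second moments."""
    mask = np.asarray(cell_mask, dtype=bool)
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        raise ValueError("empty cell mask")
    r0, c0 = rr.mean(), cc.mean()
    x = cc - c0
    y = -(rr - r0)  # y up so angles follow the math convention
    mxx, myy, mxy = (x * x).mean(), (y * y).mean(), (x * y).mean()
    # principal axes of the inertia tensor
    diff = mxx - myy
    theta = 0.5 * np.arctan2(2.0 * mxy, diff)
    l1 = 0.5 * (mxx + myy) + 0.5 * np.hypot(diff, 2 * mxy)
    l2 = 0.5 * (mxx + myy) - 0.5 * np.hypot(diff, 2 * mxy)
    degenerate = (l1 - l2) <= 0.02 * max(l1, 1e-12)
    # wrap into (-pi/2, pi/2]
    if theta <= -np.pi / 2:
        theta += np.pi
    elif theta > np.pi / 2:
        theta -= np.pi
    u = np.array([-np.sin(theta), np.cos(theta)])
    proj = (rr - r0) * u[0] + (cc - c0) * u[1]
    major_length = float(proj.max() - proj.min() + 1.0)
    if degenerate:
        logger.info("cell_geometry: nearly isotropic mask, orientation degenerate")
    return CellGeometry(
        centroid=(float(r0), float(c0)),
        orientation=float(theta),
        major_length=major_length,
        area=int(rr.size),
        degenerate=degenerate,
    )


def polar_position(ib_centroid: tuple[float, float], geom: CellGeometry) -> float:
    """Signed, normalized position of an IB along the host cell's major axis.

    Projection of (IB centroid - cell centroid) on the major-axis unit
    vector (oriented so its image-x component is positive: the positive
    pole is the right-hand one), divided by half the major length and
    clipped to [-1, 1].  Degenerate cell orientation yields 0.
    """
    if geom.degenerate:
        return 0.0
    d = np.asarray(ib_centroid, dtype=float) - np.asarray(geom.centroid)
    val = float(d @ geom.axis_vector) / (geom.major_length / 2.0)
    return float(np.clip(val, -1.0, 1.0))


@dataclass
class IBFeatureTable:
    """One record per IB plus a per-cell summary table."""

    ibs: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self):
        if len(self.ibs):
            pp = self.ibs["polar_position"].to_numpy()
            if np.nanmax(np.abs(pp)) > 1.0 + 1e-9:
                raise ValueError("polar_position outside [-1, 1]")
            enr = self.ibs["beta_enrichment"].to_numpy()
            if np.any(enr[np.isfinite(enr)] <= 0):
                raise ValueError("beta_enrichment must be positive where defined")
            resid = (
                self.ibs["pll_diff"] - (self.ibs["pll_ib"] - self.ibs["pll_cp"])
            ).to_numpy()
            if np.nanmax(np.abs(resid), initial=0.0) > 1e-9:
                raise ValueError("pll_diff != pll_ib - pll_cp")

    def to_csv(self, ibs_path, cells_path) -> None:
        self.ibs.to_csv(ibs_path, index=False)
        self.cells.to_csv(cells_path, index=False)


def _masked_mean(data: np.ndarray, valid: np.ndarray, mask: np.ndarray) -> float:
    sel = valid & mask
    if not sel.any():
        return float("nan")
    return float(data[sel].mean())


def extract_ib_features(
    pair: DatasetPair,
    seg: SegmentationMaps,
    *,
    min_denominator_quantile: float = 0.05,
    pll_rolling_window: int = 16,
) -> IBFeatureTable:
    """Quantify every IB of a registered, segmented dataset pair.

    The pair must be registered (or known aligned); the 1650 cm^-1 PLL map
    is line-corrected against the epoxy background internally.  The
    cytoplasm of a cell is its (eroded) mask minus all of its IB pixels;
    cells fully covered by IBs have no cytoplasm reference and their IBs
    are flagged (``cytoplasm_defined = False``) with NaN enrichment.
    Cells without IBs appear in the per-cell table with ``n_ibs = 0``.
    """
    amp25 = pair.ds_1625.get("IRAmplitude", "trace")
    amp50 = pair.ds_1650.get("IRAmplitude", "trace")
    px_nm = pair.pixel_size_nm
    epoxy = background_mask(seg.cell_labels) & amp25.valid & amp50.valid
    ratio = ratio_map(amp25, amp50, min_denominator_quantile, epoxy_mask=epoxy)
    pll = correct_pll_map(
        pair.ds_1650.get("PLLFrequency", "trace"), epoxy, pll_rolling_window
    )
    height = pair.ds_1650.get("Height", "trace")
    height_epoxy = _masked_mean(height.data, height.valid, epoxy)

    ib_mask_all = seg.ib_labels > 0
    owners = dict(zip(seg.ib_to_cell["ib_id"], seg.ib_to_cell["cell_id"]))

    cell_rows, geoms, cyto_masks = [], {}, {}
    for cid in range(1, seg.n_cells + 1):
        cmask = seg.cell_labels == cid
        geom = cell_geometry(cmask)
        geoms[cid] = geom
        cyto_masks[cid] = cmask & ~ib_mask_all
        n_ibs = int(sum(1 for v in owners.values() if v == cid))
        cell_rows.append(
            dict(
                cell_id=cid,
                sample_id=pair.ds_1650.sample_id,
                session_id=pair.ds_1650.session_id,
                n_ibs=n_ibs,
                cell_area_px=geom.area,
                cell_length_px=geom.major_length,
                cell_orientation=geom.orientation,
                orientation_degenerate=geom.degenerate,
                centroid_row=geom.centroid[0],
                centroid_col=geom.centroid[1],
            )
        )

    ib_rows = []
    for ib_id in range(1, seg.n_ibs + 1):
        imask = seg.ib_labels == ib_id
        cid = int(owners[ib_id])
        geom = geoms[cid]
        cyto = cyto_masks[cid]
        cyto_ok = bool(cyto.any())
        if not cyto_ok:
            logger.warning(
                "extract_ib_features: cell %d fully covered by IBs; enrichment undefined",
                cid,
            )
        rr, cc = np.nonzero(imask)
        centroid = (rr.mean(), cc.mean())
        area_px = int(imask.sum())
        beta_ib = _masked_mean(ratio.data, ratio.valid, imask)
        beta_cp = _masked_mean(ratio.data, ratio.valid, cyto) if cyto_ok else float("nan")
        pll_ib = _masked_mean(pll.data, pll.valid, imask)
        pll_cp = _masked_mean(pll.data, pll.valid, cyto) if cyto_ok else float("nan")
        pp = polar_position(centroid, geom)
        ib_rows.append(
            dict(
                ib_id=ib_id,
                cell_id=cid,
                sample_id=pair.ds_1650.sample_id,
                session_id=pair.ds_1650.session_id,
                area_px=area_px,
                area_nm2=area_px * px_nm**2,
                equiv_radius_nm=float(np.sqrt(area_px / np.pi) * px_nm),
                polar_position=pp,
                pole_proximity=abs(pp),
                beta_ratio_ib=beta_ib,
                beta_ratio_cp=beta_cp,
                beta_enrichment=beta_ib / beta_cp if cyto_ok else float("nan"),
                pll_ib=pll_ib,
                pll_cp=pll_cp,
                pll_diff=pll_ib - pll_cp,
                amp_1625_mean=_masked_mean(amp25.data, amp25.valid, imask),
                amp_1650_mean=_masked_mean(amp50.data, amp50.valid, imask),
                height_mean=_masked_mean(height.data, height.valid, imask) - height_epoxy,
                cell_orientation=geom.orientation,
                cell_length_px=geom.major_length,
                cell_area_px=geom.area,
                cytoplasm_defined=cyto_ok,
            )
        )
    ibs = pd.DataFrame(ib_rows)
    cells = pd.DataFrame(cell_rows)
    return IBFeatureTable(ibs=ibs, cells=cells)


def edge_distance_profile(
    pair: DatasetPair,
    seg: SegmentationMaps,
    bin_width_nm: float | None = None,
    *,
    max_distance_nm: float | None = None,
    n_boot: int = 999,
    level: float = 0.95,
    seed: int = 0,
    min_denominator_quantile: float = 0.05,
    pll_rolling_window: int = 16,
) -> pd.DataFrame:
    """Mean beta ratio and corrected PLL versus signed distance to the IB edge.

    Per pixel the signed Euclidean distance to the nearest IB boundary is
    computed (positive inside an IB, negative outside); outside pixels are
    restricted to cell interiors.  Pixels are binned (default bin width:
    one pixel) and each bin reports the mean 1625/1650 ratio and corrected
    PLL with percentile-bootstrap confidence intervals.
    """
    from .stats import bootstrap_ci

    if seg.n_ibs == 0:
        raise ValueError("edge distance profile undefined without IBs")
    px_nm = pair.pixel_size_nm
    bin_px = 1.0 if bin_width_nm is None else bin_width_nm / px_nm
    amp25 = pair.ds_1625.get("IRAmplitude", "trace")
    amp50 = pair.ds_1650.get("IRAmplitude", "trace")
    epoxy = background_mask(seg.cell_labels) & amp25.valid & amp50.valid
    ratio = ratio_map(amp25, amp50, min_denominator_quantile, epoxy_mask=epoxy)
    pll = correct_pll_map(
        pair.ds_1650.get("PLLFrequency", "trace"), epoxy, pll_rolling_window
    )
    ib = seg.ib_labels > 0
    # half-pixel shift centres the boundary (which lies between the last
    # inside and first outside pixel) at distance zero
    dist_px = np.where(
        ib,
        ndi.distance_transform_edt(ib) - 0.5,
        -(ndi.distance_transform_edt(~ib) - 0.5),
    )
    include = (ib | (seg.cell_labels > 0)) & ratio.valid & pll.valid
    if max_distance_nm is not None:
        include &= np.abs(dist_px) * px_nm <= max_distance_nm
    d = dist_px[include]
    r = ratio.data[include]
    p = pll.data[include]
    bins = np.floor(d / bin_px).astype(int)
    rng = np.random.default_rng(seed)
    rows = []
    for b in np.unique(bins):
        sel = bins == b
        if sel.sum() < 2:
            continue
        r_lo, r_hi = bootstrap_ci(r[sel], n_boot=n_boot, level=level, rng=rng)
        p_lo, p_hi = bootstrap_ci(p[sel], n_boot=n_boot, level=level, rng=rng)
        rows.append(
            dict(
                distance_nm=(b + 0.5) * bin_px * px_nm,
                n_px=int(sel.sum()),
                beta_ratio_mean=float(r[sel].mean()),
                beta_ratio_lo=r_lo,
                beta_ratio_hi=r_hi,
                pll_mean=float(p[sel].mean()),
                pll_lo=p_lo,
                pll_hi=p_hi,
            )
        )
    return pd.DataFrame(rows).sort_values("distance_nm", ignore_index=True)


def boundary_transition_width(
    profile: pd.DataFrame, value_col: str = "beta_ratio_mean"
) -> float:
    """Transition width (nm) of a logistic fitted to an edge profile.

    Fits ``lo + (hi - lo) / (1 + exp(-(d - d0)/s))`` to the binned means
    and reports the central 95.4% span of the fitted transition (the
    quantile range equivalent to +/-2 sigma of a Gaussian edge, whose
    transition width is conventionally 4 sigma): ``2 ln(1/q - 1) s`` with
    q = 0.02275.
    """
    d = profile["distance_nm"].to_numpy(float)
    y = profile[value_col].to_numpy(float)

    def logistic(x, lo, hi, x0, s):
        return lo + (hi - lo) / (1.0 + np.exp(-(x - x0) / s))

    span = y.max() - y.min()
    p0 = [y.min(), y.max(), 0.0, max((d.max() - d.min()) / 10.0, 1.0)]
    popt, _ = curve_fit(logistic, d, y, p0=p0, maxfev=20000)
    q = 0.02275  # Gaussian tail mass beyond 2 sigma
    return float(2.0 * np.log(1.0 / q - 1.0) * abs(popt[3]))
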