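"""Ground-truthed synthetic scenes and spectra for pipeline verification.

The phantom emulates the statistical structure of an epoxy-embedded
bacterial thin section as seen by AFM-IR:

* a flat epoxy background with elliptical cell cross-sections (random
  in-plane orientation, mimicking random sectioning of rod-shaped cells);
* disk-shaped inclusion bodies (IBs) whose 1625/1650 cm^-1 amplitude
  ratio exceeds the cytoplasmic ratio by a known enrichment factor,
  optionally with Gaussian-blurred (diffuse) edges;
* inter-map drift between the 1650 and 1625 acquisitions (translation
  plus shear, the signature of nonconstant stage drift during slow scans);
* per-line PLL pulse-rate drift plus pixel noise, and a stiffness (PLL)
  offset on cells and IBs;
* independent acquisition noise in the trace and retrace directions.

It does not attempt physical photothermal forward modelling (probe
convolution, resonance physics); contrasts are additive and Gaussian
noise is used throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .data_model import (
    AFMIRDataset,
    Category,
    ChannelMap,
    DatasetPair,
    DEFAULT_UNITS,
    Spectrum,
    WavenumberGrid,
)

logger = logging.getLogger("ibspec.synthetic")

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "make_phantom",
    "make_band_spectrum",
    "preset_spectrum",
    "BAND_PRESETS",
    "drift_transform",
]


@dataclass
class PhantomSpec:
    """Full parameterization of a synthetic AFM-IR scene.

    Amplitude levels are in the same arbitrary units as real IR Amplitude
    maps; the defaults give a cytoplasm 1625/1650 ratio of 0.8 on an epoxy
    baseline of 1.  ``beta_enrichment_true`` is the ratio of the IB ratio
    to the cytoplasm ratio (the quantity the pipeline estimates).

    ``ib_radii_px`` lists the planted IB radii per cell; ``None`` draws
    0-3 IBs of radius 2-5 px per cell.  ``inter_map_drift`` is
    (dx px, dy px, shear fraction) applied to the later 1625 acquisition.
    ``pll_line_drift`` is (slope kHz/line, per-line noise SD kHz).
    """

    image_size_px: tuple[int, int] = (256, 256)
    field_of_view_um: tuple[float, float] = (10.0, 10.0)
    n_cells: int = 5
    cell_major_um: tuple[float, float] = (2.0, 3.5)
    cell_minor_um: tuple[float, float] = (0.8, 1.3)
    ib_radii_px: list[list[int]] | None = None
    beta_enrichment_true: float = 1.4
    edge_blur_sigma_px: float = 1.0
    pll_offset_ib_khz: float = 0.3
    pll_offset_cell_khz: float = 0.15
    pll_line_drift: tuple[float, float] = (0.002, 0.01)
    pll_pixel_noise_khz: float = 0.02
    inter_map_drift: tuple[float, float, float] = (3.0, -2.0, 0.01)
    amplitude_noise_sd: float = 0.02
    height_noise_sd_nm: float = 0.5
    amp_epoxy: float = 1.0
    amp_cell_1650: float = 2.0
    amp_cyto_1625: float = 1.6
    height_cell_nm: float = 50.0
    add_border_cell: bool = False
    seed: int = 0

    def __post_init__(self):
        if min(self.image_size_px) < 16:
            raise ValueError("image must be at least 16x16 px")
        if min(self.field_of_view_um) <= 0:
            raise ValueError("field of view must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if self.beta_enrichment_true <= 0:
            raise ValueError("beta_enrichment_true must be positive")
        if self.ib_radii_px is not None and len(self.ib_radii_px) != self.n_cells:
            raise ValueError("ib_radii_px must list radii for every cell")

    @property
    def pixel_size_nm(self) -> float:
        return 1000.0 * self.field_of_view_um[0] / self.image_size_px[1]


@dataclass
class GroundTruth:
    """What was actually planted: label maps, per-IB features, true transform."""

    cell_label_map: np.ndarray
    ib_label_map: np.ndarray
    ib_table: pd.DataFrame
    transform: np.ndarray  # 3x3 alignment matrix (registers 1625 onto 1650)

    @property
    def n_cells(self) -> int:
        return int(self.cell_label_map.max())

    @property
    def n_ibs(self) -> int:
        return int(self.ib_label_map.max())


def drift_transform(dx: float, dy: float, shear: float) -> np.ndarray:
    """Alignment matrix undoing a drift of (+dx cols, +dy rows) with row-shear.

    The physical drift moves scene content by (dx, dy) and skews columns by
    ``shear`` per row between the two acquisitions; the returned matrix maps
    reference (1650) pixel coordinates (row, col) to the matching coordinates
    in the drifted 1625 map, i.e. it is the transform registration recovers.
    """
    return np.array(
        [
            [1.0, 0.0, dy],
            [shear, 1.0, dx + shear * dy],
            [0.0, 0.0, 1.0],
        ]
    )


def _ellipse_mask(shape, center, a_px, b_px, theta) -> np.ndarray:
    """Boolean mask of a filled ellipse; semi-axes in px, theta CCW from +x."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    y = -(rr - center[0])  # y up, so theta follows the math convention
    x = cc - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    return (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0


def _place_cells(spec: PhantomSpec, rng: np.random.Generator):
    """Draw non-overlapping elliptical cells; returns label map + parameters."""
    h, w = spec.image_size_px
    px_um = spec.pixel_size_nm / 1000.0
    labels = np.zeros((h, w), dtype=np.int32)
    params = []
    occupied = np.zeros((h, w), dtype=bool)
    label = 0
    for i in range(spec.n_cells):
        placed = False
        for _ in range(200):
            a = rng.uniform(*spec.cell_major_um) / 2.0 / px_um  # semi-major, px
            b = rng.uniform(*spec.cell_minor_um) / 2.0 / px_um
            theta = rng.uniform(-np.pi / 2, np.pi / 2)
            margin = a + 8.0  # keep the cell and its segmentation halo interior
            if 2 * margin >= min(h, w):
                continue
            center = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
            mask = _ellipse_mask((h, w), center, a, b, theta)
            # enforce a clear epoxy gap between cells so instance
            # segmentation is well-posed on the phantom
            dilated = ndi.binary_dilation(mask, iterations=4)
            if (dilated & occupied).any():
                continue
            label += 1
            labels[mask] = label
            occupied |= dilated
            params.append(dict(center=center, a=a, b=b, theta=theta, border=False))
            placed = True
            break
        if not placed:
            logger.warning("phantom: could not place cell %d of %d", i + 1, spec.n_cells)
    if spec.add_border_cell:
        a = np.mean(spec.cell_major_um) / 2.0 / px_um
        b = np.mean(spec.cell_minor_um) / 2.0 / px_um
        center = (h / 2.0, 0.0)  # straddles the left border
        mask = _ellipse_mask((h, w), center, a, b, 0.0)
        mask &= ~occupied
        if mask.any():
            label += 1
            labels[mask] = label
            params.append(dict(center=center, a=a, b=b, theta=0.0, border=True))
    return labels, params


def _plant_ibs(spec: PhantomSpec, rng: np.random.Generator, cell_labels, cell_params):
    """Plant disk IBs along each cell's major axis; returns label map + table."""
    h, w = cell_labels.shape
    rr, cc = np.mgrid[0:h, 0:w]
    ib_labels = np.zeros((h, w), dtype=np.int32)
    rows = []
    ib_id = 0
    for cell_id, p in enumerate(cell_params, start=1):
        cmask = cell_labels == cell_id
        if spec.ib_radii_px is not None:
            radii = list(spec.ib_radii_px[cell_id - 1])
            fracs = np.linspace(-0.7, 0.7, len(radii)) if len(radii) > 1 else [0.0]
        else:
            n_ib = int(rng.integers(0, 4))
            radii = list(rng.integers(2, 6, size=n_ib))
            fracs = rng.uniform(-0.8, 0.8, size=n_ib)
        ct, st = np.cos(p["theta"]), np.sin(p["theta"])
        axis = np.array([-st, ct])  # (row, col) unit vector along the major axis
        for r, frac in zip(radii, fracs):
            ib_id += 1
            reach = max(p["a"] - r - 2.0, 0.0)
            # integer pixel centers: keeps disk rasterization exact, so a
            # radius-r disk is precisely the r-ball of the pixel grid
            center = np.round(np.asarray(p["center"]) + frac * reach * axis)
            disk = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= r**2
            clipped = bool((disk & ~cmask).any())
            disk &= cmask & (ib_labels == 0)
            if not disk.any():
                ib_id -= 1
                continue
            ib_labels[disk] = ib_id
            rows.append(
                dict(
                    ib_id=ib_id,
                    cell_id=cell_id,
                    area_px=int(disk.sum()),
                    radius_px=float(r),
                    row=float(center[0]),
                    col=float(center[1]),
                    polar_position=float(frac),
                    enrichment=spec.beta_enrichment_true,
                    pll_offset_khz=spec.pll_offset_ib_khz,
                    clipped=clipped,
                )
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "ib_id",
            "cell_id",
            "area_px",
            "radius_px",
            "row",
            "col",
            "polar_position",
            "enrichment",
            "pll_offset_khz",
            "clipped",
        ],
    )
    return ib_labels, table


def make_phantom(spec: PhantomSpec) -> tuple[DatasetPair, GroundTruth]:
    """Generate a drifted 1650/1625 dataset pair plus its ground truth.

    The 1650 dataset shows the undrifted scene; the 1625 dataset is the
    same scene resampled through the inverse of the true alignment
    transform (the drift happened between the two acquisitions), with the
    IB contrast and optional Gaussian edge blur applied.  A fixed seed
    yields byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size_px
    cell_labels, cell_params = _place_cells(spec, rng)
    ib_labels, ib_table = _plant_ibs(spec, rng, cell_labels, cell_params)
    cell_mask = cell_labels > 0
    ib_mask = ib_labels > 0

    amp_1650 = spec.amp_epoxy + (spec.amp_cell_1650 - spec.amp_epoxy) * cell_mask
    ib_delta = (spec.beta_enrichment_true - 1.0) * spec.amp_cyto_1625 * ib_mask
    if spec.edge_blur_sigma_px > 0:
        ib_delta = ndi.gaussian_filter(ib_delta, spec.edge_blur_sigma_px)
    amp_1625 = spec.amp_epoxy + (spec.amp_cyto_1625 - spec.amp_epoxy) * cell_mask + ib_delta

    height = ndi.gaussian_filter(spec.height_cell_nm * cell_mask.astype(float), 1.5)
    pll_scene = (
        spec.pll_offset_cell_khz * (cell_mask & ~ib_mask)
        + (spec.pll_offset_cell_khz + spec.pll_offset_ib_khz) * ib_mask
    )

    transform = drift_transform(*spec.inter_map_drift)
    inv = np.linalg.inv(transform)

    def warp(img):
        return ndi.affine_transform(img, inv[:2, :2], offset=inv[:2, 2], order=1, mode="nearest")

    def line_profile():
        slope, line_sd = spec.pll_line_drift
        return slope * np.arange(h) + rng.normal(0.0, line_sd, size=h)

    def noisy(img, sd):
        return img + rng.normal(0.0, sd, size=img.shape)

    def build_dataset(wavenumber, amp, drifted):
        tf = warp if drifted else (lambda x: x)
        amp_s, height_s, pll_s = tf(amp), tf(height), tf(pll_scene)
        channels = {}

        def add(ch, direction, data, units):
            channels[(ch, direction)] = ChannelMap(ch, direction, data, units)

        add("Height", "trace", noisy(height_s, spec.height_noise_sd_nm), "nm")
        add("Deflection", "trace", noisy(np.zeros((h, w)), 0.005), "V")
        for direction in ("trace", "retrace"):
            add("IRAmplitude", direction, noisy(amp_s, spec.amplitude_noise_sd), "a.u.")
            pll = pll_s + line_profile()[:, None]
            add("PLLFrequency", direction, noisy(pll, spec.pll_pixel_noise_khz), "kHz")
            add("IRPhase", direction, noisy(np.zeros((h, w)), 1.0), "deg")
        return AFMIRDataset(
            wavenumber=wavenumber,
            channels=channels,
            field_of_view_um=spec.field_of_view_um,
            sample_id="phantom",
            session_id=f"phantom-seed{spec.seed}",
        )

    ds_1650 = build_dataset(1650.0, amp_1650, drifted=False)
    ds_1625 = build_dataset(1625.0, amp_1625, drifted=True)
    pair = DatasetPair(ds_1650=ds_1650, ds_1625=ds_1625, transform=None)
    truth = GroundTruth(
        cell_label_map=cell_labels,
        ib_label_map=ib_labels,
        ib_table=ib_table,
        transform=transform,
    )
    return pair, truth


# ---------------------------------------------------------------------------
# Synthetic spectra

#: Gaussian band lists (center cm^-1, sigma cm^-1, amplitude) per category.
#: Amide-I structure: helix/disordered ~1654, intramolecular beta-sheet ~1628;
#: the peroxide presets add the antiparallel (1678) and intermolecular (1616)
#: beta-sheet bands.  The epoxy (BG) band list is illustrative and
#: configurable, not a measured resin spectrum.
BAND_PRESETS: dict[str, list[tuple[float, float, float]]] = {
    "CP": [(1654.0, 12.0, 1.0), (1628.0, 10.0, 0.35), (1240.0, 30.0, 0.25)],
    "IB": [(1654.0, 12.0, 1.0), (1628.0, 10.0, 0.9), (1240.0, 30.0, 0.25)],
    "CP_peroxide": [
        (1654.0, 12.0, 1.0),
        (1628.0, 10.0, 0.35),
        (1678.0, 8.0, 0.4),
        (1616.0, 8.0, 0.2),
        (1240.0, 30.0, 0.25),
    ],
    "IB_peroxide": [
        (1654.0, 12.0, 1.0),
        (1628.0, 10.0, 0.9),
        (1678.0, 8.0, 0.4),
        (1616.0, 8.0, 0.3),
        (1240.0, 30.0, 0.25),
    ],
    "BG": [
        (1110.0, 25.0, 0.5),
        (1250.0, 18.0, 0.4),
        (1508.0, 10.0, 0.45),
        (1608.0, 10.0, 0.6),
        (1730.0, 12.0, 0.5),
    ],
}


def make_band_spectrum(
    bands: list[tuple[float, float, float]],
    grid: WavenumberGrid | None = None,
    *,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    pll_level_khz: float | None = None,
    rng: np.random.Generator | None = None,
    sample_id: str = "synthetic",
    session_id: str = "synthetic",
    category: Category | str = Category.CP,
) -> Spectrum:
    """Sum-of-Gaussian-bands spectrum evaluated on ``grid``.

    Each band is (center cm^-1, sigma cm^-1, amplitude); centers must lie
    within the grid and sigmas must be positive.  An empty band list gives
    an all-zero (plus baseline) spectrum.
    """
    grid = grid or WavenumberGrid.default()
    wn = grid.values
    amp = np.full_like(wn, float(baseline))
    for center, width, a in bands:
        if width <= 0:
            raise ValueError(f"band width must be positive, got {width}")
        if not (wn[0] <= center <= wn[-1]):
            raise ValueError(f"band center {center} outside grid range")
        amp = amp + a * np.exp(-0.5 * ((wn - center) / width) ** 2)
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        amp = amp + rng.normal(0.0, noise_sd, size=wn.size)
    pll = None
    if pll_level_khz is not None:
        pll = np.full_like(wn, float(pll_level_khz))
        if noise_sd > 0:
            pll = pll + (rng or np.random.default_rng(0)).normal(0, 0.01, wn.size)
    return Spectrum(
        grid=grid,
        ir_amplitude=amp,
        pll_frequency=pll,
        sample_id=sample_id,
        session_id=session_id,
        category=Category(category) if not isinstance(category, Category) else category,
    )


def preset_spectrum(name: str, grid: WavenumberGrid | None = None, **kwargs) -> Spectrum:
    """Convenience wrapper around :data:`BAND_PRESETS`.

    The category label is inferred from the preset name (BG presets are
    background, IB* presets inclusion body, everything else cytoplasm).
    """
    if name not in BAND_PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(BAND_PRESETS)}")
    if name.startswith("BG"):
        cat = Category.BG
    elif name.startswith("IB"):
        cat = Category.IB
    else:
        cat = Category.CP
    kwargs.setdefault("category", cat)
    kwargs.setdefault("baseline", 0.05)
    return make_band_spectrum(BAND_PRESETS[name], grid, **kwargs)
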