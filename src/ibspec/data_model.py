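"""Core domain types for AFM-IR spectra and multi-channel map datasets.

An AFM-IR measurement produces two kinds of data:

* point *spectra* — IR amplitude (and, in parallel, the PLL pulse-rate
  channel) as a function of wavenumber at a single sample location;
* map *datasets* — co-acquired 2D raster channels (Height, Deflection,
  IR Amplitude, PLL Frequency, IR Phase) at a single illumination
  wavenumber, some of them in both scan directions (trace/retrace).

These containers hold the arrays together with the acquisition geometry
and session metadata the downstream corrections depend on.  Masked
(invalid) pixels/points are carried as explicit boolean validity maps,
never as sentinel values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

import numpy as np

#: Canonical channel names produced by the instrument.
CHANNELS = ("Height", "Deflection", "IRAmplitude", "PLLFrequency", "IRPhase")
#: Scan directions of a raster line.
DIRECTIONS = ("trace", "retrace")

#: Conventional units per canonical channel.
DEFAULT_UNITS = {
    "Height": "nm",
    "Deflection": "V",
    "IRAmplitude": "a.u.",
    "PLLFrequency": "kHz",
    "IRPhase": "deg",
}


class Category(str, Enum):
    """Spectrum location category: inclusion body, cytoplasm or epoxy background."""

    IB = "IB"
    CP = "CP"
    BG = "BG"


def _as_float_array(x, name: str, ndim: int) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-dimensional, got shape {a.shape}")
    return a


@dataclass(frozen=True, eq=False)
class WavenumberGrid:
    """Uniform, strictly increasing wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self):
        v = _as_float_array(self.values, "wavenumber values", 1)
        if v.size < 2:
            raise ValueError("wavenumber grid needs at least 2 points")
        d = np.diff(v)
        if np.any(d <= 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        if not np.allclose(d, d[0], rtol=1e-9, atol=1e-9):
            raise ValueError("wavenumber grid must be uniformly spaced")
        object.__setattr__(self, "values", v)

    @classmethod
    def default(cls) -> "WavenumberGrid":
        """The acquisition grid used throughout: 800-1800 cm^-1, step 2."""
        return cls(np.arange(800.0, 1801.0, 2.0))

    @property
    def step(self) -> float:
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return int(self.values.size)

    def matches(self, other: "WavenumberGrid") -> bool:
        return self.values.size == other.values.size and np.allclose(
            self.values, other.values, rtol=0, atol=1e-9
        )

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of grid points inside [lo, hi], endpoints inclusive."""
        if hi < lo:
            lo, hi = hi, lo
        m = (self.values >= lo) & (self.values <= hi)
        if not m.any():
            raise ValueError(f"window ({lo}, {hi}) does not intersect the grid")
        return m

    def contains_window(self, lo: float, hi: float) -> bool:
        if hi < lo:
            lo, hi = hi, lo
        return lo >= self.values[0] and hi <= self.values[-1]


@dataclass
class Spectrum:
    """A single IR amplitude spectrum with optional parallel PLL channel.

    ``ir_amplitude`` is assumed already normalised to the laser emission
    spectrum recorded at measurement time; further processing (epoxy
    division, min-max scaling) lives in :mod:`ibspec.spectra`.

    ``mask`` is a boolean validity array (True = valid point).
    """

    grid: WavenumberGrid
    ir_amplitude: np.ndarray
    pll_frequency: np.ndarray | None = None
    sample_id: str = ""
    session_id: str = ""
    category: Category = Category.CP
    position: tuple[float, float] | None = None  # (x um, y um) from top-left
    mask: np.ndarray | None = None

    def __post_init__(self):
        amp = _as_float_array(self.ir_amplitude, "ir_amplitude", 1)
        if amp.size != len(self.grid):
            raise ValueError(
                f"ir_amplitude length {amp.size} != grid length {len(self.grid)}"
            )
        self.ir_amplitude = amp
        if self.pll_frequency is not None:
            pll = _as_float_array(self.pll_frequency, "pll_frequency", 1)
            if pll.size != len(self.grid):
                raise ValueError("pll_frequency length does not match grid")
            self.pll_frequency = pll
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != amp.shape:
                raise ValueError("mask shape does not match amplitude")
            self.mask = m
        self.category = Category(self.category)
        if not np.all(np.isfinite(amp[self.valid])):
            raise ValueError("ir_amplitude contains non-finite unmasked values")

    @property
    def valid(self) -> np.ndarray:
        """Boolean validity mask (all True when no mask is set)."""
        if self.mask is None:
            return np.ones(len(self.grid), dtype=bool)
        return self.mask

    def with_amplitude(self, amp: np.ndarray, mask: np.ndarray | None = None) -> "Spectrum":
        """Copy of this spectrum with a new amplitude array (metadata preserved)."""
        return replace(self, ir_amplitude=np.asarray(amp, float), mask=mask)


@dataclass
class ChannelMap:
    """One 2D raster channel in one scan direction.

    ``channel`` is normally one of :data:`CHANNELS`; derived maps (e.g. a
    1625/1650 ratio map) may use other descriptive names.
    ``mask`` is a boolean validity map (True = valid pixel).
    """

    channel: str
    direction: str
    data: np.ndarray
    units: str = ""
    mask: np.ndarray | None = None

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        d = _as_float_array(self.data, "channel data", 2)
        self.data = d
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != d.shape:
                raise ValueError("mask shape does not match data")
            self.mask = m
        if not np.all(np.isfinite(d[self.valid])):
            raise ValueError(
                f"channel {self.channel}/{self.direction} has non-finite unmasked pixels"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def valid(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.data.shape, dtype=bool)
        return self.mask


@dataclass
class AFMIRDataset:
    """Co-acquired channel maps at one illumination wavenumber.

    Geometry invariant: ``pixel_size_nm * width_px == 1000 * field_width_um``
    (enforced on construction; pixel size is derived from the field of view
    when not given).  Pixel coordinates are row-major, origin at the top-left
    corner, 0-based.
    """

    wavenumber: float
    channels: Mapping[tuple[str, str], ChannelMap]
    field_of_view_um: tuple[float, float]
    pixel_size_nm: float | None = None
    sample_id: str = ""
    session_id: str = ""

    def __post_init__(self):
        if not self.channels:
            raise ValueError("dataset needs at least one channel map")
        self.channels = dict(self.channels)
        shapes = {cm.shape for cm in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel maps have inconsistent shapes: {shapes}")
        for (ch, direction), cm in self.channels.items():
            if (cm.channel, cm.direction) != (ch, direction):
                raise ValueError(
                    f"channel dict key {(ch, direction)} does not match map "
                    f"({cm.channel}, {cm.direction})"
                )
        h, w = next(iter(shapes))
        derived = 1000.0 * self.field_of_view_um[0] / w
        if self.pixel_size_nm is None:
            self.pixel_size_nm = derived
        elif not np.isclose(self.pixel_size_nm, derived, rtol=5e-3):
            raise ValueError(
                f"pixel_size_nm {self.pixel_size_nm:.3f} inconsistent with "
                f"field of view ({derived:.3f} nm/px expected)"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def has(self, channel: str, direction: str = "trace") -> bool:
        return (channel, direction) in self.channels

    def get(self, channel: str, direction: str = "trace") -> ChannelMap:
        try:
            return self.channels[(channel, direction)]
        except KeyError:
            raise KeyError(f"dataset has no channel {channel}/{direction}") from None

    def with_channels(self, channels: Mapping[tuple[str, str], ChannelMap]) -> "AFMIRDataset":
        return replace(self, channels=dict(channels))


@dataclass
class DatasetPair:
    """The 1650 cm^-1 (reference) and 1625 cm^-1 (moving) datasets of one scene.

    ``transform`` is the 3x3 affine alignment matrix in pixel (row, col)
    coordinates that registers the 1625 maps onto the 1650 maps; ``None``
    until registration has run (or when the pair is known to be aligned).
    """

    ds_1650: AFMIRDataset
    ds_1625: AFMIRDataset
    transform: np.ndarray | None = None

    def __post_init__(self):
        if not np.isclose(self.ds_1650.wavenumber, 1650.0):
            raise ValueError("reference dataset must be at 1650 cm^-1")
        if not np.isclose(self.ds_1625.wavenumber, 1625.0):
            raise ValueError("moving dataset must be at 1625 cm^-1")
        if self.ds_1650.shape != self.ds_1625.shape:
            raise ValueError("paired datasets must share shape")
        if not np.isclose(self.ds_1650.pixel_size_nm, self.ds_1625.pixel_size_nm, rtol=1e-6):
            raise ValueError("paired datasets must share pixel size")
        if self.transform is not None:
            t = np.asarray(self.transform, dtype=float)
            if t.shape != (3, 3):
                raise ValueError("transform must be a 3x3 matrix")
            self.transform = t

    @property
    def pixel_size_nm(self) -> float:
        return float(self.ds_1650.pixel_size_nm)

    @property
    def shape(self) -> tuple[int, int]:
        return self.ds_1650.shape
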