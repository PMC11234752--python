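import numpy as np
import pandas as pd
import pytest

from ibspec.segment import SegmentationMaps
from ibspec.synthetic import PhantomSpec


@pytest.fixture
def quiet_spec():
    """Factory for noise-free, drift-free, blur-free phantom specs."""

    def make(**overrides) -> PhantomSpec:
        base = dict(
            edge_blur_sigma_px=0.0,
            amplitude_noise_sd=0.0,
            height_noise_sd_nm=0.0,
            pll_line_drift=(0.0, 0.0),
            pll_pixel_noise_khz=0.0,
            inter_map_drift=(0.0, 0.0, 0.0),
            seed=0,
        )
        base.update(overrides)
        return PhantomSpec(**base)

    return make


def truth_segmentation(truth) -> SegmentationMaps:
    """SegmentationMaps built from a phantom's ground-truth label maps."""
    owners = truth.ib_table[["ib_id", "cell_id"]].astype(int)
    return SegmentationMaps(
        truth.cell_label_map, truth.ib_label_map, pd.DataFrame(owners)
    )


def triangle_threshold_oracle(values, n_bins=64):
    """Independent brute-force triangle construction (loops, geometric
    point-line distance) used to cross-check the vectorized implementation."""
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    vmin, vmax = v.min(), v.max()
    hist, edges = np.histogram(v, bins=n_bins, range=(vmin, vmax))
    peak = max(range(n_bins), key=lambda i: hist[i])
    nonempty = [i for i in range(n_bins) if hist[i] > 0]
    far = max(nonempty, key=lambda i: abs(i - peak))
    # normalized coordinates: x in peak->far units, y in peak-height units
    x1, y1 = 0.0, 1.0
    x2, y2 = 1.0, hist[far] / hist[peak]
    best_i, best_d = None, -1.0
    lo, hi = min(peak, far), max(peak, far)
    for i in range(lo, hi + 1):
        x0 = (i - peak) / (far - peak)
        y0 = hist[i] / hist[peak]
        d = abs((y2 - y1) * x0 - (x2 - x1) * y0 + x2 * y1 - y2 * x1) / np.hypot(
            y2 - y1, x2 - x1
        )
        if d > best_d:
            best_d, best_i = d, i
    return 0.5 * (edges[best_i] + edges[best_i + 1])
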