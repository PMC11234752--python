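import logging

import numpy as np
import pytest
from skimage import morphology

from conftest import triangle_threshold_oracle
from ibspec.segment import (
    SegmentationMaps,
    fallback_cell_backend,
    segment_cells,
    segment_ibs,
    triangle_threshold,
)
from ibspec.synthetic import PhantomSpec, make_phantom


def random_samples(n_cases=100, seed=0):
    """A varied zoo of 1D intensity samples for threshold cross-checks."""
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        kind = i % 4
        n = int(rng.integers(200, 5000))
        if kind == 0:  # bimodal Gaussian mixture
            w = rng.uniform(0.05, 0.4)
            v = np.concatenate(
                [
                    rng.normal(1.0, 0.05, int(n * (1 - w))),
                    rng.normal(rng.uniform(1.5, 3.0), 0.05, int(n * w)),
                ]
            )
        elif kind == 1:  # skewed
            v = rng.lognormal(0.0, rng.uniform(0.2, 0.8), n)
        elif kind == 2:  # uniform plus outliers
            v = np.concatenate([rng.uniform(0, 1, n), rng.uniform(3, 4, max(3, n // 50))])
        else:  # unimodal Gaussian
            v = rng.normal(0.0, 1.0, n)
        cases.append(v)
    return cases


class TestTriangleThreshold:
    def test_matches_brute_force_construction_on_100_samples(self):
        for v in random_samples(100):
            impl = triangle_threshold(v, n_bins=64)
            oracle = triangle_threshold_oracle(v, n_bins=64)
            assert impl == pytest.approx(oracle, abs=1e-12)

    def test_bimodal_mixture_threshold_separates_modes(self):
        """The triangle threshold lands at the foot of the dominant mode,
        cleanly separating the two populations of a 9:1 Gaussian mixture."""
        rng = np.random.default_rng(1)
        lo = rng.normal(1.0, 0.05, 9000)
        hi = rng.normal(2.0, 0.05, 1000)
        thr = triangle_threshold(np.concatenate([lo, hi]))
        assert 1.0 < thr < 2.0
        assert (lo > thr).mean() < 0.02  # barely any cytoplasm above
        assert (hi > thr).mean() > 0.99  # essentially all IB pixels above

    def test_threshold_within_data_range(self):
        for v in random_samples(20, seed=5):
            thr = triangle_threshold(v)
            assert v.min() <= thr <= v.max()

    @pytest.mark.parametrize("a,b", [(2.0, 0.0), (0.5, 3.0), (10.0, -7.0)])
    def test_affine_equivariance(self, a, b):
        rng = np.random.default_rng(2)
        v = np.concatenate([rng.normal(1, 0.1, 2000), rng.normal(2, 0.1, 300)])
        thr = triangle_threshold(v)
        thr_scaled = triangle_threshold(a * v + b)
        assert thr_scaled == pytest.approx(a * thr + b, rel=1e-9, abs=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            triangle_threshold(np.full(100, 3.0))


class TestSegmentCells:
    def test_erosion_shrinks_disk_cell_as_morphology_predicts(self, quiet_spec):
        """A backend returning a 10-px disk, eroded by radius 2, leaves the
        same area as the direct morphological erosion (about pi * 8^2)."""
        pair, _ = make_phantom(quiet_spec(n_cells=0))
        disk_mask = np.zeros(pair.shape, dtype=np.int32)
        rr, cc = np.mgrid[0 : pair.shape[0], 0 : pair.shape[1]]
        disk_mask[(rr - 100) ** 2 + (cc - 100) ** 2 <= 100] = 1

        labels = segment_cells(pair.ds_1625, backend=lambda img: disk_mask,
                               erosion_radius_px=2)
        expected = morphology.erosion(disk_mask > 0, morphology.disk(2)).sum()
        assert (labels == 1).sum() == expected
        assert abs(expected - np.pi * 64) < 25  # boundary discretization

    def test_border_cells_discarded(self, quiet_spec):
        spec = quiet_spec(n_cells=3, add_border_cell=True, seed=12)
        pair, truth = make_phantom(spec)
        n_interior = truth.n_cells - 1
        labels = segment_cells(pair.ds_1625)
        assert labels.max() == n_interior
        border = np.zeros(labels.shape, bool)
        border[0], border[-1], border[:, 0], border[:, -1] = True, True, True, True
        assert not labels[border].any()

    def test_blank_image_yields_zero_cells_with_warning(self, quiet_spec, caplog):
        pair, _ = make_phantom(quiet_spec(n_cells=0))
        with caplog.at_level(logging.WARNING, logger="ibspec.segment"):
            labels = segment_cells(pair.ds_1625)
        assert labels.max() == 0
        assert "no" in caplog.text.lower()

    def test_backend_shape_mismatch_rejected(self, quiet_spec):
        pair, _ = make_phantom(quiet_spec(seed=1))
        with pytest.raises(ValueError, match="shape"):
            segment_cells(pair.ds_1625, backend=lambda img: np.zeros((4, 4), int))

    def test_fallback_backend_recovers_planted_cell_count(self, quiet_spec):
        pair, truth = make_phantom(quiet_spec(seed=21, n_cells=4))
        labels = segment_cells(pair.ds_1625)
        assert labels.max() == truth.n_cells


class TestSegmentIBs:
    def _one_cell_pair(self, quiet_spec, radii, seed=5):
        spec = quiet_spec(
            n_cells=1,
            ib_radii_px=[radii],
            cell_major_um=(3.4, 3.4),
            cell_minor_um=(1.3, 1.3),
            seed=seed,
        )
        return make_phantom(spec)

    def test_minimum_detected_radius_is_two_pixels(self, quiet_spec):
        """Disks of radii 1-5 px: the opening removes the radius-1 disk and
        keeps radius >= 2, so four IBs survive with min equivalent radius 2."""
        pair, truth = self._one_cell_pair(quiet_spec, [1, 2, 3, 4, 5])
        cells = segment_cells(pair.ds_1625)
        ib_labels, owners = segment_ibs(pair.ds_1625.get("IRAmplitude"), cells)
        n = ib_labels.max()
        assert n == 4
        areas = np.array([(ib_labels == i).sum() for i in range(1, n + 1)])
        r_eq = np.sqrt(areas / np.pi)
        assert r_eq.min() >= 2.0
        assert r_eq.min() == pytest.approx(2.0, abs=0.1)

    def test_three_ibs_map_to_one_cell(self, quiet_spec):
        pair, _ = self._one_cell_pair(quiet_spec, [3, 3, 3])
        cells = segment_cells(pair.ds_1625)
        ib_labels, owners = segment_ibs(pair.ds_1625.get("IRAmplitude"), cells)
        assert ib_labels.max() == 3
        assert set(owners["cell_id"]) == {1}

    def test_bright_pixels_outside_cells_ignored(self, quiet_spec):
        pair, _ = self._one_cell_pair(quiet_spec, [3])
        amp = pair.ds_1625.get("IRAmplitude").data.copy()
        amp[5:15, 5:15] = amp.max() * 2  # bright blob on epoxy
        cells = segment_cells(pair.ds_1625)
        ib_labels, _ = segment_ibs(amp, cells)
        assert not (ib_labels[5:15, 5:15] > 0).any()

    def test_planted_counts_exact_and_areas_within_15pct(self, quiet_spec):
        spec = quiet_spec(seed=30, n_cells=3, ib_radii_px=[[2, 5], [3], [5]])
        pair, truth = make_phantom(spec)
        cells = segment_cells(pair.ds_1625)
        ib_labels, owners = segment_ibs(pair.ds_1625.get("IRAmplitude"), cells)
        assert ib_labels.max() == truth.n_ibs
        counts = owners.groupby("cell_id").size().sort_values(ascending=False)
        truth_counts = (
            truth.ib_table.groupby("cell_id").size().sort_values(ascending=False)
        )
        assert list(counts) == list(truth_counts)
        det_areas = np.sort([(ib_labels == i).sum() for i in range(1, ib_labels.max() + 1)])
        true_areas = np.sort(truth.ib_table.area_px.to_numpy())
        np.testing.assert_allclose(det_areas, true_areas, rtol=0.15)

    def test_opening_is_idempotent_on_detected_mask(self, quiet_spec):
        pair, _ = self._one_cell_pair(quiet_spec, [2, 4])
        cells = segment_cells(pair.ds_1625)
        ib_labels, _ = segment_ibs(pair.ds_1625.get("IRAmplitude"), cells)
        mask = ib_labels > 0
        reopened = morphology.opening(mask, morphology.disk(2))
        np.testing.assert_array_equal(reopened, mask)

    def test_tiny_cell_skipped_with_warning(self, caplog):
        amp = np.ones((32, 32))
        cells = np.zeros((32, 32), int)
        cells[10:12, 10:14] = 1  # 8 px < 16
        amp[10, 10] = 5.0
        with caplog.at_level(logging.WARNING, logger="ibspec.segment"):
            ib_labels, _ = segment_ibs(amp, cells)
        assert ib_labels.max() == 0
        assert "skipped" in caplog.text


class TestSegmentationMaps:
    def test_invariants_enforced(self):
        cells = np.zeros((16, 16), np.int32)
        cells[4:10, 4:10] = 1
        ibs = np.zeros_like(cells)
        ibs[5, 5] = 1
        import pandas as pd

        seg = SegmentationMaps(cells, ibs, pd.DataFrame({"ib_id": [1], "cell_id": [1]}))
        assert seg.n_cells == 1 and seg.n_ibs == 1
        bad_ibs = ibs.copy()
        bad_ibs[0, 0] = 1  # IB off-cell
        with pytest.raises(ValueError, match="outside"):
            SegmentationMaps(cells, bad_ibs, pd.DataFrame({"ib_id": [1], "cell_id": [1]}))
        bad_cells = cells.copy()
        bad_cells[0, 0] = 2
        with pytest.raises(ValueError, match="border"):
            SegmentationMaps(bad_cells, ibs, pd.DataFrame({"ib_id": [1], "cell_id": [1]}))
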