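"""DVH endpoints against brute-force oracles, plus accumulation identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from doseaccum.core import DoseFrame, DoseGrid, GridGeometry, StructureMask
from doseaccum.metrics import (
    StructureError,
    accumulate,
    compute_dvh,
    compute_metrics,
    warp_dose,
)
from doseaccum.registration import DisplacementField


def _grid(shape=(10, 10, 10)):
    return GridGeometry(shape, (2.0, 2.0, 2.0))


def _uniform_case(value):
    g = _grid()
    dose = DoseGrid(g, np.full(g.shape, float(value)))
    mask = StructureMask(g, np.ones(g.shape, bool), name="m")
    return dose, mask


class TestComputeMetrics:
    def test_uniform_30gy_closed_form(self):
        dose, mask = _uniform_case(30.0)
        m = compute_metrics(dose, mask)
        assert (m.v20_pct, m.v30_pct, m.v40_pct) == (100.0, 100.0, 0.0)
        assert m.d50_gy == 30.0
        assert m.dmean_gy == pytest.approx(30.0)

    def test_half_low_half_high(self):
        g = GridGeometry((10, 10, 2), (2.0, 2.0, 2.0))
        vals = np.empty(g.shape)
        vals[..., 0] = 10.0
        vals[..., 1] = 40.0
        dose = DoseGrid(g, vals)
        mask = StructureMask(g, np.ones(g.shape, bool))
        m = compute_metrics(dose, mask)
        assert (m.v20_pct, m.v30_pct, m.v40_pct) == (50.0, 50.0, 50.0)
        assert m.d50_gy == 40.0  # >= convention: half the voxels get 40 Gy
        assert m.dmean_gy == pytest.approx(25.0)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_sorted_voxel_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        g = _grid()
        dose = DoseGrid(g, rng.random(g.shape) * 60.0)
        mask = StructureMask(g, rng.random(g.shape) > 0.5)
        if mask.voxel_count == 0:
            return
        m = compute_metrics(dose, mask)
        d = dose.values[mask.values]
        n = d.size
        for attr, thr in [("v20_pct", 20.0), ("v30_pct", 30.0), ("v40_pct", 40.0)]:
            assert getattr(m, attr) == 100.0 * np.sum(d >= thr) / n
        # D50 oracle: largest voxel dose with at-least-half coverage
        best = max(v for v in d if np.sum(d >= v) >= 0.5 * n)
        assert m.d50_gy == best
        assert m.dmean_gy == pytest.approx(d.mean())

    def test_metric_ordering_and_permutation_invariance(self, rng):
        g = _grid()
        vals = rng.gamma(2.0, 10.0, g.shape)
        mask = StructureMask(g, rng.random(g.shape) > 0.3)
        m1 = compute_metrics(DoseGrid(g, vals), mask)
        assert 100.0 >= m1.v20_pct >= m1.v30_pct >= m1.v40_pct >= 0.0
        # permute doses within the mask: pure distribution functionals
        shuffled = vals.copy()
        inside = shuffled[mask.values]
        rng.shuffle(inside)
        shuffled[mask.values] = inside
        m2 = compute_metrics(DoseGrid(g, shuffled), mask)
        assert m1.as_dict() == m2.as_dict()

    def test_empty_mask_raises(self):
        dose, _ = _uniform_case(10.0)
        empty = StructureMask(dose.geometry, np.zeros(dose.geometry.shape, bool))
        with pytest.raises(StructureError):
            compute_metrics(dose, empty)


class TestComputeDvh:
    def test_uniform_dose_step_curve(self):
        dose, mask = _uniform_case(30.0)
        dvh = compute_dvh(dose, mask, bin_width_gy=1.0)
        at_or_below = dvh.edges_gy <= 30.0
        np.testing.assert_array_equal(dvh.volume_fraction[at_or_below], 1.0)
        np.testing.assert_array_equal(dvh.volume_fraction[~at_or_below], 0.0)

    def test_curve_matches_brute_force_counts(self, rng):
        g = _grid()
        dose = DoseGrid(g, rng.random(g.shape) * 55.0)
        mask = StructureMask(g, np.ones(g.shape, bool))
        dvh = compute_dvh(dose, mask, bin_width_gy=0.5)
        d = dose.values[mask.values]
        for edge, frac in zip(dvh.edges_gy, dvh.volume_fraction):
            assert frac == np.sum(d >= edge) / d.size
        assert dvh.volume_fraction[0] == 1.0
        assert dvh.volume_fraction[-1] == 0.0
        assert np.all(np.diff(dvh.volume_fraction) <= 0)

    def test_metrics_agree_with_fine_dvh_within_one_bin(self, rng):
        g = _grid()
        dose = DoseGrid(g, rng.random(g.shape) * 50.0)
        mask = StructureMask(g, rng.random(g.shape) > 0.4)
        bw = 0.01
        dvh = compute_dvh(dose, mask, bin_width_gy=bw)
        m = compute_metrics(dose, mask)
        d50_dvh = dvh.edges_gy[np.searchsorted(-dvh.volume_fraction, -0.5, side="right") - 1]
        assert abs(m.d50_gy - d50_dvh) <= bw + 1e-9
        for attr, thr in [("v20_pct", 20.0), ("v30_pct", 30.0)]:
            idx = int(round(thr / bw))
            assert getattr(m, attr) == pytest.approx(100 * dvh.volume_fraction[idx])


class TestAccumulateAndWarpDose:
    def test_sum_of_identical_uniform_weeks(self):
        g = _grid()
        weekly = [DoseGrid(g, np.full(g.shape, 10.0)) for _ in range(7)]
        total = accumulate(weekly)
        np.testing.assert_allclose(total.values, 70.0)

    def test_zero_doses_accumulate_to_zero(self):
        g = _grid()
        total = accumulate([DoseGrid(g, np.zeros(g.shape)) for _ in range(3)])
        assert total.values.max() == 0.0

    def test_geometry_mismatch_rejected(self):
        a = DoseGrid(_grid(), np.zeros((10, 10, 10)))
        b = DoseGrid(GridGeometry((10, 10, 10), (1, 1, 1)), np.zeros((10, 10, 10)))
        with pytest.raises(Exception):
            accumulate([a, b])

    def test_identity_field_full_fractions_resamples(self):
        g = _grid()
        rng = np.random.default_rng(7)
        weekly = DoseGrid(g, rng.random(g.shape) * 2.0, frame=DoseFrame.WEEKLY)
        field = DisplacementField.zero(g)
        out = warp_dose(weekly, field, fractions=35, n_fractions_total=35)
        assert out.frame == DoseFrame.PLANNING
        np.testing.assert_allclose(out.values, weekly.values, atol=1e-6)

    def test_uniform_dose_scaled_by_fraction_share(self):
        g = _grid()
        weekly = DoseGrid(g, np.full(g.shape, 70.0), frame=DoseFrame.WEEKLY)
        # a smooth nonzero field: constants are interpolation-invariant
        vec = np.zeros(g.shape + (3,))
        vec[..., 0] = 1.7
        out = warp_dose(weekly, DisplacementField(g, vec), 5, 35)
        inside = out.values[1:-1, 1:-1, 1:-1]
        np.testing.assert_allclose(inside, 70.0 * 5 / 35, rtol=1e-6)

    def test_shifted_dose_and_mask_preserve_structure_dmean(self, rng):
        # rigid-shift field with correspondingly shifted mask: Dmean invariant
        g = GridGeometry((20, 20, 20), (2.0, 2.0, 2.0))
        x = g.world_points()
        smooth = 30.0 + 20.0 * np.sin(x[..., 0] / 11.0) * np.cos(x[..., 1] / 13.0)
        weekly = DoseGrid(g, smooth, frame=DoseFrame.WEEKLY)
        shift = np.zeros(g.shape + (3,))
        shift[..., 0] = 4.0  # exactly two voxels
        mask = np.zeros(g.shape, bool)
        mask[6:12, 8:14, 8:14] = True
        m_weekly = StructureMask(g, np.roll(mask, 2, axis=0))
        from doseaccum.metrics import compute_metrics

        before = compute_metrics(
            DoseGrid(g, weekly.values), m_weekly
        ).dmean_gy
        warped = warp_dose(weekly, DisplacementField(g, shift), 35, 35)
        after = compute_metrics(warped, StructureMask(g, mask)).dmean_gy
        assert abs(after - before) / before < 0.005

    def test_frame_violations_rejected(self):
        g = _grid()
        planning = DoseGrid(g, np.zeros(g.shape), frame=DoseFrame.PLANNING)
        with pytest.raises(Exception):
            warp_dose(planning, DisplacementField.zero(g), 5, 35)
        weekly = DoseGrid(g, np.zeros(g.shape), frame=DoseFrame.WEEKLY)
        with pytest.raises(Exception):
            warp_dose(weekly, DisplacementField.zero(g), 40, 35)
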