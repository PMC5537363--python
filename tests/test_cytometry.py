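import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sporecyte as sc
from sporecyte.errors import CalibrationError
from sporecyte.segmentation import Particle

from conftest import SPORE_AREA, area_gate, scene_spec


def particle(area, circ=0.9, border=False, label=1):
    return Particle(
        label=label,
        area_um2=float(area),
        perimeter_um=math.sqrt(4 * math.pi * area / circ),
        circularity=circ,
        centroid_um=(0.0, 0.0),
        bbox_um=(0.0, 0.0, 1.0, 1.0),
        touches_border=border,
    )


class TestGate:
    def test_empty_list(self):
        assert sc.gate_spores([], sc.GateSpec()) == []

    def test_area_bounds(self):
        parts = [particle(a, label=i) for i, a in enumerate([100, 5000, 20000], 1)]
        gated = sc.gate_spores(parts, sc.GateSpec(min_area_um2=1500.0))
        assert [p.area_um2 for p in gated] == [5000, 20000]

    def test_border_exclusion_flag(self):
        parts = [particle(5000, border=True), particle(5000, border=False)]
        assert len(sc.gate_spores(parts, sc.GateSpec(exclude_border=True))) == 1
        assert len(sc.gate_spores(parts, sc.GateSpec(exclude_border=False))) == 2

    def test_synthetic_debris_rejected_spores_kept(self):
        # 300 spores plus 50 sub-gate debris specks; the area gate keeps
        # exactly the 300 spores (no clustering, so one particle each)
        scene = sc.generate_scene(
            scene_spec(
                field_um=(2400.0, 1800.0), n_spores=300, debris_count=50, seed=12
            )
        )
        parts = sc.label_particles(sc.binarize(scene.chlorophyll))
        assert len(parts) == 350
        gated = sc.gate_spores(parts, area_gate())
        assert len(gated) == 300

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            sc.GateSpec(min_area_um2=10.0, max_area_um2=5.0)


class TestCorrectedCount:
    def test_exact_multiples(self):
        parts = [particle(5000.0, label=i) for i in range(1, 11)]
        res = sc.corrected_count(parts, 5000.0)
        assert res.corrected_count == pytest.approx(10.0)
        assert res.corrected_count_int == 10
        assert res.n_particles == 10

    def test_merged_cluster_counts_as_members(self):
        # one merged particle three spores large resolves to 3
        res = sc.corrected_count([particle(15000.0)], 5000.0)
        assert res.corrected_count == pytest.approx(3.0)
        assert res.corrected_count_int == 3

    def test_per_particle_variant_floors_at_one(self):
        parts = [particle(2000.0), particle(15000.0)]
        res = sc.corrected_count(parts, 5000.0, per_particle=True)
        assert res.corrected_count == pytest.approx(1 + 3)

    def test_rounding_ties_away_from_zero(self):
        res = sc.corrected_count([particle(2500.0)], 5000.0)
        assert res.corrected_count_int == 1

    def test_non_positive_reference_area(self):
        with pytest.raises(ValueError):
            sc.corrected_count([particle(10.0)], 0.0)

    def test_clustered_field_recovered_within_10pct(self, clustered_scene):
        res = sc.count_field(
            clustered_scene.chlorophyll,
            gate=area_gate(),
            single_spore_area_um2=SPORE_AREA,
        )
        truth = clustered_scene.truth.true_count
        assert abs(res.corrected_count - truth) / truth <= 0.10
        # clustering merges particles, so the raw count underestimates
        assert res.n_particles < truth

    @given(extra=st.floats(min_value=1.0, max_value=1e6))
    @settings(max_examples=30, derandomize=True)
    def test_adding_a_particle_never_decreases_count(self, extra):
        base = [particle(4000.0), particle(9000.0)]
        before = sc.corrected_count(base, 5000.0).corrected_count
        after = sc.corrected_count(base + [particle(extra)], 5000.0).corrected_count
        assert after >= before

    def test_scale_invariance_of_corrected_count(self):
        # the same physical scene rasterised at two resolutions changes the
        # corrected count by < 2%
        from sporecyte.synthetic import _coverage

        rng = np.random.default_rng(21)
        ellipses = [
            (rng.uniform(40, 260), rng.uniform(40, 260), 4.9, 3.2, rng.uniform(0, np.pi))
            for _ in range(15)
        ]  # axes in μm
        counts = []
        for ps in (1.0, 0.5):
            n = int(300 / ps)
            canvas = np.zeros((n, n))
            for cx, cy, a, b, t in ellipses:
                sl_r, sl_c, cov = _coverage((n, n), cx / ps, cy / ps, a / ps, b / ps, t)
                np.maximum(canvas[sl_r, sl_c], cov, out=canvas[sl_r, sl_c])
            im = sc.FluorImage(20.0 + canvas * 180.0, ps)
            res = sc.count_field(
                im,
                threshold=sc.ThresholdSpec("fixed", 110.0),
                gate=area_gate(),
                single_spore_area_um2=SPORE_AREA,
            )
            counts.append(res.corrected_count)
        assert counts[1] == pytest.approx(counts[0], rel=0.02)


class TestSingleSporeCalibration:
    def test_constant_areas(self):
        parts = [particle(5000.0, label=i) for i in range(100)]
        assert sc.estimate_single_spore_area(parts, sc.GateSpec()) == pytest.approx(5000.0)

    def test_median_of_balanced_mixture(self):
        parts = [particle(4000.0)] * 50 + [particle(5000.0)] * 50
        assert sc.estimate_single_spore_area(parts, sc.GateSpec()) == pytest.approx(4500.0)

    def test_sampled_singles_within_3pct(self):
        rng = np.random.default_rng(77)
        areas = np.abs(rng.normal(5000.0, 500.0, size=200))
        parts = [particle(a, label=i) for i, a in enumerate(areas, 1)]
        est = sc.estimate_single_spore_area(parts, sc.GateSpec())
        assert est == pytest.approx(5000.0, rel=0.03)

    def test_too_few_particles_raises(self):
        with pytest.raises(CalibrationError, match="3"):
            sc.estimate_single_spore_area([particle(5000.0)] * 3, sc.GateSpec())


class TestSettlementEfficiency:
    @pytest.mark.parametrize(
        "settled,initial,expected", [(0.0, 1000.0, 0.0), (260.1, 1000.0, 0.2601), (1000.0, 1000.0, 1.0)]
    )
    def test_ratio(self, settled, initial, expected):
        assert sc.settlement_efficiency(settled, initial) == pytest.approx(expected)

    def test_clips_above_one_with_warning(self):
        with pytest.warns(UserWarning, match="exceeds 1"):
            assert sc.settlement_efficiency(1200.0, 1000.0) == 1.0

    def test_non_positive_initial(self):
        with pytest.raises(ValueError):
            sc.settlement_efficiency(5.0, 0.0)

    def test_dish_scaling(self):
        # mean field count scaled by substrate/field area ratio
        assert sc.dish_settled_count(10.0, 100.0, 1000.0) == pytest.approx(100.0)
        with pytest.raises(ValueError):
            sc.dish_settled_count(10.0, 0.0, 1000.0)


class TestSummarizeFields:
    def test_constant_counts(self):
        s = sc.summarize_fields([10.0, 10.0, 10.0])
        assert (s.mean_count, s.sd_count, s.relative_error_pct) == (10.0, 0.0, 0.0)

    def test_two_point_sd(self):
        s = sc.summarize_fields([8.0, 12.0])
        assert s.sd_count == pytest.approx(2 * math.sqrt(2))
        assert s.relative_error_pct == pytest.approx(100 * s.sd_count / (10 * math.sqrt(2)))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            sc.summarize_fields([])

    def test_poisson_fields_relative_error_below_3pct(self):
        # averaging 18 fields at ~500 spores each: relative SEM stays under 3%
        rng = np.random.default_rng(123)
        counts = rng.poisson(500.0, size=18).astype(float)
        assert sc.summarize_fields(counts).relative_error_pct <= 3.0
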