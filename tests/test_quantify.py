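import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mpquant import (
    FilterSettings,
    ParticleRecord,
    ParticleTable,
    ScaleCalibration,
    apply_filters,
    exclusion_percentage,
    measure_particles,
    qc_image,
    summarize_image,
)
from mpquant.quantify import chain_perimeter


def _record(label, area_px=10, area_um2=None, circ=0.8):
    return ParticleRecord(
        label=label, area_px=area_px,
        area_um2=float(area_px * 4.0) if area_um2 is None else area_um2,
        perimeter_um=10.0, circularity=circ, centroid=(1.0, 1.0),
    )


class TestChainPerimeter:
    def test_single_pixel_zero(self):
        m = np.zeros((3, 3), bool)
        m[1, 1] = True
        assert chain_perimeter(m) == 0.0

    def test_horizontal_line(self):
        m = np.zeros((3, 22), bool)
        m[1, 1:21] = True
        assert chain_perimeter(m) == pytest.approx(38.0)

    def test_diagonal_steps_weighted_sqrt2(self):
        m = np.eye(5, dtype=bool)
        assert chain_perimeter(m) == pytest.approx(8 * math.sqrt(2))

    def test_square_block(self):
        m = np.zeros((8, 8), bool)
        m[2:6, 2:6] = True  # 4x4 block: 12 boundary steps
        assert chain_perimeter(m) == pytest.approx(12.0)


class TestMeasureParticles:
    def test_disc_area_and_circularity(self):
        rr, cc = np.mgrid[0:30, 0:30]
        labels = (((rr - 15.0) ** 2 + (cc - 15.0) ** 2) <= 10.5**2).astype(int)
        table = measure_particles(labels, ScaleCalibration(1.0), "d")
        assert len(table) == 1
        rec = table.records[0]
        assert rec.area_um2 == pytest.approx(math.pi * 10.5**2, rel=0.05)
        assert rec.circularity >= 0.9
        assert rec.centroid == pytest.approx((15.0, 15.0), abs=0.1)

    def test_line_particle_low_circularity(self):
        labels = np.zeros((5, 30), dtype=int)
        labels[2, 5:25] = 1
        rec = measure_particles(labels, ScaleCalibration(1.0), "l").records[0]
        assert rec.circularity < 0.5

    def test_empty_mask_empty_table(self):
        table = measure_particles(np.zeros((10, 10), int), ScaleCalibration(1.0), "e")
        assert len(table) == 0

    def test_uncalibrated_measures_px_only(self):
        labels = np.zeros((6, 6), int)
        labels[1:4, 1:4] = 1
        rec = measure_particles(labels, None, "u").records[0]
        assert rec.area_px == 9
        assert math.isnan(rec.area_um2) and math.isnan(rec.perimeter_um)

    def test_border_particles_retained_by_default(self):
        labels = np.zeros((10, 10), int)
        labels[0:3, 0:3] = 1
        labels[5:8, 5:8] = 2
        assert len(measure_particles(labels, None, "b")) == 2
        assert len(measure_particles(labels, None, "b", exclude_border=True)) == 1


class TestApplyFilters:
    def test_below_min_px(self):
        table = ParticleTable("x", [_record(1, area_px=4)])
        out = apply_filters(table, FilterSettings())
        assert out.records[0].exclusion_reason == "below_min_px"

    def test_exactly_min_px_retained(self):
        out = apply_filters(ParticleTable("x", [_record(1, area_px=5)]))
        assert not out.records[0].excluded

    def test_above_max_area(self):
        table = ParticleTable("x", [_record(1, area_px=100, area_um2=25_000.0)])
        out = apply_filters(table, FilterSettings())
        assert out.records[0].exclusion_reason == "above_max_area"

    def test_exactly_max_area_retained(self):
        table = ParticleTable("x", [_record(1, area_px=100, area_um2=20_000.0)])
        out = apply_filters(table, FilterSettings())
        assert not out.records[0].excluded

    def test_circularity_window(self):
        table = ParticleTable("x", [_record(1, circ=0.2), _record(2, circ=0.9)])
        out = apply_filters(table, FilterSettings(circularity_range=(0.5, 1.0)))
        assert out.records[0].exclusion_reason == "outside_circularity"
        assert not out.records[1].excluded

    def test_uncalibrated_skips_max_area_with_warning(self):
        table = ParticleTable("x", [_record(1, area_px=10**6, area_um2=float("nan"))])
        with pytest.warns(UserWarning, match="uncalibrated"):
            out = apply_filters(table, FilterSettings())
        assert not out.records[0].excluded

    def test_records_never_deleted(self):
        table = ParticleTable("x", [_record(i, area_px=i) for i in range(1, 10)])
        out = apply_filters(table, FilterSettings())
        assert len(out) == len(table)

    @settings(derandomize=True, max_examples=30)
    @given(min_a=st.integers(1, 20), min_b=st.integers(1, 20),
           areas=st.lists(st.integers(1, 40), min_size=1, max_size=30))
    def test_min_size_monotonicity(self, min_a, min_b, areas):
        """A stricter minimum size never retains more particles."""
        table = ParticleTable("x", [_record(i + 1, area_px=a)
                                    for i, a in enumerate(areas)])
        lo, hi = sorted((min_a, min_b))
        n_lo = apply_filters(table, FilterSettings(min_size_px=lo)).retained_count
        n_hi = apply_filters(table, FilterSettings(min_size_px=hi)).retained_count
        assert n_hi <= n_lo

    def test_conservation(self):
        table = ParticleTable("x", [_record(i + 1, area_px=a, circ=c)
                                    for i, (a, c) in enumerate(
                                        [(2, 0.9), (50, 0.1), (8, 0.95)])])
        out = apply_filters(table, FilterSettings(circularity_range=(0.5, 1.0)))
        s = summarize_image(out)
        excluded = s.n_below_min_px + s.n_above_max_area + s.n_outside_circ
        assert s.retained_count + excluded == s.n_total == len(table)


class TestQC:
    def test_saturated_mask_flagged(self):
        mask = np.zeros((10, 10), bool)
        mask[:5] = True  # 50% foreground
        qc = qc_image(mask, FilterSettings(saturation_cutoff=0.30))
        assert not qc.processable and "saturated" in qc.flags

    def test_sparse_mask_processable(self):
        mask = np.zeros((10, 10), bool)
        mask[0, 0] = True
        assert qc_image(mask).processable

    def test_empty_mask(self):
        qc = qc_image(np.zeros((10, 10), bool))
        assert qc.processable and qc.foreground_fraction == 0.0


class TestSummaries:
    def test_totals(self):
        recs = [_record(i + 1, area_px=25, area_um2=a)
                for i, a in enumerate([100.0, 200.0, 300.0])]
        s = summarize_image(ParticleTable("x", recs))
        assert s.retained_count == 3
        assert s.total_area_um2 == pytest.approx(600.0)

    def test_all_excluded(self):
        table = apply_filters(ParticleTable("x", [_record(1, area_px=1)]))
        s = summarize_image(table)
        assert s.retained_count == 0 and s.total_area_um2 == 0.0

    def test_large_particle_exclusion_rate_rounds_to_printed_figure(self):
        """8 of 2557 particles above the 20 000 um^2 cutoff -> ~0.3% excluded."""
        recs = [_record(i + 1, area_px=100,
                        area_um2=25_000.0 if i < 8 else 400.0)
                for i in range(2557)]
        table = apply_filters(ParticleTable("big", recs), FilterSettings())
        s = summarize_image(table)
        assert s.n_above_max_area == 8
        assert round(exclusion_percentage(s, "above_max_area"), 1) == 0.3
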