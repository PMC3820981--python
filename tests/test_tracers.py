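"""Tracer detection accounting and thermal applicability flags."""

import math

import pytest

from coretrace.records import (
    AssessmentTable,
    CoreSampleRecord,
    CoringSystem,
    TracerResult,
    ValidationError,
)
from coretrace.tracers import (
    CorePart,
    ThermalProfile,
    Tracer,
    applicability_by_depth,
    detection_rate,
    temperature_at_depth,
    threshold_exceedance,
    tracer_applicability,
)


def _record(section, depth, system=CoringSystem.HPCS, **tracers):
    defaults = dict(
        ms_interior=TracerResult.not_measured(),
        ms_exterior=TracerResult.not_measured(),
        pft_interior=TracerResult.not_measured(),
        pft_exterior=TracerResult.not_measured(),
    )
    defaults.update(tracers)
    return CoreSampleRecord(
        hole="X1A", section=section, coring_system=system, depth_mbsf=depth,
        lithology="clay", **defaults,
    )


class TestDetectionRate:
    def test_escs_epcs_interior_pft_matches_study_tally(self, expedition_table):
        summary = detection_rate(
            expedition_table, Tracer.PFT, CorePart.INTERIOR,
            where=lambda r: r.coring_system in (CoringSystem.ESCS, CoringSystem.EPCS),
        )[0]
        assert (summary.n_detected, summary.n_measured) == (7, 9)
        assert summary.rate_pct_rounded == 78

    def test_unmeasured_rows_never_enter_the_denominator(self):
        table = AssessmentTable([
            _record("1H-1", 0.0, pft_interior=TracerResult.detected(1e-5)),
            _record("1H-2", 1.0, pft_interior=TracerResult.not_detected()),
            _record("1H-3", 2.0),  # not measured
        ])
        s = detection_rate(table, Tracer.PFT, CorePart.INTERIOR)[0]
        assert (s.n_detected, s.n_measured) == (1, 2)

    def test_all_not_detected_rate_zero(self):
        table = AssessmentTable(
            [_record(f"1H-{i}", i, ms_interior=TracerResult.not_detected())
             for i in range(1, 4)]
        )
        s = detection_rate(table, Tracer.MICROSPHERE, CorePart.INTERIOR)[0]
        assert s.rate == 0.0

    def test_all_unmeasured_is_undefined_not_zero(self):
        table = AssessmentTable([_record("1H-1", 0.0)])
        s = detection_rate(table, Tracer.MICROSPHERE, CorePart.INTERIOR)[0]
        assert not s.defined
        assert s.rate is None

    def test_additive_over_disjoint_groups(self, expedition_table):
        pooled = detection_rate(expedition_table, Tracer.PFT, CorePart.INTERIOR)[0]
        by_system = detection_rate(
            expedition_table, Tracer.PFT, CorePart.INTERIOR, "coring_system"
        )
        assert sum(s.n_measured for s in by_system) == pooled.n_measured
        assert sum(s.n_detected for s in by_system) == pooled.n_detected
        by_site = detection_rate(expedition_table, Tracer.PFT, CorePart.INTERIOR, "site")
        assert sum(s.n_detected for s in by_site) == pooled.n_detected


class TestThresholdExceedance:
    def test_fixture_high_penetration_samples(self, expedition_table):
        assert threshold_exceedance(
            expedition_table, Tracer.MICROSPHERE, CorePart.INTERIOR, 1e4
        ) == ["C0013D-1H-1", "C0014D-2H-1", "C0015C-1H-1", "C0017C-2H-1"]

    def test_infinite_threshold_empty(self, expedition_table):
        assert threshold_exceedance(
            expedition_table, Tracer.MICROSPHERE, CorePart.INTERIOR, math.inf
        ) == []

    def test_zero_threshold_returns_strictly_positive_detections(self):
        table = AssessmentTable([
            _record("1H-1", 0.0, ms_interior=TracerResult.detected(0.0)),
            _record("1H-2", 1.0, ms_interior=TracerResult.detected(5.0)),
            _record("1H-3", 2.0, ms_interior=TracerResult.not_detected()),
        ])
        assert threshold_exceedance(
            table, Tracer.MICROSPHERE, CorePart.INTERIOR, 0.0
        ) == ["X1A-1H-2"]

    def test_antitone_in_threshold(self, expedition_table):
        lo = threshold_exceedance(expedition_table, Tracer.MICROSPHERE,
                                  CorePart.INTERIOR, 1e2)
        hi = threshold_exceedance(expedition_table, Tracer.MICROSPHERE,
                                  CorePart.INTERIOR, 1e4)
        assert set(hi) <= set(lo)

    def test_negative_threshold_rejected(self, expedition_table):
        with pytest.raises(ValidationError):
            threshold_exceedance(expedition_table, Tracer.PFT, CorePart.INTERIOR, -1)


class TestThermalModel:
    def test_temperature_is_linear(self):
        profile = ThermalProfile(gradient=3.0, surface_temp=5.0)
        assert temperature_at_depth(profile, 0.0) == 5.0
        assert temperature_at_depth(profile, 30.0) == pytest.approx(95.0)
        assert temperature_at_depth(
            ThermalProfile(gradient=4.0, surface_temp=5.0), 22.5
        ) == pytest.approx(95.0)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValidationError):
            temperature_at_depth(ThermalProfile(gradient=3.0), -1.0)

    def test_cold_sample_all_flags_clear(self):
        f = tracer_applicability(25.0)
        assert f.microspheres_reliable and f.liner_intact and not f.pft_caution

    def test_hot_sample_all_flags_fire(self):
        f = tracer_applicability(100.0)
        assert not f.microspheres_reliable
        assert not f.liner_intact
        assert f.pft_caution

    @pytest.mark.parametrize(
        "temp,ms,liner,pft",
        [
            (95.0, False, False, True),   # glass transition boundary
            (94.999, True, False, True),
            (70.0, True, False, False),   # liner melt onset boundary
            (69.999, True, True, False),
            (76.0, True, False, True),    # PFT boiling point boundary
            (75.999, True, False, False),
        ],
    )
    def test_boundary_temperatures(self, temp, ms, liner, pft):
        f = tracer_applicability(temp)
        assert (f.microspheres_reliable, f.liner_intact, f.pft_caution) == (
            ms, liner, pft
        )

    def test_applicability_by_depth_monotone(self):
        table = AssessmentTable(
            [_record(f"1H-{i}", float(d)) for i, d in enumerate([0, 10, 26, 40, 80])]
        )
        profile = ThermalProfile(gradient=3.5, surface_temp=5.0)
        flags = applicability_by_depth(profile, table)
        assert flags[1].microspheres_reliable        # 40 degC
        assert not flags[3].microspheres_reliable    # 145 degC
        # once unreliable, deeper never recovers (positive gradient)
        reliable = [f.microspheres_reliable for f in flags]
        assert reliable == sorted(reliable, reverse=True)

    def test_zero_gradient_shares_surface_flags(self):
        table = AssessmentTable([_record("1H-1", 0.0), _record("1H-2", 500.0)])
        flags = applicability_by_depth(ThermalProfile(gradient=0.0, surface_temp=4.0),
                                       table)
        assert flags[0] == flags[1]

    def test_empty_table_empty_flags(self):
        assert applicability_by_depth(ThermalProfile(gradient=3.0),
                                      AssessmentTable([])) == []
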