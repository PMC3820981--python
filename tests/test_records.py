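"""Table parsing conventions, fixture integrity, and round-trip identity."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coretrace.records import (
    AssessmentTable,
    COLUMNS,
    CoreSampleRecord,
    CoringSystem,
    TableParseError,
    TracerResult,
    TracerStatus,
    ValidationError,
    read_table,
    write_table,
)

HEADER = ",".join(COLUMNS)


def _write(tmp_path, text):
    path = tmp_path / "table.csv"
    path.write_text(text)
    return path


class TestParsingConventions:
    def test_sentinels_map_to_statuses(self, tmp_path):
        path = _write(
            tmp_path, HEADER + '\nX,1H-1,HPCS,1.0,clay,N.D.,,N.D.,,,\n'
        )
        table = read_table(path)
        rec = table.records[0]
        assert rec.ms_interior.status is TracerStatus.NOT_DETECTED
        assert rec.ms_exterior.status is TracerStatus.NOT_MEASURED
        assert rec.pft_interior.status is TracerStatus.NOT_DETECTED
        assert rec.pft_exterior.status is TracerStatus.NOT_MEASURED

    def test_scientific_notation_and_typeset_alias(self, tmp_path):
        path = _write(
            tmp_path,
            HEADER + '\nX,1H-1,HPCS,1.0,clay,1.7e4,5.8×10^2,0.0×10^0,3.3e-3,+,52\n',
        )
        rec = read_table(path).records[0]
        assert rec.ms_interior.value == pytest.approx(1.7e4)
        assert rec.ms_exterior.value == pytest.approx(580.0)
        # an explicit zero is a detection, not N.D.
        assert rec.pft_interior.status is TracerStatus.DETECTED
        assert rec.pft_interior.value == 0.0
        assert rec.molecular_contamination_pct == 52.0

    def test_header_only_file_yields_empty_table(self, tmp_path):
        table = read_table(_write(tmp_path, HEADER + "\n"))
        assert len(table) == 0

    def test_malformed_numeric_cell_names_row_and_column(self, tmp_path):
        path = _write(tmp_path, HEADER + '\nX,1H-1,HPCS,1.0,clay,abc,,,,,\n')
        with pytest.raises(TableParseError, match=r"row 2.*ms_interior"):
            read_table(path)

    def test_unknown_coring_system_is_a_validation_error(self, tmp_path):
        path = _write(tmp_path, HEADER + '\nX,1H-1,XXXX,1.0,clay,,,,,,\n')
        with pytest.raises(ValidationError, match="coring-system"):
            read_table(path)

    def test_wrong_header_rejected(self, tmp_path):
        with pytest.raises(TableParseError, match="header"):
            read_table(_write(tmp_path, "a,b,c\n1,2,3\n"))


class TestDomainInvariants:
    def test_detected_requires_value_and_vice_versa(self):
        with pytest.raises(ValidationError):
            TracerResult(TracerStatus.DETECTED)
        with pytest.raises(ValidationError):
            TracerResult(TracerStatus.NOT_DETECTED, 1.0)
        assert TracerResult.detected(0.0).is_detected

    def test_contamination_level_requires_amplification(self):
        with pytest.raises(ValidationError, match="pcr_amplified"):
            CoreSampleRecord(
                hole="X", section="1H-1", coring_system=CoringSystem.HPCS,
                depth_mbsf=1.0, lithology="clay",
                ms_interior=TracerResult.not_measured(),
                ms_exterior=TracerResult.not_measured(),
                pft_interior=TracerResult.not_measured(),
                pft_exterior=TracerResult.not_measured(),
                pcr_amplified=None, molecular_contamination_pct=10.0,
            )

    def test_duplicate_subsample_keys_rejected(self):
        rec = _record("X", "1H-1", 1.0)
        with pytest.raises(ValidationError, match="duplicate"):
            AssessmentTable([rec, rec])

    def test_same_section_different_depths_are_distinct_subsamples(self):
        table = AssessmentTable([_record("X", "1H-1", 0.3), _record("X", "1H-1", 1.1)])
        assert len(table) == 2

    def test_site_drops_trailing_hole_letter(self):
        assert _record("C0014G", "1H-1", 0.3).site == "C0014"


class TestFixtureIntegrity:
    def test_row_count_and_bounds(self, expedition_table):
        assert len(expedition_table) == 99
        for rec in expedition_table:
            assert rec.depth_mbsf >= 0
            pct = rec.molecular_contamination_pct
            if pct is not None:
                assert 0 <= pct <= 100

    def test_epcs_rows(self, expedition_table):
        epcs = [r for r in expedition_table if r.coring_system is CoringSystem.EPCS]
        assert sum(r.site == "C0013" for r in epcs) == 2
        assert sum(r.hole == "C0014G" for r in epcs) == 4

    def test_known_landmark_rows(self, expedition_table):
        by_id = {}
        for rec in expedition_table:
            by_id.setdefault(rec.sample_id, rec)
        hot = by_id["C0013D-1H-1"]
        assert hot.ms_interior.value == pytest.approx(1.7e4)
        assert hot.molecular_contamination_pct == 52.0
        zero = by_id["C0017C-1H-7"]
        assert zero.ms_exterior.status is TracerStatus.DETECTED
        assert zero.ms_exterior.value == 0.0


def _record(hole, section, depth, **kwargs):
    defaults = dict(
        hole=hole, section=section, coring_system=CoringSystem.HPCS,
        depth_mbsf=depth, lithology="clay",
        ms_interior=TracerResult.not_measured(),
        ms_exterior=TracerResult.not_measured(),
        pft_interior=TracerResult.not_measured(),
        pft_exterior=TracerResult.not_measured(),
    )
    defaults.update(kwargs)
    return CoreSampleRecord(**defaults)


# --------------------------------------------------------------------------
# property-based round trip
# --------------------------------------------------------------------------

tracer_results = st.one_of(
    st.just(TracerResult.not_measured()),
    st.just(TracerResult.not_detected()),
    st.floats(min_value=0, max_value=1e6, allow_nan=False).map(TracerResult.detected),
)

_molecular = st.one_of(
    st.just((None, None)),
    st.just((True, None)),
    st.just((False, None)),
    st.floats(min_value=0, max_value=100, allow_nan=False).map(lambda p: (True, p)),
)


@st.composite
def records_strategy(draw, index):
    pcr, pct = draw(_molecular)
    return CoreSampleRecord(
        hole=draw(st.text(alphabet="ABC019", min_size=2, max_size=6)),
        section=f"{index + 1}H-1",
        coring_system=draw(st.sampled_from(list(CoringSystem))),
        depth_mbsf=draw(st.floats(min_value=0, max_value=500, allow_nan=False)),
        lithology=draw(st.text(alphabet="abc ,/", max_size=20)).strip(),
        ms_interior=draw(tracer_results),
        ms_exterior=draw(tracer_results),
        pft_interior=draw(tracer_results),
        pft_exterior=draw(tracer_results),
        pcr_amplified=pcr,
        molecular_contamination_pct=pct,
    )


@st.composite
def tables_strategy(draw):
    n = draw(st.integers(min_value=0, max_value=8))
    return AssessmentTable([draw(records_strategy(i)) for i in range(n)])


@settings(derandomize=True, max_examples=60, deadline=None)
@given(tables_strategy())
def test_round_trip_identity(tmp_path_factory, table):
    """read_table(write_table(t)) reproduces every field of every record."""
    path = tmp_path_factory.mktemp("rt") / "t.csv"
    write_table(table, path)
    assert read_table(path).records == table.records


def test_round_trip_of_packaged_fixture(tmp_path, expedition_table):
    path = tmp_path / "fixture.csv"
    write_table(expedition_table, path)
    assert read_table(path).records == expedition_table.records


def test_detected_zero_round_trips_as_zero_not_nd(tmp_path):
    table = AssessmentTable(
        [_record("X", "1H-1", 1.0, ms_exterior=TracerResult.detected(0.0))]
    )
    path = write_table(table, tmp_path / "z.csv")
    text = path.read_text()
    assert "0.0" in text
    rec = read_table(path).records[0]
    assert rec.ms_exterior.status is TracerStatus.DETECTED
    assert rec.ms_exterior.value == 0.0
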