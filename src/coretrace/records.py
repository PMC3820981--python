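"""Domain types for the whole-round-core contamination-test table.

One row of the table describes a single whole-round core (WRC) subsample:
where it was cored (hole, section, depth in metres below seafloor), how
(hydraulic piston / extended punch / extended shoe coring system), what it is
made of, and the four physical tracer channels — fluorescent-microsphere
counts (beads per ml sediment) and perfluorocarbon tracer (PFT) mass
(g per ml sediment), each measured on the core interior and exterior —
plus, where a 16S rRNA gene library was obtained, the molecular
contamination level (% of clones matching drilling-fluid sequences).

Detection semantics follow the printed conventions of the source table:
an ``N.D.`` cell means the tracer was assayed and not detected, an empty
cell means it was not assayed, and any numeral — including an explicit
zero — means the assay returned that value. Detection status is therefore
carried by the recorded marker, never inferred from the magnitude.
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Iterator, Optional

__all__ = [
    "TracerStatus",
    "TracerResult",
    "CoringSystem",
    "CoreSampleRecord",
    "AssessmentTable",
    "TableParseError",
    "ValidationError",
    "read_table",
    "write_table",
    "load_expedition_table",
    "COLUMNS",
]

COLUMNS = [
    "hole",
    "section",
    "coring_system",
    "depth_mbsf",
    "lithology",
    "ms_interior",
    "ms_exterior",
    "pft_interior",
    "pft_exterior",
    "pcr_amplified",
    "contamination_pct",
]

NOT_DETECTED_SENTINEL = "N.D."


class ValidationError(ValueError):
    """A record or table violates a domain invariant."""


class TableParseError(ValueError):
    """A CSV cell could not be interpreted; names the offending row/column."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        self.row = row
        self.column = column
        where = ""
        if row is not None:
            where = f" (row {row}" + (f", column {column!r})" if column else ")")
        super().__init__(message + where)


class TracerStatus(enum.Enum):
    NOT_MEASURED = "NOT_MEASURED"
    NOT_DETECTED = "NOT_DETECTED"
    DETECTED = "DETECTED"


@dataclass(frozen=True)
class TracerResult:
    """A single tracer measurement with explicit assay semantics.

    ``value`` is present iff ``status`` is DETECTED; a recorded numeric zero
    is DETECTED with value 0.0, not NOT_DETECTED.
    """

    status: TracerStatus
    value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.status is TracerStatus.DETECTED:
            if self.value is None:
                raise ValidationError("DETECTED tracer requires a value")
            if not (self.value >= 0):
                raise ValidationError(f"tracer value must be >= 0, got {self.value}")
        elif self.value is not None:
            raise ValidationError(f"{self.status.value} tracer must not carry a value")

    @classmethod
    def not_measured(cls) -> "TracerResult":
        return cls(TracerStatus.NOT_MEASURED)

    @classmethod
    def not_detected(cls) -> "TracerResult":
        return cls(TracerStatus.NOT_DETECTED)

    @classmethod
    def detected(cls, value: float) -> "TracerResult":
        return cls(TracerStatus.DETECTED, float(value))

    @property
    def measured(self) -> bool:
        return self.status is not TracerStatus.NOT_MEASURED

    @property
    def is_detected(self) -> bool:
        return self.status is TracerStatus.DETECTED


class CoringSystem(enum.Enum):
    HPCS = "HPCS"  # hydraulic piston: least disturbed cores
    EPCS = "EPCS"  # extended punch
    ESCS = "ESCS"  # extended shoe


@dataclass(frozen=True)
class CoreSampleRecord:
    hole: str
    section: str
    coring_system: CoringSystem
    depth_mbsf: float
    lithology: str
    ms_interior: TracerResult
    ms_exterior: TracerResult
    pft_interior: TracerResult
    pft_exterior: TracerResult
    pcr_amplified: Optional[bool] = None
    molecular_contamination_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.hole:
            raise ValidationError("hole must be non-empty")
        if not self.section:
            raise ValidationError("section must be non-empty")
        if not (self.depth_mbsf >= 0):
            raise ValidationError(f"depth_mbsf must be >= 0, got {self.depth_mbsf}")
        pct = self.molecular_contamination_pct
        if pct is not None:
            if not (0 <= pct <= 100):
                raise ValidationError(f"contamination level {pct} outside [0, 100]")
            if self.pcr_amplified is not True:
                raise ValidationError(
                    "molecular contamination level requires pcr_amplified = True"
                )

    @property
    def site(self) -> str:
        """IODP site: the hole string without its trailing hole letter."""
        return self.hole[:-1] if len(self.hole) > 1 else self.hole

    @property
    def sample_id(self) -> str:
        return f"{self.hole}-{self.section}"

    def tracer(self, channel: str) -> TracerResult:
        """Tracer channel by name: ms/pft x interior/exterior."""
        if channel not in ("ms_interior", "ms_exterior", "pft_interior", "pft_exterior"):
            raise KeyError(channel)
        return getattr(self, channel)

    def with_contamination(self, pct: Optional[float]) -> "CoreSampleRecord":
        amplified = True if pct is not None else self.pcr_amplified
        return replace(self, molecular_contamination_pct=pct, pcr_amplified=amplified)


@dataclass
class AssessmentTable:
    records: list[CoreSampleRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, float]] = set()
        for rec in self.records:
            key = (rec.hole, rec.section, rec.depth_mbsf)
            if key in seen:
                raise ValidationError(f"duplicate record {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CoreSampleRecord]:
        return iter(self.records)

    def filter(self, predicate: Callable[[CoreSampleRecord], bool]) -> "AssessmentTable":
        return AssessmentTable(
            [r for r in self.records if predicate(r)],
            provenance=f"{self.provenance} (filtered)",
        )

    @property
    def sites(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.site not in out:
                out.append(rec.site)
        return out


_SCI_ALIAS = re.compile(r"\s*[×x]\s*10\^?(-?\d+)\^?\s*$")


def _normalise_number(cell: str) -> str:
    """Accept the typeset '5.8×10^2' alias alongside plain '5.8e2'."""
    s = cell.strip().replace("−", "-")
    return _SCI_ALIAS.sub(lambda m: f"e{m.group(1)}", s)


def _parse_tracer(cell: str, row: int, column: str) -> TracerResult:
    s = cell.strip()
    if s == "":
        return TracerResult.not_measured()
    if s == NOT_DETECTED_SENTINEL:
        return TracerResult.not_detected()
    try:
        value = float(_normalise_number(s))
    except ValueError:
        raise TableParseError(f"malformed numeric cell {cell!r}", row, column) from None
    if value < 0:
        raise TableParseError(f"negative tracer value {cell!r}", row, column)
    return TracerResult.detected(value)


def _parse_pcr(cell: str, row: int) -> Optional[bool]:
    s = cell.strip()
    if s == "":
        return None
    if s in ("+", "true", "True", "1"):
        return True
    if s in ("-", "false", "False", "0"):
        return False
    raise TableParseError(f"malformed pcr_amplified cell {cell!r}", row, "pcr_amplified")


def read_table(path: str | Path, dialect: dict | None = None) -> AssessmentTable:
    """Read a contamination-test table from CSV.

    ``dialect`` is passed through to :func:`csv.reader` (e.g. a different
    delimiter); the default is RFC-4180 comma-separated UTF-8. Sentinels:
    ``N.D.`` means not detected, an empty cell means not measured, and any
    numeral (plain or '×10^' scientific notation) is a detected value.
    """
    path = Path(path)
    records: list[CoreSampleRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, **(dialect or {}))
        try:
            header = next(reader)
        except StopIteration:
            raise TableParseError("empty file: missing header row") from None
        if [h.strip() for h in header] != COLUMNS:
            raise TableParseError(
                f"unexpected header {header!r}; expected {COLUMNS!r}"
            )
        for row_no, row in enumerate(reader, start=2):
            if not row or all(cell.strip() == "" for cell in row):
                continue
            if len(row) != len(COLUMNS):
                raise TableParseError(
                    f"expected {len(COLUMNS)} cells, got {len(row)}", row_no
                )
            cells = dict(zip(COLUMNS, row))
            try:
                system = CoringSystem(cells["coring_system"].strip())
            except ValueError:
                raise ValidationError(
                    f"unknown coring-system code {cells['coring_system']!r} "
                    f"(row {row_no})"
                ) from None
            try:
                depth = float(_normalise_number(cells["depth_mbsf"]))
            except ValueError:
                raise TableParseError(
                    f"malformed numeric cell {cells['depth_mbsf']!r}",
                    row_no,
                    "depth_mbsf",
                ) from None
            pct_cell = cells["contamination_pct"].strip().rstrip("%")
            if pct_cell == "":
                pct: Optional[float] = None
            else:
                try:
                    pct = float(_normalise_number(pct_cell))
                except ValueError:
                    raise TableParseError(
                        f"malformed numeric cell {cells['contamination_pct']!r}",
                        row_no,
                        "contamination_pct",
                    ) from None
            records.append(
                CoreSampleRecord(
                    hole=cells["hole"].strip(),
                    section=cells["section"].strip(),
                    coring_system=system,
                    depth_mbsf=depth,
                    lithology=cells["lithology"].strip(),
                    ms_interior=_parse_tracer(cells["ms_interior"], row_no, "ms_interior"),
                    ms_exterior=_parse_tracer(cells["ms_exterior"], row_no, "ms_exterior"),
                    pft_interior=_parse_tracer(cells["pft_interior"], row_no, "pft_interior"),
                    pft_exterior=_parse_tracer(cells["pft_exterior"], row_no, "pft_exterior"),
                    pcr_amplified=_parse_pcr(cells["pcr_amplified"], row_no),
                    molecular_contamination_pct=pct,
                )
            )
    return AssessmentTable(records, provenance=str(path))


def _format_tracer(result: TracerResult) -> str:
    if result.status is TracerStatus.NOT_MEASURED:
        return ""
    if result.status is TracerStatus.NOT_DETECTED:
        return NOT_DETECTED_SENTINEL
    return repr(result.value)


def _format_pcr(value: Optional[bool]) -> str:
    if value is None:
        return ""
    return "+" if value else "-"


def write_table(table: AssessmentTable, path: str | Path) -> Path:
    """Write a table back to CSV; round-trips exactly through read_table."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COLUMNS)
        for rec in table.records:
            pct = rec.molecular_contamination_pct
            writer.writerow(
                [
                    rec.hole,
                    rec.section,
                    rec.coring_system.value,
                    repr(rec.depth_mbsf),
                    rec.lithology,
                    _format_tracer(rec.ms_interior),
                    _format_tracer(rec.ms_exterior),
                    _format_tracer(rec.pft_interior),
                    _format_tracer(rec.pft_exterior),
                    _format_pcr(rec.pcr_amplified),
                    "" if pct is None else repr(pct),
                ]
            )
    return path


def load_expedition_table() -> AssessmentTable:
    """The packaged IODP Expedition 331 Table-1 transcription (99 WRC rows)."""
    source = resources.files("coretrace.data").joinpath("expedition331_table1.csv")
    with resources.as_file(source) as path:
        table = read_table(path)
    table.provenance = "packaged expedition331_table1.csv"
    return table
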