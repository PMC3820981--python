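"""Quantitative tracer summaries and thermal applicability flags.

Two physical tracers monitor drilling-fluid infiltration: perfluorocarbon
tracer (PFT, perfluoromethylcyclohexane dosed at 1 ppm into the mud) and
0.5-um fluorescent polystyrene microspheres released at the core cutting
shoe. Both are assayed on the core interior and exterior. This module counts
detections per group (coring system, hole, site), lists samples whose tracer
load exceeds a threshold, and flags, from a linear geothermal model, where
each tracer stops being trustworthy:

* microspheres are unreliable at or above the polystyrene glass transition
  (~95 degC) because the beads thermally degrade;
* butyrate core liners melt at 70-80 degC, so liner integrity is flagged
  conservatively at 70 degC;
* PFT boils at 76 degC at atmospheric pressure; above that it is flagged
  caution-but-usable (cooling by mud injection and hydrostatic pressure keep
  it informative at depth).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Hashable, Optional

from .records import (
    AssessmentTable,
    CoreSampleRecord,
    TracerStatus,
    ValidationError,
)

__all__ = [
    "Tracer",
    "CorePart",
    "DetectionSummary",
    "ThermalProfile",
    "TracerApplicability",
    "MICROSPHERE_GLASS_TRANSITION_C",
    "LINER_MELT_ONSET_C",
    "PFT_BOILING_POINT_C",
    "detection_rate",
    "threshold_exceedance",
    "temperature_at_depth",
    "tracer_applicability",
    "applicability_by_depth",
]

MICROSPHERE_GLASS_TRANSITION_C = 95.0
LINER_MELT_ONSET_C = 70.0  # conservative end of the 70-80 degC melting range
PFT_BOILING_POINT_C = 76.0


class Tracer(enum.Enum):
    PFT = "pft"
    MICROSPHERE = "ms"


class CorePart(enum.Enum):
    INTERIOR = "interior"
    EXTERIOR = "exterior"


def _channel(tracer: Tracer, part: CorePart) -> str:
    return f"{tracer.value}_{part.value}"


@dataclass(frozen=True)
class DetectionSummary:
    """Detections over measured assays for one group of records.

    ``rate`` is None (undefined, not zero) when nothing in the group was
    measured.
    """

    group: Hashable
    n_measured: int
    n_detected: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_detected <= self.n_measured:
            raise ValidationError(
                f"invalid counts: {self.n_detected} detected of {self.n_measured}"
            )

    @property
    def defined(self) -> bool:
        return self.n_measured > 0

    @property
    def rate(self) -> Optional[float]:
        if not self.defined:
            return None
        return self.n_detected / self.n_measured

    @property
    def rate_pct_rounded(self) -> Optional[int]:
        return None if self.rate is None else int(round(100 * self.rate))


_GROUP_KEYS: dict[str, Callable[[CoreSampleRecord], Hashable]] = {
    "coring_system": lambda r: r.coring_system.value,
    "hole": lambda r: r.hole,
    "site": lambda r: r.site,
}


def detection_rate(
    table: AssessmentTable,
    tracer: Tracer,
    part: CorePart,
    group_by: str | Callable[[CoreSampleRecord], Hashable] | None = None,
    where: Callable[[CoreSampleRecord], bool] | None = None,
) -> list[DetectionSummary]:
    """Detection counts/rates for one tracer channel, optionally grouped.

    Only assayed records (status != NOT_MEASURED) enter the denominator;
    DETECTED records (any value, including an explicit zero) enter the
    numerator. ``group_by`` may be "coring_system", "hole", "site", or a
    callable; None pools everything into a single summary with group None.
    """
    if len(table) == 0:
        raise ValidationError("detection_rate requires a non-empty table")
    if group_by is None:
        key = lambda r: None  # noqa: E731
    elif callable(group_by):
        key = group_by
    else:
        try:
            key = _GROUP_KEYS[group_by]
        except KeyError:
            raise ValueError(
                f"unknown group key {group_by!r}; expected one of {sorted(_GROUP_KEYS)}"
            ) from None

    channel = _channel(tracer, part)
    counts: dict[Hashable, list[int]] = {}
    for rec in table:
        if where is not None and not where(rec):
            continue
        g = key(rec)
        measured, detected = counts.setdefault(g, [0, 0])
        result = rec.tracer(channel)
        if result.measured:
            counts[g][0] += 1
            if result.is_detected:
                counts[g][1] += 1
    return [
        DetectionSummary(g, m, d)
        for g, (m, d) in sorted(counts.items(), key=lambda kv: str(kv[0]))
    ]


def threshold_exceedance(
    table: AssessmentTable,
    tracer: Tracer,
    part: CorePart,
    threshold: float,
) -> list[str]:
    """Sample ids whose detected tracer value strictly exceeds the threshold.

    Returned in table order; non-detected and unmeasured channels never
    exceed anything.
    """
    if threshold < 0:
        raise ValidationError(f"threshold must be >= 0, got {threshold}")
    channel = _channel(tracer, part)
    out = []
    for rec in table:
        result = rec.tracer(channel)
        if result.status is TracerStatus.DETECTED and result.value > threshold:
            out.append(rec.sample_id)
    return out


@dataclass(frozen=True)
class ThermalProfile:
    """Linear geothermal model T(z) = surface_temp + gradient * z.

    The 4 degC default surface temperature is a deep-sea bottom-water figure
    chosen as this package's default, not a measured expedition value; the
    gradient (degC per metre) must be supplied from site data (3-4 degC/m at
    the hydrothermally active sites).
    """

    gradient: float
    surface_temp: float = 4.0

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.gradient) or not math.isfinite(self.surface_temp):
            raise ValidationError("thermal profile parameters must be finite")


def temperature_at_depth(profile: ThermalProfile, depth_mbsf: float) -> float:
    if depth_mbsf < 0:
        raise ValidationError(f"depth must be >= 0 mbsf, got {depth_mbsf}")
    return profile.surface_temp + profile.gradient * depth_mbsf


@dataclass(frozen=True)
class TracerApplicability:
    """Tracer reliability flags at one temperature (pure threshold functions).

    Boundary behaviour: at exactly 95 degC microspheres are already
    unreliable, at exactly 70 degC the liner is already compromised, and at
    exactly 76 degC PFT carries the gas-phase caution.
    """

    temperature: float
    microspheres_reliable: bool
    liner_intact: bool
    pft_caution: bool


def tracer_applicability(temperature: float) -> TracerApplicability:
    import math

    if not math.isfinite(temperature):
        raise ValidationError("temperature must be finite")
    return TracerApplicability(
        temperature=temperature,
        microspheres_reliable=temperature < MICROSPHERE_GLASS_TRANSITION_C,
        liner_intact=temperature < LINER_MELT_ONSET_C,
        pft_caution=temperature >= PFT_BOILING_POINT_C,
    )


def applicability_by_depth(
    profile: ThermalProfile, table: AssessmentTable
) -> list[TracerApplicability]:
    """Per-record applicability flags from the thermal model (table order)."""
    return [
        tracer_applicability(temperature_at_depth(profile, rec.depth_mbsf))
        for rec in table
    ]
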