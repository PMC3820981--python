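"""Per-sample contamination assessment integrating all three tracers.

Each whole-round-core record is placed into one of four tiers. The tier
boundaries use only the two landmarks the tracer data themselves motivate —
a molecular contamination level above 50% of clones, and an interior
microsphere load above 1e4 beads/ml sediment — plus the qualitative rule
that any interior tracer detection marks infiltration into the subsample
actually used for microbiology. The tiering itself is a convenience of this
package, not a community standard; see docs/methods.md.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .records import (
    AssessmentTable,
    CoreSampleRecord,
    ValidationError,
    write_table,
)
from .screen import ScreenResult
from .tracers import (
    CorePart,
    DetectionSummary,
    ThermalProfile,
    Tracer,
    applicability_by_depth,
    detection_rate,
    threshold_exceedance,
)

__all__ = [
    "MOLECULAR_HIGH_PCT",
    "MICROSPHERE_HIGH_BEADS_PER_ML",
    "ContaminationTierLevel",
    "ContaminationTier",
    "StudySummary",
    "classify_tier",
    "study_summary",
    "build_report",
]

MOLECULAR_HIGH_PCT = 50.0
MICROSPHERE_HIGH_BEADS_PER_ML = 1e4


class ContaminationTierLevel(enum.IntEnum):
    """Ordered contamination tiers (higher = worse)."""

    UNCONTAMINATED = 0
    PERIPHERY_ONLY = 1
    INTERIOR_LOW = 2
    INTERIOR_HIGH = 3


@dataclass(frozen=True)
class ContaminationTier:
    tier: ContaminationTierLevel
    reasons: tuple[str, ...]


def classify_tier(record: CoreSampleRecord) -> ContaminationTier:
    """Deterministic tier for one record; reasons name the rules that fired."""
    reasons: list[str] = []
    pct = record.molecular_contamination_pct

    if pct is not None and pct > MOLECULAR_HIGH_PCT:
        reasons.append(
            f"molecular contamination {pct:g}% > {MOLECULAR_HIGH_PCT:g}% of clones"
        )
    ms_in = record.ms_interior
    if ms_in.is_detected and ms_in.value > MICROSPHERE_HIGH_BEADS_PER_ML:
        reasons.append(
            f"interior microspheres {ms_in.value:g}/ml > "
            f"{MICROSPHERE_HIGH_BEADS_PER_ML:g}/ml"
        )
    if reasons:
        return ContaminationTier(ContaminationTierLevel.INTERIOR_HIGH, tuple(reasons))

    if ms_in.is_detected:
        reasons.append("interior microspheres detected")
    if record.pft_interior.is_detected:
        reasons.append("interior PFT detected")
    if pct is not None and pct > 0:
        reasons.append(f"molecular contamination {pct:g}% > 0")
    if reasons:
        return ContaminationTier(ContaminationTierLevel.INTERIOR_LOW, tuple(reasons))

    exterior = []
    if record.ms_exterior.is_detected:
        exterior.append("exterior microspheres detected")
    if record.pft_exterior.is_detected:
        exterior.append("exterior PFT detected")
    if exterior:
        return ContaminationTier(
            ContaminationTierLevel.PERIPHERY_ONLY,
            tuple(exterior + ["no interior tracer detection"]),
        )
    return ContaminationTier(ContaminationTierLevel.UNCONTAMINATED, ())


@dataclass(frozen=True)
class StudySummary:
    """Printed-tally counters, all recomputable from the table alone."""

    n_records: int
    ms_interior: DetectionSummary
    ms_interior_high_ids: tuple[str, ...]
    ms_exterior_by_site: dict[str, DetectionSummary]
    pft_interior_by_system: dict[str, DetectionSummary]
    molecular_high_ids: tuple[str, ...]
    n_molecular_measured: int
    n_molecular_positive: int
    tier_counts: dict[str, int]

    @property
    def n_ms_interior_detected(self) -> int:
        return self.ms_interior.n_detected

    @property
    def n_ms_interior_high(self) -> int:
        return len(self.ms_interior_high_ids)

    @property
    def n_molecular_high(self) -> int:
        return len(self.molecular_high_ids)

    def ms_exterior_not_detected(self, sites: Sequence[str]) -> DetectionSummary:
        """Pooled exterior-microsphere summary over the given sites."""
        measured = sum(
            self.ms_exterior_by_site[s].n_measured
            for s in sites
            if s in self.ms_exterior_by_site
        )
        detected = sum(
            self.ms_exterior_by_site[s].n_detected
            for s in sites
            if s in self.ms_exterior_by_site
        )
        return DetectionSummary(tuple(sites), measured, detected)

    def to_dict(self) -> dict:
        def ds(d: DetectionSummary) -> dict:
            return {
                "group": d.group,
                "n_measured": d.n_measured,
                "n_detected": d.n_detected,
                "rate": d.rate,
            }

        return {
            "n_records": self.n_records,
            "ms_interior": ds(self.ms_interior),
            "ms_interior_high_ids": list(self.ms_interior_high_ids),
            "ms_exterior_by_site": {k: ds(v) for k, v in self.ms_exterior_by_site.items()},
            "pft_interior_by_system": {
                k: ds(v) for k, v in self.pft_interior_by_system.items()
            },
            "molecular_high_ids": list(self.molecular_high_ids),
            "n_molecular_measured": self.n_molecular_measured,
            "n_molecular_positive": self.n_molecular_positive,
            "tier_counts": self.tier_counts,
        }


def study_summary(table: AssessmentTable) -> StudySummary:
    """All headline tallies of the contamination study, from the table alone."""
    if len(table) == 0:
        empty = DetectionSummary(None, 0, 0)
        return StudySummary(0, empty, (), {}, {}, (), 0, 0, {})

    ms_interior = detection_rate(table, Tracer.MICROSPHERE, CorePart.INTERIOR)[0]
    ms_high = tuple(
        threshold_exceedance(
            table, Tracer.MICROSPHERE, CorePart.INTERIOR, MICROSPHERE_HIGH_BEADS_PER_ML
        )
    )
    ms_ext_site = {
        s.group: s
        for s in detection_rate(table, Tracer.MICROSPHERE, CorePart.EXTERIOR, "site")
    }
    pft_int_sys = {
        s.group: s
        for s in detection_rate(table, Tracer.PFT, CorePart.INTERIOR, "coring_system")
    }
    molecular_high = tuple(
        r.sample_id
        for r in table
        if r.molecular_contamination_pct is not None
        and r.molecular_contamination_pct > MOLECULAR_HIGH_PCT
    )
    measured = [r for r in table if r.molecular_contamination_pct is not None]
    positive = [r for r in measured if r.molecular_contamination_pct > 0]
    tier_counts: dict[str, int] = {}
    for rec in table:
        name = classify_tier(rec).tier.name
        tier_counts[name] = tier_counts.get(name, 0) + 1
    return StudySummary(
        n_records=len(table),
        ms_interior=ms_interior,
        ms_interior_high_ids=ms_high,
        ms_exterior_by_site=ms_ext_site,
        pft_interior_by_system=pft_int_sys,
        molecular_high_ids=molecular_high,
        n_molecular_measured=len(measured),
        n_molecular_positive=len(positive),
        tier_counts=tier_counts,
    )


def _resolve_screens(
    table: AssessmentTable, screens: Sequence[ScreenResult]
) -> dict[str, ScreenResult]:
    by_sample: dict[str, list[CoreSampleRecord]] = {}
    for rec in table:
        by_sample.setdefault(rec.sample_id, []).append(rec)
    missing = [s.sample_id for s in screens if s.sample_id not in by_sample]
    ambiguous = [
        s.sample_id for s in screens if len(by_sample.get(s.sample_id, [])) > 1
    ]
    if missing or ambiguous:
        parts = []
        if missing:
            parts.append(f"unresolvable sample ids: {sorted(missing)}")
        if ambiguous:
            parts.append(f"ambiguous sample ids (several depths): {sorted(ambiguous)}")
        raise ValidationError("; ".join(parts))
    return {s.sample_id: s for s in screens}


def build_report(
    table: AssessmentTable,
    out_dir: str | Path,
    screens: Sequence[ScreenResult] | None = None,
    profile: Optional[ThermalProfile] = None,
    overwrite_molecular: bool = False,
    plots: bool = False,
) -> dict[str, Path]:
    """Emit the merged per-sample report (TSV + JSON, optional SVG plot).

    Screening results are matched to table records by sample id; an id that
    resolves to no record (or to several subsamples) is an error. Screen
    percentages replace the table's molecular column only when
    ``overwrite_molecular`` is set; otherwise they are reported side by side.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    screens = list(screens or [])
    screen_map = _resolve_screens(table, screens)

    effective_records = []
    for rec in table:
        screen = screen_map.get(rec.sample_id)
        if screen is not None and overwrite_molecular:
            rec = rec.with_contamination(float(screen.contamination_level_pct))
        effective_records.append(rec)
    effective = AssessmentTable(effective_records, provenance=table.provenance)

    flags = applicability_by_depth(profile, effective) if profile is not None else None

    tsv_path = out_dir / "report.tsv"
    header = [
        "sample_id", "site", "coring_system", "depth_mbsf", "lithology",
        "ms_interior", "ms_exterior", "pft_interior", "pft_exterior",
        "pcr_amplified", "contamination_pct", "screen_pct", "tier", "reasons",
    ]
    if flags is not None:
        header += ["temperature_c", "microspheres_reliable", "liner_intact", "pft_caution"]
    with tsv_path.open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for i, rec in enumerate(effective):
            tier = classify_tier(rec)
            screen = screen_map.get(rec.sample_id)
            row = [
                rec.sample_id,
                rec.site,
                rec.coring_system.value,
                f"{rec.depth_mbsf:g}",
                rec.lithology,
                _cell(rec.ms_interior),
                _cell(rec.ms_exterior),
                _cell(rec.pft_interior),
                _cell(rec.pft_exterior),
                "" if rec.pcr_amplified is None else ("+" if rec.pcr_amplified else "-"),
                ""
                if rec.molecular_contamination_pct is None
                else f"{rec.molecular_contamination_pct:g}",
                "" if screen is None else f"{screen.contamination_level_pct:g}",
                tier.tier.name,
                "; ".join(tier.reasons),
            ]
            if flags is not None:
                f = flags[i]
                row += [
                    f"{f.temperature:g}",
                    str(f.microspheres_reliable).lower(),
                    str(f.liner_intact).lower(),
                    str(f.pft_caution).lower(),
                ]
            fh.write("\t".join(row) + "\n")

    summary = study_summary(effective)
    json_path = out_dir / "summary.json"
    payload = summary.to_dict()
    payload["screens"] = [s.to_summary() for s in screens]
    with json_path.open("w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")

    outputs = {"report": tsv_path, "summary": json_path}

    table_path = out_dir / "assessment_table.csv"
    write_table(effective, table_path)
    outputs["table"] = table_path

    if plots:
        outputs["depth_plot"] = _depth_plot(effective, out_dir / "depth_tracers.svg")
    return outputs


def _cell(result) -> str:
    from .records import TracerStatus

    if result.status is TracerStatus.NOT_MEASURED:
        return ""
    if result.status is TracerStatus.NOT_DETECTED:
        return "N.D."
    return f"{result.value:g}"


def _depth_plot(table: AssessmentTable, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .records import TracerStatus

    fig, axes = plt.subplots(1, 2, figsize=(8, 6), sharey=True)
    for ax, (channel, label) in zip(
        axes,
        [("ms_interior", "microspheres (beads/ml)"), ("pft_interior", "PFT (g/ml)")],
    ):
        xs, ys = [], []
        for rec in table:
            res = rec.tracer(channel)
            if res.status is TracerStatus.DETECTED and res.value > 0:
                xs.append(res.value)
                ys.append(rec.depth_mbsf)
        ax.scatter(xs, ys, s=14)
        ax.set_xscale("log")
        ax.set_xlabel(f"interior {label}")
    axes[0].set_ylabel("depth (mbsf)")
    axes[0].invert_yaxis()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
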