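#!/usr/bin/env python
"""Tally the expedition contamination-test table.

Loads the packaged whole-round-core table, computes the headline detection
statistics for both physical tracers stratified by coring system and site,
lists the heavily penetrated samples, and writes the integrated per-sample
report (tiers included) under results/table_summary/.

Key findings, recomputed from the table itself: interior PFT was detected
in 7 of 9 extended-shoe/extended-punch cores (78%) but only 16 of 46
hydraulic-piston cores (35%); interior microspheres appear in just 10
samples, 4 of them above 10^4 beads/ml; and only 2 of the 38 sequenced
samples carry a molecular contamination level above 50% of clones.
"""

from pathlib import Path

from coretrace import load_expedition_table
from coretrace.report import build_report, study_summary

OUT = Path("results/table_summary")


def main() -> None:
    table = load_expedition_table()
    summary = study_summary(table)

    print(f"loaded {summary.n_records} whole-round-core records")
    print(
        f"interior microspheres: detected in {summary.n_ms_interior_detected} "
        f"of {summary.ms_interior.n_measured} assayed samples"
    )
    print(
        f"  above 1e4 beads/ml in {summary.n_ms_interior_high}: "
        f"{', '.join(summary.ms_interior_high_ids)}"
    )
    ext = summary.ms_exterior_not_detected(["C0015", "C0017"])
    print(
        f"exterior microspheres at C0015/C0017: N.D. in "
        f"{ext.n_measured - ext.n_detected} of {ext.n_measured} assays"
    )
    for system, d in sorted(summary.pft_interior_by_system.items()):
        print(
            f"interior PFT, {system}: {d.n_detected}/{d.n_measured} "
            f"({d.rate_pct_rounded}%)"
        )
    print(
        f"molecular contamination > 50% of clones: {summary.n_molecular_high} "
        f"of {summary.n_molecular_measured} sequenced samples "
        f"({', '.join(summary.molecular_high_ids)})"
    )
    print(f"contamination tiers: {summary.tier_counts}")

    outputs = build_report(table, OUT)
    print(f"report written to {outputs['report']}")


if __name__ == "__main__":
    main()
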