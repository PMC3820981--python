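#!/usr/bin/env python
"""Flag where each tracer remains trustworthy under the geothermal model.

The hydrothermally active sites show a gradient of 3-4 degC per metre, so
polystyrene microspheres (glass transition ~95 degC) stop being a valid
tracer within a few tens of metres of the seafloor, the butyrate core
liner melts (70-80 degC) even shallower, and PFT (boiling point 76 degC)
carries a gas-phase caveat but remains usable. This script applies a
3.5 degC/m profile to the packaged table, prints the depth horizons, and
writes per-record flags to results/thermal/applicability.tsv.
"""

from pathlib import Path

from coretrace import ThermalProfile, applicability_by_depth, load_expedition_table
from coretrace.tracers import (
    LINER_MELT_ONSET_C,
    MICROSPHERE_GLASS_TRANSITION_C,
    PFT_BOILING_POINT_C,
)

OUT = Path("results/thermal")
GRADIENT = 3.5   # degC per metre, middle of the reported 3-4 range
SURFACE = 4.0    # degC, deep-sea bottom water default


def main() -> None:
    profile = ThermalProfile(gradient=GRADIENT, surface_temp=SURFACE)
    for name, threshold in (
        ("liner melt onset", LINER_MELT_ONSET_C),
        ("PFT boiling point", PFT_BOILING_POINT_C),
        ("microsphere glass transition", MICROSPHERE_GLASS_TRANSITION_C),
    ):
        depth = (threshold - SURFACE) / GRADIENT
        print(f"{name} ({threshold:g} degC) reached at {depth:.1f} mbsf")

    table = load_expedition_table()
    flags = applicability_by_depth(profile, table)
    unreliable = sum(not f.microspheres_reliable for f in flags)
    print(
        f"{unreliable} of {len(table)} records lie below the microsphere "
        f"reliability horizon at this gradient"
    )

    OUT.mkdir(parents=True, exist_ok=True)
    path = OUT / "applicability.tsv"
    with path.open("w") as fh:
        fh.write(
            "sample_id\tdepth_mbsf\ttemperature_c\t"
            "microspheres_reliable\tliner_intact\tpft_caution\n"
        )
        for rec, f in zip(table, flags):
            fh.write(
                f"{rec.sample_id}\t{rec.depth_mbsf:g}\t{f.temperature:.1f}\t"
                f"{f.microspheres_reliable}\t{f.liner_intact}\t{f.pft_caution}\n"
            )
    print(f"flags written to {path}")


if __name__ == "__main__":
    main()
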