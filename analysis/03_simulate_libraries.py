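#!/usr/bin/env python
"""Generate the synthetic clone libraries used by the screening analysis.

Builds a two-pool community (drilling-fluid vs indigenous taxa, 380-nt
amplicons, >=10% divergence margin), then emulates the three drilling-fluid
situations observed at sea — a near-monodominant guar-gum mud, a diverse
seawater-gel mud, and a freshly prepared gel mud that yields no amplicons —
plus core libraries with planted contamination fractions 0, 0.52 and 1.
FASTA files with embedded truth labels land in results/libraries/.
"""

from pathlib import Path

from coretrace.screen import MudType, assign_otus, composition_summary, rarefaction, \
    write_fasta_library, write_rarefaction_tsv
from coretrace.simulate import (
    GUAR_GUM_DOMINANCE,
    SEAWATER_GEL_DOMINANCE,
    CommunitySpec,
    LibrarySpec,
    make_library,
    make_mud_library,
    make_taxa,
)

OUT = Path("results/libraries")
SEED = 20260927


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    guar_comm = make_taxa(CommunitySpec(seed=SEED, dominance=GUAR_GUM_DOMINANCE))
    gel_comm = make_taxa(CommunitySpec(seed=SEED + 1, dominance=SEAWATER_GEL_DOMINANCE))

    guar = make_mud_library(guar_comm, 80, "guar_gum_mud", MudType.GUAR_GUM,
                            seed=SEED + 2)
    gel = make_mud_library(gel_comm, 80, "seawater_gel_mud", MudType.SEAWATER_GEL,
                           seed=SEED + 3)
    fresh = make_mud_library(gel_comm, 0, "fresh_gel_mud", MudType.SEAWATER_GEL)

    for lib in (guar, gel, fresh):
        write_fasta_library(lib, OUT / f"{lib.sample_id}.fasta")
        if len(lib) == 0:
            print(f"{lib.sample_id}: no amplicons (freshly prepared mud)")
            continue
        comp = composition_summary(lib)
        top_taxon, top = max(comp.items(), key=lambda kv: kv[1])
        partition = assign_otus(lib)
        curve = rarefaction(partition.sizes())
        write_rarefaction_tsv(curve, OUT / f"{lib.sample_id}_rarefaction.tsv")
        print(
            f"{lib.sample_id}: {len(lib)} clones, {partition.n_otus} OTUs, "
            f"dominant taxon {top_taxon} at {100 * top:.0f}% of clones"
        )

    for p in (0.0, 0.52, 1.0):
        core = make_library(
            guar_comm,
            LibrarySpec(n_clones=100, contamination_fraction=p,
                        seed=SEED + 10 + int(100 * p)),
            sample_id=f"core_p{int(100 * p):03d}",
            mud_library=guar,
        )
        write_fasta_library(core, OUT / f"{core.sample_id}.fasta")
        print(f"{core.sample_id}: planted contamination fraction {p:g}")


if __name__ == "__main__":
    main()
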