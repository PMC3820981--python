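# coretrace

Contamination assessment for riser-less scientific ocean-drilling cores.

Subseafloor microbiology lives or dies by one question: are the cells and
sequences in a core sample indigenous, or did they ride in with the drilling
mud? `coretrace` implements the three-tracer quality-control workflow used on
whole-round cores (WRCs) from hydrothermal-field drilling:

1. **Perfluorocarbon tracer (PFT)** — perfluoromethylcyclohexane dosed at
   1 ppm into the circulating mud; any PFT in a subsample marks fluid
   infiltration.
2. **Fluorescent microspheres** — 0.5 µm polystyrene beads released at the
   core cutting shoe; a particulate infiltration tracer, but thermally
   unreliable at or above the polystyrene glass transition (~95 °C).
3. **Molecular screening** — 16S rRNA gene clone libraries from the mud
   fluids themselves serve as the reference pool of potential contaminants:
   a core clone whose best pairwise identity to any drilling-fluid sequence
   exceeds 97 % is called a potential contaminant, and a library's
   *contamination level* is the percentage of such clones,

   `L = 100 · #{i : max_j id(c_i, m_j) > 0.97} / n`.

Around that core statistic the package provides complete-linkage OTU
assignment at the same 97 % threshold, analytic (hypergeometric) rarefaction
`E[S_n] = Σ_i (1 − C(N−N_i, n)/C(N, n))`, detection-rate accounting per
coring system (hydraulic piston HPCS vs extended punch/shoe EPCS/ESCS), a
linear geothermal model `T(z) = T₀ + g·z` that flags where each tracer stays
physically applicable, per-sample contamination tiers, and a synthetic-data
generator that plants exact contamination fractions with truth labels so the
whole pipeline is testable without any sequence download.

A transcription of the expedition's contamination-test table (99 WRC rows:
tracer values, coring system, depth, molecular contamination levels) ships
as a package fixture and is the default input everywhere.

## Worked example

```
$ coretrace report summary
records: 99
interior microsphere detections: 10 of 90 measured
interior microspheres > 1e4 beads/ml: 4 (C0013D-1H-1, C0014D-2H-1, C0015C-1H-1, C0017C-2H-1)
exterior microspheres N.D. at C0015/C0017: 4 of 19 measured
interior PFT, EPCS: 3 of 4 (75%)
interior PFT, ESCS: 4 of 5 (80%)
interior PFT, HPCS: 16 of 46 (35%)
molecular contamination > 50%: 2 (C0013D-1H-1, C0017D-11X-1)
tiers: {'PERIPHERY_ONLY': 36, 'INTERIOR_HIGH': 5, 'INTERIOR_LOW': 32, 'UNCONTAMINATED': 26}
```

Reading: the undisturbed hydraulic-piston cores show interior PFT in 35 % of
assays while the extended systems show it in 7 of 9 (78 %) — the coring
system dominates infiltration risk. Microspheres were seen inside only 10
samples, with striking penetration (>10⁴ beads/ml) in 4; and of 38 samples
with sequenced clone libraries, only 2 have more than half their clones
matching drilling-fluid sequences.

Screening a clone library against drilling-fluid references:

```
$ coretrace screen run core.fasta mud_a.fasta mud_b.fasta --out-tsv calls.tsv
core: 52/100 potential contaminants (52%)
```

The same pipeline as a library call:

```python
from coretrace import read_fasta_library, screen_contaminants, LibrarySource

core = read_fasta_library("core.fasta")
muds = [read_fasta_library(p, source=LibrarySource.DRILLING_FLUID)
        for p in ("mud_a.fasta", "mud_b.fasta")]
result = screen_contaminants(core, muds, threshold=0.97)
print(result.contamination_level_pct)
```

The numbered scripts under `analysis/` walk the full study: `01` tallies the
packaged table and writes the integrated per-sample report,
`02` applies the 3.5 °C/m geothermal model (microspheres stop being
trustworthy below ~26 mbsf at that gradient), `03` simulates the mud and
core clone libraries (monodominant guar-gum mud, diverse seawater-gel mud,
amplicon-free fresh mud, cores with planted fractions 0/0.52/1.0), and `04`
screens the cores and confirms the planted fractions are recovered exactly.
Outputs land under `results/`.

## Layout

- `src/coretrace/records.py` — table domain types, CSV I/O, packaged fixture
- `src/coretrace/screen.py` — identity, OTUs, screening, rarefaction, FASTA
- `src/coretrace/_alignment.py` — the exact global-alignment kernel (numba)
- `src/coretrace/tracers.py` — detection rates, exceedance, thermal flags
- `src/coretrace/report.py` — tiers, study summary, merged reports
- `src/coretrace/simulate.py` — synthetic communities, libraries, tracer tables
- `src/coretrace/cli.py` — `coretrace` command-line interface
- `docs/methods.md` — model conventions, parameters, and limitations
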