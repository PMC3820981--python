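# Methods

This note records the conventions, parameter choices and known limits of the
`coretrace` pipeline. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The contamination-test table

One record describes a whole-round-core (WRC) subsample: hole, section,
depth (mbsf), coring system (HPCS / EPCS / ESCS), lithology, four tracer
channels (microspheres and PFT, interior and exterior), and — where a 16S
clone library was obtained — the molecular contamination level in percent.

Detection semantics are carried by the recorded marker, never inferred from
the magnitude: `N.D.` means assayed-and-not-detected, an empty cell means
not assayed, and any numeral — including an explicit `0.0e0` — is a
detection with that value. This is the only convention under which the
packaged table reproduces its own printed tallies (one exterior microsphere
cell is an explicit zero; treating it as a non-detection would change the
site-level counts). Units are fixed per column (beads/ml sediment, g/ml
sediment) and never converted.

Two subsamples may share a hole and section (separate depths of the same
core section); records are therefore keyed by (hole, section, depth). The
IODP site is the hole string minus its trailing hole letter (C0014G →
C0014). The packaged fixture has 99 rows; summary rates are computed from
these rows as printed, so a tally can differ by one or two counts from
narrative figures quoted elsewhere for the same material.

## Pairwise identity

The screening statistic needs a pairwise similarity for ~380-nt amplicons.
Convention used throughout:

* optimal **end-to-end global alignment** (Needleman–Wunsch), match +1,
  mismatch −1, gap column −2, with **every gap column scored, terminal runs
  included**;
* identity = matched columns / alignment columns, **excluding terminal-gap
  columns** from the ratio (an overhang is penalised when choosing the
  alignment but does not dilute the identity);
* IUPAC ambiguity codes match when one symbol's base set contains the
  other's, otherwise they mismatch;
* among co-optimal alignments the value is pinned by the lexicographic
  maximum of (score, matches, fewest interior gap columns, most terminal
  gap columns), which makes the measure deterministic and symmetric.

Scoring end gaps is deliberate. If terminal gaps were free in the *score*,
the optimal alignment of two unrelated sequences would collapse to their
best short perfect end-overlap (+L for an L-base overlap versus a negative
full-length score), and unrelated sequences would routinely measure
identity ≈ 1 — useless for contaminant screening. With end gaps scored,
unrelated 380-mers measure ≈ 0.5–0.6 while near-full-length homologs are
unaffected, and the two canonical worked examples hold: 3 substitutions in
100 equal-length bases → 0.97; one interior deletion in an 8-mer → 7/8.

The kernel packs the additive (score, matches, gap) quadruple into a single
int64 and runs as a numba-compiled dynamic program (sequences ≤ 2000 nt,
integer scores |s| ≤ 8 so fields cannot overflow). The test suite checks it
against a pure-Python tuple DP on random short pairs and against exhaustive
path enumeration on tiny pairs.

Whether the original toolchain computed similarity on multiple-alignment
columns or on unaligned pairs is not recoverable; the convention above is
exposed through `AlignmentScoring` rather than hidden.

## OTUs, screening, rarefaction

**OTUs.** Clones are clustered by furthest-neighbour (complete-linkage)
agglomeration on 1 − identity, cut so that every intra-OTU pairwise
identity is ≥ the threshold (0.97 by default); scipy's hierarchy does the
agglomeration, and the certificate (worst intra-OTU pair) is verified
property-style in the tests. OTU indices follow first appearance in library
order; each OTU is represented by its lexicographically smallest clone id.

**Screening.** Every core clone receives its best identity over the pooled
drilling-fluid clones; it is a potential contaminant iff that identity is
*strictly greater* than the threshold ("more than 97 %"), so identity
exactly 0.97 is not a contaminant. Screening against an empty reference
pool raises — it is undefined, not 0 %. The `unit` switch screens either
every clone (default) or only OTU representatives, each member inheriting
its representative's call; the printed levels could have been produced
either way, so both are first-class. Contamination levels are kept exact
internally and rounded to integer percent only at report time.

**Rarefaction.** The analytic hypergeometric form
E[S_n] = Σ_i (1 − C(N−N_i, n)/C(N, n)), evaluated with log-gamma binomials;
exact at both endpoints (E[S_1] = 1, E[S_N] = S_obs), non-decreasing and
concave in n. Tests compare it with direct Monte-Carlo subsampling, using a
family-wise (Bonferroni) bound on the Monte-Carlo standard-error scale plus
a rule-of-three floor for miss events too rare to observe.

## Thermal applicability

Temperature is modelled linearly, T(z) = T₀ + g·z. The gradient must come
from site data (3–4 °C/m at the hydrothermally active sites); the default
surface temperature of 4 °C is a deep-sea bottom-water figure chosen as a
package default, not a measured value. Flags, all pure threshold functions
of temperature:

| flag | threshold | boundary behaviour |
|---|---|---|
| `microspheres_reliable` | T < 95 °C (polystyrene glass transition) | false at exactly 95 °C |
| `liner_intact` | T < 70 °C (conservative end of the 70–80 °C butyrate melting range) | false at exactly 70 °C |
| `pft_caution` | T ≥ 76 °C (PFT atmospheric boiling point) | true at exactly 76 °C |

The 95 °C microsphere flag encodes a qualitative degradation argument (the
amorphous-polymer transition, not the ~240 °C melting point); it is not a
measured in-situ loss temperature. PFT above 76 °C is caution-not-invalid:
mud-injection cooling and hydrostatic pressure keep it informative at
depth, which is why the deep PFT record remains usable where microspheres
vanish.

## Contamination tiers

The per-sample tier is a convenience of this package — the field has no
standard tiering — built only from landmarks the data themselves motivate:

* `INTERIOR_HIGH`: molecular level > 50 % of clones, **or** interior
  microspheres > 10⁴ beads/ml;
* `INTERIOR_LOW`: any interior tracer detection (any magnitude) or a
  non-zero molecular level — interior infiltration of the subsample
  actually used for microbiology;
* `PERIPHERY_ONLY`: at least one exterior detection, nothing interior;
* `UNCONTAMINATED`: otherwise.

The tier is monotone in the molecular level, and `reasons` lists every rule
that fired.

## Synthetic data

The generator exists so each pipeline stage has a computable ground truth.

**Community.** Two sequence pools derived from independent random
ancestors: "mud" taxa (drilling fluid) and "indigenous" taxa, each taxon
the ancestor substituted at a fixed 4 % of sites. Defaults: 8 + 8 taxa,
380 nt (the approximate 530F–907R amplicon span), and a verified ≥ 10 %
mud–indigenous divergence margin — every cross pair is checked with the
screening identity and regenerated on violation, so planted labels cannot
be flipped by the 97 % rule. Taxon abundances are symmetric-Dirichlet:
concentration 0.005 gives the near-monodominant guar-gum-like fluid (the
largest taxon exceeds 80 % of a 100-clone library in ≳95 % of seeds),
50 gives the even seawater-gel-like fluid (no taxon above 40 %). Archaea
are never placed in the mud pool by default, mirroring fluids in which
archaeal amplicons were not obtained; a zero-clone library models freshly
prepared mud.

**Libraries.** A library spec plants exactly `round(p·n)` mud-derived
clones (binomial mode exists behind a flag), so the true contamination
level is a constant of the spec. Contaminant clones are *re-sequenced
copies of drilling-fluid library clones* — one additional 0.5 %-per-base
error pass over a clone drawn from the mud library — rather than fresh
draws from the taxon pool. This mirrors screening practice (the
contaminating organisms are exactly those present in the sequenced fluid),
guarantees every contaminant's source is in the reference pool, and keeps
query–reference divergence at a single error pass, so recovery stays exact
at the default error rate and within binomial noise at 2 %. Indigenous
clones are drawn from the indigenous pool with the community's abundance
weights. The 0.5 % default per-base error is a package choice for
Sanger-era clone sequencing, exposed in the spec. Short-sequence test
fixtures scale the error rate down so expected per-clone errors stay well
inside the identity slack of the shorter amplicon.

**Tracer tables.** Each synthetic sample carries a log-normal latent
contamination intensity that drives all channels: PFT mass and microsphere
count (log-normal channel noise above detection floors, exterior ~30×
interior), and a molecular level saturating in the intensity. Microspheres
are assayed only on HPCS cores, as in practice, and are force-censored to
`N.D.` wherever the thermal model reaches 95 °C — reproducing the
qualitative field pattern of deep PFT detections with no deep microspheres.

**What passing synthetic tests does not show.** Generated sequences are
point-mutated random ancestors: no chimeras, no indels from sequencing, no
phylogenetically realistic rate variation, no quality scores, and a
divergence margin that real communities do not guarantee (real indigenous
taxa can sit near the 97 % line; the margin makes truth labels decidable,
not realistic). Real per-sample contamination levels and taxon compositions
require the deposited clone sequences, which this package does not fetch;
`coretrace screen run` performs exactly that screening when the sequences
are supplied locally as FASTA.

## Numerical and degenerate-input conventions

* Detection-rate summaries with an empty denominator are flagged undefined,
  never reported as 0.
* Threshold exceedance is strict (`value > threshold`), returns table
  order, and is antitone in the threshold.
* The OTU cut subtracts a 10⁻¹² relative epsilon from the distance
  threshold so an identity exactly at the threshold does not merge (the
  strict "more than 97 %" reading).
* An empty clone library is legal as data (fresh mud) but an error as a
  screening input, on either side.
* Problem sizes in tests and the acceptance script — 100–200-clone
  libraries, 30–50-clone references, 10⁴ Monte-Carlo draws — were chosen as
  the smallest sizes at which the planted-fraction and oracle checks are
  statistically meaningful.
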