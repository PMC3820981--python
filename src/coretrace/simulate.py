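"""Synthetic clone libraries and tracer tables with known ground truth.

The generator emulates the statistical shape of the expedition data so the
whole pipeline is testable without the deposited sequences:

* two disjoint sequence pools — "mud" taxa (the drilling-fluid community)
  and "indigenous" taxa — separated by a guaranteed divergence margin, so
  planted truth labels can never be flipped by the 97% screening rule;
* mud communities with a tunable dominance structure: a near-monodominant
  guar-gum-like fluid, a diverse seawater-gel-like fluid, and zero-clone
  "freshly prepared" fluids, never containing archaea by default;
* core libraries with an exact planted contamination fraction (round(p*n)
  clones are literal re-sequenced copies of drilling-fluid clones, with one
  additional per-base error pass) so the recovered contamination level has a
  deterministic truth;
* tracer tables driven by a latent per-sample contamination intensity, with
  microsphere channels force-censored to NOT_DETECTED wherever the thermal
  model predicts temperatures at or above the polystyrene glass transition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .records import (
    AssessmentTable,
    CoreSampleRecord,
    CoringSystem,
    TracerResult,
    ValidationError,
)
from .screen import (
    CloneLibrary,
    CloneSequence,
    LibrarySource,
    MudType,
    TruthLabel,
    pairwise_identity,
)
from .tracers import (
    MICROSPHERE_GLASS_TRANSITION_C,
    ThermalProfile,
    temperature_at_depth,
)

__all__ = [
    "CommunitySpec",
    "LibrarySpec",
    "Community",
    "TracerTableSpec",
    "GUAR_GUM_DOMINANCE",
    "SEAWATER_GEL_DOMINANCE",
    "make_taxa",
    "make_library",
    "make_mud_library",
    "make_tracer_table",
]

_BASES = np.array(list("ACGT"))

# Symmetric-Dirichlet concentrations for the two drilling-fluid styles:
# far below 1 collapses the community onto one taxon (guar-gum-like), far
# above 1 spreads clones evenly (seawater-gel-like). The guar-gum value is
# set so a 100-clone library is >80% monodominant in well over 90% of seeds.
GUAR_GUM_DOMINANCE = 0.005
SEAWATER_GEL_DOMINANCE = 50.0


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a synthetic two-pool 16S community.

    ``seq_length`` defaults to 380 nt, the approximate span of the
    530F-907R amplicon. ``min_intergroup_divergence`` is the guaranteed
    margin between any mud and any indigenous taxon; it must exceed
    1 - 0.97 so truth labels are unambiguous under the screening rule.
    ``within_group_divergence`` is the per-taxon distance from the group
    ancestor (taxa in the same pool sit roughly twice that apart).
    """

    n_mud_taxa: int = 8
    n_indigenous_taxa: int = 8
    seq_length: int = 380
    min_intergroup_divergence: float = 0.10
    within_group_divergence: float = 0.04
    dominance: float = SEAWATER_GEL_DOMINANCE
    include_archaea_in_mud: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mud_taxa < 0 or self.n_indigenous_taxa < 0:
            raise ValidationError("taxon counts must be >= 0")
        if self.seq_length < 20:
            raise ValidationError("seq_length must be >= 20 nt")
        if not self.min_intergroup_divergence > 0.03:
            raise ValidationError(
                "min_intergroup_divergence must exceed 0.03 (= 1 - 0.97) so "
                "planted labels are unambiguous under the screening rule"
            )
        if not 0 < self.within_group_divergence < 0.5:
            raise ValidationError("within_group_divergence must be in (0, 0.5)")
        if self.dominance <= 0:
            raise ValidationError("dominance concentration must be > 0")


@dataclass(frozen=True)
class LibrarySpec:
    """Sampling parameters for one synthetic clone library.

    ``contamination_fraction`` p plants exactly round(p * n_clones)
    mud-derived clones when ``exact_composition`` is set (the default), so
    the true contamination level is a constant of the spec rather than a
    binomial draw.
    """

    n_clones: int
    contamination_fraction: float = 0.0
    error_rate: float = 0.005
    exact_composition: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 0:
            raise ValidationError("n_clones must be >= 0")
        if not 0 <= self.contamination_fraction <= 1:
            raise ValidationError(
                f"contamination_fraction {self.contamination_fraction} outside [0, 1]"
            )
        if not 0 <= self.error_rate < 0.5:
            raise ValidationError("error_rate must be in [0, 0.5)")


@dataclass(frozen=True)
class Community:
    """Taxon sequences plus their relative abundances in each pool."""

    spec: CommunitySpec
    mud_taxa: tuple[CloneSequence, ...]
    indigenous_taxa: tuple[CloneSequence, ...]
    mud_weights: tuple[float, ...]
    indigenous_weights: tuple[float, ...]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Independent per-base substitutions to a uniformly different base."""
    arr = np.array(list(seq))
    hits = rng.random(arr.size) < rate
    for i in np.flatnonzero(hits):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _mutate_to_divergence(rng: np.random.Generator, seq: str, divergence: float) -> str:
    """Substitute at exactly round(divergence * length) distinct positions."""
    arr = np.array(list(seq))
    k = int(round(divergence * arr.size))
    sites = rng.choice(arr.size, size=k, replace=False)
    for i in sites:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def make_taxa(spec: CommunitySpec, max_retries: int = 20) -> Community:
    """Generate the two taxon pools with a verified divergence margin.

    Each pool derives from its own random ancestor; every taxon is the
    ancestor substituted at a fixed fraction of sites. Every mud-indigenous
    pair is checked with the screening identity measure; an indigenous taxon
    closer than the margin allows is regenerated (bounded retries).
    """
    rng = np.random.default_rng(spec.seed)
    mud_ancestor = _random_sequence(rng, spec.seq_length)
    indigenous_ancestor = _random_sequence(rng, spec.seq_length)
    limit = 1.0 - spec.min_intergroup_divergence

    mud_taxa: list[CloneSequence] = []
    for i in range(spec.n_mud_taxa):
        prefix = "mud_arc" if (spec.include_archaea_in_mud and i == 0) else "mud"
        mud_taxa.append(
            CloneSequence(
                id=f"{prefix}_taxon_{i:02d}",
                sequence=_mutate_to_divergence(
                    rng, mud_ancestor, spec.within_group_divergence
                ),
                truth_label=TruthLabel.MUD_DERIVED,
                taxon=f"{prefix}_taxon_{i:02d}",
            )
        )

    indigenous_taxa: list[CloneSequence] = []
    for i in range(spec.n_indigenous_taxa):
        candidate = None
        for _ in range(max_retries):
            seq = _mutate_to_divergence(
                rng, indigenous_ancestor, spec.within_group_divergence
            )
            if all(pairwise_identity(seq, t.sequence) <= limit for t in mud_taxa):
                candidate = seq
                break
        if candidate is None:
            raise ValidationError(
                "could not generate an indigenous taxon at the requested "
                f"divergence margin after {max_retries} retries"
            )
        indigenous_taxa.append(
            CloneSequence(
                id=f"ind_taxon_{i:02d}",
                sequence=candidate,
                truth_label=TruthLabel.INDIGENOUS,
                taxon=f"ind_taxon_{i:02d}",
            )
        )

    def weights(k: int) -> tuple[float, ...]:
        if k == 0:
            return ()
        w = rng.dirichlet(np.full(k, spec.dominance))
        return tuple(float(x) for x in w)

    return Community(
        spec=spec,
        mud_taxa=tuple(mud_taxa),
        indigenous_taxa=tuple(indigenous_taxa),
        mud_weights=weights(spec.n_mud_taxa),
        indigenous_weights=weights(spec.n_indigenous_taxa),
    )


def _draw_clones(
    rng: np.random.Generator,
    taxa: Sequence[CloneSequence],
    weights: Sequence[float],
    n: int,
    error_rate: float,
) -> list[CloneSequence]:
    idx = rng.choice(len(taxa), size=n, p=np.asarray(weights))
    out = []
    for i in idx:
        t = taxa[int(i)]
        out.append(
            CloneSequence(
                id="placeholder",
                sequence=_mutate(rng, t.sequence, error_rate),
                truth_label=t.truth_label,
                taxon=t.taxon,
            )
        )
    return out


def make_library(
    community: Community,
    lib_spec: LibrarySpec,
    sample_id: str = "synthetic_core",
    source: LibrarySource = LibrarySource.CORE,
    mud_type: Optional[MudType] = None,
    mud_library: Optional[CloneLibrary] = None,
) -> CloneLibrary:
    """Sample a clone library with planted, exactly counted truth labels.

    Contaminant clones are re-sequenced copies of drilling-fluid material:
    if ``mud_library`` is given they are drawn uniformly from its clones
    (one extra error pass), which mirrors screening practice — the
    contaminating organisms are exactly those present in the fluid that was
    sequenced — and keeps the query-reference divergence at a single error
    pass. Without a ``mud_library`` they are drawn from the mud taxa using
    the community's abundance weights. Indigenous clones always come from
    the indigenous taxon pool.
    """
    rng = np.random.default_rng(lib_spec.seed)
    n = lib_spec.n_clones
    p = lib_spec.contamination_fraction
    if lib_spec.exact_composition:
        n_mud = int(round(p * n))
    else:
        n_mud = int(rng.binomial(n, p))
    n_ind = n - n_mud

    if n_mud > 0 and mud_library is None and not community.mud_taxa:
        raise ValidationError("contamination_fraction > 0 requires mud taxa")
    if n_mud > 0 and mud_library is not None and len(mud_library) == 0:
        raise ValidationError("contamination_fraction > 0 requires a non-empty mud library")
    if n_ind > 0 and not community.indigenous_taxa:
        raise ValidationError("contamination_fraction < 1 requires indigenous taxa")

    clones: list[CloneSequence] = []
    if n_mud > 0:
        if mud_library is not None:
            picks = rng.integers(len(mud_library), size=n_mud)
            for i in picks:
                src = mud_library.clones[int(i)]
                clones.append(
                    CloneSequence(
                        id="placeholder",
                        sequence=_mutate(rng, src.sequence, lib_spec.error_rate),
                        truth_label=TruthLabel.MUD_DERIVED,
                        taxon=src.taxon,
                    )
                )
        else:
            clones.extend(
                _draw_clones(
                    rng, community.mud_taxa, community.mud_weights, n_mud,
                    lib_spec.error_rate,
                )
            )
    if n_ind > 0:
        clones.extend(
            _draw_clones(
                rng,
                community.indigenous_taxa,
                community.indigenous_weights,
                n_ind,
                lib_spec.error_rate,
            )
        )

    order = rng.permutation(len(clones))
    shuffled = [
        replace(clones[int(k)], id=f"{sample_id}_c{j:04d}")
        for j, k in enumerate(order)
    ]
    return CloneLibrary(
        sample_id=sample_id, source=source, clones=shuffled, mud_type=mud_type
    )


def make_mud_library(
    community: Community,
    n_clones: int,
    sample_id: str,
    mud_type: MudType,
    error_rate: float = 0.005,
    seed: int = 0,
) -> CloneLibrary:
    """A drilling-fluid reference library (all clones MUD_DERIVED).

    ``n_clones = 0`` models freshly prepared seawater-gel mud, which yields
    no amplicons — a legal, empty library.
    """
    spec = LibrarySpec(
        n_clones=n_clones, contamination_fraction=1.0, error_rate=error_rate, seed=seed
    )
    if n_clones == 0:
        return CloneLibrary(
            sample_id=sample_id, source=LibrarySource.DRILLING_FLUID,
            clones=[], mud_type=mud_type,
        )
    return make_library(
        community, spec, sample_id=sample_id,
        source=LibrarySource.DRILLING_FLUID, mud_type=mud_type,
    )


@dataclass(frozen=True)
class TracerTableSpec:
    """Latent-intensity model for synthetic tracer tables.

    Each sample carries a log-normal contamination intensity that drives all
    three channels: PFT mass, microsphere count (both detected only above a
    floor), and the molecular contamination level (saturating in the
    intensity). Microsphere channels are only assayed on HPCS cores, as in
    practice, and are force-censored to NOT_DETECTED wherever the thermal
    model reaches the glass-transition temperature.
    """

    n_samples: int
    depth_max: float = 150.0
    p_epcs: float = 0.05
    p_escs: float = 0.10
    intensity_mu: float = -1.0
    intensity_sigma: float = 1.5
    channel_noise_sigma: float = 0.5
    pft_scale: float = 1e-5       # g/ml per unit intensity
    pft_floor: float = 1e-6       # detection floor, g/ml
    ms_scale: float = 1e3         # beads/ml per unit intensity
    ms_floor: float = 1e2         # detection floor, beads/ml
    exterior_factor: float = 30.0
    molecular_halfsat: float = 1.0
    pft_measured_prob: float = 0.6
    pcr_prob: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValidationError("n_samples must be >= 0")
        if self.depth_max <= 0:
            raise ValidationError("depth_max must be > 0")
        if not 0 <= self.p_epcs + self.p_escs <= 1:
            raise ValidationError("coring-system probabilities must sum within [0, 1]")
        for name in ("pft_scale", "pft_floor", "ms_scale", "ms_floor",
                     "exterior_factor", "molecular_halfsat"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")


@dataclass(frozen=True)
class TracerTruth:
    sample_id: str
    intensity: float
    temperature: float
    microspheres_censored: bool


def make_tracer_table(
    spec: TracerTableSpec, thermal: ThermalProfile
) -> tuple[AssessmentTable, list[TracerTruth]]:
    """Simulate a tracer table plus its latent truth."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    if n == 0:
        return AssessmentTable([], provenance="synthetic tracer table"), []

    depths = np.sort(rng.uniform(0.0, spec.depth_max, size=n))
    depths += np.arange(n) * 1e-6  # guarantee distinct record keys
    system_pool = [CoringSystem.HPCS, CoringSystem.EPCS, CoringSystem.ESCS]
    system_idx = rng.choice(
        3, size=n, p=[1 - spec.p_epcs - spec.p_escs, spec.p_epcs, spec.p_escs]
    )
    systems = [system_pool[int(k)] for k in system_idx]
    intensity = rng.lognormal(spec.intensity_mu, spec.intensity_sigma, size=n)

    def noisy(x: float) -> float:
        return float(x * rng.lognormal(0.0, spec.channel_noise_sigma))

    records: list[CoreSampleRecord] = []
    truths: list[TracerTruth] = []
    for i in range(n):
        lam = float(intensity[i])
        depth = float(depths[i])
        system = systems[i]
        temp = temperature_at_depth(thermal, depth)
        censored = temp >= MICROSPHERE_GLASS_TRANSITION_C

        def channel(scale: float, floor: float) -> TracerResult:
            value = noisy(lam * scale)
            if value >= floor:
                return TracerResult.detected(value)
            return TracerResult.not_detected()

        if rng.random() < spec.pft_measured_prob:
            pft_in = channel(spec.pft_scale, spec.pft_floor)
            pft_ex = channel(spec.pft_scale * spec.exterior_factor, spec.pft_floor)
        else:
            pft_in = pft_ex = TracerResult.not_measured()

        if system is CoringSystem.HPCS:
            ms_in = channel(spec.ms_scale, spec.ms_floor)
            ms_ex = channel(spec.ms_scale * spec.exterior_factor, spec.ms_floor)
            if censored:
                ms_in = TracerResult.not_detected()
                ms_ex = TracerResult.not_detected()
        else:
            ms_in = ms_ex = TracerResult.not_measured()

        if rng.random() < spec.pcr_prob:
            amplified = True
            pct = 100.0 * lam / (lam + spec.molecular_halfsat)
        else:
            amplified = None
            pct = None

        hole = "S0001A"
        section = f"{1 + i // 9}H-{1 + i % 9}"
        records.append(
            CoreSampleRecord(
                hole=hole,
                section=section,
                coring_system=system,
                depth_mbsf=depth,
                lithology="synthetic hemipelagic mud",
                ms_interior=ms_in,
                ms_exterior=ms_ex,
                pft_interior=pft_in,
                pft_exterior=pft_ex,
                pcr_amplified=amplified,
                molecular_contamination_pct=pct,
            )
        )
        truths.append(
            TracerTruth(
                sample_id=f"{hole}-{section}",
                intensity=lam,
                temperature=temp,
                microspheres_censored=censored,
            )
        )
    return AssessmentTable(records, provenance="synthetic tracer table"), truths
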