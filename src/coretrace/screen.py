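"""Molecular contamination screening of 16S rRNA gene clone libraries.

The drilling-fluid communities serve as a molecular tracer: every clone in a
core library is compared against the pooled drilling-fluid clones, and clones
whose best pairwise identity exceeds the screening threshold (strictly more
than 97% by default) are flagged as potential contaminants. The contamination
level of a library is the percentage of flagged clones.

Also here: OTU assignment by complete-linkage (furthest-neighbour) clustering
at the same threshold, analytic rarefaction of the resulting OTU size
spectrum, clonal composition summaries, and FASTA I/O for libraries.
"""

from __future__ import annotations

import enum

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import gammaln

from ._alignment import alignment_stats, encode_sequence, identity_from_stats

__all__ = [
    "LibrarySource",
    "MudType",
    "TruthLabel",
    "CloneSequence",
    "CloneLibrary",
    "OtuPartition",
    "ContaminantCall",
    "ScreenResult",
    "RarefactionCurve",
    "ScreeningUnit",
    "AlignmentScoring",
    "pairwise_identity",
    "identity_matrix",
    "assign_otus",
    "screen_contaminants",
    "rarefaction",
    "composition_summary",
    "read_fasta_library",
    "write_fasta_library",
    "write_screen_tsv",
    "write_rarefaction_tsv",
]

DEFAULT_THRESHOLD = 0.97


class LibrarySource(enum.Enum):
    DRILLING_FLUID = "DRILLING_FLUID"
    CORE = "CORE"


class MudType(enum.Enum):
    GUAR_GUM = "GUAR_GUM"          # seawater + guar gum; near-monodominant
    SEAWATER_GEL = "SEAWATER_GEL"  # freshwater + bentonite; diverse


class TruthLabel(enum.Enum):
    MUD_DERIVED = "MUD_DERIVED"
    INDIGENOUS = "INDIGENOUS"


class ScreeningUnit(enum.Enum):
    CLONE = "CLONE"
    OTU_REPRESENTATIVE = "OTU_REPRESENTATIVE"


@dataclass(frozen=True)
class AlignmentScoring:
    """End-to-end global-alignment scoring (see ``_alignment``).

    Every gap column is scored, terminal ones included; terminal-gap
    columns are nevertheless excluded from the identity ratio.
    """

    match: int = 1
    mismatch: int = -1
    gap: int = -2


@dataclass(frozen=True)
class CloneSequence:
    id: str
    sequence: str
    truth_label: Optional[TruthLabel] = None
    taxon: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("clone id must be non-empty")
        if not self.sequence:
            raise ValueError(f"clone {self.id!r}: sequence must be non-empty")
        encode_sequence(self.sequence)  # validates the alphabet

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CloneLibrary:
    sample_id: str
    source: LibrarySource
    clones: list[CloneSequence] = field(default_factory=list)
    mud_type: Optional[MudType] = None
    primer_set: str = "Uni530F-907R"

    def __post_init__(self) -> None:
        ids = [c.id for c in self.clones]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate clone id {dup!r} in library {self.sample_id!r}")

    def __len__(self) -> int:
        return len(self.clones)

    def __iter__(self):
        return iter(self.clones)


@dataclass(frozen=True)
class OtuPartition:
    threshold: float
    assignments: Mapping[str, int]          # clone id -> OTU index
    representatives: Mapping[int, str]      # OTU index -> clone id

    @property
    def n_otus(self) -> int:
        return len(self.representatives)

    def sizes(self) -> list[int]:
        counts = Counter(self.assignments.values())
        return [counts[i] for i in sorted(counts)]


@dataclass(frozen=True)
class ContaminantCall:
    clone_id: str
    best_hit_id: Optional[str]
    best_identity: float
    is_contaminant: bool


@dataclass(frozen=True)
class ScreenResult:
    sample_id: str
    threshold: float
    calls: tuple[ContaminantCall, ...]

    @property
    def n_clones(self) -> int:
        return len(self.calls)

    @property
    def n_contaminant(self) -> int:
        return sum(c.is_contaminant for c in self.calls)

    @property
    def contamination_level_pct(self) -> float:
        return 100.0 * self.n_contaminant / self.n_clones

    @property
    def contamination_level_pct_rounded(self) -> int:
        """Report-time value: nearest integer percent."""
        return int(round(self.contamination_level_pct))

    def to_summary(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "threshold": self.threshold,
            "n_clones": self.n_clones,
            "n_contaminant": self.n_contaminant,
            "contamination_level_pct": self.contamination_level_pct,
            "contamination_level_pct_rounded": self.contamination_level_pct_rounded,
        }


@dataclass(frozen=True)
class RarefactionCurve:
    points: tuple[tuple[int, float], ...]  # (subsample size n, E[S_n])
    total_clones: int
    observed_otus: int


def pairwise_identity(
    a: CloneSequence | str,
    b: CloneSequence | str,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> float:
    """Identity fraction of the optimal end-to-end global alignment.

    Matched columns over alignment columns, excluding terminal-gap
    columns from the ratio. Symmetric, equals 1.0 on identical sequences,
    and deterministic: among co-optimal alignments the one maximising
    (matches, then fewest interior gap columns, then most terminal gap
    columns) defines the value.
    """
    sa = a.sequence if isinstance(a, CloneSequence) else a
    sb = b.sequence if isinstance(b, CloneSequence) else b
    if not sa or not sb:
        raise ValueError("pairwise identity requires non-empty sequences")
    stats = alignment_stats(
        encode_sequence(sa), encode_sequence(sb),
        scoring.match, scoring.mismatch, scoring.gap,
    )
    return identity_from_stats(*stats, scoring.match, scoring.mismatch, scoring.gap)


def identity_matrix(
    clones: Sequence[CloneSequence], scoring: AlignmentScoring = AlignmentScoring()
) -> np.ndarray:
    """Symmetric matrix of pairwise identities (1.0 on the diagonal)."""
    n = len(clones)
    encoded = [encode_sequence(c.sequence) for c in clones]
    out = np.ones((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            stats = alignment_stats(
                encoded[i], encoded[j], scoring.match, scoring.mismatch, scoring.gap
            )
            out[i, j] = out[j, i] = identity_from_stats(
                *stats, scoring.match, scoring.mismatch, scoring.gap
            )
    return out


def assign_otus(
    lib: CloneLibrary,
    threshold: float = DEFAULT_THRESHOLD,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> OtuPartition:
    """Complete-linkage OTU assignment at the similarity threshold.

    Clusters are cut so that every intra-OTU pairwise identity is at least
    the threshold (furthest-neighbour merges stop once the worst pair in a
    candidate cluster would fall below it). OTU indices follow first
    appearance in library order; each OTU is represented by its
    lexicographically smallest clone id.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if len(lib) == 0:
        raise ValueError("cannot assign OTUs in an empty library")
    clones = lib.clones
    if len(clones) == 1:
        return OtuPartition(threshold, {clones[0].id: 0}, {0: clones[0].id})

    ident = identity_matrix(clones, scoring)
    dist = 1.0 - ident
    n = len(clones)
    condensed = dist[np.triu_indices(n, k=1)]
    tree = linkage(condensed, method="complete")
    # strict cut: identities exactly at the threshold do not merge
    cut = (1.0 - threshold) * (1.0 - 1e-12)
    labels = fcluster(tree, t=cut, criterion="distance")

    assignments: dict[str, int] = {}
    remap: dict[int, int] = {}
    for clone, lab in zip(clones, labels):
        if lab not in remap:
            remap[lab] = len(remap)
        assignments[clone.id] = remap[lab]
    representatives = {
        otu: min(cid for cid, o in assignments.items() if o == otu)
        for otu in set(assignments.values())
    }
    return OtuPartition(threshold, assignments, representatives)


def _pool_references(mud_refs: Sequence[CloneLibrary]) -> list[tuple[str, CloneSequence]]:
    pooled: list[tuple[str, CloneSequence]] = []
    for lib in mud_refs:
        for clone in lib.clones:
            pooled.append((lib.sample_id, clone))
    return pooled


def screen_contaminants(
    core: CloneLibrary,
    mud_refs: Sequence[CloneLibrary] | CloneLibrary,
    threshold: float = DEFAULT_THRESHOLD,
    unit: ScreeningUnit = ScreeningUnit.CLONE,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> ScreenResult:
    """Call potential contaminants in a core library against pooled mud clones.

    Each core clone receives its best identity over every drilling-fluid
    clone; it is a contaminant iff that identity is *strictly greater* than
    the threshold. In OTU_REPRESENTATIVE mode the core library is first
    clustered at the same threshold, only OTU representatives are aligned,
    and each clone inherits its representative's call.

    Screening against an empty reference pool is undefined and raises — it
    is not a 0% result.
    """
    if isinstance(mud_refs, CloneLibrary):
        mud_refs = [mud_refs]
    if len(core) == 0:
        raise ValueError("cannot screen an empty core library")
    pooled = _pool_references(mud_refs)
    if not pooled:
        raise ValueError("empty drilling-fluid reference: screening is undefined")
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")

    ref_encoded = [(clone.id, encode_sequence(clone.sequence)) for _, clone in pooled]

    def best_hit(seq: str) -> tuple[Optional[str], float]:
        enc = encode_sequence(seq)
        best_id: Optional[str] = None
        best = -1.0
        for rid, renc in ref_encoded:
            stats = alignment_stats(
                enc, renc, scoring.match, scoring.mismatch, scoring.gap
            )
            ident = identity_from_stats(
                *stats, scoring.match, scoring.mismatch, scoring.gap
            )
            if ident > best:
                best, best_id = ident, rid
        return best_id, best

    calls: list[ContaminantCall] = []
    if unit is ScreeningUnit.CLONE:
        for clone in core.clones:
            hit, ident = best_hit(clone.sequence)
            calls.append(ContaminantCall(clone.id, hit, ident, ident > threshold))
    else:
        partition = assign_otus(core, threshold=threshold, scoring=scoring)
        by_id = {c.id: c for c in core.clones}
        rep_calls: dict[int, tuple[Optional[str], float]] = {}
        for otu, rep_id in partition.representatives.items():
            rep_calls[otu] = best_hit(by_id[rep_id].sequence)
        for clone in core.clones:
            hit, ident = rep_calls[partition.assignments[clone.id]]
            calls.append(ContaminantCall(clone.id, hit, ident, ident > threshold))

    return ScreenResult(core.sample_id, threshold, tuple(calls))


def rarefaction(otu_sizes: Sequence[int], subsample_sizes: Sequence[int] | None = None) -> RarefactionCurve:
    """Analytic (hypergeometric) rarefaction of an OTU size spectrum.

    The expected OTU richness in a random subsample of n clones drawn
    without replacement from N = sum(N_i) clones is

        E[S_n] = sum_i [ 1 - C(N - N_i, n) / C(N, n) ].

    Exact at the endpoints: E[S_1] = 1 and E[S_N] = observed richness.
    """
    sizes = np.asarray(otu_sizes, dtype=np.int64)
    if sizes.size == 0:
        raise ValueError("otu_sizes must be non-empty")
    if np.any(sizes <= 0):
        raise ValueError("all OTU sizes must be positive integers")
    total = int(sizes.sum())
    if subsample_sizes is None:
        ns = np.arange(1, total + 1)
    else:
        ns = np.asarray(sorted(set(int(n) for n in subsample_sizes)), dtype=np.int64)
        if ns.size == 0 or ns[0] < 1 or ns[-1] > total:
            raise ValueError("subsample sizes must lie in [1, total clones]")

    def log_choose(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
        n = np.asarray(n, dtype=float)
        k = np.asarray(k, dtype=float)
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    points = []
    log_cn = log_choose(total, ns)
    for n, lcn in zip(ns, log_cn):
        keep = sizes <= total - n  # otherwise C(N - N_i, n) = 0: OTU always seen
        miss = np.zeros(sizes.shape, dtype=float)
        if np.any(keep):
            miss[keep] = np.exp(log_choose(total - sizes[keep], int(n)) - lcn)
        points.append((int(n), float(np.sum(1.0 - miss))))
    return RarefactionCurve(tuple(points), total, int(sizes.size))


def composition_summary(
    lib: CloneLibrary, labels: Mapping[str, str] | None = None
) -> dict[str, float]:
    """Clonal fraction per group label; labels default to clone taxon fields."""
    if len(lib) == 0:
        return {}
    resolved: list[str] = []
    for clone in lib.clones:
        if labels is not None:
            if clone.id not in labels:
                raise ValueError(f"missing label for clone {clone.id!r}")
            resolved.append(labels[clone.id])
        else:
            if clone.taxon is None:
                raise ValueError(f"clone {clone.id!r} carries no taxon label")
            resolved.append(clone.taxon)
    counts = Counter(resolved)
    n = len(lib)
    return {label: counts[label] / n for label in sorted(counts)}


# ---------------------------------------------------------------------------
# FASTA and tabular I/O
# ---------------------------------------------------------------------------

def write_fasta_library(lib: CloneLibrary, path: str | Path) -> Path:
    """Write a library as FASTA; truth labels and taxa ride the description."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    path = Path(path)
    seq_records = []
    for clone in lib.clones:
        desc_parts = []
        if clone.truth_label is not None:
            desc_parts.append(f"label={clone.truth_label.value}")
        if clone.taxon is not None:
            desc_parts.append(f"taxon={clone.taxon}")
        seq_records.append(
            SeqRecord(Seq(clone.sequence), id=clone.id, description=" ".join(desc_parts))
        )
    with path.open("w") as fh:
        seqio_write(seq_records, fh, "fasta")
    return path


def read_fasta_library(
    path: str | Path,
    sample_id: str | None = None,
    source: LibrarySource = LibrarySource.CORE,
    mud_type: Optional[MudType] = None,
) -> CloneLibrary:
    """Read a clone library from FASTA, recovering any embedded truth labels."""
    from Bio.SeqIO import parse as seqio_parse

    path = Path(path)
    clones: list[CloneSequence] = []
    for rec in seqio_parse(str(path), "fasta"):
        label: Optional[TruthLabel] = None
        taxon: Optional[str] = None
        for token in rec.description.split()[1:]:
            if token.startswith("label="):
                label = TruthLabel(token.removeprefix("label="))
            elif token.startswith("taxon="):
                taxon = token.removeprefix("taxon=")
        clones.append(CloneSequence(rec.id, str(rec.seq).upper(), label, taxon))
    return CloneLibrary(
        sample_id=sample_id or path.stem, source=source, clones=clones, mud_type=mud_type
    )


def write_screen_tsv(result: ScreenResult, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("clone_id\tbest_hit_id\tidentity\tis_contaminant\n")
        for call in result.calls:
            fh.write(
                f"{call.clone_id}\t{call.best_hit_id or ''}\t"
                f"{call.best_identity:.6f}\t{str(call.is_contaminant).lower()}\n"
            )
    return path


def write_rarefaction_tsv(curve: RarefactionCurve, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("n\texpected_otus\n")
        for n, s in curve.points:
            fh.write(f"{n}\t{s:.6f}\n")
    return path
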