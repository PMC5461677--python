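"""Putative species delimitation and morphotype-to-morphospecies grouping.

Delimitation is single-linkage clustering of a between-population divergence
matrix: two populations belong to the same putative species whenever they
are chained by pairwise divergences at or below the threshold.  Sex-separated
morphotypes are merged into morphospecies by minimum cross-sex sequence
divergence, and all-female morphospecies with enough specimens are flagged
as thelytoky candidates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .errors import InputError
from .seqdiv import AlignedSeqSet, DivergenceMatrix, p_distance

THELYTOKOUS = "thelytokous-candidate"
SEXUAL = "sexual"
UNDETERMINED = "undetermined"


@dataclass
class SpeciesPartition:
    """Clusters of population labels deemed one putative species each."""

    morphospecies: str
    threshold: float
    clusters: list[tuple[str, ...]]

    def __post_init__(self) -> None:
        flat = [m for c in self.clusters for m in c]
        if len(flat) != len(set(flat)):
            raise InputError("clusters are not disjoint")

    @property
    def labels(self) -> list[str]:
        return sorted(m for c in self.clusters for m in c)

    @property
    def n_species(self) -> int:
        return len(self.clusters)

    def cluster_of(self, label: str) -> tuple[str, ...]:
        for c in self.clusters:
            if label in c:
                return c
        raise KeyError(label)


def single_linkage_partition(
    D: DivergenceMatrix, threshold: float, morphospecies: str = ""
) -> SpeciesPartition:
    """Connected components of the graph with edges where D(g, h) <= threshold."""
    if threshold < 0:
        raise InputError("threshold must be non-negative")
    labels = D.labels
    parent = list(range(len(labels)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(labels)), 2):
        if D.values[i, j] <= threshold:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri

    comps: dict[int, list[str]] = {}
    for i, lab in enumerate(labels):
        comps.setdefault(find(i), []).append(lab)
    clusters = sorted(
        (tuple(sorted(members)) for members in comps.values()),
        key=lambda c: c[0],
    )
    return SpeciesPartition(
        morphospecies=morphospecies, threshold=threshold, clusters=clusters
    )


@dataclass
class SpeciesCountSummary:
    counts: dict[str, int]
    total: int
    n_morphospecies: int
    ratio: float


def count_putative_species(
    partitions: list[SpeciesPartition], focal: set[str] | None = None
) -> SpeciesCountSummary:
    """Per-morphospecies species counts plus the delimited-to-morphospecies ratio.

    ``focal`` restricts the ratio to a genus of interest (e.g. the
    *Psyllaephagus* morphospecies); by default all partitions count.
    """
    thresholds = {p.threshold for p in partitions}
    if len(thresholds) > 1:
        raise InputError(
            f"partitions computed at different thresholds: {sorted(thresholds)}"
        )
    counts = {p.morphospecies: p.n_species for p in partitions}
    focal_names = sorted(focal) if focal is not None else sorted(counts)
    missing = [f for f in focal_names if f not in counts]
    if missing:
        raise InputError(f"no partition for focal morphospecies {missing}")
    focal_total = sum(counts[f] for f in focal_names)
    return SpeciesCountSummary(
        counts=counts,
        total=sum(counts.values()),
        n_morphospecies=len(focal_names),
        ratio=focal_total / len(focal_names),
    )


@dataclass
class MorphotypeRecord:
    """A sex-specific morphotype with its specimen count and sequence ids."""

    morphotype: str
    sex: str
    host_population: str | None = None
    count: int = 0
    seq_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise InputError(f"sex must be female or male, got {self.sex!r}")
        if self.count < 0:
            raise InputError("count must be non-negative")


@dataclass
class MorphospeciesGroup:
    name: str
    female_morphotypes: list[str]
    male_morphotypes: list[str]
    female_count: int
    male_count: int
    flag: str  # "both-sexes" | "female-only" | "male-only"


def _min_cross_distance(
    a: MorphotypeRecord, b: MorphotypeRecord, seqs: AlignedSeqSet
) -> float:
    return min(
        p_distance(seqs.get(i), seqs.get(j)) for i in a.seq_ids for j in b.seq_ids
    )


def match_morphotypes(
    morphotypes: list[MorphotypeRecord],
    seqs: AlignedSeqSet,
    max_divergence: float = 2.0,
) -> tuple[list[MorphospeciesGroup], list[MorphotypeRecord]]:
    """Merge female and male morphotypes by genotype matching.

    Cross-sex pairs with minimum p-distance <= ``max_divergence`` are merged
    greedily in order of increasing distance; leftovers become single-sex
    morphospecies.  Morphotypes lacking sequence data are returned separately
    as unassignable.
    """
    unassignable = [m for m in morphotypes if not m.seq_ids]
    usable = [m for m in morphotypes if m.seq_ids]
    females = [m for m in usable if m.sex == "female"]
    males = [m for m in usable if m.sex == "male"]

    pairs = sorted(
        (
            (_min_cross_distance(f, m, seqs), f.morphotype, m.morphotype)
            for f in females
            for m in males
        ),
        key=lambda t: (t[0], t[1], t[2]),
    )
    taken_f: set[str] = set()
    taken_m: set[str] = set()
    groups: list[MorphospeciesGroup] = []
    by_name = {m.morphotype: m for m in usable}
    for dist, fname, mname in pairs:
        if dist > max_divergence or fname in taken_f or mname in taken_m:
            continue
        taken_f.add(fname)
        taken_m.add(mname)
        groups.append(
            MorphospeciesGroup(
                name=f"{fname}+{mname}",
                female_morphotypes=[fname],
                male_morphotypes=[mname],
                female_count=by_name[fname].count,
                male_count=by_name[mname].count,
                flag="both-sexes",
            )
        )
    for f in females:
        if f.morphotype not in taken_f:
            groups.append(
                MorphospeciesGroup(
                    name=f.morphotype,
                    female_morphotypes=[f.morphotype],
                    male_morphotypes=[],
                    female_count=f.count,
                    male_count=0,
                    flag="female-only",
                )
            )
    for m in males:
        if m.morphotype not in taken_m:
            groups.append(
                MorphospeciesGroup(
                    name=m.morphotype,
                    female_morphotypes=[],
                    male_morphotypes=[m.morphotype],
                    female_count=0,
                    male_count=m.count,
                    flag="male-only",
                )
            )
    groups.sort(key=lambda g: g.name)
    return groups, unassignable


def infer_thelytoky(
    female_count: int, male_count: int, min_females: int = 5
) -> str:
    """Flag all-female morphospecies with enough specimens as thelytoky candidates."""
    if male_count > 0:
        return SEXUAL
    if female_count >= min_females:
        return THELYTOKOUS
    return UNDETERMINED


def infer_thelytoky_for_groups(
    groups: list[MorphospeciesGroup], min_females: int = 5
) -> dict[str, str]:
    return {
        g.name: infer_thelytoky(g.female_count, g.male_count, min_females)
        for g in groups
    }
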