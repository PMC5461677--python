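"""Synthetic data with the statistical structure the pipeline expects.

Host trees are Yule (pure-birth) trees; parasite trees track the host tree
with configurable loss and host-switch probabilities at each host divergence;
sequences evolve under Jukes-Cantor; mummy tables are drawn from known
trophic roles with species-specific detection probabilities.  Everything is
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import InputError
from .seqdiv import AlignedSeqSet, SeqRecord
from .trophic import (
    HETERONOMOUS,
    HYPERPARASITOID,
    PRIMARY,
    PSYLLID,
    MummyRecord,
)
from .cophylo import AssociationMatrix


# ---------------------------------------------------------------------------
# host tree


def simulate_host_tree(
    n_hosts: int,
    birth_rate: float = 1.0,
    seed: int | None = None,
    prefix: str = "H",
) -> dendropy.Tree:
    """Ultrametric Yule tree: with k lineages the next split waits Exp(k*rate)."""
    if n_hosts < 3:
        raise InputError("n_hosts must be at least 3")
    if birth_rate <= 0:
        raise InputError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    born: dict[int, float] = {}
    root = tree.seed_node
    active: list[dendropy.Node] = []
    t = 0.0
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        born[id(child)] = t
        active.append(child)
    while len(active) < n_hosts:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        node = active.pop(int(rng.integers(k)))
        node.edge.length = t - born[id(node)]
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            born[id(child)] = t
            active.append(child)
    t += rng.exponential(1.0 / (n_hosts * birth_rate))
    for i, node in enumerate(active, start=1):
        node.edge.length = t - born[id(node)]
        node.taxon = tns.new_taxon(label=f"{prefix}{i}")
    root.edge.length = None
    return tree


# ---------------------------------------------------------------------------
# parasite evolution on a host tree


@dataclass
class SimulatedCophylo:
    parasite_tree: dendropy.Tree | None
    association: AssociationMatrix | None
    true_events: dict[str, int]
    empty: bool


@dataclass
class _Lineage:
    host_node: dendropy.Node
    born: float
    parent: dendropy.Node | None  # parasite parent node, None before first split


def _node_times(tree: dendropy.Tree) -> dict[int, float]:
    times: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        parent_t = times.get(id(node.parent_node), 0.0)
        times[id(node)] = parent_t + (node.edge.length or 0.0)
    return times


def simulate_parasite_evolution(
    host: dendropy.Tree,
    p_switch: float = 0.0,
    p_loss: float = 0.0,
    seed: int | None = None,
    prefix: str = "P",
) -> SimulatedCophylo:
    """Track host divergences: codiverge, go extinct, or switch hosts.

    At each host divergence a resident parasite lineage is lost with
    ``p_loss``, otherwise diverges; with ``p_switch`` one daughter jumps to a
    uniformly chosen contemporary host branch instead of following a host
    child.  Duplications arise implicitly when a switch puts two parasite
    lineages on one host branch.
    """
    if not (0 <= p_switch <= 1 and 0 <= p_loss <= 1 and p_switch + p_loss <= 1):
        raise InputError("p_switch and p_loss must be probabilities summing to <= 1")
    rng = np.random.default_rng(seed)
    times = _node_times(host)
    internal = sorted(
        (n for n in host.preorder_node_iter() if n.child_nodes()),
        key=lambda n: (times[id(n)], id(n)),
    )
    leaves = list(host.leaf_node_iter())
    tip_time = max(times[id(l)] for l in leaves)

    tns = dendropy.TaxonNamespace()
    ptree = dendropy.Tree(taxon_namespace=tns)
    events = {"codivergence": 0, "loss": 0, "host_switch": 0, "decisions": 0}
    lineages: list[_Lineage] = [_Lineage(host_node=host.seed_node, born=0.0, parent=None)]

    def alive_edges(t: float) -> list[dendropy.Node]:
        out = []
        for node in host.preorder_node_iter():
            if node.parent_node is None:
                continue
            if times[id(node.parent_node)] <= t < times[id(node)]:
                out.append(node)
        return out

    def divergence_node(lin: _Lineage, t: float) -> dendropy.Node:
        if lin.parent is None:
            node = ptree.seed_node
            node.edge.length = None
        else:
            node = dendropy.Node()
            lin.parent.add_child(node)
            node.edge.length = t - lin.born
        return node

    for h in internal:
        t = times[id(h)]
        resident = [l for l in lineages if l.host_node is h]
        if not resident:
            continue
        children = h.child_nodes()
        for lin in resident:
            lineages.remove(lin)
            events["decisions"] += 1
            u = rng.random()
            if u < p_loss:
                events["loss"] += 1
                continue
            pnode = divergence_node(lin, t)
            if u < p_loss + p_switch:
                events["host_switch"] += 1
                stay_idx = int(rng.integers(len(children)))
                stay = children[stay_idx]
                pool = [e for e in alive_edges(t) if e is not stay]
                target = pool[int(rng.integers(len(pool)))] if pool else stay
                lineages.append(_Lineage(host_node=stay, born=t, parent=pnode))
                lineages.append(_Lineage(host_node=target, born=t, parent=pnode))
            else:
                events["codivergence"] += 1
                for child in children:
                    lineages.append(_Lineage(host_node=child, born=t, parent=pnode))

    # surviving lineages sit on host tip branches; make them parasite tips
    survivors = [l for l in lineages if not l.host_node.child_nodes()]
    links = []
    label_order = {id(l): i for i, l in enumerate(leaves)}
    survivors.sort(key=lambda l: (label_order[id(l.host_node)], l.born))
    for i, lin in enumerate(survivors, start=1):
        label = f"{prefix}{i}"
        if lin.parent is None:
            continue  # single never-diverged lineage; degenerate tree
        node = dendropy.Node()
        lin.parent.add_child(node)
        node.edge.length = tip_time - lin.born
        node.taxon = tns.new_taxon(label=label)
        links.append((label, lin.host_node.taxon.label))

    n_tips = len(links)
    if n_tips < 2:
        return SimulatedCophylo(
            parasite_tree=None, association=None, true_events=events, empty=True
        )
    ptree.suppress_unifurcations()
    assoc = AssociationMatrix.from_links(
        links,
        parasite_labels=[p for p, _ in links],
        host_labels=[l.taxon.label for l in leaves],
    )
    return SimulatedCophylo(
        parasite_tree=ptree, association=assoc, true_events=events, empty=False
    )


# ---------------------------------------------------------------------------
# sequence evolution


def evolve_sequences(
    tree: dendropy.Tree,
    length: int = 344,
    subst_rate: float = 1.0,
    seed: int | None = None,
    locus: str = "cytb",
) -> AlignedSeqSet:
    """Jukes-Cantor evolution along the tree; the root is uniform random.

    On a branch of length t each site changes with probability
    (3/4)(1 - exp(-4*rate*t/3)), landing uniformly on the other three bases.
    """
    if length < 50:
        raise InputError("sequence length must be at least 50")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seqs: dict[int, np.ndarray] = {}
    root = tree.seed_node
    seqs[id(root)] = rng.integers(0, 4, size=length)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length or 0.0
        p_change = 0.75 * (1.0 - np.exp(-4.0 * subst_rate * t / 3.0))
        parent_seq = seqs[id(node.parent_node)]
        seq = parent_seq.copy()
        mask = rng.random(length) < p_change
        n_changes = int(mask.sum())
        if n_changes:
            seq[mask] = (seq[mask] + rng.integers(1, 4, size=n_changes)) % 4
        seqs[id(node)] = seq
    records = []
    for gt, leaf in enumerate(tree.leaf_node_iter(), start=1):
        records.append(
            SeqRecord(
                id=leaf.taxon.label,
                residues="".join(bases[seqs[id(leaf)]]),
                host_population=leaf.taxon.label,
                genotype=gt,
                locus=locus,
            )
        )
    return AlignedSeqSet(locus=locus, records=records)


# ---------------------------------------------------------------------------
# mummy tables


@dataclass
class RoleSpec:
    """True trophic role of one morphospecies in the simulation."""

    role: str
    prey: str | None = None
    prey_by_sex: dict[str, str] | None = None
    sexes: tuple[str, ...] = ("female", "male")


def default_roles() -> dict[str, RoleSpec]:
    """The four-morphospecies community structure used throughout the tests."""
    return {
        "P1": RoleSpec(role=PRIMARY, prey=PSYLLID, sexes=("female",)),
        "P2": RoleSpec(role=PRIMARY, prey=PSYLLID),
        "H": RoleSpec(role=HYPERPARASITOID, prey="P2"),
        "HH": RoleSpec(
            role=HETERONOMOUS, prey_by_sex={"female": PSYLLID, "male": "P1"}
        ),
    }


def _validate_roles(roles: dict[str, RoleSpec]) -> None:
    for sp, spec in roles.items():
        if spec.role == HYPERPARASITOID:
            if spec.prey not in roles or roles[spec.prey].role != PRIMARY:
                raise InputError(
                    f"hyperparasitoid {sp!r} needs a primary-parasitoid prey"
                )
        elif spec.role == HETERONOMOUS:
            if not spec.prey_by_sex:
                raise InputError(f"heteronomous {sp!r} needs per-sex prey")
            for sex, prey in spec.prey_by_sex.items():
                if prey != PSYLLID and prey not in roles:
                    raise InputError(
                        f"heteronomous {sp!r} {sex} prey {prey!r} unknown"
                    )
        elif spec.role != PRIMARY:
            raise InputError(f"unknown role {spec.role!r} for {sp!r}")


def simulate_mummy_table(
    roles: dict[str, RoleSpec],
    n_per_stratum: int = 20,
    detect_prob: dict[str, float] | None = None,
    seed: int | None = None,
    host_species: str = "synthetic-host",
) -> list[MummyRecord]:
    """Draw a detection table from known roles.

    Informativeness is driven by the psyllid and emerged-species detection
    probabilities; within informative mummies the true prey's DNA is always
    present, mirroring the certainty of primary-parasitoid DNA in
    hyperparasitised mummies.
    """
    _validate_roles(roles)
    detect_prob = detect_prob or {}
    rng = np.random.default_rng(seed)
    targets = sorted(roles)
    records = []
    for sp in targets:
        spec = roles[sp]
        for sex in spec.sexes:
            if spec.role == HETERONOMOUS:
                prey = spec.prey_by_sex.get(sex, PSYLLID)
            else:
                prey = spec.prey
            prey_parasitoid = prey if prey not in (None, PSYLLID) else None
            for i in range(n_per_stratum):
                psyllid = rng.random() < detect_prob.get(PSYLLID, 1.0)
                emerged = rng.random() < detect_prob.get(sp, 1.0)
                informative = psyllid and emerged
                det = {t: False for t in targets}
                det[sp] = emerged
                if prey_parasitoid is not None:
                    det[prey_parasitoid] = (
                        True
                        if informative
                        else rng.random() < detect_prob.get(prey_parasitoid, 1.0)
                    )
                records.append(
                    MummyRecord(
                        mummy_id=f"{host_species}-{sp}-{sex}-{i + 1}",
                        host_species=host_species,
                        emerged_species=sp,
                        emerged_sex=sex,
                        psyllid_dna=psyllid,
                        detected=det,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# whole-scenario generation


@dataclass
class CophyloScenario:
    n_hosts: int = 6
    birth_rate: float = 1.0
    p_switch: float = 0.1
    p_loss: float = 0.05
    seed: int = 0
    seq_length: int = 344
    subst_rate: float = 0.05
    n_per_stratum: int = 20
    detect_prob: dict[str, float] = field(
        default_factory=lambda: {PSYLLID: 0.95, "P1": 0.25, "P2": 0.9, "H": 0.9, "HH": 0.9}
    )

    def __post_init__(self) -> None:
        if self.n_hosts < 3:
            raise InputError("n_hosts must be at least 3")
        for p in (self.p_switch, self.p_loss):
            if not 0 <= p <= 1:
                raise InputError("probabilities must lie in [0, 1]")


@dataclass
class SimulatedSystem:
    scenario: CophyloScenario
    host_tree: dendropy.Tree
    parasite_trees: dict[str, dendropy.Tree]
    associations: dict[str, AssociationMatrix]
    sequences: dict[str, AlignedSeqSet]
    roles: dict[str, RoleSpec]
    mummies: list[MummyRecord]
    true_events: dict[str, dict[str, int]]


def simulate_system(scenario: CophyloScenario) -> SimulatedSystem:
    """One internally consistent community: trees, links, sequences, mummies.

    P1 and P2 track the psyllid host tree; the hyperparasitoid H tracks P2's
    tree and the heteronomous HH tracks P1's, mirroring their trophic roles.
    """
    roles = default_roles()
    host = simulate_host_tree(
        scenario.n_hosts, scenario.birth_rate, seed=scenario.seed, prefix="H"
    )
    parasite_trees: dict[str, dendropy.Tree] = {}
    associations: dict[str, AssociationMatrix] = {}
    sequences: dict[str, AlignedSeqSet] = {}
    true_events: dict[str, dict[str, int]] = {}
    carrier = {"P1": host, "P2": host}
    for rank, sp in enumerate(["P1", "P2", "H", "HH"]):
        base = carrier.get(sp)
        if base is None:
            continue
        sim = simulate_parasite_evolution(
            base,
            p_switch=scenario.p_switch,
            p_loss=scenario.p_loss,
            seed=scenario.seed + 1000 + rank,
            prefix=f"{sp}_",
        )
        true_events[sp] = sim.true_events
        if sim.empty:
            continue
        parasite_trees[sp] = sim.parasite_tree
        associations[sp] = sim.association
        sequences[sp] = evolve_sequences(
            sim.parasite_tree,
            length=scenario.seq_length,
            subst_rate=scenario.subst_rate,
            seed=scenario.seed + 2000 + rank,
            locus="cytb",
        )
        if sp == "P2":
            carrier["H"] = sim.parasite_tree
        if sp == "P1":
            carrier["HH"] = sim.parasite_tree
    mummies = simulate_mummy_table(
        roles,
        n_per_stratum=scenario.n_per_stratum,
        detect_prob=scenario.detect_prob,
        seed=scenario.seed + 3000,
    )
    return SimulatedSystem(
        scenario=scenario,
        host_tree=host,
        parasite_trees=parasite_trees,
        associations=associations,
        sequences=sequences,
        roles=roles,
        mummies=mummies,
        true_events=true_events,
    )
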