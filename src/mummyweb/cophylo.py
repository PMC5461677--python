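"""Cophylogenetic congruence testing.

Distance-based tests (a global host-parasite congruence test on principal
coordinates, and a patristic-distance correlation test) with permutation
p-values, plus exhaustive event-based reconciliation of small rooted trees
counting codivergences, duplications, losses and host switches.

Trees are ``dendropy.Tree`` objects throughout; multi-host parasites are
handled as one link per host in the distance-based tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .errors import InputError, SizeError


# ---------------------------------------------------------------------------
# tree I/O


def read_newick(path: str | Path) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise InputError(f"cannot parse Newick file {path}: {exc}") from exc
    return _validate_tree(tree)


def tree_from_string(newick: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise InputError(f"cannot parse Newick string: {exc}") from exc
    return _validate_tree(tree)


def _validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(labels) < 2:
        raise InputError("tree must have at least 2 labelled tips")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise InputError(f"duplicate tip labels: {dupes}")
    if any(leaf.taxon is None for leaf in tree.leaf_node_iter()):
        raise InputError("tree has unlabelled tips")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise InputError("negative branch length")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# patristic distances


@dataclass
class DistMatrix:
    """Labelled symmetric distance matrix (patristic or arbitrary)."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise InputError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise InputError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise InputError("distance matrix has a non-zero diagonal")

    def reindex(self, labels: list[str]) -> "DistMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistMatrix(labels=list(labels), values=self.values[np.ix_(idx, idx)])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)


def patristic_distances(tree: dendropy.Tree) -> DistMatrix:
    """Sum of branch lengths along the unique tip-to-tip path."""
    leaves = list(tree.leaf_node_iter())
    labels = [l.taxon.label for l in leaves]
    # root-to-node depths; any edge without a length counts as 0
    depth: dict = {}
    for node in tree.preorder_node_iter():
        parent_depth = depth.get(node.parent_node, 0.0)
        depth[node] = parent_depth + (node.edge.length or 0.0)

    def ancestors(node) -> list:
        path = []
        while node is not None:
            path.append(node)
            node = node.parent_node
        return path

    anc = {leaf: ancestors(leaf) for leaf in leaves}
    anc_sets = {leaf: set(map(id, anc[leaf])) for leaf in leaves}
    n = len(leaves)
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = leaves[i], leaves[j]
        lca = next(node for node in anc[a] if id(node) in anc_sets[b])
        d = depth[a] + depth[b] - 2.0 * depth[lca]
        values[i, j] = values[j, i] = d
    return DistMatrix(labels=labels, values=values)


# ---------------------------------------------------------------------------
# association matrices


@dataclass
class AssociationMatrix:
    """Binary parasite (rows) x host (columns) association links."""

    parasite_labels: list[str]
    host_labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        if self.matrix.shape != (len(self.parasite_labels), len(self.host_labels)):
            raise InputError("association matrix shape does not match labels")
        if not np.isin(self.matrix, (0, 1)).all():
            raise InputError("association matrix must be binary")

    def links(self) -> list[tuple[str, str]]:
        out = []
        for i, p in enumerate(self.parasite_labels):
            for j, h in enumerate(self.host_labels):
                if self.matrix[i, j]:
                    out.append((p, h))
        return out

    def require_full_coverage(self, columns: bool = True) -> None:
        if (self.matrix.sum(axis=1) == 0).any():
            empty = [
                p
                for p, s in zip(self.parasite_labels, self.matrix.sum(axis=1))
                if s == 0
            ]
            raise InputError(f"parasites with no host link: {empty}")
        if columns and (self.matrix.sum(axis=0) == 0).any():
            empty = [
                h
                for h, s in zip(self.host_labels, self.matrix.sum(axis=0))
                if s == 0
            ]
            raise InputError(f"hosts with no parasite link: {empty}")

    def drop_unlinked_hosts(self) -> "AssociationMatrix":
        """Subset to host columns with at least one link."""
        keep = self.matrix.sum(axis=0) > 0
        return AssociationMatrix(
            parasite_labels=list(self.parasite_labels),
            host_labels=[h for h, k in zip(self.host_labels, keep) if k],
            matrix=self.matrix[:, keep],
        )

    @classmethod
    def from_links(
        cls,
        links: list[tuple[str, str]],
        parasite_labels: list[str] | None = None,
        host_labels: list[str] | None = None,
    ) -> "AssociationMatrix":
        ps = parasite_labels or sorted({p for p, _ in links})
        hs = host_labels or sorted({h for _, h in links})
        m = np.zeros((len(ps), len(hs)), dtype=int)
        for p, h in links:
            m[ps.index(p), hs.index(h)] = 1
        return cls(parasite_labels=ps, host_labels=hs, matrix=m)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.matrix, index=self.parasite_labels, columns=self.host_labels
        ).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AssociationMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            parasite_labels=[str(x) for x in df.index],
            host_labels=[str(x) for x in df.columns],
            matrix=df.to_numpy(dtype=int),
        )


# ---------------------------------------------------------------------------
# permutation tests


@dataclass
class CophyloResult:
    method: str
    statistic: float
    p_value: float | None
    n_permutations: int
    seed: int | None
    per_link_stats: list[dict] | None = None
    warnings: list[str] = field(default_factory=list)
    undefined: bool = False

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": None if np.isnan(self.statistic) else self.statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "per_link_stats": self.per_link_stats,
            "warnings": self.warnings,
            "undefined": self.undefined,
        }


_NEG_EIGENMASS_WARN = 0.05


def _pcoa_axes(D: np.ndarray) -> tuple[np.ndarray, float]:
    """Principal-coordinate axes of a distance matrix (Gower centring).

    Returns the coordinates on non-negative-eigenvalue axes and the relative
    negative eigenvalue mass.
    """
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    eigval, eigvec = np.linalg.eigh((G + G.T) / 2.0)
    total = np.abs(eigval).sum()
    neg_mass = float(np.abs(eigval[eigval < 0]).sum() / total) if total > 0 else 0.0
    tol = max(np.abs(eigval).max(), 1.0) * 1e-10
    keep = eigval > tol
    axes = eigvec[:, keep] * np.sqrt(eigval[keep])
    return axes, neg_mass


def parafit_statistic(
    B_parasite: np.ndarray, A: np.ndarray, B_host: np.ndarray
) -> float:
    """Sum of squared entries of the fourth-corner matrix B_p' A B_h."""
    D = B_parasite.T @ A @ B_host
    return float((D**2).sum())


def parafit(
    D_host: DistMatrix,
    D_parasite: DistMatrix,
    assoc: AssociationMatrix,
    n_perm: int = 10000,
    seed: int | None = None,
    per_link: bool = False,
    allow_unlinked_hosts: bool = False,
) -> CophyloResult:
    """Global host-parasite congruence test on principal coordinates.

    The null hypothesis is independence of parasite and host diversification:
    each parasite's host assignments are permuted independently across hosts.

    ``allow_unlinked_hosts`` keeps host columns without any link in the
    permutation space instead of rejecting them; calibration experiments need
    this so the permutation null matches an iid-host generative null exactly.
    """
    if n_perm < 99:
        raise InputError("n_perm must be at least 99")
    assoc.require_full_coverage(columns=not allow_unlinked_hosts)
    Dh = D_host.reindex(assoc.host_labels)
    Dp = D_parasite.reindex(assoc.parasite_labels)
    B_h, neg_h = _pcoa_axes(Dh.values)
    B_p, neg_p = _pcoa_axes(Dp.values)
    warnings = []
    for name, mass in (("host", neg_h), ("parasite", neg_p)):
        if mass > _NEG_EIGENMASS_WARN:
            warnings.append(
                f"{name} distance matrix has {mass:.1%} negative eigenvalue mass"
            )
    A = assoc.matrix.astype(float)
    observed = parafit_statistic(B_p, A, B_h)

    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        A_perm = rng.permuted(A, axis=1)
        if parafit_statistic(B_p, A_perm, B_h) >= observed - 1e-12:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_perm)

    per_link_stats = None
    if per_link:
        per_link_stats = []
        for i, j in zip(*np.nonzero(assoc.matrix)):
            A_wo = A.copy()
            A_wo[i, j] = 0.0
            per_link_stats.append(
                {
                    "parasite": assoc.parasite_labels[i],
                    "host": assoc.host_labels[j],
                    "stat_without_link": parafit_statistic(B_p, A_wo, B_h),
                }
            )
    return CophyloResult(
        method="parafit",
        statistic=observed,
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
        per_link_stats=per_link_stats,
        warnings=warnings,
    )


def hommola(
    D_host: DistMatrix,
    D_parasite: DistMatrix,
    links: list[tuple[str, str]],
    n_perm: int = 10000,
    seed: int | None = None,
) -> CophyloResult:
    """Correlation of host and parasite patristic distances over link pairs.

    The statistic is the Pearson correlation between host distances and
    parasite distances taken over all unordered pairs of (parasite, host)
    links; the null permutes host and parasite tip labels independently.
    """
    if len(links) < 3:
        raise InputError("at least 3 host-parasite links are required")
    if n_perm < 99:
        raise InputError("n_perm must be at least 99")
    p_idx = np.array([D_parasite.labels.index(p) for p, _ in links])
    h_idx = np.array([D_host.labels.index(h) for _, h in links])
    iu = np.triu_indices(len(links), k=1)

    def vectors(perm_h: np.ndarray, perm_p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        hh = perm_h[h_idx]
        pp = perm_p[p_idx]
        hv = D_host.values[hh[:, None], hh[None, :]][iu]
        pv = D_parasite.values[pp[:, None], pp[None, :]][iu]
        return hv, pv

    ident_h = np.arange(len(D_host.labels))
    ident_p = np.arange(len(D_parasite.labels))
    hv, pv = vectors(ident_h, ident_p)
    if hv.std() == 0 or pv.std() == 0:
        return CophyloResult(
            method="hommola",
            statistic=float("nan"),
            p_value=None,
            n_permutations=n_perm,
            seed=seed,
            warnings=["zero variance in a distance vector; statistic undefined"],
            undefined=True,
        )
    observed = float(np.corrcoef(hv, pv)[0, 1])

    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        hv_n, pv_n = vectors(
            rng.permutation(len(D_host.labels)),
            rng.permutation(len(D_parasite.labels)),
        )
        if hv_n.std() == 0 or pv_n.std() == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(hv_n, pv_n)[0, 1])
        if r >= observed - 1e-12:
            n_ge += 1
    return CophyloResult(
        method="hommola",
        statistic=observed,
        p_value=(1 + n_ge) / (1 + n_perm),
        n_permutations=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# exhaustive event-based reconciliation


@dataclass
class ReconciliationResult:
    codivergence: int
    duplication: int
    loss: int
    host_switch: int
    n_optimal: int = 1
    mapping: dict[str, str] | None = None

    def counts(self) -> tuple[int, int, int, int]:
        return (self.codivergence, self.duplication, self.loss, self.host_switch)


class _IndexedTree:
    """Rooted binary tree indexed for ancestor queries."""

    def __init__(self, tree: dendropy.Tree, name: str):
        self.nodes = list(tree.preorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.parent = [
            self.index[id(n.parent_node)] if n.parent_node else -1 for n in self.nodes
        ]
        self.children: list[list[int]] = [[] for _ in self.nodes]
        for i, n in enumerate(self.nodes):
            for c in n.child_nodes():
                self.children[i].append(self.index[id(c)])
        for i, ch in enumerate(self.children):
            if len(ch) not in (0, 2):
                raise InputError(
                    f"{name} tree is not strictly binary (node with {len(ch)} children)"
                )
        self.tips = [i for i, ch in enumerate(self.children) if not ch]
        self.tip_label = {
            i: self.nodes[i].taxon.label for i in self.tips if self.nodes[i].taxon
        }
        n = len(self.nodes)
        self.anc = np.zeros((n, n), dtype=bool)  # anc[a, d]: a is ancestor-or-self of d
        for d in range(n):
            a = d
            while a != -1:
                self.anc[a, d] = True
                a = self.parent[a]
        self.depth = np.zeros(n, dtype=int)
        for i in range(n):
            if self.parent[i] != -1:
                self.depth[i] = self.depth[self.parent[i]] + 1

    def path_edges(self, anc_node: int, desc: int) -> int:
        return int(self.depth[desc] - self.depth[anc_node])

    def label_of(self, i: int) -> str:
        if i in self.tip_label:
            return self.tip_label[i]
        return f"node{i}"


def _resolve_polytomies(tree: dendropy.Tree) -> dendropy.Tree:
    tree = tree.clone(depth=1)
    tree.resolve_polytomies(limit=2, update_bipartitions=False)
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    return tree


def enumerate_reconciliations(
    host: dendropy.Tree,
    parasite: dendropy.Tree,
    assoc: AssociationMatrix,
    max_tips: int = 8,
    polytomy: str = "refuse",
) -> list[ReconciliationResult]:
    """All optimal mappings of parasite nodes onto the host tree.

    Exhaustively enumerates maps of parasite internal nodes to host nodes
    consistent with the tip associations, scores each with event counts and
    returns every solution achieving the optimum: maximum codivergences,
    then fewest host switches, duplications and losses in that order.

    Each parasite internal node maps to a host node that is an ancestor of
    at least one child's image; a child mapping outside that host subtree is
    a host switch.  Host divergences passed without a matching parasite
    divergence count as losses.
    """
    n_h = len([1 for _ in host.leaf_node_iter()])
    n_p = len([1 for _ in parasite.leaf_node_iter()])
    if n_h > max_tips or n_p > max_tips:
        raise SizeError(
            f"trees with {n_h}/{n_p} tips exceed the exhaustive-search bound "
            f"({max_tips}); the search is exponential in tree size"
        )
    if polytomy == "resolve":
        host, parasite = _resolve_polytomies(host), _resolve_polytomies(parasite)
    elif polytomy != "refuse":
        raise InputError("polytomy must be 'refuse' or 'resolve'")
    H = _IndexedTree(host, "host")
    P = _IndexedTree(parasite, "parasite")

    host_tip_idx = {H.tip_label[i]: i for i in H.tips}
    tip_choices: dict[int, list[int]] = {}
    for p_node in P.tips:
        label = P.tip_label[p_node]
        if label not in assoc.parasite_labels:
            raise InputError(f"parasite tip {label!r} missing from associations")
        row = assoc.matrix[assoc.parasite_labels.index(label)]
        hosts = [
            host_tip_idx[h]
            for h, v in zip(assoc.host_labels, row)
            if v and h in host_tip_idx
        ]
        if not hosts:
            raise InputError(f"parasite tip {label!r} has no host association")
        tip_choices[p_node] = hosts

    postorder = [
        P.index[id(n)] for n in parasite.postorder_node_iter()
    ]
    internal = [i for i in postorder if P.children[i]]
    all_host_nodes = range(len(H.nodes))

    solutions: list[tuple[tuple[int, int, int, int], tuple[int, ...]]] = []
    phi: dict[int, int] = {}

    def node_events(h: int, f1: int, f2: int) -> tuple[int, int, int, int] | None:
        in1 = H.anc[h, f1]
        in2 = H.anc[h, f2]
        if in1 and in2:
            ch = H.children[h]
            if ch:
                hl, hr = ch
                split = (H.anc[hl, f1] and H.anc[hr, f2]) or (
                    H.anc[hl, f2] and H.anc[hr, f1]
                )
            else:
                split = False
            if split:
                loss = (H.path_edges(h, f1) - 1) + (H.path_edges(h, f2) - 1)
                return (1, 0, loss, 0)
            loss = H.path_edges(h, f1) + H.path_edges(h, f2)
            return (0, 1, loss, 0)
        if in1 or in2:
            f_in = f1 if in1 else f2
            loss = max(H.path_edges(h, f_in) - 1, 0)
            return (0, 0, loss, 1)
        return None

    def assign_tips(k: int) -> None:
        if k == len(P.tips):
            enumerate_internal(0, (0, 0, 0, 0))
            return
        t = P.tips[k]
        for h in tip_choices[t]:
            phi[t] = h
            assign_tips(k + 1)
        del phi[t]

    def enumerate_internal(k: int, events: tuple[int, int, int, int]) -> None:
        if k == len(internal):
            solutions.append(
                (events, tuple(phi[i] for i in sorted(phi)))
            )
            return
        p = internal[k]
        c1, c2 = P.children[p]
        f1, f2 = phi[c1], phi[c2]
        for h in all_host_nodes:
            delta = node_events(h, f1, f2)
            if delta is None:
                continue
            phi[p] = h
            enumerate_internal(
                k + 1, tuple(a + b for a, b in zip(events, delta))
            )
        phi.pop(p, None)

    assign_tips(0)
    if not solutions:
        raise InputError("no valid reconciliation exists")  # pragma: no cover

    def rank(ev: tuple[int, int, int, int]) -> tuple[int, int, int, int]:
        codiv, dup, loss, switch = ev
        return (-codiv, switch, dup, loss)

    best = min(rank(ev) for ev, _ in solutions)
    optimal = sorted(
        ((ev, m) for ev, m in solutions if rank(ev) == best), key=lambda s: s[1]
    )
    results = []
    phi_keys = sorted(
        set(tip_choices) | set(internal)
    )
    for ev, m in optimal:
        mapping = {
            P.label_of(k): H.label_of(h) for k, h in zip(phi_keys, m)
        }
        results.append(
            ReconciliationResult(
                codivergence=ev[0],
                duplication=ev[1],
                loss=ev[2],
                host_switch=ev[3],
                n_optimal=len(optimal),
                mapping=mapping,
            )
        )
    return results


def tanglegram_table(
    host: dendropy.Tree, parasite: dendropy.Tree, assoc: AssociationMatrix
) -> pd.DataFrame:
    """Paired tip orderings with link lines, for external plotting."""
    h_order = {l: i for i, l in enumerate(tip_labels(host))}
    p_order = {l: i for i, l in enumerate(tip_labels(parasite))}
    rows = [
        {
            "parasite": p,
            "parasite_position": p_order.get(p),
            "host": h,
            "host_position": h_order.get(h),
        }
        for p, h in assoc.links()
    ]
    return pd.DataFrame(rows)
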