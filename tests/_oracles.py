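"""Independent brute-force oracles used to cross-check the implementations.

Everything here is deliberately written from first principles with different
algorithms and libraries than the package code paths they verify.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


# --- seqdiv -----------------------------------------------------------------


def pdist_oracle(a: str, b: str) -> float:
    """Direct definition: mismatches over comparable sites, percent."""
    pairs = [
        (x, y)
        for x, y in zip(a, b)
        if x not in "-N" and y not in "-N"
    ]
    return 100.0 * sum(x != y for x, y in pairs) / len(pairs)


def divergence_matrix_oracle(groups: dict[str, list[str]], statistic: str):
    """Double loop over all pairs; returns (labels, matrix)."""
    labels = sorted(groups)
    agg = max if statistic == "max" else (lambda v: sum(v) / len(v))
    n = len(labels)
    M = np.zeros((n, n))
    for i, g in enumerate(labels):
        for j, h in enumerate(labels):
            if i == j:
                vals = [
                    pdist_oracle(a, b)
                    for a, b in itertools.combinations(groups[g], 2)
                ]
                M[i, j] = agg(vals) if vals else 0.0
            else:
                M[i, j] = agg(
                    [pdist_oracle(a, b) for a in groups[g] for b in groups[h]]
                )
    return labels, M


# --- delimit ----------------------------------------------------------------


def single_linkage_oracle(labels, values, threshold):
    """Connected components via scipy's csgraph, as frozensets of labels."""
    adj = (np.asarray(values) <= threshold).astype(int)
    np.fill_diagonal(adj, 1)
    n_comp, assign = connected_components(csr_matrix(adj), directed=False)
    clusters = []
    for c in range(n_comp):
        clusters.append(frozenset(l for l, a in zip(labels, assign) if a == c))
    return set(clusters)


def morphotype_pairing_oracle(females, males, dist, max_divergence):
    """Exhaustive search over all female-male matchings minimising total
    distance among matchings with the maximum number of pairs under the cap."""
    best = None
    k = min(len(females), len(males))
    for size in range(k, -1, -1):
        for fsub in itertools.combinations(range(len(females)), size):
            for msub in itertools.permutations(range(len(males)), size):
                if any(
                    dist[females[f]][males[m]] > max_divergence
                    for f, m in zip(fsub, msub)
                ):
                    continue
                total = sum(
                    dist[females[f]][males[m]] for f, m in zip(fsub, msub)
                )
                pairs = frozenset(
                    (females[f], males[m]) for f, m in zip(fsub, msub)
                )
                if best is None or total < best[0] - 1e-12:
                    best = (total, pairs)
        if best is not None:
            return best[1]
    return frozenset()


# --- primers ----------------------------------------------------------------


def diagnostic_sites_oracle(target_rows, other_rows):
    sites = []
    for col in range(len(target_rows[0])):
        tb = {row[col] for row in target_rows}
        if len(tb) == 1:
            b = next(iter(tb))
            if b in "ACGT" and b not in {row[col] for row in other_rows}:
                sites.append(col)
    return sites


def multiplex_stage_oracle(lengths, tms, separation, tm_window):
    """Minimum number of compatible stages by exhaustive assignment vectors."""
    n = len(lengths)

    def compatible(idxs):
        for a, b in itertools.combinations(idxs, 2):
            if abs(lengths[a] - lengths[b]) < separation:
                return False
        ts = [t for i in idxs for t in tms[i]]
        return max(ts) - min(ts) <= tm_window

    for k in range(1, n + 1):
        for assign in itertools.product(range(k), repeat=n):
            stages = [
                [i for i in range(n) if assign[i] == s] for s in range(k)
            ]
            if any(not s for s in stages):
                continue
            if all(compatible(s) for s in stages):
                return k
    return n


def pcr_scan_oracle(template, fwd, rev_rc, allowed, pentamer=5):
    """Slide both primers along the template at every offset."""
    hits = []
    for i in range(len(template) - len(fwd) + 1):
        win = template[i : i + len(fwd)]
        mm = [a != b for a, b in zip(win, fwd)]
        if not any(mm[-pentamer:]) and sum(mm[:-pentamer]) <= allowed:
            hits.append(("F", i))
    for i in range(len(template) - len(rev_rc) + 1):
        win = template[i : i + len(rev_rc)]
        mm = [a != b for a, b in zip(win, rev_rc)]
        if not any(mm[:pentamer]) and sum(mm[pentamer:]) <= allowed:
            hits.append(("R", i))
    return hits


# --- cophylo ----------------------------------------------------------------


def patristic_oracle(tree):
    """Dijkstra on the tree graph via networkx."""
    G = nx.Graph()
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None:
            G.add_edge(
                id(edge.tail_node), id(edge.head_node), weight=edge.length or 0.0
            )
    leaves = {leaf.taxon.label: id(leaf) for leaf in tree.leaf_node_iter()}
    labels = sorted(leaves)
    n = len(labels)
    M = np.zeros((n, n))
    for i, a in enumerate(labels):
        dists = nx.single_source_dijkstra_path_length(G, leaves[a])
        for j, b in enumerate(labels):
            M[i, j] = dists[leaves[b]]
    return labels, M


def hommola_r_oracle(Dh, Dp, links, h_labels, p_labels):
    """Pearson correlation computed with the textbook formula."""
    xs, ys = [], []
    for (p1, h1), (p2, h2) in itertools.combinations(links, 2):
        xs.append(Dh[h_labels.index(h1)][h_labels.index(h2)])
        ys.append(Dp[p_labels.index(p1)][p_labels.index(p2)])
    xs, ys = np.array(xs, float), np.array(ys, float)
    xc, yc = xs - xs.mean(), ys - ys.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def _tree_tables(tree):
    """Flat parent/children tables for a dendropy tree, in preorder."""
    nodes = list(tree.preorder_node_iter())
    idx = {id(n): i for i, n in enumerate(nodes)}
    parent = [idx[id(n.parent_node)] if n.parent_node else -1 for n in nodes]
    children = [[idx[id(c)] for c in n.child_nodes()] for n in nodes]
    tip_label = {
        i: nodes[i].taxon.label for i, ch in enumerate(children) if not ch
    }
    return parent, children, tip_label


def reconciliation_oracle(host, parasite, tip_map):
    """Full enumeration over all internal-node maps, no pruning.

    ``tip_map``: parasite tip label -> host tip label.  Returns the set of
    optimal event-count tuples (codiv, dup, loss, switch) and the number of
    optimal maps, using the same scoring convention as the package:
    maximise codivergence, then minimise switches, duplications, losses.
    """
    h_parent, h_children, h_tips = _tree_tables(host)
    p_parent, p_children, p_tips = _tree_tables(parasite)
    n_h = len(h_parent)

    def is_anc(a, d):
        while d != -1:
            if d == a:
                return True
            d = h_parent[d]
        return False

    def edges_between(a, d):
        k = 0
        while d != a:
            d = h_parent[d]
            k += 1
        return k

    h_tip_idx = {lab: i for i, lab in h_tips.items()}
    p_internal = [i for i, ch in enumerate(p_children) if ch]
    p_tip_assign = {i: h_tip_idx[tip_map[lab]] for i, lab in p_tips.items()}

    solutions = []
    for combo in itertools.product(range(n_h), repeat=len(p_internal)):
        phi = dict(p_tip_assign)
        for node, h in zip(p_internal, combo):
            phi[node] = h
        valid = True
        ev = [0, 0, 0, 0]  # codiv, dup, loss, switch
        for p in p_internal:
            c1, c2 = p_children[p]
            h = phi[p]
            f1, f2 = phi[c1], phi[c2]
            in1, in2 = is_anc(h, f1), is_anc(h, f2)
            if not (in1 or in2):
                valid = False
                break
            if in1 and in2:
                ch = h_children[h]
                cosp = bool(ch) and (
                    (is_anc(ch[0], f1) and is_anc(ch[1], f2))
                    or (is_anc(ch[0], f2) and is_anc(ch[1], f1))
                )
                if cosp:
                    ev[0] += 1
                    ev[2] += (edges_between(h, f1) - 1) + (edges_between(h, f2) - 1)
                else:
                    ev[1] += 1
                    ev[2] += edges_between(h, f1) + edges_between(h, f2)
            else:
                ev[3] += 1
                f_in = f1 if in1 else f2
                ev[2] += max(edges_between(h, f_in) - 1, 0)
        if valid:
            solutions.append(tuple(ev))
    key = lambda e: (-e[0], e[3], e[1], e[2])
    best = min(key(e) for e in solutions)
    optimal = [e for e in solutions if key(e) == best]
    return set(optimal), len(optimal)
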