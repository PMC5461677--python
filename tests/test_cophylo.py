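import itertools

import numpy as np
import pytest
from scipy import stats as sps

from _oracles import (
    hommola_r_oracle,
    patristic_oracle,
    reconciliation_oracle,
)
from mummyweb import synth
from mummyweb.cophylo import (
    AssociationMatrix,
    DistMatrix,
    enumerate_reconciliations,
    hommola,
    parafit,
    patristic_distances,
    read_newick,
    tanglegram_table,
    tree_from_string,
    write_newick,
)
from mummyweb.errors import InputError, SizeError


def mirror_system(n: int, seed: int = 0):
    host = synth.simulate_host_tree(n, seed=seed, prefix="H")
    parasite = tree_from_string(
        host.as_string(schema="newick").replace("H", "P")
    )
    links = [(f"P{i + 1}", f"H{i + 1}") for i in range(n)]
    assoc = AssociationMatrix.from_links(
        links,
        parasite_labels=[f"P{i + 1}" for i in range(n)],
        host_labels=[f"H{i + 1}" for i in range(n)],
    )
    return host, parasite, assoc


class TestNewickIO:
    def test_three_tip_tree(self):
        t = tree_from_string("((A:1,B:1):1,C:2);")
        assert len(t.leaf_nodes()) == 3

    def test_round_trip(self, tmp_path):
        path = tmp_path / "t.nwk"
        t = tree_from_string("((A:1.5,B:0.5):1,(C:2,D:1):0.25);")
        write_newick(t, path)
        back = read_newick(path)
        D1 = patristic_distances(t)
        D2 = patristic_distances(back)
        assert D1.labels == D2.labels
        np.testing.assert_allclose(D1.values, D2.values)

    def test_duplicate_labels_error(self):
        with pytest.raises(InputError):
            tree_from_string("((A:1,A:1):1,C:2);")

    def test_malformed_error(self, tmp_path):
        path = tmp_path / "bad.nwk"
        path.write_text("((A:1,B:1):1,C:2")
        with pytest.raises(InputError):
            read_newick(path)


class TestPatristic:
    def test_hand_computed(self):
        D = patristic_distances(tree_from_string("((A:1,B:1):1,C:2);"))
        assert D.labels == ["A", "B", "C"]
        assert D.values[0, 1] == 2.0
        assert D.values[0, 2] == 4.0
        assert D.values[1, 2] == 4.0

    def test_star_tree(self):
        D = patristic_distances(tree_from_string("(A:1.5,B:1.5,C:1.5,D:1.5);"))
        off = D.values[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 3.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_dijkstra_oracle(self, seed):
        tree = synth.simulate_host_tree(10, seed=seed)
        D = patristic_distances(tree)
        labels, M = patristic_oracle(tree)
        order = [D.labels.index(l) for l in labels]
        np.testing.assert_allclose(D.values[np.ix_(order, order)], M, rtol=1e-10)


class TestParafit:
    def test_relabeling_invariance(self):
        host, parasite, assoc = mirror_system(5, seed=2)
        Dh = patristic_distances(host)
        Dp = patristic_distances(parasite)
        res1 = parafit(Dh, Dp, assoc, n_perm=99, seed=0)
        # permute host label order in both the distance matrix and A columns
        perm = [3, 0, 4, 1, 2]
        labels = [assoc.host_labels[i] for i in perm]
        assoc2 = AssociationMatrix(
            parasite_labels=assoc.parasite_labels,
            host_labels=labels,
            matrix=assoc.matrix[:, perm],
        )
        res2 = parafit(Dh.reindex(labels), Dp, assoc2, n_perm=99, seed=0)
        assert res1.statistic == pytest.approx(res2.statistic)

    def test_empty_row_or_column_rejected(self):
        host, parasite, assoc = mirror_system(4)
        m = assoc.matrix.copy()
        m[0, 0] = 0
        bad = AssociationMatrix(
            parasite_labels=assoc.parasite_labels,
            host_labels=assoc.host_labels,
            matrix=m,
        )
        with pytest.raises(InputError):
            parafit(
                patristic_distances(host), patristic_distances(parasite), bad,
                n_perm=99, seed=0,
            )

    def test_seed_reproducibility(self):
        host, parasite, assoc = mirror_system(6, seed=5)
        Dh, Dp = patristic_distances(host), patristic_distances(parasite)
        r1 = parafit(Dh, Dp, assoc, n_perm=199, seed=42)
        r2 = parafit(Dh, Dp, assoc, n_perm=199, seed=42)
        assert r1.p_value == r2.p_value

    def test_n_perm_floor(self):
        host, parasite, assoc = mirror_system(4)
        with pytest.raises(InputError):
            parafit(
                patristic_distances(host), patristic_distances(parasite),
                assoc, n_perm=10, seed=0,
            )

    def test_per_link_stats(self):
        host, parasite, assoc = mirror_system(4, seed=1)
        res = parafit(
            patristic_distances(host), patristic_distances(parasite), assoc,
            n_perm=99, seed=0, per_link=True,
        )
        assert len(res.per_link_stats) == 4
        assert all("stat_without_link" in d for d in res.per_link_stats)


class TestHommola:
    def test_mirror_correlation_is_one(self):
        host, parasite, assoc = mirror_system(6, seed=3)
        res = hommola(
            patristic_distances(host), patristic_distances(parasite),
            assoc.links(), n_perm=99, seed=0,
        )
        assert res.statistic == pytest.approx(1.0)

    def test_four_tip_pearson_oracle(self):
        host = tree_from_string("((A:1,B:2):1,(C:1.5,D:0.5):2);")
        parasite = tree_from_string("((pA:2,pB:1):0.5,(pC:1,pD:2):1);")
        links = [("pA", "A"), ("pB", "B"), ("pC", "C"), ("pD", "D")]
        Dh, Dp = patristic_distances(host), patristic_distances(parasite)
        res = hommola(Dh, Dp, links, n_perm=99, seed=0)
        expected = hommola_r_oracle(
            Dh.values, Dp.values, links, Dh.labels, Dp.labels
        )
        assert res.statistic == pytest.approx(expected)

    def test_matches_scikit_bio(self):
        host, parasite, assoc = mirror_system(7, seed=9)
        # perturb parasite branch lengths so r is not trivially 1
        rng = np.random.default_rng(0)
        for edge in parasite.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= float(rng.uniform(0.5, 2.0))
        Dh, Dp = patristic_distances(host), patristic_distances(parasite)
        res = hommola(Dh, Dp, assoc.links(), n_perm=99, seed=0)
        from skbio.stats.evolve import hommola_cospeciation

        interaction = assoc.matrix.T  # skbio expects hosts x parasites
        r_skbio, _, _ = hommola_cospeciation(
            Dh.values, Dp.values, interaction, permutations=9
        )
        assert res.statistic == pytest.approx(float(r_skbio))

    def test_zero_variance_flagged(self):
        host = tree_from_string("(A:1,B:1,C:1);")
        parasite = tree_from_string("(pA:1,pB:1,pC:1);")
        res = hommola(
            patristic_distances(host), patristic_distances(parasite),
            [("pA", "A"), ("pB", "B"), ("pC", "C")], n_perm=99, seed=0,
        )
        assert res.undefined
        assert res.p_value is None

    def test_link_order_invariance(self):
        host, parasite, assoc = mirror_system(6, seed=4)
        Dh, Dp = patristic_distances(host), patristic_distances(parasite)
        links = assoc.links()
        r1 = hommola(Dh, Dp, links, n_perm=99, seed=1)
        r2 = hommola(Dh, Dp, links[::-1], n_perm=99, seed=1)
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_minimum_links(self):
        host, parasite, assoc = mirror_system(4)
        with pytest.raises(InputError):
            hommola(
                patristic_distances(host), patristic_distances(parasite),
                assoc.links()[:2], n_perm=99, seed=0,
            )


class TestPValueUniformity:
    def test_null_p_values_uniform(self):
        """KS test on null p-values of both methods (scaled-down run).

        Each method is fed data drawn from its own null so the permutation
        distribution is exactly exchangeable: iid uniform hosts per parasite
        (with unlinked hosts kept) for the global congruence test, a uniform
        random matching for the distance-correlation test.
        """
        rng = np.random.default_rng(123)
        n_sims, n_perm = 400, 199
        pvals_pf, pvals_hc = [], []
        for _ in range(n_sims):
            s1, s2, s3, s4 = (int(x) for x in rng.integers(0, 2**31, size=4))
            host = synth.simulate_host_tree(8, seed=s1, prefix="H")
            parasite = synth.simulate_host_tree(8, seed=s2, prefix="P")
            r3 = np.random.default_rng(s3)
            Dh, Dp = patristic_distances(host), patristic_distances(parasite)
            hosts = r3.integers(0, 8, size=8)
            assoc = AssociationMatrix.from_links(
                [(f"P{i + 1}", f"H{hosts[i] + 1}") for i in range(8)],
                parasite_labels=[f"P{i + 1}" for i in range(8)],
                host_labels=[f"H{i + 1}" for i in range(8)],
            )
            pvals_pf.append(
                parafit(
                    Dh, Dp, assoc, n_perm=n_perm, seed=s4,
                    allow_unlinked_hosts=True,
                ).p_value
            )
            perm = r3.permutation(8)
            links = [(f"P{i + 1}", f"H{perm[i] + 1}") for i in range(8)]
            pvals_hc.append(
                hommola(Dh, Dp, links, n_perm=n_perm, seed=s4).p_value
            )
        for pvals in (pvals_pf, pvals_hc):
            assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestReconciliation:
    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_mirror_gives_n_minus_1_codivergences(self, n):
        host, parasite, assoc = mirror_system(n, seed=n)
        results = enumerate_reconciliations(host, parasite, assoc)
        assert len(results) == 1
        assert results[0].counts() == (n - 1, 0, 0, 0)
        assert results[0].n_optimal == 1

    def test_one_switch_case_matches_oracle(self):
        host = tree_from_string("((A:1,B:1):1,C:2);")
        parasite = tree_from_string("((pA:1,pC:1):1,pB:2);")
        assoc = AssociationMatrix.from_links(
            [("pA", "A"), ("pB", "B"), ("pC", "C")]
        )
        results = enumerate_reconciliations(host, parasite, assoc)
        got = {r.counts() for r in results}
        expected, n_opt = reconciliation_oracle(
            host, parasite, {"pA": "A", "pB": "B", "pC": "C"}
        )
        assert got == expected
        assert results[0].n_optimal == n_opt

    @pytest.mark.parametrize("seed", range(6))
    def test_random_small_cases_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 6))
        host = synth.simulate_host_tree(n, seed=seed * 7 + 1, prefix="H")
        parasite = synth.simulate_host_tree(n, seed=seed * 7 + 2, prefix="P")
        perm = rng.permutation(n)
        tip_map = {f"P{i + 1}": f"H{perm[i] + 1}" for i in range(n)}
        assoc = AssociationMatrix.from_links(
            sorted(tip_map.items()),
            parasite_labels=[f"P{i + 1}" for i in range(n)],
            host_labels=[f"H{i + 1}" for i in range(n)],
        )
        results = enumerate_reconciliations(host, parasite, assoc)
        expected, n_opt = reconciliation_oracle(host, parasite, tip_map)
        assert {r.counts() for r in results} == expected
        assert results[0].n_optimal == n_opt

    def test_codivergence_bound(self):
        host, parasite, assoc = mirror_system(5, seed=11)
        for r in enumerate_reconciliations(host, parasite, assoc):
            assert r.codivergence <= 4

    def test_size_refusal(self):
        host, parasite, assoc = mirror_system(6, seed=0)
        with pytest.raises(SizeError):
            enumerate_reconciliations(host, parasite, assoc, max_tips=5)

    def test_polytomy_refused_then_resolved(self):
        host = tree_from_string("(A:1,B:1,C:1);")
        parasite = tree_from_string("((pA:1,pB:1):1,pC:2);")
        assoc = AssociationMatrix.from_links(
            [("pA", "A"), ("pB", "B"), ("pC", "C")]
        )
        with pytest.raises(InputError):
            enumerate_reconciliations(host, parasite, assoc)
        results = enumerate_reconciliations(
            host, parasite, assoc, polytomy="resolve"
        )
        assert results


def test_tanglegram_table():
    host, parasite, assoc = mirror_system(4, seed=0)
    df = tanglegram_table(host, parasite, assoc)
    assert len(df) == 4
    assert set(df.columns) == {
        "parasite", "parasite_position", "host", "host_position"
    }
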