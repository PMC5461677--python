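import numpy as np
import pytest

from mummyweb.seqdiv import AlignedSeqSet, SeqRecord


@pytest.fixture
def toy_alignment() -> AlignedSeqSet:
    return AlignedSeqSet(
        locus="cytb",
        records=[
            SeqRecord(id="a1", residues="ACGTACGTAC", morphospecies="P1",
                      host_population="albitextura", genotype=1, locus="cytb"),
            SeqRecord(id="a2", residues="ACGTACGTAC", morphospecies="P1",
                      host_population="albitextura", genotype=1, locus="cytb"),
            SeqRecord(id="b1", residues="ACGTTTTTAC", morphospecies="P2",
                      host_population="fiscella", genotype=2, locus="cytb"),
        ],
    )


def random_alignment(
    n_groups: int, per_group: int, length: int, seed: int, group_attr="host_population"
) -> AlignedSeqSet:
    """Random (unrelated) sequences grouped for matrix-oracle comparisons."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    records = []
    for g in range(n_groups):
        for i in range(per_group):
            residues = "".join(bases[rng.integers(0, 4, length)])
            records.append(
                SeqRecord(
                    id=f"g{g}s{i}",
                    residues=residues,
                    locus="cytb",
                    **{group_attr: f"grp{g}"},
                )
            )
    return AlignedSeqSet(locus="cytb", records=records)


@pytest.fixture(scope="session")
def species_community_alignment() -> AlignedSeqSet:
    """Four well-diverged 'species' with light within-species polymorphism."""
    from mummyweb import cophylo, synth

    nwk = (
        "((S1a:0.01,(S1b:0.005,S1c:0.005):0.005):0.4,"
        "((S2a:0.01,(S2b:0.005,S2c:0.005):0.005):0.35,"
        "((S3a:0.01,S3b:0.01):0.3,(S4a:0.01,S4b:0.01):0.3):0.15):0.1);"
    )
    tree = cophylo.tree_from_string(nwk)
    aln = synth.evolve_sequences(tree, length=600, subst_rate=1.0, seed=11)
    records = [
        SeqRecord(
            id=r.id,
            residues=r.residues,
            morphospecies=r.id[:2],
            host_population=r.host_population,
            locus="cytb",
        )
        for r in aln
    ]
    return AlignedSeqSet(locus="cytb", records=records)
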