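"""Replica detection, adjacency reordering and the cyclic-shift search."""

import numpy as np
import pytest

from oligosuper import (
    ChainCountMismatchError,
    FixtureSpec,
    chain_centroid,
    cyclic_permutations,
    detect_replica_groups,
    find_best_permutation,
    lsq_fit,
    make_cyclic_assembly,
    make_protomer,
    reorder_by_adjacency,
)
from oligosuper.fixtures import perturb_assembly, shift_chain_order
from oligosuper.seqalign import AlignParams, cached_align
from oligosuper.structure import Assembly, Atom, Chain, Residue


def ca_chain(chain_id, coords, resname="ALA"):
    residues = [
        Residue(resname=resname, seqnum=i + 1, atoms=[Atom("CA", "C", c)])
        for i, c in enumerate(np.atleast_2d(coords))
    ]
    return Chain(chain_id=chain_id, residues=residues)


class TestReplicaGroups:
    def test_homo_oligomer_single_group(self):
        a = make_cyclic_assembly(FixtureSpec(n_fold=5, protomer_length=20, seed=1))
        g = detect_replica_groups(a)
        assert g.groups == [[0, 1, 2, 3, 4]]
        assert g.rotational_symmetry_assumed

    def test_hetero_tetramer_two_groups(self):
        alpha = make_protomer(25, seed=100)
        beta = make_protomer(25, seed=200)

        def place(chain, cid, dx):
            moved = Assembly(chains=[chain], id="t").transformed(
                np.eye(3), np.array([dx, 0.0, 0.0])
            ).chains[0]
            moved.chain_id = cid
            return moved

        a = Assembly(
            chains=[place(alpha, "A", 0), place(alpha, "B", 20),
                    place(beta, "C", 40), place(beta, "D", 60)],
            id="a2b2",
        )
        g = detect_replica_groups(a)
        assert sorted(map(sorted, g.groups)) == [[0, 1], [2, 3]]
        assert g.rotational_symmetry_assumed

    def test_monomer_no_symmetry(self):
        a = Assembly(chains=[make_protomer(20, seed=3)], id="mono")
        g = detect_replica_groups(a)
        assert g.groups == [[0]]
        assert not g.rotational_symmetry_assumed


class TestChainCentroid:
    def test_mean_of_two(self):
        c = ca_chain("A", [[0, 0, 0], [2, 0, 0]])
        assert np.allclose(chain_centroid(c), [1, 0, 0])

    def test_single_ca(self):
        c = ca_chain("A", [[3.0, -1.0, 2.0]])
        assert np.allclose(chain_centroid(c), [3, -1, 2])

    def test_unit_square(self):
        c = ca_chain("A", [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        assert np.allclose(chain_centroid(c), [0.5, 0.5, 0])

    def test_no_ca_raises(self):
        c = Chain("A", [Residue("ALA", 1, atoms=[Atom("CB", "C", [0, 0, 0])])])
        with pytest.raises(ValueError):
            chain_centroid(c)


class TestReorderByAdjacency:
    def test_ring_with_scrambled_file_order(self):
        # square ring A(0,0) B(10,0) C(10,10) D(0,10); file order A,C,B,D
        a = Assembly(
            chains=[
                ca_chain("A", [[0, 0, 0], [0, 0, 2]]),
                ca_chain("C", [[10, 10, 0], [10, 10, 2]]),
                ca_chain("B", [[10, 0, 0], [10, 0, 2]]),
                ca_chain("D", [[0, 10, 0], [0, 10, 2]]),
            ],
            id="sq",
        )
        order = reorder_by_adjacency(a)
        # walk from A: B and D tie at distance 10 (C is 14.1 away); the
        # tie goes to file order, where B precedes D
        assert [a.chains[i].chain_id for i in order] == ["A", "B", "C", "D"]

    def test_already_adjacent_unchanged(self):
        a = make_cyclic_assembly(FixtureSpec(n_fold=4, protomer_length=15, seed=2))
        assert reorder_by_adjacency(a) == [0, 1, 2, 3]

    def test_single_chain(self):
        a = Assembly(chains=[make_protomer(10, seed=1)], id="m")
        assert reorder_by_adjacency(a) == [0]

    def test_is_permutation(self):
        a = make_cyclic_assembly(
            FixtureSpec(n_fold=6, protomer_length=12, seed=9,
                        rot_perturbation=4.0, trans_perturbation=1.0)
        )
        assert sorted(reorder_by_adjacency(a)) == list(range(6))


class TestCyclicPermutations:
    def test_three_element_worked_example(self):
        assert cyclic_permutations(["cal", "che", "mi"]) == [
            ["cal", "che", "mi"],
            ["mi", "cal", "che"],
            ["che", "mi", "cal"],
        ]

    def test_single_element(self):
        assert cyclic_permutations(["x"]) == [["x"]]

    def test_four_rotations_distinct(self):
        perms = cyclic_permutations([0, 1, 2, 3])
        assert len(perms) == 4
        assert len({tuple(p) for p in perms}) == 4
        for p in perms:
            assert sorted(p) == [0, 1, 2, 3]


def brute_force_best_shift(ref, tgt, reorder=True):
    """Independent exhaustive enumeration of all cyclic shifts."""
    ref_order = reorder_by_adjacency(ref) if reorder else list(range(len(ref.chains)))
    tgt_order = reorder_by_adjacency(tgt) if reorder else list(range(len(tgt.chains)))
    n = len(tgt_order)
    results = {}
    for shift in range(n):
        rotated = tgt_order[n - shift:] + tgt_order[:n - shift]
        refs, tgts = [], []
        for ri, ti in zip(ref_order, rotated):
            rc, tc = ref.chains[ri], tgt.chains[ti]
            aln = cached_align(rc.sequence, tc.sequence, AlignParams())
            for i, j in aln.pairs:
                ra, ta = rc.residues[i].get("CA"), tc.residues[j].get("CA")
                if ra is not None and ta is not None:
                    refs.append(ra.coords)
                    tgts.append(ta.coords)
        _, r = lsq_fit(np.array(refs), np.array(tgts))
        results[shift] = r
    return results


class TestFindBestPermutation:
    def test_matches_exhaustive_enumeration(self, quasi_c5_pair):
        ref, tgt = quasi_c5_pair
        search = find_best_permutation(ref, tgt)
        oracle = brute_force_best_shift(ref, tgt)
        assert len(search.evaluated) == 5
        for p in search.evaluated:
            assert p.ca_rmsd == pytest.approx(oracle[p.shift], abs=1e-9)
        best_shift = min(oracle, key=lambda s: (round(oracle[s], 9), s))
        assert search.best.shift == best_shift

    def test_quasi_symmetric_shift_recovered(self, quasi_c5_pair):
        ref, tgt = quasi_c5_pair
        search = find_best_permutation(ref, tgt)
        # the target's chain order was rotated by 2, which the search
        # undoes with the complementary cyclic shift (5 - 2) % 5 = 3
        assert search.best.shift == 3
        assert all(a == b for a, b in search.best.pairing)

    def test_unperturbed_ring_rmsd_vanishes(self):
        ref = make_cyclic_assembly(FixtureSpec(n_fold=6, protomer_length=20, seed=5))
        tgt = shift_chain_order(ref, 4)
        search = find_best_permutation(ref, tgt)
        assert search.best.ca_rmsd < 1e-6

    def test_best_not_worse_than_identity_shift(self, quasi_c5_pair):
        ref, tgt = quasi_c5_pair
        search = find_best_permutation(ref, tgt)
        identity = next(p for p in search.evaluated if p.shift == 0)
        assert search.best.ca_rmsd <= identity.ca_rmsd

    def test_chain_count_mismatch_raises(self):
        a = make_cyclic_assembly(FixtureSpec(n_fold=3, protomer_length=15, seed=1))
        b = make_cyclic_assembly(FixtureSpec(n_fold=4, protomer_length=15, seed=1))
        with pytest.raises(ChainCountMismatchError):
            find_best_permutation(a, b)

    def test_pairing_is_bijection(self, quasi_c5_pair):
        ref, tgt = quasi_c5_pair
        p = find_best_permutation(ref, tgt).best
        assert sorted(a for a, _ in p.pairing) == sorted(ref.chain_ids)
        assert sorted(b for _, b in p.pairing) == sorted(tgt.chain_ids)


@pytest.mark.parametrize("n", range(2, 9))
def test_unperturbed_shuffled_rings_recover_exact_superposition(n):
    """Shuffled exact Cn rings superpose to numerically zero RMSD and the
    winning pairing is a pure ring rotation."""
    ref = make_cyclic_assembly(FixtureSpec(n_fold=n, protomer_length=20, seed=n))
    tgt = shift_chain_order(ref, n // 2 + 1)
    search = find_best_permutation(ref, tgt)
    assert search.best.ca_rmsd < 1e-6
    # pairing maps ring position i to ring position i+k for a fixed k
    ring_pos = {cid: k for k, cid in enumerate(sorted(ref.chain_ids))}
    offsets = {(ring_pos[b] - ring_pos[a]) % n for a, b in search.best.pairing}
    assert len(offsets) == 1
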