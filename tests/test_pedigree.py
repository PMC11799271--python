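import numpy as np
import pandas as pd
import pytest

from epiblup.pedigree import (Pedigree, PedigreeError, build_a_inverse,
                              completeness_index, extract_a22,
                              inbreeding_coefficients, load_pedigree,
                              pedigree_from_frame, prune_to_depth,
                              relationship_matrix)
from conftest import make_random_pedigree


def dense_tabular_a(ped: Pedigree) -> np.ndarray:
    """Independent tabular-method oracle (scalar recursion, no vectorization)."""
    n = ped.n
    a = np.zeros((n + 1, n + 1))
    for i in range(1, n + 1):
        s, d = ped.parents(i)
        for j in range(1, i):
            a[i, j] = a[j, i] = 0.5 * (a[s, j] + a[d, j])
        a[i, i] = 1.0 + (0.5 * a[s, d] if s and d else 0.0)
    return a[1:, 1:]


class TestLoadPedigree:
    def test_trio_orders_parents_first(self, tmp_path):
        f = tmp_path / "ped.csv"
        f.write_text("id,sire,dam\n10,20,30\n20,0,0\n30,0,0\n")
        ped = load_pedigree(f)
        assert ped.n == 3
        # offspring (original id 10) must be renumbered last
        assert ped.original_id[-1] == 10
        assert ped.sire[-1] > 0 and ped.dam[-1] > 0

    def test_self_parenting_rejected(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("id,sire,dam\n1,1,0\n")
        with pytest.raises(PedigreeError, match="own parent"):
            load_pedigree(f)

    def test_cycle_rejected(self):
        df = pd.DataFrame({"id": [1, 2], "sire": [2, 1], "dam": [0, 0]})
        with pytest.raises(PedigreeError, match="cycle"):
            pedigree_from_frame(df)

    def test_duplicate_id_rejected(self):
        df = pd.DataFrame({"id": [1, 1], "sire": [0, 0], "dam": [0, 0]})
        with pytest.raises(PedigreeError, match="duplicate"):
            pedigree_from_frame(df)

    def test_phantom_parents_added_as_founders(self):
        df = pd.DataFrame({"id": [5], "sire": [8], "dam": [9]})
        ped = pedigree_from_frame(df)
        assert ped.n == 3

    def test_shuffled_file_is_topologically_sorted(self):
        ped0 = make_random_pedigree(seed=7, n=100)
        df = ped0.to_frame()[["id", "sire", "dam"]]
        df = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        ped = pedigree_from_frame(df)
        # independent scan: every parent code must refer to an earlier row
        for i in range(1, ped.n + 1):
            s, d = ped.parents(i)
            assert s < i and d < i


class TestPrune:
    def test_chain_depth(self):
        # chain 1 <- 2 <- ... <- 6 (each child of previous via sire)
        sire = np.array([0, 1, 2, 3, 4, 5])
        ped = Pedigree(sire=sire, dam=np.zeros(6, dtype=int))
        kept = prune_to_depth(ped, anchors={6}, max_gen=4)
        assert kept.n == 5

    def test_depth_zero_keeps_anchors_only(self):
        ped = make_random_pedigree(seed=1, n=30)
        anchors = set(range(21, 31))
        kept = prune_to_depth(ped, anchors, max_gen=0)
        assert kept.n == 10
        assert (kept.sire == 0).all() and (kept.dam == 0).all()

    def test_empty_anchor_set_rejected(self):
        ped = make_random_pedigree(seed=1, n=10)
        with pytest.raises(PedigreeError):
            prune_to_depth(ped, set())

    def test_branched_pedigree_matches_bruteforce(self):
        ped = make_random_pedigree(seed=11, n=30)
        anchors = {28, 29, 30}
        kept = prune_to_depth(ped, anchors, max_gen=4)
        # brute-force BFS oracle over (animal, depth) pairs
        expect = set(anchors)
        frontier = {a: 0 for a in anchors}
        for _ in range(4):
            nxt = {}
            for a in frontier:
                for p in ped.parents(a):
                    if p:
                        nxt[p] = None
            expect |= set(nxt)
            frontier = nxt
        assert set(kept.original_id.tolist()) == expect

    def test_idempotent(self):
        ped = make_random_pedigree(seed=5, n=60)
        once = prune_to_depth(ped, {55, 60}, max_gen=3)
        anchors = {int(i) for i in once.ids
                   if once.original_id[i - 1] in (55, 60)}
        twice = prune_to_depth(once, anchors, max_gen=3)
        assert twice.n == once.n
        assert np.array_equal(twice.sire, once.sire)
        assert np.array_equal(twice.dam, once.dam)


class TestCompleteness:
    def test_founder_zero(self):
        ped = Pedigree(sire=[0], dam=[0])
        assert completeness_index(ped, 4)[0] == 0.0

    def test_fully_known_is_one(self):
        # perfect binary ancestry to depth 2: 4 grandparents, 2 parents, 1 kid
        sire = np.array([0, 0, 0, 0, 1, 3, 5])
        dam = np.array([0, 0, 0, 0, 2, 4, 6])
        ped = Pedigree(sire=sire, dam=dam)
        assert completeness_index(ped, 2)[-1] == pytest.approx(1.0)

    def test_sire_line_only_hand_enumerated(self):
        # animal 7: sire 5 known with both parents (1, 2); dam unknown.
        # sire line at depth 2: (1 + 2/2)/2 = 1; dam line 0 -> index 0.5
        sire = np.array([0, 0, 0, 0, 1, 0, 5])
        dam = np.array([0, 0, 0, 0, 2, 0, 0])
        ped = Pedigree(sire=sire, dam=dam)
        assert completeness_index(ped, 2)[-1] == pytest.approx(0.5)

    def test_depth_must_be_positive(self):
        ped = Pedigree(sire=[0], dam=[0])
        with pytest.raises(ValueError):
            completeness_index(ped, 0)


class TestInbreeding:
    def test_outbred_offspring(self):
        ped = Pedigree(sire=[0, 0, 1], dam=[0, 0, 2])
        assert inbreeding_coefficients(ped)[2] == 0.0

    def test_full_sib_mating(self):
        ped = Pedigree(sire=[0, 0, 1, 1, 3], dam=[0, 0, 2, 2, 4])
        assert inbreeding_coefficients(ped)[4] == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_tabular_diagonal(self, seed):
        ped = make_random_pedigree(seed=seed, n=50, p_founder=0.1)
        f = inbreeding_coefficients(ped)
        a = dense_tabular_a(ped)
        assert np.allclose(f, np.diag(a) - 1.0, atol=1e-10)


class TestAInverse:
    def test_single_founder(self):
        ped = Pedigree(sire=[0], dam=[0])
        trip = build_a_inverse(ped)
        assert trip.to_dense() == pytest.approx(np.array([[1.0]]))

    def test_noninbred_trio_values(self):
        ped = Pedigree(sire=[0, 0, 1], dam=[0, 0, 2])
        ainv = build_a_inverse(ped).to_dense()
        expect = np.array([[1.5, 0.5, -1.0], [0.5, 1.5, -1.0],
                           [-1.0, -1.0, 2.0]])
        assert np.allclose(ainv, expect)

    @pytest.mark.parametrize("seed", [3, 4, 5, 6])
    def test_inverse_of_tabular_a(self, seed):
        ped = make_random_pedigree(seed=seed, n=50, p_founder=0.15)
        ainv = build_a_inverse(ped).to_dense()
        a = dense_tabular_a(ped)
        assert np.abs(ainv @ a - np.eye(ped.n)).max() < 1e-8

    def test_diagonal_is_one_plus_f(self):
        ped = make_random_pedigree(seed=9, n=120, p_founder=0.1)
        a = relationship_matrix(ped)
        assert np.allclose(np.diag(a), 1.0 + ped.inbreeding(), atol=1e-12)
        # symmetric positive definite
        assert np.all(np.linalg.eigvalsh(a) > 0)


class TestA22:
    def test_single_founder(self):
        ped = Pedigree(sire=[0, 0, 1], dam=[0, 0, 2])
        assert extract_a22(ped, [1]) == pytest.approx(np.array([[1.0]]))

    def test_full_sibs(self):
        ped = Pedigree(sire=[0, 0, 1, 1], dam=[0, 0, 2, 2])
        a22 = extract_a22(ped, [3, 4])
        assert a22[0, 1] == pytest.approx(0.5)

    def test_random_subset_matches_tabular(self):
        ped = make_random_pedigree(seed=21, n=100)
        rng = np.random.default_rng(0)
        subset = rng.choice(np.arange(1, 101), size=20, replace=False)
        a = dense_tabular_a(ped)
        assert np.allclose(extract_a22(ped, subset),
                           a[np.ix_(subset - 1, subset - 1)])

    def test_unknown_id_rejected(self):
        ped = Pedigree(sire=[0], dam=[0])
        with pytest.raises(PedigreeError):
            extract_a22(ped, [2])
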