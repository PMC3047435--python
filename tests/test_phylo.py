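"""JTT maximum-likelihood distances, neighbor joining and tree queries."""

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import nj as skbio_nj

from thermofold.phylo import (
    DistanceMatrix,
    closest_cross_pair,
    distance_matrix_from_msa,
    jtt_ml_distance,
    jtt_model,
    neighbor_joining,
    parse_newick,
    read_fasta_alignment,
    serialize_newick,
)

AAS = "ARNDCQEGHILKMFPSTWYV"


def _mutate(seq, positions, rng):
    out = list(seq)
    for i in positions:
        out[i] = AAS[(AAS.index(out[i]) + 1 + rng.integers(19)) % 20]
    return "".join(out)


class TestJTTModel:
    def test_rate_matrix_properties(self):
        m = jtt_model()
        # d/dt of pi_a P_ab(t) at t=0 is diag(pi) Q; divide the pi back out
        q = (m.m * m.eigenvalues) @ m.m.T / m.pi[:, None]
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-10)
        assert np.allclose(-(m.pi * np.diag(q)).sum(), 1.0)  # 1 sub/site scale
        p = m.joint_matrix(0.5) / m.pi[:, None]
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)
        assert (p >= 0).all()
        # detailed balance: pi_a P_ab = pi_b P_ba
        joint = m.joint_matrix(0.7)
        assert np.allclose(joint, joint.T, atol=1e-12)


class TestJTTDistance:
    def test_identical_sequences_near_zero(self):
        s = AAS * 5
        assert jtt_ml_distance(s, s) <= 1e-4

    def test_exact_symmetry(self):
        rng = np.random.default_rng(0)
        s1 = AAS * 5
        s2 = _mutate(s1, rng.choice(100, 30, replace=False), rng)
        assert jtt_ml_distance(s1, s2) == jtt_ml_distance(s2, s1)

    def test_matches_grid_search_oracle(self):
        """Bounded optimization agrees with a step-1e-4 grid over t."""
        rng = np.random.default_rng(3)
        m = jtt_model()
        s1 = AAS * 5
        for n_mut in (10, 25, 40):
            s2 = _mutate(s1, rng.choice(100, n_mut, replace=False), rng)
            counts = np.zeros((20, 20))
            for a, b in zip(s1, s2):
                counts[m.index[a], m.index[b]] += 1
            counts = 0.5 * (counts + counts.T)
            ts = np.arange(1e-6, 10.0, 1e-4)
            e = np.exp(np.outer(m.eigenvalues, ts))
            ia, ib = np.nonzero(counts > 0)
            coeff = m.m[ia, :] * m.m[ib, :]
            loglik = (counts[ia, ib][:, None] * np.log(coeff @ e)).sum(0)
            t_grid = ts[np.argmax(loglik)]
            assert jtt_ml_distance(s1, s2) == pytest.approx(t_grid, abs=1e-3)

    def test_monotone_in_nested_mismatch_sets(self):
        rng = np.random.default_rng(4)
        s1 = AAS * 5
        order = rng.permutation(100)
        prev = 0.0
        for k in (5, 15, 30, 50):
            s2 = _mutate(s1, order[:k], rng)
            d = jtt_ml_distance(s1, s2)
            assert d >= prev - 1e-9
            prev = d

    def test_gap_columns_skipped(self):
        d_full = jtt_ml_distance("ARNDC", "ARNDC")
        d_gap = jtt_ml_distance("ARND-", "ARNDC")
        assert d_gap == pytest.approx(d_full, abs=1e-6)
        with pytest.raises(ValueError):
            jtt_ml_distance("----", "ARND")


ADDITIVE = DistanceMatrix(
    labels=["A", "B", "C", "D"],
    d=np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float),
)


class TestNeighborJoining:
    def test_exact_on_additive_four_taxon_matrix(self):
        tree = neighbor_joining(ADDITIVE)
        tt = tree.tip_tip_distances()
        for i, a in enumerate(ADDITIVE.labels):
            for j, b in enumerate(ADDITIVE.labels):
                if i < j:
                    assert float(tt[a, b]) == pytest.approx(ADDITIVE.d[i, j], abs=1e-9)
        # AB|CD split with the constructed branch lengths
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})

    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(labels=["X", "Y", "Z"],
                            d=np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float))
        tree = neighbor_joining(dm)
        tt = tree.tip_tip_distances()
        assert float(tt["X", "Y"]) == pytest.approx(4.0)
        assert float(tt["X", "Z"]) == pytest.approx(6.0)
        assert float(tt["Y", "Z"]) == pytest.approx(8.0)

    def test_label_permutation_gives_isomorphic_tree(self):
        perm = [2, 0, 3, 1]
        dm2 = DistanceMatrix(labels=[ADDITIVE.labels[i] for i in perm],
                             d=ADDITIVE.d[np.ix_(perm, perm)])
        t1 = neighbor_joining(ADDITIVE)
        t2 = neighbor_joining(dm2)
        tt1, tt2 = t1.tip_tip_distances(), t2.tip_tip_distances()
        for a in ADDITIVE.labels:
            for b in ADDITIVE.labels:
                if a < b:
                    assert float(tt1[a, b]) == pytest.approx(float(tt2[a, b]), abs=1e-9)

    def test_matches_skbio_nj_on_random_metric(self):
        """Independent cross-check: same patristic metric as scikit-bio's NJ."""
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 4))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        labels = list("abcdef")
        ours = neighbor_joining(DistanceMatrix(labels=labels, d=d))
        theirs = skbio_nj(SkbioDM(d, ids=labels))
        tt_o = ours.tip_tip_distances()
        tt_t = theirs.tip_tip_distances()
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                assert float(tt_o[a, b]) == pytest.approx(float(tt_t[a, b]), abs=1e-6)

    def test_negative_branch_clamped_to_zero(self):
        d = np.array([[0, 1, 10, 9], [1, 0, 9.5, 9], [10, 9.5, 0, 0.2],
                      [9, 9, 0.2, 0]], float)
        tree = neighbor_joining(DistanceMatrix(labels=list("wxyz"), d=d))
        assert all((t.length or 0.0) >= 0.0 for t in tree.traverse())

    def test_fewer_than_three_labels_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(labels=["A", "B"],
                                            d=np.array([[0, 1], [1, 0]], float)))


class TestSerialization:
    def test_newick_roundtrip(self):
        tree = neighbor_joining(ADDITIVE)
        nwk = serialize_newick(tree)
        back = parse_newick(nwk)
        tt1, tt2 = tree.tip_tip_distances(), back.tip_tip_distances()
        for a in ADDITIVE.labels:
            for b in ADDITIVE.labels:
                if a < b:
                    assert float(tt1[a, b]) == pytest.approx(float(tt2[a, b]), abs=1e-9)

    def test_phylip_square_format(self):
        text = ADDITIVE.to_phylip()
        lines = text.strip().splitlines()
        assert lines[0].strip() == "4"
        assert lines[1].startswith("A")
        assert len(lines) == 5

    def test_msa_reader_validates_lengths(self):
        with pytest.raises(ValueError):
            read_fasta_alignment(">a\nARND\n>b\nARNDC\n")
        msa = read_fasta_alignment(">a\nARNDC\n>b\nARNEC\n")
        assert set(msa) == {"a", "b"}


class TestClosestCrossPair:
    LABELS = {"A": "thermophile", "B": "mesophile",
              "C": "thermophile", "D": "mesophile"}

    def test_adjacent_cross_pair_found(self):
        tree = neighbor_joining(ADDITIVE)
        # patristic: A-B 3, A-D 6, C-B 6, C-D 7 -> (A, B)
        assert closest_cross_pair(tree, self.LABELS) == ("A", "B")

    def test_tie_broken_lexicographically(self):
        d = np.array([[0, 2, 2, 2], [2, 0, 2, 2], [2, 2, 0, 2], [2, 2, 2, 0]], float)
        tree = neighbor_joining(DistanceMatrix(labels=list("ABCD"), d=d))
        pair = closest_cross_pair(tree, self.LABELS)
        assert pair == ("A", "B")

    def test_single_label_tree_rejected(self):
        tree = neighbor_joining(ADDITIVE)
        with pytest.raises(ValueError):
            closest_cross_pair(tree, {k: "thermophile" for k in "ABCD"})

    def test_pipeline_from_msa(self):
        msa = {
            "t1": "ARNDCQEGHILKMFPSTWYV" * 3,
            "t2": "ARNDCQEGHILKMFPSTWYV" * 3,
            "m1": "ARNECQEGHILKMFPSTWYV" * 3,
            "m2": "GRNECREGHILKMFPSTWYV" * 3,
        }
        labels = {"t1": "thermophile", "t2": "thermophile",
                  "m1": "mesophile", "m2": "mesophile"}
        dm = distance_matrix_from_msa(msa)
        tree = neighbor_joining(dm)
        t, m = closest_cross_pair(tree, labels)
        assert labels[t] == "thermophile" and labels[m] == "mesophile"
        assert m == "m1"
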