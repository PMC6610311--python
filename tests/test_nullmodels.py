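import numpy as np
import pandas as pd
import pytest

from assemblage.io import read_newick
from assemblage.nullmodels import (
    UndefinedMetricError,
    beta_mntd,
    beta_nti,
    mntd,
    ses_mntd,
    shuffle_labels,
    select_pairs,
)
from assemblage.phylo import cophenetic_matrix
from assemblage.io import SampleMetadata

from conftest import abund, make_table
from oracles import brute_beta_mntd, brute_mntd


class TestMntd:
    def test_three_taxon_example(self, four_tip_dist):
        # nearest distances: A->B 2, B->A 2, C->A or B 4; mean = 8/3
        value = mntd(abund(four_tip_dist, A=1, B=1, C=1), four_tip_dist)
        assert value == pytest.approx(8 / 3)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_pair_is_their_distance(self, four_tip_dist, weighted):
        value = mntd(abund(four_tip_dist, A=2, B=5), four_tip_dist, weighted=weighted)
        assert value == pytest.approx(2.0)

    def test_single_taxon_undefined(self, four_tip_dist):
        with pytest.raises(UndefinedMetricError):
            mntd(abund(four_tip_dist, A=3), four_tip_dist)


class TestBetaMntd:
    def test_identical_communities_zero(self, four_tip_dist):
        x = abund(four_tip_dist, A=2, C=5)
        assert beta_mntd(x, x, four_tip_dist) == 0.0

    def test_cross_clade_unweighted(self, four_tip_dist):
        a = abund(four_tip_dist, A=1, B=1)
        b = abund(four_tip_dist, C=1, D=1)
        assert beta_mntd(a, b, four_tip_dist, weighted=False) == pytest.approx(4.0)

    def test_weighted_example(self, four_tip_dist):
        a = abund(four_tip_dist, A=1, B=1)  # 0.5 / 0.5
        b = abund(four_tip_dist, C=1)
        assert beta_mntd(a, b, four_tip_dist, weighted=True) == pytest.approx(4.0)

    def test_empty_community_rejected(self, four_tip_dist):
        with pytest.raises(ValueError):
            beta_mntd(abund(four_tip_dist, A=1), np.zeros(4), four_tip_dist)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_symmetry_and_nonnegativity(self, random_tree_factory, weighted):
        dist = cophenetic_matrix(random_tree_factory(11, 9))
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.integers(0, 4, 9).astype(float)
            b = rng.integers(0, 4, 9).astype(float)
            if a.sum() == 0 or b.sum() == 0:
                continue
            ab = beta_mntd(a, b, dist, weighted=weighted)
            ba = beta_mntd(b, a, dist, weighted=weighted)
            assert ab == pytest.approx(ba)
            assert ab >= 0
            assert beta_mntd(a, a, dist, weighted=weighted) == 0.0

    @pytest.mark.parametrize("weighted", [False, True])
    def test_brute_force_oracle(self, random_tree_factory, weighted):
        rng = np.random.default_rng(17)
        for seed in range(5):
            n = int(rng.integers(4, 9))
            dist = cophenetic_matrix(random_tree_factory(200 + seed, n))
            for _ in range(20):
                x = (rng.random(n) < 0.5) * rng.integers(1, 9, n)
                y = (rng.random(n) < 0.5) * rng.integers(1, 9, n)
                if x.sum() == 0 or y.sum() == 0:
                    continue
                got = beta_mntd(x, y, dist, weighted=weighted)
                want = brute_beta_mntd(x, y, dist.d, weighted)
                assert got == pytest.approx(want, abs=1e-12)
                if (x > 0).sum() >= 2:
                    assert mntd(x, dist, weighted=weighted) == pytest.approx(
                        brute_mntd(x, dist.d, weighted), abs=1e-12
                    )


class TestShuffleLabels:
    def test_two_taxon_offdiagonal_preserved(self):
        from assemblage.phylo import PairwiseDistanceMatrix

        dm = PairwiseDistanceMatrix(["a", "b"], np.array([[0.0, 3.0], [3.0, 0.0]]))
        out = shuffle_labels(dm, np.random.default_rng(0))
        assert out.d[0, 1] == 3.0

    def test_multiset_preserved(self, four_tip_dist):
        out = shuffle_labels(four_tip_dist, np.random.default_rng(3))
        assert sorted(out.d.ravel()) == sorted(four_tip_dist.d.ravel())

    def test_seed_determinism(self, four_tip_dist):
        a = shuffle_labels(four_tip_dist, np.random.default_rng(9))
        b = shuffle_labels(four_tip_dist, np.random.default_rng(9))
        np.testing.assert_array_equal(a.d, b.d)


class TestSesMntd:
    def test_star_tree_undefined(self, tmp_path):
        p = tmp_path / "star.nwk"
        p.write_text("(A:1,B:1,C:1,D:1);\n")
        dist = cophenetic_matrix(read_newick(p))
        table = make_table({"s1": [1, 1, 0, 0], "s2": [0, 1, 1, 1]}, dist.labels)
        with pytest.warns(UserWarning, match="undefined"):
            res = ses_mntd(table, dist, reps=49, seed=0)
        assert res["undefined"].all()
        assert res["ses_mntd"].isna().all()

    def test_full_community_undefined(self, four_tip_dist):
        # every taxon present: a label shuffle is a bijection of the full set
        table = make_table({"s1": [1, 1, 1, 1]}, four_tip_dist.labels)
        with pytest.warns(UserWarning):
            res = ses_mntd(table, four_tip_dist, reps=49, seed=0)
        assert res["undefined"].iloc[0]

    def test_determinism_and_columns(self, random_tree_factory):
        dist = cophenetic_matrix(random_tree_factory(31, 10))
        rng = np.random.default_rng(2)
        table = make_table(
            {f"s{j}": ((rng.random(10) < 0.5) * rng.integers(1, 20, 10)).tolist() for j in range(4)},
            dist.labels,
        )
        a = ses_mntd(table, dist, reps=99, seed=5)
        b = ses_mntd(table, dist, reps=99, seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert (a["reps"] == 99).all()
        # SES definition holds where defined
        ok = ~a["undefined"]
        np.testing.assert_allclose(
            a.loc[ok, "ses_mntd"],
            (a.loc[ok, "mntd_obs"] - a.loc[ok, "null_mean"]) / a.loc[ok, "null_sd"],
        )


def _two_group_metadata(samples):
    half = len(samples) // 2
    groups = ["g1"] * half + ["g2"] * (len(samples) - half)
    return SampleMetadata(
        pd.DataFrame({"group": groups}, index=pd.Index(samples, name="sample_id"))
    )


class TestBetaNti:
    def test_identical_pair_undefined(self, random_tree_factory):
        # taxa shared by both samples keep nearest-taxon distance 0 under
        # every label permutation, so a fully identical pair has a null
        # distribution that is identically 0: flagged undefined, not scored
        dist = cophenetic_matrix(random_tree_factory(41, 16))
        x = np.zeros(16, dtype=np.int64)
        x[[0, 1, 2]] = [5, 3, 2]
        table = make_table({"s1": x.tolist(), "s2": x.tolist()}, dist.labels)
        with pytest.warns(UserWarning):
            res = beta_nti(table, dist, reps=199, seed=0, pairs="all")
        assert res["beta_mntd"].iloc[0] == 0.0
        assert res["undefined"].iloc[0]

    def test_near_identical_pair_strongly_negative(self, random_tree_factory):
        # samples differing only in a pair of sister tips: observed
        # turnover is far below the label-shuffle null
        dist = cophenetic_matrix(random_tree_factory(41, 16))
        d = dist.d.copy()
        np.fill_diagonal(d, np.inf)
        p, q = np.unravel_index(np.argmin(d), d.shape)
        shared = [i for i in range(16) if i not in (p, q)][:4]
        xa = np.zeros(16, dtype=np.int64)
        xb = np.zeros(16, dtype=np.int64)
        xa[shared] = 5
        xb[shared] = 5
        xa[p] = 5
        xb[q] = 5
        table = make_table({"s1": xa.tolist(), "s2": xb.tolist()}, dist.labels)
        res = beta_nti(table, dist, reps=199, seed=0, pairs="all")
        assert res["beta_nti"].iloc[0] < -2

    def test_star_tree_undefined(self, tmp_path):
        p = tmp_path / "star.nwk"
        p.write_text("(A:1,B:1,C:1,D:1);\n")
        dist = cophenetic_matrix(read_newick(p))
        table = make_table({"s1": [1, 1, 0, 0], "s2": [0, 0, 1, 1]}, dist.labels)
        with pytest.warns(UserWarning):
            res = beta_nti(table, dist, reps=49, seed=0, pairs="all")
        assert res["undefined"].all()

    def test_seed_determinism(self, random_tree_factory):
        dist = cophenetic_matrix(random_tree_factory(43, 12))
        rng = np.random.default_rng(8)
        table = make_table(
            {f"s{j}": ((rng.random(12) < 0.6) * rng.integers(1, 30, 12)).tolist() for j in range(5)},
            dist.labels,
        )
        a = beta_nti(table, dist, reps=99, seed=3, pairs="all")
        b = beta_nti(table, dist, reps=99, seed=3, pairs="all")
        pd.testing.assert_frame_equal(a, b)

    def test_gauge_invariance(self, random_tree_factory):
        """Relabeling taxa consistently in table and distances leaves the
        observed betaMNTD unchanged exactly and betaNTI unchanged up to
        Monte-Carlo error of the permutation null."""
        dist = cophenetic_matrix(random_tree_factory(47, 10))
        rng = np.random.default_rng(4)
        counts = {f"s{j}": ((rng.random(10) < 0.6) * rng.integers(1, 30, 10)).tolist() for j in range(4)}
        table = make_table(counts, dist.labels)
        res = beta_nti(table, dist, reps=999, seed=11, pairs="all")

        perm = rng.permutation(10)
        relabeled = [dist.labels[i] for i in perm]
        dist2 = dist.reorder(relabeled)
        table2 = make_table(
            {s: [counts[s][i] for i in perm] for s in counts}, relabeled
        )
        res2 = beta_nti(table2, dist2, reps=999, seed=11, pairs="all")
        np.testing.assert_allclose(res["beta_mntd"], res2["beta_mntd"], atol=1e-12)
        ok = ~(res["undefined"] | res2["undefined"])
        np.testing.assert_allclose(
            res.loc[ok, "beta_nti"], res2.loc[ok, "beta_nti"], atol=0.5
        )

    def test_within_group_pair_selection(self):
        samples = ["a1", "a2", "b1", "b2"]
        meta = _two_group_metadata(samples)
        pairs = select_pairs(samples, pairs="within", metadata=meta)
        assert pairs == [("a1", "a2"), ("b1", "b2")]
        assert len(select_pairs(samples, pairs="all")) == 6
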