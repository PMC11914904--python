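import numpy as np
import pandas as pd
import pytest

from auxopep.errors import InputError
from auxopep.stats import (
    bh_fdr,
    differential_peptidase_screen,
    kendall_ordered,
    pcoa,
    permanova,
    spearman_matrix,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)
from oracles import (
    bh_oracle,
    kendall_tau_b_oracle,
    permanova_exact_p_oracle,
    permanova_f_oracle,
    rank_sum_exact_p,
    signed_rank_exact_p,
)


class TestKendallOrdered:
    def test_perfect_monotone(self):
        up = kendall_ordered([1, 2, 3, 4], [1, 2, 3, 4])
        down = kendall_ordered([4, 3, 2, 1], [1, 2, 3, 4])
        assert up.statistic == pytest.approx(1.0)
        assert down.statistic == pytest.approx(-1.0)

    def test_tau_b_matches_pair_enumeration_oracle(self):
        ranks = [1, 1, 2, 2, 3, 3]
        values = [5, 4, 3, 3, 2, 1]
        res = kendall_ordered(values, ranks)
        assert res.statistic == pytest.approx(kendall_tau_b_oracle(ranks, values))

    def test_exact_p_matches_scipy_when_no_ties(self):
        from scipy.stats import kendalltau

        rng = np.random.default_rng(4)
        for _ in range(5):
            vals = rng.permutation(7).astype(float)
            ranks = np.arange(7)
            res = kendall_ordered(vals, ranks)
            ref = kendalltau(ranks, vals, variant="b", method="exact")
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_constant_values_flagged_degenerate(self):
        res = kendall_ordered([2, 2, 2, 2], [1, 2, 3, 4])
        assert res.note.startswith("degenerate")
        assert np.isnan(res.statistic)

    def test_too_few_levels_rejected(self):
        with pytest.raises(InputError):
            kendall_ordered([1, 2, 3], [1, 1, 1])


class TestRankSum:
    def test_exact_example(self):
        """{1,2,3} vs {4,5,6}: fully separated groups, exact two-sided
        p = 0.1 from all C(6,3)=20 labelings."""
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)
        assert res.p_value == pytest.approx(rank_sum_exact_p([1, 2, 3], [4, 5, 6]))

    def test_identical_multisets_give_p_one(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert res.p_value == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        a, b = [1.2, 3.4, 2.2, 5.0], [0.3, 4.4, 6.1]
        assert wilcoxon_rank_sum(a, b).p_value == pytest.approx(
            wilcoxon_rank_sum(b, a).p_value
        )

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(8):
            a = rng.uniform(0, 1, int(rng.integers(2, 5))).tolist()
            b = rng.uniform(0, 1, int(rng.integers(2, 5))).tolist()
            assert wilcoxon_rank_sum(a, b).p_value == pytest.approx(
                rank_sum_exact_p(a, b)
            )

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            wilcoxon_rank_sum([], [1.0])


class TestSignedRank:
    def test_all_positive_diffs_exact(self):
        """Five positive differences: exact two-sided p = 2/32."""
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5])
        assert res.p_value == pytest.approx(0.0625)
        assert res.p_value == pytest.approx(signed_rank_exact_p([1, 2, 3, 4, 5]))

    def test_symmetric_diffs_give_p_one(self):
        assert wilcoxon_signed_rank([-1, 1]).p_value == pytest.approx(1.0)

    def test_negation_symmetry(self):
        d = [0.5, -1.2, 2.2, 3.0, -0.1, 0.7]
        assert wilcoxon_signed_rank(d).p_value == pytest.approx(
            wilcoxon_signed_rank([-x for x in d]).p_value
        )

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(8):
            d = rng.uniform(-1, 1, int(rng.integers(4, 9))).tolist()
            assert wilcoxon_signed_rank(d).p_value == pytest.approx(
                signed_rank_exact_p(d)
            )

    def test_all_zero_diffs_degenerate(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert res.p_value == 1.0
        assert res.note.startswith("degenerate")


class TestBHFDR:
    def test_hand_example_all_equal(self):
        out = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_adjusted_never_below_raw_and_matches_oracle(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(0, 1, 15)
        out = bh_fdr(p)
        assert np.all(out >= p - 1e-12)
        assert out == pytest.approx(bh_oracle(p.tolist()))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(0, 1, 10)
        perm = rng.permutation(10)
        assert bh_fdr(p)[perm] == pytest.approx(bh_fdr(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_fdr([0.5, 1.2])


class TestSpearmanMatrix:
    def _frames(self):
        idx = [f"s{i}" for i in range(6)]
        aux = pd.DataFrame(
            {"His": [1, 2, 3, 4, 5, 6], "Trp": [2, 1, 4, 3, 6, 5]}, index=idx
        )
        pep = pd.DataFrame(
            {"S09.001": [6, 5, 4, 3, 2, 1], "M16.001": [1, 1, 1, 1, 1, 1]}, index=idx
        )
        return aux, pep

    def test_rho_values_and_joint_adjustment(self):
        aux, pep = self._frames()
        df = spearman_matrix(aux, pep)
        his = df[(df.amino_acid == "His") & (df.merops_id == "S09.001")].iloc[0]
        assert his.rho == pytest.approx(-1.0)
        ok = df["p_value"].notna()
        assert df.loc[ok, "p_adjusted"].to_numpy() == pytest.approx(
            bh_oracle(df.loc[ok, "p_value"].tolist())
        )

    def test_hand_rho(self):
        idx = ["a", "b", "c", "d"]
        aux = pd.DataFrame({"His": [1, 2, 3, 4]}, index=idx)
        pep = pd.DataFrame({"X09.001": [3, 1, 2, 4]}, index=idx)
        df = spearman_matrix(aux, pep)
        # rank-difference formula by hand: 1 - 6*sum(d^2)/(n(n^2-1)) = 0.4
        assert df.iloc[0].rho == pytest.approx(0.4)

    def test_constant_column_flagged(self):
        aux, pep = self._frames()
        df = spearman_matrix(aux, pep)
        cell = df[(df.amino_acid == "His") & (df.merops_id == "M16.001")].iloc[0]
        assert cell.note == "degenerate" and np.isnan(cell.rho)

    def test_too_few_samples_rejected(self):
        aux, pep = self._frames()
        with pytest.raises(InputError):
            spearman_matrix(aux.iloc[:3], pep.iloc[:3])


class TestPCoA:
    def test_collinear_points(self):
        """Distances {1,1,2} are realizable on a line: one positive
        eigenvalue and embedded coordinates reproduce the distances."""
        D = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        coords, eigvals = pcoa(D)
        assert (eigvals > 1e-9).sum() == 1
        for i in range(3):
            for j in range(3):
                dist = np.linalg.norm(coords[i] - coords[j])
                assert dist == pytest.approx(D[i, j], abs=1e-9)

    def test_all_zero_distances(self):
        coords, eigvals = pcoa(np.zeros((4, 4)))
        assert eigvals == pytest.approx(np.zeros(4), abs=1e-12)
        assert coords.shape[1] == 0

    def test_trace_identity_for_euclidean_input(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(7, 3))
        D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
        _, eigvals = pcoa(D)
        centered = X - X.mean(axis=0)
        assert eigvals[eigvals > 1e-9].sum() == pytest.approx(
            (centered ** 2).sum(), abs=1e-8
        )

    def test_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(22)
        X = rng.normal(size=(6, 4))
        D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
        coords, eigvals = pcoa(D)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(D))
        ref_eig = np.sort(ref.eigvals.values)[::-1]
        assert eigvals[:5] == pytest.approx(ref_eig[:5], abs=1e-8)
        # coordinates agree up to per-axis sign
        for k in range(3):
            ours, theirs = coords[:, k], ref.samples.values[:, k]
            assert min(
                np.abs(ours - theirs).max(), np.abs(ours + theirs).max()
            ) < 1e-6

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(InputError, match="symmetric"):
            pcoa(D)


def _two_cluster_matrix(rng, n_per=3, sep=5.0):
    X = np.concatenate([
        rng.normal(0, 1, size=(n_per, 2)),
        rng.normal(sep, 1, size=(n_per, 2)),
    ])
    D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    labels = ["a"] * n_per + ["b"] * n_per
    return D, labels


class TestPermanova:
    def test_perfect_separation(self):
        """Two groups of identical points with positive between-group
        distance: R^2 = 1 and p at the enumeration floor."""
        D = np.array([
            [0, 0, 1, 1],
            [0, 0, 1, 1],
            [1, 1, 0, 0],
            [1, 1, 0, 0],
        ], dtype=float)
        res = permanova(D, ["a", "a", "b", "b"], seed=1)
        assert res.effect == pytest.approx(1.0)
        # 6 distinct arrangements; only the 2 perfect splits reach F=inf
        assert res.p_value == pytest.approx(2 / 6)

    def test_f_and_r2_match_definition_oracle(self):
        rng = np.random.default_rng(33)
        D, labels = _two_cluster_matrix(rng)
        res = permanova(D, labels, seed=5)
        f_ref, r2_ref = permanova_f_oracle(D, labels)
        assert res.statistic == pytest.approx(f_ref)
        assert res.effect == pytest.approx(r2_ref)
        assert 0.0 <= res.effect <= 1.0

    def test_exact_enumeration_matches_oracle_and_montecarlo(self):
        """3+3 toy matrix: the full 20-arrangement enumeration matches
        the oracle, and Monte-Carlo converges to it."""
        rng = np.random.default_rng(34)
        D, labels = _two_cluster_matrix(rng, n_per=3, sep=2.0)
        res = permanova(D, labels, seed=7)
        assert res.p_value == pytest.approx(permanova_exact_p_oracle(D, labels))
        # Monte-Carlo on a larger version of the same design
        D2, labels2 = _two_cluster_matrix(rng, n_per=10, sep=0.0)
        mc = permanova(D2, labels2, n_perm=499, seed=8)
        assert 0 < mc.p_value <= 1

    def test_matches_scikit_bio_statistic(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(35)
        D, labels = _two_cluster_matrix(rng, n_per=5, sep=1.0)
        res = permanova(D, labels, n_perm=99, seed=3)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(D), grouping=labels, permutations=99
        )
        assert res.statistic == pytest.approx(ref["test statistic"])

    def test_seeded_reproducibility_and_ss_partition(self):
        rng = np.random.default_rng(36)
        D, labels = _two_cluster_matrix(rng, n_per=9, sep=0.5)
        r1 = permanova(D, labels, n_perm=199, seed=42)
        r2 = permanova(D, labels, n_perm=199, seed=42)
        assert (r1.statistic, r1.p_value) == (r2.statistic, r2.p_value)

    def test_group_of_one_rejected(self):
        D = np.zeros((3, 3))
        with pytest.raises(InputError):
            permanova(D, ["a", "b", "b"])

    def test_null_p_values_approximately_uniform(self):
        """Under random labels the PERMANOVA p-value is uniform on its
        achievable values (KS check over 200 replicates)."""
        from scipy.stats import kstest

        rng = np.random.default_rng(37)
        pvals = []
        for _ in range(200):
            X = rng.normal(size=(12, 2))
            D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
            labels = rng.permutation(["a"] * 6 + ["b"] * 6)
            res = permanova(D, labels, n_perm=99, seed=int(rng.integers(2**31)))
            pvals.append(res.p_value)
        ks = kstest(pvals, "uniform")
        assert ks.pvalue > 0.005


class TestDifferentialScreen:
    def _groups(self, shift=0.0, n=20, seed=44):
        rng = np.random.default_rng(seed)
        base = rng.lognormal(-3.0, 0.4, size=(n, 4))  # medians ~ 5%
        a = pd.DataFrame(base + shift, columns=list("wxyz"),
                         index=[f"s{i}" for i in range(n)])
        b = pd.DataFrame(rng.lognormal(-3.0, 0.4, size=(n, 4)), columns=list("wxyz"),
                         index=[f"s{i}" for i in range(n)])
        return a, b

    def test_prevalence_filter(self):
        """Medians of 0.5% in both groups are excluded before testing;
        2% in one group only is included."""
        a = pd.DataFrame({"low": [0.005] * 6, "hi_in_a": [0.02] * 6})
        b = pd.DataFrame({"low": [0.004] * 6, "hi_in_a": [0.001] * 6})
        out = differential_peptidase_screen(a, b, paired=False)
        assert set(out.merops_id) == {"hi_in_a"}

    def test_planted_paired_shift_detected(self):
        """Group A = group B + constant on 20 paired samples: flagged
        significant with positive direction."""
        rng = np.random.default_rng(45)
        b = pd.DataFrame(
            rng.lognormal(-3.0, 0.3, size=(20, 3)), columns=["p1", "p2", "p3"],
            index=[f"s{i}" for i in range(20)],
        )
        a = b + 0.05
        out = differential_peptidase_screen(a, b, paired=True).set_index("merops_id")
        assert out["significant"].all()
        assert (out["direction"] == "up_in_A").all()
        # one-sided shift on n=20: far below the screen threshold
        assert out["p_value"].max() < 1e-3

    def test_unpaired_uses_rank_sum(self):
        a, b = self._groups(shift=0.5)
        out = differential_peptidase_screen(a, b, paired=False, alpha=0.05)
        assert out["significant"].all()

    def test_no_peptidase_passes_filter(self, caplog):
        a = pd.DataFrame({"x": [1e-4] * 5})
        b = pd.DataFrame({"x": [1e-4] * 5})
        with caplog.at_level("WARNING"):
            out = differential_peptidase_screen(a, b)
        assert out.empty

    def test_paired_without_matched_ids_rejected(self):
        a = pd.DataFrame({"x": [0.1] * 4}, index=list("abcd"))
        b = pd.DataFrame({"x": [0.1] * 4}, index=list("wxyz"))
        with pytest.raises(InputError, match="matched"):
            differential_peptidase_screen(a, b, paired=True)

    def test_null_type_one_error_rate(self):
        """Raw-p per-test rejection rate at alpha 0.05 under the complete
        null stays near nominal (300 quick replicates here; the full
        calibration lives in the acceptance suite)."""
        rng = np.random.default_rng(46)
        hits = trials = 0
        for _ in range(300):
            a = pd.DataFrame(rng.lognormal(-3.0, 0.4, size=(12, 3)))
            b = pd.DataFrame(rng.lognormal(-3.0, 0.4, size=(12, 3)))
            out = differential_peptidase_screen(a, b, paired=False,
                                                alpha=0.05, adjust=False)
            hits += int(out["significant"].sum())
            trials += len(out)
        rate = hits / trials
        assert 0.02 < rate < 0.08
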