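"""QC filters, association estimates, LD pruning and backward elimination."""

import numpy as np
import pandas as pd
import pytest

from gliorisk import (
    SimConfig,
    backward_select,
    hwe_test,
    interaction_scan,
    ld_prune,
    pairwise_r2,
    qc_filter,
    simulate_cohort,
    simulate_ld_pair,
    univariate_assoc,
)
from gliorisk.qc import AssocResult, cohort_assoc

from .conftest import make_snp


class TestHwe:
    @pytest.mark.parametrize(
        "counts,expected_p",
        [
            ((25, 50, 25), 1.0),  # exact HWE proportions at p=0.5
            ((36, 48, 16), 1.0),  # exact HWE proportions at p=0.4
            ((100, 0, 0), 1.0),  # monomorphic convention
        ],
    )
    def test_equilibrium_counts_give_p_one(self, counts, expected_p):
        assert hwe_test(counts) == pytest.approx(expected_p)

    def test_total_het_deficit_rejected(self):
        # (50, 0, 50): chi-square = n = 100 under the standard formula
        p = hwe_test((50, 0, 50))
        assert p < 1e-20

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_test((0, 0, 0))


class TestQcFilter:
    def _cohort(self, make_cohort, col):
        """A clean HWE column plus the column under test, 200/200 split."""
        rng = np.random.default_rng(0)
        n = 400
        base = rng.binomial(2, 0.3, size=(n, 1))
        dos = np.column_stack([base, col])
        return make_cohort(dos, np.r_[np.ones(n // 2), np.zeros(n // 2)])

    def test_passing_snp_kept(self, make_cohort):
        rng = np.random.default_rng(1)
        c = self._cohort(make_cohort, rng.binomial(2, 0.3, 400))
        rep = qc_filter(c)
        assert rep.loc[1, "kept"] and rep.loc[1, "drop_reason"] == "none"

    def test_low_maf_dropped(self, make_cohort):
        rng = np.random.default_rng(2)
        col = rng.binomial(2, 0.04, 400).astype(float)
        rep = qc_filter(self._cohort(make_cohort, col))
        assert rep.loc[1, "drop_reason"] == "maf"

    def test_low_call_rate_dropped(self, make_cohort):
        rng = np.random.default_rng(3)
        col = rng.binomial(2, 0.3, 400).astype(float)
        col[rng.random(400) < 0.10] = np.nan
        rep = qc_filter(self._cohort(make_cohort, col))
        assert rep.loc[1, "drop_reason"] == "call_rate"

    def test_hwe_violation_dropped(self, make_cohort):
        # all heterozygotes: gross HWE departure among controls
        col = np.ones(400)
        rep = qc_filter(self._cohort(make_cohort, col))
        assert rep.loc[1, "drop_reason"] == "hwe"

    def test_subject_call_rate_flagging(self, make_cohort):
        dos = np.tile([1.0, 1.0, 0.0], (10, 1))
        dos[0] = np.nan  # 0% genotyped
        c = make_cohort(dos, [1] * 5 + [0] * 5)
        rep = qc_filter(c)
        assert rep.attrs["subjects_flagged"] == [c.subject_ids[0]]

    def test_order_invariance(self, dataset2_cohort):
        """QC decisions do not depend on subject or SNP order."""
        rep = qc_filter(dataset2_cohort)
        rng = np.random.default_rng(0)
        perm = rng.permutation(dataset2_cohort.n_subjects)
        shuffled = dataset2_cohort.subset(perm)
        rep2 = qc_filter(shuffled)
        pd.testing.assert_frame_equal(rep, rep2)
        flipped = dataset2_cohort.select_snps(dataset2_cohort.snp_ids[::-1])
        rep3 = qc_filter(flipped).iloc[::-1].reset_index(drop=True)
        pd.testing.assert_frame_equal(rep, rep3)

    def test_no_controls_rejected(self, make_cohort):
        c = make_cohort([[0.0], [1.0], [2.0], [1.0]], [1, 1, 1, 0])
        c.is_case = np.ones(4, int)  # force all-case after validation
        with pytest.raises(ValueError, match="control"):
            qc_filter(c)


class TestUnivariateAssoc:
    def test_binary_dosage_equals_cross_product(self):
        """With a 0/1 dosage the logistic OR is the 2x2 cross-product."""
        dosage = np.r_[np.ones(30), np.zeros(70), np.ones(20), np.zeros(80)]
        y = np.r_[np.ones(100), np.zeros(100)]
        res = univariate_assoc(dosage, y)
        assert res.or_estimate == pytest.approx((30 * 80) / (70 * 20), rel=1e-5)

    def test_null_snp_or_near_one(self):
        panel = [make_snp("rs0", 0.4, 0.4)]
        c = simulate_cohort(panel, SimConfig(n_case=30000, n_ctrl=30000, seed=4))
        res = univariate_assoc(c.dosages[:, 0], c.is_case, snp_id="rs0")
        assert res.or_estimate == pytest.approx(1.0, abs=0.03)
        assert res.ci_low <= res.or_estimate <= res.ci_high

    def test_published_frequencies_recover_published_or(self):
        """Cohorts at the rs498872 frequencies (0.349 vs 0.285, n=743/900)
        give ORs inside the published CI (1.16-1.56) for most seeds."""
        panel = [make_snp("rs498872", 0.349, 0.285)]
        hits = 0
        for seed in range(12):
            c = simulate_cohort(panel, SimConfig(n_case=743, n_ctrl=900, seed=seed))
            res = univariate_assoc(c.dosages[:, 0], c.is_case)
            hits += 1.16 <= res.or_estimate <= 1.56
        assert hits >= 9

    def test_constant_dosage_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            univariate_assoc(np.ones(40), np.r_[np.ones(20), np.zeros(20)])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            univariate_assoc(np.r_[np.zeros(5), np.ones(5)], np.ones(10))


class TestPairwiseR2:
    def test_identical_columns_r2_one(self):
        col = np.array([0.0, 1, 2, 1, 0, 2, 1])
        assert pairwise_r2(col, col) == pytest.approx(1.0)

    def test_independent_columns_r2_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.binomial(2, 0.4, 50000).astype(float)
        b = rng.binomial(2, 0.4, 50000).astype(float)
        assert pairwise_r2(a, b) < 0.005

    def test_generator_estimator_round_trip(self):
        a, b = simulate_ld_pair(0.33, 0.27, 0.334, 50000, seed=6)
        assert pairwise_r2(a, b) == pytest.approx(0.334, abs=0.02)

    def test_too_few_pairs_rejected(self):
        a = np.array([0.0, np.nan, 1.0])
        b = np.array([np.nan, 1.0, 0.0])
        with pytest.raises(ValueError):
            pairwise_r2(a, b)


def _assoc(snp_id, p):
    return AssocResult(snp_id, 1.3, 1.1, 1.5, p)


class TestLdPrune:
    def test_linked_pair_keeps_more_significant(self):
        assoc = [_assoc("rsA", 1e-5), _assoc("rsB", 1e-2)]
        r2 = pd.DataFrame(
            [[1.0, 0.5], [0.5, 1.0]], index=["rsA", "rsB"],
            columns=["rsA", "rsB"],
        )
        assert ld_prune(assoc, r2) == ["rsA"]

    def test_unlinked_identity(self):
        assoc = [_assoc(f"rs{i}", 10 ** -i) for i in range(1, 4)]
        ids = [a.snp_id for a in assoc]
        r2 = pd.DataFrame(np.eye(3) + 0.1, index=ids, columns=ids)
        np.fill_diagonal(r2.values, 1.0)
        assert ld_prune(assoc, r2) == ids

    def test_clique_keeps_single_best(self):
        assoc = [_assoc("rsA", 1e-6), _assoc("rsB", 1e-4), _assoc("rsC", 1e-2)]
        ids = ["rsA", "rsB", "rsC"]
        r2 = pd.DataFrame(0.6, index=ids, columns=ids)
        np.fill_diagonal(r2.values, 1.0)
        assert ld_prune(assoc, r2) == ["rsA"]

    def test_tie_drops_lexicographically_larger(self):
        assoc = [_assoc("rsB", 1e-3), _assoc("rsA", 1e-3)]
        ids = ["rsB", "rsA"]
        r2 = pd.DataFrame([[1.0, 0.9], [0.9, 1.0]], index=ids, columns=ids)
        assert ld_prune(assoc, r2) == ["rsA"]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        ids = [f"rs{i}" for i in range(6)]
        ps = rng.uniform(1e-6, 0.5, 6)
        m = rng.uniform(0, 1, (6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        assoc = [_assoc(i, p) for i, p in zip(ids, ps)]
        r2 = pd.DataFrame(m, index=ids, columns=ids)
        kept = set(ld_prune(assoc, r2))
        perm = rng.permutation(6)
        assoc_p = [assoc[i] for i in perm]
        r2_p = r2.iloc[perm, perm]
        assert set(ld_prune(assoc_p, r2_p)) == kept


class TestBackwardSelect:
    def test_strong_single_snp_retained(self):
        panel = [make_snp("rs1", 0.391, 0.300)]  # per-allele OR 1.5
        c = simulate_cohort(panel, SimConfig(n_case=1000, n_ctrl=1000, seed=1))
        assert backward_select(c, ["rs1"]) == ["rs1"]

    def test_noise_snp_removed_at_test_level(self):
        """A pure-noise SNP next to a causal one survives only at the
        alpha_remove level (~5% of seeds)."""
        panel = [make_snp("rs1", 0.391, 0.300), make_snp("rs2", 0.3, 0.3)]
        removed = 0
        for seed in range(20):
            c = simulate_cohort(
                panel, SimConfig(n_case=1000, n_ctrl=1000, seed=seed)
            )
            removed += backward_select(c, ["rs1", "rs2"]) == ["rs1"]
        assert removed >= 16

    def test_alpha_one_returns_full_model(self, dataset2_cohort):
        ids = dataset2_cohort.snp_ids
        assert backward_select(dataset2_cohort, ids, alpha_remove=1.0) == ids

    def test_tiny_alpha_empties_noise_model(self):
        panel = [make_snp("rs1", 0.3, 0.3), make_snp("rs2", 0.4, 0.4)]
        c = simulate_cohort(panel, SimConfig(n_case=500, n_ctrl=500, seed=2))
        assert backward_select(c, ["rs1", "rs2"], alpha_remove=1e-12) == []

    def test_complete_case_restriction(self, make_cohort):
        """Subjects with a missing genotype are excluded from the fit."""
        rng = np.random.default_rng(5)
        dos = rng.binomial(2, 0.4, size=(200, 2)).astype(float)
        y = np.r_[np.ones(100), np.zeros(100)]
        dos[:50, 0] = np.nan
        c = make_cohort(dos, y)
        # should not raise despite missing values
        backward_select(c, ["rs1", "rs2"], alpha_remove=1.0)


class TestInteractionScan:
    def test_adjusted_p_monotone(self, dataset2_cohort):
        out = interaction_scan(dataset2_cohort)
        ok = out["p_value"].notna()
        assert (out.loc[ok, "p_fdr"] >= out.loc[ok, "p_value"] - 1e-12).all()
        assert len(out) == 10  # C(5, 2) pairs

    def test_true_interaction_detected(self):
        """A product-term coefficient of ln 2 at n=5000 is detected."""
        rng = np.random.default_rng(17)
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            a = rng.binomial(2, 0.4, 5000).astype(float)
            b = rng.binomial(2, 0.4, 5000).astype(float)
            eta = -0.5 + np.log(2) * a * b - 0.5 * a - 0.5 * b
            y = (rng.random(5000) < 1 / (1 + np.exp(-eta))).astype(int)
            from gliorisk.cohort import Cohort

            c = Cohort(
                np.column_stack([a, b]), y,
                [make_snp("rsA"), make_snp("rsB")],
            )
            out = interaction_scan(c)
            hits += out["p_value"].iloc[0] < 0.05
        assert hits >= 4

    def test_requires_two_snps(self, make_cohort):
        c = make_cohort([[0.0], [1.0], [2.0], [1.0]], [1, 1, 0, 0])
        with pytest.raises(ValueError):
            interaction_scan(c)


def test_adjusted_association_accepts_covariates(dataset2_cohort):
    res = cohort_assoc(dataset2_cohort, adjust=("fmc",))
    assert all(r.adjusted_for == ("fmc",) for r in res)
    assert all(np.isfinite(r.or_estimate) for r in res)
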