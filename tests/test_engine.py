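"""Design building, OLS testing, conditional scan, LD pruning, Box-Cox."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from condgwas import (
    DegenerateDesignError,
    GenotypeMatrix,
    PhenotypeTable,
    SNPSpec,
    boxcox_select,
    build_design,
    conditional_scan,
    fit_and_test,
    ld_prune,
    r_square,
    simulate_genotypes,
    simulate_phenotypes,
    slt_inflated_variance,
)


def make_pheno(y, sample_ids, **covariates):
    frame = pd.DataFrame({"phenotype": y, **covariates},
                         index=pd.Index(sample_ids, name="sample_id"))
    return PhenotypeTable(frame=frame)


@pytest.fixture
def small_dataset(rng):
    geno = simulate_genotypes([0.3, 0.4, 0.2], n=200, seed=42)
    y = simulate_phenotypes(geno, [0.5, 0.4, 0.3], seed=43)
    return geno, make_pheno(y, geno.sample_ids)


class TestBuildDesign:
    def test_column_count_is_one_plus_p_plus_s(self, small_dataset):
        geno, pheno = small_dataset
        y, X, used = build_design(pheno, geno, ["snp1", "snp2"], "snp3")
        assert X.shape == (200, 4)
        assert len(used) == 200

    def test_complete_case_drops_missing(self, small_dataset):
        geno, pheno = small_dataset
        geno.codes[0, 2] = np.nan
        y, X, used = build_design(pheno, geno, ["snp1", "snp2"], "snp3")
        assert X.shape[0] == 199
        # the same sample is kept for a test not using the missing column
        _, X_other, _ = build_design(pheno, geno, [], "snp1")
        assert X_other.shape == (200, 2)

    def test_empty_conditional_set_is_single_locus_design(self, small_dataset):
        geno, pheno = small_dataset
        _, X, _ = build_design(pheno, geno, [], "snp1")
        assert X.shape[1] == 2

    def test_covariates_included(self, small_dataset):
        geno, _ = small_dataset
        y = simulate_phenotypes(geno, [0, 0, 0], seed=1)
        pheno = make_pheno(y, geno.sample_ids, age=np.arange(200.0))
        _, X, _ = build_design(pheno, geno, ["snp1"], "snp2")
        assert X.shape[1] == 4  # intercept, age, snp1, snp2

    def test_candidate_in_conditional_rejected(self, small_dataset):
        geno, pheno = small_dataset
        with pytest.raises(ValueError, match="conditional set"):
            build_design(pheno, geno, ["snp1"], "snp1")

    def test_disjoint_sample_ids_rejected(self, small_dataset):
        geno, _ = small_dataset
        pheno = make_pheno(np.zeros(3), ["x1", "x2", "x3"])
        with pytest.raises(ValueError, match="shared sample ids"):
            build_design(pheno, geno, [], "snp1")


class TestFitAndTest:
    def test_noiseless_interpolation(self):
        g = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        X = np.column_stack([np.ones(6), g])
        res = fit_and_test(2.0 * g, X)
        assert res.beta_hat == pytest.approx(2.0, abs=1e-12)
        assert res.p_value < 1e-10

    def test_matches_normal_equations_and_statsmodels(self, rng):
        # brute-force oracle: beta = (X'X)^-1 X'y via explicit inverse;
        # statsmodels OLS as the independent second route
        import statsmodels.api as sm

        for _ in range(50):
            n = int(rng.integers(10, 31))
            k = int(rng.integers(2, 6))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
            y = rng.normal(size=n)
            res = fit_and_test(y, X, "two")
            xtx_inv = np.linalg.inv(X.T @ X)
            beta = xtx_inv @ X.T @ y
            resid = y - X @ beta
            s2 = resid @ resid / (n - k)
            se = np.sqrt(s2 * xtx_inv[-1, -1])
            assert res.beta_hat == pytest.approx(beta[-1], abs=1e-8)
            assert res.se == pytest.approx(se, abs=1e-8)
            assert res.t_stat == pytest.approx(beta[-1] / se, abs=1e-8)
            fit = sm.OLS(y, X).fit()
            assert res.beta_hat == pytest.approx(fit.params[-1], abs=1e-8)
            assert res.se == pytest.approx(fit.bse[-1], abs=1e-8)
            assert res.p_value == pytest.approx(fit.pvalues[-1], abs=1e-8)

    def test_one_sided_p_is_upper_tail(self, rng):
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        y = rng.normal(size=50) + 0.5 * X[:, 1]
        one = fit_and_test(y, X, "one")
        two = fit_and_test(y, X, "two")
        assert one.t_stat == two.t_stat
        assert one.p_value == pytest.approx(stats.t.sf(one.t_stat, one.df))

    def test_estimate_within_sampling_error(self):
        geno = simulate_genotypes([0.3, 0.4, 0.2], n=2000, seed=10)
        y = simulate_phenotypes(geno, [0.3, 0.2, 0.1], seed=11)
        X = np.column_stack([np.ones(2000), geno.codes])
        res = fit_and_test(y, X)
        assert abs(res.beta_hat - 0.1) < 3 * res.se

    def test_unbiased_for_planted_effect(self):
        estimates = []
        for rep in range(500):
            geno = simulate_genotypes([0.3, 0.2], n=400, seed=1000 + rep)
            y = simulate_phenotypes(geno, [0.4, 0.1], seed=5000 + rep)
            X = np.column_stack([np.ones(400), geno.codes])
            estimates.append(fit_and_test(y, X).beta_hat)
        estimates = np.asarray(estimates)
        mc_se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - 0.1) < 2 * mc_se

    def test_slt_residual_variance_converges_to_inflated_value(self):
        specs = (SNPSpec("a", 0.3, 0.5), SNPSpec("b", 0.4, 0.4))
        geno = simulate_genotypes([0.3, 0.4, 0.2], n=20_000, seed=21)
        y = simulate_phenotypes(geno, [0.5, 0.4, 0.1], seed=22)
        X = np.column_stack([np.ones(20_000), geno.codes[:, 2]])
        res = fit_and_test(y, X)
        sigma_hat2 = (res.se**2) / np.linalg.inv(X.T @ X)[-1, -1]
        assert sigma_hat2 == pytest.approx(
            slt_inflated_variance(1.0, specs), rel=0.02
        )

    def test_rank_deficient_design_rejected(self):
        col = np.arange(20.0)
        X = np.column_stack([np.ones(20), col, col])
        with pytest.raises(DegenerateDesignError):
            fit_and_test(np.zeros(20), X)

    def test_more_columns_than_rows_rejected(self):
        X = np.ones((3, 4))
        with pytest.raises(ValueError, match="insufficient"):
            fit_and_test(np.zeros(3), X)


class TestConditionalScan:
    def test_slt_equals_mlt_with_empty_conditional_set(self, small_dataset):
        geno, pheno = small_dataset
        slt, _ = conditional_scan(geno, pheno, ["snp1"], method="slt")
        mlt_empty, _ = conditional_scan(geno, pheno, [], method="mlt")
        # reduction must hold field for field, except the method label
        for a, b in zip(slt, mlt_empty):
            assert a.snp_id == b.snp_id
            assert a.beta_hat == b.beta_hat
            assert a.se == b.se
            assert a.t_stat == b.t_stat
            assert a.df == b.df
            assert a.p_value == b.p_value
            assert a.n_used == b.n_used

    def test_maf_filter_excludes_rare_snp(self):
        rng = np.random.default_rng(0)
        codes = rng.binomial(2, [0.3, 0.005], size=(1000, 2)).astype(float)
        geno = GenotypeMatrix(
            sample_ids=[f"S{i}" for i in range(1000)],
            snp_ids=["common", "rare"], codes=codes,
            chrom=np.array(["1", "1"], dtype=object), pos=np.array([100, 200]),
        )
        pheno = make_pheno(rng.normal(size=1000), geno.sample_ids)
        results, _ = conditional_scan(geno, pheno, [], maf_min=0.01)
        assert [r.snp_id for r in results] == ["common"]

    def test_conditional_snps_tested_leave_one_out(self, small_dataset):
        geno, pheno = small_dataset
        results, _ = conditional_scan(geno, pheno, ["snp1", "snp2"], "mlt")
        by_id = {r.snp_id: r for r in results}
        assert set(by_id) == {"snp1", "snp2", "snp3"}
        assert by_id["snp1"].conditional_ids == ("snp2",)
        assert by_id["snp3"].conditional_ids == ("snp1", "snp2")

    def test_unknown_conditional_id_lists_available(self, small_dataset):
        geno, pheno = small_dataset
        with pytest.raises(KeyError, match="available ids"):
            conditional_scan(geno, pheno, ["nope"])

    def test_collinear_snp_recorded_not_fatal(self, small_dataset):
        geno, pheno = small_dataset
        dup = GenotypeMatrix(
            sample_ids=geno.sample_ids,
            snp_ids=np.append(geno.snp_ids, "snp1_dup"),
            codes=np.column_stack([geno.codes, geno.codes[:, 0]]),
            chrom=np.append(geno.chrom, "1"),
            pos=np.append(geno.pos, 4000),
        )
        results, failures = conditional_scan(dup, pheno, ["snp1"], "mlt")
        assert "snp1_dup" in failures
        assert {r.snp_id for r in results} == {"snp1", "snp2", "snp3"}

    def test_mlt_more_significant_than_slt_on_planted_panels(self):
        # two strong confirmed effects + one weak candidate among null SNPs:
        # conditioning should usually sharpen the candidate's p-value
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            mafs = np.full(30, 0.25)
            mafs[:3] = [0.3, 0.4, 0.2]
            geno = simulate_genotypes(mafs, n=2000, seed=seed)
            effects = np.zeros(30)
            effects[:3] = [1.2, 1.0, 0.2]
            y = simulate_phenotypes(geno, effects, seed=10_000 + seed)
            pheno = make_pheno(y, geno.sample_ids)
            mlt, _ = conditional_scan(geno, pheno, ["snp1", "snp2"], "mlt")
            slt, _ = conditional_scan(geno, pheno, [], "slt")
            p_mlt = next(r.p_value for r in mlt if r.snp_id == "snp3")
            p_slt = next(r.p_value for r in slt if r.snp_id == "snp3")
            wins += p_mlt < p_slt
        assert wins > n_seeds / 2


class TestRSquare:
    def test_self_correlation_is_one(self, small_dataset):
        geno, _ = small_dataset
        assert r_square(geno, "snp1", "snp1") == pytest.approx(1.0)

    def test_linkage_equilibrium_null(self):
        geno = simulate_genotypes([0.3, 0.4], n=10_000, seed=8)
        assert r_square(geno, "snp1", "snp2") < 0.01

    def test_matches_direct_correlation(self, rng):
        a = rng.binomial(2, 0.3, 100).astype(float)
        b = a.copy()
        b[0] = 2.0 - b[0]  # one flipped genotype
        geno = GenotypeMatrix(
            sample_ids=[f"S{i}" for i in range(100)],
            snp_ids=["a", "b"], codes=np.column_stack([a, b]),
        )
        expected = np.corrcoef(a, b)[0, 1] ** 2
        assert r_square(geno, "a", "b") == pytest.approx(expected, abs=1e-12)

    def test_monomorphic_undefined(self):
        geno = GenotypeMatrix(
            sample_ids=["S1", "S2", "S3"],
            snp_ids=["a", "b"],
            codes=np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0]]),
        )
        with pytest.raises(ValueError, match="monomorphic"):
            r_square(geno, "a", "b")


def _correlated_snp(base, r_target, maf, rng):
    """Draw a column with roughly the requested code correlation to base."""
    alt = rng.binomial(2, maf, base.size).astype(float)
    keep = rng.random(base.size) < np.sqrt(r_target)
    out = np.where(keep, base, alt)
    return out


class TestLdPrune:
    def test_perfect_ld_keeps_larger_effect(self, rng):
        g = rng.binomial(2, 0.3, 500).astype(float)
        geno = GenotypeMatrix(
            sample_ids=[f"S{i}" for i in range(500)],
            snp_ids=["a", "b"], codes=np.column_stack([g, g]),
        )
        kept = ld_prune(
            [(SNPSpec("a", 0.3, 0.3), 100), (SNPSpec("b", 0.3, 0.2), 200)],
            geno, r2_threshold=0.8,
        )
        assert [s.label for s, _ in kept] == ["a"]

    def test_unlinked_snps_all_kept_in_genomic_order(self):
        geno = simulate_genotypes([0.3, 0.4, 0.2], n=2000, seed=13)
        candidates = [
            (SNPSpec("snp2", 0.4, 0.1), 200),
            (SNPSpec("snp1", 0.3, 0.3), 100),
            (SNPSpec("snp3", 0.2, 0.2), 300),
        ]
        kept = ld_prune(candidates, geno, r2_threshold=0.8)
        assert [s.label for s, _ in kept] == ["snp1", "snp2", "snp3"]

    def test_window_limits_comparisons(self, rng):
        g = rng.binomial(2, 0.3, 500).astype(float)
        geno = GenotypeMatrix(
            sample_ids=[f"S{i}" for i in range(500)],
            snp_ids=["a", "b"], codes=np.column_stack([g, g]),
        )
        kept = ld_prune(
            [(SNPSpec("a", 0.3, 0.3), 100), (SNPSpec("b", 0.3, 0.2), 5_000_000)],
            geno, r2_threshold=0.8, window=1_000_000,
        )
        assert [s.label for s, _ in kept] == ["a", "b"]

    def test_chain_matches_exhaustive_oracle(self, rng):
        # A-B and B-C in high LD, A-C not; effects 0.3 > 0.2 > 0.1.
        a = rng.binomial(2, 0.4, 4000).astype(float)
        b = _correlated_snp(a, 0.85, 0.4, rng)
        c = _correlated_snp(b, 0.85, 0.4, rng)
        geno = GenotypeMatrix(
            sample_ids=[f"S{i}" for i in range(4000)],
            snp_ids=["A", "B", "C"], codes=np.column_stack([a, b, c]),
        )
        r2 = {p: r_square(geno, *p) for p in [("A", "B"), ("B", "C"), ("A", "C")]}
        assert r2[("A", "B")] >= 0.8 and r2[("B", "C")] >= 0.8
        assert r2[("A", "C")] < 0.8
        cands = [(SNPSpec("A", 0.4, 0.3), 100), (SNPSpec("B", 0.4, 0.2), 200),
                 (SNPSpec("C", 0.4, 0.1), 300)]
        kept = {s.label for s, _ in ld_prune(cands, geno, 0.8)}

        # brute force: every subset valid under the pairwise rule, ranked by
        # the same greedy criterion (max total |effect|, ties by position)
        from itertools import combinations

        best, best_key = None, None
        for k in range(3, 0, -1):
            for combo in combinations(cands, k):
                labels = [s.label for s, _ in combo]
                ok = all(
                    r2[tuple(sorted((x, y)))] < 0.8
                    for x, y in combinations(labels, 2)
                )
                if not ok:
                    continue
                key = sorted((-abs(s.effect), p) for s, p in combo)
                if best is None or key < best_key:
                    best, best_key = set(labels), key
            if best is not None:
                break
        assert kept == best == {"A", "C"}


class TestBoxCox:
    def test_lognormal_recovers_log_transform(self, rng):
        y = np.exp(rng.normal(0.0, 1.0, 5000))
        lam, transformed, profile = boxcox_select(y, np.arange(-2, 2.01, 0.1))
        assert abs(lam) <= 0.2
        assert profile.argmax() == pytest.approx(
            np.abs(np.arange(-2, 2.01, 0.1) - lam).argmin()
        )

    def test_normal_recovers_identity(self, rng):
        y = rng.normal(10.0, 1.0, 5000)
        lam, _, _ = boxcox_select(y, np.arange(-2, 2.01, 0.1))
        assert abs(lam - 1.0) <= 0.3

    def test_single_value_grid(self, rng):
        y = np.exp(rng.normal(size=100))
        lam, transformed, profile = boxcox_select(y, [0.5])
        assert lam == 0.5
        assert profile.shape == (1,)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            boxcox_select(np.array([1.0, 0.0, 2.0]), [0.0, 1.0])
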