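"""Two-part adaptive association: indicator, branching, combination, runs."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, optimize, special, stats

from gripmir.association import (
    AssociationOptions,
    Branch,
    EmptyDataError,
    adaptive_p,
    associate_all,
    binary_indicator,
    classify_branch,
    impute_cell_counts,
    results_to_frame,
    sex_stratified,
)
from gripmir.io import CqMatrix
from gripmir.simulate import MirnaSpec, simulate_participants

from conftest import COVARIATES, build_cohort, small_params


# -- independent oracle for the 2-df combination ---------------------------

def chi2_1_sf(x):
    # survival of chi-square(1) via the error function, no scipy.stats
    return special.erfc(np.sqrt(x / 2.0))


def combined_p_oracle(p1, p2):
    """Quantile inversion by root bisection + numerical chi-square(2) tail."""
    x1 = optimize.brentq(lambda x: chi2_1_sf(x) - p1, 0.0, 400.0, xtol=1e-14)
    x2 = optimize.brentq(lambda x: chi2_1_sf(x) - p2, 0.0, 400.0, xtol=1e-14)
    s = x1 + x2
    tail, _ = integrate.quad(
        lambda t: 0.5 * np.exp(-t / 2.0), s, np.inf, epsabs=0.0, epsrel=1e-13
    )
    return tail


class TestBinaryIndicator:
    def test_printed_rule(self):
        cq = pd.Series([25.0, 27.5, np.inf, np.nan])
        x = binary_indicator(cq, 27.0)
        assert list(x[:3]) == [0.0, 1.0, 1.0]
        assert np.isnan(x.iloc[3])

    def test_all_detected(self):
        x = binary_indicator(pd.Series([20.0, 24.0, 26.9]), 27.0)
        assert (x == 0.0).all()

    def test_boundary_is_strictly_greater(self):
        # Cq exactly at the limit counts as detected
        assert binary_indicator(pd.Series([27.0]), 27.0).iloc[0] == 0.0

    def test_all_not_assayed_raises(self):
        with pytest.raises(EmptyDataError):
            binary_indicator(pd.Series([np.nan, np.nan]), 27.0)


class TestBranching:
    @pytest.mark.parametrize(
        "frac,expected",
        [
            (0.04, Branch.INELIGIBLE),
            (0.08, Branch.BINARY_ONLY),
            (0.50, Branch.COMBINED),
            (0.90, Branch.CONTINUOUS_ONLY),
            (0.95, Branch.CONTINUOUS_ONLY),
        ],
    )
    def test_routing(self, frac, expected):
        n = 1000
        prof = classify_branch("m", n, int(frac * n), eligibility_floor=50)
        assert prof.branch == expected

    def test_boundary_ninety_percent_is_continuous(self):
        prof = classify_branch("m", 1000, 900, eligibility_floor=50)
        assert prof.branch == Branch.CONTINUOUS_ONLY

    def test_partition_is_exhaustive(self):
        """Every detected count maps to exactly one branch."""
        seen = set()
        for k in range(0, 201):
            prof = classify_branch("m", 200, k, eligibility_floor=10)
            seen.add(prof.branch)
        assert seen == set(Branch)


class TestAdaptiveP:
    def test_unit_pvalues_combine_to_one(self):
        assert adaptive_p(1.0, 1.0, Branch.COMBINED) == pytest.approx(1.0)

    def test_equal_pair_frozen_value(self):
        # two p=0.05 components: statistic 2*3.8415, survival exp(-3.8415)
        assert adaptive_p(0.05, 0.05, Branch.COMBINED) == pytest.approx(
            np.exp(-stats.chi2.isf(0.05, 1)), rel=1e-12
        )
        assert adaptive_p(0.05, 0.05, Branch.COMBINED) == pytest.approx(0.0215, abs=5e-5)

    def test_table_pair_example(self):
        """A combined-branch pair seen in real panels (p_cont 1.91e-3,
        p_bin 2.30e-4) lands near 9e-6, matching the brute-force oracle."""
        got = adaptive_p(2.30e-4, 1.91e-3, Branch.COMBINED)
        want = combined_p_oracle(2.30e-4, 1.91e-3)
        assert got == pytest.approx(want, rel=1e-10)
        assert 8e-6 < got < 1.1e-5

    def test_oracle_equivalence_on_random_pairs(self, rng):
        for _ in range(100):
            p1, p2 = 10 ** (-4 * rng.random(2))
            assert adaptive_p(p1, p2, Branch.COMBINED) == pytest.approx(
                combined_p_oracle(p1, p2), rel=1e-10
            )

    def test_single_model_branches_pass_through(self):
        assert adaptive_p(0.3, None, Branch.BINARY_ONLY) == 0.3
        assert adaptive_p(None, 0.07, Branch.CONTINUOUS_ONLY) == 0.07

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            adaptive_p(0.0, 0.5, Branch.COMBINED)
        with pytest.raises(ValueError):
            adaptive_p(0.5, 1.5, Branch.COMBINED)
        with pytest.raises(ValueError):
            adaptive_p(None, 0.5, Branch.COMBINED)


class TestAssociateAll:
    def test_fully_detected_mirna_uses_continuous_only(self, small_cohort, covariates):
        params, cohort, cq = small_cohort
        results = {r.mirna: r for r in associate_all(cohort, cq, covariates)}
        r = results["miR-all"]
        assert r.profile.branch == Branch.CONTINUOUS_ONLY
        assert r.fit_binary is None  # indicator is constant: nothing to fit
        assert r.adaptive_p == r.fit_continuous.p

    def test_ineligible_mirna_excluded_from_fdr(self, small_cohort, covariates):
        _, cohort, cq = small_cohort
        results = {r.mirna: r for r in associate_all(cohort, cq, covariates)}
        r = results["miR-inelig"]
        assert r.profile.branch == Branch.INELIGIBLE
        assert r.adaptive_p is None and r.q is None

    def test_branch_counts_partition_eligible(self, small_cohort, covariates):
        _, cohort, cq = small_cohort
        results = associate_all(cohort, cq, covariates)
        eligible = [r for r in results if r.profile.branch != Branch.INELIGIBLE]
        assert all(r.adaptive_p is not None for r in eligible)
        assert len(results) == len(cq.values.columns)

    def test_row_permutation_invariance(self, small_cohort, covariates):
        """Shuffling participants (cohort and Cq rows together) leaves every
        estimate unchanged."""
        _, cohort, cq = small_cohort
        base = associate_all(cohort, cq, covariates)
        perm = np.random.default_rng(1).permutation(len(cohort))
        cohort2 = cohort.iloc[perm].reset_index(drop=True)
        cq2 = CqMatrix(cq.values.iloc[perm], threshold=cq.threshold)
        shuffled = associate_all(cohort2, cq2, covariates)
        for a, b in zip(base, shuffled):
            assert a.mirna == b.mirna
            if a.adaptive_p is not None:
                # summation order inside the REML profile shifts the optimum
                # by O(1e-8); the estimates are otherwise identical
                assert a.adaptive_p == pytest.approx(b.adaptive_p, rel=1e-6)

    def test_null_cohort_type_one_error(self, covariates):
        """All-null miRNAs: the fraction of adaptive p < 0.05 stays inside
        a 3-sigma binomial band around 0.05."""
        specs = [MirnaSpec(f"m{i:03d}", f) for i, f in enumerate(np.linspace(0.12, 1.0, 60))]
        pvals = []
        for seed in (201, 202):
            params = small_params(n=500, mirna_specs=[MirnaSpec(s.name, s.target_detection_fraction) for s in specs], seed=seed)
            cohort, cq = build_cohort(params)
            res = associate_all(cohort, cq, covariates)
            pvals += [r.adaptive_p for r in res if r.adaptive_p is not None]
        pvals = np.asarray(pvals)
        m = len(pvals)
        band = 3 * np.sqrt(0.05 * 0.95 / m)
        assert abs((pvals < 0.05).mean() - 0.05) < band

    def test_results_frame_schema(self, small_cohort, covariates):
        _, cohort, cq = small_cohort
        df = results_to_frame(associate_all(cohort, cq, covariates))
        assert list(df.columns[:4]) == ["mirna", "n", "n_detected", "detected_fraction"]
        assert set(df.branch) <= {b.value for b in Branch}
        assert (df.mirna.sort_values() == df.mirna).all()


class TestSexStratified:
    def test_restricted_to_highly_detected(self, small_cohort, covariates):
        _, cohort, cq = small_cohort
        strata = sex_stratified(cohort, cq, covariates)
        for res in strata.values():
            assert {r.mirna for r in res} <= {"miR-high", "miR-all"}

    def test_single_sex_cohort_yields_empty_stratum(self, covariates):
        params = small_params(prop_women=0.0, n=300)
        cohort, cq = build_cohort(params)
        strata = sex_stratified(cohort, cq, covariates)
        assert strata["F"] == []
        assert len(strata["M"]) > 0

    def test_sex_dropped_from_covariates(self, small_cohort, covariates):
        """Stratified designs must not contain the constant sex column."""
        _, cohort, cq = small_cohort
        strata = sex_stratified(cohort, cq, covariates)  # sex included; dropped inside
        for res in strata.values():
            for r in res:
                if r.fit_continuous is not None:
                    assert r.fit_continuous.converged


class TestCellCountImputation:
    @staticmethod
    def _expression(n, p, seed):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(size=(n, p)),
            index=pd.Index([f"P{i:04d}" for i in range(n)], name="participant_id"),
            columns=[f"g{j}" for j in range(p)],
        )

    def test_noiseless_linear_counts_recovered(self):
        """Counts that are exact linear functions of three genes are
        recovered with held-out R^2 > 0.99."""
        expr = self._expression(300, 20, 0)
        truth = 2.0 + expr["g0"] - 0.5 * expr["g3"] + 0.25 * expr["g7"]
        measured = pd.DataFrame(
            {"participant_id": expr.index, "wbc": truth.to_numpy()}
        )
        hidden = np.arange(200, 300)
        measured.loc[hidden, "wbc"] = np.nan
        out = impute_cell_counts(expr, measured, seed=0)
        pred = out.loc[hidden, "wbc"].to_numpy()
        want = truth.to_numpy()[hidden]
        r2 = 1 - ((pred - want) ** 2).sum() / ((want - want.mean()) ** 2).sum()
        assert r2 > 0.99

    def test_measured_rows_pass_through(self):
        expr = self._expression(100, 10, 1)
        vals = np.r_[np.random.default_rng(2).normal(5, 1, 60), [np.nan] * 40]
        measured = pd.DataFrame({"participant_id": expr.index, "rbc": vals})
        out = impute_cell_counts(expr, measured, seed=0)
        np.testing.assert_array_equal(out.loc[:59, "rbc"].to_numpy(), vals[:60])
        assert out["rbc"].notna().all()

    def test_pure_noise_counts_predict_near_training_mean(self):
        """With no expression-count signal, CV picks few components and the
        imputations do not beat the mean predictor by a wide margin."""
        rng = np.random.default_rng(3)
        expr = self._expression(300, 15, 4)
        vals = rng.normal(10, 2, 300)
        truth = vals.copy()
        measured = pd.DataFrame({"participant_id": expr.index, "plt": vals})
        hidden = np.arange(200, 300)
        measured.loc[hidden, "plt"] = np.nan
        out = impute_cell_counts(expr, measured, seed=0)
        pred = out.loc[hidden, "plt"].to_numpy()
        mean_pred_rmse = np.sqrt(((truth[hidden] - vals[:200].mean()) ** 2).mean())
        pls_rmse = np.sqrt(((truth[hidden] - pred) ** 2).mean())
        assert pls_rmse < 1.5 * mean_pred_rmse
        assert np.std(pred) < 1.0  # predictions hug the training mean
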