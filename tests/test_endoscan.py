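"""Association scans, Fisher combination, BH, and the multivariate model."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaincc

from famendo import (
    assoc_scan,
    bh_adjust,
    blup,
    fisher_combine,
    fit_multivariate,
    fit_polygenic,
    joint_endophenotype_test,
    simulate_expression,
)


def fisher_oracle(pvals):
    """Log-sum plus regularized incomplete gamma, no chi2 calls."""
    stat = -2.0 * sum(math.log(p) for p in pvals)
    k = len(pvals)
    return stat, float(gammaincc(k, stat / 2.0))


def bh_oracle(pvals):
    """Literal step-up definition: q_(i) = min over j >= i of m p_(j)/j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(order):
        q[i] = min(
            min(m * pvals[order[j]] / (j + 1) for j in range(rank_pos, m)), 1.0
        )
    return q


class TestFisherCombine:
    def test_single_p_identity(self):
        res = fisher_combine([0.2])
        assert res.p_combined == pytest.approx(0.2, abs=1e-12)
        assert res.df == 2

    def test_all_ones(self):
        res = fisher_combine([1.0, 1.0, 1.0])
        assert res.chi2 == 0.0
        assert res.p_combined == 1.0

    def test_agrees_with_gamma_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            k = rng.integers(1, 8)
            p = rng.uniform(1e-6, 1.0, size=k)
            res = fisher_combine(p)
            stat, tail = fisher_oracle(p)
            assert res.chi2 == pytest.approx(stat, abs=1e-10)
            assert res.p_combined == pytest.approx(tail, abs=1e-10)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.2], []])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            fisher_combine(bad)


class TestBhAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4, atol=1e-12
        )

    def test_single_p(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(32)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_matches_brute_force_on_subsets(self):
        rng = np.random.default_rng(33)
        base = rng.uniform(0.001, 1.0, size=8).tolist()
        for r in range(1, 9):
            for subset in itertools.combinations(base, r):
                np.testing.assert_allclose(
                    bh_adjust(list(subset)), bh_oracle(list(subset)), atol=1e-12
                )

    def test_q_dominates_p_over_m(self):
        rng = np.random.default_rng(34)
        p = rng.uniform(size=30)
        q = bh_adjust(p)
        assert np.all(q >= p * (1.0 / len(p)))
        assert np.all(q <= 1.0)


class TestAssocScan:
    def test_self_association_detected(self, family_pedigree, family_eig):
        n = len(family_pedigree)
        latent, _ = simulate_expression(
            family_pedigree, family_eig.A, 1, h2=0.8, total_var=1.0, seed=35
        )
        y = latent.to_numpy()[:, 0]
        roster = family_eig.A.roster
        endo = pd.DataFrame({"G": y - y.mean()}, index=roster)
        phenos = pd.DataFrame({"T": y}, index=roster)
        out = assoc_scan(endo, phenos, family_eig)
        rec = out.iloc[0]
        assert rec["beta"] == pytest.approx(1.0, abs=1e-6)
        assert rec["p"] < 1e-10

    def test_beta_antisymmetric_under_negation(self, family_pedigree, family_eig):
        rng = np.random.default_rng(36)
        n = len(family_pedigree)
        roster = family_eig.A.roster
        latent, _ = simulate_expression(
            family_pedigree, family_eig.A, 2, h2=0.5, total_var=1.0, seed=37
        )
        endo = pd.DataFrame({"G": rng.normal(size=n)}, index=roster)
        phenos = pd.DataFrame({"T": latent.to_numpy()[:, 0]}, index=roster)
        a = assoc_scan(endo, phenos, family_eig).iloc[0]
        b = assoc_scan(-endo, phenos, family_eig).iloc[0]
        assert a["beta"] == pytest.approx(-b["beta"], abs=1e-10)
        assert a["p"] == pytest.approx(b["p"], abs=1e-10)

    def test_zero_variance_column_skipped(self, family_pedigree, family_eig):
        n = len(family_pedigree)
        roster = family_eig.A.roster
        rng = np.random.default_rng(38)
        endo = pd.DataFrame(
            {"flat": np.zeros(n), "ok": rng.normal(size=n)}, index=roster
        )
        phenos = pd.DataFrame({"T": rng.normal(size=n)}, index=roster)
        out = assoc_scan(endo, phenos, family_eig)
        assert set(out["gene_id"]) == {"ok"}

    def test_null_type_one_error_small(self, family_pedigree, family_eig):
        # reduced-size calibration; the full 500-gene check runs in the
        # acceptance suite
        n = len(family_pedigree)
        roster = family_eig.A.roster
        rng = np.random.default_rng(39)
        latent, _ = simulate_expression(
            family_pedigree, family_eig.A, 1, h2=0.4, total_var=1.0, seed=40
        )
        endo = pd.DataFrame(
            rng.normal(size=(n, 150)),
            index=roster, columns=[f"g{j}" for j in range(150)],
        )
        phenos = pd.DataFrame({"T": latent.to_numpy()[:, 0]}, index=roster)
        out = assoc_scan(endo, phenos, family_eig)
        rate = float((out["p"] < 0.05).mean())
        assert 0.0 <= rate < 0.11

    def test_injected_causal_gene_detected(self, big_pedigree, big_eig):
        n = len(big_pedigree)
        roster = big_eig.A.roster
        X = np.ones((n, 1))
        hits = 0
        for rep in range(8):
            latent, truth = simulate_expression(
                big_pedigree, big_eig.A, 1, h2=0.6, total_var=1.0,
                seed=500 + rep,
            )
            g_true = truth.true_genetic_values[:, 0]
            rng = np.random.default_rng(600 + rep)
            y = 0.5 * g_true / g_true.std() + rng.normal(size=n)
            expr = latent.to_numpy()[:, 0]
            fit = fit_polygenic(expr, X, big_eig)
            endo_col = blup(fit, expr, X, big_eig)
            endo = pd.DataFrame({"causal": endo_col}, index=roster)
            phenos = pd.DataFrame({"T": y}, index=roster)
            out = assoc_scan(endo, phenos, big_eig)
            hits += out.iloc[0]["p"] < 0.01
        assert hits >= 6


class TestPermutationCalibration:
    def test_null_gene_not_rejected_and_causal_gene_is(self, family_pedigree,
                                                       family_eig):
        n = len(family_pedigree)
        _, truth = simulate_expression(
            family_pedigree, family_eig.A, 1, h2=0.6, total_var=1.0, seed=53
        )
        shared = truth.true_genetic_values[:, 0]
        rng = np.random.default_rng(54)
        Y = pd.DataFrame(
            {
                "a": shared + 0.5 * rng.standard_normal(n),
                "b": shared + 0.5 * rng.standard_normal(n),
            },
            index=family_eig.A.roster,
        )
        from famendo import fisher_combine_permutation

        _, p_null = fisher_combine_permutation(
            rng.standard_normal(n), Y, family_eig, n_perm=200, seed=1
        )
        assert p_null > 0.01
        _, p_causal = fisher_combine_permutation(
            shared, Y, family_eig, n_perm=200, seed=1
        )
        assert p_causal < 0.02

    def test_deterministic_for_fixed_seed(self, family_eig):
        n = len(family_eig.A)
        rng = np.random.default_rng(55)
        Y = pd.DataFrame({"a": rng.standard_normal(n)},
                         index=family_eig.A.roster)
        g = rng.standard_normal(n)
        from famendo import fisher_combine_permutation

        a = fisher_combine_permutation(g, Y, family_eig, n_perm=50, seed=9)
        b = fisher_combine_permutation(g, Y, family_eig, n_perm=50, seed=9)
        assert a == b


class TestMultivariate:
    def test_t1_reduces_to_univariate(self, family_pedigree, family_eig):
        latent, _ = simulate_expression(
            family_pedigree, family_eig.A, 1, h2=0.5, total_var=1.0, seed=41
        )
        n = len(family_pedigree)
        X = np.ones((n, 1))
        Y = pd.DataFrame({"t": latent.to_numpy()[:, 0]},
                         index=family_eig.A.roster)
        mv = fit_multivariate(Y, X, family_eig, seed=0)
        uv = fit_polygenic(Y["t"].to_numpy(), X, family_eig, method="ML")
        assert mv.loglik == pytest.approx(uv.loglik, abs=1e-6)
        assert mv.Sigma_g[0, 0] == pytest.approx(uv.sigma2_g, abs=1e-4)

    def test_diagonal_constraint_factorizes(self, family_pedigree, family_eig):
        latent, _ = simulate_expression(
            family_pedigree, family_eig.A, 2, h2=[0.5, 0.3], total_var=1.0,
            seed=42,
        )
        n = len(family_pedigree)
        X = np.ones((n, 1))
        Y = pd.DataFrame(latent.to_numpy(), index=family_eig.A.roster,
                         columns=["a", "b"])
        mv = fit_multivariate(Y, X, family_eig, diagonal=True, seed=0)
        lls = [
            fit_polygenic(Y[c].to_numpy(), X, family_eig, method="ML").loglik
            for c in Y.columns
        ]
        assert mv.loglik == pytest.approx(sum(lls), abs=1e-4)

    def test_matches_dense_kronecker_likelihood(self, family_pedigree,
                                                family_eig):
        latent, _ = simulate_expression(
            family_pedigree, family_eig.A, 2, h2=0.5, total_var=1.0, seed=43
        )
        n = len(family_pedigree)
        X = np.ones((n, 1))
        Y = pd.DataFrame(latent.to_numpy(), index=family_eig.A.roster,
                         columns=["a", "b"])
        mv = fit_multivariate(Y, X, family_eig, seed=0)
        # dense oracle: 2n x 2n covariance assembled explicitly
        A = family_eig.A.values
        V = np.kron(mv.Sigma_g, A) + np.kron(mv.Sigma_e, np.eye(n))
        XX = np.kron(np.eye(2), X)
        vec_y = Y.to_numpy().T.reshape(-1)  # trait-major stacking
        L = np.linalg.cholesky(V)
        yw = np.linalg.solve(L, vec_y)
        Xw = np.linalg.solve(L, XX)
        beta = np.linalg.solve(Xw.T @ Xw, Xw.T @ yw)
        resid = yw - Xw @ beta
        ll_dense = -0.5 * (
            2 * n * math.log(2 * math.pi)
            + 2.0 * float(np.sum(np.log(np.diag(L))))
            + float(resid @ resid)
        )
        assert mv.loglik == pytest.approx(ll_dense, abs=1e-5)

    def test_genetic_correlation_recovery(self, family_pedigree, family_eig):
        # traits share half their genetic variance through a common factor
        n = len(family_pedigree)
        X = np.ones((n, 1))
        ests = []
        for rep in range(5):
            latent, truth = simulate_expression(
                family_pedigree, family_eig.A, 3, h2=1.0, total_var=1.0,
                seed=700 + rep,
            )
            g = truth.true_genetic_values
            rng = np.random.default_rng(800 + rep)
            rho = 0.6
            g1 = g[:, 0]
            g2 = rho * g[:, 0] + math.sqrt(1 - rho**2) * g[:, 1]
            y1 = g1 + rng.normal(scale=0.8, size=n)
            y2 = g2 + rng.normal(scale=0.8, size=n)
            Y = pd.DataFrame({"a": y1, "b": y2}, index=family_eig.A.roster)
            mv = fit_multivariate(Y, X, family_eig, seed=rep)
            ests.append(mv.genetic_correlation[0, 1])
        assert abs(np.mean(ests) - 0.6) < 0.2

    def test_too_many_traits_rejected(self, family_eig):
        n = len(family_eig.A)
        Y = pd.DataFrame(
            np.random.default_rng(44).normal(size=(n, 7)),
            index=family_eig.A.roster, columns=list("abcdefg"),
        )
        with pytest.raises(ValueError, match="limited"):
            fit_multivariate(Y, np.ones((n, 1)), family_eig)


class TestJointTest:
    def test_null_p_not_extreme(self, family_pedigree, family_eig):
        n = len(family_pedigree)
        latent, _ = simulate_expression(
            family_pedigree, family_eig.A, 2, h2=0.4, total_var=1.0, seed=45
        )
        Y = pd.DataFrame(latent.to_numpy(), index=family_eig.A.roster,
                         columns=["a", "b"])
        rng = np.random.default_rng(46)
        ps = [
            joint_endophenotype_test(Y, rng.standard_normal(n), family_eig,
                                     seed=r)
            for r in range(12)
        ]
        # independent predictors: p should look uniform, never all tiny
        assert min(ps) > 1e-4
        assert max(ps) > 0.2

    def test_shared_signal_detected(self, family_pedigree, family_eig):
        n = len(family_pedigree)
        latent, truth = simulate_expression(
            family_pedigree, family_eig.A, 3, h2=0.6, total_var=1.0, seed=47
        )
        g = truth.true_genetic_values[:, 0]
        rng = np.random.default_rng(48)
        Y = pd.DataFrame(
            {
                "a": 0.6 * g + rng.normal(size=n),
                "b": latent.to_numpy()[:, 1],
                "c": latent.to_numpy()[:, 2],
            },
            index=family_eig.A.roster,
        )
        p = joint_endophenotype_test(Y, g, family_eig, seed=0)
        assert p < 0.05

    def test_zero_variance_endophenotype_rejected(self, family_eig):
        n = len(family_eig.A)
        Y = pd.DataFrame(
            np.random.default_rng(49).normal(size=(n, 2)),
            index=family_eig.A.roster, columns=["a", "b"],
        )
        with pytest.raises(ValueError, match="variance"):
            joint_endophenotype_test(Y, np.zeros(n), family_eig)
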