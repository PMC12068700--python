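import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import resphylo as rp
from resphylo.pgls import PGLSError


def gls_normal_equations(x, y, V):
    """Independent oracle: explicit (X' V^-1 X)^-1 X' V^-1 y."""
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    resid = y - X @ beta
    sigma2 = resid @ Vi @ resid / (n - 2)
    se = np.sqrt(sigma2 * np.linalg.inv(X.T @ Vi @ X)[1, 1])
    t = beta[1] / se
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return beta, se, t, p


def random_spd(n, rng):
    A = rng.normal(size=(n, n))
    return A @ A.T + n * np.eye(n)


class TestPGLSFit:
    def test_identity_covariance_reduces_to_ols_exact_line(self):
        fit = rp.pgls_fit([1, 2, 3], [2, 4, 6], np.eye(3))
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)

    def test_hand_solved_three_taxon_example(self):
        V = np.array([[2.0, 1, 0], [1, 2, 0], [0, 0, 2]])
        x = np.array([0.0, 1, 2])
        y = np.array([1.0, 1, 3])
        beta, se, t, p = gls_normal_equations(x, y, V)
        fit = rp.pgls_fit(x, y, V)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)
        assert fit.se_slope == pytest.approx(se, abs=1e-10)

    def test_constant_response_gives_null_test(self):
        fit = rp.pgls_fit([1.0, 2, 3, 5], [4.0, 4, 4, 4], np.eye(4))
        assert fit.slope == pytest.approx(0.0, abs=1e-10)
        assert fit.t_stat == 0.0
        assert fit.p_value == 1.0

    def test_constant_predictor_flagged(self):
        fit = rp.pgls_fit([2.0, 2, 2], [1.0, 2, 3], np.eye(3))
        assert fit.status == "constant_predictor"
        assert fit.slope is None and fit.p_value is None

    @pytest.mark.parametrize("c", [0.25, 1.0, 7.5])
    def test_scaled_identity_matches_ols_exactly(self, c):
        rng = np.random.default_rng(17)
        x = rng.normal(size=9)
        y = 1.5 * x + rng.normal(size=9)
        ols = stats.linregress(x, y)
        fit = rp.pgls_fit(x, y, c * np.eye(9))
        assert fit.slope == pytest.approx(ols.slope, abs=1e-10)
        assert fit.intercept == pytest.approx(ols.intercept, abs=1e-10)
        assert fit.p_value == pytest.approx(ols.pvalue, abs=1e-10)

    def test_matches_normal_equation_oracle_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(4, 13))
            V = random_spd(n, rng)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            beta, se, t, p = gls_normal_equations(x, y, V)
            fit = rp.pgls_fit(x, y, V)
            assert abs(fit.slope - beta[1]) < 1e-8
            assert abs(fit.se_slope - se) < 1e-8
            assert abs(fit.p_value - p) < 1e-8

    def test_matches_frozen_nlme_gls_oracle(self, oracle_tree, oracle_data):
        """Frozen external oracle: R nlme::gls(y ~ x, corBrownian, ML) on the
        same tree and data."""
        cov = rp.bm_covariance(oracle_tree)
        perm = [list(oracle_data.species).index(t) for t in cov.taxa]
        x = oracle_data.x.to_numpy()[perm]
        y = oracle_data.y.to_numpy()[perm]
        fit = rp.pgls_fit(x, y, cov)
        assert fit.intercept == pytest.approx(10.1873324563, abs=1e-8)
        assert fit.slope == pytest.approx(0.3885905453, abs=1e-8)
        assert fit.se_slope == pytest.approx(2.7131831449, abs=1e-8)
        assert fit.t_stat == pytest.approx(0.1432231164, abs=1e-8)
        assert fit.p_value == pytest.approx(0.8889588602, abs=1e-8)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_taxon_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        V = random_spd(n, rng)
        x = rng.normal(size=n)
        y = x + rng.normal(size=n)
        perm = rng.permutation(n)
        f1 = rp.pgls_fit(x, y, V)
        f2 = rp.pgls_fit(x[perm], y[perm], V[np.ix_(perm, perm)])
        assert f1.slope == pytest.approx(f2.slope, abs=1e-9)
        assert f1.p_value == pytest.approx(f2.p_value, abs=1e-9)

    def test_singular_covariance_reports_condition_number(self):
        V = np.ones((4, 4))
        with pytest.raises(PGLSError, match="condition number"):
            rp.pgls_fit([1.0, 2, 3, 4], [1.0, 2, 3, 4], V)


def make_screen_inputs(seed=11, **cfg_kwargs):
    cfg = rp.SimConfig(seed=seed, **cfg_kwargs)
    b = rp.make_dataset(cfg)
    aln, tree, traits = rp.harmonize(b.alignment, b.tree, b.traits)
    res = rp.compute_res(aln)
    cov = rp.bm_covariance(tree)
    return b, aln, traits, res, cov


class TestSiteScreen:
    def test_constant_columns_never_become_rplars(self):
        b, aln, traits, res, cov = make_screen_inputs(
            n_taxa=12, L_total=10, linked_columns=(), neutral_rate=0.0)
        fits, rplars = rp.site_screen(res, traits, cov)
        assert all(f.status == "constant_predictor" for f in fits)
        assert len(rplars) == 0

    def test_strong_single_column_detected(self):
        hits = 0
        for s in range(10):
            b, aln, traits, res, cov = make_screen_inputs(
                seed=3000 + s, n_taxa=60, L_total=40, linked_columns=(17,),
                effect=1.0)
            _, rplars = rp.site_screen(res, traits, cov)
            hits += 17 in set(rplars["column"])
        assert hits >= 9

    def test_lambda_zero_screen_equals_ols(self):
        b, aln, traits, res, cov = make_screen_inputs(
            n_taxa=20, L_total=15, linked_columns=(4,))
        cov0 = rp.lambda_transform(cov, 0.0)
        fits, _ = rp.site_screen(res, traits, cov0)
        y = traits.lifespan().loc[res.ids].to_numpy()
        for f in fits:
            if f.status != "ok":
                continue
            jx = list(res.columns).index(f.column)
            x = res.scores[:, jx]
            # lambda=0 keeps unequal diagonals, so compare against weighted
            # OLS with those variances
            w = 1.0 / np.sqrt(np.diag(cov0.V))
            ols = stats.linregress(x, y)  # sanity only; exact check below
            beta, se, t, p = gls_normal_equations(x, y, cov0.V)
            assert f.slope == pytest.approx(beta[1], abs=1e-9)
            assert f.p_value == pytest.approx(p, abs=1e-9)

    def test_bh_correction_is_more_conservative(self):
        b, aln, traits, res, cov = make_screen_inputs(
            seed=5, n_taxa=60, L_total=120)
        _, raw = rp.site_screen(res, traits, cov, correction=None)
        _, bh = rp.site_screen(res, traits, cov, correction="bh")
        assert set(bh["column"]) <= set(raw["column"])


class TestJointModelFit:
    def test_aic_identity_and_single_column_consistency(self):
        b, aln, traits, res, cov = make_screen_inputs(
            n_taxa=30, L_total=20, linked_columns=(7,))
        jm = rp.joint_model_fit(res, traits, cov, [7])
        assert jm.aic == pytest.approx(2 * jm.k - 2 * jm.loglik, abs=1e-9)
        assert jm.k == 3
        # same beta-hat as the per-site fit
        fit = [f for f in rp.site_screen(res, traits, cov)[0]
               if f.column == 7][0]
        y = traits.lifespan().loc[res.ids].to_numpy()
        jx = list(res.columns).index(7)
        perm = [cov.taxa.index(t) for t in res.ids]
        V = cov.V[np.ix_(perm, perm)]
        beta, _, _, _ = gls_normal_equations(res.scores[:, jx], y, V)
        assert fit.slope == pytest.approx(beta[1], abs=1e-9)

    def test_matches_frozen_nlme_loglik(self, oracle_tree, oracle_data):
        """nlme::gls ML logLik=-31.38244147, AIC=68.76488293 on the oracle
        dataset with one predictor."""
        cov = rp.bm_covariance(oracle_tree)
        order = list(oracle_data.species)
        res = rp.RESMatrix(
            oracle_data.x.to_numpy()[:, None], order, np.array([1]))
        traits = rp.TraitTable(pd.DataFrame({
            "species": order, "L_avg": oracle_data.y.to_numpy(),
            "L_max": np.nan}))
        jm = rp.joint_model_fit(res, traits, cov, [1])
        assert jm.loglik == pytest.approx(-31.38244147, abs=1e-6)
        assert jm.aic == pytest.approx(68.76488293, abs=1e-6)

    def test_true_columns_fit_better_than_random_disjoint(self):
        wins = 0
        for s in range(20):
            b, aln, traits, res, cov = make_screen_inputs(
                seed=8000 + s, n_taxa=60, L_total=60,
                linked_columns=(10, 25, 40))
            truth = [10, 25, 40]
            rng = np.random.default_rng(s)
            pool = [c for c in range(1, 61) if c not in truth]
            alt = sorted(rng.choice(pool, size=3, replace=False).tolist())
            try:
                aic_true = rp.joint_model_fit(res, traits, cov, truth).aic
                aic_alt = rp.joint_model_fit(res, traits, cov, alt).aic
            except PGLSError:
                continue
            wins += aic_true < aic_alt
        assert wins >= 16

    def test_rank_deficient_design_reports_columns(self):
        b, aln, traits, res, cov = make_screen_inputs(
            n_taxa=12, L_total=10, linked_columns=(3,))
        dup = rp.RESMatrix(
            np.column_stack([res.scores[:, 2], res.scores[:, 2]]),
            res.ids, np.array([3, 4]))
        with pytest.raises(PGLSError, match="collinear"):
            rp.joint_model_fit(dup, traits, cov, [3, 4])


class TestMapToReference:
    def make_rplars(self, columns):
        return pd.DataFrame({"column": columns,
                             "p_value": [0.01] * len(columns)})

    def test_gap_free_reference_maps_identically(self):
        aln = rp.Alignment(["ref", "o1"],
                           np.array([list("MKLA"), list("MRCA")]))
        out = rp.map_to_reference(self.make_rplars([1, 3, 4]), aln, "ref")
        assert out["ref_residue"].tolist() == [1, 3, 4]
        assert out["ref_symbol"].tolist() == ["M", "L", "A"]

    def test_gapped_reference_skips_gap_columns(self):
        aln = rp.Alignment(["ref", "o1"],
                           np.array([list("A-CD"), list("AKCD")]))
        out = rp.map_to_reference(self.make_rplars([1, 2, 3, 4]), aln, "ref")
        assert out["ref_residue"][0] == 1
        assert pd.isna(out["ref_residue"][1])
        assert out["ref_residue"][2] == 2
        assert out["ref_residue"][3] == 3

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_mapping_is_strictly_increasing_over_nongap_columns(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(4, 30))
        ref = rng.choice(list("ACDEF-"), size=L)
        if (ref != "-").sum() == 0:
            ref[0] = "A"
        other = rng.choice(list("ACDEF"), size=L)
        aln = rp.Alignment(["ref", "o1"], np.stack([ref, other]))
        out = rp.map_to_reference(
            self.make_rplars(list(range(1, L + 1))), aln, "ref")
        mapped = out["ref_residue"].dropna().to_numpy(float)
        assert (np.diff(mapped) > 0).all()

    def test_unknown_reference_rejected(self):
        aln = rp.Alignment(["a", "b"], np.array([list("MK"), list("MR")]))
        with pytest.raises(PGLSError, match="reference"):
            rp.map_to_reference(self.make_rplars([1]), aln, "zz")
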