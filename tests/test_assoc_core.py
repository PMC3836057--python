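"""Model fits, adjusted phenotype, screening statistic and direct-effect FBAT.

Includes an independent statsmodels/normal-equations re-derivation of both
statistics as the oracle for the full computation.
"""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

import trioscreen as ts
from trioscreen import (
    ScenarioConfig,
    SingularDesignError,
    center_adjust,
    direct_test,
    fit_model1,
    fit_model2,
    screen_statistic,
    simulate_study,
    simulate_trio_genotypes,
)
from trioscreen.trio_genetics import TrioMarker


def _random_instance(rng, n=50):
    X = rng.integers(0, 3, n).astype(float)
    K = rng.standard_normal(n)
    L = rng.standard_normal((n, 2))
    Y = 0.5 * K + 0.2 * X + 0.1 * L[:, 0] + rng.standard_normal(n)
    return Y, K, L, X


def test_fit_model1_matches_normal_equations(rng):
    """OLS slopes equal the explicit (XᵀX)⁻¹XᵀY solution to 1e-8."""
    Y, K, L, X = _random_instance(rng)
    fit = fit_model1(Y, K, L, X)
    D = np.column_stack([np.ones(len(Y)), K, X, L])
    beta = np.linalg.solve(D.T @ D, D.T @ Y)
    np.testing.assert_allclose(
        [fit.gamma0, fit.gamma1, fit.gamma2, *fit.gamma3], beta, atol=1e-8
    )
    assert abs(fit.residuals.sum()) < 1e-8 * len(Y)


def test_fit_model2_matches_normal_equations(rng):
    Y, K, L, _ = _random_instance(rng)
    exs = rng.integers(0, 5, len(Y)) / 2.0
    fit = fit_model2(Y, K, L, exs)
    D = np.column_stack([np.ones(len(Y)), K, L, exs])
    beta = np.linalg.solve(D.T @ D, D.T @ Y)
    np.testing.assert_allclose(
        [fit.beta0, fit.gamma1_star, *fit.beta2, fit.beta3], beta, atol=1e-8
    )


def test_fit_model1_recovers_identity_slope(rng):
    n = 200
    K = rng.standard_normal(n)
    X = rng.integers(0, 3, n).astype(float)
    fit = fit_model1(K, K + 0 * X, None, X)  # Y == K
    assert fit.gamma1 == pytest.approx(1.0, abs=1e-10)
    assert fit.gamma2 == pytest.approx(0.0, abs=1e-10)


def test_constant_k_raises_named_error(rng):
    Y = rng.standard_normal(30)
    with pytest.raises(SingularDesignError, match="K"):
        fit_model1(Y, np.ones(30), None, rng.integers(0, 3, 30).astype(float))


def test_fit_model2_drops_monomorphic_exs(rng):
    Y, K, L, _ = _random_instance(rng)
    fit = fit_model2(Y, K, L, np.ones(len(Y)))
    assert fit.exs_dropped and fit.beta3 == 0.0


def test_center_adjust_identities(rng):
    Y = rng.standard_normal(40)
    K = rng.standard_normal(40)
    adj0 = center_adjust(Y, K, 0.0)
    np.testing.assert_allclose(adj0.values, Y - Y.mean())
    np.testing.assert_allclose(center_adjust(Y, Y, 1.0).values, 0.0, atol=1e-12)
    assert center_adjust(Y, K, 0.73).values.mean() == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        center_adjust(np.array([]), np.array([]), 0.0)


# ---------------------------------------------------------------------------
# full-equation oracles


def _oracle_screen(y, k, L, marker):
    """Independent screening-statistic computation via statsmodels."""
    exs = (marker.father + marker.mother) / 2.0
    D2 = sm.add_constant(np.column_stack([k, L, exs]))
    m2 = sm.OLS(y, D2).fit()
    g1s = m2.params[1]
    ytil = y - y.mean() - g1s * (k - k.mean())
    exc = exs - exs.mean()
    tstar = exc * ytil
    Dn = sm.add_constant(np.column_stack([L, exs]))
    nuis = sm.OLS(k, Dn).fit()
    mu = nuis.fittedvalues
    sig2 = nuis.ssr / (len(k) - Dn.shape[1])
    ehat = np.mean(exc * (k - k.mean()))
    ttil = tstar - ehat * (k - mu) / sig2 * m2.resid
    return tstar.sum() ** 2 / (len(k) * np.var(ttil, ddof=1))


def _oracle_direct(y, k, L, marker):
    """Independent direct-test computation via statsmodels."""
    x = marker.offspring.astype(float)
    exs = (marker.father + marker.mother) / 2.0
    D1 = sm.add_constant(np.column_stack([k, x, L]))
    m1 = sm.OLS(y, D1).fit()
    g1 = m1.params[1]
    ytil = y - y.mean() - g1 * (k - k.mean())
    t = (x - exs) * ytil
    Dn = sm.add_constant(np.column_stack([L, x, exs]))
    nuis = sm.OLS(k, Dn).fit()
    mu = nuis.fittedvalues
    sig2 = nuis.ssr / (len(k) - Dn.shape[1])
    ehat = np.mean((x - exs) * (k - k.mean()))
    ttil = t - ehat * (k - mu) / sig2 * m1.resid
    return t.sum() ** 2 / (len(k) * np.var(ttil, ddof=1))


def test_statistics_match_independent_reimplementation(study_replicate):
    panel, phen = study_replicate
    mk = panel.marker(0)
    ours = screen_statistic(phen.y, phen.k, phen.covariates, mk)
    assert ours.value == pytest.approx(
        _oracle_screen(phen.y, phen.k, phen.covariates, mk), abs=1e-10
    )
    res = direct_test(phen.y, phen.k, phen.covariates, mk)
    assert res.chi_square == pytest.approx(
        _oracle_direct(phen.y, phen.k, phen.covariates, mk), abs=1e-10
    )
    assert res.p_value == pytest.approx(stats.chi2.sf(res.chi_square, 1))


def test_direct_test_reduces_to_classical_fbat(rng):
    """With no mediation (γ̂1 ≈ 0 forced by K ⊥ everything and the correction
    term vanishing), the statistic is the classical FBAT on Y − ȳ."""
    panel = simulate_trio_genotypes(400, 0.4, seed=17)
    mk = panel.marker(0)
    y = rng.standard_normal(400)
    # make K exactly orthogonal to the FBAT ingredients so gamma1-hat and the
    # correction expectation are both ~0: use a constant-free random K, then
    # verify against the classical statistic computed with the fitted gamma1
    k = rng.standard_normal(400)
    res = direct_test(y, k, None, mk)
    x = mk.offspring.astype(float)
    exs = mk.exs
    g1 = res.gamma1_hat
    ytil = y - y.mean() - g1 * (k - k.mean())
    t = (x - exs) * ytil
    # classical FBAT form with the same adjusted phenotype, no correction:
    classical = t.sum() ** 2 / (400 * np.var(t, ddof=1))
    # correction is O(Ê[(X−E)K]) ≈ 0 here, so the two agree closely
    assert res.chi_square == pytest.approx(classical, rel=0.05)


def test_screen_statistic_ignores_offspring_column(study_replicate):
    """Mutation test: the screen is a pure function of parents + phenotypes."""
    panel, phen = study_replicate
    mk = panel.marker(0)
    base = screen_statistic(phen.y, phen.k, phen.covariates, mk)
    mutated = TrioMarker(
        father=mk.father,
        mother=mk.mother,
        offspring=np.zeros_like(mk.offspring),
        maf=mk.maf,
    )
    assert screen_statistic(phen.y, phen.k, phen.covariates, mutated).value == base.value


def test_screen_statistic_constant_exs_is_zero(rng):
    n = 120
    mk = TrioMarker(
        father=np.ones(n, dtype=np.int8),
        mother=np.ones(n, dtype=np.int8),
        offspring=rng.integers(0, 3, n).astype(np.int8),
    )
    y, k = rng.standard_normal(n), rng.standard_normal(n)
    res = screen_statistic(y, k, None, mk)
    assert res.defined and res.value == 0.0


def test_direct_test_undefined_without_informative_trios(rng):
    n = 80
    mk = TrioMarker(
        father=np.full(n, 2, dtype=np.int8),
        mother=np.zeros(n, dtype=np.int8),
        offspring=np.ones(n, dtype=np.int8),
    )
    res = direct_test(rng.standard_normal(n), rng.standard_normal(n), None, mk)
    assert not res.defined and res.n_informative == 0


@pytest.mark.parametrize("stat_kind", ["screen", "direct"])
def test_affine_and_k_scale_invariance(study_replicate, stat_kind):
    """aY+b and cK+d leave both statistics unchanged (γ̂1 rescales)."""
    panel, phen = study_replicate
    mk = panel.marker(0)

    def value(y, k):
        if stat_kind == "screen":
            return screen_statistic(y, k, phen.covariates, mk).value
        return direct_test(y, k, phen.covariates, mk).chi_square

    base = value(phen.y, phen.k)
    assert value(3.2 * phen.y - 1.7, phen.k) == pytest.approx(base, abs=1e-8)
    assert value(phen.y, -0.4 * phen.k + 2.5) == pytest.approx(base, abs=1e-8)


def test_missing_values_are_dropped_per_marker(study_replicate):
    panel, phen = study_replicate
    mk = panel.marker(0)
    y = phen.y.copy()
    y[:5] = np.nan
    res = direct_test(y, phen.k, phen.covariates, mk)
    sub = TrioMarker(mk.father[5:], mk.mother[5:], mk.offspring[5:])
    ref = direct_test(phen.y[5:], phen.k[5:], phen.covariates[5:], sub)
    assert res.chi_square == pytest.approx(ref.chi_square)


def test_uncentered_variance_option_close_under_null(study_replicate):
    panel, phen = study_replicate
    mk = panel.marker(0)
    a = direct_test(phen.y, phen.k, phen.covariates, mk, variance="centered")
    b = direct_test(phen.y, phen.k, phen.covariates, mk, variance="uncentered")
    assert a.chi_square == pytest.approx(b.chi_square, rel=0.05)


def test_null_calibration_kolmogorov_smirnov():
    """Direct-test statistic over null replicates is χ²₁ (KS at 1%)."""
    cfg = ScenarioConfig.for_scenario(2)
    vals = []
    for rep in range(2000):
        rng = np.random.default_rng([314, rep])
        panel, phen = simulate_study(1000, 0.3, cfg, rng)
        res = direct_test(phen.y, phen.k, phen.covariates, panel.marker(0))
        if res.defined:
            vals.append(res.chi_square)
    ks = stats.kstest(vals, stats.chi2(df=1).cdf)
    assert ks.pvalue > 0.01


def _gamma1_pair(scenario, n, rep):
    cfg = ScenarioConfig.for_scenario(scenario)
    rng = np.random.default_rng([271, scenario, rep])
    panel, phen = simulate_study(n, 0.3, cfg, rng)
    f1 = fit_model1(phen.y, phen.k, phen.covariates, panel.offspring[0].astype(float))
    f2 = fit_model2(phen.y, phen.k, phen.covariates, panel.marker(0).exs)
    return f1.gamma1 - f2.gamma1_star


def test_gamma1_agreement_between_models_under_null():
    """γ̂1 (model 1) and γ̂1* (model 2) estimate the same K→Y effect under
    the null of no direct effect and no stratification.

    Without an X→L edge (scenario 2) the equality is exact in the
    large-sample limit. With X→L and a U-confounded L-Y association
    (scenario 1) the conditional-mean model retains a small residual
    confounding through the within-family genotype component of L; the gap
    stays near 1% of the K→Y effect (γ1 = 0.1) and is irrelevant to the
    screening statistic's calibration, which accounts for the estimation of
    γ1* whatever its limit."""
    # scenario 2, n = 100000: 0 within 3 sampling SDs (SD ≈ 3.3e-4 per draw)
    diffs2 = np.asarray([_gamma1_pair(2, 100_000, rep) for rep in range(8)])
    assert abs(diffs2.mean()) < 3 * 3.3e-4 / np.sqrt(len(diffs2))
    # scenario 1, n = 1000 replicates: systematic gap below 2% of γ1
    diffs1 = np.asarray([_gamma1_pair(1, 1000, rep) for rep in range(400)])
    assert abs(diffs1.mean()) < 0.002
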