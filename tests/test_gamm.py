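import numpy as np
import pandas as pd
import pytest

from n15scape.basis import SmoothBasis, build_smooth_basis
from n15scape.gamm import FitError, FittedGAMM, GAMMSpec, fit


def re_table(rng, n_plots=4, n_tr=3, n_per=10, sd_plot=1.0, sd_tr=0.5,
             sd_eps=1.0, mu=2.0):
    rows = []
    for p in range(n_plots):
        bp = rng.normal(0, sd_plot)
        for t in range(n_tr):
            bt = rng.normal(0, sd_tr)
            for _ in range(n_per):
                rows.append({"plot_id": f"P{p}", "transect_id": f"T{t}",
                             "d15n_obs": mu + bp + bt + rng.normal(0, sd_eps)})
    return pd.DataFrame(rows)


# -- basis -----------------------------------------------------------------

def test_basis_penalty_psd_with_linear_nullspace(rng):
    x = rng.uniform(0, 10, 80)
    design, penalty, basis = build_smooth_basis(x, 10)
    assert np.allclose(penalty, penalty.T)
    ev = np.linalg.eigvalsh(penalty)
    assert ev.min() > -1e-8 * max(ev.max(), 1.0)
    # the linear column (index 0) is unpenalised
    e = np.zeros(design.shape[1])
    e[0] = 1.0
    assert abs(e @ penalty @ e) < 1e-12


def test_basis_columns_centered(rng):
    x = rng.uniform(-3, 4, 60)
    design, _, basis = build_smooth_basis(x, 8)
    assert np.allclose(design.mean(axis=0), 0.0, atol=1e-8)
    assert np.allclose(basis.mixed_columns(x).mean(axis=0), 0.0, atol=1e-8)


def test_basis_infinite_penalty_reduces_to_line(rng):
    x = rng.uniform(0, 1, 120)
    y = 2.0 * x + rng.normal(0, 0.05, x.size)
    design, penalty, _ = build_smooth_basis(x, 10)
    X = np.column_stack([np.ones(x.size), design])
    P = np.zeros((X.shape[1], X.shape[1]))
    P[1:, 1:] = penalty
    beta = np.linalg.solve(X.T @ X + 1e9 * P, X.T @ y)
    fitted = X @ beta
    # oracle: ordinary least-squares straight line on the same data
    line = np.polynomial.polynomial.polyfit(x, y, 1)
    assert np.allclose(fitted, line[0] + line[1] * x, atol=1e-4)
    slope_per_unit_x = beta[1] / 1.0  # x already spans ~[0, 1]
    assert abs(line[1] - 2.0) < 0.1


def test_basis_reduces_k_with_warning():
    x = np.repeat(np.arange(5.0), 4)
    with pytest.warns(UserWarning, match="reducing basis"):
        b = SmoothBasis(x, 10)
    assert b.k == 5


def test_basis_too_few_distinct_values():
    with pytest.raises(ValueError):
        SmoothBasis(np.array([1.0, 1.0, 2.0]), 5)


def test_basis_serialisation_roundtrip(rng):
    x = rng.uniform(0, 5, 50)
    b = SmoothBasis(x, 8)
    b2 = SmoothBasis.from_dict(b.to_dict())
    xn = rng.uniform(0, 5, 7)
    assert np.allclose(b.mixed_columns(xn), b2.mixed_columns(xn))
    assert np.allclose(b.linear_column(xn), b2.linear_column(xn))


# -- fit: degenerate and structural cases ---------------------------------

def test_fit_constant_response_degenerate(rng):
    tab = re_table(rng)
    tab["d15n_obs"] = 4.2
    with pytest.raises(FitError, match="degenerate"):
        fit(tab, GAMMSpec(smooth_terms=(), landform=False))


def test_fit_single_landform_level_singular(rng):
    tab = re_table(rng)
    tab["landform"] = "plain"
    with pytest.raises(FitError, match="single observed level"):
        fit(tab, GAMMSpec(smooth_terms=(), landform=True))


def test_fit_nonfinite_response(rng):
    tab = re_table(rng)
    tab.loc[0, "d15n_obs"] = np.inf
    with pytest.raises(FitError, match="non-finite"):
        fit(tab, GAMMSpec(smooth_terms=(), landform=False))


def test_random_intercepts_shrink_toward_zero(rng):
    tab = re_table(rng, n_plots=2, n_tr=1, n_per=8, sd_plot=1.0, sd_tr=0.0)
    m = fit(tab, GAMMSpec(smooth_terms=(), landform=False))
    raw = tab.groupby("plot_id")["d15n_obs"].mean() - tab["d15n_obs"].mean()
    sl = next(sl for (n, k, sl) in m.design.blocks if n == "plot")
    est = m.b[sl]
    assert np.all(np.abs(est) < np.abs(raw.to_numpy()) + 1e-9)
    assert np.abs(est).max() > 0


def test_ols_equivalence_without_smooths_or_res(rng):
    # no smooths, no random terms: the fit is plain OLS on landform
    tab = re_table(rng)
    tab["landform"] = rng.choice(["plain", "slope", "valley"], len(tab))
    m = fit(tab, GAMMSpec(smooth_terms=(), landform=True, random=False))
    X = np.column_stack([np.ones(len(tab))]
                        + [(tab["landform"] == lv).astype(float).to_numpy()
                           for lv in ["slope", "valley"]])
    y = tab["d15n_obs"].to_numpy()
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    assert np.allclose(m.beta, beta_ols, atol=1e-8)
    resid = y - X @ beta_ols
    s2 = resid @ resid / len(y)
    ll = -0.5 * len(y) * (np.log(2 * np.pi * s2) + 1)
    assert np.isclose(m.loglik, ll, atol=1e-6)


# -- fit on synthetic scenarios -------------------------------------------

def test_partial_effects_recover_truth(default_scenario, default_fit):
    m = default_fit
    for term in m.spec.smooth_terms:
        pe = m.partial_effect(term, 100)
        tru = default_scenario.truth.component(term, pe.grid)
        r = np.corrcoef(pe.effect - pe.effect.mean(), tru - tru.mean())[0, 1]
        assert r >= 0.8, (term, r)


def test_residual_sd_near_truth(default_fit):
    assert 1.5 <= np.sqrt(default_fit.sigma2) <= 2.1


def test_distance_effect_drop(default_fit):
    pe = default_fit.partial_effect("dist_ac", 101)
    drop = pe.effect[0] - pe.effect[np.argmin(np.abs(pe.grid - 10.0))]
    assert 1.5 <= drop <= 4.5


def test_prediction_self_consistency(default_scenario, default_fit):
    pred = default_fit.predict(default_scenario.table, include_random=True)
    assert np.allclose(pred, default_fit.fitted, atol=1e-8)


def test_prediction_at_means_is_intercept_plus_landform(default_scenario,
                                                        default_fit):
    tab = default_scenario.table
    modal = tab["landform"].mode().iloc[0]
    newdata = pd.DataFrame({t: [tab[t].mean()]
                            for t in default_fit.spec.smooth_terms})
    newdata["landform"] = modal
    pred = default_fit.predict(newdata, include_random=False)
    i_int = default_fit.design.X_names.index("(Intercept)")
    expect = default_fit.beta[i_int]
    if modal != default_fit.design.reference_level:
        expect += default_fit.beta[
            default_fit.design.X_names.index(f"landform[{modal}]")]
    # smooth effects at covariate means need not vanish exactly (they are
    # centred over the sample, not at the mean point), so evaluate them
    for term in default_fit.spec.smooth_terms:
        eff, _ = default_fit.term_effect(term, np.array([tab[term].mean()]))
        expect += eff[0]
    assert np.isclose(pred[0], expect, atol=1e-8)


def test_additive_decomposition_identity(default_scenario, default_fit):
    tab = default_scenario.table.head(50)
    pred = default_fit.predict(tab, include_random=False)
    total = np.full(len(tab),
                    default_fit.beta[default_fit.design.X_names.index("(Intercept)")])
    for term in default_fit.spec.smooth_terms:
        eff, _ = default_fit.term_effect(term, tab[term].to_numpy())
        total += eff
    for lev in default_fit.design.landform_levels:
        if lev == default_fit.design.reference_level:
            continue
        i = default_fit.design.X_names.index(f"landform[{lev}]")
        total += default_fit.beta[i] * (tab["landform"] == lev).to_numpy()
    assert np.allclose(pred, total, atol=1e-8)


def test_partial_effect_centered_and_ci_positive(default_fit):
    for term in ("dist_ac", "twi"):
        pe = default_fit.partial_effect(term)
        eff_at_train, _ = default_fit.term_effect(
            term, default_fit._training_covariate(term))
        assert abs(eff_at_train.mean()) < 1e-6
        assert np.all(pe.ci_halfwidth > 0)


def test_partial_effect_unknown_term(default_fit):
    with pytest.raises(ValueError):
        default_fit.partial_effect("nope")


def test_landform_partial_effect(default_fit):
    pe = default_fit.partial_effect("landform")
    assert set(pe.grid) == set(default_fit.design.landform_levels)
    ref_i = list(pe.grid).index(default_fit.design.reference_level)
    assert pe.effect[ref_i] == 0.0


def test_predict_unknown_landform_errors(default_fit, default_scenario):
    tab = default_scenario.table.head(2).copy()
    tab["landform"] = "volcano"
    with pytest.raises(ValueError, match="unknown landform"):
        default_fit.predict(tab)


def test_predict_unseen_group_uses_zero(default_fit, default_scenario):
    tab = default_scenario.table.head(3).copy()
    fixed = default_fit.predict(tab, include_random=False)
    tab["plot_id"] = "P999"
    tab["transect_id"] = "T999"
    both = default_fit.predict(tab, include_random=True)
    assert np.allclose(fixed, both)


# -- likelihood and df bookkeeping ----------------------------------------

def test_loglik_monotone_in_nested_terms(default_scenario):
    tab = default_scenario.table
    lls = []
    terms = []
    for t in ("twi", "log_cover", "dist_ac"):
        terms.append(t)
        lls.append(fit(tab, GAMMSpec(smooth_terms=tuple(terms),
                                     landform=False)).loglik)
    assert np.all(np.diff(lls) > -1e-4)


def test_fit_permutation_invariant(small_scenario):
    tab = small_scenario.table
    perm = tab.sample(frac=1.0, random_state=1)
    a = fit(tab, GAMMSpec(smooth_terms=("twi", "dist_ac"), landform=False))
    b = fit(perm, GAMMSpec(smooth_terms=("twi", "dist_ac"), landform=False))
    # identical up to optimiser tolerance (summation order perturbs the
    # profiled-likelihood surface in its flat directions)
    assert np.isclose(a.loglik, b.loglik, atol=1e-5)
    assert np.allclose(a.beta, b.beta, atol=1e-2)
    assert np.allclose(a.fitted, b.fitted[np.argsort(perm.index.to_numpy())],
                       atol=1e-2)


def test_param_count_matches_convention(default_fit):
    # intercept + 4 landform contrasts + 5 smooth linear coefficients
    # + 5 smoothing parameters + 3 variance components = 18
    assert default_fit.param_count() == 18


def test_edf_within_bounds(default_fit):
    for term in default_fit.spec.smooth_terms:
        e = default_fit.edf(term)
        assert 1.0 - 1e-6 <= e <= default_fit.spec.k - 1 + 1e-6


def test_edf_unknown_term(default_fit):
    with pytest.raises(ValueError):
        default_fit.edf("landform")


def test_variance_components_nonnegative(default_fit):
    for v in default_fit.variance_components.values():
        assert v >= 0


# -- serialisation ---------------------------------------------------------

def test_fit_json_roundtrip(tmp_path, default_fit, default_scenario):
    path = tmp_path / "fit.json"
    default_fit.to_json(path)
    back = FittedGAMM.from_json(path)
    tab = default_scenario.table.head(40)
    assert np.allclose(back.predict(tab, include_random=True),
                       default_fit.predict(tab, include_random=True),
                       atol=1e-10)
    assert back.param_count() == default_fit.param_count()
    assert np.isclose(back.loglik, default_fit.loglik)
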