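import numpy as np
import pytest
from scipy.stats import pearsonr

from _reference import krylov_pls1, nipals_pls1
from pfpmi import GeneratorConfig, MetaboliteSpec, ocpls2
from pfpmi.io_preprocess import autoscale
from pfpmi.synthetic import generate_concentrations
import pandas as pd


def _scaled_instance(seed, n=16, p=8, with_z=False, n_z=1):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    beta = rng.standard_normal(p)
    y = X @ beta + 0.5 * rng.standard_normal(n)
    Z = rng.standard_normal((n, n_z)) if with_z else None
    if Z is not None:
        Z = Z - Z.mean(axis=0)
    return X, y, Z


# -------------------------------------------------------------- reduction


@pytest.mark.parametrize("seed", range(8))
@pytest.mark.parametrize("a", [1, 2, 3])
def test_unconstrained_fit_matches_reference_nipals(seed, a):
    X, y, _ = _scaled_instance(seed)
    model = ocpls2.fit(X, y, None, a, 0)
    ref_fitted, ref_predict = nipals_pls1(X, y, a)
    assert np.allclose(ocpls2.fitted_values(model, X), ref_fitted, atol=1e-6)
    X_new = np.random.default_rng(seed + 100).standard_normal((5, X.shape[1]))
    assert np.allclose(ocpls2.predict(model, X_new), ref_predict(X_new), atol=1e-6)


@pytest.mark.parametrize("seed", range(5))
def test_unconstrained_fit_matches_krylov_characterization(seed):
    X, y, _ = _scaled_instance(seed, n=20, p=6)
    for a in (1, 2):
        model = ocpls2.fit(X, y, None, a, 0)
        assert np.allclose(
            ocpls2.fitted_values(model, X), krylov_pls1(X, y, a), atol=1e-6
        )


# ------------------------------------------------------------- constraint


@pytest.mark.parametrize("seed", range(10))
def test_scores_orthogonal_to_constraint(seed):
    n_z = 1 + seed % 2
    X, y, Z = _scaled_instance(seed, n=18, p=9, with_z=True, n_z=n_z)
    model = ocpls2.fit(X, y, Z, 2, 1)
    T = model.predictive_scores
    rel = np.abs(T.T @ Z) / (
        np.linalg.norm(T, axis=0)[:, None] * np.linalg.norm(Z, axis=0)[None, :]
    )
    assert rel.max() < 1e-8
    # predictive scores mutually orthogonal
    gram = T.T @ T
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() / np.diag(gram).max() < 1e-8


def test_more_constraints_than_predictors_rejected():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((12, 2))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    y = rng.standard_normal(12)
    Z = rng.standard_normal((12, 3))
    with pytest.raises(ValueError):
        ocpls2.fit(X, y, Z - Z.mean(0), 1, 0)


def test_constrained_model_fitted_values_carry_no_age_signal():
    """The constraint's operational meaning: fitted PMI cannot encode age.

    An age-only metabolite cannot lend the model any age-mediated
    predictive ability — the fitted values are exactly uncorrelated with
    age under the constraint, while the unconstrained fit exploits the
    age-PMI correlation.
    """
    corr_con, corr_unc = [], []
    for seed in range(50):
        panel = [
            MetaboliteSpec("m_pmi1", 0.02, pmi_slope=1.5e-3),
            MetaboliteSpec("m_pmi2", 0.05, pmi_slope=2e-3),
            MetaboliteSpec("m_age", 0.5, age_slope=8e-3),
        ] + [MetaboliteSpec(f"m_null{i}", 0.3) for i in range(6)]
        cfg = GeneratorConfig(n_samples=24, seed=7000 + seed, panel=panel)
        from pfpmi import simulate_cohort

        meta, tabs, _ = simulate_cohort(cfg)
        sc = autoscale(tabs["U"])
        y = meta.pmi_hours.to_numpy()
        age = meta.age_years.to_numpy()
        mc = ocpls2.fit(sc.values, y, age[:, None], 1, 0)
        mu = ocpls2.fit(sc.values, y, None, 1, 0)
        corr_con.append(abs(pearsonr(ocpls2.fitted_values(mc, sc.values), age)[0]))
        corr_unc.append(abs(pearsonr(ocpls2.fitted_values(mu, sc.values), age)[0]))
    assert max(corr_con) < 1e-8
    assert np.mean(corr_unc) > 0.1


def test_noiseless_recovery_through_constrained_model():
    """Exact recovery when the training design decorrelates PMI and age."""
    rng = np.random.default_rng(11)
    n = 40
    pmi = rng.uniform(16, 100, n)
    age_raw = rng.uniform(20, 87, n)
    A = np.column_stack([np.ones(n), pmi])
    age = age_raw - A @ np.linalg.lstsq(A, age_raw, rcond=None)[0] + 50
    panel = [
        MetaboliteSpec(f"m{i}", b, pmi_slope=ps, age_slope=a)
        for i, (b, ps, a) in enumerate(
            [(0.02, 1.5e-3, 0), (0.05, 2e-3, 1e-4), (0.5, 0, 8e-3),
             (0.3, 1e-3, 2e-3), (1.0, 5e-4, 0), (0.1, 0, 1e-3)]
        )
    ]
    cfg = GeneratorConfig(
        n_samples=n, noise_cv=1e-9, panel=panel, seed=5, duplicate_protocols=False
    )
    meta = pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(n)], "sex": "M",
         "age_years": age, "pmi_hours": pmi, "cause_of_death": "n/a"}
    )
    tabs, _ = generate_concentrations(meta, cfg)
    sc = autoscale(tabs["U"])
    model = ocpls2.fit(sc.values, pmi, (age - age.mean())[:, None], 1, 0)

    meta2 = meta.copy()
    meta2["pmi_hours"] = rng.uniform(16, 100, n)
    meta2["age_years"] = rng.uniform(20, 87, n)
    tabs2, _ = generate_concentrations(meta2, cfg)
    sc2 = autoscale(tabs2["U"], reference=sc)
    y_hat = ocpls2.predict(model, sc2.values)
    rmse = np.sqrt(np.mean((y_hat - meta2["pmi_hours"].to_numpy()) ** 2))
    assert rmse < 1.0
    assert pearsonr(y_hat, meta2["pmi_hours"])[0] > 0.99


# --------------------------------------------------------------- predict


def test_predicting_training_matrix_reproduces_sdec():
    X, y, Z = _scaled_instance(3, with_z=True)
    model = ocpls2.fit(X, y, Z, 1, 0)
    y_hat = ocpls2.predict(model, X)
    sdec, _ = ocpls2.performance_metrics(y, y_hat)
    assert sdec == pytest.approx(np.sqrt(np.mean((y - y_hat) ** 2)))


def test_predicting_mean_row_returns_mean_response():
    X, y, _ = _scaled_instance(4)
    model = ocpls2.fit(X, y, None, 2, 0)
    y_hat = ocpls2.predict(model, np.zeros((1, X.shape[1])))
    assert y_hat[0] == pytest.approx(y.mean())


def test_predict_panel_mismatch_error():
    X, y, _ = _scaled_instance(5)
    model = ocpls2.fit(X, y, None, 1, 0, metabolite_names=[f"m{j}" for j in range(8)])
    with pytest.raises(ValueError):
        ocpls2.predict(model, X[:, :5])


# ---------------------------------------------------------------- metrics


def test_metrics_hand_computed_example():
    y = np.array([0.0, 0.0, 3.0, 3.0])
    y_hat = np.array([1.0, -1.0, 4.0, 2.0])
    sdec, r2 = ocpls2.performance_metrics(y, y_hat)
    assert sdec == pytest.approx(1.0)
    assert r2 == pytest.approx(1 - 4 / 9)


def test_metrics_perfect_and_null_fits():
    y = np.array([1.0, 2.0, 4.0])
    assert ocpls2.performance_metrics(y, y) == pytest.approx((0.0, 1.0))
    _, r2 = ocpls2.performance_metrics(y, np.full(3, y.mean()))
    assert r2 == pytest.approx(0.0)


def test_metrics_constant_truth_errors():
    with pytest.raises(ValueError):
        ocpls2.performance_metrics(np.ones(4), np.arange(4.0))


# ---------------------------------------------------------- cross-validation


def test_cv_null_data_gives_no_predictive_power():
    q2s = []
    for s in range(50):
        rng = np.random.default_rng(s)
        X = rng.standard_normal((60, 10))
        y = rng.standard_normal(60)
        q2, _ = ocpls2.repeated_cv(
            X, y, None, 1, 0, repetitions=3, rng=np.random.default_rng(1000 + s)
        )
        q2s.append(q2)
    assert np.mean(q2s) < 0.05


def test_cv_recovers_noiseless_signal():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((40, 5))
    y = X @ rng.standard_normal(5)
    q2, sdecv = ocpls2.repeated_cv(X, y, None, 2, 0, repetitions=5,
                                   rng=np.random.default_rng(3))
    assert q2 > 0.95
    assert sdecv >= 0


def test_cv_deterministic_under_seed():
    X, y, Z = _scaled_instance(6, with_z=True)
    a = ocpls2.repeated_cv(X, y, Z, 1, 0, repetitions=4, seed=42)
    b = ocpls2.repeated_cv(X, y, Z, 1, 0, repetitions=4, seed=42)
    assert a == b


def test_cv_discards_degenerate_folds_with_warning():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((5, 3))
    y = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
    # every leave-one-out training fold here loses all response variance, so
    # each repetition warns and, with none left, the routine raises
    with pytest.warns(UserWarning), pytest.raises(ValueError):
        ocpls2.repeated_cv(X, y, None, 1, 0, k=5, repetitions=2, seed=1)


# -------------------------------------------------------- component choice


def test_single_latent_factor_selects_one_predictive_component():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        n, p = 60, 10
        t = rng.standard_normal(n)
        v = rng.standard_normal(p)
        X = np.outer(t, v) + 0.5 * rng.standard_normal((n, p))
        y = t + 0.5 * rng.standard_normal(n)
        sel = ocpls2.select_components(
            X, y, None, max_predictive=3, max_non_predictive=2,
            repetitions=10, seed=seed,
        )
        hits += sel == (1, 0)
    assert hits >= 8


def test_structured_orthogonal_noise_recruits_non_predictive_component():
    n_orth_used = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        n, p = 20, 12
        v1 = rng.standard_normal(p)
        v1 /= np.linalg.norm(v1)
        v2 = rng.standard_normal(p)
        v2 -= (v2 @ v1) * v1
        v2 /= np.linalg.norm(v2)
        v2 = 0.6 * v1 + 0.8 * v2   # overlaps the predictive direction
        t1 = rng.standard_normal(n)
        t2 = 8 * rng.standard_normal(n)
        X = np.outer(t1, v1) + np.outer(t2, v2) + 0.1 * rng.standard_normal((n, p))
        y = t1 + 0.05 * rng.standard_normal(n)
        _, n_orth = ocpls2.select_components(
            X, y, None, max_predictive=2, max_non_predictive=1,
            repetitions=10, seed=seed,
        )
        n_orth_used += n_orth >= 1
    assert n_orth_used >= 5


def test_search_space_of_one_returns_minimal_model():
    X, y, _ = _scaled_instance(7)
    sel = ocpls2.select_components(
        X, y, None, max_predictive=1, max_non_predictive=0, repetitions=3, seed=0
    )
    assert sel == (1, 0)


# ------------------------------------------------------ randomization test


def test_randomization_strong_signal_reaches_lower_bound():
    rng = np.random.default_rng(3)
    n, p = 30, 6
    X = rng.standard_normal((n, p))
    y = X @ rng.standard_normal(p)
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    p_r2, p_q2 = ocpls2.randomization_test(
        Xs, y, None, 2, 0, n_permutations=99, repetitions=3, seed=11
    )
    assert p_r2 == pytest.approx(1 / 100)
    assert p_q2 == pytest.approx(1 / 100)


def test_randomization_p_values_within_formula_bounds():
    X, y, Z = _scaled_instance(8, with_z=True)
    p_r2, p_q2 = ocpls2.randomization_test(
        X, y, Z, 1, 0, n_permutations=99, repetitions=2, seed=5
    )
    for p_val in (p_r2, p_q2):
        assert 1 / 100 <= p_val <= 1.0


def test_randomization_requires_enough_permutations():
    X, y, _ = _scaled_instance(9)
    with pytest.raises(ValueError):
        ocpls2.randomization_test(X, y, None, 1, 0, n_permutations=50, seed=0)


def test_randomization_deterministic_under_seed():
    X, y, _ = _scaled_instance(10)
    a = ocpls2.randomization_test(X, y, None, 1, 0, n_permutations=99,
                                  repetitions=2, seed=3)
    b = ocpls2.randomization_test(X, y, None, 1, 0, n_permutations=99,
                                  repetitions=2, seed=3)
    assert a == b


# -------------------------------------------------------------------- VIP


@pytest.mark.parametrize("seed", range(6))
def test_vip_normalization_identity(seed):
    with_z = seed % 2 == 0
    X, y, Z = _scaled_instance(seed, with_z=with_z)
    model = ocpls2.fit(X, y, Z, 2, 0)
    v = ocpls2.vip(model)
    assert abs(np.sum(v**2) - X.shape[1]) < 1e-8


def test_vip_two_predictor_closed_form():
    # construct weights (1, 0): second column orthogonal to y
    t = np.array([1.0, -1.0, 2.0, -2.0])
    u = np.array([1.0, 1.0, -1.0, -1.0])
    X = np.column_stack([t / t.std(ddof=1), u / u.std(ddof=1)])
    y = t.copy()
    model = ocpls2.fit(X, y, None, 1, 0)
    v = ocpls2.vip(model)
    assert v[0] == pytest.approx(np.sqrt(2.0), abs=1e-8)
    assert v[1] == pytest.approx(0.0, abs=1e-8)


def test_vip_equal_for_duplicated_columns():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((20, 6))
    X[:, 3] = X[:, 2]
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    y = X[:, 2] + 0.2 * rng.standard_normal(20)
    model = ocpls2.fit(X, y, None, 1, 0)
    v = ocpls2.vip(model)
    assert v[2] == pytest.approx(v[3], rel=1e-10)
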