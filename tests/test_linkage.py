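import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from refugia.least_cost import LCDMatrix
from refugia.linkage import (
    ancestry_contribution_distance, build_affinity_table, cohen_kappa_counts,
    correlations, f4_sign_agreement, fit_gamma_smooth, kfold_cv_mse,
    mantel_test, partial_mantel_test,
)

from conftest import make_pops


def affinity_frame(n, seed=0, labels=10):
    rng = np.random.default_rng(seed)
    lcd = rng.uniform(0, 10, n)
    bp = rng.uniform(0, 30, n)
    moderns = np.repeat([f"M{i}" for i in range(labels)],
                        int(np.ceil(n / labels)))[:n]
    return pd.DataFrame({
        "modern_pop": moderns, "ancient_pop": [f"A{i}" for i in range(n)],
        "lcd": lcd, "bp_mean": bp,
    })


# ---------------------------------------------------------------------------
# affinity table
# ---------------------------------------------------------------------------

def _toy_lcd(values, ids):
    return LCDMatrix(ids=ids, values=np.asarray(values, dtype=float))


def test_build_affinity_table_counts_and_standardization():
    moderns, ancients = ["M1", "M2"], ["A1", "A2", "A3"]
    ids = moderns + ancients
    v = np.zeros((5, 5))
    v[:2, 2:] = [[1.0, 2.0, 3.0], [2.0, 1.0, 4.0]]
    v[2:, :2] = v[:2, 2:].T
    lcd = _toy_lcd(v, ids)
    pops = make_pops({p: [p + "_s"] for p in ids},
                     mean_bp={"A1": 8000, "A2": 10000, "A3": 12000})
    f3 = pd.DataFrame([
        {"modern_pop": m, "ancient_pop": a, "f3": 0.01 + 0.001 * i}
        for i, (m, a) in enumerate((m, a) for m in moderns for a in ancients)
    ])
    table = build_affinity_table(f3, lcd, pops)
    assert len(table) == 6
    assert table["lcd_z"].mean() == pytest.approx(0.0, abs=1e-12)
    assert table["lcd_z"].std(ddof=1) == pytest.approx(1.0)
    # one unreachable pair drops one row
    v2 = v.copy()
    v2[0, 2] = v2[2, 0] = np.inf
    table2 = build_affinity_table(f3, _toy_lcd(v2, ids), pops)
    assert len(table2) == 5
    # duplicate pair errors
    with pytest.raises(ValueError, match="duplicate"):
        build_affinity_table(pd.concat([f3, f3.iloc[:1]]), lcd, pops)


# ---------------------------------------------------------------------------
# Gamma spline smoother
# ---------------------------------------------------------------------------

def test_smooth_constant_response():
    df = affinity_frame(120, seed=1)
    df["f3"] = 0.37
    fit = fit_gamma_smooth(df, basis_dim=20)
    assert fit.intercept == pytest.approx(np.log(0.37), abs=1e-6)
    assert fit.edf == pytest.approx(1.0, abs=0.5)
    assert fit.deviance_explained < 0.01


def test_smooth_recovers_noiseless_surface():
    df = affinity_frame(200, seed=2)
    df["f3"] = np.exp(-0.15 * df["lcd"] - 0.03 * df["bp_mean"])
    fit = fit_gamma_smooth(df, basis_dim=20)
    assert fit.deviance_explained > 0.99
    pred = fit.predict(df["lcd"], df["bp_mean"])
    np.testing.assert_allclose(pred, df["f3"], rtol=1e-3)


def test_smooth_infinite_penalty_collapses_to_null_space():
    df = affinity_frame(150, seed=3)
    df["f3"] = np.exp(-0.2 * df["lcd"]) + 0.05
    fit = fit_gamma_smooth(df, basis_dim=20, lam=(1e9, 0.0), select_null=False)
    assert fit.edf == pytest.approx(3.0, abs=0.05)


def test_smooth_affine_predictor_invariance():
    df = affinity_frame(150, seed=4)
    df["f3"] = np.exp(-0.1 * df["lcd"] - 0.02 * df["bp_mean"]) * 0.5
    fit1 = fit_gamma_smooth(df, basis_dim=15)
    df2 = df.copy()
    df2["lcd"] = df2["lcd"] * 123.0 + 7.0
    df2["bp_mean"] = df2["bp_mean"] * 0.01 - 3.0
    fit2 = fit_gamma_smooth(df2, basis_dim=15)
    p1 = fit1.predict(df["lcd"], df["bp_mean"])
    p2 = fit2.predict(df2["lcd"], df2["bp_mean"])
    np.testing.assert_allclose(p1, p2, rtol=1e-4)


def test_smooth_rejects_nonpositive_response():
    df = affinity_frame(50, seed=5)
    df["f3"] = np.linspace(-0.01, 0.02, 50)
    with pytest.raises(ValueError, match="drop_nonpositive"):
        fit_gamma_smooth(df, basis_dim=10)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def test_cv_perfect_fit_and_determinism():
    df = affinity_frame(100, seed=6)
    df["f3"] = np.exp(-0.1 * df["lcd"] - 0.02 * df["bp_mean"])
    a = kfold_cv_mse(df, k=5, seed=11)
    b = kfold_cv_mse(df, k=5, seed=11)
    assert a.mse == b.mse
    assert a.mse < 1e-10
    assert a.k_effective == 5


def test_cv_prefers_true_lcd_over_scrambled():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        df = affinity_frame(60, seed=seed)
        df["f3"] = np.exp(-0.25 * df["lcd"] - 0.02 * df["bp_mean"]) * (
            1 + 0.03 * rng.standard_normal(60)
        )
        wrong = df.copy()
        wrong["lcd"] = rng.permutation(wrong["lcd"].to_numpy())
        good = kfold_cv_mse(df, k=5, seed=seed, basis_dim=8).mse
        bad = kfold_cv_mse(wrong, k=5, seed=seed, basis_dim=8).mse
        hits += good < bad
    assert hits >= 8


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def test_correlation_exact_linear():
    df = affinity_frame(40, seed=7)
    df["f3"] = 0.05 - 0.002 * df["lcd"]
    res = correlations(df)["f3_lcd"]
    assert res.r == pytest.approx(-1.0, abs=1e-12)


def test_correlation_null_under_permutation():
    calm = 0
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        df = affinity_frame(60, seed=seed)
        df["f3"] = rng.uniform(0.01, 0.02, 60)  # independent of lcd
        res = correlations(df)["f3_lcd"]
        calm += res.p_value > 0.05
    assert calm >= 9


def test_semipartial_reduces_to_pearson_when_bp_orthogonal():
    rng = np.random.default_rng(8)
    df = affinity_frame(50, seed=8)
    f3 = np.exp(-0.1 * df["lcd"].to_numpy())
    bp = rng.normal(size=50)
    bp -= bp.mean()
    f3c = f3 - f3.mean()
    bp -= (bp @ f3c) / (f3c @ f3c) * f3c  # exactly uncorrelated with f3
    df["f3"] = f3
    df["bp_mean"] = bp - bp.min() + 1
    res = correlations(df)
    assert res["semipartial_f3_lcd_given_bp"].r == pytest.approx(
        res["f3_lcd"].r, abs=1e-12
    )


def test_correlation_bp_window_subsets_rows():
    df = affinity_frame(60, seed=9)
    df["f3"] = np.exp(-0.1 * df["lcd"])
    res = correlations(df, bp_window=(5.0, 20.0))["f3_lcd"]
    expected_n = int(((df["bp_mean"] >= 5) & (df["bp_mean"] <= 20)).sum())
    assert res.n == expected_n


# ---------------------------------------------------------------------------
# kappa agreement
# ---------------------------------------------------------------------------

def test_kappa_formula_against_sklearn():
    a, b, c, d = 45, 15, 25, 15
    s1 = np.array([1] * (a + b) + [0] * (c + d))
    s2 = np.array([1] * a + [0] * b + [1] * c + [0] * d)
    expected = cohen_kappa_score(s1, s2)
    assert cohen_kappa_counts(a, b, c, d) == pytest.approx(expected, abs=1e-12)
    # hand derivation: po = 0.6, pe = 0.6*0.7 + 0.4*0.3 = 0.54
    assert cohen_kappa_counts(a, b, c, d) == pytest.approx(0.06 / 0.46, abs=1e-12)


def test_kappa_balanced_margins_half_agreement_is_zero():
    assert cohen_kappa_counts(25, 25, 25, 25) == 0.0


def _agreement_inputs(signs_f4, signs_d):
    n = len(signs_f4)
    ids = ["T"] + [f"X{i}" for i in range(n)] + [f"Y{i}" for i in range(n)]
    v = np.zeros((len(ids), len(ids)))
    for i, (sf, sd) in enumerate(zip(signs_f4, signs_d)):
        # LCD(T, Xi) - LCD(T, Yi) has sign sd
        v[0, 1 + i] = 10 + (5 if sd > 0 else -5)
        v[0, 1 + n + i] = 10
        v[1 + i, 0] = v[0, 1 + i]
        v[1 + n + i, 0] = v[0, 1 + n + i]
    lcd = LCDMatrix(ids=ids, values=v)
    rows = pd.DataFrame({
        "test": "T",
        "x": [f"X{i}" for i in range(n)],
        "y": [f"Y{i}" for i in range(n)],
        "estimate": [0.01 * s for s in signs_f4],
        "z": [4.0] * n,
    })
    return rows, lcd


def test_f4_agreement_all_agree_kappa_one():
    signs = [1, 1, -1, -1, 1, -1]
    rows, lcd = _agreement_inputs(signs, signs)
    res = f4_sign_agreement(rows, lcd, n_perm=2000, seed=0)
    assert res.kappa == 1.0
    # perfect agreement with 3/3 margins: exact permutation p = 1/C(6,3)
    assert res.p_value == pytest.approx(0.05, abs=0.02)
    assert res.n_used == 6


def test_f4_agreement_excludes_insignificant_and_zero_lcdd():
    rows, lcd = _agreement_inputs([1, -1, 1, -1], [1, -1, 1, -1])
    rows.loc[0, "z"] = 1.0  # below threshold
    lcd.values[0, 1 + 1] = lcd.values[0, 1 + 4 + 1]  # LCD.D = 0 for row 1
    lcd.values[1 + 1, 0] = lcd.values[0, 1 + 1]
    res = f4_sign_agreement(rows, lcd, n_perm=500, seed=0)
    assert res.n_used == 2


def test_f4_agreement_random_signs_near_zero_kappa():
    rng = np.random.default_rng(10)
    kappas = []
    for _ in range(40):
        sf = rng.choice([-1, 1], size=30)
        sd = rng.choice([-1, 1], size=30)
        rows, lcd = _agreement_inputs(list(sf), list(sd))
        res = f4_sign_agreement(rows, lcd, n_perm=200, seed=1)
        kappas.append(res.kappa)
    assert abs(np.mean(kappas)) < 0.07


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------

def random_distance_matrix(rng, n=10):
    x = rng.normal(size=(n, 2))
    d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
    return d


def test_mantel_self_correlation():
    rng = np.random.default_rng(11)
    d = random_distance_matrix(rng)
    res = mantel_test(d, d, n_perm=499, seed=0)
    assert res.r == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1 / 500, abs=1e-9)


def test_mantel_null_p_not_small():
    rng = np.random.default_rng(12)
    big = 0
    for seed in range(10):
        d1 = random_distance_matrix(rng)
        d2 = random_distance_matrix(rng)
        p = mantel_test(d1, d2, n_perm=199, seed=seed).p_value
        big += p > 0.05
    assert big >= 7  # most independent pairs are not significant


def test_mantel_rejects_bad_matrices():
    d = np.ones((4, 4))
    with pytest.raises(ValueError):
        mantel_test(d, d, n_perm=9)  # nonzero diagonal
    np.fill_diagonal(d, 0)
    with pytest.raises(ValueError):
        mantel_test(d, d, n_perm=9)  # constant off-diagonal


def test_partial_mantel_reductions():
    rng = np.random.default_rng(13)
    d1 = random_distance_matrix(rng)
    d2 = 0.5 * d1 + 0.5 * random_distance_matrix(rng)
    d3 = random_distance_matrix(rng)  # unrelated control
    plain = mantel_test(d1, d2, n_perm=99, seed=0).r
    partial = partial_mantel_test(d1, d2, d3, n_perm=99, seed=0).r
    assert partial == pytest.approx(plain, abs=0.15)
    # controlling for d2 itself kills the correlation
    self_ctrl = partial_mantel_test(d1, d2, d2, n_perm=99, seed=0).r
    assert abs(self_ctrl) < 1e-9


def test_partial_mantel_constructed_confound():
    rng = np.random.default_rng(14)
    d3 = random_distance_matrix(rng)
    noise = random_distance_matrix(rng)
    d1 = d3 + 0.1 * noise
    d2 = d3.copy()
    plain = mantel_test(d1, d2, n_perm=99, seed=0).r
    partial = partial_mantel_test(d1, d2, d3, n_perm=99, seed=0).r
    assert abs(partial) < abs(plain) / 2


# ---------------------------------------------------------------------------
# ancestry contribution distances
# ---------------------------------------------------------------------------

def _f3_frame(rows):
    return pd.DataFrame(rows, columns=["modern_pop", "ancient_pop", "f3"])


def test_contribution_distance_hand_l1():
    rows = [
        ("M1", "a1", 0.1), ("M1", "b1", 0.2),
        ("M2", "a1", 0.3), ("M2", "b1", 0.1),
    ]
    groups = {"a1": "A", "b1": "B"}
    d = ancestry_contribution_distance(_f3_frame(rows), groups)
    assert d.loc["M1", "M2"] == pytest.approx(0.3)
    assert d.loc["M1", "M1"] == 0.0


def test_contribution_distance_median_robust_to_duplicate():
    rows = [("M1", a, v) for a, v in
            [("a1", 0.1), ("a2", 0.2), ("a3", 0.9)]]
    rows += [("M2", a, v) for a, v in
             [("a1", 0.15), ("a2", 0.25), ("a3", 0.8)]]
    groups = {f"a{i}": "A" for i in (1, 2, 3)}
    d0 = ancestry_contribution_distance(_f3_frame(rows), groups)
    # duplicating the median-valued ancient population changes nothing
    dup = rows + [("M1", "a2b", 0.2), ("M2", "a2b", 0.25)]
    groups["a2b"] = "A"
    d1 = ancestry_contribution_distance(_f3_frame(dup), groups)
    assert d0.loc["M1", "M2"] == pytest.approx(d1.loc["M1", "M2"], abs=1e-12)


def test_contribution_distance_missing_group_errors():
    rows = [("M1", "a1", 0.1), ("M2", "b1", 0.2)]
    groups = {"a1": "A", "b1": "B"}
    with pytest.raises(ValueError, match="M1|M2"):
        ancestry_contribution_distance(_f3_frame(rows), groups)
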