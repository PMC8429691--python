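"""Statistical linkage of genetic affinity to landscape permeability.

The central regression models outgroup-f3 (shared drift between a
modern and an ancient population) as a smooth surface over least-cost
distance and mean age BP: a penalized bivariate thin-plate-type spline
under a Gamma likelihood with log link, the smoothing parameter chosen
by a REML-type criterion on the working model.  Candidate friction
models are compared by k-fold cross-validated mean squared prediction
error.  Validation statistics: Pearson and semi-partial correlations,
Cohen's kappa between the signs of f4 and of LCD differences, and
(partial) Mantel tests between distance matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, qr
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from .fstats import FStatResult
from .least_cost import LCDMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SmoothFitResult",
    "AgreementResult",
    "CorrelationResult",
    "CVResult",
    "build_affinity_table",
    "fit_gamma_smooth",
    "kfold_cv_mse",
    "select_friction_model",
    "correlations",
    "f4_sign_agreement",
    "mantel_test",
    "partial_mantel_test",
    "ancestry_contribution_distance",
    "cohen_kappa_counts",
]


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    kind: str  # pearson | semipartial | mantel | partial_mantel
    n: int


@dataclass
class AgreementResult:
    """Sign agreement between f4 and LCD differences over significant tests."""

    counts: tuple[int, int, int, int]  # a, b, c, d of the 2x2 sign table
    kappa: float
    p_value: float
    n_used: int


@dataclass
class CVResult:
    mse: float
    k_effective: int
    n_rows: int


# ---------------------------------------------------------------------------
# Affinity table
# ---------------------------------------------------------------------------

def _f3_frame(f3_results) -> pd.DataFrame:
    """Normalize f3 input to a (modern_pop, ancient_pop, f3) frame."""
    if isinstance(f3_results, pd.DataFrame):
        return f3_results[["modern_pop", "ancient_pop", "f3"]].copy()
    rows = [
        {"modern_pop": r.pops[0], "ancient_pop": r.pops[1], "f3": r.estimate}
        for r in f3_results
    ]
    return pd.DataFrame(rows)


def build_affinity_table(
    f3_results,
    lcd: LCDMatrix,
    pops,
    standardize: bool = True,
    drop_nonpositive: bool = True,
) -> pd.DataFrame:
    """One row per modern x ancient pair: f3, least-cost distance and the
    ancient population's mean age BP.

    Pairs with unreachable (infinite) LCD are dropped and logged, as are
    non-positive f3 values when ``drop_nonpositive`` (the Gamma family
    needs a positive response).  ``standardize`` adds z-scored ``lcd_z``
    and ``bp_z`` columns.
    """
    df = _f3_frame(f3_results)
    if df.duplicated(["modern_pop", "ancient_pop"]).any():
        dup = df[df.duplicated(["modern_pop", "ancient_pop"])].iloc[0]
        raise ValueError(
            f"duplicate pair {dup['modern_pop']}/{dup['ancient_pop']}"
        )
    df["lcd"] = [
        lcd.loc(m, a) for m, a in zip(df["modern_pop"], df["ancient_pop"])
    ]
    bp = pops.table["mean_bp"]
    df["bp_mean"] = df["ancient_pop"].map(bp).astype(float)

    unreachable = ~np.isfinite(df["lcd"])
    if unreachable.any():
        logger.info("build_affinity_table: dropping %d unreachable pairs",
                    int(unreachable.sum()))
        df = df[~unreachable]
    if drop_nonpositive:
        bad = df["f3"] <= 0
        if bad.any():
            logger.info("build_affinity_table: dropping %d non-positive f3 rows",
                        int(bad.sum()))
            df = df[~bad]
    df = df.reset_index(drop=True)
    if standardize:
        for col, zcol in (("lcd", "lcd_z"), ("bp_mean", "bp_z")):
            sd = df[col].std(ddof=1)
            df[zcol] = (df[col] - df[col].mean()) / (sd if sd > 0 else 1.0)
    return df


# ---------------------------------------------------------------------------
# Penalized Gamma thin-plate smoother
# ---------------------------------------------------------------------------

def _tps_eta(r: np.ndarray) -> np.ndarray:
    """Thin-plate radial basis function r^2 log r (0 at r = 0)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r * r * np.log(r)
    return np.where(r > 0, out, 0.0)


class _TPSBasis:
    """Bivariate thin-plate-type basis with the polynomial-orthogonality
    constraint absorbed, giving a positive-semidefinite penalty.

    Columns: [1, x1, x2, radial...]; the radial block is R @ Z where Z
    spans the null space of the knot polynomial matrix.
    """

    def __init__(self, X: np.ndarray, k: int):
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.sd = np.where(sd > 0, sd, 1.0)
        Xs = (X - self.mean) / self.sd
        uniq = np.unique(Xs, axis=0)
        k = int(min(k, len(uniq)))
        if k >= 4 and len(uniq) > k:
            from sklearn.cluster import KMeans

            km = KMeans(n_clusters=k, n_init=4, random_state=0).fit(Xs)
            knots = km.cluster_centers_
        else:
            knots = uniq[:k]
        self.knots = knots
        k = len(knots)
        if k >= 4:
            T = np.column_stack([np.ones(k), knots])
            Q, _ = qr(T, mode="full")
            Z = Q[:, 3:]
            E = _tps_eta(
                np.linalg.norm(knots[:, None, :] - knots[None, :, :], axis=-1)
            )
            S = Z.T @ E @ Z
            S = (S + S.T) / 2
            w, V = np.linalg.eigh(S)
            S = (V * np.clip(w, 0.0, None)) @ V.T  # numerically PSD
            self.Z, self.S_rad = Z, S
        else:  # too few points for a radial part: plain planar model
            self.Z, self.S_rad = np.zeros((k, 0)), np.zeros((0, 0))

    @property
    def n_coef(self) -> int:
        return 3 + self.Z.shape[1]

    def design(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.mean) / self.sd
        R = _tps_eta(
            np.linalg.norm(Xs[:, None, :] - self.knots[None, :, :], axis=-1)
        )
        return np.column_stack([np.ones(len(Xs)), Xs, R @ self.Z])

    def penalties(self) -> tuple[np.ndarray, np.ndarray]:
        """(wiggliness penalty, null-space shrinkage penalty), both full-size."""
        p = self.n_coef
        S1 = np.zeros((p, p))
        S1[3:, 3:] = self.S_rad
        S2 = np.zeros((p, p))
        S2[1, 1] = S2[2, 2] = 1.0  # shrink the planar terms, not the intercept
        return S1, S2


@dataclass
class SmoothFitResult:
    """Fitted Gamma log-link spline surface over (LCD, BP)."""

    basis: _TPSBasis
    beta: np.ndarray
    edf: float
    r2_adj: float
    deviance_explained: float
    intercept: float
    lambda_: tuple[float, float]
    method: str
    n: int

    def predict(self, lcd, bp) -> np.ndarray:
        X = np.column_stack([np.asarray(lcd, float), np.asarray(bp, float)])
        eta = np.clip(self.basis.design(X) @ self.beta, -30.0, 30.0)
        return np.exp(eta)


def _gamma_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    return float(2.0 * np.sum((y - mu) / mu - np.log(y / mu)))


def _pirls(y, B, S_lam, max_iter=100, tol=1e-9):
    """Penalized IRLS for the Gamma/log model (unit working weights).

    Returns (beta, eta, z, H factor, A) at convergence.
    """
    A = B.T @ B
    H = A + S_lam
    factor = cho_factor(H)
    eta = np.log(np.clip(y, 1e-12, None))
    for _ in range(max_iter):
        mu = np.exp(np.clip(eta, -30, 30))
        z = eta + (y - mu) / mu
        beta = cho_solve(factor, B.T @ z)
        eta_new = np.clip(B @ beta, -30.0, 30.0)
        if np.max(np.abs(eta_new - eta)) < tol:
            eta = eta_new
            break
        eta = eta_new
    else:
        raise RuntimeError(
            f"IRLS did not converge in {max_iter} iterations "
            f"(deviance {_gamma_deviance(y, np.exp(eta)):.4g})"
        )
    mu = np.exp(np.clip(eta, -30, 30))
    z = eta + (y - mu) / mu
    beta = cho_solve(factor, B.T @ z)
    return beta, B @ beta, z, factor, A


def _logdet_psd(M: np.ndarray, tol: float = 1e-10) -> float:
    w = np.linalg.eigvalsh((M + M.T) / 2)
    w = w[w > tol * max(w.max(), 1.0)]
    return float(np.sum(np.log(w)))


def fit_gamma_smooth(
    table: pd.DataFrame,
    basis_dim: int = 30,
    lam: tuple[float, float] | None = None,
    select_null: bool = True,
    max_iter: int = 100,
) -> SmoothFitResult:
    """Fit f3 ~ s(LCD, BP) under a Gamma likelihood with log link.

    A penalized thin-plate-type radial basis (dimension ``basis_dim``)
    over the standardized predictors is fitted by penalized IRLS; the
    smoothing parameters (wiggliness, plus a null-space shrinkage term
    when ``select_null``) are chosen by a REML-type criterion on the
    Gaussian working model, falling back to GCV if that fails (flagged
    in ``method``).  Pass ``lam`` to fix the penalties instead.

    Requires a positive response: rows with f3 <= 0 must be removed
    first (``build_affinity_table(..., drop_nonpositive=True)``).
    """
    y = table["f3"].to_numpy(dtype=float)
    if (y <= 0).any():
        raise ValueError(
            "Gamma family needs a positive response; rebuild the table with "
            "drop_nonpositive=True"
        )
    n = len(y)
    X = table[["lcd", "bp_mean"]].to_numpy(dtype=float)
    basis = _TPSBasis(X, k=basis_dim)
    if n <= basis.n_coef:
        raise ValueError(
            f"n={n} rows cannot support {basis.n_coef} coefficients; "
            "reduce basis_dim"
        )
    B = basis.design(X)
    S1, S2 = basis.penalties()
    has_rad = basis.S_rad.shape[0] > 0

    def assemble(l1: float, l2: float) -> np.ndarray:
        return l1 * S1 + l2 * S2

    def reml_score(logs: np.ndarray) -> float:
        l1 = 10.0 ** np.clip(logs[0], -8, 10)
        l2 = 10.0 ** np.clip(logs[1], -8, 10) if select_null else 0.0
        S_lam = assemble(l1, l2)
        try:
            beta, eta, z, factor, A = _pirls(y, B, S_lam, max_iter=max_iter)
        except (RuntimeError, np.linalg.LinAlgError):
            return np.inf
        rss_pen = float(np.sum((z - eta) ** 2) + beta @ S_lam @ beta)
        H = A + S_lam
        m0 = 1 if select_null else 3
        score = (
            0.5 * (n - m0) * np.log(max(rss_pen, 1e-12))
            + 0.5 * (_logdet_psd(H) - _logdet_psd(S_lam))
        )
        return score if np.isfinite(score) else np.inf

    method = "REML"
    if lam is not None:
        l1, l2 = lam
    else:
        grid = np.arange(-3.0, 7.1, 2.0)
        best, best_score = None, np.inf
        for g1 in grid:
            for g2 in (grid if select_null else [0.0]):
                s = reml_score(np.array([g1, g2]))
                if s < best_score:
                    best, best_score = (g1, g2), s
        if best is None or not np.isfinite(best_score):
            method = "GCV"
            logger.warning("fit_gamma_smooth: REML failed, falling back to GCV")
            best, best_score = (0.0, 0.0), np.inf

            def gcv_score(logs):
                l1 = 10.0 ** np.clip(logs[0], -8, 10)
                l2 = 10.0 ** np.clip(logs[1], -8, 10) if select_null else 0.0
                S_lam = assemble(l1, l2)
                try:
                    beta, eta, z, factor, A = _pirls(y, B, S_lam)
                except (RuntimeError, np.linalg.LinAlgError):
                    return np.inf
                edf = float(np.trace(cho_solve(factor, A)))
                rss = float(np.sum((z - eta) ** 2))
                return n * rss / max(n - edf, 1e-6) ** 2

            objective = gcv_score
        else:
            objective = reml_score
        res = optimize.minimize(
            objective, np.array(best), method="Nelder-Mead",
            options={"maxiter": 60, "xatol": 0.05, "fatol": 1e-7},
        )
        logs = res.x if np.isfinite(res.fun) else np.array(best)
        l1 = 10.0 ** float(np.clip(logs[0], -8, 10))
        l2 = 10.0 ** float(np.clip(logs[1], -8, 10)) if select_null else 0.0

    S_lam = assemble(l1, l2)
    beta, eta, z, factor, A = _pirls(y, B, S_lam, max_iter=max_iter)
    edf = float(np.trace(cho_solve(factor, A)))
    mu = np.exp(np.clip(eta, -30, 30))
    dev = _gamma_deviance(y, mu)
    dev0 = _gamma_deviance(y, np.full(n, y.mean()))
    dev_expl = 1.0 - dev / dev0 if dev0 > 0 else 0.0
    ss_res = float(np.sum((y - mu) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / max(n - edf, 1.0)
    return SmoothFitResult(
        basis=basis, beta=beta, edf=edf, r2_adj=r2_adj,
        deviance_explained=float(np.clip(dev_expl, 0.0, 1.0)),
        intercept=float(beta[0]), lambda_=(l1, l2), method=method, n=n,
    )


# ---------------------------------------------------------------------------
# Cross-validation and model selection
# ---------------------------------------------------------------------------

def _cv_splits(labels: np.ndarray, k: int, seed: int):
    """Stratified-by-modern-population folds; plain shuffled folds when a
    population has fewer rows than folds."""
    from sklearn.model_selection import KFold, StratifiedKFold

    counts = pd.Series(labels).value_counts()
    if counts.min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return splitter.split(np.zeros(len(labels)), labels)
    logger.info("kfold_cv_mse: smallest population has %d rows < k=%d; "
                "using unstratified folds", counts.min(), k)
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return splitter.split(np.zeros(len(labels)))


def kfold_cv_mse(
    table: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    basis_dim: int | None = None,
    repeats: int = 1,
    **fit_kw,
) -> CVResult:
    """Seeded k-fold cross-validated MSE of the Gamma spline surface.

    Folds are stratified by modern population (pairs sharing a modern
    population are dependent).  Prediction error is measured on the
    response scale; degenerate folds are skipped and logged.  With
    ``repeats`` > 1 the MSE is averaged over that many independent
    seeded fold partitions, which stabilizes model comparison when the
    table is small.
    """
    n = len(table)
    if k < 2 or n < k:
        raise ValueError("need k >= 2 and at least k rows")
    labels = table["modern_pop"].to_numpy()
    seeds = np.random.default_rng(seed).integers(2**31 - 1, size=repeats)
    fold_mses = []
    for rep_seed in seeds:
        for train, test in _cv_splits(labels, k, int(rep_seed)):
            sub = table.iloc[train]
            bdim = min(basis_dim if basis_dim is not None else 30,
                       max(5, len(sub) // 3))
            try:
                fit = fit_gamma_smooth(sub, basis_dim=bdim, **fit_kw)
            except (ValueError, RuntimeError, np.linalg.LinAlgError) as err:
                logger.warning("kfold_cv_mse: fold skipped (%s)", err)
                continue
            held = table.iloc[test]
            pred = fit.predict(held["lcd"], held["bp_mean"])
            fold_mses.append(float(np.mean((held["f3"].to_numpy() - pred) ** 2)))
    if not fold_mses:
        raise RuntimeError("all CV folds failed")
    return CVResult(mse=float(np.mean(fold_mses)),
                    k_effective=len(fold_mses) // repeats, n_rows=n)


def select_friction_model(
    candidates: list,
    f3_results,
    pops,
    elevation,
    layers,
    k: int = 10,
    seed: int = 0,
    basis_dim: int | None = None,
    snap_radius: float = 10.0,
    repeats: int = 3,
) -> pd.DataFrame:
    """Rank candidate friction models by cross-validated MSE.

    For each candidate: assemble the cost grid, compute the LCD matrix,
    build the affinity table and evaluate ``kfold_cv_mse``.  Ties are
    broken in favor of fewer included feature classes.
    """
    from .friction import assemble_friction
    from .least_cost import lcd_matrix

    if len(candidates) < 1:
        raise ValueError("need at least one candidate model")
    rows = []
    errors = []
    for model in candidates:
        try:
            grid = assemble_friction(elevation, layers, model)
            lcd = lcd_matrix(grid, pops, snap_radius=snap_radius)
            table = build_affinity_table(f3_results, lcd, pops)
            cv = kfold_cv_mse(table, k=k, seed=seed, basis_dim=basis_dim,
                              repeats=repeats)
        except Exception as err:  # aggregate per-candidate failures
            errors.append((model, err))
            logger.warning("select_friction_model: candidate %s failed: %s",
                           model, err)
            continue
        rows.append({
            "model": str(model),
            "model_json": model.to_json(),
            "cv_mse": cv.mse,
            "k_effective": cv.k_effective,
            "n_rows": cv.n_rows,
            "n_features": len(model.included_classes),
        })
    if not rows:
        raise RuntimeError(
            "all candidates failed: "
            + "; ".join(f"{m}: {e}" for m, e in errors)
        )
    out = pd.DataFrame(rows).sort_values(
        ["cv_mse", "n_features"], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def correlations(
    table: pd.DataFrame, bp_window: tuple[float, float] | None = None
) -> dict[str, CorrelationResult]:
    """Pearson r(f3, LCD), r(f3, BP) and the semi-partial correlation of
    LCD with f3 after removing the linear effect of BP on f3, optionally
    restricted to a mean-BP window (inclusive)."""
    df = table
    if bp_window is not None:
        lo, hi = bp_window
        df = df[(df["bp_mean"] >= lo) & (df["bp_mean"] <= hi)]
    n = len(df)
    if n < 3:
        raise ValueError("need at least 3 rows for correlations")
    f3 = df["f3"].to_numpy(float)
    lcd = df["lcd"].to_numpy(float)
    bp = df["bp_mean"].to_numpy(float)
    for name, v in (("f3", f3), ("lcd", lcd)):
        if np.std(v) == 0:
            raise ValueError(f"zero variance in {name}")
    out: dict[str, CorrelationResult] = {}
    r, p = pearsonr(f3, lcd)
    out["f3_lcd"] = CorrelationResult(float(r), float(p), "pearson", n)
    if np.std(bp) > 0:
        r, p = pearsonr(f3, bp)
        out["f3_bp"] = CorrelationResult(float(r), float(p), "pearson", n)
        design = np.column_stack([np.ones(n), bp])
        resid = f3 - design @ np.linalg.lstsq(design, f3, rcond=None)[0]
    else:
        resid = f3 - f3.mean()
    if np.std(resid) > 0:
        r, p = pearsonr(lcd, resid)
    else:
        r, p = 0.0, 1.0
    out["semipartial_f3_lcd_given_bp"] = CorrelationResult(
        float(r), float(p), "semipartial", n
    )
    return out


# ---------------------------------------------------------------------------
# f4 sign agreement (Cohen's kappa)
# ---------------------------------------------------------------------------

def cohen_kappa_counts(a: int, b: int, c: int, d: int) -> float:
    """Cohen's kappa of a 2x2 agreement table [[a, b], [c, d]]."""
    n = a + b + c + d
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1 - pe)


def f4_rows_from_results(results: list[FStatResult]) -> pd.DataFrame:
    """f4(Outgroup, Test; X, Y) results -> (test, x, y, estimate, z) rows."""
    return pd.DataFrame([
        {"test": r.pops[1], "x": r.pops[2], "y": r.pops[3],
         "estimate": r.estimate, "z": r.z}
        for r in results
    ])


def f4_sign_agreement(
    f4_rows: pd.DataFrame,
    lcd: LCDMatrix,
    z_threshold: float = 3.0,
    n_perm: int = 100_000,
    seed: int = 0,
) -> AgreementResult:
    """Agreement between the sign of f4(O, Test; X, Y) and of
    LCD.D = LCD(Test, X) - LCD(Test, Y) over significant tests.

    Only rows with |Z| > ``z_threshold`` enter; rows with LCD.D = 0 or a
    non-finite distance are excluded (logged).  Agreement means equal
    signs (f4 < 0 and a closer X both point at X).  Cohen's kappa on the
    2x2 sign table; the p-value permutes the LCD.D margin, which with
    fixed margins is equivalent to hypergeometric resampling of the
    agreement cell (one-sided, greater).
    """
    if isinstance(f4_rows, list):
        f4_rows = f4_rows_from_results(f4_rows)
    sig = f4_rows[np.abs(f4_rows["z"]) > z_threshold].copy()
    if sig.empty:
        raise ValueError("no f4 tests exceed the Z threshold")
    lcdd = np.array([
        lcd.loc(t, x) - lcd.loc(t, y)
        for t, x, y in zip(sig["test"], sig["x"], sig["y"])
    ])
    ok = np.isfinite(lcdd) & (lcdd != 0)
    if (~ok).any():
        logger.info("f4_sign_agreement: excluding %d rows with zero or "
                    "non-finite LCD.D", int((~ok).sum()))
    sig = sig[ok]
    lcdd = lcdd[ok]
    if sig.empty:
        raise ValueError("no usable rows after LCD.D exclusion")

    s_f4 = sig["estimate"].to_numpy() > 0
    s_d = lcdd > 0
    n = len(s_f4)
    a = int(np.sum(s_f4 & s_d))
    b = int(np.sum(s_f4 & ~s_d))
    c = int(np.sum(~s_f4 & s_d))
    d = int(np.sum(~s_f4 & ~s_d))
    kappa = cohen_kappa_counts(a, b, c, d)

    rng = np.random.default_rng(seed)
    n_f4_pos, n_d_pos = a + b, a + c
    a_perm = rng.hypergeometric(n_d_pos, n - n_d_pos, n_f4_pos, size=n_perm)
    b_perm = n_f4_pos - a_perm
    c_perm = n_d_pos - a_perm
    d_perm = n - n_f4_pos - n_d_pos + a_perm
    po = (a_perm + d_perm) / n
    pe = ((a_perm + b_perm) * (a_perm + c_perm)
          + (c_perm + d_perm) * (b_perm + d_perm)) / n**2
    with np.errstate(divide="ignore", invalid="ignore"):
        kperm = np.where(pe < 1.0, (po - pe) / (1 - pe),
                         np.where(po == 1.0, 1.0, 0.0))
    p = (1 + int(np.sum(kperm >= kappa - 1e-12))) / (1 + n_perm)
    return AgreementResult(counts=(a, b, c, d), kappa=float(kappa),
                           p_value=float(p), n_used=n)


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------

def _as_distance_matrix(d) -> np.ndarray:
    m = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(
        d, dtype=float
    )
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(m, m.T, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(m), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    return m


def mantel_test(
    d1, d2, n_perm: int = 9999, seed: int = 0, alternative: str = "greater"
) -> CorrelationResult:
    """Mantel permutation test between two distance matrices.

    r is the Pearson correlation of the upper-triangular entries; the
    null distribution permutes rows and columns of ``d2`` jointly.  The
    default one-sided "greater" alternative matches the
    isolation-by-resistance expectation of a positive association.
    """
    m1, m2 = _as_distance_matrix(d1), _as_distance_matrix(d2)
    if m1.shape != m2.shape:
        raise ValueError("distance matrices must have the same shape")
    npop = m1.shape[0]
    iu = np.triu_indices(npop, 1)
    v1, v2 = m1[iu], m2[iu]
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("Mantel r undefined for a constant matrix")
    r_obs = float(np.corrcoef(v1, v2)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(npop)
        vp = m2[np.ix_(idx, idx)][iu]
        rp = np.corrcoef(v1, vp)[0, 1]
        if alternative == "greater":
            count += rp >= r_obs - 1e-12
        elif alternative == "less":
            count += rp <= r_obs + 1e-12
        else:
            count += abs(rp) >= abs(r_obs) - 1e-12
    p = (1 + count) / (1 + n_perm)
    return CorrelationResult(r=r_obs, p_value=float(p), kind="mantel", n=npop)


def partial_mantel_test(
    d1, d2, d3, n_perm: int = 9999, seed: int = 0,
    alternative: str = "greater",
) -> CorrelationResult:
    """Partial Mantel test of d1 ~ d2 controlling d3.

    The upper-triangle vectors of d1 and d2 are each residualized on
    d3's (linear regression with intercept); r is the correlation of the
    residuals, and the permutation null shuffles the d2 residual vector.
    """
    m1, m2, m3 = (_as_distance_matrix(d) for d in (d1, d2, d3))
    if not (m1.shape == m2.shape == m3.shape):
        raise ValueError("distance matrices must have the same shape")
    npop = m1.shape[0]
    iu = np.triu_indices(npop, 1)
    v1, v2, v3 = m1[iu], m2[iu], m3[iu]
    design = np.column_stack([np.ones(len(v3)), v3])

    def residualize(v):
        return v - design @ np.linalg.lstsq(design, v, rcond=None)[0]

    e1, e2 = residualize(v1), residualize(v2)
    # a matrix collinear with the control leaves only machine noise: the
    # partial correlation is zero by construction
    if np.std(e1) <= 1e-10 * np.std(v1) or np.std(e2) <= 1e-10 * np.std(v2):
        return CorrelationResult(r=0.0, p_value=1.0, kind="partial_mantel",
                                 n=npop)
    r_obs = float(np.corrcoef(e1, e2)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        ep = rng.permutation(e2)
        rp = np.corrcoef(e1, ep)[0, 1]
        if alternative == "greater":
            count += rp >= r_obs - 1e-12
        elif alternative == "less":
            count += rp <= r_obs + 1e-12
        else:
            count += abs(rp) >= abs(r_obs) - 1e-12
    p = (1 + count) / (1 + n_perm)
    return CorrelationResult(r=r_obs, p_value=float(p), kind="partial_mantel",
                             n=npop)


# ---------------------------------------------------------------------------
# Ancestry-contribution distances
# ---------------------------------------------------------------------------

def ancestry_contribution_distance(
    f3_results,
    groupings,
    subset: list[str] | None = None,
) -> pd.DataFrame:
    """Manhattan distances between modern populations in the space of
    median f3 per ancient geographic grouping.

    ``groupings`` maps ancient population id -> group label (a mapping,
    or a PopulationTable whose ``group`` column is used).  ``subset``
    restricts to the named groups.  Every modern population must have at
    least one f3 value in every used group.
    """
    df = _f3_frame(f3_results)
    if hasattr(groupings, "table"):
        groupings = groupings.table["group"].to_dict()
    df["group"] = df["ancient_pop"].map(groupings)
    if df["group"].isna().any():
        missing = df.loc[df["group"].isna(), "ancient_pop"].unique()
        raise ValueError(f"no group for ancient populations {list(missing)}")
    if subset is not None:
        df = df[df["group"].isin(subset)]
    med = df.groupby(["modern_pop", "group"])["f3"].median().unstack("group")
    if med.isna().any().any():
        pop = med.index[med.isna().any(axis=1)][0]
        grp = med.columns[med.loc[pop].isna()][0]
        raise ValueError(f"modern population {pop!r} has no f3 values in "
                         f"group {grp!r}")
    dist = squareform(pdist(med.to_numpy(), metric="cityblock"))
    return pd.DataFrame(dist, index=med.index, columns=med.index)
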