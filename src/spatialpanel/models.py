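"""Maximum-likelihood spatial panel models: SDM, SLM, SEM, and OLS baseline.

The general panel model for outcome y_it on N regions over T periods is

    y_it = a + rho * sum_j w_ij y_jt + (W x)_it' delta + x_it' beta
           + mu_i + gamma_t + eps_it,        eps_it = lambda (M eps)_it + psi_it

with W the row-standardized contiguity matrix, M the error-equation
weight matrix (equal to W by default), and psi_it ~ N(0, sigma^2) iid.
Setting lambda = 0 gives the Spatial Durbin Model (SDM); lambda = 0 and
delta = 0 the Spatial Lag Model (SLM); rho = 0 and delta = 0 the
Spatial Error Model (SEM).

Estimation is concentrated (profile) maximum likelihood on the
within-transformed panel: region and/or period fixed effects are removed
by demeaning, and for each candidate spatial parameter the slope
coefficients are recovered by least squares, giving a smooth scalar
objective

    l(rho) = const + T * sum_i ln(1 - rho * omega_i) - (NT/2) ln(SSR(rho)/NT)

where omega_i are the eigenvalues of W.  The admissible interval for the
spatial parameter is (1/omega_min, 1).  With two-way effects the
cross-sectionally demeaned data live in the zero-mean subspace, where
the spatial operator is Q_N W: the Jacobian then drops W's unit
(Perron) eigenvalue and the Gaussian dimension is (N-1)T — exact
algebra of the transformed model, not a small-sample correction.
Standard errors come from the numerical Hessian of the full
log-likelihood at the optimum; sigma^2 uses the ML (dimension-divisor)
convention.  No small-T incidental-parameter bias correction is
applied, so spatial-parameter estimates at very short T retain a mild
attenuation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .weights import SpatialWeights, weights_spectrum

__all__ = [
    "ModelSpec",
    "PanelFit",
    "CollinearityError",
    "ConvergenceError",
    "DEFAULT_COVARIATES",
    "panel_arrays",
    "within_transform",
    "log_det_jacobian",
    "fit_slm",
    "fit_sdm",
    "fit_sem",
    "fit_ols",
    "fit_model",
    "recover_effects",
    "model_report",
]

DEFAULT_COVARIATES = ["pm25", "lngdp", "lnhos", "lncost", "popudens"]

_BOUND_PAD = 1e-6


class CollinearityError(ValueError):
    """Singular design matrix; names the offending columns."""


class ConvergenceError(RuntimeError):
    """Spatial-parameter optimum pinned at the admissible-interval boundary."""


@dataclass
class ModelSpec:
    """What to fit: model family, effects treatment, covariate list."""

    family: str = "SLM"  # SDM | SLM | SEM | OLS
    effects: str = "twoway"  # pooled | individual | twoway
    durbin_style: str = "common_scalar"  # per_covariate | common_scalar (SDM)
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))

    def __post_init__(self) -> None:
        if self.family not in {"SDM", "SLM", "SEM", "OLS"}:
            raise ValueError(f"unknown family {self.family!r}")
        if self.effects not in {"pooled", "individual", "twoway"}:
            raise ValueError(f"unknown effects {self.effects!r}")
        if self.durbin_style not in {"per_covariate", "common_scalar"}:
            raise ValueError(f"unknown durbin_style {self.durbin_style!r}")


@dataclass
class PanelFit:
    """Estimates, inference, and fit statistics for one model."""

    spec: ModelSpec
    coefficients: dict[str, tuple[float, float, float, float]]  # est, se, z, p
    rho: tuple[float, float, float] | None  # est, z, p
    lam: tuple[float, float, float] | None
    sigma2_e: float
    sigma2_z: float | None
    log_likelihood: float
    pseudo_r2: float
    n_regions: int
    n_periods: int
    effects_estimates: dict[str, np.ndarray] | None = None

    def coef(self, name: str) -> float:
        return self.coefficients[name][0]


# ---------------------------------------------------------------------------
# panel plumbing

def panel_arrays(
    panel: pd.DataFrame,
    W: SpatialWeights,
    outcome: str = "respdeath",
    covariates: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str], int, int]:
    """Stack a balanced long panel into period-major arrays.

    Rows are ordered with all N regions (in the weight matrix's region
    order) for the first period, then the second, and so on, so that
    spatial operations are block-diagonal applications of W.
    Returns ``(y, X, names, N, T)``.
    """
    covariates = list(covariates or DEFAULT_COVARIATES)
    years = sorted(panel["year"].unique())
    N, T = W.n, len(years)
    blocks_y, blocks_x = [], []
    for year in years:
        grp = panel[panel["year"] == year].set_index("region_id")
        grp = grp.reindex(W.region_order)
        cols = [outcome] + covariates
        if grp[cols].isna().any().any():
            raise ValueError(f"unbalanced panel: year {year} is missing regions")
        blocks_y.append(grp[outcome].to_numpy(dtype=float))
        blocks_x.append(grp[covariates].to_numpy(dtype=float))
    y = np.concatenate(blocks_y)
    X = np.vstack(blocks_x)
    return y, X, covariates, N, T


def within_transform(
    y: np.ndarray, X: np.ndarray, N: int, T: int, effects: str
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Demean a period-major stacked panel to absorb fixed effects.

    ``individual`` subtracts region means; ``twoway`` additionally
    subtracts period means and adds back the grand mean; ``pooled``
    leaves the data untouched and signals that an intercept column is
    needed.  Returns ``(y, X, dof_correction, add_intercept)`` where
    ``dof_correction`` counts the absorbed effect parameters.
    """
    if y.shape[0] != N * T or X.shape[0] != N * T:
        raise ValueError("panel is not balanced (NT mismatch)")
    if effects == "pooled":
        return y, X, 0, True

    def demean(a: np.ndarray) -> np.ndarray:
        shape = (T, N) if a.ndim == 1 else (T, N, a.shape[1])
        b = a.reshape(shape).astype(float)
        b = b - b.mean(axis=0, keepdims=True)  # region means over time
        if effects == "twoway":
            b = b - b.mean(axis=1, keepdims=True)  # period means over regions
            # grand mean is added back implicitly: double-demeaning of the
            # grand-mean term removes it twice and the formula above
            # (sequential demeaning) is algebraically Q_T then Q_N, which
            # equals region-demean + period-demean + grand mean.
        return b.reshape(a.shape)

    dof = N if effects == "individual" else N + T - 1
    return demean(y), demean(X), dof, False


def _blockW(v: np.ndarray, Wm: np.ndarray, N: int, T: int,
            project: bool = False) -> np.ndarray:
    """Apply W period-by-period to a stacked vector or matrix.

    ``project=True`` additionally removes each period's cross-sectional
    mean (the operator Q_N W): with time-period effects the demeaned data
    live in the zero-mean subspace, on which Q_N W — not W — is the
    spatial operator of the transformed model.
    """
    if v.ndim == 1:
        out = (Wm @ v.reshape(T, N).T).T  # (T, N): one period per row
        if project:
            out = out - out.mean(axis=1, keepdims=True)
        return out.reshape(-1)
    out = np.empty_like(v)
    for t in range(T):
        blk = Wm @ v[t * N:(t + 1) * N]
        if project:
            blk = blk - blk.mean(axis=0, keepdims=True)
        out[t * N:(t + 1) * N] = blk
    return out


def _effective_spectrum(spectrum: np.ndarray, project: bool) -> np.ndarray:
    """Spectrum of the spatial operator on the estimation subspace.

    Cross-sectional demeaning removes the constant vector — the Perron
    eigenvector of the row-standardized W — so exactly one unit
    eigenvalue drops out of the Jacobian.
    """
    if not project:
        return spectrum
    k = int(np.argmin(np.abs(spectrum - 1.0)))
    return np.delete(spectrum, k)


def _check_collinearity(X: np.ndarray, names: list[str]) -> None:
    if X.size == 0:
        raise CollinearityError("empty design matrix")
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    if s[0] == 0 or s[-1] / s[0] < 1e-10:
        null = vt[-1]
        bad = [names[k] for k in np.nonzero(np.abs(null) > 0.1)[0]]
        raise CollinearityError(f"collinear design columns: {bad}")


def log_det_jacobian(rho: float, spectrum: np.ndarray) -> float:
    """ln|I - rho*W| via the eigenvalues of W: sum_i ln(1 - rho*omega_i).

    ``rho`` must lie in the admissible interval (1/omega_min, 1).
    Callers multiply by T for a panel.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    lo = 1.0 / spectrum.min()
    if not (lo < rho < 1.0):
        raise ValueError(f"rho={rho} outside admissible interval ({lo}, 1)")
    return float(np.log(1.0 - rho * spectrum).sum())


# ---------------------------------------------------------------------------
# likelihoods

def _ols_beta(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(X, y, rcond=None)[0]


def _full_ll_lag(theta, y, X, Wy, spectrum, nstar, T):
    # theta = (beta..., rho, log sigma2) ; log-parameterized variance keeps
    # the Hessian evaluation away from sigma2 <= 0
    k = X.shape[1]
    beta, rho, s2 = theta[:k], theta[k], np.exp(theta[k + 1])
    if not (rho < 1.0 and np.all(1.0 - rho * spectrum > 0)):
        return -np.inf
    e = y - rho * Wy - X @ beta
    return (-0.5 * nstar * np.log(2 * np.pi * s2)
            + T * np.log(1.0 - rho * spectrum).sum()
            - 0.5 * (e @ e) / s2)


def _full_ll_err(theta, y, X, My, MX, spectrum, nstar, T):
    k = X.shape[1]
    beta, lam, s2 = theta[:k], theta[k], np.exp(theta[k + 1])
    if not (lam < 1.0 and np.all(1.0 - lam * spectrum > 0)):
        return -np.inf
    e = (y - lam * My) - (X - lam * MX) @ beta
    return (-0.5 * nstar * np.log(2 * np.pi * s2)
            + T * np.log(1.0 - lam * spectrum).sum()
            - 0.5 * (e @ e) / s2)


def _numerical_hessian(f, theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    p = len(theta)
    h = rel_step * np.maximum(1.0, np.abs(theta))
    H = np.empty((p, p))
    f0 = f(theta)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def _se_from_hessian(f, theta: np.ndarray) -> np.ndarray:
    H = _numerical_hessian(f, theta)
    cov = np.linalg.inv(-H)
    var = np.diag(cov).copy()
    var[var < 0] = np.nan
    return np.sqrt(var)


def _wald(est: float, se: float) -> tuple[float, float]:
    z = est / se if se and np.isfinite(se) and se > 0 else np.nan
    p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
    return float(z), float(p)


# ---------------------------------------------------------------------------
# model fits

def _prepare(panel, W, spec, outcome):
    y, X, names, N, T = panel_arrays(panel, W, outcome=outcome,
                                     covariates=spec.covariates)
    if spec.family == "SDM":
        WX = _blockW(X, W.matrix, N, T)
        if spec.durbin_style == "per_covariate":
            X = np.hstack([X, WX])
            names = names + [f"W_{c}" for c in spec.covariates]
        else:
            X = np.hstack([X, WX.sum(axis=1, keepdims=True)])
            names = names + ["delta"]
    yt, Xt, dof, add_const = within_transform(y, X, N, T, spec.effects)
    if add_const:
        Xt = np.hstack([np.ones((N * T, 1)), Xt])
        names = ["const"] + names
    _check_collinearity(Xt, names)
    return yt, Xt, names, N, T, dof


def _concentrated_spatial_fit(yt, Xt, names, N, T, W, kind, fix_spatial,
                              project=False):
    """Shared concentrated-ML machinery for the lag (SLM/SDM) and error
    (SEM) families.  ``kind`` selects how the spatial parameter enters:
    filtered outcome (lag) or filtered outcome and regressors (error).
    ``project`` marks the two-way-effects case, where the demeaned data
    lie in the zero-cross-sectional-mean subspace: the spatial operator
    is Q_N W, its Jacobian loses the unit eigenvalue, and the Gaussian
    dimension is (N-1)T."""
    full_spectrum = weights_spectrum(W)
    spectrum = _effective_spectrum(full_spectrum, project)
    lo = 1.0 / full_spectrum.min()
    NT = ((N - 1) if project else N) * T
    Wy = _blockW(yt, W.matrix, N, T, project)
    if kind == "lag":
        # profile out beta: residuals of y and Wy on X
        b0 = _ols_beta(Xt, yt)
        b1 = _ols_beta(Xt, Wy)
        e0 = yt - Xt @ b0
        e1 = Wy - Xt @ b1

        def ssr(r):
            d = e0 - r * e1
            return d @ d
    else:  # error: spatially filter both sides
        MX = _blockW(Xt, W.matrix, N, T, project)

        def ssr(r):
            ys = yt - r * Wy
            Xs = Xt - r * MX
            bs = _ols_beta(Xs, ys)
            d = ys - Xs @ bs
            return d @ d

    def negll(r):
        return -(T * np.log(1.0 - r * spectrum).sum()
                 - 0.5 * NT * np.log(ssr(r) / NT))

    if fix_spatial is None:
        bounds = (lo + _BOUND_PAD, 1.0 - _BOUND_PAD)
        opt = optimize.minimize_scalar(
            negll, bounds=bounds, method="bounded",
            options={"xatol": 1e-8},
        )
        r_hat = float(opt.x)
        if min(r_hat - bounds[0], bounds[1] - r_hat) < 1e-5:
            raise ConvergenceError(
                f"spatial parameter optimum at interval boundary ({r_hat:.6f})"
            )
    else:
        r_hat = float(fix_spatial)

    if kind == "lag":
        beta = _ols_beta(Xt, yt - r_hat * Wy)
        resid = yt - r_hat * Wy - Xt @ beta
    else:
        ys = yt - r_hat * Wy
        Xs = Xt - r_hat * MX
        beta = _ols_beta(Xs, ys)
        resid = ys - Xs @ beta
    s2 = float(resid @ resid) / NT

    theta = np.concatenate([beta, [r_hat, np.log(s2)]])
    if kind == "lag":
        def full(th):
            return _full_ll_lag(th, yt, Xt, Wy, spectrum, NT, T)
    else:
        def full(th):
            return _full_ll_err(th, yt, Xt, Wy, MX, spectrum, NT, T)
    ll = float(full(theta))
    se = _se_from_hessian(full, theta)
    k = Xt.shape[1]
    # delta-method back to the sigma2 scale from log sigma2
    se_beta, se_r, se_s2 = se[:k], se[k], se[k + 1] * s2

    coeffs = {}
    for j, nm in enumerate(names):
        z, p = _wald(beta[j], se_beta[j])
        coeffs[nm] = (float(beta[j]), float(se_beta[j]), z, p)
    zr, pr = _wald(r_hat, se_r)
    zs, _ = _wald(s2, se_s2)

    if kind == "lag":
        # reduced-form fitted values: (I - rho W)^-1 X beta per period
        Weff = W.matrix
        if project:
            Weff = Weff - Weff.mean(axis=0, keepdims=True)
        A = np.linalg.inv(np.eye(N) - r_hat * Weff)
        fitted = _apply_block(A, Xt @ beta, N, T)
    else:
        fitted = Xt @ beta
    r2 = _squared_corr(yt, fitted)
    return beta, coeffs, (r_hat, zr, pr), s2, float(zs), ll, r2


def _apply_block(A, v, N, T):
    return (A @ v.reshape(T, N).T).T.reshape(-1)


def _squared_corr(y, yhat) -> float:
    sy, syh = np.std(y), np.std(yhat)
    if sy == 0 or syh == 0:
        return 0.0
    c = np.corrcoef(y, yhat)[0, 1]
    return float(c ** 2)


def fit_slm(panel, W, spec=None, outcome="respdeath", fix_rho=None) -> PanelFit:
    """Spatial Lag Model: y depends on the spatial lag of the outcome.

    The concentrated likelihood is maximized over rho on the admissible
    interval; ``fix_rho`` skips the search and evaluates at a fixed value
    (``fix_rho=0`` reproduces the within-OLS slopes exactly).
    """
    spec = spec or ModelSpec(family="SLM")
    if spec.family != "SLM":
        raise ValueError("spec.family must be SLM")
    yt, Xt, names, N, T, _ = _prepare(panel, W, spec, outcome)
    _, coeffs, rho, s2, zs, ll, r2 = _concentrated_spatial_fit(
        yt, Xt, names, N, T, W, "lag", fix_rho,
        project=spec.effects == "twoway")
    return PanelFit(spec=spec, coefficients=coeffs, rho=rho, lam=None,
                    sigma2_e=s2, sigma2_z=zs, log_likelihood=ll,
                    pseudo_r2=r2, n_regions=N, n_periods=T)


def fit_sdm(panel, W, spec=None, outcome="respdeath", fix_rho=None) -> PanelFit:
    """Spatial Durbin Model: SLM plus spatially lagged covariates.

    ``durbin_style="per_covariate"`` adds one W·x column per covariate;
    ``"common_scalar"`` adds the single row-sum of the lagged covariates,
    so one delta coefficient is reported.
    """
    spec = spec or ModelSpec(family="SDM")
    if spec.family != "SDM":
        raise ValueError("spec.family must be SDM")
    yt, Xt, names, N, T, _ = _prepare(panel, W, spec, outcome)
    _, coeffs, rho, s2, zs, ll, r2 = _concentrated_spatial_fit(
        yt, Xt, names, N, T, W, "lag", fix_rho,
        project=spec.effects == "twoway")
    return PanelFit(spec=spec, coefficients=coeffs, rho=rho, lam=None,
                    sigma2_e=s2, sigma2_z=zs, log_likelihood=ll,
                    pseudo_r2=r2, n_regions=N, n_periods=T)


def fit_sem(panel, W, spec=None, outcome="respdeath", fix_lambda=None,
            M: SpatialWeights | None = None) -> PanelFit:
    """Spatial Error Model: spatially autoregressive disturbances.

    ``M`` overrides the error-equation weight matrix (default: W).
    ``fix_lambda=0`` reproduces within-OLS exactly.
    """
    spec = spec or ModelSpec(family="SEM")
    if spec.family != "SEM":
        raise ValueError("spec.family must be SEM")
    Werr = M if M is not None else W
    yt, Xt, names, N, T, _ = _prepare(panel, Werr, spec, outcome)
    _, coeffs, lam, s2, zs, ll, r2 = _concentrated_spatial_fit(
        yt, Xt, names, N, T, Werr, "error", fix_lambda,
        project=spec.effects == "twoway")
    return PanelFit(spec=spec, coefficients=coeffs, rho=None, lam=lam,
                    sigma2_e=s2, sigma2_z=zs, log_likelihood=ll,
                    pseudo_r2=r2, n_regions=N, n_periods=T)


def fit_ols(panel, W, spec=None, outcome="respdeath") -> PanelFit:
    """Non-spatial least-squares baseline (pooled or within)."""
    spec = spec or ModelSpec(family="OLS")
    if spec.family != "OLS":
        raise ValueError("spec.family must be OLS")
    yt, Xt, names, N, T, dof = _prepare(panel, W, spec, outcome)
    NT = N * T
    beta = _ols_beta(Xt, yt)
    resid = yt - Xt @ beta
    k = Xt.shape[1]
    df = max(NT - k - dof, 1)
    s2_resid = float(resid @ resid) / df
    XtX_inv = np.linalg.inv(Xt.T @ Xt)
    se = np.sqrt(np.diag(XtX_inv) * s2_resid)
    coeffs = {}
    for j, nm in enumerate(names):
        z, p = _wald(beta[j], se[j])
        coeffs[nm] = (float(beta[j]), float(se[j]), z, p)
    s2_ml = float(resid @ resid) / NT
    ll = float(-0.5 * NT * (np.log(2 * np.pi * s2_ml) + 1))
    r2 = _squared_corr(yt, Xt @ beta)
    return PanelFit(spec=spec, coefficients=coeffs, rho=None, lam=None,
                    sigma2_e=s2_ml, sigma2_z=None, log_likelihood=ll,
                    pseudo_r2=r2, n_regions=N, n_periods=T)


def fit_model(panel, W, spec: ModelSpec, outcome="respdeath") -> PanelFit:
    """Dispatch on ``spec.family``."""
    fam = spec.family
    if fam == "SLM":
        return fit_slm(panel, W, spec, outcome)
    if fam == "SDM":
        return fit_sdm(panel, W, spec, outcome)
    if fam == "SEM":
        return fit_sem(panel, W, spec, outcome)
    return fit_ols(panel, W, spec, outcome)


def recover_effects(fit: PanelFit, panel: pd.DataFrame, W: SpatialWeights,
                    outcome: str = "respdeath") -> dict[str, np.ndarray]:
    """Recover the absorbed fixed effects from a fitted model.

    Computes the structural residual on the raw (un-demeaned) data —
    y - rho*Wy - X*beta for the lag families, y - X*beta for SEM/OLS —
    and splits it into region means (mu), period means (gamma) and the
    grand mean.  The result is stored on ``fit.effects_estimates``.
    """
    spec = fit.spec
    y, X, names, N, T = panel_arrays(panel, W, outcome=outcome,
                                     covariates=spec.covariates)
    if spec.family == "SDM":
        WX = _blockW(X, W.matrix, N, T)
        if spec.durbin_style == "per_covariate":
            X = np.hstack([X, WX])
            names = names + [f"W_{c}" for c in spec.covariates]
        else:
            X = np.hstack([X, WX.sum(axis=1, keepdims=True)])
            names = names + ["delta"]
    beta = np.array([fit.coef(nm) for nm in names])
    r = y - X @ beta
    if spec.family in {"SLM", "SDM"}:
        r = r - fit.rho[0] * _blockW(y, W.matrix, N, T)
    grid = r.reshape(T, N)
    grand = grid.mean()
    out = {
        "mu": grid.mean(axis=0) - grand,
        "gamma": grid.mean(axis=1) - grand,
        "grand_mean": np.array([grand]),
    }
    fit.effects_estimates = out
    return out


def model_report(fits: list[PanelFit]) -> pd.DataFrame:
    """Side-by-side comparison table: one (Coef., Z, p) block per model,
    rows for each covariate then delta, rho, lambda, sigma2_e and R^2."""
    if not fits:
        raise ValueError("at least one fit is required")
    rows: list[str] = []
    for f in fits:
        for nm in f.coefficients:
            if nm not in rows:
                rows.append(nm)
    spatial_rows = []
    if any(f.rho is not None for f in fits):
        spatial_rows.append("rho")
    if any(f.lam is not None for f in fits):
        spatial_rows.append("lambda")
    rows = rows + spatial_rows + ["sigma2_e", "R2"]
    out: dict[tuple[str, str], list] = {}
    for f in fits:
        label = f.spec.family
        col_c, col_z, col_p = [], [], []
        for r in rows:
            if r in f.coefficients:
                est, _, z, p = f.coefficients[r]
                col_c.append(est); col_z.append(z); col_p.append(p)
            elif r == "rho" and f.rho is not None:
                col_c.append(f.rho[0]); col_z.append(f.rho[1]); col_p.append(f.rho[2])
            elif r == "lambda" and f.lam is not None:
                col_c.append(f.lam[0]); col_z.append(f.lam[1]); col_p.append(f.lam[2])
            elif r == "sigma2_e":
                col_c.append(f.sigma2_e); col_z.append(f.sigma2_z); col_p.append(None)
            elif r == "R2":
                col_c.append(f.pseudo_r2); col_z.append(None); col_p.append(None)
            else:
                col_c.append(None); col_z.append(None); col_p.append(None)
        out[(label, "Coef.")] = col_c
        out[(label, "Z")] = col_z
        out[(label, "p")] = col_p
    return pd.DataFrame(out, index=rows)
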