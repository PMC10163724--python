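"""Animal-model machinery: design matrices, Henderson's mixed-model
equations, REML variance components, heritability and correlations.

The univariate fit uses average-information (AI) REML with an EM fallback,
evaluated in the eigenbasis of ZKZ' so each likelihood/score evaluation is
O(n) after one symmetric eigendecomposition.  The bivariate fit maximizes
the restricted likelihood over log-Cholesky factors of the 2x2 genetic and
residual covariance matrices, which keeps both positive semi-definite by
construction.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .grm import RelationshipMatrix


class REMLConvergenceError(RuntimeError):
    """REML failed to converge; carries the iterate trail."""

    def __init__(self, message: str, trail: list):
        super().__init__(message)
        self.trail = trail


@dataclasses.dataclass
class VarianceComponents:
    """Univariate additive + residual variance estimates."""

    sigma_a2: float
    sigma_e2: float
    se_a2: float
    se_e2: float
    cov: np.ndarray          # 2x2 asymptotic covariance of (sigma_a2, sigma_e2)
    loglik: float
    n_iter: int
    converged: bool
    at_bound: bool = False

    @property
    def h2(self) -> float:
        return self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)


@dataclasses.dataclass
class BivariateComponents:
    """Bivariate genetic/residual covariance matrices and correlations."""

    genetic_cov: np.ndarray   # 2x2
    residual_cov: np.ndarray  # 2x2
    param_cov: np.ndarray     # 6x6 for (ga11, ga12, ga22, re11, re12, re22)
    loglik: float
    converged: bool

    @property
    def r_g(self) -> float:
        g = self.genetic_cov
        return g[0, 1] / np.sqrt(g[0, 0] * g[1, 1])

    @property
    def r_p(self) -> float:
        p = self.genetic_cov + self.residual_cov
        return p[0, 1] / np.sqrt(p[0, 0] * p[1, 1])

    @property
    def r_g_se(self) -> float:
        a, c, b = self.genetic_cov[0, 0], self.genetic_cov[0, 1], self.genetic_cov[1, 1]
        r = self.r_g
        grad = np.zeros(6)
        grad[0] = -r / (2 * a)
        grad[1] = 1.0 / np.sqrt(a * b)
        grad[2] = -r / (2 * b)
        var = grad @ self.param_cov @ grad
        return float(np.sqrt(var)) if var > 0 else np.nan

    def h2(self, trait: int) -> float:
        g = self.genetic_cov[trait, trait]
        e = self.residual_cov[trait, trait]
        return g / (g + e)


@dataclasses.dataclass
class BlupSolution:
    beta: np.ndarray
    u: np.ndarray             # one prediction per animal in K
    ids: np.ndarray
    residual_norm: float
    fixed_names: list


# ---------------------------------------------------------------------------
# Design matrices


def build_design(
    pheno: pd.DataFrame,
    trait: str,
    rel: RelationshipMatrix,
    fixed_effects: tuple[str, ...] = ("sex", "cross", "room"),
    id_col: str = "animal_id",
):
    """Build (y, X, Z) for one trait against a relationship matrix.

    Records with a missing trait value are excluded.  Fixed effects are
    treatment-coded with the first observed level as reference; factors
    with a single level among the used records are dropped with a warning.
    Z is the n_records x n_K incidence matrix onto the columns of `rel`.
    """
    df = pheno.loc[pheno[trait].notna()].copy()
    if len(df) < 2:
        raise ValueError(f"trait {trait!r} has fewer than 2 records")
    y = df[trait].to_numpy(dtype=np.float64)
    cols = [np.ones(len(df))]
    names = ["intercept"]
    factors_used = []
    for factor in fixed_effects:
        if factor not in df.columns:
            continue
        levels = pd.unique(df[factor].astype(str))
        if len(levels) < 2:
            warnings.warn(
                f"fixed effect {factor!r} has a single level; dropped", stacklevel=2
            )
            continue
        factors_used.append(factor)
        for level in levels[1:]:
            cols.append((df[factor].astype(str) == level).to_numpy(dtype=np.float64))
            names.append(f"{factor}[{level}]")
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(
            f"fixed effects {factors_used} are confounded (rank-deficient design)"
        )
    rows = rel.index_of(df[id_col].to_numpy())
    z = np.zeros((len(df), rel.n))
    z[np.arange(len(df)), rows] = 1.0
    return y, x, z, names


# ---------------------------------------------------------------------------
# Henderson's mixed-model equations


def solve_mme(
    y: np.ndarray,
    x: np.ndarray,
    z: np.ndarray,
    k: RelationshipMatrix,
    vc: VarianceComponents,
    fixed_names: list | None = None,
) -> BlupSolution:
    """Solve Henderson's MME, returning BLUPs for every animal in K.

    Animals without records are carried through K^-1 and receive
    predictions via their relationships to recorded animals.
    """
    if vc.sigma_a2 <= 0 or vc.sigma_e2 <= 0:
        raise ValueError("variance components must be positive")
    lam = vc.sigma_e2 / vc.sigma_a2
    try:
        c_factor = linalg.cho_factor(k.values)
        kinv = linalg.cho_solve(c_factor, np.eye(k.n))
    except linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "relationship matrix is singular; apply grm.regularize first"
        )
    p = x.shape[1]
    top = np.hstack([x.T @ x, x.T @ z])
    bottom = np.hstack([z.T @ x, z.T @ z + lam * kinv])
    coeff = np.vstack([top, bottom])
    rhs = np.concatenate([x.T @ y, z.T @ y])
    try:
        sol = linalg.solve(coeff, rhs, assume_a="sym")
    except linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"singular MME coefficient matrix: {err}")
    resid = float(np.linalg.norm(coeff @ sol - rhs) / (1.0 + np.linalg.norm(rhs)))
    return BlupSolution(
        beta=sol[:p],
        u=sol[p:],
        ids=k.ids,
        residual_norm=resid,
        fixed_names=fixed_names or [f"b{i}" for i in range(p)],
    )


# ---------------------------------------------------------------------------
# Univariate AI-REML in the eigenbasis of ZKZ'


def _reml_pieces(theta, lam_eig, ystar, xstar):
    """Restricted log-likelihood, Py, and diag(P) ingredients at theta."""
    sa, se = theta
    v = sa * lam_eig + se
    w = 1.0 / v
    xw = xstar * w[:, None]
    xtwx = xstar.T @ xw
    xtwy = xw.T @ ystar
    chol = linalg.cho_factor(xtwx)
    beta = linalg.cho_solve(chol, xtwy)
    py = w * ystar - xw @ beta
    logdet_v = np.sum(np.log(v))
    logdet_xtwx = 2.0 * np.sum(np.log(np.diag(chol[0])))
    ypy = float(ystar @ py)
    ll = -0.5 * (logdet_v + logdet_xtwx + ypy)
    # diag(P) = w - w^2 * x_i' (X'WX)^-1 x_i
    b = linalg.cho_solve(chol, xw.T).T       # n x p
    h = np.einsum("ij,ij->i", b, xstar)
    pdiag = w - w * w * h
    return ll, py, pdiag, w, xstar, chol


def _project_p(vec, w, xstar, chol):
    """Apply the projection matrix P to a vector."""
    wv = w * vec
    return wv - (xstar * w[:, None]) @ linalg.cho_solve(chol, xstar.T @ wv)


def reml_univariate(
    y: np.ndarray,
    x: np.ndarray,
    z: np.ndarray,
    k: RelationshipMatrix,
    max_iter: int = 100,
    tol: float = 1e-8,
    start: tuple[float, float] | None = None,
) -> VarianceComponents:
    """AI-REML for the one-random-effect animal model.

    Maximizes the restricted log-likelihood over (sigma_a2, sigma_e2) with
    average-information updates, falling back to an EM-style step whenever
    an AI step leaves the parameter space.  Components are bounded below at
    1e-8 of the phenotypic variance.  Standard errors come from the inverse
    AI matrix at the optimum.
    """
    y = np.asarray(y, dtype=np.float64)
    n, p = x.shape
    if n < p + 2:
        raise ValueError("need at least n_fixed + 2 records for REML")
    g_obs = z @ k.values @ z.T
    lam_eig, u = linalg.eigh(g_obs)
    lam_eig = np.clip(lam_eig, 0.0, None)
    ystar = u.T @ y
    xstar = u.T @ x
    var_y = float(np.var(y))
    lb = 1e-8 * var_y
    theta = np.array(start) if start is not None else np.array([0.5 * var_y, 0.5 * var_y])
    theta = np.maximum(theta, lb)
    trail = []
    ll_old = -np.inf
    ai = np.eye(2)
    converged = False
    n_done = 0
    for it in range(1, max_iter + 1):
        n_done = it
        ll, py, pdiag, w, xs, chol = _reml_pieces(theta, lam_eig, ystar, xstar)
        trail.append((theta.copy(), ll))
        # scores: dl/dθ_i = -0.5 [tr(P dV_i) - y'P dV_i P y], dV = diag(lam) or I
        tr_pa = float(np.sum(pdiag * lam_eig))
        tr_pe = float(np.sum(pdiag))
        ypapy = float(py @ (lam_eig * py))
        ypepy = float(py @ py)
        score = -0.5 * np.array([tr_pa - ypapy, tr_pe - ypepy])
        # average information: 0.5 y'P dV_i P dV_j P y
        ta = _project_p(lam_eig * py, w, xs, chol)
        te = _project_p(py, w, xs, chol)
        ai = 0.5 * np.array(
            [
                [float((lam_eig * py) @ ta), float((lam_eig * py) @ te)],
                [float(py @ ta), float(py @ te)],
            ]
        )
        ai = 0.5 * (ai + ai.T)
        # scale-free gradient statistic, ignoring components pinned at the bound
        at_lb = (theta <= lb * (1 + 1e-9)) & (score < 0)
        grad_stat = float(np.max(np.abs(score * theta) * ~at_lb))
        if abs(ll - ll_old) < tol * (abs(ll) + 1.0) and grad_stat < 1e-3:
            converged = True
            break
        ll_old = ll
        try:
            step = np.linalg.solve(ai, score)
        except np.linalg.LinAlgError:
            step = np.linalg.pinv(ai) @ score
        if np.any(~np.isfinite(step)):
            step = np.zeros(2)
        # projected AI step with halving; EM fallback; stop if nothing improves
        accepted = False
        for _ in range(12):
            cand = np.maximum(theta + step, lb)
            ll_cand = _reml_pieces(cand, lam_eig, ystar, xstar)[0]
            if np.isfinite(ll_cand) and ll_cand > ll + 1e-13:
                theta = cand
                accepted = True
                break
            step *= 0.5
        if not accepted:
            r = n - p
            em = np.maximum(
                theta + theta**2 * np.array([ypapy - tr_pa, ypepy - tr_pe]) / r, lb
            )
            ll_em = _reml_pieces(em, lam_eig, ystar, xstar)[0]
            if np.isfinite(ll_em) and ll_em > ll + 1e-13:
                theta = em
            else:
                # no direction improves the likelihood: numerical optimum
                converged = True
                break
    if not converged:
        raise REMLConvergenceError(
            f"AI-REML did not converge in {max_iter} iterations", trail
        )
    try:
        cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(ai)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return VarianceComponents(
        sigma_a2=float(theta[0]),
        sigma_e2=float(theta[1]),
        se_a2=float(se[0]),
        se_e2=float(se[1]),
        cov=cov,
        loglik=float(trail[-1][1]),
        n_iter=n_done,
        converged=True,
        at_bound=bool(np.any(theta <= lb * (1 + 1e-12))),
    )


def restricted_loglik(theta, y, x, z, k: RelationshipMatrix) -> float:
    """Restricted log-likelihood at (sigma_a2, sigma_e2); probe utility."""
    g_obs = z @ k.values @ z.T
    lam_eig, u = linalg.eigh(g_obs)
    lam_eig = np.clip(lam_eig, 0.0, None)
    ll, *_ = _reml_pieces(np.asarray(theta, float), lam_eig, u.T @ y, u.T @ x)
    return float(ll)


# ---------------------------------------------------------------------------
# Bivariate REML


def _biv_negll(params, lam_eig, ystar2, xstar, lb_diag):
    """Negative restricted log-likelihood; params are log-Cholesky factors."""
    la = np.array(
        [[np.exp(params[0]), 0.0], [params[1], np.exp(params[2])]]
    )
    le = np.array(
        [[np.exp(params[3]), 0.0], [params[4], np.exp(params[5])]]
    )
    ga = la @ la.T
    re = le @ le.T + lb_diag * np.eye(2)
    n, p = xstar.shape
    xtwx = np.zeros((2 * p, 2 * p))
    xtwy = np.zeros(2 * p)
    quad = 0.0
    logdet = 0.0
    # per-eigencomponent 2x2 covariance C_i = lam_i * Ga + Re
    c = lam_eig[:, None, None] * ga[None] + re[None]
    det = c[:, 0, 0] * c[:, 1, 1] - c[:, 0, 1] ** 2
    if np.any(det <= 0) or np.any(c[:, 0, 0] <= 0):
        return 1e30
    logdet = float(np.sum(np.log(det)))
    winv = np.empty_like(c)
    winv[:, 0, 0] = c[:, 1, 1] / det
    winv[:, 1, 1] = c[:, 0, 0] / det
    winv[:, 0, 1] = winv[:, 1, 0] = -c[:, 0, 1] / det
    yw = np.einsum("itu,iu->it", winv, ystar2)
    quad = float(np.einsum("it,it->", yw, ystar2))
    for t in range(2):
        for s in range(2):
            xtwx[t * p : (t + 1) * p, s * p : (s + 1) * p] = (
                xstar.T * winv[:, t, s]
            ) @ xstar
        xtwy[t * p : (t + 1) * p] = xstar.T @ yw[:, t]
    try:
        cf = linalg.cho_factor(xtwx)
    except linalg.LinAlgError:
        return 1e30
    beta = linalg.cho_solve(cf, xtwy)
    logdet_xtwx = 2.0 * np.sum(np.log(np.diag(cf[0])))
    ll = -0.5 * (logdet + logdet_xtwx + quad - float(xtwy @ beta))
    return -ll


def reml_bivariate(
    y1: np.ndarray,
    y2: np.ndarray,
    x: np.ndarray,
    z: np.ndarray,
    k: RelationshipMatrix,
    min_records: int = 30,
) -> BivariateComponents:
    """Bivariate REML for two traits sharing a design and relationship matrix.

    Records missing either trait must be excluded beforehand.  Covariance
    matrices are parameterized by their Cholesky factors (hence PSD); the
    restricted likelihood is evaluated per eigencomponent of ZKZ' in O(n).
    """
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    if len(y1) != len(y2):
        raise ValueError("trait vectors differ in length")
    if len(y1) < min_records:
        raise ValueError(f"need at least {min_records} joint records")
    g_obs = z @ k.values @ z.T
    lam_eig, u = linalg.eigh(g_obs)
    lam_eig = np.clip(lam_eig, 0.0, None)
    ystar2 = np.column_stack([u.T @ y1, u.T @ y2])
    xstar = u.T @ x
    s1, s2 = np.std(y1), np.std(y2)
    lb_diag = 1e-8 * max(s1, s2) ** 2
    x0 = np.array(
        [
            np.log(0.7 * s1),
            0.0,
            np.log(0.7 * s2),
            np.log(0.7 * s1),
            0.0,
            np.log(0.7 * s2),
        ]
    )
    res = optimize.minimize(
        _biv_negll,
        x0,
        args=(lam_eig, ystar2, xstar, lb_diag),
        method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-7, "fatol": 1e-9},
    )
    res = optimize.minimize(
        _biv_negll,
        res.x,
        args=(lam_eig, ystar2, xstar, lb_diag),
        method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
    )
    if not np.isfinite(res.fun) or res.fun >= 1e29:
        raise REMLConvergenceError("bivariate REML failed to find a finite optimum", [])
    params = res.x
    la = np.array([[np.exp(params[0]), 0.0], [params[1], np.exp(params[2])]])
    le = np.array([[np.exp(params[3]), 0.0], [params[4], np.exp(params[5])]])
    ga = la @ la.T
    re = le @ le.T + lb_diag * np.eye(2)

    # observed information on the natural parameters by finite differences
    def negll_nat(v):
        a11, a12, a22, e11, e12, e22 = v
        try:
            la_ = np.linalg.cholesky(np.array([[a11, a12], [a12, a22]]))
            le_ = np.linalg.cholesky(np.array([[e11, e12], [e12, e22]]))
        except np.linalg.LinAlgError:
            return 1e30
        pr = np.array(
            [
                np.log(la_[0, 0]), la_[1, 0], np.log(la_[1, 1]),
                np.log(le_[0, 0]), le_[1, 0], np.log(le_[1, 1]),
            ]
        )
        return _biv_negll(pr, lam_eig, ystar2, xstar, lb_diag)

    nat = np.array([ga[0, 0], ga[0, 1], ga[1, 1], re[0, 0], re[0, 1], re[1, 1]])
    hess = _numeric_hessian(negll_nat, nat)
    try:
        param_cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        param_cov = np.full((6, 6), np.nan)
    return BivariateComponents(
        genetic_cov=ga,
        residual_cov=re,
        param_cov=param_cov,
        loglik=-float(res.fun),
        converged=bool(res.success or res.fun < 1e29),
    )


def _numeric_hessian(f, x0, rel_step=1e-4):
    n = len(x0)
    h = np.maximum(np.abs(x0), 1e-8) * rel_step
    hess = np.full((n, n), np.nan)
    f0 = f(x0)
    if f0 >= 1e29:
        return np.eye(n) * np.nan
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            if max(fpp, fpm, fmp, fmm) >= 1e29:
                continue
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return hess


# ---------------------------------------------------------------------------
# Heritability and classification rules


def heritability(vc: VarianceComponents) -> tuple[float, float]:
    """h2 = sigma_a2 / (sigma_a2 + sigma_e2) with a delta-method SE from the
    inverse-AI covariance of the components."""
    a, e = vc.sigma_a2, vc.sigma_e2
    if a <= 0 and e <= 0:
        raise ValueError("both variance components at bound; h2 undefined")
    h2 = a / (a + e)
    grad = np.array([e, -a]) / (a + e) ** 2
    var = grad @ vc.cov @ grad
    return float(h2), float(np.sqrt(var)) if var > 0 else np.nan


def classify_heritability(h2: float) -> str:
    """Low <= 0.2 < moderate < 0.4 <= high."""
    if not 0.0 <= h2 <= 1.0:
        raise ValueError(f"h2={h2} outside [0, 1]")
    if h2 <= 0.2:
        return "low"
    if h2 < 0.4:
        return "moderate"
    return "high"


def classify_correlation(r: float) -> str:
    """Bin |r|: [0,0.2) little, [0.2,0.4) weak, [0.4,0.7) moderate, [0.7,1] strong."""
    if abs(r) > 1.0:
        raise ValueError(f"|r|={abs(r)} exceeds 1")
    a = abs(r)
    if a < 0.2:
        return "little"
    if a < 0.4:
        return "weak"
    if a < 0.7:
        return "moderate"
    return "strong"
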