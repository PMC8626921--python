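"""Binomial mixed model with a complementary log-log link and crossed
random intercepts, fitted by Laplace approximation.

The response is the per-burst digging indicator (1 iff at least one
digging event in a 30-s burst); the cloglog link
P(y=1) = 1 - exp(-exp(eta)) is the natural choice for an "at least one
event in an interval" response and, unlike the logit, is asymmetric
(P = 1 - 1/e at eta = 0). The linear predictor is

    eta = b0 + b1 z + b2 brooding + b3 z*brooding
        + b4 female + b5 nonreproductive + b6 female*nonreproductive
        + u_fox + v_year

with z the centered/standardized goose density, reference levels
period = incubation, sex = male, status = reproductive, and independent
Gaussian random intercepts u_fox ~ N(0, s2_fox), v_year ~ N(0, s2_year),
crossed (a fox keeps one intercept across years).

Estimation: for fixed variance parameters, the joint mode of
(beta, u, v) is found by penalized iteratively reweighted least squares
(Fisher scoring on the working model, random-effect blocks ridged by
1/s2); the Laplace log-likelihood

    l(s) = logf(y | beta^, b^) - b^' D^-1 b^ / 2
           - (1/2) log det(D) - (1/2) log det(H_bb)

(2*pi factors from prior and Laplace correction cancel) is then
maximized over (log sigma_fox, log sigma_year) with Nelder-Mead.
Group indicator structure keeps every crossproduct O(n) via bincount,
so fits with tens of thousands of bursts take seconds. Inference on
the fixed effects is Wald, with standard errors from the (beta, beta)
block of the inverse joint information at the mode — the same
convention mixed-model packages report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

log = logging.getLogger("foxcache")

FIXED_TERMS = (
    "intercept",
    "density_std",
    "period_brooding",
    "density_std:period_brooding",
    "sex_female",
    "status_nonreproductive",
    "sex_female:status_nonreproductive",
)

_ETA_MAX = 30.0


def standardize(x, two_sd: bool = False) -> tuple[np.ndarray, float, float]:
    """Center and scale to unit (or two) sample SD.

    Returns ``(z, center, scale)``; scale is 1 sample SD (ddof = 1) by
    default, 2 SDs with ``two_sd=True``. The constants support exact
    back-transformation for plotting on the raw density scale.
    """
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x, ddof=1))
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot standardize a zero-variance covariate")
    scale = 2.0 * sd if two_sd else sd
    center = float(np.mean(x))
    return (x - center) / scale, center, scale


def cloglog_inverse(eta: np.ndarray) -> np.ndarray:
    """mu = 1 - exp(-exp(eta))."""
    return -np.expm1(-np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX)))


def _link_pieces(eta: np.ndarray):
    """(mu, dmu/deta, log f terms) with guarded extremes."""
    eta = np.clip(eta, -_ETA_MAX, 3.6)  # mu(3.6) ~ 1 - 1e-16
    ee = np.exp(eta)
    mu = -np.expm1(-ee)
    dmu = np.exp(eta - ee)
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
    dmu = np.maximum(dmu, 1e-12)
    return eta, mu, dmu


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    eta = np.clip(eta, -_ETA_MAX, 3.6)
    ee = np.exp(eta)
    log1m = -ee  # log(1 - mu)
    logmu = np.log(np.clip(-np.expm1(-ee), 1e-300, None))
    return float(np.sum(np.where(y == 1, logmu, log1m)))


def build_design(
    df: pd.DataFrame, require_full_rank: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-effects design matrix in the canonical term order.

    ``require_full_rank`` is enforced when fitting (a factor level
    missing from the data leaves a constant column); prediction grids
    are exempt."""
    required = {"digging", "density_std", "period", "sex", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"analysis table missing columns {sorted(missing)}")
    for col, allowed in (
        ("period", {"incubation", "brooding"}),
        ("sex", {"M", "F"}),
        ("status", {"reproductive", "nonreproductive"}),
    ):
        bad = set(df[col].unique()) - allowed
        if bad:
            raise ValueError(f"unknown {col} levels {sorted(bad)}")
    z = df["density_std"].to_numpy(dtype=float)
    brood = (df["period"] == "brooding").to_numpy(dtype=float)
    female = (df["sex"] == "F").to_numpy(dtype=float)
    nonrep = (df["status"] == "nonreproductive").to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(df)), z, brood, z * brood, female, nonrep, female * nonrep]
    )
    y = df["digging"].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("digging response must be 0/1")
    if require_full_rank and np.linalg.matrix_rank(X) < X.shape[1]:
        degenerate = [
            FIXED_TERMS[j]
            for j in range(1, X.shape[1])
            if np.ptp(X[:, j]) == 0
        ]
        raise ValueError(
            "design matrix is rank deficient; constant columns: "
            f"{degenerate or 'collinear factors'}"
        )
    return y, X


@dataclass
class GlmmFit:
    """Coefficients, Wald inference and variance components."""

    fixed: pd.DataFrame  # estimate, se, z, p, ci_low, ci_high per term
    var_fox: float
    sd_fox: float
    var_year: float
    sd_year: float
    loglik: float
    converged: bool
    n_obs: int
    n_fox: int
    n_year: int
    u_fox: pd.Series
    v_year: pd.Series
    density_center: float | None = None
    density_scale: float | None = None
    message: str = ""
    terms: tuple[str, ...] = FIXED_TERMS
    cov_fixed: np.ndarray | None = None

    @property
    def params(self) -> pd.Series:
        return self.fixed["estimate"]


class CloglogGlmm:
    """Penalized-IRLS / Laplace machinery for one analysis table."""

    def __init__(self, df: pd.DataFrame):
        self.y, self.X = build_design(df, require_full_rank=True)
        self.n, self.p = self.X.shape
        if "fox_id" not in df.columns or "year" not in df.columns:
            raise ValueError("analysis table needs fox_id and year columns")
        self.fox_codes, self.fox_levels = pd.factorize(df["fox_id"], sort=True)
        self.year_codes, self.year_levels = pd.factorize(df["year"], sort=True)
        self.nf = len(self.fox_levels)
        self.ny = len(self.year_levels)
        if self.nf < 2:
            raise ValueError("need at least 2 foxes to separate fox variance")
        if self.y.sum() == 0 or self.y.sum() == self.n:
            raise ValueError("response must contain both 0 and 1")
        self._warm: np.ndarray | None = None

    # ---- inner loop -------------------------------------------------

    def _eta(self, coef: np.ndarray) -> np.ndarray:
        p, nf = self.p, self.nf
        eta = self.X @ coef[:p]
        if nf:
            eta = eta + coef[p : p + nf][self.fox_codes]
        if self.ny:
            eta = eta + coef[p + nf : p + nf + self.ny][self.year_codes]
        return eta

    def _penalized_obj(self, coef: np.ndarray, inv_s2f: float, inv_s2y: float) -> float:
        p, nf = self.p, self.nf
        h = _bernoulli_loglik(self.y, self._eta(coef))
        h -= 0.5 * inv_s2f * float(np.sum(coef[p : p + nf] ** 2))
        h -= 0.5 * inv_s2y * float(np.sum(coef[p + nf :] ** 2))
        return h

    def _normal_matrix(self, w: np.ndarray):
        """Weighted crossproduct of [X Zf Zy] via group aggregation."""
        X, fox, year = self.X, self.fox_codes, self.year_codes
        p, nf, ny = self.p, self.nf, self.ny
        dim = p + nf + ny
        A = np.zeros((dim, dim))
        Xw = X * w[:, None]
        A[:p, :p] = X.T @ Xw
        if nf:
            for j in range(p):
                A[p : p + nf, j] = np.bincount(fox, weights=Xw[:, j], minlength=nf)
            A[:p, p : p + nf] = A[p : p + nf, :p].T
            A[p : p + nf, p : p + nf] = np.diag(
                np.bincount(fox, weights=w, minlength=nf)
            )
        if ny:
            o = p + nf
            for j in range(p):
                A[o : o + ny, j] = np.bincount(year, weights=Xw[:, j], minlength=ny)
            A[:p, o : o + ny] = A[o : o + ny, :p].T
            A[o : o + ny, o : o + ny] = np.diag(
                np.bincount(year, weights=w, minlength=ny)
            )
            if nf:
                cross = np.bincount(
                    fox * ny + year, weights=w, minlength=nf * ny
                ).reshape(nf, ny)
                A[p : p + nf, o : o + ny] = cross
                A[o : o + ny, p : p + nf] = cross.T
        return A

    def _rhs(self, w: np.ndarray, zwork: np.ndarray) -> np.ndarray:
        p, nf, ny = self.p, self.nf, self.ny
        wz = w * zwork
        rhs = np.empty(p + nf + ny)
        rhs[:p] = self.X.T @ wz
        if nf:
            rhs[p : p + nf] = np.bincount(self.fox_codes, weights=wz, minlength=nf)
        if ny:
            rhs[p + nf :] = np.bincount(self.year_codes, weights=wz, minlength=ny)
        return rhs

    def pirls(
        self,
        s2f: float,
        s2y: float,
        coef0: np.ndarray | None = None,
        tol: float = 1e-9,
        max_iter: int = 100,
    ) -> tuple[np.ndarray, np.ndarray, bool]:
        """Joint mode of (beta, u, v) for fixed variances.

        Returns ``(coef, A_pen, converged)`` where ``A_pen`` is the
        penalized information matrix at the mode.
        """
        p, nf, ny = self.p, self.nf, self.ny
        dim = p + nf + ny
        inv_s2f = 1.0 / s2f if s2f > 0 else np.inf
        inv_s2y = 1.0 / s2y if s2y > 0 else np.inf
        # infinite penalty == effect removed; handled by caller
        coef = np.zeros(dim) if coef0 is None else coef0.copy()
        if coef0 is None:
            # intercept start: cloglog of the observed frequency
            freq = np.clip(self.y.mean(), 1e-6, 1 - 1e-6)
            coef[0] = np.log(-np.log1p(-freq))
        obj = self._penalized_obj(coef, inv_s2f, inv_s2y)
        converged = False
        A_pen = None
        for _ in range(max_iter):
            eta, mu, dmu = _link_pieces(self._eta(coef))
            w = dmu**2 / (mu * (1.0 - mu))
            zwork = eta + (self.y - mu) / dmu
            A_pen = self._normal_matrix(w)
            pen = np.zeros(dim)
            pen[p : p + nf] = inv_s2f
            pen[p + nf :] = inv_s2y
            A_pen[np.diag_indices(dim)] += pen
            rhs = self._rhs(w, zwork)
            try:
                cho = linalg.cho_factor(A_pen, lower=True, check_finite=False)
                new = linalg.cho_solve(cho, rhs, check_finite=False)
            except linalg.LinAlgError:
                new = np.linalg.lstsq(A_pen, rhs, rcond=None)[0]
            step = new - coef
            new_obj = self._penalized_obj(new, inv_s2f, inv_s2y)
            # step-halve if the penalized objective worsens
            halves = 0
            while new_obj < obj - 1e-10 and halves < 20:
                step *= 0.5
                new = coef + step
                new_obj = self._penalized_obj(new, inv_s2f, inv_s2y)
                halves += 1
            delta = np.max(np.abs(step))
            coef = new
            if abs(new_obj - obj) < tol * (abs(obj) + 1.0) and delta < 1e-6:
                obj = new_obj
                converged = True
                break
            obj = new_obj
        # refresh the information matrix at the final coefficients
        eta, mu, dmu = _link_pieces(self._eta(coef))
        w = dmu**2 / (mu * (1.0 - mu))
        A_pen = self._normal_matrix(w)
        pen = np.zeros(dim)
        pen[p : p + nf] = inv_s2f
        pen[p + nf :] = inv_s2y
        A_pen[np.diag_indices(dim)] += pen
        return coef, A_pen, converged

    def laplace_loglik(self, s2f: float, s2y: float, coef0=None, tol: float = 1e-9):
        """Laplace log-likelihood at fixed variances (beta profiled at
        the joint mode)."""
        p, nf, ny = self.p, self.nf, self.ny
        coef, A_pen, ok = self.pirls(s2f, s2y, coef0=coef0, tol=tol)
        u = coef[p : p + nf]
        v = coef[p + nf :]
        ll = _bernoulli_loglik(self.y, self._eta(coef))
        ll -= 0.5 * (np.sum(u**2) / s2f + nf * np.log(s2f))
        ll -= 0.5 * (np.sum(v**2) / s2y + ny * np.log(s2y))
        Abb = A_pen[p:, p:]
        sign, logdet = np.linalg.slogdet(Abb)
        if sign <= 0:
            return -np.inf, coef, ok
        ll -= 0.5 * logdet
        return float(ll), coef, ok

    # ---- outer loop -------------------------------------------------

    def fit(
        self,
        start_sigma: tuple[float, float] = (0.5, 0.2),
        xatol: float = 1e-4,
        fatol: float = 1e-7,
        max_outer: int = 200,
        inner_tol: float = 1e-9,
        polish: bool = False,
    ) -> tuple[np.ndarray, np.ndarray, float, float, float, bool, str]:
        lo = np.log(1e-4)

        def negloglik(logs):
            s_f = float(np.exp(np.clip(logs[0], lo, 5.0)))
            s_y = float(np.exp(np.clip(logs[1], lo, 5.0)))
            ll, coef, _ = self.laplace_loglik(
                s_f**2, s_y**2, coef0=self._warm, tol=inner_tol
            )
            self._warm = coef
            return -ll

        x0 = np.log(np.asarray(start_sigma, dtype=float))
        res = optimize.minimize(
            negloglik,
            x0,
            method="Nelder-Mead",
            options={
                "xatol": xatol,
                "fatol": fatol,
                "maxfev": max_outer,
                "initial_simplex": np.array(
                    [x0, x0 + [0.5, 0.0], x0 + [0.0, 0.5]]
                ),
            },
        )
        x = res.x.copy()
        if polish:
            # coordinate-wise golden-section refinement sharpens the
            # optimum beyond Nelder-Mead's simplex tolerance
            for j in (0, 1):
                def f1d(v, j=j):
                    z = x.copy()
                    z[j] = v
                    return negloglik(z)

                r = optimize.minimize_scalar(
                    f1d,
                    bounds=(max(lo, x[j] - 0.3), min(5.0, x[j] + 0.3)),
                    method="bounded",
                    options={"xatol": 1e-8},
                )
                x[j] = r.x
        s_f = float(np.exp(np.clip(x[0], lo, 5.0)))
        s_y = float(np.exp(np.clip(x[1], lo, 5.0)))
        ll, coef, inner_ok = self.laplace_loglik(
            s_f**2, s_y**2, coef0=self._warm, tol=inner_tol
        )
        _, A_pen, _ = self.pirls(s_f**2, s_y**2, coef0=coef)
        return coef, A_pen, s_f, s_y, ll, inner_ok, res.message

    # ---- variance-free fit (plain GLM) ------------------------------

    def fit_fixed_only(self) -> tuple[np.ndarray, np.ndarray, float, bool]:
        """IRLS for the model with both variances fixed at zero."""
        saved = self.nf, self.ny, self.fox_codes, self.year_codes
        self.nf, self.ny = 0, 0
        try:
            coef, A, ok = self.pirls(1.0, 1.0)  # penalties unused, no blocks
            ll = _bernoulli_loglik(self.y, self.X @ coef)
            return coef, A, ll, ok
        finally:
            self.nf, self.ny, self.fox_codes, self.year_codes = saved


def _wald_table(beta: np.ndarray, se: np.ndarray, terms) -> pd.DataFrame:
    zval = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(zval))
    return pd.DataFrame(
        {
            "estimate": beta,
            "se": se,
            "z": zval,
            "p": pval,
            "ci_low": beta - 1.96 * se,
            "ci_high": beta + 1.96 * se,
        },
        index=list(terms),
    )


def fit_glmm_cloglog(
    df: pd.DataFrame,
    fix_variances_zero: bool = False,
    density_center: float | None = None,
    density_scale: float | None = None,
    start_sigma: tuple[float, float] = (0.5, 0.2),
) -> GlmmFit:
    """Fit the digging model to an analysis table.

    The table needs columns digging (0/1), density_std, period, sex,
    status, fox_id, year. With ``fix_variances_zero=True`` the random
    intercepts are removed and the fit reduces to an ordinary cloglog
    GLM (useful as a degenerate-case check). Variance estimates at the
    boundary (sigma ~ 0) are reported as such, not treated as errors.
    """
    model = CloglogGlmm(df)
    if fix_variances_zero:
        coef, A, ll, ok = model.fit_fixed_only()
        cov = np.linalg.inv(A)
        fixed = _wald_table(coef, np.sqrt(np.diag(cov)), FIXED_TERMS)
        return GlmmFit(
            fixed=fixed,
            var_fox=0.0,
            sd_fox=0.0,
            var_year=0.0,
            sd_year=0.0,
            loglik=ll,
            converged=ok,
            n_obs=model.n,
            n_fox=model.nf,
            n_year=model.ny,
            u_fox=pd.Series(0.0, index=list(model.fox_levels)),
            v_year=pd.Series(0.0, index=list(model.year_levels)),
            density_center=density_center,
            density_scale=density_scale,
            cov_fixed=cov,
        )

    coef, A_pen, s_f, s_y, ll, inner_ok, message = model.fit(start_sigma=start_sigma)
    p, nf = model.p, model.nf
    cov = np.linalg.inv(A_pen)
    se = np.sqrt(np.diag(cov)[:p])
    fixed = _wald_table(coef[:p], se, FIXED_TERMS)
    boundary = s_f < 1e-3 or s_y < 1e-3
    if boundary:
        log.info("variance component at the boundary (sigma_fox=%.2g, sigma_year=%.2g)", s_f, s_y)
    return GlmmFit(
        fixed=fixed,
        var_fox=s_f**2,
        sd_fox=s_f,
        var_year=s_y**2,
        sd_year=s_y,
        loglik=ll,
        converged=inner_ok,
        n_obs=model.n,
        n_fox=model.nf,
        n_year=model.ny,
        u_fox=pd.Series(coef[p : p + nf], index=list(model.fox_levels)),
        v_year=pd.Series(coef[p + nf :], index=list(model.year_levels)),
        density_center=density_center,
        density_scale=density_scale,
        message=message,
        cov_fixed=cov[:p, :p],
    )


def predict_probability(
    fit: GlmmFit,
    newdata: pd.DataFrame,
    ci: bool = False,
) -> pd.DataFrame:
    """Population-level digging probabilities (random effects at zero).

    ``newdata`` carries period/sex/status plus either ``density_std``
    or raw ``density`` (transformed internally with the fit's stored
    standardization constants). With ``ci=True`` a Wald band is added,
    computed on the linear-predictor scale and transformed — the band
    is therefore asymmetric on the probability scale.
    """
    nd = newdata.copy()
    if "density_std" not in nd.columns:
        if "density" not in nd.columns:
            raise ValueError("newdata needs density or density_std")
        if fit.density_center is None or fit.density_scale is None:
            raise ValueError(
                "fit carries no standardization constants; supply density_std"
            )
        nd["density_std"] = (nd["density"] - fit.density_center) / fit.density_scale
    nd["digging"] = 0  # placeholder for the design builder
    y, X = build_design(nd)
    beta = fit.fixed["estimate"].to_numpy()
    eta = X @ beta
    out = newdata.copy()
    out["probability"] = cloglog_inverse(eta)
    if ci:
        if fit.cov_fixed is None:
            raise ValueError("fit carries no fixed-effect covariance")
        se_eta = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov_fixed, X))
        out["ci_low"] = cloglog_inverse(eta - 1.96 * se_eta)
        out["ci_high"] = cloglog_inverse(eta + 1.96 * se_eta)
    return out
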