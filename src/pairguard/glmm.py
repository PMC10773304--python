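"""Mixed models for the dyadic summaries.

Families: binomial (binary together, mover sex), beta-binomial (daily
proportions, which are overdispersed relative to binomial because slots
within a day are autocorrelated), both with logit link, and Gaussian with
identity link (separation distances).  Random effects are a per-nest
intercept, optionally with a random slope over the day relative to clutch
initiation, with an unstructured 2x2 covariance.

Estimation is maximum marginal likelihood with a Laplace approximation of
the per-group integrals (exact for the Gaussian family).  The inner mode
search is a damped Newton iteration batched over groups; the outer
optimisation is L-BFGS-B with fixed deterministic starting values (fixed
effects at zero, dispersion at one).  On a singular random-effect
covariance the structure falls back full -> diagonal -> intercept-only,
each step logged on the fit.

Wald z tests on the fixed effects summarise significance; marginal means
are inverse-link values of the linear predictor at requested covariates
(random effects at zero) with delta-method standard errors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

log = logging.getLogger(__name__)

_ETA_CAP = 30.0


# --------------------------------------------------------------------------
# families

def _expit(eta):
    return special.expit(np.clip(eta, -_ETA_CAP, _ETA_CAP))


class _Binomial:
    name = "binomial"
    n_disp = 0

    @staticmethod
    def loglik(y, n, eta, disp):
        mu = _expit(eta)
        return (special.gammaln(n + 1) - special.gammaln(y + 1)
                - special.gammaln(n - y + 1)
                + y * np.log(mu) + (n - y) * np.log1p(-mu))

    @staticmethod
    def d_eta(y, n, eta, disp):
        mu = _expit(eta)
        return y - n * mu, -n * mu * (1.0 - mu)


class _BetaBinomial:
    """Mean/precision parameterisation: a = mu*phi, b = (1-mu)*phi."""

    name = "beta_binomial"
    n_disp = 1

    @staticmethod
    def loglik(y, n, eta, disp):
        phi = np.exp(disp[0])
        mu = _expit(eta)
        a = mu * phi
        b = (1.0 - mu) * phi
        return (special.gammaln(n + 1) - special.gammaln(y + 1)
                - special.gammaln(n - y + 1)
                + special.gammaln(y + a) + special.gammaln(n - y + b)
                - special.gammaln(n + phi)
                + special.gammaln(phi) - special.gammaln(a) - special.gammaln(b))

    @staticmethod
    def d_eta(y, n, eta, disp):
        phi = np.exp(disp[0])
        mu = _expit(eta)
        a = mu * phi
        b = (1.0 - mu) * phi
        dmu = mu * (1.0 - mu)
        g_mu = phi * (special.digamma(y + a) - special.digamma(n - y + b)
                      - special.digamma(a) + special.digamma(b))
        h_mu = phi ** 2 * (special.polygamma(1, y + a)
                           + special.polygamma(1, n - y + b)
                           - special.polygamma(1, a)
                           - special.polygamma(1, b))
        grad = g_mu * dmu
        hess = h_mu * dmu ** 2 + g_mu * dmu * (1.0 - 2.0 * mu)
        return grad, hess


class _Gaussian:
    name = "gaussian"
    n_disp = 1

    @staticmethod
    def loglik(y, n, eta, disp):
        sigma = np.exp(disp[0])
        return -0.5 * ((y - eta) / sigma) ** 2 - disp[0] - 0.5 * math.log(2 * math.pi)

    @staticmethod
    def d_eta(y, n, eta, disp):
        s2 = np.exp(2.0 * disp[0])
        return (y - eta) / s2, np.full_like(eta, -1.0 / s2)


_FAMILIES = {"binomial": _Binomial, "beta_binomial": _BetaBinomial,
             "gaussian": _Gaussian}


# --------------------------------------------------------------------------
# design matrices

@dataclass
class DesignInfo:
    terms: tuple
    levels: dict = field(default_factory=dict)
    names: tuple = ()


def _base_columns(terms: Sequence[str]) -> list[str]:
    cols = []
    for t in terms:
        for part in t.split(":"):
            cols.append(part[:-2] if part.endswith("^2") else part)
    return sorted(set(cols))


def _encode(data: pd.DataFrame, col: str, levels: dict):
    s = data[col]
    if s.dtype == bool:
        return s.to_numpy(dtype=float), col
    if s.dtype == object or str(s.dtype) == "category":
        lv = levels.setdefault(col, tuple(sorted(pd.unique(s.astype(str)))))
        if len(lv) > 2:
            raise ValueError(f"categorical term {col!r} has more than two levels")
        return (s.astype(str) == lv[-1]).astype(float).to_numpy(), f"{col}[{lv[-1]}]"
    return s.to_numpy(dtype=float), col


def build_design(data: pd.DataFrame, terms: Sequence[str],
                 info: DesignInfo | None = None):
    """Model matrix with an implicit intercept.

    Terms are column names, squares (``col^2``) or two-way products
    (``a:b``); boolean/two-level categorical columns are dummy coded.
    """
    info = info or DesignInfo(tuple(terms))
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for t in terms:
        parts = t.split(":")
        vec = np.ones(len(data))
        label = []
        for part in parts:
            if part.endswith("^2"):
                v, nm = _encode(data, part[:-2], info.levels)
                vec = vec * v ** 2
                label.append(f"{nm}^2")
            else:
                v, nm = _encode(data, part, info.levels)
                vec = vec * v
                label.append(nm)
        cols.append(vec)
        names.append(":".join(label))
    info.names = tuple(names)
    return np.column_stack(cols), info


# --------------------------------------------------------------------------
# model spec / fit containers

@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description.

    ``response``: column name (binary/gaussian) or ``(successes, totals)``
    for proportion families.  ``fixed``: term strings (see build_design).
    ``group``: grouping column for random effects, or None for a plain GLM.
    ``random_slope``: numeric column for the per-group slope, or None.
    """

    family: str
    response: object
    fixed: tuple = ()
    group: Optional[str] = None
    random_slope: Optional[str] = None
    re_structure: str = "full"    # full | diagonal | intercept | none

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        object.__setattr__(self, "fixed", tuple(self.fixed))


@dataclass
class ModelFit:
    spec: ModelSpec
    beta: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series
    cov_beta: np.ndarray
    loglik: float
    dispersion: Optional[float]
    re_cov: Optional[np.ndarray]
    structure: str
    converged: bool
    n_obs: int
    n_groups: int
    design_info: DesignInfo
    fallback_log: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.beta, "se": self.se,
                             "z": self.z, "p": self.p})

    def to_dict(self) -> dict:
        return {
            "family": self.spec.family,
            "structure": self.structure,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "dispersion": self.dispersion,
            "coefficients": {k: {"estimate": float(self.beta[k]),
                                 "se": float(self.se[k]),
                                 "p": float(self.p[k])}
                             for k in self.beta.index},
            "re_cov": None if self.re_cov is None else self.re_cov.tolist(),
            "fallbacks": list(self.fallback_log),
        }


class ConvergenceError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# random-effect covariance parameterisations

def _re_dim(structure: str) -> int:
    return {"full": 2, "diagonal": 2, "intercept": 1, "none": 0}[structure]


def _n_theta(structure: str) -> int:
    return {"full": 3, "diagonal": 2, "intercept": 1, "none": 0}[structure]


def _sigma_from_theta(theta, structure):
    if structure == "none":
        return None
    if structure == "intercept":
        s = math.exp(2.0 * theta[0])
        return np.array([[s]])
    if structure == "diagonal":
        return np.diag([math.exp(2.0 * theta[0]), math.exp(2.0 * theta[1])])
    l11 = math.exp(theta[0])
    l21 = theta[1]
    l22 = math.exp(theta[2])
    L = np.array([[l11, 0.0], [l21, l22]])
    return L @ L.T


# --------------------------------------------------------------------------
# Laplace machinery

def _segment_sum(values, starts):
    return np.add.reduceat(values, starts, axis=0)


def _laplace_loglik(params, Xb, Z, y, n, starts, family, n_beta, structure,
                    b_cache):
    """Negative marginal log-likelihood via per-group Laplace approximation."""
    q = _re_dim(structure)
    beta = params[:n_beta]
    theta = params[n_beta:n_beta + _n_theta(structure)]
    disp = params[n_beta + _n_theta(structure):]
    eta_fixed = Xb @ beta
    if q == 0:
        return -float(np.sum(family.loglik(y, n, eta_fixed, disp)))

    Sigma = _sigma_from_theta(theta, structure)
    sign, logdet_S = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return 1e12
    P = np.linalg.inv(Sigma)
    G = len(starts)
    b = b_cache.get("b")
    if b is None or b.shape != (G, q):
        b = np.zeros((G, q))
    gidx = np.repeat(np.arange(G), np.diff(np.append(starts, len(y))))
    ZZ = Z[:, :, None] * Z[:, None, :]               # (N, q, q)

    def h_of(bm):
        eta = eta_fixed + np.einsum("nq,nq->n", Z, bm[gidx])
        ll = family.loglik(y, n, eta, disp)
        pen = 0.5 * np.einsum("gq,qr,gr->g", bm, P, bm)
        return _segment_sum(ll, starts) - pen, eta

    def inner_mode(b):
        """Damped Newton for the per-group modes; None on breakdown."""
        h, eta = h_of(b)
        for _ in range(100):
            dl, d2l = family.d_eta(y, n, eta, disp)
            grad = _segment_sum(Z * dl[:, None], starts) - b @ P
            if np.max(np.abs(grad)) < 1e-9:
                break
            H = _segment_sum(ZZ * d2l[:, None, None], starts) - P
            try:
                step = np.linalg.solve(-H, grad[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                return None
            # a non-concave group can yield an ascent-violating Newton
            # direction; fall back to (preconditioned) gradient there
            bad = np.einsum("gq,gq->g", step, grad) <= 0
            if bad.any():
                step[bad] = grad[bad] / (1.0 + np.abs(H[bad, 0, 0])[:, None])
            scale = np.ones(G)
            for _ in range(25):
                b_new = b + scale[:, None] * step
                h_new, eta_new = h_of(b_new)
                worse = h_new < h - 1e-12
                if not worse.any():
                    break
                scale[worse] *= 0.5
            b, h, eta = b_new, h_new, eta_new
        else:
            log.debug("inner Newton did not fully converge")
        return b, h, eta

    # warm start from the cached modes, cold restart if that breaks down;
    # the cache is only a hint, the result never depends on its contents
    res = inner_mode(b.copy())
    if res is None and b.any():
        res = inner_mode(np.zeros((G, q)))
    if res is None:
        return 1e12
    b, h, eta = res

    dl, d2l = family.d_eta(y, n, eta, disp)
    H = _segment_sum(ZZ * d2l[:, None, None], starts) - P
    negH = -H
    # floor the per-group curvature: for non-concave families the observed
    # Hessian at the mode can be indefinite, and a hard failure here would
    # flatten the outer objective (killing its finite-difference gradient)
    if q == 1:
        det = np.maximum(negH[:, 0, 0], 1e-10)
    else:
        eig = np.linalg.eigvalsh(0.5 * (negH + negH.transpose(0, 2, 1)))
        det = np.prod(np.maximum(eig, 1e-10), axis=1)
    b_cache["b"] = b
    l = float(np.sum(h) - 0.5 * G * logdet_S - 0.5 * np.sum(np.log(det)))
    return -l


def _prepare(data: pd.DataFrame, spec: ModelSpec):
    if isinstance(spec.response, (tuple, list)):
        succ, tot = spec.response
        y = data[succ].to_numpy(dtype=float)
        n = data[tot].to_numpy(dtype=float)
    else:
        y = data[spec.response].to_numpy(dtype=float)
        n = np.ones(len(data))
        if spec.family in ("binomial", "beta_binomial"):
            if not np.all(np.isin(y, (0.0, 1.0))):
                raise ValueError("binary response must be 0/1; use a "
                                 "(successes, totals) pair for counts")
    X, info = build_design(data, spec.fixed, None)
    return X, info, y, n


def fit_glmm(data: pd.DataFrame, spec: ModelSpec,
             _allow_fallback: bool = True) -> ModelFit:
    """Fit the model by maximum (Laplace-approximated) marginal likelihood.

    Deterministic given data and spec.  Non-convergence yields a fit flagged
    ``converged=False`` (never silent); a singular random-effect covariance
    triggers the structure fallback ladder.
    """
    family = _FAMILIES[spec.family]
    data = data.reset_index(drop=True)
    structure = spec.re_structure if spec.group is not None else "none"
    if structure != "none" and spec.random_slope is None:
        structure = "intercept"

    if spec.group is not None:
        order = np.argsort(data[spec.group].astype(str).to_numpy(), kind="stable")
        data = data.iloc[order].reset_index(drop=True)
        g = data[spec.group].astype(str).to_numpy()
        starts = np.flatnonzero(np.append(True, g[1:] != g[:-1]))
        n_groups = len(starts)
        if n_groups < 2:
            raise ValueError("random effects need at least two groups")
    else:
        starts = np.array([0])
        n_groups = 0

    X, info, y, n = _prepare(data, spec)
    n_beta = X.shape[1]
    q = _re_dim(structure)
    if q == 2:
        slope = data[spec.random_slope].to_numpy(dtype=float)
        Z = np.column_stack([np.ones(len(data)), slope])
    elif q == 1:
        Z = np.ones((len(data), 1))
    else:
        Z = np.zeros((len(data), 0))

    # fixed deterministic starts: beta 0, RE sds exp(-1), dispersion 1
    x0 = np.zeros(n_beta + _n_theta(structure) + family.n_disp)
    x0[n_beta:n_beta + _n_theta(structure)] = -1.0
    if structure == "full":
        x0[n_beta + 1] = 0.0
    if spec.family == "gaussian":
        sd = float(np.std(y)) or 1.0
        x0[-1] = math.log(sd)

    b_cache: dict = {}
    obj = lambda p: _laplace_loglik(p, X, Z, y, n, starts, family, n_beta,
                                    structure, b_cache)
    bounds = [(None, None)] * n_beta
    for _ in range(_n_theta(structure)):
        bounds.append((-8.0, 8.0))
    if structure == "full":
        bounds[n_beta + 1] = (-30.0, 30.0)
    if spec.family == "beta_binomial":
        bounds.append((-3.0, 15.0))
    elif spec.family == "gaussian":
        bounds.append((None, None))

    res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 1000, "ftol": 1e-12,
                                     "gtol": 1e-8})
    params = res.x
    loglik = -float(res.fun)
    theta = params[n_beta:n_beta + _n_theta(structure)]
    re_cov = _sigma_from_theta(theta, structure)

    singular = False
    if re_cov is not None:
        var = np.diag(re_cov)
        if np.any(var < 1e-10):
            singular = True
        elif re_cov.shape[0] == 2:
            corr = re_cov[0, 1] / math.sqrt(var[0] * var[1])
            if abs(corr) > 0.999:
                singular = True

    fallback_log: list[str] = []
    if (_allow_fallback and structure in ("full", "diagonal")
            and (singular or not res.success)):
        ladder = {"full": "diagonal", "diagonal": "intercept"}
        next_struct = ladder[structure]
        fallback_log.append(f"{structure} covariance singular or fit failed; "
                            f"refit with {next_struct} structure")
        log.warning(fallback_log[-1])
        sub = replace(spec, re_structure=next_struct)
        fit = fit_glmm(data, sub, _allow_fallback=True)
        fit.fallback_log = fallback_log + fit.fallback_log
        return fit

    hess = _numeric_hessian(obj, params)
    try:
        cov = np.linalg.inv(hess)
        cov_ok = np.all(np.diag(cov)[:n_beta] > 0)
    except np.linalg.LinAlgError:
        cov_ok = False
    if not cov_ok:
        cov = np.linalg.pinv(hess)
    se_all = np.sqrt(np.maximum(np.diag(cov), 0.0))

    names = list(info.names)
    beta = pd.Series(params[:n_beta], index=names)
    se = pd.Series(se_all[:n_beta], index=names)
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(zval))

    dispersion = None
    if family.n_disp:
        dispersion = float(np.exp(params[-1]))

    return ModelFit(
        spec=spec, beta=beta, se=se, z=zval,
        p=pd.Series(pval, index=names),
        cov_beta=cov[:n_beta, :n_beta],
        loglik=loglik, dispersion=dispersion, re_cov=re_cov,
        structure=structure, converged=bool(res.success and cov_ok),
        n_obs=len(data), n_groups=n_groups, design_info=info,
        fallback_log=fallback_log,
    )


def _numeric_hessian(f, x, eps: float = 1e-4):
    k = len(x)
    H = np.zeros((k, k))
    hs = eps * np.maximum(1.0, np.abs(x))
    f0 = f(x)
    fp = np.empty(k)
    fm = np.empty(k)
    for i in range(k):
        e = np.zeros(k)
        e[i] = hs[i]
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / hs[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k); ei[i] = hs[i]
            ej = np.zeros(k); ej[j] = hs[j]
            fpp = f(x + ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j]
                                 + fmm) / (2 * hs[i] * hs[j])
    return H


# --------------------------------------------------------------------------
# quadratic-term selection, diurnal covariates, marginal means

def select_quadratic(data: pd.DataFrame, spec: ModelSpec,
                     alpha: float = 0.05):
    """Drop non-significant quadratic fixed terms, then refit once.

    Every term of the form ``col^2`` whose Wald p >= alpha in the initial
    fit is removed; all drops happen together in a single refit.  Returns
    (final_spec, final_fit, initial_fit).
    """
    quad = [t for t in spec.fixed if t.endswith("^2")]
    fit0 = fit_glmm(data, spec)
    if not quad:
        return spec, fit0, fit0
    name_of = dict(zip(spec.fixed, fit0.design_info.names[1:]))
    drop = [t for t in quad if fit0.p[name_of[t]] >= alpha]
    if not drop:
        return spec, fit0, fit0
    final = replace(spec, fixed=tuple(t for t in spec.fixed if t not in drop))
    return final, fit_glmm(data, final), fit0


def diurnal_terms(slot_times, local_offset_h: float = 0.0) -> pd.DataFrame:
    """sin/cos of time of day on the 24-h circle.

    Accepts numeric hours or timestamps (shifted into local time by
    ``local_offset_h``); returns columns sin_time, cos_time.
    """
    arr = np.asarray(slot_times)
    if np.issubdtype(arr.dtype, np.number):
        hours = arr.astype(float)
    else:
        ts = pd.to_datetime(pd.Series(arr)) + pd.Timedelta(hours=local_offset_h)
        hours = (ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0
                 ).to_numpy()
    ang = 2.0 * np.pi * hours / 24.0
    return pd.DataFrame({"sin_time": np.sin(ang), "cos_time": np.cos(ang)})


def marginal_mean(fit: ModelFit, covariates: dict):
    """Back-transformed mean at given covariate values, random effects at 0.

    Returns (mean, se); the SE is delta-method on the linear predictor.
    Logit families return a proportion in (0, 1).
    """
    base = _base_columns(fit.spec.fixed)
    missing = [c for c in base if c not in covariates]
    if missing:
        raise ValueError(f"covariate values required for {missing}")
    row = pd.DataFrame(index=[0])
    for key, value in covariates.items():
        row[key] = [value]
    X, _ = build_design(row, fit.spec.fixed, fit.design_info)
    x = X[0]
    eta = float(x @ fit.beta.to_numpy())
    var = float(x @ fit.cov_beta @ x)
    se_eta = math.sqrt(max(var, 0.0))
    if fit.spec.family == "gaussian":
        return eta, se_eta
    p = float(_expit(eta))
    return p, p * (1.0 - p) * se_eta


# --------------------------------------------------------------------------
# high-accuracy oracle for the random-intercept beta-binomial likelihood

def marginal_loglik_quadrature(data: pd.DataFrame, spec: ModelSpec,
                               beta: np.ndarray, re_sd: float,
                               dispersion: float | None = None,
                               n_nodes: int = 21) -> float:
    """Adaptive Gauss-Hermite marginal log-likelihood (random intercept).

    Centres the rule on each group's joint mode and scales by the local
    curvature, so few nodes give near-exact integrals.  Serves as an
    independent accuracy check of the Laplace fit on small problems.
    """
    if spec.random_slope is not None:
        raise ValueError("quadrature oracle covers random intercepts only")
    family = _FAMILIES[spec.family]
    data = data.sort_values(spec.group, kind="stable").reset_index(drop=True)
    X, _, y, n = _prepare(data, spec)
    disp = np.array([math.log(dispersion)]) if dispersion is not None else np.array([])
    eta_fixed = X @ np.asarray(beta, dtype=float)
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    total = 0.0
    for _, idx in data.groupby(spec.group, sort=False).indices.items():
        yi, ni, ei = y[idx], n[idx], eta_fixed[idx]

        def h(b):
            return (np.sum(family.loglik(yi, ni, ei + b, disp))
                    - 0.5 * b ** 2 / re_sd ** 2
                    - math.log(re_sd) - 0.5 * math.log(2 * math.pi))

        # mode and curvature for the adaptive centring
        b_hat = 0.0
        for _ in range(200):
            dl, d2l = family.d_eta(yi, ni, ei + b_hat, disp)
            g = np.sum(dl) - b_hat / re_sd ** 2
            hss = np.sum(d2l) - 1.0 / re_sd ** 2
            step = -g / hss
            b_hat += step
            if abs(step) < 1e-12:
                break
        sd_hat = 1.0 / math.sqrt(-hss)
        pts = b_hat + math.sqrt(2.0) * sd_hat * nodes
        vals = np.array([h(b) for b in pts]) + nodes ** 2
        m = vals.max()
        integral = math.sqrt(2.0) * sd_hat * np.sum(weights * np.exp(vals - m))
        total += m + math.log(integral)
    return float(total)
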