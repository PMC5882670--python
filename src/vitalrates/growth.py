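"""Random-effects von Bertalanffy growth model for longitudinal length-at-age.

The growth function is ``L(t) = Linf * (1 - exp(-k * (t - t0)))``.  For
longitudinal tag-recapture data, ``k`` and ``Linf`` are modelled on the log
scale as linear functions of shared predictors (cohort, sector, a static
continuous covariate) plus standardized individual random effects::

    log k_i    = a_i + sigma_u * u_i,   u_i ~ N(0, 1)
    log Linf_i = b_i + sigma_v * v_i,   v_i ~ N(0, 1)
    t0         = gamma0 (shared scalar)

with independent ``u`` and ``v`` and Gaussian measurement error
``L_obs ~ N(L(t), sigma_eps)``.  Fixed effects and variance components are
estimated by marginal maximum likelihood: the per-individual random effects
are integrated out with a Laplace approximation (second-order expansion of
the joint log-density at the per-individual posterior mode), and the modes
themselves are the empirical-Bayes estimates of ``u_i``, ``v_i``.

An adaptive Gauss-Hermite quadrature evaluation of the same marginal
likelihood is provided (:func:`marginal_loglik_ghq`) as an independent
numerical cross-check of the Laplace approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .modelsel import FitResult, aic as _aic, rank_by_aic

__all__ = [
    "GrowthParams",
    "GrowthFit",
    "vbgf_length",
    "fit_growth",
    "predict_mean_trajectory",
    "select_growth_model",
    "growth_increment",
    "build_growth_dataset",
    "marginal_loglik_ghq",
]

# categorical terms use treatment coding; reference level is the smallest
# label (earliest cohort / most-downstream sector)
CATEGORICAL_TERMS = ("cohort", "sector")
CONTINUOUS_TERMS = ("density", "gdd")

# inner mode-finding: Newton on the 2-D per-individual posterior
_INNER_TOL = 1e-8
_INNER_MAXIT = 80


@dataclass
class GrowthParams:
    """Generating/fitted parameters of the random-effects growth model.

    ``log_k``/``log_linf`` are the intercepts of the log-linear predictors;
    ``k_group``/``linf_group`` map a group level (e.g. cohort year) to an
    additive offset; ``k_slope``/``linf_slope`` multiply a static continuous
    covariate ``x``.  ``t0`` is the shared hypothetical age at length zero.
    """

    log_k: float
    log_linf: float
    t0: float = 0.0
    sigma_u: float = 0.0
    sigma_v: float = 0.0
    sigma_eps: float = 0.0
    k_group: Mapping[Any, float] = field(default_factory=dict)
    linf_group: Mapping[Any, float] = field(default_factory=dict)
    k_slope: float = 0.0
    linf_slope: float = 0.0

    def __post_init__(self):
        for name in ("sigma_u", "sigma_v", "sigma_eps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def vbgf_length(params: GrowthParams, t, u=0.0, v=0.0, group=None, x=0.0):
    """Evaluate the growth curve at age(s) ``t`` for one individual.

    ``u``/``v`` are the standardized random effects, ``group`` selects the
    group offsets, ``x`` is the static continuous covariate.  Total function:
    negative ``t - t0`` simply yields negative length.
    """
    a = params.log_k + params.k_group.get(group, 0.0) + params.k_slope * x
    b = params.log_linf + params.linf_group.get(group, 0.0) + params.linf_slope * x
    k = np.exp(a + params.sigma_u * np.asarray(u))
    linf = np.exp(b + params.sigma_v * np.asarray(v))
    return linf * (1.0 - np.exp(-k * (np.asarray(t, dtype=float) - params.t0)))


# ---------------------------------------------------------------------------
# model preparation


class _ModelData:
    """Padded per-individual arrays plus design matrices for one model spec."""

    def __init__(self, data: pd.DataFrame, k_terms, linf_terms):
        req = {"fish_id", "age", "length_mm"}
        if not req.issubset(data.columns):
            raise ValueError(f"growth data needs columns {sorted(req)}")
        df = data.sort_values(["fish_id", "age"], kind="mergesort").reset_index(drop=True)
        ids, idx = np.unique(df["fish_id"].to_numpy(), return_inverse=True)
        self.ids = ids
        n = len(ids)
        counts = np.bincount(idx, minlength=n)
        if (counts < 1).any():
            raise ValueError("each individual needs at least one observation")
        m = counts.max()
        self.T = np.zeros((n, m))
        self.L = np.zeros((n, m))
        self.M = np.zeros((n, m), dtype=bool)
        pos = np.zeros(n, dtype=int)
        ages = df["age"].to_numpy(dtype=float)
        lens = df["length_mm"].to_numpy(dtype=float)
        for r in range(len(df)):
            i = idx[r]
            j = pos[i]
            self.T[i, j] = ages[r]
            self.L[i, j] = lens[r]
            self.M[i, j] = True
            pos[i] += 1
        for i in range(n):
            a = self.T[i, self.M[i]]
            if np.any(np.diff(a) <= 0):
                raise ValueError(f"ages not strictly increasing for individual {ids[i]!r}")
        self.n_obs = counts
        self.n_ind = n
        self.n_total = int(counts.sum())

        first = df.groupby("fish_id", sort=True).first()
        self.levels: dict[str, np.ndarray] = {}
        self.scaling: dict[str, tuple[float, float]] = {}
        self.k_terms = tuple(k_terms)
        self.linf_terms = tuple(linf_terms)
        self.Zk, self.k_names = self._design(df, first, self.k_terms, "log_k")
        self.Zl, self.linf_names = self._design(df, first, self.linf_terms, "log_linf")

    def _design(self, df, first, terms, prefix):
        cols = [np.ones(self.n_ind)]
        names = [f"{prefix}:(Intercept)"]
        for term in terms:
            if term in ("1", "null", ""):
                continue
            if term not in first.columns:
                raise ValueError(f"term {term!r} not found in data columns")
            grouped = df.groupby("fish_id", sort=True)[term]
            if grouped.nunique().max() > 1:
                raise ValueError(f"covariate {term!r} must be static within individual")
            vals = first[term].to_numpy()
            if term in CATEGORICAL_TERMS:
                levels = self.levels.setdefault(term, np.unique(vals))
                for lev in levels[1:]:
                    cols.append((vals == lev).astype(float))
                    names.append(f"{prefix}:{term}[{lev}]")
            else:
                x = vals.astype(float)
                mu, sd = self.scaling.get(term, (float(x.mean()), float(x.std() or 1.0)))
                self.scaling[term] = (mu, sd)
                cols.append((x - mu) / sd)
                names.append(f"{prefix}:{term}")
        return np.column_stack(cols), names

    def row_for(self, which: str, group_values: Mapping[str, Any]) -> np.ndarray:
        """Design row for prediction at given covariate values."""
        terms = self.k_terms if which == "k" else self.linf_terms
        prefix = "log_k" if which == "k" else "log_linf"
        row = [1.0]
        for term in terms:
            if term in ("1", "null", ""):
                continue
            val = group_values.get(term)
            if val is None:
                raise ValueError(f"prediction needs a value for {term!r}")
            if term in CATEGORICAL_TERMS:
                levels = self.levels[term]
                if val not in levels:
                    raise ValueError(f"unseen {term} level {val!r}")
                row.extend([(val == lev) * 1.0 for lev in levels[1:]])
            else:
                mu, sd = self.scaling[term]
                row.append((float(val) - mu) / sd)
        return np.asarray(row)


def _unpack(model: _ModelData, theta: np.ndarray):
    pk = model.Zk.shape[1]
    pl = model.Zl.shape[1]
    th_k = theta[:pk]
    th_l = theta[pk : pk + pl]
    t0 = theta[pk + pl]
    su, sv, se = np.exp(theta[pk + pl + 1 : pk + pl + 4])
    return th_k, th_l, t0, su, sv, se


def _inner_g(model, A, B, t0, su, sv, se, U, V):
    """Joint log-density g(u, v) per individual (obs likelihood + N(0,1) priors)."""
    k = np.exp(A + su * U)[:, None]
    linf = np.exp(B + sv * V)[:, None]
    P = linf * (1.0 - np.exp(-k * (model.T - t0)))
    r = np.where(model.M, model.L - P, 0.0)
    ssr = (r * r).sum(axis=1)
    g = (
        -0.5 * ssr / se**2
        - 0.5 * model.n_obs * np.log(2 * np.pi * se**2)
        - 0.5 * (U * U + V * V)
        - np.log(2 * np.pi)
    )
    return g, P, r, k, linf


def _laplace_components(model, theta, modes):
    """Per-individual Laplace log-marginals; updates ``modes`` in place."""
    th_k, th_l, t0, su, sv, se = _unpack(model, theta)
    A = model.Zk @ th_k
    B = model.Zl @ th_l
    U, V = modes
    tau = model.T - t0

    def derivs(U, V):
        g, P, r, k, linf = _inner_g(model, A, B, t0, su, sv, se, U, V)
        E = np.exp(-k * tau)
        Pu = np.where(model.M, linf * tau * k * su * E, 0.0)
        Pv = np.where(model.M, sv * P, 0.0)
        inv = 1.0 / se**2
        gu = (r * Pu).sum(1) * inv - U
        gv = (r * Pv).sum(1) * inv - V
        # Gauss-Newton curvature (always negative definite)
        Huu = -((Pu * Pu).sum(1) * inv + 1.0)
        Hvv = -((Pv * Pv).sum(1) * inv + 1.0)
        Huv = -(Pu * Pv).sum(1) * inv
        return g, gu, gv, Huu, Hvv, Huv, (P, r, k, linf, E, Pu, Pv)

    # guard the warm-start cache: fall back to a zero start wherever the
    # cached mode is non-finite or worse than the origin
    g_c, *_ = _inner_g(model, A, B, t0, su, sv, se, U, V)
    zeros = np.zeros_like(U)
    g_z, *_ = _inner_g(model, A, B, t0, su, sv, se, zeros, zeros)
    keep = np.isfinite(g_c) & (g_c >= g_z)
    U = np.where(keep, U, 0.0)
    V = np.where(keep, V, 0.0)

    g0, gu, gv, Huu, Hvv, Huv, aux = derivs(U, V)
    for _ in range(_INNER_MAXIT):
        if max(np.abs(gu).max(initial=0), np.abs(gv).max(initial=0)) < _INNER_TOL:
            break
        det = Huu * Hvv - Huv * Huv
        du = -(Hvv * gu - Huv * gv) / det
        dv = -(Huu * gv - Huv * gu) / det
        step = np.ones(model.n_ind)
        for _ in range(20):
            U1 = U + step * du
            V1 = V + step * dv
            g1, *_ = _inner_g(model, A, B, t0, su, sv, se, U1, V1)
            bad = g1 < g0 - 1e-12
            if not bad.any():
                break
            step[bad] *= 0.5
        take = g1 >= g0
        U = np.where(take, U1, U)
        V = np.where(take, V1, V)
        g0, gu, gv, Huu, Hvv, Huv, aux = derivs(U, V)

    # exact Hessian at the mode for the Laplace determinant
    P, r, k, linf, E, Pu, Pv = aux
    inv = 1.0 / se**2
    Puu = np.where(model.M, linf * tau * su**2 * k * E * (1.0 - k * tau), 0.0)
    Puv = sv * Pu
    Pvv = sv * Pv
    Huu_t = ((r * Puu - Pu * Pu).sum(1)) * inv - 1.0
    Hvv_t = ((r * Pvv - Pv * Pv).sum(1)) * inv - 1.0
    Huv_t = ((r * Puv - Pu * Pv).sum(1)) * inv
    det_t = Huu_t * Hvv_t - Huv_t * Huv_t
    # fall back to the Gauss-Newton determinant where the exact Hessian is
    # not negative definite at the numerical mode
    det_gn = Huu * Hvv - Huv * Huv
    ok = (det_t > 0) & (Huu_t < 0) & np.isfinite(det_t)
    det_use = np.where(ok, det_t, det_gn)
    loglik_i = g0 + np.log(2 * np.pi) - 0.5 * np.log(det_use)
    modes[0][:] = U
    modes[1][:] = V
    return loglik_i


@dataclass
class GrowthFit:
    """Fitted random-effects growth model."""

    label: str
    estimates: pd.DataFrame
    loglik: float
    npar: int
    params: GrowthParams
    u_hat: pd.Series
    v_hat: pd.Series
    loglik_i: np.ndarray
    theta: np.ndarray
    cov: np.ndarray | None
    model: _ModelData
    status: str = "ok"

    @property
    def aic(self) -> float:
        return _aic(self.loglik, self.npar)

    def as_fit_result(self) -> FitResult:
        return FitResult(
            label=self.label,
            estimates=self.estimates,
            loglik=self.loglik,
            npar=self.npar,
            status=self.status,
            extra={"growth_fit": self},
        )


def _fd_hessian(fun, x, rel_step=1e-4):
    """Central finite-difference Hessian (no external differentiation dep)."""
    p = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.zeros((p, p))
    f0 = fun(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def fit_growth(
    data: pd.DataFrame,
    k_terms: Sequence[str] = ("1",),
    linf_terms: Sequence[str] = ("1",),
    start: Mapping[str, float] | None = None,
    compute_se: bool = True,
    label: str | None = None,
) -> GrowthFit:
    """Fit the random-effects growth model by Laplace-marginal ML.

    Parameters
    ----------
    data : DataFrame
        Long format, one row per (individual, age): columns ``fish_id``,
        ``age`` (years), ``length_mm``, plus any covariate columns named in
        the term lists (``cohort``/``sector`` categorical; ``density``/
        ``gdd`` continuous, standardized internally).
    k_terms, linf_terms : sequences of term names
        Predictors of ``log k`` and ``log Linf``; ``("1",)`` is
        intercept-only.

    Raises on non-convergence with the optimizer diagnostics attached.
    """
    if len(data) < 2:
        raise ValueError("need at least 2 observations")
    model = _ModelData(data, k_terms, linf_terms)
    pk, pl = model.Zk.shape[1], model.Zl.shape[1]

    lmax = float(np.max(model.L[model.M]))
    x0 = np.zeros(pk + pl + 4)
    x0[0] = np.log(0.3)
    x0[pk] = np.log(1.1 * lmax)
    x0[pk + pl] = -0.1  # t0
    x0[pk + pl + 1 : pk + pl + 4] = np.log([0.15, 0.15, 5.0])
    if start:
        for key, val in start.items():
            if key == "log_k":
                x0[0] = val
            elif key == "log_linf":
                x0[pk] = val
            elif key == "t0":
                x0[pk + pl] = val
            elif key in ("sigma_u", "sigma_v", "sigma_eps"):
                off = {"sigma_u": 1, "sigma_v": 2, "sigma_eps": 3}[key]
                x0[pk + pl + off] = np.log(max(val, 1e-3))

    min_age = float(np.min(model.T[model.M]))
    bounds = (
        [(-8.0, 4.0)] + [(-6.0, 6.0)] * (pk - 1)
        + [(0.0, 9.0)] + [(-6.0, 6.0)] * (pl - 1)
        + [(-4.0, min_age - 1e-3)]
        + [(np.log(1e-4), np.log(5.0))] * 2
        + [(np.log(1e-3), np.log(200.0))]
    )

    modes = [np.zeros(model.n_ind), np.zeros(model.n_ind)]

    def nll(theta):
        try:
            ll = _laplace_components(model, theta, modes)
        except FloatingPointError:
            return 1e10
        tot = ll.sum()
        return -tot if np.isfinite(tot) else 1e10

    with np.errstate(over="ignore", invalid="ignore"):
        res = minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 600, "ftol": 1e-11, "gtol": 1e-6},
        )
    if not res.success and "ABNORMAL" in str(res.message):
        raise RuntimeError(f"growth fit did not converge: {res.message}")

    theta = res.x
    loglik_i = _laplace_components(model, theta, modes)
    loglik = float(loglik_i.sum())
    npar = len(theta)

    status = "ok" if res.success else f"warn: {res.message}"
    cov = None
    ses = np.full(npar, np.nan)
    if compute_se:
        with np.errstate(over="ignore", invalid="ignore"):
            H = _fd_hessian(nll, theta)
        try:
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            if (d < 0).any():
                raise np.linalg.LinAlgError("negative variance")
            ses = np.sqrt(d)
        except np.linalg.LinAlgError:
            warnings.warn("singular Hessian: SEs reported as missing", stacklevel=2)
            cov = None
            status = "boundary/singular-hessian"

    th_k, th_l, t0, su, sv, se_eps = _unpack(model, theta)
    names = (
        model.k_names + model.linf_names + ["t0", "sigma_u", "sigma_v", "sigma_eps"]
    )
    values = np.concatenate([th_k, th_l, [t0, su, sv, se_eps]])
    se_out = ses.copy()
    # delta method: sigmas were estimated on the log scale
    for off, sig in zip((1, 2, 3), (su, sv, se_eps)):
        se_out[pk + pl + off] = ses[pk + pl + off] * sig
    est = pd.DataFrame({"name": names, "value": values, "se": se_out})

    # raw-scale slopes for standardized continuous covariates
    extra_rows = []
    for term, (mu, sd) in model.scaling.items():
        for prefix, nm_list, th in (("log_k", model.k_names, th_k), ("log_linf", model.linf_names, th_l)):
            nm = f"{prefix}:{term}"
            if nm in nm_list:
                i = names.index(nm)
                extra_rows.append(
                    {"name": f"{nm}[raw]", "value": values[i] / sd, "se": se_out[i] / sd}
                )
    if extra_rows:
        est = pd.concat([est, pd.DataFrame(extra_rows)], ignore_index=True)

    params = GrowthParams(
        log_k=float(th_k[0]),
        log_linf=float(th_l[0]),
        t0=float(t0),
        sigma_u=float(su),
        sigma_v=float(sv),
        sigma_eps=float(se_eps),
    )
    lbl = label or f"k~{'+'.join(model.k_terms)} | Linf~{'+'.join(model.linf_terms)}"
    return GrowthFit(
        label=lbl,
        estimates=est,
        loglik=loglik,
        npar=npar,
        params=params,
        u_hat=pd.Series(modes[0].copy(), index=model.ids, name="u_hat"),
        v_hat=pd.Series(modes[1].copy(), index=model.ids, name="v_hat"),
        loglik_i=loglik_i,
        theta=theta,
        cov=cov,
        model=model,
        status=status,
    )


def marginal_loglik_ghq(
    fit: GrowthFit, individuals: Sequence | None = None, n_nodes: int = 15
) -> float:
    """Marginal log-likelihood by adaptive Gauss-Hermite quadrature.

    Integrates the per-individual likelihood over ``(u, v)`` on a product
    quadrature grid centred and scaled at each individual's posterior mode.
    Independent numerical check of the Laplace approximation.
    """
    model = fit.model
    th_k, th_l, t0, su, sv, se = _unpack(model, fit.theta)
    A = model.Zk @ th_k
    B = model.Zl @ th_l
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    idx = (
        np.arange(model.n_ind)
        if individuals is None
        else np.asarray([np.flatnonzero(model.ids == i)[0] for i in individuals])
    )
    total = 0.0
    for i in idx:
        mu = np.array([fit.u_hat.iloc[i], fit.v_hat.iloc[i]])
        # exact Hessian of g at the mode via small central differences
        def g(uv):
            u, v = uv
            k = np.exp(A[i] + su * u)
            linf = np.exp(B[i] + sv * v)
            P = linf * (1.0 - np.exp(-k * (model.T[i] - t0)))
            r = np.where(model.M[i], model.L[i] - P, 0.0)
            return (
                -0.5 * (r * r).sum() / se**2
                - 0.5 * model.n_obs[i] * np.log(2 * np.pi * se**2)
                - 0.5 * (u * u + v * v)
                - np.log(2 * np.pi)
            )

        h = 1e-4
        Hm = np.zeros((2, 2))
        f0 = g(mu)
        for a_ in range(2):
            ea = np.zeros(2)
            ea[a_] = h
            Hm[a_, a_] = (g(mu + ea) - 2 * f0 + g(mu - ea)) / h**2
            for b_ in range(a_ + 1, 2):
                eb = np.zeros(2)
                eb[b_] = h
                Hm[a_, b_] = Hm[b_, a_] = (
                    g(mu + ea + eb) - g(mu + ea - eb) - g(mu - ea + eb) + g(mu - ea - eb)
                ) / (4 * h * h)
        Sigma = np.linalg.inv(-Hm)
        Lc = np.linalg.cholesky(Sigma)
        logdet_term = np.log(2.0) + np.log(np.diag(Lc)).sum()  # log|det(sqrt(2) L)|
        vals = np.empty((n_nodes, n_nodes))
        for p_ in range(n_nodes):
            for q_ in range(n_nodes):
                z = np.array([nodes[p_], nodes[q_]])
                uv = mu + np.sqrt(2.0) * Lc @ z
                vals[p_, q_] = g(uv) + z @ z
        logw = np.log(weights)
        from scipy.special import logsumexp

        total += logsumexp(vals + logw[:, None] + logw[None, :]) + logdet_term
    return float(total)


def predict_mean_trajectory(
    fit: GrowthFit,
    ages: Sequence[float],
    group_values: Mapping[str, Any] | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Mode growth trajectory (random effects set to zero) with delta-method CI.

    Because ``Linf`` is lognormal across individuals, the ``u = v = 0`` curve
    is the trajectory of the *modal* individual and lies below the
    population-mean trajectory whenever ``sigma_v > 0`` (Jensen's inequality);
    the output column is named ``mode_length_mm`` to make that explicit.
    """
    from scipy.stats import norm

    model = fit.model
    group_values = group_values or {}
    zk = model.row_for("k", group_values)
    zl = model.row_for("linf", group_values)
    th_k, th_l, t0, su, sv, se = _unpack(model, fit.theta)
    ages = np.asarray(ages, dtype=float)
    if (ages < t0).any():
        warnings.warn("ages below t0 give negative predicted lengths", stacklevel=2)
    a = zk @ th_k
    b = zl @ th_l
    k = np.exp(a)
    linf = np.exp(b)
    tau = ages - t0
    E = np.exp(-k * tau)
    L = linf * (1.0 - E)

    pk, pl = model.Zk.shape[1], model.Zl.shape[1]
    se_L = np.full_like(L, np.nan)
    if fit.cov is not None:
        # gradient wrt (th_k, th_l, t0) at u=v=0
        G = np.zeros((len(ages), len(fit.theta)))
        dL_da = linf * E * k * tau  # chain through log k
        G[:, :pk] = dL_da[:, None] * zk[None, :]
        G[:, pk : pk + pl] = L[:, None] * zl[None, :]
        G[:, pk + pl] = -linf * E * k
        var = np.einsum("ij,jk,ik->i", G, fit.cov, G)
        se_L = np.sqrt(np.maximum(var, 0.0))
    z = norm.ppf(0.5 + level / 2)
    return pd.DataFrame(
        {
            "age": ages,
            "mode_length_mm": L,
            "se": se_L,
            "lo": L - z * se_L,
            "hi": L + z * se_L,
        }
    )


def select_growth_model(
    data: pd.DataFrame,
    candidates: Sequence[tuple[Sequence[str], Sequence[str]]],
    compute_se: bool = False,
) -> tuple[pd.DataFrame, list[GrowthFit | None]]:
    """Fit candidate (k_terms, linf_terms) specs and rank them by AIC.

    Returns ``(ranking table, fits)``; candidates that fail to converge are
    listed in the table with a failure status, never silently dropped.
    """
    if not candidates:
        raise ValueError("need at least one candidate spec")
    fits: list[GrowthFit | None] = []
    results = []
    for k_terms, linf_terms in candidates:
        lbl = f"k~{'+'.join(k_terms)} | Linf~{'+'.join(linf_terms)}"
        try:
            f = fit_growth(data, k_terms, linf_terms, compute_se=compute_se, label=lbl)
            fits.append(f)
            results.append(f.as_fit_result())
        except Exception as exc:  # noqa: BLE001 - reported, not swallowed
            fits.append(None)
            results.append(
                FitResult(lbl, pd.DataFrame(), float("nan"), 0, status=f"failed: {exc}")
            )
    return rank_by_aic(results), fits


def growth_increment(encounters: pd.DataFrame) -> pd.DataFrame:
    """Mean daily growth between consecutive captures of tagged fish.

    For each tagged individual and each consecutive pair of capture dates,
    ``g_d = (L1 - L0) / days`` in mm/day, with start length, age and the
    season of the interval attached (Summer = June->September).  Fish caught
    once contribute no rows; non-positive day gaps are skipped with a warning.
    """
    df = encounters.copy()
    df = df[df["tag_id"].fillna("").astype(str).str.len() > 0]
    df["date"] = pd.to_datetime(df["date"])
    # one record per fish per occasion (first pass wins)
    df = df.sort_values(["tag_id", "date", "pass"], kind="mergesort")
    df = df.drop_duplicates(subset=["tag_id", "occasion_index"], keep="first")
    rows = []
    for tag, grp in df.groupby("tag_id", sort=True):
        g = grp.sort_values("date")
        d = g["date"].to_numpy()
        ln = g["length_mm"].to_numpy(dtype=float)
        age = pd.to_numeric(g.get("age_years"), errors="coerce").to_numpy()
        for a, b in zip(range(len(g) - 1), range(1, len(g))):
            days = (d[b] - d[a]) / np.timedelta64(1, "D")
            if days <= 0:
                warnings.warn(f"non-positive interval for tag {tag}; skipped", stacklevel=2)
                continue
            month0 = pd.Timestamp(d[a]).month
            rows.append(
                {
                    "tag_id": tag,
                    "date_start": pd.Timestamp(d[a]),
                    "date_end": pd.Timestamp(d[b]),
                    "days": days,
                    "length_start_mm": ln[a],
                    "length_end_mm": ln[b],
                    "g_d": (ln[b] - ln[a]) / days,
                    "age_start": age[a],
                    "season": "Summer" if month0 == 6 else "Winter",
                }
            )
    cols = [
        "tag_id", "date_start", "date_end", "days", "length_start_mm",
        "length_end_mm", "g_d", "age_start", "season",
    ]
    return pd.DataFrame(rows, columns=cols)


def build_growth_dataset(
    encounters: pd.DataFrame,
    september_only: bool = True,
    tagged_only: bool = True,
) -> pd.DataFrame:
    """Assemble a September length-at-age dataset from an encounter table.

    Fractional age is measured from a nominal mid-June emergence of the birth
    cohort, so a 0+ fish in September is 0.25 years old.  Returns columns
    ``fish_id``, ``age``, ``length_mm``, ``cohort``, ``sector``.
    """
    df = encounters.copy()
    df["date"] = pd.to_datetime(df["date"])
    if tagged_only:
        df = df[df["tag_id"].fillna("").astype(str).str.len() > 0]
    if september_only:
        df = df[df["date"].dt.month == 9]
    df = df.sort_values(["tag_id", "date", "pass"], kind="mergesort")
    df = df.drop_duplicates(subset=["tag_id", "occasion_index"], keep="first")
    age_class = pd.to_numeric(df["age_years"], errors="coerce")
    df = df[age_class.notna()]
    age_class = age_class[age_class.notna()]
    birth_year = df["date"].dt.year - age_class.astype(int)
    emergence = pd.to_datetime(birth_year.astype(str) + "-06-15")
    frac_age = (df["date"] - emergence).dt.days / 365.25
    out = pd.DataFrame(
        {
            "fish_id": df["tag_id"].to_numpy(),
            "age": frac_age.to_numpy(),
            "length_mm": pd.to_numeric(df["length_mm"]).to_numpy(),
            "cohort": birth_year.to_numpy(),
            "sector": df["sector"].to_numpy() if "sector" in df else 1,
        }
    )
    return out.sort_values(["fish_id", "age"], kind="mergesort").reset_index(drop=True)
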