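"""Density-dependence regressions and competition-coefficient estimation.

The statistical core of the pipeline:

* z-score standardization of explanatory variables (all density predictors
  are standardized before fitting; squared and interaction columns are built
  from the standardized columns, so "squared conspecific colony density"
  means z²),
* ordinary / weighted least squares and binomial logistic regression
  (iteratively reweighted least squares), both implemented here,
* a maximum-likelihood random-intercept extension of the logistic model
  (Gauss–Hermite quadrature over the colony intercept) and a linear mixed
  model for the colony-level responses (delegated to statsmodels MixedLM),
* downward stepwise model selection on AIC with a marginality rule,
* Fisher's combined-probability test, and
* the Lotka–Volterra competition-coefficient fit: per-worker-weight net
  colony growth Gw regressed on standardized con- and heterospecific
  densities, read through ``(1/N_i) dN_i/dt = r_i (1 − α_ii N_i − α_ij N_j)``.

Sign convention throughout: a negative fitted slope is a competitive
(suppressive) effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "ModelSpec",
    "FitResult",
    "LVFit",
    "SeparationError",
    "standardize",
    "add_standardized",
    "build_design",
    "fit_ols",
    "fit_logistic",
    "fit_lmm",
    "fit_model",
    "stepwise_aic",
    "fishers_method",
    "estimate_lv",
]


class SeparationError(RuntimeError):
    """Logistic estimates diverged (complete or quasi-complete separation)."""


# ---------------------------------------------------------------------------
# standardization and design construction
# ---------------------------------------------------------------------------

def standardize(values: Sequence[float]) -> np.ndarray:
    """z-score a vector: mean 0, SD 1 with the n−1 denominator.

    Raises ``ValueError`` on fewer than two values or zero variance.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values to standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector (zero variance)")
    return (x - x.mean()) / sd


def add_standardized(df: pd.DataFrame, columns: Sequence[str],
                     prefix: str = "z_") -> pd.DataFrame:
    """Return a copy of *df* with z-scored versions of *columns* added.

    Standardization is computed on the analysis sample as passed in (after
    any filtering); squared/interaction terms are then built from these z
    columns by :func:`build_design`.
    """
    out = df.copy()
    for col in columns:
        out[prefix + col] = standardize(df[col].to_numpy())
    return out


def _resolve_term(term: str, data: pd.DataFrame) -> np.ndarray:
    """Evaluate a term label against *data*.

    ``a:b`` is the elementwise product of its parts; ``x^2`` is the square of
    column ``x``; anything else is a column lookup.
    """
    if ":" in term:
        parts = term.split(":")
        col = np.ones(len(data))
        for p in parts:
            col = col * _resolve_term(p, data)
        return col
    if term.endswith("^2"):
        return _resolve_term(term[:-2], data) ** 2
    if term not in data.columns:
        raise KeyError(f"term {term!r} is not a column of the data")
    return data[term].to_numpy(dtype=float)


def build_design(data: pd.DataFrame, terms: Sequence[str],
                 intercept: bool = True) -> pd.DataFrame:
    """Build a design matrix (as a DataFrame) from term labels."""
    cols: dict[str, np.ndarray] = {}
    if intercept:
        cols["(Intercept)"] = np.ones(len(data))
    for t in terms:
        if t in cols:
            raise ValueError(f"duplicate term {t!r}")
        cols[t] = _resolve_term(t, data)
    return pd.DataFrame(cols, index=data.index)


def _interaction_components(term: str) -> set[str]:
    return set(term.split(":")) if ":" in term else set()


def droppable_terms(terms: Sequence[str]) -> list[str]:
    """Terms removable under the marginality rule.

    A main effect may not be dropped while any interaction containing it
    remains.  A squared term (``x^2``) carries no such protection for its
    linear part — it may stand alone.
    """
    protected: set[str] = set()
    for t in terms:
        protected |= _interaction_components(t)
    return [t for t in terms if t not in protected]


# ---------------------------------------------------------------------------
# model specification / fit result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A regression model: response, family, terms, optional random intercept.

    ``response`` is a data column for gaussian models, or a ``(successes,
    trials)`` column pair for binomial ones.  ``random`` names a grouping
    column for a random intercept.  ``offset`` names a size column; in the
    default per-worker link mode the response is divided by it, in
    ``log_offset`` mode ``log(offset)`` enters a log-link GLM.
    """

    response: str | tuple[str, str]
    terms: tuple[str, ...]
    family: str = "gaussian"           # "gaussian" | "binomial"
    random: Optional[str] = None
    offset: Optional[str] = None
    link_mode: str = "per_worker"      # "per_worker" | "log_offset"

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("term labels must be unique")
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")

    def drop(self, term: str) -> "ModelSpec":
        return replace(self, terms=tuple(t for t in self.terms if t != term))


@dataclass(frozen=True)
class FitResult:
    """Estimates on the standardized-predictor scale, with AIC bookkeeping."""

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    loglik: float
    aic: float
    n: int
    converged: bool
    extra: dict[str, float] = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return round((self.aic + 2.0 * self.loglik) / 2.0)


@dataclass(frozen=True)
class LVFit:
    """Lotka–Volterra competition-coefficient estimates.

    ``alpha_ii_std`` / ``alpha_ij_std`` are the standardized regression slopes
    (the field-reported quantities; negative = competitive).  ``alpha_ii`` /
    ``alpha_ij`` are the raw-scale LV coefficients obtained from the model
    ``Gw = r_i (1 − α_ii N_i − α_ij N_j)``, i.e. −slope_raw / r_i.  ``ratio``
    is the intra/inter ratio of the standardized slopes.
    """

    r_i: float
    alpha_ii_std: float
    alpha_ij_std: float
    alpha_ii: float
    alpha_ij: float
    ratio: float
    conspecific_metric: str
    standard_errors: dict[str, float]
    n: int


# ---------------------------------------------------------------------------
# least squares
# ---------------------------------------------------------------------------

def fit_ols(design: pd.DataFrame, response: Sequence[float],
            weights: Optional[Sequence[float]] = None) -> FitResult:
    """(Weighted) least squares via the QR-based solver.

    The design must be full rank after any intercept column; rank deficiency
    is reported with the offending columns.  The Gaussian log-likelihood uses
    the ML variance estimate (RSS/n), so AIC counts the residual variance as
    an estimated parameter.
    """
    X = design.to_numpy(dtype=float)
    y = np.asarray(response, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    sw = np.sqrt(w)
    Xw, yw = X * sw[:, None], y * sw
    rank = np.linalg.matrix_rank(Xw)
    if rank < p:
        # identify offending columns from the R factor's diagonal
        _, r = np.linalg.qr(Xw)
        bad = [design.columns[j] for j in range(p)
               if abs(r[j, j]) < 1e-10 * max(1.0, abs(r[0, 0]))]
        raise ValueError(f"design is rank deficient (rank {rank} < {p}); "
                         f"suspect columns: {bad}")
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(np.diag(XtX_inv) * rss / (n - p))
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + 0.5 * float(np.sum(np.log(w)))
    k = p + 1  # + residual variance
    names = list(design.columns)
    return FitResult(
        coefficients=dict(zip(names, beta.tolist())),
        standard_errors=dict(zip(names, se.tolist())),
        loglik=ll,
        aic=-2.0 * ll + 2.0 * k,
        n=n,
        converged=True,
        extra={"sigma2": sigma2, "df_resid": float(n - p)},
    )


# ---------------------------------------------------------------------------
# logistic regression (IRLS) and its random-intercept extension
# ---------------------------------------------------------------------------

def _binom_loglik(eta: np.ndarray, k: np.ndarray, m: np.ndarray) -> float:
    # log C(m,k) terms omitted: constant in parameters
    return float(np.sum(k * eta - m * np.logaddexp(0.0, eta)))


def fit_logistic(design: pd.DataFrame, outcomes: Sequence[float],
                 trials: Optional[Sequence[float]] = None,
                 cluster: Optional[Sequence] = None,
                 max_iter: int = 100, tol: float = 1e-10,
                 gh_points: int = 25) -> FitResult:
    """Binomial logistic regression by IRLS, optionally with a random intercept.

    *outcomes* are 0/1 per row (``trials=None``) or success counts with
    *trials* denominators.  With *cluster* labels a colony-level Gaussian
    random intercept is added and the marginal likelihood is maximised by
    Gauss–Hermite quadrature; rows sharing a cluster and identical predictor
    values are collapsed to binomial counts first.

    Complete separation (diverging estimates) raises :class:`SeparationError`
    rather than returning a silently degenerate fit.
    """
    X = design.to_numpy(dtype=float)
    k = np.asarray(outcomes, dtype=float)
    m = np.ones_like(k) if trials is None else np.asarray(trials, dtype=float)
    if np.any(k < 0) or np.any(k > m):
        raise ValueError("outcomes must satisfy 0 <= successes <= trials")
    tot_k, tot_m = k.sum(), m.sum()
    if tot_k == 0 or tot_k == tot_m:
        raise SeparationError("all outcomes identical: intercept diverges")

    beta = _irls(X, k, m, max_iter, tol)
    names = list(design.columns)

    if cluster is None:
        eta = X @ beta
        mu = special.expit(eta)
        W = m * mu * (1 - mu)
        cov = np.linalg.inv((X * W[:, None]).T @ X)
        se = np.sqrt(np.diag(cov))
        ll = _binom_loglik(eta, k, m)
        p = X.shape[1]
        return FitResult(dict(zip(names, beta.tolist())),
                         dict(zip(names, se.tolist())),
                         ll, -2 * ll + 2 * p, int(len(k)), True)

    # --- random intercept: collapse, then adaptive GH-quadrature ML --------
    # Binomial denominators can be large (whole colonies), making each
    # cluster's integrand far narrower than the random-effect scale, so the
    # quadrature is centred at each cluster's conditional mode and scaled by
    # the local curvature (as in lme4's nAGQ).
    groups = pd.factorize(np.asarray(cluster))[0]
    Xc, kc, mc, gc = _collapse(X, k, m, groups)
    nodes, wts = np.polynomial.hermite_e.hermegauss(gh_points)
    log_w = np.log(wts)

    n_groups = int(gc.max()) + 1

    def negll(params: np.ndarray) -> float:
        b, log_sigma = params[:-1], params[-1]
        sigma = max(np.exp(log_sigma), 1e-8)
        eta0 = Xc @ b

        def grp_sum(row_vals: np.ndarray) -> np.ndarray:
            out = np.zeros(n_groups)
            np.add.at(out, gc, row_vals)
            return out

        # Newton iterations (vectorised over clusters) for the mode of
        # h_c(u) = sum_rows [k*eta - m*log(1+e^eta)] - u^2/(2 sigma^2)
        u = np.zeros(n_groups)
        for _ in range(30):
            eta = eta0 + u[gc]
            mu = special.expit(eta)
            grad = grp_sum(kc - mc * mu) - u / sigma ** 2
            hess = -grp_sum(mc * mu * (1 - mu)) - 1.0 / sigma ** 2
            step = grad / hess
            u -= step
            if np.max(np.abs(step)) < 1e-10:
                break
        eta = eta0 + u[gc]
        curv = grp_sum(mc * special.expit(eta) * special.expit(-eta)) \
            + 1.0 / sigma ** 2
        s = 1.0 / np.sqrt(curv)                      # (groups,)

        # h_c evaluated on the shifted/scaled node grid: (groups, nodes)
        u_nodes = u[:, None] + s[:, None] * nodes[None, :]
        eta_n = eta0[:, None] + u_nodes[gc]
        row_ll = kc[:, None] * eta_n - mc[:, None] * np.logaddexp(0.0, eta_n)
        grp_ll = np.zeros((n_groups, gh_points))
        np.add.at(grp_ll, gc, row_ll)
        h = grp_ll - u_nodes ** 2 / (2 * sigma ** 2)
        # log L_c = -log(sigma sqrt(2 pi)) + log[s * sum_k w_k e^{h + x_k^2/2}]
        log_int = (np.log(s) - np.log(sigma) - 0.5 * np.log(2 * np.pi)
                   + special.logsumexp(
                       h + nodes[None, :] ** 2 / 2 + log_w[None, :], axis=1))
        return -float(np.sum(log_int))

    x0 = np.append(beta, np.log(0.3))
    res = optimize.minimize(negll, x0, method="L-BFGS-B")
    if not res.success or np.max(np.abs(res.x[:-1])) > 30:
        raise SeparationError(f"random-intercept logistic did not converge: "
                              f"{res.message}")
    from statsmodels.tools.numdiff import approx_hess

    hess = approx_hess(res.x, negll)
    try:
        cov = np.linalg.inv(hess)
        se_all = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        se_all = np.full(res.x.size, np.nan)
    p = X.shape[1] + 1  # + random-intercept SD
    ll = -res.fun
    return FitResult(dict(zip(names, res.x[:-1].tolist())),
                     dict(zip(names, se_all[:-1].tolist())),
                     ll, -2 * ll + 2 * p, int(len(k)), True,
                     extra={"random_intercept_sd": float(np.exp(res.x[-1])),
                            "n_groups": float(n_groups)})


def _irls(X: np.ndarray, k: np.ndarray, m: np.ndarray,
          max_iter: int, tol: float) -> np.ndarray:
    """Iteratively reweighted least squares for binomial logit."""
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = X @ beta
        mu = special.expit(eta)
        W = m * mu * (1 - mu)
        if np.all(W < 1e-12):
            raise SeparationError("all fitted probabilities degenerate")
        z = eta + (k - m * mu) / np.maximum(W, 1e-12)
        WX = X * W[:, None]
        try:
            beta_new = np.linalg.solve(WX.T @ X, WX.T @ z)
        except np.linalg.LinAlgError as e:
            raise ValueError(f"singular weighted design: {e}") from e
        ll = _binom_loglik(X @ beta_new, k, m)
        if np.max(np.abs(beta_new)) > 30:
            raise SeparationError(
                "estimates diverging (|beta| > 30): complete separation?")
        beta, ll_old, done = beta_new, ll, abs(ll - ll_old) < tol
        if done:
            # a log-likelihood at (numerically) zero means every outcome is
            # predicted with certainty: complete separation, not a fit
            if ll > -1e-6 and p > 0:
                raise SeparationError(
                    "perfect classification (loglik ~ 0): complete separation")
            return beta
    raise SeparationError(f"IRLS did not converge in {max_iter} iterations")


def _collapse(X, k, m, groups):
    """Sum binomial counts over rows with identical (group, predictors)."""
    key = pd.DataFrame(np.column_stack([groups, X]))
    codes = pd.factorize(key.apply(tuple, axis=1))[0]
    order = np.argsort(codes, kind="stable")
    codes_s = codes[order]
    first = np.r_[True, codes_s[1:] != codes_s[:-1]]
    idx_first = order[first]
    kc = np.bincount(codes, weights=k)
    mc = np.bincount(codes, weights=m)
    return X[idx_first], kc, mc, groups[idx_first]


# ---------------------------------------------------------------------------
# linear mixed model (random intercept) — delegated to statsmodels
# ---------------------------------------------------------------------------

def fit_lmm(design: pd.DataFrame, response: Sequence[float],
            groups: Sequence) -> FitResult:
    """Gaussian random-intercept model, ML fit via statsmodels MixedLM.

    Used for the colony-level responses with a study-month random effect.
    Fitted by maximum likelihood (not REML) so AICs are comparable across
    fixed-effect structures during stepwise selection.
    """
    import statsmodels.api as sm

    y = np.asarray(response, dtype=float)
    X = design.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=np.asarray(groups))
        res = None
        for method in (None, ["bfgs"], ["powell"]):
            try:
                cand = (model.fit(reml=False) if method is None
                        else model.fit(reml=False, method=method))
            except Exception:
                continue
            if cand.converged and np.isfinite(cand.llf):
                res = cand
                break
    if res is None:
        return FitResult({}, {}, np.nan, np.inf, len(y), False)
    names = list(design.columns)
    p = X.shape[1] + 2  # + random-intercept variance + residual variance
    ll = float(res.llf)
    return FitResult(dict(zip(names, np.asarray(res.fe_params).tolist())),
                     dict(zip(names, np.asarray(res.bse_fe).tolist())),
                     ll, -2 * ll + 2 * p, len(y), True,
                     extra={"group_var": float(np.asarray(res.cov_re)[0, 0]),
                            "resid_var": float(res.scale)})


# ---------------------------------------------------------------------------
# model dispatcher + stepwise AIC
# ---------------------------------------------------------------------------

def fit_model(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fit a :class:`ModelSpec` against a tidy data table.

    Binomial models take ``response=(successes, trials)`` and fit at the
    individual level (rows collapse to binomial counts).  Gaussian models
    with an ``offset`` use the per-worker form by default — response divided
    by the offset column — or a log-link GLM with ``log(offset)`` offset in
    ``log_offset`` mode.
    """
    design = build_design(data, spec.terms)
    if spec.family == "binomial":
        succ_col, trial_col = spec.response
        cluster = data[spec.random] if spec.random else None
        return fit_logistic(design, data[succ_col], trials=data[trial_col],
                            cluster=cluster)
    # gaussian
    y = data[spec.response].to_numpy(dtype=float)
    if spec.offset is not None:
        off = data[spec.offset].to_numpy(dtype=float)
        if spec.link_mode == "log_offset":
            return _fit_glm_log_offset(design, y, off, spec, data)
        y = y / off
    if spec.random is not None:
        return fit_lmm(design, y, data[spec.random])
    return fit_ols(design, y)


def _fit_glm_log_offset(design, y, off, spec, data) -> FitResult:
    """Alternative offset semantics: log-link Gaussian GLM with log(offset)."""
    import statsmodels.api as sm

    if np.any(y <= 0):
        raise ValueError("log_offset mode requires a positive response")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, design.to_numpy(dtype=float),
                       family=sm.families.Gaussian(sm.families.links.Log()),
                       offset=np.log(off))
        res = model.fit()
    names = list(design.columns)
    ll = float(res.llf)
    p = design.shape[1] + 1
    return FitResult(dict(zip(names, np.asarray(res.params).tolist())),
                     dict(zip(names, np.asarray(res.bse).tolist())),
                     ll, -2 * ll + 2 * p, len(y), True)


#: AIC differences below this are ties, broken by dropping the later term.
AIC_TIE_TOL = 1e-9


def stepwise_aic(full: ModelSpec, data: pd.DataFrame,
                 fitter: Callable[[ModelSpec, pd.DataFrame], FitResult] = fit_model,
                 ) -> tuple[ModelSpec, FitResult, list[dict]]:
    """Downward stepwise selection on AIC.

    Starting from the full model, repeatedly drop the single term whose
    removal lowers AIC the most (respecting marginality: a main effect stays
    while an interaction containing it remains; a squared term needs no
    linear guard), until no single removal lowers AIC.  Non-convergent
    candidates are skipped and logged.  Returns the selected spec, its fit
    and the visited-model log.
    """
    current = full
    current_fit = fitter(current, data)
    if not current_fit.converged:
        raise RuntimeError("full model did not converge; cannot start stepwise")
    path: list[dict] = [{"terms": current.terms, "aic": current_fit.aic,
                         "action": "start"}]
    while True:
        candidates: list[tuple[float, int, str, FitResult]] = []
        for idx, term in enumerate(current.terms):
            if term not in droppable_terms(current.terms):
                continue
            cand = current.drop(term)
            fit = fitter(cand, data)
            if not fit.converged:
                path.append({"terms": cand.terms, "aic": None,
                             "action": f"skip -{term} (non-convergent)"})
                continue
            candidates.append((fit.aic, idx, term, fit))
            path.append({"terms": cand.terms, "aic": fit.aic,
                         "action": f"try -{term}"})
        if not candidates:
            break
        best_aic = min(a for a, *_ in candidates)
        if best_aic >= current_fit.aic - AIC_TIE_TOL:
            break
        # ties broken by dropping the later term in the declared ordering
        tied = [c for c in candidates if c[0] <= best_aic + AIC_TIE_TOL]
        _, _, term, fit = max(tied, key=lambda c: c[1])
        current, current_fit = current.drop(term), fit
        path.append({"terms": current.terms, "aic": fit.aic,
                     "action": f"drop {term}"})
    return current, current_fit, path


# ---------------------------------------------------------------------------
# Fisher's method
# ---------------------------------------------------------------------------

def fishers_method(p_values: Sequence[float]) -> tuple[float, int, float]:
    """Combine independent p-values: ``χ² = −2 Σ ln p`` on ``2k`` df."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    return chi2, df, float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# Lotka–Volterra competition coefficients
# ---------------------------------------------------------------------------

def estimate_lv(rates: pd.DataFrame,
                conspecific_metric: str = "colony_count") -> LVFit:
    """Estimate LV competition coefficients from the per-colony rates table.

    Regresses per-worker-weight net growth ``Gw`` on the standardized
    conspecific density (persistent nest count, or worker biomass when
    ``conspecific_metric='worker_biomass'``) and standardized heterospecific
    pitfall biomass.  The standardized slopes are the reported competition
    coefficients (negative = suppressive); the raw-scale LV coefficients
    follow from ``Gw = r_i (1 − α_ii N_i − α_ij N_j)`` as −slope_raw / r_i,
    and the intra/inter ratio is taken on the standardized scale.
    """
    metric_col = {"colony_count": "conspecific_nest_count",
                  "worker_biomass": "conspecific_worker_biomass"}.get(conspecific_metric)
    if metric_col is None:
        raise ValueError(f"unknown conspecific metric {conspecific_metric!r}")
    if len(rates) < 3:
        raise ValueError(f"need at least 3 colonies, got {len(rates)}")
    con = rates[metric_col].to_numpy(dtype=float)
    het = rates["heterospecific_total_biomass"].to_numpy(dtype=float)
    gw = rates["Gw"].to_numpy(dtype=float)
    design = pd.DataFrame({
        "(Intercept)": np.ones(len(rates)),
        "z_con": standardize(con),
        "z_het": standardize(het),
    })
    fit = fit_ols(design, gw)
    r_i = fit.coefficients["(Intercept)"]
    b_con, b_het = fit.coefficients["z_con"], fit.coefficients["z_het"]
    sd_con, sd_het = con.std(ddof=1), het.std(ddof=1)
    if r_i != 0:
        alpha_ii = -(b_con / sd_con) / r_i
        alpha_ij = -(b_het / sd_het) / r_i
    else:
        alpha_ii = alpha_ij = np.nan
    ratio = b_con / b_het if b_het != 0 else np.nan
    return LVFit(r_i=r_i, alpha_ii_std=b_con, alpha_ij_std=b_het,
                 alpha_ii=alpha_ii, alpha_ij=alpha_ij, ratio=ratio,
                 conspecific_metric=conspecific_metric,
                 standard_errors=dict(fit.standard_errors), n=len(rates))
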