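"""Random-intercept mixed models and AICc-based model comparison.

The analyses compare, e.g., average speed per trajectory between the
transport and homing phases with a gamma GLMM (log link, frog identity as
random intercept to account for repeated trajectories of the same
individuals), straightness coefficients with a beta GLMM (logit link), and
angular / perpendicular deviations with gamma GLMMs or Gaussian LMMs.
Model support is judged with the small-sample Akaike information criterion

    AICc = -2 logL + 2k + 2k(k+1)/(n - k - 1).

A full model is supported over the corresponding null (intercept) model only
when Delta AICc > 2; with several explanatory variables all subsets are
fitted (all-subset modeling), models within Delta AICc <= 2 of the best are
retained, and coefficients are model-averaged with Akaike weights.

Fitting: maximum likelihood with the random intercept integrated out by
Gauss-Hermite quadrature (25 nodes) for gamma and beta families and in
closed form for the Gaussian family.  Optimizer settings are pinned for
determinism (L-BFGS-B, gtol 1e-8, max 500 iterations, starting values from
the fixed-effect GLM).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logsumexp

import statsmodels.api as sm

from .core import ValidationError

__all__ = [
    "ModelSpec",
    "ModelFit",
    "SelectionResult",
    "aicc",
    "akaike_weights",
    "squeeze_unit_interval",
    "fit_mixed_model",
    "compare_to_null",
    "all_subset_selection",
    "ConvergenceError",
]

_GH_NODES = 25
_DEFAULT_LINKS = {"gamma": "log", "beta": "logit", "gaussian": "identity"}
_SINGULAR_LOG_SD = -6.0  # random-effect sd below exp(-6) is flagged singular


class ConvergenceError(RuntimeError):
    """A model fit failed to converge."""


@dataclass(frozen=True)
class ModelSpec:
    """One candidate mixed model: response ~ fixed_terms + (1 | grouping)."""

    response: str
    family: str = "gaussian"
    link: str | None = None
    fixed_terms: tuple[str, ...] = ()
    random_intercept: str = "frog_id"

    def __post_init__(self) -> None:
        if self.family not in _DEFAULT_LINKS:
            raise ValidationError(f"unsupported family {self.family!r}")
        default = _DEFAULT_LINKS[self.family]
        if self.link is not None and self.link != default:
            warnings.warn(
                f"link {self.link!r} is not usable for the {self.family} "
                f"family here; fitting with the {default!r} link instead",
                stacklevel=3,
            )
            object.__setattr__(self, "link", default)
        if self.link is None:
            object.__setattr__(self, "link", default)

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.fixed_terms) if self.fixed_terms else "1"
        return f"{self.response} ~ {rhs} + (1 | {self.random_intercept})"


@dataclass
class ModelFit:
    spec: ModelSpec
    coefficients: dict[str, tuple[float, float]]  # name -> (estimate, se)
    loglik: float
    k: int
    n: int
    aicc: float
    dispersion: float  # gamma shape / beta precision / gaussian sigma
    random_sd: float
    converged: bool = True
    singular: bool = False


@dataclass
class SelectionResult:
    ranked: list[ModelFit]
    delta: np.ndarray
    weights: np.ndarray
    subset: list[ModelFit]
    averaged: dict[str, tuple[float, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Information criteria


def aicc(loglik: float, k: int, n: int) -> float:
    """Second-order (small-sample) Akaike information criterion."""
    if n <= k + 1:
        raise ValidationError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights: relative support of each candidate model."""
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


def squeeze_unit_interval(y: np.ndarray) -> np.ndarray:
    """Standard boundary squeeze for unit-interval responses:
    y' = (y*(n-1) + 0.5) / n, applied when any value touches 0 or 1
    (a straightness coefficient can be exactly 1)."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y > 1):
        raise ValidationError("beta-family response outside [0, 1]")
    if np.any(y <= 0) or np.any(y >= 1):
        n = y.size
        y = (y * (n - 1) + 0.5) / n
    return y


# ---------------------------------------------------------------------------
# Likelihoods


def _design(spec: ModelSpec, data: pd.DataFrame):
    y = data[spec.response].to_numpy(dtype=float)
    cols = [np.ones(len(data))]
    names = ["Intercept"]
    for term in spec.fixed_terms:
        col = data[term]
        if col.dtype == bool or col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=term, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
                names.append(str(c))
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(term)
    X = np.column_stack(cols)
    groups, _ = pd.factorize(data[spec.random_intercept], sort=True)
    return y, X, names, groups


def _group_bounds(groups_sorted: np.ndarray) -> np.ndarray:
    return np.flatnonzero(np.r_[True, np.diff(groups_sorted) != 0])


def _obs_loglik(family: str, y: np.ndarray, eta: np.ndarray, disp: float) -> np.ndarray:
    """Per-observation log density at linear predictor ``eta`` (broadcasts)."""
    if family == "gamma":
        a = disp  # shape
        return (
            a * np.log(a)
            - a * eta
            - gammaln(a)
            + (a - 1.0) * np.log(y)
            - a * y * np.exp(-eta)
        )
    if family == "beta":
        phi = disp
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        return (
            gammaln(phi)
            - gammaln(mu * phi)
            - gammaln((1.0 - mu) * phi)
            + (mu * phi - 1.0) * np.log(y)
            + ((1.0 - mu) * phi - 1.0) * np.log1p(-y)
        )
    raise ValidationError(f"no quadrature likelihood for family {family!r}")


def _neg_marginal_loglik_gh(theta, y, X, starts, family, gh_x, gh_logw):
    p = X.shape[1]
    beta = theta[:p]
    disp = np.exp(theta[p])
    sb = np.exp(theta[p + 1])
    eta = X @ beta
    b = np.sqrt(2.0) * sb * gh_x  # (q,)
    ll = _obs_loglik(family, y[None, :], eta[None, :] + b[:, None], disp)  # (q, n)
    per_group = np.add.reduceat(ll, starts, axis=1)  # (q, G)
    group_ll = logsumexp(gh_logw[:, None] + per_group, axis=0)
    val = -float(group_ll.sum())
    return val if np.isfinite(val) else 1e12


def _neg_marginal_loglik_gauss(theta, y, X, starts):
    p = X.shape[1]
    beta = theta[:p]
    s2 = np.exp(2.0 * theta[p])
    sb2 = np.exp(2.0 * theta[p + 1])
    r = y - X @ beta
    sums = np.add.reduceat(r, starts)
    sq = np.add.reduceat(r * r, starts)
    n_i = np.diff(np.r_[starts, len(y)])
    denom = s2 + n_i * sb2
    quad = (sq - sb2 * sums**2 / denom) / s2
    logdet = (n_i - 1) * np.log(s2) + np.log(denom)
    val = 0.5 * float(np.sum(n_i * np.log(2 * np.pi) + logdet + quad))
    return val if np.isfinite(val) else 1e12


def _start_values(spec: ModelSpec, y, X, groups):
    """Deterministic starting values from the fixed-effect GLM."""
    if spec.family == "gamma":
        glm = sm.GLM(y, X, family=sm.families.Gamma(sm.families.links.Log()))
        res = glm.fit()
        beta0 = np.asarray(res.params, dtype=float)
        shape0 = 1.0 / max(res.scale, 1e-6)
        log_disp0 = float(np.log(np.clip(shape0, 1e-3, 1e6)))
        z = np.log(np.clip(y, 1e-12, None))
    elif spec.family == "beta":
        z = np.log(y / (1.0 - y))
        beta0, *_ = np.linalg.lstsq(X, z, rcond=None)
        mu = expit(X @ beta0)
        resid_var = max(float(np.var(y - mu)), 1e-6)
        phi0 = max(float(np.mean(mu * (1 - mu))) / resid_var - 1.0, 1.0)
        log_disp0 = float(np.log(phi0))
    else:
        beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta0
        log_disp0 = float(np.log(max(np.std(resid), 1e-6)))
        z = y
    r = z - X @ beta0
    gm = pd.Series(r).groupby(groups).mean().to_numpy()
    sb0 = float(np.clip(np.std(gm), 0.05, 5.0))
    return np.r_[beta0, log_disp0, np.log(sb0)]


def fit_mixed_model(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Fit a random-intercept mixed model by maximum likelihood.

    Deterministic given the data (fixed optimizer settings and starting
    values).  Non-convergence is flagged on the returned fit rather than
    raised, so selection can exclude it with a logged warning; a random-
    effect variance estimated at the boundary is flagged ``singular`` but the
    fit is retained.
    """
    data = data.sort_values(spec.random_intercept, kind="stable").reset_index(drop=True)
    y, X, names, groups = _design(spec, data)
    if len(np.unique(groups)) < 2:
        raise ValidationError("random intercept needs at least 2 groups")
    if spec.family == "gamma" and np.any(y <= 0):
        raise ValidationError("gamma response must be strictly positive")
    if spec.family == "beta":
        y = squeeze_unit_interval(y)
    starts = _group_bounds(groups)
    x0 = _start_values(spec, y, X, groups)

    if spec.family == "gaussian":
        def nll(theta):
            return _neg_marginal_loglik_gauss(theta, y, X, starts)
    else:
        gh_x, gh_w = np.polynomial.hermite.hermgauss(_GH_NODES)
        gh_logw = np.log(gh_w) - 0.5 * np.log(np.pi)
        def nll(theta):
            return _neg_marginal_loglik_gh(theta, y, X, starts, spec.family, gh_x, gh_logw)

    p = X.shape[1]
    bounds = [(None, None)] * p + [(-15.0, 15.0), (-10.0, 5.0)]
    res = minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    # deterministic simplex polish; helps when the BFGS line search stalls
    res2 = minimize(nll, res.x, method="Nelder-Mead",
                    options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10})
    theta = res2.x if res2.fun <= res.fun else res.x
    converged = bool(res.success or res2.success)

    loglik = -float(nll(theta))
    se = _fixed_effect_se(nll, theta, p)
    coefficients = {nm: (float(theta[i]), float(se[i])) for i, nm in enumerate(names)}
    k = p + 2  # fixed effects + dispersion/scale + random-intercept variance
    n = len(y)
    fit = ModelFit(
        spec=spec,
        coefficients=coefficients,
        loglik=loglik,
        k=k,
        n=n,
        aicc=aicc(loglik, k, n),
        dispersion=float(np.exp(theta[p])),
        random_sd=float(np.exp(theta[p + 1])),
        converged=converged,
        singular=bool(theta[p + 1] <= _SINGULAR_LOG_SD),
    )
    if not converged:
        warnings.warn(f"model {spec.formula!r} did not converge", stacklevel=2)
    return fit


def _fixed_effect_se(nll, theta, p) -> np.ndarray:
    """Standard errors from the numerically differentiated Hessian."""
    m = len(theta)
    h = 1e-4 * np.maximum(1.0, np.abs(theta))
    H = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = h[i]
            ej = np.zeros(m); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                nll(theta + ei + ej) - nll(theta + ei - ej)
                - nll(theta - ei + ej) + nll(theta - ei - ej)
            ) / (4.0 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)[:p]
        return np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)


# ---------------------------------------------------------------------------
# Model comparison


def compare_to_null(full: ModelFit, null: ModelFit) -> dict:
    """Delta AICc = AICc(null) - AICc(full) and the reporting verdict: the
    full model is supported only when Delta > 2, otherwise the null stands
    (the explanatory variable does not improve on the intercept model)."""
    if full.n != null.n:
        raise ValidationError("full and null models fit different n")
    delta = null.aicc - full.aicc
    return {
        "delta_aicc": float(delta),
        "verdict": "full_supported" if delta > 2.0 else "null_supported",
    }


def all_subset_selection(
    base_spec: ModelSpec,
    candidate_terms: tuple[str, ...],
    data: pd.DataFrame,
    averaging: str = "full",
) -> SelectionResult:
    """All-subset modeling with AICc ranking and model averaging.

    Every subset of ``candidate_terms`` (added to ``base_spec.fixed_terms``)
    is fitted; models are ranked by AICc; the Delta AICc <= 2 subset is
    retained and its coefficients are averaged with Akaike weights
    renormalized within the subset.  ``averaging="full"`` substitutes 0 for
    terms absent from a model (the zero-substitution average);
    ``averaging="conditional"`` averages only over models containing the
    term.  Non-converged candidates are excluded with a warning.
    """
    if len(candidate_terms) > 20:
        raise ValidationError("more than 20 candidate terms (2^k models)")
    fits: list[ModelFit] = []
    for r in range(len(candidate_terms) + 1):
        for combo in itertools.combinations(candidate_terms, r):
            spec = replace(base_spec, fixed_terms=tuple(base_spec.fixed_terms) + combo)
            fit = fit_mixed_model(spec, data)
            if not fit.converged:
                warnings.warn(f"excluding non-converged model {spec.formula!r}", stacklevel=2)
                continue
            fits.append(fit)
    if not fits:
        raise ConvergenceError("no candidate model converged")
    fits.sort(key=lambda f: f.aicc)
    a = np.array([f.aicc for f in fits])
    delta = a - a[0]
    weights = akaike_weights(a)
    subset = [f for f, d in zip(fits, delta) if d <= 2.0]
    w_sub = akaike_weights([f.aicc for f in subset])

    names: list[str] = []
    for f in subset:
        for nm in f.coefficients:
            if nm not in names:
                names.append(nm)
    averaged: dict[str, tuple[float, float]] = {}
    for nm in names:
        est = np.array([f.coefficients.get(nm, (0.0, 0.0))[0] for f in subset])
        ses = np.array([f.coefficients.get(nm, (0.0, 0.0))[1] for f in subset])
        present = np.array([nm in f.coefficients for f in subset])
        if averaging == "conditional":
            wc = w_sub[present] / w_sub[present].sum()
            bbar = float(wc @ est[present])
            se = float(wc @ np.sqrt(ses[present] ** 2 + (est[present] - bbar) ** 2))
        else:
            bbar = float(w_sub @ est)
            se = float(w_sub @ np.sqrt(ses**2 + (est - bbar) ** 2))
        averaged[nm] = (bbar, se)
    return SelectionResult(
        ranked=fits, delta=delta, weights=weights, subset=subset, averaged=averaged
    )


def selection_table(result: SelectionResult) -> pd.DataFrame:
    """Tabular report of an all-subset selection (formula, k, n, logLik,
    AICc, Delta AICc, Akaike weight)."""
    return pd.DataFrame(
        {
            "formula": [f.spec.formula for f in result.ranked],
            "k": [f.k for f in result.ranked],
            "n": [f.n for f in result.ranked],
            "loglik": [f.loglik for f in result.ranked],
            "aicc": [f.aicc for f in result.ranked],
            "delta_aicc": result.delta,
            "weight": result.weights,
        }
    )
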