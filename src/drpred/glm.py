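"""Gamma-family GLM head: fitting, AIC family selection, prediction intervals.

The response (IC50) is strictly positive, so three exponential-family
candidates are supported — exponential, gamma, inverse Gaussian — with a log
link by default (guaranteeing mu > 0; the canonical inverse link is also
available).  Coefficients are obtained by iteratively reweighted least
squares.  The gamma shape k is then estimated by profile maximum likelihood
given the fitted mean (Newton/bracketing on the profile score using the
digamma function), so log-likelihoods and AIC values are coherent across
families: the exponential family is exactly the gamma family with k fixed
at 1, and shares the same IRLS coefficients because the shape factors out
of the estimating equations.

Prediction intervals are plug-in central quantile intervals of the fitted
response distribution, e.g. for the gamma fit

    [ Q_gamma(alpha/2; k, mu/k),  Q_gamma(1 - alpha/2; k, mu/k) ]

Parameter-estimation uncertainty is deliberately not propagated (documented
plug-in contract).  PICP — the fraction of held-out responses falling inside
their intervals — is the interval-quality metric.

Remaining missing values at this stage are median-imputed per column (a GLM
cannot route missingness the way the boosted trees do); the imputation
medians are recorded in the fit and reused at predict time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.special
import scipy.stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import DomainWarning

from .core_data import FeatureTable, ResponseVector, logger

FAMILIES = ("exponential", "gamma", "inverse_gaussian")
LINKS = ("log", "inverse")


@dataclass
class GLMFit:
    """A fitted exponential-family GLM with likelihood bookkeeping."""

    family: str
    link: str
    beta: np.ndarray                 # intercept first
    feature_ids: list[str]           # names for beta[1:]
    shape_k: float                   # gamma shape (1 for exponential); IG: lambda
    loglik: float
    aic: float
    converged: bool
    iterations: int
    impute_medians: np.ndarray | None = None
    all_aic: dict[str, float] = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return self.beta.size + (0 if self.family == "exponential" else 1)

    def linear_predictor(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return self.beta[0] + x @ self.beta[1:]

    def predict_mu(self, x: np.ndarray) -> np.ndarray:
        eta = self.linear_predictor(x)
        if self.link == "log":
            return np.exp(eta)
        return 1.0 / eta

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "link": self.link,
            "beta": [float(b) for b in self.beta],
            "feature_ids": list(self.feature_ids),
            "shape_k": float(self.shape_k),
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "converged": bool(self.converged),
            "impute_medians": (
                None if self.impute_medians is None
                else [float(v) for v in self.impute_medians]
            ),
        }


@dataclass
class PredictionInterval:
    """Plug-in central interval for one predicted response."""

    point: float
    lower: float
    upper: float
    level: float

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must be in (0, 1)")
        if self.upper < self.lower:
            raise ValueError("upper bound below lower bound")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, y: float) -> bool:
        return self.lower <= y <= self.upper


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _check_inputs(x: np.ndarray, yv: np.ndarray, sample_ids: list[str] | None) -> None:
    bad = np.flatnonzero(~(yv > 0))
    if bad.size:
        names = [sample_ids[i] if sample_ids else str(i) for i in bad]
        raise ValueError(f"gamma-family response must be positive; offenders: {names[:10]}")
    design = np.column_stack([np.ones(x.shape[0]), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient after adding intercept")


def _profile_shape_gamma(yv: np.ndarray, mu: np.ndarray) -> float:
    """Gamma shape by profile ML: solves n(ln k + 1 - psi(k)) + S = 0 where
    S = sum(ln y - ln mu - y/mu); the score is strictly decreasing in k."""
    n = yv.size
    s = float(np.sum(np.log(yv) - np.log(mu) - yv / mu))

    def score(k):
        return n * (np.log(k) + 1.0 - scipy.special.digamma(k)) + s

    lo, hi = 1e-8, 1.0
    while score(hi) > 0 and hi < 1e12:
        hi *= 10.0
    if score(hi) > 0:  # pragma: no cover - y == mu exactly
        return hi
    return float(scipy.optimize.brentq(score, lo, hi, xtol=1e-12, rtol=1e-12))


def _loglik(family: str, yv: np.ndarray, mu: np.ndarray, shape: float) -> float:
    if family in ("gamma", "exponential"):
        return float(scipy.stats.gamma.logpdf(yv, a=shape, scale=mu / shape).sum())
    # inverse Gaussian with shape = lambda
    lam = shape
    return float(
        np.sum(
            0.5 * np.log(lam / (2.0 * np.pi * yv**3))
            - lam * (yv - mu) ** 2 / (2.0 * mu**2 * yv)
        )
    )


def _family_funcs(family: str, link: str):
    """Variance function, deviance and link derivatives for damped IRLS."""
    if family in ("gamma", "exponential"):
        variance = lambda mu: mu**2
        deviance = lambda y, mu: 2.0 * np.sum(-np.log(y / mu) + (y - mu) / mu)
    else:
        variance = lambda mu: mu**3
        deviance = lambda y, mu: np.sum((y - mu) ** 2 / (mu**2 * y))
    if link == "log":
        inv_link = np.exp
        link_deriv = lambda mu: 1.0 / mu
    else:
        inv_link = lambda eta: 1.0 / eta
        link_deriv = lambda mu: -1.0 / mu**2
    return variance, deviance, inv_link, link_deriv


def _damped_irls(
    design: np.ndarray, yv: np.ndarray, family: str, link: str,
    start: np.ndarray, max_iter: int, tol: float,
) -> tuple[np.ndarray, bool, int]:
    """IRLS with step halving: a plain Fisher-scoring update can enter a
    period-2 limit cycle on near-saturated fits; halving the step whenever
    the deviance would increase restores monotone convergence."""
    variance, deviance, inv_link, link_deriv = _family_funcs(family, link)
    beta = start.copy()
    eta = design @ beta
    mu = inv_link(eta)
    dev = deviance(yv, mu)
    for it in range(1, max_iter + 1):
        d = link_deriv(mu)
        z = eta + (yv - mu) * d
        w = 1.0 / (variance(mu) * d**2)
        wsqrt = np.sqrt(w)
        beta_prop, *_ = np.linalg.lstsq(
            design * wsqrt[:, None], z * wsqrt, rcond=None
        )
        step = 1.0
        for _ in range(30):
            cand = beta + step * (beta_prop - beta)
            mu_c = inv_link(design @ cand)
            if np.all(np.isfinite(mu_c)) and np.all(mu_c > 0):
                dev_c = deviance(yv, mu_c)
                if np.isfinite(dev_c) and dev_c <= dev + 1e-12:
                    break
            step /= 2.0
        else:
            return beta, False, it
        beta = cand
        eta = design @ beta
        mu = inv_link(eta)
        if abs(dev - dev_c) <= tol * (abs(dev_c) + 0.1):
            return beta, True, it
        dev = dev_c
    return beta, False, max_iter


def fit_glm(
    x: np.ndarray | FeatureTable,
    y: np.ndarray | ResponseVector,
    family: str = "gamma",
    link: str = "log",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> GLMFit:
    """Fit one exponential-family GLM by IRLS and profile-ML shape.

    The design must be full column rank after adding an intercept.  Missing
    feature values are median-imputed (medians recorded in the fit).
    Non-convergence is flagged on the returned fit, not silently ignored.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    if link not in LINKS:
        raise ValueError(f"link must be one of {LINKS}")
    if isinstance(x, FeatureTable):
        feature_ids = list(x.feature_ids)
        xv, medians = impute_median(x.values)
    else:
        xv = np.asarray(x, dtype=float)
        feature_ids = [f"x{j}" for j in range(xv.shape[1])]
        if np.isnan(xv).any():
            xv, medians = impute_median(xv)
        else:
            medians = None
    sample_ids = y.sample_ids if isinstance(y, ResponseVector) else None
    yv = y.values if isinstance(y, ResponseVector) else np.asarray(y, dtype=float)
    _check_inputs(xv, yv, sample_ids)

    sm_link = sm.families.links.Log() if link == "log" else sm.families.links.InversePower()
    if family in ("gamma", "exponential"):
        sm_family = sm.families.Gamma(link=sm_link)
    else:
        sm_family = sm.families.InverseGaussian(link=sm_link)
    design = sm.add_constant(xv, has_constant="add")
    # warm start from least squares on the link-transformed response,
    # which keeps IRLS for the non-canonical links in a stable region
    gy = np.log(yv) if link == "log" else 1.0 / yv
    start, *_ = np.linalg.lstsq(design, gy, rcond=None)
    try:
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore", DomainWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            model = sm.GLM(yv, design, family=sm_family)
            res = model.fit(maxiter=max_iter, tol=tol, start_params=start)
        converged = bool(getattr(res, "converged", True))
        dev = getattr(res, "fit_history", {}).get("deviance", [])
        if not converged and len(dev) >= 2:
            # the stopping rule above is absolute; accept relative convergence
            rel = abs(dev[-1] - dev[-2]) / (abs(dev[-1]) + 0.1)
            converged = rel <= tol
        iterations = len(dev) or max_iter
        beta = np.asarray(res.params, dtype=float)
    except (ValueError, np.linalg.LinAlgError) as exc:
        # infeasible Fisher-scoring step (weights blew up mid-iteration)
        logger.warning("plain IRLS failed (%s); retrying with step halving", exc)
        converged, iterations, beta = False, 0, start
    if not converged:
        # plain Fisher scoring can limit-cycle or diverge on near-saturated
        # fits; damped IRLS restores monotone convergence
        beta2, ok, it2 = _damped_irls(design, yv, family, link, beta, max_iter, tol)
        if ok:
            logger.info("damped IRLS recovered convergence in %d steps", it2)
            beta, converged = beta2, True
            iterations += it2
    if not converged:
        logger.warning("IRLS did not converge in %d iterations (%s)", max_iter, family)
    eta = design @ beta
    mu = np.exp(eta) if link == "log" else 1.0 / eta
    if family == "gamma":
        shape = _profile_shape_gamma(yv, mu)
    elif family == "exponential":
        shape = 1.0
    else:  # inverse Gaussian: MLE of lambda given mu
        shape = float(1.0 / np.mean((yv - mu) ** 2 / (mu**2 * yv)))
    ll = _loglik(family, yv, mu, shape)
    p = beta.size + (0 if family == "exponential" else 1)
    aic = 2.0 * p - 2.0 * ll
    return GLMFit(
        family=family, link=link, beta=beta, feature_ids=feature_ids,
        shape_k=shape, loglik=ll, aic=aic, converged=converged,
        iterations=int(iterations), impute_medians=medians,
    )


def impute_median(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Median-impute NaNs per column; all-missing columns fill with 0."""
    x = np.asarray(x, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(x, axis=0)
    med = np.nan_to_num(med, nan=0.0)
    out = np.where(np.isnan(x), med, x)
    return out, med


def select_family_by_aic(
    x: np.ndarray | FeatureTable,
    y: np.ndarray | ResponseVector,
    candidates: tuple[str, ...] = FAMILIES,
    link: str = "log",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> GLMFit:
    """Fit every candidate family and return the minimum-AIC fit.

    Candidates that fail or do not converge are excluded with a warning; the
    winning fit carries all candidate AICs in ``all_aic``.
    """
    fits: dict[str, GLMFit] = {}
    for fam in candidates:
        try:
            fit = fit_glm(x, y, family=fam, link=link, max_iter=max_iter, tol=tol)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("family %s failed: %s", fam, exc)
            continue
        if not fit.converged:
            logger.warning("family %s excluded: IRLS did not converge", fam)
            continue
        fits[fam] = fit
    if not fits:
        raise ValueError("no candidate family converged")
    aics = {fam: f.aic for fam, f in fits.items()}
    logger.info("AIC by family: %s", {k: round(v, 3) for k, v in aics.items()})
    best = min(fits.values(), key=lambda f: f.aic)
    best.all_aic = aics
    return best


# ---------------------------------------------------------------------------
# Prediction intervals and PICP
# ---------------------------------------------------------------------------

def _response_dist(fit: GLMFit, mu: np.ndarray):
    if fit.family in ("gamma", "exponential"):
        return scipy.stats.gamma(a=fit.shape_k, scale=mu / fit.shape_k)
    lam = fit.shape_k
    return scipy.stats.invgauss(mu / lam, scale=lam)


def prediction_intervals(
    fit: GLMFit, x_new: np.ndarray | FeatureTable, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized plug-in intervals: (point, lower, upper) arrays."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if isinstance(x_new, FeatureTable):
        xv = x_new.values
    else:
        xv = np.atleast_2d(np.asarray(x_new, dtype=float))
    if np.isnan(xv).any():
        med = fit.impute_medians
        if med is None:
            med = np.zeros(xv.shape[1])
        xv = np.where(np.isnan(xv), med, xv)
    mu = fit.predict_mu(xv)
    alpha = 1.0 - level
    dist = _response_dist(fit, mu)
    return mu, dist.ppf(alpha / 2.0), dist.ppf(1.0 - alpha / 2.0)


def prediction_interval(
    fit: GLMFit, x_new: np.ndarray, level: float = 0.95
) -> PredictionInterval:
    """Plug-in central interval for a single feature row."""
    point, lo, hi = prediction_intervals(fit, np.atleast_2d(x_new), level)
    return PredictionInterval(
        point=float(point[0]), lower=float(lo[0]), upper=float(hi[0]), level=level
    )


def picp(
    intervals: list[PredictionInterval] | tuple[np.ndarray, np.ndarray],
    y_true: np.ndarray,
) -> float:
    """Prediction interval coverage probability: fraction of truths inside
    their (closed) intervals."""
    y_true = np.asarray(y_true, dtype=float)
    if y_true.size == 0:
        raise ValueError("empty input to picp")
    if isinstance(intervals, (list, tuple)) and intervals and isinstance(
        intervals[0], PredictionInterval
    ):
        lo = np.array([iv.lower for iv in intervals])
        hi = np.array([iv.upper for iv in intervals])
    else:
        lo, hi = (np.asarray(a, dtype=float) for a in intervals)
    if lo.shape != y_true.shape or hi.shape != y_true.shape:
        raise ValueError("intervals and y_true lengths differ")
    return float(np.mean((lo <= y_true) & (y_true <= hi)))
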