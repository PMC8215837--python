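"""Univariable two-sample MR estimators.

All estimators consume per-variant Wald ratios theta_j = beta_Yj / beta_Xj
with standard errors sigma_j and inverse-variance weights w_j = sigma_j^-2,
or the harmonized effect matrices directly (Egger).  Implemented methods:

* fixed-effect and multiplicative-random-effects inverse-variance
  weighted (IVW) meta-analysis of the ratios;
* MR-Egger weighted regression with an unconstrained intercept that
  absorbs directional pleiotropy under the InSIDE assumption;
* the weighted median, consistent when valid instruments carry a
  majority of the weight;
* the mode-based estimate (weighted kernel density argmax), consistent
  under the zero-modal-pleiotropy assumption;
* heterogeneity-penalized reweighting that downweights variants with
  outlying ratios.

Standard errors for the median and mode come from a seeded parametric
bootstrap; all p-values are two-sided normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .sumstats import AnalysisError, HarmonizedSet, InputError

__all__ = [
    "RatioEstimates",
    "MREstimate",
    "wald_ratios",
    "ivw",
    "egger",
    "weighted_median",
    "mode_based",
    "penalized_weights",
]

Z95 = stats.norm.ppf(0.975)


@dataclass
class RatioEstimates:
    """Per-variant Wald ratios theta_j, their SEs sigma_j, and weights."""

    variant_ids: list
    theta: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.variant_ids) == self.theta.size == self.sigma.size):
            raise InputError("variant_ids, theta and sigma must have equal length")
        if np.any(self.sigma <= 0):
            raise InputError("all ratio SEs must be positive")

    @property
    def weights(self) -> np.ndarray:
        return self.sigma**-2

    def __len__(self) -> int:
        return self.theta.size


@dataclass
class MREstimate:
    """A causal estimate with its uncertainty and diagnostics."""

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_variants: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pvalue: float | None = None
    heterogeneity_Q: float | None = None
    seed: int | None = None
    notes: str = ""

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "theta": self.theta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "n_variants": self.n_variants,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "Q": self.heterogeneity_Q,
            "seed": self.seed,
            "notes": self.notes,
        }


def _wald(method, theta, se, n_variants, **kw) -> MREstimate:
    theta, se = float(theta), float(se)
    p = float(2 * stats.norm.sf(abs(theta) / se)) if se > 0 else (0.0 if theta else 1.0)
    return MREstimate(
        method=method,
        theta=theta,
        se=se,
        ci_low=theta - Z95 * se,
        ci_high=theta + Z95 * se,
        pvalue=p,
        n_variants=int(n_variants),
        **kw,
    )


def wald_ratios(
    h: HarmonizedSet, exposure_index: int = 0, se_order: str = "first"
) -> RatioEstimates:
    """Per-variant ratio estimates for one exposure.

    First-order SE is se_Y/|beta_X| (exposure uncertainty ignored);
    second-order adds the delta-method term beta_Y^2 se_X^2 / beta_X^4.
    """
    bx = h.beta_exp[:, exposure_index]
    sx = h.se_exp[:, exposure_index]
    zero = np.flatnonzero(bx == 0)
    if zero.size:
        raise InputError(
            f"zero exposure beta for variant(s) {[h.variant_ids[i] for i in zero[:5]]}"
        )
    theta = h.beta_out / bx
    if se_order == "first":
        sigma = h.se_out / np.abs(bx)
    elif se_order == "second":
        sigma = np.sqrt(h.se_out**2 / bx**2 + h.beta_out**2 * sx**2 / bx**4)
    else:
        raise InputError(f"se_order must be 'first' or 'second', got {se_order!r}")
    return RatioEstimates(list(h.variant_ids), theta, sigma)


def ivw(r: RatioEstimates, model: str = "fixed") -> MREstimate:
    """Inverse-variance weighted combination of Wald ratios.

    Fixed-effect SE is (sum w_j)^(-1/2).  The multiplicative
    random-effects model inflates it by max(1, sqrt(Q/(J-1))) where Q is
    Cochran's heterogeneity statistic.
    """
    J = len(r)
    if J == 0:
        raise AnalysisError("IVW requires at least one variant")
    if model not in ("fixed", "multiplicative_random"):
        raise InputError(f"unknown IVW model {model!r}")
    if model == "multiplicative_random" and J < 2:
        raise AnalysisError("random-effects IVW requires at least two variants")
    w = r.weights
    theta = float(np.sum(w * r.theta) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    Q = float(np.sum(w * (r.theta - theta) ** 2))
    if model == "multiplicative_random":
        se *= max(1.0, np.sqrt(Q / (J - 1)))
    return _wald(f"ivw_{model}" if model != "fixed" else "ivw", theta, se, J,
                 heterogeneity_Q=Q)


def egger(h: HarmonizedSet, exposure_index: int = 0) -> MREstimate:
    """MR-Egger: weighted regression of beta_Y on beta_X with intercept.

    Variants are oriented so beta_X > 0; weights are se_Y^-2.  The slope
    is the causal estimate and the intercept the average directional
    pleiotropic effect.  SEs use multiplicative scaling max(1, RSE).
    """
    import statsmodels.api as sm

    J = h.n_variants
    if J < 3:
        raise AnalysisError(f"MR-Egger requires at least 3 variants, got {J}")
    bx = h.beta_exp[:, exposure_index].copy()
    by = h.beta_out.copy()
    flip = bx < 0
    bx[flip] *= -1
    by[flip] *= -1
    if np.ptp(bx) == 0:
        raise AnalysisError("zero spread in exposure betas: Egger design is singular")
    w = h.se_out**-2.0
    fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
    # statsmodels scales the covariance by the residual variance estimate;
    # the MR-Egger convention never deflates below the fixed-effect SE
    scale = max(1.0, np.sqrt(fit.scale))
    base_se = fit.bse / np.sqrt(fit.scale)
    inter_se, slope_se = base_se * scale
    inter, slope = fit.params
    Q = float(fit.scale * fit.df_resid)
    est = _wald(
        "egger", slope, slope_se, J,
        intercept=float(inter),
        intercept_se=float(inter_se),
        heterogeneity_Q=Q,
    )
    est.intercept_pvalue = float(2 * stats.norm.sf(abs(inter) / inter_se))
    return est


def _median_interp(theta: np.ndarray, w: np.ndarray) -> float:
    """Weighted median via standardized cumulative-weight percentiles."""
    order = np.argsort(theta, kind="mergesort")
    t, wt = theta[order], w[order]
    S = np.cumsum(wt)
    p = 100.0 * (S - wt / 2.0) / S[-1]
    return float(np.interp(50.0, p, t))


def weighted_median(
    r: RatioEstimates, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted median of the ratio estimates; SE by parametric bootstrap."""
    J = len(r)
    if J < 3:
        raise AnalysisError(f"weighted median requires at least 3 variants, got {J}")
    est = _median_interp(r.theta, r.weights)
    rng = np.random.default_rng(seed)
    draws = rng.normal(r.theta, r.sigma, size=(n_boot, J))
    boot = np.array([_median_interp(d, r.weights) for d in draws])
    se = float(boot.std(ddof=1))
    if se == 0:
        se = 1e-12  # degenerate distribution; keep the Wald machinery well-defined
    out = _wald("weighted_median", est, se, J, seed=seed)
    return out


def _silverman_bandwidth(theta: np.ndarray, phi: float) -> float:
    """Modified Silverman rule: 0.9 * min(sd, MAD/0.6745) * J^(-1/5), times phi."""
    J = theta.size
    sd = theta.std(ddof=1) if J > 1 else 0.0
    mad = np.median(np.abs(theta - np.median(theta))) / 0.6745
    spread = min(x for x in (sd, mad) if x > 0) if (sd > 0 or mad > 0) else 0.0
    return phi * 0.9 * spread * J ** (-1 / 5)


def _kde_argmax(theta: np.ndarray, w: np.ndarray, hband: float, grid: np.ndarray) -> float:
    dens = np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / hband) ** 2) @ (w / w.sum())
    # ties at the maximum resolve to the smaller grid value
    return float(grid[int(np.argmax(dens))])


def mode_based(
    r: RatioEstimates,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    grid_size: int = 512,
) -> MREstimate:
    """Mode-based estimate: argmax of the weighted kernel density of ratios.

    Normal kernel, bandwidth ``phi`` times the modified Silverman rule,
    evaluated on a fixed grid spanning [min theta - 3 max sigma,
    max theta + 3 max sigma].  SE by parametric bootstrap.
    """
    J = len(r)
    if J < 3:
        raise AnalysisError(f"mode-based estimate requires at least 3 variants, got {J}")
    w = r.weights
    lo = r.theta.min() - 3 * r.sigma.max()
    hi = r.theta.max() + 3 * r.sigma.max()
    grid = np.linspace(lo, hi, grid_size)
    tiny = 1e-10 * max(1.0, float(np.max(np.abs(r.theta))))
    hband = _silverman_bandwidth(r.theta, phi)
    rng = np.random.default_rng(seed)
    if hband <= tiny:
        # all ratios identical: the mode is that common value
        est = float(r.theta[0])
        boot = rng.normal(r.theta, r.sigma, size=(n_boot, J)).mean(axis=1)
        se = float(boot.std(ddof=1))
        return _wald("mode_based", est, se, J, seed=seed, notes="zero bandwidth")
    est = _kde_argmax(r.theta, w, hband, grid)
    draws = rng.normal(r.theta, r.sigma, size=(n_boot, J))
    boot = np.empty(n_boot)
    for b in range(n_boot):
        d = draws[b]
        hb = _silverman_bandwidth(d, phi)
        g = np.linspace(d.min() - 3 * r.sigma.max(), d.max() + 3 * r.sigma.max(), grid_size)
        boot[b] = _kde_argmax(d, w, hb if hb > tiny else hband, g)
    se = float(boot.std(ddof=1))
    return _wald("mode_based", est, se, J, seed=seed)


def penalized_weights(r: RatioEstimates, theta_ref: float, penalty: float = 20.0) -> RatioEstimates:
    """Downweight heterogeneous variants relative to a reference estimate.

    Each variant's contribution Q_j = w_j (theta_j - theta_ref)^2 is
    referred to chi-square(1); weights are multiplied by min(1, penalty * q_j)
    so only variants with upper-tail probability q_j < 1/penalty are
    penalized.  Returns new RatioEstimates with sigma recomputed from the
    penalized weights.
    """
    if not np.isfinite(theta_ref):
        raise InputError("theta_ref must be finite")
    Qj = r.weights * (r.theta - theta_ref) ** 2
    qj = stats.chi2.sf(Qj, df=1)
    w_new = r.weights * np.minimum(1.0, penalty * qj)
    w_new = np.maximum(w_new, 1e-300)  # keep sigma finite for extreme outliers
    return RatioEstimates(list(r.variant_ids), r.theta.copy(), w_new**-0.5)


def estimator_battery(
    h: HarmonizedSet,
    exposure_index: int = 0,
    seed: int = 0,
    n_boot: int = 1000,
    se_order: str = "first",
) -> list[MREstimate]:
    """IVW, Egger, weighted median, mode-based and penalized IVW on one set."""
    r = wald_ratios(h, exposure_index, se_order=se_order)
    out = [ivw(r)]
    if len(r) >= 3:
        out.append(egger(h, exposure_index))
        out.append(weighted_median(r, n_boot=n_boot, seed=seed))
        out.append(mode_based(r, n_boot=n_boot, seed=seed + 1))
        pen = penalized_weights(r, out[0].theta)
        pen_est = ivw(pen)
        pen_est.method = "ivw_penalized"
        out.append(pen_est)
    return out
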