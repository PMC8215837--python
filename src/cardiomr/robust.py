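"""Outlier detection and pleiotropy-robust re-estimation.

Two procedures produce the "altered instrument sets" used in sensitivity
analyses:

* a residual-sum-of-squares outlier scan in the spirit of MR-PRESSO:
  each variant's RSS against its leave-one-out IVW prediction is
  referred to a parametric-simulation null, globally and per variant;
* a contamination-mixture estimator: each variant is either valid
  (ratio ~ Normal(theta, sigma_j^2)) or invalid (ratio ~ Normal(0,
  sigma_j^2 + psi^2)); profiling the assignment over a theta grid gives
  a point estimate, a profile-likelihood CI and the valid set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, RatioEstimates, estimator_battery, wald_ratios
from .sumstats import AnalysisError, HarmonizedSet, InputError

__all__ = ["OutlierReport", "ConmixResult", "presso", "conmix", "refit_after_exclusion"]

CHI2_1_95 = stats.chi2.ppf(0.95, df=1) / 2.0  # 1.92 profile-likelihood cutoff


@dataclass
class OutlierReport:
    global_rss: float
    global_pvalue: float
    per_variant: pd.DataFrame  # variant_id, rss, pvalue, flagged
    n_sim: int
    seed: int
    outlier_threshold: float

    @property
    def flagged_ids(self) -> list:
        return list(self.per_variant.loc[self.per_variant["flagged"], "variant_id"])


@dataclass
class ConmixResult:
    theta: float
    ci_low: float
    ci_high: float
    se: float
    valid_ids: list
    psi: float
    grid: np.ndarray
    profile: np.ndarray
    multimodal_ci: bool = False


def _loo_ivw(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slope for each variant, vectorized.

    IVW of ratios theta_j = by/bx with weights w = (se_Y/|bx|)^-2 equals
    the origin-constrained weighted regression sum(v*bx*by)/sum(v*bx^2)
    with v = se_Y^-2; the identity lets the LOO estimates come from
    totals.
    """
    num = w * (by / bx)  # w_j * theta_j
    tot_num, tot_den = num.sum(), w.sum()
    return (tot_num - num) / (tot_den - w)


def presso(
    h: HarmonizedSet,
    exposure_index: int = 0,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> OutlierReport:
    """Residual-sum-of-squares outlier scan with a simulated null.

    Observed rss_j = (beta_Yj - theta_loo(-j) * beta_Xj)^2.  The null is
    built by drawing beta*_X ~ N(beta_X, se_X) and beta*_Y ~
    N(theta_loo(-j) * beta_X, se_Y) and recomputing the statistic
    ``n_sim`` times.  Empirical p-values use the (r+1)/(n+1) correction;
    per-variant flags apply a Bonferroni threshold ``outlier_alpha``/J.
    """
    J = h.n_variants
    if J < 4:
        raise AnalysisError(f"outlier scan requires at least 4 variants, got {J}")
    bx = h.beta_exp[:, exposure_index]
    sx = h.se_exp[:, exposure_index]
    by, sy = h.beta_out, h.se_out
    w = (sy / np.abs(bx)) ** -2.0

    theta_loo = _loo_ivw(bx, by, w)
    rss_obs = (by - theta_loo * bx) ** 2
    global_obs = float(rss_obs.sum())

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx, sx, size=(n_sim, J))
    by_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, J))
    w_sim = (sy / np.abs(bx_sim)) ** -2.0
    num = w_sim * (by_sim / bx_sim)
    loo_sim = (num.sum(axis=1, keepdims=True) - num) / (
        w_sim.sum(axis=1, keepdims=True) - w_sim
    )
    rss_sim = (by_sim - loo_sim * bx_sim) ** 2
    global_sim = rss_sim.sum(axis=1)

    global_p = (np.sum(global_sim >= global_obs) + 1.0) / (n_sim + 1.0)
    pv = (np.sum(rss_sim >= rss_obs[None, :], axis=0) + 1.0) / (n_sim + 1.0)
    threshold = outlier_alpha / J
    per = pd.DataFrame(
        dict(
            variant_id=list(h.variant_ids),
            rss=rss_obs,
            pvalue=pv,
            flagged=pv < threshold,
        )
    )
    return OutlierReport(
        global_rss=global_obs,
        global_pvalue=float(global_p),
        per_variant=per,
        n_sim=n_sim,
        seed=seed,
        outlier_threshold=threshold,
    )


def conmix(
    r: RatioEstimates,
    psi: float | None = None,
    grid_points: int = 401,
) -> ConmixResult:
    """Contamination-mixture causal estimate over a theta grid.

    Each variant contributes the larger of its valid log-density
    N(theta_j; theta, sigma_j^2) and invalid log-density N(theta_j; 0,
    sigma_j^2 + psi^2); the profile log-likelihood is the per-variant
    maximum summed over variants.  Default psi is 1.5 x SD of the ratios.
    The 95% CI collects grid points within 1.92 log-likelihood units of
    the maximum; a disjoint CI is reported as its convex hull with
    ``multimodal_ci`` set.
    """
    J = len(r)
    if J < 3:
        raise AnalysisError(f"contamination mixture requires at least 3 variants, got {J}")
    theta_j, sigma_j = r.theta, r.sigma
    spread = float(theta_j.std(ddof=1))
    if psi is None:
        psi = 1.5 * spread
    if spread <= 1e-12 * max(1.0, float(np.max(np.abs(theta_j)))):
        common = float(theta_j[0])
        grid = np.array([common])
        return ConmixResult(
            theta=common, ci_low=common, ci_high=common, se=0.0,
            valid_ids=list(r.variant_ids), psi=float(psi), grid=grid,
            profile=np.zeros(1),
        )
    smax = sigma_j.max()
    grid = np.linspace(theta_j.min() - 2 * smax, theta_j.max() + 2 * smax, grid_points)
    ll_valid = stats.norm.logpdf(theta_j[None, :], loc=grid[:, None], scale=sigma_j[None, :])
    ll_invalid = stats.norm.logpdf(theta_j, loc=0.0, scale=np.sqrt(sigma_j**2 + psi**2))
    per = np.maximum(ll_valid, ll_invalid[None, :])
    profile = per.sum(axis=1)
    imax = int(np.argmax(profile))
    theta_hat = float(grid[imax])
    valid_mask = ll_valid[imax] >= ll_invalid
    valid_ids = [v for v, m in zip(r.variant_ids, valid_mask) if m]

    inside = profile >= profile[imax] - CHI2_1_95
    idx = np.flatnonzero(inside)
    ci_low, ci_high = float(grid[idx[0]]), float(grid[idx[-1]])
    multimodal = bool(np.any(np.diff(idx) > 1))
    se = (ci_high - ci_low) / (2 * stats.norm.ppf(0.975))
    return ConmixResult(
        theta=theta_hat, ci_low=ci_low, ci_high=ci_high, se=float(se),
        valid_ids=valid_ids, psi=float(psi), grid=grid, profile=profile,
        multimodal_ci=multimodal,
    )


def conmix_estimate(result: ConmixResult, n_variants: int) -> MREstimate:
    """Package a ConmixResult as an MREstimate (p from the CI-implied SE)."""
    se = result.se if result.se > 0 else 1e-12
    p = float(2 * stats.norm.sf(abs(result.theta) / se))
    return MREstimate(
        method="conmix",
        theta=result.theta,
        se=se,
        ci_low=result.ci_low,
        ci_high=result.ci_high,
        pvalue=p,
        n_variants=n_variants,
        notes="multimodal CI hull" if result.multimodal_ci else "",
    )


def refit_after_exclusion(
    h: HarmonizedSet,
    exposure_index: int = 0,
    excluded=(),
    seed: int = 0,
    n_boot: int = 1000,
) -> dict:
    """Re-run the estimator battery after excluding flagged variants.

    Returns ``{"excluded": [...], "estimates": [MREstimate, ...]}`` with
    each estimate's notes tagged with the exclusion provenance.
    """
    excluded = list(excluded)
    if excluded:
        h = h.exclude(excluded, reason="sensitivity_exclusion")
    if h.n_variants < 3:
        raise AnalysisError(
            f"only {h.n_variants} variants remain after exclusion; need >= 3"
        )
    ests = estimator_battery(h, exposure_index, seed=seed, n_boot=n_boot)
    tag = f"excluded={','.join(excluded)}" if excluded else "no exclusions"
    for e in ests:
        e.notes = (e.notes + "; " if e.notes else "") + tag
    return {"excluded": excluded, "estimates": ests}
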