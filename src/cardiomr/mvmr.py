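"""Multivariable MR and the mediation/attenuation decomposition.

Multivariable MR regresses the variant-outcome associations jointly on
several exposures' variant associations (weighted by se_Y^-2, no
intercept), giving each exposure's conditional (direct) causal effect.
A residualized variant regresses the outcome associations on the
non-target exposures first and uses the residuals as the outcome; with
the target column residualized too this reproduces the joint coefficient
exactly (Frisch-Waugh-Lovell).

Mediation follows the difference method: indirect = total (univariable
IVW, the C path) minus direct (mediator-adjusted MVMR, the C' path),
with percent mediated 100 * indirect / total.  The difference is only
called mediation when both the exposure->mediator (A) and the
mediator->outcome (B) paths are themselves supported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .estimators import MREstimate, ivw, wald_ratios
from .sumstats import AnalysisError, HarmonizedSet, InputError

__all__ = [
    "MVMRResult",
    "MediationResult",
    "mvmr_joint",
    "mvmr_residualized",
    "mediation",
    "attenuation_table",
]


@dataclass
class MVMRResult:
    exposures: list
    theta: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    variant_count: int
    approach: str  # "joint" or "residualized"

    def coefficient(self, exposure: str) -> tuple[float, float, float]:
        i = self.exposures.index(exposure)
        return float(self.theta[i]), float(self.se[i]), float(self.pvalues[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(exposure=self.exposures, theta=self.theta, se=self.se,
                 pvalue=self.pvalues, n_variants=self.variant_count,
                 approach=self.approach)
        )


def _check_design(X: np.ndarray, names) -> None:
    J, K = X.shape
    if J <= K:
        raise AnalysisError(f"MVMR needs more variants than exposures (J={J}, K={K})")
    rank = np.linalg.matrix_rank(X)
    if rank < K:
        raise AnalysisError(
            f"exposure beta matrix is rank deficient (rank {rank} < K={K}); "
            f"collinear exposures among {list(names)}"
        )


def mvmr_joint(h: HarmonizedSet) -> MVMRResult:
    """Joint weighted regression of outcome betas on all exposure betas.

    No intercept; weights se_Y^-2; SEs from the WLS covariance with
    multiplicative scaling max(1, residual standard error).
    """
    X, y = h.beta_exp, h.beta_out
    _check_design(X, h.exposure_names)
    w = h.se_out**-2.0
    fit = sm.WLS(y, X, weights=w).fit()
    scale = max(1.0, np.sqrt(fit.scale))
    se = fit.bse / np.sqrt(fit.scale) * scale
    theta = np.asarray(fit.params, dtype=float)
    se = np.asarray(se, dtype=float)
    p = 2 * stats.norm.sf(np.abs(theta) / se)
    return MVMRResult(
        exposures=list(h.exposure_names),
        theta=theta, se=se, pvalues=p,
        variant_count=h.n_variants, approach="joint",
    )


def mvmr_residualized(
    h: HarmonizedSet, target_exposure: int = 0, residualize_target: bool = False
) -> MVMRResult:
    """Residual-outcome MVMR for one target exposure.

    The outcome betas are regressed (weighted, no intercept) on the
    non-target exposure columns and the residuals become the outcome for
    an origin-constrained weighted regression on the target column.  With
    ``residualize_target`` the target column is residualized on the same
    covariates first, which makes the coefficient identical to the joint
    fit (Frisch-Waugh-Lovell); without it, the estimate matches the
    description of regressing risk factors separately and using residuals.
    """
    X, y = h.beta_exp, h.beta_out
    _check_design(X, h.exposure_names)
    K = X.shape[1]
    if not 0 <= target_exposure < K:
        raise InputError(f"target_exposure {target_exposure} out of range for K={K}")
    others = [k for k in range(K) if k != target_exposure]
    w = h.se_out**-2.0
    sw = np.sqrt(w)
    if others:
        Z = X[:, others]
        # weighted projection onto the covariate columns
        Zw, yw = Z * sw[:, None], y * sw
        coef, *_ = np.linalg.lstsq(Zw, yw, rcond=None)
        y_res = y - Z @ coef
        x = X[:, target_exposure]
        if residualize_target:
            cx, *_ = np.linalg.lstsq(Zw, x * sw, rcond=None)
            x = x - Z @ cx
    else:
        y_res, x = y, X[:, target_exposure]
    fit = sm.WLS(y_res, x, weights=w).fit()
    scale = max(1.0, np.sqrt(fit.scale))
    se = float(fit.bse[0] / np.sqrt(fit.scale) * scale)
    theta = float(fit.params[0])
    p = float(2 * stats.norm.sf(abs(theta) / se))
    return MVMRResult(
        exposures=[h.exposure_names[target_exposure]],
        theta=np.array([theta]), se=np.array([se]), pvalues=np.array([p]),
        variant_count=h.n_variants, approach="residualized",
    )


@dataclass
class MediationResult:
    exposure: str
    mediator: str
    outcome: str
    total_effect: float      # C path: univariable IVW exposure -> outcome
    direct_effect: float     # C' path: MVMR coefficient adjusting for mediator
    indirect_effect: float   # C - C'
    percent_mediated: float | None
    a_path_pvalue: float
    b_path_pvalue: float
    qualifies_as_mediation: bool

    @property
    def label(self) -> str:
        return "mediation" if self.qualifies_as_mediation else "attenuation"


def mediation(
    h_exposure_outcome: HarmonizedSet,
    h_exposure_mediator: HarmonizedSet,
    h_joint: HarmonizedSet,
    alpha: float = 0.05,
) -> MediationResult:
    """Difference-method mediation decomposition.

    total = univariable IVW of the exposure on the outcome; direct = the
    exposure's coefficient in the mediator-adjusted MVMR; indirect =
    total - direct.  The A path is the exposure's univariable IVW on the
    mediator; the B path is the mediator's conditional (MVMR) effect on
    the outcome given the exposure.  Both must reach ``alpha`` for the
    difference to qualify as mediation rather than attenuation.
    """
    exposure = h_exposure_outcome.exposure_names[0]
    if exposure not in h_joint.exposure_names:
        raise InputError(f"joint set lacks exposure column {exposure!r}")
    mediator = h_exposure_mediator.outcome_name
    if mediator not in h_joint.exposure_names:
        raise InputError(f"joint set lacks mediator column {mediator!r}")

    total = ivw(wald_ratios(h_exposure_outcome, 0))
    joint = mvmr_joint(h_joint)
    direct, _, _ = joint.coefficient(exposure)
    _, _, b_p = joint.coefficient(mediator)
    a_est = ivw(wald_ratios(h_exposure_mediator, 0))

    indirect = total.theta - direct
    percent = None
    if abs(total.theta) > 1e-12:
        percent = 100.0 * indirect / total.theta
    qualifies = (a_est.pvalue < alpha) and (b_p < alpha)
    return MediationResult(
        exposure=exposure,
        mediator=mediator,
        outcome=h_exposure_outcome.outcome_name,
        total_effect=float(total.theta),
        direct_effect=float(direct),
        indirect_effect=float(indirect),
        percent_mediated=percent,
        a_path_pvalue=float(a_est.pvalue),
        b_path_pvalue=float(b_p),
        qualifies_as_mediation=bool(qualifies),
    )


def attenuation_table(
    base: MREstimate,
    adjusted: list,
    labels: list | None = None,
    mediation_flags: list | None = None,
    exposure: str = "",
    outcome: str = "",
) -> pd.DataFrame:
    """Attenuation of a base (univariable IVW) estimate across adjusted models.

    One row per adjusted model with the absolute and percent change from
    the base estimate; a model covering all covariates at once should be
    supplied last (the full model).  ``adjusted`` holds MVMRResults whose
    first coefficient is the exposure of interest.
    """
    rows = [
        dict(exposure=exposure, outcome=outcome, model="base",
             theta=base.theta, se=base.se, pvalue=base.pvalue,
             abs_change=0.0, pct_change=0.0, mediation_flag=False)
    ]
    labels = labels or [f"+{'/'.join(a.exposures[1:]) or a.exposures[0]}" for a in adjusted]
    flags = mediation_flags or [False] * len(adjusted)
    for res, lab, flag in zip(adjusted, labels, flags):
        th, se, p = res.theta[0], res.se[0], res.pvalues[0]
        change = th - base.theta
        pct = 100.0 * change / base.theta if base.theta != 0 else np.nan
        rows.append(
            dict(exposure=exposure, outcome=outcome, model=lab,
                 theta=float(th), se=float(se), pvalue=float(p),
                 abs_change=float(change), pct_change=float(pct),
                 mediation_flag=bool(flag))
        )
    return pd.DataFrame(rows)
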