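"""Cross-trait LD score regression.

Under a polygenic model the expected GWAS chi-square of a variant grows
linearly in its LD score ell_j (the sum of squared correlations with
nearby variants): E[chi2_j] = 1 + n h2 ell_j / m.  Regressing chi-square
on LD scores therefore estimates SNP heritability from the slope while
the intercept absorbs confounding.  For two traits the product of
z-statistics replaces chi-square: E[z1 z2] = intercept + sqrt(n1 n2) *
gencov * ell_j / m, and the genetic correlation is rg = gencov /
sqrt(h2_1 h2_2).  Standard errors come from a delete-a-block jackknife.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sumstats import AnalysisError, InputError

__all__ = ["LDScoreTable", "LDSCResult", "ld_scores", "univariate_ldsc", "cross_trait_ldsc"]


@dataclass
class LDScoreTable:
    variant_ids: list
    ld_score: np.ndarray
    n_ref: int

    def __post_init__(self) -> None:
        self.ld_score = np.asarray(self.ld_score, dtype=float)
        if self.ld_score.size != len(self.variant_ids):
            raise InputError("ld_score length must match variant_ids")

    def __len__(self) -> int:
        return self.ld_score.size


@dataclass
class LDSCResult:
    h2_trait1: float
    h2_trait2: float
    gencov: float
    rg: float | None
    intercept_uni1: float
    intercept_uni2: float
    intercept_biv: float
    h2_trait1_se: float
    h2_trait2_se: float
    gencov_se: float
    rg_se: float | None
    m_snps: int
    n1: int
    n2: int
    rg_note: str = ""

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def ld_scores(panel: np.ndarray, window_bp: int, positions, variant_ids=None) -> LDScoreTable:
    """Adjusted LD scores from a genotype dosage panel.

    ell_j sums, over variants k within ``window_bp`` of j (same
    chromosome), the bias-adjusted r^2: r2 - (1 - r2)/(n_ref - 2), with
    the self term contributing exactly 1.  ``positions`` is a list of
    (chrom, pos) or of variant ids paired with positions; zero-variance
    variants are excluded with a warning.
    """
    panel = np.asarray(panel, dtype=float)
    n_ref, M = panel.shape
    if n_ref < 3:
        raise InputError("LD score estimation needs a reference panel with n >= 3")
    if len(positions) != M:
        raise InputError("positions must match the panel's variant count")
    if positions and not isinstance(positions[0], (tuple, list)):
        positions = [("1", p) for p in positions]

    sd = panel.std(axis=0)
    usable = sd > 0
    if not usable.all():
        import logging

        logging.getLogger(__name__).warning(
            "excluding %d zero-variance variant(s) from LD scores", int((~usable).sum())
        )
    z = np.zeros_like(panel)
    z[:, usable] = (panel[:, usable] - panel[:, usable].mean(axis=0)) / sd[usable]
    r = (z.T @ z) / n_ref
    r2 = r**2
    adj = r2 - (1.0 - r2) / (n_ref - 2)

    chroms = np.array([str(c) for c, _ in positions])
    pos = np.array([p for _, p in positions], dtype=float)
    ell = np.full(M, np.nan)
    for j in np.flatnonzero(usable):
        in_win = usable & (chroms == chroms[j]) & (np.abs(pos - pos[j]) <= window_bp)
        ell[j] = adj[j, in_win].sum() - adj[j, j] + 1.0  # self term exactly 1
    ids = list(variant_ids) if variant_ids is not None else [f"snp{j}" for j in range(M)]
    return LDScoreTable(ids, ell, n_ref)


def _wls_line(y: np.ndarray, x: np.ndarray, w: np.ndarray, intercept=None):
    """Weighted straight-line fit; fixed intercept when given.

    Returns (slope, intercept).
    """
    if intercept is None:
        X = np.column_stack([np.ones_like(x), x])
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        return float(coef[1]), float(coef[0])
    yy = y - intercept
    slope = float(np.sum(w * x * yy) / np.sum(w * x * x))
    return slope, float(intercept)


def _ldsc_weights(ell: np.ndarray, kind: str) -> np.ndarray:
    if kind == "inverse_ld":
        return 1.0 / np.maximum(ell, 1.0)
    if kind == "ols":
        return np.ones_like(ell)
    raise InputError(f"unknown weighting {kind!r}")


def _two_step_fit(y, ell, cutoff, weights):
    """Step 1: free intercept on y < cutoff; step 2: slope with intercept fixed."""
    if np.ptp(ell) == 0:
        raise AnalysisError("all LD scores equal: regression design is singular")
    w = _ldsc_weights(ell, weights)
    small = y < cutoff
    if small.sum() >= 3 and np.ptp(ell[small]) > 0:
        _, intercept = _wls_line(y[small], ell[small], w[small])
    else:
        _, intercept = _wls_line(y, ell, w)
    slope, _ = _wls_line(y, ell, w, intercept=intercept)
    return slope, intercept


def _jackknife(values: np.ndarray) -> float:
    B = len(values)
    return float(np.sqrt((B - 1) / B * np.sum((values - values.mean()) ** 2)))


def _block_slices(m: int, n_blocks: int):
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:]) if b > a]


def univariate_ldsc(
    z: np.ndarray,
    ld: LDScoreTable,
    n: int,
    m: int | None = None,
    two_step_cutoff: float = 30.0,
    n_blocks: int = 200,
    weights: str = "inverse_ld",
):
    """SNP heritability from the chi-square ~ LD score regression.

    Returns (h2, intercept, h2_se, intercept_se).  h2 = slope * m / n;
    the intercept is estimated on variants with chi2 < ``two_step_cutoff``
    then held fixed; SEs by delete-a-block jackknife over ``n_blocks``
    contiguous blocks.
    """
    z = np.asarray(z, dtype=float)
    ell = ld.ld_score
    if z.size != ell.size:
        raise InputError("z and LD scores must be aligned")
    m = m or z.size
    if z.size < n_blocks:
        raise AnalysisError(f"need at least {n_blocks} variants for the jackknife")
    chi2 = z**2
    slope, intercept = _two_step_fit(chi2, ell, two_step_cutoff, weights)
    h2 = slope * m / n

    blocks = _block_slices(z.size, n_blocks)
    keep = np.ones(z.size, dtype=bool)
    h2_bs, int_bs = [], []
    for sl in blocks:
        keep[sl] = False
        s_b, i_b = _two_step_fit(chi2[keep], ell[keep], two_step_cutoff, weights)
        h2_bs.append(s_b * m / n)
        int_bs.append(i_b)
        keep[sl] = True
    return h2, intercept, _jackknife(np.array(h2_bs)), _jackknife(np.array(int_bs))


def cross_trait_ldsc(
    z1: np.ndarray,
    z2: np.ndarray,
    ld: LDScoreTable,
    n1: int,
    n2: int,
    m: int | None = None,
    n_blocks: int = 200,
    two_step_cutoff: float = 30.0,
    weights: str = "inverse_ld",
) -> LDSCResult:
    """Genetic covariance and correlation from the z1*z2 ~ LD score regression.

    gencov = slope * m / sqrt(n1 n2); rg = gencov / sqrt(h2_1 h2_2) with
    the univariate fits run on the same variants; the bivariate intercept
    (sample-overlap term) is freely estimated.  rg is missing with a
    reason when either heritability estimate is non-positive.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    ell = ld.ld_score
    if not (z1.size == z2.size == ell.size):
        raise InputError("z1, z2 and LD scores must be aligned")
    m = m or z1.size
    if z1.size < n_blocks:
        raise AnalysisError(f"need at least {n_blocks} variants for the jackknife")

    w = _ldsc_weights(ell, weights)
    prod = z1 * z2

    def _fit_all(mask):
        s1, i1 = _two_step_fit(z1[mask] ** 2, ell[mask], two_step_cutoff, weights)
        s2, i2 = _two_step_fit(z2[mask] ** 2, ell[mask], two_step_cutoff, weights)
        sb, ib = _wls_line(prod[mask], ell[mask], w[mask])
        h2a, h2b = s1 * m / n1, s2 * m / n2
        gc = sb * m / np.sqrt(n1 * n2)
        rg = gc / np.sqrt(h2a * h2b) if (h2a > 0 and h2b > 0) else np.nan
        return h2a, h2b, gc, rg, i1, i2, ib

    full = np.ones(z1.size, dtype=bool)
    h2_1, h2_2, gencov, rg, i1, i2, ib = _fit_all(full)

    blocks = _block_slices(z1.size, n_blocks)
    reps = []
    keep = np.ones(z1.size, dtype=bool)
    for sl in blocks:
        keep[sl] = False
        reps.append(_fit_all(keep)[:4])
        keep[sl] = True
    reps = np.array(reps)  # columns: h2_1, h2_2, gencov, rg
    h2_1_se = _jackknife(reps[:, 0])
    h2_2_se = _jackknife(reps[:, 1])
    gencov_se = _jackknife(reps[:, 2])

    rg_note = ""
    rg_out: float | None = float(rg)
    rg_se: float | None
    if not np.isfinite(rg):
        rg_out, rg_se = None, None
        rg_note = "nonpositive heritability estimate; rg undefined"
    else:
        finite = np.isfinite(reps[:, 3])
        rg_se = _jackknife(reps[finite, 3]) if finite.sum() >= 2 else None
        if abs(rg) > 1:
            rg_note = "|rg| exceeds 1"
    return LDSCResult(
        h2_trait1=float(h2_1), h2_trait2=float(h2_2), gencov=float(gencov),
        rg=rg_out,
        intercept_uni1=float(i1), intercept_uni2=float(i2), intercept_biv=float(ib),
        h2_trait1_se=h2_1_se, h2_trait2_se=h2_2_se, gencov_se=gencov_se,
        rg_se=rg_se, m_snps=int(m), n1=int(n1), n2=int(n2), rg_note=rg_note,
    )
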