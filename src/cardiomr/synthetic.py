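"""Synthetic GWAS summary statistics with known ground truth.

The generator emulates the statistical structure of consortium-scale
GWAS summary data used in two-sample MR: per-variant effects on a set
of traits linked by an acyclic causal diagram, standard errors scaled
by sample size and allele frequency (unit-variance trait scale,
se = 1/sqrt(2 n maf (1-maf))), independent noise for the exposure and
outcome samples (non-overlapping cohorts), optional directional or
balanced pleiotropy, and optional strand-ambiguous alleles.  A separate
generator draws z-statistic pairs from the LD-score-regression model
for the cross-trait LDSC stage.

Everything is seeded; the truth parameters travel with the data so
recovery tests can compare estimates to the generating values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .ldsc import LDScoreTable
from .sumstats import ConfigurationError, HarmonizedSet, SummaryStatTable

__all__ = [
    "TruthRecord",
    "LDSCSimConfig",
    "make_truth",
    "simulate_two_sample",
    "simulate_mediation_chain",
    "simulate_bidirectional_pair",
    "simulate_ldsc_z",
    "simulate_dosage_panel",
]

NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                        ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def _check_acyclic(B: np.ndarray) -> None:
    K = B.shape[0]
    A = (B != 0).astype(float)
    P = A.copy()
    for _ in range(K):
        if np.trace(P) != 0:
            raise ConfigurationError("causal_matrix contains a cycle")
        P = P @ A


def _total_effects(B: np.ndarray) -> np.ndarray:
    """Sum of all directed paths: B + B^2 + ... (finite for acyclic B)."""
    K = B.shape[0]
    T = np.zeros_like(B)
    P = np.eye(K)
    for _ in range(K):
        P = P @ B
        T += P
    return T


@dataclass
class TruthRecord:
    """Generating parameters for a two-sample MR dataset.

    ``causal_matrix[i, j]`` is the direct effect of trait i on trait j;
    the last trait is the outcome.  ``instrument_effects`` (J x K) holds
    each variant's direct effect on each trait (typically nonzero only
    for the home exposure).  Pleiotropy adds direct variant-on-outcome
    effects of mean ``pleiotropy_mean`` and sd ``pleiotropy_sd`` to a
    ``pleiotropy_fraction`` of the variants.
    """

    trait_names: list
    causal_matrix: np.ndarray
    instrument_effects: np.ndarray
    instrument_of: list          # per variant: home exposure index
    maf: np.ndarray
    n_exposure: int
    n_outcome: int
    seed: int
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_fraction: float = 0.0
    palindromic_fraction: float = 0.0
    noise_scale: float = 1.0
    trait_types: list | None = None

    def __post_init__(self) -> None:
        self.causal_matrix = np.asarray(self.causal_matrix, dtype=float)
        self.instrument_effects = np.atleast_2d(
            np.asarray(self.instrument_effects, dtype=float)
        )
        self.maf = np.asarray(self.maf, dtype=float)
        K = len(self.trait_names)
        if self.causal_matrix.shape != (K, K):
            raise ConfigurationError("causal_matrix must be K x K")
        _check_acyclic(self.causal_matrix)
        if not 0 <= self.pleiotropy_fraction <= 1:
            raise ConfigurationError("pleiotropy_fraction must lie in [0, 1]")
        if np.any((self.maf <= 0) | (self.maf >= 0.5)):
            raise ConfigurationError("maf must lie in (0, 0.5)")

    @property
    def n_variants(self) -> int:
        return self.instrument_effects.shape[0]

    @property
    def total_effect_matrix(self) -> np.ndarray:
        return _total_effects(self.causal_matrix)

    def total_effect(self, exposure: int, outcome: int = -1) -> float:
        """Total (all-path) causal effect of one trait on another."""
        K = len(self.trait_names)
        return float(self.total_effect_matrix[exposure, outcome % K])

    def to_json(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        with open(path, "wt") as fh:
            json.dump(d, fh, indent=1)


def _instrument_gamma(rng, maf, n, z_range):
    """Variant-exposure effects scaled to the instrument-selection regime.

    GWAS instruments are genome-wide significant by construction, so the
    true effect of each is drawn on the z-scale: |gamma|/se ~ Uniform
    over ``z_range`` (default F between 36 and 225, matching selection at
    p < 5e-8 with strong instruments), with random sign.
    """
    se = 1.0 / np.sqrt(2 * n * maf * (1 - maf))
    z = rng.uniform(*z_range, size=maf.size)
    return z * se * rng.choice([-1.0, 1.0], size=maf.size)


def make_truth(
    theta: float = 0.3,
    J: int = 100,
    n: int = 100_000,
    seed: int = 0,
    n_outcome: int | None = None,
    pleiotropy_mean: float = 0.0,
    pleiotropy_sd: float = 0.0,
    pleiotropy_fraction: float = 0.0,
    palindromic_fraction: float = 0.0,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    instrument_z_range: tuple = (5.5, 30.0),
) -> TruthRecord:
    """Single exposure -> outcome truth with J instruments of effect ``theta``."""
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.05, 0.5, size=J)
    gamma = _instrument_gamma(rng, maf, n, instrument_z_range)
    eff = np.zeros((J, 2))
    eff[:, 0] = gamma
    B = np.zeros((2, 2))
    B[0, 1] = theta
    return TruthRecord(
        trait_names=[exposure_name, outcome_name],
        causal_matrix=B,
        instrument_effects=eff,
        instrument_of=[0] * J,
        maf=maf,
        n_exposure=n,
        n_outcome=n_outcome or n,
        seed=seed,
        pleiotropy_mean=pleiotropy_mean,
        pleiotropy_sd=pleiotropy_sd,
        pleiotropy_fraction=pleiotropy_fraction,
        palindromic_fraction=palindromic_fraction,
    )


def _alleles(rng: np.random.Generator, J: int, palindromic_fraction: float):
    pal = rng.random(J) < palindromic_fraction
    ea = np.empty(J, dtype=object)
    oa = np.empty(J, dtype=object)
    for j in range(J):
        pool = PALINDROMIC_PAIRS if pal[j] else NONPALINDROMIC_PAIRS
        ea[j], oa[j] = pool[rng.integers(len(pool))]
    return ea, oa


def _table(name, ttype, ids, chrom, pos, ea, oa, eaf, beta, se, n) -> SummaryStatTable:
    z = beta / se
    df = pd.DataFrame(
        dict(
            variant_id=ids, chrom=chrom, pos=pos,
            effect_allele=ea, other_allele=oa, eaf=eaf,
            beta=beta, se=se, pvalue=2 * stats.norm.sf(np.abs(z)),
            n=n,
        ),
        index=ids,
    )
    df.index.name = None
    return SummaryStatTable(trait_name=name, records=df, trait_type=ttype)


def simulate_two_sample(truth: TruthRecord):
    """Draw exposure and outcome summary-statistic tables under ``truth``.

    Returns ``(exposure_tables, outcome_table, instrument_ids)`` where
    ``instrument_ids[k]`` lists the variants whose home exposure is k.
    True marginal effects are direct effects plus all causal paths plus
    (for the outcome) the planted pleiotropic effects; observed betas add
    Normal(0, se) noise with se = 1/sqrt(2 n maf (1-maf)), independently
    for the exposure sample and the outcome sample.
    """
    rng = np.random.default_rng(truth.seed)
    J = truth.n_variants
    K = len(truth.trait_names)
    T = truth.total_effect_matrix
    G = truth.instrument_effects @ (np.eye(K) + T)  # true marginal effects

    pleio = np.zeros(J)
    affected = rng.random(J) < truth.pleiotropy_fraction
    pleio[affected] = rng.normal(
        truth.pleiotropy_mean, truth.pleiotropy_sd, size=int(affected.sum())
    )
    # "directional" means directional per copy of the exposure-increasing
    # allele; apply the effect in that orientation so a nonzero mean is not
    # cancelled by arbitrary allele coding
    home = np.array(truth.instrument_of)
    home_effect = truth.instrument_effects[np.arange(J), home]
    orient = np.where(home_effect < 0, -1.0, 1.0)
    G = G.copy()
    G[:, -1] += orient * pleio

    maf = truth.maf
    ids = [f"rs{j + 1}" for j in range(J)]
    chrom = [str(1 + (j % 22)) for j in range(J)]
    pos = [100_000 + 10_000_000 * (j // 22) for j in range(J)]
    ea, oa = _alleles(rng, J, truth.palindromic_fraction)
    ttypes = truth.trait_types or ["continuous"] * K

    se_exp = 1.0 / np.sqrt(2 * truth.n_exposure * maf * (1 - maf))
    se_out = 1.0 / np.sqrt(2 * truth.n_outcome * maf * (1 - maf))

    exposure_tables = []
    for k in range(K - 1):
        beta = G[:, k] + truth.noise_scale * rng.normal(0, se_exp)
        exposure_tables.append(
            _table(truth.trait_names[k], ttypes[k], ids, chrom, pos, ea, oa,
                   maf, beta, se_exp, truth.n_exposure)
        )
    beta_out = G[:, -1] + truth.noise_scale * rng.normal(0, se_out)
    outcome_table = _table(truth.trait_names[-1], ttypes[-1], ids, chrom, pos,
                           ea, oa, maf, beta_out, se_out, truth.n_outcome)

    instrument_ids = [
        [ids[j] for j in range(J) if truth.instrument_of[j] == k]
        for k in range(K - 1)
    ]
    return exposure_tables, outcome_table, instrument_ids


def _harmonized_from_arrays(exp_names, out_name, ids, bexp, sexp, bout, sout):
    return HarmonizedSet(
        exposure_names=list(exp_names), outcome_name=out_name,
        variant_ids=list(ids), beta_exp=bexp, se_exp=sexp,
        beta_out=bout, se_out=sout,
    )


def simulate_mediation_chain(
    theta_xm: float,
    theta_my: float,
    theta_xy_direct: float,
    J: int = 150,
    n: int = 100_000,
    seed: int = 0,
    instrument_z_range: tuple = (5.5, 30.0),
) -> dict:
    """Three-trait chain X -> M -> Y with an optional direct X -> Y path.

    Simulates J instruments for X and J for M and returns the three
    aligned effect sets the mediation decomposition needs
    (``h_exposure_outcome``, ``h_exposure_mediator``, ``h_joint``) plus
    the truth (total effect, percent mediated).  All alleles are emitted
    pre-aligned, so the sets are harmonization-ready by construction.
    """
    rng = np.random.default_rng(seed)
    B = np.zeros((3, 3))
    B[0, 1] = theta_xm   # X -> M
    B[1, 2] = theta_my   # M -> Y
    B[0, 2] = theta_xy_direct
    maf = rng.uniform(0.05, 0.5, size=2 * J)
    eff = np.zeros((2 * J, 3))
    eff[:J, 0] = _instrument_gamma(rng, maf[:J], n, instrument_z_range)
    eff[J:, 1] = _instrument_gamma(rng, maf[J:], n, instrument_z_range)
    truth = TruthRecord(
        trait_names=["X", "M", "Y"],
        causal_matrix=B,
        instrument_effects=eff,
        instrument_of=[0] * J + [1] * J,
        maf=maf,
        n_exposure=n,
        n_outcome=n,
        seed=int(rng.integers(2**31 - 1)),
    )
    (tab_x, tab_m), tab_y, (ids_x, ids_m) = simulate_two_sample(truth)

    def _arrays(table, ids):
        sub = table.records.loc[ids]
        return sub["beta"].to_numpy(), sub["se"].to_numpy()

    bx, sx = _arrays(tab_x, ids_x)
    bm_on_x, sm_on_x = _arrays(tab_m, ids_x)
    by_on_x, sy_on_x = _arrays(tab_y, ids_x)

    h_xy = _harmonized_from_arrays(["X"], "Y", ids_x, bx[:, None], sx[:, None],
                                   by_on_x, sy_on_x)
    h_xm = _harmonized_from_arrays(["X"], "M", ids_x, bx[:, None], sx[:, None],
                                   bm_on_x, sm_on_x)

    ids_joint = ids_x + ids_m
    bX, sX = _arrays(tab_x, ids_joint)
    bM, sM = _arrays(tab_m, ids_joint)
    bY, sY = _arrays(tab_y, ids_joint)
    h_joint = _harmonized_from_arrays(
        ["X", "M"], "Y", ids_joint,
        np.column_stack([bX, bM]), np.column_stack([sX, sM]), bY, sY,
    )

    total_true = theta_xy_direct + theta_xm * theta_my
    pct_true = 100.0 * theta_xm * theta_my / total_true if total_true else np.nan
    return dict(
        h_exposure_outcome=h_xy,
        h_exposure_mediator=h_xm,
        h_joint=h_joint,
        tables=dict(X=tab_x, M=tab_m, Y=tab_y),
        truth=dict(
            theta_xm=theta_xm, theta_my=theta_my,
            theta_xy_direct=theta_xy_direct,
            total_effect=total_true, percent_mediated=pct_true,
        ),
    )


def simulate_bidirectional_pair(
    theta_ab: float,
    J_a: int = 50,
    J_b: int = 50,
    n: int = 100_000,
    seed: int = 0,
    name_a: str = "A",
    name_b: str = "B",
    instrument_z_range: tuple = (5.5, 30.0),
) -> dict:
    """Two traits with their own instruments and a one-way effect A -> B.

    Trait A's instruments affect B only through A (effect ``theta_ab``);
    trait B's instruments have no effect on A (no reverse path).  Returns
    merged per-trait tables covering both instrument sets, ready for a
    bidirectional MR run, plus the instrument id lists.
    """
    rng = np.random.default_rng(seed)
    forward = make_truth(
        theta=theta_ab, J=J_a, n=n, seed=int(rng.integers(2**31 - 1)),
        exposure_name=name_a, outcome_name=name_b,
        instrument_z_range=instrument_z_range,
    )
    reverse = make_truth(
        theta=0.0, J=J_b, n=n, seed=int(rng.integers(2**31 - 1)),
        exposure_name=name_b, outcome_name=name_a,
        instrument_z_range=instrument_z_range,
    )
    (tab_a_fwd,), tab_b_fwd, (ids_a,) = simulate_two_sample(forward)
    (tab_b_rev,), tab_a_rev, (ids_b_raw,) = simulate_two_sample(reverse)

    def _prefix(table, prefix):
        rec = table.records.copy()
        rec["variant_id"] = [f"{prefix}{v}" for v in rec["variant_id"]]
        rec.index = rec["variant_id"]
        rec.index.name = None
        return rec

    ids_b = [f"b_{v}" for v in ids_b_raw]
    tab_a = SummaryStatTable(
        name_a, pd.concat([tab_a_fwd.records, _prefix(tab_a_rev, "b_")])
    )
    tab_b = SummaryStatTable(
        name_b, pd.concat([tab_b_fwd.records, _prefix(tab_b_rev, "b_")])
    )
    return dict(
        tables={name_a: tab_a, name_b: tab_b},
        instruments={name_a: ids_a, name_b: ids_b},
        truth=dict(theta_ab=theta_ab, theta_ba=0.0),
    )


@dataclass
class LDSCSimConfig:
    """Generating model for LD-score-regression z-statistics."""

    m: int
    h2_1: float
    h2_2: float
    gencov: float
    n1: int
    n2: int
    seed: int = 0
    ld_profile: tuple = ("uniform", 1.0, 200.0)

    def __post_init__(self) -> None:
        for h in (self.h2_1, self.h2_2):
            if not 0 <= h <= 1:
                raise ConfigurationError("h2 must lie in [0, 1]")
        bound = np.sqrt(self.h2_1 * self.h2_2)
        if abs(self.gencov) > bound + 1e-12:
            raise ConfigurationError(
                f"|gencov| = {abs(self.gencov)} exceeds sqrt(h2_1 h2_2) = {bound}"
            )

    def make_ld_scores(self, n_ref: int = 500) -> LDScoreTable:
        rng = np.random.default_rng(self.seed + 7)
        kind = self.ld_profile[0]
        if kind == "uniform":
            ell = rng.uniform(self.ld_profile[1], self.ld_profile[2], size=self.m)
        elif kind == "constant":
            ell = np.full(self.m, float(self.ld_profile[1]))
        else:
            raise ConfigurationError(f"unknown ld_profile kind {kind!r}")
        return LDScoreTable([f"snp{j}" for j in range(self.m)], ell, n_ref)


def simulate_ldsc_z(config: LDSCSimConfig, ld: LDScoreTable):
    """Draw (z1, z2) pairs from the bivariate LD-score-regression model.

    Var(z1_j) = 1 + n1 h2_1 ell_j / m, analogously for z2;
    Cov(z1_j, z2_j) = sqrt(n1 n2) gencov ell_j / m (no sample overlap).
    """
    ell = ld.ld_score
    m = config.m
    if ell.size != m:
        raise ConfigurationError("LD score table length must equal config.m")
    v1 = 1.0 + config.n1 * config.h2_1 * ell / m
    v2 = 1.0 + config.n2 * config.h2_2 * ell / m
    cv = np.sqrt(config.n1 * config.n2) * config.gencov * ell / m
    resid = v2 - cv**2 / v1
    if np.any(resid < -1e-12):
        raise ConfigurationError("implied per-variant covariance is not PSD")
    rng = np.random.default_rng(config.seed)
    a = rng.standard_normal(m)
    b = rng.standard_normal(m)
    z1 = np.sqrt(v1) * a
    z2 = (cv / np.sqrt(v1)) * a + np.sqrt(np.maximum(resid, 0.0)) * b
    return z1, z2


def simulate_dosage_panel(
    n_ref: int,
    n_blocks: int,
    block_size: int,
    within_r: float = 0.6,
    seed: int = 0,
    bp_spacing: int = 50_000,
):
    """Block-correlated standardized dosage panel for LD fixtures.

    Variants come in ``n_blocks`` blocks of ``block_size``; within a block
    every pair has correlation ~``within_r`` (one-factor structure),
    across blocks ~0.  Returns (panel, variant_ids, positions) with
    positions spaced ``bp_spacing`` apart on one chromosome per block.
    """
    rng = np.random.default_rng(seed)
    cols, ids, positions = [], [], []
    lam = np.sqrt(within_r)
    for b in range(n_blocks):
        f = rng.standard_normal(n_ref)
        for k in range(block_size):
            e = rng.standard_normal(n_ref)
            cols.append(lam * f + np.sqrt(1 - within_r) * e)
            j = b * block_size + k
            ids.append(f"rs{j + 1}")
            positions.append((str(b + 1), 100_000 + k * bp_spacing))
    return np.column_stack(cols), ids, positions
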