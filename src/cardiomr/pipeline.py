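"""Orchestration: end-to-end MR runs, bidirectional analysis, thresholds.

``run_pair`` wires one exposure-outcome analysis: instrument selection
(LD clumping or a fixed list) -> harmonization -> the univariable
estimator battery -> outlier-robust sensitivity (residual-sum-of-squares
scan and contamination mixture) -> refits on the altered instrument
sets -> a consistency verdict in the style of the forest-plot rule
(nominally significant with at least two approaches and a consistent
direction of effect).  ``bidirectional`` runs a trait pair in both
directions with each trait's own instruments.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .estimators import estimator_battery, ivw, wald_ratios
from .instruments import LDMatrix, clump
from .robust import conmix, conmix_estimate, presso, refit_after_exclusion
from .sumstats import (
    AnalysisError,
    ConfigurationError,
    InputError,
    SummaryStatTable,
    harmonize,
    read_sumstats,
)

__all__ = [
    "RunConfig",
    "ConsistencyVerdict",
    "PairResult",
    "run_pair",
    "bidirectional",
    "bonferroni_threshold",
    "mr_power",
    "power_table",
    "consistency_verdict",
]


@dataclass
class RunConfig:
    """Machine form of the study design.

    ``traits`` maps a trait name to either a loaded SummaryStatTable or a
    dict with ``path`` (and optional ``column_map``/``type``).
    ``instruments`` optionally maps a trait name to a fixed instrument
    list; otherwise instruments are clumped from the trait's own table
    (which then requires ``ld``).
    """

    traits: dict
    instruments: dict = field(default_factory=dict)
    ld: LDMatrix | None = None
    p_instrument: float = 5e-8
    r2_threshold: float = 0.2
    window_bp: int = 1_000_000
    direct_effect_p: float = 5e-8
    alpha: float = 0.05
    n_tests: int = 9
    seed: int = 0
    n_boot: int = 1000
    n_sim: int = 1000
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for name, thr in (
            ("p_instrument", self.p_instrument),
            ("r2_threshold", self.r2_threshold),
            ("window_bp", self.window_bp),
            ("direct_effect_p", self.direct_effect_p),
            ("alpha", self.alpha),
        ):
            if thr <= 0:
                raise ConfigurationError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "rt") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def table(self, name: str) -> SummaryStatTable:
        if name not in self.traits:
            raise ConfigurationError(f"trait {name!r} not in the registry")
        entry = self.traits[name]
        if isinstance(entry, SummaryStatTable):
            return entry
        table = read_sumstats(
            entry["path"],
            column_map=entry.get("column_map"),
            trait_name=name,
            trait_type=entry.get("type", "continuous"),
        )
        self.traits[name] = table
        return table

    def manifest(self) -> dict:
        return dict(
            seed=self.seed,
            thresholds=dict(
                p_instrument=self.p_instrument,
                r2=self.r2_threshold,
                window_bp=self.window_bp,
                direct_effect_p=self.direct_effect_p,
                alpha=self.alpha,
                n_tests=self.n_tests,
            ),
            traits=sorted(self.traits),
        )


@dataclass
class ConsistencyVerdict:
    pair: str
    n_methods_nominal: int
    directions_agree: bool
    consistent: bool


def consistency_verdict(estimates, alpha: float = 0.05, pair: str = "") -> ConsistencyVerdict:
    """Nominal significance with >= 2 methods AND one direction of effect."""
    if len(estimates) < 2:
        raise InputError("consistency verdict needs at least two methods")
    nominal = sum(e.pvalue < alpha for e in estimates)
    signs = {np.sign(e.theta) for e in estimates if e.theta != 0}
    agree = len(signs) <= 1
    return ConsistencyVerdict(
        pair=pair,
        n_methods_nominal=int(nominal),
        directions_agree=bool(agree),
        consistent=bool(nominal >= 2 and agree),
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise InputError(f"alpha must lie in (0, 1), got {alpha}")
    if n_tests < 1:
        raise InputError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests


def mr_power(theta: float, r2_gx: float, n: int, alpha: float = 0.05) -> float:
    """Two-sided power of an MR test on unit-variance scales.

    The IVW z-statistic has mean theta * sqrt(n * r2_gx) where r2_gx is
    the variance in the exposure explained by the instruments and n the
    outcome sample size.
    """
    if not 0 < r2_gx < 1:
        raise InputError(f"r2_gx must lie in (0, 1), got {r2_gx}")
    if n < 1:
        raise InputError(f"n must be >= 1, got {n}")
    if not 0 < alpha < 1:
        raise InputError(f"alpha must lie in (0, 1), got {alpha}")
    zc = stats.norm.ppf(1 - alpha / 2)
    ncp = abs(theta) * np.sqrt(n * r2_gx)
    return float(stats.norm.cdf(ncp - zc) + stats.norm.cdf(-ncp - zc))


def power_table(thetas, r2s, ns, alpha: float = 0.05) -> pd.DataFrame:
    """Power over a (theta, r2, n) grid, one row per combination."""
    rows = [
        dict(theta=t, r2_gx=r, n=n, power=mr_power(t, r, n, alpha))
        for t in np.atleast_1d(thetas)
        for r in np.atleast_1d(r2s)
        for n in np.atleast_1d(ns)
    ]
    return pd.DataFrame(rows)


@dataclass
class PairResult:
    exposure: str
    outcome: str
    instruments: list
    harmonized: object
    estimates: list
    outlier_report: object
    conmix_result: object
    refit: dict
    verdict: ConsistencyVerdict
    manifest: dict

    def estimates_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.as_dict() for e in self.estimates])


def _select_instruments(config: RunConfig, exposure: str):
    table = config.table(exposure)
    if exposure in config.instruments:
        return list(config.instruments[exposure])
    if config.ld is None:
        # unlinked fallback: plain significance filtering
        p = table.pvalues()
        sig = p[p < config.p_instrument]
        if sig.empty:
            raise AnalysisError(f"no instruments for {exposure!r} pass the threshold")
        return list(sig.index)
    iset = clump(
        table, config.ld,
        p_threshold=config.p_instrument,
        r2_threshold=config.r2_threshold,
        window_bp=config.window_bp,
    )
    return iset.variant_ids


def run_pair(config: RunConfig, exposure: str, outcome: str) -> PairResult:
    """One exposure -> outcome MR analysis with sensitivity refits."""
    exp_table = config.table(exposure)
    out_table = config.table(outcome)
    instruments = _select_instruments(config, exposure)

    h = harmonize(
        exp_table, out_table, instruments, direct_effect_p=config.direct_effect_p
    )
    ests = estimator_battery(h, 0, seed=config.seed, n_boot=config.n_boot)

    report = None
    cm = None
    refit = {"excluded": [], "estimates": ests}
    if h.n_variants >= 4:
        report = presso(h, 0, n_sim=config.n_sim, seed=config.seed, outlier_alpha=config.alpha)
        r = wald_ratios(h, 0)
        cm = conmix(r, grid_points=2001)
        ests = ests + [conmix_estimate(cm, h.n_variants)]
        invalid = sorted(set(r.variant_ids) - set(cm.valid_ids))
        excluded = sorted(set(report.flagged_ids) | set(invalid))
        if excluded and h.n_variants - len(excluded) >= 3:
            refit = refit_after_exclusion(
                h, 0, excluded, seed=config.seed, n_boot=config.n_boot
            )

    verdict = consistency_verdict(ests, alpha=config.alpha, pair=f"{exposure}->{outcome}")
    manifest = config.manifest()
    manifest["pair"] = f"{exposure}->{outcome}"
    manifest["n_instruments_requested"] = len(instruments)
    manifest["n_variants_retained"] = h.n_variants

    result = PairResult(
        exposure=exposure, outcome=outcome, instruments=instruments,
        harmonized=h, estimates=ests, outlier_report=report,
        conmix_result=cm, refit=refit, verdict=verdict, manifest=manifest,
    )
    if config.out_dir:
        _write_bundle(result, config)
    return result


def bidirectional(config: RunConfig, trait_a: str, trait_b: str):
    """Run A -> B with A's instruments and B -> A with B's instruments."""
    return run_pair(config, trait_a, trait_b), run_pair(config, trait_b, trait_a)


def _write_bundle(result: PairResult, config: RunConfig) -> None:
    out = Path(config.out_dir) / f"{result.exposure}__{result.outcome}"
    out.mkdir(parents=True, exist_ok=True)
    df = result.estimates_frame()
    df.insert(0, "outcome", result.outcome)
    df.insert(0, "exposure", result.exposure)
    df.to_csv(out / "estimates.tsv", sep="\t", index=False)
    pd.DataFrame(result.harmonized.dropped, columns=["variant_id", "reason"]).to_csv(
        out / "drop_log.tsv", sep="\t", index=False
    )
    result.harmonized.to_frame().to_csv(out / "harmonized.tsv", sep="\t", index=False)
    if result.outlier_report is not None:
        result.outlier_report.per_variant.to_csv(
            out / "outliers.tsv", sep="\t", index=False
        )
    manifest = dict(result.manifest)
    manifest["estimates_sha256"] = hashlib.sha256(
        df.to_csv(index=False).encode()
    ).hexdigest()
    with open(out / "manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=1, default=str)
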