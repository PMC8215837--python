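"""Instrument selection: greedy LD clumping and per-variant strength.

Instruments for an exposure are genome-wide significant variants pruned
to approximate linkage equilibrium: variants are visited in order of
increasing p-value and each retained index variant removes every
remaining variant on the same chromosome within the clump window whose
squared correlation with it reaches the r-squared threshold (defaults
r^2 < 0.2 within 1 Mb).  Per-variant instrument strength is the squared
z-statistic, the large-sample F-statistic of the one-SNP regression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import AnalysisError, InputError, SummaryStatTable

__all__ = ["LDMatrix", "InstrumentSet", "clump", "f_statistic", "cross_trait_flags"]

logger = logging.getLogger(__name__)


@dataclass
class LDMatrix:
    """Pairwise variant correlations plus genomic positions.

    ``r`` is the signed correlation matrix aligned to ``variant_ids``;
    ``positions`` maps variant_id -> (chrom, pos).
    """

    variant_ids: list
    r: np.ndarray
    positions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        M = len(self.variant_ids)
        if self.r.shape != (M, M):
            raise InputError(f"r must be {M}x{M}, got {self.r.shape}")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise InputError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise InputError("LD matrix diagonal must be 1")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            raise InputError("|r| must not exceed 1")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def r2(self, a: str, b: str) -> float:
        """Squared correlation; missing pairs count as unlinked (r^2 = 0)."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r[ia, ib] ** 2)

    @classmethod
    def from_dosages(cls, dosages: np.ndarray, variant_ids, positions=None) -> "LDMatrix":
        """Correlation matrix of an (n_ref x M) genotype dosage panel."""
        dosages = np.asarray(dosages, dtype=float)
        sd = dosages.std(axis=0)
        if np.any(sd == 0):
            bad = [variant_ids[i] for i in np.flatnonzero(sd == 0)]
            raise InputError(f"zero-variance variants in panel: {bad[:5]}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = np.corrcoef(dosages, rowvar=False)
        np.fill_diagonal(r, 1.0)
        return cls(list(variant_ids), r, dict(positions or {}))

    @classmethod
    def read(cls, path, positions=None) -> "LDMatrix":
        """Read a square tab-delimited matrix (ids as header and first column)."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(), dict(positions or {}))


@dataclass
class InstrumentSet:
    exposure_name: str
    variant_ids: list
    index_pvalues: np.ndarray
    f_statistics: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                variant_id=self.variant_ids,
                pvalue=self.index_pvalues,
                F=self.f_statistics,
            )
        )


def f_statistic(beta: float, se: float) -> float:
    """Per-variant instrument strength (beta/se)^2, the squared z-statistic."""
    if se <= 0:
        raise InputError(f"se must be positive, got {se}")
    return (beta / se) ** 2


def _sort_candidates(df: pd.DataFrame) -> pd.DataFrame:
    # ties: ascending p, then (chrom, pos), then variant_id -- deterministic
    return df.sort_values(
        by=["_p", "chrom", "pos", "variant_id"],
        kind="mergesort",
    )


def clump(
    candidates: SummaryStatTable,
    ld: LDMatrix,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.2,
    window_bp: int = 1_000_000,
    window_one_sided: bool = False,
) -> InstrumentSet:
    """Greedy LD clumping of significant candidates.

    Candidates with p < ``p_threshold`` are visited by ascending p-value;
    each retained variant removes remaining same-chromosome variants
    within the window having r^2 >= ``r2_threshold`` with it.  The window
    is centered (+/- ``window_bp``) unless ``window_one_sided``.  Variants
    absent from ``ld`` are treated as unlinked, with a warning.
    """
    df = candidates.records.copy()
    df["_p"] = candidates.pvalues()
    df = df[df["_p"] < p_threshold]
    if df.empty:
        raise AnalysisError(
            f"no candidate for {candidates.trait_name!r} passes p < {p_threshold}"
        )

    # positions preferentially from the LD reference, else the sumstats
    def _where(vid, row):
        if vid in ld.positions:
            return ld.positions[vid]
        return (row["chrom"], row["pos"])

    missing_ld = [v for v in df.index if v not in ld._index]
    if missing_ld:
        logger.warning(
            "%d candidate(s) absent from LD reference, treated as unlinked: %s",
            len(missing_ld),
            missing_ld[:5],
        )

    ordered = _sort_candidates(df)
    remaining = list(ordered.index)
    pos = {vid: _where(vid, ordered.loc[vid]) for vid in remaining}
    retained: list[str] = []
    while remaining:
        index_vid = remaining.pop(0)
        retained.append(index_vid)
        ichrom, ipos = pos[index_vid]
        span = (ipos, ipos + window_bp) if window_one_sided else (ipos - window_bp, ipos + window_bp)
        keep = []
        for vid in remaining:
            vchrom, vpos = pos[vid]
            in_window = str(vchrom) == str(ichrom) and span[0] <= vpos <= span[1]
            if in_window and ld.r2(index_vid, vid) >= r2_threshold:
                continue
            keep.append(vid)
        remaining = keep

    sub = ordered.loc[retained]
    return InstrumentSet(
        exposure_name=candidates.trait_name,
        variant_ids=retained,
        index_pvalues=sub["_p"].to_numpy(),
        f_statistics=(sub["beta"] / sub["se"]).to_numpy() ** 2,
    )


def cross_trait_flags(
    instrument_sets,
    all_tables,
    p_threshold: float = 5e-8,
) -> tuple[pd.DataFrame, float]:
    """Which instruments are genome-wide significant for more than one trait.

    Returns a per-variant table (variant_id, home exposure, list and count
    of traits significant at ``p_threshold``) and the fraction of
    instruments significant for >1 trait (NaN when there are none).
    """
    rows = []
    seen = set()
    for iset in instrument_sets:
        for vid in iset.variant_ids:
            if vid in seen:
                continue
            seen.add(vid)
            hits = []
            for table in all_tables:
                if vid in table:
                    p = float(table.pvalues([vid]).iloc[0])
                    if p < p_threshold:
                        hits.append(table.trait_name)
            rows.append(
                dict(
                    variant_id=vid,
                    exposure=iset.exposure_name,
                    significant_traits=hits,
                    n_traits=len(hits),
                )
            )
    df = pd.DataFrame(rows, columns=["variant_id", "exposure", "significant_traits", "n_traits"])
    fraction = float((df["n_traits"] > 1).mean()) if len(df) else float("nan")
    return df, fraction
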