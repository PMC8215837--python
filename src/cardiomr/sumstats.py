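"""GWAS summary statistics: data model, I/O and allele harmonization.

A GWAS summary-statistic table holds one association record per variant:
effect and other allele, per-allele effect size ``beta`` with standard
error ``se``, p-value and sample size.  Two-sample MR combines an
exposure table and an outcome table; before any estimation the two must
be *harmonized* so that every retained variant's outcome effect is
expressed per copy of the exposure's effect allele.  Strand-ambiguous
(palindromic A/T and C/G) variants cannot be harmonized from alleles
alone and are excluded, as are instruments with a genome-wide significant
direct association with the outcome.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VALID_ALLELES",
    "COMPLEMENT",
    "DEFAULT_COLUMN_MAP",
    "SummaryStatTable",
    "HarmonizedSet",
    "read_sumstats",
    "write_sumstats",
    "is_palindromic",
    "harmonize",
    "ConfigurationError",
    "InputError",
    "AnalysisError",
]

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: standard field -> default column name in delimited sumstats files
DEFAULT_COLUMN_MAP = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
}

MANDATORY_FIELDS = ("variant_id", "effect_allele", "other_allele", "beta", "se")


class ConfigurationError(ValueError):
    """Bad configuration: missing columns, invalid thresholds, cyclic DAGs."""


class InputError(ValueError):
    """A single input value violates a precondition."""


class AnalysisError(RuntimeError):
    """An analysis stage cannot proceed (e.g. zero retained variants)."""


def _norm_pvalue(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Two-sided normal-tail p-value of beta/se."""
    z = np.asarray(beta, dtype=float) / np.asarray(se, dtype=float)
    return 2.0 * stats.norm.sf(np.abs(z))


@dataclass
class SummaryStatTable:
    """One trait's GWAS summary statistics.

    ``records`` is a DataFrame with the standard columns
    ``variant_id, chrom, pos, effect_allele, other_allele, eaf, beta, se,
    pvalue, n``, indexed by ``variant_id`` (unique).  Missing ``eaf``/``n``
    are NaN; a missing p-value is recomputed from the z-statistic on
    access through :meth:`pvalues`.
    """

    trait_name: str
    records: pd.DataFrame
    trait_type: str = "continuous"
    n_dropped: int = 0
    drop_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ConfigurationError(
                f"trait_type must be 'continuous' or 'binary', got {self.trait_type!r}"
            )
        if not self.records.index.is_unique:
            dupes = self.records.index[self.records.index.duplicated()].unique()
            raise InputError(f"duplicate variant_id in {self.trait_name}: {list(dupes)[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.records.index

    @property
    def variant_ids(self) -> list:
        return list(self.records.index)

    def pvalues(self, variant_ids=None) -> pd.Series:
        """P-values, recomputing missing ones from beta/se (two-sided normal)."""
        df = self.records if variant_ids is None else self.records.loc[variant_ids]
        p = df["pvalue"].copy()
        missing = p.isna()
        if missing.any():
            p[missing] = _norm_pvalue(df.loc[missing, "beta"], df.loc[missing, "se"])
        return p

    def subset(self, variant_ids) -> "SummaryStatTable":
        present = [v for v in variant_ids if v in self.records.index]
        return SummaryStatTable(
            trait_name=self.trait_name,
            records=self.records.loc[present].copy(),
            trait_type=self.trait_type,
        )


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    ea, oa = str(effect_allele).upper(), str(other_allele).upper()
    if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
        raise InputError(f"invalid allele symbol in pair ({effect_allele!r}, {other_allele!r})")
    return COMPLEMENT[ea] == oa


def read_sumstats(
    path,
    column_map: dict | None = None,
    trait_name: str | None = None,
    trait_type: str = "continuous",
) -> SummaryStatTable:
    """Read a delimited summary-statistic file into a :class:`SummaryStatTable`.

    The delimiter is auto-detected among tab, comma and whitespace.
    ``column_map`` maps standard field names to the file's column names;
    unspecified fields fall back to :data:`DEFAULT_COLUMN_MAP`.  Rows with
    non-positive SE or unparsable beta are dropped and counted in
    ``n_dropped``.  Alleles are upper-cased.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "rt") as fh:
            text = fh.read()
    if not text.strip():
        raise InputError(f"empty summary-statistic file: {path}")

    header = text.splitlines()[0]
    if "\t" in header:
        sep = "\t"
    elif "," in header:
        sep = ","
    else:
        sep = r"\s+"
    df = pd.read_csv(io.StringIO(text), sep=sep)

    for fld in MANDATORY_FIELDS:
        if cmap[fld] not in df.columns:
            raise ConfigurationError(
                f"mandatory column {cmap[fld]!r} (field {fld!r}) missing from {path}"
            )

    out = pd.DataFrame(index=df.index)
    for fld in DEFAULT_COLUMN_MAP:
        col = cmap[fld]
        out[fld] = df[col] if col in df.columns else np.nan

    out["variant_id"] = out["variant_id"].astype(str)
    out["effect_allele"] = out["effect_allele"].astype(str).str.upper()
    out["other_allele"] = out["other_allele"].astype(str).str.upper()
    for fld in ("eaf", "beta", "se", "pvalue"):
        out[fld] = pd.to_numeric(out[fld], errors="coerce")
    out["n"] = pd.to_numeric(out["n"], errors="coerce")
    out["chrom"] = out["chrom"].astype(str)

    ok = out["beta"].notna() & out["se"].notna() & (out["se"] > 0)
    n_dropped = int((~ok).sum())
    drop_log = [
        (row.variant_id, "bad_beta" if pd.isna(row.beta) else "nonpositive_se")
        for row in out[~ok].itertuples()
    ]
    out = out[ok].set_index("variant_id", drop=False)
    out.index.name = None

    return SummaryStatTable(
        trait_name=trait_name or str(path),
        records=out,
        trait_type=trait_type,
        n_dropped=n_dropped,
        drop_log=drop_log,
    )


def write_sumstats(table: SummaryStatTable, path) -> None:
    """Write a table in the default (tab-delimited) dialect."""
    df = table.records[list(DEFAULT_COLUMN_MAP)].rename(columns=DEFAULT_COLUMN_MAP)
    df.to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizedSet:
    """Exposure(s) and outcome effects aligned to one effect allele per variant.

    ``beta_exp``/``se_exp`` are J x K arrays (K exposures); ``beta_out``/
    ``se_out`` are length-J.  ``dropped`` lists (variant_id, reason) pairs
    for every requested instrument that was not retained.
    """

    exposure_names: list
    outcome_name: str
    variant_ids: list
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    dropped: list = field(default_factory=list)
    pval_out: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta_exp = np.atleast_2d(np.asarray(self.beta_exp, dtype=float))
        self.se_exp = np.atleast_2d(np.asarray(self.se_exp, dtype=float))
        if self.beta_exp.shape[0] == 1 and len(self.variant_ids) > 1:
            self.beta_exp = self.beta_exp.T
            self.se_exp = self.se_exp.T
        self.beta_out = np.asarray(self.beta_out, dtype=float)
        self.se_out = np.asarray(self.se_out, dtype=float)
        J = len(self.variant_ids)
        if self.beta_exp.shape != (J, len(self.exposure_names)):
            raise InputError(
                f"beta_exp shape {self.beta_exp.shape} inconsistent with "
                f"J={J}, K={len(self.exposure_names)}"
            )
        if np.any(self.se_exp <= 0) or np.any(self.se_out <= 0):
            raise InputError("all standard errors must be positive")
        retained = set(self.variant_ids)
        if retained & {v for v, _ in self.dropped}:
            raise InputError("a variant appears in both retained and dropped lists")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_exposures(self) -> int:
        return len(self.exposure_names)

    def exclude(self, variant_ids, reason: str = "excluded") -> "HarmonizedSet":
        """Return a copy with the given variants removed (for sensitivity refits)."""
        excluded = set(variant_ids)
        unknown = excluded - set(self.variant_ids)
        if unknown:
            raise InputError(f"variants not in harmonized set: {sorted(unknown)}")
        keep = np.array([v not in excluded for v in self.variant_ids], dtype=bool)
        return HarmonizedSet(
            exposure_names=list(self.exposure_names),
            outcome_name=self.outcome_name,
            variant_ids=[v for v in self.variant_ids if v not in excluded],
            beta_exp=self.beta_exp[keep],
            se_exp=self.se_exp[keep],
            beta_out=self.beta_out[keep],
            se_out=self.se_out[keep],
            dropped=list(self.dropped) + [(v, reason) for v in sorted(excluded)],
            pval_out=None if self.pval_out is None else self.pval_out[keep],
        )

    def select_exposures(self, indices) -> "HarmonizedSet":
        """Keep only the given exposure columns (variants unchanged)."""
        idx = list(indices)
        return HarmonizedSet(
            exposure_names=[self.exposure_names[i] for i in idx],
            outcome_name=self.outcome_name,
            variant_ids=list(self.variant_ids),
            beta_exp=self.beta_exp[:, idx],
            se_exp=self.se_exp[:, idx],
            beta_out=self.beta_out.copy(),
            se_out=self.se_out.copy(),
            dropped=list(self.dropped),
            pval_out=None if self.pval_out is None else self.pval_out.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Tab-ready long-format table (one row per variant x exposure)."""
        rows = []
        for k, name in enumerate(self.exposure_names):
            for j, vid in enumerate(self.variant_ids):
                rows.append(
                    dict(
                        variant_id=vid,
                        exposure=name,
                        beta_exp=self.beta_exp[j, k],
                        se_exp=self.se_exp[j, k],
                        beta_out=self.beta_out[j],
                        se_out=self.se_out[j],
                    )
                )
        return pd.DataFrame(rows)


def _match_orientation(ea_ref: str, oa_ref: str, ea: str, oa: str) -> int | None:
    """How do alleles (ea, oa) map onto the reference pair?

    Returns +1 (same orientation), -1 (swapped: the record's beta must be
    sign-flipped), or None if the pairs are irreconcilable.  Matching
    precedence: exact, swapped, strand complement, swapped complement.
    """
    if (ea, oa) == (ea_ref, oa_ref):
        return 1
    if (ea, oa) == (oa_ref, ea_ref):
        return -1
    ce, co = COMPLEMENT[ea], COMPLEMENT[oa]
    if (ce, co) == (ea_ref, oa_ref):
        return 1
    if (ce, co) == (oa_ref, ea_ref):
        return -1
    return None


def harmonize(
    exposures,
    outcome: SummaryStatTable,
    instrument_ids,
    direct_effect_p: float = 5e-8,
) -> HarmonizedSet:
    """Align exposure and outcome records to a common effect allele per variant.

    ``exposures`` is a single table or a list of K tables; ``instrument_ids``
    is the matching list of per-exposure instrument id lists (the union
    defines the candidate variants).  Filtering order per variant:
    missing in outcome/exposure -> palindromic -> allele mismatch ->
    direct effect on the outcome (p < ``direct_effect_p``).  The reference
    orientation is the instrument's home exposure record; other tables'
    betas are sign-flipped where their effect allele maps to the
    reference's other allele, directly or after strand complementation.
    """
    if isinstance(exposures, SummaryStatTable):
        exposures = [exposures]
        if instrument_ids and isinstance(instrument_ids[0], str):
            instrument_ids = [instrument_ids]
    if len(exposures) != len(instrument_ids):
        raise ConfigurationError("need one instrument list per exposure")

    K = len(exposures)
    # union of instruments, in first-seen order; remember the home exposure
    union: list[str] = []
    home: dict[str, int] = {}
    for k, ids in enumerate(instrument_ids):
        missing = [v for v in ids if v not in exposures[k]]
        if missing:
            raise InputError(
                f"instruments absent from exposure {exposures[k].trait_name!r}: {missing[:5]}"
            )
        for v in ids:
            if v not in home:
                home[v] = k
                union.append(v)

    dropped: list[tuple[str, str]] = []
    rows: list[dict] = []
    for vid in union:
        ref = exposures[home[vid]].records.loc[vid]
        ea_ref, oa_ref = ref["effect_allele"], ref["other_allele"]
        if ea_ref not in VALID_ALLELES or oa_ref not in VALID_ALLELES or ea_ref == oa_ref:
            dropped.append((vid, "allele_mismatch"))
            continue
        if is_palindromic(ea_ref, oa_ref):
            dropped.append((vid, "palindromic"))
            continue
        if vid not in outcome:
            dropped.append((vid, "missing_in_outcome"))
            continue

        bexp = np.zeros(K)
        sexp = np.full(K, np.nan)
        bad = None
        for k, table in enumerate(exposures):
            if vid not in table:
                bad = "missing_in_exposure"
                break
            rec = table.records.loc[vid]
            orient = _match_orientation(
                ea_ref, oa_ref, rec["effect_allele"], rec["other_allele"]
            )
            if orient is None:
                bad = "allele_mismatch"
                break
            bexp[k] = orient * rec["beta"]
            sexp[k] = rec["se"]
        if bad:
            dropped.append((vid, bad))
            continue

        orec = outcome.records.loc[vid]
        orient = _match_orientation(
            ea_ref, oa_ref, orec["effect_allele"], orec["other_allele"]
        )
        if orient is None:
            dropped.append((vid, "allele_mismatch"))
            continue
        p_out = orec["pvalue"]
        if pd.isna(p_out):
            p_out = float(_norm_pvalue(orec["beta"], orec["se"]))
        if p_out < direct_effect_p:
            dropped.append((vid, "direct_effect"))
            continue
        rows.append(
            dict(
                vid=vid,
                beta_exp=bexp,
                se_exp=sexp,
                beta_out=orient * orec["beta"],
                se_out=orec["se"],
                pval_out=p_out,
            )
        )

    if not rows:
        reasons = sorted({r for _, r in dropped})
        raise AnalysisError(
            f"harmonization retained zero variants (drop reasons: {reasons})"
        )

    return HarmonizedSet(
        exposure_names=[t.trait_name for t in exposures],
        outcome_name=outcome.trait_name,
        variant_ids=[r["vid"] for r in rows],
        beta_exp=np.array([r["beta_exp"] for r in rows]),
        se_exp=np.array([r["se_exp"] for r in rows]),
        beta_out=np.array([r["beta_out"] for r in rows]),
        se_out=np.array([r["se_out"] for r in rows]),
        dropped=dropped,
        pval_out=np.array([r["pval_out"] for r in rows]),
    )


def write_harmonized(h: HarmonizedSet, path, drop_log_path=None) -> None:
    """Write the harmonized table (TSV) and optionally the drop log."""
    h.to_frame().to_csv(path, sep="\t", index=False)
    if drop_log_path is not None:
        pd.DataFrame(h.dropped, columns=["variant_id", "reason"]).to_csv(
            drop_log_path, sep="\t", index=False
        )
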