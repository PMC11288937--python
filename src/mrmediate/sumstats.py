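"""GWAS summary-statistics I/O and validation.

A *trait panel* is the per-trait table of per-SNP association results
(beta, SE, alleles, effect-allele frequency, p-value, sample size) — the
only data the downstream causal analysis consumes.  Files are delimited
text (TSV/CSV, optionally gzipped) with one row per SNP; arbitrary column
headers are supported through a ``column_map``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyInputError, MissingColumnError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: canonical internal column order for a trait panel
STANDARD_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

#: default file dialect: the widely used exposure/outcome summary-stat headers
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "snp_id": "SNP",
    "chrom": "chr",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "samplesize",
}

#: eaf may be absent entirely; everything else is mandatory
_OPTIONAL_FIELDS = {"eaf"}


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-effect-allele effect on the log-odds scale for a
    binary trait or in SD units for a quantitative trait; ``pos`` is
    1-based.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float  # NaN when missing
    beta: float
    se: float
    pval: float
    n: int


@dataclass
class TraitPanel:
    """An ordered collection of per-SNP records for one trait, unique by snp_id."""

    trait_id: str
    trait_type: str  # exposure | mediator | outcome
    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in {"exposure", "mediator", "outcome"}:
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        missing = [c for c in STANDARD_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"panel dataframe lacks columns {missing}")
        if self.df["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_id in panel")

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> list[SummaryStatRecord]:
        return [
            SummaryStatRecord(
                snp_id=r.snp_id, chrom=str(r.chrom), pos=int(r.pos),
                effect_allele=r.effect_allele, other_allele=r.other_allele,
                eaf=float(r.eaf), beta=float(r.beta), se=float(r.se),
                pval=float(r.pval), n=int(r.n),
            )
            for r in self.df.itertuples(index=False)
        ]

    def subset(self, mask_or_index) -> "TraitPanel":
        sub = self.df.loc[mask_or_index].reset_index(drop=True)
        return TraitPanel(self.trait_id, self.trait_type, sub, dict(self.meta))


def _validate_frame(df: pd.DataFrame, *, wald_log10_tol: float = 0.5) -> tuple[pd.DataFrame, dict]:
    """Enforce record invariants, dropping offending rows and counting drops."""
    counts: dict[str, int] = {}
    df = df.copy()
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()

    def drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        k = int(mask.sum())
        if k:
            counts[reason] = counts.get(reason, 0) + k
            df = df.loc[~mask]

    drop(~df["effect_allele"].isin(VALID_ALLELES) | ~df["other_allele"].isin(VALID_ALLELES),
         "invalid_allele")
    drop(df["effect_allele"] == df["other_allele"], "identical_alleles")
    drop(df["beta"].isna() | df["se"].isna(), "missing_beta_se")
    drop(~(df["se"] > 0), "nonpositive_se")
    drop(df["pval"].isna() | ~((df["pval"] > 0) & (df["pval"] <= 1)), "pval_out_of_range")
    drop(df["pos"].isna() | (df["pos"] < 1), "bad_position")
    drop(df["n"].isna() | (df["n"] < 1), "bad_sample_size")
    # eaf outside [0,1] becomes missing rather than fatal
    bad_eaf = df["eaf"].notna() & ~df["eaf"].between(0.0, 1.0)
    if bad_eaf.any():
        counts["eaf_set_missing"] = int(bad_eaf.sum())
        df.loc[bad_eaf, "eaf"] = np.nan
    dup = df["snp_id"].duplicated()
    drop(dup, "duplicate_snp_id")

    # Wald consistency: reported p should match 2*Phi(-|beta/se|); log, never drop.
    with np.errstate(divide="ignore"):
        expected = 2.0 * stats.norm.sf(np.abs(df["beta"] / df["se"]))
        lo = np.log10(np.maximum(df["pval"].to_numpy(), 1e-300))
        le = np.log10(np.maximum(expected, 1e-300))
    n_incons = int((np.abs(lo - le) > wald_log10_tol).sum())
    if n_incons:
        counts["wald_inconsistent_logged"] = n_incons
        logger.warning("%d records have p-values inconsistent with beta/se (kept)", n_incons)

    df["pos"] = df["pos"].astype(np.int64)
    df["n"] = df["n"].astype(np.int64)
    return df.reset_index(drop=True), counts


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    trait_id: str | None = None,
    trait_type: str = "exposure",
    delimiter: str | None = None,
) -> TraitPanel:
    """Read, validate and normalize a summary-statistics table.

    Parameters
    ----------
    path
        Delimited text file with a header row; ``.gz`` handled transparently.
    column_map
        Mapping from standard field names (``snp_id``, ``beta``, ...) to the
        file's column headers; unspecified fields fall back to the default
        dialect (``SNP``, ``beta``, ``samplesize``, ...).
    delimiter
        Field separator; sniffed when omitted.

    Rows violating record invariants (se<=0, p outside (0,1], malformed
    alleles, duplicates, ...) are dropped and counted in ``panel.meta``;
    alleles are uppercased; input order is preserved.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c",
                      compression="infer")
    rename = {}
    for std, col in cmap.items():
        if col not in raw.columns:
            if std in _OPTIONAL_FIELDS:
                continue
            raise MissingColumnError(col, str(path))
        rename[col] = std
    df = raw.rename(columns=rename)
    if "eaf" not in df.columns:
        df["eaf"] = np.nan
    df = df[list(STANDARD_COLUMNS)]
    df, counts = _validate_frame(df)
    if len(df) == 0:
        raise EmptyInputError(f"no valid summary-statistic rows in {path}")
    dropped = sum(v for k, v in counts.items() if not k.endswith("_logged") and k != "eaf_set_missing")
    if dropped:
        logger.info("read_sumstats(%s): dropped %d invalid rows (%s)", path.name, dropped, counts)
    return TraitPanel(
        trait_id=trait_id or path.stem,
        trait_type=trait_type,
        df=df,
        meta={"source": str(path), "n_dropped": dropped, "drop_counts": counts},
    )


def panel_from_arrays(trait_id: str, trait_type: str, **cols) -> TraitPanel:
    """Build a panel directly from arrays (used by the simulator and tests)."""
    df = pd.DataFrame({c: cols[c] for c in STANDARD_COLUMNS})
    df["pos"] = df["pos"].astype(np.int64)
    df["n"] = df["n"].astype(np.int64)
    return TraitPanel(trait_id, trait_type, df)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

_MR_COLUMNS = [
    "result_type", "label", "method", "model", "nsnp",
    "beta", "se", "ci_low", "ci_high", "pval",
    "odds_ratio", "or_ci_low", "or_ci_high",
]
_MED_COLUMNS = [
    "result_type", "label", "total_Z", "se_total", "beta_X", "se_X", "beta_Y", "se_Y",
    "indirect_XY", "se_indirect", "indirect_ci_low", "indirect_ci_high", "indirect_or",
    "direct_Zprime", "proportion", "se_proportion", "proportion_ci_low", "proportion_ci_high",
]


def write_results(results: Sequence, path: str | Path) -> None:
    """Write MR and/or mediation results to a tab-separated table.

    Log-scale estimates are accompanied by their exponentiated (odds-ratio)
    counterparts.  Numeric values round-trip through :func:`read_results`
    to 12 significant digits.
    """
    if not results:
        raise ValueError("write_results: empty result collection")
    rows = []
    for res in results:
        rows.append(res.to_row())
    cols = list(dict.fromkeys(c for r in rows for c in r))
    # stable order: MR columns first, then mediation extras
    ordered = [c for c in _MR_COLUMNS + _MED_COLUMNS if c in cols]
    ordered += [c for c in cols if c not in ordered]
    df = pd.DataFrame(rows, columns=ordered)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a result table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")


def write_panel(panel: TraitPanel, path: str | Path) -> None:
    """Write a trait panel in the default file dialect."""
    out = panel.df.rename(columns=dict(DEFAULT_COLUMN_MAP))
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")
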