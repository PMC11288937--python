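"""Instrumental-variable selection.

Three stages, applied in order: a genome-wide significance screen
(p < 1e-5 by default, the conventional relaxed threshold for traits with
few genome-wide-significant loci), greedy LD clumping (r² < 0.001 within
10,000 kb), and an instrument-strength filter (F > 10, with the
summary-data approximation F = (beta/se)²).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import LDValidationError, NoInstrumentsError
from .sumstats import SummaryStatRecord, TraitPanel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds governing instrument selection.

    Attributes
    ----------
    p_threshold : exposure-association screen, retain p < p_threshold
    clump_r2 : LD pruning threshold on squared correlation
    clump_kb : clumping window in kilobases
    f_threshold : minimum instrument-strength F statistic
    """

    p_threshold: float = 1e-5
    clump_r2: float = 0.001
    clump_kb: int = 10_000
    f_threshold: float = 10.0

    def __post_init__(self) -> None:
        if not (self.p_threshold > 0 and self.clump_r2 > 0 and self.clump_kb > 0
                and self.f_threshold > 0):
            raise ValueError("all selection thresholds must be strictly positive")
        if self.clump_r2 >= 1:
            raise ValueError("clump_r2 must be < 1")


class LDMatrix:
    """Pairwise squared-correlation matrix over a set of SNPs.

    Symmetric, unit diagonal, entries in [0, 1].  SNPs absent from the
    matrix are treated as unlinked to everything (logged by the callers).
    """

    def __init__(self, snp_ids, r2):
        self.snp_ids = list(snp_ids)
        r2 = np.asarray(r2, dtype=float)
        if r2.ndim != 2 or r2.shape[0] != r2.shape[1] or r2.shape[0] != len(self.snp_ids):
            raise LDValidationError("r2 must be square and match snp_ids")
        if not np.allclose(r2, r2.T, atol=1e-8):
            raise LDValidationError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-8):
            raise LDValidationError("r2 diagonal must be 1")
        if r2.min() < -1e-12 or r2.max() > 1 + 1e-8:
            raise LDValidationError("r2 entries must lie in [0, 1]")
        self.r2 = r2
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r2_between(self, a: str, b: str) -> float:
        """Squared correlation between two SNPs; 0 when either is unknown."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r2[ia, ib])

    @classmethod
    def read(cls, path: str | Path) -> "LDMatrix":
        """Read the TSV dialect: first column snp_id, header row of snp_ids."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise LDValidationError(f"LD matrix in {path} is not square/aligned")
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))

    def write(self, path: str | Path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t", index_label="snp_id", float_format="%.12g")


@dataclass(frozen=True)
class InstrumentRecord:
    """A selected instrument together with its strength statistic."""

    record: SummaryStatRecord
    f_stat: float


def significance_screen(panel: TraitPanel, p_threshold: float) -> TraitPanel:
    """Retain SNPs associated with the trait at p < ``p_threshold``; order preserved."""
    kept = panel.subset(panel.df["pval"] < p_threshold)
    if len(kept) == 0:
        logger.warning("significance_screen(%s): no SNP passes p < %g",
                       panel.trait_id, p_threshold)
    return kept


def greedy_clump(panel: TraitPanel, ld: LDMatrix, config: SelectionConfig) -> TraitPanel:
    """Greedy LD clumping: keep the most significant SNP of every clump.

    SNPs are visited by ascending p-value (ties broken by snp_id for
    determinism); each accepted index SNP removes every remaining SNP on
    the same chromosome within ``clump_kb`` kilobases having
    r² >= ``clump_r2`` with it.  Output is ordered by (pval, snp_id) and
    therefore invariant to input row order.
    """
    df = panel.df.sort_values(["pval", "snp_id"], kind="mergesort").reset_index(drop=True)
    missing = [s for s in df["snp_id"] if s not in ld]
    if missing:
        logger.info("greedy_clump: %d SNPs absent from LD matrix, treated as unlinked",
                    len(missing))
    window_bp = config.clump_kb * 1000
    removed: set[str] = set()
    index_ids: list[str] = []
    rows = list(df.itertuples(index=False))
    for i, row in enumerate(rows):
        if row.snp_id in removed:
            continue
        index_ids.append(row.snp_id)
        for other in rows[i + 1:]:
            if other.snp_id in removed or other.chrom != row.chrom:
                continue
            if abs(int(other.pos) - int(row.pos)) < window_bp and \
                    ld.r2_between(row.snp_id, other.snp_id) >= config.clump_r2:
                removed.add(other.snp_id)
    out = df[df["snp_id"].isin(index_ids)].reset_index(drop=True)
    return TraitPanel(panel.trait_id, panel.trait_type, out, dict(panel.meta))


def compute_f(record: SummaryStatRecord) -> InstrumentRecord:
    """Instrument strength by the summary-data approximation F = (beta/se)²."""
    if not record.se > 0:
        raise ValueError("compute_f requires se > 0")
    return InstrumentRecord(record=record, f_stat=(record.beta / record.se) ** 2)


def select_instruments(panel: TraitPanel, ld: LDMatrix, config: SelectionConfig) -> TraitPanel:
    """Full selection: significance screen → LD clumping → F filter.

    Returns the instrument panel with an ``f_stat`` column appended.
    Raises :class:`NoInstrumentsError` when nothing survives.
    """
    screened = significance_screen(panel, config.p_threshold)
    clumped = greedy_clump(screened, ld, config) if len(screened) else screened
    df = clumped.df.copy()
    df["f_stat"] = (df["beta"] / df["se"]) ** 2
    strong = df[df["f_stat"] > config.f_threshold].reset_index(drop=True)
    logger.info("select_instruments(%s): %d input, %d pass p<%g, %d after clumping, "
                "%d with F>%g", panel.trait_id, len(panel), len(screened),
                config.p_threshold, len(clumped), len(strong), config.f_threshold)
    if len(strong) == 0:
        raise NoInstrumentsError(
            f"no valid instruments for {panel.trait_id} "
            f"(p<{config.p_threshold:g}, r2<{config.clump_r2:g}, F>{config.f_threshold:g})")
    out = TraitPanel(panel.trait_id, panel.trait_type, strong, dict(panel.meta))
    out.meta["selection"] = {
        "n_input": len(panel), "n_screened": len(screened),
        "n_clumped": len(clumped), "n_instruments": len(strong),
    }
    return out
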