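"""Allele harmonization between an exposure instrument set and an outcome panel.

Two-sample MR requires the exposure and outcome effects of every shared
SNP to refer to the same effect allele.  Swapped alleles are resolved by
negating the outcome beta (and reflecting its frequency); strand flips
are resolved by complementing; palindromic SNPs (A/T, C/G) — whose
strand cannot be inferred from allele labels — are resolved through
allele frequencies or dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sumstats import TraitPanel

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: actions recorded per retained/dropped pair
ACTIONS = ("none", "flipped", "strand_corrected", "dropped_palindromic", "dropped_mismatch")

PAIR_COLUMNS = ["snp_id", "beta_exp", "se_exp", "eaf_exp",
                "beta_out", "se_out", "eaf_out", "action"]


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome effects for one SNP on a common effect allele."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float
    eaf_out: float
    action: str = "none"


class HarmonizedPairs:
    """Collection of harmonized pairs plus the exclusion log.

    ``df`` holds the retained pairs (columns :data:`PAIR_COLUMNS`);
    ``exclusions`` records every dropped instrument with its reason.
    """

    def __init__(self, df: pd.DataFrame, exclusions: pd.DataFrame | None = None):
        self.df = df.reset_index(drop=True)
        self.exclusions = exclusions if exclusions is not None else \
            pd.DataFrame(columns=["snp_id", "reason"])

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for r in self.df.itertuples(index=False):
            yield HarmonizedPair(r.snp_id, r.beta_exp, r.se_exp, r.beta_out,
                                 r.se_out, r.eaf_exp, r.eaf_out, r.action)

    def arrays(self):
        d = self.df
        return (d["beta_exp"].to_numpy(float), d["se_exp"].to_numpy(float),
                d["beta_out"].to_numpy(float), d["se_out"].to_numpy(float))


def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT[a1] == a2


def harmonize(exposure: TraitPanel, outcome: TraitPanel,
              palindrome_eaf_window: float = 0.08) -> HarmonizedPairs:
    """Align outcome effects to the exposure's effect alleles, SNP by SNP.

    Resolution order per instrument found in the outcome panel:

    * identical alleles → keep as is;
    * swapped alleles → negate the outcome beta, reflect its EAF (``flipped``);
    * strand complements → complement the outcome alleles, then re-apply the
      two rules above (``strand_corrected``);
    * palindromic SNPs → kept only when both EAFs are present, both lie
      outside ``0.5 ± palindrome_eaf_window`` and fall on the same side of
      0.5 after alignment; otherwise ``dropped_palindromic``;
    * anything else → ``dropped_mismatch``.

    Instruments absent from the outcome panel are dropped with a log entry
    (no proxy-SNP search).  The operation is idempotent: harmonizing
    already-aligned panels changes nothing.
    """
    w = float(palindrome_eaf_window)
    out_idx = outcome.df.set_index("snp_id")
    rows: list[dict] = []
    excl: list[dict] = []

    for e in exposure.df.itertuples(index=False):
        if e.snp_id not in out_idx.index:
            excl.append({"snp_id": e.snp_id, "reason": "absent_from_outcome"})
            continue
        o = out_idx.loc[e.snp_id]
        ea_e, oa_e = e.effect_allele, e.other_allele
        ea_o, oa_o = str(o["effect_allele"]), str(o["other_allele"])
        beta_out, eaf_out = float(o["beta"]), float(o["eaf"])
        se_out = float(o["se"])

        def emit(beta_o: float, eaf_o: float, action: str) -> None:
            rows.append({
                "snp_id": e.snp_id, "beta_exp": float(e.beta), "se_exp": float(e.se),
                "eaf_exp": float(e.eaf), "beta_out": beta_o, "se_out": se_out,
                "eaf_out": eaf_o, "action": action,
            })

        if _is_palindromic(ea_e, oa_e):
            if {ea_o, oa_o} != {ea_e, oa_e}:
                excl.append({"snp_id": e.snp_id, "reason": "dropped_mismatch"})
                continue
            flip = ea_o != ea_e  # label orientation; strand is unknowable here
            eaf_o_aligned = 1.0 - eaf_out if flip else eaf_out
            ok = (not np.isnan(e.eaf) and not np.isnan(eaf_o_aligned)
                  and abs(e.eaf - 0.5) > w and abs(eaf_o_aligned - 0.5) > w
                  and (e.eaf - 0.5) * (eaf_o_aligned - 0.5) > 0)
            if ok:
                emit(-beta_out if flip else beta_out, eaf_o_aligned,
                     "flipped" if flip else "none")
            else:
                excl.append({"snp_id": e.snp_id, "reason": "dropped_palindromic"})
            continue

        strand = False
        if (ea_o, oa_o) not in ((ea_e, oa_e), (oa_e, ea_e)):
            cea, coa = COMPLEMENT[ea_o], COMPLEMENT[oa_o]
            if (cea, coa) in ((ea_e, oa_e), (oa_e, ea_e)):
                ea_o, oa_o, strand = cea, coa, True
            else:
                excl.append({"snp_id": e.snp_id, "reason": "dropped_mismatch"})
                continue
        if (ea_o, oa_o) == (ea_e, oa_e):
            emit(beta_out, eaf_out, "strand_corrected" if strand else "none")
        else:  # swapped
            emit(-beta_out, 1.0 - eaf_out if not np.isnan(eaf_out) else np.nan,
                 "strand_corrected" if strand else "flipped")

    if excl:
        logger.info("harmonize: dropped %d of %d instruments (%s)",
                    len(excl), len(exposure), pd.DataFrame(excl)["reason"].value_counts().to_dict())
    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return HarmonizedPairs(pairs, pd.DataFrame(excl, columns=["snp_id", "reason"]))
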