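"""End-to-end orchestration: forward screen, reverse-MR filter, top-exposure
selection, mediator screen and mediation.

The screening rule applied to every exposure-outcome MR is the three-part
filter: (1) IVW p < 0.05; (2) consistent direction among IVW, MR-Egger and
weighted median; (3) no heterogeneity (Cochran Q p >= 0.05) and no
horizontal pleiotropy (Egger intercept p >= 0.05).  No multiple-testing
correction is applied; the run manifest records the number of tests so
users can apply their own.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .errors import (InsufficientInstrumentsError, MRMediateError,
                     NoInstrumentsError, NoQualifyingExposureError)
from .estimators import MRFit, MRModel, SensitivityReport
from .harmonize import harmonize
from .instruments import LDMatrix, SelectionConfig, select_instruments
from .mediation import MediationResult, decompose, direction_compatible
from .sumstats import TraitPanel, write_results

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    """Outcome of the three-part filter for one exposure (or reverse) MR."""

    trait_id: str
    mr_results: dict = field(default_factory=dict)
    sensitivity: SensitivityReport = field(default_factory=SensitivityReport)
    consistency: Optional[bool] = None
    passed: bool = False
    reverse_passed: Optional[bool] = None  # None = not evaluated
    n_instruments: int = 0
    error: Optional[str] = None

    @property
    def ivw_pval(self) -> float:
        r = self.mr_results.get("ivw")
        return r.pval if r is not None else float("inf")


def _trait_seed(seed: int, trait_id: str) -> int:
    """Stable per-trait seed, independent of batch order, below 2**31."""
    return (int(seed) ^ zlib.crc32(trait_id.encode())) % (2**31 - 1)


def _mr_screen(exposure: TraitPanel, outcome: TraitPanel, ld: LDMatrix,
               config: SelectionConfig, seed: int,
               exclude_snps: Sequence[str] | None = None) -> ScreenResult:
    """Select instruments, harmonize and run the MR battery for one pairing."""
    res = ScreenResult(trait_id=exposure.trait_id)
    try:
        panel = exposure
        if exclude_snps:
            panel = panel.subset(~panel.df["snp_id"].isin(set(exclude_snps)))
        instruments = select_instruments(panel, ld, config)
        pairs = harmonize(instruments, outcome)
        if len(pairs) == 0:
            raise NoInstrumentsError("no instruments survive harmonization")
        fit: MRFit = MRModel.from_pairs(pairs, label=exposure.trait_id).fit(
            "all", seed=_trait_seed(seed, exposure.trait_id)).fit
        res.mr_results = fit.results
        res.sensitivity = fit.sensitivity
        res.consistency = fit.consistency
        res.n_instruments = len(pairs)
        ivw_res = fit.results.get("ivw")
        res.passed = bool(
            ivw_res is not None and ivw_res.pval < 0.05
            and fit.consistency is True
            and not fit.sensitivity.heterogeneity_flag
            and not fit.sensitivity.pleiotropy_flag)
    except (NoInstrumentsError, InsufficientInstrumentsError, MRMediateError) as exc:
        res.error = str(exc)
        logger.warning("screen(%s) failed: %s", exposure.trait_id, exc)
    return res


def forward_screen(exposures: Sequence[TraitPanel], outcome: TraitPanel,
                   ld: LDMatrix, config: SelectionConfig, seed: int) -> list[ScreenResult]:
    """Screen every exposure against the outcome; failures never abort the batch.

    Results are sorted by ascending IVW p-value (failed traits last).
    """
    if len(outcome) == 0:
        raise MRMediateError("outcome panel is empty")
    results = [_mr_screen(e, outcome, ld, config, seed) for e in exposures]
    results.sort(key=lambda r: (r.ivw_pval, r.trait_id))
    return results


def reverse_mr(outcome_as_exposure: TraitPanel, exposure_as_outcome: TraitPanel,
               ld: LDMatrix, config: SelectionConfig, seed: int,
               exclude_snps: Sequence[str] | None = None) -> ScreenResult:
    """Role-swapped MR to screen for reverse causation.

    ``exclude_snps`` (typically the forward analysis' instrument SNPs) are
    removed from the reverse instrument search: under a true forward
    effect those SNPs reach significance in a well-powered outcome GWAS
    and would mechanically produce a spurious reverse signal.
    ``reverse_passed`` is True when the reverse IVW p >= 0.05 (no reverse
    signal), None when no reverse instruments exist (not evaluable).
    """
    res = _mr_screen(outcome_as_exposure, exposure_as_outcome, ld, config, seed,
                     exclude_snps=exclude_snps)
    if res.error is not None or "ivw" not in res.mr_results:
        res.reverse_passed = None
    else:
        res.reverse_passed = bool(res.mr_results["ivw"].pval >= 0.05)
    return res


def select_top(screen: Sequence[ScreenResult]) -> ScreenResult:
    """The passed, reverse-passed exposure with the smallest IVW p (ties by id)."""
    qualifying = [r for r in screen if r.passed and r.reverse_passed is True]
    if not qualifying:
        raise NoQualifyingExposureError(
            "no exposure passed both the forward filter and the reverse-MR filter")
    return min(qualifying, key=lambda r: (r.ivw_pval, r.trait_id))


def two_step_mediation(exposure: TraitPanel, mediator: TraitPanel,
                       outcome: TraitPanel, ld: LDMatrix, config: SelectionConfig,
                       seed: int) -> MediationResult:
    """Unfiltered mediation estimate for one exposure-mediator-outcome triple.

    Runs the three MRs (total, step 1, step 2, each with its own
    instrument selection) and decomposes, with no significance gating —
    used for parameter-recovery studies where conditioning on filters
    would bias the average.
    """
    instruments = select_instruments(exposure, ld, config)
    total = MRModel.from_pairs(harmonize(instruments, outcome)).fit(
        "ivw", seed=seed).fit.results["ivw"]
    step1 = MRModel.from_pairs(harmonize(instruments, mediator)).fit(
        "ivw", seed=seed).fit.results["ivw"]
    med_instruments = select_instruments(mediator, ld, config)
    step2 = MRModel.from_pairs(harmonize(med_instruments, outcome)).fit(
        "ivw", seed=seed).fit.results["ivw"]
    return decompose(total, step1, step2, label=mediator.trait_id)


def mediator_screen(top_exposure: TraitPanel, mediators: Sequence[TraitPanel],
                    outcome: TraitPanel, ld: LDMatrix, config: SelectionConfig,
                    seed: int) -> tuple[list[MediationResult], pd.DataFrame]:
    """Two-step screen over candidate mediators, then mediation decomposition.

    Step 1 (exposure→mediator) reuses one fixed instrument set selected
    from the top exposure; step 2 (mediator→outcome) selects instruments
    per mediator from its own panel.  Both steps must pass the three-part
    filter; survivors must additionally be direction-compatible with the
    total effect.  Exclusions are returned with reasons, never raised.
    """
    exclusions: list[dict] = []
    results: list[MediationResult] = []
    exp_instruments = select_instruments(top_exposure, ld, config)
    total_fit = MRModel.from_pairs(
        harmonize(exp_instruments, outcome), label=top_exposure.trait_id).fit(
        "all", seed=_trait_seed(seed, top_exposure.trait_id)).fit
    total = total_fit.results["ivw"]

    for med in mediators:
        step1_res = _mr_screen_pairs(exp_instruments, med, seed)
        if step1_res.error or not step1_res.passed:
            exclusions.append({"mediator": med.trait_id, "stage": "step1",
                               "reason": step1_res.error or "failed three-part filter"})
            continue
        step2_res = _mr_screen(med, outcome, ld, config, seed)
        if step2_res.error or not step2_res.passed:
            exclusions.append({"mediator": med.trait_id, "stage": "step2",
                               "reason": step2_res.error or "failed three-part filter"})
            continue
        s1 = step1_res.mr_results["ivw"]
        s2 = step2_res.mr_results["ivw"]
        if not direction_compatible(s1, s2, total):
            exclusions.append({"mediator": med.trait_id, "stage": "direction",
                               "reason": "indirect path opposes total effect"})
            continue
        results.append(decompose(total, s1, s2, label=med.trait_id))
    excl_df = pd.DataFrame(exclusions, columns=["mediator", "stage", "reason"])
    if len(excl_df):
        logger.info("mediator_screen: %d/%d mediators excluded",
                    len(excl_df), len(mediators))
    return results, excl_df


def _mr_screen_pairs(exp_instruments: TraitPanel, outcome: TraitPanel,
                     seed: int) -> ScreenResult:
    """Three-part filter using a pre-selected instrument set (step 1)."""
    res = ScreenResult(trait_id=outcome.trait_id)
    try:
        pairs = harmonize(exp_instruments, outcome)
        if len(pairs) == 0:
            raise NoInstrumentsError("no instruments survive harmonization")
        fit = MRModel.from_pairs(pairs, label=outcome.trait_id).fit(
            "all", seed=_trait_seed(seed, outcome.trait_id)).fit
        res.mr_results, res.sensitivity = fit.results, fit.sensitivity
        res.consistency, res.n_instruments = fit.consistency, len(pairs)
        ivw_res = fit.results.get("ivw")
        res.passed = bool(ivw_res is not None and ivw_res.pval < 0.05
                          and fit.consistency is True
                          and not fit.sensitivity.heterogeneity_flag
                          and not fit.sensitivity.pleiotropy_flag)
    except MRMediateError as exc:
        res.error = str(exc)
    return res


# ---------------------------------------------------------------------------
# full run with reporting
# ---------------------------------------------------------------------------

def _screen_frame(screen: Sequence[ScreenResult]) -> pd.DataFrame:
    rows = []
    for r in screen:
        row = {"trait_id": r.trait_id, "nsnp": r.n_instruments,
               "consistency": r.consistency, "passed": r.passed,
               "reverse_passed": r.reverse_passed, "error": r.error or ""}
        for m, mr in r.mr_results.items():
            row[f"{m}_beta"] = mr.beta
            row[f"{m}_or"] = mr.odds_ratio
            row[f"{m}_pval"] = mr.pval
        s = r.sensitivity
        row["q_pval"] = s.q_pval
        row["egger_intercept_pval"] = s.intercept_pval
        rows.append(row)
    return pd.DataFrame(rows)


def run_all(exposures: Sequence[TraitPanel], mediators: Sequence[TraitPanel],
            outcome: TraitPanel, ld: LDMatrix, config: SelectionConfig,
            seed: int, out_dir: str | Path) -> dict:
    """Full design: forward screen → reverse filter → top exposure →
    mediator screen → mediation; writes result tables and a JSON manifest.

    Returns a summary dict; identical inputs and seed produce
    byte-identical output files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    screen = forward_screen(exposures, outcome, ld, config, seed)
    by_id = {p.trait_id: p for p in exposures}
    for r in screen:
        if not r.passed:
            continue
        fwd_snps = None
        try:
            fwd_snps = list(select_instruments(by_id[r.trait_id], ld, config).df["snp_id"])
        except MRMediateError:
            pass
        rev = reverse_mr(outcome, by_id[r.trait_id], ld, config, seed,
                         exclude_snps=fwd_snps)
        r.reverse_passed = rev.reverse_passed

    screen_df = _screen_frame(screen)
    screen_df.to_csv(out / "screen.tsv", sep="\t", index=False, float_format="%.12g")

    top_id, med_results, excl_df = None, [], pd.DataFrame(
        columns=["mediator", "stage", "reason"])
    try:
        top = select_top(screen)
        top_id = top.trait_id
        med_results, excl_df = mediator_screen(by_id[top_id], mediators, outcome,
                                               ld, config, seed)
    except NoQualifyingExposureError as exc:
        logger.warning("run_all: %s", exc)
    if med_results:
        write_results(med_results, out / "mediation.tsv")
    excl_df.to_csv(out / "exclusions.tsv", sep="\t", index=False)

    manifest = {
        "package": "mrmediate",
        "version": __version__,
        "seed": int(seed),
        "selection": {"p_threshold": config.p_threshold, "clump_r2": config.clump_r2,
                      "clump_kb": config.clump_kb, "f_threshold": config.f_threshold},
        "n_exposures_tested": len(exposures),
        "n_mediators_tested": len(mediators),
        "multiple_testing_correction": "none",
        "top_exposure": top_id,
        "n_mediation_results": len(med_results),
        "weighted_median_se": "parametric bootstrap (1000 reps)",
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"screen": screen, "top_exposure": top_id,
            "mediation": med_results, "exclusions": excl_df}
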