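"""Two-sample MR estimators and diagnostics.

Given J harmonized SNPs with exposure effects x_j (SE sx_j) and outcome
effects y_j (SE sy_j), the per-SNP Wald ratio is b_j = y_j / x_j with
first-order standard error s_j = sy_j / |x_j| (exposure-side uncertainty
ignored, the standard summary-data convention).

* **IVW**: inverse-variance-weighted mean of the ratios,
  ``beta = sum(w_j b_j) / sum(w_j)`` with ``w_j = 1/s_j²``; algebraically
  the zero-intercept weighted-least-squares slope of y on x with weights
  1/sy².  Cochran's Q drives the fixed- vs multiplicative-random-effects
  choice (variance inflation ``max(1, Q/(J-1))`` when the Q test rejects
  at 0.05).
* **MR-Egger**: weighted regression of y on x *with* a free intercept
  (pairs oriented so x_j > 0); the intercept estimates average
  directional pleiotropy, the slope is the pleiotropy-adjusted causal
  effect.  Inference uses t(J-2) with residual dispersion floored at 1.
* **Weighted median**: the 50% point of the inverse-variance-weight-ordered
  ratios, consistent when valid instruments carry at least half the
  weight; SE by parametric bootstrap.

Estimates are carried on the log-odds (or SD-unit) scale throughout;
odds ratios appear only at reporting time.

The statsmodels-style surface is :class:`MRModel` (construct from
harmonized pairs or arrays) whose :meth:`MRModel.fit` returns
:class:`MRResults` with estimates, uncertainties, diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInstrumentError, InsufficientInstrumentsError
from .harmonize import HarmonizedPair, HarmonizedPairs

Z95 = 1.959964  # two-sided 95% normal quantile, fixed for reproducibility

METHOD_LABELS = {
    "ivw": "Inverse variance weighted",
    "egger": "MR-Egger",
    "weighted_median": "Weighted median",
    "wald_ratio": "Wald ratio",
}


@dataclass(frozen=True)
class MRResult:
    """One method's causal estimate on the log scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    nsnp: int
    model: str = "not_applicable"  # fixed | multiplicative_random | not_applicable
    label: str | None = None

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)

    @classmethod
    def from_odds_ratio(cls, odds_ratio: float, ci_low: float, ci_high: float,
                        *, method: str = "ivw", nsnp: int = 0,
                        label: str | None = None) -> "MRResult":
        """Reconstruct a log-scale result from a printed OR and 95% CI.

        The SE is recovered from the CI width: se = (ln hi − ln lo)/(2·1.959964).
        """
        beta = math.log(odds_ratio)
        lo, hi = math.log(ci_low), math.log(ci_high)
        se = (hi - lo) / (2.0 * Z95)
        pval = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else float(beta == 0.0)
        return cls(method=method, beta=beta, se=se, ci_low=lo, ci_high=hi,
                   pval=pval, nsnp=nsnp, label=label)

    def to_row(self) -> dict:
        lo_or, hi_or = self.or_ci
        return {
            "result_type": "mr", "label": self.label or "", "method": self.method,
            "model": self.model, "nsnp": self.nsnp, "beta": self.beta, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "pval": self.pval,
            "odds_ratio": self.odds_ratio, "or_ci_low": lo_or, "or_ci_high": hi_or,
        }


@dataclass(frozen=True)
class SensitivityReport:
    """Heterogeneity (Cochran's Q) and pleiotropy (Egger intercept) diagnostics."""

    q_stat: float = float("nan")
    q_df: int = 0
    q_pval: float = float("nan")
    egger_intercept: float = float("nan")
    intercept_se: float = float("nan")
    intercept_pval: float = float("nan")

    @property
    def heterogeneity_flag(self) -> bool:
        return bool(np.isfinite(self.q_pval) and self.q_pval < 0.05)

    @property
    def pleiotropy_flag(self) -> bool:
        return bool(np.isfinite(self.intercept_pval) and self.intercept_pval < 0.05)


def _pairs_arrays(pairs) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(pairs, HarmonizedPairs):
        return pairs.arrays()
    if isinstance(pairs, pd.DataFrame):
        return (pairs["beta_exp"].to_numpy(float), pairs["se_exp"].to_numpy(float),
                pairs["beta_out"].to_numpy(float), pairs["se_out"].to_numpy(float))
    if isinstance(pairs, (list, tuple)) and pairs and isinstance(pairs[0], HarmonizedPair):
        a = np.array([[p.beta_exp, p.se_exp, p.beta_out, p.se_out] for p in pairs])
        return a[:, 0], a[:, 1], a[:, 2], a[:, 3]
    arr = [np.asarray(a, dtype=float) for a in pairs]
    if len(arr) != 4:
        raise TypeError("pairs must be HarmonizedPairs, a DataFrame, HarmonizedPair list, "
                        "or a 4-tuple of arrays (beta_exp, se_exp, beta_out, se_out)")
    return arr[0], arr[1], arr[2], arr[3]


def _ratios(bx, sx, by, sy):
    if np.any(bx == 0):
        raise DegenerateInstrumentError("beta_exp = 0 for at least one instrument")
    return by / bx, sy / np.abs(bx)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def wald_ratio(pair) -> MRResult:
    """Single-SNP causal estimate: beta_out/beta_exp with SE se_out/|beta_exp|."""
    if isinstance(pair, HarmonizedPair):
        bx, sx, by, sy = pair.beta_exp, pair.se_exp, pair.beta_out, pair.se_out
    else:
        bx, sx, by, sy = (float(v) for v in pair)
    if bx == 0:
        raise DegenerateInstrumentError("Wald ratio undefined for beta_exp = 0")
    beta = by / bx
    se = sy / abs(bx)
    p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else float(beta == 0.0)
    return MRResult("wald_ratio", beta, se, beta - Z95 * se, beta + Z95 * se, p, 1)


def ivw(pairs) -> tuple[MRResult, SensitivityReport]:
    """Inverse-variance-weighted meta-analysis of the per-SNP Wald ratios.

    Fixed-effect by default; when the Cochran Q test rejects homogeneity
    at 0.05 the SE is inflated multiplicatively by sqrt(max(1, Q/(J-1)))
    (multiplicative random effects).
    """
    bx, sx, by, sy = _pairs_arrays(pairs)
    j = len(bx)
    if j < 2:
        raise InsufficientInstrumentsError("IVW needs >= 2 SNPs; use wald_ratio for one")
    b, s = _ratios(bx, sx, by, sy)
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (b - beta) ** 2))
    q_df = j - 1
    q_p = float(stats.chi2.sf(q, q_df))
    if q_p < 0.05:
        model = "multiplicative_random"
        se = se_fixed * math.sqrt(max(1.0, q / q_df))
    else:
        model = "fixed"
        se = se_fixed
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    res = MRResult("ivw", beta, se, beta - Z95 * se, beta + Z95 * se, float(p), j, model)
    return res, SensitivityReport(q_stat=q, q_df=q_df, q_pval=q_p)


def egger(pairs) -> tuple[MRResult, SensitivityReport]:
    """MR-Egger regression: weighted LS of outcome on exposure effects with intercept.

    Pairs are oriented so every exposure effect is positive (negating both
    members of a pair leaves the model invariant).  Slope and intercept use
    t(J-2) inference with multiplicative residual dispersion floored at 1.
    """
    bx, sx, by, sy = _pairs_arrays(pairs)
    j = len(bx)
    if j < 3:
        raise InsufficientInstrumentsError("MR-Egger needs >= 3 SNPs")
    sgn = np.where(bx < 0, -1.0, 1.0)
    x = bx * sgn
    y = by * sgn
    w = 1.0 / sy**2
    # closed-form WLS with intercept
    sw, swx, swy = w.sum(), (w * x).sum(), (w * y).sum()
    swxx, swxy = (w * x * x).sum(), (w * x * y).sum()
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid = y - intercept - slope * x
    sigma2 = float((w * resid**2).sum() / (j - 2))
    disp = max(sigma2, 1.0)  # dispersion floored at 1
    se_slope = math.sqrt(disp * sw / det)
    se_int = math.sqrt(disp * swxx / det)
    p_slope = 2.0 * stats.t.sf(abs(slope) / se_slope, j - 2)
    p_int = 2.0 * stats.t.sf(abs(intercept) / se_int, j - 2)
    res = MRResult("egger", float(slope), se_slope, slope - Z95 * se_slope,
                   slope + Z95 * se_slope, float(p_slope), j)
    rep = SensitivityReport(egger_intercept=float(intercept), intercept_se=se_int,
                            intercept_pval=float(p_int))
    return res, rep


def _weighted_median(b: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median at cumulative midpoint rank 0.5."""
    order = np.argsort(b, kind="mergesort")
    bs, ws = b[order], w[order]
    total = ws.sum()
    p = (np.cumsum(ws) - 0.5 * ws) / total
    return float(np.interp(0.5, p, bs))


def weighted_median(pairs, n_boot: int = 1000, seed: int | None = None) -> MRResult:
    """Weighted-median estimator with parametric-bootstrap standard error.

    The estimate interpolates the weight-ordered Wald ratios at cumulative
    midpoint rank 0.5, using the same inverse-variance weights as IVW; it
    remains consistent when up to 50% of the weight sits on invalid
    instruments.  The SE resamples each (beta_exp, beta_out) from its
    normal sampling distribution ``n_boot`` times; deterministic given
    ``seed``.
    """
    bx, sx, by, sy = _pairs_arrays(pairs)
    j = len(bx)
    if j < 3:
        raise InsufficientInstrumentsError("weighted median needs >= 3 SNPs")
    b, s = _ratios(bx, sx, by, sy)
    w = 1.0 / s**2
    beta = _weighted_median(b, w)
    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_boot, j))
    bys = rng.normal(by, sy, size=(n_boot, j))
    bxs = np.where(bxs == 0.0, np.finfo(float).tiny, bxs)  # measure-zero guard
    bs = bys / bxs
    wsb = (bxs / sy) ** 2
    reps = np.empty(n_boot)
    for k in range(n_boot):
        reps[k] = _weighted_median(bs[k], wsb[k])
    se = float(np.std(reps, ddof=1))
    p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else float(beta == 0.0)
    return MRResult("weighted_median", beta, se, beta - Z95 * se, beta + Z95 * se,
                    float(p), j)


@dataclass(frozen=True)
class MRFit:
    """Battery of MR estimates for one exposure-outcome pairing."""

    results: dict
    sensitivity: SensitivityReport
    consistency: Optional[bool]

    @property
    def ivw(self) -> MRResult | None:
        return self.results.get("ivw")

    def __iter__(self):
        return iter(self.results.values())


def run_mr(pairs, seed: int | None = None, n_boot: int = 1000) -> MRFit:
    """Run every applicable estimator and collect diagnostics.

    J >= 3 runs IVW, MR-Egger and the weighted median; J == 2 runs IVW
    only; J == 1 falls back to the single-SNP Wald ratio.  ``consistency``
    is True when all point estimates share one sign, None when fewer than
    two estimators ran (not evaluable).  Nothing is filtered here —
    filtering rules belong to the pipeline.
    """
    bx, sx, by, sy = _pairs_arrays(pairs)
    j = len(bx)
    results: dict[str, MRResult] = {}
    if j == 0:
        raise InsufficientInstrumentsError("no harmonized pairs")
    if j == 1:
        results["wald_ratio"] = wald_ratio((bx[0], sx[0], by[0], sy[0]))
        return MRFit(results, SensitivityReport(), None)
    res_ivw, rep_ivw = ivw(pairs)
    results["ivw"] = res_ivw
    if j == 2:
        return MRFit(results, rep_ivw, None)
    res_egger, rep_egger = egger(pairs)
    results["egger"] = res_egger
    results["weighted_median"] = weighted_median(pairs, n_boot=n_boot, seed=seed)
    report = SensitivityReport(
        q_stat=rep_ivw.q_stat, q_df=rep_ivw.q_df, q_pval=rep_ivw.q_pval,
        egger_intercept=rep_egger.egger_intercept,
        intercept_se=rep_egger.intercept_se, intercept_pval=rep_egger.intercept_pval)
    signs = {1 if r.beta > 0 else (-1 if r.beta < 0 else 0) for r in results.values()}
    consistency = len(signs) == 1 and 0 not in signs
    return MRFit(results, report, consistency)


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class MRModel:
    """Two-sample MR model over a set of harmonized instruments.

    Parameters
    ----------
    beta_exposure, se_exposure, beta_outcome, se_outcome
        Per-SNP effect estimates on a common effect-allele orientation.
    snp_ids
        Optional identifiers, used in plots.

    Examples
    --------
    >>> model = MRModel.from_pairs(pairs)
    >>> fit = model.fit()          # IVW
    >>> fit = model.fit("all", seed=17)
    >>> print(fit.summary())
    """

    def __init__(self, beta_exposure, se_exposure, beta_outcome, se_outcome,
                 snp_ids: Sequence[str] | None = None, label: str | None = None):
        self.beta_exposure = np.asarray(beta_exposure, dtype=float)
        self.se_exposure = np.asarray(se_exposure, dtype=float)
        self.beta_outcome = np.asarray(beta_outcome, dtype=float)
        self.se_outcome = np.asarray(se_outcome, dtype=float)
        if not (len(self.beta_exposure) == len(self.se_exposure)
                == len(self.beta_outcome) == len(self.se_outcome)):
            raise ValueError("all effect/SE arrays must have equal length")
        if np.any(self.se_exposure <= 0) or np.any(self.se_outcome <= 0):
            raise ValueError("standard errors must be positive")
        self.snp_ids = list(snp_ids) if snp_ids is not None else \
            [f"snp{i}" for i in range(len(self.beta_exposure))]
        self.label = label

    @classmethod
    def from_pairs(cls, pairs: HarmonizedPairs, label: str | None = None) -> "MRModel":
        bx, sx, by, sy = pairs.arrays()
        return cls(bx, sx, by, sy, snp_ids=list(pairs.df["snp_id"]), label=label)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, *, beta_exp: str = "beta_exp",
                       se_exp: str = "se_exp", beta_out: str = "beta_out",
                       se_out: str = "se_out", snp_id: str = "snp_id",
                       label: str | None = None) -> "MRModel":
        ids = list(df[snp_id]) if snp_id in df.columns else None
        return cls(df[beta_exp], df[se_exp], df[beta_out], df[se_out],
                   snp_ids=ids, label=label)

    @property
    def nsnp(self) -> int:
        return len(self.beta_exposure)

    def _pairs(self):
        return (self.beta_exposure, self.se_exposure,
                self.beta_outcome, self.se_outcome)

    def fit(self, method: str = "ivw", seed: int | None = None,
            n_boot: int = 1000) -> "MRResults":
        """Estimate the causal effect.

        ``method`` is one of ``ivw``, ``egger``, ``weighted_median``,
        ``wald_ratio`` or ``all`` (the full battery with diagnostics and
        the direction-consistency flag).
        """
        pairs = self._pairs()
        if method == "all":
            fit = run_mr(pairs, seed=seed, n_boot=n_boot)
        elif method == "ivw":
            res, rep = ivw(pairs)
            fit = MRFit({"ivw": res}, rep, None)
        elif method == "egger":
            res, rep = egger(pairs)
            fit = MRFit({"egger": res}, rep, None)
        elif method == "weighted_median":
            res = weighted_median(pairs, n_boot=n_boot, seed=seed)
            fit = MRFit({"weighted_median": res}, SensitivityReport(), None)
        elif method == "wald_ratio":
            if self.nsnp != 1:
                raise ValueError("wald_ratio applies to a single SNP")
            res = wald_ratio((self.beta_exposure[0], self.se_exposure[0],
                              self.beta_outcome[0], self.se_outcome[0]))
            fit = MRFit({"wald_ratio": res}, SensitivityReport(), None)
        else:
            raise ValueError(f"unknown method {method!r}")
        if self.label:
            fit = MRFit({k: replace(r, label=self.label) for k, r in fit.results.items()},
                        fit.sensitivity, fit.consistency)
        return MRResults(self, fit)


class MRResults:
    """Fitted MR results: estimates, diagnostics, summary table and plot."""

    def __init__(self, model: MRModel, fit: MRFit):
        self.model = model
        self.fit = fit
        self.results = fit.results
        self.sensitivity = fit.sensitivity
        self.consistency = fit.consistency
        primary = fit.results.get("ivw") or next(iter(fit.results.values()))
        self.method = primary.method
        self.beta = primary.beta
        self.se = primary.se
        self.ci_low, self.ci_high = primary.ci_low, primary.ci_high
        self.pval = primary.pval
        self.nsnp = primary.nsnp

    def __getitem__(self, method: str) -> MRResult:
        return self.results[method]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.results.values()])

    def summary(self) -> str:
        lines = [
            "Two-sample Mendelian randomization"
            + (f" — {self.model.label}" if self.model.label else ""),
            f"Instruments: {self.model.nsnp} SNPs",
            "",
            f"{'method':<26}{'beta':>10}{'se':>9}{'OR':>8}{'95% CI':>18}{'p':>11}",
        ]
        for r in self.results.values():
            lo, hi = r.or_ci
            lines.append(
                f"{METHOD_LABELS.get(r.method, r.method):<26}{r.beta:>10.4f}{r.se:>9.4f}"
                f"{r.odds_ratio:>8.3f}{f'[{lo:.3f}, {hi:.3f}]':>18}{r.pval:>11.3g}")
        s = self.sensitivity
        if np.isfinite(s.q_pval):
            lines.append("")
            lines.append(f"Cochran Q = {s.q_stat:.3f} (df {s.q_df}), p = {s.q_pval:.3g}"
                         f" -> {self.results['ivw'].model.replace('_', ' ')} model")
        if np.isfinite(s.intercept_pval):
            lines.append(f"Egger intercept = {s.egger_intercept:.4f} "
                         f"(se {s.intercept_se:.4f}), p = {s.intercept_pval:.3g}")
        if self.consistency is not None:
            lines.append(f"Direction consistency across methods: {self.consistency}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of outcome vs exposure effects with fitted causal slopes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        m = self.model
        sgn = np.where(m.beta_exposure < 0, -1.0, 1.0)
        x, y = m.beta_exposure * sgn, m.beta_outcome * sgn
        ax.errorbar(x, y, xerr=m.se_exposure, yerr=m.se_outcome,
                    fmt="o", ms=4, lw=0.8, color="0.3", ecolor="0.7")
        xs = np.linspace(0, x.max() * 1.05, 50)
        for r in self.results.values():
            if r.method == "egger":
                ax.plot(xs, self.sensitivity.egger_intercept + r.beta * xs,
                        label=METHOD_LABELS[r.method])
            else:
                ax.plot(xs, r.beta * xs, label=METHOD_LABELS[r.method])
        ax.axhline(0, color="0.8", lw=0.8, zorder=0)
        ax.set_xlabel("SNP effect on exposure")
        ax.set_ylabel("SNP effect on outcome")
        ax.legend(fontsize=8)
        return ax
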