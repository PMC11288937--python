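"""Synthetic three-sample GWAS summary statistics with a known causal chain.

The generator emulates the study design the pipeline assumes: three
non-overlapping GWAS samples (exposure, mediator, binary outcome) linked
by instruments → exposure → mediator → outcome, with configurable
horizontal pleiotropy and noise, plus a matched LD matrix — so every
stage of the analysis runs with no external download.

Genetic architecture (per SNP true marginal effects):

* exposure instruments ``g``: effect gamma_j ~ N(0, gamma_sd²) on the
  exposure; theta_XM·gamma_j on the mediator; (theta_direct +
  theta_XM·theta_MY)·gamma_j + alpha_j on the outcome, where alpha_j is
  the pleiotropic effect of invalid instruments;
* mediator-specific instruments ``d``: delta_j ~ N(0, delta_sd²) on the
  mediator and theta_MY·delta_j on the outcome (these identify the
  mediator→outcome arm of the two-step analysis);
* outcome-specific instruments ``e``: eta_j ~ N(0, eta_sd²) on the
  outcome only (these provide valid instruments for reverse-direction MR);
* null SNPs: no effect of their own; those placed in LD with a causal
  SNP inherit r·beta of its effect.

Observed statistics are drawn independently per study sample as
beta_hat = beta_true + N(0, se) with the standardized-trait
approximation se = 1/sqrt(2·maf·(1−maf)·n); p-values are two-sided
normal.  Everything is reproducible from the master seed, with one
derived stream per study to honor the non-overlap assumption.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .instruments import LDMatrix
from .sumstats import TraitPanel, panel_from_arrays

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

_LN = math.log


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated causal chain.

    Defaults reproduce the shape of the motivating application — a gut
    microbiome exposure GWAS (n=18,340), a blood-metabolite mediator GWAS
    (n=8,299) and a binary osteoporosis outcome GWAS (effective
    n=28,615, from 7,300 cases / 358,014 controls) — with true effects
    Z = ln 1.292, X = ln 1.221, Y = ln 1.133 and candidate counts tuned
    so instrument selection yields roughly 11 exposure instruments.
    """

    n_snps: int = 23            # exposure instrument candidates
    n_med_snps: int = 20        # mediator-specific instrument candidates
    n_out_snps: int = 20        # outcome-specific instrument candidates
    n_null_snps: int = 60       # non-associated background SNPs (LD partners)
    n_exp: int = 18_340
    n_med: int = 8_299
    n_out: int = 28_615
    maf_range: tuple[float, float] = (0.1, 0.5)
    gamma_sd: float = 0.08      # SD of instrument->exposure effects
    delta_sd: float = 0.12      # SD of mediator-specific instrument effects
    eta_sd: float = 0.06        # SD of outcome-specific instrument effects
    theta_XM: float = _LN(1.221)     # exposure -> mediator
    theta_MY: float = _LN(1.133)     # mediator -> outcome (log-odds)
    theta_direct: float = _LN(1.292) - _LN(1.221) * _LN(1.133)  # direct log-odds
    pleiotropy: str = "none"    # none | balanced | directional
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    prop_invalid: float = 0.0   # fraction of exposure instruments with pleiotropy
    ld_block_size: int = 3
    ld_decay_r2: float = 0.3    # r2 between adjacent SNPs in a block
    seed: int = 0
    snp_prefix: str = "rs"      # namespace for SNP ids (batch simulations)

    def __post_init__(self) -> None:
        if min(self.n_exp, self.n_med, self.n_out) < 100:
            raise ValueError("all sample sizes must be >= 100")
        if not 0.0 <= self.prop_invalid <= 1.0:
            raise ValueError("prop_invalid must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.pleiotropy not in {"none", "balanced", "directional"}:
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy!r}")
        if self.ld_block_size < 1 or not 0.0 <= self.ld_decay_r2 < 1.0:
            raise ValueError("ld_block_size >= 1 and 0 <= ld_decay_r2 < 1 required")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "maf_range" in raw:
            raw["maf_range"] = tuple(raw["maf_range"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(self.maf_range)
        return d


@dataclass(frozen=True)
class SimulatedTruth:
    """Ground-truth effects behind one simulated dataset."""

    snp_ids: list
    roles: list                       # g / d / e / null per SNP
    gamma: np.ndarray                 # instrument->exposure effects
    delta: np.ndarray                 # mediator-specific effects
    eta: np.ndarray                   # outcome-specific effects
    alpha: np.ndarray                 # pleiotropic (direct-to-outcome) effects
    X_true: float
    Y_true: float
    direct_true: float
    Z_true: float
    proportion_true: float


class SimulatedChain(NamedTuple):
    exposure: TraitPanel
    mediator: TraitPanel
    outcome: TraitPanel
    ld: LDMatrix
    truth: SimulatedTruth


def _layout(config: SimulationConfig, rng: np.random.Generator):
    """Assign roles, LD blocks, chromosomes and positions.

    Each causal candidate anchors its own block, padded with null SNPs
    while the null pool lasts (never two causal SNPs in one block), so
    clumping collapses each block to one index SNP.  Blocks are spaced
    far beyond the clumping window; leftover nulls sit in singleton
    blocks.
    """
    roles = ["g"] * config.n_snps + ["d"] * config.n_med_snps + ["e"] * config.n_out_snps
    n_causal = len(roles)
    null_pool = config.n_null_snps
    blocks: list[list[str]] = []
    for i in range(n_causal):
        pad = min(config.ld_block_size - 1, null_pool)
        null_pool -= pad
        members = ["null"] * (pad // 2) + [roles[i]] + ["null"] * (pad - pad // 2)
        blocks.append(members)
    blocks.extend([["null"]] * null_pool)
    flat_roles: list[str] = []
    block_of: list[int] = []
    offset_in_block: list[int] = []
    for bi, members in enumerate(blocks):
        for oi, role in enumerate(members):
            flat_roles.append(role)
            block_of.append(bi)
            offset_in_block.append(oi)
    m = len(flat_roles)
    chroms = [str(1 + (block_of[i] % 22)) for i in range(m)]
    # blocks on the same chromosome spaced 25 Mb apart (> 10,000 kb window)
    pos = [1 + (block_of[i] // 22) * 25_000_000 + offset_in_block[i] * 1000
           for i in range(m)]
    snp_ids = [f"{config.snp_prefix}{i + 1:05d}" for i in range(m)]
    return snp_ids, flat_roles, np.array(block_of), np.array(offset_in_block), chroms, pos


def simulate_chain(config: SimulationConfig) -> SimulatedChain:
    """Draw one three-sample summary-statistics dataset plus LD and truth."""
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_exp, rng_med, rng_out = \
        (np.random.default_rng(s) for s in ss.spawn(4))

    snp_ids, roles, block_of, _, chroms, pos = _layout(config, rng_struct)
    m = len(snp_ids)
    roles_arr = np.array(roles)
    is_g, is_d, is_e = roles_arr == "g", roles_arr == "d", roles_arr == "e"

    maf = rng_struct.uniform(*config.maf_range, size=m)
    gamma = np.where(is_g, rng_struct.normal(0.0, config.gamma_sd, size=m), 0.0)
    delta = np.where(is_d, rng_struct.normal(0.0, config.delta_sd, size=m), 0.0)
    eta = np.where(is_e, rng_struct.normal(0.0, config.eta_sd, size=m), 0.0)

    alpha = np.zeros(m)
    if config.pleiotropy != "none" and config.prop_invalid > 0:
        g_idx = np.flatnonzero(is_g)
        k = int(round(config.prop_invalid * len(g_idx)))
        invalid = rng_struct.choice(g_idx, size=k, replace=False)
        mean = config.pleiotropy_mean if config.pleiotropy == "directional" else 0.0
        alpha[invalid] = rng_struct.normal(mean, config.pleiotropy_sd, size=k)

    z_true = config.theta_direct + config.theta_XM * config.theta_MY
    b_exp = gamma
    b_med = config.theta_XM * gamma + delta
    # pleiotropy is defined on the exposure-increasing allele (the
    # orientation MR-Egger's intercept estimates), so it enters the
    # outcome signed by gamma
    alpha_signed = np.where(gamma < 0, -alpha, alpha)
    b_out = z_true * gamma + config.theta_MY * delta + eta + alpha_signed

    # signed within-block correlation, r = sqrt(r2); marginal effects b <- R b
    r = math.sqrt(config.ld_decay_r2)
    dist = np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
    same_block = np.equal.outer(block_of, block_of)
    corr = np.where(same_block, r ** dist, 0.0)
    b_exp, b_med, b_out = corr @ b_exp, corr @ b_med, corr @ b_out
    ld = LDMatrix(snp_ids, corr**2)

    allele_idx = rng_struct.integers(0, len(_NONPALINDROMIC), size=m)
    ea = [_NONPALINDROMIC[i][0] for i in allele_idx]
    oa = [_NONPALINDROMIC[i][1] for i in allele_idx]

    from scipy import stats

    def panel(trait_id, trait_type, b_true, n, rng_study):
        se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
        beta_hat = b_true + rng_study.normal(0.0, se)
        pval = 2.0 * stats.norm.sf(np.abs(beta_hat) / se)
        return panel_from_arrays(
            trait_id, trait_type, snp_id=snp_ids, chrom=chroms, pos=pos,
            effect_allele=ea, other_allele=oa, eaf=maf, beta=beta_hat, se=se,
            pval=pval, n=np.full(m, n))

    exposure = panel("sim_exposure", "exposure", b_exp, config.n_exp, rng_exp)
    mediator = panel("sim_mediator", "mediator", b_med, config.n_med, rng_med)
    outcome = panel("sim_outcome", "outcome", b_out, config.n_out, rng_out)

    truth = SimulatedTruth(
        snp_ids=snp_ids, roles=roles, gamma=gamma, delta=delta, eta=eta, alpha=alpha,
        X_true=config.theta_XM, Y_true=config.theta_MY,
        direct_true=config.theta_direct, Z_true=z_true,
        proportion_true=(config.theta_XM * config.theta_MY / z_true
                         if z_true != 0 else float("nan")))
    return SimulatedChain(exposure, mediator, outcome, ld, truth)


def reference_scenario(seed: int = 0) -> SimulationConfig:
    """Configuration matching the motivating study's shape.

    Sample sizes follow the three source GWAS; the true chain is set to
    Z = ln 1.292, X = ln 1.221, Y = ln 1.133 (so the true proportion
    mediated is ~9.73%); candidate counts and effect-size SDs are chosen
    so the selection pipeline yields around 11 exposure instruments
    (within the 4-18 range of the per-trait analyses), all with F > 10.
    """
    return SimulationConfig(seed=seed)


def simulate_exposure_batch(n_exposures: int, n_causal: int,
                            base: SimulationConfig | None = None,
                            seed: int = 0):
    """Simulate a batch of exposure GWAS sharing one outcome panel.

    Emulates the many-taxa forward screen: ``n_causal`` exposures carry
    the configured causal chain; the rest have real instruments but no
    effect on the outcome (theta_direct = theta_XM = 0).  Each exposure
    owns a disjoint SNP namespace; the outcome panel is the concatenation
    of the per-chain outcome panels and the LD matrix is block-diagonal
    over chains (the chains are independent).

    Returns ``(exposures, mediator, outcome, ld, truths)`` where
    ``mediator`` belongs to the first causal chain and ``truths`` maps
    trait_id to its :class:`SimulatedTruth`.
    """
    from scipy.linalg import block_diag

    base = base or SimulationConfig()
    exposures, out_dfs, truths = [], [], {}
    ld_ids: list[str] = []
    ld_blocks = []
    mediator = None
    for k in range(n_exposures):
        causal = k < n_causal
        over = {"seed": (seed * 1000 + k) % (2**31 - 1),
                "snp_prefix": f"t{k:03d}rs"}
        if not causal:
            over.update({"theta_direct": 0.0, "theta_XM": 0.0})
        cfg = dataclasses.replace(base, **over)
        sim = simulate_chain(cfg)
        panel = sim.exposure
        panel = TraitPanel(f"trait{k:03d}", "exposure", panel.df, dict(panel.meta))
        exposures.append(panel)
        out_dfs.append(sim.outcome.df)
        ld_ids.extend(sim.ld.snp_ids)
        ld_blocks.append(sim.ld.r2)
        truths[panel.trait_id] = sim.truth
        if causal and mediator is None:
            mediator = sim.mediator
    outcome = TraitPanel("sim_outcome", "outcome",
                         pd.concat(out_dfs, ignore_index=True))
    ld = LDMatrix(ld_ids, block_diag(*ld_blocks))
    return exposures, mediator, outcome, ld, truths


def shuffle_allele_labels(panel: TraitPanel, seed: int) -> TraitPanel:
    """Randomly re-label effect/other alleles (negating beta, reflecting EAF).

    The Wald ratio of any harmonized pair is invariant to this relabeling;
    used to exercise harmonization.
    """
    rng = np.random.default_rng(seed)
    df = panel.df.copy()
    flip = rng.random(len(df)) < 0.5
    ea = df["effect_allele"].to_numpy().copy()
    oa = df["other_allele"].to_numpy().copy()
    df["effect_allele"] = np.where(flip, oa, ea)
    df["other_allele"] = np.where(flip, ea, oa)
    df["beta"] = np.where(flip, -df["beta"], df["beta"])
    df["eaf"] = np.where(flip, 1.0 - df["eaf"], df["eaf"])
    return TraitPanel(panel.trait_id, panel.trait_type, df, dict(panel.meta))
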