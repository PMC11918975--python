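"""Synthetic two-sample GWAS summary statistics with known causal truth.

Real MR studies consume per-variant association estimates from two
non-overlapping GWAS samples. This generator emulates that structure
directly on the summary-statistic scale — no individual genotypes:

* true instrument effects on the exposure, γ_j ~ Normal(0, gamma_sd²),
  kept only when the *observed* exposure association would pass the
  genome-wide significance filter at the stated sampling SE (rejection
  sampling, mimicking how instruments are discovered);
* observed exposure betas γ_j + noise(se_exp), and outcome betas
  θ·γ_j + a_j + noise(se_out), with per-variant pleiotropy a_j drawn
  per mode (none / balanced / directional);
* a mediation variant with three traits linked by
  exposure →(θ_xm)→ mediator →(θ_my)→ outcome plus a direct path
  θ_direct, which pins down the true proportion mediated
  θ_my·θ_xm / (θ_direct + θ_my·θ_xm).

The default panel sizes and sampling SEs mirror a study pairing a large
biobank GWAS of a binary exposure (tens of instruments, precise betas)
with a small cytokine GWAS (a handful of instruments, noisier betas)
and a disease-endpoint outcome GWAS. Independent noise draws for each
panel enforce two-sample independence. Identical seeds give bitwise
identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import LdMatrix
from .summary_io import SummaryTable

# non-palindromic allele pairs cycled over simulated variants
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]


@dataclass
class SimulationConfig:
    """Generating parameters of a synthetic two-sample / mediation study.

    ``theta`` drives the plain two-sample design; the mediation design
    uses the triple (theta_xm, theta_my, theta_direct): exposure→mediator,
    mediator→outcome and the direct exposure→outcome path. ``gamma_sd``
    and ``delta_sd`` scale the true instrument effects on exposure and
    mediator; ``se_exp``/``se_med``/``se_out`` are the per-panel sampling
    SEs. Pleiotropy adds a per-variant outcome offset: 'balanced' draws
    Normal(0, pleiotropy_sd²), 'directional' Normal(pleiotropy_mean,
    pleiotropy_sd²).
    """

    n_snps_exposure: int = 49
    n_snps_mediator: int = 4
    gamma_sd: float = 0.1
    delta_sd: float = 0.15
    se_exp: float = 0.01
    se_med: float = 0.03
    se_out: float = 0.05
    theta: float = 0.0
    theta_xm: Optional[float] = None
    theta_my: Optional[float] = None
    theta_direct: Optional[float] = None
    pleiotropy: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    p_significance: float = 5e-8
    ld_blocks: Optional[tuple[int, float]] = None  # (n_blocks, within-block r2)
    n_sample_exposure: int = 500_000
    n_sample_mediator: int = 3_636
    n_sample_outcome: int = 200_000
    scramble_alleles: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gamma_sd", "delta_sd", "se_exp", "se_med", "se_out"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy!r}")


@dataclass
class SimulationTruth:
    """Realized per-SNP true effects plus all generating parameters —
    enough to compute the expected value of every estimator in the
    noiseless limit."""

    config: SimulationConfig
    per_snp: pd.DataFrame  # variant_id, role, true_effect, pleiotropy
    true_proportion: Optional[float] = None

    def as_dict(self) -> dict:
        return dict(config=asdict(self.config),
                    per_snp=self.per_snp.to_dict(orient="records"),
                    true_proportion=self.true_proportion)


def _draw_instruments(rng: np.random.Generator, n: int, effect_sd: float,
                      se: float, p_sig: float) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample (true effect, observed beta) pairs whose observed
    association passes the significance filter at sampling SE ``se``."""
    z_crit = stats.norm.isf(p_sig / 2)
    true = np.empty(0)
    obs = np.empty(0)
    drawn = 0
    cap = max(1_000_000, 20_000 * n)
    while len(true) < n:
        batch = max(4 * n, 256)
        drawn += batch
        if drawn > cap:
            raise RuntimeError(
                f"rejection sampling exhausted {cap} draws: effect_sd {effect_sd:g} "
                f"rarely clears significance at se {se:g}")
        g = rng.normal(0.0, effect_sd, batch)
        b = g + rng.normal(0.0, se, batch)
        keep = np.abs(b / se) > z_crit
        true = np.concatenate([true, g[keep]])
        obs = np.concatenate([obs, b[keep]])
    return true[:n], obs[:n]


def _pleiotropy(rng: np.random.Generator, cfg: SimulationConfig, n: int) -> np.ndarray:
    if cfg.pleiotropy == "none":
        return np.zeros(n)
    mean = cfg.pleiotropy_mean if cfg.pleiotropy == "directional" else 0.0
    return rng.normal(mean, cfg.pleiotropy_sd, n)


def _table(label: str, trait_type: str, ids: list[str], beta: np.ndarray,
           se: float, n_sample: int, eaf: np.ndarray,
           alleles: list[tuple[str, str]]) -> SummaryTable:
    pval = 2 * stats.norm.sf(np.abs(beta / se))
    df = pd.DataFrame({
        "variant_id": ids,
        "effect_allele": [a for a, _ in alleles],
        "other_allele": [b for _, b in alleles],
        "beta": beta, "se": float(se), "pval": pval,
        "eaf": eaf, "n": float(n_sample),
    })
    return SummaryTable(label, trait_type, df)


def _maybe_scramble(rng: np.random.Generator, cfg: SimulationConfig,
                    beta: np.ndarray, eaf: np.ndarray,
                    alleles: list[tuple[str, str]]
                    ) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """Randomly swap allele order / flip strand in a non-reference panel,
    so harmonization has real work to do. Effects stay equivalent."""
    if not cfg.scramble_alleles:
        return beta, eaf, alleles
    from .summary_io import COMPLEMENT
    beta, eaf, out = beta.copy(), eaf.copy(), []
    for j, (ea, oa) in enumerate(alleles):
        if rng.random() < 0.5:  # report the other allele
            ea, oa = oa, ea
            beta[j] = -beta[j]
            eaf[j] = 1 - eaf[j]
        if rng.random() < 0.5:  # opposite strand
            ea, oa = COMPLEMENT[ea], COMPLEMENT[oa]
        out.append((ea, oa))
    return beta, eaf, out


def make_block_ld(ids: list[str], n_blocks: int, within_r2: float) -> LdMatrix:
    """Block-diagonal LD: variants split into contiguous blocks, r² =
    ``within_r2`` inside a block and 0 between blocks."""
    n = len(ids)
    r2 = np.eye(n)
    bounds = np.array_split(np.arange(n), n_blocks)
    for block in bounds:
        for i in block:
            for j in block:
                if i != j:
                    r2[i, j] = within_r2
    return LdMatrix(ids, r2)


def simulate_two_sample(config: SimulationConfig
                        ) -> tuple[SummaryTable, SummaryTable, SimulationTruth]:
    """One exposure panel and one outcome panel with true effect ``theta``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps_exposure
    gamma, beta_exp = _draw_instruments(rng, n, cfg.gamma_sd, cfg.se_exp,
                                        cfg.p_significance)
    pleio = _pleiotropy(rng, cfg, n)
    beta_out = cfg.theta * gamma + pleio + rng.normal(0.0, cfg.se_out, n)

    ids = [f"rs{100000 + j}" for j in range(n)]
    alleles = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(n)]
    eaf = rng.uniform(0.05, 0.95, n)
    exposure = _table("exposure", "binary", ids, beta_exp, cfg.se_exp,
                      cfg.n_sample_exposure, eaf, alleles)
    beta_o, eaf_o, alleles_o = _maybe_scramble(rng, cfg, beta_out, eaf, alleles)
    outcome = _table("outcome", "binary", ids, beta_o, cfg.se_out,
                     cfg.n_sample_outcome, eaf_o, alleles_o)
    per_snp = pd.DataFrame({"variant_id": ids, "role": "exposure_instrument",
                            "true_effect": gamma, "pleiotropy": pleio})
    return exposure, outcome, SimulationTruth(cfg, per_snp)


def simulate_mediation_study(config: SimulationConfig
                             ) -> tuple[SummaryTable, SummaryTable, SummaryTable,
                                        SimulationTruth]:
    """Three-trait study: exposure, mediator and outcome panels over the
    union of exposure- and mediator-instrument SNPs.

    Exposure instruments carry mediator associations θ_xm·γ_j and outcome
    associations (θ_direct + θ_my·θ_xm)·γ_j; mediator instruments carry
    outcome associations θ_my·δ_j and null exposure associations. The
    truth records the proportion mediated
    θ_my·θ_xm / (θ_direct + θ_my·θ_xm).
    """
    cfg = config
    if None in (cfg.theta_xm, cfg.theta_my, cfg.theta_direct):
        raise ValueError("mediation design needs theta_xm, theta_my and theta_direct")
    rng = np.random.default_rng(cfg.seed)
    nx, nm = cfg.n_snps_exposure, cfg.n_snps_mediator
    gamma, bx_obs = _draw_instruments(rng, nx, cfg.gamma_sd, cfg.se_exp,
                                      cfg.p_significance)
    delta, bm_obs = _draw_instruments(rng, nm, cfg.delta_sd, cfg.se_med,
                                      cfg.p_significance)
    pleio = _pleiotropy(rng, cfg, nx + nm)

    ids = [f"rs{100000 + j}" for j in range(nx)] + [f"rs{900000 + j}" for j in range(nm)]
    alleles = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(nx + nm)]
    eaf = rng.uniform(0.05, 0.95, nx + nm)

    theta_total = cfg.theta_direct + cfg.theta_my * cfg.theta_xm
    beta_exp = np.concatenate([bx_obs, rng.normal(0.0, cfg.se_exp, nm)])
    beta_med_true = np.concatenate([cfg.theta_xm * gamma, delta])
    beta_med = np.where(np.arange(nx + nm) < nx,
                        beta_med_true + rng.normal(0.0, cfg.se_med, nx + nm),
                        np.concatenate([np.zeros(nx), bm_obs]))
    beta_out_true = np.concatenate([theta_total * gamma, cfg.theta_my * delta])
    beta_out = beta_out_true + pleio + rng.normal(0.0, cfg.se_out, nx + nm)

    exposure = _table("exposure", "binary", ids, beta_exp, cfg.se_exp,
                      cfg.n_sample_exposure, eaf, alleles)
    bm, eaf_m, all_m = _maybe_scramble(rng, cfg, beta_med, eaf, alleles)
    mediator = _table("mediator", "continuous", ids, bm, cfg.se_med,
                      cfg.n_sample_mediator, eaf_m, all_m)
    bo, eaf_o, all_o = _maybe_scramble(rng, cfg, beta_out, eaf, alleles)
    outcome = _table("outcome", "binary", ids, bo, cfg.se_out,
                     cfg.n_sample_outcome, eaf_o, all_o)

    per_snp = pd.DataFrame({
        "variant_id": ids,
        "role": ["exposure_instrument"] * nx + ["mediator_instrument"] * nm,
        "true_effect": np.concatenate([gamma, delta]),
        "pleiotropy": pleio,
    })
    prop = cfg.theta_my * cfg.theta_xm / theta_total if theta_total != 0 else np.nan
    return exposure, mediator, outcome, SimulationTruth(cfg, per_snp, float(prop))
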