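"""Product-of-coefficients mediation on Mendelian-randomization estimates.

The decomposition combines four MR estimates, all on the log-odds scale
for binary outcomes:

* beta1 — total effect of the exposure on the outcome (univariable MR,
  with mediator-associated instruments excluded);
* beta2 — effect of the exposure on the mediator (univariable MR);
* alpha1 — direct effect of the exposure on the outcome adjusted for
  the mediator (multivariable MR);
* alpha2 — direct effect of the mediator on the outcome adjusted for
  the exposure (multivariable MR).

The mediated (indirect) effect is alpha2 × beta2 and the proportion of
the total effect transmitted through the mediator is
(alpha2 × beta2) / beta1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .instruments import LdMatrix, SelectionLog, select_instruments
from .mr import MrEstimate, ivw, univariable_panel
from .mvmr import MvmrSet, build_mvmr_set, mvmr_ivw
from .summary_io import SummaryTable, harmonize_pair


class Estimate(NamedTuple):
    """A point estimate with its standard error."""

    beta: float
    se: float

    @classmethod
    def of(cls, e: "MrEstimate | Estimate | tuple[float, float]") -> "Estimate":
        if isinstance(e, MrEstimate):
            return cls(e.beta, e.se)
        return cls(*e)


@dataclass
class MediationResult:
    beta1: Estimate
    beta2: Estimate
    alpha1: Estimate
    alpha2: Estimate
    indirect: float
    indirect_se: float
    proportion: float
    proportion_ci: tuple[float, float]
    ci_method: str
    flags: list[str]

    def as_dict(self) -> dict:
        d = {name: {"beta": e.beta, "se": e.se}
             for name, e in [("beta1", self.beta1), ("beta2", self.beta2),
                             ("alpha1", self.alpha1), ("alpha2", self.alpha2)]}
        d.update(indirect=self.indirect, indirect_se=self.indirect_se,
                 proportion=self.proportion,
                 proportion_ci=list(self.proportion_ci),
                 ci_method=self.ci_method, flags=self.flags)
        return d


def decompose(beta1, beta2, alpha1, alpha2, ci_method: str = "delta",
              n_boot: int = 5000, seed: int | None = None) -> MediationResult:
    """Combine the four MR estimates into the mediation decomposition.

    indirect = alpha2·beta2 with the delta-method SE
    sqrt(alpha2²·se_beta2² + beta2²·se_alpha2²); proportion =
    indirect/beta1, its CI either by the delta method on the ratio
    (independent components) or by parametric bootstrap of all four
    inputs. A proportion outside [0, 1] is flagged 'inconsistent
    mediation'; beta1 = 0 leaves the proportion undefined and flagged.
    """
    b1, b2 = Estimate.of(beta1), Estimate.of(beta2)
    a1, a2 = Estimate.of(alpha1), Estimate.of(alpha2)
    for name, e in [("beta1", b1), ("beta2", b2), ("alpha1", a1), ("alpha2", a2)]:
        if e.se <= 0:
            raise ValueError(f"{name}: se must be > 0")
    flags: list[str] = []
    indirect = a2.beta * b2.beta
    indirect_se = float(np.sqrt(a2.beta**2 * b2.se**2 + b2.beta**2 * a2.se**2))

    if b1.beta == 0:
        flags.append("proportion undefined: beta1 = 0")
        return MediationResult(b1, b2, a1, a2, indirect, indirect_se,
                               np.nan, (np.nan, np.nan), ci_method, flags)

    proportion = indirect / b1.beta
    if ci_method == "delta":
        if indirect == 0:
            prop_se = indirect_se / abs(b1.beta)
        else:
            rel = indirect_se**2 / indirect**2 + b1.se**2 / b1.beta**2
            prop_se = abs(proportion) * np.sqrt(rel)
        ci = (proportion - 1.959963984540054 * prop_se,
              proportion + 1.959963984540054 * prop_se)
    elif ci_method == "bootstrap":
        if seed is None:
            raise ValueError("bootstrap CI requires a seed")
        rng = np.random.default_rng(seed)
        b2s = rng.normal(b2.beta, b2.se, n_boot)
        a2s = rng.normal(a2.beta, a2.se, n_boot)
        b1s = rng.normal(b1.beta, b1.se, n_boot)
        props = a2s * b2s / b1s
        ci = tuple(np.quantile(props, [0.025, 0.975]))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    if not 0.0 <= proportion <= 1.0:
        flags.append("inconsistent mediation")
    return MediationResult(b1, b2, a1, a2, indirect, indirect_se,
                           float(proportion), (float(ci[0]), float(ci[1])),
                           ci_method, flags)


def exclude_mediator_associated(instruments_table: SummaryTable,
                                mediator: SummaryTable,
                                p_threshold: float = 5e-8,
                                log: SelectionLog | None = None) -> SummaryTable:
    """Drop exposure instruments that are themselves associated with the
    mediator at ``p_threshold`` — required for the *total*-effect arm, so
    beta1 is estimated from variants acting on the outcome only through
    the exposure, not through the mediator."""
    med = mediator.records.set_index("variant_id")["pval"]
    rec = instruments_table.records
    sig = rec["variant_id"].map(med).fillna(1.0) < p_threshold
    if log is not None:
        for vid in rec.loc[sig, "variant_id"]:
            log.add(vid, "mediator-exclusion", "removed",
                    f"mediator p < {p_threshold:g}", float(med[vid]))
    return SummaryTable(instruments_table.trait_label, instruments_table.trait_type,
                        rec[~sig].copy())


def mediation_pipeline(
    exposure: SummaryTable,
    mediator: SummaryTable,
    outcome: SummaryTable,
    seed: int,
    ld: LdMatrix | None = None,
    exclusion: pd.DataFrame | None = None,
    p_instrument: float = 5e-8,
    mediator_p_exclude: float = 5e-8,
    ci_method: str = "delta",
    n_boot: int = 1000,
    ivw_model: str = "multiplicative_random",
    palindrome_policy: str = "drop",
    full_panels: bool = False,
    log: SelectionLog | None = None,
) -> tuple[MediationResult, dict]:
    """Run the complete three-trait mediation study on summary tables.

    Stages: univariable MR exposure→outcome (beta1; exposure instruments
    with mediator p-value below ``mediator_p_exclude`` excluded),
    exposure→mediator (beta2), multivariable MR of {exposure, mediator}
    on the outcome (alpha1, alpha2), then :func:`decompose`. Returns the
    result plus a components dict with every intermediate estimate.
    """
    exp_iv = select_instruments(exposure, ld, exclusion, p_instrument, log=log)
    exp_iv_total = exclude_mediator_associated(exp_iv, mediator,
                                               mediator_p_exclude, log=log)

    h1 = harmonize_pair(exp_iv_total, outcome, palindrome_policy=palindrome_policy)
    h2 = harmonize_pair(exp_iv, mediator, palindrome_policy=palindrome_policy)
    est1, het1 = ivw(h1, model=ivw_model)
    est2, het2 = ivw(h2, model=ivw_model)

    mset = build_mvmr_set([exposure, mediator], outcome, ld, exclusion,
                          p_instrument, log=log)
    mv = mvmr_ivw(mset)
    alpha1, alpha2 = mv[0], mv[1]

    result = decompose(est1, est2, alpha1, alpha2, ci_method=ci_method,
                       n_boot=n_boot, seed=seed)
    components = {
        "beta1": est1.as_dict(), "beta2": est2.as_dict(),
        "alpha1": alpha1.as_dict(), "alpha2": alpha2.as_dict(),
        "heterogeneity_beta1": vars(het1), "heterogeneity_beta2": vars(het2),
        "n_snps_total_arm": h1.n_snps, "n_snps_mediator_arm": h2.n_snps,
        "n_snps_mvmr": mset.n_snps,
    }
    if full_panels:
        components["panel_beta1"] = univariable_panel(h1, seed=seed, n_boot=n_boot,
                                                      ivw_model=ivw_model)
        components["panel_beta2"] = univariable_panel(h2, seed=seed, n_boot=n_boot,
                                                      ivw_model=ivw_model)
    return result, components
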