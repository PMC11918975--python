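"""Study orchestration: run every arm, tier p-values, emit result bundles.

A "study" here follows the mediation-MR template: one exposure, one
candidate mediator, several outcome endpoints. For each outcome the
driver runs the univariable panels (exposure→outcome, mediator→outcome),
the multivariable panel, and the mediation decomposition; a bidirectional
exposure↔mediator screen runs once. Multiple testing across outcomes is
handled by a Bonferroni threshold alpha/m, with p-values between alpha/m
and alpha reported as suggestive rather than significant.

Everything is driven by a :class:`StudyConfig` (YAML-loadable); all
randomness flows from the config seed, so identical configs give
byte-identical JSON bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .instruments import SelectionLog, select_instruments
from .mediation import mediation_pipeline
from .mr import ivw, univariable_panel
from .mvmr import build_mvmr_set, mr_lasso, mvmr_egger, mvmr_ivw, mvmr_median
from .simulate import SimulationConfig, simulate_mediation_study
from .summary_io import SummaryTable, harmonize_pair, read_summary_table

TIER_SIGNIFICANT = "significant"
TIER_SUGGESTIVE = "suggestive"
TIER_NULL = "null"


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance level alpha/m for m outcome endpoints."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    return alpha / m


def tier(pval: float, alpha: float, m: int) -> str:
    """significant: p < alpha/m; suggestive: alpha/m <= p < alpha; else null."""
    thr = bonferroni_threshold(alpha, m)
    if pval < thr:
        return TIER_SIGNIFICANT
    if pval < alpha:
        return TIER_SUGGESTIVE
    return TIER_NULL


@dataclass
class TraitSpec:
    label: str
    trait_type: str
    path: Optional[str] = None
    column_map: Optional[dict] = None


@dataclass
class StudyConfig:
    """Everything a full study run needs, in one validated object."""

    seed: int
    mode: str = "synthetic"  # synthetic | files
    # synthetic mode: base generator settings + per-outcome causal effects
    synthetic: dict = field(default_factory=dict)
    outcomes_synthetic: list[dict] = field(default_factory=list)
    # files mode
    exposure: Optional[TraitSpec] = None
    mediator: Optional[TraitSpec] = None
    outcomes: list[TraitSpec] = field(default_factory=list)
    # thresholds (study-wide QC settings)
    p_instrument: float = 5e-8
    r2_clump: float = 0.001
    f_min: float = 10.0
    r2_proxy: float = 0.8
    mediator_p_exclude: float = 5e-8
    alpha: float = 0.05
    n_outcomes_for_bonferroni: Optional[int] = None
    # method settings
    ivw_model: str = "multiplicative_random"
    ci_method: str = "delta"
    n_boot: int = 1000
    palindrome_policy: str = "drop"
    mediation_gate: str = "all"  # all | significant_total
    run_mvmr_extras: bool = True  # Egger / median / Lasso panels

    def __post_init__(self) -> None:
        if not (0 < self.p_instrument < 1 and 0 <= self.r2_clump <= 1
                and 0 <= self.r2_proxy <= 1 and self.f_min >= 0
                and 0 < self.alpha < 1):
            raise ValueError("threshold outside its domain")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("exposure", "mediator"):
            if raw.get(key):
                raw[key] = TraitSpec(**raw[key])
        raw["outcomes"] = [TraitSpec(**o) for o in raw.get("outcomes", [])]
        return cls(**raw)


def _load_trait(spec: TraitSpec) -> SummaryTable:
    return read_summary_table(spec.path, spec.column_map, spec.label, spec.trait_type)


def _outcome_tables(config: StudyConfig) -> list[tuple[str, SummaryTable,
                                                       SummaryTable, SummaryTable,
                                                       Optional[float]]]:
    """Yield (label, exposure, mediator, outcome, true_proportion) per arm."""
    arms = []
    if config.mode == "synthetic":
        for i, arm in enumerate(config.outcomes_synthetic):
            params = dict(config.synthetic)
            label = arm.get("label", f"outcome_{i+1}")
            params.update({k: v for k, v in arm.items() if k != "label"})
            params["seed"] = config.seed + 7919 * i
            sim = SimulationConfig(**params)
            exp, med, out, truth = simulate_mediation_study(sim)
            arms.append((label, exp, med, out, truth.true_proportion))
    elif config.mode == "files":
        exp = _load_trait(config.exposure)
        med = _load_trait(config.mediator)
        for spec in config.outcomes:
            arms.append((spec.label, exp, med, _load_trait(spec), None))
    else:
        raise ValueError(f"unknown mode {config.mode!r}")
    return arms


def run_full_study(config: StudyConfig) -> dict:
    """Execute the whole study and return one nested result bundle.

    Per outcome: exposure→outcome and mediator→outcome univariable
    panels, the multivariable panel (IVW always; Egger, robust median and
    MR-Lasso when enabled), the mediation decomposition, and Bonferroni
    tier assignments. A bidirectional exposure↔mediator screen runs on
    the first arm's tables; its result is reported but never gates the
    mediation computation. Stage failures are caught per arm and land in
    a failure manifest rather than aborting the run.
    """
    arms = _outcome_tables(config)
    m = config.n_outcomes_for_bonferroni or max(len(arms), 1)
    log = SelectionLog()
    results: dict = {
        "config": {k: v for k, v in asdict(config).items()},
        "bonferroni": {"alpha": config.alpha, "m": m,
                       "threshold": bonferroni_threshold(config.alpha, m)},
        "outcomes": {},
        "failures": {},
    }

    # bidirectional exposure <-> mediator screen (first arm's tables)
    _, exp0, med0, _, _ = arms[0]
    fwd = harmonize_pair(
        select_instruments(exp0, p_threshold=config.p_instrument, f_min=config.f_min),
        med0, palindrome_policy=config.palindrome_policy)
    rev = harmonize_pair(
        select_instruments(med0, p_threshold=config.p_instrument, f_min=config.f_min),
        exp0, palindrome_policy=config.palindrome_policy)
    results["bidirectional"] = {
        "exposure_to_mediator": univariable_panel(fwd, seed=config.seed,
                                                  n_boot=config.n_boot,
                                                  ivw_model=config.ivw_model),
        "mediator_to_exposure": univariable_panel(rev, seed=config.seed,
                                                  n_boot=config.n_boot,
                                                  ivw_model=config.ivw_model),
    }

    for label, exp, med, out, true_prop in arms:
        try:
            results["outcomes"][label] = _run_arm(config, m, log, exp, med, out,
                                                  true_prop)
        except Exception as err:  # partial results + manifest, per contract
            results["failures"][label] = f"{type(err).__name__}: {err}"
    results["selection_log"] = log.entries
    return results


def _run_arm(config: StudyConfig, m: int, log: SelectionLog,
             exp: SummaryTable, med: SummaryTable, out: SummaryTable,
             true_prop: Optional[float]) -> dict:
    exp_iv = select_instruments(exp, p_threshold=config.p_instrument,
                                f_min=config.f_min, log=log)
    med_iv = select_instruments(med, p_threshold=config.p_instrument,
                                f_min=config.f_min, log=log)
    h_eo = harmonize_pair(exp_iv, out, palindrome_policy=config.palindrome_policy)
    h_mo = harmonize_pair(med_iv, out, palindrome_policy=config.palindrome_policy)
    arm: dict = {
        "univariable": {
            "exposure_on_outcome": univariable_panel(
                h_eo, seed=config.seed, n_boot=config.n_boot, ivw_model=config.ivw_model),
            "mediator_on_outcome": univariable_panel(
                h_mo, seed=config.seed, n_boot=config.n_boot, ivw_model=config.ivw_model),
        },
    }

    mset = build_mvmr_set([exp, med], out, p_threshold=config.p_instrument,
                          f_min=config.f_min, log=log)
    mv = {"ivw": [e.as_dict() for e in mvmr_ivw(mset)]}
    if config.run_mvmr_extras:
        ests, pleio = mvmr_egger(mset)
        mv["egger"] = [e.as_dict() for e in ests]
        mv["egger_intercept"] = vars(pleio)
        mv["median"] = [e.as_dict() for e in
                        mvmr_median(mset, n_boot=min(config.n_boot, 200),
                                    seed=config.seed)]
        try:
            lasso = mr_lasso(mset)
            mv["lasso"] = {"estimates": [e.as_dict() for e in lasso.estimates],
                           "valid_ids": lasso.valid_ids,
                           "chosen_lambda": lasso.chosen_lambda,
                           "path": lasso.path.to_dict(orient="records")}
        except ValueError as err:
            mv["lasso"] = {"error": str(err)}
    mv["note"] = ("conditional instrument-strength diagnostics for MVMR "
                  "are not implemented")
    arm["multivariable"] = mv

    total_p = arm["univariable"]["exposure_on_outcome"]["ivw"]["pval"]
    run_mediation = (config.mediation_gate == "all"
                     or total_p < bonferroni_threshold(config.alpha, m))
    if run_mediation:
        med_res, med_comp = mediation_pipeline(
            exp, med, out, seed=config.seed,
            p_instrument=config.p_instrument,
            mediator_p_exclude=config.mediator_p_exclude,
            ci_method=config.ci_method, n_boot=config.n_boot,
            ivw_model=config.ivw_model,
            palindrome_policy=config.palindrome_policy)
        arm["mediation"] = {"result": med_res.as_dict(), "components": med_comp}
        if true_prop is not None:
            arm["mediation"]["true_proportion"] = true_prop

    arm["tiers"] = {
        "exposure_on_outcome_ivw": tier(total_p, config.alpha, m),
        "mediator_on_outcome_ivw": tier(
            arm["univariable"]["mediator_on_outcome"]["ivw"]["pval"],
            config.alpha, m),
    }
    return arm


def write_study_json(results: dict, path: str | Path) -> None:
    """Serialize a result bundle deterministically (sorted keys, fixed
    separators) so identical runs are byte-identical."""
    Path(path).write_text(json.dumps(results, sort_keys=True, indent=1,
                                     default=_json_default) + "\n")


def _json_default(obj):
    import numpy as np
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def summary_table_rows(results: dict) -> pd.DataFrame:
    """Flatten a result bundle into the per-method rows a forest-plot or
    results table needs (one row per outcome × method)."""
    rows = []
    for label, arm in results["outcomes"].items():
        for arm_name, panel in arm["univariable"].items():
            for meth in ("ivw", "egger", "weighted_median"):
                if meth in panel:
                    e = panel[meth]
                    rows.append(dict(outcome=label, analysis=arm_name, **e))
        for e in arm["multivariable"]["ivw"]:
            rows.append(dict(outcome=label, analysis="multivariable", **e))
    return pd.DataFrame(rows)
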