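"""Univariable two-sample Mendelian randomization estimators.

Given harmonized per-variant effect pairs (beta_exp, beta_out) with
standard errors, every estimator here combines the per-variant Wald
ratios beta_out/beta_exp into one causal effect:

* IVW — inverse-variance-weighted mean of the ratios; the primary
  estimator. Fixed-effect or multiplicative random-effects (the latter
  inflates the SE by sqrt(Q/(n-1)) when Cochran's Q exceeds its df).
* MR-Egger — weighted regression of beta_out on beta_exp *with* an
  intercept; a nonzero intercept estimates directional pleiotropy and
  the slope remains consistent under it (InSIDE assumption).
* Weighted median — the 50th weighted percentile of the ratios;
  consistent when at least half the weight comes from valid instruments.

Sensitivity diagnostics: Cochran's Q heterogeneity, the Egger-intercept
pleiotropy test, leave-one-out re-estimation, and funnel-plot data
(ratio vs precision).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .summary_io import HarmonizedSet

Z95 = stats.norm.ppf(0.975)


@dataclass
class MrEstimate:
    """One method's causal estimate. ``beta`` is on the log-odds scale for
    binary outcomes; ``or_scale`` exponentiates beta and its CI."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int

    @property
    def or_scale(self) -> tuple[float, float, float]:
        return (float(np.exp(self.beta)), float(np.exp(self.ci_low)),
                float(np.exp(self.ci_high)))

    def as_dict(self) -> dict:
        orv, orlo, orhi = self.or_scale
        return dict(method=self.method, beta=self.beta, se=self.se,
                    ci_low=self.ci_low, ci_high=self.ci_high, pval=self.pval,
                    n_snps=self.n_snps, odds_ratio=orv, or_ci_low=orlo, or_ci_high=orhi)


@dataclass
class HeterogeneityResult:
    """Cochran's Q with its chi-square df and upper-tail p."""

    q: float
    df: int
    pval: float


@dataclass
class PleiotropyResult:
    """Egger intercept: nonzero mean pleiotropic effect across instruments."""

    intercept: float
    se: float
    pval: float


def wald_ratios(h: HarmonizedSet, second_order: bool = False) -> pd.DataFrame:
    """Per-variant ratio estimates beta_out/beta_exp with first-order SE
    se_out/|beta_exp| (optionally the second-order form adding the
    exposure-side term)."""
    r = h.rows
    if (r["beta_exp"] == 0).any():
        bad = r.loc[r["beta_exp"] == 0, "variant_id"].tolist()
        raise ValueError(f"zero exposure beta for {bad}; Wald ratio undefined")
    ratio = r["beta_out"] / r["beta_exp"]
    se = r["se_out"] / r["beta_exp"].abs()
    if second_order:
        se = np.sqrt(se**2 + (r["beta_out"] ** 2) * (r["se_exp"] ** 2) / r["beta_exp"] ** 4)
    return pd.DataFrame({"variant_id": r["variant_id"], "ratio": ratio,
                         "ratio_se": se}).reset_index(drop=True)


def _estimate(method: str, beta: float, se: float, n: int,
              dist: str = "norm", df: int = 0) -> MrEstimate:
    if dist == "t":
        crit = stats.t.ppf(0.975, df)
        p = 2 * stats.t.sf(abs(beta / se), df)
    else:
        crit = Z95
        p = 2 * stats.norm.sf(abs(beta / se))
    return MrEstimate(method, float(beta), float(se), float(beta - crit * se),
                      float(beta + crit * se), float(p), n)


def ivw(h: HarmonizedSet, model: str = "multiplicative_random",
        second_order: bool = False) -> tuple[MrEstimate, HeterogeneityResult]:
    """Inverse-variance-weighted estimate with Cochran's Q.

    beta = Σ w_j r_j / Σ w_j with w_j = 1/ratio_se_j². Fixed-effect SE is
    (Σ w_j)^(-1/2); the multiplicative random-effects model multiplies it
    by max(1, sqrt(Q/(n-1))), never deflating below the fixed SE. With a
    single instrument the Wald ratio itself is returned (method 'wald').
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    wr = wald_ratios(h, second_order)
    n = len(wr)
    if n < 1:
        raise ValueError("IVW requires at least one instrument")
    w = 1.0 / wr["ratio_se"] ** 2
    beta = float(np.sum(w * wr["ratio"]) / np.sum(w))
    q = float(np.sum(w * (wr["ratio"] - beta) ** 2))
    if n == 1:
        se = float(wr["ratio_se"].iloc[0])
        return _estimate("wald", beta, se, 1), HeterogeneityResult(0.0, 0, np.nan)
    se = float(np.sum(w) ** -0.5)
    if model == "multiplicative_random":
        se *= max(1.0, np.sqrt(q / (n - 1)))
    het = HeterogeneityResult(q, n - 1, float(stats.chi2.sf(q, n - 1)))
    return _estimate(f"ivw_{'fixed' if model == 'fixed' else 'mre'}", beta, se, n), het


def egger(h: HarmonizedSet) -> tuple[MrEstimate, PleiotropyResult, HeterogeneityResult]:
    """MR-Egger regression: slope = causal effect, intercept = pleiotropy.

    Rows are oriented so beta_exp ≥ 0 (the intercept is only meaningful
    on a fixed exposure orientation), then beta_out is regressed on
    beta_exp with weights 1/se_out². The slope SE uses the multiplicative
    model with the residual variance floored at 1 (never below the
    fixed-effect SE); the intercept test keeps the plain WLS t-statistic,
    which is exactly calibrated under the null. t(n-2) reference for both.
    """
    r = h.rows
    n = len(r)
    if n < 3:
        raise ValueError(f"MR-Egger needs >= 3 instruments, got {n}")
    sign = np.where(r["beta_exp"] >= 0, 1.0, -1.0)
    x = sign * r["beta_exp"].to_numpy()
    y = sign * r["beta_out"].to_numpy()
    w = 1.0 / r["se_out"].to_numpy() ** 2
    fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    q = float(np.sum(w * fit.resid**2))
    # exact fit: residual variance is numerically zero, t-ratios are 0/0 —
    # fall back to the unscaled (fixed-effect) SEs and test the intercept
    # against zero directly
    exact = q <= 1e-12 * max(1.0, float(np.sum(w * y**2)))
    unscaled_se = np.sqrt(np.diag(fit.normalized_cov_params))
    if exact:
        est = _estimate("egger", fit.params[1], unscaled_se[1], n, dist="t", df=n - 2)
        null_int = abs(fit.params[0]) <= 1e-8 * max(1.0, float(np.max(np.abs(y))))
        pleio = PleiotropyResult(float(fit.params[0]), float(unscaled_se[0]),
                                 1.0 if null_int else 0.0)
        return est, pleio, HeterogeneityResult(q, n - 2, float(stats.chi2.sf(q, n - 2)))
    scale = max(1.0, fit.scale)  # residual variance floor: never below fixed-effect
    slope_se = unscaled_se[1] * np.sqrt(scale)
    est = _estimate("egger", fit.params[1], slope_se, n, dist="t", df=n - 2)
    pleio = PleiotropyResult(float(fit.params[0]), float(fit.bse[0]),
                             float(fit.pvalues[0]))
    het = HeterogeneityResult(q, n - 2, float(stats.chi2.sf(q, n - 2)))
    return est, pleio, het


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted 50th percentile with linear interpolation between the
    order statistics bracketing cumulative probability 0.5."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    p = cum / np.sum(w)
    return float(np.interp(0.5, p, v))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000,
                    seed: int | None = None) -> MrEstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    The point estimate is the inverse-variance-weighted median of the
    Wald ratios. The SE resamples each (beta_exp, beta_out) from
    Normal(beta, se), recomputes the weighted median, and takes the SD
    across ``n_boot`` draws; ``seed`` fixes the resampling stream.
    """
    r = h.rows
    n = len(r)
    if n < 3:
        raise ValueError(f"weighted median needs >= 3 instruments, got {n}")
    if n_boot < 100:
        import logging
        logging.getLogger(__name__).warning("n_boot=%d < 100: unstable SE", n_boot)
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    wr = wald_ratios(h)
    w = (1.0 / wr["ratio_se"] ** 2).to_numpy()
    beta = _weighted_median(wr["ratio"].to_numpy(), w)

    rng = np.random.default_rng(seed)
    be = rng.normal(r["beta_exp"].to_numpy(), r["se_exp"].to_numpy(), (n_boot, n))
    bo = rng.normal(r["beta_out"].to_numpy(), r["se_out"].to_numpy(), (n_boot, n))
    se_out = r["se_out"].to_numpy()
    boot = np.empty(n_boot)
    for b in range(n_boot):
        ratios = bo[b] / be[b]
        wts = (np.abs(be[b]) / se_out) ** 2
        boot[b] = _weighted_median(ratios, wts)
    se = float(np.std(boot, ddof=1))
    return _estimate("weighted_median", beta, se, n)


def leave_one_out(h: HarmonizedSet) -> pd.DataFrame:
    """Re-estimate IVW (multiplicative random) dropping each instrument.

    Flags variants whose omission moves the estimate outside the
    full-set 95% CI — the classic single-SNP influence screen.
    """
    if h.n_snps < 3:
        raise ValueError("leave-one-out needs >= 3 instruments")
    full, _ = ivw(h)
    rows = []
    for vid in h.rows["variant_id"]:
        sub = HarmonizedSet(h.exposure_label, h.outcome_label,
                            h.rows[h.rows["variant_id"] != vid].reset_index(drop=True))
        est, _ = ivw(sub)
        outside = not (full.ci_low <= est.beta <= full.ci_high)
        rows.append((vid, est.beta, est.se, outside))
    return pd.DataFrame(rows, columns=["variant_id", "loo_beta", "loo_se", "influential"])


def funnel_data(h: HarmonizedSet) -> pd.DataFrame:
    """Plot-ready funnel table: per-variant Wald ratio vs precision
    (1/ratio_se). Asymmetry around the pooled estimate suggests
    directional pleiotropy."""
    wr = wald_ratios(h)
    wr["precision"] = 1.0 / wr["ratio_se"]
    return wr


def univariable_panel(h: HarmonizedSet, seed: int, n_boot: int = 1000,
                      ivw_model: str = "multiplicative_random") -> dict:
    """The full univariable suite one study arm gets: IVW + Egger +
    weighted median, heterogeneity, pleiotropy, leave-one-out, funnel."""
    est_ivw, het_ivw = ivw(h, model=ivw_model)
    out: dict = {"n_snps": h.n_snps, "ivw": est_ivw.as_dict(),
                 "heterogeneity_ivw": vars(het_ivw)}
    if h.n_snps >= 3:
        est_e, pleio, het_e = egger(h)
        est_m = weighted_median(h, n_boot=n_boot, seed=seed)
        out.update(egger=est_e.as_dict(), egger_intercept=vars(pleio),
                   heterogeneity_egger=vars(het_e),
                   weighted_median=est_m.as_dict(),
                   leave_one_out=leave_one_out(h).to_dict(orient="records"),
                   funnel=funnel_data(h).to_dict(orient="records"))
    return out
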