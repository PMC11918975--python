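"""Multivariable Mendelian randomization (MVMR).

With K exposures measured on a common instrument set, regressing the
outcome associations jointly on all K exposure-association columns gives
each exposure's *direct* effect, conditional on the others — the
quantity mediation analysis needs (the exposure's effect adjusted for
the mediator, and vice versa). Estimators:

* mvmr_ivw — weighted least squares, no intercept, weights 1/se_out².
* mvmr_egger — the same with an intercept after orienting on one
  exposure; the intercept estimates directional pleiotropy.
* mvmr_median — weighted least-absolute-deviations fit, robust to a
  minority of pleiotropic instruments.
* mr_lasso — per-instrument intercepts γ_j under an L1 penalty; variants
  whose γ_j shrinks to zero are deemed valid and the effect is
  re-estimated by WLS on that valid set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .instruments import (CLUMP_R2, F_MIN, GENOME_WIDE_P, LdMatrix,
                          SelectionLog, select_instruments)
from .mr import MrEstimate, PleiotropyResult, _estimate
from .summary_io import HarmonizedSet, SummaryTable, harmonize_pair


@dataclass
class MvmrSet:
    """Instrument-level design for K >= 2 exposures against one outcome.

    ``rows`` columns: variant_id, beta_exp_1..K, se_exp_1..K, beta_out,
    se_out — all on one shared effect-allele orientation. Instruments are
    the (jointly re-clumped) union of the per-exposure instrument sets.
    """

    exposure_labels: list[str]
    outcome_label: str
    rows: pd.DataFrame
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        k = len(self.exposure_labels)
        need = (["variant_id"] + [f"beta_exp_{i+1}" for i in range(k)]
                + [f"se_exp_{i+1}" for i in range(k)] + ["beta_out", "se_out"])
        missing = set(need) - set(self.rows.columns)
        if missing:
            raise ValueError(f"MvmrSet rows missing {sorted(missing)}")
        if len(self.rows) <= k:
            raise ValueError(f"need more instruments ({len(self.rows)}) than exposures ({k})")

    @property
    def k(self) -> int:
        return len(self.exposure_labels)

    @property
    def n_snps(self) -> int:
        return len(self.rows)

    def design(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(X, y, w): exposure-beta matrix, outcome betas, weights 1/se_out²."""
        x = self.rows[[f"beta_exp_{i+1}" for i in range(self.k)]].to_numpy(float)
        y = self.rows["beta_out"].to_numpy(float)
        w = 1.0 / self.rows["se_out"].to_numpy(float) ** 2
        return x, y, w

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_harmonized(cls, h: HarmonizedSet) -> "MvmrSet":
        """Lift a univariable harmonized set into a K=1 design (for the
        single-exposure MR-Lasso)."""
        rows = h.rows.rename(columns={"beta_exp": "beta_exp_1", "se_exp": "se_exp_1"})
        return cls([h.exposure_label], h.outcome_label, rows.copy(), list(h.dropped))


def build_mvmr_set(
    exposures: list[SummaryTable],
    outcome: SummaryTable,
    ld: LdMatrix | None = None,
    exclusion: pd.DataFrame | None = None,
    p_threshold: float = GENOME_WIDE_P,
    r2_max: float = CLUMP_R2,
    f_min: float = F_MIN,
    instrument_mode: str = "union",
    log: SelectionLog | None = None,
) -> MvmrSet:
    """Assemble the MVMR design from per-exposure instrument selection.

    Each exposure's instruments pass the univariable QC; their union
    (default; ``instrument_mode='intersection'`` available) is re-clumped
    jointly at the same r² threshold, using each variant's smallest
    p-value across exposures to rank index SNPs. Every trait's effects
    are then oriented onto the first table carrying each variant, and
    variants missing an association in any exposure or in the outcome
    are dropped (logged).
    """
    if len(exposures) < 2:
        raise ValueError("MVMR needs at least two exposures")
    selected = [select_instruments(t, ld, exclusion, p_threshold, r2_max, f_min, log)
                for t in exposures]
    sets = [set(s.records["variant_id"]) for s in selected]
    ids = set.union(*sets) if instrument_mode == "union" else set.intersection(*sets)

    # joint re-clump: rank by the best p across exposures
    min_p: dict[str, float] = {}
    ref_rows: dict[str, pd.Series] = {}
    for t in exposures:
        for _, row in t.records[t.records["variant_id"].isin(ids)].iterrows():
            min_p[row.variant_id] = min(min_p.get(row.variant_id, 1.0), row.pval)
            ref_rows.setdefault(row.variant_id, row)
    ref = SummaryTable("_union_", "continuous",
                       pd.DataFrame([ref_rows[v] for v in sorted(ids)]).assign(
                           pval=lambda d: d["variant_id"].map(min_p)))
    if ld is not None:
        from .instruments import clump
        ref = clump(ref, ld, r2_max, log)
    ids = sorted(ref.records["variant_id"])

    dropped: list[tuple[str, str]] = []
    aligned: list[pd.DataFrame] = []
    for table in exposures + [outcome]:
        have = set(table.records["variant_id"])
        for vid in ids:
            if vid not in have:
                dropped.append((vid, f"absent from {table.trait_label}"))
        h = harmonize_pair(ref.subset(ids), table.subset(ids))
        dropped.extend(h.dropped)
        aligned.append(h.rows.set_index("variant_id")[["beta_out", "se_out"]])

    keep = sorted(set.intersection(*[set(a.index) for a in aligned]))
    data = {"variant_id": keep}
    for i, a in enumerate(aligned[:-1]):
        data[f"beta_exp_{i+1}"] = a.loc[keep, "beta_out"].to_numpy()
        data[f"se_exp_{i+1}"] = a.loc[keep, "se_out"].to_numpy()
    data["beta_out"] = aligned[-1].loc[keep, "beta_out"].to_numpy()
    data["se_out"] = aligned[-1].loc[keep, "se_out"].to_numpy()
    return MvmrSet([t.trait_label for t in exposures], outcome.trait_label,
                   pd.DataFrame(data), dropped)


def _check_rank(x: np.ndarray, labels: list[str]) -> None:
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(f"exposure beta columns are collinear: {labels}")


def mvmr_ivw(m: MvmrSet) -> list[MrEstimate]:
    """Multivariable IVW: WLS of beta_out on the exposure-beta columns,
    no intercept, weights 1/se_out²; SEs use multiplicative residual
    scaling floored at 1; p-values from t(n-K)."""
    x, y, w = m.design()
    _check_rank(x, m.exposure_labels)
    n, k = x.shape
    fit = sm.WLS(y, x, weights=w).fit()
    bse = np.sqrt(np.diag(fit.normalized_cov_params)) * np.sqrt(max(1.0, fit.scale))
    return [_estimate(f"mvmr_ivw[{lbl}]", fit.params[i], bse[i], n, dist="t", df=n - k)
            for i, lbl in enumerate(m.exposure_labels)]


def mvmr_egger(m: MvmrSet, orient_exposure: int = 0
               ) -> tuple[list[MrEstimate], PleiotropyResult]:
    """Multivariable MR-Egger: rows sign-flipped so the orienting
    exposure's betas are nonnegative, then WLS with an intercept; the
    intercept is the pleiotropy estimate."""
    x, y, w = m.design()
    _check_rank(x, m.exposure_labels)
    n, k = x.shape
    sign = np.where(x[:, orient_exposure] >= 0, 1.0, -1.0)
    xs, ys = x * sign[:, None], y * sign
    fit = sm.WLS(ys, sm.add_constant(xs), weights=w).fit()
    bse = np.sqrt(np.diag(fit.normalized_cov_params)) * np.sqrt(max(1.0, fit.scale))
    df = n - k - 1
    ests = [_estimate(f"mvmr_egger[{lbl}]", fit.params[i + 1], bse[i + 1], n,
                      dist="t", df=df) for i, lbl in enumerate(m.exposure_labels)]
    p_int = 2 * stats.t.sf(abs(fit.params[0] / bse[0]), df)
    return ests, PleiotropyResult(float(fit.params[0]), float(bse[0]), float(p_int))


def _wlad(x: np.ndarray, y: np.ndarray, row_scale: np.ndarray) -> np.ndarray:
    """Weighted least-absolute-deviations coefficients via the LP
    formulation (HiGHS): min Σ u subject to |row_scale·(y - Xθ)| ≤ u."""
    n, k = x.shape
    xs = x * row_scale[:, None]
    ys = y * row_scale
    c = np.concatenate([np.zeros(k), np.ones(n)])
    a_ub = np.block([[xs, -np.eye(n)], [-xs, -np.eye(n)]])
    b_ub = np.concatenate([ys, -ys])
    bounds = [(None, None)] * k + [(0, None)] * n
    res = optimize.linprog(c, A_ub=a_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"weighted-LAD solve failed: {res.message}")
    return res.x[:k]


def mvmr_median(m: MvmrSet, n_boot: int = 1000, seed: int | None = None
                ) -> list[MrEstimate]:
    """Robust MVMR: weighted L1 regression of beta_out on the exposure
    betas (rows scaled by 1/se_out), with parametric-bootstrap SEs. With
    K = 1 this is a weighted-median-type slope."""
    if seed is None:
        raise ValueError("mvmr_median requires an explicit seed")
    x, y, _ = m.design()
    _check_rank(x, m.exposure_labels)
    n, k = x.shape
    se_out = m.rows["se_out"].to_numpy(float)
    se_exp = m.rows[[f"se_exp_{i+1}" for i in range(k)]].to_numpy(float)
    theta = _wlad(x, y, 1.0 / se_out)

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, k))
    for b in range(n_boot):
        xb = rng.normal(x, se_exp)
        yb = rng.normal(y, se_out)
        boot[b] = _wlad(xb, yb, 1.0 / se_out)
    ses = boot.std(axis=0, ddof=1)
    return [_estimate(f"mvmr_median[{lbl}]", theta[i], ses[i], n)
            for i, lbl in enumerate(m.exposure_labels)]


@dataclass
class LassoResult:
    """MR-Lasso output: the λ path with valid-set membership, the chosen
    λ, the valid instruments, and the post-selection WLS estimates."""

    estimates: list[MrEstimate]
    valid_ids: list[str]
    chosen_lambda: float
    path: pd.DataFrame  # columns: lam, n_valid, q, q_crit, valid ids


def _lasso_solve(x: np.ndarray, y: np.ndarray, w: np.ndarray, lam: float,
                 max_iter: int = 500, tol: float = 1e-10
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Alternating minimization of Σ w_j (y_j - x_jθ - γ_j)² + λ Σ|γ_j|.

    θ given γ is a WLS solve; each γ_j given θ is a soft-threshold of its
    residual at λ/(2 w_j). The objective is convex, so alternation
    converges to the joint minimum.
    """
    n, k = x.shape
    gamma = np.zeros(n)
    theta = np.zeros(k)
    for _ in range(max_iter):
        xtw = x.T * w
        theta_new = np.linalg.solve(xtw @ x, xtw @ (y - gamma))
        resid = y - x @ theta_new
        thresh = lam / (2.0 * w)
        gamma_new = np.sign(resid) * np.maximum(np.abs(resid) - thresh, 0.0)
        if (np.max(np.abs(theta_new - theta)) < tol
                and np.max(np.abs(gamma_new - gamma)) < tol):
            theta, gamma = theta_new, gamma_new
            break
        theta, gamma = theta_new, gamma_new
    return theta, gamma


def mr_lasso(m: MvmrSet | HarmonizedSet, lambda_grid: np.ndarray | None = None
             ) -> LassoResult:
    """L1-penalized pleiotropy detection with post-selection estimation.

    Each instrument gets its own intercept γ_j, penalized by λΣ|γ_j|
    (exposure effects are never penalized). Instruments with γ_j = 0 at
    a given λ are 'valid'. λ is chosen as the largest grid value whose
    valid-set heterogeneity Q stays below the upper-5% chi-square
    critical value on (n_valid - K) df; the reported effect is the
    multivariable IVW on that valid set. The whole path is returned.
    """
    if isinstance(m, HarmonizedSet):
        m = MvmrSet.from_harmonized(m)
    x, y, w = m.design()
    n, k = x.shape
    if n <= k + 1:
        raise ValueError("MR-Lasso needs more than K+1 instruments")
    if lambda_grid is None:
        # cover from fully-penalized (all gamma = 0) down to near-saturated
        resid0 = y - x @ np.linalg.solve((x.T * w) @ x, (x.T * w) @ y)
        lam_max = 2.0 * np.max(w * np.abs(resid0)) * 1.01 + 1e-12
        lambda_grid = lam_max * np.geomspace(1.0, 1e-3, 40)
    lambda_grid = np.sort(np.asarray(lambda_grid, float))[::-1]
    if (lambda_grid <= 0).any():
        raise ValueError("lambda = 0 saturates the per-SNP intercepts (non-identified); "
                         "use a strictly positive grid")

    ids = m.rows["variant_id"].to_numpy()
    path_rows = []
    chosen = None
    for lam in lambda_grid:
        _, gamma = _lasso_solve(x, y, w, lam)
        valid = np.abs(gamma) < 1e-9
        n_valid = int(valid.sum())
        if n_valid >= k + 1:
            xv, yv, wv = x[valid], y[valid], w[valid]
            theta_v = np.linalg.solve((xv.T * wv) @ xv, (xv.T * wv) @ yv)
            q = float(np.sum(wv * (yv - xv @ theta_v) ** 2))
            q_crit = float(stats.chi2.ppf(0.95, n_valid - k)) if n_valid > k else np.inf
        else:
            q, q_crit = np.inf, -np.inf
        path_rows.append(dict(lam=float(lam), n_valid=n_valid, q=q, q_crit=q_crit,
                              valid_ids=",".join(ids[valid])))
        if chosen is None and n_valid >= k + 1 and q <= q_crit:
            chosen = (lam, valid)
    path = pd.DataFrame(path_rows)
    if chosen is None:
        raise ValueError("no lambda on the grid yields a homogeneous valid set of "
                         "size > K; extend the grid downward")
    lam, valid = chosen
    sub = MvmrSet(m.exposure_labels, m.outcome_label,
                  m.rows[valid].reset_index(drop=True))
    return LassoResult(mvmr_ivw(sub), ids[valid].tolist(), float(lam), path)
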