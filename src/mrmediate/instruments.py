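"""Instrument quality control for Mendelian randomization.

A variant qualifies as an instrument when it is genome-wide significant
for the exposure, approximately independent of the other instruments
(LD pruned at a strict r² threshold), and strong (per-variant F ≥ 10,
F approximated as (beta/se)²). Instruments missing from the outcome GWAS
may be replaced by a high-LD proxy; variants known to act on the outcome
through other phenotypes are removed via an explicit exclusion list. LD
is always caller-supplied — nothing here touches genotypes or the web.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .summary_io import SummaryTable

GENOME_WIDE_P = 5e-8
CLUMP_R2 = 0.001
F_MIN = 10.0
PROXY_R2 = 0.8


@dataclass
class LdMatrix:
    """Pairwise LD (r²) between named variants; symmetric, unit diagonal."""

    ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.ids)
        if self.r2.shape != (k, k):
            raise ValueError(f"r2 shape {self.r2.shape} does not match {k} ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("LD matrix asymmetric beyond 1e-8")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 entries must lie in [0,1]")
        self._index = {vid: i for i, vid in enumerate(self.ids)}

    def __contains__(self, vid: str) -> bool:
        return vid in self._index

    def pair(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def from_long_tsv(cls, path: str | Path) -> "LdMatrix":
        """Build from long-format TSV (id1, id2, r2); missing pairs are 0."""
        long = pd.read_csv(path, sep="\t")
        ids = sorted(set(long["id1"]) | set(long["id2"]))
        idx = {v: i for i, v in enumerate(ids)}
        r2 = np.eye(len(ids))
        for _, row in long.iterrows():
            i, j = idx[row["id1"]], idx[row["id2"]]
            r2[i, j] = r2[j, i] = row["r2"]
        return cls(ids, r2)

    @classmethod
    def from_square_tsv(cls, path: str | Path) -> "LdMatrix":
        sq = pd.read_csv(path, sep="\t", index_col=0)
        return cls(sq.index.astype(str).tolist(), sq.to_numpy(dtype=float))


@dataclass
class ProxyTable:
    """Local proxy lookup: rows of target/proxy ids, r², and allele map.

    Columns: target, proxy, r2, target_ea, target_oa, proxy_ea, proxy_oa.
    The allele map states which proxy allele corresponds to the target's
    effect allele, so a substituted effect can be reported on the target
    orientation.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"target", "proxy", "r2", "target_ea", "target_oa", "proxy_ea", "proxy_oa"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"proxy table missing columns {sorted(missing)}")
        if (self.table["target"] == self.table["proxy"]).any():
            raise ValueError("proxy_id must differ from target_id")
        if ((self.table["r2"] < 0) | (self.table["r2"] > 1)).any():
            raise ValueError("proxy r2 outside [0,1]")
        dup = self.table.duplicated(subset=["target", "proxy"], keep=False)
        if dup.any() and self.table.loc[dup].groupby(["target", "proxy"]).nunique().max().max() > 1:
            raise ValueError("conflicting duplicate proxy rows")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProxyTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class SelectionLog:
    """Ordered audit trail: every variant's fate at every QC stage."""

    entries: list[dict] = field(default_factory=list)

    def add(self, variant_id: str, stage: str, action: str, reason: str,
            value: float | None = None) -> None:
        self.entries.append(dict(variant_id=variant_id, stage=stage,
                                 action=action, reason=reason, value=value))

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries,
                            columns=["variant_id", "stage", "action", "reason", "value"])

    def to_tsv(self, path: str | Path) -> None:
        self.frame().to_csv(path, sep="\t", index=False)


def select_genomewide(table: SummaryTable, p_threshold: float = GENOME_WIDE_P,
                      log: SelectionLog | None = None) -> SummaryTable:
    """Keep records with p strictly below the significance threshold."""
    rec = table.records
    keep = rec["pval"] < p_threshold
    if log is not None:
        for _, row in rec.iterrows():
            act = "retained" if row.pval < p_threshold else "removed"
            log.add(row.variant_id, "significance", act,
                    f"p {'<' if row.pval < p_threshold else '>='} {p_threshold:g}", row.pval)
    out = SummaryTable(table.trait_label, table.trait_type, rec[keep].copy())
    if out.n_variants == 0:
        import logging
        logging.getLogger(__name__).warning(
            "%s: no variant passes p < %g", table.trait_label, p_threshold)
    return out


def clump(table: SummaryTable, ld: LdMatrix, r2_max: float = CLUMP_R2,
          log: SelectionLog | None = None) -> SummaryTable:
    """Greedy LD pruning: repeatedly index the smallest-p unselected
    variant and discard everything correlated with a retained index at
    r² > r2_max. Ties in p break lexicographically on variant_id, making
    the result independent of input row order. Variants absent from the
    LD matrix are kept (no information to prune on) and logged.
    """
    rec = table.records
    in_ld = rec["variant_id"].apply(lambda v: v in ld)
    candidates = rec[in_ld].sort_values(
        ["pval", "variant_id"], kind="mergesort").reset_index(drop=True)
    kept: list[str] = []
    for _, row in candidates.iterrows():
        hit = next((k for k in kept if ld.pair(row.variant_id, k) > r2_max), None)
        if hit is None:
            kept.append(row.variant_id)
            if log is not None:
                log.add(row.variant_id, "clump", "retained", "index SNP", row.pval)
        elif log is not None:
            log.add(row.variant_id, "clump", "removed",
                    f"r2 > {r2_max:g} with {hit}", ld.pair(row.variant_id, hit))
    keep_ids = set(kept)
    for vid in rec.loc[~in_ld, "variant_id"]:
        keep_ids.add(vid)
        if log is not None:
            log.add(vid, "clump", "retained", "no LD info", None)
    out = rec[rec["variant_id"].isin(keep_ids)].copy()
    return SummaryTable(table.trait_label, table.trait_type, out)


def instrument_strength(table: SummaryTable, f_min: float = F_MIN,
                        log: SelectionLog | None = None
                        ) -> tuple[SummaryTable, pd.Series]:
    """Per-variant F = (beta/se)²; drop records with F < f_min."""
    rec = table.records
    f = (rec["beta"] / rec["se"]) ** 2
    f.index = rec["variant_id"].to_numpy()
    keep = f.to_numpy() >= f_min
    if log is not None:
        for vid, fv, k in zip(rec["variant_id"], f, keep):
            log.add(vid, "strength", "retained" if k else "removed",
                    f"F {'>=' if k else '<'} {f_min:g}", fv)
    return SummaryTable(table.trait_label, table.trait_type, rec[keep].copy()), f


def exclude_listed(table: SummaryTable, exclusion: pd.DataFrame | Sequence[tuple[str, str]],
                   log: SelectionLog | None = None) -> SummaryTable:
    """Remove variants named on an exclusion list (id, reason).

    The list stands in for confounder/outcome-association screening
    (e.g. variants tied to PCOS, endometriosis or thyroid function found
    by database lookup); supplying it explicitly keeps the screen
    auditable and the pipeline offline.
    """
    if not isinstance(exclusion, pd.DataFrame):
        exclusion = pd.DataFrame(list(exclusion), columns=["variant_id", "reason"])
    reasons = dict(zip(exclusion.get("variant_id", []), exclusion.get("reason", [])))
    rec = table.records
    present = rec["variant_id"].isin(reasons)
    if log is not None:
        for vid in rec.loc[present, "variant_id"]:
            log.add(vid, "exclusion", "removed", str(reasons[vid]), None)
        for vid in set(reasons) - set(rec["variant_id"]):
            log.add(vid, "exclusion", "absent", "listed id not in table", None)
    return SummaryTable(table.trait_label, table.trait_type, rec[~present].copy())


def substitute_proxies(missing_ids: Iterable[str], proxies: ProxyTable,
                       outcome: SummaryTable, r2_min: float = PROXY_R2,
                       log: SelectionLog | None = None) -> dict[str, str]:
    """Map instruments absent from the outcome GWAS to high-LD proxies.

    For each missing id, the proxy with maximal r² ≥ r2_min that exists
    in the outcome table wins; its outcome record is re-oriented onto
    the target's effect allele via the allele map (the outcome beta is
    negated when the proxy allele corresponding to the target's effect
    allele is the proxy's *other* allele). Returns {target: proxy}.
    The re-oriented proxy records are appended to ``outcome.records``
    under the target id by the caller via :func:`apply_proxy_map`.
    """
    out_ids = set(outcome.records["variant_id"])
    chosen: dict[str, str] = {}
    for tid in missing_ids:
        cand = proxies.table[(proxies.table["target"] == tid)
                             & (proxies.table["r2"] >= r2_min)]
        cand = cand[cand["proxy"].isin(out_ids)]
        if cand.empty:
            if log is not None:
                log.add(tid, "proxy", "dropped", f"no proxy >= r2 {r2_min:g}", None)
            continue
        best = cand.loc[cand["r2"].idxmax()]
        chosen[tid] = str(best["proxy"])
        if log is not None:
            log.add(tid, "proxy", "substituted", f"proxy {best['proxy']}", best["r2"])
    return chosen


def apply_proxy_map(proxy_map: dict[str, str], proxies: ProxyTable,
                    outcome: SummaryTable) -> SummaryTable:
    """Materialize proxy substitutions as outcome records under target ids,
    with effects expressed on the target's effect-allele orientation."""
    rows = []
    out = outcome.records.set_index("variant_id")
    for tid, pid in proxy_map.items():
        meta = proxies.table[(proxies.table["target"] == tid)
                             & (proxies.table["proxy"] == pid)].iloc[0]
        rec = out.loc[pid].copy()
        # does the proxy's effect allele track the target's effect allele?
        aligned = rec["effect_allele"] == meta["proxy_ea"]
        beta = rec["beta"] if aligned else -rec["beta"]
        eaf = rec["eaf"] if aligned else (1 - rec["eaf"] if not np.isnan(rec["eaf"]) else np.nan)
        rows.append((tid, meta["target_ea"], meta["target_oa"], beta,
                     rec["se"], rec["pval"], eaf, rec["n"]))
    frame = pd.DataFrame(rows, columns=outcome.records.columns)
    merged = pd.concat([outcome.records, frame], ignore_index=True)
    return SummaryTable(outcome.trait_label, outcome.trait_type, merged)


def select_instruments(table: SummaryTable, ld: LdMatrix | None = None,
                       exclusion: pd.DataFrame | None = None,
                       p_threshold: float = GENOME_WIDE_P,
                       r2_max: float = CLUMP_R2, f_min: float = F_MIN,
                       log: SelectionLog | None = None) -> SummaryTable:
    """Full QC pipeline: significance → exclusion list → LD clump → strength."""
    t = select_genomewide(table, p_threshold, log)
    if exclusion is not None:
        t = exclude_listed(t, exclusion, log)
    if ld is not None:
        t = clump(t, ld, r2_max, log)
    t, _ = instrument_strength(t, f_min, log)
    return t
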