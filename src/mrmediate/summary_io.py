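"""Reading, validating and harmonizing GWAS summary statistics.

Two-sample Mendelian randomization pairs per-variant associations from an
exposure GWAS with associations from an outcome GWAS. Before any estimator
can run, both effect sizes must refer to the same allele of each variant:
this module parses summary tables, enforces per-record invariants, and
aligns exposure/outcome effect directions, handling swapped alleles,
strand flips and palindromic (A/T, C/G) variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order of a summary table
RECORD_COLUMNS = ["variant_id", "effect_allele", "other_allele",
                  "beta", "se", "pval", "eaf", "n"]

TraitType = Literal["binary", "continuous"]


class ConfigurationError(ValueError):
    """A column map or config does not match the input file."""


@dataclass
class SummaryTable:
    """Per-variant GWAS association records for one trait from one sample.

    ``records`` columns: variant_id, effect_allele, other_allele, beta
    (log-odds per effect-allele copy for binary traits, raw units for
    continuous), se, pval, eaf (optional, NaN if absent), n (optional).
    variant_id is unique.
    """

    trait_label: str
    trait_type: TraitType
    records: pd.DataFrame

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise ValueError(f"trait_type must be binary|continuous, got {self.trait_type!r}")
        if self.records.columns.tolist() != RECORD_COLUMNS:
            missing = set(RECORD_COLUMNS) - set(self.records.columns)
            if missing:
                raise ValueError(f"records missing columns: {sorted(missing)}")
            self.records = self.records[RECORD_COLUMNS]
        if self.records["variant_id"].duplicated().any():
            dups = self.records.loc[self.records["variant_id"].duplicated(), "variant_id"]
            raise ValueError(f"duplicate variant_id in {self.trait_label}: {dups.tolist()[:5]}")
        self.records = self.records.reset_index(drop=True)

    @property
    def n_variants(self) -> int:
        return len(self.records)

    def subset(self, ids: Sequence[str]) -> "SummaryTable":
        keep = self.records[self.records["variant_id"].isin(set(ids))]
        return SummaryTable(self.trait_label, self.trait_type, keep.copy())

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs on a shared effect-allele orientation.

    ``rows`` columns: variant_id, beta_exp, se_exp, beta_out, se_out.
    The exposure table's effect allele defines the orientation; outcome
    betas have been flipped where needed. ``dropped`` records every shared
    variant that could not be harmonized, with a reason.
    """

    exposure_label: str
    outcome_label: str
    rows: pd.DataFrame
    dropped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return len(self.rows)

    def to_tsv(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    def drop_log_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.dropped, columns=["variant_id", "reason"]).to_csv(
            path, sep="\t", index=False)


def validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Split a raw record frame into valid rows and (id, reason) rejects.

    Invariants enforced: alleles are single A/C/G/T letters and differ
    (rejects indels and multi-allelic tokens), se > 0, pval in [0, 1],
    eaf when present strictly inside (0, 1), beta/se numeric.
    """
    rejects: list[tuple[str, str]] = []
    df = df.copy()
    for col in ("beta", "se", "pval", "eaf", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    df["effect_allele"], df["other_allele"] = ea, oa

    checks = [
        (~ea.isin(VALID_ALLELES) | ~oa.isin(VALID_ALLELES), "non-SNP alleles"),
        (ea == oa, "identical alleles"),
        (df["beta"].isna(), "non-numeric beta"),
        (df["se"].isna(), "non-numeric se"),
        (df["se"] <= 0, "nonpositive se"),
        (df["pval"].isna() | (df["pval"] < 0) | (df["pval"] > 1), "pval outside [0,1]"),
        (df["eaf"].notna() & ((df["eaf"] <= 0) | (df["eaf"] >= 1)), "eaf outside (0,1)"),
    ]
    bad = pd.Series(False, index=df.index)
    for mask, reason in checks:
        newly = mask & ~bad
        for vid in df.loc[newly, "variant_id"]:
            rejects.append((str(vid), reason))
        bad |= mask
    return df.loc[~bad].reset_index(drop=True), rejects


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str],
    trait_label: str,
    trait_type: TraitType,
) -> SummaryTable:
    """Read a tab-separated GWAS summary file into a validated table.

    ``column_map`` maps record fields (variant_id, effect_allele,
    other_allele, beta, se, pval, and optionally eaf, n) to the file's
    column names. Rows violating record invariants are dropped with the
    reasons logged; a missing mandatory column raises ConfigurationError.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    mandatory = ["variant_id", "effect_allele", "other_allele", "beta", "se", "pval"]
    missing = [f for f in mandatory if f not in column_map]
    if missing:
        raise ConfigurationError(f"column_map lacks mappings for {missing}")
    absent = [c for f, c in column_map.items() if c not in raw.columns]
    if absent:
        raise ConfigurationError(
            f"{path}: columns {absent} not found (header: {raw.columns.tolist()})")

    df = pd.DataFrame({f: raw[c] for f, c in column_map.items()})
    for opt in ("eaf", "n"):
        if opt not in df:
            df[opt] = np.nan
    df = df[RECORD_COLUMNS]
    valid, rejects = validate_records(df)
    if rejects:
        logger.warning("%s: rejected %d rows: %s", trait_label, len(rejects), rejects[:10])
    return SummaryTable(trait_label, trait_type, valid)


def is_palindromic(ea: str, oa: str) -> bool:
    """A/T and C/G variants: strand is unresolvable from alleles alone."""
    return COMPLEMENT[ea] == oa


def _classify_pair(exp_ea: str, exp_oa: str, out_ea: str, out_oa: str) -> str:
    """Relation of an outcome allele pair to the exposure orientation.

    Returns one of 'same', 'swap', 'mismatch'. Strand complements are
    folded in: (T,C) vs exposure (A,G) is 'same'. Palindromic variants
    must be handled before calling (here complementing is a no-op or a
    swap, so the answer would silently assume same strand).
    """
    if (out_ea, out_oa) == (exp_ea, exp_oa):
        return "same"
    if (out_ea, out_oa) == (exp_oa, exp_ea):
        return "swap"
    flipped = (COMPLEMENT[out_ea], COMPLEMENT[out_oa])
    if flipped == (exp_ea, exp_oa):
        return "same"
    if flipped == (exp_oa, exp_ea):
        return "swap"
    return "mismatch"


def harmonize_pair(
    exposure: SummaryTable,
    outcome: SummaryTable,
    palindrome_policy: Literal["drop", "infer_by_eaf"] = "drop",
    eaf_ambiguity_band: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedSet:
    """Align outcome effects onto the exposure's effect-allele orientation.

    For each variant present in both tables: matching allele pairs are
    copied; swapped pairs get a negated outcome beta; strand-complement
    images are folded onto the same rules. Palindromic variants are
    dropped under the default policy, or oriented by allele frequency
    under ``infer_by_eaf`` when both tables' EAFs fall outside
    ``eaf_ambiguity_band`` (frequencies on the same side of 0.5 imply the
    same allele, opposite sides imply a swap). Every exclusion is
    recorded in ``dropped`` with its reason. An empty intersection of
    variant ids is an error.
    """
    lo, hi = eaf_ambiguity_band
    exp = exposure.records.set_index("variant_id")
    out = outcome.records.set_index("variant_id")
    shared = [vid for vid in exp.index if vid in out.index]
    if not shared:
        raise ValueError(
            f"no shared variants between {exposure.trait_label} and {outcome.trait_label}")

    rows = []
    dropped: list[tuple[str, str]] = []
    for vid in shared:
        e, o = exp.loc[vid], out.loc[vid]
        if is_palindromic(e.effect_allele, e.other_allele):
            if palindrome_policy == "drop":
                dropped.append((vid, "palindromic"))
                continue
            if np.isnan(e.eaf) or np.isnan(o.eaf) or lo <= e.eaf <= hi or lo <= o.eaf <= hi:
                dropped.append((vid, "palindromic ambiguous eaf"))
                continue
            if {o.effect_allele, o.other_allele} != {e.effect_allele, e.other_allele}:
                dropped.append((vid, "allele mismatch"))
                continue
            # frequencies on the same side of 0.5 identify the same allele
            same_side = (e.eaf < 0.5) == (o.eaf < 0.5)
            aligned_letters = (o.effect_allele == e.effect_allele)
            sign = 1.0 if same_side == aligned_letters else -1.0
            rows.append((vid, e.beta, e.se, sign * o.beta, o.se))
            continue
        rel = _classify_pair(e.effect_allele, e.other_allele,
                             o.effect_allele, o.other_allele)
        if rel == "mismatch":
            dropped.append((vid, "allele mismatch"))
        elif rel == "same":
            rows.append((vid, e.beta, e.se, o.beta, o.se))
        else:
            rows.append((vid, e.beta, e.se, -o.beta, o.se))

    frame = pd.DataFrame(rows, columns=["variant_id", "beta_exp", "se_exp",
                                        "beta_out", "se_out"])
    return HarmonizedSet(exposure.trait_label, outcome.trait_label, frame, dropped)
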