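"""Shared definitions for the analysis scripts: the synthetic study arms,
their generating parameters, seeds and file locations.

The study emulates a mediation-MR design: a binary psychiatric exposure
instrumented by ~49 genome-wide-significant SNPs from a large biobank
GWAS, a continuous circulating-cytokine mediator instrumented by 4 SNPs
from a small cohort GWAS, and infertility-endpoint outcomes from a
disease-endpoint GWAS. Per-arm causal effects are set to the log-odds
magnitudes typical of such studies; one null endpoint is included as a
negative control.
"""

from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "results" / "study_data"
RESULTS_DIR = ROOT / "results"

SEED = 20240805

BASE = dict(
    n_snps_exposure=49,
    n_snps_mediator=4,
    theta_xm=-0.40,           # exposure lowers the mediator
    scramble_alleles=True,    # outcome/mediator panels report arbitrary strand/allele
)

# per-endpoint direct effects (log-odds) and mediator effects
ARMS = [
    dict(label="female_infertility",
         theta_direct=float(np.log(1.19)), theta_my=float(np.log(0.93))),
    dict(label="female_infertility_cervical_vaginal",
         theta_direct=float(np.log(1.18)), theta_my=float(np.log(0.92))),
    dict(label="male_infertility", theta_direct=0.0, theta_my=0.0),
]

COLUMN_MAP = dict(variant_id="SNP", effect_allele="EA", other_allele="OA",
                  beta="BETA", se="SE", pval="P", eaf="EAF", n="N")
FILE_HEADER = ["SNP", "EA", "OA", "BETA", "SE", "P", "EAF", "N"]


def arm_seed(i: int) -> int:
    return SEED + 7919 * i


def arm_dir(label: str) -> Path:
    return DATA_DIR / label
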