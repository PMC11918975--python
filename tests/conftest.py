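import numpy as np
import pandas as pd
import pytest

from mrmediate import HarmonizedSet, SummaryTable


def make_table(rows, label="trait", trait_type="continuous"):
    """Build a SummaryTable from (id, ea, oa, beta, se, pval[, eaf[, n]]) tuples."""
    full = []
    for r in rows:
        r = list(r) + [np.nan] * (8 - len(r))
        full.append(r)
    df = pd.DataFrame(full, columns=["variant_id", "effect_allele", "other_allele",
                                     "beta", "se", "pval", "eaf", "n"])
    return SummaryTable(label, trait_type, df)


def make_harmonized(ratios, ratio_ses, beta_exp=None, se_exp=1e-6,
                    exposure="X", outcome="Y"):
    """HarmonizedSet whose Wald ratios and ratio SEs are exactly as given:
    beta_out = ratio * beta_exp, se_out = ratio_se * |beta_exp|."""
    ratios = np.asarray(ratios, float)
    ratio_ses = np.asarray(ratio_ses, float)
    be = np.ones_like(ratios) if beta_exp is None else np.asarray(beta_exp, float)
    df = pd.DataFrame({
        "variant_id": [f"rs{i}" for i in range(len(ratios))],
        "beta_exp": be, "se_exp": se_exp,
        "beta_out": ratios * be, "se_out": ratio_ses * np.abs(be),
    })
    return HarmonizedSet(exposure, outcome, df)


@pytest.fixture
def simple_pair():
    """Exposure/outcome tables sharing three well-behaved variants."""
    exposure = make_table([
        ("rs1", "A", "G", 0.10, 0.01, 1e-20, 0.3),
        ("rs2", "C", "T", 0.08, 0.01, 1e-15, 0.6),
        ("rs3", "G", "A", 0.12, 0.01, 1e-25, 0.2),
    ], "exp", "binary")
    outcome = make_table([
        ("rs1", "A", "G", 0.05, 0.02, 0.01, 0.3),
        ("rs2", "T", "C", -0.04, 0.02, 0.04, 0.4),
        ("rs3", "G", "A", 0.06, 0.02, 0.02, 0.2),
    ], "out", "binary")
    return exposure, outcome
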