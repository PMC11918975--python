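"""Instrument QC for every study arm: genome-wide significance, strength
screening, and the mediator-association screen used by the total-effect
arm. Writes per-arm selection logs and a QC summary table.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_setup import ARMS, COLUMN_MAP, RESULTS_DIR, arm_dir

from mrmediate import SelectionLog, read_summary_table, select_instruments
from mrmediate.mediation import exclude_mediator_associated


def main():
    rows = []
    for arm in ARMS:
        d = arm_dir(arm["label"])
        exposure = read_summary_table(d / "exposure.tsv", COLUMN_MAP,
                                      "exposure", "binary")
        mediator = read_summary_table(d / "mediator.tsv", COLUMN_MAP,
                                      "mediator", "continuous")
        log = SelectionLog()
        exp_iv = select_instruments(exposure, log=log)
        med_iv = select_instruments(mediator, log=log)
        exp_iv_total = exclude_mediator_associated(exp_iv, mediator, log=log)
        log.to_tsv(d / "selection_log.tsv")
        rows.append(dict(arm=arm["label"],
                         exposure_instruments=exp_iv.n_variants,
                         mediator_instruments=med_iv.n_variants,
                         total_arm_instruments=exp_iv_total.n_variants))
        print(f"[{arm['label']}] {exp_iv.n_variants} exposure instruments, "
              f"{med_iv.n_variants} mediator instruments; "
              f"{exp_iv.n_variants - exp_iv_total.n_variants} removed by the "
              f"mediator-association screen")
    out = RESULTS_DIR / "qc_summary.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    print(f"\nQC summary -> {out}")


if __name__ == "__main__":
    main()
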