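"""Generate the synthetic three-trait study and write its GWAS summary
tables (TSV) plus the generating truth for every outcome arm.

Each arm gets its own exposure/mediator/outcome panels drawn with an
arm-specific seed; the truth JSON records the realized per-SNP effects
and the configured proportion mediated, which later scripts compare
against their estimates.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_setup import ARMS, BASE, COLUMN_MAP, FILE_HEADER, arm_dir, arm_seed

from mrmediate import SimulationConfig, simulate_mediation_study


def write_table(table, path):
    table.records.rename(columns=COLUMN_MAP)[FILE_HEADER].to_csv(
        path, sep="\t", index=False)


def main():
    for i, arm in enumerate(ARMS):
        cfg = SimulationConfig(seed=arm_seed(i), **BASE,
                               theta_direct=arm["theta_direct"],
                               theta_my=arm["theta_my"])
        exposure, mediator, outcome, truth = simulate_mediation_study(cfg)
        d = arm_dir(arm["label"])
        d.mkdir(parents=True, exist_ok=True)
        write_table(exposure, d / "exposure.tsv")
        write_table(mediator, d / "mediator.tsv")
        write_table(outcome, d / "outcome.tsv")
        (d / "truth.json").write_text(json.dumps(truth.as_dict(), indent=1,
                                                 sort_keys=True) + "\n")
        tp = truth.true_proportion
        print(f"[{arm['label']}] wrote {exposure.n_variants}-SNP panels; "
              f"true proportion mediated = "
              f"{'undefined (null total effect)' if tp != tp else f'{tp:.4f}'}")
    print(f"\nStudy data under {arm_dir('').parent}")


if __name__ == "__main__":
    main()
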