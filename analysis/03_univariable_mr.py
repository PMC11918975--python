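"""Univariable two-sample MR for every arm, plus the bidirectional
exposure<->mediator screen. Emits a forest-plot-ready estimates table and
per-arm funnel / leave-one-out diagnostic tables.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_setup import ARMS, COLUMN_MAP, RESULTS_DIR, SEED, arm_dir

from mrmediate import (egger, funnel_data, harmonize_pair, ivw, leave_one_out,
                       read_summary_table, select_instruments, weighted_median)


def panel_rows(h, label, analysis, seed):
    out = []
    est_i, het = ivw(h)
    out.append(dict(outcome=label, analysis=analysis, q=het.q, q_pval=het.pval,
                    **est_i.as_dict()))
    if h.n_snps >= 3:
        est_e, pleio, _ = egger(h)
        out.append(dict(outcome=label, analysis=analysis,
                        egger_intercept=pleio.intercept,
                        intercept_pval=pleio.pval, **est_e.as_dict()))
        out.append(dict(outcome=label, analysis=analysis,
                        **weighted_median(h, seed=seed).as_dict()))
    return out


def main():
    rows = []
    for i, arm in enumerate(ARMS):
        d = arm_dir(arm["label"])
        exposure = read_summary_table(d / "exposure.tsv", COLUMN_MAP, "exposure", "binary")
        mediator = read_summary_table(d / "mediator.tsv", COLUMN_MAP, "mediator", "continuous")
        outcome = read_summary_table(d / "outcome.tsv", COLUMN_MAP, arm["label"], "binary")
        exp_iv = select_instruments(exposure)
        med_iv = select_instruments(mediator)

        if i == 0:  # bidirectional screen on the first arm's panels
            fwd, _ = ivw(harmonize_pair(exp_iv, mediator))
            rev, _ = ivw(harmonize_pair(med_iv, exposure))
            print(f"Bidirectional screen: exposure->mediator beta "
                  f"{fwd.beta:+.3f} (p {fwd.pval:.2e}); reverse "
                  f"{rev.beta:+.4f} (p {rev.pval:.2f})")
            rows += panel_rows(harmonize_pair(exp_iv, mediator),
                               "mediator", "exposure_on_mediator", SEED)
            rows += panel_rows(harmonize_pair(med_iv, exposure),
                               "exposure", "mediator_on_exposure", SEED)

        h_eo = harmonize_pair(exp_iv, outcome)
        h_mo = harmonize_pair(med_iv, outcome)
        rows += panel_rows(h_eo, arm["label"], "exposure_on_outcome", SEED)
        rows += panel_rows(h_mo, arm["label"], "mediator_on_outcome", SEED)
        funnel_data(h_eo).to_csv(d / "funnel_exposure_on_outcome.tsv",
                                 sep="\t", index=False)
        leave_one_out(h_eo).to_csv(d / "loo_exposure_on_outcome.tsv",
                                   sep="\t", index=False)
        est = [r for r in rows if r.get("outcome") == arm["label"]
               and r["analysis"] == "exposure_on_outcome"][0]
        print(f"[{arm['label']}] exposure IVW OR "
              f"{est['odds_ratio']:.3f} ({est['or_ci_low']:.3f}-"
              f"{est['or_ci_high']:.3f}), p {est['pval']:.2e}")

    out = RESULTS_DIR / "univariable_mr.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    print(f"\nEstimates table -> {out}")


if __name__ == "__main__":
    main()
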