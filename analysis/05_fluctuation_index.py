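"""Measure trial-to-trial fluctuation per component and condition.

Band-passes each session time course at 0.005-0.1 Hz, subtracts the
grand-average condition response, and normalises the residual sd by the
component's grand-average response amplitude; then compares conditions by
a paired t-test on log indices and scans for association with the binary
self-report.  Writes results/fluctuation.tsv and fluct_summary.tsv.
"""
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS, TRIM, get_fit

import fluctica as fl


def main() -> None:
    cohort, cset = get_fit()
    by_subject = cset.timecourses_by_subject()
    tab = fl.fluctuation_table(by_subject, cohort.design, trim_volumes=TRIM)
    cmp_ = fl.compare_conditions(tab)
    assoc = fl.report_association(tab.task_ratio(), cohort.reports)
    summary = pd.DataFrame(
        {
            "component": np.arange(cset.n_components),
            "fluct_t": np.round(cmp_.t, 3),
            "fluct_p": np.round(cmp_.p, 6),
            "suppression_over_imagery": np.round(cmp_.geometric_ratio, 3),
            "report_t": np.round(assoc.t, 3),
            "report_p": np.round(assoc.p, 6),
        }
    )
    RESULTS.mkdir(exist_ok=True)
    tab.to_frame().to_csv(RESULTS / "fluctuation.tsv", sep="\t", index=False)
    summary.to_csv(RESULTS / "fluct_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    best = int(np.argmin(assoc.p))
    print(
        f"\ncomponent most associated with the self-report: {best} "
        f"(p={assoc.p[best]:.4g}; {assoc.n_yes} yes vs {assoc.n_no} no)"
    )


if __name__ == "__main__":
    main()
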