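"""Test every component's task-relatedness two ways.

Analysis 1: per-run OLS against the eight-regressor design (four
HRF-convolved epochs + four cue-event trains), imagery-minus-suppression
contrast, one-sample t over subjects.  Analysis 2: two-sample t between the
imagery and suppression phases of the grand-average cycle.  Writes
results/task_relatedness.tsv.
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
    dm = fl.build_design_matrix(cohort.design, trim_volumes=TRIM)
    a1 = fl.analysis1(by_subject, dm)
    a2 = fl.analysis2(by_subject, cohort.design, trim_volumes=TRIM)
    table = pd.DataFrame(
        {
            "component": np.arange(cset.n_components),
            "mean_dbeta": np.round(a1.dbeta.mean(axis=0), 4),
            "a1_t": np.round(a1.t, 3),
            "a1_p": np.round(a1.p, 6),
            "a2_t": np.round(a2.t, 3),
            "a2_p": np.round(a2.p, 6),
        }
    ).sort_values("a1_p")
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "task_relatedness.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    ref = int(np.argmin(a1.t))
    print(
        f"\nmost suppression-related component (largest negative contrast t): {ref}"
    )


if __name__ == "__main__":
    main()
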