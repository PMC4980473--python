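"""Label between-network coupling against the suppression-related component.

Block-wise Pearson correlations of the band-passed, per-block detrended
time courses (first four volumes of every block discarded), Fisher-Z pooled
over trials, tested per condition across subjects; a pair is labelled
positive/negative only when both condition tests agree.  Writes
results/coupling.tsv.
"""
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS, TRIM, get_fit

import fluctica as fl


def main() -> None:
    cohort, cset = get_fit()
    by_subject = cset.timecourses_by_subject()
    dm = fl.build_design_matrix(cohort.design, trim_volumes=TRIM)
    a1 = fl.analysis1(by_subject, dm)
    rep = fl.screen_components(cset, cohort.mask, cohort.config.tr)
    retained = rep.retained()
    ref = int(retained[np.argmin(a1.t[retained])])
    table = fl.couple_reference(
        by_subject, cohort.design, ref, partners=[k for k in retained if k != ref],
        trim_volumes=TRIM,
    )
    RESULTS.mkdir(exist_ok=True)
    frame = table.to_frame()
    frame.to_csv(RESULTS / "coupling.tsv", sep="\t", index=False)
    print(frame.to_string(index=False))
    print(f"\nreference component (suppression-related): {ref}")
    labels = dict(zip(table.partners, table.labels))
    print(
        "polarity labels:",
        {k: v for k, v in labels.items() if v != "equivocal"} or "none",
    )


if __name__ == "__main__":
    main()
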