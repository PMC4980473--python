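"""Generate the default synthetic cohort and render it to disk.

Twenty subjects x two 408-s runs on a 16x16x8 grid: eight networks (one
suppression-related with doubled within-block fluctuation, one reciprocally
coupled imagery network, a report-linked executive-control network, and
five others) plus two artifact components.  Volumes, events, participants,
and the ground-truth sidecar land under scratch/cohort/.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import MASTER_SEED, SCRATCH, get_cohort

import fluctica as fl


def main() -> None:
    gt = get_cohort()
    out = SCRATCH / "cohort"
    paths = fl.render_cohort(gt, out)
    print(f"cohort (master_seed={MASTER_SEED}) rendered to {out}")
    print(f"  {len(paths['bold'])} bold runs, {len(paths['events'])} event tables")
    print(f"  components: {', '.join(gt.component_names)}")
    print(f"  mask voxels: {int(gt.mask.sum())} of {gt.mask.size}")
    print(
        f"  self-report split: {int(gt.reports.sum())} yes / "
        f"{int((1 - gt.reports).sum())} no (median split on the "
        f"{gt.config.control_component} fluctuation ratio)"
    )


if __name__ == "__main__":
    main()
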