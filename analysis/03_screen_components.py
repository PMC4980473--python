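"""Label artifact components by spectral power ratio and spatial extent.

Computes the low-frequency power ratio of every back-projected component
time course (bands 0.003-0.10 Hz over 0.15-0.25 Hz, averaged over
subjects/runs) and the fraction of suprathreshold |z| > 2 voxels outside
the brain mask; writes results/screen.tsv.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS, get_fit

import fluctica as fl


def main() -> None:
    cohort, cset = get_fit()
    rep = fl.screen_components(cset, cohort.mask, cohort.config.tr)
    RESULTS.mkdir(exist_ok=True)
    rep.save(RESULTS, "screen")
    frame = rep.to_frame()
    print(frame.to_string(index=False))
    kept = rep.retained()
    print(
        f"\n{len(kept)} of {cset.n_components} components retained "
        f"(valid or suspicious); artifacts: "
        f"{[i for i in range(cset.n_components) if i not in kept]}"
    )


if __name__ == "__main__":
    main()
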