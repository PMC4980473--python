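"""Contrast voxelwise-GLM and component-level sensitivity under fluctuation.

Scales the suppression network's within-block fluctuation sd by 1x, 5x and
12x at a fixed mean condition effect; at each level runs the Bonferroni-
corrected voxelwise GLM and the component-level contrast test.  The GLM
detections in the fluctuating network collapse as fluctuation grows while
the component-level test remains significant.  Writes
results/sensitivity_gap.tsv.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import MASTER_SEED, RESULTS

import fluctica as fl


def main() -> None:
    df = fl.sensitivity_gap_demo(multipliers=(1.0, 5.0, 12.0), seed=MASTER_SEED + 2)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "sensitivity_gap.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    counts = df["glm_voxels_in_network"].to_numpy()
    print(
        f"\nGLM detections in the fluctuating network fall {counts[0]} -> "
        f"{counts[-1]} across fluctuation levels while the component-level "
        f"contrast p stays below {df['analysis1_p'].max():.2g}"
    )


if __name__ == "__main__":
    main()
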