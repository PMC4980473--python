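"""Shared state for the numbered analysis scripts.

The default cohort and its group-ICA fit are computed once and cached under
``scratch/`` so the later scripts start from the same decomposition.
"""
from __future__ import annotations

import pickle
from pathlib import Path

import fluctica as fl

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
MASTER_SEED = 1
TRIM = 4


def get_cohort() -> fl.GroundTruth:
    return fl.build_cohort(master_seed=MASTER_SEED)


def get_fit(cohort: fl.GroundTruth | None = None):
    """Cohort + ICASSO group-ICA fit, cached across scripts."""
    SCRATCH.mkdir(exist_ok=True)
    cache = SCRATCH / f"gica_fit_seed{MASTER_SEED}.pkl"
    cohort = cohort or get_cohort()
    if cache.exists():
        with cache.open("rb") as fh:
            return cohort, pickle.load(fh)
    cset = fl.fit_group_ica(
        cohort.datasets(trim_volumes=TRIM),
        model_order=len(cohort.specs),
        mask=cohort.mask,
        n_runs=10,
        seed=MASTER_SEED + 1,
        dataset_index=cohort.dataset_index(),
    )
    with cache.open("wb") as fh:
        pickle.dump(cset, fh)
    return cohort, cset


def truth_by_subject(cohort: fl.GroundTruth):
    cfg = cohort.config
    return [
        [cohort.timecourses[s, r][TRIM:] for r in range(cfg.n_runs)]
        for s in range(cfg.n_subjects)
    ]
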