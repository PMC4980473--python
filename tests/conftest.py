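"""Shared fixtures: the default synthetic cohort and one group-ICA fit.

The heavy objects are session-scoped so the whole suite pays for cohort
generation and the ICASSO decomposition once.
"""
from __future__ import annotations

import numpy as np
import pytest

import fluctica as fl
from fluctica.design import CONDITIONS, IMAGERY, SUPPRESSION

COHORT_SEED = 1
GICA_SEED = 2


@pytest.fixture(scope="session")
def study_design() -> fl.BlockDesign:
    """The study's run layout: 24-s lead-in, four 96-s block pairs, TR 2."""
    return fl.build_block_design(24.0, 4, 2, 2.0, 24.0)


@pytest.fixture(scope="session")
def cohort() -> fl.GroundTruth:
    return fl.build_cohort(master_seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort_truth_by_subject(cohort):
    """Ground-truth component time courses, trimmed, grouped per subject."""
    cfg = cohort.config
    return [
        [cohort.timecourses[s, r][4:] for r in range(cfg.n_runs)]
        for s in range(cfg.n_subjects)
    ]


@pytest.fixture(scope="session")
def gica_fit(cohort):
    """Full ICASSO group-ICA fit of the default cohort."""
    return fl.fit_group_ica(
        cohort.datasets(trim_volumes=4),
        model_order=len(cohort.specs),
        mask=cohort.mask,
        n_runs=10,
        seed=GICA_SEED,
        dataset_index=cohort.dataset_index(),
    )


@pytest.fixture(scope="session")
def gica_assignment(cohort, gica_fit):
    """Hungarian matching of estimated components to ground truth maps."""
    assign, spatial_r = fl.match_components(cohort.true_maps, gica_fit.group_maps)
    return assign, spatial_r


def simulate_condition_indices(
    n_components: int,
    ratio: float,
    jitter_sd: float,
    seed: int,
    n_subjects: int = 20,
    n_trials: int = 8,
    n_samples: int = 20,
    sigma: float = 0.3,
) -> np.ndarray:
    """Trial-level null/effect harness for the fluctuation-index tests.

    Simulates ``n_components`` independent replicates of a cohort of
    subjects whose condition trials are a fixed unimodal template plus white
    residual noise; the suppression residual sd is ``ratio`` times the
    imagery one, with an optional log-normal between-subject spread.
    Indices are computed through the package's pooled-response /
    fluctuation-index path with the shared (component-scope) amplitude.
    Returns the (S, K, 2) index array, conditions ordered as CONDITIONS.
    """
    rng = np.random.default_rng(seed)
    base = np.sin(np.linspace(0, np.pi, n_samples))
    base = base / (base.max() - base.min())
    mult = (
        np.exp(rng.normal(0, jitter_sd, (n_subjects, n_components)))
        if jitter_sd > 0
        else np.ones((n_subjects, n_components))
    )
    per_subj = {c: [] for c in CONDITIONS}
    for s in range(n_subjects):
        per_subj[IMAGERY].append(
            base[None, :, None] + rng.normal(0, sigma, (n_trials, n_samples, n_components))
        )
        per_subj[SUPPRESSION].append(
            base[None, :, None]
            + rng.normal(0, 1.0, (n_trials, n_samples, n_components))
            * (sigma * ratio * mult[s])[None, None, :]
        )
    pooled = {
        c: fl.pooled_response(np.concatenate(per_subj[c]), "range")[0]
        for c in CONDITIONS
    }
    cycle = np.concatenate([pooled[c] for c in CONDITIONS])
    amp = cycle.max(axis=0) - cycle.min(axis=0)
    index = np.zeros((n_subjects, n_components, len(CONDITIONS)))
    for ci, cond in enumerate(CONDITIONS):
        for s in range(n_subjects):
            index[s, :, ci] = fl.fluctuation_index(per_subj[cond][s], pooled[cond], amp)
    return index


def simulate_coupled_pair_labels(
    weight: float,
    n_reps: int,
    seed: int,
    n_subjects: int = 20,
    n_runs: int = 2,
) -> list[str]:
    """Replicate the coupling pipeline on simulated two-component cohorts
    with a known latent coupling weight; returns the pair label per
    replicate."""
    from fluctica.cohort import ComponentSpec, simulate_timecourses

    design = fl.build_block_design()
    specs = (
        ComponentSpec(
            "hub", 1, {IMAGERY: 0.3, SUPPRESSION: 0.3}, {IMAGERY: 0.4, SUPPRESSION: 0.4}
        ),
        ComponentSpec(
            "spoke",
            2,
            {IMAGERY: 0.3, SUPPRESSION: 0.3},
            {IMAGERY: 0.4, SUPPRESSION: 0.4},
            coupling={"hub": weight} if weight else {},
        ),
    )
    labels = []
    for rep_ss in np.random.SeedSequence(seed).spawn(n_reps):
        by_subject = []
        for child in rep_ss.spawn(n_subjects):
            runs = []
            for rchild in child.spawn(n_runs):
                tc, _ = simulate_timecourses(design, specs, np.random.default_rng(rchild))
                runs.append(tc[4:])
            by_subject.append(runs)
        table = fl.couple_reference(by_subject, design, 0, trim_volumes=4)
        labels.append(table.labels[0])
    return labels
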