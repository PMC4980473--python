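"""Task-relatedness tests on back-projected component time courses.

Two group tests per component:

* *Subject-level regression* (``analysis1``): each subject/run time course is
  modelled as ``y = X beta + eps`` with eight HRF-convolved regressors (four
  condition epochs and four cue-event trains); the imagery-minus-suppression
  contrast on the epoch betas is carried to a one-sample t-test over
  subjects — a random-effects test that generalises to the population.
* *Pooled-cycle comparison* (``analysis2``): all imagery+suppression cycles
  are averaged over trials and subjects into one grand-average cycle, and
  the imagery-phase samples are compared with the suppression-phase samples
  by a two-sample t-test — a descriptive ranking of relative engagement.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import CONDITIONS, IMAGERY, SUPPRESSION, BlockDesign, canonical_hrf

EPOCH_ORDER = [(IMAGERY, 0), (IMAGERY, 1), (SUPPRESSION, 0), (SUPPRESSION, 1)]


@dataclass
class DesignMatrix:
    """T x (2 * n_epochs) matrix: epoch regressors then cue-event regressors."""

    matrix: np.ndarray
    names: list[str]
    epoch_names: list[str]
    design: BlockDesign
    trim_volumes: int

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)

    def contrast(self) -> np.ndarray:
        """Imagery-minus-suppression contrast over epoch columns (mean of the
        same-condition epoch betas on each side)."""
        c = np.zeros(len(self.names))
        img = [i for i, n in enumerate(self.names) if n.startswith(f"{IMAGERY}_")]
        sup = [i for i, n in enumerate(self.names) if n.startswith(f"{SUPPRESSION}_")]
        c[img] = 1.0 / len(img)
        c[sup] = -1.0 / len(sup)
        return c


def build_design_matrix(
    design: BlockDesign, hrf: np.ndarray | None = None, trim_volumes: int = 0
) -> DesignMatrix:
    """HRF-convolved epoch boxcars plus zero-duration cue-event regressors.

    One epoch regressor per (condition, sub-block position) present in the
    design and one cue regressor per epoch type (impulses at that epoch
    type's onsets), all convolved with the canonical HRF; the first
    ``trim_volumes`` rows are dropped to match the discarded initial
    volumes.
    """
    if trim_volumes < 0:
        raise ValueError("trim_volumes must be >= 0")
    if hrf is None:
        hrf = canonical_hrf(design.tr)
    present = design.epoch_keys()
    for cond in CONDITIONS:
        if not any(c == cond for c, _ in present):
            raise ValueError(f"epoch type {cond!r} absent from design")
    boxcars = design.epoch_boxcars()
    impulses = design.epoch_cue_impulses()
    T = design.n_volumes
    cols, names = [], []
    for cond, j in present:
        cols.append(np.convolve(boxcars[(cond, j)], hrf)[:T])
        names.append(f"{cond}_{j + 1}")
    epoch_names = list(names)
    for cond, j in present:
        cols.append(np.convolve(impulses[(cond, j)], hrf)[:T])
        names.append(f"cue_{cond}_{j + 1}")
    X = np.column_stack(cols)[trim_volumes:]
    zero = [names[i] for i in range(X.shape[1]) if not np.any(X[:, i])]
    if zero:
        raise ValueError(f"all-zero design columns: {zero}")
    return DesignMatrix(X, names, epoch_names, design, trim_volumes)


@dataclass
class Analysis1Result:
    dbeta: np.ndarray  # (n_subjects, K) imagery-minus-suppression contrast
    t: np.ndarray  # (K,)
    p: np.ndarray  # (K,)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(self.t.size),
                "mean_dbeta": self.dbeta.mean(axis=0),
                "t": self.t,
                "p": self.p,
            }
        )


def _ttest_1samp_cols(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sample two-sided t per column, with the zero-variance, zero-mean
    degenerate case mapped to (t=0, p=1)."""
    n = X.shape[0]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    t = np.zeros(X.shape[1])
    p = np.ones(X.shape[1])
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2 * stats.t.sf(np.abs(t[ok]), df=n - 1)
    bad = (~ok) & (mean != 0)
    t[bad] = np.inf * np.sign(mean[bad])
    p[bad] = 0.0
    return t, p


def analysis1(
    subject_timecourses: Sequence[Sequence[np.ndarray]], dm: DesignMatrix
) -> Analysis1Result:
    """Subject-level OLS followed by a one-sample t-test on the contrast.

    ``subject_timecourses[s][r]`` is the (T, K) back-projected time-course
    matrix of subject ``s``, run ``r``.  Betas are estimated per run (with an
    internal intercept), averaged across runs within subject, contrasted,
    and tested across subjects.
    """
    n_subjects = len(subject_timecourses)
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    X = np.column_stack([np.ones(dm.matrix.shape[0]), dm.matrix])
    cond = np.linalg.cond(X)
    if cond > 1e10:
        raise ValueError(f"singular design matrix (condition number {cond:.3g})")
    pinv = np.linalg.pinv(X)
    c = np.concatenate([[0.0], dm.contrast()])
    w = c @ pinv  # (T,)
    dbeta = np.array(
        [np.mean([w @ tc for tc in runs], axis=0) for runs in subject_timecourses]
    )
    t, p = _ttest_1samp_cols(dbeta)
    return Analysis1Result(dbeta=dbeta, t=t, p=p)


@dataclass
class Analysis2Result:
    t: np.ndarray  # (K,)
    p: np.ndarray  # (K,)
    pooled_cycle: np.ndarray  # (L, K)
    n_imagery: int
    n_suppression: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"component": np.arange(self.t.size), "t": self.t, "p": self.p}
        )


def analysis2(
    subject_timecourses: Sequence[Sequence[np.ndarray]],
    design: BlockDesign,
    trim_volumes: int = 0,
    exclude_volumes: int = 0,
) -> Analysis2Result:
    """Fold every imagery+suppression cycle onto one grand-average cycle and
    compare the two condition phases with a two-sample t-test.

    ``exclude_volumes`` drops that many volumes at the start of each phase
    (cue-transition overlap) before the test; the default keeps every phase
    sample.
    """
    img = design.phase_volume_indices(IMAGERY, trim_volumes=trim_volumes)
    sup = design.phase_volume_indices(SUPPRESSION, trim_volumes=trim_volumes)
    if len(img) != len(sup) or len(img) < 1:
        raise ValueError("design must pair imagery and suppression phases")
    L_img = {idx.size for _, idx in img}
    L_sup = {idx.size for _, idx in sup}
    if len(L_img) != 1 or len(L_sup) != 1:
        raise ValueError("unequal cycle lengths across phases")
    L_img, L_sup = L_img.pop(), L_sup.pop()
    if len(img) * len(subject_timecourses) * max(len(r) for r in subject_timecourses) < 2:
        raise ValueError("need at least 2 full cycles")

    segments = []
    for runs in subject_timecourses:
        for tc in runs:
            for (_, i_idx), (_, s_idx) in zip(img, sup):
                segments.append(np.vstack([tc[i_idx], tc[s_idx]]))
    pooled = np.mean(segments, axis=0)  # (L_img + L_sup, K)
    a = pooled[exclude_volumes:L_img]
    b = pooled[L_img + exclude_volumes :]
    t, p = stats.ttest_ind(a, b, axis=0)
    return Analysis2Result(
        t=np.atleast_1d(t),
        p=np.atleast_1d(p),
        pooled_cycle=pooled,
        n_imagery=a.shape[0],
        n_suppression=b.shape[0],
    )
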