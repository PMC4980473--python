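"""Block-wise residual correlation between component time courses.

Both series are band-pass filtered at the session level, each sub-block
segment (with its first volumes discarded to skip the cue response) is
linearly detrended, and a Pearson correlation is computed per block.  The
correlations are Fisher-Z transformed, pooled over trials within subject
per task condition, and tested with a one-sample t across subjects per
condition plus a paired t for condition change.  A pair is labelled
``positive`` (``negative``) only when both per-condition tests are
significant with concordant positive (negative) mean Z, and ``equivocal``
otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .design import CONDITIONS, IMAGERY, SUPPRESSION, BlockDesign
from .fluct import DEFAULT_BAND, bandpass

LABEL_POSITIVE = "positive"
LABEL_NEGATIVE = "negative"
LABEL_EQUIVOCAL = "equivocal"

_Z_CLIP = np.arctanh(1 - 1e-6)


def block_residual_r(
    tc_a: np.ndarray,
    tc_b: np.ndarray,
    design: BlockDesign,
    trim_volumes: int = 0,
    segment_trim: int = 4,
    band: tuple[float, float] = DEFAULT_BAND,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-block Pearson correlation between two session time courses.

    Returns ``(r, conditions)`` over sub-blocks; blocks with a zero-variance
    segment yield ``nan`` (recorded as missing).
    """
    a = np.asarray(tc_a, dtype=float)
    b = np.asarray(tc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("time courses must have the same length")
    a = bandpass(a, design.tr, *band)
    b = bandpass(b, design.tr, *band)
    blocks = design.block_volume_indices(trim_volumes=trim_volumes, drop_initial=segment_trim)
    rs, conds = [], []
    for blk, idx in blocks:
        if idx.size < 3:  # need >= 3 points after detrending
            continue
        sa = signal.detrend(a[idx])
        sb = signal.detrend(b[idx])
        if sa.std() == 0 or sb.std() == 0:
            rs.append(np.nan)
        else:
            rs.append(float(np.corrcoef(sa, sb)[0, 1]))
        conds.append(blk.condition)
    return np.array(rs), np.array(conds)


@dataclass
class PairStats:
    """Pooled Fisher-Z statistics for one component pair."""

    mean_z: dict  # condition -> grand mean Z across subjects
    t: dict  # condition -> one-sample t
    p: dict  # condition -> p-value
    paired_t: float
    paired_p: float
    n_subjects: int
    n_clipped: int = 0

    def label(self, alpha: float = 0.05) -> str:
        sig = all(self.p[c] < alpha for c in CONDITIONS)
        if sig and all(self.mean_z[c] > 0 for c in CONDITIONS):
            return LABEL_POSITIVE
        if sig and all(self.mean_z[c] < 0 for c in CONDITIONS):
            return LABEL_NEGATIVE
        return LABEL_EQUIVOCAL


def _t_1samp(x: np.ndarray) -> tuple[float, float]:
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        return 0.0, 1.0
    sd = x.std(ddof=1)
    if sd == 0:
        return (0.0, 1.0) if x.mean() == 0 else (float(np.inf * np.sign(x.mean())), 0.0)
    t = x.mean() / (sd / np.sqrt(n))
    return float(t), float(2 * stats.t.sf(abs(t), df=n - 1))


def pool_and_test(
    block_r: np.ndarray, conditions: np.ndarray
) -> PairStats:
    """Fisher-Z pooling and group tests for one pair.

    ``block_r`` is (n_subjects, n_blocks) of per-block correlations and
    ``conditions`` the per-block condition labels.  Z values are averaged
    (unweighted) over a subject's valid blocks per condition; |r| = 1 is
    clipped just inside the open interval with a warning count.
    """
    R = np.asarray(block_r, dtype=float)
    if R.ndim != 2:
        raise ValueError("block_r must be (n_subjects, n_blocks)")
    S = R.shape[0]
    if S < 3:
        raise ValueError("need at least 3 subjects")
    n_clipped = int(np.sum(np.abs(R) >= 1))
    Z = np.arctanh(np.clip(R, -(1 - 1e-6), 1 - 1e-6))
    mean_z, t, p = {}, {}, {}
    per_cond = {}
    for cond in CONDITIONS:
        sel = conditions == cond
        if not np.any(sel):
            raise ValueError(f"no blocks for condition {cond!r}")
        with np.errstate(invalid="ignore"):
            subj_z = np.nanmean(Z[:, sel], axis=1)
        per_cond[cond] = subj_z
        mean_z[cond] = float(np.nanmean(subj_z))
        t[cond], p[cond] = _t_1samp(subj_z)
    paired = per_cond[IMAGERY] - per_cond[SUPPRESSION]
    paired_t, paired_p = _t_1samp(paired[np.isfinite(paired)])
    return PairStats(
        mean_z=mean_z,
        t=t,
        p=p,
        paired_t=paired_t,
        paired_p=paired_p,
        n_subjects=S,
        n_clipped=n_clipped,
    )


@dataclass
class CouplingTable:
    """Reference-vs-all coupling summary."""

    reference: int
    partners: list[int]
    stats: list[PairStats]
    alpha: float = 0.05
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = [s.label(self.alpha) for s in self.stats]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, st, lab in zip(self.partners, self.stats, self.labels):
            for cond in CONDITIONS:
                rows.append(
                    {
                        "reference": self.reference,
                        "component": k,
                        "condition": cond,
                        "mean_z": st.mean_z[cond],
                        "t": st.t[cond],
                        "p": st.p[cond],
                        "paired_p": st.paired_p,
                        "label": lab,
                    }
                )
        return pd.DataFrame(rows)


def couple_reference(
    subject_timecourses: Sequence[Sequence[np.ndarray]],
    design: BlockDesign,
    reference: int,
    partners: Sequence[int] | None = None,
    trim_volumes: int = 0,
    segment_trim: int = 4,
    band: tuple[float, float] = DEFAULT_BAND,
    alpha: float = 0.05,
) -> CouplingTable:
    """Block-wise residual coupling of every partner component with the
    reference component, pooled over runs within subject."""
    K = subject_timecourses[0][0].shape[1]
    if partners is None:
        partners = [k for k in range(K) if k != reference]
    stats_out = []
    for k in partners:
        rows, conds = [], None
        for runs in subject_timecourses:
            r_all, c_all = [], []
            for tc in runs:
                r, c = block_residual_r(
                    tc[:, reference], tc[:, k], design, trim_volumes, segment_trim, band
                )
                r_all.append(r)
                c_all.append(c)
            rows.append(np.concatenate(r_all))
            conds = np.concatenate(c_all)
        stats_out.append(pool_and_test(np.vstack(rows), conds))
    return CouplingTable(reference=reference, partners=list(partners), stats=stats_out, alpha=alpha)
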