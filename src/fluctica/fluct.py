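"""Trial-variability "fluctuation index" and its group comparisons.

An fMRI analogue of the Fano factor: after band-pass filtering
(0.005-0.1 Hz), condition segments are grand-averaged over trials and
subjects into a pooled response; the pooled response is subtracted from
each raw trial, the standard deviation of the residuals over time is taken
per subject, and that sd is divided by the grand-averaged signal amplitude
(peak-to-trough range of the pooled response by default).  The index is
therefore scale-free: it measures random deviation from the typical
response in units of the typical response size.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .design import CONDITIONS, IMAGERY, SUPPRESSION, BlockDesign

DEFAULT_BAND = (0.005, 0.1)


def bandpass(
    timecourse: np.ndarray,
    tr: float,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = 4,
    padlen: int = 150,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass; the mean is removed and length is
    preserved.

    The series is reflection-padded by up to ``padlen`` samples before
    filtering: the low corner sits far below the run's fundamental, so the
    default short padding would leave position-dependent edge transients
    that alias into the per-block residuals.
    """
    x = np.asarray(timecourse, dtype=float)
    fs = 1.0 / tr
    if not (0 < low < high <= fs / 2 + 1e-12):
        raise ValueError(f"band ({low}, {high}) must satisfy 0 < low < high <= Nyquist")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    warmup = 3 * (2 * sos.shape[0] + 1)
    if x.shape[0] <= warmup:
        raise ValueError(
            f"series of length {x.shape[0]} is shorter than the filter warm-up ({warmup})"
        )
    y = signal.sosfiltfilt(sos, x, axis=0, padlen=min(x.shape[0] - 1, padlen))
    return y - y.mean(axis=0)


def pooled_response(
    trials: np.ndarray, amplitude_method: str = "range"
) -> tuple[np.ndarray, np.ndarray]:
    """Grand-average block response over trials (axis 0) and its amplitude.

    ``trials`` is (n_trials, L) or (n_trials, L, K).  The amplitude
    normaliser is the pooled response's peak-to-trough range
    (``amplitude_method='range'``) or its sd (``'sd'``).
    """
    trials = np.asarray(trials, dtype=float)
    if trials.shape[0] == 0:
        raise ValueError("zero trials")
    pooled = trials.mean(axis=0)
    if amplitude_method == "range":
        amplitude = pooled.max(axis=0) - pooled.min(axis=0)
    elif amplitude_method == "sd":
        amplitude = pooled.std(axis=0)
    else:
        raise ValueError(f"unknown amplitude_method={amplitude_method!r}")
    return pooled, np.asarray(amplitude, dtype=float)


def fluctuation_index(
    trials: np.ndarray, pooled: np.ndarray, amplitude: np.ndarray | float
) -> np.ndarray | float:
    """Residual sd over all of a subject's trial time points, divided by the
    grand-averaged amplitude.

    ``trials`` is (n_trials, L) or (n_trials, L, K); the pooled response is
    subtracted positionally from every trial.  A zero amplitude yields an
    ``inf`` sentinel with a warning.
    """
    trials = np.asarray(trials, dtype=float)
    resid = trials - pooled
    sd = resid.std(axis=(0, 1))
    amplitude = np.asarray(amplitude, dtype=float)
    if np.any(amplitude <= 0):
        warnings.warn("non-positive amplitude; index set to inf", stacklevel=2)
    with np.errstate(divide="ignore"):
        out = np.where(amplitude > 0, sd / np.where(amplitude > 0, amplitude, 1.0), np.inf)
    return float(out) if out.ndim == 0 else out


def condition_trials(
    timecourse: np.ndarray,
    design: BlockDesign,
    condition: str,
    trim_volumes: int = 0,
    segment_trim: int = 4,
) -> np.ndarray:
    """Stack one run's condition-phase segments: (n_trials, L[, K]).

    ``segment_trim`` drops the leading volumes of each phase (cue/transition
    overlap).
    """
    segs = [
        timecourse[idx]
        for _, idx in design.phase_volume_indices(
            condition, trim_volumes=trim_volumes, drop_initial=segment_trim
        )
    ]
    if not segs:
        raise ValueError(f"no {condition!r} phases in design")
    if len({s.shape[0] for s in segs}) != 1:
        raise ValueError("condition phases have unequal volume counts")
    return np.stack(segs)


@dataclass
class FluctuationTable:
    """Per (subject, component, condition) fluctuation indices."""

    index: np.ndarray  # (S, K, 2) ordered as CONDITIONS
    conditions: tuple[str, str] = CONDITIONS
    amplitude: np.ndarray | None = None  # (K, 2)

    @property
    def n_subjects(self) -> int:
        return self.index.shape[0]

    def task_ratio(self) -> np.ndarray:
        """(S, K) suppression-over-imagery index ratio."""
        i_img = self.conditions.index(IMAGERY)
        i_sup = self.conditions.index(SUPPRESSION)
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.index[:, :, i_sup] / self.index[:, :, i_img]

    def to_frame(self) -> pd.DataFrame:
        S, K, _ = self.index.shape
        rows = []
        for s in range(S):
            for k in range(K):
                for ci, cond in enumerate(self.conditions):
                    rows.append(
                        {
                            "subject": s,
                            "component": k,
                            "condition": cond,
                            "index": self.index[s, k, ci],
                        }
                    )
        return pd.DataFrame(rows)


def fluctuation_table(
    subject_timecourses: Sequence[Sequence[np.ndarray]],
    design: BlockDesign,
    trim_volumes: int = 0,
    segment_trim: int = 4,
    band: tuple[float, float] = DEFAULT_BAND,
    amplitude_method: str = "range",
    amplitude_scope: str = "component",
) -> FluctuationTable:
    """Compute the full index table for a cohort of back-projected
    time courses (``subject_timecourses[s][r]`` of shape (T, K)).

    Filtering is applied per run at the session level; trials are pooled
    over runs within subject and over subjects for the grand average.  The
    pooled response is formed (and subtracted) per condition, but the
    amplitude normaliser spans the component's full task response
    (``amplitude_scope='component'``, the default) so the
    suppression/imagery index ratio isolates fluctuation change; with
    ``amplitude_scope='condition'`` each condition is normalised by its own
    pooled-response amplitude.
    """
    tr = design.tr
    S = len(subject_timecourses)
    per_subject: dict[str, list[np.ndarray]] = {c: [] for c in CONDITIONS}
    for runs in subject_timecourses:
        for cond in CONDITIONS:
            trials = [
                condition_trials(
                    bandpass(tc, tr, *band), design, cond, trim_volumes, segment_trim
                )
                for tc in runs
            ]
            per_subject[cond].append(np.concatenate(trials, axis=0))
    K = per_subject[IMAGERY][0].shape[-1] if per_subject[IMAGERY][0].ndim == 3 else 1
    index = np.zeros((S, K, len(CONDITIONS)))
    amplitude = np.zeros((K, len(CONDITIONS)))
    pooled_by_cond = {}
    for cond in CONDITIONS:
        all_trials = np.concatenate(per_subject[cond], axis=0)
        pooled_by_cond[cond], _ = pooled_response(all_trials, amplitude_method)
    if amplitude_scope == "component":
        cycle = np.concatenate([pooled_by_cond[c] for c in CONDITIONS], axis=0)
        if amplitude_method == "range":
            shared_amp = cycle.max(axis=0) - cycle.min(axis=0)
        else:
            shared_amp = cycle.std(axis=0)
    elif amplitude_scope != "condition":
        raise ValueError(f"unknown amplitude_scope={amplitude_scope!r}")
    for ci, cond in enumerate(CONDITIONS):
        pooled = pooled_by_cond[cond]
        if amplitude_scope == "condition":
            if amplitude_method == "range":
                amp = pooled.max(axis=0) - pooled.min(axis=0)
            else:
                amp = pooled.std(axis=0)
        else:
            amp = shared_amp
        amplitude[:, ci] = amp
        for s in range(S):
            index[s, :, ci] = np.atleast_1d(
                fluctuation_index(per_subject[cond][s], pooled, amp)
            )
    return FluctuationTable(index=index, amplitude=amplitude)


@dataclass
class ConditionComparison:
    t: np.ndarray  # (K,)
    p: np.ndarray  # (K,)
    geometric_ratio: np.ndarray  # (K,) geometric-mean suppression/imagery ratio
    n_excluded: int = 0


def compare_conditions(table: FluctuationTable | np.ndarray) -> ConditionComparison:
    """Paired two-sided t-test across subjects on log-converted indices.

    Subjects with a zero (or non-finite) index in either condition are
    excluded pairwise, counted in ``n_excluded``.
    """
    index = table.index if isinstance(table, FluctuationTable) else np.asarray(table)
    S, K, _ = index.shape
    i_img = CONDITIONS.index(IMAGERY)
    i_sup = CONDITIONS.index(SUPPRESSION)
    t = np.zeros(K)
    p = np.ones(K)
    ratio = np.full(K, np.nan)
    excluded = 0
    for k in range(K):
        img = index[:, k, i_img]
        sup = index[:, k, i_sup]
        ok = np.isfinite(img) & np.isfinite(sup) & (img > 0) & (sup > 0)
        n_bad = int(S - ok.sum())
        if n_bad:
            excluded += n_bad
            warnings.warn(
                f"component {k}: excluded {n_bad} subjects with zero index",
                stacklevel=2,
            )
        d = np.log(sup[ok]) - np.log(img[ok])
        if d.size < 2:
            continue
        sd = d.std(ddof=1)
        if sd == 0:
            t[k], p[k] = (0.0, 1.0) if d.mean() == 0 else (np.inf * np.sign(d.mean()), 0.0)
        else:
            t[k] = d.mean() / (sd / np.sqrt(d.size))
            p[k] = 2 * stats.t.sf(abs(t[k]), df=d.size - 1)
        ratio[k] = np.exp(d.mean())
    return ConditionComparison(t=t, p=p, geometric_ratio=ratio, n_excluded=excluded)


@dataclass
class ReportAssociation:
    t: np.ndarray  # (K,)
    p: np.ndarray  # (K,)
    n_yes: int
    n_no: int


def report_association(
    task_ratios: np.ndarray, report_flags: np.ndarray
) -> ReportAssociation:
    """Two-sample two-sided t-test on log task-change ratios between the
    self-report groups.

    ``task_ratios`` is (S, K); ``report_flags`` is (S,) of 0/1.
    """
    flags = np.asarray(report_flags).astype(int)
    yes = flags == 1
    no = flags == 0
    if yes.sum() == 0 or no.sum() == 0:
        raise ValueError("both report groups must be non-empty")
    ratios = np.asarray(task_ratios, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logr = np.log(ratios)
    t, p = stats.ttest_ind(logr[yes], logr[no], axis=0)
    return ReportAssociation(
        t=np.atleast_1d(t), p=np.atleast_1d(p), n_yes=int(yes.sum()), n_no=int(no.sum())
    )
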