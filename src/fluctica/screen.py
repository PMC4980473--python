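"""Operational artifact screening of components.

Two screens are applied: a spectral one — the low-frequency power ratio
(LFPR), the summed periodogram power in a low band (default 0.003-0.10 Hz)
over that in a high band (0.15-0.25 Hz), averaged across subjects/runs —
and a spatial one, the fraction of suprathreshold |z| voxels lying outside
the brain mask.  Components failing the spatial screen are labelled
``artifact_spatial``; otherwise a mean LFPR below 3.0 labels
``artifact_spectral``, between 3.0 and 3.5 ``suspicious`` (retained
downstream), and above 3.5 ``valid``.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gica import ComponentSet, zscore_map

LABEL_SPECTRAL = "artifact_spectral"
LABEL_SPATIAL = "artifact_spatial"
LABEL_SUSPICIOUS = "suspicious"
LABEL_VALID = "valid"

DEFAULT_LOW_BAND = (0.003, 0.10)
DEFAULT_HIGH_BAND = (0.15, 0.25)


def lfpr(
    timecourse: np.ndarray,
    tr: float,
    low_band: tuple[float, float] = DEFAULT_LOW_BAND,
    high_band: tuple[float, float] = DEFAULT_HIGH_BAND,
) -> float:
    """Low-frequency power ratio of one component time course.

    Periodogram (squared modulus of the DFT of the demeaned series, no
    taper); band membership is inclusive on both edges.  A zero denominator
    returns ``inf``.
    """
    x = np.asarray(timecourse, dtype=float)
    if x.size < 64:
        raise ValueError("timecourse must have at least 64 samples")
    if tr <= 0:
        raise ValueError("tr must be positive")
    nyq = 0.5 / tr
    for name, band in (("low_band", low_band), ("high_band", high_band)):
        lo, hi = band
        if not (0 < lo < hi <= nyq + 1e-12):
            raise ValueError(f"{name}={band} must lie within (0, Nyquist]")
    if high_band[0] < low_band[1]:
        raise ValueError("bands overlap or are inverted")
    x = x - x.mean()
    power = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=tr)
    lo = power[(freqs >= low_band[0] - 1e-12) & (freqs <= low_band[1] + 1e-12)].sum()
    hi = power[(freqs >= high_band[0] - 1e-12) & (freqs <= high_band[1] + 1e-12)].sum()
    # band sums at numerical-leakage level count as empty
    eps = power.sum() * 1e-12
    if hi <= eps:
        return float("inf")
    if lo <= eps:
        return 0.0
    return float(lo / hi)


@dataclass
class ScreenReport:
    """Per-component screening outcome."""

    lfpr_mean: np.ndarray  # (K,)
    lfpr_per_subject: np.ndarray  # (n_datasets, K)
    nonbrain_fraction: np.ndarray  # (K,), nan if the spatial screen was skipped
    labels: list[str]
    thresholds: dict = field(default_factory=dict)
    spatial_screened: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(len(self.labels)),
                "lfpr_mean": self.lfpr_mean,
                "nonbrain_fraction": self.nonbrain_fraction,
                "label": self.labels,
            }
        )

    def retained(self) -> np.ndarray:
        """Indices kept for downstream analysis (valid + suspicious)."""
        return np.flatnonzero(
            [lab in (LABEL_VALID, LABEL_SUSPICIOUS) for lab in self.labels]
        )

    def save(self, out_dir: str | Path, stem: str = "screen") -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out_dir / f"{stem}.tsv", sep="\t", index=False)
        payload = {
            "lfpr_mean": [float(v) for v in self.lfpr_mean],
            "lfpr_per_subject": [[float(v) for v in row] for row in self.lfpr_per_subject],
            "nonbrain_fraction": [
                None if np.isnan(v) else float(v) for v in self.nonbrain_fraction
            ],
            "labels": self.labels,
            "thresholds": self.thresholds,
            "spatial_screened": self.spatial_screened,
        }
        (out_dir / f"{stem}.json").write_text(json.dumps(payload, indent=1))


def screen_components(
    cset: ComponentSet,
    mask: np.ndarray | None,
    tr: float,
    lfpr_artifact: float = 3.0,
    lfpr_suspicious: float = 3.5,
    z_threshold: float = 2.0,
    spatial_threshold: float = 0.5,
    low_band: tuple[float, float] = DEFAULT_LOW_BAND,
    high_band: tuple[float, float] = DEFAULT_HIGH_BAND,
) -> ScreenReport:
    """Apply the spectral and spatial screens to a fitted component set."""
    K = cset.n_components
    vals = np.array(
        [
            [lfpr(tc[:, k], tr, low_band, high_band) for k in range(K)]
            for tc in cset.subject_timecourses
        ]
    )
    with np.errstate(invalid="ignore"):
        lfpr_mean = vals.mean(axis=0)

    nonbrain = np.full(K, np.nan)
    spatial_ok = mask is not None
    if not spatial_ok:
        warnings.warn("no mask provided; spatial screen skipped", stacklevel=2)
    else:
        mask = np.asarray(mask).astype(bool).ravel()
        for k in range(K):
            _, supra = zscore_map(cset.group_maps[:, k], mask, z_threshold)
            total = int(supra.sum())
            nonbrain[k] = float((supra & ~mask).sum() / total) if total else 0.0

    labels = []
    for k in range(K):
        if spatial_ok and nonbrain[k] > spatial_threshold:
            labels.append(LABEL_SPATIAL)
        elif lfpr_mean[k] < lfpr_artifact:
            labels.append(LABEL_SPECTRAL)
        elif lfpr_mean[k] < lfpr_suspicious:
            labels.append(LABEL_SUSPICIOUS)
        else:
            labels.append(LABEL_VALID)

    return ScreenReport(
        lfpr_mean=lfpr_mean,
        lfpr_per_subject=vals,
        nonbrain_fraction=nonbrain,
        labels=labels,
        thresholds={
            "lfpr_artifact": lfpr_artifact,
            "lfpr_suspicious": lfpr_suspicious,
            "z_threshold": z_threshold,
            "spatial_threshold": spatial_threshold,
            "low_band": list(low_band),
            "high_band": list(high_band),
        },
        spatial_screened=spatial_ok,
    )
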