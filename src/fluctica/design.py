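"""Block-design timing and the canonical haemodynamic response.

The experimental unit is one fMRI run: a lead-in period followed by
alternating imagery/suppression *phases*, each phase a train of consecutive
fixed-length sub-blocks.  Every sub-block onset is marked by a brief visual
cue.  All onsets are constrained to the volume grid (multiples of the TR),
block intervals are half-open ``[onset, onset + duration)``, and time is in
seconds from the start of the run.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

IMAGERY = "imagery"
SUPPRESSION = "suppression"
CONDITIONS = (IMAGERY, SUPPRESSION)
CUE = "cue"


def _require_multiple(name: str, value: float, tr: float) -> None:
    if abs(value / tr - round(value / tr)) > 1e-9:
        raise ValueError(f"{name}={value} is not a multiple of tr={tr}")


@dataclass(frozen=True)
class Block:
    """One sub-block: a condition held over the interval [onset, onset+duration)."""

    condition: str
    onset: float
    duration: float
    sub_index: int  # 0-based position within its condition phase


@dataclass(frozen=True)
class Phase:
    """A maximal run of consecutive same-condition sub-blocks."""

    condition: str
    onset: float
    duration: float


@dataclass(frozen=True)
class BlockDesign:
    blocks: tuple[Block, ...]
    cues: tuple[tuple[float, float], ...]  # (onset_s, duration_s)
    run_length_s: float
    tr: float
    lead_in_s: float = 0.0

    def __post_init__(self) -> None:
        prev_end = None
        for b in self.blocks:
            _require_multiple("block onset", b.onset, self.tr)
            if prev_end is not None and b.onset < prev_end - 1e-9:
                raise ValueError("blocks overlap or are not ordered by onset")
            prev_end = b.onset + b.duration
        if prev_end is not None and prev_end > self.run_length_s + 1e-9:
            raise ValueError("blocks extend past run_length_s")
        for onset, _ in self.cues:
            _require_multiple("cue onset", onset, self.tr)

    # ------------------------------------------------------------------ grid
    @property
    def n_volumes(self) -> int:
        return int(round(self.run_length_s / self.tr))

    def epoch_keys(self) -> list[tuple[str, int]]:
        """Distinct (condition, sub_index) epoch types, in first-onset order."""
        seen: list[tuple[str, int]] = []
        for b in self.blocks:
            key = (b.condition, b.sub_index)
            if key not in seen:
                seen.append(key)
        return seen

    def epoch_boxcars(self) -> dict[tuple[str, int], np.ndarray]:
        """Unit boxcar per epoch type, sampled on the full volume grid."""
        T = self.n_volumes
        out = {key: np.zeros(T) for key in self.epoch_keys()}
        for b in self.blocks:
            i0 = int(round(b.onset / self.tr))
            i1 = int(round((b.onset + b.duration) / self.tr))
            out[(b.condition, b.sub_index)][i0:i1] = 1.0
        return out

    def epoch_cue_impulses(self) -> dict[tuple[str, int], np.ndarray]:
        """Unit impulse at every sub-block onset, grouped by the epoch type cued."""
        T = self.n_volumes
        out = {key: np.zeros(T) for key in self.epoch_keys()}
        for b in self.blocks:
            out[(b.condition, b.sub_index)][int(round(b.onset / self.tr))] = 1.0
        return out

    def condition_boxcar(self, condition: str) -> np.ndarray:
        cars = self.epoch_boxcars()
        T = self.n_volumes
        total = np.zeros(T)
        for (cond, _), car in cars.items():
            if cond == condition:
                total += car
        return total

    def volume_conditions(self) -> np.ndarray:
        """Condition label per volume ('' outside any block)."""
        labels = np.full(self.n_volumes, "", dtype=object)
        for b in self.blocks:
            i0 = int(round(b.onset / self.tr))
            i1 = int(round((b.onset + b.duration) / self.tr))
            labels[i0:i1] = b.condition
        return labels

    # -------------------------------------------------------------- segments
    def block_volume_indices(
        self, trim_volumes: int = 0, drop_initial: int = 0
    ) -> list[tuple[Block, np.ndarray]]:
        """Volume indices per sub-block into a series whose first
        ``trim_volumes`` volumes were discarded; additionally drops the first
        ``drop_initial`` volumes of each block (cue/transition trim)."""
        out = []
        for b in self.blocks:
            i0 = int(round(b.onset / self.tr)) - trim_volumes + drop_initial
            i1 = int(round((b.onset + b.duration) / self.tr)) - trim_volumes
            idx = np.arange(max(i0, 0), max(i1, 0))
            if idx.size:
                out.append((b, idx))
        return out

    def phases(self) -> list[Phase]:
        out: list[list] = []
        for b in self.blocks:
            if out and out[-1][0] == b.condition and abs(out[-1][1] + out[-1][2] - b.onset) < 1e-9:
                out[-1][2] += b.duration
            else:
                out.append([b.condition, b.onset, b.duration])
        return [Phase(*p) for p in out]

    def phase_volume_indices(
        self,
        condition: str | None = None,
        trim_volumes: int = 0,
        drop_initial: int = 0,
    ) -> list[tuple[Phase, np.ndarray]]:
        """As :meth:`block_volume_indices` but over merged condition phases."""
        out = []
        for ph in self.phases():
            if condition is not None and ph.condition != condition:
                continue
            i0 = int(round(ph.onset / self.tr)) - trim_volumes + drop_initial
            i1 = int(round((ph.onset + ph.duration) / self.tr)) - trim_volumes
            idx = np.arange(max(i0, 0), max(i1, 0))
            if idx.size:
                out.append((ph, idx))
        return out


def build_block_design(
    block_len_s: float = 24.0,
    n_pairs: int = 4,
    sub_blocks_per_condition: int = 2,
    tr: float = 2.0,
    lead_in_s: float = 24.0,
    cue_duration_s: float = 2.0,
) -> BlockDesign:
    """Alternating imagery/suppression design with cued sub-blocks.

    Each of ``n_pairs`` block pairs holds one imagery phase followed by one
    suppression phase, each phase made of ``sub_blocks_per_condition``
    consecutive sub-blocks of ``block_len_s`` seconds, preceded overall by a
    ``lead_in_s`` rest.  A cue is placed at every sub-block onset.
    """
    _require_multiple("block_len_s", block_len_s, tr)
    _require_multiple("lead_in_s", lead_in_s, tr)
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if sub_blocks_per_condition < 1:
        raise ValueError("sub_blocks_per_condition must be >= 1")
    blocks: list[Block] = []
    cues: list[tuple[float, float]] = []
    t = float(lead_in_s)
    for _ in range(n_pairs):
        for condition in CONDITIONS:
            for j in range(sub_blocks_per_condition):
                cues.append((t, cue_duration_s))
                blocks.append(Block(condition, t, float(block_len_s), j))
                t += block_len_s
    run_length = lead_in_s + n_pairs * 2 * sub_blocks_per_condition * block_len_s
    return BlockDesign(tuple(blocks), tuple(cues), float(run_length), float(tr), float(lead_in_s))


def canonical_hrf(
    tr: float,
    duration_s: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
    normalize: str = "sum",
) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at the TR.

    Difference of two gamma densities (unit scale): a main lobe peaking
    around ``peak_delay`` seconds minus an undershoot around
    ``undershoot_delay`` seconds scaled by ``undershoot_ratio``.  With
    ``normalize='sum'`` the kernel sums to one, so convolving a sustained
    boxcar of amplitude *a* plateaus at *a*.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    n = int(round(duration_s / tr))
    t = np.arange(n) * tr
    h = stats.gamma.pdf(t, peak_delay) - undershoot_ratio * stats.gamma.pdf(t, undershoot_delay)
    if normalize == "sum":
        h = h / h.sum()
    elif normalize == "peak":
        h = h / h.max()
    else:
        raise ValueError(f"unknown normalize={normalize!r}")
    return h
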