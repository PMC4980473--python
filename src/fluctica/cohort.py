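"""Synthetic multi-subject fMRI cohorts with known ground truth.

The generator emulates an already-preprocessed block-design study: spatially
fixed networks (sums of 3-D Gaussian blobs on a small grid) whose time
courses carry

* condition-dependent baseline shifts (convolved with the canonical HRF),
* condition-dependent within-block random fluctuation (an AR(1) process
  reset at block boundaries and scaled to a target stationary sd),
* signed pairwise coupling of that fluctuation, realised through shared
  standard-normal latent streams so the latent correlation between coupled
  components equals the requested weight exactly,

plus dedicated artifact components carrying band-limited noise and/or
out-of-mask spatial support.  Voxel data are the linear mixture of maps and
time courses plus white voxel noise.  Everything downstream of a
``(config, master_seed)`` pair is deterministic.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .design import (
    CONDITIONS,
    CUE,
    IMAGERY,
    SUPPRESSION,
    BlockDesign,
    build_block_design,
    canonical_hrf,
)

DEFAULT_GRID = (16, 16, 8)
SIDECAR_SCHEMA = "fluctica-ground-truth/1"


def ellipsoid_mask(grid: Sequence[int] = DEFAULT_GRID) -> np.ndarray:
    """Boolean 'brain' mask: an ellipsoid inscribed in the grid."""
    nx, ny, nz = grid
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    return (
        ((x - cx) / (nx / 2 - 0.5)) ** 2
        + ((y - cy) / (ny / 2 - 0.5)) ** 2
        + ((z - cz) / (nz / 2 - 0.5)) ** 2
    ) <= 1.0


@dataclass(frozen=True)
class ComponentSpec:
    """Generative description of one component (network or artifact).

    ``baseline`` maps condition label to the mean response amplitude
    (arbitrary units) while the condition is on; ``fluct_sd`` maps condition
    label to the stationary sd of the within-block fluctuation process;
    ``coupling`` maps a partner component name to a signed weight in
    [-1, 1] tying the two components' latent fluctuation streams.  An
    artifact component instead sets ``spectral_band`` (Hz) and carries no
    task structure.  ``subject_ratio_sd`` is a log-normal between-subject
    spread applied to the suppression-condition fluctuation sd.
    """

    name: str
    map_seed: int
    baseline: Mapping[str, float] = field(default_factory=dict)
    fluct_sd: Mapping[str, float] = field(default_factory=dict)
    coupling: Mapping[str, float] = field(default_factory=dict)
    spectral_band: tuple[float, float] | None = None
    anchor: tuple[float, float, float] | None = None
    n_blobs: int = 2
    blob_sigma: float = 1.4
    subject_ratio_sd: float = 0.0

    def __post_init__(self) -> None:
        for cond, v in self.fluct_sd.items():
            if v < 0:
                raise ValueError(f"fluct_sd[{cond!r}] must be >= 0")
        for partner, w in self.coupling.items():
            if abs(w) > 1:
                raise ValueError(f"|coupling[{partner!r}]| must be <= 1")
        if self.spectral_band is not None:
            if any(v != 0 for v in self.baseline.values()) or self.coupling:
                raise ValueError(
                    f"artifact component {self.name!r} must have empty baseline/coupling"
                )
            lo, hi = self.spectral_band
            if not 0 <= lo < hi:
                raise ValueError("spectral_band must satisfy 0 <= low < high")

    @property
    def is_artifact(self) -> bool:
        return self.spectral_band is not None


def default_component_specs() -> tuple[ComponentSpec, ...]:
    """The default ten-component cohort: eight networks and two artifacts.

    The roster mirrors the qualitative structure of a thought-suppression
    study: a suppression-related frontoparietal network with doubled
    fluctuation during suppression, an imagery network reciprocally
    (negatively) coupled to it, an executive-control network positively
    coupled to it whose between-subject fluctuation ratio drives the
    self-report flag, plus attention, default-mode, visual, somatomotor and
    task-tonic networks, a high-frequency artifact, and an out-of-mask
    low-frequency artifact.
    """
    return (
        ComponentSpec(
            "suppression_fpn",
            map_seed=101,
            baseline={IMAGERY: 0.0, SUPPRESSION: 1.0},
            fluct_sd={IMAGERY: 0.35, SUPPRESSION: 0.7},
            anchor=(12.0, 5.0, 3.5),
        ),
        ComponentSpec(
            "imagery_fpn",
            map_seed=102,
            baseline={IMAGERY: 1.0, SUPPRESSION: 0.0},
            fluct_sd={IMAGERY: 0.35, SUPPRESSION: 0.7},
            coupling={"suppression_fpn": -0.6},
            anchor=(3.0, 5.0, 3.5),
        ),
        ComponentSpec(
            "executive_control",
            map_seed=103,
            baseline={IMAGERY: 0.6, SUPPRESSION: 0.0},
            fluct_sd={IMAGERY: 0.4, SUPPRESSION: 0.6},
            coupling={"suppression_fpn": 0.6},
            subject_ratio_sd=0.4,
            anchor=(7.5, 2.5, 4.5),
        ),
        ComponentSpec(
            "dorsal_attention",
            map_seed=104,
            baseline={IMAGERY: 0.6, SUPPRESSION: 0.0},
            fluct_sd={IMAGERY: 0.4, SUPPRESSION: 0.4},
            coupling={"suppression_fpn": 0.6},
            anchor=(7.5, 12.5, 4.5),
        ),
        ComponentSpec(
            "posterior_dmn",
            map_seed=105,
            baseline={IMAGERY: 0.4, SUPPRESSION: 0.0},
            fluct_sd={IMAGERY: 0.45, SUPPRESSION: 0.34},
            coupling={"suppression_fpn": -0.6},
            anchor=(12.0, 10.5, 3.0),
        ),
        ComponentSpec(
            "primary_visual",
            map_seed=106,
            baseline={IMAGERY: 0.5, SUPPRESSION: 0.2},
            fluct_sd={IMAGERY: 0.4, SUPPRESSION: 0.4},
            anchor=(3.0, 10.5, 3.0),
        ),
        ComponentSpec(
            "somatomotor",
            map_seed=107,
            baseline={IMAGERY: 0.3, SUPPRESSION: 0.1},
            fluct_sd={IMAGERY: 0.45, SUPPRESSION: 0.45},
            anchor=(9.5, 7.5, 5.8),
        ),
        ComponentSpec(
            "angular_tonic",
            map_seed=108,
            baseline={IMAGERY: 0.45, SUPPRESSION: 0.1},
            fluct_sd={IMAGERY: 0.45, SUPPRESSION: 0.45},
            anchor=(5.5, 7.5, 1.2),
        ),
        ComponentSpec(
            "artifact_highfreq",
            map_seed=109,
            spectral_band=(0.15, 0.25),
            anchor=(10.0, 7.5, 1.5),
            n_blobs=1,
            blob_sigma=1.0,
        ),
        ComponentSpec(
            "artifact_rim",
            map_seed=110,
            spectral_band=(0.01, 0.1),
            anchor=(14.5, 1.5, 6.5),
            n_blobs=2,
            blob_sigma=1.2,
        ),
    )


def make_component_map(
    spec: ComponentSpec, grid: Sequence[int] = DEFAULT_GRID, truncate: float = 0.05
) -> np.ndarray:
    """Smooth compact spatial map: a sum of 3-D Gaussian blobs around the
    spec's anchor, truncated at ``truncate`` of the peak, peak-normalised to
    one, returned flattened (C order)."""
    rng = np.random.default_rng(spec.map_seed)
    nx, ny, nz = grid
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    anchor = spec.anchor
    if anchor is None:
        anchor = (
            rng.uniform(3, nx - 4),
            rng.uniform(3, ny - 4),
            rng.uniform(1.5, nz - 2.5),
        )
    vals = np.zeros(grid, dtype=float)
    for _ in range(spec.n_blobs):
        c = np.asarray(anchor) + rng.normal(0, [0.8, 0.8, 0.5])
        d2 = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2
        vals += np.exp(-d2 / (2 * spec.blob_sigma**2))
    peak = vals.max()
    if peak > 0:
        vals /= peak
        vals[vals < truncate] = 0.0
    return vals.ravel()


def _validate_coupling(specs: Sequence[ComponentSpec]) -> None:
    names = {s.name for s in specs}
    by_name = {s.name: s for s in specs}
    for s in specs:
        total = 0.0
        for partner, w in s.coupling.items():
            if partner not in names:
                raise ValueError(f"{s.name!r} couples to unknown component {partner!r}")
            if by_name[partner].coupling:
                raise ValueError(
                    "coupling matrix is not symmetrizable: "
                    f"{s.name!r} couples to {partner!r}, which is itself coupled"
                )
            total += w * w
        if total > 1 + 1e-12:
            raise ValueError(f"{s.name!r}: sum of squared coupling weights exceeds 1")


def _bandlimited_noise(white: np.ndarray, tr: float, band: tuple[float, float]) -> np.ndarray:
    """Confine a white series to a frequency band; unit empirical sd."""
    spec = np.fft.rfft(white - white.mean())
    freqs = np.fft.rfftfreq(white.size, d=tr)
    spec[(freqs < band[0] - 1e-12) | (freqs > band[1] + 1e-12)] = 0.0
    out = np.fft.irfft(spec, n=white.size)
    sd = out.std()
    return out / sd if sd > 0 else out


def _ar1_within_blocks(
    innovations: np.ndarray, design: BlockDesign, phi: float
) -> np.ndarray:
    """AR(1) with coefficient ``phi``, restarted at every block boundary,
    driven by unit-variance innovations; stationary sd is one."""
    out = np.zeros_like(innovations)
    scale = np.sqrt(1 - phi * phi)
    for _, idx in design.block_volume_indices():
        prev = innovations[idx[0]]
        out[idx[0]] = prev
        for i in idx[1:]:
            prev = phi * prev + scale * innovations[i]
            out[i] = prev
    return out


def simulate_timecourses(
    design: BlockDesign,
    specs: Sequence[ComponentSpec],
    rng: np.random.Generator,
    ar_phi: float = 0.5,
    fluct_scale: Mapping[str, Mapping[str, float]] | None = None,
    hrf: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one run's component time courses.

    Returns ``(timecourses, latent)``, both (T, K).  ``latent`` records the
    exact injected fluctuation series (the residual process) per component,
    for oracle tests.  ``fluct_scale[name][condition]`` multiplies that
    component/condition's fluctuation sd (used for between-subject spread and
    for the sensitivity-gap demonstration).
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    _validate_coupling(specs)
    T = design.n_volumes
    K = len(specs)
    names = [s.name for s in specs]
    z = rng.standard_normal((T, K))

    # shared-latent construction: a coupled component mixes its partner's raw
    # stream with its own, giving the exact requested latent correlation
    e = z.copy()
    for k, s in enumerate(specs):
        if s.coupling:
            mix = np.zeros(T)
            total = 0.0
            for partner, w in s.coupling.items():
                mix += w * z[:, names.index(partner)]
                total += w * w
            e[:, k] = mix + np.sqrt(1 - total) * z[:, k]

    if hrf is None:
        hrf = canonical_hrf(design.tr)
    boxcars = design.epoch_boxcars()
    cond_per_vol = design.volume_conditions()

    tc = np.zeros((T, K))
    latent = np.zeros((T, K))
    for k, s in enumerate(specs):
        if s.is_artifact:
            tc[:, k] = _bandlimited_noise(e[:, k], design.tr, s.spectral_band)
            continue
        base = np.zeros(T)
        for (cond, _), car in boxcars.items():
            base += s.baseline.get(cond, 0.0) * car
        base = np.convolve(base, hrf)[:T]
        f = _ar1_within_blocks(e[:, k], design, ar_phi)
        sd_per_vol = np.zeros(T)
        for cond in set(c for c in cond_per_vol if c):
            sd = s.fluct_sd.get(cond, 0.0)
            if fluct_scale and s.name in fluct_scale:
                sd *= fluct_scale[s.name].get(cond, 1.0)
            sd_per_vol[cond_per_vol == cond] = sd
        f *= sd_per_vol
        tc[:, k] = base + f
        latent[:, k] = f
    return tc, latent


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the default synthetic cohort."""

    n_subjects: int = 20
    n_runs: int = 2
    block_len_s: float = 24.0
    n_pairs: int = 4
    sub_blocks_per_condition: int = 2
    tr: float = 2.0
    lead_in_s: float = 24.0
    grid: tuple[int, int, int] = DEFAULT_GRID
    voxel_noise_sd: float = 0.2
    ar_phi: float = 0.5
    control_component: str = "executive_control"
    specs: tuple[ComponentSpec, ...] = field(default_factory=default_component_specs)

    def design(self) -> BlockDesign:
        return build_block_design(
            self.block_len_s,
            self.n_pairs,
            self.sub_blocks_per_condition,
            self.tr,
            self.lead_in_s,
        )


@dataclass
class GroundTruth:
    """A fully realised cohort: maps, time courses, latent records, reports."""

    config: CohortConfig
    design: BlockDesign
    true_maps: np.ndarray  # (V, K)
    mask: np.ndarray  # (V,) bool
    timecourses: np.ndarray  # (n_subjects, n_runs, T, K)
    latent: np.ndarray  # (n_subjects, n_runs, T, K)
    fluct_ratio: np.ndarray  # (n_subjects, K) injected suppression/imagery sd ratio
    reports: np.ndarray  # (n_subjects,) 0/1
    master_seed: int
    noise_seeds: np.ndarray  # (n_subjects, n_runs)

    @property
    def specs(self) -> tuple[ComponentSpec, ...]:
        return self.config.specs

    @property
    def component_names(self) -> list[str]:
        return [s.name for s in self.specs]

    def data(self, subject: int, run: int) -> np.ndarray:
        """(T, V) voxel data for one subject/run: linear mixture plus noise."""
        tc = self.timecourses[subject, run]  # (T, K)
        clean = tc @ self.true_maps.T  # (T, V)
        if self.config.voxel_noise_sd > 0:
            noise_rng = np.random.default_rng(int(self.noise_seeds[subject, run]))
            clean = clean + noise_rng.normal(0.0, self.config.voxel_noise_sd, clean.shape)
        return clean

    def datasets(self, trim_volumes: int = 0) -> list[np.ndarray]:
        """All (T-trim, V) data arrays, subject-major then run."""
        return [
            self.data(s, r)[trim_volumes:]
            for s in range(self.config.n_subjects)
            for r in range(self.config.n_runs)
        ]

    def dataset_index(self) -> list[tuple[int, int]]:
        return [
            (s, r)
            for s in range(self.config.n_subjects)
            for r in range(self.config.n_runs)
        ]


def build_cohort(config: CohortConfig | None = None, master_seed: int = 0) -> GroundTruth:
    """Realise a cohort deterministically from (config, master_seed).

    The binary self-report flag is a median split on each subject's injected
    suppression/imagery fluctuation-sd ratio of the designated control
    component, so both report groups are always non-empty.
    """
    config = config or CohortConfig()
    design = config.design()
    specs = config.specs
    _validate_coupling(specs)
    K = len(specs)
    S, R, T = config.n_subjects, config.n_runs, design.n_volumes

    ss = np.random.SeedSequence(master_seed)
    subj_seeds = ss.spawn(S)

    true_maps = np.column_stack([make_component_map(s, config.grid) for s in specs])
    mask = ellipsoid_mask(config.grid).ravel()

    timecourses = np.zeros((S, R, T, K))
    latent = np.zeros((S, R, T, K))
    fluct_ratio = np.full((S, K), np.nan)
    noise_seeds = np.zeros((S, R), dtype=np.int64)

    for s_idx in range(S):
        sub_ss = subj_seeds[s_idx]
        jitter_rng = np.random.default_rng(sub_ss.spawn(1)[0])
        scale: dict[str, dict[str, float]] = {}
        for k, spec in enumerate(specs):
            factor = 1.0
            if spec.subject_ratio_sd > 0:
                factor = float(np.exp(jitter_rng.normal(0.0, spec.subject_ratio_sd)))
                scale[spec.name] = {SUPPRESSION: factor}
            if not spec.is_artifact:
                sd_img = spec.fluct_sd.get(IMAGERY, 0.0)
                sd_sup = spec.fluct_sd.get(SUPPRESSION, 0.0) * factor
                if sd_img > 0:
                    fluct_ratio[s_idx, k] = sd_sup / sd_img
        run_seeds = sub_ss.spawn(2 * R)
        for r_idx in range(R):
            rng = np.random.default_rng(run_seeds[r_idx])
            tc, lat = simulate_timecourses(
                design, specs, rng, ar_phi=config.ar_phi, fluct_scale=scale or None
            )
            timecourses[s_idx, r_idx] = tc
            latent[s_idx, r_idx] = lat
            noise_seeds[s_idx, r_idx] = int(
                run_seeds[R + r_idx].generate_state(1, np.uint32)[0]
            )

    ctrl = [s.name for s in specs].index(config.control_component)
    ratios = fluct_ratio[:, ctrl]
    reports = (ratios > np.median(ratios)).astype(int)

    return GroundTruth(
        config=config,
        design=design,
        true_maps=true_maps,
        mask=mask,
        timecourses=timecourses,
        latent=latent,
        fluct_ratio=fluct_ratio,
        reports=reports,
        master_seed=master_seed,
        noise_seeds=noise_seeds,
    )


# --------------------------------------------------------------------- files

def _events_frame(design: BlockDesign) -> pd.DataFrame:
    rows = [
        {"onset": b.onset, "duration": b.duration, "trial_type": b.condition}
        for b in design.blocks
    ] + [{"onset": o, "duration": d, "trial_type": CUE} for o, d in design.cues]
    return pd.DataFrame(rows).sort_values(["onset", "trial_type"], kind="stable").reset_index(
        drop=True
    )


def _sidecar_dict(gt: GroundTruth) -> dict:
    cfg = gt.config
    return {
        "schema_version": SIDECAR_SCHEMA,
        "master_seed": gt.master_seed,
        "grid": list(cfg.grid),
        "tr": cfg.tr,
        "n_subjects": cfg.n_subjects,
        "n_runs": cfg.n_runs,
        "voxel_noise_sd": cfg.voxel_noise_sd,
        "ar_phi": cfg.ar_phi,
        "control_component": cfg.control_component,
        "components": [
            {
                "name": s.name,
                "map_seed": s.map_seed,
                "baseline": dict(s.baseline),
                "fluct_sd": dict(s.fluct_sd),
                "coupling": dict(s.coupling),
                "spectral_band": list(s.spectral_band) if s.spectral_band else None,
                "subject_ratio_sd": s.subject_ratio_sd,
            }
            for s in gt.specs
        ],
        "true_maps": [[round(float(v), 6) for v in col] for col in gt.true_maps.T],
        "fluct_ratio": [
            [None if np.isnan(v) else round(float(v), 6) for v in row]
            for row in gt.fluct_ratio
        ],
        "reports": [int(v) for v in gt.reports],
    }


def render_cohort(gt: GroundTruth, out_dir: str | Path) -> dict[str, list[Path]]:
    """Write the cohort as NIfTI volumes, BIDS-style events/participants
    tables, and a schema-versioned ground-truth JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = gt.config
    grid = cfg.grid
    affine = np.diag([8.0, 8.0, 16.0, 1.0])
    paths: dict[str, list[Path]] = {"bold": [], "events": [], "other": []}
    try:
        for s_idx in range(cfg.n_subjects):
            sub = f"sub-{s_idx + 1:02d}"
            for r_idx in range(cfg.n_runs):
                data = gt.data(s_idx, r_idx)  # (T, V)
                vol = np.ascontiguousarray(
                    data.T.reshape(grid + (data.shape[0],)), dtype=np.float32
                )
                img = nib.Nifti1Image(vol, affine)
                img.header.set_zooms((8.0, 8.0, 16.0, cfg.tr))
                img.header.set_xyzt_units("mm", "sec")
                bold = out_dir / f"{sub}_run-{r_idx + 1}_bold.nii.gz"
                nib.save(img, bold)
                paths["bold"].append(bold)
                events = out_dir / f"{sub}_run-{r_idx + 1}_events.tsv"
                _events_frame(gt.design).to_csv(events, sep="\t", index=False)
                paths["events"].append(events)
        participants = pd.DataFrame(
            {
                "participant_id": [f"sub-{i + 1:02d}" for i in range(cfg.n_subjects)],
                "report_success": gt.reports,
            }
        )
        ppath = out_dir / "participants.tsv"
        participants.to_csv(ppath, sep="\t", index=False)
        mpath = out_dir / "mask.nii.gz"
        nib.save(
            nib.Nifti1Image(
                gt.mask.reshape(grid).astype(np.uint8), np.diag([8.0, 8.0, 16.0, 1.0])
            ),
            mpath,
        )
        spath = out_dir / "ground_truth.json"
        spath.write_text(json.dumps(_sidecar_dict(gt), sort_keys=True, indent=1))
        paths["other"] = [ppath, mpath, spath]
    except OSError as err:
        raise OSError(f"failed writing cohort under {out_dir}: {err}") from err
    return paths


def load_events_design(path: str | Path, tr: float, run_length_s: float) -> BlockDesign:
    """Rebuild a BlockDesign from a BIDS-style events table."""
    ev = pd.read_csv(path, sep="\t")
    from .design import Block

    blocks: list[Block] = []
    cues: list[tuple[float, float]] = []
    counters: dict[str, int] = {}
    prev_cond = None
    for _, row in ev.sort_values("onset").iterrows():
        tt = row["trial_type"]
        if tt == CUE:
            cues.append((float(row["onset"]), float(row["duration"])))
            continue
        sub_index = counters.get(tt, 0) if prev_cond == tt else 0
        counters[tt] = sub_index + 1
        blocks.append(Block(tt, float(row["onset"]), float(row["duration"]), sub_index))
        prev_cond = tt
    lead_in = blocks[0].onset if blocks else 0.0
    return BlockDesign(tuple(blocks), tuple(cues), run_length_s, tr, lead_in)


def load_cohort(
    in_dir: str | Path,
) -> tuple[list[np.ndarray], list[tuple[int, int]], BlockDesign, np.ndarray, pd.DataFrame]:
    """Read a rendered cohort directory back into memory.

    Returns (datasets, (subject, run) index, design, mask, participants).
    """
    in_dir = Path(in_dir)
    bolds = sorted(in_dir.glob("sub-*_bold.nii.gz"))
    if not bolds:
        raise FileNotFoundError(f"no bold files under {in_dir}")
    datasets: list[np.ndarray] = []
    index: list[tuple[int, int]] = []
    design = None
    for bold in bolds:
        img = nib.load(bold)
        data = np.asarray(img.dataobj, dtype=float)
        T = data.shape[-1]
        datasets.append(data.reshape(-1, T).T)
        name = bold.name
        sub = int(name.split("_")[0].split("-")[1]) - 1
        run = int(name.split("_")[1].split("-")[1]) - 1
        index.append((sub, run))
        if design is None:
            tr = float(img.header.get_zooms()[3])
            events = in_dir / name.replace("_bold.nii.gz", "_events.tsv")
            design = load_events_design(events, tr, run_length_s=T * tr)
    mask_img = nib.load(in_dir / "mask.nii.gz")
    mask = np.asarray(mask_img.dataobj).astype(bool).ravel()
    participants = pd.read_csv(in_dir / "participants.tsv", sep="\t")
    return datasets, index, design, mask, participants
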