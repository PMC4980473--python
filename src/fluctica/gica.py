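"""Temporal-concatenation group spatial ICA with stability selection.

Pipeline: per-run PCA over time (denoising), concatenation across
subjects/runs, group PCA + whitening to the model order, natural-gradient
Infomax ICA repeated under bootstrap resampling and random initialisation
(ICASSO), average-linkage clustering of the pooled estimates, centrotype
selection, and dual-regression back-projection to per-subject/run component
time courses.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


# ------------------------------------------------------------------ reduction

@dataclass
class ReducedData:
    """A whitened top-k principal subspace of a channels x samples matrix."""

    reduced: np.ndarray  # (k, n) whitened rows
    basis: np.ndarray  # (k, d): reduced = basis @ (data - mean)
    mean: np.ndarray  # (d, 1) per-channel mean
    retained_variance: float
    singular_values: np.ndarray


def pca_reduce(data: np.ndarray, k: int) -> ReducedData:
    """Retain the top-k principal subspace of the rows and whiten.

    Rows are channels, columns are samples.  Whitened rows have unit
    (population) variance and zero mutual correlation.
    """
    X = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("data must be finite")
    d, n = X.shape
    if k > min(d, n):
        raise ValueError(f"k={k} exceeds min(dimensions)={min(d, n)}")
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > (s[0] * 1e-10 if s[0] > 0 else 0)))
    if k > rank:
        raise ValueError(f"k={k} exceeds achievable rank {rank}")
    basis = (np.sqrt(n) / s[:k])[:, None] * U[:, :k].T  # (k, d)
    reduced = basis @ Xc
    total = float(np.sum(s**2))
    retained = float(np.sum(s[:k] ** 2) / total) if total > 0 else 1.0
    return ReducedData(reduced, basis, mean, retained, s)


# -------------------------------------------------------------------- infomax

class _Diverged(RuntimeError):
    pass


def _infomax_core(X, W0, lr, max_iter, tol, anneal, block, rng):
    k, n = X.shape
    eye = np.eye(k)
    W = W0.copy()
    prev = W.copy()
    for _ in range(max_iter):
        perm = rng.permutation(n)
        for t0 in range(0, n - block + 1, block):
            u = W @ X[:, perm[t0 : t0 + block]]
            y = special.expit(u)
            grad = eye + ((1.0 - 2.0 * y) @ u.T) / u.shape[1]
            W += lr * grad @ W
            if not np.all(np.isfinite(W)) or np.abs(W).max() > 1e8:
                raise _Diverged
        change = float(np.linalg.norm(W - prev))
        if change < tol:
            break
        prev = W.copy()
        lr *= anneal
    return W


def infomax_unmix(
    data: np.ndarray,
    seed: int = 0,
    lr: float = 0.01,
    max_iter: int = 512,
    tol: float = 1e-7,
    anneal: float = 0.97,
    block: int | None = None,
    max_restarts: int = 5,
) -> np.ndarray:
    """Natural-gradient Infomax with a logistic nonlinearity.

    Expects whitened input (channels x samples) and seeks a square unmixing
    matrix, returned with unit-norm rows.  The learning rate is annealed
    geometrically; convergence is declared when the weight-change Frobenius
    norm over a full pass drops below ``tol``.  On weight explosion the
    learning rate is halved and the optimisation restarted, at most
    ``max_restarts`` times.
    """
    X = np.asarray(data, dtype=float)
    k, n = X.shape
    if block is None:
        block = int(np.clip(np.sqrt(n / 3.0), 8, 256))
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((k, k))
    W0, _ = np.linalg.qr(A)
    for attempt in range(max_restarts + 1):
        try:
            W = _infomax_core(
                X, W0, lr / (2**attempt), max_iter, tol, anneal, block,
                np.random.default_rng(seed + 1),
            )
            break
        except _Diverged:
            if attempt == max_restarts:
                raise RuntimeError(
                    f"infomax diverged after {max_restarts} learning-rate restarts"
                )
    return W / np.linalg.norm(W, axis=1, keepdims=True)


# --------------------------------------------------------------------- icasso

@dataclass
class IcassoResult:
    unmixing: np.ndarray  # (K, K) centrotype unmixing rows, in whitened space
    stability_iq: np.ndarray  # (K,)
    cluster_sizes: np.ndarray  # (K,)
    similarity: np.ndarray  # pooled estimate similarity matrix
    labels: np.ndarray  # cluster label per pooled estimate
    centrotypes: np.ndarray  # pooled-estimate index per cluster
    warnings_count: int = 0


def icasso_select(
    whitened: np.ndarray,
    n_runs: int = 10,
    model_order: int | None = None,
    bootstrap: bool = True,
    seed: int = 0,
    data: np.ndarray | None = None,
    similarity: str = "timecourses",
    **infomax_kwargs,
) -> IcassoResult:
    """Stability selection over repeated Infomax runs.

    Each run bootstrap-resamples the sample axis (with replacement) and uses
    a fresh random initialisation; the resulting estimates are pooled,
    pairwise similarity is |Pearson r| between estimate time courses
    (``similarity='timecourses'``, requires ``data`` as the concatenated
    (T_total, n_samples) matrix) or between estimate maps
    (``similarity='maps'``); estimates are grouped by average-linkage
    agglomerative clustering into ``model_order`` clusters; each cluster is
    represented by its centrotype (the member with maximal average
    within-cluster similarity).  ``stability_iq`` is the mean intra-cluster
    similarity minus the mean extra-cluster similarity.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    Xw = np.asarray(whitened, dtype=float)
    k, n = Xw.shape
    K = model_order or k
    if K != k:
        raise ValueError("model_order must match the whitened dimension")
    if similarity == "timecourses" and data is None:
        similarity = "maps"
    rng = np.random.default_rng(seed)

    all_rows = []
    feats = []
    for _ in range(n_runs):
        cols = rng.integers(0, n, n) if bootstrap else np.arange(n)
        run_seed = int(rng.integers(0, 2**31 - 1))
        W = infomax_unmix(Xw[:, cols], seed=run_seed, **infomax_kwargs)
        S = W @ Xw  # estimate maps on the full data
        all_rows.append(W)
        if similarity == "timecourses":
            tc = data @ np.linalg.pinv(S)  # (T_total, K)
            feats.append(tc.T)
        else:
            feats.append(S)
    pooled_rows = np.vstack(all_rows)  # (n_runs*K, k)
    F = np.vstack(feats)  # (n_runs*K, features)
    sim = np.abs(np.corrcoef(F))
    sim = np.clip(np.nan_to_num(sim, nan=0.0), 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)

    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=K, criterion="maxclust")
    warn_count = 0
    uniq = np.unique(labels)
    if uniq.size < K:
        warnings.warn(
            f"clustering produced {uniq.size} < {K} clusters", stacklevel=2
        )
        warn_count += K - uniq.size

    iq = np.zeros(uniq.size)
    sizes = np.zeros(uniq.size, dtype=int)
    cents = np.zeros(uniq.size, dtype=int)
    for j, lab in enumerate(uniq):
        members = np.flatnonzero(labels == lab)
        others = np.flatnonzero(labels != lab)
        sizes[j] = members.size
        sub = sim[np.ix_(members, members)]
        if members.size > 1:
            intra = float((sub.sum() - members.size) / (members.size * (members.size - 1)))
            cents[j] = members[np.argmax((sub.sum(axis=1) - 1) / (members.size - 1))]
        else:
            intra = 1.0
            cents[j] = members[0]
        extra = float(sim[np.ix_(members, others)].mean()) if others.size else 0.0
        iq[j] = intra - extra

    order = np.argsort(-iq, kind="stable")
    return IcassoResult(
        unmixing=pooled_rows[cents[order]],
        stability_iq=iq[order],
        cluster_sizes=sizes[order],
        similarity=sim,
        labels=labels,
        centrotypes=cents[order],
        warnings_count=warn_count,
    )


# ------------------------------------------------------------ back-projection

def back_project(
    group_maps: np.ndarray, data: np.ndarray, cond_limit: float = 1e8
) -> tuple[np.ndarray, np.ndarray]:
    """Dual-regression back-projection of group maps onto one dataset.

    First regresses every volume (time point) of ``data`` (T, V) on the
    group maps (V, K), giving subject time courses (T, K); then regresses
    the data on those time courses (with an intercept), giving subject maps
    (K, V).
    """
    G = np.asarray(group_maps, dtype=float)
    Y = np.asarray(data, dtype=float)
    if G.shape[0] != Y.shape[1]:
        raise ValueError("data and group maps are not on the same voxel grid")
    cond = np.linalg.cond(G)
    if cond > cond_limit:
        raise ValueError(f"group maps are collinear (condition number {cond:.3g})")
    tc = Y @ np.linalg.pinv(G).T  # (T, K)
    A = np.column_stack([np.ones(len(tc)), tc])
    smaps, *_ = np.linalg.lstsq(A, Y, rcond=None)
    return tc, smaps[1:]


def zscore_map(
    values: np.ndarray, mask: np.ndarray | None = None, threshold: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score a spatial map over in-mask voxels and threshold it.

    Statistics (mean, sd) come from in-mask voxels but the z-transform is
    applied to every voxel so out-of-mask involvement can be assessed.
    Returns ``(z_map_thresholded, suprathreshold_bool)`` where sub-threshold
    values (|z| <= threshold) are zeroed.
    """
    v = np.asarray(values, dtype=float)
    sel = v[mask] if mask is not None else v
    if sel.size == 0:
        raise ValueError("mask selects no voxels")
    mu, sd = sel.mean(), sel.std()
    if sd == 0:
        warnings.warn("zero-variance map; returning all zeros", stacklevel=2)
        return np.zeros_like(v), np.zeros_like(v, dtype=bool)
    z = (v - mu) / sd
    supra = np.abs(z) > threshold
    out = np.where(supra, z, 0.0)
    return out, supra


# ------------------------------------------------------------------- fitting

@dataclass
class ComponentSet:
    """Group decomposition: z-scored spatial maps, per-dataset back-projected
    time courses, and ICASSO stability indices."""

    group_maps: np.ndarray  # (V, K) z-scored over mask
    subject_timecourses: list[np.ndarray]  # per dataset (T, K)
    stability_iq: np.ndarray  # (K,)
    model_order: int
    mask: np.ndarray | None = None
    dataset_index: list[tuple[int, int]] | None = None  # (subject, run)
    retained_variance: float = float("nan")

    @property
    def n_components(self) -> int:
        return self.group_maps.shape[1]

    def timecourses_by_subject(self) -> list[list[np.ndarray]]:
        """Group the flat dataset list into per-subject lists of runs."""
        if self.dataset_index is None:
            return [[tc] for tc in self.subject_timecourses]
        subjects = sorted({s for s, _ in self.dataset_index})
        out = []
        for s in subjects:
            runs = [
                self.subject_timecourses[i]
                for i, (si, _) in enumerate(self.dataset_index)
                if si == s
            ]
            out.append(runs)
        return out


def fit_group_ica(
    datasets: Sequence[np.ndarray],
    model_order: int,
    mask: np.ndarray | None = None,
    n_runs: int = 10,
    bootstrap: bool = True,
    seed: int = 0,
    subject_k: int | None = None,
    similarity: str = "timecourses",
    dataset_index: list[tuple[int, int]] | None = None,
    **infomax_kwargs,
) -> ComponentSet:
    """Full group ICA: two-stage reduction, ICASSO, sign fixing, z-scored
    maps, and dual-regression time courses for every dataset.

    ``datasets`` are (T, V) arrays on a common voxel grid.  The subject-stage
    dimension defaults to 1.5x the model order.
    """
    k1 = subject_k or int(np.ceil(1.5 * model_order))
    centred = [X - X.mean(axis=0) for X in datasets]
    reduced = [pca_reduce(Xc, min(k1, min(Xc.shape))).reduced for Xc in centred]
    concat = np.vstack(reduced)
    group = pca_reduce(concat, model_order)
    data_concat = np.vstack(centred) if similarity == "timecourses" else None
    ica = icasso_select(
        group.reduced,
        n_runs=n_runs,
        model_order=model_order,
        bootstrap=bootstrap,
        seed=seed,
        data=data_concat,
        similarity=similarity,
        **infomax_kwargs,
    )
    maps = ica.unmixing @ group.reduced  # (K, V)
    flip = np.where(stats.skew(maps, axis=1) < 0, -1.0, 1.0)
    maps = maps * flip[:, None]
    zmaps = np.empty_like(maps)
    for j in range(maps.shape[0]):
        sel = maps[j][mask] if mask is not None else maps[j]
        zmaps[j] = (maps[j] - sel.mean()) / sel.std()
    group_maps = zmaps.T  # (V, K)
    tcs = [back_project(group_maps, Xc)[0] for Xc in centred]
    return ComponentSet(
        group_maps=group_maps,
        subject_timecourses=tcs,
        stability_iq=ica.stability_iq,
        model_order=model_order,
        mask=mask,
        dataset_index=dataset_index,
        retained_variance=group.retained_variance,
    )


def match_components(
    reference: np.ndarray, estimated: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Match estimated components to reference ones by maximal |Pearson r|.

    Both arguments are (features, K) matrices.  Returns ``(assignment,
    abs_r)`` where ``assignment[j]`` is the estimated column matched to
    reference column j.
    """
    R = np.asarray(reference, float)
    E = np.asarray(estimated, float)
    kr, ke = R.shape[1], E.shape[1]
    C = np.zeros((kr, ke))
    for i in range(kr):
        for j in range(ke):
            C[i, j] = abs(np.corrcoef(R[:, i], E[:, j])[0, 1])
    rows, cols = optimize.linear_sum_assignment(-C)
    return cols, C[rows, cols]
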