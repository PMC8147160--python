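"""Fuzzy c-means clustering of voxel intensities into tissue classes.

The segmentation step of the normalization pipeline: the whole MRI volume
(including exterior background air, which pools with lung in the lowest
class) is clustered into three intensity classes — air/lung, soft tissue and
fat, in ascending order of cluster center — matching the T1-weighted
contrast of both the low-field torso scanner and the diagnostic scanner.

FCM minimizes sum_ij u_ij^m ||x_i - c_j||^2 subject to per-point membership
rows summing to one.  The fixed-point updates are

    u_ij = (1/d_ij)^(1/(m-1)) / sum_k (1/d_ik)^(1/(m-1)),   d_ij = (x_i-c_j)^2
    c_j  = sum_i u_ij^m x_i / sum_i u_ij^m

with the convention that an exact-zero distance gives that point full
membership in the coinciding cluster.  Centers are initialized at evenly
spaced quantiles of the intensity distribution, so a run is deterministic;
the seed only controls the optional voxel subsample used on very large
volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import Volume, TissueLabelMap

#: volumes above this many voxels are clustered on a seeded subsample
SUBSAMPLE_THRESHOLD = 2_000_000


@dataclass
class FcmConfig:
    k: int = 3
    m: float = 2.0
    tol: float = 1e-4           # relative center movement
    max_iter: int = 300
    seed: int = 0
    per_slice: bool = False     # cluster each axial slice independently

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.m <= 1:
            raise ValueError("fuzziness m must be > 1")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be > 0 and max_iter >= 1")


@dataclass
class FuzzyPartition:
    """Result of an FCM run on a 1-D list of intensities."""

    memberships: np.ndarray           # (n, k), rows sum to 1
    centers: np.ndarray               # (k,)
    m: float
    objective_history: list[float] = field(default_factory=list)

    def harden(self) -> np.ndarray:
        return harden_partition(self)


def _memberships(values: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    d = (values[:, None] - centers[None, :]) ** 2
    zero = d <= 0.0
    u = np.empty_like(d)
    with np.errstate(divide="ignore"):
        inv = d ** (-1.0 / (m - 1.0))
    row_zero = zero.any(axis=1)
    inv[row_zero] = 0.0
    # zero-distance points: full membership split over coinciding clusters
    u[row_zero] = zero[row_zero] / zero[row_zero].sum(axis=1, keepdims=True)
    ok = ~row_zero
    u[ok] = inv[ok] / inv[ok].sum(axis=1, keepdims=True)
    return u


def _objective(values: np.ndarray, centers: np.ndarray, u: np.ndarray, m: float) -> float:
    d = (values[:, None] - centers[None, :]) ** 2
    return float(np.sum(u**m * d))


def quantile_centers(values: np.ndarray, k: int) -> np.ndarray:
    """Initial centers at quantiles (2j+1)/(2k), j = 0..k-1 (deterministic)."""
    q = (2 * np.arange(k) + 1) / (2 * k)
    return np.quantile(values, q)


def fcm_cluster(values: np.ndarray, cfg: FcmConfig) -> FuzzyPartition:
    """Run fuzzy c-means on a flat list of intensities.

    Raises ``ValueError`` if the input is non-finite or has fewer distinct
    values than clusters.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite intensities")
    if np.unique(values).size < cfg.k:
        raise ValueError(f"need >= {cfg.k} distinct values, "
                         f"got {np.unique(values).size}")

    centers = quantile_centers(values, cfg.k).astype(np.float64)
    # quantile init can produce coincident centers on skewed data; nudge apart
    if np.unique(centers).size < cfg.k:
        lo, hi = values.min(), values.max()
        centers = np.linspace(lo, hi, cfg.k)

    history: list[float] = []
    u = _memberships(values, centers, cfg.m)
    scale = max(float(np.ptp(values)), np.finfo(float).tiny)
    for _ in range(cfg.max_iter):
        history.append(_objective(values, centers, u, cfg.m))
        um = u ** cfg.m
        denom = um.sum(axis=0)
        denom[denom == 0] = np.finfo(float).tiny
        new_centers = (um * values[:, None]).sum(axis=0) / denom
        u = _memberships(values, new_centers, cfg.m)
        move = np.max(np.abs(new_centers - centers)) / scale
        centers = new_centers
        if move < cfg.tol:
            break
    history.append(_objective(values, centers, u, cfg.m))
    return FuzzyPartition(memberships=u, centers=centers, m=cfg.m,
                          objective_history=history)


def harden_partition(p: FuzzyPartition) -> np.ndarray:
    """Argmax membership per point; ties go to the lowest cluster index."""
    return np.argmax(p.memberships, axis=1)


def segment_tissues(vol: Volume, cfg: FcmConfig | None = None) -> TissueLabelMap:
    """Segment an MRI volume into air/lung (0), soft tissue (1), fat (2).

    Clusters are mapped to tissue codes by ascending center intensity.  On
    volumes above ``SUBSAMPLE_THRESHOLD`` voxels the centers are fit on a
    seeded random subsample and all voxels are then assigned from the final
    centers.
    """
    cfg = cfg or FcmConfig()
    if cfg.k != 3:
        raise ValueError("tissue segmentation requires k == 3")
    if np.ptp(vol.data) == 0:
        raise ValueError("constant-intensity volume cannot be segmented")

    if cfg.per_slice:
        labels = np.empty(vol.shape, dtype=np.int32)
        for s in range(vol.n_slices):
            labels[s] = _segment_array(vol.data[s].ravel(), cfg).reshape(vol.shape[1:])
        return TissueLabelMap(labels=labels, spacing=vol.spacing)

    labels = _segment_array(vol.data.ravel(), cfg).reshape(vol.shape)
    return TissueLabelMap(labels=labels, spacing=vol.spacing)


def _segment_array(flat: np.ndarray, cfg: FcmConfig) -> np.ndarray:
    fit_values = flat
    if flat.size > SUBSAMPLE_THRESHOLD:
        rng = np.random.default_rng(cfg.seed)
        idx = rng.choice(flat.size, size=SUBSAMPLE_THRESHOLD, replace=False)
        fit_values = flat[idx]
    part = fcm_cluster(fit_values, cfg)
    order = np.argsort(part.centers)          # ascending intensity -> 0,1,2
    sorted_centers = part.centers[order]
    # assign every voxel from the final centers (hard, nearest-center with
    # the fuzzy membership rule this equals argmax membership)
    u = _memberships(flat, sorted_centers, cfg.m)
    return np.argmax(u, axis=1).astype(np.int32)
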