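"""Cluster-level inference: thresholding, labeling, sign-flip Monte Carlo
family-wise correction, and BH-FDR.

The correction follows the permutation family common in MVPA toolboxes:
voxel-wise one-sample t-maps over subjects are thresholded at an
uncorrected p (default 0.001, one-sided positive), supra-threshold voxels
are grouped into connected components (26-connectivity default), and the
observed cluster sizes are compared with the null distribution of the
maximum cluster size under random sign-flipping of the subject maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .rsa import one_sample_t

__all__ = ["ThresholdSpec", "ClusterSet", "voxel_threshold", "label_clusters",
           "montecarlo_cluster", "fdr_bh"]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class ThresholdSpec:
    """Cluster-forming threshold and Monte Carlo settings.

    voxel_p is the uncorrected cluster-forming threshold (0.001 in the
    full analysis); n_iter the number of sign-flip iterations (5000 full,
    500 in the test profile); alpha the cluster-level significance level.
    """

    voxel_p: float = 0.001
    n_iter: int = 5000
    alpha: float = 0.05
    connectivity: int = 26
    two_sided: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.voxel_p < 1:
            raise ValueError("voxel_p must be in (0, 1)")
        if self.n_iter < 100:
            raise ValueError("n_iter must be >= 100")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class ClusterSet:
    """Labeled supra-threshold clusters on a 3D grid.

    Labels partition the supra-threshold set, numbered 1..n in ascending
    order of each cluster's minimum linear voxel index.
    """

    labels: np.ndarray                 # 3D int grid, 0 = background
    sizes: np.ndarray                  # (n_clusters,)
    peak_stat: np.ndarray = field(default_factory=lambda: np.zeros(0))
    pvals: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def cluster_voxels(self, cid: int) -> np.ndarray:
        """(m, 3) grid coordinates of cluster ``cid`` (1-based)."""
        return np.argwhere(self.labels == cid)

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        """Binary grid of voxels in clusters with corrected p < alpha."""
        out = np.zeros_like(self.labels, dtype=bool)
        for cid in range(1, self.n_clusters + 1):
            if self.pvals.size and self.pvals[cid - 1] < alpha:
                out |= self.labels == cid
        return out

    def table(self):
        import pandas as pd

        rows = []
        for cid in range(1, self.n_clusters + 1):
            row = {"cluster_id": cid, "size": int(self.sizes[cid - 1])}
            if self.peak_stat.size:
                row["peak_stat"] = float(self.peak_stat[cid - 1])
            if self.pvals.size:
                row["corrected_p"] = float(self.pvals[cid - 1])
            rows.append(row)
        return pd.DataFrame(rows)


def voxel_threshold(tmap: np.ndarray, dof: int, voxel_p: float = 0.001,
                    two_sided: bool = False) -> np.ndarray:
    """Keep voxels whose t exceeds the Student-t critical value.

    One-sided positive by default (the hypotheses are positive encoding);
    two-sided keeps |t| above the p/2 critical value.
    """
    if dof < 1:
        raise ValueError("dof must be >= 1")
    tmap = np.asarray(tmap, dtype=float)
    if two_sided:
        crit = stats.t.isf(voxel_p / 2.0, dof)
        return np.abs(tmap) > crit
    return tmap > stats.t.isf(voxel_p, dof)


def label_clusters(binary: np.ndarray, connectivity: int = 26,
                   stat: np.ndarray | None = None) -> ClusterSet:
    """Connected components of a binary 3D map.

    scipy's raster-scan labeling already numbers components by ascending
    first-encountered (= minimum linear) voxel index, which is kept as the
    deterministic ordering.
    """
    binary = np.asarray(binary, dtype=bool)
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be 6, 18 or 26")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n = ndimage.label(binary, structure=structure)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:].astype(int)
    peaks = np.zeros(n)
    if stat is not None and n:
        peaks = np.asarray(ndimage.maximum(np.asarray(stat, dtype=float),
                                           labels, index=np.arange(1, n + 1)))
    return ClusterSet(labels=labels, sizes=sizes, peak_stat=peaks)


def _grid(values: np.ndarray, mask: np.ndarray, fill: float = 0.0) -> np.ndarray:
    out = np.full(mask.shape, fill, dtype=float)
    out[mask] = values
    return out


def _max_null_sizes(subject_z: np.ndarray, mask: np.ndarray,
                    spec: ThresholdSpec, rng: np.random.Generator) -> np.ndarray:
    """Null distribution of the maximum cluster size under sign flipping.

    The group t-statistics for all sign-flip iterations reduce to one
    matrix product because squared values are flip-invariant.
    """
    s, v = subject_z.shape
    signs = rng.choice((-1.0, 1.0), size=(spec.n_iter, s))
    mean = signs @ subject_z / s                          # (n_iter, v)
    ss = np.einsum("sv,sv->v", subject_z, subject_z)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.maximum(ss / s - mean ** 2, 0.0) * (s / (s - 1))
        t = mean / np.sqrt(var / s)
    t[~np.isfinite(t)] = 0.0
    crit = (stats.t.isf(spec.voxel_p / 2.0, s - 1) if spec.two_sided
            else stats.t.isf(spec.voxel_p, s - 1))
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[spec.connectivity])
    out = np.zeros(spec.n_iter, dtype=int)
    grid = np.zeros(mask.shape, dtype=bool)
    for i in range(spec.n_iter):
        grid[:] = False
        grid[mask] = np.abs(t[i]) > crit if spec.two_sided else t[i] > crit
        labels, n = ndimage.label(grid, structure=structure)
        if n:
            out[i] = np.bincount(labels.ravel())[1:].max()
    return out


def montecarlo_cluster(subject_z: np.ndarray, mask: np.ndarray,
                       spec: ThresholdSpec = ThresholdSpec()) -> ClusterSet:
    """Sign-flip Monte Carlo cluster correction of a group one-sample test.

    ``subject_z`` is (n_subjects, n_mask): per-subject statistic maps on
    masked voxels (Fisher-z RSA coefficients, or accuracy minus chance).
    Observed cluster p = (1 + #{null max size >= size}) / (1 + n_iter).
    """
    subject_z = np.asarray(subject_z, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if subject_z.ndim != 2 or subject_z.shape[0] < 2:
        raise ValueError("need an (n_subjects >= 2, n_mask) array")
    if subject_z.shape[1] != int(mask.sum()):
        raise ValueError("subject maps do not match the mask")
    t, _ = one_sample_t(subject_z, axis=0)
    dof = subject_z.shape[0] - 1
    binary = voxel_threshold(_grid(t, mask, fill=-np.inf), dof, spec.voxel_p,
                             two_sided=spec.two_sided) & mask
    clusters = label_clusters(binary, spec.connectivity, stat=_grid(t, mask))
    rng = np.random.default_rng(spec.seed)
    null_max = _max_null_sizes(subject_z, mask, spec, rng)
    pvals = np.array([(1 + np.sum(null_max >= s)) / (1 + spec.n_iter)
                      for s in clusters.sizes])
    clusters.pvals = pvals
    return clusters


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level q."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject
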