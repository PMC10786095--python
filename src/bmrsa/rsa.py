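"""Searchlight multiple-regression RSA with group-level inference.

For every gray-matter voxel, the 200 nearest mask voxels (Euclidean grid
distance, ties broken by ascending linear voxel index) form a searchlight.
The neural RDM of each searchlight (1 - Pearson between the 8 condition
t-patterns) is regressed, after z-scoring all 28-entry RDM vectors, on the
three binary attribute RDMs plus the V1 model RDM; the standardized
coefficient of each predictor is assigned to the searchlight center.
Subject coefficient maps are Fisher-transformed (atanh, clipped to ±0.999)
and tested against zero with voxel-wise one-sample t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .rdm import RDM, N_CONDITIONS, N_PAIRS, _TRIL

__all__ = ["SearchlightSpec", "Searchlights", "RSAMap", "define_searchlights",
           "regress_rdm", "searchlight_rsa", "group_rsa", "fisher_z",
           "FISHER_CLIP", "ZERO_VARIANCE_T_CAP"]

FISHER_CLIP = 0.999
ZERO_VARIANCE_T_CAP = 100.0


@dataclass(frozen=True)
class SearchlightSpec:
    """k nearest mask voxels by Euclidean distance on the voxel grid."""

    k: int = 200

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("searchlight size k must be >= 2")


@dataclass
class Searchlights:
    """One neighborhood per mask voxel.

    ``neighbors[i]`` holds indices (into the masked-voxel vector) of the k
    voxels of the searchlight centered on masked voxel i, always including i.
    """

    neighbors: np.ndarray        # (n_mask, k) int
    mask: np.ndarray             # 3D bool grid
    voxel_coords: np.ndarray     # (n_mask, 3) grid coordinates

    @property
    def n_centers(self) -> int:
        return self.neighbors.shape[0]

    @property
    def k(self) -> int:
        return self.neighbors.shape[1]


@dataclass
class RSAMap:
    """Per-voxel standardized regression coefficients, one column per predictor."""

    coefs: np.ndarray            # (n_mask, n_predictors)
    predictor_names: tuple[str, ...]
    skipped: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    subject: int | None = None


def define_searchlights(mask: np.ndarray, spec: SearchlightSpec = SearchlightSpec()) -> Searchlights:
    """k-nearest-neighbor searchlights over the mask.

    Distance ties (frequent on an integer grid) are broken by ascending
    linear voxel index, so neighborhoods are fully deterministic.
    """
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)
    n = coords.shape[0]
    if spec.k > n:
        raise ValueError(f"k={spec.k} exceeds mask size {n}")
    # Masked voxels are produced by np.argwhere in C order, so their position
    # in `coords` is already ascending linear index.
    tree = cKDTree(coords)
    k = spec.k
    kq = min(n, k + 64)
    dist, idx = tree.query(coords, k=kq)
    # Integer squared distances allow exact tie detection.
    sq = np.rint(dist ** 2).astype(np.int64)
    neighbors = np.empty((n, k), dtype=np.intp)
    for i in range(n):
        d, nb = sq[i], idx[i]
        if kq > k and d[k - 1] == d[-1]:
            # tie group may extend beyond the query slack: fall back to a ball
            nb = np.asarray(tree.query_ball_point(coords[i], np.sqrt(d[k - 1]) + 1e-6))
            d = np.sum((coords[nb] - coords[i]) ** 2, axis=1)
        order = np.lexsort((nb, d))
        neighbors[i] = nb[order[:k]]
    return Searchlights(neighbors=neighbors, mask=mask, voxel_coords=coords)


def _standardize(v: np.ndarray, axis: int = -1) -> np.ndarray:
    m = v.mean(axis=axis, keepdims=True)
    s = v.std(axis=axis, keepdims=True)
    return (v - m) / s


def regress_rdm(y: np.ndarray, predictors: np.ndarray,
                names: tuple[str, ...] | None = None) -> np.ndarray:
    """Standardized-coefficient OLS of one RDM vector on predictor RDM vectors.

    ``y`` has length 28; ``predictors`` is (n_predictors, 28).  All vectors
    are z-scored over the 28 pairs before fitting, so coefficients are
    invariant to affine rescaling of y.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if y.shape != (N_PAIRS,) or X.shape[1] != N_PAIRS:
        raise ValueError(f"RDM vectors must have length {N_PAIRS}")
    if y.std() == 0:
        raise ValueError("zero-variance dependent RDM vector")
    if np.any(X.std(axis=1) == 0):
        bad = np.flatnonzero(X.std(axis=1) == 0).tolist()
        raise ValueError(f"zero-variance predictor(s) {bad}")
    Xs = _standardize(X).T
    cond = np.linalg.cond(Xs)
    if cond > 1e8:
        raise ValueError(f"collinear predictors (condition number {cond:.3g})")
    beta, *_ = np.linalg.lstsq(Xs, _standardize(y), rcond=None)
    return beta


def neural_rdm_vectors(tmaps: np.ndarray, sl: Searchlights,
                       chunk: int = 2048) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized neural-RDM lower triangles for every searchlight.

    tmaps: (8, n_mask).  Returns (n_mask, 28) dissimilarities and a bool
    array marking searchlights skipped for a constant condition pattern.
    """
    n = sl.n_centers
    y = np.empty((n, N_PAIRS))
    skipped = np.zeros(n, dtype=bool)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        P = tmaps[:, sl.neighbors[lo:hi]]            # (8, m, k)
        P = P - P.mean(axis=2, keepdims=True)
        norm = np.sqrt(np.einsum("cmk,cmk->cm", P, P))
        bad = np.any(norm == 0, axis=0)
        norm[norm == 0] = 1.0
        P /= norm[:, :, None]
        R = np.einsum("amk,bmk->mab", P, P)
        y[lo:hi] = 1.0 - R[:, _TRIL[0], _TRIL[1]]
        skipped[lo:hi] = bad
    return y, skipped


def searchlight_rsa(tmaps: np.ndarray, model_rdms: dict[str, RDM],
                    sl: Searchlights, subject: int | None = None) -> RSAMap:
    """Multiple-regression RSA over all searchlights of one subject.

    ``tmaps`` is (8, n_mask): the condition t-patterns on masked voxels.
    ``model_rdms`` maps predictor name -> RDM (typically the three
    theoretical RDMs plus 'v1'), fitted jointly.  The design is identical
    for every searchlight, so the fit is a single precomputed projection.
    """
    tmaps = np.asarray(tmaps, dtype=float)
    if tmaps.shape != (N_CONDITIONS, sl.n_centers):
        raise ValueError("tmaps must be (8, n_mask) matching the searchlights")
    names = tuple(model_rdms)
    X = np.stack([model_rdms[n].vector() for n in names])
    Xs = _standardize(X).T                            # (28, p)
    proj = np.linalg.pinv(Xs)                         # (p, 28)
    y, skipped = neural_rdm_vectors(tmaps, sl)
    ys = np.empty_like(y)
    good = ~skipped
    ys[good] = _standardize(y[good])
    coefs = np.zeros((sl.n_centers, len(names)))
    coefs[good] = ys[good] @ proj.T
    if skipped.any():
        warnings.warn(f"{int(skipped.sum())} searchlight(s) skipped "
                      "(constant condition pattern); coefficients set to 0")
    return RSAMap(coefs=coefs, predictor_names=names,
                  skipped=np.flatnonzero(skipped), subject=subject)


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Variance-stabilizing atanh with inputs clipped to ±0.999."""
    return np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))


def group_rsa(maps: list[RSAMap] | np.ndarray) -> dict[str, np.ndarray]:
    """Voxel-wise one-sample t-tests on Fisher-transformed coefficients.

    Accepts a list of per-subject RSAMaps (or an (S, V, P) array) and
    returns ``{"z": (S,V,P), "t": (V,P), "p": (V,P), "mean_z": (V,P)}``
    with one-sided p-values for positive encoding.  Voxels with zero
    between-subject variance get t = sign(mean) * 100 (capped) and are
    handled without warnings.
    """
    if isinstance(maps, (list, tuple)):
        arr = np.stack([m.coefs for m in maps])
    else:
        arr = np.asarray(maps, dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("group inference needs >= 2 subjects")
    z = fisher_z(arr)
    t, p = one_sample_t(z, axis=0)
    return {"z": z, "t": t, "p": p, "mean_z": z.mean(axis=0)}


def one_sample_t(z: np.ndarray, axis: int = 0,
                 cap: float = ZERO_VARIANCE_T_CAP) -> tuple[np.ndarray, np.ndarray]:
    """One-sided (positive) one-sample t-test against zero along ``axis``."""
    from scipy import stats

    n = z.shape[axis]
    mean = z.mean(axis=axis)
    sd = z.std(axis=axis, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = sd == 0
    if np.any(zero_var):
        t = np.where(zero_var, np.sign(mean) * cap, t)
    t = np.clip(t, -cap, cap)
    p = stats.t.sf(t, df=n - 1)
    return t, p
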