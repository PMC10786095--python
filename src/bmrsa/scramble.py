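"""Scrambled-RDM hierarchy analysis and Dice overlap.

For a target attribute, the two non-target theoretical RDMs are scrambled
(joint row/column permutation of the 8 condition labels, preserving RDM
structure) and the 4-predictor searchlight regression is re-run; the
Fisher-transformed target coefficient map is averaged over permutations
(1,000 in the full analysis).  Group maps from the standard and scrambled
analyses are thresholded with the same Monte Carlo cluster correction, and
their overlap is quantified with the Dice coefficient
DC = 2 * N_C / (N_1 + N_2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cluster import ThresholdSpec, montecarlo_cluster
from .rdm import ATTRIBUTES, RDM, _TRIL
from .rsa import (RSAMap, Searchlights, _standardize, fisher_z,
                  neural_rdm_vectors, searchlight_rsa)

__all__ = ["ScramblePlan", "DiceResult", "scramble_rdm", "scrambled_rsa",
           "dice", "hierarchy_analysis"]


@dataclass(frozen=True)
class ScramblePlan:
    """Scrambling settings for one target attribute."""

    target: str
    n_perm: int = 1000
    seed: int = 0
    granularity: str = "labels"   # joint row/column label permutation,
    #                               or "entries": shuffle the 28-vector
    transform: str = "fisher"     # per-permutation map transform; or
    #                               "spatial_z": z-score each map over voxels

    def __post_init__(self):
        if self.target not in ATTRIBUTES:
            raise ValueError(f"target must be one of {ATTRIBUTES}")
        if self.n_perm < 10:
            raise ValueError("n_perm must be >= 10")
        if self.granularity not in ("labels", "entries"):
            raise ValueError("granularity must be 'labels' or 'entries'")
        if self.transform not in ("fisher", "spatial_z"):
            raise ValueError("transform must be 'fisher' or 'spatial_z'")


@dataclass
class DiceResult:
    """Overlap of two binary voxel maps: dc = 2*N_C / (N_1 + N_2)."""

    n_common: int
    n_map1: int
    n_map2: int
    dc: float
    both_empty: bool = False


def scramble_rdm(rdm: RDM, permutation) -> RDM:
    """Joint row/column permutation of the 8 condition labels."""
    perm = np.asarray(permutation)
    if sorted(perm.tolist()) != list(range(8)):
        raise ValueError("permutation must be a bijection on the 8 labels")
    values = rdm.values[np.ix_(perm, perm)]
    labels = tuple(np.array(rdm.labels, dtype=object)[perm]) if rdm.labels else None
    return RDM(values=values, kind=rdm.kind, labels=labels)


def scrambled_rsa(tmaps: np.ndarray, theoretical: dict[str, RDM], v1_rdm: RDM,
                  sl: Searchlights, plan: ScramblePlan,
                  precomputed: tuple[np.ndarray, np.ndarray] | None = None,
                  draw_permutation=None) -> np.ndarray:
    """Permutation-averaged Fisher-z map of the target attribute, (n_mask,).

    Per permutation, the two non-target theoretical RDM vectors are drawn
    from independent label permutations, the standardized 4-predictor OLS
    is refit (the neural RDM vectors are fixed, so each refit is a single
    projection), and the Fisher-transformed target coefficient map is
    accumulated.  A scrambled RDM occasionally coincides with another
    predictor; the minimum-norm least-squares solution is used throughout,
    which splits the coefficient across exact duplicates.

    ``precomputed`` optionally supplies (rdm_vectors, skipped) from
    :func:`bmrsa.rsa.neural_rdm_vectors` to avoid recomputation across
    attributes; ``draw_permutation`` (rng -> permutation of 0..7) overrides
    the default uniform draw.
    """
    rng = np.random.default_rng(plan.seed)
    names = list(ATTRIBUTES) + ["v1"]
    t_idx = names.index(plan.target)
    base = {a: theoretical[a].values for a in ATTRIBUTES}
    if precomputed is None:
        y, skipped = neural_rdm_vectors(np.asarray(tmaps, dtype=float), sl)
    else:
        y, skipped = precomputed
    if draw_permutation is None:
        draw_permutation = lambda r: r.permutation(8)
    good = ~skipped
    ys = np.zeros_like(y)
    ys[good] = _standardize(y[good])
    acc = np.zeros(y.shape[0])
    v1_vec = v1_rdm.vector()
    for _ in range(plan.n_perm):
        vecs = []
        for a in ATTRIBUTES:
            v = base[a][_TRIL]
            if a != plan.target:
                if plan.granularity == "labels":
                    p = draw_permutation(rng)
                    v = base[a][np.ix_(p, p)][_TRIL]
                else:
                    v = rng.permutation(v)
            vecs.append(v)
        vecs.append(v1_vec)
        Xs = _standardize(np.stack(vecs)).T
        proj = np.linalg.pinv(Xs)
        coef = ys @ proj[t_idx]
        if plan.transform == "fisher":
            acc += fisher_z(coef)
        else:
            g = coef[good]
            acc[good] += (g - g.mean()) / (g.std() or 1.0)
    acc /= plan.n_perm
    acc[skipped] = 0.0
    return acc


def dice(mask1: np.ndarray, mask2: np.ndarray) -> DiceResult:
    """Dice coefficient of two binary maps on the same grid."""
    mask1 = np.asarray(mask1, dtype=bool)
    mask2 = np.asarray(mask2, dtype=bool)
    if mask1.shape != mask2.shape:
        raise ValueError(f"grid mismatch: {mask1.shape} vs {mask2.shape}")
    n1, n2 = int(mask1.sum()), int(mask2.sum())
    nc = int((mask1 & mask2).sum())
    if n1 + n2 == 0:
        warnings.warn("both maps empty; Dice coefficient defined as 0")
        return DiceResult(n_common=0, n_map1=0, n_map2=0, dc=0.0, both_empty=True)
    return DiceResult(n_common=nc, n_map1=n1, n_map2=n2, dc=2.0 * nc / (n1 + n2))


def hierarchy_analysis(subject_tmaps: list[np.ndarray],
                       theoretical: dict[str, RDM], v1_rdm: RDM,
                       sl: Searchlights, thresh: ThresholdSpec,
                       n_perm: int = 100, seed: int = 0) -> dict[str, dict]:
    """Dice overlap of standard vs scrambled group maps per attribute.

    Runs the standard multiple-regression RSA for every subject, then per
    attribute the scrambled analysis (per-subject permutation-averaged z
    maps), applies the same group one-sample t-test plus Monte Carlo
    cluster correction to both, and returns per attribute the two
    ClusterSets and the DiceResult between their significant maps.
    """
    model = dict(theoretical)
    model["v1"] = v1_rdm
    std_maps: list[RSAMap] = [searchlight_rsa(t, model, sl, subject=i)
                              for i, t in enumerate(subject_tmaps)]
    results: dict[str, dict] = {}
    seeds = np.random.SeedSequence(seed).spawn(len(ATTRIBUTES))
    cached = [neural_rdm_vectors(np.asarray(t, dtype=float), sl)
              for t in subject_tmaps]
    for a_idx, attr in enumerate(ATTRIBUTES):
        std_z = np.stack([fisher_z(m.coefs[:, a_idx]) for m in std_maps])
        std_clusters = montecarlo_cluster(std_z, sl.mask, thresh)
        sub_seeds = seeds[a_idx].spawn(len(subject_tmaps))
        scr_z = np.stack([
            scrambled_rsa(t, theoretical, v1_rdm, sl,
                          ScramblePlan(target=attr, n_perm=n_perm,
                                       seed=int(s.generate_state(1)[0] % 2**31)),
                          precomputed=pre)
            for t, s, pre in zip(subject_tmaps, sub_seeds, cached)])
        scr_clusters = montecarlo_cluster(scr_z, sl.mask, thresh)
        dc = dice(std_clusters.significant(thresh.alpha),
                  scr_clusters.significant(thresh.alpha))
        results[attr] = {"dice": dc, "standard": std_clusters,
                         "scrambled": scr_clusters}
    return results
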