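"""Behavioral RDMs and their link to cluster-restricted neural RDMs.

Each attribute's behavioral RDM is built from the mean of the 4 repeated
1-7 ratings per stimulus; the entry for a stimulus pair is the Euclidean
distance of the two scalar means, i.e. their absolute difference.  Within
each RSA-defined cluster, the neural RDM over the cluster's voxels is
correlated (Pearson) with each subject's behavioral RDM; correlations are
Fisher-transformed, tested against zero with a one-sample t-test, and
BH-FDR corrected across clusters.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import fdr_bh
from .rdm import ATTRIBUTES, N_CONDITIONS, RDM, neural_rdm
from .rsa import fisher_z
from .simulate import RatingTable

__all__ = ["behavioral_rdm", "cluster_neural_rdm", "behavior_neural_link",
           "filter_ratings"]


def behavioral_rdm(table: RatingTable, attribute: str, n_reps: int = 4) -> RDM:
    """Euclidean-distance RDM of mean ratings for one attribute."""
    df = table.df[table.df["attribute"] == attribute]
    counts = df.groupby("stimulus_id")["rating"].count()
    bad = [int(s) for s in range(N_CONDITIONS)
           if counts.get(s, 0) != n_reps]
    if bad:
        raise ValueError(f"stimuli with missing repetitions for {attribute!r}: {bad}")
    means = df.groupby("stimulus_id")["rating"].mean().reindex(range(N_CONDITIONS))
    m = means.to_numpy(dtype=float)
    values = np.abs(m[:, None] - m[None, :])
    return RDM(values=values, kind="behavioral")


def cluster_neural_rdm(tmaps: np.ndarray, voxel_indices: np.ndarray,
                       labels=None) -> RDM:
    """Neural RDM (1 - Pearson) over one cluster's masked-voxel indices."""
    voxel_indices = np.asarray(voxel_indices)
    if voxel_indices.size < 2:
        raise ValueError("cluster must contain >= 2 voxels")
    return neural_rdm(np.asarray(tmaps, dtype=float)[:, voxel_indices],
                      labels=labels)


def behavior_neural_link(neural_rdms: dict[int, list[RDM]],
                         behavioral_rdms: list[RDM],
                         cluster_attrs: dict[int, str] | None = None,
                         q: float = 0.05, method: str = "pearson") -> pd.DataFrame:
    """Group test of behavioral-neural RDM correlations per cluster.

    ``neural_rdms[cid]`` holds one cluster RDM per subject; element s of
    ``behavioral_rdms`` is subject s's behavioral RDM for the cluster's
    attribute.  Subjects whose behavioral RDM has zero variance (all
    ratings equal) are excluded with a warning.  Returns one row per
    cluster with the Fisher-z group mean, t, p (one-sided positive), and
    an FDR flag across clusters.
    """
    rows = []
    for cid, nrdms in neural_rdms.items():
        if len(nrdms) != len(behavioral_rdms):
            raise ValueError("neural and behavioral RDM lists differ in length")
        rs, excluded = [], 0
        for nr, br in zip(nrdms, behavioral_rdms):
            bv, nv = br.vector(), nr.vector()
            if bv.std() == 0:
                excluded += 1
                continue
            if method == "spearman":
                rs.append(stats.spearmanr(bv, nv).statistic)
            else:
                rs.append(stats.pearsonr(bv, nv).statistic)
        if excluded:
            warnings.warn(f"cluster {cid}: {excluded} subject(s) excluded "
                          "(zero-variance behavioral RDM)")
        if len(rs) < 2:
            raise ValueError(f"cluster {cid}: fewer than 2 usable subjects")
        z = fisher_z(np.asarray(rs))
        t = z.mean() / (z.std(ddof=1) / np.sqrt(len(z))) if z.std(ddof=1) > 0 \
            else np.sign(z.mean()) * np.inf
        p = float(stats.t.sf(t, len(z) - 1)) if np.isfinite(t) else (
            0.0 if t > 0 else 1.0)
        rows.append({"cluster_id": cid,
                     "attribute": (cluster_attrs or {}).get(cid, ""),
                     "n_subjects": len(z), "mean_r": float(np.mean(rs)),
                     "mean_z": float(z.mean()), "t": float(t), "p": p})
    table = pd.DataFrame(rows)
    table["fdr_significant"] = fdr_bh(table["p"].to_numpy(), q)
    return table


def filter_ratings(tables: list[RatingTable],
                   not_sure_fraction: float = 0.5,
                   sigma: float = 3.0) -> tuple[list[int], pd.DataFrame]:
    """Participant exclusion on rating tables.

    Excludes a participant if (i) any attribute's mean rating deviates more
    than ``sigma`` group SDs from the group mean, or (ii) more than
    ``not_sure_fraction`` of an attribute's trials are the midpoint 4.
    Returns (kept indices, per-subject summary).
    """
    means = np.array([[t.df[t.df.attribute == a]["rating"].mean()
                       for a in ATTRIBUTES] for t in tables])
    frac4 = np.array([[(t.df[t.df.attribute == a]["rating"] == 4).mean()
                       for a in ATTRIBUTES] for t in tables])
    mu, sd = means.mean(axis=0), means.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        zdev = np.abs(means - mu) / np.where(sd > 0, sd, np.inf)
    excluded_sigma = (zdev > sigma).any(axis=1)
    excluded_ns = (frac4 > not_sure_fraction).any(axis=1)
    keep = [i for i in range(len(tables))
            if not (excluded_sigma[i] or excluded_ns[i])]
    summary = pd.DataFrame({
        "subject": range(len(tables)),
        "max_abs_z": zdev.max(axis=1),
        "max_not_sure_fraction": frac4.max(axis=1),
        "excluded_three_sigma": excluded_sigma,
        "excluded_not_sure": excluded_ns,
    })
    return keep, summary
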