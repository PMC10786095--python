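"""Searchlight decoding of the attribute dichotomies.

Each subject contributes 48 beta patterns (8 stimuli x 6 runs); for every
attribute the patterns split 24 vs 24.  Per searchlight, patterns are
demeaned across voxels (removing block amplitude), and a linear SVM
(LIBSVM via scikit-learn, C = 1) is trained and tested with
leave-one-run-out cross-validation; mean fold accuracy is assigned to the
center voxel.  Cluster accuracies (means over the voxels of RSA-defined
clusters) enter one-sample t-tests against chance (0.5) and paired t-tests
between attributes, with BH-FDR per attribute family; the three display
levels mark above-chance / higher-than-one / higher-than-both outcomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .cluster import ClusterSet, fdr_bh
from .rdm import ATTRIBUTES
from .rsa import Searchlights
from .simulate import STIMULUS_LABELS, attribute_signs

__all__ = ["ClassificationSpec", "demean_pattern", "attribute_classes",
           "searchlight_classify", "cluster_accuracy", "accuracy_tests"]


@dataclass(frozen=True)
class ClassificationSpec:
    """Leave-one-run-out linear-SVM decoding of one attribute dichotomy."""

    attribute: str = "gender"
    C: float = 1.0
    demean: bool = True

    def __post_init__(self):
        if self.attribute not in ATTRIBUTES:
            raise ValueError(f"attribute must be one of {ATTRIBUTES}")


def demean_pattern(pattern: np.ndarray) -> np.ndarray:
    """Subtract each pattern's mean over voxels (last axis)."""
    pattern = np.asarray(pattern, dtype=float)
    if pattern.shape[-1] < 2:
        raise ValueError("need >= 2 voxels to demean a pattern")
    return pattern - pattern.mean(axis=-1, keepdims=True)


def attribute_classes(attribute: str, labels=STIMULUS_LABELS) -> np.ndarray:
    """±1 class of each of the 8 stimuli on one attribute dichotomy."""
    return attribute_signs(labels)[attribute]


def _stack_betas(run_betas: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_runs, n_mask, 8) -> samples (48, n_mask), stimulus ids, run ids."""
    n_runs, _, n_stim = run_betas.shape
    samples = np.concatenate([run_betas[r].T for r in range(n_runs)])
    stim = np.tile(np.arange(n_stim), n_runs)
    runs = np.repeat(np.arange(n_runs), n_stim)
    return samples, stim, runs


def searchlight_classify(run_betas: np.ndarray, spec: ClassificationSpec,
                         sl: Searchlights,
                         centers: np.ndarray | None = None) -> np.ndarray:
    """Leave-one-run-out SVM accuracy per searchlight center.

    ``run_betas`` is (n_runs, n_mask, 8).  ``centers`` optionally restricts
    the computation to a subset of masked-voxel indices (the full map is
    the default); returns one accuracy in [0, 1] per requested center.
    Searchlights whose training patterns are all identical in a fold score
    0.5 for that fold with a warning.
    """
    samples, stim, runs = _stack_betas(np.asarray(run_betas, dtype=float))
    y = attribute_classes(spec.attribute)[stim]
    if centers is None:
        centers = np.arange(sl.n_centers)
    centers = np.asarray(centers)
    fold_ids = np.unique(runs)
    acc = np.zeros(len(centers))
    degenerate = 0
    import sklearn

    with sklearn.config_context(assume_finite=True):
        for ci, c in enumerate(centers):
            X = samples[:, sl.neighbors[c]]
            if spec.demean:
                X = demean_pattern(X)
            correct = 0
            total = 0
            for f in fold_ids:
                test = runs == f
                Xtr, ytr = X[~test], y[~test]
                if np.allclose(Xtr, Xtr[0]):
                    degenerate += 1
                    correct += 0.5 * test.sum()
                    total += test.sum()
                    continue
                clf = SVC(kernel="linear", C=spec.C)
                clf.fit(Xtr, ytr)
                pred = clf.predict(X[test])
                correct += (pred == y[test]).sum()
                total += test.sum()
            acc[ci] = correct / total
    if degenerate:
        warnings.warn(f"{degenerate} fold(s) with degenerate training patterns; "
                      "scored at chance")
    return acc


def cluster_accuracy(acc_map: np.ndarray, clusters: ClusterSet,
                     mask: np.ndarray) -> dict[int, float]:
    """Mean accuracy over each cluster's voxels; acc_map is on masked voxels."""
    mask = np.asarray(mask, dtype=bool)
    lin = -np.ones(mask.shape, dtype=int)
    lin[mask] = np.arange(int(mask.sum()))
    out = {}
    for cid in range(1, clusters.n_clusters + 1):
        vox = lin[clusters.labels == cid]
        if vox.size == 0:
            raise ValueError(f"cluster {cid} is empty")
        if np.any(vox < 0):
            raise ValueError(f"cluster {cid} extends outside the mask")
        out[cid] = float(np.mean(acc_map[vox]))
    return out


def accuracy_tests(accuracies: np.ndarray, cluster_attrs: list[str],
                   q: float = 0.05) -> pd.DataFrame:
    """Attribute-specificity tests of per-cluster decoding accuracies.

    ``accuracies`` is (n_subjects, n_clusters, 3) in ATTRIBUTES order;
    ``cluster_attrs[j]`` names the attribute whose RSA map defined cluster
    j.  Per cluster: a one-sided one-sample t-test of the own-attribute
    accuracy against chance 0.5, and one-sided paired t-tests of own vs
    each other attribute; BH-FDR is applied per attribute family (all
    clusters x tests of that attribute).  The display level counts
    (i) above chance, (ii) higher than one other attribute, (iii) higher
    than both.
    """
    acc = np.asarray(accuracies, dtype=float)
    if acc.ndim != 3 or acc.shape[0] < 2 or acc.shape[2] != len(ATTRIBUTES):
        raise ValueError("accuracies must be (n_subjects >= 2, n_clusters, 3)")
    rows = []
    for j, attr in enumerate(cluster_attrs):
        a_idx = ATTRIBUTES.index(attr)
        own = acc[:, j, a_idx]
        t_chance, p_chance = _t_one_sided(own - 0.5)
        row = {"cluster_id": j + 1, "attribute": attr,
               "mean_accuracy": float(own.mean()),
               "t_vs_chance": t_chance, "p_vs_chance": p_chance}
        for other in ATTRIBUTES:
            if other == attr:
                continue
            diff = own - acc[:, j, ATTRIBUTES.index(other)]
            t, p = _t_one_sided(diff)
            row[f"t_vs_{other}"] = t
            row[f"p_vs_{other}"] = p
        rows.append(row)
    table = pd.DataFrame(rows)
    for attr in set(cluster_attrs):
        sel = table["attribute"] == attr
        pcols = [c for c in table.columns if c.startswith("p_")]
        pv = table.loc[sel, pcols].to_numpy().ravel()
        rej = fdr_bh(pv, q).reshape(-1, len(pcols))
        for i, c in enumerate(pcols):
            table.loc[sel, c.replace("p_", "sig_")] = rej[:, i]
    sig_pair = [c for c in table.columns
                if c.startswith("sig_") and c != "sig_vs_chance"]
    levels = []
    for _, r in table.iterrows():
        n_higher = int(sum(bool(r[c]) for c in sig_pair if not pd.isna(r[c])))
        if not r["sig_vs_chance"]:
            levels.append(0)
        elif n_higher >= 2:
            levels.append(3)
        elif n_higher == 1:
            levels.append(2)
        else:
            levels.append(1)
    table["display_level"] = levels
    return table


def _t_one_sided(diff: np.ndarray) -> tuple[float, float]:
    """One-sided (greater) one-sample t on a difference vector."""
    n = len(diff)
    sd = diff.std(ddof=1)
    if sd == 0:
        m = diff.mean()
        if m > 0:
            return float("inf"), 0.0
        if m < 0:
            return float("-inf"), 1.0
        return 0.0, 0.5
    t = diff.mean() / (sd / np.sqrt(n))
    return float(t), float(stats.t.sf(t, n - 1))
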