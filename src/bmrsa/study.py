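"""Study-scale analyses on synthetic groups: the package's headline runs.

These drivers assemble the full method — stimulus generation, V1 model,
BOLD simulation, GLM, searchlight RSA, cluster correction, scrambled-RDM
hierarchy, MVPA, behavioral link — at the study's conditions (20 subjects,
6 runs, 200-voxel searchlights, voxel p = 0.001) on grids small enough for
a desk run.  Problem sizes (20-voxel grids with 7-voxel ROI cubes for RSA,
12-voxel grids with 3-voxel ROIs for decoding, permutation counts at the
test profile) are the package's own scaling choices, documented in the
methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behavior import behavior_neural_link, behavioral_rdm, cluster_neural_rdm
from .cluster import ThresholdSpec, montecarlo_cluster
from .glm import GLMResult, condition_tmaps, make_design_matrix
from .mvpa import ClassificationSpec, accuracy_tests, searchlight_classify
from .rdm import ATTRIBUTES, RDM, theoretical_rdms
from .rsa import (SearchlightSpec, Searchlights, define_searchlights, fisher_z,
                  group_rsa, searchlight_rsa)
from .scramble import dice, hierarchy_analysis
from .simulate import (DesignSpec, EffectSpec, SubjectData, default_effects,
                       simulate_group, simulate_ratings)
from .v1 import stimulus_feature, v1_rdm
from .walker import build_stimulus_set

__all__ = ["design_arithmetic", "StudyRun", "run_rsa_study", "null_fwe_rate",
           "mvpa_recovery_study", "mvpa_permutation_accuracy",
           "behavior_link_null_rate", "behavior_link_planted"]

N_SUBJECTS = 20          # analyzed sample size of the emulated study


def design_arithmetic(seed: int = 0) -> dict:
    """Run-timeline and behavioral-trial arithmetic of the design."""
    from .simulate import STIMULUS_LABELS, build_timeline

    tl = build_timeline(DesignSpec(), seed=seed)
    ratings = simulate_ratings(seed=seed)
    theo = theoretical_rdms(STIMULUS_LABELS)
    vecs = [r.vector() for r in theo.values()]
    cross = [float(np.corrcoef(vecs[i], vecs[j])[0, 1])
             for i in range(3) for j in range(i + 1, 3)]
    return {
        "run_duration_s": tl.total_duration,
        "volumes_per_run": tl.n_volumes,
        "rating_trials": len(ratings.df),
        "between_pairs": int(vecs[0].sum()),
        "within_pairs": int((vecs[0] == 0).sum()),
        "theoretical_rdm_cross_correlation": float(np.mean(cross)),
    }


@dataclass
class StudyRun:
    """Everything computed for one synthetic group at RSA study conditions."""

    effects: EffectSpec
    group: list[SubjectData]
    glms: list[GLMResult]
    searchlights: Searchlights
    theoretical: dict[str, RDM]
    v1: RDM
    hierarchy: dict = field(default_factory=dict)
    recovery: dict = field(default_factory=dict)


def run_rsa_study(seed: int, n_subjects: int = N_SUBJECTS,
                  grid_shape=(20, 20, 20), roi_size: int = 7,
                  interaction: dict | None = None, n_perm: int = 100,
                  n_iter: int = 500, searchlight_k: int = 200,
                  n_frames: int = 6) -> StudyRun:
    """Simulate a group, run RSA + Monte Carlo + hierarchy, score recovery.

    The 7-voxel ROI cubes reflect the searchlight's spatial resolution: a
    200-voxel searchlight has radius ~3.7 voxels, and a center carries
    genuine attribute information whenever its neighborhood intersects the
    ROI, so recovered maps approximate the ROI dilated by up to that
    radius.  ``recovery`` reports, per attribute, Dice against the planted
    ROI, Dice against the searchlight-informed (dilated) support, and the
    fraction of non-ROI mask covered.
    """
    design = DesignSpec()
    effects = default_effects(grid_shape=grid_shape, roi_size=roi_size,
                              interaction=interaction or {}, seed=0)
    group = simulate_group(n_subjects, design, effects, base_seed=seed)
    glms = [condition_tmaps(s.runs, [make_design_matrix(t, n) for t, n in
                                     zip(s.timelines, s.nuisance)])
            for s in group]
    from .simulate import STIMULUS_LABELS

    mask = group[0].mask
    sl = define_searchlights(mask, SearchlightSpec(k=searchlight_k))
    theo = theoretical_rdms(STIMULUS_LABELS)
    stimuli = build_stimulus_set(n_frames=n_frames)
    v1 = v1_rdm([stimulus_feature(s) for s in stimuli],
                labels=tuple(s.label for s in stimuli))
    thresh = ThresholdSpec(n_iter=n_iter, seed=seed + 1)
    hier = hierarchy_analysis([g.tmaps for g in glms], theo, v1, sl, thresh,
                              n_perm=n_perm, seed=seed + 2)
    run = StudyRun(effects=effects, group=group, glms=glms, searchlights=sl,
                   theoretical=theo, v1=v1, hierarchy=hier)
    informed = searchlight_support(sl, effects.roi_masks)
    for attr in ATTRIBUTES:
        sig = hier[attr]["standard"].significant(thresh.alpha)
        roi = effects.roi_masks[attr]
        fp = int((sig & ~roi).sum()) / int((mask & ~roi).sum())
        run.recovery[attr] = {
            "dice_vs_roi": dice(sig, roi).dc,
            "dice_vs_informed_support": dice(sig, informed[attr] & mask).dc,
            "false_positive_coverage": fp,
        }
    return run


def searchlight_support(sl: Searchlights, roi_masks: dict) -> dict:
    """Centers whose searchlight intersects each ROI: the spatial support on
    which a center-assigned searchlight statistic genuinely carries planted
    information (the ROI dilated by the searchlight radius)."""
    out = {}
    lin = -np.ones(sl.mask.shape, dtype=int)
    lin[sl.mask] = np.arange(sl.n_centers)
    for attr, roi in roi_masks.items():
        roi_idx = set(lin[roi & sl.mask].tolist())
        hits = np.array([len(roi_idx.intersection(nb.tolist())) > 0
                         for nb in sl.neighbors])
        grid = np.zeros(sl.mask.shape, dtype=bool)
        grid[sl.mask] = hits
        out[attr] = grid
    return out


def null_fwe_rate(seed: int, n_reps: int = 200, n_subjects: int = N_SUBJECTS,
                  grid_shape=(14, 14, 14), n_iter: int = 500,
                  alpha: float = 0.05) -> dict:
    """Cluster-level family-wise error of the Monte Carlo correction under
    the global null (iid Gaussian subject maps)."""
    from .simulate import make_mask

    _, mask = make_mask(grid_shape, seed=0)
    n_mask = int(mask.sum())
    rng = np.random.default_rng(seed)
    hits = 0
    for rep in range(n_reps):
        maps = rng.standard_normal((n_subjects, n_mask))
        cs = montecarlo_cluster(maps, mask,
                                ThresholdSpec(n_iter=n_iter,
                                              seed=int(rng.integers(2**31))))
        if cs.n_clusters and (cs.pvals < alpha).any():
            hits += 1
    return {"fwe_rate": hits / n_reps, "n_reps": n_reps, "alpha": alpha}


def _mvpa_conditions(seed: int, n_subjects: int, grid_shape=(12, 12, 12),
                     roi_size: int = 3, snr: float = 2.0):
    design = DesignSpec()
    effects = default_effects(grid_shape=grid_shape, roi_size=roi_size,
                              target_pattern_snr=snr, seed=0)
    group = simulate_group(n_subjects, design, effects, base_seed=seed)
    glms = [condition_tmaps(s.runs, [make_design_matrix(t, n) for t, n in
                                     zip(s.timelines, s.nuisance)])
            for s in group]
    mask = group[0].mask
    sl = define_searchlights(mask, SearchlightSpec(k=100))
    lin = -np.ones(mask.shape, dtype=int)
    lin[mask] = np.arange(int(mask.sum()))
    clusters = [(attr, lin[effects.roi_masks[attr] & mask])
                for attr in ATTRIBUTES]
    return effects, group, glms, sl, clusters


def mvpa_recovery_study(seed: int, n_subjects: int = N_SUBJECTS) -> dict:
    """Decode each dichotomy in each planted ROI at high SNR.

    Clusters are the planted ROIs themselves (the regions RSA identifies
    at this SNR); per subject and attribute the searchlight accuracy map
    is evaluated at the cluster voxels and averaged.
    """
    _, _, glms, sl, clusters = _mvpa_conditions(seed, n_subjects)
    centers = np.unique(np.concatenate([v for _, v in clusters]))
    pos = {c: i for i, c in enumerate(centers)}
    acc = np.zeros((n_subjects, len(clusters), len(ATTRIBUTES)))
    for s, res in enumerate(glms):
        for a_idx, attr in enumerate(ATTRIBUTES):
            amap = searchlight_classify(res.run_betas,
                                        ClassificationSpec(attribute=attr),
                                        sl, centers=centers)
            for j, (_, vox) in enumerate(clusters):
                acc[s, j, a_idx] = amap[[pos[v] for v in vox]].mean()
    table = accuracy_tests(acc, [a for a, _ in clusters])
    return {"accuracies": acc, "table": table,
            "cluster_attrs": [a for a, _ in clusters]}


def mvpa_permutation_accuracy(seed: int, n_perms: int = 5,
                              n_centers: int = 40) -> dict:
    """Grand-mean searchlight accuracy after destroying the label-pattern
    link (condition permutation per run); chance is 0.5."""
    _, _, glms, sl, clusters = _mvpa_conditions(seed, n_subjects=2)
    rng = np.random.default_rng(seed + 1)
    betas = glms[0].run_betas
    centers = rng.choice(sl.n_centers, size=n_centers, replace=False)
    accs = []
    for _ in range(n_perms):
        null = np.stack([betas[r][:, rng.permutation(8)]
                         for r in range(betas.shape[0])])
        accs.append(searchlight_classify(null, ClassificationSpec("gender"),
                                         sl, centers=centers).mean())
    n_trials = n_perms * 48
    return {"mean_accuracy": float(np.mean(accs)),
            "ci_halfwidth": 1.96 * float(np.sqrt(0.25 / n_trials))}


def behavior_link_null_rate(seed: int, n_reps: int = 100,
                            n_subjects: int = N_SUBJECTS,
                            n_clusters: int = 3, q: float = 0.05) -> dict:
    """Fraction of null experiments (slope-0 ratings, noise-only neural
    RDMs) with any FDR-surviving behavioral-neural link."""
    rng = np.random.default_rng(seed)
    hits = 0
    used = 0
    for _ in range(n_reps):
        neural = {c + 1: [cluster_neural_rdm(rng.standard_normal((8, 30)),
                                             np.arange(30))
                          for _ in range(n_subjects)]
                  for c in range(n_clusters)}
        beh = [behavioral_rdm(simulate_ratings(slope=0.0, criterion_sd=1.0,
                                               seed=rng), "gender")
               for _ in range(n_subjects)]
        try:
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                table = behavior_neural_link(neural, beh, q=q)
        except ValueError:
            continue
        used += 1
        if table["fdr_significant"].any():
            hits += 1
    return {"fp_rate": hits / used, "n_reps": used, "q": q}


def behavior_link_planted(seed: int, n_subjects: int = N_SUBJECTS) -> dict:
    """Positive control: ratings driven by the planted attribute, neural
    cluster patterns planted on the same attribute."""
    from .simulate import attribute_signs

    rng = np.random.default_rng(seed)
    signs = attribute_signs()["gender"]
    neural = {1: []}
    beh = []
    for _ in range(n_subjects):
        w = rng.standard_normal(30)
        patterns = np.outer(signs, w) + 0.8 * rng.standard_normal((8, 30))
        neural[1].append(cluster_neural_rdm(patterns, np.arange(30)))
        beh.append(behavioral_rdm(simulate_ratings(slope=1.5, criterion_sd=1.0,
                                                   seed=rng), "gender"))
    table = behavior_neural_link(neural, beh, {1: "gender"})
    return {"table": table, "mean_r": float(table.loc[0, "mean_r"]),
            "p": float(table.loc[0, "p"])}
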