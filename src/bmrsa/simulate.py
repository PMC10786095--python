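"""Synthetic block-design fMRI acquisition and behavioral ratings.

Emulates the study's conditions: 6 runs of 24 twelve-second stimulus
blocks (each of the 8 stimuli three times per run, seeded random order)
interleaved with 6-s fixations, TR = 2 s, 219 volumes and 438 s per run;
and a 96-trial behavioral table (8 stimuli x 3 attributes x 4 repetitions,
ratings 1-7).  Planted effects live in per-attribute ROIs with voxel-wise
Gaussian gain heterogeneity (``pattern_sd``) so they are visible both to
correlation-based RDMs and to pattern classifiers; BOLD series are
double-gamma-HRF-convolved boxcars plus AR(1) Gaussian noise, slow drift,
and a nuisance-coupled component.

The run arithmetic (24 x 12 s + 25 x 6 s = 438 s) is realized as one
leading fixation plus a fixation after every stimulus block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.signal import lfilter

from .rdm import ATTRIBUTES
from .walker import StimulusLabel

__all__ = ["DesignSpec", "Timeline", "EffectSpec", "SubjectData", "RatingTable",
           "STIMULUS_LABELS", "attribute_signs", "double_gamma_hrf",
           "build_timeline", "stimulus_regressors", "make_mask", "default_rois",
           "default_effects", "calibrate_noise_sd", "plant_amplitudes",
           "simulate_run", "simulate_subject", "simulate_group",
           "simulate_ratings"]

# Fixed stimulus order (facing outer, gender, emotion inner), matching
# walker.build_stimulus_set.
STIMULUS_LABELS = tuple(
    StimulusLabel(f, g, e)
    for f in ("left", "right") for g in ("female", "male") for e in ("happy", "sad")
)

_NEG_POLE = {"facing": "left", "gender": "female", "emotion": "happy"}


def attribute_signs(labels=STIMULUS_LABELS) -> dict[str, np.ndarray]:
    """±1 category coding per attribute for each of the 8 stimuli."""
    out = {}
    for a, attr in enumerate(ATTRIBUTES):
        out[attr] = np.array([-1.0 if l[a] == _NEG_POLE[attr] else 1.0
                              for l in labels])
    return out


# ---------------------------------------------------------------------------
# Design / timeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignSpec:
    """Block-design acquisition parameters (defaults are the study's)."""

    tr: float = 2.0
    n_runs: int = 6
    blocks_per_run: int = 24
    block_duration: float = 12.0
    fixation_duration: float = 6.0
    reps_per_stimulus_per_run: int = 3
    leading_fixation: bool = True

    def __post_init__(self):
        if self.blocks_per_run != 8 * self.reps_per_stimulus_per_run:
            raise ValueError("blocks_per_run must equal 8 x reps_per_stimulus_per_run")
        for name in ("block_duration", "fixation_duration"):
            d = getattr(self, name)
            if abs(d / self.tr - round(d / self.tr)) > 1e-9:
                raise ValueError(f"{name}={d} is not an integer multiple of tr={self.tr}")


@dataclass
class Timeline:
    """Ordered run events tiling [0, total_duration] with no gaps.

    Each event is (stimulus_id | None, onset_s, duration_s); None marks
    fixation.  n_volumes = total_duration / tr exactly.
    """

    events: list[tuple[int | None, float, float]]
    total_duration: float
    n_volumes: int
    tr: float

    def stimulus_onsets(self, stimulus_id: int) -> list[tuple[float, float]]:
        return [(on, dur) for sid, on, dur in self.events if sid == stimulus_id]


def build_timeline(spec: DesignSpec, seed: int | np.random.Generator = 0) -> Timeline:
    """Seeded random block order: each stimulus exactly 3 times per run."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    order = np.repeat(np.arange(8), spec.reps_per_stimulus_per_run)
    rng.shuffle(order)
    events: list[tuple[int | None, float, float]] = []
    t = 0.0
    if spec.leading_fixation:
        events.append((None, t, spec.fixation_duration))
        t += spec.fixation_duration
    for sid in order:
        events.append((int(sid), t, spec.block_duration))
        t += spec.block_duration
        events.append((None, t, spec.fixation_duration))
        t += spec.fixation_duration
    n_vol = t / spec.tr
    if abs(n_vol - round(n_vol)) > 1e-9:
        raise ValueError("run duration is not an integer number of volumes")
    return Timeline(events=events, total_duration=t, n_volumes=int(round(n_vol)),
                    tr=spec.tr)


def double_gamma_hrf(t: np.ndarray, peak_delay: float = 6.0,
                     undershoot_delay: float = 16.0, peak_disp: float = 1.0,
                     undershoot_disp: float = 1.0, ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response (peak 6 s, undershoot 16 s),
    normalized to unit peak."""
    from scipy.stats import gamma

    t = np.asarray(t, dtype=float)
    h = (gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
         - ratio * gamma.pdf(t, undershoot_delay / undershoot_disp,
                             scale=undershoot_disp))
    return h / h.max()


def stimulus_regressors(timeline: Timeline, oversample: int = 16) -> np.ndarray:
    """HRF-convolved per-stimulus boxcars sampled at volume times, (8, n_volumes)."""
    dt = timeline.tr / oversample
    n_fine = int(round(timeline.total_duration / dt))
    hrf = double_gamma_hrf(np.arange(0, 32.0, dt))
    out = np.zeros((8, timeline.n_volumes))
    for sid in range(8):
        box = np.zeros(n_fine)
        for onset, dur in timeline.stimulus_onsets(sid):
            box[int(round(onset / dt)): int(round((onset + dur) / dt))] = 1.0
        conv = np.convolve(box, hrf)[:n_fine] * dt
        out[sid] = conv[::oversample][: timeline.n_volumes]
    return out


# ---------------------------------------------------------------------------
# Effects and ROIs
# ---------------------------------------------------------------------------

@dataclass
class EffectSpec:
    """Planted ground truth and noise model for one synthetic group.

    effect_size is in the same units as baseline (baseline 100 makes an
    effect of 1 a 1% signal change).  pattern_sd is the SD of the voxel-wise
    Gaussian gain on each attribute effect (N(1, pattern_sd)); without it a
    spatially uniform effect would be invisible to pattern-centering RDMs.
    interaction[(a, b)] plants a product-coded component (sign_a x sign_b)
    with its own gain map in the union of the two ROIs.
    """

    grid_shape: tuple[int, int, int] = (20, 20, 20)
    roi_masks: dict = field(default_factory=dict)          # attr -> 3D bool
    effect_size: dict = field(default_factory=dict)        # attr -> amplitude
    interaction: dict = field(default_factory=dict)        # (a, b) -> coupling
    pattern_sd: float = 1.0
    idiosyncratic_sd: float = 0.0
    noise_sd: float = 1.0
    ar1: float = 0.3
    drift: float = 1.0
    nuisance_coupling: float = 0.05
    baseline: float = 100.0
    subject_effect_sd: float = 0.0
    allow_roi_overlap: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.ar1 < 1:
            raise ValueError("ar1 must be in [0, 1)")
        for v in self.effect_size.values():
            if not np.isfinite(v):
                raise ValueError("effect sizes must be finite")
        if self.roi_masks and not self.allow_roi_overlap:
            total = sum(m.astype(int) for m in self.roi_masks.values())
            if np.any(total > 1):
                raise ValueError(
                    "ROIs overlap; set allow_roi_overlap=True to combine "
                    "their effects additively")


def make_mask(grid_shape: tuple[int, int, int], threshold: float = 0.2,
              seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic tissue-probability grid and its thresholded binary mask.

    A smooth radial probability (analog of a gray-matter probability map)
    thresholded at 0.2, mirroring absolute-threshold masking.
    """
    rng = np.random.default_rng(seed)
    grids = np.meshgrid(*[np.linspace(-1, 1, s) for s in grid_shape], indexing="ij")
    r2 = sum(g ** 2 for g in grids)
    prob = np.exp(-r2 / (2 * 0.7 ** 2))
    prob = np.clip(prob + gaussian_filter(rng.normal(0, 0.25, grid_shape), 2.0), 0, 1)
    return prob, prob >= threshold


def default_rois(grid_shape: tuple[int, int, int], size: int = 5) -> dict[str, np.ndarray]:
    """Three disjoint cubic ROIs in the mask interior, one per attribute."""
    nx, ny, nz = grid_shape
    out = {}
    h = size // 2

    def clamp(c, n):
        return min(max(c, h + 1), n - h - 2)

    # Disjoint by construction: facing/gender separated along x, emotion
    # separated from both along y; all on the central z plane where the
    # tissue-probability mask is densest, clamped one voxel off the edge.
    centers = {
        "facing": (clamp(nx // 4, nx), clamp(ny // 4, ny), nz // 2),
        "gender": (clamp(3 * nx // 4, nx), clamp(ny // 4, ny), nz // 2),
        "emotion": (clamp(nx // 2, nx), clamp(3 * ny // 4, ny), nz // 2),
    }
    for attr, (cx, cy, cz) in centers.items():
        m = np.zeros(grid_shape, dtype=bool)
        m[cx - h: cx - h + size, cy - h: cy - h + size, cz - h: cz - h + size] = True
        out[attr] = m
    return out


def calibrate_noise_sd(design: DesignSpec, effect_size: float = 1.0,
                       pattern_sd: float = 1.0,
                       target_pattern_snr: float = 0.5) -> float:
    """Per-volume noise SD yielding a target t-pattern SNR for a planted effect.

    Pattern SNR is the SD of the planted condition amplitudes across ROI
    voxels (effect_size * pattern_sd) divided by the standard error of a
    condition beta from the concatenated 6-run design, the scale on which
    the RSA t-patterns live.  Computed from the design matrix alone.
    """
    from .glm import make_design_matrix, concatenated_design

    tls = [build_timeline(design, seed=r) for r in range(design.n_runs)]
    dms = [make_design_matrix(tl, nuisance=np.zeros((0, tl.n_volumes))) for tl in tls]
    X, stim_cols = concatenated_design(dms)
    inv = np.linalg.inv(X.T @ X)
    se_unit = float(np.sqrt(np.mean(np.diag(inv)[stim_cols])))  # SE per unit noise_sd
    return effect_size * pattern_sd / (target_pattern_snr * se_unit)


def default_effects(grid_shape=(16, 16, 16), effect_size: float = 1.0,
                    design: DesignSpec = DesignSpec(), roi_size: int = 5,
                    target_pattern_snr: float = 0.5, **kw) -> EffectSpec:
    """Study-condition effects: 3 disjoint ROIs, 1% signal effects, noise
    calibrated to the target t-pattern SNR."""
    noise_sd = kw.pop("noise_sd", None)
    if noise_sd is None:
        noise_sd = calibrate_noise_sd(design, effect_size,
                                      kw.get("pattern_sd", 1.0), target_pattern_snr)
    return EffectSpec(grid_shape=grid_shape,
                      roi_masks=default_rois(grid_shape, roi_size),
                      effect_size={a: effect_size for a in ATTRIBUTES},
                      noise_sd=noise_sd, **kw)


def plant_amplitudes(effects: EffectSpec, mask: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """True per-voxel, per-stimulus amplitudes on masked voxels, (n_mask, 8).

    amplitude(v, s) = baseline
                    + sum_attr [v in ROI_attr] * effect_attr * gain_attr(v) * sign_s(attr)
                    + sum_(a,b) [v in ROI_a u ROI_b] * c_ab * gain_ab(v) * sign_s(a) * sign_s(b)
                    + idiosyncratic jitter (within any ROI).
    """
    for attr, roi in effects.roi_masks.items():
        if np.any(roi & ~mask):
            raise ValueError(f"ROI {attr!r} extends outside the analysis mask")
    missing = set(effects.effect_size) - set(effects.roi_masks)
    if missing:
        raise ValueError(f"effects planted without an ROI: {sorted(missing)}")
    signs = attribute_signs()
    n_mask = int(mask.sum())
    amp = np.full((n_mask, 8), effects.baseline)
    for attr, e in effects.effect_size.items():
        roi_v = effects.roi_masks[attr][mask]
        gain = rng.normal(1.0, effects.pattern_sd, n_mask)
        amp += np.outer(roi_v * gain * e, signs[attr])
    for (a, b), c in effects.interaction.items():
        roi_v = (effects.roi_masks[a] | effects.roi_masks[b])[mask]
        gain = rng.normal(1.0, effects.pattern_sd, n_mask)
        amp += np.outer(roi_v * gain * c, signs[a] * signs[b])
    if effects.idiosyncratic_sd > 0 and effects.roi_masks:
        any_roi = np.zeros(n_mask, dtype=bool)
        for roi in effects.roi_masks.values():
            any_roi |= roi[mask]
        amp[any_roi] += rng.normal(0.0, effects.idiosyncratic_sd,
                                   (int(any_roi.sum()), 8))
    return amp


# ---------------------------------------------------------------------------
# BOLD simulation
# ---------------------------------------------------------------------------

def _motion_regressors(n_volumes: int, rng: np.random.Generator) -> np.ndarray:
    """Six smooth synthetic head-motion traces, standardized, (6, T)."""
    walk = np.cumsum(rng.normal(0, 1, (6, n_volumes)), axis=1)
    walk = gaussian_filter1d(walk, sigma=3.0, axis=1)
    walk -= walk.mean(axis=1, keepdims=True)
    walk /= walk.std(axis=1, keepdims=True)
    return walk


def simulate_run(timeline: Timeline, amplitudes: np.ndarray, effects: EffectSpec,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One run: (series (n_mask, T) float32, nuisance (6, T)).

    The series is a constant baseline level plus evoked responses: the
    planted amplitude map carries ``baseline + evoked``, so the evoked
    amplitude (amplitudes - baseline) scales each stimulus's HRF-convolved
    boxcar and the baseline enters as a constant.  Noise is stationary
    AR(1) with marginal SD ``noise_sd``; drift is a random
    linear-plus-cosine trend scaled by ``drift``; a small nuisance-coupled
    component ties the series to the motion regressors.
    """
    regs = stimulus_regressors(timeline)                    # (8, T)
    T = timeline.n_volumes
    evoked = np.asarray(amplitudes, dtype=float) - effects.baseline
    series = effects.baseline + evoked @ regs               # (V, T)
    V = series.shape[0]
    if effects.noise_sd > 0:
        innov = rng.normal(0.0, effects.noise_sd * np.sqrt(1 - effects.ar1 ** 2),
                           (V, T))
        innov[:, 0] = rng.normal(0.0, effects.noise_sd, V)
        series += lfilter([1.0], [1.0, -effects.ar1], innov, axis=1)
    tt = np.linspace(-1, 1, T)
    if effects.drift > 0:
        basis = np.stack([tt, np.cos(np.pi * (tt + 1))])
        series += effects.drift * rng.normal(0, 1, (V, 2)) @ basis
    nuisance = _motion_regressors(T, rng)
    if effects.nuisance_coupling > 0:
        series += effects.nuisance_coupling * rng.normal(0, 1, (V, 6)) @ nuisance
    if not np.all(np.isfinite(series)):
        raise FloatingPointError("simulated series contains non-finite values")
    return series.astype(np.float32), nuisance


@dataclass
class SubjectData:
    """One synthetic participant: runs, mask, timelines, nuisance, truth."""

    runs: list[np.ndarray]               # per-run (n_mask, T) float32
    mask: np.ndarray                     # 3D bool
    tissue_prob: np.ndarray              # 3D float
    timelines: list[Timeline]
    nuisance: list[np.ndarray]           # per-run (6, T)
    truth: np.ndarray                    # (n_mask, 8) planted amplitudes
    effects: EffectSpec
    subject: int = 0

    @property
    def n_mask(self) -> int:
        return int(self.mask.sum())

    def run_volume(self, run: int) -> np.ndarray:
        """Reconstruct the 4D (x, y, z, t) grid series of one run."""
        series = self.runs[run]
        out = np.zeros(self.mask.shape + (series.shape[1],), dtype=np.float32)
        out[self.mask] = series
        return out


def simulate_subject(design: DesignSpec, effects: EffectSpec,
                     seed: int | np.random.SeedSequence = 0,
                     subject: int = 0) -> SubjectData:
    """Simulate all runs of one participant from a single seed."""
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rng = np.random.default_rng(ss)
    _, mask = make_mask(effects.grid_shape, seed=effects.seed)
    prob, _ = make_mask(effects.grid_shape, seed=effects.seed)
    eff = effects
    if effects.subject_effect_sd > 0:
        scale = max(0.0, 1.0 + rng.normal(0, effects.subject_effect_sd))
        eff = replace(effects,
                      effect_size={a: e * scale for a, e in effects.effect_size.items()})
    truth = plant_amplitudes(eff, mask, rng)
    runs, timelines, nuisance = [], [], []
    for _ in range(design.n_runs):
        tl = build_timeline(design, rng)
        series, nuis = simulate_run(tl, truth, eff, rng)
        runs.append(series)
        timelines.append(tl)
        nuisance.append(nuis)
    return SubjectData(runs=runs, mask=mask, tissue_prob=prob, timelines=timelines,
                       nuisance=nuisance, truth=truth, effects=eff, subject=subject)


def simulate_group(n_subjects: int, design: DesignSpec, effects: EffectSpec,
                   base_seed: int = 0) -> list[SubjectData]:
    """Independent subjects (default group size mirrors the analyzed n = 20);
    ROI geometry is shared via the EffectSpec."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    seeds = np.random.SeedSequence(base_seed).spawn(n_subjects)
    return [simulate_subject(design, effects, seed=s, subject=i)
            for i, s in enumerate(seeds)]


# ---------------------------------------------------------------------------
# Behavioral ratings
# ---------------------------------------------------------------------------

@dataclass
class RatingTable:
    """96 behavioral trials: 8 stimuli x 3 attributes x 4 repetitions, 1-7."""

    df: pd.DataFrame

    def __post_init__(self):
        required = {"stimulus_id", "attribute", "repetition", "rating"}
        if not required <= set(self.df.columns):
            raise ValueError(f"rating table needs columns {sorted(required)}")
        if not self.df["rating"].isin(range(1, 8)).all():
            raise ValueError("ratings must be integers in 1..7")

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def simulate_ratings(labels=STIMULUS_LABELS, slope: float = 1.5,
                     criterion_sd: float = 1.0,
                     seed: int | np.random.Generator = 0,
                     n_reps: int = 4) -> RatingTable:
    """Semantic-differential ratings around the scale midpoint.

    rating = clamp(round(4 + slope * sign(attribute level) + noise), 1, 7).
    Defaults (slope 1.5, criterion SD 1.0) emulate raters who discriminate
    every attribute reliably but not at ceiling.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    signs = attribute_signs(labels)
    rows = []
    for attr in ATTRIBUTES:
        for sid, label in enumerate(labels):
            for rep in range(1, n_reps + 1):
                raw = 4.0 + slope * signs[attr][sid] + rng.normal(0, criterion_sd)
                rows.append({"stimulus_id": sid, "facing": label[0],
                             "gender": label[1], "emotion": label[2],
                             "attribute": attr, "repetition": rep,
                             "rating": int(np.clip(np.round(raw), 1, 7))})
    return RatingTable(df=pd.DataFrame(rows))
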