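"""Parametric point-light walker stimuli.

A linear morphable walker stands in for motion-capture morph spaces used in
biological-motion research: a 15-joint sinusoidal skeleton in 3D body
coordinates (x lateral, y vertical, z anterior), plus additive gender and
emotion axes scaled in "standard deviation" morph units, orthographically
projected at the facing azimuth.  The eight experimental stimuli cross
facing (left/right view), gender (female/male, ±6 SD) and emotional state
(happy/sad, ±6 SD).

Facing geometry: "right" is rendered at azimuth −45° and "left" at +135°.
Because cos(135°) = −cos(−45°) and sin(135°) = −sin(−45°), the projected
x-coordinates of the two views are exact mirror images frame-by-frame even
though each view is a true 3D rotation (orthographic projection cannot
distinguish a −45° view from the mirrored +135° view).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

__all__ = [
    "WalkerParams",
    "DotTrajectory",
    "FrameStack",
    "StimulusLabel",
    "JOINT_NAMES",
    "make_walker",
    "render_frames",
    "build_stimulus_set",
    "write_trajectory_tsv",
    "write_framestack_tiff",
    "write_labels_json",
    "OutOfBoundsError",
]

JOINT_NAMES = (
    "head", "sternum", "pelvis",
    "l_shoulder", "r_shoulder", "l_elbow", "r_elbow", "l_wrist", "r_wrist",
    "l_hip", "r_hip", "l_knee", "r_knee", "l_ankle", "r_ankle",
)

N_DOTS = 15

# Azimuths (degrees) chosen so the two projected views are mirror pairs.
_AZIMUTH_DEG = {"right": -45.0, "left": 135.0}


class OutOfBoundsError(ValueError):
    """A dot falls outside the rendering canvas."""


class StimulusLabel(NamedTuple):
    facing: str   # 'left' | 'right'
    gender: str   # 'female' | 'male'
    emotion: str  # 'happy' | 'sad'

    @property
    def name(self) -> str:
        return f"{self.facing[0].upper()}{self.gender[0].upper()}{self.emotion[0].upper()}"


@dataclass(frozen=True)
class WalkerParams:
    """Morph parameters of one walker.

    gender_level / emotion_level are in SD units on the morph axes
    (the study uses ±6); 0/0 is the average walker.
    """

    facing: str = "right"
    gender_level: float = 0.0
    emotion_level: float = 0.0
    cycle_duration: float = 1.0
    n_dots: int = N_DOTS

    def __post_init__(self):
        if self.facing not in ("left", "right"):
            raise ValueError(f"facing must be 'left' or 'right', got {self.facing!r}")
        if self.n_dots != N_DOTS:
            raise ValueError(f"walker skeleton has exactly {N_DOTS} dots")
        if not self.cycle_duration > 0:
            raise ValueError("cycle_duration must be positive")
        if not (np.isfinite(self.gender_level) and np.isfinite(self.emotion_level)):
            raise ValueError("morph levels must be finite")


@dataclass
class DotTrajectory:
    """Image-plane dot positions, (n_frames, 15, 2) in normalized units."""

    positions: np.ndarray
    frame_rate: float
    params: WalkerParams

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


@dataclass
class FrameStack:
    """Rendered grayscale frames, (height, width, n_frames), intensities in [0, 1]."""

    images: np.ndarray
    dot_radius: float
    label: StimulusLabel | None = None

    @property
    def n_frames(self) -> int:
        return self.images.shape[2]


# ---------------------------------------------------------------------------
# 3D skeleton model
# ---------------------------------------------------------------------------

# Mean standing pose, (x lateral, y vertical, z anterior), body height ~1.
_MEAN_POSE = np.array([
    [0.000, 0.930, 0.010],   # head
    [0.000, 0.720, 0.020],   # sternum
    [0.000, 0.500, 0.000],   # pelvis
    [-0.110, 0.700, 0.000],  # l_shoulder
    [0.110, 0.700, 0.000],   # r_shoulder
    [-0.130, 0.550, 0.010],  # l_elbow
    [0.130, 0.550, 0.010],   # r_elbow
    [-0.140, 0.410, 0.020],  # l_wrist
    [0.140, 0.410, 0.020],   # r_wrist
    [-0.060, 0.480, 0.000],  # l_hip
    [0.060, 0.480, 0.000],   # r_hip
    [-0.070, 0.260, 0.010],  # l_knee
    [0.070, 0.260, 0.010],   # r_knee
    [-0.080, 0.030, 0.000],  # l_ankle
    [0.080, 0.030, 0.000],   # r_ankle
])

_LEFT_LIMB = np.array([3, 5, 7, 9, 11, 13])
_RIGHT_LIMB = np.array([4, 6, 8, 10, 12, 14])
_TORSO = np.array([0, 1, 2])
_ARMS = np.array([5, 6, 7, 8])        # elbows + wrists
_WRISTS = np.array([7, 8])
_LEGS = np.array([11, 12, 13, 14])    # knees + ankles
_ANKLES = np.array([13, 14])


def _mean_motion(phase: np.ndarray) -> np.ndarray:
    """Gait displacement of the average walker at phase φ (radians).

    Right limbs lead at phase φ, left limbs at φ+π; vertical bounce at 2φ.
    Returns (len(phase), 15, 3).
    """
    p = np.asarray(phase, dtype=float)
    disp = np.zeros((p.size, N_DOTS, 3))
    swing_r = np.sin(p)
    swing_l = np.sin(p + np.pi)
    # Legs: anterior-posterior swing, ankles larger than knees.
    disp[:, 13, 2] += 0.10 * swing_l
    disp[:, 14, 2] += 0.10 * swing_r
    disp[:, 11, 2] += 0.05 * swing_l
    disp[:, 12, 2] += 0.05 * swing_r
    # Stance-leg lift: ankles rise during swing phase.
    disp[:, 13, 1] += 0.030 * np.maximum(0.0, np.sin(p + np.pi))
    disp[:, 14, 1] += 0.030 * np.maximum(0.0, np.sin(p))
    # Arms swing counter to the ipsilateral leg.
    disp[:, 7, 2] += 0.08 * swing_r
    disp[:, 8, 2] += 0.08 * swing_l
    disp[:, 5, 2] += 0.04 * swing_r
    disp[:, 6, 2] += 0.04 * swing_l
    # Torso bounce (double frequency) and lateral sway.
    disp[:, _TORSO, 1] += (0.012 * np.cos(2 * p))[:, None]
    disp[:, _TORSO, 0] += (0.015 * np.sin(p))[:, None]
    return disp


def _gender_axis(phase: np.ndarray) -> np.ndarray:
    """Structural/dynamic displacement per +1 SD toward 'male'.

    Broader shoulders, narrower hips, larger lateral upper-body sway.
    Returns (len(phase), 15, 3).
    """
    p = np.asarray(phase, dtype=float)
    ax = np.zeros((p.size, N_DOTS, 3))
    ax[:, 3, 0] -= 0.006
    ax[:, 4, 0] += 0.006
    ax[:, [5, 7], 0] -= 0.004
    ax[:, [6, 8], 0] += 0.004
    ax[:, 9, 0] += 0.003
    ax[:, 10, 0] -= 0.003
    ax[:, [0, 1], 0] += (0.004 * np.sin(p))[:, None]   # shoulder sway
    return ax


def _emotion_axis(phase: np.ndarray) -> np.ndarray:
    """Displacement per +1 SD toward 'happy'.

    More vertical bounce, upright/forward head, larger arm swing.
    Returns (len(phase), 15, 3).
    """
    p = np.asarray(phase, dtype=float)
    ax = np.zeros((p.size, N_DOTS, 3))
    ax[:, :, 1] += (0.003 * np.cos(2 * p))[:, None]    # bounce amplitude
    ax[:, 0, 1] += 0.004                               # head held higher
    ax[:, [0, 1], 2] += 0.003                          # torso forward lean
    ax[:, 7, 2] += 0.004 * np.sin(p)                   # arm swing amplitude
    ax[:, 8, 2] += 0.004 * np.sin(p + np.pi)
    return ax


def skeleton_3d(t: np.ndarray, params: WalkerParams) -> np.ndarray:
    """3D joint positions at times ``t`` (seconds), shape (len(t), 15, 3).

    Morph axes are applied additively before any projection, so morphing is
    linear in (gender_level, emotion_level).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    phase = 2.0 * np.pi * t / params.cycle_duration
    pos = _MEAN_POSE[None, :, :] + _mean_motion(phase)
    pos = pos + params.gender_level * _gender_axis(phase)
    pos = pos + params.emotion_level * _emotion_axis(phase)
    return pos


def project(points3d: np.ndarray, facing: str) -> np.ndarray:
    """Orthographic projection at the facing azimuth; (..., 3) -> (..., 2)."""
    theta = np.deg2rad(_AZIMUTH_DEG[facing])
    x = points3d[..., 0] * np.cos(theta) + points3d[..., 2] * np.sin(theta)
    y = points3d[..., 1]
    return np.stack([x, y], axis=-1)


def make_walker(params: WalkerParams, n_frames: int) -> DotTrajectory:
    """Sample one gait cycle at ``n_frames`` equally spaced frames.

    Frame i is at t = i * cycle_duration / n_frames, so the sequence is
    periodic with period ``cycle_duration`` by construction.
    """
    if not isinstance(n_frames, (int, np.integer)) or n_frames < 2:
        raise ValueError(f"n_frames must be an integer >= 2, got {n_frames!r}")
    t = np.arange(n_frames) * params.cycle_duration / n_frames
    pts = project(skeleton_3d(t, params), params.facing)
    # Center laterally on the time-averaged mean-walker midline (a constant,
    # not data-dependent, so the left/right mirror relation is preserved).
    pts = pts - np.array([0.0, 0.48])
    return DotTrajectory(positions=pts, frame_rate=n_frames / params.cycle_duration,
                         params=params)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

# Stimulus window aspect: 6.9° tall x 3.9° wide.
WINDOW_DEG = (6.9, 3.9)


def render_frames(traj: DotTrajectory, image_size: tuple[int, int] = (128, 72),
                  dot_radius: float = 1.5, label: StimulusLabel | None = None,
                  jitter_px: tuple[float, float] = (0.0, 0.0)) -> FrameStack:
    """Render white dots on black as truncated Gaussian blobs.

    image_size is (height, width); its aspect should match the 6.9°x3.9°
    stimulus window.  Each dot is an isotropic Gaussian of scale
    ``dot_radius`` pixels truncated at 4 sigma; dots closer than 4 sigma to
    an edge raise :class:`OutOfBoundsError` naming the frame and dot.
    """
    h, w = image_size
    pos = traj.positions
    # The walker (height ~1 unit) fills ~80% of the window height.
    scale = 0.8 * h
    col = pos[:, :, 0] * scale + (w - 1) / 2.0 + jitter_px[1]
    row = (h - 1) / 2.0 - pos[:, :, 1] * scale + jitter_px[0]

    margin = 4.0 * dot_radius
    bad = (row < margin) | (row > h - 1 - margin) | (col < margin) | (col > w - 1 - margin)
    if bad.any():
        f, d = np.argwhere(bad)[0]
        raise OutOfBoundsError(
            f"dot {d} ({JOINT_NAMES[d]}) in frame {f} falls within {margin:.1f} px "
            f"of the {h}x{w} canvas edge")

    n_frames = pos.shape[0]
    images = np.zeros((h, w, n_frames))
    half = int(np.ceil(margin))
    win = np.arange(-half, half + 1)
    dy, dx = np.meshgrid(win, win, indexing="ij")
    for f in range(n_frames):
        for d in range(pos.shape[1]):
            r0, c0 = int(round(row[f, d])), int(round(col[f, d]))
            rr = r0 + win
            cc = c0 + win
            g = np.exp(-(((rr[:, None] - row[f, d]) ** 2 + (cc[None, :] - col[f, d]) ** 2)
                         / (2.0 * dot_radius ** 2)))
            g[dy ** 2 + dx ** 2 > margin ** 2] = 0.0
            images[np.ix_(rr, cc, [f])] += g[:, :, None]
    np.clip(images, 0.0, 1.0, out=images)
    return FrameStack(images=images, dot_radius=dot_radius, label=label)


def build_stimulus_set(gender_sd: float = 6.0, emotion_sd: float = 6.0,
                       n_frames: int = 30, image_size: tuple[int, int] = (128, 72),
                       dot_radius: float = 1.5) -> list[FrameStack]:
    """The eight stimuli of the 2 (facing) x 2 (gender) x 2 (emotion) cross.

    Gender/emotion morph magnitudes are in SD units (the study uses ±6).
    Female/happy are the negative poles on their axes.  Returns the stimuli
    in a fixed label order (facing outer, gender middle, emotion inner).
    """
    if gender_sd < 0 or emotion_sd < 0:
        raise ValueError("morph SD magnitudes must be non-negative")
    out = []
    for facing in ("left", "right"):
        for gender in ("female", "male"):
            for emotion in ("happy", "sad"):
                params = WalkerParams(
                    facing=facing,
                    gender_level=gender_sd if gender == "male" else -gender_sd,
                    emotion_level=-emotion_sd if emotion == "happy" else emotion_sd,
                )
                traj = make_walker(params, n_frames)
                out.append(render_frames(traj, image_size, dot_radius,
                                         label=StimulusLabel(facing, gender, emotion)))
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_trajectory_tsv(traj: DotTrajectory, path: str | Path) -> None:
    """Per-frame dot coordinates as TSV (frame, dot_id, x, y)."""
    with open(path, "w") as fh:
        fh.write("frame\tdot_id\tx\ty\n")
        for f in range(traj.n_frames):
            for d in range(traj.positions.shape[1]):
                x, y = traj.positions[f, d]
                fh.write(f"{f}\t{d}\t{x:.6f}\t{y:.6f}\n")


def write_framestack_tiff(stack: FrameStack, path: str | Path) -> None:
    """Multi-frame grayscale TIFF (frames as pages, uint8)."""
    import tifffile

    pages = np.moveaxis((stack.images * 255).astype(np.uint8), 2, 0)
    tifffile.imwrite(str(path), pages)


def write_labels_json(stimuli: list[FrameStack], path: str | Path) -> None:
    labels = [dict(stimulus=i, **s.label._asdict()) if s.label else dict(stimulus=i)
              for i, s in enumerate(stimuli)]
    Path(path).write_text(json.dumps(labels, indent=2))
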