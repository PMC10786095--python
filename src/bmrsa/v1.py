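"""HMAX S1/C1 approximation of early visual cortex responses.

S1: a bank of zero-mean, unit-norm Gabor filters (4 orientations, 4 scale
bands of 2 filter sizes each, the standard C1 recipe with sizes 7-21 px)
applied as rectified normalized cross-correlations, so responses lie in
[0, 1] and are invariant to global intensity scaling.  C1: max over the two
scales within a band, then local spatial max pooling on a half-overlapping
grid.  A stimulus feature is the mean of per-frame C1 vectors (units are
treated as instantaneous, so a movie is modeled frame by frame and
averaged).  The V1 predictor RDM is 1 - Pearson over stimulus features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter
from scipy.signal import fftconvolve

from .rdm import RDM

__all__ = ["GaborBank", "C1Feature", "s1_filter", "c1_pool",
           "stimulus_feature", "v1_rdm", "write_features_tsv"]

# Standard C1 parameterization: per filter size, (sigma, wavelength);
# two sizes per band; per band, spatial pool size (stride = pool//2).
_SIZES = (7, 9, 11, 13, 15, 17, 19, 21)
_SIGMA = (2.8, 3.6, 4.5, 5.4, 6.3, 7.3, 8.2, 9.2)
_LAMBDA = (3.5, 4.6, 5.6, 6.8, 7.9, 9.1, 10.3, 11.5)
_POOL = (8, 10, 12, 14)
_GAMMA = 0.3  # Gabor aspect ratio


def _gabor(size: int, sigma: float, wavelength: float, theta: float) -> np.ndarray:
    """Zero-mean, unit-norm Gabor with a circular aperture."""
    half = size // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    xr = x * np.cos(theta) + y * np.sin(theta)
    yr = -x * np.sin(theta) + y * np.cos(theta)
    g = np.exp(-(xr ** 2 + _GAMMA ** 2 * yr ** 2) / (2 * sigma ** 2)) \
        * np.cos(2 * np.pi * xr / wavelength)
    g[x ** 2 + y ** 2 > half ** 2] = 0.0
    g -= g.mean()
    g /= np.linalg.norm(g)
    return g


@dataclass
class GaborBank:
    """S1 filter bank: ``filters[band][scale][orientation]``."""

    orientations_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    n_bands: int = 4
    filters: list = field(init=False, repr=False)
    pool_sizes: tuple[int, ...] = field(init=False)

    def __post_init__(self):
        if len(self.orientations_deg) < 2:
            raise ValueError("need at least 2 orientations")
        if not 1 <= self.n_bands <= 4:
            raise ValueError("n_bands must be in 1..4")
        self.pool_sizes = _POOL[: self.n_bands]
        self.filters = []
        for b in range(self.n_bands):
            scales = []
            for s in (2 * b, 2 * b + 1):
                scales.append([_gabor(_SIZES[s], _SIGMA[s], _LAMBDA[s],
                                      np.deg2rad(th))
                               for th in self.orientations_deg])
            self.filters.append(scales)

    @property
    def n_orientations(self) -> int:
        return len(self.orientations_deg)

    @property
    def max_size(self) -> int:
        return _SIZES[2 * self.n_bands - 1]


@dataclass
class C1Feature:
    """Flat pooled-response vector, layout band x orientation x grid cell."""

    values: np.ndarray
    layout: tuple  # ((band, orientation, (gh, gw)), ...)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


def s1_filter(frame: np.ndarray, bank: GaborBank) -> list:
    """Rectified normalized correlation maps, ``maps[band][scale][ori]``.

    Each map value is |<patch, gabor>| / ||patch||, in [0, 1] by
    Cauchy-Schwarz (filters are unit-norm), computed densely with 'same'
    padding.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    if min(frame.shape) < bank.max_size:
        raise ValueError(
            f"frame {frame.shape} smaller than largest filter ({bank.max_size} px)")
    sq = frame ** 2
    out = []
    for band in bank.filters:
        band_maps = []
        for scale in band:
            size = scale[0].shape[0]
            norm = fftconvolve(sq, np.ones((size, size)), mode="same")
            norm = np.sqrt(np.clip(norm, 0.0, None))
            half = size // 2
            maps = []
            for filt in scale:
                num = np.abs(fftconvolve(frame, filt[::-1, ::-1], mode="same"))
                with np.errstate(invalid="ignore", divide="ignore"):
                    r = np.where(norm > 1e-12, num / np.maximum(norm, 1e-12), 0.0)
                r = np.clip(r, 0.0, 1.0)
                # zero the half-filter border where the aperture is truncated
                r[:half], r[-half:], r[:, :half], r[:, -half:] = 0.0, 0.0, 0.0, 0.0
                maps.append(r)
            band_maps.append(maps)
        out.append(band_maps)
    return out


def c1_pool(s1maps: list, bank: GaborBank) -> C1Feature:
    """Max over the two scales in each band, then local spatial max.

    Pooling windows of size ``pool`` are placed with stride ``pool // 2``
    (half overlap); window placement depends only on image size and band,
    so the output length is fixed for a fixed bank and image size.
    """
    values = []
    layout = []
    for b, band_maps in enumerate(s1maps):
        pool = bank.pool_sizes[b]
        stride = pool // 2
        for o in range(bank.n_orientations):
            m = np.maximum(band_maps[0][o], band_maps[1][o])
            pooled = maximum_filter(m, size=pool, mode="constant", cval=0.0)
            # window centers on the stride grid
            off = pool // 2
            cells = pooled[off::stride, off::stride]
            values.append(cells.ravel())
            layout.append((b, o, cells.shape))
    return C1Feature(values=np.concatenate(values), layout=tuple(layout))


def stimulus_feature(stack, bank: GaborBank | None = None) -> C1Feature:
    """Mean of per-frame C1 vectors over all frames of a rendered stimulus."""
    if bank is None:
        bank = GaborBank()
    images = stack.images if hasattr(stack, "images") else np.asarray(stack)
    if images.ndim != 3 or images.shape[2] < 1:
        raise ValueError("need a (height, width, n_frames) stack with >= 1 frame")
    acc = None
    layout = None
    for f in range(images.shape[2]):
        c1 = c1_pool(s1_filter(images[:, :, f], bank), bank)
        acc = c1.values if acc is None else acc + c1.values
        layout = c1.layout
    return C1Feature(values=acc / images.shape[2], layout=layout)


def write_features_tsv(features: list[C1Feature], path) -> None:
    """C1 features as TSV (stimulus_id, feature_index, value)."""
    with open(path, "w") as fh:
        fh.write("stimulus_id\tfeature_index\tvalue\n")
        for sid, feat in enumerate(features):
            for i, v in enumerate(feat.values):
                fh.write(f"{sid}\t{i}\t{v:.8g}\n")


def v1_rdm(features: list[C1Feature], labels=None) -> RDM:
    """1 - Pearson dissimilarity between the 8 stimulus C1 features."""
    mat = np.stack([np.asarray(f.values, dtype=float) for f in features])
    if np.any(mat.std(axis=1) == 0):
        bad = np.flatnonzero(mat.std(axis=1) == 0).tolist()
        raise ValueError(f"zero-variance C1 feature(s) {bad}: correlation undefined")
    values = 1.0 - np.corrcoef(mat)
    np.fill_diagonal(values, 0.0)
    return RDM(values=values, kind="v1", labels=labels)
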