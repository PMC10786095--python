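"""Representational dissimilarity matrices over the 8 stimulus conditions.

Variants: theoretical (binary between/within-category), neural and V1
(1 - Pearson), behavioral (Euclidean distance of mean ratings).  All RDMs
are 8x8, symmetric, zero-diagonal.  Vectorization uses the row-major lower
triangle — pairs (1,0), (2,0), (2,1), ... (7,6) — fixed across the whole
analysis so permutation operations are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["RDM", "N_CONDITIONS", "N_PAIRS", "PAIR_INDICES", "ATTRIBUTES",
           "vectorize", "theoretical_rdms", "neural_rdm", "write_rdm_csv",
           "read_rdm_csv"]

N_CONDITIONS = 8
_TRIL = np.tril_indices(N_CONDITIONS, -1)
PAIR_INDICES = tuple(zip(_TRIL[0].tolist(), _TRIL[1].tolist()))
N_PAIRS = len(PAIR_INDICES)  # 28

ATTRIBUTES = ("facing", "gender", "emotion")


@dataclass
class RDM:
    """8x8 dissimilarity matrix with a kind tag and optional condition labels."""

    values: np.ndarray
    kind: str = "neural"  # theoretical | neural | v1 | behavioral
    labels: tuple | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_CONDITIONS, N_CONDITIONS):
            raise ValueError(f"RDM must be {N_CONDITIONS}x{N_CONDITIONS}, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValueError("RDM diagonal must be zero")
        if self.kind == "theoretical" and not np.isin(v, (0.0, 1.0)).all():
            raise ValueError("theoretical RDMs are binary {0,1}")
        self.values = v

    def vector(self) -> np.ndarray:
        """Lower-triangle vector of length 28 in the fixed pair order."""
        return self.values[_TRIL]


def vectorize(values: np.ndarray) -> np.ndarray:
    return np.asarray(values)[_TRIL]


def theoretical_rdms(labels) -> dict[str, RDM]:
    """Binary attribute RDMs: 1 between categories, 0 within.

    ``labels`` is a sequence of 8 (facing, gender, emotion) triples forming
    the full 2x2x2 cross; each attribute must split the set 4/4.
    """
    labels = [tuple(l) for l in labels]
    if len(labels) != N_CONDITIONS or len(set(labels)) != N_CONDITIONS:
        raise ValueError("need 8 distinct stimulus labels")
    out = {}
    for a, attr in enumerate(ATTRIBUTES):
        cats = [l[a] for l in labels]
        levels = sorted(set(cats))
        if len(levels) != 2 or cats.count(levels[0]) != 4:
            raise ValueError(f"attribute {attr!r} does not split the stimuli 4/4")
        v = np.not_equal.outer(cats, cats).astype(float)
        out[attr] = RDM(values=v, kind="theoretical", labels=tuple(labels))
    return out


def neural_rdm(patterns: np.ndarray, kind: str = "neural", labels=None) -> RDM:
    """1 - Pearson dissimilarity between 8 activity patterns (8 x k array)."""
    patterns = np.asarray(patterns, dtype=float)
    if patterns.shape[0] != N_CONDITIONS:
        raise ValueError("need one pattern per condition (8 rows)")
    sd = patterns.std(axis=1)
    if np.any(sd == 0):
        raise ValueError(
            f"constant pattern(s) {np.flatnonzero(sd == 0).tolist()}: "
            "correlation undefined")
    v = 1.0 - np.corrcoef(patterns)
    np.fill_diagonal(v, 0.0)
    return RDM(values=v, kind=kind, labels=labels)


def write_rdm_csv(rdm: RDM, path: str | Path) -> None:
    names = [("|".join(l) if isinstance(l, tuple) else str(l))
             for l in (rdm.labels or range(N_CONDITIONS))]
    lines = ["," + ",".join(names)]
    for name, row in zip(names, rdm.values):
        lines.append(name + "," + ",".join(f"{x:.8f}" for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_rdm_csv(path: str | Path, kind: str = "neural") -> RDM:
    rows = [line.split(",") for line in Path(path).read_text().strip().splitlines()]
    labels = tuple(rows[0][1:])
    values = np.array([[float(x) for x in r[1:]] for r in rows[1:]])
    return RDM(values=values, kind=kind, labels=labels)
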