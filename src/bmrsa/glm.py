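"""Voxel-wise general linear model for the simulated runs.

Per run: ordinary least squares on a design of 8 HRF-convolved stimulus
regressors, 6 motion regressors, an intercept and low-order drift terms;
the 8 stimulus betas per run feed the MVPA.  For RSA, runs are
concatenated with shared stimulus columns and run-wise
intercept/nuisance/drift columns, and each condition's t-map is
beta / SE(beta) from the pooled fit.  No prewhitening is applied; AR(1)
autocorrelation in the simulated noise is absorbed into tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import Timeline, stimulus_regressors

__all__ = ["DesignMatrix", "GLMResult", "make_design_matrix", "fit_run_glm",
           "condition_tmaps", "concatenated_design"]

N_STIM = 8


@dataclass
class DesignMatrix:
    """Volumes x columns design with named columns; stimulus columns first."""

    matrix: np.ndarray
    names: tuple[str, ...]

    @property
    def stimulus_cols(self) -> slice:
        return slice(0, N_STIM)

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]


@dataclass
class GLMResult:
    """Per-run stimulus betas and pooled condition t-maps on masked voxels."""

    run_betas: np.ndarray        # (n_runs, n_mask, 8)
    tmaps: np.ndarray            # (8, n_mask)
    residual_var: np.ndarray     # (n_mask,)
    dof: int


def _check_rank(X: np.ndarray, names: tuple[str, ...]) -> None:
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    dropped = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    dropped += [names[p] for p in piv[len(diag):]]
    if dropped:
        raise ValueError(f"design matrix is rank deficient; collinear or empty "
                         f"column(s): {dropped}")


def make_design_matrix(timeline: Timeline, nuisance: np.ndarray,
                       drift_order: int = 1) -> DesignMatrix:
    """Stimulus boxcars convolved with the double-gamma HRF, plus nuisance,
    intercept, and linear/cosine drift columns.

    ``nuisance`` is (n_nuisance, n_volumes); pass an empty (0, T) array for
    a stimulus-plus-intercept-only design.
    """
    nuisance = np.asarray(nuisance, dtype=float)
    if nuisance.size and nuisance.shape[1] != timeline.n_volumes:
        raise ValueError("nuisance regressors do not match the run length")
    stim = stimulus_regressors(timeline).T                    # (T, 8)
    T = timeline.n_volumes
    cols = [stim]
    names = [f"stim_{i}" for i in range(N_STIM)]
    if nuisance.size:
        cols.append(nuisance.T)
        names += [f"motion_{i}" for i in range(nuisance.shape[0])]
    cols.append(np.ones((T, 1)))
    names.append("intercept")
    tt = np.linspace(-1, 1, T)
    for d in range(1, drift_order + 1):
        cols.append(tt[:, None] ** d)
        names.append(f"drift_poly{d}")
        cols.append(np.cos(d * np.pi * (tt[:, None] + 1) / 2))
        names.append(f"drift_cos{d}")
    X = np.hstack(cols)
    _check_rank(X, tuple(names))
    return DesignMatrix(matrix=X, names=tuple(names))


def fit_run_glm(series: np.ndarray, dm: DesignMatrix,
                return_all: bool = False) -> np.ndarray:
    """Per-voxel OLS betas for one run; (n_mask, 8) in stimulus order."""
    series = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    if series.shape[1] != dm.n_volumes:
        raise ValueError("series length does not match the design")
    beta, *_ = np.linalg.lstsq(dm.matrix, series.T, rcond=None)  # (C, V)
    return beta.T if return_all else beta[dm.stimulus_cols].T


def concatenated_design(dms: list[DesignMatrix]) -> tuple[np.ndarray, slice]:
    """Stack runs: shared stimulus columns, block-diagonal everything else."""
    n_other = [dm.matrix.shape[1] - N_STIM for dm in dms]
    total_T = sum(dm.n_volumes for dm in dms)
    X = np.zeros((total_T, N_STIM + sum(n_other)))
    row = 0
    col = N_STIM
    for dm, no in zip(dms, n_other):
        T = dm.n_volumes
        X[row:row + T, :N_STIM] = dm.matrix[:, :N_STIM]
        X[row:row + T, col:col + no] = dm.matrix[:, N_STIM:]
        row += T
        col += no
    return X, slice(0, N_STIM)


def condition_tmaps(run_series: list[np.ndarray], dms: list[DesignMatrix],
                    ) -> GLMResult:
    """Pooled condition t-maps from all runs, plus per-run stimulus betas.

    t = beta / SE(beta) per condition per voxel from the concatenated fit;
    voxels with zero residual variance get t = 0 with a warning.
    """
    import warnings

    if len(run_series) < 2:
        raise ValueError("pooled t-maps need >= 2 runs")
    run_betas = np.stack([fit_run_glm(s, dm) for s, dm in zip(run_series, dms)])
    X, stim_cols = concatenated_design(dms)
    Y = np.vstack([np.asarray(s, dtype=float).T for s in run_series])  # (T, V)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = X.shape[0] - np.linalg.matrix_rank(X)
    sigma2 = np.einsum("tv,tv->v", resid, resid) / dof
    inv_diag = np.diag(np.linalg.inv(X.T @ X))[stim_cols]
    se = np.sqrt(np.outer(inv_diag, sigma2))
    zero = sigma2 == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} voxel(s) with zero residual variance; "
                      "t set to 0 there")
        se[:, zero] = np.inf
    tmaps = beta[stim_cols] / se
    return GLMResult(run_betas=run_betas, tmaps=tmaps, residual_var=sigma2, dof=dof)
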