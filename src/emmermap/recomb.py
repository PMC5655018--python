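"""Recombination-rate profiles (cM/Mb) by local polynomial kernel derivatives.

At each grid point x0 a weighted cubic polynomial of genetic position (cM)
on centred physical position (Mb - x0) is fitted with Gaussian kernel
weights exp(-((x - x0)/h)^2 / 2); the first-order coefficient is the local
derivative d cM / d Mb, i.e. the recombination rate. The default bandwidth
is 20 Mb. Local polynomial fits reproduce polynomials up to the fit degree
exactly, which is the defining oracle for this estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RateProfile", "rate_profile"]


@dataclass
class RateProfile:
    grid_mb: np.ndarray
    rate: np.ndarray          # cM/Mb; NaN where masked
    valid: np.ndarray         # bool; False where effective n < degree+1 or singular
    boundary: np.ndarray      # bool; grid point within one bandwidth of the data edge
    bandwidth_mb: float
    degree: int


def rate_profile(genetic_cm, physical_mb, bandwidth_mb: float = 20.0,
                 degree: int = 3, grid=None, grid_step_mb: float = 1.0) -> RateProfile:
    """Local polynomial derivative of the genetic map versus physical position.

    Parameters
    ----------
    genetic_cm, physical_mb
        Paired marker coordinates; physical positions are sorted ascending
        internally and exact physical ties are collapsed to their mean cM.
    bandwidth_mb
        Gaussian kernel standard deviation h, in Mb.
    grid
        Evaluation points; defaults to ``grid_step_mb`` spacing from the
        first to the last marker.

    Grid points with effective sample size (sum of kernel weights) below
    ``degree + 1``, or a singular local design, are masked rather than
    extrapolated. Boundary points (within h of the data edge) are retained
    but flagged.
    """
    g = np.asarray(genetic_cm, dtype=float)
    x = np.asarray(physical_mb, dtype=float)
    if g.shape != x.shape or g.ndim != 1:
        raise ValueError("genetic and physical positions must be paired 1-D arrays")
    if len(x) < degree + 2:
        raise ValueError(f"need at least degree+2 = {degree + 2} markers")
    if bandwidth_mb <= 0:
        raise ValueError("bandwidth must be positive")
    order = np.argsort(x, kind="stable")
    x, g = x[order], g[order]
    # collapse exact physical ties to mean cM
    ux, inv = np.unique(x, return_inverse=True)
    if len(ux) < len(x):
        ug = np.zeros(len(ux))
        cnt = np.zeros(len(ux))
        np.add.at(ug, inv, g)
        np.add.at(cnt, inv, 1.0)
        x, g = ux, ug / cnt
    if len(x) < degree + 2:
        raise ValueError("too few distinct physical positions after collapsing ties")

    if grid is None:
        grid = np.arange(x[0], x[-1] + 0.5 * grid_step_mb, grid_step_mb)
    grid = np.asarray(grid, dtype=float)

    rate = np.full(len(grid), np.nan)
    valid = np.zeros(len(grid), dtype=bool)
    h = float(bandwidth_mb)
    for i, x0 in enumerate(grid):
        t = x - x0
        w = np.exp(-0.5 * (t / h) ** 2)
        if w.sum() < degree + 1:
            continue
        sw = np.sqrt(w)
        X = np.vander(t, degree + 1, increasing=True)
        coef, _, rank, _ = np.linalg.lstsq(X * sw[:, None], g * sw, rcond=None)
        if rank < degree + 1:
            continue
        rate[i] = coef[1]
        valid[i] = True
    boundary = (grid < x[0] + h) | (grid > x[-1] - h)
    return RateProfile(grid, rate, valid, boundary, h, degree)
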