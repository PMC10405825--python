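"""Niche overlap (Schoener's D) and niche breadth (Levins B1 / Shannon B2).

Both metrics act on a suitability surface normalized to a probability
distribution over valid cells:

    D(p, q) = 1 - 0.5 * sum |p_i - q_i|            in [0, 1]
    B1      = ((1 / sum p_i^2) - 1) / (n - 1)      standardized inverse concentration
    B2      = (-sum p_i ln p_i) / ln n             standardized Shannon entropy

The primary comparison space is geographic (the raster lattice itself). A
reduced environment-space mode projects cells onto the first two principal
axes of the standardized background variables and compares smoothed 2-D
densities there instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geodata import EnvStack, Grid, GridAlignmentError
from .maxent import SuitabilityMap


@dataclass
class NicheBreadth:
    b1: float
    b2: float
    n_cells: int


def _as_grid(suit: SuitabilityMap | Grid) -> Grid:
    return suit.grid if isinstance(suit, SuitabilityMap) else suit


def normalize_density(suit: SuitabilityMap | Grid) -> Grid:
    """Scale non-negative suitability to a probability grid (sum 1)."""
    grid = _as_grid(suit)
    v = grid.values
    ok = ~np.isnan(v)
    if (v[ok] < 0).any():
        raise ValueError("suitability values must be non-negative")
    total = v[ok].sum()
    if total <= 0:
        raise ValueError("all-zero suitability cannot be normalized")
    out = np.full(v.shape, np.nan)
    out[ok] = v[ok] / total
    return grid.copy(values=out)


def schoener_d(p: Grid | np.ndarray, q: Grid | np.ndarray) -> float:
    """Schoener's overlap D = 1 - 0.5 * sum |p - q| between two densities."""
    if isinstance(p, Grid) and isinstance(q, Grid):
        if not p.same_geometry(q):
            raise GridAlignmentError("density grids do not align")
        pv, qv = p.values, q.values
    else:
        pv = np.asarray(p, dtype=float)
        qv = np.asarray(q, dtype=float)
        if pv.shape != qv.shape:
            raise GridAlignmentError("density arrays do not align")
    pv = np.nan_to_num(pv, nan=0.0)
    qv = np.nan_to_num(qv, nan=0.0)
    return float(1.0 - 0.5 * np.abs(pv - qv).sum())


def niche_breadth(suit: SuitabilityMap | Grid) -> NicheBreadth:
    """Levins B1 and Shannon B2 of the normalized suitability, both in [0,1].

    Returns NaN breadths for fewer than 2 valid cells (undefined).
    """
    dens = normalize_density(suit)
    p = dens.values[~np.isnan(dens.values)]
    n = p.size
    if n < 2:
        return NicheBreadth(b1=float("nan"), b2=float("nan"), n_cells=n)
    b1 = (1.0 / np.sum(p**2) - 1.0) / (n - 1)
    pz = p[p > 0]
    b2 = float(-np.sum(pz * np.log(pz)) / np.log(n))
    return NicheBreadth(b1=float(b1), b2=b2, n_cells=n)


def env_space_density(stack: EnvStack, weights: SuitabilityMap | Grid,
                      grid_size: int = 100, bandwidth: float = 2.0,
                      axes: np.ndarray | None = None,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Suitability-weighted density on the first two principal environment axes.

    Background cells are standardized per variable; the principal axes come
    from the eigendecomposition of their correlation matrix. Cells are
    binned on a grid_size x grid_size lattice spanning the background cloud
    on axes 1-2, weighted by suitability, Gaussian-smoothed with `bandwidth`
    (in lattice cells) and normalized to sum 1.

    Returns (density, axes); pass `axes` back in to score a second scenario
    in the same plane, then feed both densities to :func:`schoener_d`.
    """
    if len(stack.names) < 2:
        raise ValueError("environment-space mode needs at least 2 variables")
    mask = stack.mask
    rr, cc = np.nonzero(mask)
    if rr.size < 3:
        raise ValueError("need at least 3 valid cells")
    X = np.column_stack([stack[n].values[rr, cc] for n in stack.names])
    mu, sd = X.mean(axis=0), X.std(axis=0)
    if (sd == 0).any():
        raise ValueError("constant variable makes the principal axes degenerate")
    Z = (X - mu) / sd
    if axes is None:
        C = np.corrcoef(Z, rowvar=False)
        evals, evecs = np.linalg.eigh(C)
        if evals[-2] <= 1e-10:
            raise ValueError("correlation matrix is singular; axes degenerate")
        axes = evecs[:, ::-1][:, :2]
    scores = Z @ axes

    w_grid = _as_grid(weights)
    if not w_grid.same_geometry(stack.grid):
        raise GridAlignmentError("weights grid does not align with the stack")
    w = np.nan_to_num(w_grid.values[rr, cc], nan=0.0)
    if w.sum() <= 0:
        raise ValueError("weights are all zero on valid cells")

    lo = scores.min(axis=0)
    hi = scores.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    ij = np.clip(((scores - lo) / span * (grid_size - 1)).astype(int),
                 0, grid_size - 1)
    dens = np.zeros((grid_size, grid_size))
    np.add.at(dens, (ij[:, 0], ij[:, 1]), w)
    dens = ndimage.gaussian_filter(dens, sigma=bandwidth, mode="constant")
    dens /= dens.sum()
    return dens, axes
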