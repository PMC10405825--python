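"""Synthetic study-system generator with known ground truth.

Produces spatially smooth, cross-correlated environmental raster stacks, a
true suitability surface that is logistic in a linear combination of some
layers, presence points sampled proportionally to that suitability (with a
uniform-noise admixture and duplicates), and shifted "future" stacks whose
suitable region migrates poleward. Every stage is deterministic under the
configured seed, so downstream model fits can be checked against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .geodata import EnvStack, Grid, OccurrenceSet


@dataclass
class SyntheticConfig:
    """Knobs for the synthetic study system.

    The defaults emulate the real study's structure at test scale: a stack of
    12 smooth, moderately cross-correlated predictors on a 2.5-arc-minute-like
    lattice, a logistic truth driven by a 3-variable subset, a few hundred
    presence points with a 10% uniform-noise admixture, and additive future
    deltas that push suitability toward higher latitude.
    """

    n_rows: int = 60
    n_cols: int = 60
    cell_size: float = 1.0 / 24.0  # 2.5 arc-minutes
    origin: tuple[float, float] = (100.0, 25.0)  # (lon, lat) of lower-left corner
    n_vars: int = 12
    smoothness: float = 6.0
    target_correlation: np.ndarray | None = None  # default: AR(1)-style, rho=0.3
    true_coefficients: dict[str, float] = field(
        default_factory=lambda: {"bio01": 2.5, "bio02": -1.5, "bio03": 1.0})
    intercept: float = -1.0
    n_presences: int = 400
    noise_fraction: float = 0.1
    seed: int = 0
    future_deltas: dict[str, dict[str, float]] = field(default_factory=dict)

    def correlation(self) -> np.ndarray:
        if self.target_correlation is not None:
            C = np.asarray(self.target_correlation, dtype=float)
        else:
            idx = np.arange(self.n_vars)
            C = 0.3 ** np.abs(idx[:, None] - idx[None, :])
        _validate_correlation(C, self.n_vars)
        return C

    def var_names(self) -> list[str]:
        return [f"bio{i + 1:02d}" for i in range(self.n_vars)]


def _validate_correlation(C: np.ndarray, n_vars: int) -> None:
    if C.shape != (n_vars, n_vars):
        raise ValueError(f"target_correlation must be {n_vars}x{n_vars}")
    if not np.allclose(C, C.T):
        raise ValueError("target_correlation must be symmetric")
    if not np.allclose(np.diag(C), 1.0):
        raise ValueError("target_correlation must have unit diagonal")
    eigmin = np.linalg.eigvalsh(C).min()
    if eigmin <= 0:
        raise ValueError(f"target_correlation is not positive-definite (min eig {eigmin:.3g})")


def gaussian_field(n_rows: int, n_cols: int, smoothness: float, seed: int,
                   cell_size: float = 1.0 / 24.0,
                   origin: tuple[float, float] = (100.0, 25.0)) -> Grid:
    """A smooth Gaussian random field, standardized to mean 0 / sd 1.

    White noise is convolved with a Gaussian kernel whose sigma equals
    `smoothness` (in cells), then z-scored, so the empirical moments are
    exact and the spatial correlation length scales with `smoothness`.
    """
    if n_rows <= 0 or n_cols <= 0 or smoothness <= 0:
        raise ValueError("n_rows, n_cols and smoothness must be positive")
    rng = np.random.default_rng(seed)
    field_ = _smooth_standard_field(rng, n_rows, n_cols, smoothness)
    return Grid(n_rows, n_cols, origin[0], origin[1], cell_size, -9999.0, field_)


def _smooth_standard_field(rng: np.random.Generator, n_rows: int, n_cols: int,
                           smoothness: float) -> np.ndarray:
    noise = rng.standard_normal((n_rows, n_cols))
    sm = ndimage.gaussian_filter(noise, sigma=smoothness, mode="reflect")
    sm -= sm.mean()
    sd = sm.std()
    if sd == 0:  # degenerate 1x1 case
        return np.zeros_like(sm)
    return sm / sd


def make_env_stack(config: SyntheticConfig) -> EnvStack:
    """Generate `n_vars` smooth layers with the configured cross-correlation.

    Independent standardized fields are first whitened exactly (so their
    empirical correlation is the identity) and then mixed by the Cholesky
    factor of the target correlation; the empirical cross-correlation of the
    output therefore equals the target up to floating-point error.
    """
    C = config.correlation()
    rng = np.random.default_rng(config.seed)
    n = config.n_rows * config.n_cols
    fields = np.empty((config.n_vars, n))
    for i in range(config.n_vars):
        fields[i] = _smooth_standard_field(
            rng, config.n_rows, config.n_cols, config.smoothness).ravel()
    if config.n_vars > 1 and n > config.n_vars:
        # exact whitening: make rows empirically uncorrelated, unit variance
        cov = fields @ fields.T / n
        L = np.linalg.cholesky(cov)
        fields = np.linalg.solve(L, fields)
        fields = np.linalg.cholesky(C) @ fields
    layers = {}
    for i, name in enumerate(config.var_names()):
        layers[name] = Grid(config.n_rows, config.n_cols, config.origin[0],
                            config.origin[1], config.cell_size, -9999.0,
                            fields[i].reshape(config.n_rows, config.n_cols))
    return EnvStack(layers)


def true_suitability(stack: EnvStack, coefficients: Mapping[str, float],
                     intercept: float) -> Grid:
    """Logistic ground-truth suitability p = sigmoid(intercept + sum w_v x_v)."""
    unknown = set(coefficients) - set(stack.names)
    if unknown:
        raise KeyError(f"unknown variable(s) in coefficients: {sorted(unknown)}")
    ref = stack.grid
    eta = np.full((ref.n_rows, ref.n_cols), float(intercept))
    for name, w in coefficients.items():
        eta = eta + w * stack[name].values
    with np.errstate(over="ignore", invalid="ignore"):
        p = 1.0 / (1.0 + np.exp(-eta))
    p[~stack.mask] = np.nan
    return ref.copy(values=p)


def sample_occurrences(suit: Grid, n: int, seed: int,
                       noise_fraction: float = 0.0,
                       species: str = "synthetic") -> OccurrenceSet:
    """Sample `n` presences at cell centers, probability proportional to suitability.

    A `noise_fraction` share is drawn uniformly over valid cells instead
    (location error / misidentification analogue). Duplicates are allowed,
    so occurrence cleaning has real work to do.
    """
    if not 0 <= noise_fraction < 1:
        raise ValueError("noise_fraction must be in [0, 1)")
    mask = suit.mask
    if not mask.any():
        raise ValueError("suitability grid has no valid cells")
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(mask)
    weights = suit.values[rows, cols].astype(float)
    if weights.sum() <= 0:
        raise ValueError("suitability grid has no positive values")
    n_noise = int(round(n * noise_fraction))
    n_signal = n - n_noise
    idx_signal = rng.choice(len(rows), size=n_signal, replace=True,
                            p=weights / weights.sum())
    idx_noise = rng.choice(len(rows), size=n_noise, replace=True)
    points = [suit.cell_center(rows[i], cols[i])
              for i in np.concatenate([idx_signal, idx_noise]).astype(int)]
    return OccurrenceSet(species=species, points=points)


def make_future_stack(stack: EnvStack, deltas: Mapping[str, object]) -> EnvStack:
    """Apply additive climate-change deltas; unnamed layers are unchanged.

    A delta is either a number (uniform additive shift) or a mapping with
    keys ``offset`` and ``lat_gradient``: the shift at a cell is
    ``offset + lat_gradient * (lat - lat_mid)`` with `lat_mid` the grid's
    central latitude. A latitude gradient on a variable the species responds
    to moves the suitable region poleward, emulating warming scenarios.
    """
    unknown = set(deltas) - set(stack.names)
    if unknown:
        raise KeyError(f"unknown variable(s) in deltas: {sorted(unknown)}")
    ref = stack.grid
    lat = ref.row_latitudes()[:, None]  # (n_rows, 1), broadcasts over columns
    lat_mid = 0.5 * (ref.y_min + ref.y_max)
    new_layers = {}
    for name in stack.names:
        g = stack[name]
        if name in deltas:
            d = deltas[name]
            if isinstance(d, Mapping):
                shift = float(d.get("offset", 0.0)) + \
                    float(d.get("lat_gradient", 0.0)) * (lat - lat_mid)
            else:
                shift = float(d)
            new_layers[name] = g.copy(values=g.values + shift)
        else:
            new_layers[name] = g.copy()
    return EnvStack(new_layers)


def default_future_deltas(config: SyntheticConfig,
                          severity: float = 1.0) -> dict[str, dict[str, float]]:
    """Scenario deltas that shift the suitable region toward higher latitude.

    The leading positive-coefficient variable gets a negative offset plus a
    positive latitude gradient, so the band where the linear predictor is
    high moves north; `severity` scales the shift (emulating increasing
    radiative forcing across scenarios).
    """
    if config.future_deltas:
        return config.future_deltas
    pos = [k for k, w in config.true_coefficients.items() if w > 0]
    if not pos:
        raise ValueError("no positive-coefficient variable to perturb")
    lead = max(pos, key=lambda k: config.true_coefficients[k])
    lat_span = config.n_rows * config.cell_size
    return {lead: {"offset": -0.4 * severity,
                   "lat_gradient": 1.6 * severity / lat_span}}
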