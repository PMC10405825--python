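"""Suitability classification, range-change accounting, centroid migration.

Suitability maps are cut into four classes (unsuitable / low / moderate /
high) at fixed logistic thresholds, binarized at the suitable/unsuitable
cut, and compared across climate scenarios cell by cell: 0->1 is gain,
1->0 is loss, 1->1 is stable. Areas use latitude-dependent spherical cell
areas; percentages follow

    percent_gain  = 100 * gain  / current_area
    percent_loss  = 100 * loss  / current_area
    range_change  = 100 * (gain - loss) / current_area

Centroids of the suitable region are area-weighted means of suitable-cell
centers; migration distance between centroids is the WGS84 ellipsoidal
geodesic (Vincenty's inverse formula).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geodata import EnvStack, Grid, GridAlignmentError, cell_areas_km2
from .maxent import SuitabilityMap

#: Default classification thresholds (suitable, moderate, high).
DEFAULT_THRESHOLDS = (0.374, 0.57, 0.7)

CODE_UNSUITABLE, CODE_LOW, CODE_MODERATE, CODE_HIGH = 0, 1, 2, 3
CHANGE_NEVER, CHANGE_GAIN, CHANGE_LOSS, CHANGE_STABLE = 0, 1, 2, 3


@dataclass
class ClassifiedMap:
    grid: Grid  # codes 0..3, nodata propagated
    thresholds: tuple[float, float, float]


@dataclass
class AreaReport:
    """Areas (km^2) by suitability class; total suitable = low+moderate+high."""

    low: float
    moderate: float
    high: float

    @property
    def total_suitable(self) -> float:
        return self.low + self.moderate + self.high


@dataclass
class ChangeStats:
    gain_area: float
    loss_area: float
    stable_area: float
    current_area: float

    @property
    def future_area(self) -> float:
        return self.stable_area + self.gain_area

    @property
    def percent_gain(self) -> float:
        return 100.0 * self.gain_area / self.current_area

    @property
    def percent_loss(self) -> float:
        return 100.0 * self.loss_area / self.current_area

    @property
    def range_change(self) -> float:
        return 100.0 * (self.gain_area - self.loss_area) / self.current_area


@dataclass
class Centroid:
    longitude: float
    latitude: float


def _suit_values(suit: SuitabilityMap | Grid) -> Grid:
    grid = suit.grid if isinstance(suit, SuitabilityMap) else suit
    vals = grid.values
    finite = vals[~np.isnan(vals)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("suitability values must lie in [0, 1]")
    return grid


def classify_suitability(suit: SuitabilityMap | Grid,
                         thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
                         ) -> ClassifiedMap:
    """Four-class cut at half-open intervals [0,t1), [t1,t2), [t2,t3), [t3,1]."""
    t1, t2, t3 = thresholds
    if not (0 < t1 < t2 < t3 < 1):
        raise ValueError("thresholds must be strictly increasing within (0, 1)")
    grid = _suit_values(suit)
    v = grid.values
    codes = np.full(v.shape, np.nan)
    ok = ~np.isnan(v)
    codes[ok] = (v[ok] >= t1).astype(float) + (v[ok] >= t2) + (v[ok] >= t3)
    return ClassifiedMap(grid=grid.copy(values=codes), thresholds=thresholds)


def binarize(suit: SuitabilityMap | Grid, threshold: float = DEFAULT_THRESHOLDS[0]) -> Grid:
    """Presence/absence grid: 1 where suitability >= threshold, else 0."""
    grid = _suit_values(suit)
    v = grid.values
    out = np.full(v.shape, np.nan)
    ok = ~np.isnan(v)
    out[ok] = (v[ok] >= threshold).astype(float)
    return grid.copy(values=out)


def area_by_class(classified: ClassifiedMap) -> AreaReport:
    """Per-class area, summing latitude-dependent cell areas."""
    codes = classified.grid.values
    areas_row = cell_areas_km2(classified.grid)[:, None]
    out = {}
    for code, name in ((1, "low"), (2, "moderate"), (3, "high")):
        sel = codes == code
        out[name] = float((sel * areas_row).sum())
    return AreaReport(**out)


def change_matrix(current: Grid, future: Grid) -> tuple[Grid, ChangeStats]:
    """Per-cell transition codes and area accounting between two binary grids.

    Codes: 0 never suitable, 1 gain (0->1), 2 loss (1->0), 3 stable (1->1).
    """
    if not current.same_geometry(future):
        raise GridAlignmentError("current and future grids do not align")
    c, f = current.values, future.values
    ok = ~np.isnan(c) & ~np.isnan(f)
    codes = np.full(c.shape, np.nan)
    codes[ok] = 0.0
    codes[ok & (c == 0) & (f == 1)] = CHANGE_GAIN
    codes[ok & (c == 1) & (f == 0)] = CHANGE_LOSS
    codes[ok & (c == 1) & (f == 1)] = CHANGE_STABLE
    areas_row = cell_areas_km2(current)[:, None]
    gain = float(((codes == CHANGE_GAIN) * areas_row).sum())
    loss = float(((codes == CHANGE_LOSS) * areas_row).sum())
    stable = float(((codes == CHANGE_STABLE) * areas_row).sum())
    stats = ChangeStats(gain_area=gain, loss_area=loss, stable_area=stable,
                        current_area=loss + stable)
    return current.copy(values=codes), stats


def change_stats_from_areas(gain: float, loss: float, stable: float,
                            current: float | None = None) -> ChangeStats:
    """ChangeStats from externally tabulated areas (any consistent unit)."""
    if current is None:
        current = loss + stable
    return ChangeStats(gain_area=gain, loss_area=loss, stable_area=stable,
                       current_area=current)


def centroid(binary: Grid) -> Centroid:
    """Area-weighted centroid of the suitable (value 1) cells."""
    sel = binary.values == 1
    if not sel.any():
        raise ValueError("suitable set is empty; centroid undefined")
    areas_row = cell_areas_km2(binary)
    rr, cc = np.nonzero(sel)
    w = areas_row[rr]
    lons = binary.x_min + (cc + 0.5) * binary.cell_size
    lats = binary.y_min + (binary.n_rows - rr - 0.5) * binary.cell_size
    return Centroid(longitude=float(np.average(lons, weights=w)),
                    latitude=float(np.average(lats, weights=w)))


# WGS84 ellipsoid
_WGS84_A = 6378137.0
_WGS84_F = 1.0 / 298.257223563
_WGS84_B = _WGS84_A * (1.0 - _WGS84_F)


def geodesic_distance(a: Centroid | tuple[float, float],
                      b: Centroid | tuple[float, float]) -> float:
    """WGS84 ellipsoidal geodesic distance in meters (Vincenty inverse).

    Accepts Centroids or (lon, lat) tuples. Converges to sub-mm accuracy for
    non-near-antipodal pairs; falls back to the spherical great circle if
    the iteration fails to converge (near-antipodal inputs).
    """
    lon1, lat1 = (a.longitude, a.latitude) if isinstance(a, Centroid) else a
    lon2, lat2 = (b.longitude, b.latitude) if isinstance(b, Centroid) else b
    if (lon1, lat1) == (lon2, lat2):
        return 0.0
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    L = np.radians(lon2 - lon1)
    U1 = np.arctan((1 - _WGS84_F) * np.tan(phi1))
    U2 = np.arctan((1 - _WGS84_F) * np.tan(phi2))
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)
    lam = L
    for _ in range(200):
        sin_lam, cos_lam = np.sin(lam), np.cos(lam)
        sin_sigma = np.hypot(cosU2 * sin_lam,
                             cosU1 * sinU2 - sinU1 * cosU2 * cos_lam)
        if sin_sigma == 0:
            return 0.0
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = np.arctan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha**2
        cos_2sigma_m = (cos_sigma - 2 * sinU1 * sinU2 / cos2_alpha
                        if cos2_alpha != 0 else 0.0)
        C = _WGS84_F / 16 * cos2_alpha * (4 + _WGS84_F * (4 - 3 * cos2_alpha))
        lam_prev = lam
        lam = L + (1 - C) * _WGS84_F * sin_alpha * (
            sigma + C * sin_sigma * (
                cos_2sigma_m + C * cos_sigma * (-1 + 2 * cos_2sigma_m**2)))
        if abs(lam - lam_prev) < 1e-12:
            break
    else:
        # near-antipodal: spherical fallback (error < 0.6%)
        d = np.arccos(np.clip(np.sin(phi1) * np.sin(phi2)
                              + np.cos(phi1) * np.cos(phi2) * np.cos(L), -1, 1))
        return float(d * 6371008.8)
    u2 = cos2_alpha * (_WGS84_A**2 - _WGS84_B**2) / _WGS84_B**2
    A = 1 + u2 / 16384 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
    B = u2 / 1024 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))
    delta_sigma = B * sin_sigma * (
        cos_2sigma_m + B / 4 * (
            cos_sigma * (-1 + 2 * cos_2sigma_m**2)
            - B / 6 * cos_2sigma_m * (-3 + 4 * sin_sigma**2)
            * (-3 + 4 * cos_2sigma_m**2)))
    return float(_WGS84_B * A * (sigma - delta_sigma))


def zonal_env_means(stack: EnvStack, binary: Grid) -> dict[str, float]:
    """Area-weighted mean of every layer over the suitable (value 1) cells."""
    sel = binary.values == 1
    if not sel.any():
        raise ValueError("suitable set is empty")
    areas_row = cell_areas_km2(binary)
    rr, cc = np.nonzero(sel)
    w = areas_row[rr]
    out: dict[str, float] = {}
    for name in stack.names:
        v = stack[name].values[rr, cc]
        ok = ~np.isnan(v)
        out[name] = float(np.average(v[ok], weights=w[ok]))
    return out
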