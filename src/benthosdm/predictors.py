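"""Environmental predictor stacks: terrain derivatives, geographic proxies,
site extraction, and the Spearman collinearity filter.

Terrain metrics follow the conventions of standard marine-terrain toolkits:
slope by Horn's eight-neighbour method (degrees), aspect decomposed into
eastness/northness, Zevenbergen–Thorne profile and plan curvature, rugosity
as the triangulated surface-to-planar area ratio, the local standard
deviation of depth, and the topographic position index (TPI).  All metrics
use a square moving window; a cell whose window touches a nodata cell or
the grid edge becomes nodata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .grids import GridSurface, ZoneSet, require_aligned

logger = logging.getLogger(__name__)

__all__ = [
    "PredictorStack",
    "CorrelationFilterResult",
    "derive_topographic",
    "derive_geographic",
    "filter_correlated",
    "extract_at_sites",
    "TOPOGRAPHIC_NAMES",
    "GEOGRAPHIC_NAMES",
]

TOPOGRAPHIC_NAMES = [
    "depth",
    "slope",
    "eastness",
    "northness",
    "profile_curvature",
    "plan_curvature",
    "rugosity",
    "depth_sd",
    "tpi",
]
GEOGRAPHIC_NAMES = ["easting", "northing", "dist_feature1", "dist_feature2"]

FAMILIES = ("spectral", "topographic", "geographic")


@dataclass
class PredictorStack:
    """An ordered, aligned set of named predictor grids with family tags."""

    names: list[str] = field(default_factory=list)
    grids: dict[str, GridSurface] = field(default_factory=dict)
    family: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("predictor names are not unique")
        if set(self.names) != set(self.grids) or set(self.names) != set(self.family):
            raise ValueError("names, grids and family tags must cover the same predictors")
        for name, fam in self.family.items():
            if fam not in FAMILIES:
                raise ValueError(f"predictor {name!r}: unknown family {fam!r}")
        if self.names:
            require_aligned(*(self.grids[n] for n in self.names))

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> GridSurface:
        return self.grids[name]

    def add(self, name: str, grid: GridSurface, family: str) -> None:
        if name in self.grids:
            raise ValueError(f"duplicate predictor name {name!r}")
        if self.names:
            require_aligned(self.grids[self.names[0]], grid)
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        self.names.append(name)
        self.grids[name] = grid
        self.family[name] = family

    def subset(self, names: list[str]) -> "PredictorStack":
        keep = [n for n in self.names if n in set(names)]
        return PredictorStack(
            names=keep,
            grids={n: self.grids[n] for n in keep},
            family={n: self.family[n] for n in keep},
        )

    def merged(self, other: "PredictorStack") -> "PredictorStack":
        out = PredictorStack(list(self.names), dict(self.grids), dict(self.family))
        for n in other.names:
            out.add(n, other.grids[n], other.family[n])
        return out

    @property
    def common_mask(self) -> np.ndarray:
        """Cells valid in every predictor grid."""
        mask = np.ones(self.grids[self.names[0]].shape, dtype=bool)
        for n in self.names:
            mask &= self.grids[n].mask
        return mask


# ---------------------------------------------------------------------------
# Topographic derivatives
# ---------------------------------------------------------------------------

def _window_views(z: np.ndarray, window: int) -> np.ndarray:
    """Sliding (window x window) views; shape (r-w+1, c-w+1, w, w)."""
    return sliding_window_view(z, (window, window))


def derive_topographic(depth: GridSurface, window_cells: int = 3) -> PredictorStack:
    """Nine seafloor-topography predictors from a depth grid.

    Depth is in metres, positive downward.  Slope/aspect/curvature use the
    3x3 Horn / Zevenbergen-Thorne stencils regardless of ``window_cells``;
    rugosity, depth_sd and TPI use the full ``window_cells`` window.
    """
    if window_cells < 3 or window_cells % 2 == 0:
        raise ValueError("window_cells must be an odd integer >= 3")
    if window_cells >= min(depth.shape):
        raise ValueError("window_cells must be smaller than the grid extent")

    z = depth.values
    cs = depth.cell_size
    half = window_cells // 2

    # elevation convention: curvature/slope formulas assume height; with
    # depth positive-down the sign flips for curvature but slope magnitude,
    # rugosity, sd and TPI are unaffected. Work on -z as height.
    h = -z

    nan_pad = np.full(depth.shape, np.nan)

    def full(interior: np.ndarray, pad: int) -> np.ndarray:
        out = nan_pad.copy()
        out[pad:-pad or None, pad:-pad or None] = interior
        return out

    # 3x3 neighbour views for Horn / ZT stencils
    w3 = _window_views(h, 3)
    z1, z2, z3 = w3[..., 0, 0], w3[..., 0, 1], w3[..., 0, 2]
    z4, z5, z6 = w3[..., 1, 0], w3[..., 1, 1], w3[..., 1, 2]
    z7, z8, z9 = w3[..., 2, 0], w3[..., 2, 1], w3[..., 2, 2]

    # Horn 1981: weighted central differences over the 3x3 window
    dzdx = ((z3 + 2 * z6 + z9) - (z1 + 2 * z4 + z7)) / (8 * cs)
    dzdy = ((z1 + 2 * z2 + z3) - (z7 + 2 * z8 + z9)) / (8 * cs)
    slope_rad = np.arctan(np.hypot(dzdx, dzdy))
    slope = full(np.degrees(slope_rad), 1)

    # aspect: direction of steepest descent, decomposed to avoid circularity
    aspect = np.arctan2(dzdy, -dzdx)  # radians, east = 0, CCW
    grad = np.hypot(dzdx, dzdy)
    flat = grad < 1e-12
    east = np.where(flat, 0.0, np.cos(aspect))
    north = np.where(flat, 0.0, np.sin(aspect))
    eastness = full(east, 1)
    northness = full(north, 1)

    # Zevenbergen & Thorne 1987 quadratic-surface coefficients
    D = ((z4 + z6) / 2 - z5) / cs**2
    E = ((z2 + z8) / 2 - z5) / cs**2
    F = (-z1 + z3 + z7 - z9) / (4 * cs**2)
    G = (-z4 + z6) / (2 * cs)
    H = (z2 - z8) / (2 * cs)
    g2 = G**2 + H**2
    with np.errstate(invalid="ignore", divide="ignore"):
        prof = np.where(g2 < 1e-24, 0.0, -2 * (D * G**2 + E * H**2 + F * G * H) / np.where(g2 < 1e-24, 1, g2))
        plan = np.where(g2 < 1e-24, 0.0, 2 * (D * H**2 + E * G**2 - F * G * H) / np.where(g2 < 1e-24, 1, g2))
    profile_curv = full(prof, 1)
    plan_curv = full(plan, 1)

    # rugosity: triangulated 3-D surface area / planar area over the window
    rug_interior = _rugosity(h, window_cells, cs)
    rugosity = full(rug_interior, half)

    # local sd and TPI over the full window
    wv = _window_views(h, window_cells)
    flat_win = wv.reshape(wv.shape[0], wv.shape[1], -1)
    sd_interior = flat_win.std(axis=-1, ddof=1)
    center_idx = (window_cells * window_cells) // 2
    center = flat_win[..., center_idx]
    neigh_sum = flat_win.sum(axis=-1) - center
    tpi_interior = center - neigh_sum / (window_cells * window_cells - 1)
    depth_sd = full(sd_interior, half)
    tpi = full(tpi_interior, half)  # positive = locally elevated seafloor

    grids = {
        "depth": depth.like(z.copy()),
        "slope": depth.like(slope),
        "eastness": depth.like(eastness),
        "northness": depth.like(northness),
        "profile_curvature": depth.like(profile_curv),
        "plan_curvature": depth.like(plan_curv),
        "rugosity": depth.like(rugosity),
        "depth_sd": depth.like(depth_sd),
        "tpi": depth.like(tpi),
    }
    # nodata propagation: any nodata inside the window poisons the cell
    bad = np.isnan(z)
    if bad.any():
        grow = _window_views(np.pad(bad, half, constant_values=True), window_cells).any(axis=(-2, -1))
        for name in TOPOGRAPHIC_NAMES:
            if name != "depth":
                grids[name].values[grow] = np.nan
    return PredictorStack(
        names=list(TOPOGRAPHIC_NAMES),
        grids=grids,
        family={n: "topographic" for n in TOPOGRAPHIC_NAMES},
    )


def _rugosity(h: np.ndarray, window: int, cs: float) -> np.ndarray:
    """Triangulated surface-area / planar-area ratio per window.

    Each quad of four adjacent grid points splits into two triangles along
    the NW-SE diagonal; the ratio sums triangle areas over the window's
    (window-1)^2 quads against their planar area.
    """
    # per-quad surface area over the whole grid, then box-sum over windows
    a = h[:-1, :-1]  # NW
    b = h[:-1, 1:]   # NE
    c = h[1:, :-1]   # SW
    d = h[1:, 1:]    # SE
    # triangle (a, b, d): edges (cs,0,b-a) and (cs,cs,d-a)
    t1 = _tri_area(cs, 0.0, b - a, cs, cs, d - a)
    # triangle (a, d, c): edges (cs,cs,d-a) and (0,cs,c-a)
    t2 = _tri_area(cs, cs, d - a, 0.0, cs, c - a)
    area = t1 + t2
    q = window - 1  # quads per window side
    qa = sliding_window_view(area, (q, q)).sum(axis=(-2, -1))
    planar = (q * cs) ** 2
    return qa / planar


def _tri_area(ux, uy, uz, vx, vy, vz):
    """Vectorised area of 3-D triangles from their two edge vectors."""
    cxx = uy * vz - uz * vy
    cyy = uz * vx - ux * vz
    czz = ux * vy - uy * vx
    return 0.5 * np.sqrt(cxx**2 + cyy**2 + czz**2)


# ---------------------------------------------------------------------------
# Geographic proxies
# ---------------------------------------------------------------------------

def derive_geographic(grid_template: GridSurface, features: ZoneSet) -> PredictorStack:
    """Four geographic predictor grids: x, y, and distance to two features.

    ``features`` must contain at least two polygons (e.g. a reef-crest
    proxy and a shore edge); distances are Euclidean from each cell centre
    to the nearest point of the feature geometry.
    """
    if len(features) < 2:
        raise ValueError("derive_geographic requires at least two feature polygons")
    xs, ys = grid_template.center_grids()
    f1, f2 = features.zones[0], features.zones[1]
    pts = shapely.points(xs.ravel(), ys.ravel())
    d1 = shapely.distance(pts, f1.polygon).reshape(grid_template.shape)
    d2 = shapely.distance(pts, f2.polygon).reshape(grid_template.shape)
    grids = {
        "easting": grid_template.like(xs),
        "northing": grid_template.like(ys),
        "dist_feature1": grid_template.like(d1),
        "dist_feature2": grid_template.like(d2),
    }
    return PredictorStack(
        names=list(GEOGRAPHIC_NAMES),
        grids=grids,
        family={n: "geographic" for n in GEOGRAPHIC_NAMES},
    )


# ---------------------------------------------------------------------------
# Collinearity filter
# ---------------------------------------------------------------------------

@dataclass
class CorrelationFilterResult:
    """Outcome of the pairwise Spearman screen."""

    retained: list[str]
    dropped: list[tuple[str, str, float]]  # (dropped name, retained partner, rho)

    @property
    def dropped_names(self) -> list[str]:
        return [d[0] for d in self.dropped]


def spearman_rho(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties."""
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def filter_correlated(
    sites: pd.DataFrame,
    predictor_names: list[str] | None = None,
    rho_threshold: float = 0.9,
) -> CorrelationFilterResult:
    """Drop the later member of every highly rank-correlated predictor pair.

    Scans predictors in stack order; for each pair whose |Spearman rho|
    meets ``rho_threshold`` the later-ordered predictor is dropped against
    its earliest retained partner.  Constant predictors have undefined rho
    and are treated as uncorrelated (a warning is logged).
    """
    from .grids import SITE_BASE_COLUMNS

    if predictor_names is None:
        predictor_names = [c for c in sites.columns if c not in SITE_BASE_COLUMNS]
    if len(predictor_names) < 2:
        raise ValueError("need at least two predictors to filter")
    if len(sites) < 3:
        raise ValueError("need at least three sites to estimate rank correlations")

    retained: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for name in predictor_names:
        col = sites[name].to_numpy(dtype=float)
        if np.nanstd(col) == 0:
            logger.warning("predictor %r is constant; Spearman rho undefined, retained", name)
            retained.append(name)
            continue
        partner = None
        rho_hit = np.nan
        for kept in retained:
            kcol = sites[kept].to_numpy(dtype=float)
            if np.nanstd(kcol) == 0:
                continue
            rho = spearman_rho(col, kcol)
            if np.isfinite(rho) and abs(rho) >= rho_threshold:
                partner, rho_hit = kept, rho
                break
        if partner is None:
            retained.append(name)
        else:
            dropped.append((name, partner, rho_hit))
    return CorrelationFilterResult(retained=retained, dropped=dropped)


# ---------------------------------------------------------------------------
# Site extraction
# ---------------------------------------------------------------------------

def extract_at_sites(stack: PredictorStack, sites: pd.DataFrame) -> pd.DataFrame:
    """Attach the containing-cell value of every predictor to each site.

    Sites landing on a nodata cell (in any predictor) are excluded; the
    exclusion count is logged.
    """
    out = sites.copy()
    template = stack.grids[stack.names[0]]
    row, col = template.cell_of(out["x"].to_numpy(), out["y"].to_numpy())
    for name in stack.names:
        out[name] = stack.grids[name].values[row, col]
    valid = ~out[stack.names].isna().any(axis=1)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning("extract_at_sites: excluded %d site(s) on nodata cells", n_dropped)
    return out[valid].reset_index(drop=True)
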