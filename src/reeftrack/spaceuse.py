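"""Kernel home ranges, structure association, fidelity and residency.

Daily, diel-split utilization distributions with a fixed smoothing
bandwidth; the home range is the smallest region holding 95% of the
UD mass. Polygons are filtered on position count and time extent,
associated to the nearest structure within 30 m of the centroid, and
summarized into fidelity and residency metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from skimage import measure

from .diel import label_diel
from .simulate import DEFAULT_EPOCH, ArrayLayout

__all__ = [
    "UDGrid",
    "UDRegion",
    "split_diel",
    "fit_ud",
    "extract_ud95",
    "positions_in_region",
    "qualify_polygon",
    "associate_structure",
    "fidelity",
    "daily_homeranges",
    "residency",
]

DEFAULT_BANDWIDTH = 6.0  # m, fixed smoothing
MIN_POSITIONS = 6
MIN_EXTENT_H = 2.0
ASSOC_RADIUS = 30.0  # m, centroid-to-structure association


@dataclass
class UDGrid:
    """Gridded utilization density. ``density`` is indexed [iy, ix]."""

    xc: np.ndarray  # cell-centre x coordinates
    yc: np.ndarray
    density: np.ndarray
    cell_area: float

    @property
    def mass(self) -> float:
        return float(self.density.sum() * self.cell_area)


@dataclass
class UDRegion:
    """Smallest super-level region holding >= the target UD mass."""

    mask: np.ndarray
    threshold: float
    mass: float
    area: float
    centroid: tuple[float, float]
    polygons: list[Polygon] = field(default_factory=list)
    n_components: int = 1


def split_diel(
    positions: pd.DataFrame,
    anchor: tuple[float, float],
    *,
    epoch: pd.Timestamp = DEFAULT_EPOCH,
) -> pd.DataFrame:
    """Label positions day/night by solar elevation and assign a date.

    Night periods spanning midnight are attributed to the civil date the
    night started on (pre-noon night hours count toward the previous
    day).
    """
    pos = positions.copy()
    when = epoch + pd.to_timedelta(pos["t"], unit="s")
    pos["diel"] = label_diel(when, anchor[0], anchor[1])
    date = when.dt.date
    before_noon = when.dt.hour < 12
    night_prev = (pos["diel"] == "night") & before_noon
    date = pd.Series(date, index=pos.index)
    date[night_prev] = (when[night_prev] - pd.Timedelta(days=1)).dt.date
    pos["date"] = date
    return pos


def fit_ud(
    xy: np.ndarray,
    h: float = DEFAULT_BANDWIDTH,
    grid_step: float = 1.0,
    *,
    pad_factor: float = 4.0,
) -> UDGrid:
    """Bivariate Gaussian KDE with fixed bandwidth ``h`` on a grid.

    The grid pads the data extent by ``pad_factor * h`` so that the
    density integrates to 1 over the grid (renormalized numerically).
    """
    xy = np.asarray(xy, float)
    if len(xy) < MIN_POSITIONS:
        raise ValueError(f"need at least {MIN_POSITIONS} positions")
    pad = pad_factor * h
    x0, y0 = xy.min(axis=0) - pad
    x1, y1 = xy.max(axis=0) + pad
    xc = np.arange(x0, x1 + grid_step, grid_step)
    yc = np.arange(y0, y1 + grid_step, grid_step)
    inv2h2 = 1.0 / (2.0 * h * h)
    dens = np.zeros((len(yc), len(xc)))
    # chunk over points to bound memory
    for i in range(0, len(xy), 256):
        pts = xy[i : i + 256]
        dx2 = (xc[None, :] - pts[:, 0, None]) ** 2
        dy2 = (yc[None, :] - pts[:, 1, None]) ** 2
        dens += np.einsum(
            "py,px->yx", np.exp(-dy2 * inv2h2), np.exp(-dx2 * inv2h2)
        )
    dens /= 2.0 * np.pi * h * h * len(xy)
    cell = grid_step * grid_step
    total = dens.sum() * cell
    dens /= total
    return UDGrid(xc, yc, dens, cell)


def extract_ud95(ud: UDGrid, mass: float = 0.95) -> UDRegion:
    """Smallest-area region containing >= ``mass`` of the UD.

    Cells are accumulated in decreasing density order until the target
    mass is reached; the region is the super-level set at the last
    included cell's density. Contours are traced by marching squares.
    When the region is disjoint, all components count as "inside" but
    the centroid comes from the largest-mass component.
    """
    flat = ud.density.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order]) * ud.cell_area
    k = int(np.searchsorted(csum, mass) + 1)
    k = min(k, len(flat))
    threshold = float(flat[order[k - 1]])
    mask = ud.density >= threshold
    region_mass = float(ud.density[mask].sum() * ud.cell_area)
    area = float(mask.sum() * ud.cell_area)

    labels = measure.label(mask, connectivity=1)
    n_comp = int(labels.max())
    comp_mass = np.array(
        [ud.density[labels == c].sum() for c in range(1, n_comp + 1)]
    )
    main = int(np.argmax(comp_mass)) + 1 if n_comp else 0
    yy, xx = np.nonzero(labels == main)
    w = ud.density[labels == main]
    cx = float(np.average(ud.xc[xx], weights=w))
    cy = float(np.average(ud.yc[yy], weights=w))

    polygons = []
    level = threshold * (1.0 - 1e-9)
    for cont in measure.find_contours(ud.density, level):
        if len(cont) < 4:
            continue
        px = np.interp(cont[:, 1], np.arange(len(ud.xc)), ud.xc)
        py = np.interp(cont[:, 0], np.arange(len(ud.yc)), ud.yc)
        poly = Polygon(np.column_stack([px, py]))
        if poly.is_valid and poly.area > 0:
            polygons.append(poly)
    return UDRegion(
        mask=mask,
        threshold=threshold,
        mass=region_mass,
        area=area,
        centroid=(cx, cy),
        polygons=polygons,
        n_components=max(n_comp, 1),
    )


def positions_in_region(region: UDRegion, ud: UDGrid, xy: np.ndarray) -> np.ndarray:
    """Boolean: does each position fall in the UD95 region (any component)?"""
    xy = np.asarray(xy, float)
    ix = np.clip(np.round((xy[:, 0] - ud.xc[0]) / (ud.xc[1] - ud.xc[0])), 0, len(ud.xc) - 1).astype(int)
    iy = np.clip(np.round((xy[:, 1] - ud.yc[0]) / (ud.yc[1] - ud.yc[0])), 0, len(ud.yc) - 1).astype(int)
    return region.mask[iy, ix]


def qualify_polygon(
    t: np.ndarray, inside: np.ndarray
) -> tuple[bool, int, float]:
    """Apply the acceptance filters to a candidate home-range polygon.

    Requires at least :data:`MIN_POSITIONS` in-region positions whose
    time extent exceeds :data:`MIN_EXTENT_H` hours. Returns
    (accepted, n_inside, extent_h).
    """
    n_in = int(inside.sum())
    if n_in < MIN_POSITIONS:
        return False, n_in, 0.0
    tt = np.asarray(t, float)[inside]
    extent_h = float((tt.max() - tt.min()) / 3600.0)
    return extent_h > MIN_EXTENT_H, n_in, extent_h


def associate_structure(
    centroid: tuple[float, float],
    structures: pd.DataFrame,
    radius: float = ASSOC_RADIUS,
) -> str:
    """Nearest structure id if within ``radius`` of the centroid, else
    "other". Distance ties break to the lexicographically smaller id."""
    d = np.hypot(
        structures["x"].to_numpy(float) - centroid[0],
        structures["y"].to_numpy(float) - centroid[1],
    )
    order = sorted(range(len(d)), key=lambda i: (d[i], str(structures["id"].iloc[i])))
    best = order[0]
    if d[best] < radius:
        return str(structures["id"].iloc[best])
    return "other"


def fidelity(n_total: int, n_inside: int) -> float:
    """Fraction of window positions inside the home-range polygon."""
    if n_total <= 0:
        raise ValueError("no positions in window")
    if not 0 <= n_inside <= n_total:
        raise ValueError("n_inside must lie in [0, n_total]")
    return n_inside / n_total


def daily_homeranges(
    positions: pd.DataFrame,
    structures: pd.DataFrame,
    anchor: tuple[float, float],
    *,
    h: float = DEFAULT_BANDWIDTH,
    grid_step: float = 1.0,
    epoch: pd.Timestamp = DEFAULT_EPOCH,
) -> pd.DataFrame:
    """One qualified home-range polygon per (animal, date, diel).

    Returns a DataFrame with columns tag_id, date, diel, area, cx, cy,
    n_positions, extent_h, structure, fidelity, ud_mass. Windows whose
    polygon fails the position-count or time-extent filters are
    dropped.
    """
    pos = split_diel(positions, anchor, epoch=epoch)
    rows = []
    for (tag_id, date, diel), grp in pos.groupby(["tag_id", "date", "diel"]):
        if len(grp) < MIN_POSITIONS:
            continue
        xy = grp[["x", "y"]].to_numpy(float)
        ud = fit_ud(xy, h=h, grid_step=grid_step)
        region = extract_ud95(ud)
        inside = positions_in_region(region, ud, xy)
        ok, n_in, extent_h = qualify_polygon(grp["t"].to_numpy(), inside)
        if not ok:
            continue
        rows.append(
            {
                "tag_id": tag_id,
                "date": date,
                "diel": diel,
                "area": region.area,
                "cx": region.centroid[0],
                "cy": region.centroid[1],
                "n_positions": int(len(grp)),
                "n_inside": n_in,
                "extent_h": extent_h,
                "structure": associate_structure(region.centroid, structures),
                "fidelity": fidelity(len(grp), n_in),
                "ud_mass": region.mass,
            }
        )
    cols = [
        "tag_id", "date", "diel", "area", "cx", "cy", "n_positions",
        "n_inside", "extent_h", "structure", "fidelity", "ud_mass",
    ]
    return pd.DataFrame(rows, columns=cols)


def residency(
    detections: pd.DataFrame,
    release_times: dict[str, float],
    homeranges: pd.DataFrame,
    *,
    battery_life_days: float = 278.0,
    censor_margin_days: float = 5.0,
) -> pd.DataFrame:
    """Residency (days release -> last detection) and structure use.

    A residency within ``censor_margin_days`` of the battery life is
    flagged censored. ``structure_days`` holds, per structure, the
    number of distinct dates with at least one associated polygon.
    """
    rows = []
    for tag_id, t0 in release_times.items():
        det = detections[detections["tag_id"] == tag_id]
        if det.empty:
            res_days = 0.0
        else:
            t_col = "t" if "t" in det.columns else "t_local"
            res_days = max(0.0, (float(det[t_col].max()) - t0) / 86400.0)
        hr = homeranges[homeranges["tag_id"] == tag_id]
        sdays = {
            str(s): int(g["date"].nunique())
            for s, g in hr.groupby("structure")
        }
        rows.append(
            {
                "tag_id": tag_id,
                "residency_days": res_days,
                "censored": res_days >= battery_life_days - censor_margin_days,
                "structure_days": sdays,
            }
        )
    return pd.DataFrame(rows, columns=["tag_id", "residency_days", "censored", "structure_days"])
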