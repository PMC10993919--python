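"""Spatial line scans along cell borders and border-pair grouping.

A two-dimensional OF line scan is drawn between two anchor points along a cell
border: 18 parallel sampling lines with a lateral spacing of 1 pixel (a band
about 2 μm wide at the acquisition scale), each sampled at 1-pixel steps with
bilinear interpolation; samples outside the binary analysis mask are dropped,
and the surviving lines are averaged along their normal direction.

For scratch-wound fields, the puncta flanking a border are grouped by distance
to the leading edge: the object nearest the edge is group A, the farthest is
group B. In confluent regions no leading edge exists, so the border's objects
are randomly split into groups A' and B' (seeded) and compared by group mean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger("polorder")


@dataclass
class LineScanProfile:
    anchor_points: tuple[tuple[float, float], tuple[float, float]]
    n_lines: int
    spacing_px: float
    positions: np.ndarray  # distance along the scan, px
    mean_of: np.ndarray    # NaN where no line contributed
    n_contributing: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position_px": self.positions, "mean_of": self.mean_of,
                             "n_contributing": self.n_contributing})


def line_scan(
    of_map: np.ndarray,
    mask: np.ndarray,
    anchors: tuple[tuple[float, float], tuple[float, float]],
    n_lines: int = 18,
    spacing: float = 1.0,
    step: float = 1.0,
) -> LineScanProfile:
    """Average OF profile over parallel lines offset along the anchor normal.

    ``anchors`` are two distinct (row, col) points. The band of lines is
    centered on the anchor line. A sample contributes only if its entire
    bilinear support lies inside ``mask`` (conservative masking).
    """
    p0 = np.asarray(anchors[0], dtype=float)
    p1 = np.asarray(anchors[1], dtype=float)
    length = float(np.linalg.norm(p1 - p0))
    if length == 0:
        raise ValueError("anchor points must be distinct")
    u = (p1 - p0) / length                      # along-scan unit vector (row, col)
    normal = np.array([-u[1], u[0]])            # lateral unit vector
    offsets = (np.arange(n_lines) - (n_lines - 1) / 2.0) * spacing
    positions = np.arange(0.0, length + step / 2, step)

    # sample grid: (line, position, 2)
    pts = (p0[None, None, :]
           + positions[None, :, None] * u[None, None, :]
           + offsets[:, None, None] * normal[None, None, :])
    coords = pts.reshape(-1, 2).T
    vals = ndimage.map_coordinates(np.asarray(of_map, dtype=float), coords,
                                   order=1, mode="constant", cval=np.nan)
    inmask = ndimage.map_coordinates(np.asarray(mask, dtype=float), coords,
                                     order=1, mode="constant", cval=0.0)
    vals = vals.reshape(n_lines, positions.size)
    # require every pixel in the bilinear support to be inside the mask
    ok = (inmask.reshape(n_lines, positions.size) > 1.0 - 1e-9) & np.isfinite(vals)

    n_contrib = ok.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n_contrib > 0,
                        np.nansum(np.where(ok, vals, 0.0), axis=0) / np.maximum(n_contrib, 1),
                        np.nan)
    if not n_contrib.any():
        warnings.warn("line scan: every sample fell outside the mask", stacklevel=2)
    return LineScanProfile(anchor_points=(tuple(p0), tuple(p1)), n_lines=n_lines,
                           spacing_px=spacing, positions=positions,
                           mean_of=mean, n_contributing=n_contrib)


def _point_line_distance(points: np.ndarray, edge: tuple[tuple[float, float], tuple[float, float]]) -> np.ndarray:
    """Perpendicular distance of (row, col) points to the infinite line through edge."""
    a = np.asarray(edge[0], dtype=float)
    b = np.asarray(edge[1], dtype=float)
    d = b - a
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("leading-edge anchor points must be distinct")
    rel = np.asarray(points, dtype=float) - a
    return np.abs(rel[:, 0] * d[1] - rel[:, 1] * d[0]) / n


def pair_border_desmosomes(
    objects: pd.DataFrame,
    border_id,
    leading_edge: tuple[tuple[float, float], tuple[float, float]] | None = None,
    rng: np.random.Generator | int | None = None,
    metric: str = "mean_of",
) -> dict | None:
    """Form one (A, B) pair of OF values for the objects flanking a border.

    With a leading edge (two points defining the wound line): A is the object
    whose centroid is nearest the edge, B the farthest. Without one (confluent
    control), objects are randomly split into A'/B' halves and each group's
    mean metric is used; the split is reproducible given the seed.
    Returns None (and logs) when fewer than 2 objects are available.
    """
    if len(objects) < 2:
        logger.info("border %s skipped: fewer than 2 objects", border_id)
        return None
    vals = objects[metric].to_numpy(dtype=float)
    if leading_edge is not None:
        cents = objects[["centroid_row", "centroid_col"]].to_numpy(dtype=float)
        dist = _point_line_distance(cents, leading_edge)
        a_val = float(vals[np.argmin(dist)])
        b_val = float(vals[np.argmax(dist)])
        group = "AB"
    else:
        rng = np.random.default_rng(rng)
        perm = rng.permutation(len(vals))
        half = len(vals) // 2
        a_val = float(np.mean(vals[perm[:half]]))
        b_val = float(np.mean(vals[perm[half:]]))
        group = "A'B'"
    return {"border_id": border_id, "group_scheme": group, "A": a_val, "B": b_val}


def pair_borders_table(
    objects: pd.DataFrame,
    leading_edge: tuple[tuple[float, float], tuple[float, float]] | None = None,
    rng: np.random.Generator | int | None = None,
    metric: str = "mean_of",
) -> pd.DataFrame:
    """Apply :func:`pair_border_desmosomes` per border_id column of ``objects``."""
    rng = np.random.default_rng(rng)
    rows = []
    for bid, grp in objects.groupby("border_id", sort=True):
        pair = pair_border_desmosomes(grp, bid, leading_edge=leading_edge, rng=rng, metric=metric)
        if pair is not None:
            rows.append(pair)
    return pd.DataFrame(rows, columns=["border_id", "group_scheme", "A", "B"])
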