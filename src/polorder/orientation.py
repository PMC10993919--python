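"""Per-pixel Order Factor and azimuth from a normalized four-polarization stack.

With normalized intensities I0, I45, I90, I135 at one pixel, the differential
responses are

    A  = I0  - I90
    B  = I45 - I135
    OF = sqrt(A^2 + B^2)
    alpha = arctan2(B, A) / 2

OF reports the in-plane orientational order of the fluorophore transition
dipoles within the pixel; alpha is their mean in-plane orientation, an axial
quantity with a 180° ambiguity, reported in degrees on (-90, +90].

Two properties of this estimator are deliberate and preserved:

* OF is **not** clipped to [0, 1]. Because normalization divides by the
  per-pixel four-channel maximum, a perfectly aligned population at 22.5° to
  an acquisition axis yields OF ≈ 1.17 while the same population at 0° yields
  OF = 1. Clipping would silently alter the published estimator.
* Where OF = 0 (isotropic pixel), arctan2(0, 0) is convention-dependent; the
  azimuth is flagged undefined (NaN + valid_mask False) rather than set to 0,
  so disorder statistics never ingest fabricated angles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stacks import NormalizedStack


@dataclass
class OrientationMaps:
    """Per-pixel OF map and azimuth map with validity mask.

    ``azimuth_deg`` is NaN wherever ``valid_mask`` is False (zero-signal pixel
    or OF = 0 making the azimuth undefined).
    """

    of_map: np.ndarray
    azimuth_deg: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self):
        if not (self.of_map.shape == self.azimuth_deg.shape == self.valid_mask.shape):
            raise ValueError("of_map, azimuth_deg and valid_mask must share a shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.of_map.shape


def wrap_azimuth_deg(alpha: np.ndarray) -> np.ndarray:
    """Wrap axial angles (degrees) to the half-open interval (-90, +90]."""
    wrapped = (np.asarray(alpha, dtype=float) + 90.0) % 180.0 - 90.0
    # map the -90 representative to +90 so the interval is half-open at -90
    return np.where(wrapped == -90.0, 90.0, wrapped)


def compute_orientation_maps(normalized: NormalizedStack) -> OrientationMaps:
    """Compute OF and azimuth maps from a pixel-wise max-normalized stack."""
    i0, i45, i90, i135 = normalized.images
    a = i0 - i90
    b = i45 - i135
    of = np.sqrt(a * a + b * b)
    of = np.where(normalized.valid_mask, of, 0.0)
    valid = normalized.valid_mask & (of > 0)
    alpha = np.degrees(np.arctan2(b, a) / 2.0)
    alpha = wrap_azimuth_deg(alpha)
    alpha = np.where(valid, alpha, np.nan)
    return OrientationMaps(of_map=of, azimuth_deg=alpha, valid_mask=valid)


def azimuth_lines_overlay(
    maps: OrientationMaps,
    mask: np.ndarray | None = None,
    scale: float = 1.0,
) -> np.ndarray:
    """Line segments visualizing pixel azimuths, length proportional to OF.

    Returns an ``(n, 4)`` array of segments ``(x0, y0, x1, y1)`` in pixel
    coordinates (x = column, y = row), one per masked valid pixel, centered on
    the pixel and oriented at its azimuth. Pixels with OF = 0 emit no segment.
    Use :func:`plot_azimuth_overlay` to render them.
    """
    if mask is None:
        mask = np.ones(maps.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != maps.shape:
        raise ValueError("mask dimensions must match the maps")
    sel = mask & maps.valid_mask & (maps.of_map > 0)
    rows, cols = np.nonzero(sel)
    of = maps.of_map[rows, cols]
    alpha = np.radians(maps.azimuth_deg[rows, cols])
    # screen y grows downward; a positive (counterclockwise) azimuth needs -sin
    dx = 0.5 * scale * of * np.cos(alpha)
    dy = -0.5 * scale * of * np.sin(alpha)
    return np.column_stack([cols - dx, rows - dy, cols + dx, rows + dy])


def plot_azimuth_overlay(maps: OrientationMaps, mask=None, scale: float = 1.0, ax=None,
                         background: np.ndarray | None = None, **line_kw):
    """Render the azimuth-line overlay on a matplotlib axis."""
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection

    if ax is None:
        _, ax = plt.subplots()
    if background is not None:
        ax.imshow(background, cmap="gray")
    segs = azimuth_lines_overlay(maps, mask=mask, scale=scale)
    coll = LineCollection(segs.reshape(-1, 2, 2), **({"colors": "w", "linewidths": 0.8} | line_kw))
    ax.add_collection(coll)
    ax.set_xlim(-0.5, maps.shape[1] - 0.5)
    ax.set_ylim(maps.shape[0] - 0.5, -0.5)
    ax.set_aspect("equal")
    return ax
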