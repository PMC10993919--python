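"""Forward simulation of polarized-excitation imaging of dipole ensembles.

Scenes emulate punctate adhesive junctions along cell borders: each punctum is
a small disk of fluorophores whose in-plane transition dipoles follow a
wrapped-normal distribution around a mean azimuth (typically the border
normal). For excitation polarization θ the expected photon signal at a pixel is

    E(θ) = background + Σ_puncta amplitude · shape(pixel) · <cos²(θ − φ)>

where the ensemble average over a wrapped normal with mean μ and spread σ has
the closed form

    <cos²(θ − φ)> = ½ (1 + c₂ cos 2(θ − μ)),   c₂ = exp(−2σ²)  (σ in radians).

The dipole spread σ_d of a punctum is partitioned into a within-pixel
component σ_w and a between-pixel component σ_b with σ_w² + σ_b² = σ_d²
(equal split by default): each pixel's sub-ensemble mean is drawn from a
wrapped normal around the punctum mean with spread σ_b, and the within-pixel
average uses c₂(σ_w). The within-pixel spread controls the pixel OF, the
between-pixel spread controls the azimuthal disorder of the punctum — so a
single σ_d knob degrades both order readouts together, as junction immaturity
does.

The expected image is then blurred by an isotropic Gaussian PSF, multiplied by
a smooth flat-field (radial vignette), and corrupted by Poisson shot noise and
Gaussian read noise. Rendering is deterministic given the scene's RNG seed.

Out-of-plane dipole tilt is not modeled; the measurement is an in-plane
projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .stacks import FlatFieldStack, PolarizationStack

POL_ANGLES_DEG = (0.0, 45.0, 90.0, 135.0)

#: fraction of the total dipole variance assigned to the within-pixel spread
WITHIN_PIXEL_VARIANCE_FRACTION = 0.5


@dataclass
class Punctum:
    center: tuple[float, float]        # (row, col)
    diameter_px: float = 5.0
    amplitude: float = 400.0           # expected photons/pixel at full alignment
    mean_azimuth_deg: float = 0.0
    circ_spread_deg: float = 10.0      # total dipole spread σ_d
    border_id: int = -1
    edge_distance: float = np.nan      # distance to the leading edge, px


@dataclass
class SceneSpec:
    image_size: tuple[int, int] = (256, 256)
    puncta: list[Punctum] = field(default_factory=list)
    background: float = 20.0           # expected photons/pixel/channel
    vignette_depth: float = 0.3        # relative falloff of the flat field at the corners
    psf_sigma: float = 1.2             # px, isotropic Gaussian
    poisson_noise: bool = True
    read_noise_sigma: float = 2.0      # photons-equivalent
    rng_seed: int = 0
    pixel_size_um: float = 0.108

    def validate(self) -> None:
        h, w = self.image_size
        for p in self.puncta:
            if p.amplitude <= 0:
                raise ValueError("punctum amplitudes must be > 0")
            if p.circ_spread_deg < 0:
                raise ValueError("circular spreads must be >= 0")
            r, c = p.center
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"punctum center {p.center} out of bounds for {self.image_size}")


@dataclass
class GroundTruth:
    puncta: pd.DataFrame               # one record per punctum incl. analytic OF
    label_map: np.ndarray              # punctum id per pixel (0 = background)
    rng_seed: int = 0


def wrapped_normal_c2(sigma_deg: float) -> float:
    """Second circular moment (resultant length of doubled angles) of a wrapped normal."""
    s = np.radians(sigma_deg)
    return float(np.exp(-2.0 * s * s))


def noiseless_of(mean_azimuth_deg: float, sigma_deg: float) -> float:
    """Analytic OF of a wrapped-normal dipole ensemble, after max-normalization.

    Channel responses are ½(1 + c₂ cos 2(θ − μ)); the raw differentials give
    A² + B² = c₂², and dividing by the largest of the four channels yields

        OF = 2 c₂ / (1 + c₂ · max(|cos 2μ|, |sin 2μ|)).

    The estimator is therefore not rotation-invariant: OF = 1 for a fully
    aligned ensemble on an acquisition axis but ≈ 1.17 at 22.5° between axes.
    """
    c2 = wrapped_normal_c2(sigma_deg)
    mu = np.radians(mean_azimuth_deg)
    m = max(abs(np.cos(2 * mu)), abs(np.sin(2 * mu)))
    return 2.0 * c2 / (1.0 + c2 * m)


def make_radial_vignette(shape: tuple[int, int], depth: float) -> np.ndarray:
    """Smooth multiplicative field: 1 at the center, 1 − depth at the corners."""
    if not 0 <= depth < 1:
        raise ValueError("vignette depth must be in [0, 1)")
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    r2 = ((rr - (h - 1) / 2) ** 2 + (cc - (w - 1) / 2) ** 2)
    r2max = ((h - 1) / 2) ** 2 + ((w - 1) / 2) ** 2
    return 1.0 - depth * r2 / r2max


def scene_flat_field(spec: SceneSpec) -> FlatFieldStack:
    """The flat-field stack a calibration acquisition of this scene would yield."""
    v = make_radial_vignette(spec.image_size, spec.vignette_depth)
    images = np.broadcast_to(v, (4, *spec.image_size)).copy()
    return FlatFieldStack(images / images.max(), source_count=1, flat_id="simulated-vignette")


def _disk_pixels(center: tuple[float, float], diameter: float, shape: tuple[int, int]):
    r0, c0 = center
    rad = diameter / 2.0
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    sel = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad * rad
    return np.nonzero(sel)


def render_scene(spec: SceneSpec) -> tuple[PolarizationStack, GroundTruth]:
    """Render the four-polarization raw stack and its ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.image_size
    expected = np.full((4, h, w), float(spec.background))
    label_map = np.zeros((h, w), dtype=np.int32)
    frac = WITHIN_PIXEL_VARIANCE_FRACTION
    records = []
    thetas = np.radians(POL_ANGLES_DEG)
    for pid, p in enumerate(spec.puncta, start=1):
        rows, cols = _disk_pixels(p.center, p.diameter_px, (h, w))
        sigma_w = p.circ_spread_deg * np.sqrt(frac)
        sigma_b = p.circ_spread_deg * np.sqrt(1.0 - frac)
        # per-pixel sub-ensemble means around the punctum mean azimuth
        phi = np.radians(p.mean_azimuth_deg + rng.normal(0.0, sigma_b, size=rows.size))
        c2w = wrapped_normal_c2(sigma_w)
        for k, th in enumerate(thetas):
            expected[k, rows, cols] += p.amplitude * 0.5 * (1.0 + c2w * np.cos(2.0 * (th - phi)))
        label_map[rows, cols] = pid
        records.append(dict(
            punctum_id=pid, center_row=p.center[0], center_col=p.center[1],
            diameter_px=p.diameter_px, amplitude=p.amplitude,
            mean_azimuth_deg=p.mean_azimuth_deg, circ_spread_deg=p.circ_spread_deg,
            sigma_within_deg=sigma_w, sigma_between_deg=sigma_b,
            c2_within=c2w, true_of=noiseless_of(p.mean_azimuth_deg, sigma_w),
            border_id=p.border_id, edge_distance=p.edge_distance,
            n_pixels=rows.size,
        ))
    if spec.psf_sigma > 0:
        for k in range(4):
            expected[k] = ndimage.gaussian_filter(expected[k], spec.psf_sigma)
    expected *= make_radial_vignette((h, w), spec.vignette_depth)[None]
    if spec.poisson_noise:
        images = rng.poisson(expected).astype(np.float64)
    else:
        images = expected.copy()
    if spec.read_noise_sigma > 0:
        images += rng.normal(0.0, spec.read_noise_sigma, size=images.shape)
    images = np.clip(images, 0.0, None)
    raw = PolarizationStack(images, pixel_size=spec.pixel_size_um,
                            field_id=f"sim-seed{spec.rng_seed}")
    cols = ["punctum_id", "center_row", "center_col", "diameter_px", "amplitude",
            "mean_azimuth_deg", "circ_spread_deg", "sigma_within_deg",
            "sigma_between_deg", "c2_within", "true_of", "border_id",
            "edge_distance", "n_pixels"]
    gt = GroundTruth(pd.DataFrame(records, columns=cols), label_map, rng_seed=spec.rng_seed)
    return raw, gt


# ---------------------------------------------------------------------------
# Scene builders
# ---------------------------------------------------------------------------

def _puncta_along_line(start, end, spacing, rng, amplitude, diameter, sigma_d,
                       azimuth_jitter_deg=8.0, sigma_jitter_deg=3.0,
                       border_id=-1, edge=None) -> list[Punctum]:
    """Place puncta along a border segment, dipole means near the border normal."""
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    length = float(np.linalg.norm(end - start))
    u = (end - start) / length
    # azimuths are measured from +x (columns), counterclockwise with y up, so a
    # (row, col) direction maps to xy angle atan2(-u_row, u_col); normal = +90°
    normal_az = np.degrees(np.arctan2(-u[0], u[1])) + 90.0
    n = int(length // spacing) + 1
    out = []
    for i in range(n):
        pos = start + (i * spacing) * u
        mu = normal_az + rng.normal(0.0, azimuth_jitter_deg)
        sd = max(float(sigma_d + rng.uniform(-sigma_jitter_deg, sigma_jitter_deg)), 1.0)
        dist = np.nan
        if edge is not None:
            a, b = np.asarray(edge[0], float), np.asarray(edge[1], float)
            d = b - a
            dist = abs((pos[0] - a[0]) * d[1] - (pos[1] - a[1]) * d[0]) / np.linalg.norm(d)
        out.append(Punctum(center=(float(pos[0]), float(pos[1])), diameter_px=diameter,
                           amplitude=amplitude, mean_azimuth_deg=float(mu),
                           circ_spread_deg=sd, border_id=border_id, edge_distance=float(dist)))
    return out


def build_border_field(
    sigma_d: float,
    rng: np.random.Generator,
    image_size: tuple[int, int] = (256, 256),
    n_borders: int = 5,
    spacing: float = 14.0,
    amplitude: float = 400.0,
    diameter: float = 5.0,
    template: SceneSpec | None = None,
) -> SceneSpec:
    """One field of view: straight cell borders with puncta of spread sigma_d."""
    h, w = image_size
    margin = 12
    puncta: list[Punctum] = []
    row_positions = np.linspace(margin + 8, h - margin - 8, n_borders)
    for bid, r in enumerate(row_positions):
        r = float(r + rng.uniform(-4, 4))
        puncta += _puncta_along_line((r, margin), (r, w - margin), spacing, rng,
                                     amplitude, diameter, sigma_d, border_id=bid)
    base = template or SceneSpec()
    return replace(base, image_size=image_size, puncta=puncta,
                   rng_seed=int(rng.integers(2**31 - 1)))


def render_assembly_series(
    spread_schedule: list[tuple[str, float]],
    rng: np.random.Generator | int | None = 0,
    n_fields_per_label: int = 3,
    template: SceneSpec | None = None,
    image_size: tuple[int, int] = (256, 256),
    n_borders: int = 5,
) -> tuple[list[dict], pd.DataFrame]:
    """Render a synchronized-assembly series: one dipole-spread level per label.

    ``spread_schedule`` maps condition labels (e.g. 2h..8h, no-pulse) to the
    dipole spread σ_d applied to that label's puncta. Presets:
    "gradual" 60→40→25→15→10, "constant" 10 at every label, "stepwise"
    60,60,60,10,10. Returns the rendered fields and a manifest table.
    """
    if len(spread_schedule) < 2:
        raise ValueError("need at least 2 schedule entries")
    rng = np.random.default_rng(rng)
    fields, manifest = [], []
    for label, sigma_d in spread_schedule:
        for j in range(n_fields_per_label):
            spec = build_border_field(sigma_d, rng, image_size=image_size,
                                      n_borders=n_borders, template=template)
            raw, gt = render_scene(spec)
            flat = scene_flat_field(spec)
            field_id = f"{label}-f{j}"
            raw.field_id = field_id
            fields.append(dict(label=label, field_id=field_id, sigma_d=sigma_d,
                               spec=spec, raw=raw, flat=flat, gt=gt))
            manifest.append(dict(field_id=field_id, condition=label,
                                 sigma_d=sigma_d, n_puncta=len(spec.puncta),
                                 rng_seed=spec.rng_seed))
    return fields, pd.DataFrame(manifest)


SPREAD_PRESETS = {
    "gradual": [("2h", 60.0), ("4h", 40.0), ("6h", 25.0), ("8h", 15.0), ("no-pulse", 10.0)],
    "constant": [("2h", 10.0), ("4h", 10.0), ("6h", 10.0), ("8h", 10.0), ("no-pulse", 10.0)],
    "stepwise": [("2h", 60.0), ("4h", 60.0), ("6h", 60.0), ("8h", 10.0), ("no-pulse", 10.0)],
}


def render_scratch_scene(
    gradient: tuple[float, float] | None,
    rng: np.random.Generator | int | None = 0,
    n_borders: int = 15,
    puncta_per_border: int = 8,
    punctum_spacing: float = 16.0,
    border_spacing: float = 16.0,
    edge_offset: float = 8.0,
    amplitude: float = 400.0,
    diameter: float = 5.0,
    template: SceneSpec | None = None,
) -> tuple[SceneSpec, PolarizationStack, FlatFieldStack, GroundTruth]:
    """A wounded-monolayer field: borders run perpendicular to a straight edge.

    ``gradient = (sigma_near, sigma_far)`` sets the dipole spread linearly in
    distance from the leading edge (decreasing spread = maturing desmosomes);
    ``None`` renders the confluent control where the spread is flat (uses the
    far value 10°). The leading edge is the vertical line col = ``edge_offset``
    and is recorded in the ground truth.
    """
    rng = np.random.default_rng(rng)
    h = int(n_borders * border_spacing + 24)
    w = int(edge_offset + puncta_per_border * punctum_spacing + 20)
    edge = ((0.0, edge_offset), (float(h), edge_offset))
    puncta: list[Punctum] = []
    for bid in range(n_borders):
        r = 16.0 + bid * border_spacing + rng.uniform(-3, 3)
        for k in range(puncta_per_border):
            dist = 6.0 + k * punctum_spacing
            c = edge_offset + dist
            if gradient is None:
                sd = 10.0
            else:
                near, far = gradient
                t = k / max(puncta_per_border - 1, 1)
                sd = near + (far - near) * t
            sd = max(sd + rng.uniform(-2, 2), 1.0)
            mu = 0.0 + rng.normal(0.0, 8.0)   # border normal points along +x here
            puncta.append(Punctum(center=(r, float(c)), diameter_px=diameter,
                                  amplitude=amplitude, mean_azimuth_deg=float(mu),
                                  circ_spread_deg=float(sd), border_id=bid,
                                  edge_distance=float(dist)))
    base = template or SceneSpec()
    spec = replace(base, image_size=(h, w), puncta=puncta,
                   rng_seed=int(rng.integers(2**31 - 1)))
    raw, gt = render_scene(spec)
    flat = scene_flat_field(spec)
    gt.puncta.attrs["leading_edge"] = edge if gradient is not None else None
    return spec, raw, flat, gt
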