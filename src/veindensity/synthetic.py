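"""Synthetic stained-leaf image generator with exact ground truth.

Emulates cleared, iodine-stained leaf micrographs — dark curvilinear vein
strands of finite stroke width on a bright, noisy, unevenly illuminated
background — in two topologies:

* ``parallel``: longitudinal veins (rails) running the image height, as in
  grass leaves, plus short transverse commissural rungs between adjacent
  rails;
* ``reticulate``: wavy primaries joined by slanted secondaries forming
  closed areoles, a coarse dicot-like mesh.

Centrelines are polylines with a known analytic arc length, so every
generated image carries an exact ground-truth total vein length (and, for
the parallel topology, a rails-only length that excludes the rungs). The
geometry is a deterministic function of the geometric parameters alone;
the seed drives only the noise field, so two seeds give identical vein
networks under different noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import line as _draw_line
from skimage.morphology import dilation, disk

__all__ = ["SyntheticVeinSpec", "SyntheticImage", "generate",
           "ground_truth_density", "rails_only_density"]

_GOLDEN_ANGLE = 2.399963229728653  # rad; staggers per-primary waviness phases


@dataclass(frozen=True)
class SyntheticVeinSpec:
    """Parameters + seed describing one generated venation image.

    Defaults emulate the study conditions: a 1392 x 1040 px microscope
    frame at 0.65 um/px (~x100 magnification), vein strands ~5 px wide,
    interveinal spacing 150 px (~98 um, within the grass range), dark
    strands (0.25) on a light background (0.85) with Gaussian noise
    (sd 0.03) and a 10% linear illumination ramp across the width.
    """

    topology: str = "parallel"          # "parallel" or "reticulate"
    image_height: int = 1040
    image_width: int = 1392
    pixel_length_um: float = 0.65
    n_primaries: int = 8
    rail_spacing_px: float = 150.0
    waviness_amplitude_px: float = 6.0
    commissural_spacing_px: float = 220.0   # parallel topology only
    stroke_width_px: int = 5
    background_level: float = 0.85
    vein_level: float = 0.25
    noise_sd: float = 0.03
    illumination_gradient: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in ("parallel", "reticulate"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.vein_level >= self.background_level:
            raise ValueError("vein_level must be below background_level (dark-on-light)")
        if self.stroke_width_px < 1:
            raise ValueError("stroke_width_px must be >= 1")
        if self.image_height < 16 or self.image_width < 16:
            raise ValueError("image must be at least 16 x 16")
        if self.noise_sd < 0 or self.waviness_amplitude_px < 0:
            raise ValueError("noise_sd and waviness_amplitude_px must be >= 0")
        if self.n_primaries > 0:
            margin = self.stroke_width_px + self.waviness_amplitude_px + 1
            span = (self.n_primaries - 1) * self.rail_spacing_px
            if span + 2 * margin > self.image_width:
                raise ValueError(
                    f"{self.n_primaries} primaries at spacing {self.rail_spacing_px} px "
                    f"(+{margin:.0f} px margin) exceed image width {self.image_width}")


@dataclass(frozen=True)
class SyntheticImage:
    """One rendered image with its exact ground truth."""

    image: np.ndarray                 # float64 in [0, 1]
    ground_truth_length_um: float     # analytic centreline arc length
    centreline: np.ndarray            # uint8 {0,1} rasterized centrelines
    rails_only_length_um: float       # excludes commissural rungs


def _polyline_length(points: np.ndarray) -> float:
    """Arc length of a polyline given as an (n, 2) float array of (row, col)."""
    d = np.diff(points, axis=0)
    return float(np.sqrt((d ** 2).sum(axis=1)).sum())


def _primary_polyline(spec: SyntheticVeinSpec, i: int) -> np.ndarray:
    """Centreline of primary ``i``: a vertical sinusoid sampled every row."""
    h = spec.image_height
    margin = spec.stroke_width_px + spec.waviness_amplitude_px + 1
    span = (spec.n_primaries - 1) * spec.rail_spacing_px
    x0 = (spec.image_width - span) / 2.0 + i * spec.rail_spacing_px
    if spec.n_primaries == 1:
        x0 = spec.image_width / 2.0
    x0 = min(max(x0, margin), spec.image_width - margin)
    y = np.arange(h, dtype=np.float64)
    wavelength = max(h / 2.5, 1.0)
    phase = _GOLDEN_ANGLE * i
    x = x0 + spec.waviness_amplitude_px * np.sin(2.0 * np.pi * y / wavelength + phase)
    return np.column_stack([y, x])


def _x_on_primary(poly: np.ndarray, y: float) -> float:
    """Column of a primary's centreline at (integer-ish) row y."""
    return float(poly[int(round(y)), 1])


def _network_polylines(spec: SyntheticVeinSpec):
    """Return (primary polylines, connector polylines).

    Connectors are the commissural rungs (parallel) or the areole-forming
    secondaries (reticulate); placement is deterministic. Parallel rungs
    are aligned across gaps, keeping the along-rail junction spacing above
    the rung span as in grass leaves (where commissural veins are short
    relative to the distance between them along a vein); reticulate
    secondaries are staggered by half a spacing in alternating gaps to
    form an irregular areole mesh.
    """
    primaries = [_primary_polyline(spec, i) for i in range(spec.n_primaries)]
    connectors: list[np.ndarray] = []
    if spec.n_primaries < 2:
        return primaries, connectors
    h = spec.image_height
    spacing = spec.commissural_spacing_px if spec.topology == "parallel" else 2.2 * spec.rail_spacing_px
    pad = spec.stroke_width_px + 2.0
    stagger = spec.topology == "reticulate"
    for gap in range(spec.n_primaries - 1):
        offset = (spacing / 2.0) * (gap % 2 if stagger else 0) + spacing / 2.0
        y = offset
        while y < h - pad:
            if y >= pad:
                ya = y
                # reticulate secondaries slant, closing polygonal areoles
                yb = min(max(y + (0.35 * spacing if spec.topology == "reticulate" else 0.0),
                             pad), h - pad - 1)
                xa = _x_on_primary(primaries[gap], ya)
                xb = _x_on_primary(primaries[gap + 1], yb)
                connectors.append(np.array([[ya, xa], [yb, xb]]))
            y += spacing
    return primaries, connectors


def _rasterize(polys: list[np.ndarray], shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for poly in polys:
        pts = np.rint(poly).astype(int)
        # drop consecutive duplicates after rounding
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = (np.diff(pts, axis=0) != 0).any(axis=1)
        pts = pts[keep]
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            rr, cc = _draw_line(r0, c0, r1, c1)
            ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
            mask[rr[ok], cc[ok]] = True
        if len(pts) == 1:
            r, c = pts[0]
            if 0 <= r < shape[0] and 0 <= c < shape[1]:
                mask[r, c] = True
    return mask


def generate(spec: SyntheticVeinSpec) -> SyntheticImage:
    """Render the image described by ``spec``; deterministic for a given seed."""
    shape = (spec.image_height, spec.image_width)
    primaries, connectors = _network_polylines(spec)

    rails_len_px = sum(_polyline_length(p) for p in primaries)
    total_len_px = rails_len_px + sum(_polyline_length(c) for c in connectors)

    centreline = _rasterize(primaries + connectors, shape)
    radius = (spec.stroke_width_px - 1) // 2
    stroke = dilation(centreline, disk(radius)) if radius > 0 else centreline

    cols = np.arange(spec.image_width, dtype=np.float64)
    ramp = spec.illumination_gradient * (cols / max(spec.image_width - 1, 1) - 0.5)
    img = np.full(shape, spec.background_level, dtype=np.float64) + ramp[None, :]
    img[stroke] = spec.vein_level
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=shape)
    img = np.clip(img, 0.0, 1.0)

    return SyntheticImage(
        image=img,
        ground_truth_length_um=total_len_px * spec.pixel_length_um,
        centreline=centreline.astype(np.uint8),
        rails_only_length_um=rails_len_px * spec.pixel_length_um,
    )


def ground_truth_density(spec: SyntheticVeinSpec) -> float:
    """Analytic vein density of ``spec`` in um mm^-2 (same unit convention
    as the pipeline's measurement)."""
    primaries, connectors = _network_polylines(spec)
    length_um = sum(_polyline_length(p) for p in primaries + connectors) * spec.pixel_length_um
    area_mm2 = spec.image_height * spec.image_width * spec.pixel_length_um ** 2 * 1e-6
    return length_um / area_mm2


def rails_only_density(spec: SyntheticVeinSpec) -> float:
    """Analytic density of the longitudinal veins alone (rungs excluded)."""
    primaries, _ = _network_polylines(spec)
    length_um = sum(_polyline_length(p) for p in primaries) * spec.pixel_length_um
    area_mm2 = spec.image_height * spec.image_width * spec.pixel_length_um ** 2 * 1e-6
    return length_um / area_mm2
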