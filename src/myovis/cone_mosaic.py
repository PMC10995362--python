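"""Cone photoreceptor mosaic detection and morphometry.

Cones in adaptive-optics (AO) fundus images appear as bright, roughly
Gaussian spots on a quasi-hexagonal lattice.  Within 100 x 100 um regions of
interest (ROIs) placed at fixed eccentricities from the fovea we detect cone
centers and summarize the mosaic with three standard morphometric measures:

density
    number of cones per square millimeter of retina;
spacing
    mean center-to-center distance of adjacent cones, where adjacency is
    defined by the Delaunay triangulation (long convex-hull edges pruned);
regularity
    percentage of cones whose Voronoi cell has 5-7 sides, evaluated on cells
    fully interior to the ROI (border cells have undercounted neighbors and
    are excluded from both numerator and denominator).

Detection is a difference-of-Gaussians band-pass tuned to the expected cone
period, followed by local-maximum picking with a minimum-separation
constraint and sub-pixel center-of-mass refinement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import Delaunay, Voronoi
from skimage.feature import peak_local_max

__all__ = [
    "AOImage",
    "ROISpec",
    "ConeMosaic",
    "ConeMetrics",
    "DetectionParams",
    "MERIDIANS",
    "detect_cones",
    "mosaic_metrics",
    "average_regions",
    "read_ao_image",
    "mosaics_to_csv",
    "metrics_to_frame",
]

MERIDIANS = ("superior", "temporal", "inferior", "nasal")

# unit vectors (dx, dy) in image coordinates per meridian; y grows downward,
# superior retina is up in the image, temporal direction taken toward +x
_MERIDIAN_DIR = {
    "superior": (0.0, -1.0),
    "inferior": (0.0, 1.0),
    "temporal": (1.0, 0.0),
    "nasal": (-1.0, 0.0),
}


@dataclass(frozen=True)
class AOImage:
    """Single-channel AO montage with physical scale and fovea location.

    ``pixel_scale`` is um/pixel *after* any ocular-magnification correction;
    ``fovea_xy`` is the (x, y) pixel coordinate of the foveal center.
    """

    pixels: np.ndarray
    pixel_scale: float
    fovea_xy: tuple[float, float]

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("AOImage.pixels must be a 2-D grayscale array")
        object.__setattr__(self, "pixels", px)
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        x, y = self.fovea_xy
        h, w = px.shape
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError("fovea_xy outside image bounds")


@dataclass(frozen=True)
class ROISpec:
    """Square ROI at a given eccentricity along one meridian.

    ``center_eccentricity`` is the distance from the fovea to the ROI center
    in mm; ``offset_um`` shifts the center perpendicular to the meridian so
    callers can dodge blood vessels (vessel detection is out of scope).
    """

    center_eccentricity: float
    meridian: str
    side_length: float = 100.0
    region_label: str = "inner"
    offset_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.side_length <= 0:
            raise ValueError("side_length must be positive")
        if self.center_eccentricity < 0:
            raise ValueError("eccentricity must be non-negative")
        if self.meridian not in _MERIDIAN_DIR:
            raise ValueError(f"meridian must be one of {MERIDIANS}")

    @property
    def area_mm2(self) -> float:
        return (self.side_length / 1000.0) ** 2


@dataclass(frozen=True)
class ConeMosaic:
    """Detected cone centers, in um within the ROI frame (origin = ROI corner)."""

    positions: np.ndarray
    roi: ROISpec

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "positions", pos)
        s = self.roi.side_length
        if pos.size and (pos.min() < -1e-9 or pos.max() > s + 1e-9):
            raise ValueError("cone positions outside ROI bounds")

    @property
    def n_cones(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class ConeMetrics:
    """Density (cones/mm^2), spacing (um), regularity (% of 5-7 neighbor cells)."""

    density: float
    spacing: float
    regularity: float
    n_cones: int
    nn_spacing: float = float("nan")  # mean nearest-neighbor distance, um
    region_label: str = ""
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class DetectionParams:
    """Tunables for the band-pass + local-maxima cone detector.

    ``expected_spacing_um`` sets the band-pass scale and the minimum allowed
    separation (``min_separation_fraction`` of the expected spacing).
    """

    expected_spacing_um: float = 5.0
    min_separation_fraction: float = 0.5
    dog_sigma_fraction: float = 0.20  # inner DoG sigma as fraction of spacing
    dog_sigma_ratio: float = 2.0
    refine_radius_px: int = 2
    rel_threshold: float = 0.10  # peak threshold relative to band-passed max


def roi_bounds(image: AOImage, roi: ROISpec) -> tuple[int, int, int, int]:
    """Pixel bounds (x0, y0, x1, y1) of the ROI; raises if not fully inside."""
    dx, dy = _MERIDIAN_DIR[roi.meridian]
    ecc_um = roi.center_eccentricity * 1000.0
    cx = image.fovea_xy[0] + (dx * ecc_um + roi.offset_um[0]) / image.pixel_scale
    cy = image.fovea_xy[1] + (dy * ecc_um + roi.offset_um[1]) / image.pixel_scale
    half = roi.side_length / 2.0 / image.pixel_scale
    x0, x1 = int(round(cx - half)), int(round(cx + half))
    y0, y1 = int(round(cy - half)), int(round(cy + half))
    h, w = image.pixels.shape
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise ValueError(f"ROI {roi} extends outside the image ({w}x{h} px)")
    return x0, y0, x1, y1


def detect_cones(
    image: AOImage, roi: ROISpec, params: DetectionParams = DetectionParams()
) -> ConeMosaic:
    """Detect cone centers inside ``roi``.

    Returns positions in um relative to the ROI's top-left corner.  A flat
    (zero-variance) ROI yields an empty mosaic with a warning.
    """
    x0, y0, x1, y1 = roi_bounds(image, roi)
    patch = image.pixels[y0:y1, x0:x1].astype(float)
    if patch.std() < 1e-12:
        warnings.warn("flat ROI: no cones detected", stacklevel=2)
        return ConeMosaic(positions=np.empty((0, 2)), roi=roi)

    sigma1 = params.dog_sigma_fraction * params.expected_spacing_um / image.pixel_scale
    sigma2 = params.dog_sigma_ratio * sigma1
    band = ndimage.gaussian_filter(patch, sigma1) - ndimage.gaussian_filter(patch, sigma2)

    min_sep_px = max(
        1,
        int(round(params.min_separation_fraction * params.expected_spacing_um / image.pixel_scale)),
    )
    peak_max = band.max()
    if peak_max <= 0:
        return ConeMosaic(positions=np.empty((0, 2)), roi=roi)
    coords = peak_local_max(
        band,
        min_distance=min_sep_px,
        threshold_abs=params.rel_threshold * peak_max,
        exclude_border=False,
    )

    # sub-pixel refinement: center of mass of the positive band-passed signal
    r = params.refine_radius_px
    refined = []
    h, w = band.shape
    for py, px in coords:
        ys = slice(max(0, py - r), min(h, py + r + 1))
        xs = slice(max(0, px - r), min(w, px + r + 1))
        win = np.clip(band[ys, xs], 0, None)
        tot = win.sum()
        if tot <= 0:
            refined.append((float(px), float(py)))
            continue
        yy, xx = np.mgrid[ys, xs]
        refined.append((float((win * xx).sum() / tot), float((win * yy).sum() / tot)))
    pos_um = np.asarray(refined, dtype=float) * image.pixel_scale
    side = roi.side_length
    if pos_um.size:
        pos_um = pos_um[
            (pos_um[:, 0] >= 0) & (pos_um[:, 0] <= side)
            & (pos_um[:, 1] >= 0) & (pos_um[:, 1] <= side)
        ]
    return ConeMosaic(positions=pos_um, roi=roi)


def _delaunay_edges(points: np.ndarray) -> np.ndarray:
    tri = Delaunay(points)
    edges = set()
    for simplex in tri.simplices:
        for a, b in ((0, 1), (1, 2), (0, 2)):
            i, j = sorted((simplex[a], simplex[b]))
            edges.add((i, j))
    return np.array(sorted(edges), dtype=int)


def mosaic_metrics(
    mosaic: ConeMosaic, long_edge_factor: float = 3.0
) -> ConeMetrics:
    """Compute density, spacing, and regularity for a detected mosaic.

    Spacing is the mean length of Delaunay edges after discarding edges longer
    than ``long_edge_factor`` times the median edge length (suppresses
    convex-hull artifacts).  Regularity uses Voronoi cells whose vertices all
    lie strictly inside the ROI square.  With fewer than 3 cones, spacing and
    regularity are NaN and flagged undefined.
    """
    pts = mosaic.positions
    n = len(pts)
    area = mosaic.roi.area_mm2
    density = n / area
    flags: list[str] = []
    if n < 3:
        return ConeMetrics(
            density=density,
            spacing=float("nan"),
            regularity=float("nan"),
            n_cones=n,
            region_label=mosaic.roi.region_label,
            flags=("spacing_regularity_undefined",),
        )

    edges = _delaunay_edges(pts)
    lengths = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
    keep = lengths <= long_edge_factor * np.median(lengths)
    spacing = float(lengths[keep].mean()) if keep.any() else float("nan")

    # nearest-neighbor spacing over retained Delaunay adjacency
    nn = np.full(n, np.inf)
    for (i, j), l in zip(edges, lengths):
        nn[i] = min(nn[i], l)
        nn[j] = min(nn[j], l)
    nn_spacing = float(nn[np.isfinite(nn)].mean())

    side = mosaic.roi.side_length
    vor = Voronoi(pts)
    n_sides: list[int] = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:
            continue
        verts = vor.vertices[region]
        if (verts < 0).any() or (verts > side).any():
            continue  # cell clipped by the ROI border
        n_sides.append(len(region))
    if n_sides:
        counts = np.asarray(n_sides)
        regularity = 100.0 * np.mean((counts >= 5) & (counts <= 7))
    else:
        regularity = float("nan")
        flags.append("no_interior_voronoi_cells")

    return ConeMetrics(
        density=density,
        spacing=spacing,
        regularity=float(regularity),
        n_cones=n,
        nn_spacing=nn_spacing,
        region_label=mosaic.roi.region_label,
        flags=tuple(flags),
    )


def average_regions(metrics_per_roi: list[ConeMetrics]) -> ConeMetrics:
    """Unweighted mean of density/spacing/regularity over ROIs of one region."""
    if not metrics_per_roi:
        raise ValueError("average_regions requires at least one ROI")
    labels = {m.region_label for m in metrics_per_roi}
    if len(labels) > 1:
        raise ValueError(f"ROIs span multiple regions: {labels}")
    return ConeMetrics(
        density=float(np.mean([m.density for m in metrics_per_roi])),
        spacing=float(np.mean([m.spacing for m in metrics_per_roi])),
        regularity=float(np.mean([m.regularity for m in metrics_per_roi])),
        n_cones=int(np.sum([m.n_cones for m in metrics_per_roi])),
        nn_spacing=float(np.mean([m.nn_spacing for m in metrics_per_roi])),
        region_label=labels.pop(),
    )


def read_ao_image(path: str | Path, pixel_scale: float, fovea_xy: tuple[float, float]) -> AOImage:
    """Read a single-channel TIFF/PNG montage into an AOImage."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        px = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        px = iio.imread(path)
    px = np.asarray(px, dtype=float)
    if px.ndim == 3:
        px = px.mean(axis=-1)
    return AOImage(pixels=px, pixel_scale=pixel_scale, fovea_xy=fovea_xy)


def mosaics_to_csv(mosaics: dict[str, ConeMosaic], path: str | Path) -> None:
    """Write detected positions as tidy CSV (x_um, y_um, roi_id)."""
    rows = []
    for roi_id, m in mosaics.items():
        for x, y in m.positions:
            rows.append({"x_um": x, "y_um": y, "roi_id": roi_id})
    pd.DataFrame(rows, columns=["x_um", "y_um", "roi_id"]).to_csv(
        path, index=False, float_format="%.6g"
    )


def metrics_to_frame(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-ROI metric dicts into the tidy output table."""
    cols = ["subject", "region", "meridian", "density", "spacing", "regularity", "n_cones"]
    return pd.DataFrame(rows)[cols]
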