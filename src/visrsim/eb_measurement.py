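"""Automated elastogram-to-B-mode (E/B) diameter measurement.

The B-mode diameter is the largest extent of the annotated lesion boundary.
That line ROI is copied, fixed in position and orientation, onto each
parametric image, and only its endpoints may move: each endpoint slides along
the line to the outermost crossing of the half-contrast level between the
in-boundary median (L) and out-of-boundary median (B) of the sampled profile
— a deterministic surrogate for a reader nudging endpoints to the perceived
lesion boundary.  E/B is the adjusted length over the B-mode length.

Quality is scored by the lesion-vs-annulus contrast-to-noise ratio (CNR);
low-CNR images are flagged "unsure" and excluded from downstream modeling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from shapely import contains_xy
from shapely.geometry import Polygon as ShapelyPolygon
from skimage.draw import polygon as draw_polygon

from .param_imaging import ParametricImageSet
from .phantom import BoundaryPolygon

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiameterROI:
    p1: tuple[float, float]     # (lateral mm, axial mm)
    p2: tuple[float, float]
    modality: str = "bmode"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("diameter endpoints must be distinct")

    @property
    def length(self) -> float:
        return math.hypot(self.p2[0] - self.p1[0], self.p2[1] - self.p1[1])


@dataclass(frozen=True)
class MeasureSettings:
    extend_frac: float = 0.5      # search window, fraction of B-mode radius
    level_frac: float = 1.0       # background-level context, ditto
    step_frac: float = 0.25       # profile step, fraction of the finer pixel
    min_contrast: float = 0.05    # relative |L - B| floor
    cnr_threshold: float = 0.5    # below -> unsure


@dataclass(frozen=True)
class AdjustedROI:
    roi: DiameterROI
    low_contrast: bool
    moved: tuple[bool, bool]      # whether each endpoint found a crossing


@dataclass(frozen=True)
class QualityFlag:
    cnr: float
    unsure: bool
    modality: str


@dataclass(frozen=True)
class LesionCharacteristics:
    depth_mm: float
    area_mm2: float
    circularity: float
    doa: dict          # modality -> DoA (None if < 2 rotations)


def largest_diameter(boundary: BoundaryPolygon,
                     modality: str = "bmode") -> DiameterROI:
    """Vertex pair of maximum separation; ties resolve to the most lateral."""
    v = boundary.vertices
    if abs(boundary.area) < 1e-9:
        raise ValueError("degenerate polygon: zero enclosed area")
    d2 = np.sum((v[:, None, :] - v[None, :, :]) ** 2, axis=2)
    dmax = d2.max()
    ii, jj = np.nonzero(d2 >= dmax - 1e-12)
    best, best_angle = None, np.inf
    for i, j in zip(ii, jj):
        if i >= j:
            continue
        dx, dz = abs(v[j, 0] - v[i, 0]), abs(v[j, 1] - v[i, 1])
        ang = math.atan2(dz, dx)     # 0 = purely lateral
        if ang < best_angle - 1e-12:
            best, best_angle = (i, j), ang
    i, j = best
    p1, p2 = v[i], v[j]
    if (p2[0], p2[1]) < (p1[0], p1[1]):       # deterministic endpoint order
        p1, p2 = p2, p1
    return DiameterROI(tuple(p1), tuple(p2), modality=modality)


def _sample_line(image: np.ndarray, spacings: tuple[float, float],
                 start: np.ndarray, direction: np.ndarray,
                 s: np.ndarray) -> np.ndarray:
    """Bilinear samples of `image` at points start + s*direction (mm)."""
    pts = start[None, :] + s[:, None] * direction[None, :]
    rows = pts[:, 1] / spacings[0]
    cols = pts[:, 0] / spacings[1]
    return ndimage.map_coordinates(image, [rows, cols], order=1,
                                   mode="nearest"), pts


def adjust_endpoints(roi: DiameterROI, image: np.ndarray,
                     spacings: tuple[float, float],
                     boundary: BoundaryPolygon,
                     cfg: MeasureSettings = MeasureSettings(),
                     modality: str = "param") -> AdjustedROI:
    """Slide the fixed-line endpoints to the outermost half-contrast crossing.

    ``spacings`` is (axial mm/px, lateral mm/px).  The line is extended by
    ``extend_frac`` of the B-mode radius beyond each endpoint; the profile is
    sampled at quarter-pixel steps with bilinear interpolation.  If the
    in/out contrast is below ``min_contrast`` the ROI is returned unchanged
    with the low-contrast marker set.
    """
    p1 = np.asarray(roi.p1, dtype=float)
    p2 = np.asarray(roi.p2, dtype=float)
    length = roi.length
    u = (p2 - p1) / length
    radius = length / 2.0
    ext_search = cfg.extend_frac * radius
    ext_level = max(cfg.level_frac, cfg.extend_frac) * radius
    step = cfg.step_frac * min(spacings)
    s = np.arange(-ext_level, length + ext_level + step, step)
    vals, pts = _sample_line(image, spacings, p1, u, s)
    inside = contains_xy(ShapelyPolygon(boundary.vertices),
                         pts[:, 0], pts[:, 1])
    # background level from the outer halves of the tails, beyond any
    # mechanically altered rim that hugs the B-mode boundary
    far = (s < -ext_level / 2.0) | (s > length + ext_level / 2.0)
    if inside.sum() < 2 or far.sum() < 2:
        return AdjustedROI(replace(roi, modality=modality), True,
                           (False, False))
    lev_in = float(np.median(vals[inside]))
    lev_out = float(np.median(vals[far]))
    if abs(lev_in - lev_out) < cfg.min_contrast * max(abs(lev_in),
                                                      abs(lev_out), 1e-30):
        return AdjustedROI(replace(roi, modality=modality), True,
                           (False, False))
    thr = 0.5 * (lev_in + lev_out)

    sign = np.sign(vals - thr)
    flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    # linear interpolation of the crossing coordinate
    cross = s[flips] + (thr - vals[flips]) / (vals[flips + 1] - vals[flips]) \
        * (s[flips + 1] - s[flips])
    cross = cross[(cross >= -ext_search) & (cross <= length + ext_search)]
    mid = length / 2.0
    s1, s2 = 0.0, length
    moved1 = moved2 = False
    c1 = cross[cross < mid]
    if c1.size:
        s1, moved1 = float(c1.min()), True      # outermost on endpoint-1 side
    c2 = cross[cross >= mid]
    if c2.size:
        s2, moved2 = float(c2.max()), True
    if s2 - s1 <= step:                          # collapsed: keep B-mode line
        s1, s2, moved1, moved2 = 0.0, length, False, False
    q1 = tuple(p1 + s1 * u)
    q2 = tuple(p1 + s2 * u)
    return AdjustedROI(DiameterROI(q1, q2, modality=modality), False,
                       (moved1, moved2))


def eb_ratio(param_roi: DiameterROI, bmode_roi: DiameterROI) -> float:
    if bmode_roi.length <= 0 or param_roi.length <= 0:
        raise ValueError("diameter lengths must be > 0")
    return param_roi.length / bmode_roi.length


def _polygon_mask(boundary: BoundaryPolygon, shape: tuple[int, int],
                  spacings: tuple[float, float]) -> np.ndarray:
    rows = boundary.vertices[:, 1] / spacings[0]
    cols = boundary.vertices[:, 0] / spacings[1]
    rr, cc = draw_polygon(rows, cols, shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def quality_flag(image: np.ndarray, boundary: BoundaryPolygon,
                 spacings: tuple[float, float],
                 threshold: float = 0.5,
                 modality: str = "param") -> QualityFlag:
    """Lesion-vs-annulus CNR; the annulus is one equivalent radius wide."""
    mask = _polygon_mask(boundary, image.shape, spacings)
    if not mask.any():
        raise ValueError("boundary polygon lies outside the image")
    r_eq = math.sqrt(boundary.area / math.pi)
    dist = ndimage.distance_transform_edt(~mask, sampling=spacings)
    annulus = (dist > 0) & (dist <= r_eq)
    if (annulus & _edge_mask(image.shape)).any():
        log.debug("CNR annulus clipped at the image edge")
    mean_in, var_in = image[mask].mean(), image[mask].var()
    mean_out, var_out = image[annulus].mean(), image[annulus].var()
    denom = math.sqrt(var_in + var_out)
    cnr = abs(mean_in - mean_out) / denom if denom > 0 else (
        0.0 if mean_in == mean_out else np.inf)
    return QualityFlag(cnr=float(cnr), unsure=bool(cnr < threshold),
                       modality=modality)


def _edge_mask(shape: tuple[int, int]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[0, :] = m[-1, :] = True
    m[:, 0] = m[:, -1] = True
    return m


def lesion_characteristics(
        views: list[tuple[ParametricImageSet, BoundaryPolygon]],
        ) -> LesionCharacteristics:
    """Geometry from the first view's outline; DoA across rotations.

    DoA per modality is the max/min ratio, over rotations, of the median
    in-lesion parameter value — 1 for isotropic tissue.
    """
    if not views:
        raise ValueError("at least one view is required")
    boundary0 = views[0][1]
    area = boundary0.area
    perim = boundary0.perimeter
    circularity = 4.0 * math.pi * area / perim ** 2
    depth = boundary0.centroid[1]
    doa = {}
    for mod in ("pd", "re", "rv"):
        if len(views) < 2:
            doa[mod] = None
            continue
        medians = []
        for images, boundary in views:
            mask = _polygon_mask(boundary, images.shape,
                                 (images.axial_spacing,
                                  images.lateral_spacing))
            medians.append(float(np.median(images.modality(mod)[mask])))
        doa[mod] = max(medians) / min(medians)
    return LesionCharacteristics(depth_mm=depth, area_mm2=area,
                                 circularity=circularity, doa=doa)
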