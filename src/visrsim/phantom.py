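"""Viscoelastic breast-lesion phantoms and seeded cohorts.

A phantom is a 2-D field of Voigt parameters (elasticity ``E`` in kPa,
viscosity ``mu`` in Pa*s) on the acquisition grid, with an elliptical lesion
that is visible on B-mode and a mechanically altered margin whose parametric
extent differs from the B-mode extent by a signed ``margin_width``:

* ``margin_width > 0``: an elliptical annulus *outside* the B-mode boundary
  takes the lesion values scaled by the margin factors (a desmoplastic /
  vascularized rim extending the parametric lesion, E/B > 1).
* ``margin_width < 0``: an annulus just *inside* the B-mode boundary takes the
  background values scaled by the margin factors (factors of 1 make the
  parametric lesion simply smaller than its B-mode appearance, E/B < 1).

Cohorts additionally encode two displacement-confound mechanisms motivated by
the degeneracy of peak displacement (PD): distinct (E, mu) pairs can produce
the same PD, so PD conflates stiffness and viscosity that the RE/RV fit
separates (see :func:`confound_pair`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from skimage import measure

from .msd_model import (MaterialPoint, TrackingSequenceSpec,
                        double_push_schedule, peak_displacement,
                        tracking_times, voigt_response)

Pair = tuple[float, float]


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int] = (2049, 40)   # (axial samples, lateral lines)
    axial_spacing: float = 0.0195              # mm per axial sample
    lateral_spacing: float = 0.5               # mm per line
    background_E: float = 3.0                  # kPa
    background_mu: float = 0.6                 # Pa*s
    lesion_center: Pair = (10.0, 20.0)         # (lateral mm, axial mm)
    lesion_axes: Pair = (6.0, 4.0)             # (semi-major, semi-minor) mm
    lesion_rotation: float = 0.0               # degrees
    lesion_E: float = 7.5                      # kPa
    lesion_mu: float = 1.5                     # Pa*s
    margin_width: float = 0.0                  # signed mm
    margin_E_factor: float = 1.0
    margin_mu_factor: float = 1.0
    heterogeneity_cv: float = 0.0
    lesion_echo_db: float = -6.0               # B-mode lesion echogenicity
    scatterers_per_mm: float = 48.0
    label: str = "benign"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.background_E, self.lesion_E) <= 0:
            raise ValueError("elasticities must be > 0")
        if min(self.background_mu, self.lesion_mu) < 0:
            raise ValueError("viscosities must be >= 0")
        if min(self.lesion_axes) <= 0:
            raise ValueError("lesion axes must be > 0")
        if self.margin_E_factor <= 0 or self.margin_mu_factor < 0:
            raise ValueError("margin factors must be positive")
        if abs(self.margin_width) >= self.lesion_axes[1]:
            raise ValueError("|margin_width| must be < semi-minor axis")
        if self.label not in ("benign", "malignant"):
            raise ValueError("label must be 'benign' or 'malignant'")
        if self.heterogeneity_cv < 0:
            raise ValueError("heterogeneity_cv must be >= 0")

    @property
    def axial_extent_mm(self) -> float:
        return (self.grid_shape[0] - 1) * self.axial_spacing

    @property
    def lateral_extent_mm(self) -> float:
        return (self.grid_shape[1] - 1) * self.lateral_spacing


@dataclass(frozen=True)
class BoundaryPolygon:
    """Closed simple polygon in physical (lateral mm, axial mm) coordinates."""

    vertices: np.ndarray                # (n, 2), ring without repeated vertex
    source: str = "bmode"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 8:
            raise ValueError("polygon needs >= 8 (x, z) vertices")
        if self.signed_area_of(v) <= 0:
            raise ValueError("polygon must have positive signed area")
        object.__setattr__(self, "vertices", v)

    @staticmethod
    def signed_area_of(v: np.ndarray) -> float:
        x, z = v[:, 0], v[:, 1]
        return 0.5 * float(np.sum(x * np.roll(z, -1) - np.roll(x, -1) * z))

    @property
    def area(self) -> float:
        return self.signed_area_of(self.vertices)

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    @property
    def centroid(self) -> tuple[float, float]:
        v = self.vertices
        vn = np.roll(v, -1, axis=0)
        cross = v[:, 0] * vn[:, 1] - vn[:, 0] * v[:, 1]
        a = 0.5 * np.sum(cross)
        cx = np.sum((v[:, 0] + vn[:, 0]) * cross) / (6 * a)
        cz = np.sum((v[:, 1] + vn[:, 1]) * cross) / (6 * a)
        return float(cx), float(cz)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.vertices, delimiter=",",
                   header="lateral_mm,axial_mm", comments="")

    @classmethod
    def from_csv(cls, path, source: str = "bmode") -> "BoundaryPolygon":
        return cls(np.loadtxt(path, delimiter=",", skiprows=1), source=source)


@dataclass
class Phantom:
    E_map: np.ndarray        # kPa, (axial, lateral)
    mu_map: np.ndarray       # Pa*s
    bmode_mask: np.ndarray   # bool, the B-mode-visible lesion
    scatterers: list[tuple[np.ndarray, np.ndarray]]  # per line: (mm, refl)
    spec: PhantomSpec

    def save_maps_tiff(self, path) -> None:
        import tifffile
        tifffile.imwrite(path, np.stack([self.E_map, self.mu_map]
                                        ).astype(np.float32),
                         photometric="minisblack")


def _ellipse_r2(x: np.ndarray, z: np.ndarray, spec: PhantomSpec,
                axes: Pair) -> np.ndarray:
    """Squared normalized elliptical radius (<= 1 means inside)."""
    th = math.radians(spec.lesion_rotation)
    cx, cz = spec.lesion_center
    dx, dz = x - cx, z - cz
    u = dx * math.cos(th) + dz * math.sin(th)
    v = -dx * math.sin(th) + dz * math.cos(th)
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2


def _check_inside_grid(spec: PhantomSpec, axes_out: Pair) -> None:
    th = math.radians(spec.lesion_rotation)
    a, b = axes_out
    half_lat = math.hypot(a * math.cos(th), b * math.sin(th))
    half_ax = math.hypot(a * math.sin(th), b * math.cos(th))
    cx, cz = spec.lesion_center
    if cx - half_lat < 0 or cx + half_lat > spec.lateral_extent_mm:
        raise ValueError("lesion exceeds grid along the lateral axis")
    if cz - half_ax < 0 or cz + half_ax > spec.axial_extent_mm:
        raise ValueError("lesion exceeds grid along the axial axis")


def grid_coords(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Meshgrid of physical coordinates: x (lateral mm), z (axial mm)."""
    z = np.arange(spec.grid_shape[0]) * spec.axial_spacing
    x = np.arange(spec.grid_shape[1]) * spec.lateral_spacing
    return np.meshgrid(x, z)


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Materialize maps, B-mode mask and speckle scatterers from a spec."""
    a, b = spec.lesion_axes
    w = spec.margin_width
    axes_out = (a + w, b + w) if w > 0 else (a, b)
    _check_inside_grid(spec, axes_out)

    x, z = grid_coords(spec)
    r2 = _ellipse_r2(x, z, spec, (a, b))
    mask = r2 <= 1.0
    E = np.where(mask, spec.lesion_E, spec.background_E)
    mu = np.where(mask, spec.lesion_mu, spec.background_mu)
    if w > 0:
        ring = (~mask) & (_ellipse_r2(x, z, spec, axes_out) <= 1.0)
        E = np.where(ring, spec.lesion_E * spec.margin_E_factor, E)
        mu = np.where(ring, spec.lesion_mu * spec.margin_mu_factor, mu)
    elif w < 0:
        inner = _ellipse_r2(x, z, spec, (a + w, b + w)) <= 1.0
        ring = mask & ~inner
        E = np.where(ring, spec.background_E * spec.margin_E_factor, E)
        mu = np.where(ring, spec.background_mu * spec.margin_mu_factor, mu)

    rng_maps = np.random.default_rng([spec.seed, 0])
    if spec.heterogeneity_cv > 0:
        sig = math.sqrt(math.log(1.0 + spec.heterogeneity_cv ** 2))
        E = E * rng_maps.lognormal(-0.5 * sig * sig, sig, size=E.shape)
        mu = mu * rng_maps.lognormal(-0.5 * sig * sig, sig, size=mu.shape)

    rng_scat = np.random.default_rng([spec.seed, 1])
    depth = spec.axial_extent_mm
    n_scat = max(int(round(spec.scatterers_per_mm * depth)), 1)
    echo_amp = 10.0 ** (spec.lesion_echo_db / 20.0)
    scatterers = []
    for j in range(spec.grid_shape[1]):
        pos = np.sort(rng_scat.uniform(0.0, depth, n_scat))
        refl = rng_scat.normal(0.0, 1.0, n_scat)
        xl = j * spec.lateral_spacing
        inside = _ellipse_r2(np.full(n_scat, xl), pos, spec, (a, b)) <= 1.0
        refl = np.where(inside, refl * echo_amp, refl)
        scatterers.append((pos, refl))
    return Phantom(E_map=E, mu_map=mu, bmode_mask=mask,
                   scatterers=scatterers, spec=spec)


def lesion_boundary(phantom: Phantom, n_vertices: int = 256) -> BoundaryPolygon:
    """Trace the B-mode lesion contour as an evenly resampled polygon (mm).

    The contour is extracted at the sub-pixel level-1 crossing of the
    normalized elliptical radius field (equivalent to the 0.5 level of the
    binary mask, but free of staircase bias on the coarse lateral grid).
    """
    if not phantom.bmode_mask.any():
        raise ValueError("empty B-mode mask: no lesion to outline")
    spec = phantom.spec
    x, z = grid_coords(spec)
    r2 = _ellipse_r2(x, z, spec, spec.lesion_axes)
    contours = measure.find_contours(r2, 1.0)
    if not contours:
        raise ValueError("no lesion contour found")
    c = max(contours, key=len)                       # (row, col)
    verts = np.column_stack([c[:, 1] * spec.lateral_spacing,
                             c[:, 0] * spec.axial_spacing])
    if np.allclose(verts[0], verts[-1]):
        verts = verts[:-1]
    # even arc-length resampling
    ring = np.vstack([verts, verts[:1]])
    seg = np.hypot(*np.diff(ring, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    si = np.linspace(0.0, total, n_vertices, endpoint=False)
    vx = np.interp(si, s, ring[:, 0])
    vz = np.interp(si, s, ring[:, 1])
    out = np.column_stack([vx, vz])
    if BoundaryPolygon.signed_area_of(out) < 0:
        out = out[::-1]
    return BoundaryPolygon(out, source="bmode")


def confound_pair(E1: float, mu1: float,
                  seq: TrackingSequenceSpec) -> tuple[float, float]:
    """A softer, more viscous material with the same sampled peak displacement.

    Fixes ``E2 = E1 / 2`` and root-solves the viscosity ``mu2`` whose Voigt
    double-push peak displacement, sampled on the tracking timeline, matches
    that of ``(E1, mu1)``.  Demonstrates the PD degeneracy: low stiffness with
    high viscosity mimics the displacement of stiffer, less viscous tissue,
    while the fitted RE differs by a factor of 2.
    """
    _, times = tracking_times(seq)
    schedule = double_push_schedule(seq)
    target = peak_displacement(voigt_response(MaterialPoint(E1, mu1),
                                              schedule, times))
    E2 = E1 / 2.0

    def f(mu2: float) -> float:
        return peak_displacement(voigt_response(MaterialPoint(E2, mu2),
                                                schedule, times)) - target

    lo = mu1 / 2.0 if mu1 > 0 else 1e-4 * E2   # tau2 = tau1: PD is 2x target
    hi = max(lo * 2, 1e-3 * E2)
    while f(hi) > 0:
        hi *= 2.0
        if hi / E2 > 50.0:    # tau beyond 50 ms: no root in bracket
            raise ValueError(
                f"no PD-matching viscosity in bracket ({lo:.4g}, {hi:.4g})")
    mu2 = brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)
    return E2, float(mu2)


@dataclass(frozen=True)
class CohortSpec:
    """Class-conditional lesion population (the simulated clinical cohort).

    Defaults encode a ~65/35 benign/malignant balance imaged at four 30
    degree rotations.  In the default ``confounded`` margin mode, malignant
    lesions carry stiff+viscous rims (a subset replaced by background-PD-
    matched confound rims visible only in RV), and a subset of benign lesions
    carry a jointly-but-mildly elevated rim that only PD mistakes for lesion
    extension.  ``plain`` uses the simple class margins with no confounds;
    ``null`` disables all margin effects (no class signal).
    """

    n_lesions: int = 40
    benign_fraction: float = 0.65
    rotations: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0)
    seed: int = 0
    margin_mode: str = "confounded"            # confounded | plain | null
    seq: TrackingSequenceSpec = field(default_factory=TrackingSequenceSpec)
    # desk-scale acquisition grid (full clinical grid is (2049, 40))
    grid_shape: tuple[int, int] = (256, 40)
    axial_spacing: float = 0.15625
    lateral_spacing: float = 0.5
    background_E: float = 3.0
    background_mu: float = 0.6
    heterogeneity_cv: float = 0.05
    # geometry draws (uniform ranges)
    semi_major_mm: Pair = (4.5, 6.5)
    axis_ratio: Pair = (0.6, 0.85)
    center_depth_mm: Pair = (14.0, 26.0)
    center_lateral_mm: Pair = (9.2, 10.8)
    # interior contrast factors relative to background
    interior_E_factor: Pair = (2.2, 3.2)
    benign_mu_factor: Pair = (2.2, 3.2)
    malignant_mu_factor: Pair = (1.2, 1.6)
    # class margins
    malignant_margin_mm: Pair = (0.5, 2.5)
    malignant_margin_factor: Pair = (1.5, 3.0)     # relative to lesion
    benign_margin_mm: Pair = (-2.0, -0.3)
    # confound mechanisms (confounded mode only; deterministic counts)
    confound_fraction: float = 0.3    # of malignant: PD-matched soft rim
    decoy_fraction: float = 0.4       # of benign: sub-threshold stiff rim
    decoy_margin_mm: Pair = (0.5, 2.0)
    decoy_subthreshold: float = 0.93

    def __post_init__(self) -> None:
        if self.n_lesions < 2:
            raise ValueError("n_lesions must be >= 2")
        if not 0 < self.benign_fraction < 1:
            raise ValueError("benign_fraction must be in (0, 1)")
        nb = int(round(self.n_lesions * self.benign_fraction))
        if nb == 0 or nb == self.n_lesions:
            raise ValueError("both classes must be represented")
        if self.margin_mode not in ("confounded", "plain", "null"):
            raise ValueError("margin_mode must be confounded|plain|null")


@dataclass
class CohortLesion:
    lesion_id: int
    label: str
    subtype: str                     # classic | confound | decoy | receded | null
    specs: list[PhantomSpec]         # one per rotation
    programmed_ratio: float          # (semi-major + margin)/(semi-major)

    def phantoms(self) -> list[Phantom]:
        return [make_phantom(s) for s in self.specs]


def _phantom_seed(cohort_seed: int, lesion_id: int, rot_idx: int) -> int:
    ss = np.random.SeedSequence((cohort_seed, lesion_id, rot_idx))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def sample_cohort(cohort: CohortSpec) -> list[CohortLesion]:
    """Draw a seeded lesion cohort; one PhantomSpec per rotation per lesion."""
    rng = np.random.default_rng([cohort.seed, 7])
    nb = int(round(cohort.n_lesions * cohort.benign_fraction))
    labels = np.array(["benign"] * nb
                      + ["malignant"] * (cohort.n_lesions - nb))
    rng.shuffle(labels)

    # deterministic confound/decoy counts within each class
    b_idx = np.flatnonzero(labels == "benign")
    m_idx = np.flatnonzero(labels == "malignant")
    subtype = {}
    if cohort.margin_mode == "confounded":
        n_decoy = int(round(cohort.decoy_fraction * b_idx.size))
        n_conf = int(round(cohort.confound_fraction * m_idx.size))
        decoys = set(rng.permutation(b_idx)[:n_decoy].tolist())
        confounds = set(rng.permutation(m_idx)[:n_conf].tolist())
        for i in b_idx:
            subtype[i] = "decoy" if i in decoys else "receded"
        for i in m_idx:
            subtype[i] = "confound" if i in confounds else "classic"
    elif cohort.margin_mode == "plain":
        subtype = {i: ("receded" if labels[i] == "benign" else "classic")
                   for i in range(cohort.n_lesions)}
    else:
        subtype = {i: "null" for i in range(cohort.n_lesions)}

    E_bg, mu_bg = cohort.background_E, cohort.background_mu
    if cohort.margin_mode == "confounded" and m_idx.size:
        E_conf, mu_conf = confound_pair(E_bg, mu_bg, cohort.seq)

    lesions = []
    for i in range(cohort.n_lesions):
        lrng = np.random.default_rng([cohort.seed, 1000 + i])
        a = lrng.uniform(*cohort.semi_major_mm)
        b = a * lrng.uniform(*cohort.axis_ratio)
        base_rot = lrng.uniform(0.0, 180.0)
        cx = lrng.uniform(*cohort.center_lateral_mm)
        cz = lrng.uniform(*cohort.center_depth_mm)
        f_E = lrng.uniform(*cohort.interior_E_factor)
        mu_rng = (cohort.benign_mu_factor if labels[i] == "benign"
                  else cohort.malignant_mu_factor)
        f_mu = lrng.uniform(*mu_rng)
        if cohort.margin_mode == "null":
            f_mu = lrng.uniform(*cohort.benign_mu_factor)  # shared null dist
        lesion_E, lesion_mu = f_E * E_bg, f_mu * mu_bg

        st = subtype[i]
        mf_E = mf_mu = 1.0
        if st == "classic":
            w = min(lrng.uniform(*cohort.malignant_margin_mm),
                    0.45 * a, 0.9 * b)
            mf_E = lrng.uniform(*cohort.malignant_margin_factor)
            mf_mu = lrng.uniform(*cohort.malignant_margin_factor)
        elif st == "confound":
            w = min(lrng.uniform(*cohort.malignant_margin_mm),
                    0.45 * a, 0.9 * b)
            mf_E = E_conf / lesion_E     # margin holds (E_bg/2, mu_conf)
            mf_mu = mu_conf / lesion_mu
        elif st == "decoy":
            w = min(lrng.uniform(*cohort.decoy_margin_mm), 0.45 * a, 0.9 * b)
            alpha = cohort.decoy_subthreshold
            # jointly elevated rim, each channel below its half-max threshold
            mf_E = alpha * (1.0 + f_E) / (2.0 * f_E)
            mf_mu = alpha * (1.0 + f_mu) / (2.0 * f_mu)
        elif st == "receded":
            w = max(lrng.uniform(*cohort.benign_margin_mm), -0.9 * b)
        else:
            w = 0.0

        specs = []
        for r, rot in enumerate(cohort.rotations):
            specs.append(PhantomSpec(
                grid_shape=cohort.grid_shape,
                axial_spacing=cohort.axial_spacing,
                lateral_spacing=cohort.lateral_spacing,
                background_E=E_bg, background_mu=mu_bg,
                lesion_center=(cx, cz), lesion_axes=(a, b),
                lesion_rotation=(base_rot + rot) % 180.0,
                lesion_E=lesion_E, lesion_mu=lesion_mu,
                margin_width=w, margin_E_factor=mf_E, margin_mu_factor=mf_mu,
                heterogeneity_cv=cohort.heterogeneity_cv,
                label=str(labels[i]),
                seed=_phantom_seed(cohort.seed, i, r)))
        lesions.append(CohortLesion(
            lesion_id=i, label=str(labels[i]), subtype=st, specs=specs,
            programmed_ratio=(a + w) / a if st != "decoy" else 1.0))
    return lesions
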