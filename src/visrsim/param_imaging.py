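"""Co-registered B-mode / PD / RE / RV parametric images with corrections.

``compute_images`` runs the per-pixel estimation chain: displacement profiles
come either from the analytic Voigt response of the phantom's material maps
(``ideal`` mode, no tracking noise) or from synthesized RF tracked by
normalized cross-correlation (``rf`` mode); peak displacement (PD) is the
profile maximum and RE/RV come from the mass-spring-damper fit.

Because the applied radiation force decays with depth, raw RE/RV estimates
carry the force profile.  ``build_calibration`` simulates homogeneous tissue
under the same acquisition to tabulate median RE/RV/PD versus depth plus an
RV bias factor versus fitted RE; ``apply_corrections`` normalizes each image
row against those curves (PD is left uncorrected, as acquired).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .msd_model import (FORCE_SCALE_UM_KPA, FitSettings, MaterialPoint,
                        TrackingSequenceSpec, double_push_schedule,
                        fit_visr_grid, tracking_times, unit_voigt_response)
from .phantom import Phantom, PhantomSpec, make_phantom
from .rf_tracking import (AcousticsSpec, KernelSpec, ncc_track,
                          push_amplitude, resample_to_grid, synth_rf)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImagingSettings:
    """Speed/accuracy knobs of the vectorized per-pixel fit."""

    fit: FitSettings = FitSettings()
    n_tau: int = 40
    refine_passes: int = 1
    dtype: str = "float32"
    fill_nonconverged: bool = True


@dataclass
class ParametricImageSet:
    bmode: np.ndarray          # envelope, a.u. (rf mode: dB)
    pd: np.ndarray             # um
    re: np.ndarray             # a.u.
    rv: np.ndarray             # a.u. * ms
    axial_spacing: float       # mm
    lateral_spacing: float     # mm
    rotation: float            # degrees
    converged_mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.pd.shape

    def modality(self, name: str) -> np.ndarray:
        return {"bmode": self.bmode, "pd": self.pd,
                "re": self.re, "rv": self.rv}[name]

    def save_tiff(self, path) -> None:
        import tifffile
        stack = np.stack([self.bmode, self.pd, self.re, self.rv])
        tifffile.imwrite(path, stack.astype(np.float32),
                         photometric="minisblack")
        with open(str(path) + ".txt", "w") as fh:
            fh.write("layers=bmode,pd,re,rv\n"
                     f"axial_spacing_mm={self.axial_spacing}\n"
                     f"lateral_spacing_mm={self.lateral_spacing}\n"
                     f"rotation_deg={self.rotation}\n")

    def save_png(self, path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, axes = plt.subplots(1, 4, figsize=(10, 3))
        for ax, name in zip(axes, ("bmode", "pd", "re", "rv")):
            img = self.modality(name)
            ax.imshow(img, cmap="gray", aspect="auto")
            ax.set_title(name.upper())
            ax.axis("off")
        fig.tight_layout()
        fig.savefig(path, dpi=100)
        plt.close(fig)


def _ideal_profiles(phantom: Phantom, seq: TrackingSequenceSpec,
                    ac: AcousticsSpec) -> np.ndarray:
    """Analytic per-pixel displacement profiles, (n_pixels, n_samples) in um."""
    spec = phantom.spec
    _, times = tracking_times(seq)
    schedule = double_push_schedule(seq)
    z = np.arange(spec.grid_shape[0]) * spec.axial_spacing
    amp = push_amplitude(z, ac, seq)[:, None]               # (rows, 1)
    plateau = FORCE_SCALE_UM_KPA * amp / phantom.E_map      # um
    tau_s = (phantom.mu_map / phantom.E_map).ravel() * 1e-3
    unit = unit_voigt_response(times, schedule, tau_s)      # (n_px, nt)
    return plateau.ravel()[:, None] * unit


def _ideal_bmode(phantom: Phantom, seed: int) -> np.ndarray:
    """Envelope-like contrast rendering with Rayleigh speckle texture."""
    spec = phantom.spec
    echo = 10.0 ** (spec.lesion_echo_db / 20.0)
    base = np.where(phantom.bmode_mask, echo, 1.0)
    rng = np.random.default_rng([seed, 4])
    sigma = np.sqrt(2.0 / np.pi)          # Rayleigh with unit mean
    return base * rng.rayleigh(sigma, size=base.shape)


def _rf_bmode(rf_ref: np.ndarray, ds_mm: float, n_rows: int,
              axial_spacing: float) -> np.ndarray:
    from scipy.signal import hilbert
    env = np.abs(hilbert(rf_ref, axis=1))                   # (lines, n_rf)
    rows_mm = np.arange(n_rows) * axial_spacing
    rf_mm = np.arange(env.shape[1]) * ds_mm
    out = np.stack([np.interp(rows_mm, rf_mm, e) for e in env], axis=1)
    out = np.maximum(out, 1e-6 * out.max())
    return 20.0 * np.log10(out / out.max())


def _fill_nonconverged(img: np.ndarray, bad: np.ndarray) -> np.ndarray:
    if not bad.any():
        return img
    med = ndimage.median_filter(img, size=3)
    return np.where(bad, med, img)


def compute_images(phantom: Phantom, seq: TrackingSequenceSpec,
                   ac: AcousticsSpec, mode: str = "ideal", seed: int = 0,
                   settings: ImagingSettings = ImagingSettings(),
                   kernel: KernelSpec = KernelSpec()) -> ParametricImageSet:
    """Estimate the PD/RE/RV parametric images for one lesion view."""
    spec = phantom.spec
    shape = spec.grid_shape
    if mode == "ideal":
        profiles = _ideal_profiles(phantom, seq, ac)
        bmode = _ideal_bmode(phantom, seed)
    elif mode == "rf":
        rf = synth_rf(phantom, seq, ac, seed=seed)
        tracked = ncc_track(rf, kernel)
        disp = resample_to_grid(tracked, shape[0], spec.axial_spacing)
        profiles = disp.transpose(1, 0, 2).reshape(-1, disp.shape[2])
        bmode = _rf_bmode(rf.reference, rf.sample_spacing_mm, shape[0],
                          spec.axial_spacing)
    else:
        raise ValueError("mode must be 'ideal' or 'rf'")

    dtype = np.float32 if settings.dtype == "float32" else np.float64
    fit = fit_visr_grid(profiles, seq, cfg=settings.fit,
                        n_tau=settings.n_tau,
                        refine_passes=settings.refine_passes, dtype=dtype)
    re = fit["re"].reshape(shape).astype(float)
    rv = fit["rv"].reshape(shape).astype(float)
    pd = fit["pd"].reshape(shape).astype(float)
    conv = fit["converged"].reshape(shape)
    if settings.fill_nonconverged:
        re = _fill_nonconverged(re, ~conv)
        rv = _fill_nonconverged(rv, ~conv)
    return ParametricImageSet(bmode=bmode, pd=pd, re=re, rv=rv,
                              axial_spacing=spec.axial_spacing,
                              lateral_spacing=spec.lateral_spacing,
                              rotation=spec.lesion_rotation,
                              converged_mask=conv)


@dataclass
class CalibrationCurves:
    depths_mm: np.ndarray
    re_med: np.ndarray
    rv_med: np.ndarray
    pd_med: np.ndarray
    focal_depth_mm: float
    bias_re: np.ndarray       # fitted-RE abscissa of the bias table
    bias_factor: np.ndarray   # RV (tau) bias factor, ~1 when unbiased


@dataclass(frozen=True)
class CalibrationSpec:
    E: float = 3.0                      # homogeneous calibration material
    mu: float = 0.6
    n_lines: int = 4
    bias_E: tuple[float, ...] = (1.5, 3.0, 6.0, 12.0)   # kPa grid
    bias_mu: tuple[float, ...] = (0.15, 0.6, 1.5, 3.0)  # Pa*s grid


def build_calibration(seq: TrackingSequenceSpec, ac: AcousticsSpec,
                      grid_shape: tuple[int, int], axial_spacing: float,
                      cal: CalibrationSpec = CalibrationSpec(),
                      settings: ImagingSettings = ImagingSettings(),
                      ) -> CalibrationCurves:
    """Simulate homogeneous tissue to learn depth and elasticity corrections."""
    n_rows = grid_shape[0]
    spec = PhantomSpec(
        grid_shape=(n_rows, cal.n_lines), axial_spacing=axial_spacing,
        lateral_spacing=0.5, background_E=cal.E, background_mu=cal.mu,
        lesion_E=cal.E, lesion_mu=cal.mu,
        lesion_center=(0.5 * (cal.n_lines - 1) * 0.5,
                       0.5 * (n_rows - 1) * axial_spacing),
        lesion_axes=(0.4, 0.3), heterogeneity_cv=0.0, seed=0)
    images = compute_images(make_phantom(spec), seq, ac, mode="ideal",
                            settings=settings)
    depths = np.arange(n_rows) * axial_spacing

    _, times = tracking_times(seq)
    schedule = double_push_schedule(seq)
    amp_f = float(push_amplitude(ac.focal_depth_mm, ac, seq))
    bias_re, bias_factor = [], []
    for E in cal.bias_E:
        res, biases = [], []
        for mu in cal.bias_mu:
            m = MaterialPoint(E, mu)
            prof = (FORCE_SCALE_UM_KPA * amp_f / E
                    * unit_voigt_response(times, schedule, m.tau_s))
            fit = fit_visr_grid(prof[None, :], seq, cfg=settings.fit,
                                n_tau=settings.n_tau,
                                refine_passes=settings.refine_passes)
            res.append(fit["re"][0])
            biases.append(fit["tau_ms"][0] / m.tau_ms if m.tau_ms > 1e-12
                          else 1.0)
        bias_re.append(np.mean(res))
        bias_factor.append(np.mean(biases))
    order = np.argsort(bias_re)
    return CalibrationCurves(
        depths_mm=depths,
        re_med=np.median(images.re, axis=1),
        rv_med=np.median(images.rv, axis=1),
        pd_med=np.median(images.pd, axis=1),
        focal_depth_mm=ac.focal_depth_mm,
        bias_re=np.asarray(bias_re)[order],
        bias_factor=np.asarray(bias_factor)[order])


def calibration_from_images(images: ParametricImageSet,
                            focal_depth_mm: float) -> CalibrationCurves:
    """Depth curves taken from an image's own row medians (flat-field check)."""
    n_rows = images.shape[0]
    depths = np.arange(n_rows) * images.axial_spacing
    return CalibrationCurves(
        depths_mm=depths,
        re_med=np.median(images.re, axis=1),
        rv_med=np.median(images.rv, axis=1),
        pd_med=np.median(images.pd, axis=1),
        focal_depth_mm=focal_depth_mm,
        bias_re=np.array([0.0, 1e9]), bias_factor=np.array([1.0, 1.0]))


def apply_corrections(images: ParametricImageSet,
                      cal: CalibrationCurves) -> ParametricImageSet:
    """Row-normalize RE/RV against the homogeneous depth curves, then divide
    RV by the elasticity-bias factor looked up at the corrected RE.  PD is
    deliberately left uncorrected."""
    n_rows = images.shape[0]
    z = np.arange(n_rows) * images.axial_spacing
    if z[0] < cal.depths_mm[0] - 1e-9 or z[-1] > cal.depths_mm[-1] + 1e-9:
        log.warning("image depth range exceeds calibration; using "
                    "nearest-edge extrapolation")
    re_c = np.interp(z, cal.depths_mm, cal.re_med)
    rv_c = np.interp(z, cal.depths_mm, cal.rv_med)
    re_f = np.interp(cal.focal_depth_mm, cal.depths_mm, cal.re_med) / re_c
    rv_f = np.interp(cal.focal_depth_mm, cal.depths_mm, cal.rv_med) / rv_c
    re = images.re * re_f[:, None]
    rv = images.rv * rv_f[:, None]
    bias = np.interp(re, cal.bias_re, cal.bias_factor)
    rv = rv / bias
    return replace(images, re=re, rv=rv)
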