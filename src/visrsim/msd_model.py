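"""Voigt / mass-spring-damper tissue response under a double-push ARFI sequence.

The forward model treats each tissue point as a Kelvin-Voigt body (spring E and
dashpot mu in parallel) driven by boxcar radiation-force pushes.  A push of
relative amplitude ``a`` displaces the point toward a plateau
``A = FORCE_SCALE_UM_KPA * a / E`` micrometers with time constant
``tau = mu / E`` (mu in Pa*s over E in kPa gives tau directly in
milliseconds).  Displacement is sampled on the reference/tracking timeline of
the acquisition sequence; the inverse problem (``fit_visr``) recovers the
force-relative elasticity RE = 1/A and viscosity RV = tau * RE from a sampled
profile.

An inertial variant (``msd_response_numeric``) integrates
``m*x'' + mu*x' + E*x = F(t)`` numerically and serves as an independent
oracle for the closed form; the imaging chain itself is inertia-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

# Maps relative push amplitude to a steady-state displacement in micrometers:
# plateau = FORCE_SCALE_UM_KPA * amplitude / E[kPa].  The absolute radiation
# force is unknown in vivo (RE/RV are force-relative); this single constant
# only sets a realistic micron scale for simulated displacements.
FORCE_SCALE_UM_KPA = 50.0


@dataclass(frozen=True)
class TrackingSequenceSpec:
    """Double-push ARFI timing: events occupy consecutive PRF slots."""

    n_ref: int = 2
    push_cycles: int = 300
    push_freq_mhz: float = 4.21
    track_prf_khz: float = 11.5
    n_track_between: int = 8
    n_track_after: int = 43
    n_lines: int = 40
    fov_cm: float = 2.0

    def __post_init__(self) -> None:
        for name in ("n_ref", "push_cycles", "n_track_between",
                     "n_track_after", "n_lines"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.push_duration_s >= self.slot_width_s:
            raise ValueError(
                "push duration {:.3g} s does not fit one PRF slot of "
                "{:.3g} s".format(self.push_duration_s, self.slot_width_s))

    @property
    def slot_width_s(self) -> float:
        return 1.0 / (self.track_prf_khz * 1e3)

    @property
    def push_duration_s(self) -> float:
        return self.push_cycles / (self.push_freq_mhz * 1e6)

    @property
    def n_samples(self) -> int:
        return self.n_ref + self.n_track_between + self.n_track_after


def tracking_times(seq: TrackingSequenceSpec) -> tuple[np.ndarray, np.ndarray]:
    """Push onsets and displacement sample times (s) on the PRF slot grid.

    Slot order: [ref x n_ref, push, track x n_between, push, track x n_after].
    Pushes occupy their own slots and contribute no displacement sample.
    """
    w = seq.slot_width_s
    slots_ref = np.arange(seq.n_ref)
    slot_push1 = seq.n_ref
    slots_between = slot_push1 + 1 + np.arange(seq.n_track_between)
    slot_push2 = slot_push1 + 1 + seq.n_track_between
    slots_after = slot_push2 + 1 + np.arange(seq.n_track_after)
    push_onsets = np.array([slot_push1, slot_push2]) * w
    sample_slots = np.concatenate([slots_ref, slots_between, slots_after])
    return push_onsets, sample_slots * w


@dataclass(frozen=True)
class ForceSchedule:
    """Piecewise-constant forcing: (onset s, duration s, relative amplitude)."""

    intervals: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for onset, dur, amp in self.intervals:
            if amp < 0:
                raise ValueError("force amplitudes must be >= 0")
            if dur <= 0:
                raise ValueError("force durations must be > 0")
            if onset < prev_end:
                raise ValueError("force intervals must not overlap")
            prev_end = onset + dur

    @property
    def end_time_s(self) -> float:
        return max(o + d for o, d, _ in self.intervals)


def double_push_schedule(seq: TrackingSequenceSpec,
                         amplitude: float = 1.0) -> ForceSchedule:
    onsets, _ = tracking_times(seq)
    tp = seq.push_duration_s
    return ForceSchedule(tuple((float(t0), tp, amplitude) for t0 in onsets))


@dataclass(frozen=True)
class MaterialPoint:
    """Ground-truth Voigt parameters: E in kPa, mu in Pa*s."""

    E: float
    mu: float

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("E must be > 0")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")

    @property
    def tau_ms(self) -> float:
        return self.mu / self.E

    @property
    def tau_s(self) -> float:
        return self.tau_ms * 1e-3


@dataclass(frozen=True)
class DisplacementProfile:
    times: np.ndarray          # s, strictly increasing
    displacement: np.ndarray   # um

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.displacement, dtype=float)
        if t.shape != d.shape or t.ndim != 1:
            raise ValueError("times and displacement must be equal-length 1-D")
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError("times must be nonnegative, strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "displacement", d)


@dataclass(frozen=True)
class ViscoelasticEstimate:
    RE: float            # a.u., 1 / (um per unit force)
    RV: float            # a.u. * ms
    tau_hat_ms: float    # = RV / RE
    pd: float            # um
    residual_rms: float  # um
    converged: bool


@dataclass(frozen=True)
class FitSettings:
    tau_bounds_ms: tuple[float, float] = (1e-3, 50.0)
    residual_frac: float = 0.2     # converged iff residual_rms < frac * PD
    max_nfev: int = 200


def unit_voigt_response(times: np.ndarray, schedule: ForceSchedule,
                        tau_s: np.ndarray | float) -> np.ndarray:
    """Voigt response per unit plateau amplitude, superposed over intervals.

    ``tau_s`` may be an array of shape (...,); output has shape (..., nt).
    tau = 0 is handled as the limit: plateau during a push, zero after.
    """
    t = np.asarray(times, dtype=float)
    tau = np.atleast_1d(np.asarray(tau_s, dtype=float))[..., None]
    scalar = np.isscalar(tau_s) or np.ndim(tau_s) == 0
    out = np.zeros(np.broadcast_shapes(tau.shape, (1, t.size)), dtype=float)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        for t0, dur, amp in schedule.intervals:
            dt = t - t0
            during = (dt >= 0) & (dt < dur)
            after = dt >= dur
            safe_tau = np.where(tau > 0, tau, 1.0)
            rise = 1.0 - np.exp(-dt / safe_tau)
            plateau = 1.0 - np.exp(-dur / safe_tau)
            decay = plateau * np.exp(-(dt - dur) / safe_tau)
            zero_tau = tau <= 0
            rise = np.where(zero_tau, 1.0, rise)
            decay = np.where(zero_tau, 0.0, decay)
            out += amp * np.where(during, rise, np.where(after, decay, 0.0))
    return out[0] if scalar else out


def voigt_response(m: MaterialPoint, schedule: ForceSchedule,
                   times: np.ndarray) -> DisplacementProfile:
    """Closed-form inertia-free displacement (um) at the given times."""
    unit = unit_voigt_response(times, schedule, m.tau_s)
    amp = FORCE_SCALE_UM_KPA / m.E
    return DisplacementProfile(np.asarray(times, float), amp * unit)


def msd_response_numeric(m: MaterialPoint, mass: float,
                         schedule: ForceSchedule, times: np.ndarray,
                         rtol: float = 1e-10, atol: float = 1e-14,
                         ) -> DisplacementProfile:
    """Numerically integrated mass-spring-damper response (um).

    Solves ``meff * x'' + tau * x' + x = A(t)`` piecewise between forcing
    breakpoints (x in um, t in s, ``meff`` in s^2; with mass = 0 the system
    degenerates to the first-order Voigt equation).  Independent oracle for
    :func:`voigt_response`.
    """
    if mass < 0:
        raise ValueError("mass must be >= 0")
    times = np.asarray(times, dtype=float)
    tau = m.tau_s
    scale = FORCE_SCALE_UM_KPA / m.E

    def forcing(t: float) -> float:
        for t0, dur, amp in schedule.intervals:
            if t0 <= t < t0 + dur:
                return amp * scale
        return 0.0

    breaks = sorted({0.0, float(times[-1])}
                    | {t0 for t0, _, _ in schedule.intervals}
                    | {t0 + d for t0, d, _ in schedule.intervals})
    breaks = [b for b in breaks if b <= times[-1] + 1e-15]
    if breaks[-1] < times[-1]:
        breaks.append(float(times[-1]))

    out = np.zeros_like(times)
    if mass == 0.0 and tau == 0.0:
        out[:] = [forcing(t) for t in times]
        return DisplacementProfile(times, out)

    state = np.array([0.0, 0.0]) if mass > 0 else np.array([0.0])

    def rhs_second(t, y):
        return [y[1], (forcing(t) - tau * y[1] - y[0]) / mass]

    def rhs_first(t, y):
        return [(forcing(t) - y[0]) / tau]

    rhs = rhs_second if mass > 0 else rhs_first
    for a, b in zip(breaks[:-1], breaks[1:]):
        sel = (times > a) & (times <= b)
        t_eval = np.append(times[sel], b)  # piece end carries the state over
        mid = forcing(0.5 * (a + b))  # constant within the piece
        def rhs_piece(t, y, f=mid):
            if mass > 0:
                return [y[1], (f - tau * y[1] - y[0]) / mass]
            return [(f - y[0]) / tau]
        sol = solve_ivp(rhs_piece, (a, b), state, method="Radau",
                        t_eval=np.unique(t_eval),
                        rtol=rtol, atol=atol, dense_output=False)
        if not sol.success:
            raise RuntimeError(
                f"stiff integration failed (E={m.E}, mu={m.mu}, mass={mass}): "
                f"{sol.message}")
        if sel.any():
            out[sel] = sol.y[0, :sel.sum()] if t_eval[-2] < b else sol.y[0]
        state = sol.y[:, -1]
    out[times <= 0] = 0.0
    return DisplacementProfile(times, out)


def peak_displacement(profile: DisplacementProfile) -> float:
    if profile.displacement.size == 0:
        raise ValueError("empty displacement profile")
    return float(np.max(profile.displacement))


def true_relative_params(m: MaterialPoint,
                         amplitude: float = 1.0) -> tuple[float, float]:
    """Ground-truth (RE, RV) the fit should recover at a given push amplitude."""
    re = m.E / (FORCE_SCALE_UM_KPA * amplitude)
    return re, m.tau_ms * re


def _init_guess(times: np.ndarray, disp: np.ndarray,
                seq: TrackingSequenceSpec,
                bounds_s: tuple[float, float]) -> tuple[float, float]:
    pd = float(np.max(disp))
    i_peak = int(np.argmax(disp))
    tau0 = None
    below = np.nonzero(disp[i_peak:] < 0.5 * pd)[0]
    if below.size and pd > 0:
        dt = times[i_peak + below[0]] - times[i_peak]
        if dt > 0:
            tau0 = dt / np.log(2.0)
    if tau0 is None:
        tau0 = np.sqrt(bounds_s[0] * bounds_s[1])
    tau0 = float(np.clip(tau0, *bounds_s))
    a0 = pd / max(1.0 - np.exp(-seq.push_duration_s / tau0), 1e-9)
    return max(a0, 1e-9), tau0


def fit_visr(profile: DisplacementProfile, seq: TrackingSequenceSpec,
             cfg: FitSettings = FitSettings()) -> ViscoelasticEstimate:
    """Two-parameter (amplitude, tau) Voigt fit of a double-push profile.

    Trust-region nonlinear least squares against the unit double-push model;
    RE = 1/amplitude, RV = tau * RE.  A poor fit is reported via
    ``converged=False`` rather than an exception.
    """
    _, t_expect = tracking_times(seq)
    if profile.times.size != t_expect.size:
        raise ValueError(
            f"profile has {profile.times.size} samples, sequence timeline "
            f"has {t_expect.size}")
    schedule = double_push_schedule(seq, amplitude=1.0)
    t = profile.times
    d = profile.displacement - profile.displacement[seq.n_ref - 1]
    bounds_s = (cfg.tau_bounds_ms[0] * 1e-3, cfg.tau_bounds_ms[1] * 1e-3)
    a0, tau0 = _init_guess(t, d, seq, bounds_s)

    def residuals(p):
        return p[0] * unit_voigt_response(t, schedule, p[1]) - d

    ok = True
    try:
        sol = least_squares(
            residuals, x0=[a0, tau0],
            bounds=([1e-12, bounds_s[0]], [np.inf, bounds_s[1]]),
            method="trf", max_nfev=cfg.max_nfev)
        a_hat, tau_hat_s = float(sol.x[0]), float(sol.x[1])
        resid = sol.fun
        ok = bool(sol.success)
    except Exception:
        a_hat, tau_hat_s = a0, tau0
        resid = residuals([a_hat, tau_hat_s])
        ok = False
    pd_val = float(np.max(d))
    rms = float(np.sqrt(np.mean(resid ** 2)))
    re = 1.0 / a_hat
    tau_ms = tau_hat_s * 1e3
    converged = ok and pd_val > 0 and rms < cfg.residual_frac * pd_val
    return ViscoelasticEstimate(RE=re, RV=tau_ms * re, tau_hat_ms=tau_ms,
                                pd=pd_val, residual_rms=rms,
                                converged=converged)


def fit_visr_grid(profiles: np.ndarray, seq: TrackingSequenceSpec,
                  cfg: FitSettings = FitSettings(),
                  n_tau: int = 48, refine_passes: int = 2,
                  dtype=np.float64) -> dict[str, np.ndarray]:
    """Vectorized Voigt fit of many profiles (rows) on the sequence timeline.

    Variable projection: for each tau on a log grid the optimal amplitude is
    closed-form, so the 2-parameter fit reduces to a 1-D search over tau,
    refined by parabolic interpolation of the SSE in log-tau.  Agrees with
    :func:`fit_visr` to solver tolerance on noise-free profiles and is used
    for whole-image estimation where per-pixel trust-region fits would be
    prohibitively slow.

    Returns arrays ``re, rv, tau_ms, pd, residual_rms, converged`` with one
    entry per profile row.
    """
    _, t = tracking_times(seq)
    P = np.asarray(profiles, dtype=dtype)
    if P.ndim != 2 or P.shape[1] != t.size:
        raise ValueError("profiles must be (n, n_samples) on the seq timeline")
    P = P - P[:, seq.n_ref - 1][:, None]
    schedule = double_push_schedule(seq, amplitude=1.0)
    lo, hi = cfg.tau_bounds_ms
    tau_grid = np.geomspace(lo * 1e-3, hi * 1e-3, n_tau)
    G = unit_voigt_response(t, schedule, tau_grid).astype(dtype)  # (n_tau, nt)
    gg = np.sum(G * G, axis=1)                            # (n_tau,)
    num = P @ G.T                                         # (n, n_tau)
    sse = np.sum(P * P, axis=1)[:, None] - num ** 2 / gg
    j = np.argmin(sse, axis=1)

    # parabolic refinement of log-tau at interior grid minima
    log_tau = np.log(tau_grid)
    jm = np.clip(j, 1, n_tau - 2)
    idx = np.arange(P.shape[0])
    s0, s1, s2 = sse[idx, jm - 1], sse[idx, jm], sse[idx, jm + 1]
    denom = s0 - 2 * s1 + s2
    shift = np.where(np.abs(denom) > 1e-300,
                     0.5 * (s0 - s2) / np.where(denom == 0, 1, denom), 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    h = log_tau[1] - log_tau[0]
    log_hat = np.where((j > 0) & (j < n_tau - 1),
                       log_tau[jm] + shift * h, log_tau[j])

    def sse_at(log_t):
        g = unit_voigt_response(t, schedule, np.exp(log_t)).astype(dtype)
        gg_l = np.sum(g * g, axis=1)
        num_l = np.sum(P * g, axis=1)
        return np.sum(P * P, axis=1) - num_l ** 2 / gg_l

    # local parabolic passes sharpen tau well below grid resolution
    lo_l, hi_l = np.log(lo * 1e-3), np.log(hi * 1e-3)
    for step in [h / 4.0 ** k for k in range(1, refine_passes + 1)]:
        l0, l1, l2 = log_hat - step, log_hat, log_hat + step
        s0, s1, s2 = sse_at(l0), sse_at(l1), sse_at(l2)
        denom = s0 - 2 * s1 + s2
        shift = np.where(np.abs(denom) > 1e-300,
                         0.5 * (s0 - s2) / np.where(denom == 0, 1, denom), 0.0)
        log_hat = np.clip(log_hat + np.clip(shift, -1, 1) * step, lo_l, hi_l)
    tau_hat = np.exp(log_hat)

    g_hat = unit_voigt_response(t, schedule, tau_hat).astype(dtype)  # (n, nt)
    gg_hat = np.sum(g_hat * g_hat, axis=1)
    a_hat = np.maximum(np.sum(P * g_hat, axis=1) / gg_hat, 1e-12)
    resid = P - a_hat[:, None] * g_hat
    rms = np.sqrt(np.mean(resid ** 2, axis=1))
    pd_val = np.max(P, axis=1)
    re = 1.0 / a_hat
    tau_ms = tau_hat * 1e3
    converged = (pd_val > 0) & (rms < cfg.residual_frac * pd_val)
    return {"re": re, "rv": tau_ms * re, "tau_ms": tau_ms, "pd": pd_val,
            "residual_rms": rms, "converged": converged}
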