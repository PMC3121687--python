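"""Lateral diffusion: tracking, time-averaged MSD, Saffman-Delbruck fit.

A membrane inclusion of radius R in the Saffman-Delbruck regime (R much
smaller than the Saffman length mu_m h / mu_w) diffuses with

    D(R) = k_BT / (4 pi mu_m h) * [ ln( mu_m h / (mu_w R) ) - gamma_E ]

where ``mu_m h`` is the membrane surface viscosity, ``mu_w = mu_+ + mu_-``
the summed viscosity of the fluids above and below the membrane, and
gamma_E Euler's constant. Both ``mu_m h`` and ``mu_w`` are free parameters
of the fit, matching how size-dependent diffusion data of membrane
proteins are conventionally analyzed. The relation applies equally to
diffusion coefficients normalized by the lipid's own D (the normalization
is absorbed by the parameter units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Track", "MSDResult", "SDFit",
    "extract_track", "msd", "saffman_delbruck_fit", "sd_curve",
    "EULER_GAMMA",
]

EULER_GAMMA = 0.5772156649015329


@dataclass
class Track:
    times: np.ndarray      # (n,), strictly increasing
    xy: np.ndarray         # (n, 2) unwrapped lateral COM positions

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.xy = np.asarray(self.xy, dtype=np.float64)
        if self.times.ndim != 1 or self.xy.shape != (self.times.size, 2):
            raise ValueError("track must be (n,) times with (n, 2) positions")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class MSDResult:
    lag_times: np.ndarray
    msd: np.ndarray
    D: float               # r_c^2 / tau
    fit_lags: tuple        # (first, last) lag index used
    stderr: float


@dataclass
class SDFit:
    mu_w: float
    mu_m_h: float
    cov: np.ndarray
    residuals: np.ndarray


def extract_track(frames, molecule: int) -> Track:
    """Unwrapped lateral center-of-mass track of one molecule.

    The COM increment between consecutive frames is taken under the
    minimum image, so boundary crossings do not produce jumps; the frame
    interval must be short enough that no bead moves more than half a box
    edge between frames (a sampling-rate error otherwise).
    """
    times, coms = [], []
    prev = None
    pos_acc = None
    for state in frames:
        idx = state.molecule_indices(molecule)
        if idx.size == 0:
            raise ValueError(f"molecule {molecule} absent from a frame")
        p = state.positions[idx, :2]
        ref = p[0]
        rel = p - ref
        rel -= state.box[:2] * np.round(rel / state.box[:2])
        com = ref + rel.mean(axis=0)
        if prev is None:
            pos_acc = com.astype(float)
        else:
            inc = com - prev
            wrapped = inc - state.box[:2] * np.round(inc / state.box[:2])
            if np.any(np.abs(inc - wrapped) > 0) and \
                    np.any(np.abs(wrapped) > state.box[:2] / 2 - 1e-9):
                raise ValueError("per-frame displacement exceeds box/2: "
                                 "increase the sampling rate")
            pos_acc = pos_acc + wrapped
        prev = com
        times.append(state.time)
        coms.append(pos_acc.copy())
    return Track(times=np.array(times), xy=np.array(coms))


def _tamsd_fft(x: np.ndarray) -> np.ndarray:
    """Time-averaged MSD of a 1-D series for all lags (FFT algorithm)."""
    n = x.size
    nfft = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(fx * np.conj(fx), nfft)[:n]
    sq = x * x
    ssum = 2.0 * sq.sum()
    msd = np.empty(n)
    msd[0] = 0.0
    for lag in range(1, n):
        ssum -= sq[lag - 1] + sq[n - lag]
        msd[lag] = (ssum - 2.0 * acf[lag]) / (n - lag)
    return msd


def msd(
    track: Track,
    max_lag: int | None = None,
    fit_window: tuple[float, float] = (0.10, 0.25),
) -> MSDResult:
    """Time-averaged MSD and a 2-D diffusion coefficient.

    The MSD is averaged over all start points per lag (FFT evaluation).
    ``D`` comes from a least-squares fit of ``MSD = 4 D t`` through the
    origin over lags in ``fit_window`` (fractions of ``max_lag``, default
    10-25%; the default ``max_lag`` is n/100, keeping the fitted lags
    short enough that the single-trajectory statistical error stays at
    the few-percent level).
    """
    n = track.times.size
    if n < 2:
        raise ValueError("track too short")
    if max_lag is None:
        max_lag = max(10, n // 100)
    max_lag = min(max_lag, n - 1)
    if n < 2 * max_lag:
        import warnings
        warnings.warn("track shorter than 2*max_lag; MSD tail is noisy")
    m = _tamsd_fft(track.xy[:, 0]) + _tamsd_fft(track.xy[:, 1])
    m = m[:max_lag + 1]
    dt = float(np.mean(np.diff(track.times)))
    lags = np.arange(max_lag + 1) * dt

    lo = max(1, int(round(fit_window[0] * max_lag)))
    hi = max(lo + 1, int(round(fit_window[1] * max_lag)))
    t = lags[lo:hi + 1]
    y = m[lo:hi + 1]
    # LSQ through the origin: MSD = 4 D t
    denom = float(np.sum(t * t))
    d = float(np.sum(y * t) / (4.0 * denom))
    resid = y - 4.0 * d * t
    dof = max(1, t.size - 1)
    stderr = float(np.sqrt(np.sum(resid ** 2) / dof / denom) / 4.0)
    return MSDResult(lag_times=lags, msd=m, D=d, fit_lags=(lo, hi),
                     stderr=stderr)


def sd_curve(radii: np.ndarray, mu_w: float, mu_m_h: float,
             k_BT: float = 1.0) -> np.ndarray:
    """Saffman-Delbruck D(R) for given viscosity parameters."""
    radii = np.asarray(radii, dtype=np.float64)
    return k_BT / (4.0 * np.pi * mu_m_h) * (
        np.log(mu_m_h / (mu_w * radii)) - EULER_GAMMA)


def saffman_delbruck_fit(
    radii: np.ndarray,
    D: np.ndarray,
    k_BT: float = 1.0,
) -> SDFit:
    """Two-parameter nonlinear least-squares fit of the SD relation.

    Free parameters: the summed bulk viscosity ``mu_w`` and the membrane
    surface viscosity ``mu_m h``. Initial guesses come from the exact
    log-linear structure of the model (slope of D vs ln R fixes
    ``mu_m h``; the intercept fixes ``mu_w``).
    """
    radii = np.asarray(radii, dtype=np.float64)
    D = np.asarray(D, dtype=np.float64)
    if radii.size < 3 or np.unique(radii).size < 3:
        raise ValueError("underdetermined: need at least 3 distinct radii")
    slope, intercept = np.polyfit(np.log(radii), D, 1)
    if slope >= 0:
        raise ValueError("D must decrease with radius in the SD regime")
    mu_m_h0 = -k_BT / (4.0 * np.pi * slope)
    mu_w0 = mu_m_h0 * np.exp(
        -(intercept / (-slope) + np.log(mu_m_h0) - EULER_GAMMA))
    p0 = [max(mu_w0, 1e-8), max(mu_m_h0, 1e-8)]
    try:
        popt, pcov = curve_fit(
            lambda r, mw, mmh: sd_curve(r, mw, mmh, k_BT),
            radii, D, p0=p0, bounds=(1e-12, np.inf), maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(
            f"Saffman-Delbruck fit did not converge (p0={p0}): {err}") from err
    resid = D - sd_curve(radii, *popt, k_BT)
    return SDFit(mu_w=float(popt[0]), mu_m_h=float(popt[1]),
                 cov=pcov, residuals=resid)
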