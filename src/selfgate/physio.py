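"""Selection and conditioning of physiological components; trigger detection.

Given a set of separated components, the respiratory and cardiac components
are chosen automatically from their Welch power spectral densities: within
the physiological band (respiratory 0.1-0.7 Hz, cardiac 0.5-2.0 Hz) the
tallest in-band local PSD maximum of every component is fitted with a
Gaussian and the component with the largest fitted amplitude wins
("most prominent peak").  The respiratory component is conditioned --
zero-phase low-pass at 0.7 Hz, linear detrend, sign adjusted so inspiration
is high -- and the cardiac component yields triggers through interpolated
zero crossings with a refractory rule and automatic polarity selection.

All filtering is zero-phase (forward-backward), since any phase shift would
bias the trigger timing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.optimize import curve_fit
from scipy.stats import skew

from .bss import SourceSet
from .triggers import TriggerTrain

__all__ = [
    "RESP_BAND_HZ",
    "CARDIAC_BAND_HZ",
    "SpectralPeakFit",
    "NoCandidateError",
    "estimate_psd",
    "select_component",
    "condition_respiratory",
    "detect_triggers",
]

logger = logging.getLogger(__name__)

RESP_BAND_HZ = (0.1, 0.7)
CARDIAC_BAND_HZ = (0.5, 2.0)


class NoCandidateError(RuntimeError):
    """No component shows a local PSD maximum inside the requested band."""


@dataclass
class SpectralPeakFit:
    """Gaussian fit to the tallest in-band PSD peak of one component."""

    component: int
    amplitude: float
    center_hz: float
    width_hz: float
    in_band: bool
    residual: float


def estimate_psd(
    source: np.ndarray, fs: float, segment_seconds: float = 30.0
) -> tuple[np.ndarray, np.ndarray]:
    """Welch-averaged power spectral density on a 0..fs/2 frequency grid."""
    source = np.asarray(source, dtype=float)
    nperseg = int(round(segment_seconds * fs))
    if source.size < 2 * nperseg:
        raise ValueError(
            f"signal of {source.size} samples is shorter than two {nperseg}-sample segments"
        )
    return signal.welch(source, fs=fs, nperseg=nperseg)


def _gauss_peak(f, amp, center, width, base):
    return base + amp * np.exp(-0.5 * ((f - center) / width) ** 2)


def _fit_peak(f: np.ndarray, P: np.ndarray, peak: int, band) -> tuple[float, float, float, float]:
    """Fit a Gaussian on a local window around a PSD peak; returns
    (amplitude, center, width, residual).  Falls back to the raw peak height
    if the fit fails."""
    lo = max(0, peak - 5)
    hi = min(f.size, peak + 6)
    fw, Pw = f[lo:hi], P[lo:hi]
    df = f[1] - f[0]
    p0 = [max(P[peak] - Pw.min(), 1e-12), f[peak], 2 * df, Pw.min()]
    try:
        popt, _ = curve_fit(
            _gauss_peak,
            fw,
            Pw,
            p0=p0,
            bounds=([0, band[0], df / 4, 0], [np.inf, band[1], band[1] - band[0], np.inf]),
            maxfev=2000,
        )
        resid = float(np.sqrt(np.mean((_gauss_peak(fw, *popt) - Pw) ** 2)))
        return float(popt[0]), float(popt[1]), float(popt[2]), resid
    except (RuntimeError, ValueError):
        return float(P[peak]), float(f[peak]), float(2 * df), float("nan")


def select_component(
    ss: SourceSet,
    band_hz,
    segment_seconds: float = 30.0,
    exclude=(),
) -> tuple[int, SpectralPeakFit]:
    """Pick the component with the most prominent in-band spectral peak.

    For each candidate component the tallest local PSD maximum inside
    ``band_hz`` is Gaussian-fitted on a local window; the component with the
    largest fitted amplitude is returned (ties break to the lowest index).
    Components listed in ``exclude`` (e.g. the already-selected respiratory
    component) are skipped.  If no component has an in-band local maximum a
    :class:`NoCandidateError` is raised; callers may fall back to the raw
    in-band power argmax, which is logged here as a helper.
    """
    lo, hi = band_hz
    best: tuple[float, int, SpectralPeakFit] | None = None
    for j in range(ss.n_sources):
        if j in exclude:
            continue
        f, P = estimate_psd(ss.sources[:, j], ss.fs, segment_seconds)
        # prominence floor rejects numerical ripples of out-of-band tones
        peaks, _ = signal.find_peaks(P, prominence=1e-6 * P.max())
        peaks = peaks[(f[peaks] >= lo) & (f[peaks] <= hi)]
        if peaks.size == 0:
            continue
        tallest = peaks[np.argmax(P[peaks])]
        amp, center, width, resid = _fit_peak(f, P, tallest, band_hz)
        fit = SpectralPeakFit(j, amp, center, width, lo <= center <= hi, resid)
        if best is None or amp > best[0] + 1e-15:
            best = (amp, j, fit)
    if best is None:
        raise NoCandidateError(f"no component has a local PSD maximum in band {band_hz}")
    return best[1], best[2]


def fallback_inband_argmax(ss: SourceSet, band_hz, segment_seconds: float = 30.0) -> int:
    """Fallback selection: component with the largest total in-band power."""
    lo, hi = band_hz
    powers = []
    for j in range(ss.n_sources):
        f, P = estimate_psd(ss.sources[:, j], ss.fs, segment_seconds)
        powers.append(P[(f >= lo) & (f <= hi)].sum())
    j = int(np.argmax(powers))
    logger.warning("no in-band peak found; falling back to in-band power argmax (component %d)", j)
    return j


def condition_respiratory(source: np.ndarray, fs: float, cutoff_hz: float = 0.7) -> np.ndarray:
    """Low-pass, detrend and sign-adjust a respiratory component.

    Zero-phase 4th-order Butterworth low-pass at ``cutoff_hz`` removes
    cardiac and noise contamination; a least-squares linear trend is
    subtracted; the sign is chosen so that inspiration corresponds to higher
    values.  The sign rule exploits the shape of tidal breathing: the signal
    dwells at end-expiration, so a correctly signed signal has its long
    plateau below the median, i.e. positive skewness -- the signal is flipped
    if its skewness is negative.
    """
    x = np.asarray(source, dtype=float)
    sos = signal.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    y = signal.detrend(y, type="linear")
    if skew(y) < 0:
        y = -y
    return y


def _rising_crossings(x: np.ndarray, fs: float) -> np.ndarray:
    """Sub-sample times (ms) of negative-to-positive zero crossings."""
    below = x[:-1] < 0
    above = x[1:] >= 0
    idx = np.flatnonzero(below & above)
    frac = x[idx] / (x[idx] - x[idx + 1])
    return (idx + frac) / fs * 1000.0


def _refractory(times: np.ndarray, fraction: float = 0.4) -> np.ndarray:
    """Suppress crossings closer than ``fraction`` x the running median interval."""
    if times.size < 3:
        return times
    out = [times[0]]
    recent: list[float] = []
    init_med = float(np.median(np.diff(times)))
    for t in times[1:]:
        med = float(np.median(recent[-10:])) if len(recent) >= 3 else init_med
        if t - out[-1] < fraction * med:
            continue
        recent.append(t - out[-1])
        out.append(t)
    return np.asarray(out)


def detect_triggers(
    source: np.ndarray,
    fs: float,
    band_hz=CARDIAC_BAND_HZ,
    source_label: str = "SG",
) -> TriggerTrain:
    """Cardiac trigger detection by interpolated zero crossings.

    The cardiac component is zero-phase band-passed to ``band_hz`` and
    demeaned; negative-to-positive crossings are located with linear
    interpolation for sub-sample timing.  Crossings closer than 0.4x the
    running median interval are suppressed (refractory rule).  Both
    polarities (rising crossings of the signal and of its negation) are
    evaluated and the one with the lower interval coefficient of variation
    is kept, so the detector is invariant to the sign ambiguity of separated
    components; near-ties resolve to the set whose first trigger is earlier,
    which is itself sign-symmetric.
    """
    x = np.asarray(source, dtype=float)
    sos = signal.butter(4, band_hz, btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    y = y - y.mean()
    if y.std() < 1e-9 * max(x.std(), 1.0):
        raise ValueError("no in-band signal; cannot detect triggers")

    candidates = []
    for pol in (y, -y):
        t = _refractory(_rising_crossings(pol, fs))
        if t.size >= 3:
            iv = np.diff(t)
            cv = iv.std() / iv.mean() if iv.mean() > 0 else np.inf
            candidates.append((cv, t))
    if not candidates:
        raise ValueError("fewer than 3 zero crossings; cannot detect triggers")
    cvs = [c[0] for c in candidates]
    if len(candidates) == 2 and abs(cvs[0] - cvs[1]) <= 1e-9 * max(cvs[0], cvs[1], 1e-300):
        times = min(candidates, key=lambda c: c[1][0])[1]
    else:
        times = min(candidates, key=lambda c: c[0])[1]
    return TriggerTrain(times=times, source=source_label)
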