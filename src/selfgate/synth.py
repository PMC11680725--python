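"""Synthetic inputs with known ground truth for the self-gating pipeline.

Everything the pipeline consumes can be generated here: cardiac/respiratory
physiology (trigger trains with heart-rate variability and optional
respiratory sinus arrhythmia), superior-inferior (SI) readout stacks as a
free-running radial acquisition would record them (one SI readout per
22-line trajectory segment, so the self-gating sampling rate is
1/(22*TR)), defective ECG trigger trains, beating-disk k-space data for the
toy motion-resolved reconstruction, and sigmoid-edge phantoms for the
sharpness metric.

The physiological defaults emulate the acquisition regime of a free-running
whole-heart protocol: TR = 2.84 ms and 22 readouts per segment give an SI
sampling rate of ~16 Hz; respiration sits at 0.25 Hz inside the 0.1-0.7 Hz
band and the heart at 60 bpm (1 Hz) inside the 0.5-2.0 Hz band.

The respiratory waveform is the two-harmonic cycle
``sin(phi) + 0.3 sin(2 phi + 13 pi/8)``: band-limited to twice the breathing
frequency (so below the 0.7 Hz respiratory band edge at the default rate),
with a shorter inspiration than expiration, an end-expiratory dwell, and an
inspiration-phase mean above the expiration-phase mean -- the asymmetries of
real tidal breathing that the conditioning and binning stages rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import j1

from .triggers import TriggerTrain

__all__ = [
    "DEFAULT_FS_HZ",
    "PhysioGroundTruth",
    "SIStack",
    "simulate_physio",
    "simulate_si_stack",
    "simulate_ecg_train",
    "make_edge_phantom",
    "sigmoid_edge",
    "disk_kspace",
    "raster_disk",
    "BeatingDiskData",
    "simulate_beating_disk",
]

#: SI self-gating sampling rate for TR = 2.84 ms and 22 lines per segment.
DEFAULT_FS_HZ = 1.0 / (22 * 2.84e-3)

_RESP_H2_AMP = 0.3
_RESP_H2_PHASE = 13 * np.pi / 8


@dataclass
class PhysioGroundTruth:
    """Ground-truth physiology underlying a simulated acquisition."""

    trigger_times: np.ndarray  # ms, strictly increasing
    resp_waveform: np.ndarray  # arbitrary units, sampled at fs
    resp_phase_labels: np.ndarray  # True where inspiration (rising resp)
    fs: float  # Hz
    params: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return float(self.params.get("duration_s", self.resp_waveform.size / self.fs))


@dataclass
class SIStack:
    """Complex SI readouts (time x readout position x coil) with ground truth."""

    readouts: np.ndarray
    segment_index: np.ndarray  # position within the repeating trajectory pattern
    fs: float
    ground_truth: PhysioGroundTruth
    resp_weights: np.ndarray  # (n_positions, n_coils)
    card_weights: np.ndarray  # (n_positions, n_coils)
    resp_source: np.ndarray  # (n_t,), unit variance
    cardiac_source: np.ndarray  # (n_t,), unit variance
    modulation: np.ndarray  # (n_t, n_positions, n_coils) additive component
    params: dict = field(default_factory=dict)


def _resp_waveform(phase: np.ndarray, freq_hz: float):
    """Two-harmonic asymmetric breathing cycle and its analytic derivative sign."""
    if 2.0 * freq_hz <= 0.7:
        w = np.sin(phase) + _RESP_H2_AMP * np.sin(2.0 * phase + _RESP_H2_PHASE)
        dw = np.cos(phase) + 2.0 * _RESP_H2_AMP * np.cos(2.0 * phase + _RESP_H2_PHASE)
    else:  # keep the waveform inside the respiratory band
        w = np.sin(phase)
        dw = np.cos(phase)
    return w, dw


def simulate_physio(
    hr_mean_bpm: float = 60.0,
    hr_sd_bpm: float = 2.0,
    resp_freq_hz: float = 0.25,
    rsa_gain_bpm: float = 0.0,
    duration_s: float = 300.0,
    fs: float = DEFAULT_FS_HZ,
    seed: int = 0,
) -> PhysioGroundTruth:
    """Simulate a cardiac trigger train and respiratory waveform.

    The instantaneous heart rate is ``hr_mean_bpm`` plus white beat-to-beat
    variability (SD ``hr_sd_bpm``) plus the respiratory sinus arrhythmia term
    ``rsa_gain_bpm * (normalised inspiratory flow)``, where the flow is the
    time derivative of the respiratory waveform: the heart accelerates while
    air flows in (inspiration) and decelerates during expiration, which is
    the phase relationship of vagally mediated sinus arrhythmia.  Trigger
    times are accumulated beat by beat from the instantaneous rate.  With
    zero variability and zero gain the train is exactly periodic.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration and sampling rate must be positive")
    if duration_s < 30:
        raise ValueError("duration must be at least 30 s")
    if not 30 <= hr_mean_bpm <= 150:
        raise ValueError("mean heart rate must lie in [30, 150] bpm")
    if resp_freq_hz <= 0 or resp_freq_hz > 0.7:
        raise ValueError("respiratory frequency must lie in (0, 0.7] Hz")
    rng = np.random.default_rng(seed)

    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    phase = 2.0 * np.pi * resp_freq_hz * t
    w, dw = _resp_waveform(phase, resp_freq_hz)
    labels = dw > 0

    norm = dw / np.max(np.abs(dw))  # inspiratory-flow RSA driver

    duration_ms = duration_s * 1000.0
    times = [0.0]
    while True:
        idx = min(int(times[-1] / 1000.0 * fs), n - 1)
        hr = hr_mean_bpm + rsa_gain_bpm * norm[idx]
        if hr_sd_bpm > 0:
            hr += rng.normal(0.0, hr_sd_bpm)
        hr = float(np.clip(hr, 20.0, 220.0))
        nxt = times[-1] + 60000.0 / hr
        if nxt > duration_ms + 1e-9:
            break
        times.append(nxt)

    return PhysioGroundTruth(
        trigger_times=np.asarray(times),
        resp_waveform=w,
        resp_phase_labels=labels,
        fs=float(fs),
        params=dict(
            hr_mean_bpm=hr_mean_bpm,
            hr_sd_bpm=hr_sd_bpm,
            resp_freq_hz=resp_freq_hz,
            rsa_gain_bpm=rsa_gain_bpm,
            duration_s=duration_s,
            seed=seed,
        ),
    )


def cardiac_waveform(t_ms: np.ndarray, trigger_times: np.ndarray, duty: float = 0.35) -> np.ndarray:
    """Raised-cosine pulse train whose upstrokes coincide with the triggers.

    Each cardiac cycle carries one smooth pulse 0.5*(1 - cos(2 pi p/duty))
    over the first ``duty`` fraction of the cycle; the waveform is extended
    by one extrapolated cycle on each side so readouts outside the trigger
    span still see a cardiac signal.
    """
    tt = np.asarray(trigger_times, dtype=float)
    if tt.size < 2:
        raise ValueError("need at least 2 triggers for a cardiac waveform")
    ext = np.concatenate(([2 * tt[0] - tt[1]], tt, [2 * tt[-1] - tt[-2]]))
    k = np.clip(np.searchsorted(ext, t_ms, side="right") - 1, 0, ext.size - 2)
    p = (t_ms - ext[k]) / (ext[k + 1] - ext[k])
    return np.where(p < duty, 0.5 * (1.0 - np.cos(2.0 * np.pi * p / duty)), 0.0)


def _gauss(z: np.ndarray, mu: float, sig: float) -> np.ndarray:
    return np.exp(-0.5 * ((z - mu) / sig) ** 2)


def simulate_si_stack(
    gt: PhysioGroundTruth,
    n_positions: int = 40,
    n_coils: int = 4,
    noise_sd: float = 0.3,
    modulation_amplitude: float = 1.0,
    seed: int = 0,
    segment_length: int = 22,
    resp_amplitude: float = 2.5,
    card_amplitude: float = 1.2,
) -> SIStack:
    """Simulate complex SI readouts containing the two physiological sources.

    Each (position, coil) projection signal is
    ``baseline + resp_weight*resp + card_weight*cardiac + modulation + noise``
    where the spatial weight maps of the two sources overlap (their channel
    vectors are deliberately non-orthogonal, as the heart sits inside the
    thorax), so plain PCA cannot align its components with the sources while
    a spectral method can.  The trajectory modulation is an additive offset
    keyed to the position within the repeating ``segment_length``-line
    pattern, one random level pattern per channel.  The complex readouts are
    the inverse Fourier transform of the projections, so re-transforming
    recovers them.
    """
    if n_positions < 8:
        raise ValueError("need at least 8 SI positions")
    if n_coils < 2:
        raise ValueError("need at least 2 coils")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)

    n_t = gt.resp_waveform.size
    t_ms = np.arange(n_t) / gt.fs * 1000.0

    resp = gt.resp_waveform - gt.resp_waveform.mean()
    resp = resp / resp.std()
    card = cardiac_waveform(t_ms, gt.trigger_times)
    card = (card - card.mean()) / card.std()

    z = np.linspace(0.0, 1.0, n_positions)
    g_resp = _gauss(z, 0.35, 0.18)
    g_card = _gauss(z, 0.55, 0.12)
    gain_r = rng.uniform(0.5, 1.5, n_coils)
    gain_c = rng.uniform(0.5, 1.5, n_coils)
    # respiration shifts the whole projection profile (broad weight with a
    # floor); the heart is localised.  The cross-terms make the two
    # channel-space weight vectors non-orthogonal.
    w_resp = resp_amplitude * np.outer(0.4 + g_resp + 0.3 * g_card, gain_r)
    w_card = card_amplitude * np.outer(0.15 + g_card + 0.3 * g_resp, gain_c)
    w_resp *= 1.0 + 0.05 * rng.standard_normal(w_resp.shape)
    w_card *= 1.0 + 0.05 * rng.standard_normal(w_card.shape)

    seg = np.arange(n_t) % segment_length
    offsets = modulation_amplitude * rng.standard_normal((segment_length, n_positions, n_coils))
    modulation = offsets[seg]

    baseline = 10.0 + 30.0 * _gauss(z, 0.5, 0.28)
    profiles = (
        baseline[None, :, None]
        + w_resp[None, :, :] * resp[:, None, None]
        + w_card[None, :, :] * card[:, None, None]
        + modulation
    )
    if noise_sd > 0:
        profiles = profiles + rng.normal(0.0, noise_sd, profiles.shape)

    readouts = np.fft.ifft(np.fft.ifftshift(profiles, axes=1), axis=1)

    return SIStack(
        readouts=readouts,
        segment_index=seg,
        fs=gt.fs,
        ground_truth=gt,
        resp_weights=w_resp,
        card_weights=w_card,
        resp_source=resp,
        cardiac_source=card,
        modulation=modulation,
        params=dict(
            n_positions=n_positions,
            n_coils=n_coils,
            noise_sd=noise_sd,
            modulation_amplitude=modulation_amplitude,
            segment_length=segment_length,
            seed=seed,
        ),
    )


def simulate_ecg_train(
    gt: PhysioGroundTruth,
    missing_rate: float = 0.0,
    extrasystole_rate: float = 0.0,
    jitter_sd_ms: float = 0.0,
    seed: int = 0,
) -> tuple[TriggerTrain, dict]:
    """Derive a defective ECG train from the ground-truth triggers.

    Applies independent per-trigger deletions (missed R waves), per-interval
    insertions at a random mid-interval position (extrasystolic/false
    triggers) and Gaussian timing jitter.  Returns the train together with
    defect bookkeeping (which times were deleted/inserted) so cleaning rules
    can be scored against the truth.
    """
    for name, r in (("missing_rate", missing_rate), ("extrasystole_rate", extrasystole_rate)):
        if not 0.0 <= r <= 0.2:
            raise ValueError(f"{name} must lie in [0, 0.2]")
    if jitter_sd_ms < 0:
        raise ValueError("jitter_sd_ms must be non-negative")
    rng = np.random.default_rng(seed)

    times = np.asarray(gt.trigger_times, dtype=float)
    delete = rng.random(times.size) < missing_rate
    # never delete the endpoints: the observed train must span the recording
    delete[0] = delete[-1] = False
    deleted_times = times[delete]
    kept = times[~delete]

    iv = np.diff(kept)
    ins_mask = rng.random(iv.size) < extrasystole_rate
    u = rng.uniform(0.2, 0.8, iv.size)
    inserted_times = kept[:-1][ins_mask] + (u * iv)[ins_mask]

    out = np.concatenate([kept, inserted_times])
    is_inserted = np.concatenate([np.zeros(kept.size, bool), np.ones(inserted_times.size, bool)])
    order = np.argsort(out, kind="stable")
    out, is_inserted = out[order], is_inserted[order]

    if jitter_sd_ms > 0:
        out = out + rng.normal(0.0, jitter_sd_ms, out.size)
        order = np.argsort(out, kind="stable")
        out, is_inserted = out[order], is_inserted[order]

    train = TriggerTrain(times=out, source="ECG")
    bookkeeping = dict(
        deleted_times=deleted_times,
        inserted_times=out[is_inserted],
        n_deleted=int(delete.sum()),
        n_inserted=int(is_inserted.sum()),
    )
    return train, bookkeeping


# ---------------------------------------------------------------------------
# Edge phantom for the sharpness metric


def sigmoid_edge(x, a0: float, a1: float, a2: float, s: float):
    """Sigmoid edge profile a2 + (a1 - a2) / (1 + 10^((a0 - x) s)).

    ``a2``/``a1`` are the minimum/maximum intensities, ``a0`` the profile
    coordinate of the half-way intensity and ``s`` the steepness (larger s =
    sharper edge).
    """
    expo = np.clip((a0 - np.asarray(x, dtype=float)) * s, -300.0, 300.0)
    return a2 + (a1 - a2) / (1.0 + 10.0**expo)


def make_edge_phantom(
    a0_px: float = 0.0,
    a1: float = 100.0,
    a2: float = 10.0,
    s: float = 0.5,
    image_size: int = 64,
    curve_control_points=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Image whose intensity across a stated curve follows the sigmoid edge.

    With no control points the curve is a vertical line through the image
    centre and the profile coordinate is the signed horizontal distance to
    it; with control points, a curve is interpolated through them and the
    signed perpendicular distance to the curve is used.  Intensity at every
    pixel is ``sigmoid_edge(distance)`` plus optional Gaussian noise, so
    profiles sampled perpendicular to the curve reproduce the generating
    sigmoid exactly in the noiseless case.
    """
    if a1 <= a2:
        raise ValueError("a1 (maximum intensity) must exceed a2 (minimum)")
    if image_size < 32:
        raise ValueError("image_size must be at least 32")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:image_size, 0:image_size].astype(float)

    if curve_control_points is None:
        d = xx - image_size / 2.0
    else:
        from .sharpness import fit_bezier  # local import: sharpness does not import synth

        curve = fit_bezier(np.asarray(curve_control_points, dtype=float))
        pts, tans = curve.sample_even(2048)
        pix = np.stack([xx.ravel(), yy.ravel()], axis=1)
        d2 = ((pix[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        nearest = np.argmin(d2, axis=1)
        delta = pix - pts[nearest]
        tan = tans[nearest]
        # signed distance: positive on the left-normal side of the tangent
        d = (-tan[:, 1] * delta[:, 0] + tan[:, 0] * delta[:, 1]).reshape(xx.shape)

    img = sigmoid_edge(d, a0_px, a1, a2, s)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return img


# ---------------------------------------------------------------------------
# Beating-disk phantom for the toy motion-resolved reconstruction


def disk_kspace(kx, ky, radius: float, center, amplitude: float = 1.0):
    """Analytic 2D Fourier transform of a uniform disk, sampled at (kx, ky).

    k in cycles/pixel; the disk has the given radius (pixels) and centre
    (pixels).  FT of the unit disk is amplitude * R * J1(2 pi R k)/k with the
    usual k -> 0 limit of pi R^2.
    """
    kx = np.asarray(kx, dtype=float)
    ky = np.asarray(ky, dtype=float)
    k = np.hypot(kx, ky)
    with np.errstate(divide="ignore", invalid="ignore"):
        mag = np.where(k > 1e-12, radius * j1(2.0 * np.pi * radius * k) / k, np.pi * radius**2)
    phase = np.exp(-2j * np.pi * (kx * center[0] + ky * center[1]))
    return amplitude * mag * phase


def raster_disk(image_size: int, radius: float, center, amplitude: float = 1.0) -> np.ndarray:
    """Rasterised disk with a half-pixel anti-aliased rim (reference image)."""
    yy, xx = np.mgrid[0:image_size, 0:image_size].astype(float)
    r = np.hypot(xx - center[0], yy - center[1])
    return amplitude * np.clip(radius + 0.5 - r, 0.0, 1.0)


@dataclass
class BeatingDiskData:
    """Radial k-space of a pulsating, breathing disk plus all ground truth."""

    kspace: np.ndarray  # (n_spokes, n_read, n_coils) complex samples
    kx: np.ndarray  # (n_spokes, n_read) cycles/pixel
    ky: np.ndarray
    spoke_times_ms: np.ndarray  # acquisition time of each spoke
    coil_sens: np.ndarray  # (n_coils, N, N) complex
    image_size: int
    ground_truth: PhysioGroundTruth
    radius_of_phase: object  # callable phase in [0,1) -> radius px
    center_of_resp: object  # callable resp amplitude in [-1,1] -> (cx, cy)
    systole_fraction: float = 0.30  # cardiac phase fraction with motion


def simulate_beating_disk(
    gt: PhysioGroundTruth,
    image_size: int = 32,
    n_spokes: int = 480,
    n_coils: int = 2,
    noise_sd: float = 0.02,
    seed: int = 0,
    radius_range: tuple[float, float] = (5.0, 10.0),
    resp_shift_px: float = 2.0,
) -> BeatingDiskData:
    """Golden-angle radial acquisition of a disk that beats and breathes.

    At each spoke time the true object is a disk whose radius follows the
    cardiac phase (systolic contraction: minimum radius right after the
    trigger, smooth raised-cosine refilling) and whose centre is displaced
    along y by the respiratory amplitude.  Each spoke's samples are the
    explicit non-uniform DFT of the coil-weighted rasterised disk at that
    instant, so the data are exactly consistent with the reconstruction's
    forward model up to binning error and noise.
    """
    rng = np.random.default_rng(seed)
    n_read = image_size
    duration_ms = gt.resp_waveform.size / gt.fs * 1000.0
    spoke_times = np.linspace(0.0, duration_ms, n_spokes, endpoint=False)

    ga = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    angles = (np.arange(n_spokes) * ga) % np.pi
    kr = np.fft.fftshift(np.fft.fftfreq(n_read))  # cycles/pixel, [-0.5, 0.5)
    kx = np.outer(np.cos(angles), kr)
    ky = np.outer(np.sin(angles), kr)

    tt = gt.trigger_times
    k = np.clip(np.searchsorted(tt, spoke_times, side="right") - 1, 0, tt.size - 2)
    phase = np.clip((spoke_times - tt[k]) / (tt[k + 1] - tt[k]), 0.0, 1.0)

    r_lo, r_hi = radius_range
    duty = 0.30  # systolic fraction of the cycle; diastole is quiescent

    def radius_of_phase(p):
        # brief systolic contraction right after the trigger, then diastasis
        p = np.asarray(p, dtype=float)
        return r_hi - (r_hi - r_lo) * np.where(p < duty, np.sin(np.pi * p / duty) ** 2, 0.0)

    resp = gt.resp_waveform - gt.resp_waveform.mean()
    resp = resp / np.max(np.abs(resp))
    ridx = np.clip((spoke_times / 1000.0 * gt.fs).astype(int), 0, resp.size - 1)

    c0 = image_size / 2.0

    def center_of_resp(a):
        return (c0, c0 + resp_shift_px * a)

    yy, xx = np.mgrid[0:image_size, 0:image_size].astype(float)
    sens = np.empty((n_coils, image_size, image_size), complex)
    for q in range(n_coils):
        mu = (image_size * (0.25 + 0.5 * (q % 2)), image_size * (0.25 + 0.5 * (q // 2 % 2)))
        sens[q] = _gauss(xx, mu[0], image_size * 0.6) * _gauss(yy, mu[1], image_size * 0.6)
        sens[q] = sens[q] * np.exp(1j * 0.1 * q)

    pix_x = xx.ravel()
    pix_y = yy.ravel()
    sens_flat = sens.reshape(n_coils, -1)
    ks = np.empty((n_spokes, n_read, n_coils), complex)
    for i in range(n_spokes):
        rad = float(radius_of_phase(phase[i]))
        ctr = center_of_resp(float(resp[ridx[i]]))
        img = raster_disk(image_size, rad, ctr).ravel()
        E = np.exp(-2j * np.pi * (np.outer(kx[i], pix_x) + np.outer(ky[i], pix_y)))
        ks[i] = (E @ (sens_flat * img).T)
    if noise_sd > 0:
        scale = float(np.sqrt(np.mean(np.abs(ks) ** 2)))
        ks = ks + noise_sd * scale * (
            rng.standard_normal(ks.shape) + 1j * rng.standard_normal(ks.shape)
        ) / np.sqrt(2.0)

    return BeatingDiskData(
        kspace=ks,
        kx=kx,
        ky=ky,
        spoke_times_ms=spoke_times,
        coil_sens=sens,
        image_size=image_size,
        ground_truth=gt,
        radius_of_phase=radius_of_phase,
        center_of_resp=center_of_resp,
        systole_fraction=duty,
    )
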