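"""Trigger trains and their evaluation against an ECG reference.

Self-gated (SG) cardiac triggers are compared with ECG triggers through a
fixed sequence: the ECG train is cleaned with moving-median interval rules,
the SG train is aligned to it by a 10 ms grid search, matched trigger pairs
define paired cardiac intervals, and the interval SD (ISD) of the absolute
interval differences quantifies (the inverse of) trigger precision.  The
module also carries the statistics used to compare extraction methods:
a paired Bonett-Seier dispersion test, Bland-Altman limits of agreement with
a paired linear fit, and the inspiration/expiration heart-rate split used to
probe respiratory sinus arrhythmia.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "TriggerTrain",
    "TriggerComparison",
    "clean_ecg",
    "align_triggers",
    "compute_isd",
    "rsa_split",
    "rsa_paired_test",
    "bonett_seier_paired",
    "bland_altman",
]

VALID = "valid"
MISSING = "missing-adjacent"
EXTRA = "extrasystolic"


@dataclass
class TriggerTrain:
    """Strictly increasing trigger times in ms with per-trigger validity flags."""

    times: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]
    source: str = "unknown"
    interval_flags: np.ndarray | None = None  # set by clean_ecg; length len-1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("trigger times must be a 1D array")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("trigger times must be strictly increasing")
        if self.flags is None:
            self.flags = np.full(self.times.shape, VALID, dtype=object)
        else:
            self.flags = np.asarray(self.flags, dtype=object)
            if self.flags.shape != self.times.shape:
                raise ValueError("flags must have one entry per trigger")
        if self.interval_flags is not None:
            self.interval_flags = np.asarray(self.interval_flags, dtype=object)
            if self.interval_flags.shape != (self.times.size - 1,):
                raise ValueError("interval_flags must have one entry per interval")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def intervals(self) -> np.ndarray:
        """Trigger-to-trigger intervals in ms (length = len - 1)."""
        return np.diff(self.times)

    def interval_valid(self) -> np.ndarray:
        """Per-interval usability: cleaning flags if present, else all valid."""
        if self.interval_flags is not None:
            return self.interval_flags == VALID
        return np.ones(max(len(self) - 1, 0), dtype=bool)

    def shifted(self, offset_ms: float) -> "TriggerTrain":
        return replace(self, times=self.times + offset_ms)


@dataclass
class TriggerComparison:
    """Paired SG/ECG cardiac intervals and the ISD precision statistic.

    ``sg_intervals`` and ``ecg_intervals`` are the N paired interval lengths
    (ms); ``abs_diff`` their absolute differences d_n; ``mu`` the mean of the
    d_n; ``isd`` the sample SD of the d_n (divisor N-1); ``offset_ms`` the
    alignment shift that was applied to the SG train; ``ecg_index`` the index
    of the ECG interval each pair came from (used to pair two methods against
    the same reference intervals).
    """

    sg_intervals: np.ndarray
    ecg_intervals: np.ndarray
    abs_diff: np.ndarray
    mu: float
    isd: float
    n: int
    offset_ms: float
    ecg_index: np.ndarray

    @property
    def signed_diff(self) -> np.ndarray:
        return self.sg_intervals - self.ecg_intervals


def clean_ecg(train: TriggerTrain, window: int = 40) -> TriggerTrain:
    """Flag implausible ECG intervals by comparison with a moving median.

    For each interval the median of its ``window`` nearest intervals (half
    before, half after, truncated at the series edges and excluding itself)
    is computed.  Intervals longer than 1.5x that median indicate a missing
    trigger; intervals shorter than 0.5x indicate a false or extrasystolic
    trigger.  Flagged intervals drop out of downstream pairing (recorded in
    ``interval_flags``); the trigger closing a flagged interval is marked as
    well, for reporting.  Times are never altered.
    """
    if len(train) < 3:
        raise ValueError("need at least 3 triggers to clean a train")
    iv = train.intervals
    n = iv.size
    half = window // 2
    if n - 1 < window:
        warnings.warn(
            f"only {n - 1} neighbour intervals available; window shrunk from {window}",
            stacklevel=2,
        )
    flags = np.array(train.flags, dtype=object)
    iv_flags = np.full(n, VALID, dtype=object)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        neigh = np.delete(iv[lo:hi], i - lo)
        if neigh.size == 0:
            continue
        med = float(np.median(neigh))
        if iv[i] > 1.5 * med:
            iv_flags[i] = MISSING
            flags[i + 1] = MISSING
        elif iv[i] < 0.5 * med:
            iv_flags[i] = EXTRA
            flags[i + 1] = EXTRA
    return replace(train, flags=flags, interval_flags=iv_flags)


def _nearest_match(sg_times: np.ndarray, ecg_times: np.ndarray):
    """Index of nearest ECG trigger for each SG trigger, plus distances."""
    pos = np.searchsorted(ecg_times, sg_times)
    pos = np.clip(pos, 1, ecg_times.size - 1)
    left = ecg_times[pos - 1]
    right = ecg_times[pos]
    idx = np.where(sg_times - left <= right - sg_times, pos - 1, pos)
    return idx, np.abs(sg_times - ecg_times[idx])


def align_triggers(
    sg: TriggerTrain, ecg: TriggerTrain, step_ms: float = 10.0
) -> tuple[TriggerTrain, float]:
    """Align SG triggers to ECG triggers by a grid search over time shifts.

    SG triggers lag the ECG R-wave by an unknown physiological delay; the
    shift (searched in ``step_ms`` increments over +/- one median ECG
    interval) minimising the mean absolute distance between each shifted SG
    trigger and its nearest ECG trigger is applied.  Matches farther than
    half the median ECG interval are excluded from the score.  Ties prefer
    the smaller absolute shift.
    """
    if len(sg) < 10 or len(ecg) < 10:
        raise ValueError("need at least 10 triggers in each train to align")
    if sg.times[-1] < ecg.times[0] or ecg.times[-1] < sg.times[0]:
        raise ValueError("trigger trains do not overlap in time")
    med = float(np.median(ecg.intervals))
    n_steps = int(med // step_ms)
    offsets = np.arange(-n_steps, n_steps + 1) * step_ms
    offsets = offsets[np.argsort(np.abs(offsets), kind="stable")]
    gate = 0.5 * med
    best_offset, best_score = 0.0, np.inf
    for off in offsets:
        _, dist = _nearest_match(sg.times + off, ecg.times)
        matched = dist[dist <= gate]
        score = matched.mean() if matched.size else np.inf
        if score < best_score - 1e-12:
            best_score, best_offset = score, float(off)
    return sg.shifted(best_offset), best_offset


def compute_isd(sg: TriggerTrain, ecg: TriggerTrain, offset_ms: float = 0.0) -> TriggerComparison:
    """Interval SD of the absolute SG-vs-ECG cardiac interval differences.

    Each SG trigger is matched to its nearest ECG trigger (gated at half the
    median ECG interval); pairs of consecutive SG triggers matched to
    consecutive unflagged ECG triggers define the paired intervals.  With
    d_n = |(S_{n+1}-S_n) - (E_{n+1}-E_n)| and mu their mean,
    ISD = sqrt(sum((d_n - mu)^2) / (N - 1)).  ISD is 0 when every paired
    interval agrees and is invariant to shifting either train as a whole.
    """
    med = float(np.median(ecg.intervals))
    idx, dist = _nearest_match(sg.times, ecg.times)
    gate = 0.5 * med
    ok = dist <= gate
    ecg_iv_ok = ecg.interval_valid()

    sg_iv, ecg_iv, eidx = [], [], []
    for n in range(len(sg) - 1):
        if not (ok[n] and ok[n + 1]):
            continue
        m, m1 = idx[n], idx[n + 1]
        if m1 != m + 1:
            continue  # an ECG trigger was skipped or doubly matched
        if not ecg_iv_ok[m]:
            continue  # interval rejected by ECG cleaning
        sg_iv.append(sg.times[n + 1] - sg.times[n])
        ecg_iv.append(ecg.times[m1] - ecg.times[m])
        eidx.append(m)
    if len(sg_iv) < 3:
        raise ValueError(f"only {len(sg_iv)} paired intervals; need at least 3")
    sg_iv = np.asarray(sg_iv)
    ecg_iv = np.asarray(ecg_iv)
    d = np.abs(sg_iv - ecg_iv)
    mu = float(d.mean())
    isd = float(np.sqrt(np.sum((d - mu) ** 2) / (d.size - 1)))
    return TriggerComparison(
        sg_intervals=sg_iv,
        ecg_intervals=ecg_iv,
        abs_diff=d,
        mu=mu,
        isd=isd,
        n=int(d.size),
        offset_ms=offset_ms,
        ecg_index=np.asarray(eidx, dtype=int),
    )


def rsa_split(
    train: TriggerTrain, resp: np.ndarray, fs: float
) -> tuple[float, float, float]:
    """Mean heart rate during inspiration vs expiration for one train.

    Each cardiac interval is assigned to inspiration when the respiratory
    derivative at the interval midpoint is positive (the conditioned
    respiratory signal increases during inspiration), else to expiration.
    Returns (mean inspiration HR, mean expiration HR, Welch t-test p) in bpm.
    Use :func:`rsa_paired_test` for the paired test across several subjects.
    """
    resp = np.asarray(resp, dtype=float)
    iv = train.intervals
    mid = (train.times[:-1] + train.times[1:]) / 2.0
    deriv = np.gradient(resp) * fs
    idx = np.clip((mid / 1000.0 * fs).astype(int), 0, resp.size - 1)
    insp = deriv[idx] > 0
    if insp.all() or (~insp).all():
        raise ValueError("all intervals fall in a single respiratory phase")
    hr = 60000.0 / iv
    hr_in, hr_ex = hr[insp], hr[~insp]
    if np.ptp(hr) == 0:
        p = 1.0
    else:
        p = float(stats.ttest_ind(hr_in, hr_ex, equal_var=False).pvalue)
    return float(hr_in.mean()), float(hr_ex.mean()), p


def rsa_paired_test(means_insp, means_exp) -> tuple[float, float]:
    """Paired t-test of per-subject inspiration vs expiration mean HR."""
    a = np.asarray(means_insp, dtype=float)
    b = np.asarray(means_exp, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need matched per-subject means for at least 2 subjects")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def bonett_seier_paired(
    d1, d2, alternative: str = "less"
) -> tuple[float, float]:
    """Bonett-Seier test comparing the dispersion of two paired samples.

    Tests the ratio of the two mean absolute deviations (MAD about the
    sample mean) with a z statistic on the log MAD ratio whose variance is
    adjusted for the correlation between the paired absolute deviations.
    ``alternative='less'`` gives the one-sided p for sample 1 being LESS
    dispersed than sample 2.  Swapping the samples negates the statistic;
    identical samples give statistic 0 and one-sided p = 0.5.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape or d1.ndim != 1:
        raise ValueError("paired samples must be 1D and of equal length")
    n = d1.size
    if n < 5:
        raise ValueError("need at least 5 pairs")
    a1 = np.abs(d1 - d1.mean())
    a2 = np.abs(d2 - d2.mean())
    tau1, tau2 = a1.mean(), a2.mean()
    if tau1 == 0 or tau2 == 0:
        raise ValueError("zero mean absolute deviation in a sample")
    num = np.log(tau1) - np.log(tau2)
    v1 = a1.var(ddof=1) / tau1**2
    v2 = a2.var(ddof=1) / tau2**2
    c12 = np.cov(a1, a2, ddof=1)[0, 1] / (tau1 * tau2)
    var = (v1 + v2 - 2.0 * c12) / n
    if num == 0.0:
        z = 0.0
    elif var <= 0:
        z = np.inf if num > 0 else -np.inf
    else:
        z = float(num / np.sqrt(var))
    if alternative == "less":
        p = float(stats.norm.cdf(z))
    elif alternative == "greater":
        p = float(stats.norm.sf(z))
    elif alternative == "two-sided":
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return z, p


@dataclass
class BlandAltman:
    mean_diff: float
    lower_limit: float
    upper_limit: float
    slope: float
    intercept: float
    r_squared: float
    n: int


def bland_altman(int_sg, int_ecg) -> BlandAltman:
    """Bland-Altman agreement of paired intervals plus a paired linear fit.

    Returns the mean difference with 95% limits of agreement
    (mean +/- 1.96 SD) and the slope/intercept/R^2 of regressing the SG
    intervals on the ECG intervals.
    """
    x = np.asarray(int_ecg, dtype=float)
    y = np.asarray(int_sg, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired intervals")
    diff = y - x
    m = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.ptp(x) == 0:
        slope, intercept, r2 = 0.0, float(y.mean()), 1.0 if np.ptp(y) == 0 else 0.0
    else:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue**2) if not np.isnan(res.rvalue) else 1.0
    return BlandAltman(m, m - 1.96 * sd, m + 1.96 * sd, slope, intercept, r2, int(x.size))
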