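"""Sorting readouts into respiratory and cardiac motion states.

Respiratory binning divides the conditioned respiratory amplitude into four
equally populated phases from end-expiration (lowest amplitude, bin 0) to
end-inspiration.  Cardiac binning uses the triggers only: the mean cardiac
interval divided by the desired 50 ms bin width (rounded half away from
zero) fixes the number of bins per cycle, and each interval is then divided
into that many equal phase fractions, so every heartbeat contributes the
same phase grid regardless of its length.  Readouts outside the trigger
span are rejected rather than wrapped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .triggers import TriggerTrain

__all__ = ["BinAssignment", "bin_respiratory", "bin_cardiac", "combine_bins"]

REJECTED = -1


@dataclass
class BinAssignment:
    """Per-readout respiratory and cardiac bin indices (-1 = rejected)."""

    resp_bin: np.ndarray
    card_bin: np.ndarray
    n_resp_bins: int
    n_cardiac_bins: int
    width_ms: float

    @property
    def accepted(self) -> np.ndarray:
        return (self.resp_bin != REJECTED) & (self.card_bin != REJECTED)

    def counts(self) -> np.ndarray:
        """Occupancy per (respiratory, cardiac) bin; sums to accepted readouts."""
        out = np.zeros((self.n_resp_bins, self.n_cardiac_bins), dtype=int)
        ok = self.accepted
        np.add.at(out, (self.resp_bin[ok], self.card_bin[ok]), 1)
        return out


def bin_respiratory(resp_values: np.ndarray, n_phases: int = 4) -> np.ndarray:
    """Assign each readout to an equally populated respiratory amplitude bin.

    Quantile thresholds split the amplitude distribution into ``n_phases``
    phases; bin 0 is the lowest quantile (end-expiration).  Values exactly on
    a threshold go to the lower bin.
    """
    v = np.asarray(resp_values, dtype=float)
    if np.ptp(v) == 0:
        raise ValueError("constant respiratory signal has no amplitude range")
    thresholds = np.quantile(v, np.arange(1, n_phases) / n_phases)
    return np.searchsorted(thresholds, v, side="left").astype(int)


def n_cardiac_bins(mean_interval_ms: float, width_ms: float = 50.0) -> int:
    """Number of cardiac bins: mean interval / width, rounded half away from zero."""
    if width_ms <= 0:
        raise ValueError("bin width must be positive")
    return max(1, int(np.floor(mean_interval_ms / width_ms + 0.5)))


def bin_cardiac(
    train: TriggerTrain, readout_times_ms: np.ndarray, width_ms: float = 50.0
) -> tuple[np.ndarray, int]:
    """Assign each readout to a cardiac phase bin within its trigger interval.

    The bin count comes from the mean interval and ``width_ms``; within each
    interval the bin is ``floor(n_bins * fractional phase)`` clipped to the
    last bin, with the phase measured from that interval's own start (no
    normalisation across intervals).  Readouts before the first or at/after
    the last trigger are rejected (-1).
    """
    if len(train) < 2:
        raise ValueError("need at least 2 triggers for cardiac binning")
    t = np.asarray(readout_times_ms, dtype=float)
    tt = train.times
    nb = n_cardiac_bins(float(np.mean(train.intervals)), width_ms)
    k = np.searchsorted(tt, t, side="right") - 1
    inside = (k >= 0) & (k < tt.size - 1)
    bins = np.full(t.shape, REJECTED, dtype=int)
    ki = k[inside]
    phase = (t[inside] - tt[ki]) / (tt[ki + 1] - tt[ki])
    bins[inside] = np.minimum((nb * phase).astype(int), nb - 1)
    return bins, nb


def combine_bins(
    resp_values: np.ndarray,
    train: TriggerTrain,
    readout_times_ms: np.ndarray,
    n_phases: int = 4,
    width_ms: float = 50.0,
) -> BinAssignment:
    """Joint respiratory/cardiac assignment for a set of readouts."""
    resp_bin = bin_respiratory(resp_values, n_phases)
    card_bin, nb = bin_cardiac(train, readout_times_ms, width_ms)
    return BinAssignment(
        resp_bin=resp_bin,
        card_bin=card_bin,
        n_resp_bins=n_phases,
        n_cardiac_bins=nb,
        width_ms=width_ms,
    )
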