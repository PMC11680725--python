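"""From complex SI readouts to the real self-gating matrix.

The 1D Fourier transform of each SI readout gives a body profile along the
superior-inferior axis; taking its magnitude and concatenating all coil
elements column-wise yields the 2D self-gating matrix (rows = readout times,
columns = SI position x coil).  The pseudo-periodic sampling trajectory
modulates these signals with the segment position (the angle of the readout
within the repeating pattern); subtracting each column's per-segment-position
temporal mean cancels any purely angle-dependent additive component while
leaving the physiological time courses untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .synth import SIStack

__all__ = ["SGMatrix", "assemble_sg_matrix", "correct_angular_dependence"]


@dataclass
class SGMatrix:
    """Real self-gating matrix: time x (SI position * coil)."""

    values: np.ndarray
    fs: float
    positions: np.ndarray  # SI position index per column
    coils: np.ndarray  # coil index per column
    segment_index: np.ndarray  # trajectory segment position per row

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("self-gating matrix contains non-finite entries")

    @property
    def n_times(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def assemble_sg_matrix(stack: SIStack) -> SGMatrix:
    """Fourier-transform SI readouts and concatenate coil magnitudes.

    Per readout and coil element the 1D DFT along the readout dimension is
    taken (DC shifted to the centre position) and its magnitude kept; the
    per-coil blocks are concatenated along the column axis in coil order,
    preserving acquisition time in the row order.
    """
    if stack.readouts.size == 0:
        raise ValueError("empty SI stack")
    n_t, n_pos, n_coils = stack.readouts.shape
    profiles = np.abs(np.fft.fftshift(np.fft.fft(stack.readouts, axis=1), axes=1))
    values = profiles.transpose(0, 2, 1).reshape(n_t, n_coils * n_pos)
    coils = np.repeat(np.arange(n_coils), n_pos)
    positions = np.tile(np.arange(n_pos), n_coils)
    return SGMatrix(
        values=values,
        fs=stack.fs,
        positions=positions,
        coils=coils,
        segment_index=np.asarray(stack.segment_index),
    )


def correct_angular_dependence(m: SGMatrix) -> SGMatrix:
    """Remove trajectory-angle-dependent offsets from every channel.

    For each column and each segment-position group of rows, the group's
    temporal mean is subtracted, leaving (approximately) zero mean within
    every group.  A signal that is a pure function of the segment position is
    cancelled exactly; the operation is idempotent.  Groups with fewer than
    2 rows are left unchanged with a warning.
    """
    values = m.values.copy()
    for g in np.unique(m.segment_index):
        rows = np.flatnonzero(m.segment_index == g)
        if rows.size < 2:
            warnings.warn(
                f"segment-position group {g} has {rows.size} row(s); left unchanged",
                stacklevel=2,
            )
            continue
        values[rows] -= values[rows].mean(axis=0, keepdims=True)
    return replace(m, values=values)
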