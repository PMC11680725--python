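import numpy as np
import pytest

from selfgate import bss, si_preproc, synth


@pytest.fixture(scope="session")
def default_gt():
    """300 s of RSA-coupled physiology at the default ~16 Hz rate."""
    return synth.simulate_physio(rsa_gain_bpm=6.0, seed=11)


@pytest.fixture(scope="session")
def default_stack(default_gt):
    return synth.simulate_si_stack(default_gt, noise_sd=0.3, seed=12)


@pytest.fixture(scope="session")
def default_pca(default_stack):
    m = si_preproc.correct_angular_dependence(si_preproc.assemble_sg_matrix(default_stack))
    return bss.pca_reduce(m)


def make_sg_matrix(values, fs=16.0, segment_index=None):
    """Wrap a plain array as an SGMatrix for unit tests."""
    values = np.asarray(values, dtype=float)
    n_t, n_ch = values.shape
    if segment_index is None:
        segment_index = np.arange(n_t) % 22
    return si_preproc.SGMatrix(
        values=values,
        fs=fs,
        positions=np.arange(n_ch),
        coils=np.zeros(n_ch, dtype=int),
        segment_index=np.asarray(segment_index),
    )
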