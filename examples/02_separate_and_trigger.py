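"""Separate cardiac from respiratory motion and detect triggers.

Runs the self-gating matrix assembly, angular correction, PCA reduction and
the SOBI rotation, then selects components by spectral prominence and
detects cardiac triggers by zero crossings.
"""

import numpy as np

from selfgate import bss, physio, synth
from selfgate.si_preproc import assemble_sg_matrix, correct_angular_dependence

gt = synth.simulate_physio(rsa_gain_bpm=6.0, duration_s=300.0, seed=0)
stack = synth.simulate_si_stack(gt, noise_sd=0.3, seed=1)

m = correct_angular_dependence(assemble_sg_matrix(stack))
pca = bss.pca_reduce(m, n_components=10)
print(f"first 10 PCs explain    : {100 * pca.explained_variance.sum():.1f}% of variance")

for name, ss in (("PCA", pca), ("SOBI", bss.sobi(pca))):
    ri, rfit = physio.select_component(ss, physio.RESP_BAND_HZ)
    ci, cfit = physio.select_component(ss, physio.CARDIAC_BAND_HZ, exclude={ri})
    corr = abs(np.corrcoef(ss.sources[:, ci], stack.cardiac_source)[0, 1])
    train = physio.detect_triggers(ss.sources[:, ci], ss.fs, source_label=f"SG-{name}")
    print(
        f"{name:4s}: resp comp {ri} ({rfit.center_hz:.2f} Hz), cardiac comp {ci} "
        f"({cfit.center_hz:.2f} Hz), |corr| with true cardiac source {corr:.3f}, "
        f"{len(train)} triggers"
    )

print(
    "\nSOBI's cardiac component correlates more strongly with the hidden\n"
    "cardiac source than PCA's: joint diagonalization of lagged covariances\n"
    "separates sources that PCA leaves mixed when their spatial weights\n"
    "overlap and RSA couples them in time."
)
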