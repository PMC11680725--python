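"""Evaluate self-gated triggers against a defective ECG recording.

Cleans the ECG with the moving-median interval rules, aligns the self-gated
train on a 10 ms grid, and computes the ISD precision statistic plus
Bland-Altman agreement.
"""

from selfgate import synth, triggers
from selfgate.pipeline import RunConfig, run_extraction

cfg = RunConfig(
    duration_s=300.0,
    methods=("PCA", "SOBI"),
    ecg_missing_rate=0.02,
    ecg_jitter_sd_ms=3.0,
    seed=4,
)
report = run_extraction(cfg)

ecg = report["ecg"]
n_flagged = int((~ecg.interval_valid()).sum())
print(f"ECG cleaning            : {n_flagged} of {len(ecg) - 1} intervals flagged")

for name, res in report["methods"].items():
    c = res["comparison"]
    ba = triggers.bland_altman(c.sg_intervals, c.ecg_intervals)
    print(
        f"{name:4s}: ISD {c.isd:6.2f} ms over {c.n} paired intervals "
        f"(alignment offset {c.offset_ms:+.0f} ms); "
        f"Bland-Altman mean {ba.mean_diff:+.1f} ms, "
        f"95% limits [{ba.lower_limit:+.1f}, {ba.upper_limit:+.1f}] ms, R^2 {ba.r_squared:.3f}"
    )

print(
    "\nISD is the SD of the absolute differences between self-gated and ECG\n"
    "interval lengths: the lower value marks the more precise extraction\n"
    "even though 2% of the ECG triggers were deliberately deleted."
)
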