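"""Couple trigger quality to image quality with the toy reconstruction.

Bins a radial acquisition of a beating disk twice -- with the true triggers
and with triggers jittered by +/-100 ms -- reconstructs both with the ADMM
compressed-sensing solver, and compares the diastolic-bin RMSE.
Takes about 20 s.
"""

from selfgate.pipeline import run_binning_experiment

res = run_binning_experiment(seed=0)

print(f"cardiac bins            : {res['n_cardiac_bins']} (diastolic: {res['diastolic_bins']})")
print(f"RMSE, true triggers     : {res['rmse_true']:.4f}")
print(f"RMSE, jittered triggers : {res['rmse_jittered']:.4f}")
print("per-bin RMSE (true)     :", [f"{v:.3f}" for v in res["per_bin_rmse_true"]])
print("per-bin RMSE (jittered) :", [f"{v:.3f}" for v in res["per_bin_rmse_jittered"]])
print(
    "\nWith correct triggers the diastolic bins see a static disk and come\n"
    "out sharp; jittered triggers leak contracting systolic frames into\n"
    "them and blur the reconstruction -- the mechanism by which imprecise\n"
    "self-gating degrades motion-resolved images."
)
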