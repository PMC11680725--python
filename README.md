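# selfgate

Self-gated cardiac motion extraction for free-running whole-heart MRI,
implemented end to end on synthetic data with known ground truth.

In free-running acquisitions the scanner samples k-space continuously and
the cardiac/respiratory timing is recovered from the data themselves: the
repeated superior-inferior (SI) projection of a 3D radial trajectory gives
a ~16 Hz time series of body profiles in which respiration (0.1-0.7 Hz)
and the heartbeat (0.5-2.0 Hz) are mixed.  PCA is the standard way to
extract these signals, but respiratory sinus arrhythmia and overlapping
spatial footprints leave its components mixed.  This package implements
and compares the three separation strategies used for this task — PCA,
second-order blind identification (SOBI, joint diagonalization of lagged
covariances), and FastICA — together with everything needed to judge them:

- a **simulator** for SI readout stacks, trigger trains with heart-rate
  variability and respiratory sinus arrhythmia, defective ECGs, beating
  radial k-space phantoms and sigmoid edge images (`selfgate.synth`);
- **self-gating matrix** assembly and trajectory-angle correction
  (`selfgate.si_preproc`);
- the three **separation methods** (`selfgate.bss`; the SOBI Jacobi joint
  diagonaliser is written here in full);
- automated **component selection**, respiratory conditioning and
  zero-crossing **trigger detection** (`selfgate.physio`);
- **evaluation against ECG**: interval cleaning, 10-ms-grid alignment, the
  interval-SD (ISD) precision statistic
  `ISD = sqrt( Σ(d_n − μ)² / (N−1) )`, `d_n = |ΔS_n − ΔE_n|`,
  plus Bland-Altman limits and a paired Bonett-Seier dispersion test
  (`selfgate.triggers`);
- respiratory/cardiac **binning** (4 amplitude quartiles; ~50 ms cardiac
  phase bins per heartbeat) (`selfgate.binning`);
- a toy **k-t sparse SENSE reconstruction**
  `argmin ‖FCx − y‖² + λr|∇r x|₁ + λc|∇c x|₁` solved by ADMM
  (`selfgate.recon`);
- an edge-**sharpness** metric: sigmoid fits on Bézier-curve
  perpendiculars, 10-90% rise distance `(FOV/BR)·2·log10(9)/|s|`
  (`selfgate.sharpness`).

`selfgate.pipeline` chains the stages and a thin `selfgate` CLI exposes
them; `examples/` holds one narrative script per capability.
See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

```bash
selfgate demo --seed 1 --duration-s 300
```

prints (computed live; five minutes of simulated free-running data with
RSA gain 6 bpm and channel noise 0.3):

```
PCA : ISD  15.35 ms | mu  22.23 ms | N  297 | offset   -380 ms | HR insp/exp 62.6/57.9 bpm
SOBI: ISD  12.59 ms | mu  16.47 ms | N  297 | offset   -380 ms | HR insp/exp 62.4/58.1 bpm
ICA : ISD  13.39 ms | mu  17.11 ms | N  297 | offset   -380 ms | HR insp/exp 62.3/58.1 bpm
```

Each line evaluates one extraction method against the (here: ground-truth)
ECG train: `ISD` is the standard deviation of the absolute differences
between self-gated and ECG cardiac interval lengths — the precision of the
extracted triggers, smaller is better; `mu` is the mean absolute interval
difference; `N` the number of paired intervals; `offset` the constant
SG-to-ECG delay removed by the alignment search; the last column is the
mean heart rate during inspiration vs expiration, showing the simulated
respiratory sinus arrhythmia (the heart beats ~4 bpm faster while air
flows in).  On this record SOBI extracts the most precise triggers,
PCA the least precise — the separation the whole framework exists to
demonstrate.

The same run from Python:

```python
from selfgate.pipeline import RunConfig, run_extraction
report = run_extraction(RunConfig(seed=1, duration_s=300.0))
print(report["methods"]["SOBI"]["comparison"].isd)   # 12.59... (ms)
```

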