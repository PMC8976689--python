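# cine4d

Real-time predictive 4D-MRI reconstruction from a single 2D cine-MR plane,
for MR-guided radiotherapy of moving lung tumors, evaluated end to end on a
synthetic breathing phantom with analytic ground truth.

During MR-guided treatment the device only images one sagittal plane at
~4 Hz, while the tumor moves in 3D and the chain from image acquisition to
beam delivery takes on the order of 1.5 s. `cine4d` closes both gaps: it
translates each incoming MR cine frame to CT appearance, regresses the 3D
displacement of a tumor-surrounding tracked-voxel set **6 frames (1.5 s)
into the future** with a recurrent model trained from the patient's planning
4D data, densifies the scattered prediction into a deformation field, and
warps the reference MR volume — emitting one predicted 3D frame per cine
frame.

Everything runs on one CPU with no deep-learning framework: the LSTM
regressor and the cycle-adversarial intensity translator are implemented in
NumPy with manual backprop. See `docs/methods.md` for the model, the
numerical choices and their rationale.

## Modules

| Module | Role |
| --- | --- |
| `cine4d.phantom` | Synthetic 4D breathing phantom (CT/MR renderings, analytic truth) |
| `cine4d.flow` | 3D Lucas–Kanade optical flow of a tracked voxel set |
| `cine4d.translate` | MR→CT intensity translation (lookup or cycle-adversarial) |
| `cine4d.motion` | LSTM regression: cine window → future 3D displacement |
| `cine4d.reconstruct` | Scattered→dense flow, backward warping of the reference volume |
| `cine4d.pipeline` | `pretreat` (training branch) + `stream` (real-time loop) + latency report |
| `cine4d.io` | NIfTI volumes/cine stacks, npz+JSON flow/model artifacts, checksums |

## Worked example

The headline experiment — full pretreatment on a phantom with 16 mm
peak-to-peak tumor motion and respiratory-period augmentation
{4.0, 4.5, 5.0, 5.5, 6.0} s, then streaming one full cine cycle at an
*unseen* 5.2-s breathing period — runs in one command (~5–6 min on one CPU):

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Output from an actual run:

```
pretreat: (64, 64, 64) phantom, amplitude 16.0 mm, periods (4.0, 4.5, 5.0, 5.5, 6.0) s, seed 1 ...
pretreat done in 326 s
streamed 22 frames at unseen period 5.2 s in 9 s
per-frame stage times (s):
  translate    mean 0.0003  max 0.0005
  input_prep   mean 0.0000  max 0.0000
  predict      mean 0.0038  max 0.0043
  reconstruct  mean 0.4263  max 0.4737
latency budget: horizon 1.50 s vs imaging 0.25 + beam 0.50 + margin 0.00 + compute
budget violations: 0/22 frames
per-axis RMSE (mm): x 0.153 y 0.144 z 0.974
max 3D error: 1.861 mm
  inspiration_peak   RMSE (mm) 0.128 0.174 0.948
  expiration_peak    RMSE (mm) 0.073 0.071 0.529
  transition         RMSE (mm) 0.205 0.178 1.252
wrote results/acceptance.json: {"t1": {"value": 1.860733489291677, "n": 22}}
```

The maximum 3D error of the predicted tumor-mean displacement at the 1.5-s
horizon stays below 2 mm for a tumor moving ~16 mm, with the residual
concentrated in the superior–inferior axis around peak inspiration.

The same experiment in Python:

```python
from cine4d import pipeline as pl

result = pl.pretreat(pl.PretreatConfig(seed=1), outdir="artifacts/")
for out in pl.stream(result, cine_frames):     # any iterable of CineFrame
    out.frame        # predicted 3D MR volume, stamped 1.5 s ahead
    out.flow         # predicted tracked-set displacement (mm)
    out.budget       # per-stage compute times + latency-contract flag
```

## Command line

A thin `cine4d` console script wraps the library:

```sh
cine4d phantom --out data/ --frames 21 --modality mr   # generate phantom series
cine4d translate-train --mr mr.nii.gz --ct ct.nii.gz --out model
cine4d translate-apply --model model --cine cine.nii.gz --out ct_cine.nii.gz
cine4d pretreat --config config.yaml --out artifacts/
cine4d stream --models artifacts/ --cine cine.nii.gz --out recon/
cine4d evaluate --pred recon/predicted_flows --truth labels/flows
```

## Tests

```sh
python -m pytest tests -q
```

The suite contains per-module oracle/property tests plus
`tests/test_acceptance.py` with one test per acceptance criterion (headline
≤ 2 mm recovery, exact horizon arithmetic, optical-flow oracles, warping
oracles, translation fidelity incl. a scaled-down adversarial run, and
artifact-checksum determinism). The full suite takes ~12 min on one CPU;
the headline experiment dominates.
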