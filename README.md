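# cestnoe

Quantification of the NOE(−1.6 ppm) CEST signal at low field (4.7 T) with a
regressor trained on partially synthetic Z-spectra.

## The problem

The nuclear Overhauser enhancement saturation-transfer signal at −1.6 ppm
upfield of water — NOE(−1.6), likely from choline phospholipid protons — is a
promising marker for brain tumors and stroke, but at 4.7 T it sits on the
shoulder of the direct water saturation dip, under the broad semi-solid MT
background and the tail of the fast amine CEST effect. It never forms a
visible dip in the Z-spectrum Z(Δω) = S(Δω)/S₀, so the standard multi-pool
Lorentzian decomposition recovers its amplitude noisily and with large bias.

`cestnoe` is for CEST-MRI researchers who want to quantify this signal
per voxel or per ROI. It provides:

- **`cestnoe.core`** — the closed-form machinery: the exchange-dependent
  relaxation rate of a dilute pool
  `Rex(Δω) = f_s·k_sw·ω₁²/(ω₁² + (R_2s+k_sw)·k_sw + (Δω−Δ)²·k_sw/(R_2s+k_sw))`,
  its analytic width `W = 2√(ω₁²(R_2s+k_sw)/k_sw + (R_2s+k_sw)²)`, the
  effective water rate Reff, the AREX metric
  `R_1obs(1/S_lab − 1/S_ref)(1+f_m)`, and the 89-point acquisition grid.
- **`cestnoe.lorentz`** — six-pool Lorentzian decomposition with B0
  correction, per-pool AREX spectra and NOE(−1.6) amplitude/width extraction
  (the comparison baseline).
- **`cestnoe.synth`** — partially synthetic Z-spectra by inverse summation:
  measured NOE(−3.5), amine/guanidine and MT components from one fitted
  spectrum, combined with an analytic NOE(−1.6) term and Reff, so every
  training sample has an exact label.
- **`cestnoe.quant`** — a small 1-D convolutional regressor (three conv
  layers 64/32/16, dense 256/128, ELU, Adam) trained with a curriculum that
  re-injects σ = 0.005 Gaussian noise to learn denoising; input is
  R_1obs/Z on the 43 offsets in [−10, −0.8] ∪ [5, 10] ppm.
- **`cestnoe.bloch`** — a multi-pool Bloch–McConnell simulator (matrix
  exponential propagator) generating tissue-mimicking validation spectra with
  analytic ground truth, and fully simulated training data.
- **`cestnoe.evaluate` / `cestnoe.study`** — the five training-regime
  emulations, loss evaluation against ground truth across SNR levels, and the
  bundled reproducible comparison study.

## Worked example

```python
import numpy as np

from cestnoe.bloch import default_brain_model, ground_truth, simulate_zspectrum
from cestnoe.core import SaturationParams
from cestnoe.io import default_grid
from cestnoe.lorentz import fit_multipool, noe16_from_fit
from cestnoe.quant import CurriculumConfig, ModelConfig, predict, train_curriculum
from cestnoe.synth import SynthRanges, extract_components, sample_dataset

grid = default_grid()                      # 89 offsets, -10..10 ppm at 4.7 T
sat = SaturationParams(B1_uT=1.0, t_sat=5.0)

# a brain-like seven-pool spectrum with known NOE(-1.6) ground truth
model = default_brain_model()
zspec = simulate_zspectrum(model, sat, grid)
A_true, W_true = ground_truth(model, sat, grid)
print(f"ground truth:     A = {A_true:.4f} s^-1, W = {W_true:.3f} ppm")

# baseline: six-pool Lorentzian fit
fit = fit_multipool(zspec)
A_fit, W_fit, _, _ = noe16_from_fit(fit, zspec.R1obs, zspec.fm, grid)
print(f"Lorentzian fit:   A = {A_fit:.4f} s^-1, W = {W_fit:.3f} ppm")

# partially synthetic training data from this one spectrum's fitted components
comp = extract_components(zspec, fit)
train = sample_dataset([comp], SynthRanges(), n=4000, seed=0, sat=sat, grid=grid)
cfg = ModelConfig(epochs_first=100, epochs_later=25)
regressor = train_curriculum(train, cfg, CurriculumConfig(), target="A", seed=0)

A_ml = predict(regressor, [zspec])[0]
print(f"ML prediction:    A = {A_ml:.4f} s^-1")
```

Output (about two minutes on one CPU):

```
ground truth:     A = 0.0394 s^-1, W = 0.678 ppm
Lorentzian fit:   A = 0.1506 s^-1, W = 0.564 ppm
ML prediction:    A = 0.0325 s^-1
```

The amplitude `A` is the NOE(−1.6) exchange-dependent relaxation rate at the
peak centre in s⁻¹ (the AREX scale) and `W` its full width at half maximum in
ppm. The Lorentzian fit overshoots the true amplitude almost fourfold —
the water-shoulder interference that motivates this package — while the
regressor trained on partially synthetic data from that same single spectrum
lands close to the truth. Larger training sets and the full epoch schedule
(see `cestnoe.study.StudyConfig`) tighten the prediction further.

There is also a CLI mirroring the library:

```sh
cest-noe simulate --n-select 100 --seed 1 --out tissue.npz
cest-noe fit --in spectra.csv --out fitted.csv
cest-noe synth --spectra spectra.csv --n 50000 --seed 1 --out train.npz
cest-noe train --data train.npz --target A --seed 1 --out model/
cest-noe predict --model model/ --in spectra.csv --out pred.csv
cest-noe evaluate --test-data tissue.npz --model model/ --snr 75 --out-dir results/
cest-noe fixtures --seed 1 --out-dir fixtures/
```

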