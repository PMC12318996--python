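# leafspec

Non-destructive detection of microplastic stress in plant leaves from
spectroscopy.  Plants exposed to microplastics (PET, polystyrene, PVC)
show pigment degradation, water-transport interference and cell-wall
remodelling long before visible damage; those changes leave fingerprints
in visible/near-infrared leaf reflectance and in mid-infrared absorption.
`leafspec` implements the full analysis stack for such experiments:

* **VNIR hyperspectral ingest** — ENVI/HDF5 cube I/O, single-band
  threshold segmentation of leaves on a bright board (reflectance < 0.6
  at 655 nm), per-leaf mean spectra, cropping to the retained 425–965 nm
  window (256 bands).
* **Chemometrics** — PCA scores/loadings with explained-variance
  reporting and a PLS-DA baseline classifier.
* **SE-LSTM classifier** — a squeeze-and-excitation channel-attention
  block over the 256 band channels,

      z = GAP(x),  s = σ(W₂ relu(W₁ z + b₁) + b₂),  x′ = s ⊙ x,

  feeding a stacked LSTM (one band per time step, low → high wavelength)

      f_t = σ(W_fx x_t + W_fh h_{t−1} + b_f)        i_t = σ(W_ix x_t + W_ih h_{t−1} + b_i)
      o_t = σ(W_ox x_t + W_oh h_{t−1} + b_o)        g_t = tanh(W_gx x_t + W_gh h_{t−1} + b_g)
      c_t = f_t ⊙ c_{t−1} + i_t ⊙ g_t               h_t = o_t ⊙ tanh(c_t)

  with a softmax head over the exposure classes 0 / 10 / 100 mg/L, the
  architecture grid (1–3 layers × 16–128 units) and optimizer ×
  learning-rate sweep, and accuracy / loss / overfitting-coefficient
  evaluation against plain-LSTM and PLS-DA baselines.
* **Wavelength selection** — SPA, GA, binary PSO and BOSS with a shared
  cross-validated PLS-DA wrapper fitness, plus simplified models
  retrained on the selected bands.
* **Shapley attribution** — exact coalition enumeration (per band for
  d ≤ 15, or over 16 contiguous band groups for full spectra) and seeded
  permutation sampling, with global-importance and per-class beeswarm
  tables.
* **SR-FTIR + 2DCOS** — transmission → absorbance (A = −log₁₀ T),
  rubberband/ALS baseline correction, functional-group and fingerprint
  region splitting, synchronous/asynchronous correlation maps
  (Φ = ỸᵀỸ/(m−1), Ψ = ỸᵀNỸ/(m−1) with the Hilbert–Noda matrix) and
  band-response sequencing by Noda's cross-peak sign rules.

No public dataset accompanies this problem, so the package ships a
first-class synthetic generator (`leafspec.synth`) producing seeded leaf
reflectance cubes, labelled spectra and FTIR series with planted ground
truth; every stage is validated against it.  See `docs/methods.md` for
the models, defaults and their rationale.

## Worked example

```python
import numpy as np
from leafspec.synth import (ProfileConfig, make_class_profiles,
                            simulate_spectra, simulate_ftir_series)
from leafspec.chemometrics import pca_fit
from leafspec.selstm import SELSTMConfig, train_selstm
from leafspec.ftir import compute_2dcos, noda_ordering

# 3-class leaf spectra for one polymer (32-band grid for a quick demo)
cfg = ProfileConfig(wavelengths=np.linspace(425, 965, 32), seed=0)
data = simulate_spectra(make_class_profiles(cfg).restrict("PET"),
                        n_per_class=60, seed=0)
print(f"{data.n_samples} spectra x {data.n_bands} bands, "
      f"classes {np.unique(data.concentration).tolist()} mg/L")

pca = pca_fit(data.X, k=3)
print("cumulative explained variance (3 PCs):", f"{pca.cumulative_ratio[-1]:.4f}")

model, report, _ = train_selstm(
    SELSTMConfig(n_bands=32, n_layers=2, units=32, reduction_ratio=4,
                 epochs=15, seed=0),
    data,
)
print(report.summary())

# FTIR series with a planted response order, sequenced by 2DCOS
series, truth = simulate_ftir_series(
    [(3356.0, 40.0, 0), (2910.0, 30.0, 1), (1730.0, 25.0, 2)],
    n_levels=16, seed=0, mode="absorbance",
)
res = compute_2dcos(series)
order = noda_ordering(res.sync, res.async_, series.wavenumbers,
                      [3356.0, 2910.0, 1730.0])
print("recovered FTIR band order:", order.arrow_notation())
```

prints

```
180 spectra x 32 bands, classes [0, 10, 100] mg/L
cumulative explained variance (3 PCs): 0.9770
calibration: 100.00%  loss 0.0013
prediction:  100.00%  loss 0.0013
overfitting coefficient: 0.00 points
recovered FTIR band order: 3356 → 2910 → 1730
```

The first three principal components carry ~98 % of the spectral
variance (the regime real leaf data sits in); the SE-LSTM separates the
three exposure classes perfectly on this clean synthetic benchmark —
an upper bound, not a field prediction (see the methods note); and the
asynchronous cross-peak signs recover the planted molecular response
sequence O–H (3356 cm⁻¹) before CH₂ (2910 cm⁻¹) before ester C=O
(1730 cm⁻¹).

The same pipeline is scriptable from the shell:

```sh
leafspec simulate --seed 1 --out run/
leafspec segment  --cube run/cube.h5 --out run/
leafspec extract  --cube run/cube.h5 --mask run/mask.png --out run/
leafspec pca      --spectra run/spectra.csv --out run/
leafspec train    --spectra run/spectra.csv --epochs 40 --out run/
leafspec select   --spectra run/spectra.csv --method ga --out run/
leafspec explain  --spectra run/spectra.csv --model run/model.npz --out run/
leafspec twodcos  --ftir run/ftir.csv --mode transmission \
                  --bands 3356,2910,1730 --out run/
```

Every command writes a manifest JSON (parameters, seeds, SHA-256 of each
artifact) so runs can be checked for bitwise reproducibility.

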