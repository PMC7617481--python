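# lateralpred

A tested reimplementation of a recurrent temporal-prediction model of primary
visual cortex (V1), together with the complete in-silico physiology and
connectivity pipeline used to characterize it — receptive-field mapping,
grating tuning, functional-connectivity motifs, ablation experiments,
prediction-error detection and noise-ceiling-normalized neural response
fitting — exercised end to end on synthetic naturalistic movies so that
everything runs on one CPU with no external downloads.

## Who this is for

Computational neuroscientists who want to probe how V1-like lateral
connectivity (like-to-like excitatory coupling, co-axial long-range biases,
direction-dependent excitatory/inhibitory input asymmetries) can emerge from
a normative objective — predicting the future of the visual input — and who
need the measurement machinery (RWA, Gabor fits, OSI/DSI, Cochran-Armitage
trend tests, shuffle controls, CC_norm) as reusable, tested components.

## The model

A single-layer recurrent network with linear readout:

```
s[t] = ReLU(W_in u[t] + W_rec s[t-1] + b_rec)
v̂[t] = W_out s[t] + b_out
```

where `u[t]` is a flattened movie frame (36×36 = 1,296 pixels at full scale)
and `s[t]` the hidden state (2,592 units, 90% excitatory / 10% inhibitory).
Dale's law is enforced by reparameterizing each recurrent weight as
`sign(presynaptic) · |w|` on every forward pass.  Training minimizes

```
E = Σ_n Σ_t ‖v̂_n[t] − v_n[t+1]‖² + λ(‖W_in‖₁ + ‖W_rec‖₁ + ‖W_out‖₁)
```

by Adam/backpropagation through time (implemented in numpy, gradient-checked
against finite differences).  Comparison objectives — denoising, inpainting,
sparse autoencoding — share the architecture with modified input/target
pairings.  Functional connectivity is read out by thresholding |W_rec| at
the 95th percentile over ordered unit pairs and relating edges to the units'
measured tuning and receptive-field geometry.

## Worked example

```python
import numpy as np
from lateralpred import synthetic_data as sd, netmodel as nm
from lateralpred import receptive_fields as rf, tuning as tn, connectivity as conn

# 1. synthetic drifting-texture corpus (16x16 px, 50-frame clips)
train, val = sd.generate_movie_corpus(sd.MovieGenParams(n_clips=2000, seed=1))

# 2. train the desk-profile predictor (512 hidden units)
cfg = nm.NetworkConfig.desk_profile(seed=0)
model = nm.init_network(cfg)
model, history = nm.train(model, train, cfg, validation=val)
print(f"validation MSE {history.val_mse.iloc[-1]:.3f} "
      f"vs persistence {nm.persistence_mse(val):.3f}")

# 3. physiology: receptive fields, inclusion, tuning
rfs = rf.response_weighted_average(model, 25000, seed=11)
fits = rf.fit_gabors(rfs, seed=3)
included, summary = rf.apply_inclusion_criteria(fits)
resp, grid = tn.grating_battery(model)
profiles = [tn.unit_tuning(resp[i], grid) for i in range(model.n_hidden)]
osi = np.array([p.OSI for p in profiles])

# 4. connectivity: like-to-like motif
graph = conn.threshold_connections(model.w_rec_effective,
                                   model.excitatory_mask,
                                   included=included, fits=fits)
prof = conn.probability_by_tuning_difference(
    graph, profiles, "orientation", "EE",
    selective=np.nan_to_num(osi) > 0.4)
print("E->E connection probability by Δorientation bin:", prof.probability)
print("trend test:", conn.cochran_armitage_trend(prof))
```

With these seeds this prints a validation MSE near 0.21 against a
persistence baseline near 0.66 (the network learns to extrapolate the
drifting texture rather than copy the current frame), and a
connection-probability profile over the Δorientation bins (0–22.5°,
22.5–67.5°, 67.5–90°) of roughly `[0.08, 0.04, 0.01]` — connection
probability falls monotonically as orientation preferences diverge, the
like-to-like motif — with a Cochran-Armitage trend statistic near z = −10
(p ≪ 1e-6).  Shuffling the recurrent weights among the same units (see
`connectivity.shuffle_control`) flattens the profile to its overall mean,
showing the bias is carried by which pairs are connected, not by the
distribution of preferred orientations.

An equivalent end-to-end run, with manifest and figures, is available from
the command line:

```
lateralpred run --config examples/desk_run.yaml --verbose
```

## Layout

```
src/lateralpred/
  synthetic_data.py    stimuli and surrogate datasets (movies, gratings,
                       bars/dots, oddballs, reference neurons)
  netmodel.py          the Dale-constrained recurrent predictor + training
  receptive_fields.py  response-weighted averages, Gabor fits, inclusion
  tuning.py            OSI/DSI, modulation ratio, response correlations
  connectivity.py      thresholded graph, motif profiles, trend tests,
                       shuffle controls, connectivity score
  perturbation.py      ablations, silhouette clustering, prediction errors
  neural_fit.py        PCA + Lasso + rectified sigmoid, CC_norm
  pipeline.py, cli.py  reproducible end-to-end runs (`lateralpred …`)
```

See `docs/methods.md` for the scientific conventions, parameter defaults
and known limitations.
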