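# Methods

## The model

The package implements a recurrent temporal-prediction account of primary
visual cortex (V1): a single recurrent layer is trained to predict the next
frame of a movie from the frames seen so far, under a biological sign
constraint and an L1 wiring cost, and the trained network is then probed
with the standard tools of in-silico physiology.

The dynamics are

    s[t] = ReLU(W_in u[t] + W_rec s[t-1] + b_rec)
    v_hat[t] = W_out s[t] + b_out

with u[t] the flattened input frame.  Hidden units carry a fixed
excitatory/inhibitory label (90% / 10% by default) and the recurrent matrix
is reparameterized on every forward pass as `sign(presynaptic unit) * |w|`,
so Dale's law holds exactly throughout training rather than being projected
back after each step.  The loss is the summed squared prediction error plus
`lambda * (||W_in||_1 + ||W_rec||_1 + ||W_out||_1)`; the sparse-autoencoder
variant adds an activity L1 term.  Optimization is Adam with
backpropagation through the full recurrence; both the gradients and the
optimizer are implemented directly in numpy, and the analytic gradient is
checked against central finite differences to 1e-4 relative error in the
test suite.

Initialization: feedforward weights are uniform with 1/sqrt(fan-in) scale.
The recurrent matrix uses the smaller 1/fan-in scale because the Dale
reparameterization rectifies weight magnitudes; column means are then
non-zero and a 1/sqrt(fan-in) recurrent init produces a runaway
ReLU-positive feedback loop (we observed immediate divergence), while
1/fan-in keeps the mean-field recurrent gain below 1.

## Scale profiles

The full-scale architecture (36x36-pixel input, 2,592 hidden units) is what
the configuration defaults describe and what the architecture checks
instantiate; it keeps the published optimization settings (learning rate
1e-4, lambda 1e-6, no gradient clipping).  All analyses that require
training run on a desk profile — 16x16-pixel input, 512 hidden units, 2,000
synthetic clips of 50 frames — chosen so the complete study (training plus
every downstream analysis) runs on one CPU core in minutes.

The desk profile's optimizer settings differ deliberately: batch size 8,
learning rate 1e-3, global-norm gradient clipping at 200, lambda_l1 1e-4,
30 epochs.  The reason is step count, not loss scale.  Structured input
weights develop over optimizer steps, and a desk budget affords only a few
thousand of them; large batches at the full-scale learning rate leave W_in
at an unstructured random projection that nevertheless predicts well (an
overcomplete recurrent network can implement the predictive map in any
basis, so nothing but regularization pressure and optimization dynamics
favors structured per-unit filters).  Small batches with a tenfold larger
clipped learning rate multiply the effective steps; without clipping this
setting diverges late in training through occasional exploding BPTT
gradients.  All values were selected by validation MSE and training
stability — the same criterion used for the full-scale hyperparameter
search.  Under these conditions the desk model develops
orientation-selective units (most units exceed OSI 0.4), a subpopulation
with Gabor-fittable receptive fields, and the like-to-like excitatory
connectivity motif with its shuffle-control flattening.

## The synthetic movie corpus

The naturalistic surrogate generator produces what the learning problem
actually needs from natural movies: spatially bandpass, kurtotic
(edge-like) structure that translates coherently over time.  Each clip is a
sparse superposition of randomly placed, randomly oriented line elements,
projected exactly onto an annulus of spatial frequencies (so the amplitude
spectrum is strictly in-band), advected rigidly at a velocity drawn per
clip (0.5-2 px/frame by default), lightly jittered per frame, and
normalized to zero mean and unit variance.  Gaussian noise at 6 dB SNR is
added to the network input (not the prediction target) on every training
presentation, mimicking upstream neural noise.

The sparse elements make the surrogate's statistics closer to natural
input: natural scenes are kurtotic and edge-dominated, while a Gaussian
texture with the same spectrum carries no higher-order structure.  In
control runs under the final optimization regime, orientation selectivity
emerges on spectrally matched Gaussian textures as well — the decisive
factor for feature emergence at this scale is the optimizer step budget
(see above), with the input statistics shaping which features are learned
rather than whether any are.  What the surrogate still lacks relative to wildlife footage:
occlusion, scale-invariant power spectra across octaves, locally varying
optic flow, and temporal luminance adaptation.  Conclusions about the
precise receptive-field taxonomy of the full-scale model therefore do not
transfer from these tests; the motif analyses (which depend on relative
tuning between units, not absolute RF shape) are the quantities the desk
profile is designed to exercise.

## Physiology pipeline

Receptive fields: response-weighted average of 25,000 standard-normal noise
frames presented continuously (recurrent state carried, not reset),
normalized by the summed response so the estimate is response-scale
invariant.  The spatiotemporal variant stacks the 7 past frames.  Gabor
parameterization by bounded nonlinear least squares with multi-start
initialization (data-driven guess from the squared-amplitude centroid and
dominant FFT component, a 90-degree-rotated variant, and seeded jitters).
Units are excluded when the fitted envelope size (geometric mean sigma)
falls below 0.5 px or the fit correlation below 0.7.

Tuning: drifting sinusoidal gratings on a grid of 5 log-spaced temporal
frequencies (0.02-0.25 cycles/frame), 6 log-spaced spatial frequencies
(0.03-0.5 cycles/pixel) and 16 directions; the mean response discards the
first 10 onset frames.  OSI/DSI are the usual contrast indices; the
orientation response curve averages the two directions sharing an axis.
Thresholds are strict inequalities; a DSI of exactly 0.8 counts as weakly
selective under the stringent direction threshold.  The modulation ratio
F1/F0 uses a least-squares sinusoid with free phase at the known stimulus
frequency, and is reported only when that sinusoid correlates at least 0.9
with the response trace.

Connectivity: units are connected when |w| strictly exceeds the 95th
percentile (linear-interpolation convention) of |w| over all ordered pairs
of included units, zero weights included in the pool, self-connections
excluded.  Absolute weight is used so inhibitory edges are detectable.
`W_rec[post, pre]` is the direction convention.  Visual-space normalization
translates the postsynaptic RF center to the origin and rotates by
R(theta - pi/2), mapping the preferred-orientation axis onto the vertical;
co-axial means |y| > |x|.  For direction analyses the preferred direction
is rotated onto +x and "ahead" is x > 0.  Distances convert at 6 degrees
per pixel; short range is < 2.5 px, long range 5-9.17 px, scalable for
reduced frames.  Shuffle controls permute recurrent weights among ordered
pairs of the analysis subset (multiset preserved exactly) and are used only
to re-measure connectivity, never to generate responses.

Perturbation: ablation replaces selected E->E edges with the median
connected E->E weight.  Classes: co-tuned (delta orientation < 22.5
degrees), orthogonal (> 67.5), co/anti-tuned (delta direction < 22.5 or >
157.5).  The silhouette analysis presents three grating classes offset by
0, 11.25 and 22.5 degrees across base orientations spanning the circle,
with input noise at the quoted SNRs, and scores time-averaged hidden
activity in the full hidden space (the 2-D embedding is display-only).
Prediction-error units are classified strictly (silent in both control
sequences, responsive at >= 5 deviant positions for some orientation pair;
"any pair" quantifier) or loosely (deviant response strictly exceeding 3x
control).  "Silent" means response <= machine epsilon, which rectified
units can attain exactly.

Neural fit: hidden activity -> first 200 PCs (fit on training segments) ->
Lasso (alpha from 40 log-spaced values in [1e-5, 10], selected by 5-fold
cross-validated CC_norm of the combined mapping; k=5 is our choice where
only "k-fold" is specified) -> rectified sigmoid `max(0, a/(1+e^((c-x)/b))
+ d)` by nonlinear least squares.  CC_norm divides the prediction/trial-mean
correlation by CC_max = sqrt(SP/var(mean)) with SP the standard unbiased
across-trial signal power (N var(mean) - mean var)/(N - 1); neurons with
non-positive SP estimates or noise-to-signal power ratio >= 60 are
excluded.  If the sigmoid degrades validation CC_norm by more than 0.05 the
linear stage is used alone and logged.

## Numerical choices and degenerate inputs

All randomness flows from explicit integer seeds; generators are pure
functions of (parameters, seed).  The pipeline fans one global seed out to
per-stage seeds via SHA-256.  Zero-variance units are skipped per clip in
response correlations (with counts reported), dead units get flagged
undefined RFs, empty profile bins report NaN rather than zero, degenerate
trend-test margins return p = 1 with a warning, and ablation draws are
rejected when a class has fewer edges than requested.

## Known limitations

Desk-scale training for a few minutes does not reproduce the clean
Gabor-like receptive-field taxonomy or the published percentages
(prediction-error prevalence, CC_norm table, connectivity scores): those
depend on full-scale training on wildlife footage and on recorded
Neuropixels data.  In particular, the desk model's included units have
near-full-field Gabor envelopes (median fitted size around 10 px on a 16 px
frame), so analyses that depend on receptive-field *position* geometry —
the co-axial/co-orthogonal long-range comparison and the bar-length
dependence of the co-axial ablation deficit — are degenerate at this scale:
orientation-based motifs reproduce, position-based ones do not, and the
test suite states this expectation where it applies.  The reference connectivity profiles shipped for the
connectivity score are synthetic qualitative stand-ins (labelled as such),
since the published values were digitized from figures and are not printed.
The Cochran-Armitage test uses the asymptotic normal null; for very sparse
tables the permutation comparison in the test suite bounds the error.
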