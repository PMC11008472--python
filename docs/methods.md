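# Methods

## Model overview and assumptions

`ffgcn` decodes multichannel motor-imagery EEG in three stages: a
functional-connectivity graph over channels, a Chebyshev spectral graph
convolutional feature extractor, and a dense classifier trained by the
forward-forward mechanism. The central assumption is that class
information is carried by the *functional topology* of the recording —
which channels co-fluctuate — rather than by channel means or marginal
amplitudes. Everything downstream is built to exploit exactly that
structure.

**Graph stage.** Edge weights are `w_ij = |corr(x_i, x_j)|` over the
concatenated training-split samples. Taking the absolute value makes
weights polarity-invariant (EEG referencing and dipole orientation can
flip signs); it also means anticorrelated channels are treated as
strongly connected. The adjacency diagonal is zeroed: self-correlation
is trivially 1 and would distort degrees in `L = D − A`. One graph is
built per training set (a per-trial-graph mode is not offered at the
pipeline level, but per-trial connectivity enters through the node
features, below).

**GCN stage.** Spectral filters are parameterized as order-K Chebyshev
expansions on the rescaled Laplacian and evaluated by the three-term
recursion, never through the eigenbasis. Four conv + max-pool stages
follow a node-halving schedule produced by greedy heavy-edge matching;
each coarsened graph gets its own independently rescaled Laplacian.
Convolution weights are shared across nodes (the standard Chebyshev
parameterization); bias is one value per output map. Pretraining is
plain supervised learning (softmax cross-entropy, Adam); afterwards the
output head alone can be fine-tuned with the earlier stages frozen, and
the penultimate `feature_width` vector is what the forward-forward
stack consumes.

**Forward-forward stage.** Layers are trained greedily and in order;
once a layer is trained it is frozen and only the unit-normalized
orientation of its activity propagates. Positive samples embed the true
one-hot label in the first C feature slots; negative samples either
embed a wrong label, or blend two trials' payloads through a binary
mask with large constant runs, mixed 50/50 by default. Inference embeds
each candidate label in turn and accumulates goodness over all layers
except the first — the first layer sees the label prefix directly, so
its goodness is trivially driven by the embedding and carries little
evidence (this exclusion is configurable).

## Node features for the GCN

The node-feature representation fed to the GCN is configurable and is a
genuine design choice of this package:

* `connectivity` (default): node *i* receives row *i* of the trial's
  own |PCC| matrix — its within-trial functional-connectivity profile.
  This is computed per trial from that trial's samples only, so it
  introduces no cross-trial statistics and no leakage.
* `signal`: node *i* receives its raw time series.

The default was chosen because the method's premise is that class
information lives in functional topology. When oscillatory sources have
trial-random phases, raw time samples are individually uninformative
(their expectation is zero under phase randomization) and a small
network must first learn an envelope/coherence detector before it can
classify; the connectivity profile hands the network the sufficient
statistic directly. Both modes run through identical machinery.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| split ratios | 7:2:1 | train/validation/test partition, stratified by class |
| epochs | 300 | training epochs (GCN pretrain and F-F schedule cap) |
| batch size | 64 | minibatch size; F-F batches split 32 positive / 32 negative |
| learning rate | 0.03 | Adam step size for the F-F stack |
| GCN learning rate | 1e-3 | Adam step for pretraining; the dense stack's 0.03 is too coarse for the conv weights |
| Chebyshev order K | 3 | filter support = 3-hop neighborhoods; standard small default |
| GCN maps F1..F4 | 64, 128, 128, 512 | feature maps per conv stage |
| feature width | 512 | penultimate projection, matches the first F-F layer |
| F-F widths | 512, 256, 256, 4 | dense stack layer sizes; a 512-256-128-4 preset is one `widths=` call away |
| goodness threshold θ | 2.0 | per-layer; the logistic link is centred here |
| negative mode | both | wrong-label and mask-hybrid negatives, 50/50 |
| mask smoothing passes | 4 | neighbor-averaging passes; more passes → longer constant runs |
| saturation rule | tol 1e-4, patience 10 | stop a layer when relative loss improvement stays below tol for 10 epochs |

Units: signals are arbitrary amplitude (µV for real EEG), sampling
rates in Hz, correlations dimensionless in [0, 1].

## Synthetic data: what it emulates, what it does not

The generator emulates four-class recordings in which each class is a
distinct partition of the channels into communities. Channels in a
community share a unit-variance band-limited source (mu band, 8–12 Hz,
at 160 Hz by default); a weak global source gives a between-community
correlation floor; independent Gaussian noise dilutes both. Given noise
σ and targets (r_w, r_b), mixing gains are solved exactly from

    r_w = (a² + b²)/(a² + b² + σ²),   r_b = b²/(a² + b² + σ²),

which requires `0 ≤ r_b ≤ r_w < 1`; infeasible targets are rejected.
With σ = 0 the channels are pure community sources (within-community
|PCC| exactly 1). Per-channel gains with random magnitude *and sign*
are applied: the |PCC| graph is provably invariant to them, so they
only stress the pipeline's invariances. Class templates are balanced
partitions drawn once from a fixed generator, independent of the data
seed.

Deliberately not modeled: volume conduction and field spread, 1/f
background spectra, artifacts (blinks, EMG), nonstationarity, and
subject variability. Passing the end-to-end recovery test therefore
shows that the pipeline extracts planted connectivity structure under
controlled conditions — not that it reaches any particular accuracy on
real EEG, where the correlation structure is weaker, dynamic, and
confounded by conduction.

## Numerical choices

* **Eigendecomposition convention.** `spectrum` sorts eigenvalues
  ascending and fixes each eigenvector's sign so its largest-magnitude
  entry is positive (earliest index wins ties), making repeated calls
  and degenerate eigenvalues reproducible. Symmetry tolerance on input:
  1e-8.
* **λ_max.** Computed exactly per coarsening level (graphs here have at
  most a few hundred nodes); `lambda_max="bound2"` skips the solve
  using the normalized-Laplacian bound of 2.
* **Isolated nodes.** `D^{−1/2}` is undefined at degree 0; the
  normalized Laplacian gets the identity row/column there
  (pseudo-inverse convention).
* **Zero-variance channels.** Flat channels (std below a relative
  1e-12 tolerance) get all-zero edge weights plus a warning, so dead
  electrodes do not abort a run.
* **Coarse edge weights.** Heavy-edge matching sums merged weights; if
  a sum exceeds 1 the coarse adjacency is rescaled by its maximum —
  harmless, since each level's Laplacian is rescaled by its own λ_max.
* **Softplus.** The contrastive loss uses `log1p(exp(·))` through
  scipy's `log_expit`, safe against overflow for large goodness.
* **Zero-norm activities.** Normalization returns the zero vector (with
  a warning at the public API; silenced inside batched training where
  dead samples are expected).
* **Ties at inference.** Equal accumulated goodness predicts the lowest
  label index.
* **Determinism.** All randomness flows through `numpy.random.Generator`
  seeded from the experiment seed; two runs with one seed are
  bit-identical, including trained weights.

## Open design points, resolved

* **Adaptive rate.** The target-goodness rate is implemented as
  `α = (S* − S_L)/S_L`: zero exactly at target, positive below,
  negative above. An alternative reading, `S*/S_L − 1`, is the same
  quantity; a third, `(S* − 1)/S_L`, lacks the at-target fixed point
  and was rejected.
* **Manual-rule derivative.** With `p = σ(S − θ)`,
  `∂log p/∂S = 1 − p` for positives; for negatives the update is
  `−2εp·y_j·x`, pushing goodness down. The per-neuron activity change
  after an update is `Δw_jᵀx ∝ y_j`, preserving orientation.
* **Two trainer paths.** The default trains each layer by Adam on the
  contrastive loss; the literal per-sample manual rule is retained
  (`trainer="manual"`) and passes the same direction checks.
* **Hybrid negatives** may blend any two distinct trials; when the two
  sources share a class, the embedded label is drawn to differ from it.
* **First-layer goodness** is excluded from inference scores by
  default (configurable), for the reason given above.

## Problem sizes used in the shipped checks

The end-to-end recovery check and the acceptance script run a reduced
configuration chosen as a desk-scale version of the full recipe:
16 channels, 320 samples per trial, 500 trials per class (2,000 total,
200 in the test split), conv maps 8-16-16-32, feature width 64, F-F
stack 64-32-32-4, 30 pretraining + 10 fine-tuning + 40 F-F epochs.
Under these conditions the pipeline decodes the planted four-class
structure at ≈99% test accuracy in well under a minute, while a
label-shuffled control stays inside the 95% binomial band around the
25% chance level. Full-scale settings (64 channels, maps
64-128-128-512, width 512) run through the identical code paths.

## Known limitations

* No GPU path; all linear algebra is dense NumPy, appropriate for
  montages up to a few hundred channels.
* The combinatorial Laplacian option is exposed for the graph module
  but the GCN default is the normalized Laplacian, whose [0, 2]
  spectrum makes rescaling well-conditioned.
* Group-level pooling of multiple subjects simply concatenates their
  trials; no cross-subject alignment is attempted.
* EDF export quantizes to 16 bits over the data's symmetric range; the
  round-trip error bound is one quantization step.
* Accuracy on real recordings depends on electrode placement and
  montage consistency; a model trained on one montage must be retrained
  for another.
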