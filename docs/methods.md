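# Methods

This note records the models, conventions, numerical choices and known
limitations of the package, in the order the pipeline runs.

## Signal containers and units

Epoched data live in `EpochContainer` arrays of shape
(trials × channels × samples) with a millisecond time axis relative to a
named lock event (`cue` or `action_effect`) and a sampling rate in Hz
(256 Hz throughout the synthetic studies). Voxel maps carry millimetre
coordinates (x right+, y anterior+, z superior+) on a regular grid.

## Synthetic generators

The generators define the study conditions every downstream claim is
tested under.

**Coupled envelope systems** (`simulate_nmvar`) draw from the same model
class the estimator fits: a stationary VAR(p) with Gaussian innovations
plus planted nonlinear couplings. Stationarity is checked via the
companion-matrix spectral radius before simulation and non-stationary
specs are rejected. Burn-in is `max(10·p, 200)` samples from a zero
initial state. The nonlinear term library spans sub- and super-linear
couplings: `quadratic` (gain·x_i²), `product` (gain·x_i·x_j at equal
lag), and `threshold` (tanh(gain·x_i)); innovations are Gaussian, the
convention for MVAR residuals. Channel names default to the four-node
theta network (ATL, PTL, IC, IFC) for readability.

**Flicker epochs** (`simulate_flicker_eeg`) add a deterministic sinusoid
at the tag frequency (default 4.5 Hz, control 8 Hz, 2000 ms duration) to
a subset of responsive channels over 1/f background noise (spectral
shaping of white noise, exponent 1, DC removed). The default epoch
window −1000..2500 ms leaves the −350..−150 ms baseline clear of the
4.5 Hz wavelet's edge region. Default amplitude 0.6 (SNR per trial
well below 1) was chosen so that detection is reliable only at the
group level (n ≈ 50 virtual subjects, 20 trials each) — the synthetic
regime probes the statistics, not scalp microvolt realism. No forward
model, no blink/muscle artifacts: passing tests demonstrate the
statistical pipeline, not robustness to real-world artifacts.

**Voxel maps** (`simulate_voxel_map`) plant spherical high-power
clusters on a synthetic head: ellipsoidal brain mask, inner-sphere
"white matter", a posterior-inferior "cerebellum" block, and synthetic
atlas label ids stamped per cluster. These are synthetic stand-ins for
template-brain geometry, adequate for exercising selection, clustering
and labelling logic only.

## Frequency tagging

Morlet wavelets use 5 cycles with the Gaussian envelope truncated at 3
standard deviations (the conventional reading of a "length" parameter
alongside a cycles parameter). Wavelets are amplitude-normalized so a
unit sinusoid yields power ≈ 1 at its bin; all downstream statistics are
normalization-invariant. Samples within the half-wavelet support of an
epoch edge are flagged invalid and *excluded* from statistics rather
than zero-padded, which would bias the baseline. Relative power change
is (P − P̄_base)/P̄_base with baseline −350..−150 ms, computed after
trial averaging (the unit of observation in group tests is the subject).
The tagged-vs-control contrast is a pointwise paired t-test per
(channel, time) with Benjamini–Hochberg FDR over the full channel × time
family of one lock condition. Phase windows are half-open [0, 1000) ms:
`action_planning` locked to the cue, `perception` locked to the action
effect. ROI band-power envelopes average wavelet power across voxels
within an ROI before any standardization.

## ROI selection

Stage order is fixed and meaningful: exclusion filters (inside brain,
not white matter, not cerebellum) → top-fraction selection → DBSCAN →
atlas labelling and the anterior/posterior temporal split. The
top-fraction count is `ceil(fraction · N_valid)` (so "top 3%" selects at
least one voxel on any grid) with a deterministic tie-break (power
descending, then x, y, z ascending). DBSCAN uses eps = 2 × the voxel
edge length and `min_samples = 3` — the smallest neighbourhood count
that still rejects isolated voxels, which are labelled noise and
discarded. Atlas labelling is a deterministic recipe from label ids to
ROI names (replacing any manual segmentation step, which is not
reproducible); temporal-lobe voxels split at a reference y (default
−21 mm, the median anterior-posterior coordinate of the transverse
temporal region in template space), boundary voxels going posterior.
The module contains no randomness.

## The nMVAR estimator

The network is x̂(n) = W₂·act(W₁·x_p + b₁) + b₂ with 6 hidden units,
`act = tanh` by default. tanh is used because the Taylor separation
needs a smooth derivative; a `linear` activation is available and makes
the estimator collapse exactly onto linear VAR (used as an internal
consistency oracle). Channels are z-scored over pooled samples before
the lag design is built; lag vectors never straddle trial boundaries.
Standardization makes the ±0.5 weight-initialization range and the
Taylor expansion point (zero = the data mean) well-scaled.

Training is incremental (per-sample) gradient descent with momentum
(α = 0.9), weights initialized uniformly in ±0.5, and an adaptive
learning rate: ×1.05 after an epoch whose training MSE fell, ×0.7
otherwise, floored at 1e−6 (the mechanism is standard; the constants
are this package's choice). Early stopping monitors a validation split
with patience 15 and restores the best weights. A non-finite loss
triggers one retry from fresh initialization at half the learning rate,
then fails with diagnostics. Generalization metrics come from 5-fold
permuted cross-validation: per fold, the pooled sample order is shuffled
with a fold-specific seed and split 80/10/10 contiguously; the reported
model is always a final refit on all data with early stopping against a
held-out 10%. The fold loop is a diagnostic and can be skipped
(`compute_cv=False`) when only the connectivity matrices are needed —
surrogate refits do this. The per-sample update loop is numba-compiled;
everything else is vectorized numpy.

Order selection fits linear VARs by least squares for each candidate
order on the same effective sample (the one feasible for the largest
candidate) and minimizes SBC = ln det Σ̂ + (p·M² + M)·ln N / N.

**Taylor separation.** The linear part of the input–output map about
zero is J = W₂·diag(act′(b₁))·W₁, reshaped to a coefficient tensor
A[j, i, k] (target j, source i, lag k). lC(i→j) is the mean of |A[j,i,·]|
over lags — the mean (not the sum) keeps lC comparable across orders.
No further normalization is applied; lC values are on the z-scored data
scale and are not claimed to be numerically identical to any particular
published table.

**NC.** The restricted prediction keeps channel i's Taylor-linear
contribution and removes it from the nonlinear component only:
pred = f_Lin(x) + f_NonLin(x with channel i's lags set to 0). On
standardized data, zero equals mean-substitution, making the
"purely linear" restriction well-defined. NC(i→j) is the log ratio of
restricted to full mean squared residual for target j, computed on the
fitted data; a zero denominator (degenerate perfect fit) is rejected.
With a linear activation f_NonLin ≡ 0 identically, so NC ≡ 0 exactly.
NC can dip slightly below zero from optimization noise; the invariant
enforced in tests is NC ≥ −0.05.

## Surrogate testing

Surrogates circularly shift every channel of every trial independently
by an offset uniform on [p+1, T−p−1]. The minimum shift of p+1 prevents
near-identity surrogates, and offsets are redrawn until every *pairwise
relative* circular shift is also at least p+1 — two channels shifted by
the same amount would keep their alignment intact and contaminate the
null. Each surrogate is refit with identical hyperparameters
("identical network parameters" is read as a refit: scoring shifted
inputs through a fixed network could not generate a null for lC, which
depends only on the weights). Thresholds are one-sided per pair and per
measure at the 95th percentile, computed with the `higher`
order-statistic method: with S surrogates the threshold at q = 0.95 is
the ⌈q(S−1)⌉-th order statistic, so under exchangeability the null
rejection probability is exact at 1/(S+1) when the threshold is the
surrogate maximum (S = 20) and ≈ 0.05 at S = 100; linear interpolation
would be anti-conservative at small S. Per-pair thresholds are the
conservative reading of gating "connections exceeding the surrogate
null". Failed surrogate fits are logged, counted and excluded.

## Group statistics

`paired_test` is the classical paired t with df = n−1 and two-tailed p;
Cohen's d = |t|/√n (the convention consistent with published (t, d)
pairs at n = 50); BF10 is the default JZS Bayes factor (zero-centered
Cauchy prior on the standardized effect, scale √2/2), computed through
pingouin's numerical integration and cross-checked in the tests against
a direct quadrature of the inverse-gamma mixture integral. Evidence
labels follow the Lee & Wagenmakers bins with boundaries assigned to the
higher-evidence bin and BF10 = 1 counted as anecdotal evidence toward
H0 (bin edges use exact reciprocals 1/3, 1/10, 3/100, 1/100).

`run_contrast` runs three batteries on long-format per-subject values:
bidirectional asymmetries (A→B vs B→A within condition and phase),
stimulation contrasts (condition vs condition per directed pair within
phase), and net bilateral differences ((A→B − B→A) between conditions).
The FDR family is exactly the rows of one battery — per (kind, measure,
phase, and condition for asymmetries): 6 unordered pairs for
asymmetry/net, 12 ordered pairs for stimulation with four regions.
Subjects missing either side of a pairing are dropped with a log entry.
Surrogate gating enters as an optional allowed-pair set.

## Pipeline and reproducibility

All randomness fans out from one master seed through
`derive_seed(master, *tags)` (SHA-256, reduced below 2³¹), so stages can
be rerun independently yet reproducibly; rerunning with the same config
and seed is bit-identical, and deleting an intermediate regenerates it
identically. Every result table carries the config hash. Configs are
YAML over fully-resolved defaults with unknown-key rejection. The demo
pipeline's connectivity stage consumes simulated envelope systems
directly — the coupled-system generator produces exactly the
ROI-envelope-level signal the estimator expects; voxel-level envelope
extraction (`roi_band_envelope`) is exercised separately. In the demo's
group gating, a directed pair enters a battery if it exceeded its
surrogate null in at least a configurable fraction of subjects (default
0.5).

## Validation experiments and problem sizes

`ncreann.experiments` (driven by `scripts/acceptance.py` and the
acceptance tests) uses scaled-down study conditions chosen for adequate
statistical power at desk scale:

* linear limit: one VAR(2), M = 4, T = 2000; the linear-activation fit
  uses a longer schedule with stronger learning-rate decay (×0.5) since
  the target here is the precise least-squares optimum;
* support recovery: 20 systems, M = 4, p = 2, four planted couplings
  with |a| ≥ 0.3, T = 2000, AUC of lC ranking;
* nonlinear specificity: 20 systems, M = 2, quadratic gain 0.5,
  T = 512, 20 surrogates each;
* type-I calibration: 50 independent-channel datasets, M = 3, T = 360,
  20 surrogates, rejections pooled over pairs and both measures;
* fit quality: 20 subjects with self-coupling drawn from 0.96–0.99
  (predictability, hence R², varies across subjects; R² is invariant to
  the innovation scale, so heterogeneity must come from the dynamics),
  T = 1500, full 5-fold CV;
* tagging: 50 virtual subjects × 20 trials, coverage scored on the
  flicker interval interior (600–1400 ms, clear of wavelet smearing);
* global null: 200 replicates of the 12-pair stimulation battery at
  n = 50.

## Known limitations

* The estimator's absolute lC/NC scales depend on the z-scored data and
  the lag-mean aggregation; only within-study comparisons (asymmetries,
  condition contrasts) are meaningful.
* Surrogate refits inherit the estimator's optimization noise; at
  S = 20 the threshold is the surrogate maximum and per-pair decisions
  have the granularity of 1/(S+1).
* Synthetic 1/f backgrounds contain no line noise, no artifacts and no
  channel covariance; voxel maps use synthetic geometry and labels.
  Passing tests show the statistics behave as designed, not that
  preprocessing-stage problems of real recordings are handled.
* The demo pipeline does not implement beamforming; it consumes
  precomputed (here: simulated) source-level signals by design.
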