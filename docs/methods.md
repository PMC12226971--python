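# Methods

This note documents the models and procedures implemented in `statefinder`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic benchmarks do and do not demonstrate.

## Problem setting

Structure-prediction networks run with subsampled alignments emit ensembles
of plausible protein conformations, but no kinetics and no notion of which
conformations are metastable. The workflow implemented here turns such an
ensemble, plus short simulation time series started from a few representative
structures, into (i) a small set of informative collective variables (CVs),
(ii) a set of metastable-state labels, and (iii) a 2D latent space in which
any structure — simulated or predicted — can be placed.

The stages, in pipeline order:

1. **RMSD filter.** The ensemble is superposed onto a reference — by default
   the structure with the highest mean pLDDT (read from the PDB B-factor
   column, the AlphaFold2 convention), ties broken toward the earlier file —
   and structures beyond a user-chosen RMSD cutoff are discarded as unfolded
   or unphysical. Superposition is the Kabsch least-squares rigid fit with
   reflections excluded; the fit and the RMSD use the same atom selection
   unless a separate one is given. The cutoff has no default: it is a
   system-specific judgement and must be stated in the configuration.
2. **Feature enumeration and CoV ranking.** All pairwise atom distances
   within a user selection, excluding pairs fewer than
   `min_residue_separation` (default 3) residues apart on the same chain
   (those are trivially rigid); pairs across chains are always kept. Features
   are ranked by the coefficient of variance across the ensemble, defined
   deliberately as **variance/mean** (units: Å, not dimensionless); the
   conventional std/mean is also reported and can be used instead via a
   flag. Variance is the population variance (divide by N): the ensemble is
   treated as the complete population of generated hypotheses, and the
   choice rescales every feature identically so ranks are unaffected. The
   top `min(ceil(0.05 n), 200)` features are kept by default.
3. **Regular-space clustering.** One pass over the structures in input
   order: a structure becomes a new center iff its Euclidean distance (in
   the selected feature subspace, unscaled) to every existing center is
   strictly greater than `d_min`. This guarantees centers are mutually
   separated by more than `d_min` and every structure is covered within
   `d_min`. When `d_min` is not given it is found by bisection (30
   iterations) so the center count lands in a target range, 5–20 by
   default — the practical number of short simulations to launch. No
   feature standardization is applied; dimensionality is controlled by
   capping the feature count instead.
4. **Short dynamics (external boundary).** The pipeline writes the center
   structures and a CV watch-list, then ingests time series. Real use feeds
   MD output; tests and demos use the built-in emulation: independent
   Ornstein–Uhlenbeck diffusion of the feature vector in a harmonic basin
   around each center (exact OU updates, so any step size is stable).
5. **Mutual-information pruning (AMINO-style).** See below.
6. **SPIB.** See below.

## Mutual-information CV pruning

Variance-ranked distance CVs are heavily redundant. Redundancy is removed by
clustering CVs under the normalized information dissimilarity

    D(X, Y) = 1 − I(X; Y) / H(X, Y) ∈ [0, 1],

estimated by the plug-in (histogram) method on equal-width bins of the
pooled frames — redundancy is a static property, so trajectory boundaries
are irrelevant here. Two degenerate constant signals have H = 0 and are
defined to be identical (D = 0, with a warning).

k-medoid clustering (seeded k-medoids++ initialization, PAM swap local
search, deterministic given the seed) is run for each k up to `k_max`, and k
is chosen by the distortion-jump criterion: with distortion d_k = mean
squared D to the nearest medoid, pick `argmax_k d_k^(−1) − d_{k−1}^(−1)`
(with d_0^(−1) := 0, and the transform power p = 1 because the distortion is
a one-dimensional quantity). A k whose medoids reproduce every CV exactly
(d_k = 0) terminates the scan with an infinite jump, which gives the right
answers in the two boundary cases: exact duplicates collapse immediately,
and a set of mutually independent CVs scanned up to k_max = n keeps all n.

Two numerical choices matter and are config-exposed:

* **Bin count, default 20.** The plug-in estimator's bias grows with the
  number of joint cells relative to the frame count. At 50×50 cells and the
  10³–10⁵ frames typical of these analyses, the bias is large enough that
  even strongly correlated CV copies sit at D ≈ 0.8 and the distortion
  curve loses its elbow; at 20 bins the same copies sit well below the
  independent background and group recovery is reliable. Users with much
  longer series can raise the resolution.
* **`k_max` must be meaningfully smaller than the number of CVs** whenever
  the CVs are noisy near-duplicates: at k = n the distortion is identically
  zero and any inverse-transform jump criterion degenerates to selecting n.
  In practice the method is used to reduce hundreds of CVs to fewer than
  20, so k_max ≪ n holds automatically; the toy benchmarks respect it
  explicitly (k_max = 8 for 15 CVs).

The redundancy benchmark (`toy_dynamics.redundant_cv_series`) uses three
independent AR(1) signals observed as five copies each with 10% relative
independent Gaussian noise. The noise level encodes the phenomenon being
emulated: the distances (m, n) and (m±1, n±1) track the same underlying
motion and are correlated well above 0.9, not loosely related signals.

## State Predictive Information Bottleneck

SPIB learns a stochastic encoder q(z|x) from the CV vector at time t to a
low-dimensional latent z (default 2D, for direct visualization), and a
decoder p(y|z) over discrete state labels, by minimizing

    E[ −log p(y_{t+Δt} | z_t) ] + β · KL( q(z|x_t) ‖ p(z) ),

i.e. the latent space keeps only information predictive of the state label a
lag Δt ahead. Prediction pairs are formed strictly within each trajectory.
The prior p(z) is a learnable mixture of Gaussians with one component per
state; the KL term is estimated from the sampled z (single-sample
reparameterization).

Labels are self-consistent rather than fixed: training starts from seeded
k-means labels (default 10 clusters, deliberately overshooting so refinement
prunes downward), and periodically every frame is relabeled to the argmax
decoded state of its own encoded mean. States that lose all frames die.
Training converges when fewer than 1% of frames change label for 10
consecutive refinements. The lag is the physically meaningful control: at
Δt longer than the interconversion time of two states, the future label
becomes uninformative about which of the two the system is in, and
refinement merges them — so the state count is expected to fall as the lag
grows, while the latent geometry of the surviving states is preserved.

Implementation: a small multilayer perceptron in NumPy (two tanh hidden
layers of 64 units, linear Gaussian latent head, linear-softmax decoder)
with analytically derived gradients, verified against finite differences in
the test suite, and an Adam optimizer (learning rate 2·10⁻³, batch 1024).
Inputs are standardized per CV with training statistics that are stored and
reused at projection time. All randomness flows from one seed; training is
bit-reproducible on a fixed platform. β defaults to 0.01 — large enough to
regularize the latent scale, small enough that label prediction dominates.

One scheduling choice proved important: **relabeling every epoch merges
genuinely distinct states**, because early in training the decoder is still
underfit and its argmax regions are too coarse; refinement every 3 epochs
(the default) lets the decoder catch up between relabelings. This was
observed directly on the 2D triple-well benchmark, where per-epoch
refinement fused the two fast wells even at small lag.

Model selection knobs that remain open by design: β, the architecture, and
the initial state count are exposed in `SpibConfig` with the defaults above;
latent_dim is fixed at 2 by default because the 2D map is itself an output,
but can be raised.

## Synthetic benchmarks

`toy_dynamics` provides the ground-truthed fixtures all tests run against:

* **Overdamped Langevin sampling** (Euler–Maruyama, kT and friction absorbed
  into the units) of analytic potentials. The harmonic well has a closed-form
  stationary distribution (variance kT/κ, with the scheme's known O(dt)
  correction kT/(κ(1−κ·dt/2))) used for calibration tests.
* **Double well** V = B(x²−1)², barrier B = 8 kT: a two-state system whose
  well labels (nearest minimum) are the ground truth for SPIB recovery.
  At dt = 0.002 and 10⁶ steps (10⁵ frames at stride 10) it shows a handful
  of transitions, as Kramers' rate predicts.
* **Triple well in 2D**, built as the negative log of a three-component
  Gaussian mixture, so the stationary density is exactly that mixture and
  barriers follow from the well separations (≈ d²/(8σ²) − ln 2 for an
  equal-weight pair). The default geometry places wells A and B ≈ 3 kT
  apart (measured interconversion ≈ 77 frames at the benchmark sampling)
  and well C behind a ≈ 7 kT barrier (≈ 1900 frames), giving a constructed
  timescale separation: lags of 2 / 200 / 1000 frames yield 3 / 2 / 1
  states.
* **Bead-chain ensembles**: a Cα-only chain (3.8 Å spacing) bent at its
  midpoint by a per-state hinge angle, with isotropic Gaussian coordinate
  noise and per-state pLDDT written to the B-factor column. Two states at
  30° hinge and 0.3 Å noise are cleanly separable, with truth tables
  returned alongside the files.

What these fixtures do **not** show: real CV sets are not Gaussian wells;
real ensembles have correlated, anisotropic noise, heterogeneous pLDDT
within a state, and slow degrees of freedom invisible to any distance
selection; and the emulated "MD" around cluster centers cannot discover
basins the structure generator never produced. Passing these benchmarks
demonstrates the machinery is correct and self-consistent, not that any
particular protein's state decomposition is right.

## Problem sizes used in the shipped checks

The automated checks run at deliberately modest scale so the whole suite
completes on a single CPU: 10⁵-frame double-well and 5·10⁴-frame triple-well
trajectories, 5 seeds per configuration, 200 random clustering instances,
and a 100-structure two-state ensemble for the end-to-end run. All sizes are
parameters of the generators and can be raised freely.

## Known limitations

* The plug-in MI estimator is biased upward for undersampled histograms; the
  bin-count default trades resolution for robustness rather than applying a
  bias correction.
* The jump criterion cannot distinguish "no redundancy" from "all noise" at
  k = n (see above); `k_max` should stay well below the CV count.
* SPIB's state count at a given lag is a property of the model class and
  optimization, not a guaranteed physical invariant; scanning several lags
  (`state_count_scan`) is the supported way to read granularity.
* The regular-space pass is order-dependent by construction; input order is
  part of the specification of a run (and is deterministic given the file
  list).
* Insertion codes in PDB files are rejected rather than handled.
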