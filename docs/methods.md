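# Methods

## The task and what the simulator emulates

The package models a two-stage gambling task. In stage 1 a chooser picks
between two *environments*, each a bundle of 20 items displayed as 20
reward-probability bars plus one number, the bundle's mean reward magnitude
(currency units in [-10, 10]). The chosen environment then supplies the
items for 0-3 stage-2 trials, ordinary binary choices between two concrete
probabilistic rewards drawn from that bundle. Each block carries a bonus in
[-4, 6] that is either *linked* (paid only when the chosen item's gamble
wins — so a large bonus should make probability matter more) or *unlinked*
(paid unconditionally — a control that should leave choices untouched).
Blocks are gain-gain, loss-loss, or mixed-valence in a 53.5/31.5/15 split;
the loss trials exist to decorrelate option value from option salience.

`envchoice.task.generate_task` reproduces these design constants exactly:
valence pairs, bonus conditions, and the stage-2 trial total are assigned by
largest-remainder allocation rather than independent draws, so the printed
proportions hold in counts for every seed. The defaults are 200 stage-1
trials (400 distinct environments) and 200 stage-2 trials.

Where the source design constants end, the generator's choices begin:

* **Item probabilities.** Per environment, Beta-distributed with mean
  mu ~ U(0.2, 0.8) and concentration kappa ~ U(2, 10). This gives
  environments that genuinely differ in mean, variance, and skewness —
  necessary for moment-preference regressions and the CNN's feature
  detectors to have anything to find. Recovery experiments that need a wider
  variance spread lower the concentration range to (1, 6); this is recorded
  with each experiment's config.
* **Item magnitudes.** Drawn as antithetic pairs m ± delta with
  delta ~ U(0, d), d capped by the distance from the displayed mean m to the
  [-10, 10] boundary (and by a default spread of 2.5). The pairing makes the
  displayed mean exact and keeps every item in range by construction.
* **Stage-2 structure.** Per-block item-trial counts start uniform on
  {0, 1, 2, 3} and are repaired by seeded increments/decrements until the
  configured total is met; item pairs are drawn without replacement within a
  block. Which items a stage-2 trial offers depends on the environment the
  *agent actually chose*, so the cross-stage linkage is honored.
* **Timing.** Each block occupies stage-1 duration (5 s) + 4 s per item
  trial + 2 s ITI; onsets feed the BOLD-style simulator.

What the simulator does **not** emulate: learning or session effects,
response times, left/right biases, visual confounds, and any spatial
structure of real imaging data (patterns are ROI-level unit matrices, not
volumes). Passing tests therefore validate the estimators' statistical
machinery, not their robustness to those real-data complications.

## Choice models

All models map a trial to two decision values (DVs) whose softmax gives the
choice probability; the GLM-DV baseline scores a single rightward DV
through the logistic link, which is the same contract with one DV pinned
to zero.

**CNN (stage 1).** Input is the 20 x 2 item-probability matrix (items x
environments, column order left/right). Four 2 x 1 feature detectors slide
along the items (valid cross-correlation, stride 1), giving four 19 x 2
feature maps. The concatenated feature vector is, in this fixed order:
flattened feature maps; the two mean magnitudes; the feature maps with each
environment's magnitude scaling its own column; bonus; condition. A fully
connected ReLU layer (default 512 nodes; smaller widths are used in the
shipped experiments, see below) and a final linear layer produce the two
DVs. Every input channel (probabilities pooled, magnitudes, bonus) is
z-scored with constants estimated on the training folds and stored on the
fitted model.

**Simplified CNNs** replace the 20-item input with explicit per-environment
moment summaries (mean, mean+var, mean+skew, var+skew, mean+var+skew) and
skip the convolution; everything downstream is identical. **The stage-2
ANN** feeds the two items' probabilities, magnitudes, and their products
plus bonus/condition straight into the hidden layer. **The autoencoder**
uses a sigmoid hidden layer on the hand-listed value features (Mag, Prob,
Bon, Cond, Mag x Prob, Prob x Bon x Cond per option).

Networks are plain numpy with hand-written gradients: full-batch softmax
cross-entropy, Adam (plain gradient descent available for convexity
checks), L2 weight decay 1e-2 on the weight matrices, early stopping on a
training-loss plateau (tol 1e-6/trial, patience 30). Defaults live in each
constructor and everything is overridable per fit.

**Parametric models.** MVS: subjective probability = mean + rho*variance +
sigma*skewness of the item probabilities (population moments). Power law:
mean of p^g. CPT: value function Mag^alpha for gains, -lambda*(-Mag)^beta
for losses; probability weighting w(p) = p^gamma / (p^gamma +
(1-p)^gamma)^(1/gamma) with gamma for gains and delta for losses, averaged
over the 20 items. All three share the six-term DV combination b1*Mag +
b2*Phat + b3*Bon + b4*Cond + b5*(Mag*Phat) + b6*(Phat*Bon*Cond); the b5
interaction uses the subjective (transformed) quantities. Because Bon and
Cond are identical for both options, their main-effect terms cancel in the
softmax; they are carried in the parameter set for completeness but held
fixed during fitting (they are not identifiable from choices). Fitting is
bounded maximum likelihood (L-BFGS-B) with multi-start (default 10
restarts; the first start is the identity/neutral point, which is also the
reduction point where CPT = power = MVS = EV). Bounds: alpha, beta, gamma,
delta in [0.2, 1.5] (keeps the weighting function numerically monotone),
lambda in [0, 5], g in [0.05, 5], linear weights in [-20, 20].

**Cross-validation.** Choices are pooled across subjects and split into 20
random, seeded folds; held-out NLL is recorded per fold both as a sum and
as a per-trial mean. Model comparison uses independent-samples t-tests on
the per-trial fold NLLs (df = 38 for two 20-fold models) plus a mean ± SEM
table. Prediction accuracy counts held-out trials with P(made choice) >
0.5; exact ties count as incorrect.

## Feature analysis

A detector's *partial DV* is the trained network's forward pass with every
other detector's feature maps (raw and magnitude-scaled) zeroed after the
convolution; weights are never retrained, and the fc biases are retained,
so a detector-free pass defines the bias-only baseline. Partial-DV
differences (right - left) are correlated (Pearson) with the trials'
differences in environment mean, variance, and skewness; dependent
correlations sharing a variable are compared with Steiger's (1980) z on
Fisher-transformed coefficients.

## RSA

RDM = 1 - Pearson correlation between every pair of trials' activation
patterns (zero diagonal enforced; zero-variance rows are an error naming
the offending trials). RDM similarity is the Spearman correlation of strict
upper triangles, computed on the trial intersection when one source lacks
trials. Group inference: Wilcoxon signed-rank of per-subject rhos against
zero, plus a permutation test that jointly permutes rows and columns of the
model RDM with one trial permutation per subject per iteration, averaging
rhos across subjects; p = (1 + #{null >= observed}) / (1 + n_perm), so the
identity ordering bounds p away from zero. Default n_perm = 1000. Layer-wise
RSA concatenates the requested layers' activations (z-scored per node
across trials by default, to stop wide layers from dominating) in the fixed
order input, hidden, final_fc.

## Synthetic neural data

*Patterns*: the source activations (e.g. a model layer) are row-centered
and mixed into `n_units` units through a per-subject random matrix with
orthonormal, zero-mean columns, then Gaussian noise of the requested SD is
added. The orthonormal mixing preserves the source's correlation RDM
exactly at zero noise, which makes planted-structure tests sharp; it is a
deliberate idealization of voxel sampling. *Time series*: stick functions
of per-trial regressor values convolved with a canonical double-gamma HRF
(peak 6 s, undershoot 16 s, undershoot ratio 1/6, unit peak height) at
TR = 1.6 s, scaled by planted amplitudes, plus AR(1) noise (default
coefficient 0.3).

## Time-course statistics

GLM designs: (3) the chosen-minus-unchosen DV difference per stage; (4) the
DV split into a bonus-free basic term plus linked-/unlinked-bonus terms —
the bonus contribution is computed with the condition forced to linked and
booked to the regressor matching the trial's actual condition, so the
unlinked term carries the bonus "as if linked"; (5) adds the first-item-
trial indicator (+1/-1) and its interaction with the linked-bonus term;
(6) DV difference plus salience (sum of absolute option EVs) and EV sum,
both computed from EV rather than the network DV because the normalized
network DV loses the options' signs. Parametric regressors are
mean-centered before convolution.

Beta time courses: the ROI series is cubic-spline upsampled 10x, epoched
-2 s to +14 s around onset (covers response peaks in the 3-8 s range), and
OLS is fit across trials at every upsampled timepoint. Peaks are extracted
leave-one-subject-out: the full group curve defines the extremum (largest
|beta|) and its FWHM window; each subject's beta is read at the extremum of
the group curve recomputed without that subject, restricted to the window.
The alternative reading — each subject's own extremum inside the window —
is exposed via `rule="own_argmax"`. Peak statistics are a two-tailed
one-sample t plus a JZS Bayes factor (Cauchy prior scale sqrt(2)/2, via
pingouin's numerical integration). The PPI design is the five-column set
[stage dummy, two mean-centered physiological series, their stage
interactions], with a collinearity warning when the psychological variable
is constant. High-pass filtering and AR prewhitening are deliberately
omitted: the synthetic data are generated from the fitted model class, so
the OLS estimates are unbiased there; on real data this module would
understate autocorrelation-induced variance.

## Problem sizes in the shipped experiments

The validation suite and `scripts/acceptance.py` use sizes chosen so each
experiment is informative on a single CPU: parameter recovery uses 5000
pooled stage-1 choices (8 simulated subjects on one 625-block design) and
10 generation seeds, asserting mean recovery within ±25%; behavioral
coefficient recovery uses 24 agents x 200 trials against a ±2 SEM band;
model selection uses 8 subjects x 200 trials, a 24-node fitted CNN, and 20
folds over 10 seeds; RSA calibration uses 500 null group analyses of 6
subjects x 20 trials at 200 permutations; time-course recovery uses 8
subjects at SNR 5. The generating agent for the model-selection experiment
is a hand-constructed CNN whose readout sums rectified adjacent-item
probability differences — a total-variation dispersion preference that no
linear-in-EV model can express — plus a linear EV channel, keeping its
choices stochastic but structured.

## Known limitations

* Exact coefficient magnitudes from regressions on real participants are
  not reproducible from synthetic agents; the package validates recovery
  and calibration, not point values.
* The `simulate_bold` noise model is AR(1) Gaussian; physiological and
  scanner drift structure is absent.
* Network fits at the 512-node default on thousands of trials are
  CPU-minutes per 20-fold run; the shipped experiments use narrower hidden
  layers, which the weight-decay regularization makes near-equivalent in
  held-out NLL at these sample sizes.
* The behavioral GLMs fit each subject independently and then t-test the
  coefficients; no hierarchical shrinkage is provided.
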