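# Methods

## Problem

Small ophthalmic imaging studies often produce wide feature tables — here,
20 wide-field OCT-angiography (OCTA) metrics per eye plus logMAR
best-corrected visual acuity and intraocular pressure — with far fewer
independent sampling units than features would suggest: both eyes of a
participant are correlated, and cohorts number in the tens of
participants. The task is three-fold: pick a small discriminative feature
subset, tune a classifier on it, and estimate generalisation without
letting fellow-eye correlation leak across the train/test boundary. The
package implements a wrapper that does the first two jointly with a
metaheuristic, evaluates with participant-grouped cross-validation, and
explains the resulting model with exact Shapley values.

## The optimizer

The Equilibrium Optimizer (EO) is a population metaheuristic derived from
a control-volume mass balance. A population of `I` candidate vectors
("concentrations" `C`) is updated toward an *equilibrium pool*: the four
best population members plus their component-wise mean, one of the five
drawn uniformly per particle per iteration. The move is

    C' = Ceq + (C − Ceq)·F + G/(γV)·(1 − F)

with, per particle and iteration (all random draws uniform on [0, 1]):

* `t = (1 − Ite/Itemax)^(a2·Ite/Itemax)` — a nonlinear clock decaying from
  1 to 0;
* `F = a1·sign(r − 0.5)·(e^(−γt) − 1)` element-wise, so |F| < a1 and F → 0
  as t → 0 (late iterations collapse onto the pool);
* `G = 0.5·γ1·(Ceq − γ·C)·F` with probability `1 − GP`, else 0 — a local
  perturbation sharing the flow-rate vector γ with the update's
  denominator.

After each move a particle's fitness is compared with its previous value
and the worse state is discarded (memory saving), which makes the
best-so-far trace non-increasing. Positions are clipped to the box after
every move; components with γ = 0 drop the generation term rather than
divide by zero. Defaults: `V = 1`, `a1 = 2`, `a2 = 1`, `GP = 0.5`,
`Itemax = 100`; the iteration counter runs 1..Itemax so t < 1 after the
start. The population size is not fixed by the method's description;
30 is the default, and the wrapper experiments below use 20.

The pool is recomputed from the current (memory-saved) population each
iteration with a stable index tie-break, which — because every particle
retains its personal best — equals a best-so-far pool. The mean candidate
is an attractor only and is never evaluated.

## Encoding and fitness

A particle has `J = 2 + M` dimensions for `M` candidate features:
dimension 1 is the SVM penalty weight α, dimension 2 the RBF bandwidth β,
both bounded to [0.001, 1000] and evolved on that linear scale; the
remaining dimensions live on [0, 1] and are thresholded at 0.5 into a
feature mask. The implemented convention *discards* a feature when its
dimension exceeds 0.5 and selects at ≤ 0.5 — the reverse of the common
mapping — because that is the stated rule of the method reproduced here; a
`mask_convention="select_above"` switch restores the usual direction. Since
initial positions are uniform, the two conventions are statistically
equivalent at initialisation.

Fitness of a decoded particle is

    fitness = φ · mean_CV_error + (1 − φ) · Num / M,     φ = 0.98,

where the error is the mean test-fold misclassification rate over a
participant-grouped 5-fold split and `Num` the mask's size. The fold
assignment is drawn once per run and reused for every evaluation so the
fitness landscape is stationary during the search. An empty mask scores
fitness 1 without fitting, keeping the objective total; a fold whose
training split lacks a class contributes error 1 with a warning.

## Classifier

Each unordered class pair gets its own soft-margin SVM with the Gaussian
kernel `K(x, y) = exp(−‖x − y‖² / (2β²))` — β is a length-scale on the
standardized-feature axis, so the [0.001, 1000] box spans effectively
linear (large β) to highly local (small β) decision surfaces. Multi-class
predictions use one-vs-one majority voting; ties go to the larger summed
signed decision margin, then to label order. The per-class *vote fraction*
(votes / number of pairs) is the model's continuous score: deterministic,
in [0, 1], summing to 1 per sample. It feeds one-vs-rest ROC/AUC and the
Shapley attributions. The pairwise quadratic programs are solved by
libsvm's SMO (via scikit-learn) at its default tolerance 1e−3; the
contract is the optimum of the soft-margin dual, not a particular solver.
Probability calibration is deliberately out of scope — the vote fraction
is coarse (K(K−1)/2 + 1 levels) but needs no held-out calibration data.

## Cross-validation and metrics

Within each class, participants are shuffled with the run's seeded
generator and dealt round-robin over k = 5 folds, so per-class participant
counts per fold differ by at most one and both eyes of a participant share
a fold. Metrics per fold: the K×K confusion matrix, one-vs-rest
sensitivity and specificity per class (0/0 reported as missing, never 0),
overall accuracy, and per-class AUC on the vote-fraction score; the report
aggregates mean ± sample SD across folds.

Standardization policy: `train_only` (default) fits the z-score on the
training folds and applies it to the test fold; `global` z-scores the
whole table once, which mirrors a common simpler practice but lets test
statistics into the scaler. Both are available so the difference is
measurable; all shipped experiments use `train_only`.

`repeat_best` reruns the whole wrapper n times (seeds base+i) and keeps
the lowest-fitness run (ties: higher mean CV accuracy, then lower index),
retaining all runs for across-run mean ± SD summaries.

## Shapley explanation

Attributions use the coalition value
`v(S) = mean over background rows of f(x_S, b_{∖S})` — the marginal
(interventional) expectation with coalition features pinned to the
explained instance — with the full standardized training table as
background and the per-class vote fraction as the explained output `f`.
For the 4–6 feature subsets the wrapper typically selects, all `2^M`
coalitions are enumerated, so efficiency (base + Σφ = f(x)), dummy and
symmetry hold to numerical precision; enumeration is refused above 15
features in favour of a permutation-sampling estimator that reports
standard errors and is unbiased for the exact value. Global importance is
the mean |φ| per feature per class; the local ("force") view orders signed
contributions by magnitude around the base value.

## Synthetic cohorts

The generator emulates the *structure* of the motivating study, not real
OCTA physics: three groups — 30 healthy-control eyes from 15 participants,
20 acute-phase eyes from 13, 30 convalescent-phase eyes from 17 — and the
22-feature roster above. Each participant draws a latent normal vector;
each eye's value is

    noise_sd · (shift_group + √ρ·latent + √(1−ρ)·eye_noise),

so the marginal SD is `noise_sd` (default 1), fellow eyes correlate at ρ
(default 0.5), and `shift` is the per-feature, per-group effect in SD
units. Which participants contribute one vs two eyes is randomised within
each group's eye budget. Four analysis views mirror the study design:
imaging-only vs all features, crossed with merged (control vs disease) vs
three-phase labels.

Default effects plant exactly three informative features at 2-SD
magnitude: `whole_FOV_CC_VPD` depressed in both disease phases (a
persistent choriocapillaris perfusion deficit), and two phase-specific
markers moving in opposite directions between phases —
`macular_DVP_VLD` elevated in acute disease (inflammatory engorgement)
and depressed in convalescence (attenuation), `AFAZ` the reverse. The
opposite-sign pattern was fixed at design time by a power calculation:
with only three 2-SD features, same-sign phase effects leave the
acute/convalescent Bayes error too high for any classifier to reach the
recovery experiment's 0.90 accuracy level, so same-sign templates cannot
represent the separable three-class regime the experiments probe. All
informative features are imaging metrics so the planted signal survives in
every dataset view. Gaussian noise and equicorrelation are deliberate
simplifications: passing tests demonstrate correct machinery and
recoverability under a known signal, not performance on real OCTA
distributions (heavier tails, inter-feature correlation, site effects).

## Experiment sizes and numerical choices

Shipped experiments (tests and `scripts/acceptance.py`) use a 20-particle
population for 50 iterations (≈1,000 fitness evaluations, each a 5-fold
CV of an 80-eye table) and 10 repeat runs — sizes chosen so a full
recovery experiment completes in minutes on one CPU while leaving the
optimizer enough budget to recover the planted subset in essentially
every run. The optimizer benchmark (10-D sphere, 30 particles, 100
iterations) reaches 1e−12-scale optima.

Ties in the equilibrium pool break by particle index; prediction ties by
summed margin then label order; fold dealing is round-robin after a
seeded shuffle — every stochastic step flows from one `numpy` Generator
per run, so a stored seed reproduces a run bit-for-bit.

## Known limitations

* **In-search CV optimism.** The reported best-run CV accuracy is computed
  on the same folds the optimizer searched. With ~1,000 masks explored
  over 80 samples this estimate is substantially optimistic — on
  zero-effect cohorts the wrapper reports ≈0.5–0.7 accuracy where chance
  is 1/3, and re-folding the same table does not remove the bias because
  the selected features themselves encode sample-specific noise
  correlations. Only evaluation on independent data (or nested CV, not
  implemented) is unbiased; `scripts/acceptance.py` therefore reports the
  external re-evaluation on a fresh null cohort alongside the in-search
  number. Reported accuracies on real single-cohort data should be read
  with the same caution.
* The vote-fraction score is piecewise constant, making ROC curves coarse
  for small K.
* Hyperparameters evolve on a linear [0.001, 1000] scale, so the search
  spends most of its volume at large α, β; the bounds are part of the
  method's stated encoding and are kept.
* `scripts/acceptance.py` and the test suite exercise synthetic cohorts
  only; no claim is made about clinical performance.
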