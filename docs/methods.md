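# Methods

## Model

The classifier is a standard extreme learning machine (ELM): a single
hidden layer of L nodes with input weights `W` drawn i.i.d. uniform on
[−1, 1], biases `b` uniform on [0, 1], both fixed after drawing, and output
weights fitted in closed form as the minimum-Frobenius-norm least-squares
solution `β̂ = H†T` of `Hβ = T`, where `H = g(XWᵀ + b)` is the N×L
hidden-layer output and `T` the N×m one-hot targets.  The pseudo-inverse is
computed by SVD with singular values below `max(N, L)·ε·σmax` discarded
(`numpy.linalg.lstsq`, `rcond=None`); no ridge term is used.  The
activation `g` is the logistic sigmoid by default (`tanh` and `relu` are
available).  Class decisions are the per-row argmax of the score matrix,
ties going to the lowest class index; accuracy is the fraction of rows
whose argmax matches the one-hot position — equivalently the quantize-then-
compare reading of the squared-error accuracy functional, the only reading
under which accuracies are fractions of correctly classified subjects.

Models are immutable after fitting.  All pruning state lives in a pair of
binary masks (feature mask, hidden mask), so any mask is reproducibly
evaluable against any dataset, and a masked model is exactly equivalent to
the structurally reduced network with the corresponding columns and nodes
deleted (asserted to 1e-10 in tests).

## Ensemble convergence and selection

Single ELMs fluctuate with their random hidden layer, so classifiers are
trained repeatedly, re-dividing the train/validation subjects before every
training.  For a window length *Loop*, convergence requires every window of
*Loop* consecutive validation accuracies among the first 2·*Loop* recorded
to have a mean within *p* of the first window's mean.  *Loop* is grown
incrementally (2, 3, …) and the smallest satisfying value is returned —
re-verifiable post hoc from the persisted accuracy trace.  The validation
accuracy stream feeds the rule because validation accuracy is also the
selection criterion (highest wins, earliest on ties).  A hard cap
(default 500 classifiers) turns pathological non-convergence into an
explicit error.

The tolerance defaults to `p = 0.0015`, appropriate at the scale the method
was developed at (90-subject validation parts, near-constant validation
accuracy).  `p` should be read relative to the validation-accuracy quantum
1/N_val: requiring mean stability far below the quantum forces averaging
over O((sd/p)²) classifiers.  The desk-scale demonstrations in this
repository (54-subject validation parts, per-classifier sd ≈ 0.06) use
`p = 0.01` — about half a quantum — which converges within ~100 classifiers
while still enforcing genuine stabilization.

## Pruning

Greedy backward elimination under an accuracy-preservation rule, evaluated
on the pooled train+validation subjects (one number; the held-out test set
never participates).  Active nodes are visited in ascending index order;
each is tentatively zeroed and the removal is kept iff the correct-count
does not decrease, the incumbent updating after every kept removal
(strictly greedy, which guarantees a monotone accuracy trajectory).
Comparisons use integer correct-counts, never floats — accuracies are
multiples of 1/N, so the decision is exact.  Feature sweeps repeat until a
sweep removes nothing; hidden sweeps need a single pass per round because
the output is linear in the hidden contributions; any hidden removal
re-opens feature pruning; the procedure terminates because node counts
strictly decrease.  At the fixed point no single active node is removable
without a strict accuracy drop (exhaustively audited in tests).  β̂ is
never re-solved.

Tentative evaluations use rank-1 updates of cached pre-activations
(feature removals) and cached scores (hidden removals); caches are rebuilt
from scratch at the start of every sweep and agree with full recomputation
to 1e-10.

## Screening and weight accumulation

A test split is frozen first and never touches screening.  Each round:
re-split train/validation inside the remaining pool, build a converged
ensemble, select the best classifier, prune it, and add its surviving
feature mask to the integer weight vector `W*`.  A feature's weight is the
number of pruned classifiers that retained it; the weight vector conserves
mask mass (Σ weights = Σ mask sizes) and its support grows monotonically.
After each round a fresh ELM restricted to the support of `W*` is trained
on a new train/validation split (single seeded model by default; a flag
enables a full converged ensemble at higher cost) and screening stops once
its validation accuracy has not improved for `patience` consecutive rounds
(default 1).  The full accuracy trajectory is recorded so alternative
stopping rules can be applied post hoc.  Region-level importance is the
sum of the weights of a region's incident edges, keyed by numeric region
index.

## Feature-group validation and contributions

For thresholds w = 0..s the group F_w (weight ≥ w) is evaluated with
repeats × folds (default 10×10 = 100) independent stratified resamples at
160:20:20 train/validation/test proportions, one seeded ELM per resample;
means and the test-accuracy sample standard deviation are reported, and
the per-evaluation accuracies are persisted so the aggregation is
re-derivable.  A strict stratified-k-fold mode is available behind a flag.
Empty groups yield missing-value rows, never zeros.  Contribution of the
weight-w stratum to a metric is metric(F_w) − metric(F_{w+1}); per-feature
contributions divide by the stratum size.  Differences are applied to
percentages rounded to two decimals by default (matching how such tables
are printed; a full-precision mode exists, in which contributions
telescope exactly).  The top stratum is dropped automatically when the
top-threshold classifier cannot fit its own training data (training
accuracy below 0.9), since a difference against an untrainable classifier
is meaningless.

## Synthetic data

The generator emulates the edge-level structure of a case/control
connectome study.  Each edge k gets a baseline Fisher-z mean
μ_k ~ N(0.2, 0.3); subject values are μ_k plus within-class noise of
sd 0.3; the second class is shifted by `effect_size × noise_sd` on the
planted informative edges only; tanh maps everything into (−1, 1) and rows
fold back into symmetric unit-diagonal R×R matrices.  Defaults: 45 regions
(990 edges), 60 subjects per class, 15 informative edges, effect 1.5 —
sized so a full screen runs in seconds to minutes on one CPU.  The
generator does not simulate time series, hemodynamics, or the spatial
autocorrelation of real connectomes, so passing tests demonstrate the
screening mechanics and statistical calibration, not performance on real
fMRI data.

## Numerical and design notes

* **Feature ordering.** Row-major upper triangle with 1-based region
  indices; feature k ↔ pair (i, j) via k = (i−1)·R − i(i+1)/2 + j, a
  documented bijection tested exhaustively up to R = 120.  Any consistent
  ordering would do; this one matches the "i–j" pair notation used in
  reported tables.
* **Symmetry tolerance.** Input matrices may deviate from symmetry by up
  to 1e-6 (file rounding); they are symmetrized as (M+Mᵀ)/2 after the
  check.  Entries outside [−1, 1] are errors, not clipped.
* **Splits.** Ratios are absolute part sizes; every part is class-balanced
  1:1 (±1 when a part size is odd, the extra going to the lexicographically
  first class).  `scale_ratios` maps the canonical 90:90:20 / 160:20:20
  proportions onto smaller cohorts with even part sizes.
* **Visit order.** Ascending index by default; a caller-supplied order is
  accepted for research use.
* **Problem sizes.** Test-suite fixtures use 7–45 regions, 40–200
  subjects and L = 30–500, chosen so the whole suite and the acceptance
  script each finish in well under a minute on one CPU while exercising
  every code path at realistic signal-to-noise.

## Known limitations

* Pruning measures *marginal* removability under fixed β̂.  Exactly
  duplicated features are therefore not guaranteed redundant: removing one
  copy halves the signal's effective input weight and perturbs every
  hidden activation, which can flip examples.  One copy is removed on some
  fixtures (tested) but not in general.
* Removability needs margin: when L ≈ N the min-norm fit interpolates with
  near-zero margins and no node may be removable.  Use L comfortably above
  the training-set size.
* With patience 1 and a saturated or noisy union-feature accuracy the
  screening loop can stop after very few rounds; raise `patience` (or
  inspect the recorded trajectory) when a more complete weight spectrum is
  wanted.
* Weights carry no significance calibration (no permutation null); they
  are selection frequencies, not p-values.  Multi-class screening is
  untested territory: the types allow m > 2 but the protocol is two-class.
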