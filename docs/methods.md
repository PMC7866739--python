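# Methods

`grnnfoa` models designed elicitation experiments in plant cell
suspension culture — four culture inputs (cell-extract and
culture-filtrate concentration in % v/v, elicitor adding day, harvest
day) against six responses (dry weight; intracellular paclitaxel per g
DW and per litre; extracellular, total, and the extracellular portion)
— with general regression neural networks whose single bandwidth is
tuned by the fruit-fly optimization algorithm, and then searches the
culture-input box for the predicted optima.  This note records the
model, the numerical choices, and what the synthetic experiments do and
do not establish.

## The regression model

The GRNN is Nadaraya–Watson kernel regression with an isotropic
Gaussian kernel on standardized inputs.  For a query x and stored
patterns x_i with targets w_i,

    p_i = exp(−‖x − x_i‖² / (2σ²)),
    Ŷ(x) = Σ w_i p_i / Σ p_i.

The prediction is a convex combination of training targets, hence
bounded by their range; σ → 0 gives nearest-neighbour interpolation and
σ → ∞ the target mean.  The network orientation (weighted sum over
simple sum) follows Specht's formulation; the opposite orientation would
make the output dimensionless and break the convex-combination bound,
so it is not offered.  The pattern-neuron "interconnection weights" are
the training targets themselves.  Activations are normalized after
subtracting the largest exponent, so small bandwidths are handled
stably; if every activation underflows (query far from all patterns at
a tiny σ) the prediction degrades to the nearest pattern's target and a
warning is raised.

Distances are computed on standardized inputs (training mean/sd), with a
single σ shared across dimensions.  Responses are Box-Cox transformed
before fitting (λ by bounded profile maximum likelihood on [−5, 5], an
automatic shift of 1 − min for non-positive data); all reported metrics
are computed on the original units after inverting the transform, so
RMSE values carry the response's units.  Per-dimension bandwidths and
compressed pattern layers are out of scope.

## Bandwidth selection

σ is chosen per response by maximizing the negative mean cross-validated
RMSE over σ ∈ [10⁻³, 10] (standardized-input scale) under a repeated
k-fold plan (5 folds × 10 repeats by default, deterministic under the
run seed).  The same tuned σ is held fixed across all folds when the 50
per-split metrics are collected — the evaluation mirrors a workflow in
which a single σ feeds the deployed model — and a `retune_per_fold`
flag provides the stricter per-split alternative.  The transform and
scaling state are likewise fitted once on the full dataset before the
cross-validation loop; this mild optimism is a property of the emulated
workflow and is deliberately reproduced rather than corrected.  Training
("in-fold") metrics are near-interpolating by construction, which is
why training bias is essentially zero; the honest skill estimate is the
testing column.

## The fruit-fly optimizer

FOA maintains one (X, Y) location-coordinate pair per search dimension.
Each generation every fly perturbs the pair by a uniform draw from the
flight-distance range (FDR, default [−10, 10]; initial coordinates in
[0, 1]), a smell-concentration judgment value S = 1/Dist is formed from
the flight geometry, the candidate is scored ("smell concentration"),
and the group relocates to the best fly whenever it improves on the
elitist incumbent.  Budget: exactly sizepop × maxgen evaluations
(defaults 10 × 100).  Non-finite fitness discards the fly for that
generation.

The map from flight geometry to a candidate inside an arbitrary box is
the one genuinely open design point, because S is positive, unbounded
and heavily right-skewed.  Three schemes are provided:

- **scale_free** (default): candidates step away from the incumbent,
  c_j = clip(x_best_j ± (hi_j − lo_j)·exp(−L_j)), with L_j the fly's
  flight length in dimension j.  Flight lengths are uniform over the
  FDR, so step sizes are log-uniform: every spatial scale from the full
  box width down to ~e^(−14) of it is sampled equally often.  The swarm
  therefore has global coverage and unlimited local refinement without
  any adaptive schedule, and the same configuration resolves both the
  1-D bandwidth search and the 4-D culture-input search (interior and
  boundary optima) to well under 1% of range.
- **minmax**: each generation's S values are affinely squashed onto the
  bounds per dimension (order-preserving).  This was evaluated as a
  default and rejected: the right-skew of S piles candidates at the
  lower bound and the swarm never contracts, which fails
  multi-dimensional recovery badly (0/20 seeds within even 10% of range
  on a 4-D concave quadratic).  It is retained for comparison studies.
- **clip**: the literal classical form c = clip(S, lo, hi), appropriate
  when the variable is itself a small positive quantity (bandwidths).

The initialization scale ([0, 1]) being much smaller than the FDR
([−10, 10]) means first-generation flights dwarf the initial
coordinates; this is inherited as-is, and none of the candidate schemes
depends on the initialization resolving finer structure.

## The genetic algorithm

The comparison optimizer is a conventional real-coded GA: tournament
selection (size 3), BLX-α blend crossover (rate 0.9, α = 0.5), Gaussian
mutation (rate 0.1, scale 5% of each dimension's range) clipped to
bounds, elitism 1, population 50, 100 generations.  These settings are
desk-scale conventions, not calibrated values.  On smooth concave test
surfaces the GA recovers the optimum essentially exactly, which makes
it a stringent agreement check for FOA.

## Culture-input optimization

Each trained response model is maximized over the experimental box
(CE, CF ∈ [0, 10] % v/v; adding day ∈ [13, 17]; harvest ∈ [13, 23])
subject to harvest > adding day; infeasible candidates get −∞ fitness.
Because a GRNN extrapolates as a plateau at the nearest pattern's value,
an unconstrained search wanders onto extrapolation plateaus where the
"optimum" is arbitrary; by default the search is therefore confined to
the convex hull of the training inputs (Delaunay membership test), with
an `allow_extrapolation` override.  Each response is optimized
independently; multi-response trade-offs are out of scope.  Reports
carry the derived quantities practitioners quote: total dose ce + cf,
the CE:CF split as whole percentages, and exposure hours
(harvest − adding) × 24.  Harvest time is encoded as culture day
throughout; fractional days are meaningful (20.68 ≈ 88.3 h after a
day-17 elicitation).

## Sensitivity analysis

Variable importance is leave-one-covariate-out: the model is retrained
without the input (bandwidth retuned with the same seeded procedure; a
flag keeps σ fixed instead), and the variable sensitivity error (VSE)
is the RMSE of that reduced model over the entire dataset.  VSR divides
VSE by the full model's RMSE on the same rows, and VSRs are min-max
rescaled to [0, 1] within each response (rescaling is monotone, so the
two rankings agree).  Retraining — not mean substitution — is the right
reading of "input unavailable" for a lazy learner.  A consequence worth
noting: dropping a genuinely uninformative input *reduces* the error of
the retrained model, because an irrelevant coordinate only adds noise
to the kernel distance; uninformative inputs therefore show VSR below
1, not near 1.  The ranking, which is what the analysis is used for, is
unaffected.

## The synthetic study

Real elicitation datasets of this design are rarely deposited, so the
generator reproduces the study conditions: a completely randomized
factorial with five CE:CF ratios (100:0 … 0:100), three total doses
(2.5, 5, 10% v/v), elicitor addition at day 13 or 17, harvests every
two days after elicitation through day 23, three replicates — 360
elicitor rows, plus optional water/PDB control arms that enter the
numeric design as ce = cf = 0.

Ground truth is a separable quadratic-exponential (Gaussian) bump per
primitive response — dry weight, intracellular µg/l, extracellular —
each a product of one factor per input plus a small positive baseline.
The derived responses follow the exact identity chain
intra_l = intra_g · dw, total = intra_l + extra,
portion = 100 · extra/total, which holds exactly at zero noise and, by
construction (noise is applied to the measured primitives and the
derived columns recomputed), in every emitted table.  Peak locations
and heights sit at the reported per-response optima, and the paclitaxel
primitives are jointly rescaled so the feasible-box maximum of total
yield equals the reported 372.89 µg/l, used as a calibration constant.
Bump widths were set once so that, at the default 10% multiplicative
Gaussian noise, the cross-validated testing R² of the fitted models
lands in the reported 0.88–0.97 band (observed 0.89–0.96 across seeds);
the noise level itself is not stated in the source and 10% is a typical
HPLC/biomass measurement spread.

What the generator does **not** emulate: longitudinal correlation
between harvests of the same flask (rows are independent), non-Gaussian
measurement error, batch effects, and any mechanistic elicitation
kinetics.  Passing tests therefore demonstrate that the pipeline
recovers smooth unimodal dose-response structure under multiplicative
noise at the study's design size — not that it would do so on data with
flask-level dependence or structured artifacts.

## Outlier screening

Rows are screened by PCA score distance: columns standardized,
components kept to 95% cumulative variance, each row's squared
Mahalanobis distance in that subspace compared with the chi-square
1 − α/n quantile (α = 0.05), a family-wise cutoff under which a clean
dataset is expected to yield no flags while grossly contaminated rows
are flagged reliably.  The screen is advisory — it reports indices and
the CLI only drops rows behind an explicit flag.

## Numerical and testing choices

Degenerate cases: constant responses are rejected by the Box-Cox fit;
constant input columns are rejected by the scaler; FOA/GA ties go to
the lowest fly index / first individual; degenerate min-max columns map
to the box midpoint.  All randomness flows from explicit seeds through
`numpy.random.default_rng`; per-response sub-seeds are derived by
hashing, kept below 2³¹, so adding a response does not shift another's
stream.  Serialization (models, pipelines, plans) is plain JSON with
sorted keys; two runs with the same configuration produce byte-identical
artifacts.

Test problem sizes are chosen to keep the default suite fast: the full
360-row, 5 × 10-fold, 6-response evaluation runs once; optimizer
recovery and sensitivity replicates use single-replicate designs
(120 rows), reduced repeats, and reduced swarm budgets where the
property under test does not depend on the full budget.  The
optimization-recovery test places the true peak at a design-supported
point: a kernel smoother cannot localize an optimum between design rays
more finely than the design resolves, and the test is about optimizer
correctness, not design-of-experiment resolution.

## Known limitations

- With only two elicitor-addition levels (days 13 and 17) the fitted
  dependence on adding day is close to an interpolation between two
  level means; optima in that coordinate should be read coarsely.
- The convex-hull constraint makes reported optima conservative: a true
  optimum just outside the tested mixture region cannot be found by
  design.
- VSE/VSR depends on the retuning budget; with very small swarm budgets
  the reduced models' bandwidths are noisy and rankings of
  nearly-equally-important inputs can swap.
- Metrics aggregate per-fold (mean ± sd over the 50 splits) rather than
  pooling predictions; both conventions exist, and pooled values are a
  few tenths of a point different at this design size.
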