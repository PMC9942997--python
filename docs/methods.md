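# Methods

`fungicast` models six cultivation outcomes of the wood-ear mushroom
*Auricularia cornea* — fresh yield (g/bag), biological efficiency (BE, %),
spawn run period (SRP), days to pinhead formation (DPHF), days to first
harvest (DFFH) and total cultivation period (TCP, all in days) — as functions
of the four-component substrate composition: beech sawdust (BS), hornbeam
sawdust (HS), wheat bran (WB) and rice bran (RB), percentages by dry mass
summing to 100. Two model families are compared under one shared
cross-validation plan: a multilayer perceptron whose hidden-layer size is
selected by an elitist genetic algorithm (MLP-GA), and a bidirectional
stepwise linear regression (SR). Input importance is quantified by
leave-variable-out sensitivity (VSE/VSR).

## Data model and synthetic replicates

The experimental anchor is a 16-formulation summary table (per-response mean
± standard error over n = 12 bags of 825 g substrate at 70% moisture),
shipped as an embedded CSV. Replicate-level observations were never
published, so the generator emulates them:

* per formulation and response, draws are independent Gaussian with the
  printed mean and SD = SE·√12;
* non-positive values are redrawn (rejection, not clipping, to avoid a point
  mass at zero);
* the within-bag ordering SRP ≤ DPHF ≤ DFFH ≤ TCP is enforced by jointly
  redrawing a record's four period values (up to 1000 attempts).

Because the printed means satisfy the ordering but the implied noise
distributions overlap (e.g. pure-bran DPHF has SD ≈ 8–10 days against a
3-day gap to DFFH), conditioning on the ordering truncates those
distributions: sample means of overlapping cells are biased by up to a few
days relative to the printed means. The package treats the ordering as a
plausibility constraint, not a calibration target; the generator's
mean/SE fidelity is verified with the ordering disabled, against the exact
zero-truncated Gaussian for all cells and against the printed means wherever
the mean exceeds 4 SD (truncation bias negligible). No cross-response
correlations are simulated — the summary table carries no covariance
information, and inventing structure would change the attainable R² in
unverifiable ways. Consequently the synthetic data are *independent* noise
around the printed response surface: passing model-comparison tests shows
the pipeline recovers that surface under realistic replicate noise, not that
it would reproduce the original study's exact error statistics, whose raw
data may have had correlated, heteroscedastic or non-Gaussian structure.

The printed BE and yield columns imply per-bag dry masses drifting between
≈245.4 g and ≈248.0 g across rows; the package fixes the nominal
825 g × (1 − 0.70) = 247.5 g as a single auditable convention, which
reproduces all printed BE values within 0.3 percentage points (and the
reference rows exactly at one decimal).

A linear benchmark generator provides known ground truth for validating the
selection and sensitivity stages: inputs uniform on the composition simplex
(flat Dirichlet × 100), response `intercept + Σ coefᵢ xᵢ + N(0, σ)`. The
simplex constraint removes one linear degree of freedom, so only coefficient
differences are identified — and every three-input subset encodes the fourth
input exactly. For leave-variable-out validation this matters: on the
simplex a "zero-coefficient" variable is still fully informative (with
coefficients (5,5,5,0) the response equals `500 − 5·rb`), so the benchmark
also offers independent uniform inputs (`simplex=False`), under which the
inert input is genuinely removable and sensitivity rankings can be validated
against ground truth.

## Preprocessing

Targets are Box-Cox transformed; λ maximizes the profile log-likelihood over
the grid [−5, 5] in steps of 0.01 (exact ties broken toward λ = 1). The
default follows the whole-dataset convention — one λ per response fitted on
all records before splitting, which leaks a small amount of information into
the held-out folds; a `per_fold` mode refits λ inside each training fold for
a leak-free alternative. Reported RMSE is always back-transformed to
original response units; the inverse transform floors λ·y + 1 at 1e-12 so
linear-output extrapolations map back into the positive response domain.

Inputs and transformed targets are affinely scaled to [−1, 1] by min-max
fitted on the training partition only (required by the saturating tanh
layer); held-out values outside the training range pass through unclipped.
A PCA screen standardizes the response matrix, keeps components covering
95% of variance, computes Hotelling-style score distances and flags records
above mean + 3 SD — advisory only, since nothing in the workflow drops
records automatically.

Model comparison uses a 5-fold plan with 10 independent shuffles (50
fits per model family per response). Folds are drawn over records without
stratifying by formulation; pooled metrics concatenate all held-out
predictions (each record appears once per shuffle in the test pool), which
is the headline statistic; per-fold metrics are emitted alongside.

## Network and trainer

The regression network is 4 inputs → `hidden_n` tanh units → 1 linear
output. Training is full-batch gradient descent with momentum 0.9 on the MSE
in scaled space: learning rate 0.2 halved after 40 stagnant epochs (floor
1e-5), early stopping after 100 stagnant epochs, cap 800 epochs, epoch
selection on an internal 15% validation split (on training loss when the
split is disabled for tiny representability checks), best of 3 seeded
restarts. Weights initialize uniform on [−0.5, 0.5] scaled by 1/√fan-in.
These constants were fixed on the noiseless linear benchmark (training
R² ≥ 0.9999 at `hidden_n = 3`) and the smooth nonlinear benchmark; on the
[−1, 1]-scaled problems this aggressive rate with plateau halving converges
in roughly half the epochs a conservative 0.01 rate needs. A guard refuses
fits with fewer than 6 training records per hidden neuron (configurable; the
4-point XOR representability test disables it). A constant target is handled
by a degenerate target scaler (half-range 1), for which training reduces to
the bias solution.

## Architecture search

The GA minimizes pooled cross-validated test RMSE over a 5-bit gene decoded
to `hidden_n ∈ [1, 20]` (wrap-around decoding keeps every chromosome
feasible): tournament selection of size 2, single-point crossover at rate
0.85, per-bit mutation at rate 0.01, population 50, one elite carried over,
fitness ties broken toward fewer neurons. Fitness is cached per decoded
architecture and the training seed is a deterministic function of the
architecture, so each of the ≤ 20 states is trained at most once per search
and the search is reproducible. During the search each candidate is scored
on the first shuffle replicate only; the winner is re-scored under the full
5 × 10 plan and refit on all records for sensitivity analysis. The study
profile of 500 generations is available (`paper_faithful`), but on a
20-state space the desk default of 40 generations with early stop after 15
stagnant generations reaches the same optimum — the cache makes the extra
460 generations pure bookkeeping. Architectures infeasible for the dataset
size are quarantined at +∞ fitness with a warning.

## Sensitivity analysis (VSE/VSR)

Computed on all records with the GA-chosen architecture, per the study's
convention. Baseline RMSE comes from the all-inputs model; VSE(v) is the
RMSE when input v is "nonexistent", which is ambiguous and therefore
implemented twice: `retrain` (default) refits a three-input network of the
same hidden size, `ablate` freezes the weights and replaces v by its mean.
VSR(v) = VSE(v)/baseline RMSE; the four VSRs are min-max rescaled so the
most influential input reads 1.000 and the least 0.000. An all-equal VSR
vector rescales to 0.5s and a relative spread below 5% flags the ranking as
unstable. On compositional inputs retrain-mode VSRs measure how readily the
network exploits the remaining encoding rather than pure information loss
(any three inputs determine the fourth); this cap is inherent to the design
and no correction is applied.

## Stepwise baseline

Bidirectional p-value stepwise OLS on the linear main effects:
enter the best candidate with partial-t p ≤ 0.05, then drop any included
variable with p > 0.10 (conventional defaults, configurable); candidates
that would make the intercept-plus-three-components design singular are
skipped (rank/condition check), a variable may not re-enter in the step it
was dropped, and the loop is capped at 50 steps. Under the shared CV plan
the stepwise model is re-selected per training fold and a selection-stability
table reports how often each input entered. The same Box-Cox treatment as
the network is applied by default so the family comparison is
apples-to-apples on original units.

## Orchestration, determinism and problem sizes

`run_full_study` executes generate → screen → per-response {Box-Cox, GA
search, CV comparison, sensitivity} and writes `table4_analogue.csv`
(train/test R²/RMSE per response and family), `table5_analogue.csv`
(VSE/VSR/rescaled VSR and chosen hidden size), predicted-vs-observed pairs,
GA convergence histories and a JSON run log. Every CSV carries the
configuration hash (excluding the output directory) and generator seed;
all randomness flows from `numpy.random.default_rng` with deterministic
derived seeds, so identical configurations reproduce byte-identical reports.
The default desk-scale study (16 formulations × 12 bags, 6 responses, GA
desk profile, full 5 × 10 final scoring) runs in a few minutes on one CPU;
the test suite exercises end-to-end determinism on a two-response
study-faithful-GA run and the full comparison on all six responses.

## Known limitations

* Replicate-level ground truth is unpublished; all replicate structure is
  synthetic and independent per response, so attainable R² is capped by the
  printed SEs (≈ 0.98 for yield at SE·√12 noise) and the original study's
  headline accuracies are not reproduction targets.
* The original trainer is unspecified (likely a Levenberg–Marquardt
  default); absolute RMSE magnitudes are therefore not comparable, only the
  qualitative MLP-vs-SR contrast, which is robust here.
* Sensitivity rankings on compositional inputs are identifiable only up to
  the simplex redundancy discussed above; the published input rankings
  depend on the unpublished raw data and the removal semantics, and are
  reported qualitatively, not asserted.
* The default Box-Cox convention is deliberately leaky to match the study's
  procedure; use `boxcox_mode="per_fold"` for clean inference.
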