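# Methods

## Model

The package models parcellated brain activity as a discrete-time nonlinear
dynamical system: `x_{t+1} = x_t + W ψ_α(x_t) − D ⊙ x_t + B u_t + ε_w`,
observed through a linear hemodynamic system `y = h * x + ε_v`. The
activation `ψ_α(x) = √(α²+(bx+½)²) − √(α²+(bx−½)²)` (fixed `b = 20/3`) is
odd, strictly increasing, and saturates in (−1, 1); its slope at the origin
is `b/√(α²+¼)`, so small per-parcel `α` gives a step-like regional response
and large `α` a flat one. Connectivity is parameterized sparse-plus-low-rank,
`W = Ws + W1 W2ᵀ` with rank bound `k` (72, capped at `n−1` for small
problems). Process and observation noise are zero-mean Gaussian and
independent across parcels. Task inputs are one-hot box-cars per condition;
rest and block-interval volumes carry the zero vector.

Assumptions inherited from this formulation: a canonical, region-invariant
HRF (SPM double-gamma: response gamma peaking at 6 s, undershoot at 16 s,
unit dispersions, ratio 1/6, 32 s support, unit peak); a flat 50:1
signal-to-observation-noise ratio across frequency bands, which licenses the
Wiener deconvolution `X(f) = H*(f) Y(f)/(|H(f)|² + 1/50)` as the MMSE
estimate of the neural series.

## Preprocessing

Runs are detrended (first-order, per parcel) and standardized against
reference statistics — a run's own statistics for rest, block-interval
statistics for task runs, so interval activity is standardized like rest.
Confound regression is per-parcel OLS with intercept (pseudo-inverse with a
warning when rank-deficient). High-motion volumes (framewise displacement
above 0.2 mm for rest, 0.9 mm for task) are linearly interpolated between
the nearest unflagged neighbors, boundary volumes copying the nearest
unflagged value; the flagged fraction is returned so callers can apply the
conventional "more than 1/3 flagged" run exclusion. Deconvolution operates
per run: each parcel is mean-removed (a nonzero baseline against the zero
padding would ring), zero-padded to the next power of two, filtered, and
the mean re-added through the filter's DC gain — with a unit-impulse kernel
the whole operation reduces exactly to multiplication by snr/(snr+1).

## Fitting

Parameters `(Ws, W1, W2, α, D, B)` are estimated by minibatch NADAM
(Nesterov-accelerated Adam) on the mean one-step half-squared error over
300-triplet minibatches plus ℓ1 penalties (λ1, λ2, λ3) =
(0.075, 0.2, 0.05); 5000 minibatches by default. Triplets are drawn
uniformly over all consecutive-volume pairs across runs, never spanning a
run boundary. Gradients are analytic; all arithmetic is float64.
Initialization: `Ws, W1, W2, B ~ N(0, 0.01²)`, `α = 5` (the typical fitted
value), `D = 0.5`. `α` and `D` are projected to ≥ 1e−6 after every update.
Optimizer defaults: learning rate 2e−3 (β1 = 0.9, β2 = 0.999, ε = 1e−8)
with a linear decay to 10% over training — the schedule is a free choice
here, and the decay removes the late-training oscillation floor.

The ℓ1 terms are applied by proximal soft-thresholding after each NADAM
step with the textbook proximal-gradient threshold (nominal learning rate ×
λ), which produces exact zeros in `Ws`. A deliberate design choice: the
threshold is *not* scaled by Adam's per-coordinate adaptive step. Because
the data term `½‖·‖²` sums over parcels while the penalties count entries,
the penalty-to-data ratio grows as problems shrink; at the desk-scale
default (n = 15) an exact minimizer of the composite objective zeroes out
the entire connectivity, whereas the nominal-threshold prox behaves like a
milder effective penalty and recovers generating parameters accurately.
The consequence is that the composite loss trace can drift slightly upward
late in training while the misfit keeps decreasing; `FitReport` therefore
exposes both `loss_trace` (composite) and `mse_trace` (misfit component).

The final 10% of each training run is held out internally: it supplies a
validation R² and the per-parcel root-mean-squared one-step prediction
error, which doubles as the process-noise scale for noise-driven simulation
(unexplained one-step variability is attributed to intrinsic noise). After
optimization, three scalars `(pW, pD, pB)` are fit by ordinary least squares
(no intercept) to minimize
`‖x_{t+1} − (x_t + pW Wψ − pD D⊙x + pB Bu)‖²` over all training triplets
and multiplied into `W` (via `Ws` and `W1`), `D`, `B`, compensating the
shrinkage bias of the penalties. A term identically zero in the data (e.g.
the input term on all-rest data) keeps factor 1 and is flagged. Rescaling
is a projection onto a larger least-squares family containing the identity,
so it never increases training SSE.

Baselines: VARX(1,1) `x' = A x + B u` with ℓ1 on `A` only (per-coefficient
penalty via statsmodels elastic net), penalty weight selected from
{0, 0.001, 0.005, 0.01, 0.05} by one-step R² on the internal validation
split; ARX(1,1) and the static GLM `x = μ + β u` by per-parcel OLS.
Cross-validated one-step R² is `1 − SSE/SST` of the actual against the
predicted next state, per parcel and pooled.

## Simulation and attractor identification

Noise-free simulation iterates the map deterministically (states with
sup-norm above 1e6 are flagged divergent). Noise-driven simulation runs
1000 warm-up steps with zero input and process noise before applying the
design's input sequence. The observation model convolves each parcel with
the HRF causally and adds Gaussian noise with variance equal to the parcel's
neural-signal variance divided by the SNR.

Attractors are found from 120 standard-normal initial conditions iterated
1600 steps under a constant input. A trajectory is a converged equilibrium
when every parcel's step change is below 1e−6 over the trailing 10 steps;
otherwise it is a limit cycle if it entered and later left the Euclidean
ball of radius 0.5 around its final state. The cycle period is the interval
between the last two entries into that ball — one full revolution ending in
the final approach; the more literal "last entry to the end" reading
undercounts when several consecutive samples of the final approach fall
inside the ball. Unresolved trajectories are extended by doubling up to
25600 steps; any still unresolved set an `unclassified_flag` on the result
rather than being dropped. Equilibria are merged by single-linkage at
Euclidean distance 0.1 (centroid representative, group size as basin
count); cycles are deduplicated by symmetric mean minimum point-to-orbit
distance with threshold 0.5, floored at the orbit's own sampling spacing
(two discretizations of one orbit can be phase-shifted by half a spacing).
Topology: oscillatory if any stable cycle exists, else multistable if two
or more equilibria, else monostable; a bifurcation is any class difference
between two conditions. Stability is established by convergence of forward
simulation, not by Jacobian eigenvalues.

## Motifs and features

Stable equilibria pooled across subjects within one condition are clustered
by spherical K-means: points are unit-normalized, assignment maximizes the
dot product, centroids are renormalized cluster means, and the best of the
random restarts by within-cluster cosine dissimilarity is kept. K ∈ [2, 10]
is selected by clustering instability: for each K, repeated random
half-splits are clustered independently, all points are labeled by each
half's centroids, labels are matched by the Hungarian algorithm, and
instability is the mean disagreement (50 resamples by default). The
selected K is the smallest whose instability is at or below its left
neighbor and strictly below its right neighbor — perfectly stable solutions
tie at zero, and the largest K on such a plateau is the finest stable
partition — falling back to the global minimum when the curve has no such
point.

Volumes are labeled by the most cosine-similar motif (ties to the lowest
index; zero-norm volumes get a null label excluded from occupancy).
Occupancy is the label frequency; the mean distance to motif k averages the
Euclidean distance from *every* volume to centroid k, computed in the same
deconvolved, standardized state space the model is fit in. The feature
table emits, per subject, the binary bifurcation indicator, occupancy
columns with the first motif's share dropped (occupancies sum to one), and
distance columns, optionally with a rest-condition distance block scored
against rest motifs. Motifs are named `motif_1..K` unless a parcel-network
map is supplied; behavioral models are OLS with intercept (statsmodels),
with standardized coefficients reported alongside raw ones and nested-model
F tests available.

Reliability uses ICC(2,1) — two-way random effects, absolute agreement,
single measure — with the consistency variant ICC(3,1) available; AIC/BIC
come from the Gaussian likelihood with estimated variance.

## Synthetic study conditions

The generator mirrors a joint rest + N-back protocol at desk scale: 15
parcels, rank-5 connectivity, two resting runs of 1000 volumes, one task
run of 400 volumes with four 25 s blocks per condition separated by equal
intervals, TR 0.72 s, observation SNR 50:1. Process-noise sd defaults to
0.3 in standardized state units: large enough to excite the system for
identification, below the ~0.6 implied by applying the held-out-MSE rule to
published human one-step R² values (real scans carry physiological and
residual-motion noise the generator does not emulate).

Ground-truth regimes are planted through the linearized gain at the origin:
monostable keeps the map contractive (weak sparse background only);
multistable plants a symmetric recurrent loop along a ±1 pattern whose gain
exceeds the mean decay, so saturation creates a stable root on each side;
oscillatory plants a rotational (skew-symmetric) two-dimensional loop with
supercritical gain, bounded by saturation into a stable invariant loop.
Because the landscape is not analytic for n > 2, every candidate is
verified with the attractor search and the planted gain is escalated over a
bounded number of retries. Task-input weights `B` carry a planted
task-positive/task-negative parcel split. Synthetic BOLD is already in the
model's standardized state units, so the pipeline deconvolves it directly;
re-standardizing would move the data off the activation's operating range.

What passing these conditions shows — and does not. Parameter recovery,
baseline ordering, statistics recreation, and motif selection are assessed
on data whose generative process *is* the model; they establish the
estimator's and the landscape machinery's correctness, not the model's
adequacy for real fMRI. The end-to-end BOLD path (deconvolve → fit →
attractors) recovers the generating *topology class* reliably, but
entrywise connectivity recovery through BOLD is information-limited: the
Wiener filter cannot restore white process noise outside the HRF passband,
and filter-colored residual noise biases one-step regression. Entrywise
recovery is therefore assessed at the neural level. The generator does not
emulate head motion, physiological noise spectra, regionally varying HRFs,
or multiband artifacts.

Problem sizes used in the shipped tests and in `scripts/acceptance.py`
(n = 15 parcels, 2000 minibatches, 5 fitting seeds, 20 K-selection seeds,
40–120 attractor starts) are the package's desk-scale defaults; every
routine accepts larger values unchanged.

## Known limitations

- The λ defaults are calibrated to the published 200-parcel setting; at
  much smaller n the composite objective over-penalizes connectivity (see
  Fitting), which the nominal-threshold prox mitigates by design.
- Limit-cycle periods are integer step counts of the sampled map; rotation
  numbers that are irrational multiples of the step give quasiperiodic
  orbits whose reported period is the nearest revolution length.
- `find_attractors` samples basins from standard-normal initial conditions;
  attractors with very small basins in that measure can be missed.
- GLM baselines model states, not transitions, and expose no one-step
  prediction; they participate in parameter-reliability comparisons only.
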