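# Methods

This note records the modelling assumptions, parameter choices, numerical
details and known limitations of the package. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate conventions and data model

The pitch is 105 × 68 m with the origin at the center, x ∈ [−52.5, 52.5],
y ∈ [−34, 34]. All analyses assume the team under study attacks toward
+x; callers flip coordinates per half before analysis if needed, because
the pitch-value scaling requires a fixed attacked goal. Tracking is a
tidy table (one row per agent per frame) at a constant frame rate, 25 Hz
by default, overridable by a header comment; gaps in tracking are hard
errors rather than being interpolated, because silent interpolation
corrupts finite-difference velocities. Positions outside the pitch bounds
are rejected at read time with the offending row named.

Grids place nodes at cell centers, ordered row-major with x varying
fastest. Two grids matter in practice: the 21 × 16 training grid for the
defensive-influence network (5 m × 4.25 m cells) and a fine analysis grid
for space metrics (0.5 m nominal; the test suite and examples use 2–6 m
to keep runtimes short — coarser grids change absolute space-generation
sums roughly in proportion to node count but not rankings).

Event/tracking alignment maps each event to the nearest frame, rejecting
matches farther than 0.1 s; an equidistant tie goes to the later frame so
the mapping is deterministic. Possessions are maximal runs of consecutive
passes by one team, closed by a shot or by the other team's pass; a
possession is successful iff it ends with a shot by the possessing team,
and possessions with fewer than three passes are flagged (not deleted).
The event log itself carries no possession labels, so this segmentation
rule is a documented package choice.

## Player kinematic state

Velocity is the backward finite difference over δ = 0.2 s (5 frames);
speed is reported in km/h (3.6‖v‖); the heading is atan2 of the
displacement. A stationary player has an undefined heading, so θ := 0 by
convention and influence queries use the standing bin, where direction is
irrelevant.

## Data-driven movement models

Triplets (p<sub>t−δ</sub>, p<sub>t</sub>, p<sub>t+Δ</sub>) are extracted
for every horizon Δ ∈ T = {0.2, 0.4, …, 5.0} s with a stride of one frame
(overlapping triplets are correlated but maximize data; correlation only
smooths the density estimate). The local-frame transform subtracts the
heading angle from the endpoint displacement angle — an
orientation-preserving rotation, so a left turn stays a left turn in the
local frame — and is exactly invariant under rigid motions of the raw
trajectory.

Endpoints are pooled per (speed bin, horizon) cell; cells with fewer than
`min_count = 50` endpoints (a stability floor; KDEs on fewer points are
unreliable) are marked unavailable and queries fall back to the nearest
available horizon in the same bin, logged. Densities use a Gaussian
kernel with Scott's rule bandwidth — deterministic and adequate at this
scale; a cross-validated bandwidth search can be passed through
`bw_method`. A degenerate endpoint cloud (zero variance in some
direction, e.g. a perfectly straight synthetic walk) would make the
kernel covariance singular; such cells are skipped with a warning.

The main mode is found by Gaussian mean shift with the KDE's kernel
covariance, tolerance 10⁻⁴ m, at most 500 iterations, started both from
the sample mean and from the highest-density endpoint, keeping the better
optimum. Because mean shift ascends the density and one start is the
densest endpoint, the stored peak dominates the density at every sample,
which guarantees normalized influence PI = density/peak ∈ [0, 1] with
PI = 1 exactly at the mode. A continuous horizon snaps to the nearest
element of T with ties upward.

## Gaussian baseline influence

The baseline models influence as a bivariate normal centered at
p + ½ s · v (the velocity is read in m/s, i.e. displacement divided by δ,
for dimensional consistency with a maximum speed in m/s). The covariance
is R V V R<sup>⊤</sup> with V diagonal, entries
(r ± r(‖v‖/v<sub>max</sub>)²)/2, where the influence radius r(d) grows
with distance to the ball. The exact r(d) form is a package choice (the
concept fixes only the [4, 10] m range and a sigmoidal shape): a logistic
in d with midpoint 15 m and scale 3 m, rescaled so r(0) = 4 exactly and
r → 10 within 10⁻³ by d = 60 m; it is configurable. v<sub>max</sub>
defaults to 13 m/s and should be estimated from data when available;
faster observed speeds are clipped with a log entry. At ‖v‖ =
v<sub>max</sub> the smaller V entry vanishes and the covariance would be
singular, so V entries are floored at ε = 10⁻⁶ m; flooring (rather than
adding ε) keeps every non-degenerate case, including the
stationary-at-ball closed form Σ = 4I, exact. Normalizing the density by
its value at the mean gives exp(−½ (p−μ)<sup>⊤</sup>Σ<sup>−1</sup>(p−μ)),
directly comparable to the movement-model influence.

## Pass-time regression

The time a receiver has before the ball arrives is learned from completed
passes: d = passer–receiver distance at pass initiation, Δ = reception
minus initiation time; durations above max(T) = 5 s are dropped (logged),
and incomplete passes are excluded because their reception time is
ill-defined. The model is a Yeo–Johnson power transform of the predictor
d (response untransformed) followed by ordinary least squares on an 80/20
split. The transform exponent λ is a hyperparameter selected by held-out
MSE among the maximum-likelihood value and a fixed grid
{−1, −0.5, 0, 0.5, 1, 1.5, 2}; the identity (λ = 1) is always a
candidate, so a genuinely linear relation is recovered without transform
bias. Predictions are snapped to the nearest element of T (ties upward)
and clipped to [0.2, 5.0] s. Monotonicity of the prediction in d follows
from the monotone transform whenever the fitted slope is nonnegative,
which planted and realistic data produce.

For pitch control, each player's horizon is their own distance to the
ball through this model; the ball carrier, identified as the player
nearest the ball, gets the smallest horizon min(T) = 0.2 s (no external
rule exists for the carrier, and the carrier needs no time to reach the
ball).

## Defensive influence and pitch value

Observed defensive influence is the capped sum of defender influences,
min(Σ PI, 1), with goalkeepers excluded (their fixed station would
dominate the surface without carrying tactical information). The learned
surface fn<sub>θ</sub> is a scikit-learn `MLPRegressor` — two hidden
layers of 64 ReLU units, Adam on the MSE, features
(x<sub>node</sub>, y<sub>node</sub>, x<sub>ball</sub>, y<sub>ball</sub>)
standardized, single-threaded and deterministic under a fixed seed. This
implementation has no dropout layer; the L2 penalty `alpha` (default
10⁻⁴) serves as the regularizer instead. Network outputs are clipped to
[0, 1] at inference to match the target's range. Training rows come from
frames × the 21 × 16 grid; validation uses a random 20% of rows, and the
fit reports held-out MSE and R². A non-finite loss raises with
diagnostics.

Pitch value multiplies the learned surface by the goal-proximity factor
1 − ‖p − p<sup>g</sup>‖/‖p<sup>c</sup> − p<sup>g</sup>‖, whose
denominator ‖p<sup>c</sup> − p<sup>g</sup>‖ = √(105² + 34²) ≈ 110.37 m is
the longest possible on-pitch distance to the goal; the factor is 1 at
the goal center and 0 at the far corner, so PV ∈ [0, 1] and PV never
exceeds the network's DI estimate.

## Space metrics

Space quality is the node-wise product PC · PV, so |SQ| ≤ PV ≤ 1.
Possession features weight SQ by exp(−λ‖node − anchor‖) around each pass
origin (λ<sub>o</sub>) and destination (λ<sub>d</sub>), summed over the
grid and averaged over the possession's passes; λ = 0 recovers the plain
grid sum and large λ isolates the anchor's nearest node. The default λ
selection grid is {0.05, 0.1, 0.2, 0.5, 1, 2} m⁻¹. The outcome
classifier is a linear SVM on standardized features with repeated random
80/20 splits scored by ROC AUC; 100 repeats by default (1,000 available
via the argument), single-class splits are redrawn and logged.

Per-player space quality — needed by space generation but not formally
fixed by the SQ definition — is defined as PI<sub>i</sub>(p) · PV(p):
the player's own normalized influence weighted by the value surface. The
surplus sum in SG runs over all 21 other players of both teams, unsigned.
An alternative reading would credit SG<sub>pas</sub> with quality at the
destination rather than with the receiver's SG; the chosen reading (both
SG<sub>rec</sub> and SG<sub>pas</sub> average the receiver's SG at pass
initiation, credited to receiver and passer respectively) keeps the two
aggregates directly comparable and is isolated in `aggregate_sg`.
Players with fewer than 30 pass involvements are flagged rather than
dropped; per-90 values scale each player's summed credit by 90/minutes
tracked.

## The synthetic-match generator

The generator emulates the *structure* of professional tracking data so
every downstream stage is testable with known ground truth:

* 22 players (configurable) plus ball at 25 Hz on the standard pitch;
* per-player kinematic caps (defaults: 8 m/s speed, 6 m/s² acceleration,
  2π rad/s turn rate) enforced exactly at every frame — positional noise
  enters through the acceleration channel *before* the caps are applied,
  so reachability bounds hold by construction;
* a planted pass-duration law Δ = α + β d^γ + ε (defaults α = 0.5 s,
  β = 0.045 s/m, γ = 1, ε ~ N(0, 0.05²) — a ball traveling ~20 m/s plus
  a fixed reaction component, consistent with passes completing within
  5 s);
* defenders placed by a fixed affine function of the ball position
  projected into the defending half, plus isotropic noise (0.5 m), so the
  defensive-influence surface is a learnable function of (node, ball);
* passes led onto the receiver's run: the destination is the receiver's
  position extrapolated by the flight time, as real passes are;
* possession outcomes drawn from a logistic law on an openness proxy
  (tanh of the final receiver's nearest-defender distance / 10 m) —
  computing the full destination-quality feature inside the simulator
  would be circular, so classifier-recovery experiments plant labels on
  the computed features directly;
* per-player space-creation multipliers: skill biases how deep (toward
  the attacked goal) a player roams — capped so the deepest roamers sit
  just ahead of the defensive block, where surplus space is actually
  available rather than already occupied by defenders — and scales how
  far a receiver detaches before a pass.

The trajectory corpus generator emits fixed-length (10.2 s) free-space
episodes round-robin over the five speed bins until the requested triplet
count is reached. Within an episode the heading changes gently every
1–2.5 s and the cruise speed follows a mean-reverting random walk around
the bin's nominal speed, so the player brakes and bursts at all phases
and endpoint clouds fill the reachable set instead of collapsing onto the
constant-speed arc. Bins are always assigned from each triplet's actual
initial speed.

What the generator does **not** emulate: tactical structure (formations,
pressing, off-ball screening), ball flight physics (flights are linear
interpolations), measurement noise and identity switches of real optical
tracking, or two-sided possession play (one team attacks throughout, with
brief scripted turnovers). Passing tests on this data therefore
demonstrates correctness and recoverability of the package's estimators
under known ground truth — not that the metrics capture real tactical
behavior, which requires real tracking data.

## Problem sizes and numerical details

Test and acceptance runs use desk-scale sizes chosen as the package's own
defaults: ~5,000-triplet corpora (≈ 23,000 raw triplets populate all 125
cells with 63+ endpoints each), 200 frames × 336 grid nodes for the
defensive-influence network, 100 classifier repeats, 1,000 random frames
for control-bound sweeps, and 1,500 s leagues with 20 outfield players
for ranking recovery. KDE normalization is verified by quadrature over
the endpoint bounding box padded by five bandwidths on a 100 × 100 grid.
Vectorized grid evaluations are required to match naive per-node loops to
10⁻¹² and do. Dual-path checks (independent transform implementations,
closed-form densities, enumeration counters) back every nontrivial
computation in the test suite.

## Known limitations

* Movement models pool one endpoint set per player across all matches;
  fatigue or tactical-role drift within and across matches is ignored.
* The influence of a player is evaluated independently of opponents; the
  movement model does not condition on nearby defenders.
* The Gaussian baseline's r(d) curve is a plausible reconstruction, not
  a fitted quantity.
* Fields are computed frame-by-frame with no temporal smoothing.
* The defensive-influence network is trained per data set; transferring
  it across leagues or rule variants is untested.
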