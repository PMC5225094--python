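# Methods

`rosettrack` implements a complete desk-scale pipeline for organ-level
phenotyping of *Arabidopsis thaliana* rosettes from daily top-view
images: leaf segmentation, leaf identity tracking across days, an
organ-scale source–sink growth model, and calibration of that model
from the extracted per-leaf area trajectories. This note records the
models, the defaults and why they were chosen, and what the synthetic
validation does and does not demonstrate.

## Image measurements

Inputs are background-removed RGB images (one per day). The plant mask
is the largest 8-connected foreground component; 8-connectivity avoids
fragmenting thin petioles. From the mask's mass center C, every
candidate leaf segment is summarised by three quantities:

- **direction** `d`: the angle of the vector from C to the segment's
  extremity E (the segment pixel farthest from C, Euclidean distance,
  ties broken by smallest (row, col)), reported in a mathematical y-up
  frame in [0, 360);
- **extremity** `e`: the Euclidean length of C→E (an `norm="l1"` option
  reports the L1 length instead, for compatibility with conventions
  that measure ruler distances axis-wise);
- **area** `a`: pixel count divided by the platform calibration,
  28,900 px per cm² by default (overridable per series).

Coordinates are 0-based internally and 1-based in CSV outputs.

## Segmentation

Two steps. First, a marker-based watershed: Canny edges of the image
luminance (sigma 2, automatic hysteresis) are removed from the mask so
contact lines between overlapping leaves become valleys of the
Euclidean distance transform (EDT); EDT local maxima (minimum
separation 10 px) become markers; the watershed of the inverted EDT
floods the *full* mask so each foreground pixel lands in exactly one
segment; regions below 50 px merge into their largest neighbour. The
peak search runs on a Gaussian-smoothed copy of the EDT (sigma 2 px):
integer-valued EDTs of elongated blades carry many spurious strict
local maxima along their ridge, and without smoothing small leaves
over-segment. The watershed itself floods the exact EDT.

Second, a shape filter: a segment is a single leaf when its solidity
(area / convex-hull area) strictly exceeds i0 = 0.9. A failing segment
is assumed to be merged leaves: the two dominant EDT maxima P1 ≥ P2 are
located (ties by larger watershed basin, then lexicographic), and an
ellipse is placed at P1 with one semi-axis along the line through C and
P1 and the other perpendicular, each axis being 1.05× the distance from
P1 to the nearest non-segment sample along its direction (marched at
0.5 px steps both ways, minimum of the two sides). The segment is split
into (segment ∩ ellipse, remainder); parts are re-tested recursively to
depth 5, disconnected parts re-labelled first, and unsplittable or
sub-50-px parts flagged as residuals. The second ellipse at P2 is
computed only for diagnostics; splitting with E1 alone already
partitions the input.

Degenerate inputs: an empty mask yields no segments; a mask too small
to contain any EDT peak is returned whole.

## Tracking

Leaf identities are reconstructed day by day. A track's expectation of
its next observation is a 4-parameter logistic
`s(x) = y0 + y1 / (1 + exp(-k (x - x0)))` least-squares fitted through
its last four (day, value) pairs — the recorded day values, so gaps
need no special casing — with deterministic initialisation (y0 = min,
y1 = range, x0 = median day, k = 1) and non-negative bounds on k, y0,
y1 so extrapolation stays finite and positive. With fewer than four
observations the fallbacks are mu_e = 1.2 e and mu_a = 2 a from the last
observed values; the spreads are always sigma_e = e/2 and sigma_a = 2a.

Each candidate segment is scored
`s = gamma_d s_d + gamma_e s_e + gamma_a s_a` with defaults
(10, 1, 1): s_d is 1 when the candidate's direction lies within
±30° (inclusive, circular) of the track's last direction, else 0;
s_e and s_a are sup-normalised Gaussian scores
`exp(-(x - mu)^2 / (2 sigma^2))`. Assignments are resolved globally and
greedily by descending score — equivalent to one auction pass, checked
against brute-force enumeration on small instances — a segment joins at
most one track, and only scores strictly above the safety score
s0 = 11 are accepted; a track without an admissible candidate records a
gap and keeps competing on later days.

First occurrences follow the rosette's phyllotaxy. Day 1 must show the
two cotyledons; leaf 2 is the one opposite leaf 1. Leaf 3 first appears
at least 60° (configurable; a 40° convention also circulates) from both
cotyledons, leaf 4 opposite leaf 3, and leaf 5 is the next new leaf
regardless of direction. Once leaf 5 exists, ranks 1/3 are relabelled
to the pair members whose mean direction is closest to leaf 5's (labels
only, histories untouched), the spiral orientation is the sign of the
wrapped angle from leaf 4 to leaf 5, and leaf 5+j is sought within the
direction window around `d5 + j * sign * 137.5°`. Two design choices
here are the package's own:

- `d5` is leaf 5's **most recent** tracked direction, not its first
  one, so the search window follows day-to-day pot rotation — the same
  reasoning that makes the d-score use only the last direction.
- a first occurrence must be **smaller** than the previously emerged
  leaf (and leaf 5 smaller than the true-leaf pair). A new leaf is
  necessarily the youngest and smallest; without this bound an old leaf
  whose own track misses a day can be stolen as a "new" one.

Known limitations, both visible in synthetic runs and consistent with
what real rosettes show: golden-angle arithmetic parks rank 6 about 5°
and rank 10 about 15° from the cotyledons, so when trajectories cross
under occlusion the score cannot always separate them (the "fork"
problem); and a leaf that loses several days during its steepest growth
phase may not resume, because the multiplicative fallbacks cannot
bridge a many-fold area change. Tracking is exact on overlap-free
scenes and degrades gracefully (≥95% rank accuracy over 21-day
sequences with daily rotations up to 10°).

## Growth model

An hourly source–sink model of the rosette stage only (no senescence,
bolting, roots, or stress). Organogenesis: leaves 1–4 appear in two
pairs at known times (defaults: cotyledons at hour 0, first true leaves
at 48 h), and leaf 5+j at the leaf-5 time (96 h) plus j phyllochrons
(phi, default 40 h); appearance hours may be fractional, leaves count
from their appearance hour inclusive, and each leaf records the thermal
time at appearance (thermal time = cumulative max(0, T − T_base),
T_base default 0 °C — under constant chamber conditions the base is not
identifiable, so it is a fixed input).

Hourly production from the previous hour's total biomass Q:

    q(t) = r(t) * mu * s * (1 - exp(-(k / (e s)) * Q(t-1)))

with radiation r in MJ cm⁻² h⁻¹, radiation-use efficiency mu
(g MJ⁻¹), ground area s (cm²), light-extinction coefficient k, and
leaf mass per area e (g cm⁻²); the exponent is Beer–Lambert on the
leaf-area index (total leaf area Q/e over ground area s), and the
explicit one-hour forward step avoids an implicit fixed point. A
helper converts chamber set points in umol m⁻² s⁻¹ of PAR using
0.2188 J per umol.

Each appeared leaf's sink demand is a sup-normalised lognormal in its
thermal age x: `f(x; mu_i, sigma_i) / f(mode)` with mode
`exp(mu_i − sigma_i²)`, law 1 for the four preformed leaves and law 2
scaled by an intensity ratio rho for all later leaves; demands are
exactly 0 at x ≤ 0, peak at 1 (or rho). Produced biomass is shared
proportionally to demands (exact conservation; an all-zero demand
vector leaves the pool unallocated and logged, which never occurs under
the defaults), accumulated per leaf, and areas are A_v = Q_v / e. The
seed biomass q0 is split equally between the leaves present at hour 0 —
demands vanish identically at zero thermal age, so "allocate by demand"
is 0/0 there; a flag instead holds q0 as a pool released at the first
hour with positive demand.

Internally the hourly recursion couples hours only through the total
biomass, so the loop runs on scalars and per-leaf allocation is
vectorised afterwards (~0.5 ms per 3-week simulation), which is what
makes the calibration studies below affordable.

Defaults were chosen once to reproduce the magnitudes a 3-week chamber
experiment shows — about 15 leaves on day 21, a leaf-7 area near 1 cm²,
total rosette area ~11 cm²: mu = 3.5 g MJ⁻¹, s = 50 cm², k = 0.9,
e = 0.002 g cm⁻², q0 = 20 µg (a typical seed), mu1 = 8.0, sigma1 = 0.6,
mu2 = 8.5, sigma2 = 0.8 (modes ≈ 2100 and 2600 °C·h ≈ 4.6 and 5.7 days
of thermal age), rho = 1.2. (mu, s, k) and the appearance times of
leaves 1–5 are treated as fixed, known inputs and are not estimated.

## Calibration

Observations are (hour, rank, area) records with arbitrary missingness,
flattened row-major by (rank, hour); missing entries are dropped, not
imputed. The error model is multiplicative, y = f(theta)(1 + eps), so
the estimator alternates (i) freezing weights w_i = 1/f_i(theta_prev)²
and (ii) bounded trust-region nonlinear least squares on
sum w_i (y_i − f_i(theta))², until the largest relative parameter
change falls below 1e-6 or 50 outer rounds pass (non-convergence is
flagged, last iterate returned). The estimated subset is
(phi, e, mu1, sigma1, mu2, sigma2, rho, q0); strictly positive
components are optimised in log space, sigma_i bounded in [0.01, 5],
rho in [0.1, 10]. Model predictions for ranks the parameter set never
produces return a tiny positive area so weights stay finite. Standard
errors come from the Gauss–Newton approximation (Jᵀ W J)⁻¹ sigmâ²
with a forward-difference Jacobian in natural space; a singular
information matrix yields NaN errors with a warning. A seeded
multi-start (default 5, first start at the supplied init, the rest
log-normally jittered, best objective wins) guards against local
minima; the recovery studies run single-start from a deterministically
perturbed init because they probe local identifiability, not global
search.

Fit quality: modeling efficiency `1 − SSE/SST`, accuracy
`mean |ŷ/y|`, and NRMSE = RMSE / mean(y) (mean-normalisation;
range-normalisation available via a flag). The genotype confusion
matrix puts NRMSE(simulation with genotype i's estimate, data of
genotype j) at entry (i, j), restricted to the (hour, rank) index
common to all datasets; discrimination holds when every row's minimum
is on the diagonal.

## Synthetic scenes and what they show

The renderer emulates post-preprocessing platform images: a black
background; leaves as filled ellipses (aspect ratio 0.6) whose blades
sit beyond thin petioles (petiole length 0.3 of blade length) attached
to a small central stem disk — blade-only geometry was tried and
rejected because every blade tip then meets at the center and merges
all leaves into one EDT basin, unlike real rosettes. Cotyledons are
opposite, the true-leaf pair perpendicular to them, ranks ≥ 5 one
golden angle apart (per-leaf Gaussian placement jitter, default sd 5°),
and the whole rosette rotates day to day (Gaussian, default sd 3°,
optional hard truncation). Per-leaf areas follow logistic curves with
later leaves larger and steeper; per-leaf color jitter gives the edge
detector gradients. Truth consists of per-day label masks, so recorded
areas are pixel-exact, and overlap is reported per day (pixels where
one leaf occludes another away from the insertion zone). Occlusion is
resolved young-over-old.

Trajectory datasets for calibration sample the growth model daily and
apply multiplicative Gaussian noise (default CV 2%) and independent
missingness; all randomness flows from one seeded generator.

What passing these suites shows: the segmentation recovers exact leaf
counts and ≤5% areas when leaves do not overlap; the refinement splits
moderately overlapping pairs; the tracker keeps ≥95% of rank
assignments correct under bounded pot rotation; and the estimator
recovers all eight parameters to well under 10% median error from 2%
noise. What it does not show: performance on real texture (venation,
specular soil residue, color gradients), on leaves that deviate from
ellipses, under heavy mutual occlusion of similar-rank leaves, or under
structured (non-multiplicative) measurement error. The renderer's
geometry is deliberately simple; its value is exact ground truth, not
photorealism.

## Numerical choices

- Angle arithmetic is circular everywhere: wrapping to (−180, 180],
  circular means for conventions, inclusive direction windows.
- Demand normalisation divides entrywise by the column sum only after
  forming ratios bounded by 1, so denormally small demands cannot
  overflow.
- The sigmoid and GLS solvers are deterministic given inputs and seeds;
  the tracker and segmentation contain no randomness at all.
- Degenerate inputs fail loudly (empty masks, empty tracks, constant
  observation vectors in the efficiency) rather than returning
  placeholder values.
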