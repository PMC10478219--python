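# Methods

## The model

`cpim` simulates two-state gene networks in a growing bacterial colony
as an interacting particle system on an L x L square lattice.  Each
site is vacant (0), occupied by an undifferentiated cell (`*`, code 2),
or occupied by a differentiated cell in one of two expression states
(sigma = +1 or -1).  Two processes are coupled:

* **Contact-process demography.**  A vacant site with k occupied
  neighbours becomes undifferentiated with probability 1 - (1-b)^k per
  attempt (independent colonization attempts by each neighbour).  Any
  cell dies with probability d per attempt.  An undifferentiated cell
  that survives its death draw differentiates with probability g,
  choosing +1 or -1 with equal probability.  The all-vacant lattice is
  absorbing.
* **Ising/Metropolis state dynamics.**  Differentiated cells carry the
  interaction energy H = -J * sum over neighbouring pairs of
  sigma_i sigma_j, where only pairs of differentiated cells contribute;
  vacant and undifferentiated neighbours contribute zero (dilution, not
  exclusion).  A differentiated cell that survives its death draw
  attempts a spin flip, accepted with the Metropolis probability
  min(1, exp(-dH/T)), with k_B = 1 and T measured in units of |J|/k_B.
  J = +1 favours like neighbours (ferromagnetic), J = -1 unlike
  neighbours (anti-ferromagnetic).  T is the noise-to-coupling control
  parameter: cell-cell coupling is strong at small T and weak at
  large T.

Updates are asynchronous random sequential: one sweep performs L^2
single-site attempts at uniformly random sites.  Synchronous updating
would introduce checkerboard artifacts in the spin dynamics.  At a
differentiated site death is evaluated before the flip attempt (a dead
cell cannot flip); the ordering is invisible at the default
d = 1e-5 but is fixed for reproducibility.

Colony runs start from a single undifferentiated cell at the lattice
centre on an open-boundary lattice and can stop at a sweep budget or at
first contact with the lattice edge, whichever is requested.  A pure
Ising reference mode runs the same flip rule on a fully occupied
periodic lattice.

Default parameters: b = 0.03 and d = 1e-5 (the demographic regime used
for the colony experiments the model describes, a contact process with
reproductive number b/d >> 1), g = 0.1 (the differentiation rate is a
free parameter of the model; 0.1 keeps the undifferentiated rim thin
relative to the colony radius), von Neumann neighbourhood (the Moore /
next-nearest-neighbour variant is available and shifts the transition
to higher T).

The simulation kernel is a numba-compiled loop with incrementally
tracked occupancy, magnetization and energy (the energy identity
`delta_energy == H(after) - H(before)` and the kernel-vs-recomputed
Hamiltonian agreement are tested exactly).  Every run is a pure
function of (parameters, seed); the compiled kernel draws from a
dedicated generator seeded per run.

## Observables and finite-size scaling

M = sum of sigma over differentiated cells; m = M / n_occupied.  The
susceptibility per occupied site is
chi^N = <n_occ> (<m^2> - <|m|>^2) / T, the standard finite-lattice
|m| convention (sign symmetry drives <m> to 0 on long runs).
Temperature scans run independent seeded replicates per T.  Pure-Ising
scans start from the ordered state: below T_c a random start needs
O(L^2) sweeps of domain coarsening and contaminates chi with a
transient, while an ordered start relaxes quickly at every T.  Colony
scans begin measuring only after the colony covers 50% of the lattice
(configurable) plus a burn-in fraction of the remaining records, so
chi is not dominated by the small early colony.

Finite-size scaling extracts per-size peak height X_max^N and location
T_c^N by three-point quadratic interpolation around the chi grid
maximum, fits log-log slopes against L, and extrapolates T_c linearly
in 1/L (the leading finite-size correction).  With free boundaries the
peaks approach T_c from below.

## Spatial statistics

**Radial sACF.**  The spatial autocorrelation of the signed state
field (+1/-1 on differentiated sites, arbitrary mask) is the
overlap-normalized covariance at each lag, computed via FFT
cross-correlation of the mean-subtracted masked field (a brute-force
`method="direct"` oracle verifies the fast path exactly).  Lags are
binned by Euclidean distance with **bin width 0.5** by default, so the
first occupied bin beyond r = 0 contains exactly the axis-distance-1
lags: a perfect checkerboard then reports C = -1 there, matching the
anticorrelation semantics of the statistic.  C(0) = 1 by construction.

Two ensemble estimators are provided and differ deliberately:

* `radial_autocorrelation` + `average_acfs` — each pattern is
  mean-subtracted on its own, then curves are pair-count-weighted
  averaged.  This matches the colony-by-colony image workflow.
* `ensemble_radial_autocorrelation` — lag surfaces are pooled and the
  pooled mean is subtracted.  Per-pattern subtraction removes each
  snapshot's net magnetization from every lag; near criticality that
  depresses long-range correlations and inflates the fitted decay
  exponent (pure Ising at T_c: eta ~ 0.30 per-snapshot vs ~ 0.27
  pooled, exact value 0.25).  The critical-exponent pipelines therefore
  use the pooled estimator.

**Decay fits.**  The length constant b comes from nonlinear least
squares of y0 * exp(-r/b) + C (initialized from the tail mean, the
amplitude, and the 1/e crossing).  The critical form
C(r) = A exp(-r/B) / r^eta is fitted over r in [1, L/4] by default
(beyond that, boundary effects dominate); eta is bounded at 0 and
reported with its asymptotic standard error.

**Clusters.**  Same-state connected components are labelled per state
with scipy.ndimage (4-connectivity default, matching the lattice
adjacency; 8 available) and pooled across states.  The discrete
power-law exponent gamma is estimated two ways: (i) maximum likelihood
with the Hurwitz-zeta normalization, x_min chosen by minimizing the
Kolmogorov-Smirnov distance among cutoffs that retain at least 5% of
the sample — an unrestricted cutoff search can always find a locally
straight stretch deep in a light-tailed distribution, which is exactly
the misspecification the KS flag is meant to catch; the fit is flagged
implausible when KS > 1.6/sqrt(n_tail); (ii) least squares on the
log-binned density, as a cross-check.  On 10^5 Zipf draws the MLE bias
is below 2% for gamma in {1.8, 2.0, 2.5}.

## Pattern comparison

Binary patterns are compared by the normalized Hamming distance
(fraction of differing pixels).  Patterns are first rescaled to a
common shape by nearest-neighbour resampling, then one pattern is
rotated about its centre in 15-degree steps (24 orientations,
nearest-neighbour interpolation, background fill 0, exact array
rotations at multiples of 90) and the minimum distance over
orientations is reported, since a simulated population has no
preferred orientation relative to an observed colony.

## Dose-response model

Each dual-input promoter is a two-state (ON/OFF) thermodynamic system;
the equilibrium active-state probability is

P_on(L) = ( 1 + [ (1 + L/Kd_off) / (1 + L/Kd_on) ]^n * e^(-n beta dE) )^-1

with dE = E_off - E_on.  beta and dE are not separately identifiable,
so the compound n*beta*dE is fitted as one parameter; concentrations
are handled in log10 space; the Hill exponent can be fixed (default
n = 1) or fitted.  Fits are weighted by 1/SD^2 when replicate SDs are
present; a Kd whose CI spans more than three decades is flagged
non-identifiable.  P_on is monotone increasing in L when
Kd_on < Kd_off, decreasing when reversed.  At a 12-point, 3-decade
design with 3% noise, the energy gap is recovered within a few percent
but Kd_off — which only shapes the upper plateau — is identified only
to within a factor of ~3; this is a property of the design, not the
optimizer, and is reflected in the test tolerances.

The synthetic generator emulates a bistable toggle read out through
mutually exclusive reporters: RFP = P_on, GFP = 1 - P_on, Gaussian
replicate noise clipped at zero, per-channel max normalization.  The
channels cross where P_on = 1/2 (near 1e-8 M for the default
ferromagnetic scenario).

## Synthetic pattern fixtures

`make_fixture` generates deterministic stand-ins for colony images:
checkerboard, iid random field, stripes, two-domain split, disk mosaic
and sectored colony.  The disk mosaic thresholds a Gaussian-smoothed
noise field at its in-disk median; the smoothing width is 0.66 x the
requested domain scale, calibrated (via the arcsine law for the sign
of a Gaussian field, then verified empirically) so the exponential
length constant fitted to the mosaic's sACF equals the requested scale.
The sectored colony draws random angular wedge boundaries; its domains
scale with colony radius, so its fitted length constant grows with
radius — a deliberate contrast to the fixed-scale mosaic.  These
fixtures exercise the analysis stack with known ground truth; they do
not emulate microscope noise, uneven illumination or segmentation
artifacts, so passing tests validate the statistics, not image
preprocessing.

## Problem sizes and numerical choices

The standard characterization pipelines run at desk scale: critical
ensembles of 20 populations at L = 128 grown for 2000 sweeps (full
lattice cover; edge-stopped colonies are still too young for mature
critical correlations), pure-Ising reference snapshots at L = 128
from 32 independent runs equilibrated 8000 sweeps from random starts
(one snapshot per run — each run's net magnetization adds a long-range
offset to the pooled correlation, and only independent runs average
that sampling fluctuation down; the fitted exponent's ensemble-to-
ensemble spread is ~0.03 at 20 runs),
finite-size scans at L in {16, 32, 64} with budgets 4000/6000/10000
sweeps, and birth-rate comparisons at L = 201 for 1500 sweeps (chosen
so the faster b = 0.0255 colony stays below ~60% cover and clear of
the boundary).  Fit tolerances, initializations and degenerate-input
behaviour (constant fields, empty tails, non-convergent fits) are
specified per function and exercised in the test suite.

## Known limitations

* The colony ensemble at L = 128 is a scaled-down version of larger
  published grids; its fitted eta carries a finite-size/finite-age
  exponential cutoff (B ~ 30-50 lattice units) absorbed by the fit's
  exp(-r/B) factor.
* Metropolis dynamics at T_c suffers critical slowing; the pure-Ising
  snapshot protocol buys equilibrium at the fitted scales (r <= 32)
  rather than global equilibrium at r ~ L.
* No external-field term, no explicit signal transport, and no
  off-lattice cell mechanics: patterns produced by rod-shaped cell
  buckling are outside the model by construction.
* In growing colonies the fitted sACF length constant is not a pure
  material property: it tracks colony age and radius (domain
  boundaries between sectors keep coarsening and wandering as the
  colony grows).  Colonies grown for an equal sweep budget at
  different birth rates therefore differ modestly (~25%) in length
  constant simply because they differ in size, even though the
  cluster-size exponent is insensitive to the birth rate; comparisons
  of domain scale across growth conditions should control for colony
  size or age.
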