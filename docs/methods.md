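# Methods

## Model

Every neuron is a three-variable Hindmarsh–Rose oscillator: fast membrane
variable `x`, recovery `y`, slow adaptation `z`. The fast equation is
divided by a capacitance-like factor `C`, which rescales the neuron's
intrinsic time scale without touching the slow subsystem; `C < 1` makes a
neuron faster than the reference cell. With the standard constants
(a = 1, b = 3, c = 1, d = 5, s = 4, r = 0.005, x_st = −1.6, J₀ = 3.25,
C = 1) the isolated neuron is a chaotic burster: groups of spikes whose
intra-burst ISIs first shrink and then grow, separated by silent gaps of
roughly 80 time units.

Coupling is diffusive and unidirectional: a directed edge (pre → post,
strength k) adds `k (x_pre − x_post)` to the post-neuron's fast equation.
The basic chain is master (C = 1) → n intermediaries → slave (C = 0.7),
capacitances equispaced in the open interval (0.7, 1) using n + 1 equal
steps so neither endpoint is duplicated, all couplings 1.7. The strictly
decreasing capacitances make every driven neuron slightly faster than its
driver, which is the precondition for the slave anticipating the master.

The convergent neuron X is an ordinary HR cell with its own applied
current `J0X` and capacitance `C_X`, receiving two feed-forward diffusive
inputs: `k_MX (x_m − x_X)` from the master (excitatory, k_MX > 0) and
`k_SX (x_s − x_X)` from the slave (inhibitory, k_SX < 0). X never feeds
back — the master/slave dynamics are rigorously independent of X, which
the tests assert by comparing runs with and without X. The "no
anticipation" control swaps k_MX and k_SX, feeding X the same two signals
with their roles exchanged. The same diffusive form is used for X's
afferents as for the chain; this is a modelling choice (the chain coupling
is the only form defined by the network equations).

## Numerical protocol

Integration starts from exactly zero initial conditions and uses an
adaptive explicit Runge–Kutta 4(5) pair (Dormand–Prince) at relative and
absolute tolerance 1e-10. The first 300 time units are discarded as a
transient; the remaining window of length T (default 5 × 10⁴) is sampled
from the solver's quartic dense-output interpolant on a uniform grid of
step 0.01. Output sampling does not constrain the adaptive internal steps.

The default backend is a nopython-compiled Dormand–Prince loop with the
same tableau, error norm (RMS of the scaled embedded-error estimate),
step-size controller (safety 0.9, factors in [0.2, 10]) and dense-output
polynomial as `scipy.integrate.solve_ivp`'s RK45. At tolerance 1e-10 a
full-length chain run takes a few million accepted steps; the compiled
loop finishes in seconds where the interpreted driver needs minutes. The
scipy backend is retained verbatim and the test suite cross-checks the two
on short horizons (they agree to ~1e-7 before chaotic amplification takes
over), plus a fixed-step RK4 mode as a second cross-check. Solver failure
(step-size underflow or a non-finite state) raises an error naming the
divergence time rather than returning partial data.

Chaos makes pointwise trajectories irreproducible across platforms: two
correct solvers at tolerance 1e-10 diverge to O(1) differences within a
few hundred time units (local errors ~1e-7 amplified at the positive
Lyapunov rate). Consequently every trajectory-level claim in the tests is
statistical or bound-based — spike counts, medians, cluster means — and
those statistics are stable: runs at tolerance 1e-6 and 1e-10, and the
compiled versus scipy backends, agree on spike counts within a few percent
and on anticipation-band medians within ~0.005 time units.

## Spike analysis conventions

Spike times are strict local maxima of `x` above a threshold, default 0
(HR spikes peak near +2, subthreshold oscillation near −1). A parabola
through the three samples around each grid maximum refines the time below
the 0.01 grid — necessary because the smallest anticipations (~0.03–0.05)
span only a few output samples. Maxima on the first or last sample are
excluded.

Anticipation is `t_master − t_slave` for the slave spike nearest each
master spike (positive when the slave leads). If two master spikes claim
the same slave spike the closer pair wins and the other master spike is
dropped; an equidistant tie goes to the earlier slave spike (favouring
anticipation, the phenomenon under study). Each matched record carries the
slave spike's *preceding* ISI; under this convention the largest-ISI
spikes are exactly the ones that open a burst after a silent gap, which is
what the cluster analysis relies on.

Burst segmentation starts a new burst at every spike whose preceding ISI
exceeds a threshold. The automatic threshold is the geometric mean of the
two centers of an exact 2-means split of the log-ISIs (1-D 2-means is
solved exactly by scanning the sorted split points). If the two centers
lie within a factor 2 of each other the ISI distribution is treated as
unimodal — one burst, flagged degenerate — rather than inventing a split.

The ISI–anticipation structure is summarized by binning the (preceding
ISI, anticipation) pairs on a 40 × 40 histogram over the observed range
and taking connected components (8-connectivity) of the occupied cells as
clusters. Components holding fewer than max(5, 1% of pairs) spikes are
isolated strays and are dropped by `principal_clusters`; the remaining
summaries are ordered by mean ISI, so the first row is the fastest
intra-burst group and the last row the burst-initiating group. The grid
size is an artifact choice; 30–60 bins give the same principal clusters on
the chain runs.

Anticipation enhancement between two chain runs is reported as the ratio
of a chosen statistic of the two anticipation tables. The default
statistic is the maximum — the peak anticipation, the "up to" reading of
enhancement. Medians compare typical spikes instead and give a smaller
ratio (~2.3 for n = 3 over n = 0) because direct coupling anticipates all
spikes nearly equally while the chain spreads anticipation over
[~0.03, ~0.76].

## Firing-regime classification

The regime label is a coarse operational classifier (the regimes it names
are conventionally identified by eye):

- fewer than 10 spikes → `insufficient-activity`;
- a single burst, a degenerate segmentation, or ISI coefficient of
  variation below 0.5 → `tonic`;
- at least two bursts averaging ≥ 3 spikes with median intra-burst ISI
  below 0.15 × the median inter-burst gap → `fast-spiking-in-slow-bursts`;
- otherwise → `phasic-bursting`.

The intra-burst ISI is compared against the inter-burst *gap*, not the
overall median ISI: for any train whose bursts hold several spikes the
overall median ISI is itself an intra-burst ISI, so a ratio against it
cannot detect fast spiking inside slow bursts. The thresholds were fixed
by inspecting the five X-network presets (intra/gap ratios 0.08–0.09 for
the fast-spiking-type runs against 0.22 for phasic bursting; CV 0.37 for
the tonic control against 0.80–1.59 elsewhere) and the classifier exposes
them as keyword arguments for sensitivity analysis. The mean-burst-size
guard keeps trains of isolated spikes or doublets, whose intra/gap ratio
is small for the wrong reason, out of the fast-spiking label.

## Plasticity rule

The slave→X synapse is updated per matched spike pair, in master-spike
order. The temporal window of half-width `w` is centred on the master
event: the pair potentiates iff `0 ≤ anticipation ≤ w` (closed
boundaries), i.e. the slave-origin spike arrives first and within the
window. Everything else depresses under the default `depress-outside`
variant; the `ignore-outside` variant leaves pairs with anticipation > w
untouched (and is kept only for sensitivity analysis — with all chain
anticipations positive it can never produce net depression). Updates are
amplitude-constant: +r_i on potentiation, −r_d on depression (defaults
r_i = 0.02, r_d = r_i/7), clipped below at a floor (default 0). The weight
tracked is the non-negative magnitude g(t) with g(0) = |k_SX|;
"potentiation" strengthens the inhibitory synapse's magnitude.

The trace is computed offline from the master–slave anticipation table
rather than by mutating the coupling during integration. Because X
receives strictly feed-forward input, the master and slave spike
sequences — and hence the event sequence and the trace — are identical
either way; X's own activity under a time-varying weight is out of scope.

Whether a window yields net growth or decay reduces to exact bookkeeping:
final = g0 + r_i·N_pot − r_d·N_dep while the floor is never hit, so the
net change is positive iff the potentiating fraction exceeds
r_d/(r_i + r_d) = 1/8. On the three-intermediary chain the measured
fraction of anticipations ≤ 0.3 is ≈ 0.17 — above the breakeven — so the
w = 0.3 window still produces slow net growth rather than decay; w = 0.5
captures the bulk cluster and grows strongly. The net change is
monotonically non-decreasing in w whenever all anticipations are
non-negative (enlarging a closed window only converts depressions to
potentiations), which holds for every chain run observed.

## Synthetic generators

The fixtures emulate only the structural features the analysis operators
consume: bursts of short-ISI spikes separated by long gaps (default intra
ISIs 12–20, gap 80, matching the scales of the chaotic dynamics), a slave
train built by shifting each master spike earlier by a step function of
its preceding ISI, and sampled traces made of one Gaussian bump per spike
(σ = 0.1, peak 2, baseline −1) so the detector can be tested against exact
ground truth. They are pure functions of their parameters and seed; jitter
is uniform with stated half-width. They make no attempt to reproduce the
chaotic ISI distributions, amplitude fluctuations, or master–slave phase
dynamics, so fixture-based tests validate the *operators*, not the
dynamics — the dynamical claims are tested on actual network runs.

Two structural constraints matter when composing fixtures: trace bumps
must not overlap (every ISI > 6σ), and a prescribed anticipation is only
recoverable by nearest-spike matching if every ISI exceeds twice the
anticipation imposed on it.

## Problem sizes and defaults

| quantity | default | note |
|---|---|---|
| T (analysis window) | 5 × 10⁴ | all headline statistics; ~1.5 k slave spikes |
| transient | 300 | discarded before sampling |
| output step | 0.01 | dense-output sampling, not the solver step |
| tolerances | 1e-10 | robustness checked against 1e-6 |
| chain | C_m = 1, C_s = 0.7, k = 1.7 | capacitances equispaced in (0.7, 1) |
| spike threshold | x > 0 | configurable |
| cluster grid | 40 × 40 | principal clusters ≥ max(5, 1% of pairs) |
| plasticity | r_i = 0.02, r_d = r_i/7 | windows w ∈ {0.3, 0.4, 0.5} |

Full-length runs are cheap enough (seconds per run with the compiled
backend) that the tests and the acceptance script use T = 5 × 10⁴
throughout; the tolerance-robustness comparison uses a 5 × 10³ window.

## Known limitations

- No synaptic or axonal transmission delays, no chemical-synapse models,
  no stochastic input currents: couplings are instantaneous, diffusive and
  deterministic.
- The regime classifier is a threshold rule calibrated on the five preset
  runs; it is not a general-purpose burst taxonomy.
- The plasticity trace assumes strictly feed-forward X coupling; with
  feedback from X the offline-equivalence argument breaks down.
- Pointwise trajectory values are platform-dependent (chaos); only
  statistics are comparable between machines.
- The 2-means burst threshold assumes a bimodal ISI distribution; heavily
  overlapping intra/inter ISI scales fall back to a single flagged burst.
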