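# Methods

## Model

Each of N neurons is a conditionally Poisson (nonlinear Hawkes / spiking
GLM) unit: in a window dt it fires with probability lambda_i(t) dt, where

    lambda_i(t) = lambda0 * phi( mu_i + sum_j integral J_ij(t - t') dn_j(t') ),
    J_ij(t) = J_ij g_j(t),  integral_0^inf g = 1.

Assumptions inherited by everything downstream: tonic drives mu_i are
constant (no time-dependent external input), interactions factor into a
scalar weight times a normalized causal waveform, self-couplings stand for
intrinsic history effects (refractoriness/burstiness), and the network is
studied in its stationary state.  Time is measured in units of 1/lambda0,
so weights are dimensionless numbers of "integrated input per spike".

Supported waveforms: alpha function `a^2 t e^{-at}`, single exponential
`b e^{-bt}`, and a formal delta kernel used only for zero-frequency
analyses.  Supported nonlinearities: exponential (the canonical GLM choice;
gain equals rate), rectified linear (derivative is a step, which kills
higher-order fluctuation corrections — used for the worked circuits), and
the bounded sigmoid `c/(1+e^{-x})` (used to stabilize ensembles whose
unbounded mean field can diverge).

## From hidden neurons to effective interactions

Recorded neurons are described by conditioning on their own spikes and
averaging the hidden input.  At mean-field level the hidden subnetwork,
*with the recorded neurons removed*, settles to rates nu_h solving

    nu_h = lambda0 phi(mu_h + sum_h' J_hh' nu_h'),   gamma_h = lambda0 phi'(same argument).

The package solves this by damped fixed-point iteration
`nu <- (1-eta) nu + eta lambda0 phi(mu + J_HH nu)` with eta = 0.5,
tolerance 1e-10 on the sup-norm residual, at most 10,000 iterations and a
divergence cap of 1e6 lambda0, initialized at the zero-coupling rates
lambda0 phi(mu_h).  Damping suppresses the period-2 oscillations of plain
iteration near strong negative feedback.  Multiple fixed points are not
searched for; the state reached from this initialization is the one
reported.  Divergence raises a catchable error carrying the residual trace,
so ensemble pipelines skip-and-count unstable draws (relevant under Dale's
law with an unbounded nonlinearity; with the bounded sigmoid rates can
never exceed lambda0 * ceiling and the solver cannot diverge).

Linearizing around this state gives the hidden linear response in the
frequency domain (`fhat(w) = int dt e^{-iwt} f(t)`):

    Gammahat(w) = [I - Vhat(w)]^{-1} diag(gamma),  Vhat_hh'(w) = gamma_h Jhat_hh'(w),

computed by a dense per-frequency LU solve (never an explicit inverse); a
singular system raises an error naming the frequency.  The effective model
of the recorded subnetwork is then

    mu_r^eff = mu_r + sum_h J_rh nu_h,
    Jhat_eff(w) = Jhat_RR(w) + Jhat_RH(w) Gammahat(w) Jhat_HR(w).

Neglected relative to the full conditional average: fluctuations of hidden
input around its conditional mean (zero at mean-field order; they would
appear as effective noise, not as changes to these filters) and
second-and-higher-order spike filtering of recorded activity.

### Path expansion

When the spectral radius of Vhat is below one, the resolvent expands as a
Neumann series whose terms are directed paths through hidden neurons.
Factoring repeated visits to a node into `gamma_h/(1 - gamma_h Jhat_hh(w))`
leaves paths with no immediate self-repeats.  The truncated series at paths
of at most L hidden nodes is evaluated as the matrix partial sum
`sum_{l<L} (D V_off)^l D diag(gamma)` with `D = [I - diag(V)]^{-1}` — this
equals the sum over all enumerated path contributions exactly, and is what
the equivalence tests compare against the LU route.  Explicit depth-first
enumeration (for interpretation and CSV export) is capped at 1e6 paths with
an explicit truncation flag; the spectral radius (the sharp convergence
criterion among matrix norms) is reported, with closed-form margins for the
one-hidden-neuron (`1 - gamma J_self`) and two-neuron-loop (loop gain)
topologies.

## Transforms and grids

Inverse transforms use the exact Riemann sum with the frequency step,
`f(t_k) = (1/2pi) sum_w e^{i w t_k} fhat(w) dw`, realized as an inverse DFT
divided by the time step.  Consequences and choices:

* With an unoversampled grid the zero-frequency value equals dt times the
  time-bin sum identically, so the effective weights (computed by one exact
  real solve at w = 0) match the time integral of the filters to machine
  precision.
* Sampling a continuous transform on a finite grid truncates the 1/w^2
  kernel tails; the error concentrates in the first time bins.  The grid
  supports frequency oversampling (denser and wider omega grid conjugate to
  dt/oversample, keeping every oversample-th time bin), which shrinks that
  error proportionally.  Effective-filter corrections decay like 1/w^4
  (products of two kernel transforms), so the circuit comparisons reach
  1e-3 of peak with dt = 0.002 and no oversampling.
* The Nyquist bin of an even grid has no negative partner; it is forced
  real in the inverse transform (Hermitian completion), and excluded from
  the Hermitian-symmetry defect diagnostic.  Non-Hermitian inputs beyond
  1e-9 of scale trigger a warning and symmetrization.
* Default pipeline grid: dt = 0.1/(fastest kernel rate), 4096 bins.
  Wrap-around/truncation leakage is reported as the relative filter
  amplitude in the last 5% of the window, not silently clipped.

## Worked circuits

Two fixtures reproduce classic motifs with rectified-linear units (gain =
lambda0 exactly), recorded = {1, 2}:

* 3-neuron feedforward inhibition: J21 = 1, J23 = -2, J31 = 2, J33 = -0.9;
  alpha kernels with rates 1.0 (2<-1, 2<-3), 1.8 (3<-1); exponential
  self-history with rate 1.0.  Requires 1 - lambda0 J33 > 0.
* 4-neuron degenerate variant: the refractory loop replaced by a second
  inhibitory neuron (J34 = J43 = -0.9, all alpha kernels with rate 1.294;
  J21 = J31 = J41 = 1, J23 = -3).  Requires |J34 J43| < 1.  Its loop
  resummation generates decay and oscillation rates
  a (1 ± (J34 J43)^{1/4}) absent from every true kernel.

Closed forms are obtained by exact partial fractions of the rational
frequency-domain path expressions over their analytically known poles
(numerator Taylor shifts and binomial series — stable for the
sixth-order repeated poles where numerical root-finding fails), giving
analytic time-domain oracles fully independent of the FFT pipeline.  The
hidden baselines are not fixed by the motif; they default to 0.95 (hidden
rates 0.5) and, because the rectified-linear gain is flat, the effective
interactions are provably independent of them as long as the fixed-point
argument stays positive — asserted in tests.

## Random ensembles and deviation statistics

Generators draw sparse networks (sparsity p, nonzero weights Normal with
std J0/(pN)^a, zero diagonal): Erdos-Renyi with mixed synapses, Erdos-Renyi
with Dale's law (E/I labels i.i.d. with probability 1/2; half-normal
magnitudes signed by the presynaptic label, so the overall weight law
matches the mixed case up to sign assignment), and Watts-Strogatz
small-world topology (networkx ring-rewiring; each undirected edge becomes
two directed edges with independent weights).  Defaults follow the
large-network study conditions: N = 1000, p = 0.2, J0 in {0.25..1.0},
mu0 = -1, lambda0 = 1, exponential nonlinearity, alpha kernels with rate 10.
At a = 1/2 the overall weight variance J0^2/N is p-independent.

The deviation pipeline measures, per (network, subset) draw, the
off-diagonal sample statistics of J_eff - J (diagonals excluded: true
self-couplings are pinned at zero and have different statistics; sample
variance uses the n-1 denominator for n = Nrec(Nrec-1) entries), normalizes
by the off-diagonal sample sd of the true weights, and averages in two
levels: over random subsets within a network draw, then over independent
draws; the quoted error is the across-subset standard error averaged across
draws.  Recorded subsets are uniform (seeded permutation, last Nrec
indices).  Analytic companions: the length-3 strong-coupling prediction
for the sd ratio and the fourth-order variance-ratio series at finite N for
either scaling (reducing to `1 + x^2 (1-f) + 3 x^4 (1-f)^2`,
x = lambda0 J0 e^{mu0}, as N grows at a = 1/2).

## Simulator

Bernoulli thinning per bin: spike probability min(lambda dt, 1).  Synaptic
convolutions use exact recursive state-space updates of the kernel impulse
responses (one state per presynaptic neuron for exponentials, two for alpha
kernels, propagated by the analytic matrix exponential each bin), so a
spike in bin k contributes exactly J g(m dt) to bin k+m — no history
truncation, O(N) state.  Rates use the states before the bin's spikes are
injected (strict causality).  Delta kernels are rejected.  A warning fires
if max lambda dt exceeds 0.2; fifty consecutive saturated bins raise an
error carrying the onset time.  Burn-in defaults to 10% of the duration.

## What the synthetic studies do and do not show

All experiments are synthetic and parameterized from the model itself;
there is no measurement noise, no inference step, and "measured" effective
interactions are the theory's own output.  Passing tests therefore validate
the internal consistency of the theory (mean field <-> simulation,
path series <-> matrix inversion, analytic <-> Monte-Carlo ensembles) and
its structural claims, not the fidelity of any inference procedure on real
spike data.  Real recordings add estimation error and model mismatch on top
of the subsampling bias quantified here.

Problem sizes used by the test suite and acceptance script (chosen as
desk-scale study conditions): the headline ensemble runs 10 subsets x 3
networks at N = 1000, Nrec = 10; the analytic-vs-Monte-Carlo comparison 10
subsets x 3 networks per (J0, f) cell; the weak-coupling size scaling 8
subsets x 3 networks at N = 500 and 1000; the path-series equivalence 50
random hidden networks of up to 8 neurons at truncation length 20.

The simulator validation runs the full N = 200 strongly coupled ER network
(J0 = 0.5, duration 5000, dt = 0.01) against its mean-field rates, with
kernel rate alpha = 1/lambda0.  The kernel rate matters here for an
interesting reason: per-spike input transients scale with alpha
(integral g^2 = alpha/4 for the alpha family), and with the unbounded
exponential nonlinearity the sharp alpha = 10 kernel makes a small, strongly
coupled network metastable — runaway firing within the simulated window.
The mean-field rate prediction being validated is independent of kernel
shape (only time-integrated weights enter the fixed point), so the slower
kernel tests the same claim in the regime where the stationary state
exists.  The metastability itself is a real property of unbounded-
nonlinearity Hawkes networks, surfaced by the simulator's instability error.

## Known limitations

* Mean-field only: fluctuation (loop) corrections, effective noise
  correlations between recorded neurons, and higher-order (3+ neuron)
  effective interactions are out of scope.
* Stationary drives only; no time-dependent external input or
  nonstationary linear response.
* The hidden fixed point is assumed unique along the iteration path;
  bounded nonlinearities can in principle support chaotic mean-field
  dynamics that the solver would report as non-convergence.
* Path enumeration is exponential in path length and intended for small
  hidden sets; large networks should use the matrix route throughout.
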