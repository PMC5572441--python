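# Methods

## The memory and its baseline

The benchmark workload is the Willshaw/Palm binary associative memory:
`N` key–value pairs of fixed-weight binary vectors (`m`-dimensional keys
with `c` ones, `n`-dimensional values with `d` ones) stored by OR-ing outer
products into a binary matrix `M`, recalled by thresholding `xᵀM` at
`‖x‖₁`. Recall of a trained key never misses a stored bit; false positives
appear as `M` fills and their expected number per sample is approximated by

    α̃(N) = (n−d) · (1 − (1 − cd/mn)^N)^c .

This classic estimate treats the `c` relevant matrix entries of a column as
independent. They are not — a single stored sample can cover several of
them at once — and the bias is a few percent low at the benchmark sizes
(7% at m=112, n=128, N=735). `core.exact_false_positives` provides the
exact inclusion–exclusion value for i.i.d. fixed-weight data and is used as
the oracle in Monte-Carlo validation; the classic form is kept for the
capacity objective because the optimal-`N` argmax is insensitive to the
bias.

Benchmark scoring normalises against the *realised* ideal recall: `I_th`
and `ᾱ_th` are computed by running the binary memory itself on the same
trained matrix and dataset (false negatives zero by construction), not from
the expectation `α̃`. Only this convention makes a perfect substrate score
exactly `I_n = 1, ᾱ_n = 0, β̄_n = 0` on every individual dataset; the
expectation differs from the realised false-positive mean on any single
draw.

The information formula is evaluated through log-gamma generalised
binomials so that non-integer (expected) error counts are valid arguments;
integer arguments reduce to ordinary binomials to double precision.
`optimal_sample_count` scans integer `N` up to the point where `α̃` reaches
99% of saturation and returns the argmax, ties toward smaller `N`. The
objective is extremely flat near its maximum (the top five integers differ
by < 10⁻⁵ relative); the argmax under this convention lands within one
sample of the published workload sizes, which were presumably computed with
a slightly different floating-point path.

Pattern generation is balanced: each new row sets the `weight` least-used
columns with random tie-breaks, which keeps every prefix's column-sum
spread at one unless duplicate avoidance forces a perturbed choice. Two
independent RNG streams (keys, values) spawned from one seed make datasets
bit-reproducible. The random-matrix information baseline `I_rand`
(saturated-memory sanity check) is computed from the one-probability
`℘ = P(Binomial(m, c/2m) ≥ c_th)`; the error-count orientation
`ᾱ_rand = (n−d)·℘, β̄_rand = d·(1−℘)` follows the definition of `℘` as the
probability of a one (a configuration flag restores the transposed printed
form — numerically the information value is identical either way, the
formula being symmetric under the swap). The standard benchmark workloads
sit at `I_rand/I_th ≈ 0.07–0.10`; the runner warns above 5%.

## Spike coding

One sample per `T = 100 ms` window. A one-bit is a burst of `s` spikes at
`Δt = 2 ms` spacing (nominal per-synapse burst rate 500 /s) on each of the
bit's `ω` redundant channels, plus i.i.d. Gaussian jitter `σ_t = 2 ms` per
spike per channel; jittered times are clamped to ≥ 0 and re-sorted. The
jitter RNG is a dedicated stream, decoupled from data generation. Windows
are half-open `[kT, (k+1)T)`; a jittered or early output spike may cross a
boundary and is then counted in the neighbouring window — accepted as part
of the modelled noise. Decoding sets a bit when the `ω`-neuron population's
summed count reaches `ω`. The threshold is `count ≥ ω` (not strictly
greater): with `s = 1` a correct neuron emits exactly one spike per
presented bit, so a strict threshold could never be met in the burst-less
single-neuron mode.

## The reference substrate

The neuron is the standard conductance-based exponential-synapse LIF
("IfCondExp"; potentials mV, conductances nS, capacitance nF, times ms,
currents nA):

    c_m dv/dt = g_leak (v_rest − v) + g_e (e_exc − v) + i_offset
    τ_exc dg_e/dt = −g_e ,   spike arrival: g_e += w

Threshold checks and spike deliveries are synchronous on a grid of spacing
`dt`; inputs are delivered at `⌈t/dt⌉·dt`, never before their true time.
On crossing `v ≥ v_th` at a grid point the neuron spikes, resets to
`v_reset` and is clamped there for `τ_ref` (conductances keep evolving —
the common convention for this model; the reference description does not
fix it). Two integrators advance the state between grid points:

* `rkf45` — embedded Runge–Kutta–Fehlberg 4(5) with adaptive sub-steps,
  absolute error target `1e-3` per step (max of the membrane and
  conductance estimates), grid `dt = 0.1 ms`. Step-size control uses the
  standard 0.9·(tol/err)^(1/5) rule clamped to [0.2, 5]; a 1e-6 ms floor
  forces acceptance to guarantee progress. No root-finding for the exact
  crossing: thresholds are only inspected at grid times, as in the
  synchronous reference simulators this substrate mirrors.
* `euler` — one naive explicit step per grid interval (`dt` = 0.1 or
  1.0 ms), deliberately without exact-exponential conductance updates or
  other stabilisation, so the accuracy cost of coarse fixed-step
  integration is observable. The conductance is floored at zero (the
  explicit step overshoots for `dt > τ_exc`). A true non-finite state
  aborts with an error naming the step size; note that plain instability
  cannot reach it — the threshold reset catches the positive overshoot —
  so the guard fires only on non-finite inputs.

Neurons at exact rest with zero conductance and zero offset are skipped
(the state is a fixed point, so the shortcut is exact for both
integrators). The inner loops are numba-compiled; simulating the
(112, 128, 735) workload — 73.5 s of biological time, 128 neurons, ~2×10⁵
synaptic events — takes under ten seconds single-threaded.

Synaptic transmission delay is fixed at zero in the network description:
the network is a single feed-forward layer decoded over 100 ms windows,
insensitive to sub-millisecond delays. All neurons share one parameter
record. Hardware-emulation transforms (range clamping, 4-bit weight
quantisation) are available but never applied silently.

## Parameter selection

Each neuron must implement a spike-count threshold: zero output spikes for
0 and `s·ω·(c−1)` input spikes, firing for `s·ω·c` and `s·ω·(c+1)`. The
fractional spike count `q = n + p` smooths the integer count for
optimisation: `p = j⁻/(j⁺+j⁻)`, where `j⁺` is the minimal constant
excitatory offset current that increases the count and `j⁻` the minimal
inhibitory one that decreases it (for silent neurons: that pins the
membrane at or below rest for the whole window). Both are found by
bracketed binary search — doubling from 1e-4 nA to a 10 nA cap, bisection
to 1e-3 relative width — under the assumption that the count is monotone
in the offset; violations are detected and reported as warnings. The
perturbation current is a constant offset over the whole window, the
simplest waveform compatible with the whole-trace silence condition.
Tuning stimuli start 10 ms into the window so that jitter acts
symmetrically instead of being truncated at time zero (truncation
artificially synchronises spikes and overstates robustness).

The joint probability of meeting all count targets is approximated by a
Student-t surrogate, `Σ log f_t((q_i − ½ − target_i)/scale; ν)` with
`ν = 2`, `scale = ½` (heavy tails keep the objective informative when a
target is missed by whole spikes; one missing spike costs about two nats),
and maximised by Nelder–Mead over `(v_th, g_leak, w)` with out-of-bounds
penalties. The full pipeline `tune_threshold_parameters` adds three stages
around it, because the deterministic surrogate cannot see jitter
robustness: a coarse lattice screen keeps only parameter points that
realise every count deterministically (the weight axis scaled by the
stimulus spike count, so one lattice covers all burst/population modes);
the Nelder–Mead local optima are re-ranked by the joint *empirical*
probability of the targets under jittered trials; and the threshold
potential of the winner is fine-tuned on an empirical grid — an automated
version of the manual fine-tuning a practitioner would perform on the
empirical-probability report.

Two constraints of the search box are load-bearing. `v_th ≥ v_rest + 5 mV`
keeps the threshold out of the band of jitter-induced fluctuations, and
`g_leak ≥ 20 nS` caps the membrane time constant at `c_m/g_leak = 10 ms`:
the 100 ms presentation period guarantees recovery to rest between samples
only for membranes at least this fast, and slower ones carry residual
depolarisation into the next window (measured as an `ᾱ_n ≈ +0.25`
false-positive excess at `τ_m = 40 ms` — invisible to single-window
tuning trials, which is why the box enforces it).

For the shipped reference presets the per-neuron output target is one
spike per presented sample, which is exactly what `count ≥ ω` window
decoding requires of a deterministic software substrate (the `ω` neurons
of a population receive identical input here and act in unison). The
`s`-spike burst target remains the default of `threshold_objectives`; it
buys headroom against spike loss on real hardware but is substantially
harder to realise and unnecessary for the reference. The shipped presets
(`presets.REFERENCE_SETS`, regenerated by
`scripts/derive_reference_parameters.py`) meet every deterministic target
exactly and every jittered target with probability ≥ 0.99.

The published default parameter sets are retained verbatim as
`presets.PARAMETER_SETS`, but they do not implement the threshold
function under these dynamics: for set II the total synaptic charge of the
16 input spikes of the population mode bounds the depolarisation at
12.8 mV from rest — short of the 15.3 mV threshold distance for any leak
conductance and any integrator — and exact integration shows the same
shortfall for sets I and III in their modes. The reference benchmarks
therefore run on the re-derived sets.

## What the synthetic workloads do and do not show

All inputs are generated internally: balanced fixed-weight patterns,
deterministic spike schedules, Gaussian timing jitter. This captures the
stochasticity the benchmark is designed to measure (timing noise against a
threshold) but none of the failure modes of physical platforms —
spike loss under bandwidth pressure, parameter quantisation and mismatch,
analog crosstalk, trial-to-trial drift. Results on the built-in substrate
are therefore upper bounds: they show what the network description itself
supports, and external recordings scored through the same metrics
(`score_recall`, spike-CSV in) show how far a real platform falls short.
The balanced generator also technically violates the sample-independence
assumption behind the capacity formulas; the effect is negligible at the
benchmark sizes but visible in very small memories.

## Benchmark execution details

A run executes generate → train → build → encode → back-end → decode →
score. Execution time `t` is wall clock around the back-end call including
its setup/teardown; the efficiency measure is `E_eff = I_n·N/(P·t)` with
externally supplied power readings (power measurement itself is out of
scope). Repetitions average either over different data/jitter seeds (the
sweep convention) or over identical inputs (the convention for averaging
non-deterministic hardware). Independent networks with shared neuron
parameters can be multiplexed into one back-end call by index offsetting
and demultiplexed deterministically. One-dimensional sweeps vary a data
parameter and keep infeasible points as failed rows; the two-dimensional
sweep varies `(v_th, w)` per grid point (parameters differ per point, so
multiplexing does not apply there).

Problem sizes used by the automated checks: the acceptance script runs the
published workload sizes ((28, 32, 54) and (112, 128, 735)); the test
suite uses those plus scaled-down fixtures (e.g. 48×48, N = 140 for the
integrator-degradation comparison) chosen so the whole suite completes in
a few minutes single-threaded.

## Known limitations

* No inhibition, recurrence, auto-association or iterated recall; the
  model interface covers the conductance-based LIF only.
* The fractional spike count's monotonicity assumption can fail for exotic
  parameters; it is detected, warned about, and the binary search result
  is then only a bracket, not the minimal current.
* `rkf45` locates spikes on the 0.1 ms grid, not at the exact crossing;
  spike times carry up to one grid step of quantisation.
* No actual hardware adapters are included — only the black-box contract
  (network JSON plus spike CSV in, spike CSV out).
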