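# Methods

`evspike` is an event-driven simulator for networks of spiking neurons.
Nothing in it integrates a differential equation numerically: every state
trajectory used is available in closed form between events, so the engine
only ever needs to know *when* the next state-changing event occurs, and
the simulation is exact to floating-point precision. This note documents
the simulation kernel, the two neuron models, the validation machinery,
the synthetic inputs the experiments run on, and the numerical and design
choices made where more than one reasonable option existed.

## 1. The event-driven kernel

A network is a set of *elements* (neurons, synapses, spike responses,
clocks, recorders, modifiers) with enumerated input and output ports.
Three relations wire them together:

* **Event connections** `(src_id, src_port, dest_id, dest_port, delay)`
  route timestamped point events; `delay >= 0` in seconds, and zero is
  legal. All connections leaving one output port with the same delay form
  an *event target group* (ETG); an emission queues one event per ETG and
  its delivery is simultaneous at all the group's destinations.
* **Couplings** declare that one element holds a direct handle to
  another's state (e.g. a synapse writes into its neuron's input
  accumulator). The engine records couplings for introspection and
  validation dumps only; the calls themselves go through the handles.
* **Causal update links** `(src, dest, update_id)` declare that whenever
  `src` changes state, `dest` must update too. At `finalize()` each ETG
  precomputes its *update array*: the elements reachable from the group's
  destinations through links, in a topological order (Kahn's algorithm,
  recomputed from scratch per group; ties broken by element id so the
  order is deterministic), each tagged with the `update_id` of the first
  link through which it was reached. The directed link graph must be
  acyclic; a cycle is reported at `finalize()` with the name of a member.
  Elements that received the event directly (the group's destinations)
  are not re-updated by the array, even when another destination's links
  reach them.

Delivering an event therefore means: call every destination's event
handler, then walk the update array calling each element's update handler
— so a spike response recomputes its value first, then the synapses
coupled to it push weighted deltas, then the postsynaptic neurons
re-predict their next spikes, in dependency order, with no recursion.

**Scheduling.** Two binary heaps: one for scheduled events, one for
*pending* events. Each element owns at most one pending event — its
predicted next spike — and may cancel or reschedule it at any time.
Cancellation is lazy (O(1)): a per-element token invalidates old heap
entries, which are discarded when popped. Ties at equal timestamps are
broken first-in-first-out by a global sequence number, with scheduled
events taking precedence over pending events; zero-delay events are
enqueued rather than delivered re-entrantly, so handler code never
re-enters but causal order is preserved. A configurable guard (default
10^6 deliveries at one identical timestamp) converts silent zero-delay
livelock into an error. Emissions may carry future timestamps (never past
ones); this is how clock-style elements live inside the event-driven
loop: a clock is an ordinary element with a zero-delay self-connection
that re-emits `start + k*dt`, computed by multiplication so tick times
accumulate no floating-point drift. (A self-connection with delay `dt`
would drift by one rounding per tick and can land 1 ulp *after* the exact
multiplicative tick, which would turn the drift-free emission into a
causality violation — hence the zero-delay loopback.)

**Reproducibility.** One seeded NumPy `Generator` per network; all
stochastic elements draw from it in event-processing order, and all
tie-breaks are deterministic, so equal seeds plus equal construction
order give byte-identical spike output. Dynamic element creation during a
run is not supported; topology is frozen at `finalize()`.

## 2. Stochastic exponential-rate neuron (`ExpPoissonNeuron`)

When not refractory the neuron fires as an inhomogeneous Poisson process
with instantaneous rate

    rho(u) = C * exp(u),      u(t) = b + s(t),

where `b` is a bias and `s(t)` the synaptic accumulator maintained by the
synapses (all in arbitrary units; `C` in Hz). After each spike it is
silent for an absolute refractory period `t_ref`. Because the synaptic
responses are rectangular or piecewise linear, `u(t)` is piecewise linear
between network events, and the next spike time can be sampled *exactly*
by inverting the integrated hazard: with a unit-exponential draw `E` and
a current course `u(t) = u0 + m t`,

    m = 0:  dt = E / (C exp(u0))
    m != 0: dt = log1p(m E exp(-u0) / C) / m,

with no spike scheduled when the total remaining hazard is finite and
below `E` (decaying membrane). Whenever the membrane changes, the pending
spike is resampled from scratch with a fresh draw; by memorylessness of
the exponential this is exact — the previously drawn time is valid
conditional on the course not changing, and it is only ever delivered in
that case. Resampling (rather than hazard-rescaling the old draw) costs
one extra random number per membrane change and is far easier to audit.
A multi-segment inverter (`next_spike_time_piecewise_linear`) is provided
for offline use and validated against an independent Ogata-thinning
oracle. Membranes above 700 (where `exp` overflows double precision)
raise rather than wrap; `u = -inf` is the supported sentinel for a silent
neuron. Refractory bookkeeping reuses the single pending slot: it holds
either the predicted spike or the refractory-end event, never both, and
membrane changes during refractoriness defer resampling to refractory
end.

## 3. Event-based LIF neuron with voltage jumps (`LifJumpNeuron`)

Between inputs the membrane obeys

    u(t) = E_L + (u(t_last) - E_L) * exp(-(t - t_last)/tau_m),

stored lazily: state is exact at the last update, queries decay
analytically (the variable recorder uses this to sample the true membrane
at arbitrary instants). Each delivered input instantaneously jumps the
membrane by the synaptic weight (mV). If `E_L > V_thresh` the neuron
drifts across threshold by itself at the closed-form time
`tau_m * ln((E_L - u)/(E_L - V_thresh))`, kept as the cancellable pending
event and rescheduled after every jump; if `E_L <= V_thresh` and the
membrane is subthreshold, no pending event exists. Spikes reset the
membrane to `V_reset` and start an absolute refractory period `t_ref`.
Two refractory policies are provided: `"discard"` (default) clamps the
membrane at `V_reset` and drops arriving jumps, `"accumulate"` integrates
them silently with only spiking suppressed. Default parameters are the
standard sparse-network voltage-jump benchmark values: `E_L = -49 mV`,
`V_thresh = -50 mV`, `V_reset = -60 mV`, `tau_m = 20 ms`, `t_ref = 5 ms`,
jumps `+0.25 mV` (excitatory) and `-2.25 mV` (inhibitory). Because all
jumps within a weight class are equal, one `JumpSynapse` element per
(neuron, class) serves all afferents — memory per neuron stays constant
while routing tables grow with connectivity.

## 4. Spike responses and synapses

A *spike response* element tracks one presynaptic neuron's postsynaptic
kernel; all synapses from that neuron share it (valid because all its
outgoing connections use one common delay — the constructor enforces
this per `(presynaptic, delay)` key). The rectangular response holds
value `1` on the half-open interval `[t_spike, t_spike + tau)` with reset
dynamics; its end is signalled to itself over a recurrent event
connection of delay exactly `tau`, and ends belonging to superseded
pulses are recognised by a generation counter and ignored. The important
consequence: end events are scheduled once per *emitted* spike, not once
per delivered spike, which is what makes sharing profitable. Piecewise
kernels (constant or linear segments; reset or additive dynamics) emit
one future-timestamped breakpoint notification per kernel edge so coupled
neurons are updated exactly when the membrane's functional form changes;
in additive mode all active spikes superpose with no truncation (cost
grows with the number of simultaneously active spikes — fine for the
rates used here). Because breakpoint event times are computed as
`t_spike + edge` while queries compute `t - t_spike`, a query can land
within one rounding of an edge; kernel segment lookup nudges the query by
`1e-9 * support` so notifications and values always agree on which
segment is current. The static synapse pushes
`weight * (eps_now - eps_predicted)` value deltas (plus slope deltas for
piecewise-linear kernels) into its neuron's accumulator, so over any
window where the response starts and ends at zero its net contribution
telescopes to exactly zero.

Plasticity is a pluggable hook interface, deliberately rule-free: pattern
A feeds the synapse the postsynaptic spike times over an event connection
(`on_pre`/`on_post` callbacks), pattern B couples it additionally to the
postsynaptic neuron's own response and dispatches `on_trace_update` with
the update id that identifies which trace changed. The repository ships
only a trivial additive counting rule for tests; hooks may mutate only
the owning synapse's weight.

## 5. Sampling networks and validation

For a Boltzmann distribution over K binary variables,
`p(z) ∝ exp(sum_{i<j} w_ij z_i z_j + sum_i b_i z_i)` with symmetric `W`
and zero diagonal, the sampling network uses K neurons
`ExpPoissonNeuron(1/tau, b_k, tau)`, one shared rectangular response of
duration `tau` per neuron, zero synaptic delays, and two synapses of
weight `w_ij` per nonzero coupling. Then `u_k(t) = b_k + sum_i w_ki
z_i(t)` with `z_i(t) = 1` iff neuron i spiked in `(t - tau, t]`, and in
the stationary regime the network state is a continuous-time MCMC sample
from `p(z)`.

Validation machinery, all independent of the simulator code paths:

* `exact_distribution` enumerates all `2^K` states (capped at K = 20,
  about 8 MB of doubles; beyond that the Gibbs chain is the reference).
* `gibbs_chain` is a systematic-scan Gibbs sampler using the full
  conditionals `p(z_k = 1 | z_-k) = sigmoid(b_k + sum_i w_ki z_i)`
  (random scan available as an option).
* `states_from_spikes` reconstructs the piecewise-constant joint state by
  an exact boundary sweep over all on-interval edges and accumulates
  occupancy time per state; it rejects trains whose inter-spike intervals
  undercut `tau` (impossible for refractory neurons) and conserves total
  time to 1e-9 s.
* `kl_divergence` and `marginal` compare tables; `add_pseudomass` gives
  unobserved states `eps` mass (suggested `0.5 * resolution / T`) when an
  empirical table must appear in the second KL argument.
* `analytic_lif_membrane` re-derives the LIF trace by an independent
  sequential sweep over the merged jump/crossing/refractory timeline and
  is compared bit-for-bit against the recorded trace.

Statistical tolerances: distributional checks use three Monte-Carlo
standard errors, with the occupancy estimator's effective sample size
taken as `T / tau` (one roughly independent state per window) and the
Gibbs chain's as the post-burn-in sweep count; burn-in defaults to the
first 10 % of simulated time or sweeps.

## 6. Synthetic inputs: what the experiments run on

No external data is used; all inputs are generated:

* **Random Boltzmann models**: `b_i ~ N(-1.5, 0.5^2)`,
  `w_ij = w_ji ~ N(0, 0.3^2)` (full connectivity by default; Bernoulli(p)
  optional), biases mildly inhibitory so states are sparse but all
  reachable. The validation experiment uses K = 5, `tau` = 20 ms, zero
  delays, 500 s simulated.
* **Random LIF benchmark networks**: N neurons, 80 % excitatory,
  each ordered pair connected independently with probability p = 0.02,
  all delays 1 ms, neuron parameters as in section 3, initial membranes
  uniform on `[V_reset, V_thresh)`. The standard run is 1 s of biological
  time at N = 1000, with the N in {250, 500, 1000} family used for
  delivered-event scaling.
* **Poisson input trains** (LIF accuracy): one neuron driven by seeded
  homogeneous Poisson excitatory (800 Hz) and inhibitory (200 Hz) trains,
  membrane recorded at 5 kHz for 1 s.
* **Deterministic drive** (demo): a 1 kHz clock steps a modifier through
  `u(t) = 2 sin(t) - 1`, written into a `C = 50 Hz`, 1-ms-refractory
  stochastic neuron.

These generators emulate the network structures the simulator is designed
for, not biological recordings: weights are homogeneous or Gaussian,
delays are uniform, and inputs are stationary. Passing tests therefore
demonstrate algorithmic exactness and statistical correctness of the
machinery, not fidelity to any particular biological dataset.

## 7. Observed behaviour of the LIF benchmark network

With the defaults above, the N = 1000 network settles into an
inhibition-dominated state at a population mean rate of ≈ 15 Hz (1 s,
seed-dependent ± ~0.5 Hz), and the rate drifts slowly downward with
network size (≈ 18.6 Hz at N = 250, ≈ 12.6 Hz at N = 2000) as the
in-degree grows. This is structural, not incidental: the isolated-neuron
drift rate `1/(t_ref + tau_m ln((E_L - V_reset)/(E_L - V_thresh)))` =
18.9 Hz is an upper bound on the mean rate whenever the recurrent input
is net inhibitory, which it is here (0.8 * 0.25 < 0.2 * 2.25 per unit
rate). Delivered synaptic events match `r * p * N * (N - 1) * T` to
within a fraction of a percent, so simulation cost scales quadratically
with network size at fixed rate.

## 8. Known limitations

* Single-threaded, single-process; no distributed simulation, no
  dynamic topology changes during a run, no conductance-based or
  multi-compartment neuron models.
* Exactness of the stochastic neuron requires piecewise-linear membrane
  courses; smooth kernels must be approximated by piecewise segments
  (finer segmentation costs one breakpoint event per segment per spike).
* The pure-Python event loop processes on the order of 10^6 deliveries
  per second; the N = 1000 benchmark second simulates in about a second,
  and sampling validation runs are seconds, but the design favours
  auditability over raw throughput.
* Couplings are declared, not enforced: the registry cannot detect an
  element mutating state it never declared a coupling for.
* Plasticity rules themselves are out of scope; only the wiring patterns
  and hook interface are provided.
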