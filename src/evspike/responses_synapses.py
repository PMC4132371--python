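"""Spike-response elements, static synapses, and synapse wiring patterns.

A *spike response* element tracks a variable driven by a spike train and a
response kernel: each arriving spike triggers the kernel, which either
replaces the previous course (reset dynamics) or superposes on it
(additive dynamics).  Rectangular, piecewise-constant and piecewise-linear
kernels are provided; the latter two approximate arbitrary PSP shapes
(e.g. alpha functions) while keeping the membrane piecewise linear, which
is what makes exact next-spike sampling possible for the stochastic
neuron.

Synapses from the same presynaptic neuron *share* one response element
(all its outgoing connections must then use the same delay): the response
schedules its internal end-of-pulse / breakpoint events once per *emitted*
spike, not once per delivered spike, which is the efficiency argument for
this wiring.  Each synapse is coupled one-way to its response and to its
postsynaptic neuron; causal update links response -> synapse -> neuron
propagate every response change as a weighted membrane delta, and the
neuron then resamples its pending spike.

:func:`connect_with_synapse` performs the full wiring recipe; a
:class:`SynapseFactory` bundles the choices (kernel, dynamics, weight,
optional plasticity hook).  Two plastic-synapse wiring patterns are
scaffolded: pattern A feeds the synapse the postsynaptic spike times over
an event connection, pattern B couples it additionally to the
postsynaptic neuron's own response so the hook sees both traces and can
tell them apart by update id.  The plasticity rules themselves are
pluggable hooks; only a trivial additive test rule ships here.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from collections import deque
from dataclasses import dataclass, field

from .engine import Network, NetworkElement, SimulationError

__all__ = [
    "RectSpikeResponse",
    "PiecewiseKernel",
    "piecewise_constant_kernel",
    "piecewise_linear_kernel",
    "alpha_kernel",
    "PiecewiseResponse",
    "StaticSynapse",
    "SynapseFactory",
    "connect_with_synapse",
    "PlasticityHook",
    "AdditiveTestRule",
    "wire_plastic_pattern_A",
    "wire_plastic_pattern_B",
]


class RectSpikeResponse(NetworkElement):
    """Rectangular response with reset dynamics.

    The value is ``amplitude`` iff a spike arrived within the preceding
    ``tau`` seconds (half-open on-interval ``[t_spike, t_spike + tau)``); a
    new spike restarts the pulse.  The end of the pulse is signalled over a
    recurrent event connection from output port 0 back to input port 1
    with delay exactly ``tau``; ends belonging to superseded pulses are
    recognised as stale by a generation counter and ignored.

    Input ports: 0 = presynaptic spikes, 1 = end signal (loopback).
    """

    n_in_ports = 2
    n_out_ports = 1

    def __init__(self, tau: float, amplitude: float = 1.0):
        super().__init__()
        if tau <= 0:
            raise SimulationError(f"response duration tau must be > 0, got {tau}")
        self.tau = tau
        self.amplitude = amplitude
        self.value = 0.0
        self.generation = 0
        self._end_gens: deque[int] = deque()
        self.n_end_signals = 0
        self.register_field("value", "value")

    def wire(self, net: Network) -> None:
        net.connect(self.id, 0, self.id, 1, self.tau)

    def value_at(self, t: float) -> float:
        return self.value

    def slope_at(self, t: float) -> float:
        return 0.0

    def on_event(self, t: float, port: int) -> None:
        if port == 0:  # presynaptic spike: (re)start the pulse
            self.value = self.amplitude
            self.generation += 1
            self._end_gens.append(self.generation)
            self.n_end_signals += 1
            self.net.emit(self.id, 0, t)
        else:  # end signal; stale if the pulse was restarted meanwhile
            if self._end_gens and self._end_gens.popleft() == self.generation:
                self.value = 0.0


@dataclass(frozen=True)
class PiecewiseKernel:
    """Piecewise-linear kernel on ``[0, edges[-1])``, zero outside.

    ``edges[k] <= dt < edges[k+1]`` maps to
    ``intercepts[k] + slopes[k] * (dt - edges[k])``.  A piecewise-constant
    kernel is the special case of all-zero slopes.
    """

    edges: tuple  # len n+1, edges[0] == 0, strictly increasing
    intercepts: tuple  # len n, value at each segment start
    slopes: tuple  # len n

    def __post_init__(self):
        if len(self.edges) < 2 or self.edges[0] != 0.0:
            raise SimulationError("kernel edges must start at 0 with >= 1 segment")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise SimulationError("kernel edges must be strictly increasing")
        if len(self.intercepts) != len(self.edges) - 1 or \
                len(self.slopes) != len(self.edges) - 1:
            raise SimulationError("need one (intercept, slope) per segment")

    @property
    def support(self) -> float:
        return self.edges[-1]

    def _segment(self, dt: float) -> int:
        # events land within 1 ulp of edges; nudge queries onto the new
        # segment so value and breakpoint notifications agree
        return bisect_right(self.edges, dt + 1e-9 * self.support) - 1

    def eval(self, dt: float) -> float:
        if dt < 0.0 or dt >= self.support:
            return 0.0
        k = self._segment(dt)
        if k < 0 or k >= len(self.intercepts):
            return 0.0
        return self.intercepts[k] + self.slopes[k] * (dt - self.edges[k])

    def slope(self, dt: float) -> float:
        if dt < 0.0 or dt >= self.support:
            return 0.0
        k = self._segment(dt)
        if k < 0 or k >= len(self.slopes):
            return 0.0
        return self.slopes[k]


def piecewise_constant_kernel(edges, values) -> PiecewiseKernel:
    """Kernel that holds ``values[k]`` on ``[edges[k], edges[k+1])``."""
    return PiecewiseKernel(tuple(float(e) for e in edges),
                           tuple(float(v) for v in values),
                           (0.0,) * len(values))


def piecewise_linear_kernel(edges, node_values) -> PiecewiseKernel:
    """Continuous kernel interpolating ``node_values`` at ``edges``.

    ``node_values`` has one entry per edge; the last one is the value the
    kernel approaches at the end of its support (it drops to 0 there).
    """
    edges = tuple(float(e) for e in edges)
    vals = [float(v) for v in node_values]
    if len(vals) != len(edges):
        raise SimulationError("need one node value per edge")
    intercepts = tuple(vals[:-1])
    slopes = tuple(
        (vals[k + 1] - vals[k]) / (edges[k + 1] - edges[k])
        for k in range(len(edges) - 1)
    )
    return PiecewiseKernel(edges, intercepts, slopes)


def alpha_kernel(tau_alpha: float, n_segments: int = 10,
                 t_max: float | None = None) -> PiecewiseKernel:
    """Piecewise-linear approximation of the alpha shape
    ``(t/tau) * exp(1 - t/tau)`` (unit peak at ``t = tau``)."""
    if t_max is None:
        t_max = 5.0 * tau_alpha
    edges = [k * t_max / n_segments for k in range(n_segments + 1)]
    vals = [(t / tau_alpha) * math.exp(1.0 - t / tau_alpha) for t in edges]
    vals[-1] = 0.0 if vals[-1] < 1e-3 else vals[-1]
    return piecewise_linear_kernel(edges, vals)


class PiecewiseResponse(NetworkElement):
    """Spike response with a piecewise kernel, reset or additive dynamics.

    On each presynaptic spike the element emits, over a zero-delay
    loopback, one future-timestamped event per kernel breakpoint so that
    coupled synapses (and through them the neurons) are notified exactly
    when the response's functional form changes.  In additive mode all
    active spikes superpose; in reset mode only the latest spike
    contributes (breakpoint events of superseded spikes still arrive but
    recompute the same, already-correct value).

    Input ports: 0 = presynaptic spikes, 1 = breakpoint notifications.
    """

    n_in_ports = 2
    n_out_ports = 1

    def __init__(self, kernel: PiecewiseKernel, mode: str = "additive"):
        super().__init__()
        if mode not in ("reset", "additive"):
            raise SimulationError(f"mode must be 'reset' or 'additive', got {mode!r}")
        self.kernel = kernel
        self.mode = mode
        self._active: list[float] = []  # spike times still inside support
        self.n_end_signals = 0
        self.register_field("value", "value")

    def wire(self, net: Network) -> None:
        net.connect(self.id, 0, self.id, 1, 0.0)

    @property
    def value(self) -> float:
        t = self.net.current_time if self.net is not None else 0.0
        return self.value_at(t)

    def value_at(self, t: float) -> float:
        return sum(self.kernel.eval(t - s) for s in self._active)

    def slope_at(self, t: float) -> float:
        return sum(self.kernel.slope(t - s) for s in self._active)

    def on_event(self, t: float, port: int) -> None:
        if port == 0:  # presynaptic spike
            if self.mode == "reset":
                self._active = [t]
            else:
                self._active.append(t)
            for e in self.kernel.edges[1:]:
                self.n_end_signals += 1
                self.net.emit(self.id, 0, t + e)
        else:  # breakpoint notification: prune spikes past their support
            if len(self._active) > 4:
                sup = self.kernel.support
                self._active = [s for s in self._active if t - s < sup]


class StaticSynapse(NetworkElement):
    """Static synapse reading a shared response, pushing weighted deltas.

    On every causal update from its response element the synapse reads the
    response's current value and slope, computes the difference from the
    course it last communicated, and adds ``weight * delta`` (value and
    slope) to the postsynaptic neuron's synaptic accumulator.  Over any
    window where the response starts and ends at zero, the pushed deltas
    telescope to zero net contribution.

    Input port 0 receives postsynaptic spikes when the pattern-A plastic
    wiring is installed.
    """

    n_in_ports = 1
    n_out_ports = 0

    def __init__(self, weight: float, response_id: int, post_id: int,
                 hook: "PlasticityHook | None" = None):
        super().__init__()
        self.weight = weight
        self.response_id = response_id
        self.post_id = post_id
        self.hook = hook
        self._seen_value = 0.0
        self._seen_slope = 0.0
        self._seen_t = 0.0
        # pattern-B bookkeeping: update ids of pre/post responses
        self._pre_uid: int | None = None
        self._post_uid: int | None = None
        self._post_response_id: int | None = None
        self.register_field("weight", "weight")

    def on_update(self, update_id: int, t: float) -> None:
        if self._post_uid is not None and update_id == self._post_uid:
            self._hook_trace(update_id, t)
            return
        resp = self.net.elements[self.response_id]
        value = resp.value_at(t)
        slope = resp.slope_at(t)
        predicted = self._seen_value + self._seen_slope * (t - self._seen_t)
        dvalue = self.weight * (value - predicted)
        dslope = self.weight * (slope - self._seen_slope)
        self._seen_value = value
        self._seen_slope = slope
        self._seen_t = t
        if dvalue != 0.0 or dslope != 0.0:
            self.net.elements[self.post_id].add_input(t, dvalue, dslope)
        if self.hook is not None:
            if self._post_uid is not None:
                self._hook_trace(update_id, t)
            else:
                self.hook.on_pre(self, t)

    def _hook_trace(self, update_id: int, t: float) -> None:
        eps_pre = self.net.elements[self.response_id].value_at(t)
        eps_post = self.net.elements[self._post_response_id].value_at(t)
        self.hook.on_trace_update(self, update_id, eps_pre, eps_post, t)

    def on_event(self, t: float, port: int) -> None:
        # postsynaptic spike (pattern A wiring)
        if self.hook is None:
            raise SimulationError(
                f"synapse {self.id} received a postsynaptic spike but has "
                "no plasticity hook installed"
            )
        self.hook.on_post(self, t)


class PlasticityHook:
    """Interface for pluggable plasticity rules.

    Pattern A implements :meth:`on_pre` / :meth:`on_post` (spike-driven);
    pattern B implements :meth:`on_trace_update` (trace-driven).  Hooks may
    only mutate the owning synapse's ``weight``.
    """

    def on_pre(self, synapse: StaticSynapse, t: float) -> None:
        pass

    def on_post(self, synapse: StaticSynapse, t: float) -> None:
        pass

    def on_trace_update(self, synapse: StaticSynapse, update_id: int,
                        eps_pre: float, eps_post: float, t: float) -> None:
        pass


class AdditiveTestRule(PlasticityHook):
    """Trivial rule: add fixed increments on pre/post activations."""

    def __init__(self, d_pre: float = 0.0, d_post: float = 0.0):
        self.d_pre = d_pre
        self.d_post = d_post
        self.n_pre = 0
        self.n_post = 0

    def on_pre(self, synapse, t):
        self.n_pre += 1
        synapse.weight += self.d_pre

    def on_post(self, synapse, t):
        self.n_post += 1
        synapse.weight += self.d_post


@dataclass
class SynapseFactory:
    """Everything :func:`connect_with_synapse` needs to wire one synapse.

    ``response`` is one of ``"rect"``, ``"pconst"``, ``"plin"``; ``tau``
    is the rectangular pulse duration (ignored when an explicit ``kernel``
    is given); ``mode`` selects reset or additive dynamics for piecewise
    kernels (rectangular responses are always reset); ``shared`` turns off
    response sharing for benchmarking the unoptimised wiring.
    """

    weight: float
    response: str = "rect"
    tau: float = 0.02
    mode: str = "reset"
    kernel: PiecewiseKernel | None = None
    hook: PlasticityHook | None = None
    shared: bool = True

    def make_response(self) -> NetworkElement:
        if self.response == "rect":
            return RectSpikeResponse(self.tau)
        if self.response in ("pconst", "plin"):
            if self.kernel is None:
                raise SimulationError(
                    f"response kind {self.response!r} requires a kernel"
                )
            return PiecewiseResponse(self.kernel, self.mode)
        raise SimulationError(
            f"unknown response kind {self.response!r}; "
            "expected rect, pconst or plin"
        )

    def response_key(self):
        return (self.response, self.tau, self.mode, self.kernel)


def _shared_responses(net: Network) -> dict:
    if not hasattr(net, "_shared_responses"):
        net._shared_responses = {}
    return net._shared_responses


def connect_with_synapse(net: Network, pre_id: int, post_id: int,
                         factory: SynapseFactory, delay: float = 0.0) -> int:
    """Connect two neurons with a composite synapse; return the synapse ID.

    Reuses (or creates) the shared response element for ``(pre_id, delay)``,
    creates the synapse element, and wires: event connection
    pre -> response (first use only), couplings synapse -> response and
    synapse -> postsynaptic neuron, and causal update links
    response -> synapse and synapse -> neuron.
    """
    registry = _shared_responses(net)
    key = (pre_id, delay)
    if factory.shared and key in registry:
        resp_id, kind = registry[key]
        if kind != factory.response_key():
            raise SimulationError(
                f"presynaptic neuron {pre_id} at delay {delay} already has a "
                f"shared response of a different kind; all synapses sharing "
                "a response must use the same kernel"
            )
    else:
        resp_id = net.create(factory.make_response())
        net.connect(pre_id, 0, resp_id, 0, delay)
        if factory.shared:
            registry[key] = (resp_id, factory.response_key())

    syn_id = net.create(
        StaticSynapse(factory.weight, resp_id, post_id, hook=factory.hook)
    )
    net.register_coupling(syn_id, resp_id)
    net.register_coupling(syn_id, post_id)
    net.add_update_link(resp_id, syn_id, update_id=resp_id)
    net.add_update_link(syn_id, post_id, update_id=syn_id)
    return syn_id


def wire_plastic_pattern_A(net: Network, syn_id: int, post_id: int) -> None:
    """Feed postsynaptic spikes into the synapse (spike-driven plasticity).

    Adds an event connection from the postsynaptic neuron's output port to
    the synapse's dedicated post-spike input port; the synapse then calls
    ``hook.on_post`` at each postsynaptic spike and ``hook.on_pre`` within
    each response-triggered update.
    """
    syn = net.elements[syn_id]
    if syn.hook is None:
        raise SimulationError("pattern A wiring requires a plasticity hook")
    net.connect(post_id, 0, syn_id, 0, 0.0)


def wire_plastic_pattern_B(net: Network, syn_id: int,
                           post_response_id: int) -> None:
    """Couple the synapse to the postsynaptic neuron's response (trace-driven).

    Adds a causal update link post_response -> synapse with a distinct
    update id so the hook's ``on_trace_update`` can tell which trace
    changed, and a one-way coupling for reading the post trace.
    """
    syn = net.elements[syn_id]
    if syn.hook is None:
        raise SimulationError("pattern B wiring requires a plasticity hook")
    syn._pre_uid = syn.response_id
    syn._post_uid = post_response_id
    syn._post_response_id = post_response_id
    net.register_coupling(syn_id, post_response_id)
    net.add_update_link(post_response_id, syn_id, update_id=post_response_id)
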