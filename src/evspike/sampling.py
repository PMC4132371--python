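"""Neural-sampling networks and their validation machinery.

A *neural sampling* network of K stochastic exponential-rate neurons
performs MCMC sampling from a Boltzmann distribution over binary variables

    p(z) = (1/Z) * exp( sum_{i<j} w_ij z_i z_j + sum_i b_i z_i ),

with symmetric weights ``W`` (zero diagonal) and biases ``b``.  A
sufficient condition is that neuron k's membrane potential equals
``u_k(t) = b_k + sum_i w_ki z_i(t)``, where ``z_i(t) = 1`` iff neuron i
spiked within the preceding window ``(t - tau, t]``.  This is realised
with rectangular PSPs of duration ``tau``, refractory period ``tau``,
rate coefficient ``C = 1/tau`` and zero synaptic delays: the network
state read off the spike trains is then, at any instant of the
stationary regime, a sample from ``p(z)``.

This module builds such networks (:func:`build_sampling_network`),
enumerates the target distribution exactly (:func:`exact_distribution`),
runs an independent systematic-scan Gibbs reference sampler
(:func:`gibbs_chain`), reconstructs the empirical state-occupancy
distribution from spike trains (:func:`states_from_spikes`), and provides
KL / marginal diagnostics.  It also generates the random
sparsely-connected LIF benchmark network (80/20 excitatory/inhibitory,
pairwise connection probability p) used for performance and accuracy
experiments (:func:`build_benchmark4`).

Distribution tables are plain dicts mapping state tuples (0/1 per
variable) to probabilities.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np

from .engine import Network, SimulationError
from .elements import SpikeRecorder
from .neurons import ExpPoissonNeuron, JumpSynapse, LifJumpNeuron
from .responses_synapses import SynapseFactory, connect_with_synapse

__all__ = [
    "BoltzmannModel",
    "random_model",
    "build_sampling_network",
    "attach_spike_recorders",
    "exact_distribution",
    "gibbs_chain",
    "StateTrajectory",
    "states_from_spikes",
    "marginal",
    "kl_divergence",
    "add_pseudomass",
    "Benchmark4Config",
    "build_benchmark4",
    "mean_firing_rate",
    "sigmoid",
]

_ENUM_CAP = 20  # 2^20 doubles ~ 8 MB; beyond this use the Gibbs reference


def sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@dataclass
class BoltzmannModel:
    """Target distribution over K binary variables (second-order interactions)."""

    W: np.ndarray  # (K, K) symmetric, zero diagonal
    b: np.ndarray  # (K,)

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        K = self.b.shape[0]
        if self.W.shape != (K, K):
            raise SimulationError("W must be K x K for K biases")
        if not np.allclose(self.W, self.W.T):
            raise SimulationError("weight matrix W must be symmetric")
        if not np.allclose(np.diag(self.W), 0.0):
            raise SimulationError("weight matrix W must have a zero diagonal")

    @property
    def K(self) -> int:
        return self.b.shape[0]

    def unnormalized_logp(self, z) -> float:
        z = np.asarray(z, dtype=float)
        return float(0.5 * z @ self.W @ z + self.b @ z)

    def to_dict(self) -> dict:
        iu = np.triu_indices(self.K, k=1)
        weights = [
            [int(i), int(j), float(self.W[i, j])]
            for i, j in zip(*iu) if self.W[i, j] != 0.0
        ]
        return {"K": self.K, "b": self.b.tolist(), "weights": weights}

    @classmethod
    def from_dict(cls, d: dict) -> "BoltzmannModel":
        K = d["K"]
        W = np.zeros((K, K))
        for i, j, w in d["weights"]:
            W[i, j] = W[j, i] = w
        return cls(W=W, b=np.asarray(d["b"], dtype=float))


def random_model(K: int, mu_b: float = -1.5, sigma_b: float = 0.5,
                 mu_w: float = 0.0, sigma_w: float = 0.3,
                 connectivity: str = "full", p: float | None = None,
                 seed=None) -> BoltzmannModel:
    """Draw a random Boltzmann model.

    Biases ``b_i ~ N(mu_b, sigma_b^2)``; for each connected pair ``i < j``
    a symmetric weight ``w_ij ~ N(mu_w, sigma_w^2)``.  ``connectivity``
    is ``"full"`` or ``"random"`` (each unordered pair connected
    independently with probability ``p``).
    """
    if sigma_b < 0 or sigma_w < 0:
        raise SimulationError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    b = rng.normal(mu_b, sigma_b, size=K)
    W = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            if connectivity == "full":
                connected = True
            elif connectivity == "random":
                if p is None or not 0 < p <= 1:
                    raise SimulationError(
                        "random connectivity requires 0 < p <= 1"
                    )
                connected = rng.random() < p
            else:
                raise SimulationError(
                    f"connectivity must be 'full' or 'random', got {connectivity!r}"
                )
            if connected:
                W[i, j] = W[j, i] = rng.normal(mu_w, sigma_w)
    return BoltzmannModel(W=W, b=b)


def build_sampling_network(net: Network, model: BoltzmannModel,
                           tau: float = 0.02,
                           psp: SynapseFactory | None = None,
                           delay: float = 0.0) -> list[int]:
    """Wire a neural-sampling network for ``model``; return neuron IDs.

    Creates K ``ExpPoissonNeuron(1/tau, b_k, tau)``; for every nonzero
    ``w_ij`` two synapses (i -> j and j -> i, each with weight ``w_ij``)
    via :func:`connect_with_synapse`, sharing one response element per
    presynaptic neuron.  The default PSP is the exact rectangular kernel
    of duration ``tau``; pass a :class:`SynapseFactory` (weight field is
    overridden per synapse) for piecewise approximations.
    """
    if psp is None:
        psp = SynapseFactory(weight=0.0, response="rect", tau=tau)
    neuron_ids = [
        net.create(ExpPoissonNeuron(C=1.0 / tau, bias=float(bk),
                                    refractory=tau))
        for bk in model.b
    ]
    for i in range(model.K):
        for j in range(model.K):
            if i != j and model.W[i, j] != 0.0:
                connect_with_synapse(
                    net, neuron_ids[i], neuron_ids[j],
                    replace(psp, weight=float(model.W[i, j])), delay,
                )
    return neuron_ids


def attach_spike_recorders(net: Network, neuron_ids) -> list[int]:
    """One zero-delay spike recorder per neuron; returns recorder IDs."""
    rec_ids = []
    for nid in neuron_ids:
        rid = net.create(SpikeRecorder())
        net.connect(nid, 0, rid, 0, 0.0)
        rec_ids.append(rid)
    return rec_ids


def exact_distribution(model: BoltzmannModel) -> dict:
    """Enumerate all 2^K states of ``p(z)``; K <= 20."""
    K = model.K
    if K > _ENUM_CAP:
        raise SimulationError(
            f"exact enumeration is capped at K = {_ENUM_CAP} "
            f"(got K = {K}); use gibbs_chain as the reference instead"
        )
    states = np.array(list(itertools.product((0, 1), repeat=K)), dtype=float)
    logp = 0.5 * np.einsum("si,ij,sj->s", states, model.W, states) \
        + states @ model.b
    logp -= logp.max()
    mass = np.exp(logp)
    mass /= mass.sum()
    return {
        tuple(int(v) for v in s): float(m) for s, m in zip(states, mass)
    }


def gibbs_chain(model: BoltzmannModel, n_sweeps: int, burn_in: int = 0,
                seed=None, scan: str = "systematic") -> dict:
    """Empirical distribution from a Gibbs sampler on ``p(z)``.

    Full conditionals are ``p(z_k = 1 | z_-k) = sigmoid(b_k + sum_i w_ki
    z_i)``.  One sweep resamples every coordinate (systematic scan
    ``0..K-1``, or ``K`` random coordinates with ``scan="random"``); the
    state after each post-burn-in sweep is counted.
    """
    if not n_sweeps > burn_in >= 0:
        raise SimulationError("need n_sweeps > burn_in >= 0")
    rng = np.random.default_rng(seed)
    K = model.K
    W = model.W
    b = model.b
    z = rng.integers(0, 2, size=K)
    counts: dict[tuple, int] = {}
    u = rng.random(size=(n_sweeps, K))
    for sweep in range(n_sweeps):
        if scan == "systematic":
            order = range(K)
        else:
            order = rng.integers(0, K, size=K)
        for idx, k in enumerate(order):
            pk = sigmoid(b[k] + W[k] @ z)
            z[k] = 1 if u[sweep, idx] < pk else 0
        if sweep >= burn_in:
            key = tuple(int(v) for v in z)
            counts[key] = counts.get(key, 0) + 1
    n = n_sweeps - burn_in
    return {s: c / n for s, c in counts.items()}


@dataclass
class StateTrajectory:
    """Occupancy times of the joint binary network state over a window."""

    occupancy: dict  # state tuple -> seconds
    T: float  # window length
    tau: float  # state-definition window

    def distribution(self) -> dict:
        return {s: d / self.T for s, d in self.occupancy.items()}


def states_from_spikes(spike_trains, K: int, tau: float,
                       t_start: float, t_end: float) -> StateTrajectory:
    """Reconstruct the piecewise-constant network state from spike trains.

    ``spike_trains`` is a sequence of K sorted spike-time lists.  Neuron
    k is *on* (``z_k = 1``) during ``[t_s, t_s + tau)`` after each of its
    spikes; refractoriness guarantees these intervals do not overlap
    within one train (violations raise).  Sweeps the union of all
    interval boundaries in ``[t_start, t_end]`` and accumulates exact
    occupancy durations per joint state.
    """
    if not t_end > t_start:
        raise SimulationError("need t_end > t_start")
    if len(spike_trains) != K:
        raise SimulationError(f"expected {K} spike trains, got {len(spike_trains)}")
    events: list[tuple[float, int, int]] = []  # (time, neuron, +1/-1)
    for k, train in enumerate(spike_trains):
        prev = None
        for t_s in train:
            if prev is not None:
                if t_s < prev:
                    raise SimulationError(f"spike train {k} is not sorted")
                if t_s - prev < tau * (1 - 1e-12):
                    raise SimulationError(
                        f"spike train {k} has an inter-spike interval "
                        f"shorter than tau = {tau}; the on-intervals of a "
                        "refractory neuron cannot overlap"
                    )
            prev = t_s
            on, off = t_s, t_s + tau
            if off <= t_start or on >= t_end:
                continue
            if on >= t_start:
                events.append((on, k, +1))
            if off <= t_end:
                events.append((off, k, -1))
    events.sort()
    z = [0] * K
    # initialise with intervals straddling t_start
    for k, train in enumerate(spike_trains):
        for t_s in train:
            if t_s <= t_start < t_s + tau:
                z[k] = 1
    occupancy: dict[tuple, float] = {}
    t_prev = t_start
    i = 0
    n_ev = len(events)
    while i < n_ev:
        t = events[i][0]
        if t > t_prev:
            key = tuple(z)
            occupancy[key] = occupancy.get(key, 0.0) + (t - t_prev)
            t_prev = t
        while i < n_ev and events[i][0] == t:
            _, k, d = events[i]
            z[k] += d
            i += 1
    if t_end > t_prev:
        key = tuple(z)
        occupancy[key] = occupancy.get(key, 0.0) + (t_end - t_prev)
    return StateTrajectory(occupancy=occupancy, T=t_end - t_start, tau=tau)


def marginal(dist: dict, indices) -> dict:
    """Marginalise a distribution table onto the given coordinates."""
    indices = list(indices)
    out: dict[tuple, float] = {}
    for state, p in dist.items():
        key = tuple(state[i] for i in indices)
        out[key] = out.get(key, 0.0) + p
    return out


def kl_divergence(p: dict, q: dict) -> float:
    """KL(p || q) in nats; requires q > 0 wherever p > 0."""
    kl = 0.0
    for state, pp in p.items():
        if pp <= 0.0:
            continue
        qq = q.get(state, 0.0)
        if qq <= 0.0:
            raise SimulationError(
                f"q has zero mass on state {state} in p's support; "
                "apply add_pseudomass() to the empirical table first"
            )
        kl += pp * math.log(pp / qq)
    return kl


def add_pseudomass(dist: dict, K: int, eps: float) -> dict:
    """Give every unobserved state mass ``eps``, then renormalise.

    For empirical occupancy tables a natural choice is
    ``eps = 0.5 * resolution / T`` (half of one resolvable dwell time).
    """
    out = dict(dist)
    for state in itertools.product((0, 1), repeat=K):
        if state not in out:
            out[state] = eps
    total = sum(out.values())
    return {s: v / total for s, v in out.items()}


# ---------------------------------------------------------------------------
# Random LIF benchmark network (sparse 80/20 voltage-jump network)
# ---------------------------------------------------------------------------


@dataclass
class Benchmark4Config:
    """Sparse random network of LIF voltage-jump neurons.

    Defaults follow the standard benchmark definition: 80% excitatory /
    20% inhibitory, ordered-pair connection probability ``p = 0.02``, all
    synaptic delays 1 ms, resting potential above threshold
    (``E_L = -49 mV > V_thresh = -50 mV``) so neurons fire spontaneously,
    and voltage jumps of +0.25 mV (excitatory) / -2.25 mV (inhibitory).
    """

    N: int = 1000
    exc_fraction: float = 0.8
    p: float = 0.02
    delay: float = 1e-3
    E_L: float = -49.0
    V_thresh: float = -50.0
    V_reset: float = -60.0
    tau_m: float = 0.02
    t_ref: float = 0.005
    w_e: float = 0.25
    w_i: float = -2.25
    refractory_jumps: str = "discard"

    @property
    def n_exc(self) -> int:
        return int(self.exc_fraction * self.N)


def build_benchmark4(net: Network, config: Benchmark4Config) -> list[int]:
    """Build the random LIF network; returns the neuron IDs.

    Neurons ``0 .. n_exc-1`` are excitatory.  Each neuron gets two
    voltage-jump synapse elements (one per afferent class — sufficient
    because all weights within a class are equal); every ordered pair
    ``(i, j), i != j`` is connected independently with probability ``p``
    from neuron i's output to the matching synapse of neuron j, at the
    common delay.  Initial membrane potentials are drawn uniformly from
    ``[V_reset, V_thresh)`` using the network's seeded stream.
    """
    c = config
    rng = net.rng
    u0 = rng.uniform(c.V_reset, c.V_thresh, size=c.N)
    neuron_ids = [
        net.create(LifJumpNeuron(
            E_L=c.E_L, V_thresh=c.V_thresh, V_reset=c.V_reset,
            tau_m=c.tau_m, t_ref=c.t_ref, u_init=float(u0[k]),
            refractory_jumps=c.refractory_jumps,
        ))
        for k in range(c.N)
    ]
    exc_syn, inh_syn = [], []
    for nid in neuron_ids:
        se = net.create(JumpSynapse(c.w_e, nid))
        si = net.create(JumpSynapse(c.w_i, nid))
        net.register_coupling(se, nid)
        net.register_coupling(si, nid)
        net.add_update_link(se, nid, update_id=se)
        net.add_update_link(si, nid, update_id=si)
        exc_syn.append(se)
        inh_syn.append(si)
    n_exc = c.n_exc
    for i in range(c.N):
        targets = np.nonzero(rng.random(c.N) < c.p)[0]
        syn_table = exc_syn if i < n_exc else inh_syn
        for j in targets:
            if j == i:
                continue
            net.connect(neuron_ids[i], 0, syn_table[j], 0, c.delay)
    return neuron_ids


def mean_firing_rate(spike_trains, T: float) -> float:
    """Population mean rate in Hz: total spikes / (N * T)."""
    if T <= 0:
        raise SimulationError("need T > 0")
    n = len(spike_trains)
    if n == 0:
        return 0.0
    return sum(len(tr) for tr in spike_trains) / (n * T)
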