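"""Boltzmann models, Gibbs reference, occupancy estimation, benchmark builder."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evspike.engine import Network, SimulationError
from evspike.neurons import LifJumpNeuron
from evspike.responses_synapses import RectSpikeResponse, StaticSynapse
from evspike.sampling import (Benchmark4Config, BoltzmannModel,
                              add_pseudomass, attach_spike_recorders,
                              build_benchmark4, build_sampling_network,
                              exact_distribution, gibbs_chain, kl_divergence,
                              marginal, mean_firing_rate, random_model,
                              sigmoid, states_from_spikes)


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def test_degenerate_random_model_is_deterministic():
    m = random_model(4, mu_b=-1.5, sigma_b=0.0, mu_w=0.2, sigma_w=0.0,
                     seed=0)
    assert np.allclose(m.b, -1.5)
    off_diag = m.W[~np.eye(4, dtype=bool)]
    assert np.allclose(off_diag, 0.2)
    assert np.allclose(np.diag(m.W), 0.0)


def test_random_model_bias_mean_clt_check():
    m = random_model(40, mu_b=-1.5, sigma_b=0.5, seed=7)
    assert abs(m.b.mean() - (-1.5)) < 3 * 0.5 / math.sqrt(40)
    assert np.allclose(m.W, m.W.T)


def test_performance_variant_row_sums():
    # homogeneous weights w = 0.3 / (p (N-1)) on Bernoulli(p) connectivity
    N, p = 200, 0.1
    rng = np.random.default_rng(5)
    w = 0.3 / (p * (N - 1))
    W = np.zeros((N, N))
    for i in range(N):
        for j in range(i + 1, N):
            if rng.random() < p:
                W[i, j] = W[j, i] = w
    model = BoltzmannModel(W=W, b=np.full(N, -1.0))
    assert model.W.sum(axis=1).mean() == pytest.approx(0.3, rel=0.15)


def test_asymmetric_weights_rejected():
    W = np.array([[0.0, 1.0], [0.5, 0.0]])
    with pytest.raises(SimulationError, match="symmetric"):
        BoltzmannModel(W=W, b=np.zeros(2))


def test_model_json_roundtrip():
    m = random_model(5, seed=3)
    m2 = BoltzmannModel.from_dict(m.to_dict())
    assert np.allclose(m.W, m2.W) and np.allclose(m.b, m2.b)


# ---------------------------------------------------------------------------
# network construction counts
# ---------------------------------------------------------------------------

def test_unconnected_pair_creates_no_synapses(net):
    model = BoltzmannModel(W=np.zeros((2, 2)), b=np.zeros(2))
    build_sampling_network(net, model)
    assert sum(isinstance(e, StaticSynapse) for e in net.elements) == 0
    assert sum(isinstance(e, RectSpikeResponse) for e in net.elements) == 0


def test_fully_connected_triplet_counts(net):
    model = BoltzmannModel(
        W=np.array([[0.0, 0.1, 0.2], [0.1, 0.0, 0.3], [0.2, 0.3, 0.0]]),
        b=np.zeros(3))
    ids = build_sampling_network(net, model)
    assert len(ids) == 3
    assert sum(isinstance(e, RectSpikeResponse) for e in net.elements) == 3
    assert sum(isinstance(e, StaticSynapse) for e in net.elements) == 6


def test_all_to_all_synapse_count(net):
    K = 5
    model = random_model(K, sigma_w=0.3, seed=1)
    build_sampling_network(net, model)
    assert sum(isinstance(e, StaticSynapse) for e in net.elements) \
        == K * (K - 1)
    assert sum(isinstance(e, RectSpikeResponse) for e in net.elements) == K


# ---------------------------------------------------------------------------
# exact enumeration
# ---------------------------------------------------------------------------

def test_exact_single_unbiased_variable():
    m = BoltzmannModel(W=np.zeros((1, 1)), b=np.zeros(1))
    assert exact_distribution(m) == {(0,): 0.5, (1,): 0.5}


def test_exact_single_variable_logistic():
    m = BoltzmannModel(W=np.zeros((1, 1)), b=np.array([-1.5]))
    d = exact_distribution(m)
    assert d[(1,)] == pytest.approx(sigmoid(-1.5))
    assert d[(1,)] == pytest.approx(0.182426, abs=1e-6)


def test_exact_coupled_pair():
    m = BoltzmannModel(W=np.array([[0.0, 1.0], [1.0, 0.0]]), b=np.zeros(2))
    d = exact_distribution(m)
    e = math.e
    assert d[(1, 1)] == pytest.approx(e / (3 + e))
    assert d[(1, 1)] == pytest.approx(0.475367, abs=1e-6)


def test_enumeration_cap():
    m = BoltzmannModel(W=np.zeros((21, 21)), b=np.zeros(21))
    with pytest.raises(SimulationError, match="[Gg]ibbs"):
        exact_distribution(m)


# ---------------------------------------------------------------------------
# Gibbs reference
# ---------------------------------------------------------------------------

def test_gibbs_independent_marginals_match_sigmoid():
    b = np.array([-1.0, 0.0, 1.5])
    m = BoltzmannModel(W=np.zeros((3, 3)), b=b)
    d = gibbs_chain(m, 40_000, 2_000, seed=2)
    n = 38_000
    for k in range(3):
        pk = marginal(d, [k]).get((1,), 0.0)
        tgt = sigmoid(b[k])
        assert abs(pk - tgt) < 3 * math.sqrt(tgt * (1 - tgt) / n) + 0.005


def test_gibbs_converges_to_exact_in_kl():
    m = random_model(5, seed=21)
    d = gibbs_chain(m, 100_000, 10_000, seed=22)
    assert kl_divergence(d, exact_distribution(m)) < 0.005


def test_gibbs_deterministic_under_seed():
    m = random_model(4, seed=1)
    assert gibbs_chain(m, 5000, 100, seed=9) == \
        gibbs_chain(m, 5000, 100, seed=9)


# ---------------------------------------------------------------------------
# occupancy estimation
# ---------------------------------------------------------------------------

def test_single_train_occupancy_interval_arithmetic():
    traj = states_from_spikes([[0.1, 0.5]], 1, 0.02, 0.0, 1.0)
    assert traj.occupancy[(1,)] == pytest.approx(0.04)
    assert traj.occupancy[(0,)] == pytest.approx(0.96)


def test_no_spikes_all_time_in_zero_state():
    traj = states_from_spikes([[], []], 2, 0.02, 0.0, 1.0)
    assert traj.occupancy == {(0, 0): 1.0}


def test_two_train_joint_occupancy_boundary_sweep():
    traj = states_from_spikes([[0.1], [0.11]], 2, 0.02, 0.0, 1.0)
    occ = traj.occupancy
    assert occ[(0, 0)] == pytest.approx(0.97)
    assert occ[(1, 0)] == pytest.approx(0.01)
    assert occ[(1, 1)] == pytest.approx(0.01)
    assert occ[(0, 1)] == pytest.approx(0.01)


def test_overlapping_on_intervals_rejected():
    with pytest.raises(SimulationError, match="refractory"):
        states_from_spikes([[0.1, 0.105]], 1, 0.02, 0.0, 1.0)


def test_spike_straddling_window_start_counts():
    traj = states_from_spikes([[0.99]], 1, 0.02, 1.0, 2.0)
    assert traj.occupancy[(1,)] == pytest.approx(0.01)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=0, max_value=4000), min_size=0,
                max_size=60))
def test_occupancy_times_always_sum_to_window(raw):
    # spike times on a grid coarser than tau -> valid trains; conservation
    # must hold exactly regardless of alignment with the window edges
    tau = 0.02
    train = sorted({0.025 * k for k in raw})
    traj = states_from_spikes([train], 1, tau, 10.0, 90.0)
    assert sum(traj.occupancy.values()) == pytest.approx(80.0, abs=1e-9)


# ---------------------------------------------------------------------------
# marginals and KL
# ---------------------------------------------------------------------------

def test_marginal_identity_and_projection():
    m = random_model(3, seed=13)
    d = exact_distribution(m)
    assert marginal(d, [0, 1, 2]) == d
    # oracle: brute-force double sum
    proj = marginal(d, [0, 2])
    brute = {}
    for (z0, z1, z2), p in d.items():
        brute[(z0, z2)] = brute.get((z0, z2), 0.0) + p
    for k in brute:
        assert proj[k] == pytest.approx(brute[k])


def test_kl_of_identical_tables_is_zero():
    m = random_model(3, seed=4)
    d = exact_distribution(m)
    assert kl_divergence(d, d) == pytest.approx(0.0, abs=1e-14)


def test_kl_closed_form_two_point():
    p = {(0,): 0.5, (1,): 0.5}
    q = {(0,): 0.75, (1,): 0.25}
    expected = 0.5 * math.log(0.5 / 0.75) + 0.5 * math.log(0.5 / 0.25)
    assert kl_divergence(p, q) == pytest.approx(expected)
    assert expected == pytest.approx(0.143841, abs=1e-6)


def test_kl_nonnegative_on_random_pairs():
    rng = np.random.default_rng(6)
    for _ in range(100):
        a = rng.dirichlet(np.ones(8))
        b = rng.dirichlet(np.ones(8))
        states = [(int(i),) for i in range(8)]
        p = dict(zip(states, a))
        q = dict(zip(states, b))
        assert kl_divergence(p, q) >= 0.0


def test_kl_missing_support_raises_and_pseudomass_fixes():
    p = {(0,): 0.5, (1,): 0.5}
    q = {(0,): 1.0}
    with pytest.raises(SimulationError, match="pseudomass"):
        kl_divergence(p, q)
    q2 = add_pseudomass(q, 1, 1e-6)
    assert kl_divergence(p, q2) > 0.0
    assert sum(q2.values()) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# benchmark network builder
# ---------------------------------------------------------------------------

def test_full_connectivity_count():
    net = Network(seed=0)
    build_benchmark4(net, Benchmark4Config(N=10, p=1.0))
    # every ordered pair once; two synapse elements per neuron
    syn_conns = [c for c in net.connections]
    assert len(syn_conns) == 90


def test_excitatory_population_size_is_floor_of_fraction():
    cfg = Benchmark4Config(N=1001)
    assert cfg.n_exc == 800
    net = Network(seed=0)
    ids = build_benchmark4(net, Benchmark4Config(N=25))
    # neurons 0..19 excitatory: their synaptic targets carry w_e
    from evspike.neurons import JumpSynapse
    n_syn = sum(isinstance(e, JumpSynapse) for e in net.elements)
    assert n_syn == 50


def test_connection_count_within_binomial_bounds():
    N, p = 100, 0.02
    net = Network(seed=42)
    build_benchmark4(net, Benchmark4Config(N=N, p=p))
    n_conn = len(net.connections)
    mean = p * N * (N - 1)
    assert abs(n_conn - mean) < 4 * math.sqrt(mean)


def test_isolated_lif_population_fires_at_drift_rate():
    # p = 0 -> every neuron fires at 1/(t_ref + tau_m ln((E_L-V_r)/(E_L-V_t)))
    cfg = Benchmark4Config(N=10, p=0.0)
    net = Network(seed=3)
    ids = build_benchmark4(net, cfg)
    recs = attach_spike_recorders(net, ids)
    net.finalize()
    T = 10.0
    net.run(T)
    trains = [net.elements[r].times for r in recs]
    period = cfg.t_ref + cfg.tau_m * math.log(
        (cfg.E_L - cfg.V_reset) / (cfg.E_L - cfg.V_thresh))
    expected = 1.0 / period
    r = mean_firing_rate(trains, T)
    assert r == pytest.approx(expected, rel=0.02)


def test_mean_firing_rate_arithmetic():
    assert mean_firing_rate([[], []], 2.0) == 0.0
    assert mean_firing_rate([[0.1, 0.2], [0.3, 0.4]], 2.0) == 1.0


# ---------------------------------------------------------------------------
# end-to-end sampling correctness (small, fast versions)
# ---------------------------------------------------------------------------

def test_single_neuron_occupancy_matches_logistic():
    # K = 1 spiking occupancy of the on-state converges to sigmoid(b)
    b = 0.5
    model = BoltzmannModel(W=np.zeros((1, 1)), b=np.array([b]))
    net = Network(seed=14)
    ids = build_sampling_network(net, model, tau=0.02)
    recs = attach_spike_recorders(net, ids)
    net.finalize()
    net.run(100.0)
    train = net.elements[recs[0]].times
    traj = states_from_spikes([train], 1, 0.02, 0.0, 100.0)
    occ = traj.distribution().get((1,), 0.0)
    tgt = sigmoid(b)
    se = math.sqrt(tgt * (1 - tgt) / len(train))
    assert abs(occ - tgt) < 3 * se


def test_coupled_pair_occupancy_matches_exact():
    model = BoltzmannModel(W=np.array([[0.0, 1.0], [1.0, 0.0]]),
                           b=np.array([-0.5, 0.0]))
    net = Network(seed=15)
    ids = build_sampling_network(net, model, tau=0.02)
    recs = attach_spike_recorders(net, ids)
    net.finalize()
    net.run(150.0)
    trains = [net.elements[r].times for r in recs]
    traj = states_from_spikes(trains, 2, 0.02, 15.0, 150.0)
    kl = kl_divergence(traj.distribution(), exact_distribution(model))
    assert kl < 0.01


def test_alpha_shaped_psp_approximation_stays_close():
    # piecewise-linear alpha PSPs: K = 4 marginals within 0.05 total
    # variation of the exact table (approximation, not exact sampling)
    from evspike.responses_synapses import SynapseFactory, alpha_kernel
    tau = 0.02
    model = random_model(4, seed=31)
    kern = alpha_kernel(tau, n_segments=8, t_max=2.5 * tau)
    psp = SynapseFactory(weight=0.0, response="plin", kernel=kern,
                         mode="additive")
    net = Network(seed=32)
    ids = build_sampling_network(net, model, tau=tau, psp=psp)
    recs = attach_spike_recorders(net, ids)
    net.finalize()
    net.run(300.0)
    trains = [net.elements[r].times for r in recs]
    traj = states_from_spikes(trains, 4, tau, 30.0, 300.0)
    emp = marginal(traj.distribution(), [0, 1, 2, 3])
    ex = exact_distribution(model)
    tv = 0.5 * sum(abs(emp.get(s, 0.0) - ex[s]) for s in ex)
    assert tv < 0.05
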