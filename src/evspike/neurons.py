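"""Neuron models with analytically scheduled, cancellable next-spike events.

Two models are provided:

* :class:`ExpPoissonNeuron` — the stochastic neuron used in neural-sampling
  networks.  When not refractory it fires as an inhomogeneous Poisson
  process with instantaneous rate ``rho(u) = C * exp(u)``, where the
  membrane ``u = bias + s(t)`` and ``s(t)`` is the weighted sum of
  postsynaptic responses maintained by the synapses.  After each spike the
  neuron is silent for an absolute refractory period.  Because the membrane
  between network events is (at most) piecewise linear, the time of the
  next spike can be sampled *exactly* by inverting the integrated hazard;
  whenever the membrane changes, the pending spike is resampled from
  scratch, which is exact by the memorylessness of the exponential
  distribution.  All state variables are in arbitrary units.

* :class:`LifJumpNeuron` — a deterministic current-based leaky
  integrate-and-fire neuron with voltage-jump (Dirac pulse) synapses.
  Between inputs the membrane decays analytically toward the resting
  potential ``E_L``; each input instantly jumps it by the synaptic weight.
  The threshold-crossing time from the current state is available in
  closed form, so the neuron keeps exactly one cancellable pending spike
  that it reschedules on every jump.  No numerical integration is
  performed anywhere: the simulation is exact to machine precision.
  Units: membrane quantities in mV, times in seconds.
"""

from __future__ import annotations

import math

from .engine import NetworkElement, SimulationError

__all__ = [
    "ExpPoissonNeuron",
    "LifJumpNeuron",
    "JumpSynapse",
    "next_spike_dt_linear",
    "next_spike_time_piecewise_linear",
]

#: membrane values above this raise instead of overflowing exp()
_U_MAX = 700.0

NEG_INF = float("-inf")


def next_spike_dt_linear(u: float, slope: float, C: float, E: float):
    """Exact waiting time for rate ``C * exp(u + slope * dt)``.

    Inverts the integrated hazard for a membrane assumed to continue on its
    current linear course, given a unit-exponential draw ``E``.  Returns
    the waiting time ``dt`` with accumulated hazard equal to ``E``, or
    ``None`` if the total hazard is finite and below ``E`` (decaying
    membrane that never fires under this course).
    """
    if u == NEG_INF:
        return None
    if u > _U_MAX:
        raise SimulationError(
            f"membrane potential {u} exceeds the supported regime "
            f"(u <= {_U_MAX} in arbitrary units)"
        )
    if slope == 0.0:
        lam = C * math.exp(u)
        if lam == 0.0:  # underflow: rate indistinguishable from zero
            return None
        return E / lam
    # hazard on [0, dt]: (C/slope) * (exp(u + slope*dt) - exp(u)) = E
    x = slope * E / C
    if u > -700.0:
        arg = x * math.exp(-u)
        if 1.0 + arg <= 0.0:
            return None  # slope < 0 and total remaining hazard < E
        return math.log1p(arg) / slope
    # exp(u) underflows: solve exp(u + slope*dt) = x directly
    if x <= 0.0:
        return None
    return (math.log(x) - u) / slope


def next_spike_time_piecewise_linear(segments, t_end: float, E: float,
                                     C: float, t_now: float | None = None):
    """Sample the next spike time for a piecewise-linear membrane course.

    Parameters
    ----------
    segments
        List of ``(t_start, u_start, slope)``, contiguous and in increasing
        ``t_start`` order; segment ``k`` covers ``[t_start_k, t_start_{k+1})``
        and the last segment ends at ``t_end``.
    t_end
        End of the covered horizon.
    E
        Unit-exponential draw.
    C
        Rate coefficient (Hz): instantaneous rate is ``C * exp(u(t))``.
    t_now
        Start accumulating hazard here (defaults to the first segment's
        start; must lie within the covered span).

    Returns the time at which the accumulated hazard reaches ``E``, or
    ``None`` if the horizon is reached first.
    """
    if not segments:
        raise SimulationError("need at least one segment")
    starts = [s[0] for s in segments]
    if any(b <= a for a, b in zip(starts, starts[1:])):
        raise SimulationError("segments must have strictly increasing starts")
    if t_now is None:
        t_now = starts[0]
    if not starts[0] <= t_now <= t_end:
        raise SimulationError("t_now outside the covered span")
    remaining = E
    for k, (t0, u0, m) in enumerate(segments):
        t1 = starts[k + 1] if k + 1 < len(segments) else t_end
        if t1 <= t_now:
            continue
        lo = max(t0, t_now)
        u_lo = u0 + m * (lo - t0)
        span = t1 - lo
        if m == 0.0:
            lam = C * math.exp(u_lo) * span
        else:
            lam = C / m * (math.exp(u_lo + m * span) - math.exp(u_lo))
        if lam >= remaining:
            dt = next_spike_dt_linear(u_lo, m, C, remaining)
            return lo + dt
        remaining -= lam
    return None


class ExpPoissonNeuron(NetworkElement):
    """Stochastic exponential-rate neuron for neural sampling.

    Parameters mirror the usual construction ``(C, bias, refractory)``:
    ``C`` is the rate coefficient in Hz (``1/tau`` in sampling networks),
    ``bias`` the constant membrane offset, ``refractory`` the absolute
    refractory period in seconds (during which the neuron is silent and
    ignores membrane changes).

    Registered fields: ``"Vm"`` (the synaptic accumulator ``s``) and
    ``"bias"``.  Writing ``"Vm"`` (e.g. from an :class:`ArrayModifier`)
    overrides the accumulator with the given value and zero slope.
    """

    n_in_ports = 0
    n_out_ports = 1
    emits_spikes = True

    def __init__(self, C: float, bias: float = 0.0, refractory: float = 0.0):
        super().__init__()
        if C <= 0:
            raise SimulationError(f"rate coefficient C must be > 0, got {C}")
        if refractory < 0:
            raise SimulationError("refractory duration must be >= 0")
        self.C = C
        self.bias = bias
        self.refractory = refractory
        # synaptic accumulator s(t) = s_val + s_slope * (t - s_t)
        self._s_val = 0.0
        self._s_slope = 0.0
        self._s_t = 0.0
        self._refractory_now = False
        self.refractory_until = NEG_INF
        self.register_field("Vm", "Vm")
        self.register_field("bias", "bias")

    # "Vm" is a computed view of the accumulator at the current time.
    @property
    def Vm(self) -> float:
        t = self.net.current_time if self.net is not None else self._s_t
        return self.s_at(t)

    @Vm.setter
    def Vm(self, value: float) -> None:
        t = self.net.current_time if self.net is not None else 0.0
        self._s_val = float(value)
        self._s_slope = 0.0
        self._s_t = t

    def s_at(self, t: float) -> float:
        return self._s_val + self._s_slope * (t - self._s_t)

    def u_at(self, t: float) -> float:
        """Total membrane potential ``bias + s(t)``."""
        return self.bias + self.s_at(t)

    def rate(self, u_total: float, t: float | None = None) -> float:
        """Instantaneous firing rate ``C * exp(u_total)`` in Hz.

        Zero if the neuron is refractory at query time ``t``.
        """
        if t is not None and self.is_refractory(t):
            return 0.0
        if u_total == NEG_INF:
            return 0.0
        if u_total > _U_MAX:
            raise SimulationError(
                f"membrane potential {u_total} exceeds the supported regime "
                f"(u <= {_U_MAX} in arbitrary units)"
            )
        return self.C * math.exp(u_total)

    def is_refractory(self, t: float) -> bool:
        return self._refractory_now and t < self.refractory_until

    # -- synaptic input (called by synapses through their coupling) -----

    def add_input(self, t: float, dvalue: float, dslope: float = 0.0) -> None:
        """Apply a jump ``dvalue`` and slope change ``dslope`` to ``s`` at ``t``."""
        self._s_val = self.s_at(t) + dvalue
        self._s_slope += dslope
        self._s_t = t

    # -- simulation handlers --------------------------------------------

    def on_start(self, t: float) -> None:
        self._s_t = t
        self.resample_next_spike(t)

    def on_update(self, update_id: int, t: float) -> None:
        # membrane changed; refractory neurons wait until refractory end
        if not self._refractory_now:
            self.resample_next_spike(t)

    def resample_next_spike(self, t: float) -> None:
        """Draw a fresh next-spike time under the current membrane course.

        Exact: conditional on no earlier membrane change, the drawn time has
        the correct inhomogeneous-Poisson distribution; any change triggers
        a new draw, which is valid by memorylessness.
        """
        E = self.net.rng.standard_exponential()
        dt = next_spike_dt_linear(self.u_at(t), self._s_slope, self.C, E)
        if dt is None:
            self.net.cancel_pending(self.id)
        else:
            self.net.schedule_pending(self.id, t + dt)

    def on_pending(self, t: float) -> None:
        if self._refractory_now:
            # refractory period over: resume stochastic firing
            self._refractory_now = False
            self.resample_next_spike(t)
        else:
            self.net.emit(self.id, 0, t, spike=True)
            if self.refractory > 0:
                self._refractory_now = True
                self.refractory_until = t + self.refractory
                self.net.schedule_pending(self.id, self.refractory_until)
            else:
                self.resample_next_spike(t)


class LifJumpNeuron(NetworkElement):
    """Event-based leaky integrate-and-fire neuron with voltage jumps.

    Between inputs ``u(t) = E_L + (u(t_last) - E_L) * exp(-(t-t_last)/tau_m)``;
    the stored state is exact at ``t_last`` and queries decay analytically.
    If ``E_L > V_thresh`` the neuron drifts across threshold on its own and
    keeps a pending spike at the closed-form crossing time

        ``t_last + tau_m * ln((E_L - u) / (E_L - V_thresh))``.

    During the absolute refractory period ``t_ref`` after a spike the
    neuron cannot fire; what happens to inputs arriving then is
    configurable: ``refractory_jumps="discard"`` (default) holds the
    membrane clamped at ``V_reset`` and drops the jumps, while
    ``"accumulate"`` lets the membrane decay and integrate jumps normally
    with only spike emission suppressed (a spike fires immediately at
    refractory end if the membrane sits at or above threshold then).
    Registered field: ``"Vm"``.
    """

    n_in_ports = 0
    n_out_ports = 1
    emits_spikes = True

    def __init__(self, E_L: float = -49.0, V_thresh: float = -50.0,
                 V_reset: float = -60.0, tau_m: float = 0.02,
                 t_ref: float = 0.005, u_init: float | None = None,
                 refractory_jumps: str = "discard"):
        super().__init__()
        if tau_m <= 0:
            raise SimulationError("membrane time constant must be > 0")
        if t_ref < 0:
            raise SimulationError("refractory period must be >= 0")
        if refractory_jumps not in ("discard", "accumulate"):
            raise SimulationError(
                "refractory_jumps must be 'discard' or 'accumulate', "
                f"got {refractory_jumps!r}"
            )
        self.refractory_jumps = refractory_jumps
        self.E_L = E_L
        self.V_thresh = V_thresh
        self.V_reset = V_reset
        self.tau_m = tau_m
        self.t_ref = t_ref
        self.u = V_reset if u_init is None else u_init
        self.t_last = 0.0
        self._refractory_now = False
        self.refractory_until = NEG_INF
        self._jump_inbox = 0.0
        self.register_field("Vm", "u")

    # -- analytic membrane ----------------------------------------------

    def membrane_at(self, t: float) -> float:
        """Membrane potential at ``t >= t_last`` without mutating state."""
        if (self._refractory_now and t < self.refractory_until
                and self.refractory_jumps == "discard"):
            return self.V_reset  # clamped during refractoriness
        if t < self.t_last:
            raise SimulationError(
                f"membrane query at t={t} precedes last update {self.t_last}"
            )
        return self.E_L + (self.u - self.E_L) * math.exp(
            -(t - self.t_last) / self.tau_m
        )

    def field_at(self, name: str, t: float):
        if name == "Vm":
            return self.membrane_at(t)
        return self.get_field(name)

    def crossing_dt(self) -> float | None:
        """Time from ``t_last`` to the drift-driven threshold crossing.

        ``None`` if the decay toward ``E_L`` stays subthreshold
        (``E_L <= V_thresh``).  Requires ``u < V_thresh``.
        """
        if self.E_L <= self.V_thresh:
            return None
        return self.tau_m * math.log(
            (self.E_L - self.u) / (self.E_L - self.V_thresh)
        )

    # -- dynamics --------------------------------------------------------

    def _reschedule_crossing(self, t: float) -> None:
        dt = self.crossing_dt()
        if dt is None:
            self.net.cancel_pending(self.id)
        else:
            self.net.schedule_pending(self.id, self.t_last + dt)

    def _spike(self, t: float) -> None:
        self.net.emit(self.id, 0, t, spike=True)
        self.u = self.V_reset
        if self.t_ref > 0:
            self._refractory_now = True
            self.refractory_until = t + self.t_ref
            if self.refractory_jumps == "discard":
                self.t_last = self.refractory_until  # decay starts after t_ref
            else:
                self.t_last = t  # decay (and jumps) continue immediately
            self.net.schedule_pending(self.id, self.refractory_until)
        else:
            self.t_last = t
            self._reschedule_crossing(t)

    def apply_jump(self, t: float, du: float) -> None:
        """Instantaneously change the membrane by ``du`` mV at time ``t``.

        Discarded during refractoriness.  Crossing threshold emits a spike
        at exactly ``t``; otherwise the pending crossing is rescheduled.
        """
        if self._refractory_now and t < self.refractory_until:
            if self.refractory_jumps == "accumulate":
                # integrate silently; the refractory-end pending stays put
                self.u = self.membrane_at(t) + du
                self.t_last = t
            return
        self._refractory_now = False
        self.u = self.membrane_at(t) + du
        self.t_last = t
        if self.u >= self.V_thresh:
            self._spike(t)
        else:
            self._reschedule_crossing(t)

    # -- simulation handlers ---------------------------------------------

    def on_start(self, t: float) -> None:
        self.t_last = t
        if self.u >= self.V_thresh:
            self._spike(t)
        else:
            self._reschedule_crossing(t)

    def on_update(self, update_id: int, t: float) -> None:
        # collect jumps pushed by JumpSynapse couplings during this pass
        du = self._jump_inbox
        if du != 0.0:
            self._jump_inbox = 0.0
            self.apply_jump(t, du)

    def on_pending(self, t: float) -> None:
        if self._refractory_now:
            self._refractory_now = False
            self.u = self.membrane_at(t)
            self.t_last = t
            if self.u >= self.V_thresh:
                self._spike(t)
            else:
                self._reschedule_crossing(t)
        else:
            # predicted drift crossing reached: membrane is at threshold
            self.u = self.V_thresh
            self.t_last = t
            self._spike(t)


class JumpSynapse(NetworkElement):
    """Static voltage-jump synapse for LIF networks.

    Relays every event delivered on its input port into a membrane jump of
    fixed ``weight`` (mV) on its postsynaptic neuron.  The jump is written
    into the neuron's inbox through the declared coupling; the causal
    update link synapse -> neuron then triggers the neuron's update, which
    applies the jump and reschedules its pending spike.  Because all jumps
    of one weight class are identical, one such element per (neuron,
    class) serves all its afferents.
    """

    n_in_ports = 1
    n_out_ports = 0

    def __init__(self, weight: float, post_id: int):
        super().__init__()
        self.weight = weight
        self.post_id = post_id
        self.n_delivered = 0

    def on_event(self, t: float, port: int) -> None:
        self.n_delivered += 1
        self.net.elements[self.post_id]._jump_inbox += self.weight
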