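"""Utility network elements: clocks, recorders, modifiers, spike sources.

These are the plumbing elements every experiment needs around the neuron
models: regular and variable-step clocks that drive clock-style behaviour
inside the event-driven kernel, spike and variable recorders, an
array-driven field modifier, and sources that inject predetermined spike
trains.

Clocks illustrate how time-stepped behaviour coexists with event-driven
simulation: a clock is an ordinary element with a zero-delay recurrent
event connection from its output port 0 back to its input port 0.  Each
tick it emits an event carrying a *future* timestamp, which the engine
delivers back to it at that time, producing the next tick.  Tick times are
computed as ``start + k * dt`` (multiplication, not repeated addition) so
they carry no accumulated floating-point drift.
"""

from __future__ import annotations

import logging

from .engine import Network, NetworkElement, SimulationError

logger = logging.getLogger(__name__)

__all__ = [
    "RegularClock",
    "VariableStepClock",
    "SpikeRecorder",
    "VariableRecorder",
    "ArrayModifier",
    "SpikeTrainSource",
    "write_spike_tsv",
    "write_trace_tsv",
]


class RegularClock(NetworkElement):
    """Emits events at ``start + k*dt`` for ``k = 0, 1, 2, ...``.

    The first tick fires at run start.  Consumers connect to output port 0;
    their connection delay offsets the tick as usual.
    """

    n_in_ports = 1
    n_out_ports = 1

    def __init__(self, dt: float):
        super().__init__()
        if dt <= 0:
            raise SimulationError(f"clock interval must be > 0, got {dt}")
        self.dt = dt
        self._start = 0.0
        self._k = 0

    def wire(self, net: Network) -> None:
        net.connect(self.id, 0, self.id, 0, 0.0)

    def on_start(self, t: float) -> None:
        self._start = t
        self._k = 0
        self.net.emit(self.id, 0, t)

    def on_event(self, t: float, port: int) -> None:
        # own tick came back on the zero-delay loopback: emit the next one
        # with a future timestamp computed multiplicatively.
        self._k += 1
        self.net.emit(self.id, 0, self._start + self._k * self.dt)


class VariableStepClock(NetworkElement):
    """Clock whose k-th inter-tick interval is ``steps[k]``.

    Ticks at ``start + steps[0]``, ``start + steps[0] + steps[1]``, ... and
    stops after the schedule is exhausted.  Each tick is emitted with a
    future timestamp from within the previous tick's handler.
    """

    n_in_ports = 1
    n_out_ports = 1

    def __init__(self, steps):
        super().__init__()
        self.steps = [float(s) for s in steps]
        if any(s <= 0 for s in self.steps):
            raise SimulationError("all clock steps must be > 0")
        self._k = 0
        self._t_tick = 0.0

    def wire(self, net: Network) -> None:
        net.connect(self.id, 0, self.id, 0, 0.0)

    def _next(self) -> None:
        if self._k < len(self.steps):
            self._t_tick = self._t_tick + self.steps[self._k]
            self._k += 1
            self.net.emit(self.id, 0, self._t_tick)

    def on_start(self, t: float) -> None:
        self._k = 0
        self._t_tick = t
        self._next()

    def on_event(self, t: float, port: int) -> None:
        self._next()


class SpikeRecorder(NetworkElement):
    """Stores the delivery times of every event arriving on its input port."""

    n_in_ports = 1
    n_out_ports = 0

    def __init__(self):
        super().__init__()
        self.times: list[float] = []

    def on_event(self, t: float, port: int) -> None:
        self.times.append(t)


class VariableRecorder(NetworkElement):
    """Samples a field of a target element at a fixed rate.

    Self-clocked: sample instants are ``start + k / rate``.  The value
    recorded is ``target.field_at(name, t)``, so elements with lazily
    evaluated state (the LIF membrane) report their analytic value at the
    sampling instant.
    """

    n_in_ports = 1
    n_out_ports = 1

    def __init__(self, target_id: int, field_name: str, rate: float):
        super().__init__()
        if rate <= 0:
            raise SimulationError(f"sampling rate must be > 0, got {rate}")
        self.target_id = target_id
        self.field_name = field_name
        self.rate = rate
        self.samples: list[tuple[float, float]] = []
        self._start = 0.0
        self._k = 0

    def wire(self, net: Network) -> None:
        net.connect(self.id, 0, self.id, 0, 0.0)

    def on_start(self, t: float) -> None:
        self._start = t
        self._k = 0
        self.net.emit(self.id, 0, t)

    def on_event(self, t: float, port: int) -> None:
        target = self.net.elements[self.target_id]
        self.samples.append((t, target.field_at(self.field_name, t)))
        self._k += 1
        self.net.emit(self.id, 0, self._start + self._k / self.rate)


class ArrayModifier(NetworkElement):
    """On each input event, writes the next value of an array into a field.

    After ``k`` delivered events the target field holds
    ``values[min(k - 1, len(values) - 1)]`` — the cursor clamps at the end
    of the array (logged once) rather than erroring.  Install a causal
    update link modifier -> target so the target re-evaluates its state
    (e.g. resamples its next spike) right after the write.
    """

    n_in_ports = 1
    n_out_ports = 0

    def __init__(self, target_id: int, field_name: str, values):
        super().__init__()
        self.target_id = target_id
        self.field_name = field_name
        self.values = list(values)
        if not self.values:
            raise SimulationError("modifier needs a non-empty value array")
        self._cursor = 0
        self._clamp_logged = False

    def on_event(self, t: float, port: int) -> None:
        if self._cursor >= len(self.values):
            if not self._clamp_logged:
                self._clamp_logged = True
                logger.info(
                    "modifier %d exhausted its array; clamping to last value",
                    self.id,
                )
            idx = len(self.values) - 1
        else:
            idx = self._cursor
            self._cursor += 1
        target = self.net.elements[self.target_id]
        target.set_field(self.field_name, self.values[idx])


class SpikeTrainSource(NetworkElement):
    """Emits spikes at a predetermined, sorted list of times."""

    n_in_ports = 0
    n_out_ports = 1
    emits_spikes = True

    def __init__(self, times):
        super().__init__()
        self.times = [float(t) for t in times]
        if any(b < a for a, b in zip(self.times, self.times[1:])):
            raise SimulationError("spike times must be sorted")
        self._idx = 0

    def on_start(self, t: float) -> None:
        self._idx = 0
        while self._idx < len(self.times) and self.times[self._idx] < t:
            self._idx += 1  # skip spikes before the run window
        if self._idx < len(self.times):
            self.net.schedule_pending(self.id, self.times[self._idx])

    def on_pending(self, t: float) -> None:
        self.net.emit(self.id, 0, t, spike=True)
        self._idx += 1
        if self._idx < len(self.times):
            self.net.schedule_pending(self.id, self.times[self._idx])


def write_spike_tsv(path, trains: dict) -> None:
    """Write spike trains as two-column TSV ``element_id<TAB>time_seconds``,
    sorted by time (ties by element id)."""
    rows = sorted(
        ((t, eid) for eid, times in trains.items() for t in times)
    )
    with open(path, "w") as fh:
        for t, eid in rows:
            fh.write(f"{eid}\t{t:.9f}\n")


def write_trace_tsv(path, samples) -> None:
    """Write a variable trace as two-column TSV ``time_seconds<TAB>value``."""
    with open(path, "w") as fh:
        for t, v in samples:
            fh.write(f"{t:.9f}\t{v!r}\n")
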