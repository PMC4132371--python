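"""Shared test elements and fixtures."""

import pytest

from evspike.engine import Network, NetworkElement


class Relay(NetworkElement):
    """Re-emits every received event at the same timestamp (zero delay)."""

    n_in_ports = 1
    n_out_ports = 1

    def on_event(self, t, port):
        self.net.emit(self.id, 0, t)


class EventLogger(NetworkElement):
    """Appends ``(tag, t, port)`` to a shared list on every delivery."""

    n_in_ports = 4
    n_out_ports = 0

    def __init__(self, tag, log):
        super().__init__()
        self.tag = tag
        self.log = log

    def on_event(self, t, port):
        self.log.append((self.tag, t, port))


class UpdateLogger(NetworkElement):
    """Records ``(update_id, t)`` for every causal update it receives."""

    n_in_ports = 1
    n_out_ports = 0

    def __init__(self):
        super().__init__()
        self.updates = []

    def on_update(self, update_id, t):
        self.updates.append((update_id, t))


class Accumulator(NetworkElement):
    """Deterministic stand-in for a postsynaptic neuron.

    Records every ``add_input`` push and reconstructs the piecewise-linear
    total contribution at arbitrary query times.
    """

    n_in_ports = 0
    n_out_ports = 0

    def __init__(self):
        super().__init__()
        self.pushes = []  # (t, dvalue, dslope)
        self._value = 0.0
        self._slope = 0.0
        self._t = 0.0

    def add_input(self, t, dvalue, dslope=0.0):
        self._value += self._slope * (t - self._t) + dvalue
        self._slope += dslope
        self._t = t
        self.pushes.append((t, dvalue, dslope))

    def value_at(self, t):
        """Total contribution at ``t`` (replayed from the push history)."""
        value, slope, t_prev = 0.0, 0.0, 0.0
        for tp, dv, dm in self.pushes:
            if tp > t:
                break
            value += slope * (tp - t_prev) + dv
            slope += dm
            t_prev = tp
        return value + slope * (t - t_prev)


class FieldHolder(NetworkElement):
    """Bare element exposing one registered scalar field."""

    n_in_ports = 0
    n_out_ports = 0

    def __init__(self, name="x", value=0.0):
        super().__init__()
        self.x = value
        self.register_field(name, "x")


@pytest.fixture
def net():
    return Network(seed=1234)
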