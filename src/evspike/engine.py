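"""Event-driven simulation kernel.

A :class:`Network` is a registry of :class:`NetworkElement` instances wired
together by three distinct kinds of relations:

* **event connections** — directed routes ``(src_id, src_port) ->
  (dest_id, dest_port)`` with a fixed non-negative delay (zero is legal),
  along which timestamped point events travel;
* **couplings** — declared direct state access between two elements (one
  holds a handle to the other and reads or writes its state outside the
  event mechanism); the engine records them for introspection only;
* **causal update links** — directed edges ``(src_id, dest_id, update_id)``
  declaring that whenever ``src`` changes state, ``dest`` must run its
  update handler, tagged with an integer so one element can dispatch on
  where the update came from.

All outgoing connections of one output port that share the same delay form
an *event target group* (ETG).  An emitted event is queued once per ETG;
popping it delivers the event to every destination of the group and then
walks the group's precomputed *update array* — a topological order of the
elements reachable from the destinations through causal update links — so
state changes propagate in dependency order.

Scheduling uses two binary heaps: one for already-emitted events, and one
for *pending* events, of which each element owns at most one and may cancel
or reschedule at any time (used for predicted next-spike times).
Cancellation is lazy: stale heap entries are recognised by a per-element
token and discarded on pop.

Ties at equal timestamps are broken FIFO by scheduling sequence number, with
scheduled events taking precedence over pending events.  Together with a
single seeded random stream per network this makes runs bit-reproducible:
the same seed and the same construction script yield identical event
sequences.
"""

from __future__ import annotations

import copy
import heapq
import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "NetworkElement",
    "EventConnection",
    "CausalUpdateLink",
    "EventTargetGroup",
    "SimulationError",
    "CausalityError",
    "CycleError",
    "UnknownFieldError",
]


class SimulationError(RuntimeError):
    """Base class for errors raised by the simulation kernel."""


class CausalityError(SimulationError):
    """An event was emitted or scheduled before the current time."""


class CycleError(SimulationError):
    """The causal-update-link graph contains a directed cycle."""


class UnknownFieldError(KeyError):
    """A field name was not registered on the element."""


@dataclass(frozen=True)
class EventConnection:
    """Directed event route ``(src_id, src_port) -> (dest_id, dest_port)``."""

    src_id: int
    src_port: int
    dest_id: int
    dest_port: int
    delay: float


@dataclass(frozen=True)
class CausalUpdateLink:
    src_id: int
    dest_id: int
    update_id: int


@dataclass
class EventTargetGroup:
    """All destinations of one output port reached at one common delay."""

    src_id: int
    src_port: int
    delay: float
    dest_ids: list = field(default_factory=list)  # [(dest_id, dest_port)]
    # resolved at finalize():
    destinations: list = field(default_factory=list)  # [(element, port)]
    update_array: list = field(default_factory=list)  # [(element, update_id)]


class NetworkElement:
    """Base class for all simulated nodes.

    Subclasses declare ``n_in_ports`` / ``n_out_ports`` and override the
    handlers they need.  Elements are *prototypes*: :meth:`Network.create`
    deep-copies the instance passed to it, so one prototype can seed many
    live elements.
    """

    n_in_ports: int = 1
    n_out_ports: int = 1
    #: emissions from this element count as spikes in run summaries
    emits_spikes: bool = False

    def __init__(self):
        self.id: int | None = None
        self.net: Network | None = None
        self._fields: dict[str, str] = {}
        self._pending_token = 0
        self._pending_time: float | None = None

    # -- field metadata ------------------------------------------------

    def register_field(self, name: str, attr: str) -> None:
        """Expose attribute ``attr`` under the public field name ``name``."""
        self._fields[name] = attr

    def field_names(self):
        return set(self._fields)

    def _resolve_field(self, name: str) -> str:
        try:
            return self._fields[name]
        except KeyError:
            avail = ", ".join(sorted(self._fields)) or "<none>"
            raise UnknownFieldError(
                f"element {self.id} ({type(self).__name__}) has no field "
                f"{name!r}; available fields: {avail}"
            ) from None

    def get_field(self, name: str):
        return getattr(self, self._resolve_field(name))

    def set_field(self, name: str, value) -> None:
        setattr(self, self._resolve_field(name), value)

    def field_at(self, name: str, t: float):
        """Value of a field at time ``t``; default ignores ``t``.

        Elements with lazily-evaluated state (e.g. a decaying membrane)
        override this so recorders see the analytic value at the sampling
        instant rather than the stored state at the last event.
        """
        return self.get_field(name)

    # -- wiring hook ---------------------------------------------------

    def wire(self, net: "Network") -> None:
        """Install construction-time connections (e.g. recurrent loopbacks).

        Called by :meth:`Network.create` right after the element is
        registered and has received its ID.
        """

    # -- simulation handlers -------------------------------------------

    def on_start(self, t: float) -> None:
        """Called once, in ID order, when the run begins."""

    def on_event(self, t: float, port: int) -> None:
        """An event was delivered to input port ``port`` at time ``t``."""

    def on_update(self, update_id: int, t: float) -> None:
        """A causal update link fired; dispatch on ``update_id``."""

    def on_pending(self, t: float) -> None:
        """The element's pending (cancellable) event came due."""

    def describe_fields(self) -> dict:
        return {name: self.get_field(name) for name in self._fields}


class Network:
    """Element registry, wiring tables, and the event-driven run loop.

    Parameters
    ----------
    seed
        Seed for the single pseudo-random stream shared by all stochastic
        elements.  Equal seeds plus equal construction order give
        byte-identical runs.
    max_events_per_timepoint
        Guard against runaway zero-delay loops: exceeding this many event
        deliveries at one identical timestamp raises :class:`SimulationError`.
    """

    def __init__(self, seed=None, max_events_per_timepoint: int = 1_000_000):
        self.rng = np.random.default_rng(seed)
        self.elements: list[NetworkElement] = []
        self.connections: list[EventConnection] = []
        self.update_links: list[CausalUpdateLink] = []
        self.couplings: list[tuple[int, int]] = []
        self._etgs: dict[tuple, EventTargetGroup] = {}
        self._etgs_by_port: dict[tuple, list[EventTargetGroup]] = {}
        self.finalized = False
        self.current_time = 0.0
        self.max_events_per_timepoint = max_events_per_timepoint
        self._sched: list = []  # (time, seq, etg)
        self._pend: list = []  # (time, seq, element, token)
        self._seq = 0
        self._started = False
        self.n_delivered = 0
        self.n_emissions = 0
        self.n_spikes = 0

    # -- construction --------------------------------------------------

    def create(self, prototype: NetworkElement) -> int:
        """Register a deep copy of ``prototype``; return its new ID."""
        if self.finalized:
            raise SimulationError("cannot create elements after finalize()")
        if not isinstance(prototype, NetworkElement):
            raise SimulationError(
                f"prototype must be a NetworkElement, got {type(prototype).__name__}"
            )
        if prototype.n_in_ports < 0 or prototype.n_out_ports < 0:
            raise SimulationError("port counts must be non-negative")
        el = copy.deepcopy(prototype)
        el.id = len(self.elements)
        el.net = self
        self.elements.append(el)
        el.wire(self)
        return el.id

    def element(self, elem_id: int) -> NetworkElement:
        try:
            return self.elements[elem_id]
        except IndexError:
            raise SimulationError(f"unknown element ID {elem_id}") from None

    def _check_port(self, elem_id: int, port: int, kind: str) -> None:
        el = self.element(elem_id)
        n = el.n_out_ports if kind == "out" else el.n_in_ports
        if not 0 <= port < n:
            raise SimulationError(
                f"element {elem_id} ({type(el).__name__}) has {n} {kind}put "
                f"port(s); port {port} is out of range"
            )

    def connect(self, src_id, src_port, dest_id, dest_port, delay) -> None:
        """Add an event connection; groups it into the ETG for its key."""
        if self.finalized:
            raise SimulationError("cannot connect after finalize()")
        if delay < 0:
            raise SimulationError(f"connection delay must be >= 0, got {delay}")
        self._check_port(src_id, src_port, "out")
        self._check_port(dest_id, dest_port, "in")
        self.connections.append(
            EventConnection(src_id, src_port, dest_id, dest_port, delay)
        )
        key = (src_id, src_port, delay)
        etg = self._etgs.get(key)
        if etg is None:
            etg = EventTargetGroup(src_id, src_port, delay)
            self._etgs[key] = etg
            self._etgs_by_port.setdefault((src_id, src_port), []).append(etg)
        etg.dest_ids.append((dest_id, dest_port))

    def add_update_link(self, src_id, dest_id, update_id) -> None:
        self.element(src_id)
        self.element(dest_id)
        self.update_links.append(CausalUpdateLink(src_id, dest_id, update_id))

    def register_coupling(self, src_id, dest_id) -> None:
        self.element(src_id)
        self.element(dest_id)
        self.couplings.append((src_id, dest_id))

    # -- finalize: ETG update arrays -----------------------------------

    def finalize(self) -> None:
        """Freeze topology; precompute per-ETG update arrays.

        For every ETG the update array holds the elements reachable from the
        group's destinations through causal update links, in a topological
        order of the link graph, each paired with the update_id of the link
        it was first reached through.  Raises :class:`CycleError` (naming a
        member) if the global link graph has a directed cycle.
        """
        if self.finalized:
            raise SimulationError("finalize() called twice")

        g = nx.DiGraph()
        g.add_nodes_from(range(len(self.elements)))
        adj: dict[int, list[CausalUpdateLink]] = {}
        for link in self.update_links:
            g.add_edge(link.src_id, link.dest_id)
            adj.setdefault(link.src_id, []).append(link)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            member = cycle[0][0]
            raise CycleError(
                f"causal update links form a cycle through element {member} "
                f"({type(self.elements[member]).__name__})"
            )

        for etg in self._etgs.values():
            etg.destinations = [
                (self.elements[d], p) for d, p in etg.dest_ids
            ]
            etg.update_array = self._build_update_array(
                {d for d, _ in etg.dest_ids}, adj
            )

        self.finalized = True
        max_ua = max(
            (len(e.update_array) for e in self._etgs.values()), default=0
        )
        logger.info(
            "finalize: %d elements, %d connections, %d ETGs, "
            "max update-array length %d",
            len(self.elements), len(self.connections), len(self._etgs), max_ua,
        )

    def _build_update_array(self, roots: set, adj) -> list:
        """Kahn's algorithm on the link subgraph reachable from ``roots``.

        Returns ``[(element, update_id), ...]`` excluding the roots
        themselves (they receive the event directly), ordered so every link
        source precedes its target.  The update_id attached to a node is
        taken from the first link (in insertion order) through which it is
        reachable within the subgraph.
        """
        # reachable closure
        closure = set(roots)
        stack = list(roots)
        while stack:
            for link in adj.get(stack.pop(), ()):
                if link.dest_id not in closure:
                    closure.add(link.dest_id)
                    stack.append(link.dest_id)
        indeg = {n: 0 for n in closure}
        for n in closure:
            for link in adj.get(n, ()):
                if link.dest_id in closure:
                    indeg[link.dest_id] += 1
        uid: dict[int, int] = {}
        for link in self.update_links:  # global insertion order
            if (link.src_id in closure and link.dest_id in closure
                    and link.dest_id not in uid):
                uid[link.dest_id] = link.update_id
        # deterministic Kahn: ready set kept sorted by element id
        ready = sorted(n for n in closure if indeg[n] == 0)
        order = []
        while ready:
            n = ready.pop(0)
            order.append(n)
            newly = []
            for link in adj.get(n, ()):
                d = link.dest_id
                if d in closure:
                    indeg[d] -= 1
                    if indeg[d] == 0:
                        newly.append(d)
            for d in sorted(newly):
                # insert keeping ready sorted
                lo = 0
                while lo < len(ready) and ready[lo] < d:
                    lo += 1
                ready.insert(lo, d)
        assert len(order) == len(closure)
        return [
            (self.elements[n], uid.get(n, 0)) for n in order if n not in roots
        ]

    # -- event emission and pending slots ------------------------------

    def emit(self, src_id: int, out_port: int, timestamp: float,
             spike: bool = False) -> None:
        """Queue one event per ETG of ``(src_id, out_port)`` at ``timestamp + delay``.

        ``timestamp`` may lie in the future (variable-step clocks exploit
        this) but never in the past.
        """
        if timestamp < self.current_time:
            raise CausalityError(
                f"element {src_id} emitted at t={timestamp} < current time "
                f"{self.current_time}"
            )
        self.n_emissions += 1
        if spike:
            self.n_spikes += 1
        for etg in self._etgs_by_port.get((src_id, out_port), ()):
            self._seq += 1
            heapq.heappush(self._sched, (timestamp + etg.delay, self._seq, etg))

    def schedule_pending(self, owner_id: int, time: float) -> None:
        """Replace the owner's single cancellable slot with one at ``time``."""
        if time < self.current_time:
            raise CausalityError(
                f"pending event for element {owner_id} scheduled at "
                f"t={time} < current time {self.current_time}"
            )
        el = self.elements[owner_id]
        el._pending_token += 1  # invalidates any live heap entry
        el._pending_time = time
        self._seq += 1
        heapq.heappush(self._pend, (time, self._seq, el, el._pending_token))

    def cancel_pending(self, owner_id: int) -> None:
        el = self.elements[owner_id]
        el._pending_token += 1
        el._pending_time = None

    def pending_time(self, owner_id: int):
        """Time of the owner's live pending event, or None."""
        return self.elements[owner_id]._pending_time

    # -- run loop -------------------------------------------------------

    def run(self, duration: float) -> dict:
        """Advance the simulation by ``duration`` seconds of model time.

        Repeatedly pops the earliest head of the two queues (scheduled
        before pending at equal times, FIFO within each), delivers the
        event, and walks the ETG's update array.  Returns a summary dict.
        """
        if not self.finalized:
            raise SimulationError("run() requires finalize() first")
        if not self._started:
            self._started = True
            t0 = self.current_time
            for el in self.elements:
                el.on_start(t0)
        t_end = self.current_time + duration
        sched, pend = self._sched, self._pend
        delivered0, spikes0 = self.n_delivered, self.n_spikes
        guard_t = -1.0
        guard_n = 0
        guard_max = self.max_events_per_timepoint

        while sched or pend:
            if sched and (not pend or sched[0][0] <= pend[0][0]):
                t = sched[0][0]
                if t > t_end:
                    break
                _, _, etg = heapq.heappop(sched)
                if t < self.current_time:  # pragma: no cover - invariant
                    raise CausalityError("non-monotone event delivery")
                self.current_time = t
                ndest = len(etg.destinations)
                self.n_delivered += ndest
                for el, port in etg.destinations:
                    el.on_event(t, port)
                for el, update_id in etg.update_array:
                    el.on_update(update_id, t)
                if t == guard_t:
                    guard_n += ndest
                    if guard_n > guard_max:
                        raise SimulationError(
                            f"more than {guard_max} event deliveries at "
                            f"t={t}: runaway zero-delay loop?"
                        )
                else:
                    guard_t, guard_n = t, ndest
            else:
                t = pend[0][0]
                if t > t_end:
                    break
                _, _, el, token = heapq.heappop(pend)
                if token != el._pending_token:
                    continue  # lazily cancelled
                self.current_time = t
                el._pending_token += 1  # slot consumed
                el._pending_time = None
                el.on_pending(t)

        self.current_time = t_end
        summary = {
            "events_delivered": self.n_delivered - delivered0,
            "spikes": self.n_spikes - spikes0,
            "final_time": self.current_time,
        }
        logger.info(
            "run: %(events_delivered)d events, %(spikes)d spikes, "
            "t=%(final_time)g s", summary,
        )
        return summary

    # -- introspection --------------------------------------------------

    def describe(self) -> dict:
        """JSON-serialisable dump of the network structure."""
        return {
            "elements": [
                {
                    "id": el.id,
                    "type": type(el).__name__,
                    "fields": el.describe_fields(),
                }
                for el in self.elements
            ],
            "connections": [
                [c.src_id, c.src_port, c.dest_id, c.dest_port, c.delay]
                for c in self.connections
            ],
            "update_links": [
                [l.src_id, l.dest_id, l.update_id] for l in self.update_links
            ],
            "couplings": [list(c) for c in self.couplings],
        }

    def dump_description(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.describe(), fh, indent=1)
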