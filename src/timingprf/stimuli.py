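"""Visual event-timing stimulus schedules.

The experiment presents a small circle that repeatedly appears (for the event
*duration*) and recurs (at the event *period*).  Four stimulus configurations
decorrelate duration, period, mean display luminance (occupancy) and event
frequency:

``constant_luminance``
    duration == period per state, so an event is always ongoing.
``constant_duration``
    50 ms events with varying period.
``constant_period``
    varying duration with a fixed 1000 ms period.
``gaps``
    four shorter progressions co-varying duration and period to sample
    timings the other configurations miss.

Each configuration block lasts 56 fMRI volumes of TR 2.1 s (117.6 s).  The
three main configurations run an ascending 20-state progression (50 -> 1000 ms
in 50 ms steps, one state per TR), a 16.8 s baseline, the descending
progression and a second 16.8 s baseline.  Baseline events use 2000 ms
duration and/or 2100 ms period, which drive monotonic responses strongly but
sub-second tuned responses weakly.  A run presents all four configurations
once, in one of the 24 possible orders.

All event times live on a 50 ms grid (the 20 frame/s display update) and are
handled internally as integer ticks, so schedule arithmetic is exact.  The
timing state changes at the event onset nearest each nominal TR boundary;
both nominal and realized change times are retained and analyses use the
realized (presented) event times.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GRID = 0.05
"""Event time resolution in seconds (display updates at 20 frames/s)."""

TR_DEFAULT = 2.1
N_VOLUMES_BLOCK = 56

CONFIGURATIONS = (
    "constant_luminance",
    "constant_duration",
    "constant_period",
    "gaps",
)


def _ticks(seconds: float) -> int:
    t = round(seconds / GRID)
    if abs(t * GRID - seconds) > 1e-9:
        raise ValueError(f"{seconds} s is not on the {GRID} s event grid")
    return t


@dataclass(frozen=True)
class TimingState:
    """One presented event timing: duration and period in seconds."""

    duration: float
    period: float

    def __post_init__(self) -> None:
        if not (0.0 < self.duration <= self.period):
            raise ValueError(
                f"require 0 < duration <= period, got ({self.duration}, {self.period})"
            )


@dataclass(frozen=True)
class DerivedTiming:
    """Equivalent two-parameter descriptions of a timing state.

    ``frequency`` is 1/period (Hz); ``inter_event_interval`` is the offset to
    next-onset gap (s); ``occupancy`` is the duty cycle duration/period, which
    is proportional to mean display luminance.
    """

    frequency: float
    inter_event_interval: float
    occupancy: float


def derive_timing(state: TimingState) -> DerivedTiming:
    """Convert (duration, period) to the equivalent (frequency, ISI, occupancy)."""
    return DerivedTiming(
        frequency=1.0 / state.period,
        inter_event_interval=state.period - state.duration,
        occupancy=state.duration / state.period,
    )


def state_from_interval(duration: float, interval: float) -> TimingState:
    return TimingState(duration=duration, period=duration + interval)


def state_from_occupancy(period: float, occupancy: float) -> TimingState:
    return TimingState(duration=period * occupancy, period=period)


@dataclass
class EventSchedule:
    """Realized event times for one configuration block.

    ``events`` is a DataFrame with columns onset, offset, duration, period,
    state_index (seconds; exact multiples of :data:`GRID`).  ``states`` holds
    the nominal :class:`TimingState` active during each TR.
    """

    configuration: str
    events: pd.DataFrame
    states: list[TimingState]
    tr: float = TR_DEFAULT
    n_volumes: int = N_VOLUMES_BLOCK
    nominal_changes: np.ndarray = field(default_factory=lambda: np.array([]))
    realized_changes: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def total_duration(self) -> float:
        return self.n_volumes * self.tr

    @property
    def n_ticks(self) -> int:
        return _ticks(self.tr) * self.n_volumes


@dataclass
class RunSchedule:
    """Four configuration blocks concatenated in a given order."""

    order: tuple[str, ...]
    blocks: dict[str, EventSchedule]
    events: pd.DataFrame
    tr: float = TR_DEFAULT

    @property
    def n_volumes(self) -> int:
        return sum(b.n_volumes for b in self.blocks.values())

    @property
    def total_duration(self) -> float:
        return self.n_volumes * self.tr

    @property
    def n_ticks(self) -> int:
        return _ticks(self.tr) * self.n_volumes


def _main_progression(name: str, step: float) -> list[TimingState]:
    k = np.arange(1, 21)
    if name == "constant_luminance":
        pairs = [(round(step * i, 10), round(step * i, 10)) for i in k]
    elif name == "constant_duration":
        pairs = [(step, round(step * i, 10)) for i in k]
    elif name == "constant_period":
        pairs = [(round(step * i, 10), round(20 * step, 10)) for i in k]
    else:  # pragma: no cover - guarded by caller
        raise ValueError(name)
    return [TimingState(d, p) for d, p in pairs]


def _baseline_state(name: str) -> TimingState:
    # 2000 ms duration events and/or 2100 ms periods, depending on which
    # parameter the configuration holds constant.
    if name == "constant_duration":
        return TimingState(0.05, 2.1)
    return TimingState(2.0, 2.1)


def _gaps_progressions() -> list[list[TimingState]]:
    def st(d, p):
        return TimingState(round(d, 10), round(p, 10))

    k = np.arange(10)
    progs = []
    progs.append([st(0.05 + 0.05 * i, 0.95 - 0.05 * i) for i in k])
    progs.append([st(0.05 + 0.05 * i, 0.55 + 0.05 * i) for i in k])
    progs.append([st(0.50 - 0.05 * i, 0.50 + 0.05 * i) for i in k])
    progs.append([st(0.50 - 0.05 * i, 1.00 - 0.05 * i) for i in k])
    return progs


def _segment_plan(name: str, tr: float, step: float) -> list[tuple[TimingState, int]]:
    """(state, nominal tick length) segments composing one block."""
    tr_ticks = _ticks(tr)
    if name == "gaps":
        if abs(step - GRID) > 1e-9:
            raise ValueError("gaps progressions are defined on the 50 ms step")
        base = TimingState(0.05, 2.1)
        plan: list[tuple[TimingState, int]] = []
        progs = _gaps_progressions()
        for i, prog in enumerate(progs):
            plan.extend((s, tr_ticks) for s in prog)
            if i < 3:
                plan.append((base, 3 * tr_ticks))  # 6.3 s
        plan.append((base, 7 * tr_ticks))  # 14.7 s
        return plan
    asc = _main_progression(name, step)
    base = _baseline_state(name)
    plan = [(s, tr_ticks) for s in asc]
    plan.append((base, 8 * tr_ticks))  # 16.8 s
    plan.extend((s, tr_ticks) for s in asc[::-1])
    plan.append((base, 8 * tr_ticks))
    return plan


def make_configuration(
    name: str, tr: float = TR_DEFAULT, step: float = GRID
) -> EventSchedule:
    """Generate the realized event schedule for one configuration block.

    Events repeat at the active state's period; the state advances at the
    event onset nearest each nominal segment boundary, so realized change
    times deviate from nominal ones by at most half the current period.
    """
    if name not in CONFIGURATIONS:
        raise ValueError(f"unknown configuration {name!r}; expected one of {CONFIGURATIONS}")
    if tr <= 0 or step <= 0:
        raise ValueError("tr and step must be positive")
    tr_ticks = _ticks(tr)
    plan = _segment_plan(name, tr, step)
    n_ticks = N_VOLUMES_BLOCK * tr_ticks
    assert sum(n for _, n in plan) == n_ticks

    nominal = np.cumsum([0] + [n for _, n in plan])  # segment boundaries, ticks
    realized = [0]
    rows = []
    t = 0
    for i, (state, _) in enumerate(plan):
        p = _ticks(state.period)
        d = _ticks(state.duration)
        b_next = nominal[i + 1]
        # emit events of this state while the current onset is nearer this
        # segment than the next boundary is
        while 2 * (b_next - t) > p:
            if t >= n_ticks or t + d > n_ticks:
                break
            rows.append((t, t + d, state.duration, state.period, i))
            t += p
        realized.append(t)

    events = pd.DataFrame(
        rows, columns=["onset_t", "offset_t", "duration", "period", "state_index"]
    )
    events["onset"] = events.pop("onset_t") * GRID
    events["offset"] = events.pop("offset_t") * GRID
    events = events[["onset", "offset", "duration", "period", "state_index"]]

    # nominal per-TR state
    seg_of_tick = np.searchsorted(nominal, np.arange(N_VOLUMES_BLOCK) * tr_ticks, "right") - 1
    states = [plan[j][0] for j in seg_of_tick]
    return EventSchedule(
        configuration=name,
        events=events,
        states=states,
        tr=tr,
        n_volumes=N_VOLUMES_BLOCK,
        nominal_changes=nominal[1:-1] * GRID,
        realized_changes=np.array(realized[1:-1]) * GRID,
    )


def make_run(
    order: tuple[str, ...] = CONFIGURATIONS,
    tr: float = TR_DEFAULT,
    step: float = GRID,
) -> RunSchedule:
    """Concatenate the four configuration blocks in ``order`` into one run."""
    order = tuple(order)
    if sorted(order) != sorted(CONFIGURATIONS):
        raise ValueError(
            f"order must be a permutation of {CONFIGURATIONS}, got {order!r}"
        )
    blocks = {}
    tables = []
    offset_s = 0.0
    for name in order:
        block = make_configuration(name, tr=tr, step=step)
        blocks[name] = block
        tab = block.events.copy()
        tab["onset"] += offset_s
        tab["offset"] += offset_s
        tab["configuration"] = name
        tables.append(tab)
        offset_s += block.total_duration
    events = pd.concat(tables, ignore_index=True)
    return RunSchedule(order=order, blocks=blocks, events=events, tr=tr)


def all_run_orders() -> list[tuple[str, ...]]:
    """All 24 configuration orders (one run each, per subject)."""
    return [tuple(p) for p in itertools.permutations(CONFIGURATIONS)]


# ---------------------------------------------------------------------------
# BIDS-events-style TSV I/O

_EVENT_COLUMNS = ["onset", "duration", "period", "configuration", "state_index"]


def write_events_tsv(schedule: EventSchedule | RunSchedule, path) -> None:
    """Write a schedule as a BIDS-events-style TSV (seconds, 6 decimals)."""
    tab = schedule.events.copy()
    if "configuration" not in tab.columns:
        tab["configuration"] = schedule.configuration
    tab = tab[_EVENT_COLUMNS]
    tab.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events_tsv(path) -> pd.DataFrame:
    """Read a schedule TSV, validating the expected column schema."""
    tab = pd.read_csv(path, sep="\t")
    missing = [c for c in _EVENT_COLUMNS if c not in tab.columns]
    if missing:
        raise ValueError(f"events table missing column(s): {', '.join(missing)}")
    return tab
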