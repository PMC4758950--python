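"""Event-driven stochastic simulation of microtubule dynamic instability,
with and without coupling to plus-end-directed motor traffic.

Four simulators are provided, in increasing order of mechanism:

``simulate_reset_process``
    Growth punctuated by Poisson catastrophes with instantaneous reset to
    zero length — the minimal process whose mean length is the closed form
    :func:`kip2mt.model_core.expected_length`.
``simulate_dynamic_instability``
    The standard two-state model: growth and shrinkage at constant speeds,
    exponential waiting times to catastrophe and rescue, renucleation when
    a shrinking filament reaches the seed.
``simulate_coupled``
    The antenna positive-feedback model: motors land along the filament in
    proportion to its length, walk to the plus end, accumulate in a finite
    end pool, and the instantaneous growth rate and catastrophe propensity
    are set by the pool occupancy.
``simulate_single_molecule_runs``
    Single-motor runs on a stabilized lattice with exponential run length,
    Gaussian velocity, exponential end residence, and photobleaching as a
    competing exponential clock.

All waiting times are sampled exactly (first-reaction Gillespie); rates
are piecewise constant between events, so no time-stepping error exists.
Randomness derives from a single integer seed through
``numpy.random.SeedSequence`` spawning (:func:`substreams`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .params import CouplingParams, DynamicsParams, MotorParams

__all__ = [
    "EventRecord",
    "Trajectory",
    "MotorRun",
    "substreams",
    "simulate_reset_process",
    "simulate_dynamic_instability",
    "simulate_coupled",
    "simulate_single_molecule_runs",
]

TRAJECTORY_SCHEMA_VERSION = 1


def substreams(seed: int, n: int) -> list[np.random.Generator]:
    """Expand one root seed into ``n`` independent generators.

    Uses ``SeedSequence(seed).spawn(n)``; the i-th child is a documented,
    reproducible function of (seed, i), so per-trajectory streams never
    overlap and adding trajectories never perturbs earlier ones.
    """
    return [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass(frozen=True)
class EventRecord:
    """One transition of the filament state machine."""

    time: float          # min
    kind: str            # catastrophe | rescue | reset_to_seed | nucleation
    length_at_event: float  # um

    def __post_init__(self):
        if self.kind not in ("catastrophe", "rescue", "reset_to_seed", "nucleation"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.length_at_event < -1e-12:
            raise ValueError("length_at_event must be >= 0")


@dataclass
class Trajectory:
    """Event-resolved filament length history.

    ``times``/``lengths`` are the vertices of the piecewise-linear length
    path; ``phases[i]`` labels the segment between vertex i and i+1
    ('growing' or 'shrinking').  ``end_occupancy[i]``, present for
    motor-coupled runs, is the plus-end motor count on that segment.
    """

    times: np.ndarray
    lengths: np.ndarray
    phases: np.ndarray
    events: list[EventRecord]
    end_occupancy: np.ndarray | None = None
    rng_seed: int | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.phases = np.asarray(self.phases, dtype=object)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("vertex times must be strictly increasing")
        if np.any(self.lengths < -1e-9):
            raise ValueError("lengths must be >= 0")
        if len(self.phases) != len(self.times) - 1:
            raise ValueError("need one phase label per segment")

    def length_at(self, t):
        """Interpolate filament length (um) at time(s) ``t`` (min)."""
        return np.interp(t, self.times, self.lengths)

    def to_frame(self, mt_id: str = "mt0") -> pd.DataFrame:
        occ = (self.end_occupancy if self.end_occupancy is not None
               else np.full(len(self.phases), np.nan))
        return pd.DataFrame({
            "mt_id": mt_id,
            "time_min": self.times[:-1],
            "length_um": self.lengths[:-1],
            "phase": self.phases,
            "end_occupancy": occ,
        })

    def event_log_json(self) -> str:
        """Serialize the event list to the versioned JSON event-log dialect."""
        return json.dumps({
            "schema": "kip2mt.trajectory_events",
            "version": TRAJECTORY_SCHEMA_VERSION,
            "rng_seed": self.rng_seed,
            "events": [asdict(e) for e in self.events],
        })

    @staticmethod
    def events_from_json(text: str) -> list[EventRecord]:
        doc = json.loads(text)
        if doc.get("schema") != "kip2mt.trajectory_events":
            raise ValueError("not a kip2mt trajectory event log")
        if doc.get("version") != TRAJECTORY_SCHEMA_VERSION:
            raise ValueError(f"unsupported event-log version {doc.get('version')}")
        return [EventRecord(**e) for e in doc["events"]]


@dataclass(frozen=True)
class MotorRun:
    """One single-molecule run on a (stabilized) microtubule lattice."""

    landing_position: float   # um from the minus end (nan if lattice unbounded)
    velocity: float           # um/min, this molecule's speed
    run_distance: float       # um actually travelled on the lattice
    run_time: float           # s spent on the lattice
    reached_end: bool
    end_dwell: float          # s in the plus-end pool (0 unless reached_end)
    terminated_by: str        # detach | bleach | end_release

    def __post_init__(self):
        if self.terminated_by not in ("detach", "bleach", "end_release"):
            raise ValueError(f"unknown termination {self.terminated_by!r}")
        if self.end_dwell > 0 and not self.reached_end:
            raise ValueError("end_dwell > 0 requires reached_end")


# ---------------------------------------------------------------------------
# (a) instant-reset growth/catastrophe process


def simulate_reset_process(d: DynamicsParams, t_end: float, n_trials: int,
                           seed: int) -> tuple[float, float]:
    """Ensemble mean length (and its standard error) at ``t_end`` of the
    instant-reset process: grow at v+, catastrophe at rate f+-, reset to 0.

    The length at ``t_end`` is v+ times the backward recurrence time of a
    Poisson process, simulated literally by accumulating exponential
    interarrival times per trial.

    Returns ``(mean, se)`` in um.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    f = d.catastrophe_freq
    if f == 0:
        lengths = np.full(n_trials, d.growth_rate * t_end)
        return float(lengths.mean()), 0.0

    last_event = np.zeros(n_trials)   # time of most recent catastrophe
    t_next = rng.exponential(1.0 / f, n_trials)
    active = t_next <= t_end
    while active.any():
        idx = np.flatnonzero(active)
        last_event[idx] = t_next[idx]
        t_next[idx] += rng.exponential(1.0 / f, idx.size)
        active[idx] = t_next[idx] <= t_end
    lengths = d.growth_rate * (t_end - last_event)
    se = float(lengths.std(ddof=1) / math.sqrt(n_trials)) if n_trials > 1 else 0.0
    return float(lengths.mean()), se


# ---------------------------------------------------------------------------
# (b) full two-state dynamic instability


def simulate_dynamic_instability(d: DynamicsParams, t_end: float, seed,
                                 L0: float = 0.0,
                                 nucleation_delay: float = 0.0) -> Trajectory:
    """Simulate one filament for ``t_end`` minutes of two-state dynamic
    instability starting from length ``L0`` in the growing state.

    Catastrophes (rate f+-) interrupt growth; shrinkage at v- ends either
    by rescue (rate f-+) or by reaching the seed (length 0), where the
    filament renucleates — instantly by default, or after an exponential
    delay with mean ``nucleation_delay`` minutes.

    ``seed`` may be an integer or a ``numpy.random.Generator`` (the latter
    lets callers hand in a substream).
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed))))
    times, lengths, phases = [0.0], [float(L0)], []
    events: list[EventRecord] = []
    t, L, growing = 0.0, float(L0), True
    while t < t_end:
        if growing:
            dt = (rng.exponential(1.0 / d.catastrophe_freq)
                  if d.catastrophe_freq > 0 else math.inf)
            if t + dt >= t_end:
                L += d.growth_rate * (t_end - t)
                times.append(t_end); lengths.append(L); phases.append("growing")
                break
            t += dt
            L += d.growth_rate * dt
            times.append(t); lengths.append(L); phases.append("growing")
            events.append(EventRecord(t, "catastrophe", L))
            growing = False
            if d.shrink_rate == 0:
                raise ValueError("catastrophe occurred but shrink_rate is 0")
        else:
            t_rescue = (rng.exponential(1.0 / d.rescue_freq)
                        if d.rescue_freq > 0 else math.inf)
            t_zero = L / d.shrink_rate
            dt = min(t_rescue, t_zero)
            if t + dt >= t_end:
                L -= d.shrink_rate * (t_end - t)
                times.append(t_end); lengths.append(L); phases.append("shrinking")
                break
            t += dt
            if t_rescue < t_zero:
                L -= d.shrink_rate * dt
                times.append(t); lengths.append(L); phases.append("shrinking")
                events.append(EventRecord(t, "rescue", L))
            else:
                L = 0.0
                times.append(t); lengths.append(L); phases.append("shrinking")
                events.append(EventRecord(t, "reset_to_seed", 0.0))
                if nucleation_delay > 0:
                    delay = rng.exponential(nucleation_delay)
                    t_nuc = t + delay
                    if t_nuc >= t_end:
                        times.append(t_end); lengths.append(0.0); phases.append("growing")
                        break
                    t = t_nuc
                    times.append(t); lengths.append(0.0); phases.append("growing")
                    events.append(EventRecord(t, "nucleation", 0.0))
            growing = True
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return Trajectory(np.array(times), np.array(lengths), np.array(phases, dtype=object),
                      events, rng_seed=seed_val)


# ---------------------------------------------------------------------------
# (c) coupled motor-filament antenna model


def _sample_landing_time(rng, k: float, L0: float, slope: float,
                         horizon: float) -> float:
    """Waiting time to the next landing under rate k*(L0 + slope*t),
    valid while the rate stays nonnegative and t <= horizon.

    Exact inversion of the integrated rate Lambda(t) = k*(L0 t + s t^2/2)
    against a unit exponential draw; returns inf if no landing occurs
    before the rate hits zero or the horizon.
    """
    if k <= 0 or (L0 <= 0 and slope <= 0):
        return math.inf
    target = rng.exponential(1.0)
    t_stop = horizon if slope >= 0 else min(horizon, L0 / -slope)
    lam_stop = k * (L0 * t_stop + 0.5 * slope * t_stop * t_stop)
    if target > lam_stop:
        return math.inf
    if abs(slope) < 1e-15:
        return target / (k * L0)
    # solve 0.5*s*t^2 + L0*t - target/k = 0 for the smallest positive root
    a, b, c = 0.5 * slope, L0, -target / k
    disc = b * b - 4 * a * c
    t = (-b + math.sqrt(max(disc, 0.0))) / (2 * a)
    if t < 0:
        t = (-b - math.sqrt(max(disc, 0.0))) / (2 * a)
    return t


def simulate_coupled(d0: DynamicsParams, m: MotorParams, p: CouplingParams,
                     c: float, t_end: float, seed,
                     L0: float = 0.0) -> Trajectory:
    """Simulate the antenna positive-feedback model for one filament.

    Motors land along the lattice as a Poisson process with instantaneous
    rate ``landing_rate * c * L(t)``, walk toward the plus end at
    ``velocity_dynamic``, detach with rate velocity/run_length, join the
    plus-end pool on arrival (capacity ``end_capacity``; arrivals at a
    full pool are turned away), and leave the pool with rate
    60/end_residence.  The filament obeys two-state dynamic instability
    whose growth rate and catastrophe frequency are linear in the pool
    occupancy ``N``::

        v = v0 + (vmax - v0) * N / end_capacity
        f = f0 - (f0 - fmin) * N / end_capacity

    Shrinkage releases motors as the tip depolymerizes past them; a
    catastrophe disperses the end pool; reaching the seed releases
    everything and renucleates instantly.  At ``c = 0`` the model is the
    plain two-state simulator (same substream, identical trajectory).

    All inter-event rates are constant between events and all waiting
    times are sampled exactly; the length-proportional landing process is
    sampled by closed-form inversion of its integrated rate.
    """
    if c < 0:
        raise ValueError("concentration must be >= 0")
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed))))
    if c == 0:
        traj = simulate_dynamic_instability(d0, t_end, rng, L0=L0)
        traj.end_occupancy = np.zeros(len(traj.phases))
        return traj

    vm = m.velocity_dynamic
    detach = m.detach_rate
    release = m.end_release_rate
    k_land = m.landing_rate * c
    n_sat = m.end_capacity

    def v_of(n):  # um/min
        return p.v0 + (p.vmax - p.v0) * n / n_sat

    def f_of(n):  # 1/min
        return p.f0 - (p.f0 - p.fmin) * n / n_sat

    # lattice motors: x_i(t) = b_i + vm * t  (all share the same speed)
    b: list[float] = []
    n_end = 0
    t, L, growing = 0.0, float(L0), True
    times, lengths, phases, occs = [0.0], [float(L0)], [], []
    events: list[EventRecord] = []

    def record_vertex(tv, Lv, phase_label):
        times.append(tv); lengths.append(max(Lv, 0.0))
        phases.append(phase_label); occs.append(n_end)

    while t < t_end:
        slope = v_of(n_end) if growing else -d0.shrink_rate
        phase_label = "growing" if growing else "shrinking"
        horizon = t_end - t

        # candidate waiting times (all measured from t)
        w_land = _sample_landing_time(rng, k_land, L, slope, horizon)
        w_detach = rng.exponential(1.0 / (len(b) * detach)) if b else math.inf
        w_release = rng.exponential(1.0 / (n_end * release)) if n_end else math.inf
        if growing:
            f_now = f_of(n_end)
            w_switch = rng.exponential(1.0 / f_now) if f_now > 0 else math.inf
            w_zero = math.inf
        else:
            w_switch = (rng.exponential(1.0 / d0.rescue_freq)
                        if d0.rescue_freq > 0 else math.inf)
            w_zero = L / d0.shrink_rate if d0.shrink_rate > 0 else math.inf
        # deterministic tip crossing: closest lattice motor meets the tip
        if b:
            bmax_i = max(range(len(b)), key=b.__getitem__)
            gap = (L + slope * 0 + 0) - (b[bmax_i] + vm * t)  # current gap
            closing = vm - slope
            w_tip = gap / closing if closing > 1e-12 and gap >= -1e-9 else math.inf
            if w_tip < 0:
                raise RuntimeError("motor ahead of tip: propensity bookkeeping error")
        else:
            w_tip = math.inf

        w = min(w_land, w_detach, w_release, w_switch, w_zero, w_tip, horizon)
        t_new = t + w
        L_new = L + slope * w
        if L_new < -1e-9:
            raise RuntimeError("negative length: event ordering error")

        if w == horizon:
            record_vertex(t_end, L_new, phase_label)
            break
        if w == w_land:
            u = rng.uniform(0.0, max(L_new, 1e-12))
            b.append(u - vm * t_new)
        elif w == w_detach:
            b.pop(rng.integers(len(b)))
        elif w == w_release:
            record_vertex(t_new, L_new, phase_label)
            n_end -= 1
        elif w == w_tip:
            # motor reaches the tip: absorbed if growing and room; released otherwise
            b.pop(bmax_i)
            if growing and n_end < n_sat:
                record_vertex(t_new, L_new, phase_label)
                n_end += 1
        elif growing and w == w_switch:
            record_vertex(t_new, L_new, "growing")
            events.append(EventRecord(t_new, "catastrophe", L_new))
            growing = False
            n_end = 0  # the growing-end structure (and its pool) is lost
            if d0.shrink_rate == 0:
                raise ValueError("catastrophe occurred but shrink_rate is 0")
        elif not growing and w == w_switch:
            record_vertex(t_new, L_new, "shrinking")
            events.append(EventRecord(t_new, "rescue", L_new))
            growing = True
        elif w == w_zero:
            L_new = 0.0
            record_vertex(t_new, 0.0, "shrinking")
            events.append(EventRecord(t_new, "reset_to_seed", 0.0))
            b.clear()
            growing = True
        t, L = t_new, L_new

    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return Trajectory(np.array(times), np.array(lengths),
                      np.array(phases, dtype=object), events,
                      end_occupancy=np.array(occs, dtype=float),
                      rng_seed=seed_val)


# ---------------------------------------------------------------------------
# (d) single-molecule runs


def simulate_single_molecule_runs(m: MotorParams, n: int, seed,
                                  track_length: float | None = None) -> list[MotorRun]:
    """Draw ``n`` independent single-molecule runs on a stabilized lattice.

    Each molecule gets a Gaussian velocity (mean ``velocity_lattice``, SD
    ``velocity_sd``, truncated to positive), an exponential intended run
    distance (mean ``run_length``), and an exponential photobleach clock
    (mean ``bleach_time`` seconds) that competes with everything.  With a
    finite ``track_length`` the molecule lands uniformly along the track
    and may reach the plus end, where it dwells for an exponential time
    (mean ``end_residence`` seconds) unless bleached first.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed))))
    runs = []
    for _ in range(n):
        v = rng.normal(m.velocity_lattice, m.velocity_sd)
        while v <= 0:
            v = rng.normal(m.velocity_lattice, m.velocity_sd)
        intended = rng.exponential(m.run_length)
        t_bleach = rng.exponential(m.bleach_time)  # s
        if track_length is None:
            pos, to_end = math.nan, math.inf
        else:
            pos = rng.uniform(0.0, track_length)
            to_end = track_length - pos
        t_detach = intended / v * 60.0      # s
        t_reach = to_end / v * 60.0         # s
        t_leave = min(t_detach, t_reach, t_bleach)
        if t_leave == t_bleach:
            runs.append(MotorRun(pos, v, v * t_bleach / 60.0, t_bleach,
                                 False, 0.0, "bleach"))
        elif t_leave == t_detach:
            runs.append(MotorRun(pos, v, intended, t_detach, False, 0.0, "detach"))
        else:
            dwell = rng.exponential(m.end_residence)
            bleach_left = t_bleach - t_reach
            if dwell < bleach_left:
                runs.append(MotorRun(pos, v, to_end, t_reach, True, dwell,
                                     "end_release"))
            else:
                runs.append(MotorRun(pos, v, to_end, t_reach, True, bleach_left,
                                     "bleach"))
    return runs
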