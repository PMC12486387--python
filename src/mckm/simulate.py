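"""Bolus fed-batch simulation by chained batch integrations.

A fed-batch culture with discrete (bolus) feeds is simulated by integrating
the batch model between consecutive sampling times and applying an
instantaneous feed update at each interval boundary that coincides with a
feed event: volume increases by the bolus volume, every concentration is
diluted accordingly, and glucose/glutamate additionally receive the fed
mass. With the canonical 7 sampling times this yields exactly 6 batch
integrations. The estimated growth rate ``mu_est`` is not a concentration
and is not diluted; since its ODE is the chain-rule derivative of the
Monod law, the glucose jump carries it by mu(glc_post) - mu(glc_pre).

The lactate switch makes the right-hand side discontinuous at
``glc = alpha_glc``. Within a feed-free interval glucose is non-increasing,
so at most one downward crossing can occur; the integrator detects it with
a terminal event and restarts on the other branch, keeping step-size
control valid across the discontinuity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    CultureState,
    _rhs_core,
    KineticParameters,
    ModelConstants,
    N_VARIABLES,
    SimulationError,
    VARIABLE_NAMES,
    batch_rhs,
    growth_rate,
)

__all__ = [
    "FeedEvent",
    "FeedSchedule",
    "SimulationResult",
    "SolverOptions",
    "apply_bolus_feed",
    "simulate_fedbatch",
]

FEED_COLUMNS = ("time_h", "V_feed_L", "glc_feed_gL", "glu_feed_mM")

# mu_est is excluded from feed dilution (index in the state vector).
_MU_EST_IDX = VARIABLE_NAMES.index("mu_est")
_GLC_IDX = VARIABLE_NAMES.index("glc")
_GLU_IDX = VARIABLE_NAMES.index("glu")


@dataclass(frozen=True)
class FeedEvent:
    """One bolus addition: volume [L] and feed concentrations."""

    time: float
    V_feed: float
    glc_conc: float
    glu_conc: float

    def __post_init__(self):
        if self.V_feed < 0:
            raise ValueError(f"V_feed must be non-negative, got {self.V_feed}")


@dataclass(frozen=True)
class FeedSchedule:
    """An ordered sequence of bolus feed events."""

    events: tuple[FeedEvent, ...] = ()

    def __post_init__(self):
        events = tuple(self.events)
        times = [e.time for e in events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"feed times must be strictly increasing, got {times}")
        object.__setattr__(self, "events", events)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.events], dtype=float)

    def event_at(self, time: float, tol: float = 1e-9) -> FeedEvent | None:
        for event in self.events:
            if abs(event.time - time) <= tol:
                return event
        return None

    @classmethod
    def default(
        cls,
        sample_times: Sequence[float],
        V_feed: float = 0.0005,
        glc_conc: float = 100.0,
        glu_conc: float = 70.0,
        n_feeds: int = 5,
    ) -> "FeedSchedule":
        """Synthetic default schedule: feeds right after samples 2..6.

        Five 0.5 mL boluses into a 15 mL working volume with concentrated
        glucose (100 g/L) and glutamate (70 mM) stocks, sized so each bolus
        raises glucose by roughly 3 g/L. This emulates, but is not, a real
        feeding recipe.
        """
        times = np.asarray(sample_times, dtype=float)
        if len(times) < n_feeds + 2:
            raise ValueError(
                f"need at least {n_feeds + 2} sampling times for {n_feeds} feeds"
            )
        return cls(
            tuple(
                FeedEvent(float(t), V_feed, glc_conc, glu_conc)
                for t in times[1 : 1 + n_feeds]
            )
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.time, e.V_feed, e.glc_conc, e.glu_conc) for e in self.events],
            columns=list(FEED_COLUMNS),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeedSchedule":
        missing = set(FEED_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"feed table is missing columns: {sorted(missing)}")
        return cls(
            tuple(
                FeedEvent(
                    float(row.time_h),
                    float(row.V_feed_L),
                    float(row.glc_feed_gL),
                    float(row.glu_feed_mM),
                )
                for row in frame.itertuples()
            )
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeedSchedule":
        return cls.from_frame(pd.read_csv(path))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_frame().to_dict(orient="records"), indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FeedSchedule":
        return cls.from_frame(pd.DataFrame(json.loads(Path(path).read_text())))


@dataclass(frozen=True)
class SolverOptions:
    """Integrator settings for the batch intervals (explicit RK 4(5))."""

    method: str = "RK45"
    rtol: float = 1e-6
    atol: float = 1e-8
    max_step: float = np.inf


@dataclass
class SimulationResult:
    """Trajectory of one fed-batch simulation.

    ``states`` holds the post-feed state at each sampling time (the state
    handed to the next batch interval); ``states_prefeed`` the state just
    before the feed, which is what an at-line sample drawn right before
    feeding would measure.
    """

    sample_times: np.ndarray
    states: np.ndarray
    states_prefeed: np.ndarray
    volumes: np.ndarray
    dense_times: np.ndarray
    dense_states: np.ndarray
    diagnostics: list[dict] = field(default_factory=list)

    def to_frame(self, prefeed: bool = True) -> pd.DataFrame:
        states = self.states_prefeed if prefeed else self.states
        frame = pd.DataFrame(states, columns=list(VARIABLE_NAMES))
        frame.insert(0, "time_h", self.sample_times)
        frame["volume_L"] = self.volumes
        return frame

    def to_csv(self, path: str | Path, prefeed: bool = True) -> None:
        self.to_frame(prefeed=prefeed).to_csv(path, index=False)


def apply_bolus_feed(
    state: CultureState, V: float, event: FeedEvent
) -> tuple[CultureState, float]:
    """Instantaneous bolus addition with full mixing.

    Glucose and glutamate receive fed mass; every other concentration is
    diluted by the volume increase; mu_est is not a concentration and is
    unchanged. Returns the post-feed state and the new volume.
    """
    if V <= 0:
        raise ValueError(f"working volume must be positive, got {V}")
    if event.V_feed == 0:
        return state, V
    y = state.as_array()
    V_new = V + event.V_feed
    y_new = y * V / V_new
    y_new[_GLC_IDX] = (y[_GLC_IDX] * V + event.V_feed * event.glc_conc) / V_new
    y_new[_GLU_IDX] = (y[_GLU_IDX] * V + event.V_feed * event.glu_conc) / V_new
    y_new[_MU_EST_IDX] = y[_MU_EST_IDX]
    return CultureState.from_array(y_new), V_new


def _integrate_interval(
    t0: float,
    t1: float,
    y0: np.ndarray,
    theta: KineticParameters,
    constants: ModelConstants,
    options: SolverOptions,
    interval: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Integrate the batch model over [t0, t1] with event handling.

    Two kinds of terminal events keep the error control valid across the
    model's discontinuities: the lactate-switch threshold crossing, and
    depletion of a consumable species (glucose, glutamine, glutamate,
    lactate) reaching zero. A depleted species is pinned at exactly zero
    for the rest of the interval — none of them feeds back into the other
    rates once exhausted, so pinning is the model's own dynamics without
    the step-size chatter a hard clamp would cause.
    """
    p = theta.as_array()
    alpha = constants.alpha_glc
    printed = constants.lactate_switch_as_printed
    depletable = [
        VARIABLE_NAMES.index(n) for n in ("glc", "gln", "glu", "lac")
    ]
    pinned: list[int] = []

    def rhs(t, y):
        if pinned:
            y = np.array(y, dtype=float)
            y[pinned] = 0.0
            dy = _rhs_core(t, y, p, alpha, printed)
            dy[pinned] = 0.0
            return dy
        return _rhs_core(t, y, p, alpha, printed)

    def switch_crossing(t, y):
        return y[_GLC_IDX] - alpha

    switch_crossing.terminal = True
    switch_crossing.direction = -1  # glucose is non-increasing within an interval

    def make_depletion(idx):
        def depletion(t, y):
            return y[idx]

        depletion.terminal = True
        depletion.direction = -1
        depletion.idx = idx
        return depletion

    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    nfev = 0
    n_events = 0
    t, y = t0, np.asarray(y0, dtype=float).copy()
    # Species already at (or below) zero whose flow is outward start pinned.
    d0 = _rhs_core(t0, np.maximum(y, 0.0), p, alpha, printed)
    for idx in depletable:
        if y[idx] <= 0 and d0[idx] < 0:
            pinned.append(idx)
            y[idx] = 0.0
    while True:
        events = []
        if y[_GLC_IDX] > alpha and _GLC_IDX not in pinned:
            events.append(switch_crossing)
        for idx in depletable:
            if idx not in pinned and y[idx] > 0:
                events.append(make_depletion(idx))
        sol = solve_ivp(
            rhs,
            (t, t1),
            y,
            method=options.method,
            rtol=options.rtol,
            atol=options.atol,
            max_step=options.max_step,
            events=events,
        )
        nfev += sol.nfev
        if not sol.success and sol.status != 1:
            raise SimulationError(
                f"integration failed on interval {interval} "
                f"[{t0:.3g}, {t1:.3g}] h: {sol.message}",
                interval=interval,
            )
        times.append(sol.t)
        states.append(sol.y)
        if sol.status == 1:  # event: restart on the other side
            n_events += 1
            fired = next(k for k, te in enumerate(sol.t_events) if len(te))
            t = float(sol.t_events[fired][0])
            y = sol.y_events[fired][0].copy()
            event = events[fired]
            if event is switch_crossing:
                # The root finder can land a few ulp above the threshold,
                # which would re-arm the event; pin to the boundary.
                y[_GLC_IDX] = min(y[_GLC_IDX], alpha)
            else:
                idx = event.idx
                pinned.append(idx)
                y[idx] = 0.0
            if t >= t1:
                break
            continue
        break
    y_final = states[-1][:, -1]
    # mu_est is exempt: it is not a concentration and may cross zero.
    conc = np.delete(y_final, _MU_EST_IDX)
    scale = np.maximum(np.abs(np.delete(states[0][:, 0], _MU_EST_IDX)), 1.0)
    scale = np.maximum(scale, np.abs(conc))
    if np.any(conc < -1e-5 * scale):
        raise SimulationError(
            f"state became significantly negative on interval {interval}: {y_final}",
            interval=interval,
        )
    diag = {"interval": interval, "nfev": nfev, "n_switch_events": n_events}
    return np.concatenate(times), np.concatenate(states, axis=1), y_final, diag


def simulate_fedbatch(
    theta: KineticParameters,
    initial: CultureState,
    constants: ModelConstants,
    schedule: FeedSchedule,
    sample_times: Sequence[float],
    options: SolverOptions | None = None,
) -> SimulationResult:
    """Simulate a bolus fed-batch run over the given sampling times.

    Runs ``len(sample_times) - 1`` batch integrations, applying the bolus
    feed scheduled at each interval boundary to the interval's final state
    before handing it to the next interval.
    """
    options = options or SolverOptions()
    t_sample = np.asarray(sample_times, dtype=float)
    if t_sample.ndim != 1 or len(t_sample) < 2:
        raise ValueError("need at least two sampling times")
    if np.any(np.diff(t_sample) <= 0):
        raise ValueError(f"sampling times must be strictly increasing: {t_sample}")
    for event in schedule:
        if not np.any(np.isclose(event.time, t_sample, rtol=0, atol=1e-9)):
            raise ValueError(
                f"feed time {event.time} h does not coincide with a sampling time"
            )

    T = len(t_sample)
    states = np.empty((T, N_VARIABLES))
    states_prefeed = np.empty((T, N_VARIABLES))
    volumes = np.empty(T)
    dense_t: list[np.ndarray] = []
    dense_y: list[np.ndarray] = []
    diagnostics: list[dict] = []

    y = initial.as_array()
    V = constants.V0
    states_prefeed[0] = y
    event0 = schedule.event_at(t_sample[0])
    if event0 is not None:
        state, V = apply_bolus_feed(CultureState.from_array(y), V, event0)
        y = state.as_array()
    states[0] = y
    volumes[0] = V

    for i in range(T - 1):
        t_grid, y_grid, y_final, diag = _integrate_interval(
            t_sample[i], t_sample[i + 1], y, theta, constants, options, interval=i
        )
        dense_t.append(t_grid)
        dense_y.append(y_grid)
        diagnostics.append(diag)
        mu_est = y_final[_MU_EST_IDX]
        y = np.maximum(y_final, 0.0)
        y[_MU_EST_IDX] = mu_est
        states_prefeed[i + 1] = y
        event = schedule.event_at(t_sample[i + 1])
        if event is not None:
            glc_before = y[_GLC_IDX]
            state, V = apply_bolus_feed(CultureState.from_array(y), V, event)
            y = state.as_array()
            # mu_est obeys the chain rule of the Monod law, so the glucose
            # jump carries it along; without this the growth state can only
            # ratchet downward across feeds.
            y[_MU_EST_IDX] += growth_rate(theta, y[_GLC_IDX]) - growth_rate(
                theta, glc_before
            )
        states[i + 1] = y
        volumes[i + 1] = V

    return SimulationResult(
        sample_times=t_sample,
        states=states,
        states_prefeed=states_prefeed,
        volumes=volumes,
        dense_times=np.concatenate(dense_t),
        dense_states=np.concatenate(dense_y, axis=1),
        diagnostics=diagnostics,
    )
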