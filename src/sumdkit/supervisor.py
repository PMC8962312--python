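"""The SuMD supervision loop.

Supervised molecular dynamics accelerates ligand-binding sampling without
energetic bias: dynamics run in short windows (600 ps by default), the
ligand–site center-of-mass distance is sampled at evenly spaced
checkpoints inside each window, and an ordinary-least-squares line is
fitted through those samples. A *tabù-like* acceptance rule keeps the
window only when the fitted slope is strictly negative (the ligand is
approaching); otherwise the window is discarded, the state is restored to
the window start, and velocities are reassigned from the thermostat before
retrying. Once the end-of-window distance drops below the switch-off
threshold (5 Å by default) supervision is permanently disabled and a fixed
number of further windows (30 by default) run as plain MD, all retained.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .engine import Propagator
from .system_model import Frame, Selection, Topology, Trajectory, com_distance

__all__ = [
    "SupervisionConfig",
    "StepRecord",
    "SumdRun",
    "TerminationReason",
    "fit_slope",
    "judge_step",
    "checkpoint_schedule",
    "run_sumd",
    "windows_to_switchoff",
    "run_unsupervised_reference",
]


@dataclass(frozen=True)
class SupervisionConfig:
    """SuMD control constants.

    ``max_consecutive_failures`` and ``max_total_steps`` are safeguards
    against landscapes where the ligand never approaches; both are
    generous and configurable.
    """

    step_duration_ps: float = 600.0
    n_checkpoints: int = 5
    switchoff_distance: float = 5.0
    post_switchoff_steps: int = 30
    max_consecutive_failures: int = 40
    max_total_steps: int = 1000

    def __post_init__(self) -> None:
        if self.n_checkpoints < 2:
            raise ValueError("need at least 2 checkpoints to fit a slope")
        if self.step_duration_ps <= 0 or self.switchoff_distance <= 0:
            raise ValueError("durations and distances must be positive")


class TerminationReason(str, enum.Enum):
    COMPLETED = "completed"
    FAILURE_LIMIT = "failure_limit"
    STEP_LIMIT = "step_limit"


@dataclass
class StepRecord:
    """Audit record of one propagated window (attempt)."""

    step_index: int            # index among *retained* windows (-1 if discarded)
    attempt_index: int         # global count of propagated windows
    checkpoint_times: list[float]
    checkpoint_distances: list[float]
    slope: float               # Å/ps
    productive: bool
    supervised: bool
    end_distance: float        # Å, distance at the last checkpoint

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SumdRun:
    """Outcome of one SuMD run: retained trajectory plus the full audit log."""

    config: SupervisionConfig
    retained_trajectory: Trajectory | None
    step_log: list[StepRecord]
    switchoff_step: int | None
    terminated_reason: TerminationReason
    frame_provenance: list[int] = field(default_factory=list)  # retained step_index per frame

    @property
    def n_propagated_windows(self) -> int:
        return len(self.step_log)


def fit_slope(times, distances) -> float:
    """Ordinary-least-squares slope (Å/ps) of distance vs time.

    Closed form ``Σ(t-t̄)(d-d̄) / Σ(t-t̄)²``; degenerate (all-equal) times
    are an error.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(distances, dtype=float)
    if t.size < 2 or t.size != d.size:
        raise ValueError("need at least two (time, distance) pairs of equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("checkpoint times must strictly increase")
    tc = t - t.mean()
    denom = float(tc @ tc)
    if denom == 0.0:
        raise ValueError("degenerate checkpoint times (zero variance)")
    return float(tc @ (d - d.mean()) / denom)


def judge_step(slope: float) -> bool:
    """Tabù-like verdict: productive iff the fitted slope is strictly negative.

    A negative slope means the ligand is approaching the site. Zero slope
    (no approach) is rejected; NaN is an error.
    """
    if math.isnan(slope):
        raise ValueError("slope is NaN")
    return slope < 0.0


def checkpoint_schedule(config: SupervisionConfig) -> list[float]:
    """Checkpoint offsets (ps) inside one window: k·(T/n) for k = 1..n.

    The window start is excluded: n samples over n equal time intervals,
    the last falling exactly at the window end.
    """
    dt = config.step_duration_ps / config.n_checkpoints
    return [k * dt for k in range(1, config.n_checkpoints + 1)]


def run_sumd(
    engine: Propagator,
    ligand: Selection,
    site: Selection,
    topology: Topology,
    config: SupervisionConfig = SupervisionConfig(),
    on_step: Callable[[StepRecord], None] | None = None,
) -> SumdRun:
    """Run the supervised-MD loop on any propagator.

    Contract:

    * every retained supervised window has strictly negative slope;
    * a rejected window restores the engine state to the window start and
      reassigns velocities before the retry — no frame from a rejected
      attempt reaches the retained trajectory;
    * supervision switches off permanently the first time a *retained*
      window ends with COM distance below ``switchoff_distance``; exactly
      ``post_switchoff_steps`` further windows then run unsupervised and
      are all retained;
    * ``max_consecutive_failures`` rejections in a row or
      ``max_total_steps`` propagated windows terminate the run early.

    ``on_step`` (if given) receives every :class:`StepRecord` as it is
    produced — the accept/reject event stream.
    """
    offsets = checkpoint_schedule(config)
    window_start = engine.get_state()
    retained_frames: list[Frame] = []
    provenance: list[int] = []
    step_log: list[StepRecord] = []
    supervised = True
    switchoff_step: int | None = None
    retained_count = 0
    post_steps_done = 0
    consecutive_failures = 0
    reason = TerminationReason.COMPLETED

    while True:
        if len(step_log) >= config.max_total_steps:
            reason = TerminationReason.STEP_LIMIT
            break
        # propagate one window, sampling the COM distance at each checkpoint
        frames: list[Frame] = []
        distances: list[float] = []
        prev = 0.0
        t0 = window_start.time
        for off in offsets:
            _, seg = engine.propagate(off - prev)
            frames.extend(seg)
            cf = engine.current_frame()
            distances.append(com_distance(cf, ligand, site, topology))
            if not seg or seg[-1].time < cf.time - 1e-12:
                frames.append(cf)
            prev = off
        slope = fit_slope(offsets, distances)
        productive = judge_step(slope) if supervised else True
        record = StepRecord(
            step_index=retained_count if productive else -1,
            attempt_index=len(step_log),
            checkpoint_times=[t0 + off for off in offsets],
            checkpoint_distances=list(distances),
            slope=slope,
            productive=productive,
            supervised=supervised,
            end_distance=distances[-1],
        )
        step_log.append(record)
        if on_step is not None:
            on_step(record)

        if not productive:
            engine.set_state(window_start)
            engine.resample_velocities()
            consecutive_failures += 1
            if consecutive_failures >= config.max_consecutive_failures:
                reason = TerminationReason.FAILURE_LIMIT
                break
            continue

        # retained window
        consecutive_failures = 0
        retained_frames.extend(frames)
        provenance.extend([retained_count] * len(frames))
        retained_count += 1
        window_start = engine.get_state()
        if supervised:
            if record.end_distance < config.switchoff_distance:
                supervised = False
                switchoff_step = record.step_index
        else:
            post_steps_done += 1
        if not supervised and post_steps_done >= config.post_switchoff_steps:
            reason = TerminationReason.COMPLETED
            break

    retained = None
    if retained_frames:
        retained = Trajectory(topology, retained_frames)
    return SumdRun(
        config=config,
        retained_trajectory=retained,
        step_log=step_log,
        switchoff_step=switchoff_step,
        terminated_reason=reason,
        frame_provenance=provenance,
    )


def windows_to_switchoff(run: SumdRun) -> int | None:
    """Propagated windows (rejected attempts included) until switch-off.

    ``None`` if supervision never switched off.
    """
    for rec in run.step_log:
        if rec.supervised and rec.productive and rec.end_distance < run.config.switchoff_distance:
            return rec.attempt_index + 1
    return None


def run_unsupervised_reference(
    engine: Propagator,
    ligand: Selection,
    site: Selection,
    topology: Topology,
    config: SupervisionConfig = SupervisionConfig(),
    max_windows: int = 200,
) -> int | None:
    """Plain-MD reference: windows until the end-of-window distance first
    drops below the switch-off threshold, with no supervision.

    The paired supervised-vs-unsupervised comparison measures the
    acceleration the supervisor buys. ``None`` means no arrival within
    ``max_windows`` (a right-censored observation: arrival would take
    longer than every window count the cap allows).
    """
    for w in range(max_windows):
        engine.propagate(config.step_duration_ps)
        d = com_distance(engine.current_frame(), ligand, site, topology)
        if d < config.switchoff_distance:
            return w + 1
    return None
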