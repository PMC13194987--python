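"""Synthetic smartphone-sensing cohorts for smoking-behaviour prediction.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without access to a real cohort:

* multi-channel rows at 5 samples/minute: accelerometer, gyroscope and
  magnetometer (x, y, z, stationary AR(1) noise), ambient light with a 24-h
  diurnal profile, and a time-of-day channel (minutes since midnight
  scaled to [0, 1]);
* sparse behavioural events placed homogeneously within waking hours
  (07:00-23:00): smoked cigarettes in Phase 1 (pre-quit), lapses and
  craving reports (level 1-5, at least one per day) in Phase 2 (post-quit);
* a cohort-shared movement motif superimposed on the inertial channels in
  the minutes leading up to every event, with per-participant amplitude and
  phase jitter and per-event variation in which sensors are involved;
* independent per-row sample dropout (missing rows keep their timestamp
  but carry no channel values).

Everything is deterministic given (config.seed, participant_id).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CohortConfig, MotifSpec
from .io import CHANNELS, EventLog, SensorStream, write_events, write_stream

PHASE1_START = pd.Timestamp("2024-01-01 00:00:00")
QUIT_GAP_DAYS = 5          # window between end of Phase 1 and start of Phase 2
WAKING_HOURS = (7.0, 23.0)
AR1_PHI = 0.8

_INERTIAL = {
    "acc": ("acc_x", "acc_y", "acc_z"),
    "gyr": ("gyr_x", "gyr_y", "gyr_z"),
    "mag": ("mag_x", "mag_y", "mag_z"),
}
_AXIS_PHASE = {"x": 0.0, "y": 2 * np.pi / 3, "z": 4 * np.pi / 3}


@dataclass
class ParticipantBundle:
    participant_id: str
    phase1_stream: SensorStream
    phase2_stream: SensorStream
    phase1_events: EventLog
    phase2_events: EventLog


Cohort = list[ParticipantBundle]


def _stable_hash(*parts: str) -> int:
    """Deterministic 32-bit hash of string labels (crc32 chain)."""
    h = 0
    for part in parts:
        h = zlib.crc32(part.encode("utf-8"), h)
    return h & 0x7FFFFFFF


def child_seed(master_seed: int, *labels: str) -> int:
    """Derive an independent child seed from a master seed and stage labels."""
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF,
                                 _stable_hash(*labels)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _rng(master_seed: int, *labels: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(master_seed, *labels))


def _ar1(rng: np.random.Generator, n: int, phi: float = AR1_PHI) -> np.ndarray:
    """Stationary AR(1) with unit marginal variance."""
    innov = rng.standard_normal(n) * np.sqrt(1.0 - phi * phi)
    out = np.empty(n)
    out[0] = rng.standard_normal()
    for i in range(1, n):
        out[i] = phi * out[i - 1] + innov[i]
    return out


def _baseline(rng: np.random.Generator, n_rows: int,
              tod: np.ndarray) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    for sensor, axes in _INERTIAL.items():
        for ax in axes:
            offset = rng.normal(0.0, 0.5)
            cols[ax] = offset + _ar1(rng, n_rows)
    # daylight profile: zero overnight, peaking midday, plus sensor noise
    daylight = np.maximum(0.0, np.sin(2 * np.pi * (tod - 0.25)))
    cols["light"] = 3.0 * daylight + 0.3 * np.abs(rng.standard_normal(n_rows))
    cols["tod"] = tod
    return cols


def _waking_times(rng: np.random.Generator, day_start: pd.Timestamp,
                  count: int) -> list[pd.Timestamp]:
    lo, hi = WAKING_HOURS
    hours = rng.uniform(lo, hi, size=count)
    return [day_start + pd.Timedelta(seconds=round(h * 3600)) for h in hours]


def _phase1_events(rng: np.random.Generator, start: pd.Timestamp,
                   days: int, smokes_per_day: float) -> pd.DataFrame:
    rows = []
    for d in range(days):
        day = start + pd.Timedelta(days=d)
        for ts in _waking_times(rng, day, rng.poisson(smokes_per_day)):
            rows.append((ts, "smoke", pd.NA))
    return _event_frame(rows)


def _phase2_events(rng: np.random.Generator, start: pd.Timestamp, days: int,
                   lapse_rate: float, craving_rate: float,
                   level_probs: np.ndarray) -> pd.DataFrame:
    rows = []
    for d in range(days):
        day = start + pd.Timedelta(days=d)
        for ts in _waking_times(rng, day, rng.poisson(lapse_rate / 7.0)):
            rows.append((ts, "lapse", pd.NA))
        # protocol: report craving at least once a day
        n_craving = 1 + rng.poisson(max(craving_rate - 1.0, 0.0))
        for ts in _waking_times(rng, day, n_craving):
            level = int(rng.choice(5, p=level_probs)) + 1
            rows.append((ts, "craving", level))
    return _event_frame(rows)


def _event_frame(rows: list[tuple]) -> pd.DataFrame:
    frame = pd.DataFrame(rows, columns=["timestamp", "kind", "level"])
    frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    frame["level"] = frame["level"].astype("Int64")
    frame = frame.sort_values("timestamp", kind="stable").reset_index(drop=True)
    # collapse sub-second collisions so stream/event timestamps stay unique
    frame = frame.drop_duplicates(subset="timestamp").reset_index(drop=True)
    return frame


def _superimpose_motif(cols: dict[str, np.ndarray], seconds: np.ndarray,
                       events: pd.DataFrame, start: pd.Timestamp,
                       config: CohortConfig, motif: MotifSpec,
                       rng: np.random.Generator,
                       amp_jitter: float, phase_jitter: float) -> None:
    """Add the pre-event movement signature in place.

    Each event activates the motif for ``pre_event_window`` minutes before
    its timestamp: an additive oscillation at ``burst_period`` plus extra
    high-frequency noise (variance multiplied by ``variance_gain``), scaled
    by the cohort amplitude, the participant's jitter, and a per-event
    Dirichlet draw of sensor involvement.
    """
    if config.motif_amplitude == 0.0 or len(events) == 0:
        # still consume the per-event draws so event placement and motif
        # randomness stay decoupled from the amplitude setting
        if len(events):
            rng.dirichlet([2.0, 2.0, 2.0], size=len(events))
        return
    window_s = motif.pre_event_window * 60.0
    extra_sd = np.sqrt(motif.variance_gain - 1.0)
    involvements = rng.dirichlet([2.0, 2.0, 2.0], size=len(events)) * 3.0
    for (ts, _, _), invol in zip(events.itertuples(index=False), involvements):
        t_event = (ts - start).total_seconds()
        lo = np.searchsorted(seconds, t_event - window_s, side="left")
        hi = np.searchsorted(seconds, t_event, side="left")
        if hi <= lo:
            continue
        t_rel = seconds[lo:hi] - t_event
        for (sensor, axes), w_event in zip(_INERTIAL.items(), invol):
            weight = (config.motif_amplitude * amp_jitter
                      * motif.channel_weights[sensor] * w_event)
            if weight == 0.0:
                continue
            for ax in axes:
                osc = np.sin(2 * np.pi * t_rel / motif.burst_period
                             + _AXIS_PHASE[ax[-1]] + phase_jitter)
                noise = extra_sd * rng.standard_normal(hi - lo)
                cols[ax][lo:hi] += weight * (osc + noise)


def _generate_stream(config: CohortConfig, motif: MotifSpec,
                     participant_id: str, phase: int, start: pd.Timestamp,
                     days: int, events: pd.DataFrame,
                     amp_jitter: float, phase_jitter: float) -> SensorStream:
    dt = 60.0 / config.samples_per_minute
    n_rows = days * 1440 * config.samples_per_minute
    seconds = np.arange(n_rows) * dt
    timestamps = start + pd.to_timedelta(np.round(seconds), unit="s")
    minutes_of_day = (timestamps - timestamps.normalize()) / pd.Timedelta(minutes=1)
    tod = (minutes_of_day / 1440.0).to_numpy()

    base_rng = _rng(config.seed, "baseline", participant_id, str(phase))
    cols = _baseline(base_rng, n_rows, tod)
    motif_rng = _rng(config.seed, "motif", participant_id, str(phase))
    _superimpose_motif(cols, seconds, events, start, config, motif,
                       motif_rng, amp_jitter, phase_jitter)

    frame = pd.DataFrame({"timestamp": timestamps})
    for col in CHANNELS:
        frame[col] = cols[col]
    frame["missing"] = False
    stream = SensorStream(participant_id=participant_id, phase=phase, frame=frame)
    if config.missing_prob > 0:
        stream = inject_missingness(
            stream, config.missing_prob,
            child_seed(config.seed, "missing", participant_id, str(phase)))
    return stream


def participant_motif_jitter(config: CohortConfig,
                             participant_id: str) -> tuple[float, float]:
    """Per-participant motif amplitude multiplier and phase offset, drawn
    once per participant; with subject_jitter=0 every participant shares
    the cohort motif exactly (amplitude 1, phase 0)."""
    jitter_rng = _rng(config.seed, "jitter", participant_id)
    amp = max(0.1, 1.0 + config.subject_jitter * jitter_rng.standard_normal())
    phase = config.subject_jitter * jitter_rng.uniform(0, 2 * np.pi)
    return amp, phase


def generate_participant(config: CohortConfig, motif: MotifSpec,
                         participant_id: str,
                         phase2_silent: bool = False) -> ParticipantBundle:
    """Generate both phases of one participant's streams and event logs.

    Deterministic for a fixed (config.seed, participant_id).  With
    ``phase2_silent`` the Phase-2 event log is empty, emulating a
    participant who never reported after quitting.
    """
    amp_jitter, phase_jitter = participant_motif_jitter(config, participant_id)

    p1_start = PHASE1_START
    p2_start = p1_start + pd.Timedelta(days=config.phase1_days + QUIT_GAP_DAYS)

    ev_rng1 = _rng(config.seed, "events", participant_id, "1")
    events1 = _phase1_events(ev_rng1, p1_start, config.phase1_days,
                             config.smokes_per_day)
    if phase2_silent:
        events2 = _event_frame([])
    else:
        ev_rng2 = _rng(config.seed, "events", participant_id, "2")
        events2 = _phase2_events(
            ev_rng2, p2_start, config.phase2_days, config.lapse_rate,
            config.craving_rate, np.asarray(config.craving_level_probs))

    stream1 = _generate_stream(config, motif, participant_id, 1, p1_start,
                               config.phase1_days, events1,
                               amp_jitter, phase_jitter)
    stream2 = _generate_stream(config, motif, participant_id, 2, p2_start,
                               config.phase2_days, events2,
                               amp_jitter, phase_jitter)
    return ParticipantBundle(participant_id, stream1, stream2,
                             EventLog(events1), EventLog(events2))


def generate_cohort(config: CohortConfig, motif: MotifSpec) -> Cohort:
    """Generate the whole cohort; a configured fraction reports nothing in
    Phase 2 (default 3/17)."""
    ids = [f"p{i + 1:02d}" for i in range(config.n_participants)]
    n_silent = int(round(config.silent_phase2_fraction * config.n_participants))
    silent_rng = _rng(config.seed, "silent-selection")
    silent = set(silent_rng.choice(config.n_participants, size=n_silent,
                                   replace=False).tolist()) if n_silent else set()
    return [generate_participant(config, motif, pid, phase2_silent=(i in silent))
            for i, pid in enumerate(ids)]


def inject_missingness(stream: SensorStream, missing_prob: float,
                       seed: int) -> SensorStream:
    """Flag each row missing independently with probability ``missing_prob``;
    flagged rows keep timestamps but lose channel values."""
    if not 0.0 <= missing_prob < 1.0:
        raise ValueError("missing_prob must be in [0, 1)")
    if missing_prob == 0.0:
        return stream
    rng = np.random.default_rng(seed)
    frame = stream.frame.copy()
    new_miss = rng.random(len(frame)) < missing_prob
    miss = frame["missing"].to_numpy(dtype=bool) | new_miss
    for col in CHANNELS:
        vals = frame[col].to_numpy(dtype=float).copy()
        vals[miss] = np.nan
        frame[col] = vals
    frame["missing"] = miss
    return SensorStream(stream.participant_id, stream.phase, frame)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write every bundle as four CSV files under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for b in cohort:
        write_stream(b.phase1_stream, out / f"{b.participant_id}_phase1_stream.csv")
        write_stream(b.phase2_stream, out / f"{b.participant_id}_phase2_stream.csv")
        write_events(b.phase1_events, out / f"{b.participant_id}_phase1_events.csv")
        write_events(b.phase2_events, out / f"{b.participant_id}_phase2_events.csv")


def read_cohort(in_dir: str | Path) -> Cohort:
    """Load a cohort previously written by :func:`write_cohort`."""
    from .io import read_events, read_stream
    in_dir = Path(in_dir)
    pids = sorted({p.name.split("_")[0]
                   for p in in_dir.glob("*_phase1_stream.csv")})
    if not pids:
        raise FileNotFoundError(f"no cohort stream files under {in_dir}")
    cohort = []
    for pid in pids:
        cohort.append(ParticipantBundle(
            pid,
            read_stream(in_dir / f"{pid}_phase1_stream.csv", pid, 1),
            read_stream(in_dir / f"{pid}_phase2_stream.csv", pid, 2),
            read_events(in_dir / f"{pid}_phase1_events.csv"),
            read_events(in_dir / f"{pid}_phase2_events.csv"),
        ))
    return cohort
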