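"""Cohort and motif configuration objects.

The defaults describe the study design the analysis assumes: a two-week
pre-quit phase in which every smoked cigarette is logged, followed by a
three-month post-quit phase with sparse lapse reports and craving reports
(level 1-5, at least one per day), while the phone records accelerometer,
gyroscope, magnetometer, ambient light and time-of-day at 5 samples per
minute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

#: fraction of participants whose post-quit event log is empty (3 of 17 in
#: the emulated study design)
DEFAULT_SILENT_PHASE2_FRACTION = 3 / 17


@dataclass
class CohortConfig:
    """Study-design parameters for one synthetic cohort.

    Rates are interpreted within waking hours (07:00-23:00): smokes_per_day
    and craving_rate are expected events per day, lapse_rate expected events
    per week.  craving_level_probs gives the distribution of self-reported
    craving intensity 1..5.
    """

    n_participants: int = 17
    phase1_days: int = 14
    phase2_days: int = 90
    samples_per_minute: int = 5
    smokes_per_day: float = 10.0
    lapse_rate: float = 1.0            # per week, Phase 2
    craving_rate: float = 1.3          # per day, Phase 2 (>=1/day enforced)
    craving_level_probs: tuple[float, ...] = (0.15, 0.20, 0.30, 0.20, 0.15)
    motif_amplitude: float = 1.0
    subject_jitter: float = 0.2
    missing_prob: float = 0.02
    silent_phase2_fraction: float = DEFAULT_SILENT_PHASE2_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.phase1_days < 1 or self.phase2_days < 1:
            raise ValueError("phase durations must be >= 1 day")
        if self.samples_per_minute < 1:
            raise ValueError("samples_per_minute must be >= 1")
        for name in ("smokes_per_day", "lapse_rate", "craving_rate",
                     "motif_amplitude", "subject_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.missing_prob < 1.0:
            raise ValueError("missing_prob must be in [0, 1)")
        if not 0.0 <= self.silent_phase2_fraction <= 1.0:
            raise ValueError("silent_phase2_fraction must be in [0, 1]")
        probs = np.asarray(self.craving_level_probs, dtype=float)
        if probs.shape != (5,) or (probs < 0).any():
            raise ValueError("craving_level_probs must be 5 non-negative values")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("craving_level_probs must sum to 1")


@dataclass
class MotifSpec:
    """Shape of the cohort-shared pre-event movement signature.

    The motif is active for ``pre_event_window`` minutes leading up to each
    logged event: the inertial channels receive an additive oscillation with
    period ``burst_period`` seconds (a hand-to-mouth-like cadence) plus
    extra high-frequency noise whose variance is multiplied by
    ``variance_gain``.  ``channel_weights`` gives the mean involvement of
    each sensor group; per-event involvement varies around it.
    """

    pre_event_window: float = 3.0      # minutes
    burst_period: float = 30.0         # seconds
    variance_gain: float = 3.0
    channel_weights: Mapping[str, float] = field(
        default_factory=lambda: {"acc": 1.0, "gyr": 0.8, "mag": 0.5})

    def __post_init__(self) -> None:
        if self.pre_event_window <= 0:
            raise ValueError("pre_event_window must be > 0")
        if self.burst_period <= 0:
            raise ValueError("burst_period must be > 0")
        if self.variance_gain < 1:
            raise ValueError("variance_gain must be >= 1")
        for key in ("acc", "gyr", "mag"):
            if key not in self.channel_weights:
                raise ValueError(f"channel_weights missing {key!r}")
            if self.channel_weights[key] < 0:
                raise ValueError("channel weights must be >= 0")


def load_cohort_config(path) -> tuple[CohortConfig, MotifSpec]:
    """Read a YAML file with optional ``cohort:`` and ``motif:`` sections."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    cohort_kwargs = dict(doc.get("cohort", {}))
    if "craving_level_probs" in cohort_kwargs:
        cohort_kwargs["craving_level_probs"] = tuple(
            cohort_kwargs["craving_level_probs"])
    motif_kwargs = dict(doc.get("motif", {}))
    return CohortConfig(**cohort_kwargs), MotifSpec(**motif_kwargs)
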