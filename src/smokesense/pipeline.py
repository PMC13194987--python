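"""From raw streams + event logs to model-ready labeled window datasets.

The stages mirror the analysis design: non-overlapping 25-row (5-minute)
windows, removal of majority-missing windows, binary labeling (a window is
positive iff a reported event falls inside it), optional lapse-vs-craving
reclassification, variance-screened random downsampling of the majority
class, channel selection, and a seeded stratified 90/10 shuffle split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CHANNELS, EventLog, SensorStream

WINDOW_ROWS = 25           # 5 minutes at 5 samples/minute
MAJORITY_MISSING = 13      # >= this many missing rows -> window removed

#: named channel subsets selectable for modelling
CHANNEL_SUBSETS: dict[str, tuple[str, ...]] = {
    "ACC": ("acc_x", "acc_y", "acc_z"),
    "GYR": ("gyr_x", "gyr_y", "gyr_z"),
    "MAG": ("mag_x", "mag_y", "mag_z"),
    "L": ("light",),
    "T": ("tod",),
    "ACC-GYR-MAG": ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z",
                    "mag_x", "mag_y", "mag_z"),
    "ACC-GYR-MAG-L-T": CHANNELS,
}


@dataclass
class LabeledDataset:
    """Fixed-shape windows with labels and per-window metadata.

    ``X`` is (n, 25, C) in the order of ``channel_spec``; ``y`` is the 0/1
    label; ``meta`` has one row per window with participant_id, phase,
    start_time, event_kind ('none', 'smoke', 'lapse', 'craving'),
    craving_level (NaN unless a craving), and hour_of_day (0-23).
    """

    X: np.ndarray
    y: np.ndarray
    meta: pd.DataFrame
    channel_spec: tuple[str, ...] = field(default=CHANNELS)

    def __post_init__(self) -> None:
        if self.X.ndim != 3 or self.X.shape[1] != WINDOW_ROWS:
            raise ValueError(f"X must be (n, {WINDOW_ROWS}, C)")
        if self.X.shape[2] != len(self.channel_spec):
            raise ValueError("channel_spec width does not match X")
        if len(self.y) != len(self.X) or len(self.meta) != len(self.X):
            raise ValueError("X, y and meta lengths disagree")

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(self.X[idx], self.y[idx],
                              self.meta.iloc[idx].reset_index(drop=True),
                              self.channel_spec)

    def concat(self, other: "LabeledDataset") -> "LabeledDataset":
        if self.channel_spec != other.channel_spec:
            raise ValueError("cannot concatenate datasets with different channels")
        return LabeledDataset(
            np.concatenate([self.X, other.X]),
            np.concatenate([self.y, other.y]),
            pd.concat([self.meta, other.meta], ignore_index=True),
            self.channel_spec)


@dataclass
class RawWindow:
    """A sliced 25-row window before labeling."""
    start_time: pd.Timestamp
    matrix: np.ndarray          # (25, 11), NaN where missing
    missing: np.ndarray         # (25,) bool


def slice_windows(stream: SensorStream) -> list[RawWindow]:
    """Cut the stream into consecutive non-overlapping 25-row windows
    aligned to the stream start; a trailing remainder of <25 rows is
    dropped.  A stream shorter than 25 rows yields an empty list."""
    n = len(stream)
    n_windows = n // WINDOW_ROWS
    if n_windows == 0:
        return []
    mat = stream.channel_matrix[: n_windows * WINDOW_ROWS]
    miss = stream.missing_mask[: n_windows * WINDOW_ROWS]
    starts = stream.frame["timestamp"].iloc[::WINDOW_ROWS].to_numpy()
    return [RawWindow(pd.Timestamp(starts[i]),
                      mat[i * WINDOW_ROWS:(i + 1) * WINDOW_ROWS],
                      miss[i * WINDOW_ROWS:(i + 1) * WINDOW_ROWS])
            for i in range(n_windows)]


def drop_incomplete(windows: list[RawWindow]) -> list[RawWindow]:
    """Remove windows with a majority (>=13 of 25) of missing rows; impute
    remaining missing rows by last observation carried forward within the
    window (leading edge back-filled)."""
    kept = []
    for w in windows:
        n_miss = int(w.missing.sum())
        if n_miss >= MAJORITY_MISSING:
            continue
        if n_miss:
            frame = pd.DataFrame(w.matrix)
            frame = frame.ffill().bfill()
            w = RawWindow(w.start_time, frame.to_numpy(),
                          np.zeros_like(w.missing))
        kept.append(w)
    return kept


def label_windows(windows: list[RawWindow], events: EventLog,
                  phase: int, participant_id: str) -> LabeledDataset:
    """Label each window 1 iff at least one event timestamp falls in
    [start, start + 5 min); event kind/level come from the earliest
    contained event.  Events outside the windows' time span are ignored
    with a warning."""
    n = len(windows)
    X = np.stack([w.matrix for w in windows]) if n else \
        np.empty((0, WINDOW_ROWS, len(CHANNELS)))
    y = np.zeros(n, dtype=int)
    kinds = np.array(["none"] * n, dtype=object)
    levels = np.full(n, np.nan)
    if n:
        starts = pd.DatetimeIndex([w.start_time for w in windows])
        span = pd.Timedelta(minutes=5)
        ev = events.frame.sort_values("timestamp", kind="stable")
        used = np.zeros(len(ev), dtype=bool)
        # windows are ordered but need not be contiguous after filtering
        for ts, kind, level, j in zip(ev["timestamp"], ev["kind"], ev["level"],
                                      range(len(ev))):
            i = int(starts.searchsorted(ts, side="right")) - 1
            if i >= 0 and ts < starts[i] + span:
                used[j] = True
                if y[i] == 0:          # earliest event wins the metadata
                    y[i] = 1
                    kinds[i] = kind
                    levels[i] = float(level) if pd.notna(level) else np.nan
        n_outside = int((~used).sum())
        if n_outside:
            warnings.warn(f"{n_outside} event(s) fell outside the windowed "
                          "time range and were ignored", stacklevel=2)
    meta = pd.DataFrame({
        "participant_id": participant_id,
        "phase": phase,
        "start_time": pd.DatetimeIndex([w.start_time for w in windows])
        if n else pd.DatetimeIndex([]),
        "event_kind": kinds,
        "craving_level": levels,
        "hour_of_day": [w.start_time.hour for w in windows],
    })
    return LabeledDataset(X, y, meta, CHANNELS)


def windows_from_stream(stream: SensorStream, events: EventLog) -> LabeledDataset:
    """Convenience: slice -> drop_incomplete -> label."""
    return label_windows(drop_incomplete(slice_windows(stream)),
                         events, stream.phase, stream.participant_id)


def reclassify(dataset: LabeledDataset, scheme: str) -> LabeledDataset:
    """'binary' is the identity; 'lapse_vs_craving' keeps the binary label
    but partitions positives by event kind for split evaluation (Phase-2
    data only)."""
    if scheme == "binary":
        return dataset
    if scheme != "lapse_vs_craving":
        raise ValueError(f"unknown reclassification scheme {scheme!r}")
    if (dataset.meta["phase"] == 1).any():
        raise ValueError("lapse_vs_craving reclassification requires Phase-2 data")
    pos_kinds = dataset.meta.loc[dataset.y == 1, "event_kind"]
    if not pos_kinds.isin(["lapse", "craving"]).all():
        raise ValueError("positive windows must be lapses or cravings")
    return dataset


def positive_class_counts(dataset: LabeledDataset) -> dict[str, int]:
    pos = dataset.meta.loc[dataset.y == 1, "event_kind"]
    return pos.value_counts().to_dict()


def balance_downsample(dataset: LabeledDataset, seed: int,
                       noise_percentile: float = 95.0) -> LabeledDataset:
    """Equalise class sizes by seeded random subsampling of the majority
    class, after excluding its highest-variance windows.

    Majority-class windows whose mean within-window channel variance lies
    above ``noise_percentile`` are screened out first (the noise-removal
    step); the survivors are subsampled without replacement to the minority
    count.
    """
    n_pos, n_neg = int((dataset.y == 1).sum()), int((dataset.y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to balance; use the "
                         "non-balanced evaluation mode instead")
    major, minor = (0, 1) if n_neg >= n_pos else (1, 0)
    major_idx = np.flatnonzero(dataset.y == major)
    minor_idx = np.flatnonzero(dataset.y == minor)
    variances = dataset.X[major_idx].var(axis=1).mean(axis=1)
    cutoff = np.percentile(variances, noise_percentile)
    quiet = major_idx[variances <= cutoff]
    rng = np.random.default_rng(seed)
    target = min(len(minor_idx), len(quiet))
    chosen_major = rng.choice(quiet, size=target, replace=False)
    chosen_minor = (minor_idx if target == len(minor_idx)
                    else rng.choice(minor_idx, size=target, replace=False))
    keep = np.sort(np.concatenate([chosen_major, chosen_minor]))
    return dataset.subset(keep)


def select_channels(dataset: LabeledDataset, subset: str) -> LabeledDataset:
    """Reduce window matrices to a named channel subset (ACC, GYR, MAG, L,
    T, ACC-GYR-MAG, or ACC-GYR-MAG-L-T)."""
    key = subset.upper()
    if key not in CHANNEL_SUBSETS:
        raise KeyError(f"unknown channel subset {subset!r}; "
                       f"choose from {sorted(CHANNEL_SUBSETS)}")
    wanted = CHANNEL_SUBSETS[key]
    missing = [c for c in wanted if c not in dataset.channel_spec]
    if missing:
        raise KeyError(f"channels {missing} not present in dataset")
    cols = [dataset.channel_spec.index(c) for c in wanted]
    return LabeledDataset(dataset.X[:, :, cols], dataset.y,
                          dataset.meta.copy(), wanted)


def shuffle_split(dataset: LabeledDataset, train_frac: float = 0.9,
                  seed: int = 0) -> tuple[LabeledDataset, LabeledDataset]:
    """Seeded shuffle then per-participant split, stratified by label where
    each (participant, label) group is large enough."""
    if len(dataset) < 10:
        raise ValueError("need at least 10 samples to split")
    rng = np.random.default_rng(seed)
    train_parts: list[np.ndarray] = []
    test_parts: list[np.ndarray] = []
    groups = dataset.meta.groupby("participant_id", sort=True).indices
    for pid in sorted(groups):
        idx = np.asarray(groups[pid])
        labels = dataset.y[idx]
        if min((labels == 0).sum(), (labels == 1).sum()) < 2:
            warnings.warn(f"participant {pid}: too few samples in one class "
                          "for stratification; splitting unstratified",
                          stacklevel=2)
            strata = [idx]
        else:
            strata = [idx[labels == 0], idx[labels == 1]]
        for stratum in strata:
            perm = rng.permutation(stratum)
            n_train = int(round(train_frac * len(stratum)))
            n_train = min(max(n_train, 1), len(stratum) - 1) \
                if len(stratum) > 1 else n_train
            train_parts.append(perm[:n_train])
            test_parts.append(perm[n_train:])
    train_idx = np.sort(np.concatenate(train_parts))
    test_idx = np.sort(np.concatenate(test_parts))
    return dataset.subset(train_idx), dataset.subset(test_idx)
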