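"""Evaluation designs and statistics for the window classifiers.

Three designs:

* within-subject — shuffled 90/10 split of one participant's Phase-1
  (pre-quit) windows;
* phase transfer — train on all of a participant's Phase-1 windows, test on
  their Phase-2 (post-quit) windows, with lapse/craving and hour-of-day
  stratification;
* LOPO — leave one participant out: train on everyone else's Phase-1 data,
  score the held-out participant's Phase-2 windows, report per-participant
  ROC curves and the mean AUC, plus lapse-only and craving-only splits.

Statistics: accuracy, confusion counts, PPV/NPV (null when undefined), ROC
by threshold sweep with trapezoidal AUC, and the Friedman rank test across
input types with participants as blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .nn.models import Model, ModelConfig, build_model, predict, train
from .pipeline import (CHANNEL_SUBSETS, LabeledDataset, balance_downsample,
                       select_channels, shuffle_split, windows_from_stream)
from .synthetic import Cohort, ParticipantBundle, child_seed


@dataclass
class EvalReport:
    design: str
    arch: str
    channels: str
    accuracy: float
    tp: int
    fp: int
    tn: int
    fn: int
    ppv: float | None
    npv: float | None
    roc_fpr: np.ndarray | None = None
    roc_tpr: np.ndarray | None = None
    auc: float | None = None
    strata_by_kind: dict[str, float] = field(default_factory=dict)
    strata_by_hour: dict[int, float] = field(default_factory=dict)
    strata_by_level: dict[int, float] = field(default_factory=dict)
    auc_lapse: float | None = None
    auc_craving: float | None = None
    participant_id: str | None = None
    n_test: int = 0

    def to_dict(self) -> dict:
        out = {k: v for k, v in self.__dict__.items()
               if k not in ("roc_fpr", "roc_tpr")}
        if self.roc_fpr is not None:
            out["roc"] = {"fpr": self.roc_fpr.tolist(),
                          "tpr": self.roc_tpr.tolist()}
        return out


@dataclass
class FriedmanResult:
    Q: float
    df: int
    p: float
    significant_05: bool
    significant_01: bool


# ----------------------------------------------------------------------
# metric primitives

def confusion_counts(y_true: np.ndarray,
                     y_pred: np.ndarray) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    return tp, fp, tn, fn


def roc_auc(scores: np.ndarray,
            labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points by threshold sweep and trapezoidal AUC.

    AUC equals the probability that a random positive outranks a random
    negative (ties counted half).
    """
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes in labels")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return fpr, tpr, float(np.trapezoid(tpr, fpr))


def friedman_test(score_grid: np.ndarray) -> FriedmanResult:
    """Friedman rank test over a (blocks x treatments) score grid.

    Ranks within each block (mean ranks on ties), then
    Q = 12n / (k(k+1)) * sum_j (Rbar_j - (k+1)/2)^2 with df = k - 1 and the
    p-value from the chi-square upper tail.
    """
    grid = np.asarray(score_grid, dtype=float)
    if grid.ndim != 2 or grid.shape[0] < 2 or grid.shape[1] < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")
    n, k = grid.shape
    ranks = np.vstack([stats.rankdata(row) for row in grid])
    mean_ranks = ranks.mean(axis=0)
    q = 12.0 * n / (k * (k + 1)) * float(((mean_ranks - (k + 1) / 2.0) ** 2).sum())
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    return FriedmanResult(Q=q, df=df, p=p,
                          significant_05=p < 0.05, significant_01=p < 0.01)


def _predictive_values(tp, fp, tn, fn) -> tuple[float | None, float | None]:
    ppv = tp / (tp + fp) if (tp + fp) else None
    npv = tn / (tn + fn) if (tn + fn) else None
    return ppv, npv


def _strata(meta: pd.DataFrame, y: np.ndarray, y_pred: np.ndarray):
    correct = (y == np.asarray(y_pred)).astype(float)
    by_kind = {str(k): float(correct[g].mean())
               for k, g in meta.groupby("event_kind").indices.items()}
    by_hour = {int(h): float(correct[g].mean())
               for h, g in meta.groupby("hour_of_day").indices.items()}
    lvl = meta["craving_level"]
    by_level = {int(v): float(correct[(lvl == v).to_numpy()].mean())
                for v in sorted(lvl.dropna().unique())}
    return by_kind, by_hour, by_level


# ----------------------------------------------------------------------
# dataset assembly

def _phase_dataset(bundle: ParticipantBundle, phase: int) -> LabeledDataset:
    stream = bundle.phase1_stream if phase == 1 else bundle.phase2_stream
    events = bundle.phase1_events if phase == 1 else bundle.phase2_events
    return windows_from_stream(stream, events)


def _prepared(dataset: LabeledDataset, channels: str, seed: int,
              balance: bool) -> LabeledDataset:
    if balance:
        dataset = balance_downsample(dataset, seed)
    return select_channels(dataset, channels)


def _fit(train_set: LabeledDataset, arch: str, seed: int,
         model_config: ModelConfig | None) -> Model:
    base = model_config if model_config is not None else ModelConfig()
    cfg = replace(base, arch=arch, n_channels=len(train_set.channel_spec),
                  seed=seed)
    model = build_model(cfg)
    return train(model, train_set.X, train_set.y)


def _report(design: str, arch: str, channels: str, test: LabeledDataset,
            scores: np.ndarray, y_pred: np.ndarray,
            participant_id: str | None = None,
            with_roc: bool = True) -> EvalReport:
    tp, fp, tn, fn = confusion_counts(test.y, y_pred)
    ppv, npv = _predictive_values(tp, fp, tn, fn)
    by_kind, by_hour, by_level = _strata(test.meta, test.y, y_pred)
    fpr = tpr = None
    auc = auc_lapse = auc_craving = None
    if with_roc and len(np.unique(test.y)) == 2:
        fpr, tpr, auc = roc_auc(scores, test.y)
        auc_lapse = _split_auc(test, scores, "lapse")
        auc_craving = _split_auc(test, scores, "craving")
    return EvalReport(
        design=design, arch=arch, channels=channels,
        accuracy=(tp + tn) / max(tp + fp + tn + fn, 1),
        tp=tp, fp=fp, tn=tn, fn=fn, ppv=ppv, npv=npv,
        roc_fpr=fpr, roc_tpr=tpr, auc=auc,
        strata_by_kind=by_kind, strata_by_hour=by_hour,
        strata_by_level=by_level,
        auc_lapse=auc_lapse, auc_craving=auc_craving,
        participant_id=participant_id, n_test=len(test))


def _split_auc(test: LabeledDataset, scores: np.ndarray,
               kind: str) -> float | None:
    """AUC restricted to negatives plus positives of one event kind."""
    mask = (test.y == 0) | (test.meta["event_kind"] == kind).to_numpy()
    labels = test.y[mask]
    if len(np.unique(labels)) < 2:
        return None
    _, _, auc = roc_auc(scores[mask], labels)
    return auc


# ----------------------------------------------------------------------
# evaluation designs

def within_subject_eval(bundle: ParticipantBundle, arch: str, channels: str,
                        seed: int, model_config: ModelConfig | None = None,
                        balance: bool = True) -> EvalReport:
    """Shuffled, stratified 90/10 split of one participant's Phase-1 data."""
    dataset = _prepared(_phase_dataset(bundle, 1), channels,
                        child_seed(seed, "balance", bundle.participant_id),
                        balance)
    train_set, test_set = shuffle_split(
        dataset, 0.9, child_seed(seed, "split", bundle.participant_id))
    model = _fit(train_set, arch, child_seed(seed, "train"), model_config)
    scores, y_pred = predict(model, test_set.X)
    return _report("within_subject", arch, channels, test_set, scores, y_pred,
                   bundle.participant_id)


def phase_transfer_eval(bundle: ParticipantBundle, arch: str, channels: str,
                        seed: int, model_config: ModelConfig | None = None,
                        balance_test: bool = True) -> EvalReport | None:
    """Train on all Phase-1 windows, evaluate on Phase-2 windows.

    ``balance_test=False`` keeps the naturally imbalanced Phase-2 windows
    (the non-downsampled reporting mode).  Returns None (with a warning)
    when the participant reported nothing in Phase 2.
    """
    if len(bundle.phase2_events) == 0:
        warnings.warn(f"participant {bundle.participant_id} has no Phase-2 "
                      "events; skipping phase transfer", stacklevel=2)
        return None
    train_set = _prepared(_phase_dataset(bundle, 1), channels,
                          child_seed(seed, "balance1", bundle.participant_id),
                          balance=True)
    test_set = _prepared(_phase_dataset(bundle, 2), channels,
                         child_seed(seed, "balance2", bundle.participant_id),
                         balance=balance_test)
    model = _fit(train_set, arch, child_seed(seed, "train"), model_config)
    scores, y_pred = predict(model, test_set.X)
    return _report("phase_transfer", arch, channels, test_set, scores, y_pred,
                   bundle.participant_id)


def lopo_eval(cohort: Cohort, arch: str = "1dcnn-bilstm",
              channels: str = "ACC-GYR-MAG", seed: int = 0,
              model_config: ModelConfig | None = None
              ) -> tuple[list[EvalReport], dict[str, float | None]]:
    """Leave-one-participant-out over the cohort.

    For each held-out participant with Phase-2 events, trains on the pooled
    (balanced) Phase-1 data of everyone else and scores the held-out
    Phase-2 windows.  Returns per-participant reports and summary mean AUCs
    (overall, lapse-only, craving-only).
    """
    eligible = [b for b in cohort if len(b.phase2_events) > 0]
    if len(eligible) < 3:
        raise ValueError("LOPO needs at least 3 participants with Phase-2 events")
    phase1 = {b.participant_id: _phase_dataset(b, 1) for b in cohort}
    reports: list[EvalReport] = []
    for held_out in eligible:
        pool: LabeledDataset | None = None
        for b in cohort:
            if b.participant_id == held_out.participant_id:
                continue
            pool = phase1[b.participant_id] if pool is None \
                else pool.concat(phase1[b.participant_id])
        assert not (pool.meta["participant_id"]
                    == held_out.participant_id).any(), \
            "held-out participant leaked into the training pool"
        train_set = _prepared(pool, channels,
                              child_seed(seed, "balance", held_out.participant_id),
                              balance=True)
        test_set = _prepared(_phase_dataset(held_out, 2), channels,
                             0, balance=False)
        model = _fit(train_set, arch,
                     child_seed(seed, "train", held_out.participant_id),
                     model_config)
        scores, y_pred = predict(model, test_set.X)
        reports.append(_report("lopo", arch, channels, test_set, scores,
                               y_pred, held_out.participant_id))
    summary = {
        "mean_auc": _mean_or_none([r.auc for r in reports]),
        "mean_auc_lapse": _mean_or_none([r.auc_lapse for r in reports]),
        "mean_auc_craving": _mean_or_none([r.auc_craving for r in reports]),
        "n_participants": len(reports),
    }
    return reports, summary


def _mean_or_none(values: Sequence[float | None]) -> float | None:
    present = [v for v in values if v is not None]
    return float(np.mean(present)) if present else None


def grid_experiment(cohort: Cohort, archs: Sequence[str],
                    channel_subsets: Sequence[str], seed: int,
                    design: str = "within_subject",
                    model_config: ModelConfig | None = None
                    ) -> tuple[pd.DataFrame, dict[str, FriedmanResult]]:
    """Accuracy matrix (input types x architectures) averaged over
    participants, plus a Friedman test per architecture across input types
    (participants as blocks)."""
    if design not in ("within_subject", "phase_transfer"):
        raise ValueError("grid design must be within_subject or phase_transfer")
    evaluator = within_subject_eval if design == "within_subject" \
        else phase_transfer_eval
    per_participant: dict[str, np.ndarray] = {}
    matrix = pd.DataFrame(index=list(channel_subsets), columns=list(archs),
                          dtype=float)
    cells: dict[tuple[str, str], list[float]] = {
        (ch, a): [] for ch in channel_subsets for a in archs}
    for bundle in cohort:
        for ch in channel_subsets:
            for arch in archs:
                rep = evaluator(bundle, arch, ch,
                                child_seed(seed, "grid", bundle.participant_id),
                                model_config)
                if rep is not None:
                    cells[(ch, arch)].append(rep.accuracy)
    for (ch, arch), vals in cells.items():
        matrix.loc[ch, arch] = float(np.mean(vals)) if vals else np.nan
    friedman: dict[str, FriedmanResult] = {}
    for arch in archs:
        block_rows = []
        for i, bundle in enumerate(cohort):
            row = [cells[(ch, arch)][i] if i < len(cells[(ch, arch)]) else None
                   for ch in channel_subsets]
            if all(v is not None for v in row):
                block_rows.append(row)
        if len(block_rows) >= 2:
            friedman[arch] = friedman_test(np.asarray(block_rows, dtype=float))
    return matrix, friedman
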