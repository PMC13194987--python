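"""End-to-end reproducible experiments tying all stages together.

An experiment is described by a YAML/ dict config with sections:

    cohort:   CohortConfig fields (or ``cohort_dir`` to load from disk)
    motif:    MotifSpec fields
    model:    ModelConfig overrides (arch etc.)
    designs:  any of [within, transfer, lopo, grid]
    channels: channel subset name (default ACC-GYR-MAG)
    seed:     master seed; every stage derives its own child seed from it

Reports are written as JSON plus a manifest recording seeds and counts.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .config import CohortConfig, MotifSpec
from .evaluation import (grid_experiment, lopo_eval, phase_transfer_eval,
                         within_subject_eval)
from .nn.models import ModelConfig
from .pipeline import CHANNEL_SUBSETS
from .synthetic import child_seed, generate_cohort, read_cohort, write_cohort

DESIGN_NAMES = ("within", "transfer", "lopo", "grid")


@dataclass
class ExperimentConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    motif: MotifSpec = field(default_factory=MotifSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    designs: tuple[str, ...] = ("within",)
    channels: str = "ACC-GYR-MAG"
    grid_archs: tuple[str, ...] = ("lstm", "1dcnn", "bilstm", "1dcnn-bilstm")
    grid_channels: tuple[str, ...] = ("ACC", "GYR", "MAG", "L", "T",
                                      "ACC-GYR-MAG")
    seed: int = 0
    cohort_dir: str | None = None

    def __post_init__(self) -> None:
        for d in self.designs:
            if d not in DESIGN_NAMES:
                raise ValueError(f"unknown design {d!r}; choose from {DESIGN_NAMES}")
        if self.channels.upper() not in CHANNEL_SUBSETS:
            raise ValueError(f"unknown channel subset {self.channels!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "ExperimentConfig":
        cohort_kwargs = dict(doc.get("cohort", {}))
        if "craving_level_probs" in cohort_kwargs:
            cohort_kwargs["craving_level_probs"] = tuple(
                cohort_kwargs["craving_level_probs"])
        model_kwargs = dict(doc.get("model", {}))
        if "dense_sizes" in model_kwargs:
            model_kwargs["dense_sizes"] = tuple(model_kwargs["dense_sizes"])
        return cls(
            cohort=CohortConfig(**cohort_kwargs),
            motif=MotifSpec(**doc.get("motif", {})),
            model=ModelConfig(**model_kwargs),
            designs=tuple(doc.get("designs", ["within"])),
            channels=doc.get("channels", "ACC-GYR-MAG"),
            grid_archs=tuple(doc.get("grid_archs",
                                     ("lstm", "1dcnn", "bilstm", "1dcnn-bilstm"))),
            grid_channels=tuple(doc.get("grid_channels",
                                        ("ACC", "GYR", "MAG", "L", "T",
                                         "ACC-GYR-MAG"))),
            seed=int(doc.get("seed", 0)),
            cohort_dir=doc.get("cohort_dir"),
        )


def run_all(config: ExperimentConfig, out_dir: str | Path) -> dict:
    """Run every requested design and write JSON reports + a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.cohort_dir is not None:
        cohort = read_cohort(config.cohort_dir)
    else:
        cohort_cfg = replace(config.cohort,
                             seed=child_seed(config.seed, "cohort"))
        cohort = generate_cohort(cohort_cfg, config.motif)

    bundle_reports: dict = {}
    arch = config.model.arch
    if "within" in config.designs:
        reps = [within_subject_eval(b, arch, config.channels,
                                    child_seed(config.seed, "within"),
                                    config.model)
                for b in cohort]
        bundle_reports["within"] = {
            "per_participant": [r.to_dict() for r in reps],
            "mean_accuracy": float(np.mean([r.accuracy for r in reps])),
        }
    if "transfer" in config.designs:
        reps = [phase_transfer_eval(b, arch, config.channels,
                                    child_seed(config.seed, "transfer"),
                                    config.model)
                for b in cohort]
        reps = [r for r in reps if r is not None]
        bundle_reports["transfer"] = {
            "per_participant": [r.to_dict() for r in reps],
            "mean_accuracy": float(np.mean([r.accuracy for r in reps]))
            if reps else None,
        }
    if "lopo" in config.designs:
        reports, summary = lopo_eval(cohort, arch, config.channels,
                                     child_seed(config.seed, "lopo"),
                                     config.model)
        bundle_reports["lopo"] = {
            "per_participant": [r.to_dict() for r in reports],
            **summary,
        }
    if "grid" in config.designs:
        matrix, friedman = grid_experiment(
            cohort, config.grid_archs, config.grid_channels,
            child_seed(config.seed, "grid"), "within_subject", config.model)
        matrix.to_csv(out / "accuracy_grid.csv")
        bundle_reports["grid"] = {
            "accuracy_matrix": {ch: {a: _nan_to_none(matrix.loc[ch, a])
                                     for a in matrix.columns}
                                for ch in matrix.index},
            "friedman": {a: asdict(f) for a, f in friedman.items()},
        }

    manifest = {
        "smokesense_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "designs": list(config.designs),
        "channels": config.channels,
        "arch": arch,
        "n_participants": len(cohort),
        "cohort": asdict(config.cohort) | {
            "craving_level_probs": list(config.cohort.craving_level_probs)},
        "motif": {**asdict(config.motif),
                  "channel_weights": dict(config.motif.channel_weights)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "report.json").write_text(json.dumps(bundle_reports, indent=2))
    return bundle_reports


def _nan_to_none(v):
    v = float(v)
    return None if np.isnan(v) else v


FIXTURE_SIZES = {
    "tiny": dict(n_participants=2, phase1_days=1, phase2_days=1,
                 smokes_per_day=20.0, craving_rate=6.0, lapse_rate=14.0,
                 silent_phase2_fraction=0.0),
    "demo": dict(n_participants=6, phase1_days=7, phase2_days=7,
                 smokes_per_day=12.0, craving_rate=4.0, lapse_rate=7.0,
                 silent_phase2_fraction=1 / 6),
}


def make_fixtures(out_dir: str | Path, size: str = "tiny",
                  seed: int = 0) -> Path:
    """Write a versioned toy cohort (CSV streams + event logs) for tests
    and demos.  Byte-stable for a fixed seed."""
    if size not in FIXTURE_SIZES:
        raise ValueError(f"size must be one of {sorted(FIXTURE_SIZES)}")
    cfg = CohortConfig(seed=seed, missing_prob=0.02, **FIXTURE_SIZES[size])
    cohort = generate_cohort(cfg, MotifSpec())
    out = Path(out_dir) / size
    write_cohort(cohort, out)
    (out / "fixture.json").write_text(json.dumps(
        {"size": size, "seed": seed, "version": __version__}, indent=2))
    return out
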