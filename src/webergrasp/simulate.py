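"""Synthetic trial-table generation.

Produces tidy trial tables with the statistical structure of within-subject
size-response experiments: a fixed set of object sizes, a fixed number of
repetitions per size, one or more feedback conditions each bound to its own
two-stage parameterization, and optional between-subject heterogeneity
(a random intercept on the overshoot, optionally multiplicative jitter on
the mapping slope).

An optional drift component interpolates the generative parameters
exponentially across trials toward per-condition targets, emulating
trial-by-trial adaptation under feedback.  It is an invented convenience
for exploring adaptation-like dynamics, disabled by default, and makes no
claim to describe any particular empirical learning curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidDesignError, InvalidParameterError, SchemaError
from .model import (
    ESTIMATE_PARAMS,
    GRASP_PARAMS,
    STANDARD_SIZES,
    StimulusSet,
    TwoStageParams,
)

__all__ = [
    "TRIAL_COLUMNS",
    "ExperimentDesign",
    "SubjectProfile",
    "DriftSpec",
    "generate_experiment",
    "generate_mga_mse_cohort",
    "read_trial_table",
    "write_trial_table",
    "validate_trial_table",
]

#: Canonical column order of a tidy trial table.
TRIAL_COLUMNS = [
    "subject",
    "group",
    "condition",
    "block",
    "size_mm",
    "repetition",
    "response_mm",
]


@dataclass(frozen=True)
class DriftSpec:
    """Exponential per-trial interpolation of generative parameters.

    Within each subject x condition sequence, trial ``t`` (0-based) uses

        ``param_t = target + (initial - target) * (1 - rate) ** t``

    so ``rate = 0`` leaves parameters untouched and ``rate = 1`` jumps to
    the target from the second trial onward.  Conditions listed in
    ``washout`` instead start fully adapted (at the target) and relax
    toward ``initial + retention * (target - initial)``, i.e. with
    ``retention = 0`` adaptation washes out completely and with
    ``retention = 1`` it persists.
    """

    enabled: bool = False
    targets: Mapping[str, TwoStageParams] = field(default_factory=dict)
    rate: float = 0.0
    retention: float = 1.0
    washout: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise InvalidParameterError(f"drift rate must be in [0, 1], got {self.rate}")
        if not 0.0 <= self.retention <= 1.0:
            raise InvalidParameterError(
                f"drift retention must be in [0, 1], got {self.retention}"
            )
        if self.enabled and not self.targets:
            raise InvalidDesignError("drift enabled but no target parameters given")


@dataclass(frozen=True)
class SubjectProfile:
    """Subject-specific deviations from the condition parameters."""

    subject: int
    overshoot_offsets: Mapping[str, float]
    k_factors: Mapping[str, float]

    def params_for(self, condition: str, base: TwoStageParams) -> TwoStageParams:
        return TwoStageParams(
            k=base.k * self.k_factors.get(condition, 1.0),
            overshoot=base.overshoot + self.overshoot_offsets.get(condition, 0.0),
            sigma_impl=base.sigma_impl,
            weber_v=base.weber_v,
        )


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of a simulated experiment.

    ``conditions`` maps unique labels to the generative parameters used in
    that condition.  By default each condition occupies its own block,
    numbered in design order; an explicit ``blocks`` sequence of condition
    labels overrides this (one block per entry, in presentation order),
    allowing repeated conditions across blocks.
    """

    sizes: StimulusSet = STANDARD_SIZES
    conditions: Mapping[str, TwoStageParams] = field(default_factory=dict)
    reps_per_size: int = 20
    n_subjects: int = 20
    group: str = "all"
    blocks: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        if not self.conditions:
            raise InvalidDesignError("design must declare at least one condition")
        if self.reps_per_size < 1:
            raise InvalidDesignError(f"reps_per_size must be >= 1, got {self.reps_per_size}")
        if self.n_subjects < 1:
            raise InvalidDesignError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.blocks is not None:
            unknown = set(self.blocks) - set(self.conditions)
            if unknown:
                raise InvalidDesignError(f"blocks reference unknown conditions: {unknown}")
        if len(self.sizes) == 0:
            raise InvalidDesignError("design must declare at least one size")

    @property
    def block_sequence(self) -> list:
        """(block_number, condition_label) pairs in presentation order."""
        labels = list(self.blocks) if self.blocks is not None else list(self.conditions)
        return [(i + 1, lab) for i, lab in enumerate(labels)]

    def to_json(self) -> dict:
        obj = {
            "sizes": list(self.sizes),
            "conditions": {lab: p.to_json() for lab, p in self.conditions.items()},
            "reps_per_size": self.reps_per_size,
            "n_subjects": self.n_subjects,
            "group": self.group,
        }
        if self.blocks is not None:
            obj["blocks"] = list(self.blocks)
        return obj

    @classmethod
    def from_json(cls, obj: Mapping) -> "ExperimentDesign":
        try:
            return cls(
                sizes=StimulusSet(tuple(obj["sizes"])),
                conditions={
                    lab: TwoStageParams.from_json(p) for lab, p in obj["conditions"].items()
                },
                reps_per_size=int(obj.get("reps_per_size", 20)),
                n_subjects=int(obj.get("n_subjects", 20)),
                group=str(obj.get("group", "all")),
                blocks=obj.get("blocks"),
            )
        except KeyError as exc:
            raise InvalidDesignError(f"missing design field: {exc}") from exc

    @classmethod
    def from_json_file(cls, path) -> "ExperimentDesign":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(json.load(fh))


def _draw_profiles(
    design: ExperimentDesign,
    between_subject_sd: float,
    slope_jitter_sd: float,
    rng: np.random.Generator,
) -> list:
    if between_subject_sd < 0 or slope_jitter_sd < 0:
        raise InvalidParameterError("between-subject SDs must be >= 0")
    labels = list(design.conditions)
    profiles = []
    for subj in range(1, design.n_subjects + 1):
        offsets = {
            lab: float(rng.normal(0.0, 1.0) * between_subject_sd) for lab in labels
        }
        factors = {
            lab: float(1.0 + rng.normal(0.0, 1.0) * slope_jitter_sd) for lab in labels
        }
        profiles.append(SubjectProfile(subj, offsets, factors))
    return profiles


def _drifted_params(
    initial: TwoStageParams,
    drift: DriftSpec,
    condition: str,
    n_trials: int,
) -> list:
    """Per-trial parameter sequence under the drift spec."""
    target = drift.targets.get(condition)
    if target is None:
        return [initial] * n_trials
    decay = (1.0 - drift.rate) ** np.arange(n_trials)
    if condition in drift.washout:
        start = target
        asym = TwoStageParams(
            k=initial.k + drift.retention * (target.k - initial.k),
            overshoot=initial.overshoot + drift.retention * (target.overshoot - initial.overshoot),
            sigma_impl=initial.sigma_impl
            + drift.retention * (target.sigma_impl - initial.sigma_impl),
            weber_v=initial.weber_v + drift.retention * (target.weber_v - initial.weber_v),
        )
    else:
        start, asym = initial, target
    return [
        TwoStageParams(
            k=asym.k + (start.k - asym.k) * d,
            overshoot=asym.overshoot + (start.overshoot - asym.overshoot) * d,
            sigma_impl=asym.sigma_impl + (start.sigma_impl - asym.sigma_impl) * d,
            weber_v=asym.weber_v + (start.weber_v - asym.weber_v) * d,
        )
        for d in decay
    ]


def generate_experiment(
    design: ExperimentDesign,
    between_subject_sd: float = 0.0,
    seed=None,
    slope_jitter_sd: float = 0.0,
    drift: Optional[DriftSpec] = None,
) -> pd.DataFrame:
    """Simulate a full experiment and return a tidy trial table.

    Each subject receives a random additive offset on the overshoot per
    condition (SD ``between_subject_sd``, mm) and, if ``slope_jitter_sd``
    > 0, a multiplicative factor on the mapping slope.  Trials within a
    block are ordered by repetition then size (interleaved presentation);
    the drift index follows that order.

    The same ``seed`` always yields a bit-identical table.
    """
    rng = np.random.default_rng(seed)
    profiles = _draw_profiles(design, between_subject_sd, slope_jitter_sd, rng)
    sizes = np.asarray(list(design.sizes), dtype=float)
    n_sizes = len(sizes)
    reps = design.reps_per_size
    # within-block trial order: repetition-major, sizes interleaved
    size_seq = np.tile(sizes, reps)
    rep_seq = np.repeat(np.arange(1, reps + 1), n_sizes)
    n_trials = n_sizes * reps

    frames = []
    for profile in profiles:
        for block_no, label in design.block_sequence:
            base = profile.params_for(label, design.conditions[label])
            if drift is not None and drift.enabled:
                per_trial = _drifted_params(base, drift, label, n_trials)
                k = np.array([p.k for p in per_trial])
                overshoot = np.array([p.overshoot for p in per_trial])
                sigma = np.array([p.sigma_impl for p in per_trial])
                weber = np.array([p.weber_v for p in per_trial])
            else:
                k, overshoot = base.k, base.overshoot
                sigma, weber = base.sigma_impl, base.weber_v
            s_hat = size_seq + rng.normal(0.0, 1.0, n_trials) * (weber * size_seq)
            resp = k * s_hat + overshoot + rng.normal(0.0, 1.0, n_trials) * sigma
            frames.append(
                pd.DataFrame(
                    {
                        "subject": profile.subject,
                        "group": design.group,
                        "condition": label,
                        "block": block_no,
                        "size_mm": size_seq,
                        "repetition": rep_seq,
                        "response_mm": resp,
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)
    return table[TRIAL_COLUMNS]


def generate_mga_mse_cohort(
    seed=None,
    n_subjects: int = 20,
    reps_per_size: int = 20,
    between_subject_sd: float = 0.0,
) -> pd.DataFrame:
    """Simulate the grasping-versus-estimation demonstration cohort.

    Both conditions share the same visual Weber fraction (0.06) but differ
    in the motor stage: MGA uses a compressed slope (0.7), a large safety
    margin (18 mm) and large implementation noise (6 mm); MSE uses a unity
    slope, a 4 mm overshoot and 2 mm implementation noise.  Defaults: 20
    subjects, 20 repetitions per size at {21, 28, 35, 42} mm, no
    between-subject variance.
    """
    design = ExperimentDesign(
        sizes=STANDARD_SIZES,
        conditions={"MGA": GRASP_PARAMS, "MSE": ESTIMATE_PARAMS},
        reps_per_size=reps_per_size,
        n_subjects=n_subjects,
        group="simulated",
    )
    return generate_experiment(design, between_subject_sd=between_subject_sd, seed=seed)


def validate_trial_table(table: pd.DataFrame) -> None:
    """Raise :class:`SchemaError` if a required column is missing."""
    for col in TRIAL_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"trial table is missing required column '{col}'")


def write_trial_table(table: pd.DataFrame, path, seed=None) -> None:
    """Write a trial table as UTF-8 CSV; optionally record the seed alongside.

    If ``seed`` is given, a ``<name>.meta.json`` file with the seed and row
    count is written next to the CSV.
    """
    validate_trial_table(table)
    path = Path(path)
    # repr round-trips float64 exactly; pandas' default 16-digit formatting
    # does not
    table[TRIAL_COLUMNS].to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    if seed is not None:
        meta = {"seed": int(seed), "n_rows": int(len(table))}
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2), encoding="utf-8")


def read_trial_table(path) -> pd.DataFrame:
    """Read a trial-table CSV, enforcing the schema."""
    table = pd.read_csv(path, float_precision="round_trip")
    validate_trial_table(table)
    return table[TRIAL_COLUMNS]
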