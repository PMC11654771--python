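"""Initial processing of trial tables.

Implements the standard within-subject reduction for size-response data:
trial-level outlier exclusion, removal of initial repetitions, per-cell
means and SDs, slope measures (response slope ``k`` and apparent Weber
fraction ``W``), and subject-level outlier exclusion.

Conventions: a "cell" is one subject x condition x size combination.  All
SDs use the sample (n-1) denominator.  The apparent Weber fraction is the
OLS slope of the within-subject response SD on object size.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import EmptyCellError, InvalidParameterError, SchemaError, UndefinedSlopeError
from .simulate import validate_trial_table

__all__ = [
    "exclude_outlier_trials",
    "drop_initial_repetitions",
    "summarize_subjects",
    "fit_slopes",
    "exclude_outlier_subjects",
    "estimate_implementation_noise",
]

_CELL = ["subject", "condition", "size_mm"]


def exclude_outlier_trials(table: pd.DataFrame, z: float = 2.5):
    """Remove trials deviating by ``z`` SD or more from their cell mean.

    Within each subject x condition x size cell, a trial is excluded when
    ``|response - cell mean| >= z * cell SD``.  Cells with fewer than 3
    trials, or with zero SD, are passed through untouched and flagged.

    Returns ``(filtered_table, report)`` where the report records the
    threshold, per-cell removal counts and flagged cells.
    """
    validate_trial_table(table)
    if table.empty:
        raise SchemaError("trial table is empty")
    if not z > 0:
        raise InvalidParameterError(f"z threshold must be > 0, got {z}")

    keep = np.ones(len(table), dtype=bool)
    removed_cells = []
    flagged_cells = []
    for key, idx in table.groupby(_CELL, sort=False).indices.items():
        values = table["response_mm"].to_numpy()[idx]
        if len(values) < 3:
            flagged_cells.append({"cell": list(key), "n": int(len(values)), "reason": "n<3"})
            continue
        sd = float(np.std(values, ddof=1))
        if sd == 0.0 or not math.isfinite(z * sd):
            # identical responses (or an infinite threshold): nothing can
            # be classified as deviant
            continue
        dev = np.abs(values - values.mean())
        bad = dev >= z * sd
        if bad.any():
            keep[idx[bad]] = False
            removed_cells.append({"cell": list(key), "n_removed": int(bad.sum())})
    filtered = table.loc[keep].reset_index(drop=True)
    report = {
        "rule": "trial |response - cell mean| >= z * cell SD",
        "z": float(z),
        "n_input": int(len(table)),
        "n_removed": int(len(table) - len(filtered)),
        "removed_cells": removed_cells,
        "flagged_cells": flagged_cells,
    }
    return filtered, report


def drop_initial_repetitions(table: pd.DataFrame, n_drop: int = 2) -> pd.DataFrame:
    """Remove repetitions ``1..n_drop`` within each subject x block x size.

    Used to discard transient behavior right after a feedback regime
    changes at a block boundary.
    """
    validate_trial_table(table)
    if n_drop < 0:
        raise InvalidParameterError(f"n_drop must be >= 0, got {n_drop}")
    if n_drop == 0:
        return table.copy()
    min_reps = table.groupby(["subject", "block", "size_mm"])["repetition"].max().min()
    if n_drop >= min_reps:
        raise EmptyCellError(
            f"dropping {n_drop} repetitions would empty a cell with only {min_reps}"
        )
    return table.loc[table["repetition"] > n_drop].reset_index(drop=True)


def summarize_subjects(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell sample mean and SD of the response.

    Returns one row per subject x condition x size with columns
    ``mean_response``, ``sd_response`` (NaN and flagged when n < 2) and
    ``n_trials``.
    """
    validate_trial_table(table)
    if table.empty:
        raise SchemaError("trial table is empty")
    out = (
        table.groupby(_CELL, sort=True)["response_mm"]
        .agg(mean_response="mean", sd_response=lambda v: v.std(ddof=1), n_trials="size")
        .reset_index()
    )
    out["sd_defined"] = out["n_trials"] >= 2
    return out


def fit_slopes(summary: pd.DataFrame) -> pd.DataFrame:
    """Slope measures per subject x condition.

    OLS of cell mean on size gives the response slope ``k_resp`` and
    ``intercept_resp``; OLS of cell SD on size gives the apparent Weber
    fraction ``weber_fraction`` and ``intercept_sd``.  Requires at least
    two distinct sizes per subject x condition.
    """
    required = {"subject", "condition", "size_mm", "mean_response", "sd_response"}
    missing = required - set(summary.columns)
    if missing:
        raise SchemaError(f"summary table is missing columns {sorted(missing)}")
    rows = []
    for (subject, condition), grp in summary.groupby(["subject", "condition"], sort=True):
        sizes = grp["size_mm"].to_numpy(dtype=float)
        if len(np.unique(sizes)) < 2:
            raise UndefinedSlopeError(
                f"subject {subject}, condition {condition}: need >= 2 distinct sizes"
            )
        k_resp, icpt_resp = np.polyfit(sizes, grp["mean_response"].to_numpy(dtype=float), 1)
        sd_ok = grp["sd_response"].notna()
        if sd_ok.sum() >= 2 and len(np.unique(sizes[sd_ok])) >= 2:
            w, icpt_sd = np.polyfit(
                sizes[sd_ok], grp.loc[sd_ok, "sd_response"].to_numpy(dtype=float), 1
            )
        else:
            w, icpt_sd = np.nan, np.nan
        rows.append(
            {
                "subject": subject,
                "condition": condition,
                "k_resp": float(k_resp),
                "intercept_resp": float(icpt_resp),
                "weber_fraction": float(w),
                "intercept_sd": float(icpt_sd),
            }
        )
    return pd.DataFrame(rows)


def exclude_outlier_subjects(summary: pd.DataFrame, z: float = 2.5):
    """Single-pass subject-level exclusion on the cell summaries.

    For every condition x size cell and for each of the two summary
    measures (mean and SD of the response), the across-subject mean and SD
    are computed; a subject is excluded if ANY of its values deviates by
    ``z`` across-subject SD or more.  Cells whose across-subject SD is
    zero are skipped.  The criterion is evaluated once on the input
    summaries (no iterative re-exclusion).

    Returns ``(filtered_summary, report)``; the report lists the excluded
    subjects and the cells that triggered each exclusion.
    """
    if not z > 0:
        raise InvalidParameterError(f"z threshold must be > 0, got {z}")
    subjects = summary["subject"].unique()
    if len(subjects) < 3:
        raise InvalidParameterError("subject-level exclusion needs at least 3 subjects")

    triggers: dict = {}
    for (condition, size), grp in summary.groupby(["condition", "size_mm"], sort=True):
        for measure in ("mean_response", "sd_response"):
            vals = grp[measure].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            if ok.sum() < 2:
                continue
            mu = vals[ok].mean()
            sd = vals[ok].std(ddof=1)
            if sd == 0.0 or not math.isfinite(z * sd):
                continue
            bad = ok & (np.abs(vals - mu) >= z * sd)
            for subj in grp.loc[bad, "subject"]:
                triggers.setdefault(subj, []).append(
                    {"condition": condition, "size_mm": float(size), "measure": measure}
                )
    excluded = sorted(triggers)
    filtered = summary.loc[~summary["subject"].isin(excluded)].reset_index(drop=True)
    report = {
        "rule": "subject excluded if any cell mean or SD deviates >= z across-subject SD",
        "z": float(z),
        "n_subjects_input": int(len(subjects)),
        "excluded_subjects": [
            {"subject": s, "triggering_cells": triggers[s]} for s in excluded
        ],
    }
    return filtered, report


def estimate_implementation_noise(
    sizes, per_size_sd, k: float, weber_v: float
) -> float:
    """Recover the implementation-noise SD by variance decomposition.

    Under the two-stage model the response variance at size ``s`` is
    ``(k * weber_v * s)**2 + sigma_impl**2``; given the mapping slope and
    the visual Weber fraction, subtracting the visual term from each
    per-size variance and averaging the square roots estimates
    ``sigma_impl``.  Negative differences (sampling noise) are clipped at
    zero before the square root.
    """
    sizes = np.asarray(sizes, dtype=float)
    per_size_sd = np.asarray(per_size_sd, dtype=float)
    if sizes.shape != per_size_sd.shape:
        raise InvalidParameterError("sizes and per_size_sd must have matching shapes")
    resid_var = per_size_sd**2 - (k * weber_v * sizes) ** 2
    return float(np.mean(np.sqrt(np.clip(resid_var, 0.0, None))))
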