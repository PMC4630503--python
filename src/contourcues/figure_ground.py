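"""Figure-ground choice rates and the six-term multiple linear regression.

2AFC responses (which side of the contour looks like figure) are scored
against each patch's convex-side normal to give per-patch convex-choice
rates, which are regressed on the three cue indices and their pairwise
products by ordinary least squares -- a linear probability model, with
per-term two-sided p-values and adjusted R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cues import CueVector
from .geometry import LocalFrame
from .synth import _ANSWER_DIRS, GROUP_ANSWERS

TERM_NAMES = [
    "Intercept",
    "Convexity",
    "Closure",
    "Symmetry",
    "Convexity x Closure",
    "Convexity x Symmetry",
    "Closure x Symmetry",
]


@dataclass
class ChoiceTable:
    """Per-patch convex-side choice counts and rates.

    ``table`` has columns patch_id, group, n_convex_chosen, n_trials, rate;
    ``excluded`` lists patch ids dropped for a degenerate local frame.
    """

    table: pd.DataFrame
    excluded: list = field(default_factory=list)


@dataclass
class RegressionResult:
    coefficients: dict
    p_values: dict
    adjusted_r2: float
    n_patches: int = 0
    n_excluded_degenerate: int = 0


def convex_choice_rate(responses: pd.DataFrame, frames: dict,
                       per_observer: bool = False) -> ChoiceTable:
    """Score 2AFC answers against the convex normal of each patch.

    ``responses`` columns: observer_id, patch_id, repetition, group
    (vertical|horizontal), answer (right/left or top/bottom). An answer
    counts as convex-chosen iff its direction has positive dot product
    with the patch's convex normal. Degenerate-frame patches are excluded
    (listed in ``excluded``); an answer outside the group's vocabulary is
    an error.
    """
    rows = []
    excluded = []
    group_cols = ["observer_id", "patch_id", "group"] if per_observer else ["patch_id", "group"]
    for key, sub in responses.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        patch_id = key[1] if per_observer else key[0]
        group = key[-1]
        if group not in GROUP_ANSWERS:
            raise ValueError(f"unknown group {group!r}")
        frame: LocalFrame = frames[patch_id]
        if frame.degenerate:
            if patch_id not in excluded:
                excluded.append(patch_id)
            continue
        allowed = set(GROUP_ANSWERS[group])
        bad = set(sub["answer"]) - allowed
        if bad:
            raise ValueError(f"answer {bad.pop()!r} inconsistent with group {group!r}")
        dots = np.array([float(np.dot(_ANSWER_DIRS[a], frame.convex_normal))
                         for a in sub["answer"]])
        if np.any(dots == 0):
            raise ValueError(f"convex normal of {patch_id!r} is orthogonal to the "
                             f"answer axis of group {group!r}")
        n_convex = int(np.sum(dots > 0))
        n_trials = len(sub)
        rows.append((*key, n_convex, n_trials, n_convex / n_trials))
    cols = group_cols + ["n_convex_chosen", "n_trials", "rate"]
    return ChoiceTable(table=pd.DataFrame(rows, columns=cols), excluded=excluded)


def _design_matrix(cues: list) -> np.ndarray:
    m = np.array([[c.convexity, c.closure, c.symmetry] for c in cues], dtype=float)
    cv, cl, sy = m[:, 0], m[:, 1], m[:, 2]
    return np.column_stack([np.ones(len(cues)), cv, cl, sy, cv * cl, cv * sy, cl * sy])


def mlra(table: ChoiceTable, cues: list) -> RegressionResult:
    """OLS of convex-choice rate on the raw cues and their pairwise products.

    ``cues`` is one CueVector per patch, matched to ``table`` rows by
    patch_id (or by position when ids are absent). Predictors enter raw,
    not standardized, so coefficients keep the indices' natural units and
    remain comparable across stimulus sets. Requires at least
    8 patches; a zero-variance predictor or a rank-deficient design is an
    error. A constant response leaves adjusted R^2 undefined (NaN).
    """
    df = table.table
    by_id = {c.patch_id: c for c in cues if c.patch_id is not None}
    if by_id and set(df["patch_id"]) <= set(by_id):
        cue_rows = [by_id[p] for p in df["patch_id"]]
    else:
        if len(cues) != len(df):
            raise ValueError("cue list does not match choice table")
        cue_rows = list(cues)
    if len(cue_rows) < 8:
        raise ValueError("need at least 8 patches for the regression")
    x = _design_matrix(cue_rows)
    for k, name in enumerate(TERM_NAMES[1:], start=1):
        if np.ptp(x[:, k]) == 0:
            raise ValueError(f"zero-variance predictor: {name}")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient design matrix")
    y = df["rate"].to_numpy(dtype=float)
    fit = sm.OLS(y, x).fit()
    adj = float(fit.rsquared_adj) if np.ptp(y) > 0 else float("nan")
    return RegressionResult(
        coefficients=dict(zip(TERM_NAMES, map(float, fit.params))),
        p_values=dict(zip(TERM_NAMES, map(float, fit.pvalues))),
        adjusted_r2=adj,
        n_patches=len(cue_rows),
        n_excluded_degenerate=len(table.excluded),
    )
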