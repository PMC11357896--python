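"""Baseline-adjusted difference scores.

Every altered-feedback (AAF) performance is scored relative to a control
baseline by plain subtraction, on two baselines:

* individual-adjusted: the participant's own headphone-feedback (HF)
  control performance of the same task — 0 means the same error as their
  control, positive means more error, negative less;
* group-adjusted: the group-mean control accuracy for that task — how the
  performance compares with the average control performance.

The sign convention is pinned by the worked example of a performer whose
control CV was 15.43 and 200-ms-delay CV 3.64: 3.64 − 15.43 = −11.79.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DesignError, DomainError
from .model import AAF_CONDITIONS, CONTROL_CONDITION, Condition

__all__ = [
    "MEASURES",
    "individual_adjusted",
    "group_adjusted",
    "BaselineTable",
    "build_baselines",
    "adjust_measures",
]

#: Accuracy measures carried through the per-performance measures table.
MEASURES = ("trd", "cv", "mb_mean_abs", "mb_per_beat")


def individual_adjusted(
    score_aaf: float,
    score_control: float,
    measure: Optional[str] = None,
    control_measure: Optional[str] = None,
) -> float:
    """AAF score minus the participant's own control score.

    Antisymmetric; adjusting a performance against itself is exactly 0.
    """
    if measure is not None and control_measure is not None and measure != control_measure:
        raise DomainError(
            f"measure mismatch: {measure!r} adjusted against {control_measure!r}"
        )
    return score_aaf - score_control


def group_adjusted(score_aaf: float, group_mean_control: float) -> float:
    """AAF score minus the group-mean control score."""
    return score_aaf - group_mean_control


@dataclass
class BaselineTable:
    """Control-condition baselines for the adjustment step.

    group      : (task, measure) → group-mean control accuracy (Table-1 role);
                 NaN marks not-applicable cells (MB in the Normal task).
    individual : (participant_id, task, measure) → that participant's control
                 accuracy.
    """

    group: dict[tuple[str, str], float] = field(default_factory=dict)
    individual: dict[tuple[str, str, str], float] = field(default_factory=dict)
    control_condition: Condition = CONTROL_CONDITION

    def group_frame(self) -> pd.DataFrame:
        """Group baselines as a task × measure table."""
        tasks = sorted({t for t, _ in self.group})
        return pd.DataFrame(
            {m: [self.group.get((t, m), np.nan) for t in tasks] for m in MEASURES},
            index=pd.Index(tasks, name="task"),
        )


def build_baselines(
    measures: pd.DataFrame,
    control_condition: Condition = CONTROL_CONDITION,
) -> BaselineTable:
    """Compute group and individual baselines from the measures table.

    ``measures`` is the per-performance table with columns
    participant_id, task, condition and one column per measure. Every
    participant must have a control-condition row for every task they
    appear in; missing control rows are reported together.
    """
    needed = {"participant_id", "task", "condition"}
    missing_cols = needed - set(measures.columns)
    if missing_cols:
        raise DesignError(f"measures table missing columns {sorted(missing_cols)}")
    present_measures = [m for m in MEASURES if m in measures.columns]
    if not present_measures:
        raise DesignError("measures table has no measure columns")

    ctrl = measures[measures["condition"] == control_condition.value]
    missing = []
    for (pid, task), grp in measures.groupby(["participant_id", "task"], sort=True):
        if not (grp["condition"] == control_condition.value).any():
            missing.append(f"{pid}/{task}")
    if missing:
        raise DesignError(
            f"no {control_condition.value} control row for: {', '.join(missing)}"
        )

    table = BaselineTable(control_condition=control_condition)
    for (task,), grp in ctrl.groupby(["task"], sort=True):
        for m in present_measures:
            vals = grp[m].astype(float)
            # MB is undefined in the Normal task; an all-NaN control column
            # yields a NaN baseline (the Table-1 "N/A" marker), never 0.
            table.group[(task, m)] = (
                float(vals.mean()) if vals.notna().any() else float("nan")
            )
    for row in ctrl.itertuples(index=False):
        for m in present_measures:
            table.individual[(row.participant_id, row.task, m)] = float(getattr(row, m))
    return table


def adjust_measures(measures: pd.DataFrame, baselines: BaselineTable) -> pd.DataFrame:
    """Append ``<measure>_indadj`` and ``<measure>_grpadj`` columns.

    Only AAF-condition rows receive adjusted scores; control rows keep NaN
    (they are the baseline, not an adjusted observation).
    """
    out = measures.copy()
    aaf_values = {c.value for c in AAF_CONDITIONS}
    present_measures = [m for m in MEASURES if m in measures.columns]
    for m in present_measures:
        ind = np.full(len(out), np.nan)
        grp = np.full(len(out), np.nan)
        for i, row in enumerate(out.itertuples(index=False)):
            if row.condition not in aaf_values:
                continue
            key = (row.participant_id, row.task, m)
            if key not in baselines.individual:
                raise DesignError(f"no individual baseline for {key}")
            raw = float(getattr(row, m))
            ind[i] = individual_adjusted(raw, baselines.individual[key])
            grp[i] = group_adjusted(raw, baselines.group[(row.task, m)])
        out[f"{m}_indadj"] = ind
        out[f"{m}_grpadj"] = grp
    return out
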