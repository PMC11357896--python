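"""Inference: median split, mixed factorial ANOVA, pairwise tests, correlations.

The design is a classical mixed factorial: one between-subjects factor
(imagery group from a median split on the average BAIS score) and two
within-subjects factors (task and feedback condition), one observation per
cell. F tests use the univariate sums-of-squares partition with separate
error strata:

===================  =========================================
effect               error term
===================  =========================================
group                subjects within group
task, group×task     task × subjects-within-group
cond, group×cond     cond × subjects-within-group
task×cond (+×group)  task × cond × subjects-within-group
===================  =========================================

No sphericity correction is applied by default (a Greenhouse–Geisser
epsilon can be requested); the partition is exact for equal group sizes.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DesignError, DomainError, InsufficientDataError
from .model import AAF_CONDITIONS, ParticipantRecord

__all__ = [
    "median_split",
    "AnovaResult",
    "mixed_anova",
    "PairwiseResult",
    "pairwise_by_condition",
    "CorrelationResult",
    "pearson",
    "partial_r_formula",
    "partial_correlation",
    "nf_hf_equivalence",
]


def median_split(
    records: Sequence[ParticipantRecord],
) -> tuple[list[ParticipantRecord], float]:
    """Assign each participant to the high or low imagery group.

    The split point is the sample median of ``bais_avg``; scores strictly
    above it are "high", scores at or below it "low" (a deterministic tie
    rule — ties at the median go low). Returns the relabelled records and
    the median used.
    """
    if len(records) < 2:
        raise InsufficientDataError("median split needs at least 2 participants")
    avgs = np.array([r.bais_avg for r in records])
    if np.ptp(avgs) == 0:
        raise DesignError("all BAIS averages identical; median split is degenerate")
    med = float(np.median(avgs))
    out = []
    for r in records:
        out.append(
            ParticipantRecord(
                participant_id=r.participant_id,
                bais_v=r.bais_v,
                bais_c=r.bais_c,
                years_performing=r.years_performing,
                years_theory=r.years_theory,
                primary_instrument=r.primary_instrument,
                bais_group="high" if r.bais_avg > med else "low",
            )
        )
    return out, med


@dataclass
class AnovaResult:
    """Mixed-ANOVA summary.

    table  : one row per effect — ss, df, ms, error term, F, p.
    strata : stratum name → total sum of squares (components add to these).
    flags  : notes such as zero-error-variance strata.
    """

    table: pd.DataFrame
    strata: dict[str, float]
    flags: list[str] = field(default_factory=list)

    def effect(self, name: str) -> pd.Series:
        hit = self.table[self.table["effect"] == name]
        if hit.empty:
            raise KeyError(name)
        return hit.iloc[0]

    def p(self, name: str) -> float:
        return float(self.effect(name)["p"])


def _check_balanced(df: pd.DataFrame, subject: str, within: Sequence[str]) -> None:
    levels = [sorted(df[w].unique()) for w in within]
    subjects = df[subject].unique()
    counts = df.groupby([subject, *within], sort=False).size()
    if (counts != 1).any():
        bad = counts[counts != 1].index.tolist()[:5]
        raise DesignError(f"duplicated cells (subject, {', '.join(within)}): {bad}")
    expected = len(subjects) * int(np.prod([len(lv) for lv in levels]))
    if len(df) != expected:
        missing = expected - len(df)
        raise DesignError(
            f"incomplete design: {missing} missing cell(s); every subject needs "
            f"one observation per {' × '.join(within)} cell"
        )


def _f_and_p(ss_eff: float, df_eff: int, ss_err: float, df_err: int,
             flags: list[str], name: str) -> tuple[float, float]:
    ms_eff = ss_eff / df_eff if df_eff > 0 else np.nan
    ms_err = ss_err / df_err if df_err > 0 else np.nan
    if not np.isfinite(ms_err) or ms_err <= 0:
        if ms_eff == 0 or not np.isfinite(ms_eff):
            flags.append(f"{name}: zero error variance and zero effect; F set to 0")
            return 0.0, 1.0
        flags.append(f"{name}: zero error variance with nonzero effect")
        return float("inf"), 0.0
    f = ms_eff / ms_err
    return float(f), float(sps.f.sf(f, df_eff, df_err))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k × (k−1) orthonormal contrast matrix (columns orthogonal to 1)."""
    q, _ = np.linalg.qr(np.column_stack([np.ones(k), np.eye(k)[:, :-1]]))
    return q[:, 1:]


def _gg_epsilons(
    df: pd.DataFrame, dv: str, subject: str, between: str,
    within: Sequence[str],
) -> dict[str, float]:
    """Greenhouse–Geisser epsilon per within-subject error stratum.

    Uses the pooled within-group covariance of the subject cell vectors and
    the effect's orthonormal contrast space: eps = tr(A)² / (d·tr(A²)) with
    A = Wᵀ S W, clipped to [1/d, 1].
    """
    w1, w2 = within
    wide = df.pivot_table(index=subject, columns=[w1, w2], values=dv,
                          sort=True)
    groups = df.drop_duplicates(subject).set_index(subject)[between]
    centered = wide - wide.groupby(groups).transform("mean")
    s = centered.T @ centered  # pooled within-group scatter (scale-free for eps)
    b = df[w1].nunique()
    c = df[w2].nunique()
    cb, cc = _orthonormal_contrasts(b), _orthonormal_contrasts(c)
    ub = np.full((b, 1), 1.0 / math.sqrt(b))
    uc = np.full((c, 1), 1.0 / math.sqrt(c))
    spaces = {
        w1: np.kron(cb, uc),
        w2: np.kron(ub, cc),
        f"{w1}*{w2}": np.kron(cb, cc),
    }
    out = {}
    for name, w in spaces.items():
        a = w.T @ s.to_numpy() @ w
        d = a.shape[0]
        denom = d * float(np.trace(a @ a))
        eps = 1.0 if denom <= 0 else float(np.trace(a)) ** 2 / denom
        out[name] = float(np.clip(eps, 1.0 / d, 1.0))
    return out


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "participant_id",
    between: str = "bais_group",
    within: Sequence[str] = ("task", "condition"),
    sphericity: str = "none",
) -> AnovaResult:
    """Two-within, one-between mixed factorial ANOVA on a long table.

    Requires a complete balanced design: exactly one observation per
    subject × within-cell, with each subject in a single between group.
    Missing or duplicated cells raise; nothing is imputed.

    ``sphericity="greenhouse-geisser"`` adds per-stratum epsilon and
    GG-adjusted p values (columns ``eps``/``p_gg``) for the within-subject
    effects; the default reports uncorrected univariate F tests.
    """
    if sphericity not in ("none", "greenhouse-geisser"):
        raise DesignError(f"unknown sphericity option {sphericity!r}")
    if len(within) != 2:
        raise DesignError("mixed_anova expects exactly two within-subject factors")
    w1, w2 = within
    df = data[[subject, between, w1, w2, dv]].copy()
    if df[dv].isna().any():
        raise DesignError(f"{int(df[dv].isna().sum())} missing value(s) in {dv!r}")
    grp_per_subj = df.groupby(subject)[between].nunique()
    if (grp_per_subj != 1).any():
        raise DesignError("a subject appears in more than one between-group level")
    _check_balanced(df, subject, within)

    y = df[dv].to_numpy(dtype=float)
    m = y.mean()
    t = lambda cols: df.groupby(list(cols))[dv].transform("mean").to_numpy()
    m_g, m_s = t([between]), t([subject])
    m_t, m_c = t([w1]), t([w2])
    m_gt, m_gc = t([between, w1]), t([between, w2])
    m_st, m_sc = t([subject, w1]), t([subject, w2])
    m_tc = t([w1, w2])
    m_gtc = t([between, w1, w2])

    n_subj = df[subject].nunique()
    a = df[between].nunique()
    b = df[w1].nunique()
    c = df[w2].nunique()

    effects = {
        between: (m_g - m, a - 1),
        f"subjects({between})": (m_s - m_g, n_subj - a),
        w1: (m_t - m, b - 1),
        f"{between}*{w1}": (m_gt - m_g - m_t + m, (a - 1) * (b - 1)),
        f"{w1}*subjects": (m_st - m_s - m_gt + m_g, (n_subj - a) * (b - 1)),
        w2: (m_c - m, c - 1),
        f"{between}*{w2}": (m_gc - m_g - m_c + m, (a - 1) * (c - 1)),
        f"{w2}*subjects": (m_sc - m_s - m_gc + m_g, (n_subj - a) * (c - 1)),
        f"{w1}*{w2}": (m_tc - m_t - m_c + m, (b - 1) * (c - 1)),
        f"{between}*{w1}*{w2}": (
            m_gtc - m_gt - m_gc - m_tc + m_g + m_t + m_c - m,
            (a - 1) * (b - 1) * (c - 1),
        ),
        f"{w1}*{w2}*subjects": (
            y - m_st - m_sc - m_gtc + m_s + m_gt + m_gc - m_g,
            (n_subj - a) * (b - 1) * (c - 1),
        ),
    }
    ss = {k: float(np.sum(eff**2)) for k, (eff, _) in effects.items()}
    dfs = {k: d for k, (_, d) in effects.items()}

    strata = {
        "between": float(np.sum((m_s - m) ** 2)),
        w1: float(np.sum((m_st - m_s) ** 2)),
        w2: float(np.sum((m_sc - m_s) ** 2)),
        f"{w1}*{w2}": float(np.sum((y - m_st - m_sc + m_s) ** 2)),
    }

    err_of = {
        between: f"subjects({between})",
        w1: f"{w1}*subjects",
        f"{between}*{w1}": f"{w1}*subjects",
        w2: f"{w2}*subjects",
        f"{between}*{w2}": f"{w2}*subjects",
        f"{w1}*{w2}": f"{w1}*{w2}*subjects",
        f"{between}*{w1}*{w2}": f"{w1}*{w2}*subjects",
    }

    # which epsilon (by within-stratum) corrects each tested effect
    gg_stratum_of = {
        w1: w1, f"{between}*{w1}": w1,
        w2: w2, f"{between}*{w2}": w2,
        f"{w1}*{w2}": f"{w1}*{w2}", f"{between}*{w1}*{w2}": f"{w1}*{w2}",
    }
    epsilons = (
        _gg_epsilons(df, dv, subject, between, within)
        if sphericity == "greenhouse-geisser" else None
    )

    flags: list[str] = []
    rows = []
    for name in effects:
        err = err_of.get(name)
        if err is None:
            rows.append(
                dict(effect=name, ss=ss[name], df=dfs[name],
                     ms=ss[name] / dfs[name] if dfs[name] else np.nan,
                     error_term="", F=np.nan, p=np.nan)
            )
            continue
        f, p = _f_and_p(ss[name], dfs[name], ss[err], dfs[err], flags, name)
        row = dict(effect=name, ss=ss[name], df=dfs[name],
                   ms=ss[name] / dfs[name], error_term=err, F=f, p=p)
        if epsilons is not None:
            eps = epsilons.get(gg_stratum_of.get(name, ""), np.nan)
            row["eps"] = eps
            row["p_gg"] = (
                float(sps.f.sf(f, eps * dfs[name], eps * dfs[err]))
                if np.isfinite(eps) and np.isfinite(f) else p
            )
        rows.append(row)
    return AnovaResult(table=pd.DataFrame(rows), strata=strata, flags=flags)


@dataclass
class PairwiseResult:
    """Per-condition high-vs-low group comparisons with Bonferroni control."""

    table: pd.DataFrame
    family_size: int


def pairwise_by_condition(
    data: pd.DataFrame,
    dv: str,
    group_col: str = "bais_group",
    condition_col: str = "condition",
    groups: tuple[str, str] = ("high", "low"),
    conditions: Optional[Sequence[str]] = None,
    family_size: Optional[int] = None,
) -> PairwiseResult:
    """Pooled-variance two-sample t-tests (high vs low) per condition.

    The Bonferroni family defaults to the set of conditions compared (one
    family per measure/adjustment); a different family size may be imposed
    when comparisons are grouped differently.
    """
    if conditions is None:
        conditions = [c.value for c in AAF_CONDITIONS
                      if c.value in set(data[condition_col])]
        if not conditions:
            conditions = sorted(data[condition_col].unique())
    m = family_size if family_size is not None else len(conditions)
    rows = []
    for cond in conditions:
        sub = data[data[condition_col] == cond]
        hi = sub.loc[sub[group_col] == groups[0], dv].dropna().to_numpy(dtype=float)
        lo = sub.loc[sub[group_col] == groups[1], dv].dropna().to_numpy(dtype=float)
        if len(hi) < 2 or len(lo) < 2:
            raise InsufficientDataError(
                f"condition {cond}: need >= 2 observations per group "
                f"(got {len(hi)} high, {len(lo)} low)"
            )
        tt = sps.ttest_ind(hi, lo, equal_var=True)
        df_t = len(hi) + len(lo) - 2
        p_raw = float(tt.pvalue)
        rows.append(
            dict(
                condition=cond,
                n_high=len(hi), n_low=len(lo),
                mean_high=float(hi.mean()), sd_high=float(hi.std(ddof=1)),
                mean_low=float(lo.mean()), sd_low=float(lo.std(ddof=1)),
                t=float(tt.statistic), df=df_t,
                p_raw=p_raw, p_bonf=min(1.0, m * p_raw),
            )
        )
    return PairwiseResult(table=pd.DataFrame(rows), family_size=m)


@dataclass
class CorrelationResult:
    r: float
    n: int
    p: float
    kind: str = "full"  # "full" or "partial"
    controlled: tuple[str, ...] = ()


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with a two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise DomainError("x and y must have equal length")
    if len(x) < 3:
        raise InsufficientDataError("Pearson r needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DomainError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), n=len(x), p=float(p))


def partial_r_formula(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation from the three pairwise correlations."""
    denom = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom <= 0:
        raise DomainError("degenerate control: |r_xz| or |r_yz| is 1")
    return (r_xy - r_xz * r_yz) / np.sqrt(denom)


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    controls: Sequence[Sequence[float]] | Sequence[float] = (),
    control_names: tuple[str, ...] = (),
) -> CorrelationResult:
    """Correlation of x and y after removing linear effects of the controls.

    Computed as the Pearson correlation of the residuals from least-squares
    fits of x and y on the controls (with intercept); for a single control
    this equals the textbook first-order formula. With no controls it
    reduces exactly to the full correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(controls, dtype=float)
    if z.size == 0:
        return pearson(x, y)
    if z.ndim == 1:
        z = z[:, None]
    elif z.shape[0] != len(x):
        z = z.T
    n, k = z.shape
    if n != len(x) or len(x) != len(y):
        raise DomainError("x, y and controls must have equal length")
    if n < k + 4:
        raise InsufficientDataError(f"partial correlation needs n >= {k + 4}")
    design = np.column_stack([np.ones(n), z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise DomainError("degenerate control: a variable is collinear with z")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    t = r * np.sqrt(df / max(1e-300, 1.0 - r**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return CorrelationResult(
        r=r, n=n, p=p, kind="partial",
        controlled=control_names or tuple(f"z{i}" for i in range(k)),
    )


def nf_hf_equivalence(
    measures: pd.DataFrame, measure_cols: Sequence[str] = ("trd", "cv")
) -> pd.DataFrame:
    """Paired t-tests of the two control conditions (NF vs HF) per measure.

    A report-only check that the headphone control behaves like room
    feedback; nothing downstream is gated on it. Pairs are formed per
    participant × task.
    """
    rows = []
    keys = ["participant_id", "task"]
    for m in measure_cols:
        if m not in measures.columns:
            continue
        nf = measures[measures["condition"] == "NF"].set_index(keys)[m]
        hf = measures[measures["condition"] == "HF"].set_index(keys)[m]
        common = nf.index.intersection(hf.index)
        if len(common) < len(nf.index.union(hf.index)):
            raise DesignError(f"{m}: unmatched NF/HF pairs")
        a = nf.loc[common].to_numpy(dtype=float)
        b = hf.loc[common].to_numpy(dtype=float)
        ok = ~(np.isnan(a) | np.isnan(b))
        if ok.sum() < 2:
            raise InsufficientDataError(f"{m}: need >= 2 NF/HF pairs")
        if np.allclose(a[ok], b[ok]):
            t_val, p_val = 0.0, 1.0
        else:
            tt = sps.ttest_rel(a[ok], b[ok])
            t_val, p_val = float(tt.statistic), float(tt.pvalue)
        rows.append(dict(measure=m, n_pairs=int(ok.sum()), t=t_val,
                         df=int(ok.sum()) - 1, p=p_val))
    return pd.DataFrame(rows)
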