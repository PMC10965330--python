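"""Two-group morphometric comparison with assumption-based test selection.

Summary statistics and hypothesis tests operate on mean values per biological
placenta (one value per placenta), never on pooled villus replicates. Groups
are compared with a two-sided t-test when both groups pass a Shapiro normality
check and a Levene homogeneity check (at the assumption alpha), otherwise
with a two-sided Mann–Whitney U-test. The full decision trail is recorded.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, SchemaError

__all__ = ["GroupSample", "ComparisonResult", "aggregate_per_placenta",
           "compare_groups"]

MIN_VILLI_PER_PLACENTA = 5  # sampling floor; fewer triggers a warning
SHAPIRO_MIN_N = 3


@dataclass
class GroupSample:
    """Per-placenta means for one group (one value per biological placenta)."""

    group: str
    values: np.ndarray  # one entry per placenta
    placenta_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise SchemaError("GroupSample values must be one value per placenta")

    @property
    def n_placentas(self) -> int:
        return len(self.values)

    @property
    def testing_eligible(self) -> bool:
        return self.n_placentas >= 2

    def mean(self) -> float:
        return float(np.mean(self.values))

    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.n_placentas > 1 else 0.0


@dataclass
class ComparisonResult:
    """Outcome of a two-group comparison, including the assumption trail."""

    test_used: str  # "t_test" | "mann_whitney"
    statistic: float
    p_value: float
    group_means: dict[str, float]
    group_sds: dict[str, float]
    assumption_report: dict
    notes: list[str] = field(default_factory=list)


def aggregate_per_placenta(records: pd.DataFrame, value_col: str,
                           group_col: str = "group",
                           placenta_col: str = "placenta_id") -> dict[str, GroupSample]:
    """Collapse per-villus records to one (unweighted) mean per placenta.

    Returns one :class:`GroupSample` per group. Placentas with fewer than
    five villus replicates trigger a warning (the study's sampling floor).
    """
    for col in (value_col, group_col, placenta_col):
        if col not in records.columns:
            raise SchemaError(f"records table lacks required column {col!r}")
    if records[placenta_col].isna().any():
        raise SchemaError("records with missing placenta_id cannot be aggregated")
    counts = records.groupby(placenta_col, sort=True)[value_col].count()
    thin = counts[counts < MIN_VILLI_PER_PLACENTA]
    if len(thin):
        warnings.warn(
            f"placentas with fewer than {MIN_VILLI_PER_PLACENTA} villus "
            f"replicates: {', '.join(map(str, thin.index))}", stacklevel=2)
    out: dict[str, GroupSample] = {}
    for group, sub in records.groupby(group_col, sort=True):
        per_placenta = sub.groupby(placenta_col, sort=True)[value_col].mean()
        out[str(group)] = GroupSample(group=str(group),
                                      values=per_placenta.to_numpy(),
                                      placenta_ids=list(per_placenta.index))
    return out


def _welch_wanted(a: GroupSample, b: GroupSample) -> bool:
    # Welch when group sizes differ; Student's when balanced (Levene has
    # already passed whenever a t-test is selected).
    return a.n_placentas != b.n_placentas


def compare_groups(a: GroupSample, b: GroupSample,
                   alpha: float = 0.05) -> ComparisonResult:
    """Compare two groups of per-placenta means.

    Assumption checks: Shapiro normality per group and Levene homogeneity of
    variance across groups, both at ``alpha``. If every check passes, a
    two-sided two-sample t-test is used (Welch's for unequal group sizes,
    Student's otherwise); if any fails — or a group is too small for Shapiro —
    a two-sided Mann–Whitney U-test is used instead.
    """
    for s in (a, b):
        if s.n_placentas < 2:
            raise InsufficientDataError(
                f"group {s.group!r} has {s.n_placentas} placenta value(s); "
                "need ≥ 2 for any comparison")
    notes: list[str] = []
    shapiro_p: dict[str, float | None] = {}
    for s in (a, b):
        if s.n_placentas >= SHAPIRO_MIN_N and np.ptp(s.values) > 0:
            shapiro_p[s.group] = float(sps.shapiro(s.values).pvalue)
        else:
            shapiro_p[s.group] = None
            notes.append(
                f"Shapiro not computable for group {s.group!r} "
                f"(n={s.n_placentas}, spread={np.ptp(s.values):.3g}); "
                "falling back to Mann–Whitney")
    if all(p is not None for p in shapiro_p.values()):
        levene_p = float(sps.levene(a.values, b.values).pvalue)
    else:
        levene_p = None

    normal = all(p is not None and p >= alpha for p in shapiro_p.values())
    homogeneous = levene_p is not None and levene_p >= alpha
    use_t = normal and homogeneous

    if use_t:
        equal_var = not _welch_wanted(a, b)
        res = sps.ttest_ind(a.values, b.values, equal_var=equal_var)
        test_used = "t_test"
        notes.append("Student's t (equal n)" if equal_var
                     else "Welch's t (unequal n)")
    else:
        method = "exact" if max(a.n_placentas, b.n_placentas) <= 8 else "asymptotic"
        res = sps.mannwhitneyu(a.values, b.values, alternative="two-sided",
                               method=method)
        test_used = "mann_whitney"
        notes.append(f"Mann–Whitney U ({method})")

    return ComparisonResult(
        test_used=test_used,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_means={a.group: a.mean(), b.group: b.mean()},
        group_sds={a.group: a.sd(), b.group: b.sd()},
        assumption_report={
            "alpha": alpha,
            "shapiro_p": shapiro_p,
            "levene_p": levene_p,
            "normality_ok": normal,
            "homogeneity_ok": homogeneous,
        },
        notes=notes,
    )
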