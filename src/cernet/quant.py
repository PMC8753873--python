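"""Relative qPCR quantification (2^-ΔΔCt) and group-comparison statistics.

Relative expression uses the double-delta-Ct convention: per sample,
ΔCt = Ct(target) − Ct(reference); ΔΔCt subtracts the *mean* control-group
ΔCt (replicate-based centering rather than a single calibrator well), so
the control group's geometric-mean fold is 1 by construction.

Group comparisons follow the classical two-stage recipe: Student's
pooled-variance t-test for two groups; one-way fixed-effects ANOVA for
three or more, with Student–Newman–Keuls (SNK, the "q test") stepwise
studentized-range post-hoc pairwise comparisons.  Tukey HSD is offered
as an alternative post-hoc.  Summaries are mean ± SD with the n−1
denominator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtRecord",
    "GroupSummary",
    "PairwiseComparison",
    "TwoGroupResult",
    "AnovaResult",
    "relative_expression",
    "compare_two_groups",
    "compare_many_groups",
    "summarize_od",
    "load_ct_table",
]


@dataclass(frozen=True)
class CtRecord:
    """One qPCR well: sample, group, gene, threshold cycle."""

    sample_id: str
    group: str
    gene: str
    ct: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.ct):
            raise ValueError(f"{self.sample_id}/{self.gene}: Ct must be finite")
        if not 5 < self.ct < 40:
            warnings.warn(
                f"{self.sample_id}/{self.gene}: Ct {self.ct:.2f} outside the "
                "usual 5-40 range",
                stacklevel=2,
            )


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float | None  # undefined for n == 1


def _as_ct_frame(table: pd.DataFrame | Iterable[CtRecord]) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        missing = {"sample_id", "group", "gene", "ct"} - set(table.columns)
        if missing:
            raise ValueError(f"Ct table missing column(s) {sorted(missing)}")
        return table
    recs = list(table)
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in recs],
            "group": [r.group for r in recs],
            "gene": [r.gene for r in recs],
            "ct": [r.ct for r in recs],
        }
    )


def relative_expression(
    ct_table: pd.DataFrame | Iterable[CtRecord],
    target_gene: str,
    reference_gene: str,
    control_group: str,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample 2^-ΔΔCt fold changes for ``target_gene``.

    Returns (per-sample frame with delta_ct / ddct / fold, excluded
    sample ids).  Samples lacking exactly one Ct for either gene are
    excluded and reported rather than silently dropped.
    """
    df = _as_ct_frame(ct_table)
    excluded: list[str] = []
    rows = []
    for sample, sub in df.groupby("sample_id", sort=False):
        t = sub.loc[sub["gene"] == target_gene, "ct"]
        r = sub.loc[sub["gene"] == reference_gene, "ct"]
        if len(t) != 1 or len(r) != 1:
            excluded.append(str(sample))
            continue
        rows.append(
            {
                "sample_id": sample,
                "group": sub["group"].iloc[0],
                "delta_ct": float(t.iloc[0]) - float(r.iloc[0]),
            }
        )
    out = pd.DataFrame(rows, columns=["sample_id", "group", "delta_ct"])
    control = out.loc[out["group"] == control_group, "delta_ct"]
    if control.empty:
        raise ValueError(f"control group {control_group!r} has no usable samples")
    out["ddct"] = out["delta_ct"] - control.mean()
    out["fold"] = np.exp2(-out["ddct"])
    return out, excluded


@dataclass(frozen=True)
class TwoGroupResult:
    t: float
    df: int
    p: float
    degenerate: bool = False  # zero pooled variance with equal means


def compare_two_groups(a: Sequence[float], b: Sequence[float]) -> TwoGroupResult:
    """Student's pooled-variance two-sample t-test (two-sided).

    Zero pooled variance with equal means returns p = 1 flagged as
    degenerate; with unequal means it is an error (an infinite t
    statistic is not a meaningful answer).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    dof = len(a) + len(b) - 2
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return TwoGroupResult(t=0.0, df=dof, p=1.0, degenerate=True)
        raise ValueError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TwoGroupResult(t=float(t), df=dof, p=float(p))


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float
    q_statistic: float | None
    p: float | None  # None when untested under SNK step-down logic
    significant: bool


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int
    posthoc: tuple[PairwiseComparison, ...]
    method: str = "snk"


def _snk_posthoc(
    labels: list[str],
    means: np.ndarray,
    ns: np.ndarray,
    msw: float,
    df_within: int,
    alpha: float,
) -> list[PairwiseComparison]:
    """Student-Newman-Keuls stepwise studentized-range comparisons.

    Means are ordered; the widest stretch is tested first at range r; a
    non-significant stretch declares every pair inside it non-significant
    without testing (those pairs carry p = None).
    """
    order = np.argsort(means, kind="stable")
    labels = [labels[i] for i in order]
    means = means[order]
    ns = ns[order]
    k = len(labels)
    decisions: dict[tuple[int, int], tuple[float | None, float | None, bool]] = {}

    # widest ranges first; a homogeneous stretch freezes everything inside it
    for r in range(k, 1, -1):
        for i in range(0, k - r + 1):
            j = i + r - 1
            if (i, j) in decisions:
                continue
            se = math.sqrt(msw / 2 * (1 / ns[i] + 1 / ns[j]))  # Tukey-Kramer SE
            if se == 0:
                q = math.inf if means[j] != means[i] else 0.0
                p = 0.0 if q else 1.0
            else:
                q = float((means[j] - means[i]) / se)
                p = float(stats.studentized_range.sf(q, r, df_within))
            if p < alpha:
                decisions[(i, j)] = (q, p, True)
            else:
                decisions[(i, j)] = (q, p, False)
                for a in range(i, j + 1):
                    for b in range(a + 1, j + 1):
                        decisions.setdefault((a, b), (None, None, False))
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            q, p, sig = decisions[(i, j)]
            out.append(
                PairwiseComparison(
                    group_a=labels[i],
                    group_b=labels[j],
                    mean_diff=float(means[j] - means[i]),
                    q_statistic=q,
                    p=p,
                    significant=sig,
                )
            )
    return out


def _tukey_posthoc(
    labels: list[str],
    groups: list[np.ndarray],
    msw: float,
    df_within: int,
    alpha: float,
) -> list[PairwiseComparison]:
    k = len(labels)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[i], groups[j]
            se = math.sqrt(msw / 2 * (1 / len(a) + 1 / len(b)))
            diff = float(b.mean() - a.mean())
            q = abs(diff) / se if se else (math.inf if diff else 0.0)
            p = float(stats.studentized_range.sf(q, k, df_within)) if se else float(q == 0)
            out.append(
                PairwiseComparison(
                    group_a=labels[i], group_b=labels[j], mean_diff=diff,
                    q_statistic=float(q), p=p, significant=p < alpha,
                )
            )
    return out


def compare_many_groups(
    groups: Sequence[tuple[str, Sequence[float]]],
    alpha: float = 0.05,
    posthoc: str = "snk",
) -> AnovaResult:
    """One-way fixed-effects ANOVA with q-test post-hoc pairwise comparisons.

    Requires at least three groups (use :func:`compare_two_groups` for
    two) with n >= 2 each.  ``posthoc`` is "snk" (default) or "tukey".
    Group order does not affect any decision.
    """
    if len(groups) < 3:
        raise ValueError("fewer than 3 groups: use compare_two_groups")
    labels = [str(g) for g, _ in groups]
    arrays = [np.asarray(v, dtype=float) for _, v in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    n_total = sum(len(a) for a in arrays)
    df_between = len(arrays) - 1
    df_within = n_total - len(arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    msw = ssw / df_within
    if ssw == 0 and ssb == 0:
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*arrays)
    means = np.array([a.mean() for a in arrays])
    ns = np.array([len(a) for a in arrays])
    if posthoc == "snk":
        pairs = _snk_posthoc(labels, means, ns, msw, df_within, alpha)
    elif posthoc == "tukey":
        pairs = _tukey_posthoc(labels, arrays, msw, df_within, alpha)
    else:
        raise ValueError(f"unknown posthoc {posthoc!r}")
    # canonical pair order: by input label order
    rank = {lab: i for i, lab in enumerate(labels)}
    pairs.sort(key=lambda c: (min(rank[c.group_a], rank[c.group_b]),
                              max(rank[c.group_a], rank[c.group_b])))
    return AnovaResult(
        f=float(f_stat), p=float(p), df_between=df_between,
        df_within=df_within, posthoc=tuple(pairs), method=posthoc,
    )


def summarize_od(
    readings: pd.DataFrame | Sequence[tuple[str, float]],
    alpha: float = 0.05,
) -> tuple[list[GroupSummary], TwoGroupResult | AnovaResult | None]:
    """Mean ± SD per group and the appropriate between-group test.

    Two eligible groups dispatch to the pooled t-test, three or more to
    ANOVA + SNK; single-replicate groups are summarized without an SD and
    excluded from testing (reported via a warning).
    """
    if not isinstance(readings, pd.DataFrame):
        readings = pd.DataFrame(list(readings), columns=["group", "od510"])
    summaries: list[GroupSummary] = []
    eligible: list[tuple[str, np.ndarray]] = []
    for group, sub in readings.groupby("group", sort=False):
        vals = sub["od510"].to_numpy(dtype=float)
        sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else None
        summaries.append(
            GroupSummary(group=str(group), n=len(vals), mean=float(vals.mean()), sd=sd)
        )
        if len(vals) >= 2:
            eligible.append((str(group), vals))
        else:
            warnings.warn(
                f"group {group!r} has a single replicate; excluded from testing",
                stacklevel=2,
            )
    if len(eligible) < 2:
        return summaries, None
    if len(eligible) == 2:
        return summaries, compare_two_groups(eligible[0][1], eligible[1][1])
    return summaries, compare_many_groups(eligible, alpha=alpha)


def load_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str, "gene": str})
    missing = {"sample_id", "group", "gene", "ct"} - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing column(s) {sorted(missing)}")
    return df
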