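"""Group summaries, one-way ANOVA and the Student-Newman-Keuls procedure.

The study design compares three groups of n = 10 subjects on each ISS
metric (D*, lambda, k', t_1/2, maximum spread volume) by one-way ANOVA
followed by the SNK stepwise range test at alpha = 0.05.  The ANOVA is
computed from sums of squares directly; the SNK critical ranges use the
studentized-range distribution (scipy's ``studentized_range``), which an
independent test cross-checks pair by pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "SnkPair",
    "AnovaSnkResult",
    "one_way_anova",
    "snk_test",
    "summarize_groups",
]


@dataclass
class GroupSummary:
    group: str
    n: int
    mean: float
    sem: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ms_within: float
    degenerate: bool = False


@dataclass
class SnkPair:
    groups: tuple[str, str]
    mean_diff: float  # larger mean minus smaller mean, always >= 0
    span: int  # number of ordered means the pair stretches across
    critical_range: float
    significant: bool
    tested: bool  # False when skipped by the stepwise rule


@dataclass
class AnovaSnkResult:
    metric: str
    anova: AnovaResult
    snk_pairs: list[SnkPair] = field(default_factory=list)
    alpha: float = 0.05


def _validate_groups(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    out = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float).ravel()
        if v.size < 2:
            raise ValueError(f"group {name!r} needs >= 2 values")
        out[name] = v
    return out


def one_way_anova(groups: dict[str, np.ndarray]) -> AnovaResult:
    """One-way fixed-effects ANOVA from sums of squares.

    ``groups`` maps group label to a 1D array of per-subject values.
    F = MS_between / MS_within with the usual k-1 and N-k degrees of
    freedom; p from the F distribution's survival function.
    """
    groups = _validate_groups(groups)
    k = len(groups)
    ns = np.array([v.size for v in groups.values()])
    N = int(ns.sum())
    grand = np.concatenate(list(groups.values())).mean()
    ss_between = float(sum(v.size * (v.mean() - grand) ** 2 for v in groups.values()))
    ss_within = float(sum(((v - v.mean()) ** 2).sum() for v in groups.values()))
    df_b, df_w = k - 1, N - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        if ss_between == 0:
            return AnovaResult(F=0.0, df_between=df_b, df_within=df_w, p=1.0, ms_within=0.0)
        warnings.warn(
            "zero within-group variance with unequal means: F is infinite, p = 0",
            stacklevel=2,
        )
        return AnovaResult(
            F=np.inf, df_between=df_b, df_within=df_w, p=0.0, ms_within=0.0, degenerate=True
        )
    F = ms_b / ms_w
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=p, ms_within=ms_w)


def snk_test(groups: dict[str, np.ndarray], alpha: float = 0.05) -> list[SnkPair]:
    """Student-Newman-Keuls stepwise multiple comparisons.

    Group means are ordered; a pair spanning ``p`` ordered means is declared
    significant when its range exceeds

        q(alpha; p, df_within) * sqrt(MS_within / n_h)

    with ``n_h`` the harmonic mean of the two group sizes, stepping down
    from the widest span.  Pairs nested inside a non-significant span are
    not tested (reported with ``tested=False``), which is what keeps SNK
    coherent: it can never find a sub-range significant inside a range that
    was not.
    """
    groups = _validate_groups(groups)
    anova = one_way_anova(groups)
    if anova.ms_within == 0:
        # all comparisons degenerate; significant iff means differ at all
        names = list(groups)
        return [
            SnkPair(
                groups=(a, b),
                mean_diff=abs(groups[a].mean() - groups[b].mean()),
                span=2,
                critical_range=0.0,
                significant=groups[a].mean() != groups[b].mean(),
                tested=True,
            )
            for a, b in combinations(names, 2)
        ]
    ns = {g: v.size for g, v in groups.items()}
    if len(set(ns.values())) > 1:
        warnings.warn(
            "unequal group sizes: SNK uses the harmonic mean n per pair",
            stacklevel=2,
        )
    order = sorted(groups, key=lambda g: groups[g].mean())
    means = {g: groups[g].mean() for g in groups}
    df_w = anova.df_within

    results: dict[frozenset, SnkPair] = {}
    blocked: set[frozenset] = set()
    k = len(order)
    for span in range(k, 1, -1):
        q_crit = float(stats.studentized_range.ppf(1.0 - alpha, span, df_w))
        for start in range(0, k - span + 1):
            lo_g, hi_g = order[start], order[start + span - 1]
            key = frozenset((lo_g, hi_g))
            diff = means[hi_g] - means[lo_g]
            n_h = 2.0 / (1.0 / ns[lo_g] + 1.0 / ns[hi_g])
            crit = q_crit * np.sqrt(anova.ms_within / n_h)
            if key in blocked:
                results[key] = SnkPair(
                    groups=(lo_g, hi_g), mean_diff=diff, span=span,
                    critical_range=crit, significant=False, tested=False,
                )
                continue
            sig = diff > crit
            results[key] = SnkPair(
                groups=(lo_g, hi_g), mean_diff=diff, span=span,
                critical_range=crit, significant=bool(sig), tested=True,
            )
            if not sig:
                # everything nested inside a non-significant range is
                # declared non-significant without testing
                for i in range(start, start + span):
                    for j in range(i + 1, start + span):
                        inner = frozenset((order[i], order[j]))
                        if inner != key:
                            blocked.add(inner)
    return sorted(results.values(), key=lambda p: (-p.span, p.groups))


def summarize_groups(
    results: pd.DataFrame,
    metrics: list[str] | None = None,
    alpha: float = 0.05,
) -> tuple[list[GroupSummary], list[AnovaSnkResult], pd.DataFrame]:
    """Per-group mean ± SEM plus ANOVA/SNK for each metric.

    ``results`` holds one row per subject with a ``group`` column and one
    column per metric.  Subjects missing a metric are excluded from that
    metric with a warning.  Returns the flat summaries, one ANOVA/SNK
    record per metric, and a tidy table (metric x group) ready for report
    output.
    """
    if "group" not in results.columns:
        raise ValueError("results must have a 'group' column")
    if metrics is None:
        metrics = [
            c for c in results.columns
            if c not in ("group", "subject_id") and np.issubdtype(results[c].dtype, np.number)
        ]
    if not metrics:
        raise ValueError("no metric columns found")

    summaries: list[GroupSummary] = []
    tests: list[AnovaSnkResult] = []
    rows = []
    for metric in metrics:
        grouped: dict[str, np.ndarray] = {}
        for gname, sub in results.groupby("group", sort=True):
            vals = sub[metric].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            if not ok.all():
                warnings.warn(
                    f"{metric}: dropped {int((~ok).sum())} subject(s) in group "
                    f"{gname!r} with missing values",
                    stacklevel=2,
                )
            vals = vals[ok]
            if vals.size == 0:
                continue
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            summaries.append(
                GroupSummary(
                    group=str(gname), n=int(vals.size), mean=float(vals.mean()),
                    sem=sd / np.sqrt(vals.size), sd=sd,
                )
            )
            grouped[str(gname)] = vals
            rows.append(
                {"metric": metric, "group": str(gname), "n": vals.size,
                 "mean": vals.mean(), "sem": sd / np.sqrt(vals.size)}
            )
        if len(grouped) >= 2 and all(v.size >= 2 for v in grouped.values()):
            anova = one_way_anova(grouped)
            pairs = snk_test(grouped, alpha=alpha)
            tests.append(AnovaSnkResult(metric=metric, anova=anova, snk_pairs=pairs, alpha=alpha))
        else:
            warnings.warn(
                f"{metric}: ANOVA skipped (need >= 2 groups with >= 2 subjects)",
                stacklevel=2,
            )
    table = pd.DataFrame(rows)
    return summaries, tests, table
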