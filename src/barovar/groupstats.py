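"""Group comparison: Levene homogeneity check, one-way ANOVA, SNK post-hoc.

The post-hoc stage is the stepwise Student–Newman–Keuls procedure on
ordered group means: the extremes of a span of ``r`` ordered means are
compared through the studentized range ``q = |diff| / sqrt(MS_within/n_h)``
(``n_h`` the harmonic mean of the two group sizes) against the
``q`` critical value for that span, and every pair inside a span already
declared non-significant is blocked.  Significance is inclusive at
``p <= alpha_level``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "GroupData",
    "AnovaResult",
    "LeveneResult",
    "SnkResult",
    "SnkPair",
    "levene_test",
    "oneway_anova",
    "snk_posthoc",
    "summarize",
]


@dataclass(frozen=True)
class GroupData:
    """Per-group vectors of one endpoint (one value per animal)."""

    groups: dict[str, np.ndarray]
    endpoint: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        cleaned = {}
        for name, values in self.groups.items():
            arr = np.asarray(values, dtype=float)
            if arr.size < 2:
                raise ValueError(f"group {name!r} needs at least 2 values")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"group {name!r} contains non-finite values")
            cleaned[str(name)] = arr
        if not cleaned:
            raise ValueError("no groups")
        object.__setattr__(self, "groups", cleaned)

    @property
    def k(self) -> int:
        return len(self.groups)

    @property
    def n_total(self) -> int:
        return int(sum(v.size for v in self.groups.values()))


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    ms_within: float


@dataclass(frozen=True)
class LeveneResult:
    w_stat: float
    p_value: float


@dataclass(frozen=True)
class SnkPair:
    group_a: str
    group_b: str
    mean_diff: float
    q_stat: float
    significant: bool
    blocked: bool = False


@dataclass(frozen=True)
class SnkResult:
    pairwise: list[SnkPair]
    letters: dict[str, str]
    alpha_level: float
    omnibus_significant: bool | None = None

    def significant_pairs(self) -> set[frozenset]:
        return {
            frozenset((p.group_a, p.group_b)) for p in self.pairwise if p.significant
        }

    def is_significant(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.significant_pairs()


def _require_two_groups(g: GroupData) -> None:
    if g.k < 2:
        raise ValueError("at least 2 groups are required")


def oneway_anova(g: GroupData) -> AnovaResult:
    """Classical one-way between/within decomposition with an F reference."""
    _require_two_groups(g)
    values = list(g.groups.values())
    all_vals = np.concatenate(values)
    grand = all_vals.mean()
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in values)
    ssw = sum(float(np.sum((v - v.mean()) ** 2)) for v in values)
    dfb = g.k - 1
    dfw = g.n_total - g.k
    msw = ssw / dfw
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, dfb, dfw, 1.0, 0.0)
        return AnovaResult(float("inf"), dfb, dfw, 0.0, 0.0)
    f = (ssb / dfb) / msw
    p = float(stats.f.sf(f, dfb, dfw))
    return AnovaResult(float(f), dfb, dfw, p, float(msw))


def levene_test(g: GroupData, center: str = "mean") -> LeveneResult:
    """Levene's homogeneity-of-variance test.

    ``center="mean"`` is the original Levene statistic; ``center="median"``
    gives the Brown–Forsythe variant.  The statistic is the one-way ANOVA F
    on the absolute deviations from the group centers.
    """
    _require_two_groups(g)
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    devs = {}
    for name, v in g.groups.items():
        c = np.mean(v) if center == "mean" else np.median(v)
        devs[name] = np.abs(v - c)
    res = oneway_anova(GroupData(devs))
    if np.isinf(res.f_stat):
        log.warning("Levene within-group deviation spread is zero; W reported as +inf")
    return LeveneResult(w_stat=res.f_stat, p_value=res.p_value)


@lru_cache(maxsize=512)
def _q_crit(alpha_level: float, r: int, dfw: int) -> float:
    q = float(stats.studentized_range.ppf(1.0 - alpha_level, r, dfw))
    if not np.isfinite(q):
        raise ValueError(
            f"studentized-range quantile unavailable for r={r}, df={dfw}"
        )
    return q


def snk_posthoc(
    g: GroupData,
    a: AnovaResult | None = None,
    alpha_level: float = 0.05,
) -> SnkResult:
    """Student–Newman–Keuls stepwise comparison of ordered group means.

    Spans are tested from the widest (all ``k`` means) downward; a
    non-significant span blocks every pair it contains.  With unequal group
    sizes the harmonic mean of the two compared sizes enters the standard
    error.  Returns all pairwise decisions plus a compact-letter display
    (groups sharing a letter are mutually non-significant).
    """
    _require_two_groups(g)
    if a is None:
        a = oneway_anova(g)
    names = list(g.groups)
    means = np.array([g.groups[n].mean() for n in names])
    sizes = np.array([g.groups[n].size for n in names])
    order = np.argsort(means, kind="stable")
    names = [names[i] for i in order]
    means = means[order]
    sizes = sizes[order]
    k = len(names)
    ns_spans: list[tuple[int, int]] = []
    decisions: dict[tuple[int, int], tuple[float, bool, bool]] = {}
    for r in range(k, 1, -1):
        for i in range(0, k - r + 1):
            j = i + r - 1
            diff = means[j] - means[i]
            n_h = 2.0 / (1.0 / sizes[i] + 1.0 / sizes[j])
            if a.ms_within > 0:
                q = diff / np.sqrt(a.ms_within / n_h)
            else:
                q = 0.0 if diff == 0 else float("inf")
            blocked = any(lo <= i and j <= hi for lo, hi in ns_spans)
            if blocked:
                sig = False
            else:
                sig = q >= _q_crit(alpha_level, r, a.df_within)
                if not sig:
                    ns_spans.append((i, j))
            decisions[(i, j)] = (float(q), sig, blocked)
    pairwise = [
        SnkPair(
            group_a=names[i],
            group_b=names[j],
            mean_diff=float(means[j] - means[i]),
            q_stat=q,
            significant=sig,
            blocked=blocked,
        )
        for (i, j), (q, sig, blocked) in sorted(decisions.items())
    ]
    letters = _compact_letters(names, ns_spans, k)
    return SnkResult(
        pairwise=pairwise,
        letters=letters,
        alpha_level=alpha_level,
        omnibus_significant=(a.p_value <= alpha_level),
    )


def _compact_letters(
    names: list[str], ns_spans: list[tuple[int, int]], k: int
) -> dict[str, str]:
    # maximal non-significant intervals on the ordered means; singletons
    # not covered by any interval get their own letter
    maximal = [
        (lo, hi)
        for lo, hi in ns_spans
        if not any((lo2 <= lo and hi <= hi2) and (lo2, hi2) != (lo, hi)
                   for lo2, hi2 in ns_spans)
    ]
    covered = set()
    for lo, hi in maximal:
        covered.update(range(lo, hi + 1))
    for i in range(k):
        if i not in covered:
            maximal.append((i, i))
    maximal.sort()
    letters: dict[str, list[str]] = {n: [] for n in names}
    for idx, (lo, hi) in enumerate(maximal):
        letter = chr(ord("a") + idx)
        for i in range(lo, hi + 1):
            letters[names[i]].append(letter)
    return {n: "".join(v) for n, v in letters.items()}


def summarize(
    g: GroupData,
    snk: SnkResult | None = None,
    order: list[str] | None = None,
    ref_symbols: tuple[str, ...] = ("*", "#", "§"),
    digits: int = 2,
) -> pd.DataFrame:
    """Mean ± SD table with significance annotations per reference group.

    ``order`` fixes the group columns (defaults to insertion order); a
    group is annotated with symbol ``i`` when the SNK decision against
    ``order[i]`` is significant, mirroring the vs.-SO / vs.-SOE / vs.-TO
    marking convention of small-animal physiology tables.
    """
    if order is None:
        order = list(g.groups)
    if snk is None and g.k >= 2:
        snk = snk_posthoc(g)
    rows = []
    for name in order:
        v = g.groups[name]
        mean, sd = float(np.mean(v)), float(np.std(v, ddof=1))
        marks = ""
        if snk is not None:
            for i, ref in enumerate(order[: len(ref_symbols)]):
                if ref == name:
                    continue
                if order.index(name) > i and snk.is_significant(name, ref):
                    marks += ref_symbols[i]
        rows.append(
            {
                "group": name,
                "n": int(v.size),
                "mean": mean,
                "sd": sd,
                "label": f"{mean:.{digits}f} ± {sd:.{digits}f}{marks}",
                "letters": snk.letters.get(name, "") if snk is not None else "",
            }
        )
    return pd.DataFrame(rows)
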