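"""Cohort-weighted one-way ANOVA, group means with 95% CIs, Tukey-Kramer
pairwise comparisons, Bonferroni thresholds and compact letter display.

The unit of analysis is the sample set; each set contributes its variant-
allele frequency ``y`` with weight ``w`` equal to its cohort size. The
weighted one-way ANOVA is algebraically identical to weighted least squares
of ``y`` on group indicator variables (a property the test suite asserts to
1e-10):

    SSB = sum_g W_g (ybar_g - ybar)^2        (between groups)
    SSW = sum_i w_i (y_i - ybar_g(i))^2      (within groups)
    F   = (SSB / (k-1)) / (SSW / (N-k))

with ``r^2 = SSB/(SSB+SSW)`` and ``adj r^2 = 1 - (1-r^2)(N-1)/(N-k)``. All
quantities are invariant to rescaling the weights by a positive constant.

Confidence intervals use the pooled mean square within on the weighted scale:
``mean_g +/- t(df_w, (1+level)/2) * sqrt(MSW / W_g)``. They are deliberately
not clamped to [0, 1]: a model-based interval around a frequency near 0 or 1
can cross the boundary, and such bounds are reported as-is.

Tukey-Kramer pairwise p values come from the studentized range distribution
(scipy.stats.studentized_range) with the unequal-size form

    q_ij = |ybar_i - ybar_j| / sqrt( (MSW/2) (1/W_i + 1/W_j) ).
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data_io import GROUP_PAIRS, GROUPS, DataValidationError, FrequencyMatrix, SampleSet


@dataclass(frozen=True)
class SignificanceThresholds:
    """Bonferroni-adjusted significance thresholds (strict inequality)."""

    alpha_assoc: float = 0.001
    alpha_pairwise: float = 0.0001

    def __post_init__(self) -> None:
        for a in (self.alpha_assoc, self.alpha_pairwise):
            if not (0.0 < a < 1.0):
                raise DataValidationError(f"alpha {a} not in (0,1)")


@dataclass
class WeightedGroups:
    """Per-set observations for one variant: value, weight (cohort n), group."""

    y: np.ndarray
    w: np.ndarray
    groups: np.ndarray  # group label per observation
    group_order: tuple[str, ...] = GROUPS

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        self.groups = np.asarray(self.groups, dtype=object)
        if not (self.y.size == self.w.size == self.groups.size):
            raise DataValidationError("y, w and groups must have equal length")
        if (self.w <= 0).any():
            raise DataValidationError("weights must be positive")
        present = set(self.groups)
        self.group_order = tuple(g for g in self.group_order if g in present)
        if len(self.group_order) < 2:
            raise DataValidationError("need >= 2 groups with data")


def assemble_weighted_groups(
    freq: FrequencyMatrix, sets: Sequence[SampleSet], rsid: str
) -> tuple[WeightedGroups, int, int]:
    """Extract one variant's non-missing observations.

    Returns the weighted groups plus the number of sets and subjects used
    (per-variant missingness makes these smaller than the full roster).
    """
    by_id = {s.id: s for s in sets}
    col = freq.column(rsid)
    ids = [i for i in col.index if i in by_id and not np.isnan(col.loc[i])]
    y = np.array([col.loc[i] for i in ids])
    w = np.array([by_id[i].n for i in ids], dtype=float)
    g = np.array([by_id[i].group for i in ids], dtype=object)
    wg = WeightedGroups(y=y, w=w, groups=g)
    return wg, len(ids), int(w.sum())


@dataclass
class AnovaResult:
    group_order: tuple[str, ...]
    group_means: dict[str, float]
    group_weights: dict[str, float]   # W_g = sum of cohort sizes in group
    group_counts: dict[str, int]      # number of sample sets in group
    grand_mean: float
    ssb: float
    ssw: float
    df_between: int
    df_within: int
    f_stat: float
    p_value: float
    r2: float
    adj_r2: float
    msw: float
    perfect_separation: bool = False


def weighted_group_means(data: WeightedGroups) -> dict[str, tuple[float, float, int]]:
    """Per-group (weighted mean, weight total, set count)."""
    out = {}
    for g in data.group_order:
        m = data.groups == g
        out[g] = (
            float(np.average(data.y[m], weights=data.w[m])),
            float(data.w[m].sum()),
            int(m.sum()),
        )
    return out


def weighted_anova(data: WeightedGroups) -> AnovaResult:
    """Cohort-weighted one-way ANOVA across the geographic groups."""
    k = len(data.group_order)
    n = data.y.size
    if n <= k:
        raise DataValidationError(f"need more sets ({n}) than groups ({k})")
    if max(np.sum(data.groups == g) for g in data.group_order) < 2:
        raise DataValidationError("at least one group needs >= 2 sets")
    per_group = weighted_group_means(data)
    grand = float(np.average(data.y, weights=data.w))
    ssb = sum(wg * (m - grand) ** 2 for m, wg, _ in per_group.values())
    group_mean_of = {g: per_group[g][0] for g in data.group_order}
    resid = data.y - np.array([group_mean_of[g] for g in data.groups])
    ssw = float(np.sum(data.w * resid**2))
    dfb, dfw = k - 1, n - k
    # guard against catastrophic cancellation on (near-)constant data
    tiny = 1e-12 * max(1.0, float(np.sum(data.w * data.y**2)))
    if ssw <= tiny and ssb <= tiny:
        ssb = ssw = 0.0
    elif ssw <= tiny:
        ssw = 0.0
    msw = ssw / dfw
    perfect = False
    if ssw == 0.0 and ssb > 0.0:
        f = float("inf")
        p = 0.0
        perfect = True
    elif ssb == 0.0 and ssw == 0.0:
        f, p = 0.0, 1.0
    else:
        f = (ssb / dfb) / msw
        p = float(stats.f.sf(f, dfb, dfw))
    total = ssb + ssw
    r2 = ssb / total if total > 0 else 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / dfw
    return AnovaResult(
        group_order=data.group_order,
        group_means=group_mean_of,
        group_weights={g: per_group[g][1] for g in data.group_order},
        group_counts={g: per_group[g][2] for g in data.group_order},
        grand_mean=grand,
        ssb=float(ssb),
        ssw=ssw,
        df_between=dfb,
        df_within=dfw,
        f_stat=f,
        p_value=p,
        r2=float(r2),
        adj_r2=float(adj_r2),
        msw=msw,
        perfect_separation=perfect,
    )


def group_confidence_interval(
    result: AnovaResult, group: str, level: float = 0.95
) -> tuple[float, float]:
    """Model-based CI for a group mean from the pooled within-group variance.

    Bounds are not clamped to [0, 1]; intervals around frequencies near the
    boundary may legitimately cross it.
    """
    if group not in result.group_means:
        raise KeyError(group)
    mean = result.group_means[group]
    if result.msw == 0.0:
        return (mean, mean)
    half = stats.t.ppf(0.5 + level / 2.0, result.df_within) * np.sqrt(
        result.msw / result.group_weights[group]
    )
    return (float(mean - half), float(mean + half))


def tukey_kramer(result: AnovaResult) -> dict[tuple[str, str], float]:
    """All-pairs Tukey-Kramer p values from the studentized range distribution."""
    k = len(result.group_order)
    if result.df_within < 1:
        raise DataValidationError("Tukey-Kramer requires df_within >= 1")
    out: dict[tuple[str, str], float] = {}
    for i, gi in enumerate(result.group_order):
        for gj in result.group_order[i + 1:]:
            diff = abs(result.group_means[gi] - result.group_means[gj])
            if result.msw == 0.0:
                out[(gi, gj)] = 1.0 if diff == 0.0 else 0.0
                continue
            se = np.sqrt(
                (result.msw / 2.0)
                * (1.0 / result.group_weights[gi] + 1.0 / result.group_weights[gj])
            )
            q = diff / se
            out[(gi, gj)] = float(stats.studentized_range.sf(q, k, result.df_within))
    return out


def apply_bonferroni(
    p_assoc: float,
    pairwise_p: Mapping[tuple[str, str], float],
    thresholds: SignificanceThresholds = SignificanceThresholds(),
) -> tuple[bool, dict[tuple[str, str], bool]]:
    """Significance flags at the Bonferroni-adjusted thresholds (strict <)."""
    assoc = p_assoc < thresholds.alpha_assoc
    pairs = {pair: (p < thresholds.alpha_pairwise) for pair, p in pairwise_p.items()}
    return assoc, pairs


def compact_letter_display(
    pairwise_p: Mapping[tuple[str, str], float],
    groups: Sequence[str] = GROUPS,
    alpha: float = 0.0001,
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Two groups share at least one letter iff their pairwise p >= ``alpha``.
    Groups are processed in the fixed order given (EUR, EAS, AFR by default)
    so the assignment is deterministic.
    """
    groups = list(groups)
    index = {g: i for i, g in enumerate(groups)}

    def significant(a: str, b: str) -> bool:
        p = pairwise_p.get((a, b), pairwise_p.get((b, a)))
        if p is None:
            raise DataValidationError(f"missing pairwise p for ({a}, {b})")
        return p < alpha

    letter_sets: list[set[str]] = [set(groups)]
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            if not significant(a, b):
                continue
            new_sets: list[set[str]] = []
            for s in letter_sets:
                if a in s and b in s:
                    new_sets.append(s - {a})
                    new_sets.append(s - {b})
                else:
                    new_sets.append(s)
            # absorb: dedupe and drop sets contained in another set
            uniq: list[set[str]] = []
            for s in new_sets:
                if s and s not in uniq:
                    uniq.append(s)
            letter_sets = [s for s in uniq if not any(s < t for t in uniq)]
    letter_sets.sort(key=lambda s: tuple(sorted(index[g] for g in s)))
    labels = {g: "" for g in groups}
    for letter, s in zip(string.ascii_lowercase, letter_sets):
        for g in sorted(s, key=index.get):
            labels[g] += letter
    return labels
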