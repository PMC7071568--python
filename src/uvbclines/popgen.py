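"""Allele-frequency computation, fixation-index estimation, FST-ranked variant
selection and pigmentation-marker ancestry validation.

Two FST estimators are provided. The default, :func:`wright_fst`, is Wright's
frequency-variance form (weighted variance of subpopulation allele frequencies
over p̄(1−p̄)), which operates directly on frequency-table input as supplied
by allele-frequency databases. :func:`weir_cockerham_fst` is the Weir &
Cockerham (1984) variance-components estimator for genotype-mode (VCF) input;
it corrects for finite sample sizes and can therefore go negative on
undifferentiated data, in which case the reported value is truncated to zero
(raw estimate kept in the debug log).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .data_io import (
    DataValidationError,
    FrequencyMatrix,
    GenotypeCounts,
    SampleSet,
    VariantAnnotation,
)

logger = logging.getLogger(__name__)


def allele_frequency(hom_ref: int, het: int, hom_alt: int) -> float:
    """Variant-allele frequency from diploid genotype counts.

    Returns NaN when no samples were called.
    """
    n = hom_ref + het + hom_alt
    if n == 0:
        return float("nan")
    return (2 * hom_alt + het) / (2 * n)


def wright_fst(freqs: Sequence[float], weights: Sequence[float] | None = None) -> float:
    """Wright's fixation index: weighted variance of subpopulation frequencies
    divided by p̄(1−p̄).

    ``weights`` default to equal; the variance is the population-weighted
    (maximum-likelihood) form. Returns 0 for monomorphic input (p̄(1−p̄)=0);
    the ratio is clamped to [0, 1].
    """
    p_all = np.asarray(freqs, dtype=float)
    if weights is None:
        w_all = np.ones_like(p_all)
    else:
        w_all = np.asarray(weights, dtype=float)
        if w_all.size != p_all.size:
            raise DataValidationError("weights length must match frequencies")
    present = ~np.isnan(p_all)
    p, w = p_all[present], w_all[present]
    if p.size < 2:
        raise DataValidationError("wright_fst requires >= 2 present frequencies")
    if (w <= 0).any():
        raise DataValidationError("weights must be positive")
    pbar = float(np.average(p, weights=w))
    denom = pbar * (1.0 - pbar)
    if denom == 0.0:
        return 0.0
    var = float(np.average((p - pbar) ** 2, weights=w))
    return float(min(1.0, max(0.0, var / denom)))


def weir_cockerham_fst(
    counts: Sequence[tuple[int, int, int]], truncate: bool = True
) -> float:
    """Weir & Cockerham (1984) FST from per-population diploid genotype counts.

    ``counts`` holds one (hom_ref, het, hom_alt) triple per population. The
    estimate is the ratio of the among-population variance component ``a`` to
    ``a + b + c``. Returns NaN when the total variance is zero (monomorphic
    across all populations). Negative estimates are truncated to 0 when
    ``truncate`` (the raw value is logged).
    """
    triples = [(hr, het, ha) for hr, het, ha in counts]
    if len(triples) < 2:
        raise DataValidationError("weir_cockerham_fst requires >= 2 populations")
    n_i, p_i, h_i = [], [], []
    for hr, het, ha in triples:
        n = hr + het + ha
        if n < 1:
            raise DataValidationError("each population needs >= 1 called sample")
        n_i.append(float(n))
        p_i.append((2 * ha + het) / (2.0 * n))
        h_i.append(het / float(n))
    n_i = np.array(n_i)
    p_i = np.array(p_i)
    h_i = np.array(h_i)
    r = len(n_i)
    nbar = n_i.mean()
    # nc: corrected average sample size accounting for size variation
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n_i * p_i).sum() / (r * nbar)
    s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum() / (r * nbar)
    if nbar <= 1:
        raise DataValidationError("Weir-Cockerham estimator requires nbar > 1")
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2.0
    denom = a + b + c
    if denom == 0.0:
        return float("nan")
    theta = a / denom
    if truncate and theta < 0.0:
        logger.debug("truncating negative Weir-Cockerham estimate %g to 0", theta)
        return 0.0
    return float(theta)


@dataclass(frozen=True)
class SelectionCriteria:
    """Differentiation-based inclusion rules for the variant panel.

    Variants are ranked by fixation index; those in the top ``top_fraction``
    that also meet ``fst_floor`` are retained, then variants in
    ``exclude_function_classes`` (by default those with unknown functional
    consequences) are dropped.
    """

    top_fraction: float = 0.30
    fst_floor: float = 0.13
    exclude_function_classes: frozenset[str] = frozenset({"Unknown"})

    def __post_init__(self) -> None:
        if not (0.0 < self.top_fraction <= 1.0):
            raise DataValidationError(f"top_fraction {self.top_fraction} not in (0,1]")
        if not (0.0 <= self.fst_floor <= 1.0):
            raise DataValidationError(f"fst_floor {self.fst_floor} not in [0,1]")


BELOW_RANK = "BELOW_RANK"
BELOW_FLOOR = "BELOW_FLOOR"
FUNCTION_CLASS = "FUNCTION_CLASS"


def select_variants(
    annotations: Sequence[VariantAnnotation],
    criteria: SelectionCriteria = SelectionCriteria(),
) -> tuple[list[VariantAnnotation], list[tuple[VariantAnnotation, str]]]:
    """Rank variants by fixation index and apply the inclusion criteria.

    Returns ``(included, excluded)`` where each exclusion carries a reason
    code (BELOW_RANK, BELOW_FLOOR or FUNCTION_CLASS). Ranking ties at the
    top-fraction boundary are broken by rsid lexicographic order, so the
    output is invariant to input order.
    """
    if not annotations:
        raise DataValidationError("select_variants requires a non-empty annotation list")
    missing = [a.rsid for a in annotations if a.fst is None]
    if missing:
        raise DataValidationError(f"annotations without fst (compute upstream): {missing}")
    ranked = sorted(annotations, key=lambda a: (-a.fst, a.rsid))
    n_keep = int(math.floor(criteria.top_fraction * len(ranked) + 1e-9))
    n_keep = max(n_keep, 0)
    included: list[VariantAnnotation] = []
    excluded: list[tuple[VariantAnnotation, str]] = []
    for rank, ann in enumerate(ranked):
        if rank >= n_keep:
            excluded.append((ann, BELOW_RANK))
        elif ann.fst < criteria.fst_floor:
            excluded.append((ann, BELOW_FLOOR))
        elif ann.function_class in criteria.exclude_function_classes:
            excluded.append((ann, FUNCTION_CLASS))
        else:
            included.append(ann)
    return included, excluded


@dataclass(frozen=True)
class ValidationRule:
    """Expected cohort-weighted group-mean frequency window for one marker.

    ``expectations`` maps group label to an inclusive (lo, hi) window; use 0.0
    / 1.0 for unbounded sides. E.g. a marker near fixation in Europeans gets
    EUR: (0.90, 1.0) and EAS/AFR: (0.0, 0.10).
    """

    rsid: str
    expectations: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for g, (lo, hi) in self.expectations.items():
            if not (0.0 <= lo <= hi <= 1.0):
                raise DataValidationError(
                    f"rule {self.rsid}/{g}: invalid window ({lo}, {hi})"
                )


def default_ancestry_rules() -> list[ValidationRule]:
    """Pigmentation-marker windows validating the three ancestry groups.

    rs1426654 (SLC24A5) and rs16891982 (SLC45A2) are near fixation in
    European-ancestry populations and near absent elsewhere; rs1800414 (OCA2)
    is confined to East Asian populations at intermediate frequency and
    separates EAS from AFR.
    """
    high = (0.90, 1.0)
    low = (0.0, 0.10)
    return [
        ValidationRule("rs1426654", {"EUR": high, "EAS": low, "AFR": low}),
        ValidationRule("rs16891982", {"EUR": high, "EAS": low, "AFR": low}),
        ValidationRule("rs1800414", {"EAS": (0.50, 0.65), "EUR": low, "AFR": low}),
    ]


@dataclass
class RuleOutcome:
    rsid: str
    group: str
    observed_mean: float
    window: tuple[float, float]
    passed: bool


@dataclass
class AncestryValidationReport:
    outcomes: list[RuleOutcome]
    flagged_sets: list[str]  # sets lacking data for some validation marker

    @property
    def overall_pass(self) -> bool:
        return all(o.passed for o in self.outcomes)

    def failures(self) -> list[RuleOutcome]:
        return [o for o in self.outcomes if not o.passed]


def validate_ancestry_groups(
    freq: FrequencyMatrix,
    sets: Sequence[SampleSet],
    rules: Sequence[ValidationRule] | None = None,
) -> AncestryValidationReport:
    """Check that the derived geographic groups carry the expected
    pigmentation-marker frequencies.

    Group means are cohort-size weighted over the sets with data for all rule
    markers; sets lacking any validation marker are flagged for exclusion from
    downstream analysis.
    """
    if rules is None:
        rules = default_ancestry_rules()
    missing_markers = [r.rsid for r in rules if r.rsid not in freq.freq.columns]
    if missing_markers:
        raise DataValidationError(
            f"validation markers absent from frequency matrix: {missing_markers}"
        )
    by_id = {s.id: s for s in sets}
    unknown = [i for i in freq.sample_set_ids if i not in by_id]
    if unknown:
        raise DataValidationError(f"frequency matrix rows without metadata: {unknown}")
    marker_cols = freq.freq[[r.rsid for r in rules]]
    complete = marker_cols.notna().all(axis=1)
    flagged = [i for i in freq.sample_set_ids if not complete.loc[i]]
    usable = [i for i in freq.sample_set_ids if complete.loc[i]]
    outcomes: list[RuleOutcome] = []
    for rule in rules:
        col = freq.freq.loc[usable, rule.rsid]
        for group, window in rule.expectations.items():
            ids = [i for i in usable if by_id[i].group == group]
            if not ids:
                raise DataValidationError(f"no usable sets in group {group} for {rule.rsid}")
            w = np.array([by_id[i].n for i in ids], dtype=float)
            y = col.loc[ids].to_numpy()
            mean = float(np.average(y, weights=w))
            lo, hi = window
            outcomes.append(
                RuleOutcome(
                    rsid=rule.rsid,
                    group=group,
                    observed_mean=mean,
                    window=window,
                    passed=bool(lo <= mean <= hi),
                )
            )
    for o in outcomes:
        if not o.passed:
            logger.warning(
                "ancestry validation FAIL: %s in %s mean %.3f outside [%.2f, %.2f]",
                o.rsid, o.group, o.observed_mean, o.window[0], o.window[1],
            )
    return AncestryValidationReport(outcomes=outcomes, flagged_sets=flagged)


def fst_from_frequency_matrix(
    freq: FrequencyMatrix,
    sets: Sequence[SampleSet],
    rsid: str,
    by_group: bool = False,
) -> float:
    """Wright FST for one variant computed from the frequency matrix.

    ``by_group=False`` (default) treats every sample set as a subpopulation,
    weighted by cohort size; ``by_group=True`` first collapses sets to
    cohort-weighted group means and computes FST across the groups, weighted
    by group subject totals.
    """
    by_id = {s.id: s for s in sets}
    col = freq.column(rsid)
    ids = [i for i in col.index if not np.isnan(col.loc[i])]
    p = np.array([col.loc[i] for i in ids])
    w = np.array([by_id[i].n for i in ids], dtype=float)
    if not by_group:
        return wright_fst(p, w)
    groups = sorted({by_id[i].group for i in ids})
    gp, gw = [], []
    for g in groups:
        mask = np.array([by_id[i].group == g for i in ids])
        gp.append(float(np.average(p[mask], weights=w[mask])))
        gw.append(float(w[mask].sum()))
    return wright_fst(gp, gw)
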