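"""Distribution-pattern labels and UVB-cline directions per variant, plus
assembly of the final per-variant report rows.

A variant's pattern is determined entirely by its three pairwise significance
flags, in the fixed pair order (EUR-EAS, EUR-AFR, EAS-AFR):

* all three pairs differ        -> ALL_DIFFER  ("EUR!=AFR!=EAS")
* exactly two pairs differ      -> the group common to both significant pairs
  differs from the other two (EUR_DIFFERS / EAS_DIFFERS / AFR_DIFFERS)
* exactly one pair differs      -> PARTIAL (a configuration the published
  footnote taxonomy never needed; named explicitly rather than forced into
  another label)
* no pair differs               -> NONE

The UVB cline compares point estimates of the group means along the groups
ordered by ascending mean annual UVB (EUR < EAS < AFR in the reference
design): strictly increasing frequency -> INCREASING, strictly decreasing ->
DECREASING, anything else (including ties) -> NONE. No trend test is applied.
"""

from __future__ import annotations

import enum
from typing import Mapping, Sequence

from .data_io import (
    GROUP_PAIRS,
    GROUPS,
    DataValidationError,
    VariantComparisonResult,
)
from .groupstats import AnovaResult


class PatternLabel(str, enum.Enum):
    ALL_DIFFER = "EUR!=AFR!=EAS"
    EUR_DIFFERS = "EUR!=AFR and EAS"
    EAS_DIFFERS = "EAS!=AFR and EUR"
    AFR_DIFFERS = "AFR!=EUR and EAS"
    PARTIAL = "PARTIAL"
    NONE = "NONE"


class UVBClineLabel(str, enum.Enum):
    INCREASING = "INCREASING"
    DECREASING = "DECREASING"
    NONE = "NONE"


def classify_pattern(
    sig_eur_eas: bool, sig_eur_afr: bool, sig_eas_afr: bool
) -> PatternLabel:
    """Map the three pairwise significance flags to a distribution pattern."""
    flags = (bool(sig_eur_eas), bool(sig_eur_afr), bool(sig_eas_afr))
    total = sum(flags)
    if total == 3:
        return PatternLabel.ALL_DIFFER
    if total == 2:
        if flags == (True, True, False):
            return PatternLabel.EUR_DIFFERS
        if flags == (True, False, True):
            return PatternLabel.EAS_DIFFERS
        return PatternLabel.AFR_DIFFERS  # (False, True, True)
    if total == 1:
        return PatternLabel.PARTIAL
    return PatternLabel.NONE


def classify_uvb_cline(
    group_means: Mapping[str, float],
    uvb_ascending: Sequence[str] = ("EUR", "EAS", "AFR"),
) -> UVBClineLabel:
    """Direction of the frequency cline along ascending group mean UVB."""
    try:
        means = [group_means[g] for g in uvb_ascending]
    except KeyError as exc:
        raise DataValidationError(f"group mean missing for {exc}") from exc
    if all(a < b for a, b in zip(means, means[1:])):
        return UVBClineLabel.INCREASING
    if all(a > b for a, b in zip(means, means[1:])):
        return UVBClineLabel.DECREASING
    return UVBClineLabel.NONE


def build_results(
    variants: Sequence[str],
    loci: Mapping[str, str],
    anova: Mapping[str, AnovaResult],
    cis: Mapping[str, Mapping[str, tuple[float, float]]],
    pairwise: Mapping[str, Mapping[tuple[str, str], float]],
    letters: Mapping[str, Mapping[str, str]],
    set_counts: Mapping[str, tuple[int, int]],
    patterns: Mapping[str, PatternLabel],
    clines: Mapping[str, UVBClineLabel],
) -> list[VariantComparisonResult]:
    """Assemble one report row per variant, enforcing component agreement."""
    results = []
    for rsid in variants:
        for component, mapping in (
            ("anova", anova), ("cis", cis), ("pairwise", pairwise),
            ("letters", letters), ("set_counts", set_counts),
            ("patterns", patterns), ("clines", clines),
        ):
            if rsid not in mapping:
                raise DataValidationError(f"variant {rsid} missing from {component}")
        res = anova[rsid]
        n_sets, n_subjects = set_counts[rsid]
        results.append(
            VariantComparisonResult(
                rsid=rsid,
                locus=loci.get(rsid, "NA"),
                n_sets=n_sets,
                n_subjects=n_subjects,
                means=dict(res.group_means),
                ci_lo={g: cis[rsid][g][0] for g in res.group_order},
                ci_hi={g: cis[rsid][g][1] for g in res.group_order},
                p_assoc=res.p_value,
                adj_r2=res.adj_r2,
                pairwise_p=dict(pairwise[rsid]),
                letters=dict(letters[rsid]),
                pattern=patterns[rsid].value,
                uvb_cline=clines[rsid].value,
            )
        )
    return results
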