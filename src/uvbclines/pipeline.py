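"""End-to-end orchestration: ancestry validation, set exclusion, variant
selection, per-variant group comparison, UVB summaries, classification and
report/manifest writing.

Stage order:

1. validate ancestry groups on the pigmentation markers; abort on failure
   unless ``continue_on_validation_failure`` (sets lacking any validation
   marker are excluded either way);
2. drop duplicate cohorts (``dup_key`` metadata policy: keep the most recent);
3. select panel variants by fixation-index ranking;
4. cohort-weighted ANOVA + Tukey-Kramer + letters per selected variant;
5. UVB aggregation and group comparison;
6. pattern / UVB-cline classification;
7. write the report TSV and a JSON run manifest (input checksums, seed,
   thresholds, per-stage record counts) so every filtering decision is
   auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .data_io import (
    GROUPS,
    DataValidationError,
    FrequencyMatrix,
    SampleSet,
    VariantAnnotation,
    deduplicate_sample_sets,
    read_frequency_matrix,
    read_sample_sets,
    read_uvb_raster,
    read_variant_annotations,
    write_report,
)
from .groupstats import (
    SignificanceThresholds,
    apply_bonferroni,
    assemble_weighted_groups,
    compact_letter_display,
    group_confidence_interval,
    tukey_kramer,
    weighted_anova,
)
from .patterns import (
    PatternLabel,
    UVBClineLabel,
    build_results,
    classify_pattern,
    classify_uvb_cline,
)
from .popgen import (
    SelectionCriteria,
    ValidationRule,
    select_variants,
    validate_ancestry_groups,
)
from .uvb import UVBSummary, summarize_uvb, uvb_ascending_order

logger = logging.getLogger(__name__)


class AncestryValidationFailure(RuntimeError):
    """Raised when the derived groups fail pigmentation-marker validation."""


def analyze_variants(
    freq: FrequencyMatrix,
    sets: Sequence[SampleSet],
    variants: Sequence[VariantAnnotation],
    thresholds: SignificanceThresholds = SignificanceThresholds(),
    uvb_ascending: Sequence[str] = ("EUR", "EAS", "AFR"),
    ci_level: float = 0.95,
):
    """Per-variant group comparison, letters and classification.

    Returns a list of VariantComparisonResult, one per annotation whose rsid
    is present in the frequency matrix (missing variants raise).
    """
    by_id = {s.id: s for s in sets}
    rsids, loci = [], {}
    anova, cis, pairwise, letters, counts, pats, clines = {}, {}, {}, {}, {}, {}, {}
    for ann in variants:
        rsid = ann.rsid
        if rsid not in freq.freq.columns:
            raise DataValidationError(f"selected variant {rsid} absent from frequency matrix")
        wg, n_sets, n_subjects = assemble_weighted_groups(freq, sets, rsid)
        res = weighted_anova(wg)
        pw = tukey_kramer(res)
        _, sig_pairs = apply_bonferroni(res.p_value, pw, thresholds)
        flags = tuple(
            sig_pairs.get(pair, sig_pairs.get((pair[1], pair[0]), False))
            for pair in (("EUR", "EAS"), ("EUR", "AFR"), ("EAS", "AFR"))
        )
        rsids.append(rsid)
        loci[rsid] = ann.locus
        anova[rsid] = res
        cis[rsid] = {g: group_confidence_interval(res, g, ci_level) for g in res.group_order}
        pairwise[rsid] = pw
        letters[rsid] = compact_letter_display(
            pw, groups=res.group_order, alpha=thresholds.alpha_pairwise
        )
        counts[rsid] = (n_sets, n_subjects)
        pats[rsid] = classify_pattern(*flags)
        clines[rsid] = classify_uvb_cline(res.group_means, uvb_ascending)
    return build_results(rsids, loci, anova, cis, pairwise, letters, counts, pats, clines)


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run."""

    sample_sets: str | Path
    frequency_matrix: str | Path
    annotations: str | Path
    uvb_raster: str | Path | None = None
    out_report: str | Path = "report.tsv"
    out_manifest: str | Path = "manifest.json"
    selection: SelectionCriteria = field(default_factory=SelectionCriteria)
    thresholds: SignificanceThresholds = field(default_factory=SignificanceThresholds)
    validation_rules: Sequence[ValidationRule] | None = None
    uvb_range_mode: str = "all"
    uvb_ascending: tuple[str, ...] | None = None  # None: derive from the raster
    continue_on_validation_failure: bool = False
    skip_ancestry_validation: bool = False
    seed: int = 0


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run manifest (also written to disk)."""
    manifest: dict = {"seed": config.seed, "stages": {}, "inputs": {}}
    for label, p in (
        ("sample_sets", config.sample_sets),
        ("frequency_matrix", config.frequency_matrix),
        ("annotations", config.annotations),
        ("uvb_raster", config.uvb_raster),
    ):
        if p is not None:
            manifest["inputs"][label] = {"path": str(p), "sha256": _sha256(p)}
    manifest["thresholds"] = {
        "alpha_assoc": config.thresholds.alpha_assoc,
        "alpha_pairwise": config.thresholds.alpha_pairwise,
    }
    manifest["selection"] = {
        "top_fraction": config.selection.top_fraction,
        "fst_floor": config.selection.fst_floor,
    }

    sets = read_sample_sets(config.sample_sets)
    freq = read_frequency_matrix(config.frequency_matrix)
    annotations = read_variant_annotations(config.annotations)
    manifest["stages"]["load"] = {
        "sample_sets": len(sets),
        "groups": len({s.group for s in sets}),
        "variants": len(annotations),
    }
    logger.info("load: %d sets, %d annotated variants", len(sets), len(annotations))

    sets = deduplicate_sample_sets(sets)
    manifest["stages"]["deduplicate"] = {"sample_sets": len(sets)}

    if not config.skip_ancestry_validation:
        report = validate_ancestry_groups(freq, sets, config.validation_rules)
        manifest["stages"]["ancestry_validation"] = {
            "overall_pass": report.overall_pass,
            "failed_rules": [
                f"{o.rsid}/{o.group}" for o in report.failures()
            ],
            "flagged_sets": report.flagged_sets,
        }
        if not report.overall_pass:
            msg = f"ancestry validation failed: {[f'{o.rsid}/{o.group}' for o in report.failures()]}"
            if config.continue_on_validation_failure:
                logger.warning("%s (continuing as requested)", msg)
            else:
                raise AncestryValidationFailure(msg)
        if report.flagged_sets:
            logger.info(
                "excluding %d sets lacking validation-marker data: %s",
                len(report.flagged_sets), report.flagged_sets,
            )
            keep = [s for s in sets if s.id not in set(report.flagged_sets)]
            sets = keep
            freq = freq.subset_sets([s.id for s in sets if s.id in freq.freq.index])
    manifest["stages"]["post_validation"] = {"sample_sets": len(sets)}

    included, excluded = select_variants(annotations, config.selection)
    manifest["stages"]["variant_selection"] = {
        "included": len(included),
        "excluded": {reason: sum(1 for _, r in excluded if r == reason)
                     for reason in {r for _, r in excluded}},
    }
    logger.info("variant selection: %d included, %d excluded", len(included), len(excluded))

    uvb_ascending = config.uvb_ascending
    uvb_summary: UVBSummary | None = None
    if config.uvb_raster is not None:
        raster = read_uvb_raster(config.uvb_raster)
        uvb_summary = summarize_uvb(sets, raster, range_mode=config.uvb_range_mode)
        if uvb_ascending is None:
            uvb_ascending = uvb_ascending_order(uvb_summary)
        manifest["stages"]["uvb"] = {
            "range_mode": config.uvb_range_mode,
            "group_means": {g: round(v, 3) for g, v in uvb_summary.group_means.items()},
            "ascending_order": list(uvb_ascending),
            "pairwise_p": {f"{a}_{b}": p for (a, b), p in uvb_summary.pairwise_p.items()},
        }
    if uvb_ascending is None:
        uvb_ascending = GROUPS  # default reference ordering EUR < EAS < AFR

    analysis_variants = [a for a in included if a.rsid in freq.freq.columns]
    skipped = [a.rsid for a in included if a.rsid not in freq.freq.columns]
    if skipped:
        logger.warning("selected variants without frequency data skipped: %s", skipped)
    results = analyze_variants(
        freq, sets, analysis_variants, config.thresholds, uvb_ascending
    )
    manifest["stages"]["comparison"] = {
        "variants_analyzed": len(results),
        "patterns": {
            lab.name: sum(1 for r in results if r.pattern == lab.value)
            for lab in PatternLabel
        },
    }

    write_report(results, config.out_report)
    manifest["report"] = str(config.out_report)
    with open(config.out_manifest, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
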