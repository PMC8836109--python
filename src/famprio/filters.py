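"""Per-variant tier filters: QC, frequency, region, classification, CADD,
conservation, intolerance, and deleteriousness.

Each filter is a pure predicate returning a :class:`TierDecision` whose
``detail`` map records every quantity that entered the decision (numerator
and denominator for the fraction-based panels), giving a full audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import (
    ExonicClass,
    Favorability,
    FavorabilityMap,
    FilterConfig,
    INTOLERANCE_SCORE_NAMES,
    MissingFrequencyPolicy,
    MissingScorePolicy,
    PREDICTORS,
    RegionClass,
    VariantRecord,
    favorability,
)

__all__ = [
    "TierDecision",
    "qc_filter",
    "frequency_filter",
    "coding_filter",
    "nonsynonymous_filter",
    "cadd_filter",
    "conservation_filter",
    "intolerance_filter",
    "deleteriousness_filter",
]

#: Exonic classes kept after removing synonymous changes: amino-acid altering
#: substitutions, frameshifts, stop changes, and unclassifiable exonic calls.
DAMAGING_CLASSES = frozenset(
    {
        ExonicClass.NONSYNONYMOUS_SNV,
        ExonicClass.FRAMESHIFT_DELETION,
        ExonicClass.FRAMESHIFT_INSERTION,
        ExonicClass.STOPGAIN,
        ExonicClass.STOPLOSS,
        ExonicClass.UNKNOWN,
    }
)

CODING_REGIONS = frozenset({RegionClass.EXONIC, RegionClass.SPLICING})


@dataclass
class TierDecision:
    stage: str
    passed: bool
    detail: dict = field(default_factory=dict)


def qc_filter(variant: VariantRecord, config: FilterConfig) -> TierDecision:
    """Call-quality filter: quality and coverage must strictly exceed their
    minima (qual > 20 and depth > 5x under defaults)."""
    passed = variant.qual > config.qual_min and variant.depth > config.depth_min
    return TierDecision(
        "qc", passed, {"qual": variant.qual, "depth": variant.depth}
    )


def frequency_filter(variant: VariantRecord, config: FilterConfig) -> TierDecision:
    """Rarity filter: every present population MAF must be <= maf_max and the
    local cohort frequency strictly < local_freq_max.

    Missing frequency fields pass under ``treat_as_rare`` (absence from the
    reference panels is itself evidence of rarity) and fail under ``drop``.
    """
    pop_mafs = {
        "maf_1kg": variant.maf_1kg,
        "maf_exac_nontcga": variant.maf_exac_nontcga,
        "maf_gnomad_nfe": variant.maf_gnomad_nfe,
    }
    treat_as_rare = (
        config.missing_frequency_policy is MissingFrequencyPolicy.TREAT_AS_RARE
    )
    passed = True
    for value in pop_mafs.values():
        if value is None:
            passed = passed and treat_as_rare
        elif value > config.maf_max:
            passed = False
    local = variant.local_cohort_freq
    if local is None:
        passed = passed and treat_as_rare
    elif not (local < config.local_freq_max):
        passed = False
    detail = dict(pop_mafs, local_cohort_freq=local)
    return TierDecision("frequency", passed, detail)


def coding_filter(variant: VariantRecord) -> TierDecision:
    """Keep exonic and splicing variants; drop intronic/intergenic/UTR."""
    passed = variant.region_class in CODING_REGIONS
    return TierDecision("coding", passed, {"region_class": variant.region_class.value})


def nonsynonymous_filter(variant: VariantRecord) -> TierDecision:
    """Drop synonymous (and other protein-preserving) exonic calls; keep
    amino-acid-changing, frameshift, stop-altering and unclassified calls."""
    passed = variant.exonic_classification in DAMAGING_CLASSES
    return TierDecision(
        "nonsynonymous",
        passed,
        {"exonic_classification": variant.exonic_classification.value},
    )


def cadd_filter(variant: VariantRecord, config: FilterConfig) -> TierDecision:
    """PHRED-scaled CADD filter: score present and >= cadd_min (>= 10 keeps
    roughly the top decile of deleterious substitutions genome-wide)."""
    passed = variant.cadd_phred is not None and variant.cadd_phred >= config.cadd_min
    return TierDecision("cadd", passed, {"cadd_phred": variant.cadd_phred})


def conservation_filter(variant: VariantRecord, config: FilterConfig) -> TierDecision:
    """Evolutionary-conservation filter over the fixed three-score panel.

    Counts satisfied criteria among GERP++ >= gerp_min, PhastCons >
    phastcons_min, and PhyloP >= phylop_min; passes iff at least
    ``conservation_required`` (default 2 of 3) are satisfied. A missing score
    counts as unsatisfied — the denominator is fixed at 3.
    """
    checks = {
        "gerp": variant.gerp is not None and variant.gerp >= config.gerp_min,
        "phastcons": variant.phastcons is not None
        and variant.phastcons > config.phastcons_min,
        "phylop": variant.phylop is not None and variant.phylop >= config.phylop_min,
    }
    satisfied = sum(checks.values())
    return TierDecision(
        "conservation",
        satisfied >= config.conservation_required,
        {"satisfied": satisfied, "required": config.conservation_required,
         "denominator": 3, **checks},
    )


def intolerance_filter(variant: VariantRecord, config: FilterConfig) -> TierDecision:
    """Gene-intolerance filter over a five-member panel.

    Panel members: the three ratio-based intolerance scores (favorable when
    < 0), the missense constraint Z-score (favorable when > 0), and the
    loss-of-function pLI (favorable when >= 0.9). All available members are
    pooled regardless of variant type. Passes iff favorable/denominator >=
    intolerance_fraction; the denominator is the available members under the
    default missing-score policy, or the full panel of 5 under
    ``count_unfavorable``. An empty panel fails.
    """
    calls: dict[str, Optional[bool]] = {}
    for name in INTOLERANCE_SCORE_NAMES:
        v = variant.intolerance_scores.get(name)
        calls[f"intol_{name}"] = None if v is None else v < 0
    calls["z_score"] = None if variant.z_score is None else variant.z_score > 0
    calls["pli"] = None if variant.pli is None else variant.pli >= 0.9
    favorable = sum(1 for c in calls.values() if c is True)
    available = sum(1 for c in calls.values() if c is not None)
    if config.missing_score_policy is MissingScorePolicy.COUNT_UNFAVORABLE:
        denominator = len(calls)
    else:
        denominator = available
    passed = denominator > 0 and favorable / denominator >= config.intolerance_fraction
    return TierDecision(
        "intolerance",
        passed,
        {"favorable": favorable, "available": available,
         "denominator": denominator, **calls},
    )


def deleteriousness_filter(
    variant: VariantRecord,
    config: FilterConfig,
    fmap: Optional[FavorabilityMap] = None,
) -> TierDecision:
    """Deleteriousness-panel filter over the 12 predictor calls.

    Each call is mapped through the favorability rules; passes iff
    favorable/denominator >= deleteriousness_fraction, with the denominator
    the non-missing calls (default policy) or the full panel of 12. A fully
    missing panel fails.
    """
    fmap = fmap or FavorabilityMap.from_config(config)
    calls = {
        name: favorability(variant.deleteriousness_panel.get(name), name, fmap)
        for name in PREDICTORS
    }
    favorable = sum(1 for c in calls.values() if c is Favorability.FAVORABLE)
    present = sum(1 for c in calls.values() if c is not Favorability.MISSING)
    if config.missing_score_policy is MissingScorePolicy.COUNT_UNFAVORABLE:
        denominator = len(PREDICTORS)
    else:
        denominator = present
    passed = (
        denominator > 0 and favorable / denominator >= config.deleteriousness_fraction
    )
    return TierDecision(
        "deleteriousness",
        passed,
        {"favorable": favorable, "present": present, "denominator": denominator,
         **{k: v.value for k, v in calls.items()}},
    )
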