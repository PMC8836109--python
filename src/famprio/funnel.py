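"""Funnel orchestration: run the fixed stage sequence over an annotated
table, produce the per-stage survivor report and the ranked candidate list.

Stage order is fixed: call QC, population/local frequency, pedigree
segregation, coding region, non-synonymous classification, CADD,
conservation, intolerance, deleteriousness. Every stage filter is a pure
per-variant predicate, so the order affects only the intermediate counts,
never the final candidate set.
"""

from __future__ import annotations

from typing import Iterable, Optional

from .filters import (
    TierDecision,
    cadd_filter,
    coding_filter,
    conservation_filter,
    deleteriousness_filter,
    frequency_filter,
    intolerance_filter,
    nonsynonymous_filter,
    qc_filter,
)
from .io import AnnotatedTable
from .model import FavorabilityMap, FilterConfig, FunnelReport, PedigreeMember, VariantRecord
from .segregation import SegregationPolicy, assign_roles, segregates

__all__ = ["STAGE_SEQUENCE", "run_funnel", "candidate_report"]

STAGE_SEQUENCE = (
    "qc",
    "frequency",
    "segregation",
    "coding",
    "nonsynonymous",
    "cadd",
    "conservation",
    "intolerance",
    "deleteriousness",
)


def _final_sort_key(v: VariantRecord):
    # CADD descending, then chrom/pos for a deterministic tie-break
    cadd = v.cadd_phred if v.cadd_phred is not None else float("-inf")
    return (-cadd, v.chrom, v.pos, v.ref, v.alt)


def run_funnel(
    table: AnnotatedTable,
    pedigree: Iterable[PedigreeMember],
    config: Optional[FilterConfig] = None,
    policy: Optional[SegregationPolicy] = None,
    audit: Optional[list] = None,
) -> tuple[FunnelReport, list[VariantRecord]]:
    """Run all stages; return the report and the final ranked candidates.

    Survivors of each stage are exactly the inputs of the next; the report
    records an ``input`` pseudo-stage followed by every stage's survivor
    count and identifiers. Pass a list as ``audit`` to collect every
    (variant_id, TierDecision) evaluated. The final list is ordered by CADD
    descending, then chromosome/position.
    """
    config = config or FilterConfig()
    policy = policy or SegregationPolicy()
    members = assign_roles(list(pedigree), policy)
    fmap = FavorabilityMap.from_config(config)

    def _stage_decision(variant: VariantRecord, stage: str) -> TierDecision:
        if stage == "qc":
            return qc_filter(variant, config)
        if stage == "frequency":
            return frequency_filter(variant, config)
        if stage == "segregation":
            ok = segregates(variant, members, policy)
            return TierDecision("segregation", ok, {})
        if stage == "coding":
            return coding_filter(variant)
        if stage == "nonsynonymous":
            return nonsynonymous_filter(variant)
        if stage == "cadd":
            return cadd_filter(variant, config)
        if stage == "conservation":
            return conservation_filter(variant, config)
        if stage == "intolerance":
            return intolerance_filter(variant, config)
        if stage == "deleteriousness":
            return deleteriousness_filter(variant, config, fmap)
        raise ValueError(f"unknown stage {stage!r}")

    alive = list(table.records)
    stages: list[tuple[str, int]] = [("input", len(alive))]
    survivors: dict[str, list[str]] = {"input": [v.variant_id for v in alive]}
    for stage in STAGE_SEQUENCE:
        nxt = []
        for v in alive:
            decision = _stage_decision(v, stage)
            if audit is not None:
                audit.append((v.variant_id, decision))
            if decision.passed:
                nxt.append(v)
        alive = nxt
        stages.append((stage, len(alive)))
        survivors[stage] = [v.variant_id for v in alive]

    final = sorted(alive, key=_final_sort_key)
    survivors[STAGE_SEQUENCE[-1]] = [v.variant_id for v in final]
    report = FunnelReport(
        stages=stages, survivors=survivors, config_snapshot=config.to_dict()
    )
    report.validate()
    return report, final


_REPORT_HEADER = (
    "gene", "variant", "exonic_classification", "carriers",
    "maf_exac_nontcga", "maf_gnomad_nfe", "cadd_phred",
    "gerp", "phylop", "phastcons",
    "deleteriousness_pct", "intolerance_pct",
)


def candidate_report(
    final: list[VariantRecord],
    config: Optional[FilterConfig] = None,
    policy: Optional[SegregationPolicy] = None,
) -> str:
    """Render the final candidates as a ranked tab-separated report.

    One row per candidate with its identifiers, carrier set, frequencies,
    scores and the evaluated panel percentages, ordered by CADD descending
    (ties by chromosome/position). Passthrough annotation columns (e.g.
    externally added driver predictions) are appended verbatim.
    """
    config = config or FilterConfig()
    policy = policy or SegregationPolicy()
    fmap = FavorabilityMap.from_config(config)
    extra_cols = sorted({c for v in final for c in v.passthrough})
    lines = ["\t".join(_REPORT_HEADER + tuple(extra_cols))]
    for v in sorted(final, key=_final_sort_key):
        dele = deleteriousness_filter(v, config, fmap).detail
        intol = intolerance_filter(v, config).detail
        carriers = sorted(
            mid for mid, gt in v.genotypes.items() if gt in policy.carrier_genotypes
        )

        def pct(d):
            return "." if d["denominator"] == 0 else (
                f"{100.0 * d['favorable'] / d['denominator']:.2f}"
            )

        row = [
            v.gene, v.variant_id, v.exonic_classification.value,
            ",".join(carriers),
            "." if v.maf_exac_nontcga is None else repr(v.maf_exac_nontcga),
            "." if v.maf_gnomad_nfe is None else repr(v.maf_gnomad_nfe),
            "." if v.cadd_phred is None else repr(v.cadd_phred),
            "." if v.gerp is None else repr(v.gerp),
            "." if v.phylop is None else repr(v.phylop),
            "." if v.phastcons is None else repr(v.phastcons),
            pct(dele), pct(intol),
        ] + [v.passthrough.get(c, ".") for c in extra_cols]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
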