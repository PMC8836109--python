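"""Validation-cohort carrier screen: tally genotyping calls by group and
test carrier enrichment with a two-sided exact test on the 2x2 table.

The two-sided p-value follows the standard exact convention: with margins
fixed, sum the hypergeometric point probabilities of every table whose
probability does not exceed the observed table's. Tables are compared by
exact integer weight so probability ties are handled exactly.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Tuple, Union

import numpy as np
from scipy.stats import hypergeom

from .model import Genotype

__all__ = ["Group", "CarrierCounts", "ExactTestResult", "tally_genotyping",
           "carrier_exact_test"]


class Group(enum.Enum):
    CASE = "case"
    CONTROL = "control"


@dataclass
class CarrierCounts:
    case_carriers: int
    case_total: int
    control_carriers: int
    control_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.case_carriers <= self.case_total):
            raise ValueError("case carriers outside [0, case_total]")
        if not (0 <= self.control_carriers <= self.control_total):
            raise ValueError("control carriers outside [0, control_total]")


@dataclass
class ExactTestResult:
    odds_ratio: Optional[float]  # None when a zero cell makes it unbounded
    unbounded: bool
    p_value: float


_CARRIER_STATES = frozenset({Genotype.HET, Genotype.HOM_ALT})


def tally_genotyping(
    calls: Iterable[Tuple[Union[Group, str], Genotype]],
) -> tuple[CarrierCounts, dict[str, int]]:
    """Count carriers (het or hom-alt) per group.

    Missing calls are excluded from the group totals and reported in the
    returned missing-count map. Unknown group labels raise ValueError.
    """
    carriers = {Group.CASE: 0, Group.CONTROL: 0}
    totals = {Group.CASE: 0, Group.CONTROL: 0}
    missing = {Group.CASE: 0, Group.CONTROL: 0}
    for group, gt in calls:
        group = Group(group) if not isinstance(group, Group) else group
        if gt is Genotype.MISSING:
            missing[group] += 1
            continue
        totals[group] += 1
        if gt in _CARRIER_STATES:
            carriers[group] += 1
    counts = CarrierCounts(
        case_carriers=carriers[Group.CASE],
        case_total=totals[Group.CASE],
        control_carriers=carriers[Group.CONTROL],
        control_total=totals[Group.CONTROL],
    )
    return counts, {g.value: n for g, n in missing.items()}


def carrier_exact_test(counts: CarrierCounts) -> ExactTestResult:
    """Two-sided exact test of carrier frequency between cases and controls.

    The odds ratio is the sample (cross-product) estimate; with a zero cell
    it is flagged unbounded (``odds_ratio`` None) rather than reported as a
    number. Both totals must be positive.
    """
    a, n1 = counts.case_carriers, counts.case_total
    c, n2 = counts.control_carriers, counts.control_total
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both group totals must be positive")
    b, d = n1 - a, n2 - c
    if 0 in (a, b, c, d):
        # a zero cell puts the cross-product estimate at 0 or infinity;
        # flag it rather than reporting a degenerate number
        or_estimate, unbounded = None, True
    else:
        or_estimate, unbounded = (a * d) / (b * c), False

    # two-sided p by enumeration over the hypergeometric support; table
    # weights are compared in exact integer arithmetic so ties are never
    # lost to floating point, then the selected probabilities are summed
    k = a + c  # total carriers, fixed margin
    w_obs = math.comb(n1, a) * math.comb(n2, c)
    included = np.array(
        [
            x
            for x in range(max(0, k - n2), min(k, n1) + 1)
            if math.comb(n1, x) * math.comb(n2, k - x) <= w_obs
        ]
    )
    p = float(hypergeom.pmf(included, n1 + n2, k, n1).sum())
    p = min(1.0, max(p, math.nextafter(0.0, 1.0)))
    return ExactTestResult(odds_ratio=or_estimate, unbounded=unbounded, p_value=p)
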