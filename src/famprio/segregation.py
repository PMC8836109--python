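"""Role-based pedigree segregation filter.

Under a dominant-transmission model for a familial cancer, every affected
case is expected to carry the predisposing variant (obligate carrier), polyp
patients may carry it (optional carrier), and relatives who have not reached
the family's earliest onset age are uninformative. A variant segregates iff
every obligate carrier has a carrier genotype; no member is required to be a
non-carrier. This is a set-membership constraint, not a likelihood model.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Optional

import yaml

from .model import (
    ConfigError,
    Genotype,
    PedigreeMember,
    Phenotype,
    Role,
    VariantRecord,
)

__all__ = ["MissingGenotypePolicy", "SegregationPolicy", "assign_roles", "segregates"]


class MissingGenotypePolicy(enum.Enum):
    FAIL_IF_OBLIGATE_MISSING = "fail_if_obligate_missing"
    PERMISSIVE = "permissive"


def _default_role_map() -> dict[Phenotype, Role]:
    return {
        Phenotype.CRC_CASE: Role.OBLIGATE_CARRIER,
        Phenotype.POLYP: Role.OPTIONAL_CARRIER,
        Phenotype.UNAFFECTED: Role.UNINFORMATIVE,
    }


@dataclass
class SegregationPolicy:
    role_of_phenotype: dict[Phenotype, Role] = field(default_factory=_default_role_map)
    carrier_genotypes: frozenset = frozenset({Genotype.HET, Genotype.HOM_ALT})
    missing_genotype_policy: MissingGenotypePolicy = (
        MissingGenotypePolicy.FAIL_IF_OBLIGATE_MISSING
    )

    def __post_init__(self) -> None:
        missing = set(Phenotype) - set(self.role_of_phenotype)
        if missing:
            raise ConfigError(
                f"segregation policy lacks a role for {sorted(p.value for p in missing)}"
            )
        self.carrier_genotypes = frozenset(self.carrier_genotypes)
        if isinstance(self.missing_genotype_policy, str):
            self.missing_genotype_policy = MissingGenotypePolicy(
                self.missing_genotype_policy
            )

    def to_dict(self) -> dict[str, Any]:
        return {
            "role_of_phenotype": {
                p.value: r.value for p, r in self.role_of_phenotype.items()
            },
            "carrier_genotypes": sorted(g.value for g in self.carrier_genotypes),
            "missing_genotype_policy": self.missing_genotype_policy.value,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SegregationPolicy":
        kwargs: dict[str, Any] = {}
        if "role_of_phenotype" in d:
            kwargs["role_of_phenotype"] = {
                Phenotype(k): Role(v) for k, v in d["role_of_phenotype"].items()
            }
        if "carrier_genotypes" in d:
            kwargs["carrier_genotypes"] = frozenset(
                Genotype(g) for g in d["carrier_genotypes"]
            )
        if "missing_genotype_policy" in d:
            kwargs["missing_genotype_policy"] = MissingGenotypePolicy(
                d["missing_genotype_policy"]
            )
        unknown = set(d) - {
            "role_of_phenotype", "carrier_genotypes", "missing_genotype_policy"
        }
        if unknown:
            raise ConfigError(f"unknown segregation key(s): {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, text: str) -> "SegregationPolicy":
        d = yaml.safe_load(text) or {}
        return cls.from_dict(d.get("segregation", {}))


def assign_roles(
    pedigree: Iterable[PedigreeMember],
    policy: Optional[SegregationPolicy] = None,
    overrides: Optional[Mapping[str, Role]] = None,
) -> list[PedigreeMember]:
    """Set each member's carrier-expectation role from its phenotype.

    Explicit per-member ``overrides`` (member_id -> Role) win over the
    policy's phenotype mapping, keeping manual reclassification auditable.
    Roles are set in place; the member list is returned for chaining.
    """
    policy = policy or SegregationPolicy()
    overrides = overrides or {}
    members = list(pedigree)
    for m in members:
        m.role = overrides.get(m.member_id, policy.role_of_phenotype[m.phenotype])
    return members


def segregates(
    variant: VariantRecord,
    pedigree: Iterable[PedigreeMember],
    policy: Optional[SegregationPolicy] = None,
) -> bool:
    """True iff every obligate carrier in the pedigree carries the variant.

    Optional-carrier and uninformative members are unconstrained. An
    obligate member with no genotype (absent from the map, or an explicit
    missing call) fails the variant under the default policy, or is skipped
    under the permissive policy.
    """
    policy = policy or SegregationPolicy()
    for member in pedigree:
        role = member.role
        if role is None:
            role = policy.role_of_phenotype[member.phenotype]
        if role is not Role.OBLIGATE_CARRIER:
            continue
        gt = variant.genotypes.get(member.member_id, Genotype.MISSING)
        if gt is Genotype.MISSING:
            if policy.missing_genotype_policy is MissingGenotypePolicy.PERMISSIVE:
                continue
            return False
        if gt not in policy.carrier_genotypes:
            return False
    return True
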