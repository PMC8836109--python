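"""Core domain types for family-based germline variant prioritization.

The pipeline consumes an annotated rare-variant table (one row per variant,
with population frequencies, per-position conservation scores, gene-level
intolerance metrics, a panel of deleteriousness predictor calls, and one
genotype per sequenced family member) together with a pedigree whose members
are classified by phenotype (cancer case, polyp patient, unaffected). This
module holds the shared value types, the threshold configuration, and the
categorical favorability mapping used by the deleteriousness panel filter.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Union

import yaml

__all__ = [
    "ConfigError",
    "PedigreeError",
    "TableParseError",
    "Sex",
    "Phenotype",
    "Role",
    "Genotype",
    "PedigreeMember",
    "VariantRecord",
    "ExonicClass",
    "RegionClass",
    "PREDICTORS",
    "Favorability",
    "FavorabilityMap",
    "favorability",
    "FilterConfig",
    "FunnelReport",
    "MissingFrequencyPolicy",
    "MissingScorePolicy",
]


class ConfigError(ValueError):
    """Invalid threshold configuration or unknown predictor name."""


class PedigreeError(ValueError):
    """Structural problem in a pedigree (dangling parent, duplicate id, cycle)."""


class TableParseError(ValueError):
    """Malformed annotated variant table; message carries the line number."""


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Phenotype(enum.Enum):
    CRC_CASE = "crc_case"
    POLYP = "polyp"
    UNAFFECTED = "unaffected"


class Role(enum.Enum):
    """Carrier expectation of a member under the dominant-transmission model.

    Affected cases are obligate carriers of a causal variant; polyp patients
    may carry it (a possible precursor state); members too young to have
    reached the family's earliest onset age are uninformative.
    """

    OBLIGATE_CARRIER = "obligate_carrier"
    OPTIONAL_CARRIER = "optional_carrier"
    UNINFORMATIVE = "uninformative"


class Genotype(enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


class ExonicClass(enum.Enum):
    NONSYNONYMOUS_SNV = "nonsynonymous_snv"
    SYNONYMOUS_SNV = "synonymous_snv"
    FRAMESHIFT_DELETION = "frameshift_deletion"
    FRAMESHIFT_INSERTION = "frameshift_insertion"
    NONFRAMESHIFT = "nonframeshift"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    UNKNOWN = "unknown"
    NONCODING = "noncoding"


class RegionClass(enum.Enum):
    EXONIC = "exonic"
    SPLICING = "splicing"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    UTR = "utr"
    OTHER = "other"


class MissingFrequencyPolicy(enum.Enum):
    TREAT_AS_RARE = "treat_as_rare"
    DROP = "drop"


class MissingScorePolicy(enum.Enum):
    EXCLUDE_FROM_DENOMINATOR = "exclude_from_denominator"
    COUNT_UNFAVORABLE = "count_unfavorable"


@dataclass
class PedigreeMember:
    member_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Sex = Sex.UNKNOWN
    phenotype: Phenotype = Phenotype.UNAFFECTED
    age_at_event: Optional[int] = None
    role: Optional[Role] = None

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


#: Names of the intolerance panel's three ratio-based gene scores.
INTOLERANCE_SCORE_NAMES = ("inhouse", "esp", "exac")

#: The 12-member deleteriousness panel: ten individual predictors plus two
#: meta-predictors, with the prediction reliability index counted as the
#: twelfth panel member.
PREDICTORS = (
    "SIFT",
    "Polyphen2_HumDiv",
    "Polyphen2_HumVar",
    "LRT",
    "MutationTaster",
    "MutationAssessor",
    "FATHMM",
    "MetaSVM",
    "MetaLR",
    "VEST3",
    "PROVEAN",
    "ReliabilityIndex",
)


@dataclass
class VariantRecord:
    """One annotated variant with per-member genotypes.

    Frequency and score fields use ``None`` for missing annotation ("." in
    the tab-separated input). ``deleteriousness_panel`` maps each of the 12
    predictor names to a categorical code, a number, or ``None``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = "."
    exonic_classification: ExonicClass = ExonicClass.NONCODING
    region_class: RegionClass = RegionClass.OTHER
    qual: float = 0.0
    depth: int = 0
    maf_1kg: Optional[float] = None
    maf_exac_nontcga: Optional[float] = None
    maf_gnomad_nfe: Optional[float] = None
    local_cohort_freq: Optional[float] = None
    cadd_phred: Optional[float] = None
    gerp: Optional[float] = None
    phylop: Optional[float] = None
    phastcons: Optional[float] = None
    intolerance_scores: dict[str, Optional[float]] = field(
        default_factory=lambda: {k: None for k in INTOLERANCE_SCORE_NAMES}
    )
    z_score: Optional[float] = None
    pli: Optional[float] = None
    deleteriousness_panel: dict[str, Union[str, float, None]] = field(
        default_factory=lambda: {k: None for k in PREDICTORS}
    )
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    passthrough: dict[str, str] = field(default_factory=dict)

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}_{self.pos}_{self.ref}_{self.alt}"

    def validate(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: pos must be >= 1")
        if self.ref == self.alt:
            raise ValueError(f"{self.variant_id}: ref equals alt")
        for name in ("maf_1kg", "maf_exac_nontcga", "maf_gnomad_nfe",
                     "local_cohort_freq", "phastcons"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.variant_id}: {name}={v} outside [0, 1]")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError(f"{self.variant_id}: cadd_phred must be >= 0")
        unknown = set(self.deleteriousness_panel) - set(PREDICTORS)
        if unknown:
            raise ConfigError(
                f"{self.variant_id}: unknown predictor(s) {sorted(unknown)}"
            )


class Favorability(enum.Enum):
    FAVORABLE = "favorable"
    UNFAVORABLE = "unfavorable"
    MISSING = "missing"


@dataclass(frozen=True)
class NumericRule:
    """Numeric favorability rule: favorable iff value >= threshold (direction
    'ge') or <= threshold ('le')."""

    threshold: float
    direction: str = "ge"

    def applies(self, value: float) -> bool:
        if self.direction == "ge":
            return value >= self.threshold
        if self.direction == "le":
            return value <= self.threshold
        raise ConfigError(f"unknown direction {self.direction!r}")


def _default_rules() -> dict[str, Union[frozenset, NumericRule]]:
    return {
        "SIFT": frozenset({"D"}),
        "Polyphen2_HumDiv": frozenset({"D", "P"}),
        "Polyphen2_HumVar": frozenset({"D", "P"}),
        "LRT": frozenset({"D"}),
        "MutationTaster": frozenset({"D", "A"}),
        "MutationAssessor": frozenset({"H", "M"}),
        "FATHMM": frozenset({"D"}),
        "MetaSVM": frozenset({"D"}),
        "MetaLR": frozenset({"D"}),
        "VEST3": NumericRule(0.5, "ge"),
        "PROVEAN": frozenset({"D"}),
        "ReliabilityIndex": NumericRule(5, "ge"),
    }


@dataclass
class FavorabilityMap:
    """Per-predictor definition of which calls count as deleterious-favorable.

    Defaults: SIFT D; PolyPhen-2 (HumDiv and HumVar) D or P; LRT D;
    MutationTaster D or A; MutationAssessor H or M; FATHMM D; MetaSVM D;
    MetaLR D; VEST3 >= 0.5; PROVEAN D; reliability index >= 5.
    """

    rules: dict[str, Union[frozenset, NumericRule]] = field(
        default_factory=_default_rules
    )

    @classmethod
    def from_config(cls, config: "FilterConfig") -> "FavorabilityMap":
        rules = _default_rules()
        rules["VEST3"] = NumericRule(config.vest3_min, "ge")
        rules["ReliabilityIndex"] = NumericRule(config.reliability_index_min, "ge")
        return cls(rules)


def favorability(
    call: Union[str, float, int, None],
    predictor: str,
    fmap: Optional[FavorabilityMap] = None,
) -> Favorability:
    """Classify one predictor call as favorable, unfavorable, or missing.

    A categorical call is favorable iff it is in the predictor's favorable
    set; a numeric call against a numeric rule is compared to the threshold.
    A numeric call to a categorical predictor, or an unparseable string to a
    numeric predictor, is unfavorable (unknown codes fail closed).
    """
    fmap = fmap or FavorabilityMap()
    try:
        rule = fmap.rules[predictor]
    except KeyError:
        raise ConfigError(f"unknown predictor name {predictor!r}") from None
    if call is None or (isinstance(call, str) and call.strip() in (".", "")):
        return Favorability.MISSING
    if isinstance(call, float) and math.isnan(call):
        return Favorability.MISSING
    if isinstance(rule, NumericRule):
        try:
            value = float(call)
        except (TypeError, ValueError):
            return Favorability.UNFAVORABLE
        return Favorability.FAVORABLE if rule.applies(value) else Favorability.UNFAVORABLE
    code = str(call).strip()
    return Favorability.FAVORABLE if code in rule else Favorability.UNFAVORABLE


@dataclass
class FilterConfig:
    """Every threshold and policy of the filtering funnel.

    Boundary inclusivity follows the stated rules literally: call quality and
    coverage are strict bounds ("greater than"), the CADD, GERP and PhyloP
    cutoffs are inclusive, the PhastCons cutoff and the intolerance sign test
    are strict, and the two 60% panel fractions are inclusive.
    """

    qual_min: float = 20.0            # strict: qual must exceed this
    depth_min: int = 5                # strict: depth must exceed this
    maf_max: float = 0.001            # inclusive: population MAF <= 0.1%
    local_freq_max: float = 0.05      # strict: local cohort frequency < 5%
    cadd_min: float = 10.0            # inclusive
    gerp_min: float = 2.0             # inclusive
    phastcons_min: float = 0.3        # strict
    phylop_min: float = 3.0           # inclusive
    conservation_required: int = 2    # of the fixed 3-score panel
    intolerance_fraction: float = 0.60    # inclusive
    deleteriousness_fraction: float = 0.60  # inclusive
    vest3_min: float = 0.5            # inclusive
    reliability_index_min: int = 5    # inclusive
    missing_frequency_policy: MissingFrequencyPolicy = MissingFrequencyPolicy.TREAT_AS_RARE
    missing_score_policy: MissingScorePolicy = MissingScorePolicy.EXCLUDE_FROM_DENOMINATOR

    def __post_init__(self) -> None:
        for name in ("intolerance_fraction", "deleteriousness_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.conservation_required not in (0, 1, 2, 3):
            raise ConfigError(
                f"conservation_required={self.conservation_required} not in 0..3"
            )
        if isinstance(self.missing_frequency_policy, str):
            self.missing_frequency_policy = MissingFrequencyPolicy(
                self.missing_frequency_policy
            )
        if isinstance(self.missing_score_policy, str):
            self.missing_score_policy = MissingScorePolicy(self.missing_score_policy)

    # -- flat YAML round-trip ------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["missing_frequency_policy"] = self.missing_frequency_policy.value
        d["missing_score_policy"] = self.missing_score_policy.value
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "FilterConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**dict(d))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "FilterConfig":
        d = yaml.safe_load(text) or {}
        if not isinstance(d, dict):
            raise ConfigError("config file must be a flat key/value mapping")
        d.pop("segregation", None)  # handled by SegregationPolicy.from_yaml
        return cls.from_dict(d)


@dataclass
class FunnelReport:
    """Ordered per-stage survivor counts plus surviving variant identifiers.

    ``stages`` is the ordered list of (stage_name, survivor_count);
    ``survivors`` maps each stage name to the identifiers alive after that
    stage. Counts must be non-increasing along the stage order.
    """

    stages: list[tuple[str, int]]
    survivors: dict[str, list[str]]
    config_snapshot: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        counts = [c for _, c in self.stages]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError(f"funnel counts increase along stages: {counts}")
        for name, count in self.stages:
            if name in self.survivors and len(self.survivors[name]) != count:
                raise ValueError(
                    f"stage {name}: count {count} != "
                    f"{len(self.survivors[name])} recorded survivors"
                )

    @property
    def final_count(self) -> int:
        return self.stages[-1][1] if self.stages else 0
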