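"""Seeded generator of family-annotated variant datasets.

Emulates the post-frequency-filter variant pool of a family exome study: a
background of rare variants whose genotypes are gene-dropped Mendelianly
through the pedigree under the null of no linkage to disease, with
annotation scores drawn from a mixture of a benign-like and a
deleterious-like regime spanning the filter thresholds, plus optional
planted causal variants with fully specified annotations and carrier sets.
Fixed seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .datasets import crc_family_pedigree
from .io import AnnotatedTable
from .model import (
    ExonicClass,
    Genotype,
    INTOLERANCE_SCORE_NAMES,
    PREDICTORS,
    PedigreeError,
    PedigreeMember,
    RegionClass,
    VariantRecord,
)

__all__ = [
    "ScoreRegime",
    "PlantedVariant",
    "SimulationParams",
    "SyntheticTruth",
    "gene_drop",
    "generate_dataset",
]


# ---------------------------------------------------------------------------
# gene dropping

def _transmission_order(pedigree: Sequence[PedigreeMember]) -> list[PedigreeMember]:
    """Members sorted so every known parent precedes its children; raises on
    a cyclic pedigree."""
    by_id = {m.member_id: m for m in pedigree}
    order: list[PedigreeMember] = []
    placed: set[str] = set()
    remaining = list(pedigree)
    while remaining:
        progressed = False
        still = []
        for m in remaining:
            parents = [p for p in (m.father_id, m.mother_id)
                       if p is not None and p in by_id]
            if all(p in placed for p in parents):
                order.append(m)
                placed.add(m.member_id)
                progressed = True
            else:
                still.append(m)
        if not progressed:
            raise PedigreeError(
                f"cyclic pedigree: cannot order {[m.member_id for m in still]}"
            )
        remaining = still
    return order


def gene_drop(
    pedigree: Sequence[PedigreeMember],
    founder_allele_freq: float,
    seed: Union[int, np.random.Generator],
) -> dict[str, Genotype]:
    """Drop one biallelic variant through the pedigree.

    Founder alleles (and alleles from parents absent from the pedigree) are
    Bernoulli draws at ``founder_allele_freq``; a child inherits one allele
    from each parent, picking uniformly between the parent's two alleles.
    """
    if not (0.0 <= founder_allele_freq <= 1.0):
        raise ValueError("founder_allele_freq outside [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_id = {m.member_id: m for m in pedigree}
    alleles: dict[str, tuple[int, int]] = {}
    for m in _transmission_order(pedigree):
        pair = []
        for parent_id in (m.father_id, m.mother_id):
            if parent_id is None or parent_id not in by_id:
                pair.append(int(rng.random() < founder_allele_freq))
            else:
                pair.append(alleles[parent_id][rng.integers(0, 2)])
        alleles[m.member_id] = (pair[0], pair[1])
    out = {}
    for mid, (a1, a2) in alleles.items():
        n = a1 + a2
        out[mid] = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[n]
    return out


def _gene_drop_matrix(
    pedigree: Sequence[PedigreeMember],
    founder_allele_freqs: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Vectorized gene drop: per-member arrays of alt-allele counts, one
    entry per variant (same transmission model as :func:`gene_drop`)."""
    n = founder_allele_freqs.shape[0]
    by_id = {m.member_id: m for m in pedigree}
    alleles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for m in _transmission_order(pedigree):
        pair = []
        for parent_id in (m.father_id, m.mother_id):
            if parent_id is None or parent_id not in by_id:
                pair.append((rng.random(n) < founder_allele_freqs).astype(np.int8))
            else:
                p1, p2 = alleles[parent_id]
                pick = rng.integers(0, 2, size=n)
                pair.append(np.where(pick == 0, p1, p2).astype(np.int8))
        alleles[m.member_id] = (pair[0], pair[1])
    return {mid: a1 + a2 for mid, (a1, a2) in alleles.items()}


# ---------------------------------------------------------------------------
# score regimes and parameters

@dataclass(frozen=True)
class ScoreRegime:
    """Distribution parameters for one annotation regime.

    Gaussian (mean, sd) for CADD / GERP++ / PhyloP, Beta (a, b) for
    PhastCons, a common favorable probability for the five intolerance panel
    members, and per-predictor favorable / missing probabilities for the
    deleteriousness panel.
    """

    name: str
    cadd: tuple[float, float]
    gerp: tuple[float, float]
    phylop: tuple[float, float]
    phastcons: tuple[float, float]
    p_intolerance_favorable: float
    p_predictor_favorable: float
    p_predictor_missing: float


#: Benign-like regime: scores centered below every threshold, panels mostly
#: tolerant — the bulk of rare variation in a family exome.
BENIGN_REGIME = ScoreRegime(
    name="benign",
    cadd=(3.0, 3.0),
    gerp=(0.0, 1.5),
    phylop=(0.0, 1.0),
    phastcons=(1.0, 4.0),
    p_intolerance_favorable=0.25,
    p_predictor_favorable=0.10,
    p_predictor_missing=0.10,
)

#: Deleterious-like regime: scores centered above the thresholds, panels
#: mostly damaging — the tail the funnel is designed to keep.
DELETERIOUS_REGIME = ScoreRegime(
    name="deleterious",
    cadd=(25.0, 6.0),
    gerp=(4.5, 1.0),
    phylop=(5.0, 1.5),
    phastcons=(8.0, 1.0),
    p_intolerance_favorable=0.85,
    p_predictor_favorable=0.85,
    p_predictor_missing=0.05,
)

_FAVORABLE_CALL = {
    "SIFT": "D", "Polyphen2_HumDiv": "D", "Polyphen2_HumVar": "P", "LRT": "D",
    "MutationTaster": "D", "MutationAssessor": "M", "FATHMM": "D",
    "MetaSVM": "D", "MetaLR": "D", "VEST3": 0.8, "PROVEAN": "D",
    "ReliabilityIndex": 8.0,
}
_UNFAVORABLE_CALL = {
    "SIFT": "T", "Polyphen2_HumDiv": "B", "Polyphen2_HumVar": "B", "LRT": "N",
    "MutationTaster": "N", "MutationAssessor": "L", "FATHMM": "T",
    "MetaSVM": "T", "MetaLR": "T", "VEST3": 0.2, "PROVEAN": "N",
    "ReliabilityIndex": 3.0,
}

_REGION_CLASSES = (
    RegionClass.INTRONIC, RegionClass.INTERGENIC, RegionClass.EXONIC,
    RegionClass.UTR, RegionClass.SPLICING,
)
_REGION_PROBS = (0.50, 0.25, 0.15, 0.08, 0.02)

_EXONIC_CLASSES = (
    ExonicClass.NONSYNONYMOUS_SNV, ExonicClass.SYNONYMOUS_SNV,
    ExonicClass.FRAMESHIFT_DELETION, ExonicClass.FRAMESHIFT_INSERTION,
    ExonicClass.STOPGAIN, ExonicClass.NONFRAMESHIFT, ExonicClass.UNKNOWN,
)
_EXONIC_PROBS = (0.55, 0.30, 0.03, 0.02, 0.03, 0.04, 0.03)

_BASES = ("A", "C", "G", "T")


@dataclass
class PlantedVariant:
    """A fully specified variant injected into the generated table.

    ``record`` carries the annotations; ``carriers`` is the exact set of
    members given a heterozygous genotype (everyone else sequenced is
    homozygous reference).
    """

    record: VariantRecord
    carriers: frozenset

    def __post_init__(self) -> None:
        self.carriers = frozenset(self.carriers)


@dataclass
class SimulationParams:
    seed: int = 0
    n_background: int = 10_000
    pedigree: list[PedigreeMember] = field(default_factory=crc_family_pedigree)
    #: Per-variant founder allele frequency ~ Uniform(low, high). The pool
    #: emulates variants actually observed in the family, so rows are
    #: conditioned on carrying at least one alternate allele (see
    #: generate_dataset); moderate in-pedigree frequencies stand in for that
    #: ascertainment.
    background_carrier_freq: tuple[float, float] = (0.05, 0.5)
    benign_regime: ScoreRegime = BENIGN_REGIME
    deleterious_regime: ScoreRegime = DELETERIOUS_REGIME
    fraction_deleterious_background: float = 0.05
    planted: list[PlantedVariant] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")
        if not (0.0 <= self.fraction_deleterious_background <= 1.0):
            raise ValueError("fraction_deleterious_background outside [0, 1]")
        lo, hi = self.background_carrier_freq
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("background_carrier_freq bounds outside [0, 1]")


@dataclass
class SyntheticTruth:
    planted_ids: list[str]
    params: SimulationParams


_GT_FROM_COUNT = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)


def generate_dataset(
    params: SimulationParams,
) -> tuple[AnnotatedTable, list[PedigreeMember], SyntheticTruth]:
    """Generate (annotated table, pedigree, truth) from the parameters.

    Background rows: genotypes gene-dropped under the null (resampled until
    at least one sequenced member carries an alternate allele, emulating
    that every pooled variant was called in the family), scores from the
    benign/deleterious regime mixture, population MAFs log-uniform in
    [1e-6, 1e-3] with a small fraction of common contaminants and missing
    annotations to exercise the frequency stage. Planted rows are appended
    with exactly their specified carrier sets.
    """
    rng = np.random.default_rng(params.seed)
    pedigree = [replace(m) for m in params.pedigree]
    member_ids = [m.member_id for m in pedigree]
    planted_ids = {p.record.variant_id for p in params.planted}
    for p in params.planted:
        unknown = set(p.carriers) - set(member_ids)
        if unknown:
            raise ValueError(f"planted carrier id(s) not in pedigree: {sorted(unknown)}")

    n = params.n_background
    records: list[VariantRecord] = []
    if n:
        lo, hi = params.background_carrier_freq
        freqs = rng.uniform(lo, hi, size=n)
        counts = _gene_drop_matrix(pedigree, freqs, rng)
        # condition on ascertainment: every pooled variant was seen in the family
        for _ in range(64):
            total = np.zeros(n, dtype=np.int32)
            for mid in member_ids:
                total += counts[mid]
            empty = np.flatnonzero(total == 0)
            if empty.size == 0:
                break
            redraw = _gene_drop_matrix(pedigree, freqs[empty], rng)
            for mid in member_ids:
                counts[mid][empty] = redraw[mid]

        deleterious = rng.random(n) < params.fraction_deleterious_background
        regimes = (params.benign_regime, params.deleterious_regime)

        def mix_normal(attr):
            out = np.empty(n)
            for flag, regime in ((False, regimes[0]), (True, regimes[1])):
                mask = deleterious == flag
                mean, sd = getattr(regime, attr)
                out[mask] = rng.normal(mean, sd, size=int(mask.sum()))
            return out

        cadd = np.clip(mix_normal("cadd"), 0.0, None)
        gerp = mix_normal("gerp")
        phylop = mix_normal("phylop")
        phastcons = np.empty(n)
        for flag, regime in ((False, regimes[0]), (True, regimes[1])):
            mask = deleterious == flag
            a, b = regime.phastcons
            phastcons[mask] = rng.beta(a, b, size=int(mask.sum()))

        p_intol = np.where(
            deleterious,
            params.deleterious_regime.p_intolerance_favorable,
            params.benign_regime.p_intolerance_favorable,
        )
        p_fav = np.where(
            deleterious,
            params.deleterious_regime.p_predictor_favorable,
            params.benign_regime.p_predictor_favorable,
        )
        p_miss = np.where(
            deleterious,
            params.deleterious_regime.p_predictor_missing,
            params.benign_regime.p_predictor_missing,
        )
        intol_fav = rng.random((n, 5)) < p_intol[:, None]
        pred_fav = rng.random((n, len(PREDICTORS))) < p_fav[:, None]
        pred_miss = rng.random((n, len(PREDICTORS))) < p_miss[:, None]

        region_idx = rng.choice(len(_REGION_CLASSES), size=n, p=_REGION_PROBS)
        exonic_idx = rng.choice(len(_EXONIC_CLASSES), size=n, p=_EXONIC_PROBS)
        qual = np.clip(rng.normal(60.0, 20.0, size=n), 0.0, None)
        depth = rng.poisson(40.0, size=n) + 1
        log_maf = rng.uniform(np.log10(1e-6), np.log10(1e-3), size=(n, 3))
        maf = 10.0 ** log_maf
        common = rng.random(n) < 0.02  # frequency-stage contaminants
        maf[common, :] = rng.uniform(0.002, 0.5, size=(int(common.sum()), 3))
        maf_missing = rng.random((n, 3)) < 0.10
        local_freq = rng.uniform(0.0, 0.04, size=n)
        local_common = rng.random(n) < 0.01
        local_freq[local_common] = rng.uniform(0.05, 0.5, size=int(local_common.sum()))

        ref_idx = rng.integers(0, 4, size=n)
        alt_shift = rng.integers(1, 4, size=n)
        positions = np.sort(rng.integers(0, 250_000_000, size=n))
        chroms = rng.integers(1, 23, size=n)

        for i in range(n):
            region = _REGION_CLASSES[region_idx[i]]
            if region in (RegionClass.EXONIC, RegionClass.SPLICING):
                exonic = _EXONIC_CLASSES[exonic_idx[i]]
            else:
                exonic = ExonicClass.NONCODING
            intol_scores: dict[str, Optional[float]] = {}
            for j, name in enumerate(INTOLERANCE_SCORE_NAMES):
                intol_scores[name] = -1.0 if intol_fav[i, j] else 0.5
            z_score = 1.0 if intol_fav[i, 3] else -0.5
            pli = 0.95 if intol_fav[i, 4] else 0.1
            panel: dict = {}
            for j, name in enumerate(PREDICTORS):
                if pred_miss[i, j]:
                    panel[name] = None
                elif pred_fav[i, j]:
                    panel[name] = _FAVORABLE_CALL[name]
                else:
                    panel[name] = _UNFAVORABLE_CALL[name]
            rec = VariantRecord(
                chrom=str(chroms[i]),
                pos=int(positions[i]) + 1,
                ref=_BASES[ref_idx[i]],
                alt=_BASES[(ref_idx[i] + alt_shift[i]) % 4],
                gene=f"BG{i:05d}",
                exonic_classification=exonic,
                region_class=region,
                qual=float(np.round(qual[i], 2)),
                depth=int(depth[i]),
                maf_1kg=None if maf_missing[i, 0] else float(maf[i, 0]),
                maf_exac_nontcga=None if maf_missing[i, 1] else float(maf[i, 1]),
                maf_gnomad_nfe=None if maf_missing[i, 2] else float(maf[i, 2]),
                local_cohort_freq=float(np.round(local_freq[i], 5)),
                cadd_phred=float(np.round(cadd[i], 3)),
                gerp=float(np.round(gerp[i], 3)),
                phylop=float(np.round(phylop[i], 3)),
                phastcons=float(np.round(phastcons[i], 4)),
                intolerance_scores=intol_scores,
                z_score=z_score,
                pli=pli,
                deleteriousness_panel=panel,
                genotypes={
                    mid: _GT_FROM_COUNT[counts[mid][i]] for mid in member_ids
                },
            )
            if rec.variant_id not in planted_ids:
                records.append(rec)

    for p in params.planted:
        rec = replace(
            p.record,
            intolerance_scores=dict(p.record.intolerance_scores),
            deleteriousness_panel=dict(p.record.deleteriousness_panel),
            genotypes={
                mid: Genotype.HET if mid in p.carriers else Genotype.HOM_REF
                for mid in member_ids
            },
        )
        rec.validate()
        records.append(rec)

    table = AnnotatedTable(records=records, columns=[], source="synthetic")
    truth = SyntheticTruth(planted_ids=sorted(planted_ids), params=params)
    return table, pedigree, truth
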