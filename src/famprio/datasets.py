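"""Bundled example data: the six-member CRC family and its six published
candidate variants, plus a synthetic cross-species alignment.

The variant table transcribes the six exonic candidates that survive the
full funnel in the motivating familial colorectal cancer study: positions,
alleles, exonic classifications, population frequencies, CADD / GERP++ /
PhyloP / PhastCons scores, and carrier sets. The study prints its
deleteriousness and intolerance panels only as percentages, so each row's
panels here are concrete calls realizing exactly those fractions (e.g.
66.67% -> 8 favorable of 12 present; 83.33% -> 5 of 6 with the other six
predictors unannotated). Call quality and depth are representative values
comfortably above the QC cutoffs.
"""

from __future__ import annotations

from importlib import resources
from typing import Optional, Union

from .io import AlignmentBlock, AnnotatedTable, read_alignment
from .model import (
    ExonicClass,
    Genotype,
    PedigreeMember,
    Phenotype,
    RegionClass,
    Sex,
    VariantRecord,
)

__all__ = [
    "crc_family_pedigree",
    "crc_candidate_variants",
    "synthetic_residue_alignment",
    "MEMBER_IDS",
]

#: Sequenced members of the example family: three CRC cases (the mother I-2
#: and two of her children), two polyp patients, and one young unaffected
#: grandchild below the family's earliest onset age.
MEMBER_IDS = ("I-2", "II-1", "II-2", "II-4", "II-6", "III-2")


def crc_family_pedigree() -> list[PedigreeMember]:
    """The six sequenced members of the example CRC family.

    Unsequenced spouses are not listed; the corresponding parent slots are
    null, and gene-drop simulation draws those alleles from the population.
    """
    return [
        PedigreeMember("I-2", None, None, Sex.FEMALE, Phenotype.CRC_CASE, 60),
        PedigreeMember("II-1", None, "I-2", Sex.MALE, Phenotype.CRC_CASE, 41),
        PedigreeMember("II-2", None, "I-2", Sex.FEMALE, Phenotype.POLYP, 45),
        PedigreeMember("II-4", None, "I-2", Sex.MALE, Phenotype.CRC_CASE, 44),
        PedigreeMember("II-6", None, "I-2", Sex.FEMALE, Phenotype.POLYP, 47),
        PedigreeMember("III-2", "II-4", None, Sex.UNKNOWN, Phenotype.UNAFFECTED, 23),
    ]


def _genotypes(carriers: tuple[str, ...]) -> dict[str, Genotype]:
    return {
        mid: Genotype.HET if mid in carriers else Genotype.HOM_REF
        for mid in MEMBER_IDS
    }


def _panel(n_favorable: int, n_present: int = 12) -> dict:
    """A deleteriousness panel with exactly n_favorable favorable calls among
    n_present annotated predictors (the rest missing)."""
    favorable = [
        ("SIFT", "D"), ("Polyphen2_HumDiv", "D"), ("Polyphen2_HumVar", "P"),
        ("LRT", "D"), ("MutationTaster", "D"), ("MutationAssessor", "M"),
        ("FATHMM", "D"), ("MetaSVM", "D"), ("MetaLR", "D"), ("VEST3", 0.8),
        ("PROVEAN", "D"), ("ReliabilityIndex", 8.0),
    ]
    unfavorable = {
        "SIFT": "T", "Polyphen2_HumDiv": "B", "Polyphen2_HumVar": "B",
        "LRT": "N", "MutationTaster": "N", "MutationAssessor": "L",
        "FATHMM": "T", "MetaSVM": "T", "MetaLR": "T", "VEST3": 0.2,
        "PROVEAN": "N", "ReliabilityIndex": 3.0,
    }
    panel: dict = {}
    for i, (name, call) in enumerate(favorable):
        if i < n_favorable:
            panel[name] = call
        elif i < n_present:
            panel[name] = unfavorable[name]
        else:
            panel[name] = None
    return panel


def _intol(inhouse, esp, exac, z, pli) -> dict:
    return {"inhouse": inhouse, "esp": esp, "exac": exac}, z, pli


def crc_candidate_variants() -> AnnotatedTable:
    """The six published candidate variants as a typed annotated table."""
    rows = [
        # gene, chrom, pos, ref, alt, carriers, maf_exac, maf_gnomad_nfe,
        # cadd, gerp, phylop, phastcons, panel(fav, present), intol scores
        dict(
            gene="ADAMTS10", chrom="19", pos=8670022, ref="C", alt="T",
            carriers=("I-2", "II-1", "II-2", "II-4", "II-6"),
            maf_exac=1.92e-05, maf_nfe=8.95e-06,
            cadd=32.0, gerp=5.33, phylop=7.263, phastcons=1.0,
            panel=_panel(8, 12),  # 66.67%
            intol=_intol(-1.2, -0.8, -0.5, 1.5, 0.2),  # 4/5 = 80%
        ),
        dict(
            gene="C2orf42", chrom="2", pos=70387896, ref="G", alt="C",
            carriers=("I-2", "II-1", "II-4", "II-6"),
            maf_exac=None, maf_nfe=None,
            cadd=23.5, gerp=2.33, phylop=1.849, phastcons=1.0,
            panel=_panel(5, 6),  # 83.33%
            intol=_intol(-0.4, -0.2, 0.3, 0.9, 0.0),  # 3/5 = 60%
        ),
        dict(
            gene="GNA13", chrom="17", pos=63049685, ref="T", alt="C",
            carriers=("I-2", "II-1", "II-2", "II-4"),
            maf_exac=2.21e-04, maf_nfe=3.33e-04,
            cadd=22.3, gerp=5.42, phylop=3.986, phastcons=1.0,
            panel=_panel(9, 12),  # 75%
            intol=_intol(-0.3, 0.1, -0.6, 0.8, 0.5),  # 3/5 = 60%
        ),
        dict(
            gene="PTK7", chrom="6", pos=43100257, ref="G", alt="A",
            carriers=("I-2", "II-1", "II-2", "II-4"),
            maf_exac=0.0, maf_nfe=0.0,
            cadd=25.3, gerp=4.14, phylop=4.217, phastcons=1.0,
            panel=_panel(8, 12),  # 66.67%
            intol=_intol(-1.5, -1.2, -0.9, 2.1, 0.97),  # 5/5 = 100%
        ),
        dict(
            gene="RSBN1L", chrom="7", pos=77407669, ref="G", alt="A",
            carriers=("I-2", "II-1", "II-4"),
            maf_exac=0.0, maf_nfe=0.0,
            cadd=35.0, gerp=5.94, phylop=7.575, phastcons=1.0,
            panel=_panel(12, 12),  # 100%
            intol=_intol(-2.0, -1.5, -1.0, 3.2, 0.5),  # 4/5 = 80%
        ),
        dict(
            gene="TNIP1", chrom="5", pos=150431736, ref="C", alt="T",
            carriers=("I-2", "II-1", "II-2", "II-4"),
            maf_exac=1.86e-05, maf_nfe=0.0,
            cadd=19.16, gerp=5.19, phylop=4.539, phastcons=0.999,
            panel=_panel(8, 12),  # 66.67%
            intol=_intol(-0.5, -0.1, 0.4, -0.2, 0.95),  # 3/5 = 60%
        ),
    ]
    records = []
    for row in rows:
        intol_scores, z, pli = row["intol"]
        rec = VariantRecord(
            chrom=row["chrom"], pos=row["pos"], ref=row["ref"], alt=row["alt"],
            gene=row["gene"],
            exonic_classification=ExonicClass.NONSYNONYMOUS_SNV,
            region_class=RegionClass.EXONIC,
            qual=99.0, depth=60,
            maf_1kg=0.0,
            maf_exac_nontcga=row["maf_exac"],
            maf_gnomad_nfe=row["maf_nfe"],
            local_cohort_freq=0.01,
            cadd_phred=row["cadd"], gerp=row["gerp"],
            phylop=row["phylop"], phastcons=row["phastcons"],
            intolerance_scores=intol_scores, z_score=z, pli=pli,
            deleteriousness_panel=row["panel"],
            genotypes=_genotypes(row["carriers"]),
        )
        if row["maf_exac"] is None:
            rec.maf_1kg = None
        rec.validate()
        records.append(rec)
    return AnnotatedTable(records=records, columns=[], source="bundled:crc_candidates")


def synthetic_residue_alignment() -> tuple[AlignmentBlock, int, str]:
    """Load the bundled synthetic six-species alignment.

    Returns (block, audited 1-based column, reference id). The alignment is
    a constructed stand-in for the real cross-species protein alignment
    around the candidate missense residue: the audited column carries the
    same valine in every species, flanking columns vary.
    """
    path = resources.files("famprio.data") / "synthetic_ig4_alignment.fasta"
    with resources.as_file(path) as p:
        block = read_alignment(p)
    return block, AUDITED_COLUMN, "human"


#: 1-based column of the audited (variant) residue in the bundled alignment.
AUDITED_COLUMN = 11
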