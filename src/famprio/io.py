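"""Readers and writers for the formats the pipeline touches.

Covers the extended PED pedigree dialect (6 standard columns plus phenotype
keyword and age), the tab-separated annotated variant table, the
tab-separated funnel report, and aligned-FASTA alignment blocks with a
column-identity audit. Parsing is total: every line either yields a record
or raises an error carrying the line number; "." and the empty string parse
to missing.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from Bio import SeqIO

from .model import (
    ExonicClass,
    FunnelReport,
    Genotype,
    INTOLERANCE_SCORE_NAMES,
    PREDICTORS,
    PedigreeError,
    PedigreeMember,
    Phenotype,
    RegionClass,
    Sex,
    TableParseError,
    VariantRecord,
)

__all__ = [
    "AnnotatedTable",
    "AlignmentBlock",
    "read_pedigree",
    "write_pedigree",
    "read_annotated_table",
    "write_annotated_table",
    "read_funnel_report",
    "write_funnel_report",
    "read_alignment",
    "column_identity",
]


# ---------------------------------------------------------------------------
# pedigree (PED + phenotype keyword + age)

_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_PHENOTYPE_KEYWORDS = {
    "crc_case": Phenotype.CRC_CASE,
    "crc": Phenotype.CRC_CASE,
    "case": Phenotype.CRC_CASE,
    "polyp": Phenotype.POLYP,
    "cp": Phenotype.POLYP,
    "unaffected": Phenotype.UNAFFECTED,
    "healthy": Phenotype.UNAFFECTED,
    "control": Phenotype.UNAFFECTED,
}


def _null_id(token: str) -> Optional[str]:
    return None if token in ("0", ".", "") else token


def read_pedigree(path: Union[str, Path]) -> list[PedigreeMember]:
    """Read an extended PED file: the six standard columns (family,
    individual, father, mother, sex, affection) plus a phenotype keyword
    (crc_case / polyp / unaffected) and an age-at-event column ("." for
    unknown). Parent ids must resolve within the file or be null ("0"/".").
    """
    members: list[PedigreeMember] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = re.split(r"\s+", line)
        if len(fields) < 8:
            raise PedigreeError(
                f"{path}:{lineno}: expected 8 columns "
                f"(6 PED + phenotype + age), got {len(fields)}"
            )
        _, member_id, father, mother, sex_code, _affection, pheno, age = fields[:8]
        if member_id in seen:
            raise PedigreeError(f"{path}:{lineno}: duplicate member id {member_id!r}")
        seen.add(member_id)
        try:
            phenotype = _PHENOTYPE_KEYWORDS[pheno.lower()]
        except KeyError:
            raise PedigreeError(
                f"{path}:{lineno}: unknown phenotype keyword {pheno!r}"
            ) from None
        members.append(
            PedigreeMember(
                member_id=member_id,
                father_id=_null_id(father),
                mother_id=_null_id(mother),
                sex=_SEX_CODES.get(sex_code, Sex.UNKNOWN),
                phenotype=phenotype,
                age_at_event=None if age in (".", "") else int(age),
            )
        )
    for m in members:
        for parent in (m.father_id, m.mother_id):
            if parent is not None and parent not in seen:
                raise PedigreeError(
                    f"{path}: member {m.member_id!r} references "
                    f"unknown parent {parent!r}"
                )
    return members


_SEX_TO_CODE = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_AFFECTION = {Phenotype.CRC_CASE: "2", Phenotype.POLYP: "2", Phenotype.UNAFFECTED: "1"}


def write_pedigree(
    members: Iterable[PedigreeMember], path: Union[str, Path], family_id: str = "FAM1"
) -> None:
    lines = []
    for m in members:
        lines.append(
            "\t".join(
                [
                    family_id,
                    m.member_id,
                    m.father_id or "0",
                    m.mother_id or "0",
                    _SEX_TO_CODE[m.sex],
                    _AFFECTION[m.phenotype],
                    m.phenotype.value,
                    "." if m.age_at_event is None else str(m.age_at_event),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# annotated variant table

@dataclass
class AnnotatedTable:
    records: list[VariantRecord]
    columns: list[str] = field(default_factory=list)
    source: Optional[str] = None


#: Core columns every table must carry.
MANDATORY_COLUMNS = (
    "chrom", "pos", "ref", "alt", "gene",
    "exonic_classification", "region_class", "qual", "depth",
)

_FLOAT_COLUMNS = (
    "maf_1kg", "maf_exac_nontcga", "maf_gnomad_nfe", "local_cohort_freq",
    "cadd_phred", "gerp", "phylop", "phastcons", "z_score", "pli",
)

_INTOL_COLUMNS = tuple(f"intol_{name}" for name in INTOLERANCE_SCORE_NAMES)

#: Canonical column order for a written table (genotype columns are appended,
#: one per pedigree member, headed by the member id).
TABLE_COLUMNS = MANDATORY_COLUMNS + _FLOAT_COLUMNS + _INTOL_COLUMNS + PREDICTORS

_EXONIC_TOKENS = {
    "nonsynonymous_snv": ExonicClass.NONSYNONYMOUS_SNV,
    "nonsynonymous snv": ExonicClass.NONSYNONYMOUS_SNV,
    "nonsyn snv": ExonicClass.NONSYNONYMOUS_SNV,
    "synonymous_snv": ExonicClass.SYNONYMOUS_SNV,
    "synonymous snv": ExonicClass.SYNONYMOUS_SNV,
    "frameshift_deletion": ExonicClass.FRAMESHIFT_DELETION,
    "frameshift deletion": ExonicClass.FRAMESHIFT_DELETION,
    "frameshift_insertion": ExonicClass.FRAMESHIFT_INSERTION,
    "frameshift insertion": ExonicClass.FRAMESHIFT_INSERTION,
    "nonframeshift": ExonicClass.NONFRAMESHIFT,
    "stopgain": ExonicClass.STOPGAIN,
    "stoploss": ExonicClass.STOPLOSS,
    "unknown": ExonicClass.UNKNOWN,
    "noncoding": ExonicClass.NONCODING,
}

_GENOTYPE_TOKENS = {
    "0/0": Genotype.HOM_REF, "ref": Genotype.HOM_REF, "hom_ref": Genotype.HOM_REF,
    "0/1": Genotype.HET, "1/0": Genotype.HET, "het": Genotype.HET,
    "1/1": Genotype.HOM_ALT, "hom": Genotype.HOM_ALT, "hom_alt": Genotype.HOM_ALT,
    "./.": Genotype.MISSING, ".": Genotype.MISSING, "missing": Genotype.MISSING,
}

_GENOTYPE_TO_TOKEN = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def _missing(token: str) -> bool:
    return token.strip() in (".", "", "NA")


def _parse_float(token: str, column: str, lineno: int) -> Optional[float]:
    if _missing(token):
        return None
    try:
        return float(token)
    except ValueError:
        raise TableParseError(
            f"line {lineno}: column {column!r}: not a number: {token!r}"
        ) from None


def read_annotated_table(
    path: Union[str, Path],
    pedigree: Optional[Iterable[PedigreeMember]] = None,
) -> AnnotatedTable:
    """Parse a tab-separated annotated variant table into typed records.

    Header columns equal to pedigree member ids are genotype columns; known
    annotation columns are typed; anything else is preserved verbatim in each
    record's passthrough map. Every row is validated against the record
    invariants (pos >= 1, ref != alt, frequencies in [0, 1], ...) and
    rejected with its line number on violation.
    """
    member_ids = [m.member_id for m in pedigree] if pedigree is not None else []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise TableParseError(f"{path}: empty file, no header") from None
        missing_cols = [c for c in MANDATORY_COLUMNS if c not in header]
        if missing_cols:
            raise TableParseError(f"{path}: missing mandatory column(s): {missing_cols}")
        known = set(TABLE_COLUMNS)
        gt_cols = [c for c in header if c in member_ids]
        extra_cols = [c for c in header if c not in known and c not in member_ids]
        records: list[VariantRecord] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise TableParseError(
                    f"line {lineno}: {len(row)} fields, header has {len(header)}"
                )
            cell = dict(zip(header, row))
            try:
                pos = int(cell["pos"])
            except ValueError:
                raise TableParseError(
                    f"line {lineno}: pos is not an integer: {cell['pos']!r}"
                ) from None
            try:
                exonic = _EXONIC_TOKENS[cell["exonic_classification"].strip().lower()]
            except KeyError:
                raise TableParseError(
                    f"line {lineno}: unknown exonic classification "
                    f"{cell['exonic_classification']!r}"
                ) from None
            try:
                region = RegionClass(cell["region_class"].strip().lower())
            except ValueError:
                raise TableParseError(
                    f"line {lineno}: unknown region class {cell['region_class']!r}"
                ) from None
            genotypes = {}
            for col in gt_cols:
                token = cell[col].strip()
                try:
                    genotypes[col] = _GENOTYPE_TOKENS[token]
                except KeyError:
                    raise TableParseError(
                        f"line {lineno}: malformed genotype token {token!r} "
                        f"for member {col!r}"
                    ) from None
            panel: dict[str, Union[str, float, None]] = {}
            for name in PREDICTORS:
                token = cell.get(name, ".")
                if _missing(token):
                    panel[name] = None
                else:
                    try:
                        panel[name] = float(token)
                    except ValueError:
                        panel[name] = token.strip()
            record = VariantRecord(
                chrom=cell["chrom"],
                pos=pos,
                ref=cell["ref"],
                alt=cell["alt"],
                gene=cell["gene"],
                exonic_classification=exonic,
                region_class=region,
                qual=_parse_float(cell["qual"], "qual", lineno) or 0.0,
                depth=int(_parse_float(cell["depth"], "depth", lineno) or 0),
                intolerance_scores={
                    name: _parse_float(cell.get(f"intol_{name}", "."),
                                       f"intol_{name}", lineno)
                    for name in INTOLERANCE_SCORE_NAMES
                },
                deleteriousness_panel=panel,
                genotypes=genotypes,
                passthrough={c: cell[c] for c in extra_cols},
            )
            for col in _FLOAT_COLUMNS:
                setattr(record, col, _parse_float(cell.get(col, "."), col, lineno))
            try:
                record.validate()
            except ValueError as exc:
                raise TableParseError(f"line {lineno}: {exc}") from None
            records.append(record)
    return AnnotatedTable(records=records, columns=list(header), source=str(path))


def _fmt(value) -> str:
    if value is None:
        return "."
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_annotated_table(
    table: AnnotatedTable,
    path: Union[str, Path],
    pedigree: Optional[Iterable[PedigreeMember]] = None,
) -> None:
    """Write records in the canonical column order; genotype columns follow
    the pedigree's member order (or the union of genotype keys)."""
    if pedigree is not None:
        member_ids = [m.member_id for m in pedigree]
    else:
        member_ids = sorted({mid for r in table.records for mid in r.genotypes})
    extra_cols = sorted({c for r in table.records for c in r.passthrough})
    header = list(TABLE_COLUMNS) + extra_cols + member_ids
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for r in table.records:
            row = [
                r.chrom, str(r.pos), r.ref, r.alt, r.gene,
                r.exonic_classification.value, r.region_class.value,
                _fmt(r.qual), str(r.depth),
            ]
            row += [_fmt(getattr(r, c)) for c in _FLOAT_COLUMNS]
            row += [_fmt(r.intolerance_scores.get(n)) for n in INTOLERANCE_SCORE_NAMES]
            row += [_fmt(r.deleteriousness_panel.get(n)) for n in PREDICTORS]
            row += [r.passthrough.get(c, ".") for c in extra_cols]
            row += [_GENOTYPE_TO_TOKEN[r.genotypes.get(m, Genotype.MISSING)]
                    for m in member_ids]
            writer.writerow(row)


# ---------------------------------------------------------------------------
# funnel report

def write_funnel_report(report: FunnelReport, path: Union[str, Path]) -> None:
    """Write a funnel report as tab-separated stage counts plus survivor ids.

    The config snapshot rides on a comment line as JSON so the file
    round-trips losslessly. A report violating the non-increasing count
    invariant is refused.
    """
    report.validate()
    lines = ["#famprio funnel report"]
    lines.append("#config\t" + json.dumps(report.config_snapshot, sort_keys=True))
    lines.append("stage\tcount\tsurvivors")
    for name, count in report.stages:
        if name in report.survivors:
            ids = ",".join(report.survivors[name])
        else:
            ids = "-"
        lines.append(f"{name}\t{count}\t{ids}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_funnel_report(path: Union[str, Path]) -> FunnelReport:
    stages: list[tuple[str, int]] = []
    survivors: dict[str, list[str]] = {}
    config: dict = {}
    for raw in Path(path).read_text().splitlines():
        if raw.startswith("#config\t"):
            config = json.loads(raw.split("\t", 1)[1])
            continue
        if raw.startswith("#") or raw.startswith("stage\t") or not raw.strip():
            continue
        name, count, ids = raw.split("\t")
        stages.append((name, int(count)))
        if ids != "-":
            survivors[name] = [] if ids == "" else ids.split(",")
    report = FunnelReport(stages=stages, survivors=survivors, config_snapshot=config)
    report.validate()
    return report


# ---------------------------------------------------------------------------
# alignment audit

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*-")


@dataclass
class AlignmentBlock:
    """A pre-aligned protein block: sequence id -> aligned residue string."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"aligned rows differ in length: {sorted(lengths)}")
        for sid, seq in self.sequences.items():
            bad = set(seq.upper()) - _AA_ALPHABET
            if bad:
                raise ValueError(f"{sid}: non-amino-acid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0


def read_alignment(path: Union[str, Path]) -> AlignmentBlock:
    """Read a pre-aligned FASTA file (gap character '-')."""
    sequences = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    return AlignmentBlock(sequences=sequences)


def column_identity(
    block: AlignmentBlock, column_index: int, reference_id: str
) -> float:
    """Fraction of non-reference rows matching the reference residue at a
    1-based alignment column; gaps count as mismatch.

    A fully conserved position returns 1.0, the usual evidence that the
    residue a missense variant disrupts is functionally constrained.
    """
    if reference_id not in block.sequences:
        raise KeyError(f"reference id {reference_id!r} not in alignment")
    if not (1 <= column_index <= block.length):
        raise IndexError(
            f"column {column_index} outside alignment of length {block.length}"
        )
    i = column_index - 1
    ref_res = block.sequences[reference_id][i]
    others = [s[i] for sid, s in block.sequences.items() if sid != reference_id]
    if not others:
        raise ValueError("alignment has no non-reference rows")
    matches = sum(1 for res in others if res == ref_res and res != "-")
    return matches / len(others)
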