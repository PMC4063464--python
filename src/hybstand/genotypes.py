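"""Genotype records, readers/writers, missingness QC and call-rate accounting.

Genotypes are unordered diploid allele pairs (array genotyping is
unphased); the canonical serialization sorts the two alleles
lexicographically.  A partially missing call (one allele unreadable) is
treated as fully missing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from ._util import round_half_up
from .panel import MarkerPanel


class Stage(str, Enum):
    ADULT = "adult"
    SEED = "seed"
    SEEDLING = "seedling"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class CpHaplotype(str, Enum):
    """Chloroplast haplotype — maternally inherited species label."""

    B_TYPE = "B_type"
    D_TYPE = "D_type"
    UNKNOWN = "unknown"


#: A call is an unordered allele pair, canonically sorted; ``None`` is missing.
Call = Optional[Tuple[str, str]]

#: CSV column order preceding the locus columns.
META_COLUMNS: Tuple[str, ...] = ("individual_id", "stage", "sex", "mother_id", "cp_haplotype")

_MISSING_TOKENS = {"NA", ".", "./.", ""}


class GenotypeParseError(ValueError):
    """Malformed genotype input, reported with row/column context."""

    def __init__(self, message: str, row: Optional[int] = None, column: Optional[str] = None):
        where = []
        if row is not None:
            where.append(f"row {row}")
        if column is not None:
            where.append(f"column {column!r}")
        suffix = f" ({', '.join(where)})" if where else ""
        super().__init__(message + suffix)
        self.row = row
        self.column = column


def make_call(a: str, b: str) -> Call:
    """Canonical unordered call: alleles sorted lexicographically."""
    return (a, b) if a <= b else (b, a)


@dataclass
class GenotypeRecord:
    """One individual's unordered diploid calls plus survey metadata.

    ``calls`` is keyed by locus ID and may span more than one panel (an
    adult typed on both intraspecific panels carries the union); readers
    validate completeness against the panel they are given.
    """

    individual_id: str
    stage: Stage
    sex: Sex = Sex.UNKNOWN
    mother_id: Optional[str] = None
    cp_haplotype: CpHaplotype = CpHaplotype.UNKNOWN
    calls: Dict[str, Call] = field(default_factory=dict)

    def call(self, locus_id: str) -> Call:
        return self.calls.get(locus_id)

    def n_missing(self, panel: Optional[MarkerPanel] = None) -> int:
        ids: Iterable[str] = panel.locus_ids if panel is not None else self.calls.keys()
        return sum(1 for locus_id in ids if self.calls.get(locus_id) is None)


def _parse_call(text: str, row: Optional[int] = None, column: Optional[str] = None) -> Call:
    token = text.strip()
    if token in _MISSING_TOKENS:
        return None
    parts = token.split("/")
    if len(parts) != 2:
        raise GenotypeParseError(f"malformed call {text!r} (expected 'x/y' or 'NA')", row, column)
    a, b = (p.strip() for p in parts)
    if a in _MISSING_TOKENS or b in _MISSING_TOKENS:
        return None  # partially missing -> fully missing
    for allele in (a, b):
        if not allele.isalnum():
            raise GenotypeParseError(f"malformed allele symbol {allele!r}", row, column)
    return make_call(a, b)


def _format_call(call: Call) -> str:
    return "NA" if call is None else "/".join(call)


def read_genotypes_csv(path: Union[str, Path], panel: MarkerPanel) -> List[GenotypeRecord]:
    """Read the canonical genotype CSV dialect.

    Header: ``individual_id,stage,sex,mother_id,cp_haplotype,<locus_1>,...``;
    calls are ``x/y`` with ``NA`` for missing.  Locus columns must match the
    panel exactly (unknown columns are rejected).
    """
    records: List[GenotypeRecord] = []
    seen: set = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise GenotypeParseError("empty genotype file")
        if tuple(header[: len(META_COLUMNS)]) != META_COLUMNS:
            raise GenotypeParseError(
                f"header must start with {','.join(META_COLUMNS)}", row=1
            )
        locus_cols = header[len(META_COLUMNS):]
        unknown = [c for c in locus_cols if c not in panel]
        if unknown:
            raise GenotypeParseError(f"unknown locus columns {unknown}", row=1)
        missing_cols = sorted(set(panel.locus_ids) - set(locus_cols))
        if missing_cols:
            raise GenotypeParseError(f"panel loci absent from file: {missing_cols}", row=1)
        if len(set(locus_cols)) != len(locus_cols):
            raise GenotypeParseError("duplicate locus columns", row=1)
        for rownum, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise GenotypeParseError(
                    f"expected {len(header)} fields, got {len(row)}", row=rownum
                )
            individual_id, stage, sex, mother_id, cp = (v.strip() for v in row[:5])
            if individual_id in seen:
                raise GenotypeParseError(
                    f"duplicate individual_id {individual_id!r}", row=rownum
                )
            seen.add(individual_id)
            try:
                record = GenotypeRecord(
                    individual_id=individual_id,
                    stage=Stage(stage),
                    sex=Sex(sex) if sex else Sex.UNKNOWN,
                    mother_id=mother_id or None,
                    cp_haplotype=CpHaplotype(cp) if cp else CpHaplotype.UNKNOWN,
                )
            except ValueError as exc:
                raise GenotypeParseError(str(exc), row=rownum) from exc
            record.calls = {
                col: _parse_call(value, rownum, col)
                for col, value in zip(locus_cols, row[5:])
            }
            records.append(record)
    return records


def write_genotypes_csv(
    records: Sequence[GenotypeRecord], panel: MarkerPanel, path: Union[str, Path]
) -> None:
    """Write the canonical CSV dialect (panel locus order, sorted alleles, ``NA``)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(list(META_COLUMNS) + list(panel.locus_ids))
        for record in records:
            writer.writerow(
                [
                    record.individual_id,
                    record.stage.value,
                    record.sex.value,
                    record.mother_id or "",
                    record.cp_haplotype.value,
                ]
                + [_format_call(record.calls.get(l)) for l in panel.locus_ids]
            )


def _read_metadata_sidecar(path: Union[str, Path]) -> Dict[str, dict]:
    meta: Dict[str, dict] = {}
    with open(path, newline="") as fh:
        for rownum, row in enumerate(csv.DictReader(fh), start=2):
            individual_id = row["individual_id"].strip()
            if individual_id in meta:
                raise GenotypeParseError(
                    f"duplicate individual_id {individual_id!r} in metadata", row=rownum
                )
            meta[individual_id] = row
    return meta


def read_genotypes_vcf(
    vcf_path: Union[str, Path],
    panel: MarkerPanel,
    metadata_path: Union[str, Path],
) -> List[GenotypeRecord]:
    """Read a minimal VCF (biallelic sites, GT only, diploid).

    Variant IDs map to panel locus IDs; samples map to individuals via a
    metadata sidecar CSV with the same columns as the genotype CSV header
    (minus the locus columns).  ``./.`` becomes a missing call.
    """
    from cyvcf2 import VCF

    meta = _read_metadata_sidecar(metadata_path)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    calls: Dict[str, Dict[str, Call]] = {s: {} for s in samples}
    seen_loci: set = set()
    for variant in vcf:
        locus_id = variant.ID
        if locus_id is None or locus_id not in panel:
            raise GenotypeParseError(f"VCF site {variant.CHROM}:{variant.POS} has unknown locus ID {locus_id!r}")
        if locus_id in seen_loci:
            raise GenotypeParseError(f"duplicate VCF site for locus {locus_id!r}")
        seen_loci.add(locus_id)
        alleles = [variant.REF] + list(variant.ALT)
        for sample, gt in zip(samples, variant.genotypes):
            a0, a1 = int(gt[0]), int(gt[1])
            if a0 < 0 or a1 < 0:
                calls[sample][locus_id] = None
            else:
                calls[sample][locus_id] = make_call(alleles[a0], alleles[a1])
    absent = sorted(set(panel.locus_ids) - seen_loci)
    if absent:
        raise GenotypeParseError(f"panel loci absent from VCF: {absent}")
    records = []
    for sample in samples:
        if sample not in meta:
            raise GenotypeParseError(f"sample {sample!r} missing from metadata sidecar")
        row = meta[sample]
        records.append(
            GenotypeRecord(
                individual_id=sample,
                stage=Stage(row["stage"].strip()),
                sex=Sex(row.get("sex", "unknown").strip() or "unknown"),
                mother_id=(row.get("mother_id") or "").strip() or None,
                cp_haplotype=CpHaplotype((row.get("cp_haplotype") or "unknown").strip() or "unknown"),
                calls=calls[sample],
            )
        )
    return records


def qc_filter_missingness(
    records: Sequence[GenotypeRecord],
    max_missing: int = 10,
    panel: Optional[MarkerPanel] = None,
) -> Tuple[List[GenotypeRecord], List[GenotypeRecord]]:
    """Partition records into (retained, removed) by missing-locus count.

    A record is removed iff it has strictly more than ``max_missing``
    missing loci — the survey's ">10 missing SNP loci" rule at the
    default.  The partition is exhaustive and disjoint.
    """
    if max_missing < 0:
        raise ValueError("max_missing must be >= 0")
    retained: List[GenotypeRecord] = []
    removed: List[GenotypeRecord] = []
    for record in records:
        (removed if record.n_missing(panel) > max_missing else retained).append(record)
    return retained, removed


@dataclass(frozen=True)
class StageCallRate:
    n_individuals: int
    missing_calls: int
    n_loci: int

    @property
    def total_calls(self) -> int:
        return self.n_individuals * self.n_loci

    @property
    def success_rate(self) -> float:
        return (self.total_calls - self.missing_calls) / self.total_calls


@dataclass(frozen=True)
class CallRateSummary:
    """Exact integer call accounting over a cohort, with per-stage breakdown."""

    n_individuals: int
    n_loci: int
    total_calls: int
    missing_calls: int
    by_stage: Mapping[Stage, StageCallRate]

    @property
    def success_rate(self) -> float:
        return (self.total_calls - self.missing_calls) / self.total_calls

    def success_percent(self, ndigits: int = 1) -> float:
        return round_half_up(self.success_rate * 100.0, ndigits)

    def failure_percent(self, ndigits: int = 1) -> float:
        return round_half_up((1.0 - self.success_rate) * 100.0, ndigits)


def call_rate_summary(records: Sequence[GenotypeRecord], panel: MarkerPanel) -> CallRateSummary:
    """Per-call accounting: total = n_individuals x n_loci, exact integers."""
    if not records:
        raise ValueError("call_rate_summary requires at least one record")
    n_loci = len(panel)
    missing_total = 0
    stage_n: Dict[Stage, int] = {}
    stage_missing: Dict[Stage, int] = {}
    for record in records:
        m = record.n_missing(panel)
        missing_total += m
        stage_n[record.stage] = stage_n.get(record.stage, 0) + 1
        stage_missing[record.stage] = stage_missing.get(record.stage, 0) + m
    by_stage = {
        stage: StageCallRate(stage_n[stage], stage_missing[stage], n_loci)
        for stage in stage_n
    }
    return CallRateSummary(
        n_individuals=len(records),
        n_loci=n_loci,
        total_calls=len(records) * n_loci,
        missing_calls=missing_total,
        by_stage=by_stage,
    )
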