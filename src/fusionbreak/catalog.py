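"""Breakpoint catalog: loading, validation, coordinate conversion, summaries.

Coordinates are 1-based inclusive and intron-relative throughout. Conversion
to genomic coordinates supports both a plus-anchored mode (intron position 1
at ``genomic_start``) and a minus-anchored mode (position 1 at
``genomic_end``); TCF3 is transcribed on the chromosome 19 minus strand, so
the anchoring mode is recorded in every exported artifact.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

__all__ = [
    "IntronSpace",
    "PatientRecord",
    "Breakpoint",
    "Catalog",
    "TCF3_INTRON16",
    "PBX1_INTRON2",
    "CatalogSchemaError",
    "CatalogValidationError",
    "load_catalog",
    "load_packaged_catalog",
    "intron_to_genomic",
    "genomic_to_intron",
    "catalog_summary",
    "export_bed",
]

GENES = ("TCF3", "PBX1")
ORIENTATIONS = ("TCF3::PBX1", "PBX1::TCF3")
SEXES = ("f", "m")
PHENOTYPES = ("pre-B", "common")
SAMPLE_TYPES = ("bm", "pb", "unknown")

REQUIRED_COLUMNS = (
    "patient_id", "sex", "age", "phenotype", "sample_type",
    "gene", "orientation", "position",
)


class CatalogSchemaError(ValueError):
    """Raised when a catalog file is structurally unusable."""


class CatalogValidationError(ValueError):
    """Raised when a catalog row violates a domain invariant."""


@dataclass(frozen=True)
class IntronSpace:
    """A named intron with its genomic span (1-based inclusive)."""

    name: str
    chrom: str
    genomic_start: int
    genomic_end: int

    def __post_init__(self) -> None:
        if self.genomic_end < self.genomic_start:
            raise ValueError(f"{self.name}: genomic_end < genomic_start")

    @property
    def length(self) -> int:
        return self.genomic_end - self.genomic_start + 1

    def contains_genomic(self, g: int) -> bool:
        return self.genomic_start <= g <= self.genomic_end


#: TCF3 intron 16 on NC_000019.10 (GRCh38.p13), 3289 bp.
TCF3_INTRON16 = IntronSpace("TCF3_intron16", "chr19", 1_615_822, 1_619_110)
#: PBX1 intron 2 (long variant) on NC_000001.11, 229,182 bp.
PBX1_INTRON2 = IntronSpace("PBX1_intron2", "chr1", 164_563_312, 164_792_493)

INTRON_BY_GENE = {"TCF3": TCF3_INTRON16, "PBX1": PBX1_INTRON2}


@dataclass(frozen=True)
class PatientRecord:
    id: str
    sex: str
    age: int
    phenotype: str
    sample_type: str
    accessions: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise CatalogValidationError(f"patient {self.id}: sex {self.sex!r} not in {SEXES}")
        if self.phenotype not in PHENOTYPES:
            raise CatalogValidationError(
                f"patient {self.id}: phenotype {self.phenotype!r} not in {PHENOTYPES}")
        if self.sample_type not in SAMPLE_TYPES:
            raise CatalogValidationError(
                f"patient {self.id}: sample_type {self.sample_type!r} not in {SAMPLE_TYPES}")
        if self.age < 0:
            raise CatalogValidationError(f"patient {self.id}: negative age")


@dataclass(frozen=True)
class Breakpoint:
    """One break event: a 1-based intron-relative position on one gene side."""

    patient_id: str
    gene: str
    orientation: str
    position: int

    def __post_init__(self) -> None:
        if self.gene not in GENES:
            raise CatalogValidationError(f"{self.patient_id}: gene {self.gene!r} not in {GENES}")
        if self.orientation not in ORIENTATIONS:
            raise CatalogValidationError(
                f"{self.patient_id}: orientation {self.orientation!r} not in {ORIENTATIONS}")
        limit = INTRON_BY_GENE[self.gene].length
        if not 1 <= self.position <= limit:
            raise CatalogValidationError(
                f"{self.patient_id}: {self.gene} position {self.position} outside 1..{limit}")


@dataclass(frozen=True)
class Catalog:
    patients: tuple[PatientRecord, ...]
    breakpoints: tuple[Breakpoint, ...]

    def breaks_for(self, gene: str, orientation: str | None = None) -> list[Breakpoint]:
        return [b for b in self.breakpoints
                if b.gene == gene and (orientation is None or b.orientation == orientation)]

    def positions(self, gene: str, orientation: str | None = None) -> list[int]:
        return [b.position for b in self.breaks_for(gene, orientation)]


def _parse_row(idx: int, row: pd.Series) -> Breakpoint:
    try:
        position = int(row["position"])
    except (TypeError, ValueError) as exc:
        raise CatalogValidationError(f"row {idx}: non-integer position {row['position']!r}") from exc
    try:
        return Breakpoint(
            patient_id=str(row["patient_id"]),
            gene=str(row["gene"]),
            orientation=str(row["orientation"]),
            position=position,
        )
    except CatalogValidationError as exc:
        raise CatalogValidationError(f"row {idx}: {exc}") from exc


def load_catalog(path: str | Path) -> Catalog:
    """Load a long-format breakpoint TSV (one row per break event).

    Required columns: patient_id, sex, age, phenotype, sample_type, gene,
    orientation, position. Optional: accession (comma-separated), note.
    Lines starting with ``#`` are comments. Every row is returned; any
    invalid row raises, naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise CatalogSchemaError(f"{path}: empty catalog file") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogSchemaError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise CatalogSchemaError(f"{path}: no data rows")

    breakpoints = tuple(_parse_row(i, row) for i, row in df.iterrows())

    patients: dict[str, PatientRecord] = {}
    for i, row in df.iterrows():
        pid = str(row["patient_id"])
        acc = row.get("accession")
        accessions = tuple(a.strip() for a in str(acc).split(",") if a.strip()) \
            if isinstance(acc, str) else ()
        try:
            rec = PatientRecord(
                id=pid, sex=str(row["sex"]), age=int(row["age"]),
                phenotype=str(row["phenotype"]), sample_type=str(row["sample_type"]),
                accessions=accessions,
            )
        except (TypeError, ValueError) as exc:
            raise CatalogValidationError(f"row {i}: {exc}") from exc
        prev = patients.get(pid)
        if prev is not None and (prev.sex, prev.age, prev.phenotype, prev.sample_type) != (
                rec.sex, rec.age, rec.phenotype, rec.sample_type):
            raise CatalogValidationError(f"row {i}: inconsistent metadata for patient {pid}")
        patients.setdefault(pid, rec)

    return Catalog(patients=tuple(patients.values()), breakpoints=breakpoints)


def load_packaged_catalog() -> Catalog:
    """Load the breakpoint catalog shipped with the package (49 patients)."""
    ref = resources.files("fusionbreak.data").joinpath("table1_breakpoints.tsv")
    with resources.as_file(ref) as path:
        return load_catalog(path)


Mode = Literal["plus-anchored", "minus-anchored"]


def intron_to_genomic(space: IntronSpace, position: int, mode: Mode = "plus-anchored") -> tuple[str, int]:
    """Map a 1-based intron-relative position to (chrom, genomic coordinate)."""
    if not 1 <= position <= space.length:
        raise ValueError(f"position {position} outside 1..{space.length} of {space.name}")
    if mode == "plus-anchored":
        return space.chrom, space.genomic_start + position - 1
    if mode == "minus-anchored":
        return space.chrom, space.genomic_end - position + 1
    raise ValueError(f"unknown mode {mode!r}")


def genomic_to_intron(space: IntronSpace, genomic: int, mode: Mode = "plus-anchored") -> int:
    """Inverse of :func:`intron_to_genomic`."""
    if not space.contains_genomic(genomic):
        raise ValueError(f"genomic coordinate {genomic} outside {space.name}")
    if mode == "plus-anchored":
        return genomic - space.genomic_start + 1
    if mode == "minus-anchored":
        return space.genomic_end - genomic + 1
    raise ValueError(f"unknown mode {mode!r}")


def catalog_summary(catalog: Catalog) -> dict:
    """Cohort-level counts and age statistics.

    Median of an even-size multiset is the mean of the two central values.
    """
    if not catalog.patients:
        raise ValueError("empty catalog")
    patients = catalog.patients
    ages = sorted(p.age for p in patients)
    summary = {
        "n_patients": len(patients),
        "sex": {s: sum(p.sex == s for p in patients) for s in SEXES},
        "phenotype": {ph: sum(p.phenotype == ph for p in patients) for ph in PHENOTYPES},
        "sample_type": {st: sum(p.sample_type == st for p in patients) for st in SAMPLE_TYPES},
        "age": {
            "median": float(statistics.median(ages)),
            "min": ages[0],
            "max": ages[-1],
        },
        "breaks": {
            gene: {
                "total": len(catalog.breaks_for(gene)),
                **{o: len(catalog.breaks_for(gene, o)) for o in ORIENTATIONS},
            }
            for gene in GENES
        },
    }
    return summary


def export_bed(breakpoints: Iterable[Breakpoint], path: str | Path,
               mode: Mode = "plus-anchored") -> None:
    """Write genomic-converted breakpoints as BED (0-based, half-open).

    A header line records the anchoring mode used for the conversion.
    """
    lines = [f'track name="fusionbreak_breakpoints" description="anchoring={mode}"']
    for b in breakpoints:
        space = INTRON_BY_GENE[b.gene]
        chrom, g = intron_to_genomic(space, b.position, mode)
        lines.append(f"{chrom}\t{g - 1}\t{g}\t{b.patient_id}|{b.gene}|{b.orientation}")
    Path(path).write_text("\n".join(lines) + "\n")


def summary_json(catalog: Catalog) -> str:
    return json.dumps(catalog_summary(catalog), indent=2)
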