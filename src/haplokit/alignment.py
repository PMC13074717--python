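"""Locus alignment I/O and population labelling.

The universal input of the pipeline is a multiple-sequence alignment of one
locus across individuals (equal-length rows over ``A C G T - N``) plus a
sample-to-population map. Coordinates are 0-based internally; every
user-facing report renders column ``c`` as 1-based position ``c + 1``, and
the first alignment column is defined as CDS position 1 of the fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

VALID_STATES = frozenset("ACGT-N")
GAP = "-"


@dataclass(frozen=True)
class SequenceRecord:
    """One individual's consensus sequence at the locus.

    ``population`` is ``None`` until :func:`label_populations` attaches the
    sample map; residues are upper-case over ``{A,C,G,T,-,N}``.
    """

    sample_id: str
    residues: str
    population: str | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.sample_id!r}: residues must be non-empty")
        bad = set(self.residues) - VALID_STATES
        if bad:
            raise ValueError(
                f"record {self.sample_id!r}: invalid residue(s) {sorted(bad)}; "
                f"allowed states are A, C, G, T, '-', N"
            )


class Alignment:
    """An equal-length set of :class:`SequenceRecord` with unique IDs."""

    def __init__(self, records: Iterable[SequenceRecord]):
        records = list(records)
        if not records:
            raise ValueError("alignment must contain at least one record")
        length = len(records[0].residues)
        seen: set[str] = set()
        for rec in records:
            if rec.sample_id in seen:
                raise ValueError(f"duplicate sample ID {rec.sample_id!r}")
            seen.add(rec.sample_id)
            if len(rec.residues) != length:
                raise ValueError(
                    f"length mismatch: record {rec.sample_id!r} has "
                    f"{len(rec.residues)} columns, expected {length}"
                )
        self.records: list[SequenceRecord] = records
        self.length: int = length

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and [(r.sample_id, r.residues, r.population) for r in self.records]
            == [(r.sample_id, r.residues, r.population) for r in other.records]
        )

    def populations(self) -> list[str]:
        """Distinct population labels, sorted; unlabeled records are skipped."""
        return sorted({r.population for r in self.records if r.population is not None})

    def population_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for rec in self.records:
            if rec.population is not None:
                sizes[rec.population] = sizes.get(rec.population, 0) + 1
        return sizes

    def subset(self, population: str) -> "Alignment":
        """Records belonging to one population, in alignment order."""
        subset = [r for r in self.records if r.population == population]
        if not subset:
            raise ValueError(f"unknown population {population!r}")
        return Alignment(subset)


def read_fasta(path: str | Path) -> Alignment:
    """Read an aligned FASTA file; residues are upper-cased on ingest."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"alignment file not found: {path}")
    records = [
        SequenceRecord(sample_id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return Alignment(records)


def write_fasta(aln: Alignment, path: str | Path, wrap: int = 70) -> None:
    """Write the alignment; ``read_fasta`` of the output reproduces it."""
    bio = [
        _BioRecord(Seq(rec.residues), id=rec.sample_id, description="")
        for rec in aln.records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=wrap)
        writer.write_file(bio)


def read_popmap(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample_id<TAB>population`` map.

    A header row is detected by the literal word "sample" in the first field
    and skipped. Duplicate sample IDs and rows with a column count other than
    two are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"population map not found: {path}")
    mapping: dict[str, str] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and "sample" in fields[0].lower():
                continue
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ValueError(
                    f"{path}:{lineno}: expected 'sample_id<TAB>population', got {line!r}"
                )
            sample_id, population = fields
            if sample_id in mapping:
                raise ValueError(f"{path}:{lineno}: duplicate sample ID {sample_id!r}")
            mapping[sample_id] = population
    if not mapping:
        raise ValueError(f"population map {path} contains no entries")
    return mapping


def write_popmap(mapping: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("sample_id\tpopulation\n")
        for sample_id, population in mapping.items():
            handle.write(f"{sample_id}\t{population}\n")


def label_populations(aln: Alignment, mapping: Mapping[str, str]) -> Alignment:
    """Attach population labels; an alignment ID missing from the map is an
    error (records are never silently dropped)."""
    missing = [r.sample_id for r in aln.records if r.sample_id not in mapping]
    if missing:
        raise ValueError(
            f"{len(missing)} sample ID(s) missing from population map: "
            f"{', '.join(missing[:5])}{' ...' if len(missing) > 5 else ''}"
        )
    return Alignment(
        replace(rec, population=mapping[rec.sample_id]) for rec in aln.records
    )
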