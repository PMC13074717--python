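"""Curated variable-site detection and haplotype (sequence-class) assignment.

Variants are called directly from a curated consensus alignment. Indels are
treated as sequence characters: each gap-bearing column is an independent
single-column indel site, and the gap is a fifth character state. Columns
containing any ambiguous base (``N``) are excluded from sequence-class
definition entirely, mirroring conservative Sanger-consensus curation.

Because direct amplicon sequencing does not resolve allelic phase, a
"haplotype" here is a consensus sequence class: a distinct combination of
states over the variable columns. Carrier counts are individuals, not
chromosomes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alignment import Alignment, GAP


class VariantType(str, enum.Enum):
    SUBSTITUTION = "substitution"
    INDEL = "indel"


class CodingConsequence(str, enum.Enum):
    """Reference-based in silico annotation only — no functional validation."""

    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SUBSTITUTION = "substitution"


@dataclass(frozen=True)
class VariantSite:
    """One curated variable alignment column.

    ``ref_state`` is the majority state across all records (used in reports
    in lieu of an external reference sequence); ``allele_counts`` maps
    population -> state -> number of individuals.
    """

    column: int
    vtype: VariantType
    alleles: tuple[str, ...]
    allele_counts: Mapping[str, Mapping[str, int]]
    ref_state: str
    minor_count_total: int

    @property
    def position_1based(self) -> int:
        return self.column + 1

    @property
    def var_states(self) -> tuple[str, ...]:
        return tuple(a for a in self.alleles if a != self.ref_state)

    def total_count(self, state: str) -> int:
        if state not in self.alleles:
            raise ValueError(
                f"state {state!r} not observed at column {self.column} "
                f"(alleles: {self.alleles})"
            )
        return sum(counts.get(state, 0) for counts in self.allele_counts.values())


@dataclass(frozen=True)
class HaplotypeTable:
    """Distinct sequence classes over the variable columns.

    Labels are assigned H1, H2, ... in descending total copy count, ties
    broken by lexicographic key, so labelling is content-based and stable
    under any record order.
    """

    columns: tuple[int, ...]
    haplotypes: tuple[tuple[str, tuple[str, ...]], ...]  # (label, key)
    counts: Mapping[str, Mapping[str, int]]  # population -> label -> copies
    member_ids: Mapping[str, tuple[str, ...]]  # label -> sorted sample IDs

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.haplotypes)

    def key_of(self, label: str) -> tuple[str, ...]:
        for lab, key in self.haplotypes:
            if lab == label:
                return key
        raise KeyError(label)

    def total_count(self, label: str) -> int:
        return sum(counts.get(label, 0) for counts in self.counts.values())

    def population_counts(self, label: str) -> dict[str, int]:
        return {pop: counts.get(label, 0) for pop, counts in self.counts.items()}


def _state_matrix(aln: Alignment) -> np.ndarray:
    """Alignment as an (n_records, L) array of single characters."""
    return np.array([list(rec.residues) for rec in aln.records])


def detect_variable_sites(aln: Alignment) -> list[VariantSite]:
    """Detect curated variable columns (>= 2 distinct non-N states).

    Columns containing any ``N`` are excluded entirely; monomorphic columns
    are skipped. Requires a population-labelled alignment with >= 2 records.
    """
    if len(aln) < 2:
        raise ValueError("variant detection requires at least 2 records")
    unlabeled = [r.sample_id for r in aln.records if r.population is None]
    if unlabeled:
        raise ValueError(
            f"alignment must be population-labelled (unlabeled: {unlabeled[:3]})"
        )
    matrix = _state_matrix(aln)
    pops = np.array([rec.population for rec in aln.records])
    pop_labels = aln.populations()

    sites: list[VariantSite] = []
    for col in range(aln.length):
        column = matrix[:, col]
        if "N" in column:
            continue
        states = sorted(str(s) for s in set(column))
        if len(states) < 2:
            continue
        counts = {
            pop: {
                s: int(np.sum((column == s) & (pops == pop)))
                for s in states
                if np.any((column == s) & (pops == pop))
            }
            for pop in pop_labels
        }
        totals = {s: int(np.sum(column == s)) for s in states}
        # majority state is the working reference; ties break lexicographically
        ref_state = max(states, key=lambda s: (totals[s], s))
        vtype = VariantType.INDEL if GAP in states else VariantType.SUBSTITUTION
        sites.append(
            VariantSite(
                column=col,
                vtype=vtype,
                alleles=tuple(states),
                allele_counts=counts,
                ref_state=ref_state,
                minor_count_total=len(aln) - totals[ref_state],
            )
        )
    return sites


def classify_coding_consequence(
    site: VariantSite, indel_span: int = 1
) -> CodingConsequence:
    """Reference-based in silico coding consequence of a variant.

    Substitutions are reported as such; an indel shifts the reading frame
    unless its span is a multiple of 3. This is an annotation of the
    alignment only — it implies no transcript- or protein-level validation.
    """
    if site.vtype is VariantType.SUBSTITUTION:
        return CodingConsequence.SUBSTITUTION
    if indel_span < 1:
        raise ValueError(f"indel_span must be >= 1, got {indel_span}")
    if indel_span % 3 != 0:
        return CodingConsequence.FRAMESHIFT
    return CodingConsequence.INFRAME_INDEL


def assign_haplotypes(
    aln: Alignment, sites: Sequence[VariantSite]
) -> HaplotypeTable:
    """Collapse records into sequence classes over the variable columns.

    With no variable sites every record belongs to the single class H1.
    """
    columns = tuple(site.column for site in sites)
    pop_labels = aln.populations()

    keys: dict[tuple[str, ...], list] = {}
    for rec in aln.records:
        key = tuple(rec.residues[c] for c in columns)
        keys.setdefault(key, []).append(rec)

    # H1, H2, ... by descending total count; lexicographic key breaks ties
    ordered = sorted(keys.items(), key=lambda item: (-len(item[1]), item[0]))
    haplotypes = tuple(
        (f"H{rank}", key) for rank, (key, _) in enumerate(ordered, start=1)
    )
    counts: dict[str, dict[str, int]] = {pop: {} for pop in pop_labels}
    member_ids: dict[str, tuple[str, ...]] = {}
    for (label, key), (_, members) in zip(haplotypes, ordered):
        member_ids[label] = tuple(sorted(rec.sample_id for rec in members))
        for rec in members:
            if rec.population is not None:
                counts[rec.population][label] = (
                    counts[rec.population].get(label, 0) + 1
                )
    return HaplotypeTable(
        columns=columns, haplotypes=haplotypes, counts=counts, member_ids=member_ids
    )


def carrier_counts(
    tbl: HaplotypeTable, site: VariantSite, variant_state: str
) -> dict[str, int]:
    """Individuals per population whose class carries ``variant_state`` at
    ``site`` (consensus-level counts; heterozygosity is not resolved)."""
    if variant_state not in site.alleles:
        raise ValueError(
            f"state {variant_state!r} not observed at column {site.column}"
        )
    idx = tbl.columns.index(site.column)
    carriers = {label for label, key in tbl.haplotypes if key[idx] == variant_state}
    return {
        pop: sum(count for label, count in labels.items() if label in carriers)
        for pop, labels in tbl.counts.items()
    }
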