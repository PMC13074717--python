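"""Synthetic locus alignments with known ground truth.

Two generators are provided. :func:`anafp_fixture` reconstructs, from its
haplotype composition, the bundled demonstration dataset: a 594 bp coding
fragment of the AnAFP antifreeze-protein gene surveyed in 75 individuals of
the desert shrub *Ammopiptanthus nanus* — one wild population (Y, n=29) and
two ex situ collections (T, n=30; K, n=16) — whose only variation is a +C
insertion at CDS position 54 and an A deletion at CDS position 55. The
backbone sequence is arbitrary but fixed: every statistic computed by this
package depends only on the variant columns, so the dataset is fully
determined by the variant positions and per-population class counts.

:func:`generate_alignment` realises arbitrary :class:`PopulationSpec`
instances (random backbone, planted substitution/indel columns,
per-population class frequencies) for property testing against ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alignment import Alignment, SequenceRecord, GAP
from .variants import VariantType

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class VariantDef:
    """One planted variant column.

    ``ref_state`` is carried by non-carriers, ``var_state`` by carriers;
    either may be the gap for a single-column indel.
    """

    column: int
    vtype: VariantType
    ref_state: str
    var_state: str

    def __post_init__(self) -> None:
        if self.ref_state == self.var_state:
            raise ValueError("ref_state and var_state must differ")
        gapped = GAP in (self.ref_state, self.var_state)
        if gapped != (self.vtype is VariantType.INDEL):
            raise ValueError("vtype must be indel iff one state is the gap")


@dataclass(frozen=True)
class PopulationSpec:
    """Ground-truth description of a synthetic dataset."""

    backbone_length: int
    variants: tuple[VariantDef, ...]
    haplotypes: tuple[tuple[str, frozenset[int]], ...]  # (label, carried columns)
    pop_counts: Mapping[str, Mapping[str, int]]  # population -> label -> copies
    seed: int = 0

    def __post_init__(self) -> None:
        cols = [v.column for v in self.variants]
        if len(set(cols)) != len(cols):
            raise ValueError("variant columns must be distinct")
        if any(c < 0 or c >= self.backbone_length for c in cols):
            raise ValueError("variant column outside backbone")
        carried = [carry for _, carry in self.haplotypes]
        if len(set(carried)) != len(carried):
            raise ValueError("haplotype carrier sets must be distinct")
        known = {v.column for v in self.variants}
        for _, carry in self.haplotypes:
            if not carry <= known:
                raise ValueError("haplotype carries an undefined variant column")
        for pop, counts in self.pop_counts.items():
            for label, c in counts.items():
                if c < 0:
                    raise ValueError(f"negative count for {label} in {pop}")

    def class_counts(self) -> dict[str, int]:
        """Total realized copies per haplotype label."""
        totals: dict[str, int] = {}
        for counts in self.pop_counts.values():
            for label, c in counts.items():
                totals[label] = totals.get(label, 0) + c
        return totals

    def carrier_totals(self) -> dict[int, int]:
        """Realized carriers of each variant column's var_state."""
        class_totals = self.class_counts()
        carried_by = {lab: carry for lab, carry in self.haplotypes}
        return {
            v.column: sum(
                c for lab, c in class_totals.items() if v.column in carried_by[lab]
            )
            for v in self.variants
        }

    def expected_segregating_columns(self) -> list[int]:
        """Columns actually polymorphic given the realized counts."""
        n = sum(self.class_counts().values())
        return sorted(
            col for col, m in self.carrier_totals().items() if 0 < m < n
        )


def generate_alignment(
    spec: PopulationSpec, shuffle: bool = True
) -> tuple[Alignment, dict[str, str]]:
    """Realise a spec: random A/C/G/T backbone from the seed, variant states
    applied per carrier set, record order shuffled deterministically.

    Returns the alignment (population-labelled) and the matching popmap.
    """
    rng = np.random.default_rng(spec.seed)
    backbone = rng.choice(_BASES, size=spec.backbone_length)
    for v in spec.variants:
        backbone[v.column] = v.ref_state
    carried_by = {lab: carry for lab, carry in spec.haplotypes}

    hap_seq: dict[str, str] = {}
    for label, carry in spec.haplotypes:
        seq = backbone.copy()
        for v in spec.variants:
            if v.column in carry:
                seq[v.column] = v.var_state
        hap_seq[label] = "".join(seq)

    records: list[SequenceRecord] = []
    for pop in sorted(spec.pop_counts):
        i = 0
        for label, _ in spec.haplotypes:
            for _ in range(spec.pop_counts[pop].get(label, 0)):
                i += 1
                records.append(
                    SequenceRecord(
                        sample_id=f"{pop}{i:02d}",
                        residues=hap_seq[label],
                        population=pop,
                    )
                )
    if not records:
        raise ValueError("spec realises zero records")
    if shuffle:
        order = rng.permutation(len(records))
        records = [records[i] for i in order]
    popmap = {rec.sample_id: rec.population for rec in records}
    return Alignment(records), popmap


def fixture_spec(seed: int = 594) -> PopulationSpec:
    """The spec behind :func:`anafp_fixture`: L=594; a +C insertion column at
    CDS position 54 (gap in non-carriers) and an A deletion column at CDS
    position 55; classes H1 (reference), H2 (deletion), H3 (insertion) with
    counts Y = 22/4/3, T = 29/1/0, K = 16/0/0."""
    return PopulationSpec(
        backbone_length=594,
        variants=(
            VariantDef(53, VariantType.INDEL, ref_state=GAP, var_state="C"),
            VariantDef(54, VariantType.INDEL, ref_state="A", var_state=GAP),
        ),
        haplotypes=(
            ("H1", frozenset()),
            ("H2", frozenset({54})),
            ("H3", frozenset({53})),
        ),
        pop_counts={
            "Y": {"H1": 22, "H2": 4, "H3": 3},
            "T": {"H1": 29, "H2": 1},
            "K": {"H1": 16},
        },
        seed=seed,
    )


def anafp_fixture() -> tuple[Alignment, dict[str, str]]:
    """The bundled 75-individual AnAFP dataset (pure function; deterministic
    IDs Y01..Y29, T01..T30, K01..K16 in population blocks)."""
    return generate_alignment(fixture_spec(), shuffle=False)


def random_population_spec(
    seed: int,
    n_pops: int = 3,
    n_variants: int = 4,
    size_range: tuple[int, int] = (8, 30),
    frequency_dirichlet_alpha: float = 1.0,
    backbone_length: int = 200,
    indel_prob: float = 0.25,
) -> PopulationSpec:
    """Random ground-truth spec, reproducible from the seed.

    Variant columns are drawn without collision; class frequencies per
    population come from a symmetric Dirichlet with the given concentration
    and are realised as multinomial counts. Class j carries variant j-1 plus
    a random subset of earlier variants, so carrier sets are always
    distinct.
    """
    if n_pops < 1 or n_variants < 0 or backbone_length < 1:
        raise ValueError("parameters must be positive")
    if n_variants >= backbone_length:
        raise ValueError("n_variants must be < backbone_length")
    lo, hi = size_range
    if not (2 <= lo <= hi):
        raise ValueError("size_range must satisfy 2 <= lo <= hi")
    rng = np.random.default_rng(seed)
    columns = sorted(rng.choice(backbone_length, size=n_variants, replace=False))
    variants = []
    for col in columns:
        if rng.random() < indel_prob:
            ref = str(rng.choice(_BASES))
            variants.append(VariantDef(int(col), VariantType.INDEL, ref, GAP))
        else:
            ref, var = rng.choice(_BASES, size=2, replace=False)
            variants.append(
                VariantDef(int(col), VariantType.SUBSTITUTION, str(ref), str(var))
            )
    haplotypes: list[tuple[str, frozenset[int]]] = [("H1", frozenset())]
    for j, v in enumerate(variants):
        earlier = [u.column for u in variants[:j]]
        extra = {c for c in earlier if rng.random() < 0.3}
        haplotypes.append((f"H{j + 2}", frozenset({v.column}) | extra))

    n_classes = len(haplotypes)
    pop_counts: dict[str, dict[str, int]] = {}
    for p in range(n_pops):
        n = int(rng.integers(lo, hi + 1))
        probs = rng.dirichlet([frequency_dirichlet_alpha] * n_classes)
        draws = rng.multinomial(n, probs)
        pop_counts[f"P{p + 1}"] = {
            haplotypes[i][0]: int(draws[i]) for i in range(n_classes) if draws[i] > 0
        }
    return PopulationSpec(
        backbone_length=backbone_length,
        variants=tuple(variants),
        haplotypes=tuple(haplotypes),
        pop_counts=pop_counts,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
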