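"""Per-population diversity, Hudson FST and neutrality statistics.

All statistics treat indel columns as ordinary polymorphic characters
(a gap is a fifth state) and exclude columns containing ``N`` from the
pairwise-difference substrate. Nucleotide diversity normalizes by the full
alignment length L, so per-site values remain comparable across populations
regardless of which columns were excluded.

Mean pairwise difference counts k̄ are exact rationals (ratios of integer
totals); FST keeps them as :class:`fractions.Fraction` so that degenerate
and exactly-zero cases are decided without floating-point noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .alignment import Alignment
from .variants import assign_haplotypes, detect_variable_sites

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiversitySummary:
    """DnaSP-style descriptive diversity for one population."""

    population: str
    n: int
    S: int
    h: int
    Hd: float
    pi: float
    mean_pairwise_diff: float  # k̄ per sequence pair, unnormalized
    L: int


@dataclass(frozen=True)
class FstResult:
    """Hudson sequence-based FST: 1 - Hw/Hb.

    ``hw_exact``/``hb_exact`` retain the exact rational means; when the
    between-population mean Hb is zero (jointly monomorphic populations)
    the ratio is undefined and fst is reported as 0 with ``degenerate``
    set.
    """

    comparison: tuple[str, ...]  # (popA, popB) or all populations for overall
    hw_exact: Fraction
    hb_exact: Fraction
    degenerate: bool

    @property
    def Hw(self) -> float:
        return float(self.hw_exact)

    @property
    def Hb(self) -> float:
        return float(self.hb_exact)

    @property
    def fst(self) -> float:
        if self.degenerate:
            return 0.0
        return float(1 - self.hw_exact / self.hb_exact)


@dataclass(frozen=True)
class NeutralityResult:
    """Tajima's D and Fu & Li's D*/F* for one population.

    All statistics are ``None`` (reported "NA") when the population has no
    segregating sites. ``constants`` retains the internal coefficient sets
    for audit.
    """

    population: str
    n: int
    S: int
    eta: int
    eta_singletons: int
    tajima_d: float | None
    fu_li_d_star: float | None
    fu_li_f_star: float | None
    constants: Mapping[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# pairwise-difference substrate


def _encoded(records) -> np.ndarray:
    return np.array([list(rec.residues) for rec in records])


def pairwise_differences(records: Sequence) -> np.ndarray:
    """Symmetric matrix of pairwise difference counts.

    Any state mismatch (base-base or base-gap) counts 1; columns containing
    ``N`` in any of the given records are excluded.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    lengths = {len(rec.residues) for rec in records}
    if len(lengths) != 1:
        raise ValueError(f"length mismatch among records: {sorted(lengths)}")
    matrix = _encoded(records)
    keep = ~np.any(matrix == "N", axis=0)
    matrix = matrix[:, keep]
    n = len(records)
    out = np.zeros((n, n), dtype=int)
    for i in range(n):
        diffs = np.sum(matrix[i + 1 :] != matrix[i], axis=1)
        out[i, i + 1 :] = diffs
        out[i + 1 :, i] = diffs
    return out


def _kbar_exact(records) -> Fraction:
    """Exact mean pairwise difference count over all C(n,2) pairs."""
    d = pairwise_differences(records)
    n = d.shape[0]
    total = int(np.sum(np.triu(d, k=1)))
    return Fraction(total, math.comb(n, 2))


def _kbar_between_exact(records_a, records_b) -> Fraction:
    """Exact mean difference count over all nA*nB between-population pairs."""
    combined = list(records_a) + list(records_b)
    d = pairwise_differences(combined)
    na = len(records_a)
    total = int(np.sum(d[:na, na:]))
    return Fraction(total, na * len(records_b))


# ---------------------------------------------------------------------------
# descriptive diversity


def diversity_summary(aln: Alignment, population: str) -> DiversitySummary:
    """S, h, Hd and π for one population.

    Hd is Nei's haplotype diversity with the small-sample correction,
    ``(n/(n-1)) (1 - Σ p_i²)``; π is the mean pairwise difference count per
    pair divided by the alignment length L.
    """
    sub = aln.subset(population)
    n = len(sub)
    if n < 2:
        raise ValueError(f"population {population!r} has n={n} < 2")
    sites = detect_variable_sites(sub)
    table = assign_haplotypes(sub, sites)
    freqs = [table.total_count(label) / n for label in table.labels]
    hd = (n / (n - 1)) * (1 - sum(p * p for p in freqs))
    kbar = _kbar_exact(sub.records)
    return DiversitySummary(
        population=population,
        n=n,
        S=len(sites),
        h=len(table.labels),
        Hd=hd,
        pi=float(kbar) / aln.length,
        mean_pairwise_diff=float(kbar),
        L=aln.length,
    )


# ---------------------------------------------------------------------------
# Hudson sequence-based FST


def hudson_fst_pairwise(aln: Alignment, pop_a: str, pop_b: str) -> FstResult:
    """Hudson–Slatkin–Maddison FST between two populations.

    ``Hw = (k̄_A + k̄_B)/2`` (unweighted), ``Hb`` the mean difference count
    over all between-population pairs, ``fst = 1 - Hw/Hb``. Symmetric in its
    arguments.
    """
    sub_a, sub_b = aln.subset(pop_a), aln.subset(pop_b)
    if len(sub_a) < 2 or len(sub_b) < 2:
        raise ValueError("both populations need n >= 2")
    hw = (_kbar_exact(sub_a.records) + _kbar_exact(sub_b.records)) / 2
    hb = _kbar_between_exact(sub_a.records, sub_b.records)
    degenerate = hb == 0
    if degenerate:
        logger.warning(
            "FST %s-%s: between-population diversity is zero (jointly "
            "monomorphic); reporting fst=0 with degenerate flag",
            pop_a,
            pop_b,
        )
    return FstResult(
        comparison=(pop_a, pop_b), hw_exact=hw, hb_exact=hb, degenerate=degenerate
    )


def hudson_fst_overall(aln: Alignment, pops: Sequence[str]) -> FstResult:
    """Multi-population extension: Hw is the unweighted mean of per-population
    k̄, Hb the unweighted mean of between-pair mean difference counts."""
    pops = list(pops)
    if len(pops) < 2:
        raise ValueError("overall FST requires at least 2 populations")
    if len(pops) == 2:
        res = hudson_fst_pairwise(aln, pops[0], pops[1])
        return FstResult(
            comparison=tuple(pops),
            hw_exact=res.hw_exact,
            hb_exact=res.hb_exact,
            degenerate=res.degenerate,
        )
    subsets = {p: aln.subset(p) for p in pops}
    for p, sub in subsets.items():
        if len(sub) < 2:
            raise ValueError(f"population {p!r} has n < 2")
    hw = sum(_kbar_exact(subsets[p].records) for p in pops) / len(pops)
    pairs = list(combinations(pops, 2))
    hb = sum(
        _kbar_between_exact(subsets[a].records, subsets[b].records) for a, b in pairs
    ) / len(pairs)
    degenerate = hb == 0
    if degenerate:
        logger.warning(
            "overall FST %s: zero between-population diversity; fst=0 "
            "with degenerate flag",
            pops,
        )
    return FstResult(
        comparison=tuple(pops), hw_exact=hw, hb_exact=hb, degenerate=degenerate
    )


# ---------------------------------------------------------------------------
# neutrality statistics


def _tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def _fu_li_constants(n: int) -> dict[str, float]:
    # Outgroup-free D*/F* coefficients with the standard corrections
    # (Simonsen et al. 1995), as used by DnaSP and libsequence.
    an = sum(1 / i for i in range(1, n))
    bn = sum(1 / (i * i) for i in range(1, n))
    an1 = an + 1 / n  # a_{n+1}
    cn = 2 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (
        cn
        + (n - 2) / ((n - 1) ** 2)
        + (2 / (n - 1)) * (1.5 - (2 * an1 - 3) / (n - 2) - 1 / n)
    )
    v_d = (
        (n / (n - 1)) ** 2 * bn
        + an * an * dn
        - 2 * n * an * (an + 1) / ((n - 1) ** 2)
    ) / (an * an + bn)
    u_d = (n / (n - 1)) * (an - n / (n - 1)) - v_d
    v_f = (
        (2 * n**3 + 110 * n**2 - 255 * n + 153) / (9 * n**2 * (n - 1))
        + 2 * (n - 1) * an / n**2
        - 8 * bn / n
    ) / (an * an + bn)
    u_f = (
        (4 * n**2 + 19 * n + 3 - 12 * (n + 1) * an1) / (3 * n * (n - 1))
    ) / an - v_f
    return {"an": an, "bn": bn, "cn": cn, "dn": dn,
            "uD": u_d, "vD": v_d, "uF": u_f, "vF": v_f}


def _site_spectrum(sub: Alignment) -> tuple[int, int, int]:
    """(S, eta, eta_singletons) within one population's alignment.

    eta counts mutations as (number of states - 1) per segregating site;
    a singleton is a non-majority state carried by exactly one sequence.
    """
    sites = detect_variable_sites(sub)
    eta = sum(len(site.alleles) - 1 for site in sites)
    eta_s = 0
    for site in sites:
        for state in site.alleles:
            if state != site.ref_state and site.total_count(state) == 1:
                eta_s += 1
    return len(sites), eta, eta_s


def tajimas_d(aln: Alignment, population: str) -> NeutralityResult:
    """Tajima's (1989) D, with indel columns counted as segregating sites and
    k̄ the per-pair (not per-site) mean difference count; NA when S = 0."""
    sub = aln.subset(population)
    n = len(sub)
    if n < 4:
        raise ValueError(f"Tajima's D requires n >= 4 (got n={n})")
    S, eta, eta_s = _site_spectrum(sub)
    consts = _tajima_constants(n)
    if S == 0:
        return NeutralityResult(population, n, 0, 0, 0, None, None, None, consts)
    kbar = float(_kbar_exact(sub.records))
    var = consts["e1"] * S + consts["e2"] * S * (S - 1)
    d = (kbar - S / consts["a1"]) / math.sqrt(var)
    return NeutralityResult(population, n, S, eta, eta_s, d, None, None, consts)


def fu_li_star(aln: Alignment, population: str) -> NeutralityResult:
    """Fu & Li's (1993) outgroup-free D* and F*; NA when S = 0."""
    sub = aln.subset(population)
    n = len(sub)
    if n < 4:
        raise ValueError(f"Fu & Li statistics require n >= 4 (got n={n})")
    S, eta, eta_s = _site_spectrum(sub)
    consts = _fu_li_constants(n)
    if S == 0:
        return NeutralityResult(population, n, 0, 0, 0, None, None, None, consts)
    an = consts["an"]
    kbar = float(_kbar_exact(sub.records))
    d_star = ((n / (n - 1)) * eta - an * eta_s) / math.sqrt(
        consts["uD"] * eta + consts["vD"] * eta * eta
    )
    f_star = (kbar - ((n - 1) / n) * eta_s) / math.sqrt(
        consts["uF"] * eta + consts["vF"] * eta * eta
    )
    return NeutralityResult(population, n, S, eta, eta_s, None, d_star, f_star, consts)


def neutrality_summary(aln: Alignment, population: str) -> NeutralityResult:
    """Combined Tajima D + Fu & Li D*/F* record for reporting."""
    taj = tajimas_d(aln, population)
    fl = fu_li_star(aln, population)
    consts = dict(taj.constants)
    consts.update(fl.constants)
    return NeutralityResult(
        population=population,
        n=taj.n,
        S=taj.S,
        eta=fl.eta,
        eta_singletons=fl.eta_singletons,
        tajima_d=taj.tajima_d,
        fu_li_d_star=fl.fu_li_d_star,
        fu_li_f_star=fl.fu_li_f_star,
        constants=consts,
    )
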