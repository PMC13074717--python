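"""Shared test helpers and independently coded brute-force oracles.

The oracles deliberately avoid the package's vectorized code paths: plain
character loops, explicit pair enumeration, exact rational arithmetic, and
exhaustive search. They exist so the implementation can be checked against
a second, structurally different derivation of each statistic.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations, product

import numpy as np

from haplokit import Alignment, SequenceRecord


def random_alignment(rng, n=None, L=None, gap_prob=0.15):
    """Small random alignment over A/C/G/T with a handful of variable
    columns (optionally gapped) planted on a constant backbone."""
    n = n or int(rng.integers(4, 13))
    L = L or int(rng.integers(12, 30))
    backbone = rng.choice(list("ACGT"), size=L)
    seqs = np.tile(backbone, (n, 1))
    for col in rng.choice(L, size=int(rng.integers(0, 5)), replace=False):
        alt = "-" if rng.random() < gap_prob else str(rng.choice(list("ACGT")))
        carriers = rng.choice(n, size=int(rng.integers(1, n)), replace=False)
        seqs[carriers, col] = alt
    return make_alignment(["".join(row) for row in seqs])


def make_alignment(seqs, populations=None):
    """Build an alignment from a list of residue strings (one population
    unless a parallel list of labels is given)."""
    if populations is None:
        populations = ["P"] * len(seqs)
    return Alignment(
        SequenceRecord(sample_id=f"s{i:03d}", residues=seq, population=pop)
        for i, (seq, pop) in enumerate(zip(seqs, populations))
    )


# ---------------------------------------------------------------------------
# diversity oracles (plain loops, exact rationals)


def oracle_pair_diff(a: str, b: str) -> int:
    """Differences between two sequences, no N handling (use on N-free data)."""
    return sum(1 for x, y in zip(a, b) if x != y)


def oracle_segregating_columns(seqs) -> list[int]:
    cols = []
    for c in range(len(seqs[0])):
        states = {s[c] for s in seqs}
        if "N" in states:
            continue
        if len(states) >= 2:
            cols.append(c)
    return cols


def oracle_diversity(seqs):
    """(S, h, Hd, pi, kbar) from first principles on N-free sequences."""
    n = len(seqs)
    L = len(seqs[0])
    S = len(oracle_segregating_columns(seqs))
    classes: dict[str, int] = {}
    for s in seqs:
        classes[s] = classes.get(s, 0) + 1
    h = len(classes)
    hd = Fraction(n, n - 1) * (
        1 - sum(Fraction(c, n) ** 2 for c in classes.values())
    )
    total = sum(oracle_pair_diff(a, b) for a, b in combinations(seqs, 2))
    kbar = Fraction(total, math.comb(n, 2))
    return S, h, float(hd), float(kbar) / L, float(kbar)


def oracle_site_counts(seqs):
    """(S, eta, eta_singletons) with eta = sum(states-1) per variable column
    and a singleton = a non-majority state carried by exactly one sequence."""
    S = eta = eta_s = 0
    for c in oracle_segregating_columns(seqs):
        counts: dict[str, int] = {}
        for s in seqs:
            counts[s[c]] = counts.get(s[c], 0) + 1
        S += 1
        eta += len(counts) - 1
        major = max(sorted(counts), key=lambda st: (counts[st], st))
        eta_s += sum(
            1 for st, ct in counts.items() if st != major and ct == 1
        )
    return S, eta, eta_s


def oracle_tajima_d(seqs):
    """Tajima's D from the textbook definition, written as explicit sums."""
    n = len(seqs)
    S, _, _ = oracle_site_counts(seqs)
    if S == 0:
        return None
    _, _, _, _, kbar = oracle_diversity(seqs)
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (kbar - S / float(a1)) / math.sqrt(float(e1) * S + float(e2) * S * (S - 1))


def oracle_fu_li(seqs):
    """Fu & Li's outgroup-free D* and F* (corrected coefficients), written
    with exact rationals; returns (D*, F*) or None when S = 0."""
    n = len(seqs)
    S, eta, eta_s = oracle_site_counts(seqs)
    if S == 0:
        return None
    _, _, _, _, kbar = oracle_diversity(seqs)
    an = sum(Fraction(1, i) for i in range(1, n))
    bn = sum(Fraction(1, i * i) for i in range(1, n))
    an1 = an + Fraction(1, n)
    cn = Fraction(2) * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (
        cn
        + Fraction(n - 2, (n - 1) ** 2)
        + Fraction(2, n - 1) * (Fraction(3, 2) - (2 * an1 - 3) / (n - 2) - Fraction(1, n))
    )
    nf = Fraction(n)
    v_d = (
        (nf / (n - 1)) ** 2 * bn + an**2 * dn - 2 * nf * an * (an + 1) / (n - 1) ** 2
    ) / (an**2 + bn)
    u_d = (nf / (n - 1)) * (an - nf / (n - 1)) - v_d
    d_star = (float(nf / (n - 1)) * eta - float(an) * eta_s) / math.sqrt(
        float(u_d) * eta + float(v_d) * eta * eta
    )
    v_f = (
        Fraction(2 * n**3 + 110 * n**2 - 255 * n + 153, 9 * n**2 * (n - 1))
        + 2 * (nf - 1) * an / n**2
        - 8 * bn / n
    ) / (an**2 + bn)
    u_f = (
        Fraction(4 * n**2 + 19 * n + 3, 3 * n * (n - 1))
        - 4 * (nf + 1) * an1 / (n * (n - 1))
    ) / an - v_f
    f_star = (kbar - float(nf - 1) / n * eta_s) / math.sqrt(
        float(u_f) * eta + float(v_f) * eta * eta
    )
    return d_star, f_star


# ---------------------------------------------------------------------------
# network oracle


def oracle_mst_cost(keys) -> int:
    """Prim's algorithm on explicit Hamming distances (no networkx)."""
    keys = list(keys)
    if len(keys) <= 1:
        return 0
    in_tree = {0}
    cost = 0
    while len(in_tree) < len(keys):
        best = None
        for i in in_tree:
            for j in range(len(keys)):
                if j in in_tree:
                    continue
                d = oracle_pair_diff("".join(keys[i]), "".join(keys[j]))
                if best is None or d < best[0]:
                    best = (d, j)
        cost += best[0]
        in_tree.add(best[1])
    return cost


def oracle_steiner_cost(observed_keys, alphabet="ACGT-") -> int:
    """Exhaustive Steiner-augmented minimum connection cost: minimum MST
    cost over observed keys plus any subset of candidate intermediate keys.
    Exponential — only for instances with <= 2 variable columns."""
    n_cols = len(observed_keys[0])
    assert n_cols <= 2, "exhaustive search only feasible for <= 2 columns"
    states_per_col = [
        sorted({k[c] for k in observed_keys}) for c in range(n_cols)
    ]
    candidates = [
        key for key in product(*states_per_col) if key not in set(observed_keys)
    ]
    best = oracle_mst_cost(observed_keys)
    for r in range(1, len(candidates) + 1):
        for extra in combinations(candidates, r):
            cost = oracle_mst_cost(list(observed_keys) + list(extra))
            if cost < best:
                best = cost
    return best
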