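"""Independent brute-force oracles used only by the test suite.

Each oracle implements the same quantity as the package via a different
route (path counting, exact rational enumeration, exhaustive window
enumeration) and is deliberately slow and simple.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


# --- pedigree inbreeding via Wright's path counting -------------------------

def fped_path_counting(parents: dict) -> dict:
    """F for every animal from common-ancestor path enumeration.

    ``parents`` maps animal -> (sire or None, dam or None).  For each animal,
    F = sum over common ancestors A and pairs of ancestor paths (sire side,
    dam side) meeting only at A of (1/2)^(n1+n2+1) * (1 + F_A).
    """

    def paths_up(start):
        """All ancestor paths from ``start`` as node tuples (start first)."""
        if start is None:
            return []
        out = [(start,)]
        for p in parents.get(start, (None, None)):
            for tail in paths_up(p):
                out.append((start,) + tail)
        return out

    F: dict = {}

    def f_of(animal) -> float:
        if animal in F:
            return F[animal]
        sire, dam = parents.get(animal, (None, None))
        total = 0.0
        if sire is not None and dam is not None:
            for p1 in paths_up(sire):
                for p2 in paths_up(dam):
                    if p1[-1] != p2[-1]:
                        continue
                    if set(p1[:-1]) & set(p2):
                        continue  # paths may share only the common ancestor
                    a = p1[-1]
                    total += 0.5 ** (len(p1) + len(p2) - 1) * (1.0 + f_of(a))
        F[animal] = total
        return total

    for animal in parents:
        f_of(animal)
    return F


# --- exact HWE enumeration with rationals -----------------------------------

def hwe_enumeration(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact HWE p-value by full rational enumeration."""
    n = n_hom1 + n_het + n_hom2
    n_a = 2 * n_hom1 + n_het  # allele-1 count
    n_b = 2 * n - n_a
    if n_a == 0 or n_b == 0:
        return 1.0
    n_rare = min(n_a, n_b)
    probs = {}
    total = Fraction(0)
    for het in range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2):
        rare_hom = (n_rare - het) // 2
        common_hom = n - het - rare_hom
        w = Fraction(
            comb(n, het) * comb(n - het, rare_hom) * 2**het
        )
        probs[het] = w
        total += w
    obs = probs[n_het]
    p = sum(w for w in probs.values() if w <= obs) / total
    return float(min(1, p))


# --- exhaustive ROH window enumeration --------------------------------------

def roh_enumeration(pos, dosage, *, min_snps=15, min_length=1_000_000,
                    max_gap=500_000, min_density=1e-5, max_het=1,
                    max_missing=1):
    """Reference ROH windows [i, j] on one chromosome.

    A window is valid when it has homozygous endpoints, at most ``max_het``
    heterozygotes and ``max_missing`` missing calls, and no internal gap
    above ``max_gap``.  Keeps windows not strictly contained in any other
    valid window, applies the min-SNP / min-length / density filters, then
    selects non-overlapping windows greedily from the left.
    """
    pos = np.asarray(pos)
    dosage = np.asarray(dosage)
    n = len(pos)
    hom = (dosage == 0) | (dosage == 2)

    def composition_ok(i, j):
        if i < 0 or j >= n or i > j:
            return False
        w = dosage[i : j + 1]
        if not (hom[i] and hom[j]):
            return False
        if (w == 1).sum() > max_het or (w < 0).sum() > max_missing:
            return False
        if j > i and np.max(np.diff(pos[i : j + 1])) > max_gap:
            return False
        return True

    def longest_from(i):
        """Largest j with composition_ok(i, j), or None; fresh scan per i."""
        best = None
        n_het = n_miss = 0
        for j in range(i, n):
            if j > i and pos[j] - pos[j - 1] > max_gap:
                break
            n_het += dosage[j] == 1
            n_miss += dosage[j] < 0
            if n_het > max_het or n_miss > max_missing:
                break
            if hom[j]:
                best = j
        return best if best is not None and composition_ok(i, best) else None

    # any valid [i, j] is contained in [i, longest_from(i)]; it is maximal
    # iff no i' < i reaches at least as far right
    reach = {i: longest_from(i) for i in range(n) if hom[i]}
    maximal = [
        (i, j)
        for i, j in reach.items()
        if j is not None
        and not any(
            i2 < i and j2 is not None and j2 >= j for i2, j2 in reach.items()
        )
    ]

    filtered = []
    for i, j in sorted(set(maximal)):
        n_snps = j - i + 1
        length = pos[j] - pos[i]
        if n_snps < min_snps or length < min_length:
            continue
        if length > 0 and n_snps / length < min_density:
            continue
        filtered.append((i, j))

    selected = []
    last_end = -1
    for i, j in filtered:
        if i > last_end:
            selected.append((i, j))
            last_end = j
    return selected


# --- direct r2 from the 3x3 genotype table ----------------------------------

def r2_from_counts(x, y) -> float:
    """Squared correlation computed from the genotype count table."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x >= 0) & (y >= 0)
    x, y = x[ok], y[ok]
    table = np.zeros((3, 3))
    for a, b in zip(x.astype(int), y.astype(int)):
        table[a, b] += 1
    n = table.sum()
    gx = table.sum(axis=1)
    gy = table.sum(axis=0)
    dos = np.array([0.0, 1.0, 2.0])
    mx = (gx * dos).sum() / n
    my = (gy * dos).sum() / n
    cov = sum(table[a, b] * (dos[a] - mx) * (dos[b] - my)
              for a in range(3) for b in range(3)) / n
    vx = (gx * (dos - mx) ** 2).sum() / n
    vy = (gy * (dos - my) ** 2).sum() / n
    return float(cov**2 / (vx * vy))


# --- random pedigree generator for oracle comparisons -----------------------

def random_pedigree(rng, n_animals=30, n_founders=6):
    """Random acyclic pedigree as a parents dict (ids are ints)."""
    parents = {}
    for i in range(n_animals):
        if i < n_founders:
            parents[i] = (None, None)
            continue
        k = int(rng.integers(3))
        sire = int(rng.integers(i)) if k != 1 else None
        dam = int(rng.integers(i)) if k != 2 else None
        if sire is not None and dam == sire:
            dam = None
        parents[i] = (sire, dam)
    return parents
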