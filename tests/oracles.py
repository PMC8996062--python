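"""Exhaustive brute-force twins of the fast implementations.

Each oracle recomputes a quantity by direct enumeration (windows, Hamming
neighborhoods, index tuples, positive-negative pairs) in plain Python, and
is deliberately independent of the package's fast paths.
"""

from __future__ import annotations

import itertools

BASES = "ACGU"


def kmer_count_oracle(residues: str, k: int) -> dict[str, int]:
    counts = {"".join(p): 0 for p in itertools.product(BASES, repeat=k)}
    for i in range(len(residues) - k + 1):
        counts[residues[i : i + k]] += 1
    return counts


def kmer_freq_oracle(residues: str, k: int) -> list[float]:
    counts = kmer_count_oracle(residues, k)
    n = len(residues) - k + 1
    return [counts[t] / n for t in sorted(counts)]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def mismatch_oracle(residues: str, k: int, m: int) -> list[float]:
    """Per type, count windows within Hamming distance m (Σ_{j<=m} c_{i,j})."""
    windows = [residues[i : i + k] for i in range(len(residues) - k + 1)]
    out = []
    for t in ("".join(p) for p in itertools.product(BASES, repeat=k)):
        out.append(float(sum(1 for w in windows if _hamming(w, t) <= m)))
    return out


def subsequence_oracle(residues: str, k: int, delta: float) -> list[float]:
    """Per type, Σ over matching index tuples of δ^span (contiguous: δ^0=1)."""
    totals = {"".join(p): 0.0 for p in itertools.product(BASES, repeat=k)}
    for tup in itertools.combinations(range(len(residues)), k):
        word = "".join(residues[p] for p in tup)
        span = tup[-1] - tup[0] + 1
        totals[word] += 1.0 if span == k else delta**span
    return [totals[t] for t in sorted(totals)]


def triplet_oracle(residues: str, brackets: str) -> list[float]:
    """32-bin frequency: center nucleotide x paired/unpaired 3-pattern."""
    patterns = ["".join(p) for p in itertools.product(".(", repeat=3)]
    names = [f"{b}{pat}" for b in BASES for pat in patterns]
    counts = dict.fromkeys(names, 0)
    collapsed = "".join("." if c == "." else "(" for c in brackets)
    l = len(residues)
    for i in range(1, l - 1):
        counts[residues[i] + collapsed[i - 1 : i + 2]] += 1
    return [counts[n] / (l - 2) for n in names]


STATUS_ORDER = ("A", "C", "G", "U", "A-U", "U-A", "G-C", "C-G", "G-U", "U-G")


def psedsspc_oracle(
    statuses: list[str], energies: list[float], d: int, lam: int, w: float
) -> list[float]:
    """Status frequencies + ordered pair frequencies per distance + tiers."""
    l = len(statuses)
    g_status = [statuses.count(s) / l for s in STATUS_ORDER]
    g_pairs = []
    for dist in range(1, d + 1):
        for x in STATUS_ORDER:
            for y in STATUS_ORDER:
                n = sum(
                    1
                    for i in range(l - dist)
                    if statuses[i] == x and statuses[i + dist] == y
                )
                g_pairs.append(n / (l - dist))
    g_tiers = [
        sum((energies[i] - energies[i + k]) ** 2 for i in range(l - k)) / (l - k)
        for k in range(1, lam + 1)
    ]
    z = sum(g_status) + sum(g_pairs) + w * sum(g_tiers)
    return [g / z for g in g_status + g_pairs] + [w * g / z for g in g_tiers]


def auroc_pairs_oracle(labels, scores) -> float:
    """Fraction of positive-negative pairs correctly ordered, ties 1/2."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))
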