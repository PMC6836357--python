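"""Independent oracles used by the test suite.

Each oracle is a deliberately naive re-derivation (exact enumeration, direct
loop, union-find, brute-force double loop) kept separate from the library
code paths it validates.
"""

from __future__ import annotations

from fractions import Fraction
from math import factorial

import numpy as np


def hwe_enumeration_p(n_ref_hom: int, n_het: int, n_alt_hom: int) -> Fraction:
    """Exact HWE p by full enumeration with rational arithmetic.

    Conditional on the allele counts, P(h het) is proportional to
    n! / (hom_min! h! hom_maj!) * 2^h; the p-value sums probabilities no
    larger than the observed configuration's.
    """
    n = n_ref_hom + n_het + n_alt_hom
    na = 2 * n_alt_hom + n_het
    n_minor = min(na, 2 * n - na)
    weights: dict[int, int] = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        if hom_maj < 0:
            continue
        weights[h] = factorial(n) // (
            factorial(hom_min) * factorial(h) * factorial(hom_maj)
        ) * 2**h
    total = sum(weights.values())
    obs = weights[n_het]
    return Fraction(sum(w for w in weights.values() if w <= obs), total)


def trend_score_test(case_dosages: np.ndarray, control_dosages: np.ndarray) -> float:
    """Squared logistic-score statistic from per-sample dosage arrays."""
    x = np.concatenate([case_dosages, control_dosages]).astype(float)
    y = np.concatenate([np.ones(len(case_dosages)), np.zeros(len(control_dosages))])
    ybar = y.mean()
    u = np.sum((y - ybar) * x)
    v = ybar * (1 - ybar) * np.sum((x - x.mean()) ** 2)
    return u * u / v


def es_direct_loop(values_ranked: np.ndarray, in_set: np.ndarray) -> float:
    """Enrichment score by walking the full running sum, one gene at a time."""
    n = len(values_ranked)
    m = int(in_set.sum())
    assert 0 < m
    if m == n:
        return 1.0
    denom = np.abs(values_ranked[in_set]).sum()
    running = 0.0
    path_max, path_min = 0.0, 0.0
    for i in range(n):
        if in_set[i]:
            if denom > 0:
                running += abs(values_ranked[i]) / denom
            else:
                running += 1.0 / m
        else:
            running -= 1.0 / (n - m)
        path_max = max(path_max, running)
        path_min = min(path_min, running)
    # signed extremum; exact ties (to numerical noise) resolve positive
    if path_max >= -path_min - 1e-12:
        return path_max
    return path_min


def union_find_fuse(gene_sets: list[set[str]]) -> list[set[str]]:
    """Merge gene sets sharing a member, via explicit union-find."""
    parent = list(range(len(gene_sets)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    owner: dict[str, int] = {}
    for i, s in enumerate(gene_sets):
        for g in s:
            if g in owner:
                union(owner[g], i)
            else:
                owner[g] = i
    groups: dict[int, set[str]] = {}
    for i, s in enumerate(gene_sets):
        groups.setdefault(find(i), set()).update(s)
    return sorted(groups.values(), key=lambda s: sorted(s))


def top_k_by_full_corrcoef(matrix: np.ndarray, genes: list[str], seed_idx: int, k: int):
    """Top-k neighbors via the full correlation matrix and a stable argsort."""
    r = np.corrcoef(matrix)
    sd = matrix.std(axis=1)
    cand = [
        (genes[j], r[seed_idx, j])
        for j in range(len(genes))
        if j != seed_idx and sd[j] > 0
    ]
    cand.sort(key=lambda t: (-t[1], t[0]))
    return cand[:k]


def low_expression_keep_bruteforce(
    matrices: list[np.ndarray], gene_lists: list[list[str]],
    threshold: float = 1.0, fraction: float = 0.8
) -> set[str]:
    keep = set()
    for mat, genes in zip(matrices, gene_lists):
        for gi, gene in enumerate(genes):
            n_above = sum(1 for v in mat[gi] if v > threshold)
            if n_above / mat.shape[1] >= fraction:
                keep.add(gene)
    return keep
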