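"""Independent oracles used by the test suite.

Each oracle re-derives an expected result by brute force or closed form,
sharing no code path with the implementation it checks.
"""

from __future__ import annotations

from itertools import combinations
from typing import List, Sequence, Tuple

import numpy as np


def exhaustive_best_score(
    read: str,
    refs: Sequence[str],
    match: int = 1,
    mismatch: int = -2,
    gap_per_base: int = 3,
    max_del: int = 6,
) -> float:
    """Optimal alignment score of ``read`` over every placement on every
    oriented reference: mismatches anywhere, reference deletions up to
    ``max_del`` total bases, free 3' soft-clipping.  Dynamic program
    vectorized over all start positions."""
    L = len(read)
    q = np.frombuffer(read.encode(), dtype=np.uint8)
    best = -np.inf
    for R in refs:
        P = len(R)
        if P == 0:
            continue
        r = np.frombuffer(R.encode(), dtype=np.uint8)
        pad = np.concatenate([r, np.zeros(L + max_del + 1, dtype=np.uint8)])
        offsets = np.arange(P)
        S_prev = np.zeros((max_del + 1, P))
        S_prev[1:, :] = -np.inf  # no deletion before the first consumed base
        for i in range(1, L + 1):
            S = np.full((max_del + 1, P), -np.inf)
            for d in range(max_del + 1):
                refbase = pad[i - 1 + d : i - 1 + d + P]
                sc = np.where(refbase == q[i - 1], match, mismatch)
                valid = (offsets + i - 1 + d) < P
                S[d] = np.where(valid, S_prev[d] + sc, -np.inf)
                for g in (1, 2, 3):
                    if d - g >= 0:
                        S[d] = np.maximum(S[d], S[d - g] - gap_per_base * g)
            best = max(best, float(S.max()))  # clip the remaining suffix
            S_prev = S
    return best


def brute_force_complete_linkage(dist: np.ndarray) -> List[Tuple[frozenset, frozenset, float]]:
    """Agglomerative complete linkage recomputing the max-linkage between
    every cluster pair from scratch at each step."""
    n = dist.shape[0]
    clusters: List[frozenset] = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(clusters, 2):
            d = max(dist[i, j] for i in a for j in b)
            key = (d, min(min(a), min(b)), max(min(a), min(b)))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        merges.append((a, b, best[0][0]))
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
    return merges


def chi2_closed_form(a: int, b: int, c: int, d: int) -> float:
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def suffix_adapter_scan(seq: str, adapter: str, min_overlap: int = 5) -> str:
    """Reference adapter trimmer: leftmost suffix matching an adapter
    prefix at 10% mismatch rate (exact below min_overlap)."""
    for start in range(len(seq)):
        tail = seq[start:]
        n = min(len(tail), len(adapter))
        allowed = n // 10 if n >= min_overlap else 0
        if sum(x != y for x, y in zip(tail, adapter[:n])) <= allowed:
            return seq[:start]
    return seq


def per_read_junction_class(record, feature) -> str:
    """Classify a simulated read from its manifest truth: does its
    templated genomic span cross an intron boundary (IE) or was it drawn
    from the spliced template across a junction (EE)?  Returns 'IE', 'EE'
    or 'neither'."""
    s, e = record.genomic_start, record.genomic_end
    introns = feature.introns
    if record.template == "precursor":
        for ia, ib in introns:
            if (s < ia <= e - 1) or (s <= ib - 1 < e - 1):
                return "IE"
        return "neither"
    for ia, ib in introns:
        if s < ia and e > ib:
            return "EE"
    return "neither"
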