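"""Binding-profile clustering and gene-set enrichment.

mRNAs (or experiments) are clustered by complete-linkage agglomeration on
the correlation distance ``d = 1 - Pearson r`` computed on log10(1+hpm)
rows.  The linkage is implemented here so the tie-break is deterministic
(smallest leaf-index pair); scipy's implementation serves as an
independent cross-check in the test suite, never as the computation.

Clusters cut from the dendrogram are tested for gene-set enrichment with
the closed-form 2x2 chi-square statistic N(ad-bc)^2/((a+b)(c+d)(a+c)(b+d))
(1 df, no continuity correction); Fisher's exact test is substituted and
flagged when any expected cell is below 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class Dendrogram:
    """Agglomerative merge history over ``labels``.

    ``merges`` lists (node_a, node_b, height, new_node); leaves are
    0..n-1, internal nodes n, n+1, ... in merge order.
    """

    labels: List[str]
    merges: List[Tuple[int, int, float, int]]
    metric: str = "correlation"
    linkage: str = "complete"

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def heights(self) -> List[float]:
        return [h for _, _, h, _ in self.merges]

    def cut(self, k: int) -> Dict[str, int]:
        """Leaf label -> cluster id (0..k-1) after cutting at k clusters."""
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}]")
        groups: Dict[int, List[int]] = {i: [i] for i in range(n)}
        node_of: Dict[int, int] = {i: i for i in range(n)}
        for a, b, _h, new in self.merges[: n - k]:
            ga, gb = node_of.pop(a), node_of.pop(b)
            groups[ga].extend(groups.pop(gb))
            node_of[new] = ga
        out = {}
        for cid, (_, members) in enumerate(sorted(groups.items())):
            for m in members:
                out[self.labels[m]] = cid
        return out

    def to_newick(self) -> str:
        n = self.n_leaves
        node: Dict[int, str] = {i: self.labels[i] for i in range(n)}
        h: Dict[int, float] = {i: 0.0 for i in range(n)}
        for a, b, height, new in self.merges:
            la = (height - h[a]) / 2
            lb = (height - h[b]) / 2
            node[new] = f"({node[a]}:{la:g},{node[b]}:{lb:g})"
            h[new] = height
        root = self.merges[-1][3] if self.merges else 0
        return node[root] + ";"


def correlation_distance(matrix: pd.DataFrame, log_transform: bool = True) -> np.ndarray:
    """Pairwise 1 - Pearson r between rows of an hpm matrix.

    Rows are log10(1+x) transformed first by default.  A zero-variance row
    gets distance 1 to everything (r treated as 0) and is flagged with a
    warning.  Result is symmetric with a zero diagonal, range [0, 2].
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if log_transform:
        X = np.log10(1.0 + X)
    sd = X.std(axis=1)
    flat = sd == 0
    if flat.any():
        import warnings

        warnings.warn(f"{int(flat.sum())} zero-variance rows: distance set to 1")
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1))
    norms[flat] = 1.0
    Xn = Xc / norms[:, None]
    r = Xn @ Xn.T
    np.clip(r, -1.0, 1.0, out=r)
    r[flat, :] = 0.0
    r[:, flat] = 0.0
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def complete_linkage(dist: np.ndarray, labels: Optional[Sequence[str]] = None) -> Dendrogram:
    """Agglomerative complete-linkage clustering of a distance matrix.

    At each step the pair of clusters with the smallest maximum inter-point
    distance merges; ties break on the smallest (minimum leaf index) pair.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    labels = list(labels) if labels is not None else [str(i) for i in range(n)]
    active: Dict[int, List[int]] = {i: [i] for i in range(n)}  # node -> leaf members
    D: Dict[Tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[(i, j)] = dist[i, j]
    merges: List[Tuple[int, int, float, int]] = []
    next_node = n
    min_leaf = {i: i for i in range(n)}
    while len(active) > 1:
        best = None
        for (i, j), d in D.items():
            key = (d, min(min_leaf[i], min_leaf[j]), max(min_leaf[i], min_leaf[j]))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        h = D[(i, j)]
        members = active.pop(i) + active.pop(j)
        for k in list(active):
            a, b = (min(i, k), max(i, k)), (min(j, k), max(j, k))
            dk = max(D.pop(a), D.pop(b))
            D[(min(k, next_node), max(k, next_node))] = dk
        del D[(i, j)]
        active[next_node] = members
        min_leaf[next_node] = min(min_leaf[i], min_leaf[j])
        merges.append((i, j, h, next_node))
        next_node += 1
    return Dendrogram(labels=labels, merges=merges)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> Tuple[float, float]:
    """Closed-form 2x2 chi-square statistic and p-value (1 df, no correction)."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0
    stat = n * (a * d - b * c) ** 2 / denom
    return float(stat), float(stats.chi2.sf(stat, df=1))


@dataclass
class EnrichmentResult:
    cluster_id: int
    gene_set: str
    table: Tuple[int, int, int, int]  # (in-cluster&in-set, in-cluster&out, out&in-set, out&out)
    statistic: float
    p_value: float
    direction: str  # enriched | depleted
    test: str = "chi-square"  # or fisher (small expected cells)


def cut_and_enrich(
    dendrogram: Dendrogram,
    k: int,
    gene_sets: Dict[str, Sequence[str]],
) -> List[EnrichmentResult]:
    """Cut at ``k`` clusters and chi-square-test every (cluster, set) pair.

    ``gene_sets`` maps set label -> member feature ids.  Raw p-values are
    reported (no multiple-testing correction by default); Fisher's exact
    test replaces the chi-square when any expected cell count is < 5.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    assignment = dendrogram.cut(k)
    universe = set(dendrogram.labels)
    results: List[EnrichmentResult] = []
    for set_label, members in sorted(gene_sets.items()):
        in_set = set(members) & universe
        if not in_set:
            import warnings

            warnings.warn(f"gene set {set_label!r} empty in matrix, skipped")
            continue
        for cid in range(k):
            cluster = {g for g, c in assignment.items() if c == cid}
            a = len(cluster & in_set)
            b = len(cluster - in_set)
            c = len(in_set - cluster)
            d = len(universe - cluster - in_set)
            n = a + b + c + d
            expected_a = (a + b) * (a + c) / n if n else 0.0
            test = "chi-square"
            row_tot = [a + b, c + d]
            col_tot = [a + c, b + d]
            min_expected = min(
                (rt * ct / n for rt in row_tot for ct in col_tot), default=0.0
            )
            if min_expected < 5:
                test = "fisher"
                _odds, p = stats.fisher_exact([[a, b], [c, d]])
                stat = float("nan")
            else:
                stat, p = chi_square_2x2(a, b, c, d)
            direction = "enriched" if a >= expected_a else "depleted"
            results.append(
                EnrichmentResult(cid, set_label, (a, b, c, d), stat, float(p), direction, test)
            )
    return results


def enrichment_to_tsv(results: Sequence[EnrichmentResult], path) -> None:
    rows = [
        {
            "cluster": r.cluster_id,
            "gene_set": r.gene_set,
            "a": r.table[0],
            "b": r.table[1],
            "c": r.table[2],
            "d": r.table[3],
            "statistic": r.statistic,
            "p_value": r.p_value,
            "direction": r.direction,
            "test": r.test,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
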