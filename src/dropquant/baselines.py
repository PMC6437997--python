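"""Reference counters the deduplication pipeline is compared against.

These are deliberately simple, independently coded strategies: a per-class
UMI counter (which over-counts molecules whose reads land in different
equivalence classes), a discard-multigene foil (which drops every read whose
class spans more than one gene, biasing shared genes low), a directional UMI
clusterer operating on raw UMI count dictionaries, and an exhaustive minimum
dominating set solver for small graphs.  None of them share code with the
PUG machinery.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations
from typing import Iterable, Mapping


def naive_eqclass_gene_counts(
    cell_table: Mapping[tuple[str, tuple], int], t2g: Mapping[str, str]
) -> dict[str, float]:
    """Treat every equivalence class independently: one molecule per distinct
    UMI per class.  Multi-gene classes are split uniformly across their genes."""
    per_class_umis: dict[tuple, set[str]] = {}
    for (umi, eqclass), _count in cell_table.items():
        per_class_umis.setdefault(tuple(eqclass), set()).add(umi)
    counts: dict[str, float] = {}
    for eqclass, umis in per_class_umis.items():
        genes = sorted({t2g[t] for t in eqclass})
        for g in genes:
            counts[g] = counts.get(g, 0.0) + len(umis) / len(genes)
    return counts


def directional_cluster_count(umi_counts: Mapping[str, int]) -> int:
    """Cluster UMIs of one gene with the directional error-collapse rule.

    A directed link u -> v exists when the UMIs are at Hamming distance 1 and
    c_u > 2*c_v - 1 (v could be a PCR/sequencing error of u); distance-1
    pairs with no directed link in either direction are joined undirected.
    Clusters are grown greedily from the root reaching the most unclustered
    UMIs.  This re-implements the collapse rule directly on a UMI count
    dictionary, independent of any graph/equivalence-class machinery.
    """
    umis = list(umi_counts)
    counts = [umi_counts[u] for u in umis]
    n = len(umis)
    succ: list[set[int]] = [set() for _ in range(n)]
    for i, j in combinations(range(n), 2):
        if sum(a != b for a, b in zip(umis[i], umis[j])) != 1:
            continue
        fwd = counts[i] > 2 * counts[j] - 1
        rev = counts[j] > 2 * counts[i] - 1
        if fwd:
            succ[i].add(j)
        if rev:
            succ[j].add(i)
        if not (fwd or rev):
            succ[i].add(j)
            succ[j].add(i)

    remaining = set(range(n))
    clusters = 0
    while remaining:
        best: set[int] = set()
        for v in range(n):
            if v not in remaining:
                continue
            seen = {v}
            stack = [v]
            while stack:
                x = stack.pop()
                for w in succ[x]:
                    if w in remaining and w not in seen:
                        seen.add(w)
                        stack.append(w)
            if len(seen) > len(best):
                best = seen
        remaining -= best
        clusters += 1
    return clusters


def discard_multigene_counts(
    cell_table: Mapping[tuple[str, tuple], int], t2g: Mapping[str, str]
) -> dict[str, float]:
    """Foil pipeline: drop reads whose class spans more than one gene, then
    deduplicate the remainder with the regular covering."""
    from .em_tiers import quantify_cell

    filtered = {
        key: count
        for key, count in cell_table.items()
        if len({t2g[t] for t in key[1]}) == 1
    }
    if not filtered:
        return {}
    counts, _ambiguous = quantify_cell(filtered, t2g)
    return counts


def min_dominating_set_size(n: int, edges: Iterable[tuple[int, int]]) -> int:
    """Exhaustive minimum dominating set size for a small undirected graph."""
    if n == 0:
        return 0
    closed = [1 << i for i in range(n)]
    for a, b in edges:
        if a == b:
            continue
        closed[a] |= 1 << b
        closed[b] |= 1 << a
    full = (1 << n) - 1
    best = n
    for mask in range(1, 1 << n):
        if mask.bit_count() >= best:
            continue
        dominated = 0
        for v in range(n):
            if mask >> v & 1:
                dominated |= closed[v]
        if dominated == full:
            best = mask.bit_count()
    return best
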