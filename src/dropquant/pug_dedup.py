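"""Parsimonious UMI graph (PUG) construction and arborescence covering.

Each vertex of the per-cell PUG is a (UMI, equivalence class) pair with its
read count.  A directed edge v_i -> v_j exists when c_i > 2*c_j - 1, the
transcript sets intersect, and the UMIs are at Hamming distance exactly 1
(the count condition marks v_j as a plausible PCR/sequencing error of v_i).
Pairs with intersecting transcript sets and Hamming distance <= 1 that carry
no directed edge get a single bi-directed edge; in particular, vertices
sharing a UMI but carrying different equivalence classes (reads of one
molecule fragmented at different positions) are joined at Hamming distance 0.
After edge formation the counts play no further role.

Deduplication covers the graph with vertex-disjoint monochromatic
arborescences: rooted trees whose vertices' transcript sets have a non-empty
intersection, each representing one pre-PCR molecule.  Minimising the number
of arborescences is NP-complete (it encodes minimum dominating set), so the
covering is computed greedily: per weakly connected component, repeatedly
pick the (vertex, transcript) pair whose colour-restricted BFS reaches the
most remaining vertices, emit that arborescence, delete it, and repeat.  An
exhaustive solver over vertex-set partitions is provided as a small-instance
oracle.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Optional, Sequence

BRUTE_FORCE_LIMIT = 12


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance undefined for unequal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class PUGVertex:
    umi: str
    transcripts: frozenset
    count: int


@dataclass
class PUG:
    """Vertices plus disjoint directed and bi-directed edge sets.

    ``directed`` holds ordered index pairs (i, j) for edges i -> j;
    ``bidirected`` holds unordered pairs stored as (min, max).
    """

    vertices: list[PUGVertex]
    directed: set[tuple[int, int]] = field(default_factory=set)
    bidirected: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for i, j in self.directed | self.bidirected:
            if i == j:
                raise ValueError("self edges are not allowed")
        dir_pairs = {tuple(sorted(e)) for e in self.directed}
        if dir_pairs & self.bidirected:
            raise ValueError("directed and bi-directed edge sets must be disjoint")

    def successors(self) -> list[set[int]]:
        """Traversal neighbours: directed edges forward, bi-directed both ways."""
        succ: list[set[int]] = [set() for _ in self.vertices]
        for i, j in self.directed:
            succ[i].add(j)
        for i, j in self.bidirected:
            succ[i].add(j)
            succ[j].add(i)
        return succ

    def undirected_neighbors(self) -> list[set[int]]:
        und: list[set[int]] = [set() for _ in self.vertices]
        for i, j in self.directed | self.bidirected:
            und[i].add(j)
            und[j].add(i)
        return und


def build_pug(cell_table: Mapping[tuple[str, tuple], int]) -> PUG:
    """Build the PUG for one cell from its (UMI, eqclass) -> read count table."""
    vertices: list[PUGVertex] = []
    seen = set()
    umi_len = None
    for (umi, eqclass), count in cell_table.items():
        if umi_len is None:
            umi_len = len(umi)
        elif len(umi) != umi_len:
            raise ValueError("inconsistent UMI lengths within a cell")
        if count < 1:
            raise ValueError("vertex counts must be >= 1")
        key = (umi, tuple(eqclass))
        if key in seen:
            raise ValueError(f"duplicate (UMI, eqclass) entry {key}")
        seen.add(key)
        vertices.append(PUGVertex(umi, frozenset(eqclass), int(count)))

    directed: set[tuple[int, int]] = set()
    bidirected: set[tuple[int, int]] = set()
    n = len(vertices)
    for i in range(n):
        vi = vertices[i]
        for j in range(i + 1, n):
            vj = vertices[j]
            if not (vi.transcripts & vj.transcripts):
                continue
            d = hamming(vi.umi, vj.umi)
            if d > 1:
                continue
            has_directed = False
            if d == 1:
                if vi.count > 2 * vj.count - 1:
                    directed.add((i, j))
                    has_directed = True
                if vj.count > 2 * vi.count - 1:
                    directed.add((j, i))
                    has_directed = True
            if not has_directed:
                bidirected.add((i, j))
    return PUG(vertices, directed, bidirected)


@dataclass(frozen=True)
class Arborescence:
    """One vertex-disjoint covering unit: a molecule candidate.

    ``feasible`` is the intersection of the transcript sets over its
    vertices; ``label`` is the transcript the greedy search grew it with.
    """

    root: int
    vertex_set: frozenset[int]
    feasible: frozenset
    label: Hashable


def _reach(
    start: int,
    transcript: Hashable,
    remaining: set[int],
    succ: Sequence[set[int]],
    vertices: Sequence[PUGVertex],
) -> set[int]:
    """Vertices reachable from ``start`` through ``transcript``-coloured nodes."""
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        for w in succ[v]:
            if w in remaining and w not in seen and transcript in vertices[w].transcripts:
                seen.add(w)
                stack.append(w)
    return seen


def _components(pug: PUG) -> list[list[int]]:
    und = pug.undirected_neighbors()
    seen: set[int] = set()
    comps: list[list[int]] = []
    for start in range(len(pug.vertices)):
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        stack = [start]
        while stack:
            v = stack.pop()
            for w in und[v]:
                if w not in seen:
                    seen.add(w)
                    comp.append(w)
                    stack.append(w)
        comps.append(sorted(comp))
    return comps  # already ordered by smallest contained vertex index


def greedy_cover(pug: PUG, tie_seed: Optional[int] = None) -> list[Arborescence]:
    """Greedy minimum-cardinality covering by monochromatic arborescences.

    Weakly connected components are processed independently in order of
    their smallest vertex index.  Within a component the (vertex, transcript)
    pair reaching the largest arborescence is selected, emitted and removed,
    until no vertices remain.  Ties are broken deterministically on the
    smallest (vertex index, transcript) pair; passing ``tie_seed`` switches
    to seeded random tie-breaking instead.
    """
    import numpy as _np

    rng = None if tie_seed is None else _np.random.default_rng(tie_seed)
    succ = pug.successors()
    vertices = pug.vertices
    covering: list[Arborescence] = []
    for comp in _components(pug):
        remaining = set(comp)
        while remaining:
            best_size = 0
            best: list[tuple[int, Hashable, set[int]]] = []
            for v in sorted(remaining):
                for t in sorted(vertices[v].transcripts, key=repr):
                    reach = _reach(v, t, remaining, succ, vertices)
                    if len(reach) > best_size:
                        best_size = len(reach)
                        best = [(v, t, reach)]
                    elif len(reach) == best_size and rng is not None:
                        best.append((v, t, reach))
            root, label, reach = (
                best[0] if rng is None else best[int(rng.integers(len(best)))]
            )
            feasible = frozenset.intersection(
                *(vertices[v].transcripts for v in reach)
            )
            covering.append(Arborescence(root, frozenset(reach), feasible, label))
            remaining -= reach
    return covering


def validate_covering(pug: PUG, covering: Sequence[Arborescence]) -> None:
    """Raise unless the covering is disjoint, complete, monochromatic and
    each arborescence is reachable from its root within its own vertex set."""
    all_vertices = set(range(len(pug.vertices)))
    seen: set[int] = set()
    succ = pug.successors()
    for arb in covering:
        if not arb.vertex_set:
            raise AssertionError("empty arborescence")
        if seen & arb.vertex_set:
            raise AssertionError("arborescences are not vertex-disjoint")
        seen |= arb.vertex_set
        feas = frozenset.intersection(
            *(pug.vertices[v].transcripts for v in arb.vertex_set)
        )
        if not feas:
            raise AssertionError("arborescence is not monochromatic")
        if feas != arb.feasible:
            raise AssertionError("stored feasible set is wrong")
        if arb.label not in feas:
            raise AssertionError("chosen label outside the feasible set")
        if arb.root not in arb.vertex_set:
            raise AssertionError("root outside the arborescence")
        reach = _reach(arb.root, arb.label, set(arb.vertex_set), succ, pug.vertices)
        if reach < arb.vertex_set:
            raise AssertionError("vertices unreachable from the root")
    if seen != all_vertices:
        raise AssertionError("covering does not include every vertex")


def brute_force_cover(pug: PUG) -> int:
    """Exact minimum covering cardinality by exhaustive subset partitioning.

    Guarded to small instances; this exists as an oracle for the greedy
    covering, not as a production path.
    """
    n = len(pug.vertices)
    if n > BRUTE_FORCE_LIMIT:
        raise ValueError(f"brute force limited to {BRUTE_FORCE_LIMIT} vertices")
    if n == 0:
        return 0
    succ = pug.successors()

    def reachable_within(root: int, mask: int) -> int:
        seen = 1 << root
        stack = [root]
        while stack:
            v = stack.pop()
            for w in succ[v]:
                bit = 1 << w
                if mask & bit and not seen & bit:
                    seen |= bit
                    stack.append(w)
        return seen

    # every vertex subset that forms a monochromatic arborescence
    feasible_by_vertex: list[list[int]] = [[] for _ in range(n)]
    for mask in range(1, 1 << n):
        members = [v for v in range(n) if mask >> v & 1]
        colors = frozenset.intersection(*(pug.vertices[v].transcripts for v in members))
        if not colors:
            continue
        if not any(reachable_within(r, mask) == mask for r in members):
            continue
        feasible_by_vertex[members[0]].append(mask)

    INF = n + 1
    f = [INF] * (1 << n)
    f[0] = 0
    for mask in range(1, 1 << n):
        v = (mask & -mask).bit_length() - 1
        best = INF
        for s in feasible_by_vertex[v]:
            if s & mask == s:
                cand = f[mask ^ s] + 1
                if cand < best:
                    best = cand
        f[mask] = best
    return f[(1 << n) - 1]


def label_arborescences(
    covering: Sequence[Arborescence], t2g: Mapping[str, str]
) -> tuple[Counter, list[frozenset]]:
    """Resolve each arborescence to a gene or to an ambiguous gene set.

    An arborescence whose feasible transcripts all belong to one gene adds
    one molecule to that gene; otherwise its gene set joins the ambiguous
    list for the EM to distribute.
    """
    unique: Counter = Counter()
    ambiguous: list[frozenset] = []
    for arb in covering:
        if not arb.feasible:
            raise RuntimeError("covering violates the monochromaticity invariant")
        genes = frozenset(t2g[t] for t in arb.feasible)
        if len(genes) == 1:
            unique[next(iter(genes))] += 1
        else:
            ambiguous.append(genes)
    return unique, ambiguous


def dominating_set_pug(n: int, edges: Iterable[tuple[int, int]]) -> PUG:
    """Encode an undirected graph as a PUG whose minimum monochromatic-
    arborescence covering equals the graph's minimum dominating set size.

    Every edge becomes bi-directed and each node is labelled with itself plus
    its neighbours (closed neighbourhood), so an arborescence coloured ``i``
    can cover exactly the vertices node ``i`` dominates.
    """
    labels = [{i} for i in range(n)]
    bidirected = set()
    for a, b in edges:
        if a == b:
            continue
        labels[a].add(b)
        labels[b].add(a)
        bidirected.add((min(a, b), max(a, b)))
    vertices = [PUGVertex(umi=f"v{i}", transcripts=frozenset(labels[i]), count=1) for i in range(n)]
    return PUG(vertices, set(), bidirected)


def pug_to_dot(pug: PUG) -> str:
    """Render a PUG in DOT format for debugging."""
    lines = ["digraph pug {"]
    for i, v in enumerate(pug.vertices):
        txs = ",".join(sorted(map(str, v.transcripts)))
        lines.append(f'  n{i} [label="{v.umi}\\n{{{txs}}}\\nc={v.count}"];')
    for i, j in sorted(pug.directed):
        lines.append(f"  n{i} -> n{j};")
    for i, j in sorted(pug.bidirected):
        lines.append(f"  n{i} -> n{j} [dir=both];")
    lines.append("}")
    return "\n".join(lines)
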