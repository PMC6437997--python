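"""EM resolution of gene-ambiguous molecules, tier assignment and bootstraps.

Each ambiguous arborescence contributes one molecule that may belong to any
gene in its feasible set.  The EM distributes these molecules across genes
proportionally to current abundances (a plain multinomial model: tagged-end
protocols have no fragment-length effect, so abundance is not divided by an
effective length).  Tiers grade the evidence behind each per-gene count:
0 = no reads, 1 = only single-gene classes, 2 = ambiguous but connected to
unique evidence through the equivalence-class graph, 3 = fully ambiguous.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .pug_dedup import build_pug, greedy_cover, label_arborescences

DEFAULT_TOL = 1e-3
DEFAULT_MAX_ITER = 1000


def em_log_likelihood(
    abundances: Mapping[str, float],
    unique_counts: Mapping[str, float],
    ambiguous: Sequence[frozenset],
) -> float:
    """Multinomial log-likelihood of the molecule assignments under the
    normalized abundances (uniquely assigned molecules plus one term per
    ambiguous molecule)."""
    total = sum(abundances.values())
    if total <= 0:
        return 0.0
    ll = 0.0
    for gene, c in unique_counts.items():
        if c > 0:
            ll += c * np.log(abundances[gene] / total)
    for genes in ambiguous:
        p = sum(abundances[g] for g in genes) / total
        ll += np.log(p) if p > 0 else -np.inf
    return float(ll)


def em_resolve(
    unique_counts: Mapping[str, float],
    ambiguous: Sequence[frozenset | set],
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    return_history: bool = False,
):
    """Distribute ambiguous molecules across their gene sets by EM.

    E-step: each ambiguous molecule is split across its genes proportionally
    to the current abundances (uniformly when every gene in the set is at
    zero).  M-step: abundance = unique count + assigned fractions.  Stops
    when the largest absolute count change drops below ``tol``.
    """
    ambiguous = [frozenset(s) for s in ambiguous]
    for s in ambiguous:
        if not s:
            raise ValueError("ambiguous molecule with empty gene set")
    genes = sorted(set(unique_counts) | set().union(*ambiguous) if ambiguous else set(unique_counts))
    gene_idx = {g: i for i, g in enumerate(genes)}
    u = np.array([float(unique_counts.get(g, 0.0)) for g in genes])
    if np.any(u < 0):
        raise ValueError("unique counts must be non-negative")
    groups = [np.array([gene_idx[g] for g in sorted(s)]) for s in ambiguous]

    alpha = u.copy()
    history: list[float] = []
    if not groups:
        result = dict(zip(genes, alpha))
        return (result, history) if return_history else result

    for _ in range(max_iter):
        assigned = np.zeros_like(alpha)
        for idx in groups:
            w = alpha[idx]
            s = w.sum()
            if s > 0:
                assigned[idx] += w / s
            else:
                assigned[idx] += 1.0 / len(idx)
        new = u + assigned
        delta = float(np.max(np.abs(new - alpha)))
        alpha = new
        if return_history:
            history.append(
                em_log_likelihood(dict(zip(genes, alpha)), dict(zip(genes, u)), ambiguous)
            )
        if delta < tol:
            break
    result = dict(zip(genes, alpha))
    return (result, history) if return_history else result


def assign_tiers(
    class_counts: Mapping[tuple, int],
    t2g: Mapping[str, str],
    genes: Iterable[str],
) -> dict[str, int]:
    """Per-gene evidence tiers for one cell.

    ``class_counts`` maps each observed equivalence class (transcript tuple)
    to its read count.  Class "size" is measured in genes: a class whose
    transcripts all belong to one gene is unique evidence for that gene.
    """
    tiers = {g: 0 for g in genes}
    tier1_marked: set[str] = set()
    graph = nx.Graph()
    for eqclass, count in class_counts.items():
        if count <= 0:
            continue
        class_genes = {t2g[t] for t in eqclass}
        if len(class_genes) == 1:
            tier1_marked.add(next(iter(class_genes)))
        else:
            txs = sorted(eqclass)
            graph.add_nodes_from(txs)
            for a, b in zip(txs, txs[1:]):
                graph.add_edge(a, b)  # a path connects the class's clique
    for g in tier1_marked:
        tiers[g] = 1
    for comp in nx.connected_components(graph):
        comp_genes = {t2g[t] for t in comp}
        if comp_genes & tier1_marked:
            for g in comp_genes:
                tiers[g] = 2
        else:
            for g in comp_genes:
                if tiers[g] == 0:
                    tiers[g] = 3
    return tiers


def quantify_cell(
    cell_table: Mapping[tuple[str, tuple], int],
    t2g: Mapping[str, str],
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[dict[str, float], list[frozenset]]:
    """Deduplicate one cell and resolve ambiguous molecules.

    Runs the full per-cell chain (PUG construction, greedy covering, gene
    labelling, EM) and returns the per-gene molecule counts along with the
    ambiguous gene sets that the EM distributed.
    """
    if not cell_table:
        return {}, []
    pug = build_pug(cell_table)
    covering = greedy_cover(pug)
    unique, ambiguous = label_arborescences(covering, t2g)
    counts = em_resolve(unique, ambiguous, tol=tol, max_iter=max_iter)
    return counts, ambiguous


def bootstrap_variance(
    cell_table: Mapping[tuple[str, tuple], int],
    t2g: Mapping[str, str],
    n_boot: int,
    seed: int = 0,
) -> dict[str, float]:
    """Per-gene variance of counts under multinomial read resampling.

    Reads are resampled over the cell's (UMI, eqclass) records with the
    total preserved, and the whole deduplication chain is rerun per
    replicate, so UMI-error edge structure can change across replicates.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    keys = list(cell_table)
    counts = np.array([cell_table[k] for k in keys], dtype=float)
    total = int(counts.sum())
    probs = counts / counts.sum()
    gene_rows: list[dict[str, float]] = []
    for _ in range(n_boot):
        resampled = rng.multinomial(total, probs)
        table = {k: int(c) for k, c in zip(keys, resampled) if c > 0}
        est, _ = quantify_cell(table, t2g)
        gene_rows.append(est)
    genes = sorted(set().union(*gene_rows)) if gene_rows else []
    variances: dict[str, float] = {}
    for g in genes:
        vals = np.array([row.get(g, 0.0) for row in gene_rows])
        variances[g] = float(vals.var(ddof=1))
    return variances
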