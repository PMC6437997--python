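"""Stranded k-mer transcript assignment and the gene-uniqueness statistic.

Tagged-end droplet protocols are stranded, so a read cannot multimap to a
gene through the reverse complement of its sequence; the index therefore
stores forward-strand (non-canonical) k-mers only.  A read's equivalence
class is the intersection of the indexed transcript sets over its k-mers,
accepted only when at least a fraction ``tau`` of the read's k-mers are
present in the index.  This intersection-with-coverage rule approximates
pseudoalignment and is adequate for synthetic reads drawn verbatim from the
transcriptome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

DEFAULT_K = 31
DEFAULT_TAU = 0.8

_VALID = frozenset("ACGT")


def _kmers(seq: str, k: int) -> list[str]:
    """All positional k-mers of ``seq`` over {A,C,G,T}; others skipped."""
    out = []
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if _VALID.issuperset(km):
            out.append(km)
    return out


@dataclass
class KmerIndex:
    k: int
    kmer_to_tx: dict[str, frozenset[str]]
    t2g: dict[str, str]
    transcripts: tuple[str, ...]
    collapsed: dict[str, str] = field(default_factory=dict)
    """Duplicate transcript id -> retained representative (when collapsing)."""


def build_index(
    transcriptome: Sequence[tuple[str, str]],
    t2g: dict[str, str],
    k: int = DEFAULT_K,
    keep_duplicates: bool = True,
) -> KmerIndex:
    """Index every forward k-mer of the transcriptome.

    With ``keep_duplicates=False``, sequence-identical transcripts are
    collapsed to a single representative and the collapse is recorded in
    ``KmerIndex.collapsed``; with the flag on, every identical transcript id
    is retained in the k-mer sets.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ids = [tid for tid, _ in transcriptome]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate transcript ids in transcriptome")
    missing = [tid for tid in ids if tid not in t2g]
    if missing:
        raise ValueError(f"transcripts missing from t2g map: {missing[:5]}")

    collapsed: dict[str, str] = {}
    kept: list[tuple[str, str]] = []
    if keep_duplicates:
        kept = list(transcriptome)
    else:
        by_seq: dict[str, str] = {}
        for tid, seq in transcriptome:
            rep = by_seq.get(seq)
            if rep is None:
                by_seq[seq] = tid
                kept.append((tid, seq))
            else:
                collapsed[tid] = rep

    index: dict[str, set[str]] = {}
    for tid, seq in kept:
        if len(seq) < k:
            warnings.warn(f"transcript {tid!r} shorter than k={k}; skipped")
            continue
        for km in _kmers(seq, k):
            index.setdefault(km, set()).add(tid)
    if keep_duplicates:
        # identical transcripts share every k-mer, so each other's id must
        # appear in all of its sets; the plain loop above already ensures it.
        pass
    frozen = {km: frozenset(txs) for km, txs in index.items()}
    return KmerIndex(k, frozen, dict(t2g), tuple(ids), collapsed)


def map_read(
    cdna: str, index: KmerIndex, tau: float = DEFAULT_TAU
) -> Optional[tuple[str, ...]]:
    """Equivalence class of a read, or ``None`` when it fails to map.

    The class is the intersection of transcript sets over the read's indexed
    k-mers; reads where fewer than ``tau`` of the valid k-mers hit the index,
    or whose intersection is empty, are unmapped.
    """
    kms = _kmers(cdna.upper(), index.k)
    if not kms:
        return None
    hits = [index.kmer_to_tx[km] for km in kms if km in index.kmer_to_tx]
    if len(hits) < tau * len(kms) or not hits:
        return None
    eqclass = frozenset.intersection(*hits)
    if not eqclass:
        return None
    return tuple(sorted(eqclass))


def gene_uniqueness(
    transcriptome: Sequence[tuple[str, str]],
    t2g: dict[str, str],
    k: int = DEFAULT_K,
) -> dict[str, float]:
    """Per gene, the fraction of its distinct forward k-mers found in no
    other gene.

    Computed on non-canonicalized k-mers (stranded protocols).  Genes with
    no valid k-mer are omitted from the result.
    """
    gene_kmers: dict[str, set[str]] = {}
    for tid, seq in transcriptome:
        gene = t2g[tid]
        gene_kmers.setdefault(gene, set()).update(_kmers(seq, k))
    owners: dict[str, int] = {}
    for gene, kms in gene_kmers.items():
        for km in kms:
            owners[km] = owners.get(km, 0) + 1
    result: dict[str, float] = {}
    for gene, kms in gene_kmers.items():
        if not kms:
            continue
        unique = sum(1 for km in kms if owners[km] == 1)
        result[gene] = unique / len(kms)
    return result
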