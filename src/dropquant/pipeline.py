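"""End-to-end quantification: whitelisting, correction, mapping, UMI-graph
deduplication, EM, tiers and final whitelisting, in pipeline order."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .em_tiers import assign_tiers, bootstrap_variance, quantify_cell
from .io_formats import (
    BarcodeGeometry,
    QuantOutput,
    read_fasta,
    read_fastq_pairs,
    read_t2g,
    read_whitelist,
    write_eqclasses,
    write_quant,
    write_whitelist,
)
from .pseudo_mapper import DEFAULT_K, DEFAULT_TAU, build_index, map_read
from .pug_dedup import build_pug, pug_to_dot
from .whitelist_final import CellProfile, RegionSplit, final_whitelist, split_regions
from .whitelist_initial import WhitelistPartition, correct_barcodes, find_knee, tally_barcodes

logger = logging.getLogger(__name__)


@dataclass
class RunResult:
    quant: QuantOutput
    final_whitelist: set[str]
    manifest: dict
    cell_tables: dict[str, dict[tuple[str, tuple[str, ...]], int]]


def _read_gene_list(path: str | os.PathLike) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def _md5(path: str | os.PathLike) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_quant(
    read1: str | os.PathLike,
    read2: str | os.PathLike,
    transcriptome: str | os.PathLike,
    t2g: str | os.PathLike,
    out_dir: Optional[str | os.PathLike] = None,
    *,
    geometry: Optional[BarcodeGeometry] = None,
    k: int = DEFAULT_K,
    tau: float = DEFAULT_TAU,
    keep_duplicates: bool = True,
    whitelist: Optional[str | os.PathLike] = None,
    seed: int = 0,
    num_cell_bootstraps: int = 0,
    mrna: Optional[str | os.PathLike] = None,
    rrna: Optional[str | os.PathLike] = None,
    use_correlation: bool = False,
    dump_eqclasses: bool = False,
    dump_pug: bool = False,
) -> RunResult:
    """Quantify a demultiplexed FASTQ pair against a transcriptome.

    With ``whitelist`` given, the provided barcodes are used as the fixed
    final whitelist: the knee search and the final classification are both
    skipped (erroneous barcodes are still corrected toward the whitelist).
    """
    geometry = geometry or BarcodeGeometry()
    t2g_map = read_t2g(t2g)
    transcripts = read_fasta(transcriptome)
    genes = sorted(set(t2g_map.values()))
    index = build_index(transcripts, t2g_map, k=k, keep_duplicates=keep_duplicates)

    reads = []
    n_in = 0
    n_flagged = 0
    for rec in read_fastq_pairs(read1, read2, geometry):
        n_in += 1
        if rec.has_n:  # N in CB or UMI: neither knee nor correction is defined over N
            n_flagged += 1
            continue
        reads.append(rec)
    if not reads:
        raise ValueError("no usable reads after filtering ambiguous barcodes")
    tally = tally_barcodes(r.cb for r in reads)

    external = whitelist is not None
    if external:
        fixed = read_whitelist(whitelist)
        observed_w = fixed & set(tally)
        partition = WhitelistPartition(
            whitelist=observed_w, erroneous=set(tally) - observed_w, threshold=float("nan")
        )
    else:
        partition = find_knee(tally)
    correction = correct_barcodes(partition, seed=seed)
    label_of = {w: w for w in partition.whitelist}
    label_of.update({h: w for h, (w, _kind) in correction.assignments.items()})

    split: Optional[RegionSplit] = None
    low_set: set[str] = set()
    if not external:
        corrected = set(correction.assignments)
        split = split_regions(tally, partition.threshold, exclude_low=corrected)
        low_set = set(split.low)

    cell_tables: dict[str, dict[tuple[str, tuple[str, ...]], int]] = defaultdict(
        lambda: defaultdict(int)
    )
    reads_total: dict[str, int] = defaultdict(int)
    reads_mapped: dict[str, int] = defaultdict(int)
    n_mapped = 0
    for rec in reads:
        assigned = label_of.get(rec.cb)
        if assigned is None:
            if rec.cb in low_set:  # retained only to train the final classifier
                assigned = rec.cb
            else:
                continue
        reads_total[assigned] += 1
        eqclass = map_read(rec.cdna, index, tau=tau)
        if eqclass is None:
            continue
        reads_mapped[assigned] += 1
        n_mapped += 1
        cell_tables[assigned][(rec.umi, eqclass)] += 1

    quant_barcodes = sorted(b for b in partition.whitelist if reads_total.get(b, 0) > 0)
    gene_idx = {g: i for i, g in enumerate(genes)}
    counts = np.zeros((len(quant_barcodes), len(genes)))
    tiers = np.zeros((len(quant_barcodes), len(genes)), dtype=int)
    variance = (
        np.zeros((len(quant_barcodes), len(genes))) if num_cell_bootstraps >= 2 else None
    )
    profiles: dict[str, CellProfile] = {}
    n_molecules = 0.0
    for row, cb in enumerate(quant_barcodes):
        table = cell_tables.get(cb, {})
        cell_counts, _amb = quantify_cell(table, t2g_map)
        class_counts: dict[tuple, int] = defaultdict(int)
        for (_umi, eqclass), c in table.items():
            class_counts[eqclass] += c
        cell_tiers = assign_tiers(class_counts, t2g_map, genes)
        for g, c in cell_counts.items():
            counts[row, gene_idx[g]] = c
        for g, t in cell_tiers.items():
            tiers[row, gene_idx[g]] = t
        if variance is not None and table:
            for g, v in bootstrap_variance(
                table, t2g_map, num_cell_bootstraps, seed=seed + row
            ).items():
                variance[row, gene_idx[g]] = v
        n_molecules += sum(cell_counts.values())
        profiles[cb] = CellProfile(reads_total[cb], reads_mapped[cb], cell_counts)

    if external:
        final = set(read_whitelist(whitelist))
    else:
        assert split is not None
        for cb in low_set:
            table = cell_tables.get(cb, {})
            cell_counts, _ = quantify_cell(table, t2g_map)
            profiles[cb] = CellProfile(
                reads_total.get(cb, 0), reads_mapped.get(cb, 0), cell_counts
            )
        mito_genes = _read_gene_list(mrna) if mrna else None
        rrna_genes = _read_gene_list(rrna) if rrna else None
        final = final_whitelist(
            split,
            profiles,
            mito_genes=mito_genes,
            rrna_genes=rrna_genes,
            use_correlation=use_correlation,
        )

    quant = QuantOutput(quant_barcodes, genes, counts, tiers, variance)
    manifest = {
        "parameters": {
            "k": k,
            "tau": tau,
            "keep_duplicates": keep_duplicates,
            "seed": seed,
            "num_cell_bootstraps": num_cell_bootstraps,
            "use_correlation": use_correlation,
            "external_whitelist": external,
            "cb_length": geometry.cb_length,
            "umi_length": geometry.umi_length,
        },
        "inputs": {
            "read1_md5": _md5(read1),
            "read2_md5": _md5(read2),
            "transcriptome_md5": _md5(transcriptome),
            "t2g_md5": _md5(t2g),
        },
        "counts": {
            "reads_in": n_in,
            "reads_flagged_n": n_flagged,
            "reads_assigned": int(sum(reads_total.values())),
            "reads_mapped": n_mapped,
            "barcodes_observed": len(tally),
            "whitelist_initial_size": len(partition.whitelist),
            "knee_threshold": None if external else partition.threshold,
            "cells_quantified": len(quant_barcodes),
            "molecules_total": n_molecules,
            "final_whitelist_size": len(final),
        },
    }

    if out_dir is not None:
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        write_quant(out_dir, quant)
        write_whitelist(os.path.join(out_dir, "whitelist.txt"), final)
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
        if dump_eqclasses:
            write_eqclasses(
                os.path.join(out_dir, "eqclasses.tsv"),
                {cb: dict(cell_tables[cb]) for cb in quant_barcodes},
            )
        if dump_pug:
            pug_dir = os.path.join(out_dir, "pugs")
            os.makedirs(pug_dir, exist_ok=True)
            for cb in quant_barcodes:
                dot = pug_to_dot(build_pug(cell_tables[cb]))
                with open(os.path.join(pug_dir, f"{cb}.dot"), "w") as fh:
                    fh.write(dot)

    return RunResult(quant, final, manifest, {cb: dict(t) for cb, t in cell_tables.items()})
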