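"""Droplet scRNA-seq simulator with full ground truth.

The generator emulates the data-generating process of tagged-end droplet
protocols: per-cell gene abundance profiles, pre-PCR molecules tagged with
uniformly drawn UMIs (collisions possible), whole-molecule PCR amplification
*before* fragmentation with per-base per-cycle barcode/UMI errors inherited
along the copy tree, 3'-biased fragmentation with a Gaussian fragment-length
distribution, sequencing errors, and ambient barcodes emitting low-count
reads from the library-wide mean abundance profile.  Every emitted read
traces to exactly one pre-PCR molecule in the ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io_formats

_BASES = np.array(list("ACGT"))
_OTHER = {b: [o for o in "ACGT" if o != b] for b in "ACGT"}


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment.

    Rates are probabilities per base (per cycle, for the PCR error rate);
    ``pcr_dup_prob`` is the per-copy duplication probability per cycle and
    ``read_sampling_rate`` the probability that an amplified copy is
    sequenced.  ``sharing_fractions`` builds one gene pair per entry whose
    sequences share that fraction of their 3' ends (creating multi-gene
    equivalence classes); ``isoform_overlap`` is the fraction of the gene
    body that the shortest 3' isoform retains.
    """

    seed: int = 0
    n_cells: int = 50
    n_ambient_barcodes: int = 500
    n_genes: int = 100
    transcripts_per_gene: int = 1
    transcript_length: int = 300
    sharing_fractions: tuple[float, ...] = ()
    isoform_overlap: float = 0.5
    cb_length: int = 16
    umi_length: int = 10
    mean_molecules_per_cell: float = 100.0
    profile_dispersion: float = 1.0
    pcr_cycles: int = 2
    pcr_dup_prob: float = 0.5
    pcr_error_rate: float = 0.0
    seq_error_rate: float = 0.0
    fragment_length_mean: float = 150.0
    fragment_length_sd: float = 20.0
    three_prime_bias: float = 0.8
    read_length: int = 100
    read_sampling_rate: float = 0.5
    ambient_mean_reads: float = 5.0

    def validate(self) -> None:
        for name in ("pcr_dup_prob", "pcr_error_rate", "seq_error_rate",
                     "three_prime_bias", "isoform_overlap", "read_sampling_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_cells", "n_genes", "transcripts_per_gene",
                     "transcript_length", "cb_length", "umi_length",
                     "read_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for s in self.sharing_fractions:
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"infeasible sharing fraction {s}")
        if 2 * len(self.sharing_fractions) > self.n_genes:
            raise ValueError("more shared gene pairs than genes")


@dataclass
class GroundTruth:
    """True pre-PCR molecule counts plus per-read and per-molecule traces."""

    counts: pd.DataFrame  # cells x genes, true pre-PCR molecules
    reads: pd.DataFrame  # read_id, barcode, molecule, transcript, gene, is_cell
    molecules: pd.DataFrame  # molecule, barcode, gene, transcript, umi
    whitelist: list[str]


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hits) == 0:
        return seq
    chars = list(seq)
    for i in hits:
        chars[i] = _OTHER[chars[i]][rng.integers(3)]
    return "".join(chars)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def simulate_transcriptome(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Generate a transcriptome with controllable inter-gene sharing.

    Genes 2p and 2p+1 share the 3'-most ``sharing_fractions[p]`` of their
    sequence (verbatim), so reads from the shared block produce multi-gene
    equivalence classes.  Within a gene, isoform j is a 3' suffix of isoform
    0, producing multi-transcript single-gene classes.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    L = config.transcript_length
    gene_seqs: list[str] = [""] * config.n_genes
    for p, s in enumerate(config.sharing_fractions):
        shared_len = round(s * L)
        shared = _rand_seq(rng, shared_len)
        gene_seqs[2 * p] = _rand_seq(rng, L - shared_len) + shared
        gene_seqs[2 * p + 1] = _rand_seq(rng, L - shared_len) + shared
    for g in range(2 * len(config.sharing_fractions), config.n_genes):
        gene_seqs[g] = _rand_seq(rng, L)

    records: list[tuple[str, str]] = []
    t2g: dict[str, str] = {}
    tpg = config.transcripts_per_gene
    for g, seq in enumerate(gene_seqs):
        gene = f"gene_{g:04d}"
        for j in range(tpg):
            if j == 0 or tpg == 1:
                iso = seq
            else:
                frac = 1.0 - (1.0 - config.isoform_overlap) * j / (tpg - 1)
                iso = seq[-max(1, int(L * frac)) :]
            tid = f"{gene}_t{j}"
            records.append((tid, iso))
            t2g[tid] = gene
    return records, t2g


def _draw_barcodes(
    rng: np.random.Generator, n: int, length: int, min_distance: int = 3,
    avoid: Sequence[str] = (),
) -> list[str]:
    out: list[str] = []
    taken = set(avoid)
    while len(out) < n:
        cand = _rand_seq(rng, length)
        if cand in taken:
            continue
        if min_distance > 1 and any(_hamming(cand, b) < min_distance for b in out):
            continue
        out.append(cand)
        taken.add(cand)
    return out


def _amplify(
    rng: np.random.Generator, cb: str, umi: str, cycles: int, dup_prob: float,
    error_rate: float,
) -> list[tuple[str, str]]:
    """Whole-molecule PCR: each copy duplicates per cycle with ``dup_prob``;
    new copies inherit their parent's barcode/UMI including earlier errors."""
    copies = [(cb, umi)]
    for _ in range(cycles):
        for idx in range(len(copies)):
            if rng.random() < dup_prob:
                c_cb, c_umi = copies[idx]
                copies.append(
                    (_mutate(rng, c_cb, error_rate), _mutate(rng, c_umi, error_rate))
                )
    return copies


def _fragment_read(
    rng: np.random.Generator, seq: str, config: SimConfig
) -> str:
    """One read from a 3'-biased fragment of the transcript."""
    tlen = len(seq)
    fl = int(np.clip(rng.normal(config.fragment_length_mean, config.fragment_length_sd),
                     1, tlen))
    max_offset = tlen - fl
    scale = (1.0 - config.three_prime_bias) * tlen
    offset = min(int(rng.exponential(scale)) if scale > 0 else 0, max_offset)
    end = tlen - offset
    start = end - fl
    return seq[start : start + min(config.read_length, fl)]


def simulate_reads(
    config: SimConfig,
    transcriptome: Sequence[tuple[str, str]],
    t2g: dict[str, str],
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], GroundTruth]:
    """Emit read-1/read-2 records plus the ground truth for the experiment."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    seqs = dict(transcriptome)
    genes = sorted({t2g[t] for t, _ in transcriptome})
    gene_txs = {g: [] for g in genes}
    for tid, _ in transcriptome:
        gene_txs[t2g[tid]].append(tid)

    cells = _draw_barcodes(rng, config.n_cells, config.cb_length, min_distance=3)
    weights = rng.lognormal(0.0, config.profile_dispersion, (config.n_cells, len(genes)))
    profiles = weights / weights.sum(axis=1, keepdims=True)

    r1: list[tuple[str, str]] = []
    r2: list[tuple[str, str]] = []
    counts = np.zeros((config.n_cells, len(genes)), dtype=int)
    read_rows: list[tuple] = []
    mol_rows: list[tuple] = []
    read_no = 0
    mol_no = 0
    for ci, cb in enumerate(cells):
        n_mol = rng.poisson(config.mean_molecules_per_cell)
        gene_draws = rng.choice(len(genes), size=n_mol, p=profiles[ci])
        for gi in gene_draws:
            gene = genes[gi]
            txs = gene_txs[gene]
            tid = txs[rng.integers(len(txs))] if len(txs) > 1 else txs[0]
            umi = _rand_seq(rng, config.umi_length)
            counts[ci, gi] += 1
            mol_id = mol_no
            mol_no += 1
            mol_rows.append((mol_id, cb, gene, tid, umi))
            copies = _amplify(rng, cb, umi, config.pcr_cycles,
                              config.pcr_dup_prob, config.pcr_error_rate)
            for c_cb, c_umi in copies:
                if rng.random() >= config.read_sampling_rate:
                    continue
                cdna = _fragment_read(rng, seqs[tid], config)
                name = f"read_{read_no:08d}"
                read_no += 1
                r1.append((name, _mutate(rng, c_cb + c_umi, config.seq_error_rate)))
                r2.append((name, _mutate(rng, cdna, config.seq_error_rate)))
                read_rows.append((name, cb, mol_id, tid, gene, True))

    # ambient (empty-droplet) barcodes draw from the pooled profile
    pooled = profiles.mean(axis=0)
    ambient = _draw_barcodes(rng, config.n_ambient_barcodes, config.cb_length,
                             min_distance=1, avoid=cells)
    for ab in ambient:
        n_reads = int(rng.geometric(1.0 / max(config.ambient_mean_reads, 1.0)))
        for _ in range(n_reads):
            gi = int(rng.choice(len(genes), p=pooled))
            gene = genes[gi]
            txs = gene_txs[gene]
            tid = txs[rng.integers(len(txs))] if len(txs) > 1 else txs[0]
            umi = _rand_seq(rng, config.umi_length)
            mol_id = mol_no
            mol_no += 1
            mol_rows.append((mol_id, ab, gene, tid, umi))
            cdna = _fragment_read(rng, seqs[tid], config)
            name = f"read_{read_no:08d}"
            read_no += 1
            r1.append((name, _mutate(rng, ab + umi, config.seq_error_rate)))
            r2.append((name, _mutate(rng, cdna, config.seq_error_rate)))
            read_rows.append((name, ab, mol_id, tid, gene, False))

    truth = GroundTruth(
        counts=pd.DataFrame(counts, index=cells, columns=genes),
        reads=pd.DataFrame(
            read_rows,
            columns=["read_id", "barcode", "molecule", "transcript", "gene", "is_cell"],
        ),
        molecules=pd.DataFrame(
            mol_rows, columns=["molecule", "barcode", "gene", "transcript", "umi"]
        ),
        whitelist=list(cells),
    )
    return r1, r2, truth


@dataclass
class SimPaths:
    read1: str
    read2: str
    transcriptome: str
    t2g: str
    truth_counts: str
    truth_reads: str
    truth_whitelist: str
    manifest: str


def simulate_experiment(
    config: SimConfig, out_dir: str | os.PathLike
) -> tuple[SimPaths, GroundTruth]:
    """Run the full simulation and write FASTQ, FASTA, t2g, truth tables and
    a JSON manifest recording the configuration (seed included)."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    transcriptome, t2g = simulate_transcriptome(config, rng)
    r1, r2, truth = simulate_reads(config, transcriptome, t2g, rng)
    paths = SimPaths(
        read1=os.path.join(out_dir, "reads_1.fastq"),
        read2=os.path.join(out_dir, "reads_2.fastq"),
        transcriptome=os.path.join(out_dir, "transcriptome.fa"),
        t2g=os.path.join(out_dir, "t2g.tsv"),
        truth_counts=os.path.join(out_dir, "truth_counts.tsv"),
        truth_reads=os.path.join(out_dir, "truth_reads.tsv"),
        truth_whitelist=os.path.join(out_dir, "truth_whitelist.txt"),
        manifest=os.path.join(out_dir, "sim_manifest.json"),
    )
    io_formats.write_fastq(paths.read1, r1)
    io_formats.write_fastq(paths.read2, r2)
    io_formats.write_fasta(paths.transcriptome, transcriptome)
    io_formats.write_t2g(paths.t2g, t2g)
    truth.counts.to_csv(paths.truth_counts, sep="\t")
    truth.reads.to_csv(paths.truth_reads, sep="\t", index=False)
    with open(paths.truth_whitelist, "w") as fh:
        fh.writelines(b + "\n" for b in truth.whitelist)
    manifest = dataclasses.asdict(config)
    with open(paths.manifest, "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
    return paths, truth
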