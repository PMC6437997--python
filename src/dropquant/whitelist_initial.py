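"""Initial cell-barcode whitelisting and one-edit barcode correction.

The observed barcode tally is split at the "knee" of the barcode frequency
distribution: a Gaussian KDE is fitted to log10 read counts and the
threshold is placed at the largest local minimum of the density below the
mode of the high-count component.  Barcodes at or above the threshold form
the (deliberately liberal) initial whitelist W; everything else is the
erroneous set E.  Each erroneous barcode is then corrected to a whitelisted
barcode from which it is reachable by a single substitution, a single
insertion (clipping the terminal base) or a single deletion (appending a
base), with substitutions taking priority and remaining ties broken by a
seeded RNG.  Barcodes with no one-edit label are noise and are discarded.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import gaussian_kde

ALPHABET = "ACGT"

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"


def tally_barcodes(barcodes: Iterable[str]) -> Counter:
    """Count every observed barcode, errors included."""
    tally = Counter(barcodes)
    if not tally:
        raise ValueError("no barcodes observed; nothing to whitelist")
    if len({len(b) for b in tally}) != 1:
        raise ValueError("observed barcodes have mixed lengths")
    return tally


@dataclass
class WhitelistPartition:
    """The observed barcodes split into whitelist W and erroneous set E."""

    whitelist: set[str]
    erroneous: set[str]
    threshold: float

    def __post_init__(self) -> None:
        if self.whitelist & self.erroneous:
            raise ValueError("whitelist and erroneous sets overlap")


def _fallback_threshold(counts: np.ndarray) -> float:
    # Unimodal / degenerate tallies have no interior density minimum; keep
    # everything within two orders of magnitude of the deepest barcode, but
    # never exclude the deepest barcode itself.
    cmax = float(counts.max())
    return min(max(10.0, 0.01 * cmax), cmax)


def find_knee(tally: Mapping[str, int], grid_size: int = 512) -> WhitelistPartition:
    """Locate the knee of the barcode frequency distribution.

    Fits a Gaussian KDE (Scott's-rule bandwidth) to log10 counts over the
    distinct barcodes.  The threshold is the count at the largest local
    minimum of the density below the mode of the high-count component; when
    the density has no usable interior minimum the fallback threshold
    min(max(10, 0.01 * max count), max count) is used instead.
    """
    if not tally:
        raise ValueError("empty tally")
    counts = np.asarray(list(tally.values()), dtype=float)
    threshold = None
    if len(counts) > 2 and np.ptp(counts) > 0:
        logc = np.log10(counts)
        try:
            kde = gaussian_kde(logc)
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate spread
            kde = None
        if kde is not None:
            pad = 0.25
            grid = np.linspace(logc.min() - pad, logc.max() + pad, grid_size)
            dens = kde(grid)
            d = np.diff(dens)
            # interior local maxima / minima via slope sign changes
            maxima = [i + 1 for i in range(len(d) - 1) if d[i] > 0 and d[i + 1] <= 0]
            minima = [i + 1 for i in range(len(d) - 1) if d[i] < 0 and d[i + 1] >= 0]
            if maxima and minima:
                high_mode = maxima[-1]
                below = [i for i in minima if i < high_mode]
                if below:
                    threshold = float(10 ** grid[max(below)])
    if threshold is None:
        threshold = _fallback_threshold(counts)
    whitelist = {b for b, c in tally.items() if c >= threshold}
    if not whitelist:  # the minimum sits above every barcode; fall back
        threshold = _fallback_threshold(counts)
        whitelist = {b for b, c in tally.items() if c >= threshold}
    erroneous = set(tally) - whitelist
    return WhitelistPartition(whitelist, erroneous, threshold)


def _substitution_neighbors(w: str) -> set[str]:
    out = set()
    for i, base in enumerate(w):
        for b in ALPHABET:
            if b != base:
                out.add(w[: i] + b + w[i + 1 :])
    return out


def _insertion_neighbors(w: str) -> set[str]:
    # insert one base before position i, then clip the terminal base
    n = len(w)
    out = set()
    for i in range(n):
        for b in ALPHABET:
            out.add(w[:i] + b + w[i : n - 1])
    out.discard(w)
    return out


def _deletion_neighbors(w: str) -> set[str]:
    # delete position i, then append a valid base at the end
    out = set()
    for i in range(len(w)):
        for b in ALPHABET:
            out.add(w[:i] + w[i + 1 :] + b)
    out.discard(w)
    return out


def one_edit_neighbors(w: str) -> set[str]:
    """All same-length barcodes reachable from ``w`` by one edit.

    The three edit families are substitution, insertion-with-terminal-clip
    and deletion-with-appended-base; ``w`` itself is excluded.
    """
    out = _substitution_neighbors(w) | _insertion_neighbors(w) | _deletion_neighbors(w)
    out.discard(w)
    return out


@dataclass
class CorrectionMap:
    """Erroneous barcode -> (whitelisted label, edit kind); rest discarded."""

    assignments: dict[str, tuple[str, str]] = field(default_factory=dict)
    discarded: set[str] = field(default_factory=set)

    def label(self, barcode: str) -> str | None:
        entry = self.assignments.get(barcode)
        return entry[0] if entry else None


def correct_barcodes(partition: WhitelistPartition, seed: int = 0) -> CorrectionMap:
    """Assign every erroneous barcode a one-edit whitelisted label or discard.

    Iterates over the whitelist (barcodes are short, so enumerating each
    whitelisted barcode's one-edit neighborhood is cheap), collects candidate
    labels per erroneous barcode, prefers substitution labels over indels and
    breaks remaining ties uniformly at random with the given seed.
    """
    erroneous = partition.erroneous
    sub_cand: dict[str, list[str]] = defaultdict(list)
    indel_cand: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for w in sorted(partition.whitelist):
        subs = _substitution_neighbors(w)
        ins = _insertion_neighbors(w)
        dels = _deletion_neighbors(w)
        for h in subs:
            if h in erroneous:
                sub_cand[h].append(w)
        for h in ins - subs:
            if h in erroneous:
                indel_cand[h].append((w, INSERTION))
        for h in dels - subs - ins:
            if h in erroneous:
                indel_cand[h].append((w, DELETION))

    rng = np.random.default_rng(seed)
    result = CorrectionMap()
    for h in sorted(erroneous):
        if h in sub_cand:
            pool = [(w, SUBSTITUTION) for w in sorted(set(sub_cand[h]))]
        elif h in indel_cand:
            pool = sorted(set(indel_cand[h]))
        else:
            result.discarded.add(h)
            continue
        choice = pool[0] if len(pool) == 1 else pool[int(rng.integers(len(pool)))]
        result.assignments[h] = choice
    return result
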