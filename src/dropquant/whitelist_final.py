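"""Final whitelisting: naive-Bayes classification of ambiguous barcodes.

The initial knee is deliberately liberal, so everything above it is split
into a high-quality upper half H and an ambiguous lower half L (by read
count).  A Gaussian naive Bayes classifier is trained on H (positive) versus
n_l = max(0.2*|H|, 1000) barcodes just below the knee (negative), using
features derived from the quantification, and each ambiguous barcode is kept
when its posterior of being high quality reaches 0.5.  The final whitelist
is H plus the positively classified members of L.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import spearmanr
from sklearn.naive_bayes import GaussianNB

logger = logging.getLogger(__name__)


@dataclass
class RegionSplit:
    """Above-knee barcodes split into H and L, plus the low training set."""

    high: list[str]
    ambiguous: list[str]
    low: list[str]
    n_l: int
    threshold: float


def split_regions(
    tally: Mapping[str, int],
    threshold: float,
    exclude_low: Optional[set[str]] = None,
) -> RegionSplit:
    """Deterministic region split by descending count (ties lexicographic).

    ``exclude_low`` removes barcodes from the below-knee training pool
    (barcodes whose reads were already corrected into a whitelisted barcode
    no longer exist as cells).
    """
    ordered = sorted(tally, key=lambda b: (-tally[b], b))
    above = [b for b in ordered if tally[b] >= threshold]
    below = [b for b in ordered if tally[b] < threshold]
    if exclude_low:
        below = [b for b in below if b not in exclude_low]
    if not above:
        raise ValueError("no barcodes above the knee; cannot train a classifier")
    h_size = (len(above) + 1) // 2
    high = above[:h_size]
    ambiguous = above[h_size:]
    n_l = int(max(0.2 * len(high), 1000))
    low = below[:n_l]
    if len(low) < n_l:
        logger.warning(
            "only %d barcodes available below the knee (wanted %d)", len(low), n_l
        )
    return RegionSplit(high, ambiguous, low, n_l, threshold)


@dataclass
class CellProfile:
    """Per-barcode quantities the classifier features are computed from."""

    reads_total: int
    reads_mapped: int
    counts: dict[str, float] = field(default_factory=dict)

    @property
    def molecules(self) -> float:
        return float(sum(self.counts.values()))


def _fraction_of(counts: Mapping[str, float], genes: set[str]) -> float:
    total = sum(counts.values())
    if total <= 0:
        return 0.0
    return sum(c for g, c in counts.items() if g in genes) / total


def _log1p_vector(counts: Mapping[str, float], genes: Sequence[str]) -> np.ndarray:
    return np.log1p(np.array([counts.get(g, 0.0) for g in genes]))


def max_high_correlation(
    profile: CellProfile, high_profiles: Sequence[CellProfile]
) -> float:
    """Max Spearman correlation of log1p gene counts against the H cells,
    restricted, per pair, to genes expressed in either cell."""
    best = -1.0
    mine = profile.counts
    for other in high_profiles:
        if other is profile:
            continue
        genes = sorted(set(mine) | set(other.counts))
        if len(genes) < 2:
            continue
        rho = spearmanr(_log1p_vector(mine, genes), _log1p_vector(other.counts, genes)).statistic
        if not math.isnan(rho):
            best = max(best, float(rho))
    return best if best > -1.0 else 0.0


def extract_features(
    profile: CellProfile,
    mito_genes: Optional[set[str]] = None,
    rrna_genes: Optional[set[str]] = None,
    high_profiles: Optional[Sequence[CellProfile]] = None,
) -> np.ndarray:
    """Quantification-derived features for one barcode.

    Always: fraction of reads mapped, duplication rate
    (mapped reads - molecules) / mapped reads, and mean gene count
    (molecules / expressed genes).  Optionally: mitochondrial fraction, rRNA
    fraction and the maximum correlation with the high-quality cells.
    Barcodes with zero mapped reads yield all-zero features.
    """
    feats: list[float] = []
    if profile.reads_mapped == 0 or profile.reads_total == 0:
        logger.warning("barcode with no mapped reads; features set to zero")
        n = 3 + (mito_genes is not None) + (rrna_genes is not None) + (
            high_profiles is not None
        )
        return np.zeros(n)
    molecules = profile.molecules
    feats.append(profile.reads_mapped / profile.reads_total)
    feats.append((profile.reads_mapped - molecules) / profile.reads_mapped)
    expressed = sum(1 for c in profile.counts.values() if c > 0)
    feats.append(molecules / expressed if expressed else 0.0)
    if mito_genes is not None:
        feats.append(_fraction_of(profile.counts, mito_genes))
    if rrna_genes is not None:
        feats.append(_fraction_of(profile.counts, rrna_genes))
    if high_profiles is not None:
        feats.append(max_high_correlation(profile, high_profiles))
    return np.array(feats)


def feature_matrix(
    barcodes: Sequence[str],
    profiles: Mapping[str, CellProfile],
    mito_genes: Optional[set[str]] = None,
    rrna_genes: Optional[set[str]] = None,
    high_profiles: Optional[Sequence[CellProfile]] = None,
) -> np.ndarray:
    return np.vstack(
        [
            extract_features(profiles[b], mito_genes, rrna_genes, high_profiles)
            for b in barcodes
        ]
    )


def classify_ambiguous(
    features_high: np.ndarray,
    features_low: np.ndarray,
    features_ambiguous: np.ndarray,
) -> np.ndarray:
    """Gaussian naive Bayes: True where an ambiguous barcode's posterior of
    being high quality is >= 0.5.  Zero-variance features are handled by the
    classifier's variance smoothing (1e-9 times the largest feature variance)."""
    if len(features_high) < 2 or len(features_low) < 2:
        raise ValueError("need at least 2 training examples per class")
    X = np.vstack([features_high, features_low])
    y = np.concatenate([np.ones(len(features_high)), np.zeros(len(features_low))])
    clf = GaussianNB(var_smoothing=1e-9)
    clf.fit(X, y)
    if len(features_ambiguous) == 0:
        return np.zeros(0, dtype=bool)
    posterior = clf.predict_proba(features_ambiguous)[:, list(clf.classes_).index(1.0)]
    return posterior >= 0.5


def final_whitelist(
    split: RegionSplit,
    profiles: Mapping[str, CellProfile],
    mito_genes: Optional[set[str]] = None,
    rrna_genes: Optional[set[str]] = None,
    use_correlation: bool = False,
) -> set[str]:
    """Classify the ambiguous region and return H plus its positive members."""
    high_profiles = [profiles[b] for b in split.high] if use_correlation else None
    X_high = feature_matrix(split.high, profiles, mito_genes, rrna_genes, high_profiles)
    X_low = feature_matrix(split.low, profiles, mito_genes, rrna_genes, high_profiles)
    keep = set(split.high)
    if split.ambiguous:
        X_amb = feature_matrix(
            split.ambiguous, profiles, mito_genes, rrna_genes, high_profiles
        )
        positive = classify_ambiguous(X_high, X_low, X_amb)
        keep |= {b for b, ok in zip(split.ambiguous, positive) if ok}
    return keep
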