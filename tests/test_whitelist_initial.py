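import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dropquant.synthetic_data import _draw_barcodes
from dropquant.whitelist_initial import (
    CorrectionMap,
    WhitelistPartition,
    correct_barcodes,
    find_knee,
    one_edit_neighbors,
    tally_barcodes,
)

BC4 = st.text(alphabet="ACGT", min_size=4, max_size=4)


class TestTally:
    def test_multiplicities(self):
        assert tally_barcodes(["AAAA", "AAAA", "CCCC"]) == {"AAAA": 2, "CCCC": 1}

    def test_order_invariance(self, rng):
        stream = ["AAAA"] * 3 + ["CCCC"] * 2 + ["GGGG"]
        shuffled = list(stream)
        rng.shuffle(shuffled)
        assert tally_barcodes(stream) == tally_barcodes(shuffled)

    def test_empty_stream_errors(self):
        with pytest.raises(ValueError):
            tally_barcodes([])


class TestKnee:
    def test_single_barcode_is_whitelisted(self):
        part = find_knee({"AAAA": 5})
        assert part.whitelist == {"AAAA"}
        assert part.erroneous == set()

    def test_uniform_counts_fall_back_to_everything(self):
        tally = {f"{a}{b}AA": 3 for a in "ACGT" for b in "ACGT"}
        part = find_knee(tally)
        assert part.whitelist == set(tally)

    def test_bimodal_distribution_recovers_real_cells(self, rng):
        """50 deep barcodes vs 2000 ambient ones: the KDE valley separates them."""
        barcodes = set()
        while len(barcodes) < 2050:
            barcodes.add("".join("ACGT"[i] for i in rng.integers(0, 4, 16)))
        barcodes = sorted(barcodes)
        tally = {b: max(1, int(rng.normal(1e4, 1e3))) for b in barcodes[:50]}
        tally.update({b: int(rng.geometric(0.1)) for b in barcodes[50:]})
        part = find_knee(tally)
        real = set(barcodes[:50])
        assert real <= part.whitelist
        assert abs(len(part.whitelist) - 50) <= 2

    def test_partition_covers_all_barcodes(self, rng):
        tally = {f"AA{a}{b}": int(c) for (a, b), c in zip(
            itertools.product("ACGT", repeat=2), rng.integers(1, 100, 16))}
        part = find_knee(tally)
        assert part.whitelist | part.erroneous == set(tally)
        assert not part.whitelist & part.erroneous
        assert all(tally[b] >= part.threshold for b in part.whitelist)


def _oracle_neighbors(w):
    """Brute-force enumeration over all same-length strings using the three
    edit-relation predicates directly."""
    n = len(w)
    out = set()
    for h in map("".join, itertools.product("ACGT", repeat=n)):
        if h == w:
            continue
        sub = sum(a != b for a, b in zip(w, h)) == 1
        ins = any(
            h[:i] == w[:i] and h[i + 1 :] == w[i : n - 1] for i in range(n)
        )
        dele = any(
            h[:i] == w[:i] and h[i : n - 1] == w[i + 1 :] for i in range(n)
        )
        if sub or ins or dele:
            out.add(h)
    return out


class TestOneEditNeighbors:
    def test_length_one(self):
        assert one_edit_neighbors("A") == {"C", "G", "T"}

    @pytest.mark.parametrize("w", ["ACGT", "AAAA", "AGGT", "TTAC"])
    def test_matches_brute_force_enumeration(self, w):
        assert one_edit_neighbors(w) == _oracle_neighbors(w)

    @given(BC4)
    def test_never_contains_itself(self, w):
        assert w not in one_edit_neighbors(w)


class TestCorrection:
    def test_unique_substitution_candidate(self):
        part = WhitelistPartition({"AAAA"}, {"AAAT"}, 10)
        cm = correct_barcodes(part)
        assert cm.assignments["AAAT"] == ("AAAA", "substitution")

    def test_substitution_prioritized_over_indel(self):
        # AAAT is a substitution neighbor of AAAA (Hamming 1) and a
        # deletion-neighbor of TAAA (drop the T, append T); Hamming(AAAT,
        # TAAA)=2 so the only substitution label is AAAA
        part = WhitelistPartition({"AAAA", "TAAA"}, {"AAAT"}, 10)
        cm = correct_barcodes(part)
        assert cm.assignments["AAAT"][0] == "AAAA"
        assert cm.assignments["AAAT"][1] == "substitution"

    def test_no_candidate_is_discarded(self):
        part = WhitelistPartition({"AAAA"}, {"TTTT"}, 10)
        cm = correct_barcodes(part)
        assert "TTTT" in cm.discarded
        assert not cm.assignments

    def test_every_label_is_a_one_edit_neighbor(self, rng):
        whitelist = set(_draw_barcodes(rng, 10, 8, min_distance=3))
        erroneous = {
            "".join("ACGT"[i] for i in rng.integers(0, 4, 8)) for _ in range(100)
        } - whitelist
        cm = correct_barcodes(WhitelistPartition(whitelist, erroneous, 10), seed=1)
        for h, (w, _kind) in cm.assignments.items():
            assert h in one_edit_neighbors(w)

    def test_deterministic_given_seed(self):
        # AAAG has two substitution candidates: AAAA and AAAC
        part = WhitelistPartition({"AAAA", "AAAC"}, {"AAAG"}, 10)
        first = correct_barcodes(part, seed=7)
        second = correct_barcodes(part, seed=7)
        assert first.assignments == second.assignments
        assert first.assignments["AAAG"][0] in {"AAAA", "AAAC"}

    def test_error_reads_reassigned_to_true_origin(self, rng):
        """With a 1% per-read substitution rate and well-separated true
        barcodes, at least 99% of error-bearing reads recover their origin."""
        true_bcs = _draw_barcodes(rng, 20, 16, min_distance=3)
        reads = []
        origins = []
        for bc in true_bcs:
            for _ in range(500):
                if rng.random() < 0.01:
                    pos = int(rng.integers(16))
                    base = "ACGT"[int(rng.integers(4))]
                    obs = bc[:pos] + base + bc[pos + 1 :]
                else:
                    obs = bc
                reads.append(obs)
                origins.append(bc)
        tally = tally_barcodes(reads)
        whitelist = set(true_bcs)
        part = WhitelistPartition(whitelist, set(tally) - whitelist, 10)
        cm = correct_barcodes(part, seed=0)
        label = {w: w for w in whitelist}
        label.update({h: w for h, (w, _) in cm.assignments.items()})
        errored = [(obs, true) for obs, true in zip(reads, origins) if obs != true]
        assert errored, "simulation produced no CB errors"
        recovered = sum(label.get(obs) == true for obs, true in errored)
        assert recovered / len(errored) >= 0.99
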