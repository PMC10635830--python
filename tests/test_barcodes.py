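"""Combinatorial whitelist construction, code generation, and matching."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pipflow import (BarcodeSchema, SubBarcodeSet, Whitelist, build_whitelist,
                     generate_subbarcode_sets, hamming, match_barcode)
from pipflow.barcodes import read_whitelist_tsv, write_whitelist_tsv

DNA = st.text(alphabet="ACGT", min_size=6, max_size=6)


class TestWhitelistArithmetic:
    def test_full_scale_size_without_materialization(self):
        rounds = generate_subbarcode_sets(96, 6, 3, 4, seed=0)
        wl = Whitelist(rounds)
        assert wl.size == 96 ** 4 == 84_934_656

    def test_single_round_identity(self):
        wl = Whitelist([SubBarcodeSet(1, ("ACGTAC",))])
        assert wl.size == 1
        assert list(wl.materialize()) == ["ACGTAC"]

    def test_toy_product_enumeration(self, toy_whitelist):
        assert toy_whitelist.size == 4
        assert set(toy_whitelist.materialize()) == {
            "AAAGGG", "AAATTT", "CCCGGG", "CCCTTT"}

    def test_membership_matches_enumeration(self, toy_whitelist):
        members = set(toy_whitelist.materialize())
        for cand in ("AAAGGG", "CCCTTT", "AAACCC", "GGGGGG"):
            assert (cand in toy_whitelist) == (cand in members)


class TestGeneration:
    def test_full_plate_meets_distance_bound(self):
        rounds = generate_subbarcode_sets(96, 6, 3, 1, seed=0)
        (r,) = rounds
        assert len(r) == 96
        dists = [hamming(a, b)
                 for a, b in itertools.combinations(r.sequences, 2)]
        assert min(dists) >= 3

    def test_infeasible_distance_errors(self):
        with pytest.raises(ValueError):
            generate_subbarcode_sets(2, 2, 3, 1, seed=0)

    def test_single_sequence_vacuous(self):
        (r,) = generate_subbarcode_sets(1, 6, 3, 1, seed=0)
        assert len(r) == 1

    def test_deterministic_under_seed(self):
        a = generate_subbarcode_sets(20, 6, 3, 2, seed=5)
        b = generate_subbarcode_sets(20, 6, 3, 2, seed=5)
        assert [r.sequences for r in a] == [r.sequences for r in b]


class TestMatching:
    def test_exact(self, toy_whitelist):
        m = match_barcode("AAACCC".replace("CCC", "GGG"), toy_whitelist)
        assert m.status == "exact" and m.distance == 0

    def test_one_mismatch_corrected(self, toy_whitelist):
        m = match_barcode("AAAGGT", toy_whitelist)
        assert m.status == "corrected"
        assert m.corrected_barcode == "AAAGGG"
        assert m.distance == 1

    def test_two_mismatches_discarded(self, toy_whitelist):
        assert match_barcode("AATGGT", toy_whitelist).status == "unmatched"

    def test_ambiguous_rejected(self):
        wl = Whitelist([SubBarcodeSet(1, ("AAA", "AAT"))])
        assert match_barcode("AAG", wl).status == "ambiguous"

    def test_length_mismatch_is_an_error_not_unmatched(self, toy_whitelist):
        with pytest.raises(ValueError):
            match_barcode("AAAGG", toy_whitelist)

    def test_tolerance_above_one_rejected(self, toy_whitelist):
        with pytest.raises(ValueError):
            match_barcode("AAAGGG", toy_whitelist, max_dist=2)


def brute_force_match(observed: str, members: np.ndarray, codes: list[str]):
    """Whole-barcode Hamming scan over a materialized whitelist (numpy)."""
    obs = np.frombuffer(observed.encode(), dtype=np.uint8)
    d = (members != obs).sum(axis=1)
    if (d == 0).any():
        return "exact", observed
    at1 = np.where(d == 1)[0]
    if len(at1) == 1:
        return "corrected", codes[at1[0]]
    if len(at1) >= 2:
        return "ambiguous", None
    return "unmatched", None


@pytest.fixture(scope="module")
def dense_whitelist():
    # 4 rounds of 10 3-mers drawn with no distance constraint, so
    # ambiguous Hamming-1 neighborhoods actually occur
    rng = np.random.default_rng(42)
    rounds = []
    for i in range(4):
        seqs = set()
        while len(seqs) < 10:
            seqs.add("".join(rng.choice(list("ACGT"), 3)))
        rounds.append(SubBarcodeSet(i + 1, tuple(sorted(seqs))))
    return Whitelist(rounds)


class TestMatcherEquivalence:
    """The per-segment matcher must equal a brute-force whole-barcode scan
    for a full-product whitelist (distance <= 1 decomposes per segment)."""

    def test_agreement_on_random_barcodes(self, dense_whitelist):
        wl = dense_whitelist
        assert wl.size == 10_000
        codes = list(wl.materialize())
        members = np.array([np.frombuffer(c.encode(), np.uint8)
                            for c in codes])
        rng = np.random.default_rng(7)
        statuses = set()
        for i in range(1200):
            if i % 3 == 0:  # random string
                obs = "".join(rng.choice(list("ACGT"), 12))
            else:  # mutated member: 0-2 substitutions
                obs = list(codes[rng.integers(len(codes))])
                for pos in rng.choice(12, size=rng.integers(0, 3),
                                      replace=False):
                    obs[pos] = "ACGT"[rng.integers(4)]
                obs = "".join(obs)
            expected_status, expected_bc = brute_force_match(
                obs, members, codes)
            got = match_barcode(obs, wl)
            assert got.status == expected_status, obs
            if expected_status in ("exact", "corrected"):
                assert got.corrected_barcode == expected_bc
            statuses.add(expected_status)
        assert statuses == {"exact", "corrected", "ambiguous", "unmatched"}


class TestHammingProperties:
    @given(DNA, DNA)
    @settings(derandomize=True, max_examples=200)
    def test_symmetric_and_zero_iff_equal(self, a, b):
        assert hamming(a, b) == hamming(b, a)
        assert (hamming(a, b) == 0) == (a == b)

    @given(DNA, DNA, DNA)
    @settings(derandomize=True, max_examples=200)
    def test_triangle_inequality(self, a, b, c):
        assert hamming(a, c) <= hamming(a, b) + hamming(b, c)


class TestSchemaAndIO:
    def test_schema_geometry(self, toy_schema):
        assert toy_schema.barcode_length == 6
        assert toy_schema.read1_min_length == 10
        assert toy_schema.segment_offsets() == [(0, 3), (3, 6)]
        assert toy_schema.umi_offset() == (6, 10)

    def test_schema_with_linkers_shifts_offsets(self):
        schema = BarcodeSchema(
            rounds=(SubBarcodeSet(1, ("AAA",)), SubBarcodeSet(2, ("GGG",))),
            linkers=("TT",), umi_length=4)
        assert schema.read1_min_length == 12
        assert schema.segment_offsets() == [(0, 3), (5, 8)]

    def test_duplicate_subbarcodes_rejected(self):
        with pytest.raises(ValueError):
            SubBarcodeSet(1, ("AAA", "AAA"))

    def test_whitelist_tsv_round_trip(self, toy_schema, tmp_path):
        p = tmp_path / "wl.tsv.gz"
        write_whitelist_tsv(toy_schema.rounds, p)
        back = read_whitelist_tsv(p)
        assert [r.sequences for r in back] == [
            r.sequences for r in toy_schema.rounds]

    def test_schema_yaml_round_trip(self, toy_schema, tmp_path):
        p = tmp_path / "schema.yaml"
        toy_schema.save(p)
        assert BarcodeSchema.load(p) == toy_schema
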