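"""Combinatorial split-pool barcode spaces and Hamming-tolerant matching.

Particle-templated beads carry a barcode assembled by split-pool ligation:
four rounds of 6-bp sub-barcodes drawn from 96-well plates, giving a
96^4 ~ 8.5e7 combinatorial space, followed by a 12-nt UMI. The whitelist of
valid barcodes is the full product of the per-round sets, so membership and
single-mismatch correction decompose per segment and never require
materializing the ~10^8 strings.
"""

from __future__ import annotations

import gzip
import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import yaml

ALPHABET = "ACGT"

__all__ = [
    "SubBarcodeSet",
    "BarcodeSchema",
    "Whitelist",
    "MatchResult",
    "hamming",
    "build_whitelist",
    "generate_subbarcode_sets",
    "match_barcode",
    "default_schema",
    "read_whitelist_tsv",
    "write_whitelist_tsv",
]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings.

    Raises ValueError on length mismatch. 'N' (or any non-ACGT symbol)
    mismatches every base, including another 'N' position comparison is
    literal: N vs N counts as equal characters, but N never appears in a
    whitelist, so an N in the observed read always costs one mismatch.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class SubBarcodeSet:
    """One ligation round's plate of sub-barcodes."""

    round_index: int
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.round_index < 1:
            raise ValueError("round_index must be >= 1")
        if not self.sequences:
            raise ValueError("empty sub-barcode set")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"unequal sub-barcode lengths in round {self.round_index}")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError(f"duplicate sub-barcodes in round {self.round_index}")
        bad = {c for s in self.sequences for c in s} - set(ALPHABET)
        if bad:
            raise ValueError(f"non-ACGT symbols in round {self.round_index}: {sorted(bad)}")
        object.__setattr__(self, "sequences", tuple(self.sequences))

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.sequences)

    def min_pairwise_distance(self) -> int:
        """Smallest Hamming distance over all within-round pairs (brute force)."""
        if len(self.sequences) == 1:
            return self.length  # vacuous; no pair exists
        return min(
            hamming(a, b) for a, b in itertools.combinations(self.sequences, 2)
        )


@dataclass(frozen=True)
class BarcodeSchema:
    """Read-1 layout: ordered sub-barcode rounds, optional linkers, UMI.

    Default geometry is the prototype bead: 4 rounds x 6 bp, no linkers,
    12-nt UMI, so read 1 must be at least 36 bases.
    """

    rounds: tuple[SubBarcodeSet, ...]
    linkers: tuple[str, ...] = ()
    umi_length: int = 12

    def __post_init__(self) -> None:
        if not self.rounds:
            raise ValueError("schema needs at least one round")
        if self.umi_length < 1:
            raise ValueError("umi_length must be >= 1")
        if self.linkers and len(self.linkers) != len(self.rounds) - 1:
            raise ValueError(
                f"need {len(self.rounds) - 1} linkers for {len(self.rounds)} rounds"
            )
        object.__setattr__(self, "rounds", tuple(self.rounds))
        object.__setattr__(self, "linkers", tuple(self.linkers))

    @property
    def segment_lengths(self) -> tuple[int, ...]:
        return tuple(r.length for r in self.rounds)

    @property
    def barcode_length(self) -> int:
        return sum(self.segment_lengths)

    @property
    def read1_min_length(self) -> int:
        return self.barcode_length + sum(len(x) for x in self.linkers) + self.umi_length

    def segment_offsets(self) -> list[tuple[int, int]]:
        """Half-open [start, stop) slices of each barcode segment in read 1."""
        out = []
        pos = 0
        for i, r in enumerate(self.rounds):
            out.append((pos, pos + r.length))
            pos += r.length
            if self.linkers and i < len(self.linkers):
                pos += len(self.linkers[i])
        return out

    def umi_offset(self) -> tuple[int, int]:
        start = self.read1_min_length - self.umi_length
        return (start, self.read1_min_length)

    def to_dict(self) -> dict:
        return {
            "rounds": [
                {"round_index": r.round_index, "sequences": list(r.sequences)}
                for r in self.rounds
            ],
            "linkers": list(self.linkers),
            "umi_length": self.umi_length,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BarcodeSchema":
        rounds = tuple(
            SubBarcodeSet(r["round_index"], tuple(r["sequences"])) for r in d["rounds"]
        )
        return cls(rounds=rounds, linkers=tuple(d.get("linkers") or ()),
                   umi_length=int(d.get("umi_length", 12)))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=1)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "BarcodeSchema":
        path = Path(path)
        with open(path) as fh:
            d = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        return cls.from_dict(d)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one observed barcode against the whitelist."""

    status: str  # exact | corrected | ambiguous | unmatched
    corrected_barcode: str | None = None
    distance: int | None = None

    def __post_init__(self) -> None:
        if self.status == "exact" and self.distance != 0:
            raise ValueError("exact implies distance 0")
        if self.status == "corrected" and self.distance != 1:
            raise ValueError("corrected implies distance 1")

    @property
    def kept(self) -> bool:
        return self.status in ("exact", "corrected")


class Whitelist:
    """Implicit product whitelist: a full barcode is valid iff every segment
    belongs to its round's set. Size is the product of round sizes (distinct
    concatenations are guaranteed when all segments within a round have equal
    length, which SubBarcodeSet enforces)."""

    def __init__(self, rounds: Sequence[SubBarcodeSet]):
        self.rounds = tuple(rounds)
        if not self.rounds:
            raise ValueError("whitelist needs at least one round")
        self._sets = [frozenset(r.sequences) for r in self.rounds]

    @property
    def size(self) -> int:
        n = 1
        for r in self.rounds:
            n *= len(r)
        return n

    @property
    def barcode_length(self) -> int:
        return sum(r.length for r in self.rounds)

    def __contains__(self, barcode: str) -> bool:
        if len(barcode) != self.barcode_length:
            return False
        pos = 0
        for r, s in zip(self.rounds, self._sets):
            if barcode[pos:pos + r.length] not in s:
                return False
            pos += r.length
        return True

    def split(self, barcode: str) -> list[str]:
        if len(barcode) != self.barcode_length:
            raise ValueError(
                f"barcode length {len(barcode)} != whitelist length {self.barcode_length}"
            )
        out, pos = [], 0
        for r in self.rounds:
            out.append(barcode[pos:pos + r.length])
            pos += r.length
        return out

    def materialize(self, limit: int | None = 10_000_000) -> Iterator[str]:
        """Enumerate full barcodes. Guarded: refuses spaces above `limit`."""
        if limit is not None and self.size > limit:
            raise ValueError(
                f"whitelist of size {self.size:,} exceeds materialization limit"
            )
        for parts in itertools.product(*(r.sequences for r in self.rounds)):
            yield "".join(parts)

    def match(self, observed: str, max_dist: int = 1) -> MatchResult:
        return match_barcode(observed, self, max_dist=max_dist)


def build_whitelist(schema: BarcodeSchema) -> Whitelist:
    """Whitelist from a schema. The product representation stays implicit;
    96^4 needs four 96-string sets, not 8.5e7 strings."""
    return Whitelist(schema.rounds)


def match_barcode(observed: str, whitelist: Whitelist, max_dist: int = 1) -> MatchResult:
    """Match an observed barcode with Hamming tolerance <= 1.

    For a full-product whitelist, whole-barcode distance <= 1 decomposes: all
    segments must be exact except at most one segment at distance exactly 1.
    Exactly one candidate at distance 1 corrects the read; two or more make
    it ambiguous and it is discarded; anything further is unmatched.
    """
    if max_dist not in (0, 1):
        raise ValueError("max_dist must be 0 or 1; larger tolerances are ambiguous "
                         "at this code density")
    segments = whitelist.split(observed)  # raises on length mismatch
    mismatched: list[int] = []
    for i, (seg, s) in enumerate(zip(segments, whitelist._sets)):
        if seg not in s:
            mismatched.append(i)
    if not mismatched:
        return MatchResult("exact", observed, 0)
    if max_dist == 0 or len(mismatched) > 1:
        return MatchResult("unmatched")
    i = mismatched[0]
    seg = segments[i]
    candidates = [t for t in whitelist.rounds[i].sequences if hamming(seg, t) == 1]
    if len(candidates) == 1:
        fixed = segments.copy()
        fixed[i] = candidates[0]
        return MatchResult("corrected", "".join(fixed), 1)
    if len(candidates) >= 2:
        return MatchResult("ambiguous")
    return MatchResult("unmatched")


# ---------------------------------------------------------------------------
# sub-barcode set generation

_BASE_IDX = {c: i for i, c in enumerate(ALPHABET)}


def _encode(seqs: Sequence[str]) -> np.ndarray:
    return np.array([[_BASE_IDX[c] for c in s] for s in seqs], dtype=np.uint8)


def generate_subbarcode_sets(
    n_per_round: int = 96,
    length: int = 6,
    min_pairwise_distance: int = 3,
    n_rounds: int = 4,
    seed: int = 0,
    max_restarts: int = 400,
) -> list[SubBarcodeSet]:
    """Generate per-round sub-barcode sets with a guaranteed minimum pairwise
    Hamming distance (default 3, which makes single-mismatch correction
    unambiguous within a round).

    Uses randomized maximal greedy packing over the full 4^length space,
    restarting with fresh shuffles until `n_per_round` codewords are found or
    the restart bound is hit. Deterministic under `seed`.
    """
    if min_pairwise_distance > length:
        raise ValueError(
            f"min_pairwise_distance {min_pairwise_distance} exceeds length {length}"
        )
    if n_per_round < 1 or n_rounds < 1:
        raise ValueError("n_per_round and n_rounds must be >= 1")
    space = 4 ** length
    if n_per_round > space:
        raise ValueError(f"{n_per_round} codes requested from a space of {space}")

    rng = np.random.default_rng(seed)
    if length > 10:
        raise ValueError("generation enumerates 4^length candidates; length > 10 unsupported")
    all_codes = _encode(["".join(p) for p in itertools.product(ALPHABET, repeat=length)])

    out: list[SubBarcodeSet] = []
    for round_index in range(1, n_rounds + 1):
        best: np.ndarray | None = None
        for _ in range(max_restarts):
            order = rng.permutation(space)
            kept = np.empty((n_per_round, length), dtype=np.uint8)
            n_kept = 0
            for idx in order:
                cand = all_codes[idx]
                if n_kept == 0 or (
                    (kept[:n_kept] != cand).sum(axis=1).min() >= min_pairwise_distance
                ):
                    kept[n_kept] = cand
                    n_kept += 1
                    if n_kept == n_per_round:
                        break
            if n_kept == n_per_round:
                best = kept
                break
        if best is None:
            raise RuntimeError(
                f"could not find {n_per_round} length-{length} codes at distance "
                f">= {min_pairwise_distance} within {max_restarts} restarts"
            )
        seqs = tuple("".join(ALPHABET[b] for b in row) for row in best)
        out.append(SubBarcodeSet(round_index, seqs))
    return out


def default_schema(seed: int = 7) -> BarcodeSchema:
    """Prototype bead schema: 4 rounds x 96 six-mers (distance >= 3), 12-nt UMI."""
    rounds = generate_subbarcode_sets(96, 6, 3, 4, seed=seed)
    return BarcodeSchema(rounds=tuple(rounds), umi_length=12)


# ---------------------------------------------------------------------------
# whitelist file I/O: TSV of round_index TAB sequence (gzip-transparent)

def write_whitelist_tsv(rounds: Sequence[SubBarcodeSet], path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for r in rounds:
            for s in r.sequences:
                fh.write(f"{r.round_index}\t{s}\n")


def read_whitelist_tsv(path: str | Path) -> list[SubBarcodeSet]:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    by_round: dict[int, list[str]] = {}
    with opener(path, "rt") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{line_no}: expected 'round<TAB>sequence'")
            by_round.setdefault(int(parts[0]), []).append(parts[1])
    return [SubBarcodeSet(i, tuple(seqs)) for i, seqs in sorted(by_round.items())]
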