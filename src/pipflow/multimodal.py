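"""CROP-seq guide assignment, antibody/hashtag tag counting, demultiplexing.

Guide assignment follows the dominance rule: a cell expresses a single
guide when the top guide's UMI count is at least tenfold the sum of all
other guides; zero guide UMIs is "none"; anything in between is "multiple".
The three labels partition the called cells.

Hashtag processing counts tag reads (read-2 prefix matched at Hamming <= 1
against the tag whitelist, UMI-deduplicated) and demultiplexes with a
CLR-transform / background-quantile scheme: per hash, the threshold is the
`positive_quantile` of CLR values over cells whose best hash is some other
hash; 0/1/>=2 positive hashes give negative/singlet/doublet.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .barcodes import hamming
from .quant import CountMatrix, FeatureTable, UmiRecord, collapse_umis

__all__ = ["GuideCall", "assign_guides", "count_tags", "demux_hashes"]


@dataclass(frozen=True)
class GuideCall:
    barcode: str
    top_guide: str | None
    top_count: int
    other_count: int
    dominance_ratio: float  # inf when no other guides
    label: str  # none | single | multiple


def assign_guides(
    cm: CountMatrix,
    ratio_threshold: float = 10.0,
) -> pd.DataFrame:
    """Classify each barcode's guide content from CRISPR-type features.

    r = top guide count / sum of other guide counts. Zero total -> "none";
    r >= ratio_threshold (including the zero-denominator case, r = +inf)
    -> "single"; otherwise "multiple".
    """
    guides = cm.subset_feature_type("CRISPR")
    if guides.shape[1] == 0:
        raise ValueError("no CRISPR features in the matrix")
    counts = np.asarray(guides.matrix.toarray(), dtype=np.int64)
    guide_ids = guides.features["feature_id"].to_numpy()
    rows = []
    for bc, vec in zip(guides.barcodes, counts):
        total = int(vec.sum())
        if total == 0:
            rows.append((bc, None, 0, 0, 0.0, "none"))
            continue
        top_idx = int(np.argmax(vec))
        top = int(vec[top_idx])
        other = total - top
        ratio = np.inf if other == 0 else top / other
        label = "single" if ratio >= ratio_threshold else "multiple"
        rows.append((bc, guide_ids[top_idx], top, other, float(ratio), label))
    df = pd.DataFrame(rows, columns=["barcode", "top_guide", "top_count",
                                     "other_count", "dominance_ratio", "label"])
    df.attrs["ratio_threshold"] = ratio_threshold
    return df


def count_tags(
    tagged: Iterable[tuple[str, str, str, str]],
    tag_whitelist: dict[str, str],
    tag_length: int | None = None,
    max_dist: int = 1,
    barcodes: list[str] | None = None,
) -> tuple[CountMatrix, dict]:
    """UMI-deduplicated tag counts per (barcode, tag).

    `tagged` yields (read_id, barcode, umi, read2); the read-2 prefix of
    `tag_length` bases is matched at Hamming <= max_dist against the tag
    whitelist. Ambiguous matches (two tags at the same best distance) are
    discarded. The whitelist should be separated by more than 2*max_dist;
    if not, a warning is raised since correction can then be ambiguous.
    """
    if not tag_whitelist:
        raise ValueError("empty tag whitelist")
    lengths = {len(s) for s in tag_whitelist.values()}
    if len(lengths) != 1:
        raise ValueError("tag sequences must share one length")
    L = tag_length if tag_length is not None else lengths.pop()
    pairs = itertools.combinations(tag_whitelist.items(), 2)
    min_d = min((hamming(a[1][:L], b[1][:L]) for a, b in pairs), default=L)
    if min_d <= 2 * max_dist:
        warnings.warn(
            f"tag whitelist min pairwise distance {min_d} <= {2 * max_dist}; "
            "Hamming correction may be ambiguous", stacklevel=2)
    stats = {"matched": 0, "corrected": 0, "ambiguous": 0, "unmatched": 0,
             "too_short": 0}
    records: list[UmiRecord] = []
    for _rid, bc, umi, seq in tagged:
        if len(seq) < L:
            stats["too_short"] += 1
            continue
        prefix = seq[:L]
        best, best_d, n_best = None, max_dist + 1, 0
        for tag_id, tag_seq in tag_whitelist.items():
            d = hamming(prefix, tag_seq[:L])
            if d < best_d:
                best, best_d, n_best = tag_id, d, 1
            elif d == best_d:
                n_best += 1
        if best_d > max_dist:
            stats["unmatched"] += 1
            continue
        if n_best > 1:
            stats["ambiguous"] += 1
            continue
        stats["matched" if best_d == 0 else "corrected"] += 1
        records.append(UmiRecord(bc, umi, best))
    counts = collapse_umis(records)
    features = FeatureTable(
        [{"feature_id": t, "feature_type": "Antibody"} for t in tag_whitelist]
    )
    return CountMatrix.from_counts(counts, features, barcodes=barcodes), stats


def _high_cluster_mask(values: np.ndarray, n_iter: int = 50) -> np.ndarray:
    """Membership in the upper cluster of a deterministic 1-D two-means
    split over all cells (initialized at the 10th/90th percentiles).

    Returns all-False when the split degenerates (near-constant values).
    """
    lo, hi = np.quantile(values, 0.1), np.quantile(values, 0.9)
    if np.isclose(lo, hi):
        return np.zeros(len(values), dtype=bool)
    assign_hi = np.zeros(len(values), dtype=bool)
    for _ in range(n_iter):
        assign_hi = np.abs(values - hi) < np.abs(values - lo)
        if assign_hi.all() or (~assign_hi).all():
            return np.zeros(len(values), dtype=bool)
        new_lo, new_hi = values[~assign_hi].mean(), values[assign_hi].mean()
        if np.isclose(new_lo, lo) and np.isclose(new_hi, hi):
            break
        lo, hi = new_lo, new_hi
    return assign_hi


def demux_hashes(
    cm: CountMatrix,
    positive_quantile: float = 0.99,
) -> pd.DataFrame:
    """Singlet/doublet/negative hash calls from a tag count matrix.

    CLR transform per hash across cells (pseudocount 1). A hash's background
    is the low cluster of a two-means split of its CLR values, restricted to
    cells whose maximum CLR lies on some other hash — excluding the positive
    cluster keeps genuine inter-hash doublets from inflating the threshold.
    The positivity threshold is the empirical `positive_quantile` of that
    background. A cell is positive for every hash whose CLR exceeds the
    hash's threshold; 0 positives -> negative, 1 -> singlet, >= 2 -> doublet.
    """
    hashes = cm.subset_feature_type("Antibody")
    if hashes.shape[1] < 2:
        raise ValueError("need >= 2 hashes to demultiplex")
    if hashes.shape[0] < 10:
        raise ValueError("need >= 10 cells to estimate background quantiles")
    counts = np.asarray(hashes.matrix.toarray(), dtype=float) + 1.0
    # CLR across cells within each hash: log(x) - mean(log(x)) per column
    logc = np.log(counts)
    clr = logc - logc.mean(axis=0, keepdims=True)
    hash_ids = hashes.features["feature_id"].tolist()
    best_idx = np.argmax(clr, axis=1)
    thresholds = np.empty(len(hash_ids))
    for j in range(len(hash_ids)):
        high = _high_cluster_mask(clr[:, j])
        background = clr[(best_idx != j) & ~high, j]
        if background.size == 0:
            raise ValueError(
                f"hash {hash_ids[j]} has an empty background set (every cell "
                "maximal there); add cells or drop the hash")
        thresholds[j] = np.quantile(background, positive_quantile)
    positive = clr > thresholds[None, :]
    n_pos = positive.sum(axis=1)
    classification = np.where(n_pos == 0, "negative",
                              np.where(n_pos == 1, "singlet", "doublet"))
    best_hash = [
        hash_ids[int(np.argmax(np.where(pos, row, -np.inf)))] if n else None
        for row, pos, n in zip(clr, positive, n_pos)
    ]
    df = pd.DataFrame({
        "barcode": hashes.barcodes,
        "classification": classification,
        "n_positive": n_pos,
        "best_hash": best_hash,
    })
    for j, h in enumerate(hash_ids):
        df[f"clr_{h}"] = clr[:, j]
    df.attrs["positive_quantile"] = positive_quantile
    df.attrs["thresholds"] = dict(zip(hash_ids, thresholds))
    return df
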