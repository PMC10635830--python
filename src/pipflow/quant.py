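"""Feature assignment, UMI collapsing, and sparse count-matrix I/O.

The mapping stage of a real run is an external pseudo-aligner; here a toy
exact-substring matcher against a transcript FASTA lets the whole pipeline
run on synthetic reads, and `import_assignments` adapts any external
per-read gene assignment (TSV) into the same counting path. Counts are
distinct UMIs per (barcode, feature) after resolving UMIs observed on
multiple features within one barcode by read-support majority (ties drop
the UMI). Matrices are written as MatrixMarket + barcodes.tsv + features.tsv.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "FeatureTable",
    "UmiRecord",
    "CountMatrix",
    "SubstringIndex",
    "import_assignments",
    "collapse_umis",
    "count_reads",
]

FEATURE_TYPES = ("GeneExpression", "CRISPR", "Antibody")
FEATURE_COLUMNS = ["feature_id", "name", "feature_type", "species", "mito"]


def FeatureTable(records: Iterable[dict | tuple]) -> pd.DataFrame:
    """Normalize a feature description into the canonical feature frame.

    Columns: feature_id, name, feature_type, species, mito. feature_ids must
    be unique.
    """
    df = pd.DataFrame(list(records))
    if df.empty:
        return pd.DataFrame(columns=FEATURE_COLUMNS)
    if "name" not in df:
        df["name"] = df["feature_id"]
    if "feature_type" not in df:
        df["feature_type"] = "GeneExpression"
    if "species" not in df:
        df["species"] = "none"
    if "mito" not in df:
        df["mito"] = False
    df["name"] = df["name"].where(df["name"].notna(), df["feature_id"])
    df["species"] = df["species"].where(df["species"].notna(), "none")
    df["mito"] = (df["mito"].notna()
                  & df["mito"].astype("boolean").fillna(False)).astype(bool)
    bad = set(df["feature_type"]) - set(FEATURE_TYPES)
    if bad:
        raise ValueError(f"unknown feature types: {sorted(bad)}")
    if df["feature_id"].duplicated().any():
        dups = df.loc[df["feature_id"].duplicated(), "feature_id"].tolist()
        raise ValueError(f"duplicate feature_ids: {dups}")
    return df[FEATURE_COLUMNS].reset_index(drop=True)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"mito": "boolean"})
    df["mito"] = df.get("mito", False)
    df["mito"] = df["mito"].fillna(False).astype(bool)
    return FeatureTable(df.to_dict("records"))


@dataclass(frozen=True)
class UmiRecord:
    barcode: str
    umi: str
    feature_id: str
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")


class SubstringIndex:
    """Toy exact matcher: a read maps to a feature iff the read (or its
    reverse complement) is an exact substring of >= 1 of that feature's
    transcripts and of no other feature's. Seeded by a k-mer lookup table so
    per-read cost does not scan every transcript."""

    def __init__(self, transcripts: dict[str, str], transcript_to_feature: dict[str, str],
                 k: int = 31):
        if not transcripts:
            raise ValueError("empty reference")
        self.k = k
        self.transcripts = dict(transcripts)
        self.t2f = dict(transcript_to_feature)
        missing = set(self.transcripts) - set(self.t2f)
        if missing:
            raise ValueError(f"transcripts without a feature: {sorted(missing)[:5]}")
        self._kmers: dict[str, set[str]] = {}
        for tid, seq in self.transcripts.items():
            for i in range(max(1, len(seq) - k + 1)):
                self._kmers.setdefault(seq[i:i + k], set()).add(tid)

    @classmethod
    def from_fasta(cls, fasta: str | Path, features: pd.DataFrame,
                   k: int = 31) -> "SubstringIndex":
        """Build from a transcript FASTA whose record ids are either feature
        ids or `transcript|feature` pairs."""
        known = set(features["feature_id"])
        transcripts: dict[str, str] = {}
        t2f: dict[str, str] = {}
        for rec in SeqIO.parse(str(fasta), "fasta"):
            tid = rec.id
            fid = tid.split("|")[-1] if "|" in tid else tid
            if fid not in known:
                raise ValueError(f"transcript {tid} references unknown feature {fid}")
            transcripts[tid] = str(rec.seq).upper()
            t2f[tid] = fid
        return cls(transcripts, t2f, k=k)

    def assign(self, read: str) -> str | None:
        """Feature id, or None for unassigned, or "__multimapped__"."""
        read = read.upper()
        hits: set[str] = set()
        for query in (read, str(Seq(read).reverse_complement())):
            seed = query[: self.k] if len(query) >= self.k else query
            if len(seed) < self.k:
                candidates = [t for t, s in self.transcripts.items() if seed in s]
            else:
                candidates = self._kmers.get(seed, ())
            for tid in candidates:
                if query in self.transcripts[tid]:
                    hits.add(self.t2f[tid])
        if not hits:
            return None
        if len(hits) > 1:
            return "__multimapped__"
        return hits.pop()


MULTIMAPPED = "__multimapped__"


def import_assignments(path: str | Path) -> dict[str, str]:
    """Read a per-read feature assignment TSV (read_id TAB feature_id).

    A read_id listed with two different features is multimapped and marked
    for exclusion. Returns read_id -> feature_id (or MULTIMAPPED).
    """
    out: dict[str, str] = {}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{line_no}: expected 'read_id<TAB>feature_id'")
            rid, fid = parts
            if rid in out and out[rid] != fid:
                out[rid] = MULTIMAPPED
            else:
                out[rid] = fid
    return out


def collapse_umis(records: Iterable[UmiRecord]) -> dict[tuple[str, str], int]:
    """Distinct-UMI counts per (barcode, feature) with conflict resolution.

    A UMI seen for several features within one barcode is credited to the
    feature with the most supporting reads; a tie drops the UMI entirely.
    """
    support: dict[tuple[str, str], dict[str, int]] = {}
    for r in records:
        key = (r.barcode, r.umi)
        support.setdefault(key, {}).setdefault(r.feature_id, 0)
        support[key][r.feature_id] += r.multiplicity
    counts: dict[tuple[str, str], int] = {}
    for (bc, _umi), by_feature in support.items():
        best = max(by_feature.values())
        winners = [f for f, n in by_feature.items() if n == best]
        if len(winners) != 1:
            continue
        k = (bc, winners[0])
        counts[k] = counts.get(k, 0) + 1
    return counts


class CountMatrix:
    """Sparse non-negative integer matrix: barcodes (rows) x typed features
    (columns)."""

    def __init__(self, matrix: sp.spmatrix, barcodes: list[str],
                 features: pd.DataFrame):
        matrix = sp.csr_matrix(matrix)
        if matrix.shape != (len(barcodes), len(features)):
            raise ValueError(
                f"matrix {matrix.shape} does not match {len(barcodes)} barcodes x "
                f"{len(features)} features"
            )
        if matrix.nnz and matrix.data.min() < 0:
            raise ValueError("negative counts")
        self.matrix = matrix
        self.barcodes = list(barcodes)
        self.features = features.reset_index(drop=True)
        self._bc_index = {b: i for i, b in enumerate(self.barcodes)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def barcode_totals(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def subset_barcodes(self, keep: Iterable[str]) -> "CountMatrix":
        keep = list(keep)
        idx = [self._bc_index[b] for b in keep]
        return CountMatrix(self.matrix[idx], keep, self.features)

    def subset_feature_type(self, feature_type: str) -> "CountMatrix":
        mask = (self.features["feature_type"] == feature_type).to_numpy()
        return CountMatrix(self.matrix[:, mask], self.barcodes,
                           self.features.loc[mask])

    def to_dense_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix.toarray(), index=self.barcodes,
                            columns=self.features["feature_id"])

    @classmethod
    def from_counts(cls, counts: dict[tuple[str, str], int],
                    features: pd.DataFrame,
                    barcodes: list[str] | None = None) -> "CountMatrix":
        """Build from (barcode, feature) -> count. Row order is sorted
        barcodes unless given; column order follows the feature table."""
        if barcodes is None:
            barcodes = sorted({bc for bc, _ in counts})
        f_index = {f: j for j, f in enumerate(features["feature_id"])}
        b_index = {b: i for i, b in enumerate(barcodes)}
        rows, cols, data = [], [], []
        for (bc, fid), n in counts.items():
            if bc not in b_index:
                continue
            if fid not in f_index:
                raise ValueError(f"count for unknown feature {fid!r}")
            rows.append(b_index[bc])
            cols.append(f_index[fid])
            data.append(n)
        mat = sp.coo_matrix((data, (rows, cols)),
                            shape=(len(barcodes), len(features)), dtype=np.int64)
        return cls(mat.tocsr(), barcodes, features)

    # -- disk round trip ----------------------------------------------------

    def write(self, directory: str | Path, gzipped: bool = False) -> None:
        """MatrixMarket triplet layout: matrix.mtx (barcodes x features),
        barcodes.tsv, features.tsv, and a manifest documenting orientation."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        suffix = ".gz" if gzipped else ""
        mtx = d / "matrix.mtx"
        scipy.io.mmwrite(str(mtx), self.matrix.tocoo(), field="integer")
        if gzipped:
            with open(mtx, "rb") as src, gzip.open(str(mtx) + ".gz", "wb") as dst:
                dst.write(src.read())
            mtx.unlink()
        _write_lines(d / f"barcodes.tsv{suffix}", self.barcodes)
        feat_lines = [
            "\t".join(str(v) for v in row)
            for row in self.features[FEATURE_COLUMNS].itertuples(index=False)
        ]
        _write_lines(d / f"features.tsv{suffix}", feat_lines)
        (d / "manifest.json").write_text(json.dumps({
            "matrix": f"matrix.mtx{suffix}",
            "orientation": "barcodes x features (rows x columns)",
            "barcodes": f"barcodes.tsv{suffix}",
            "features": f"features.tsv{suffix}",
            "feature_columns": FEATURE_COLUMNS,
        }, indent=1))

    @classmethod
    def read(cls, directory: str | Path) -> "CountMatrix":
        d = Path(directory)
        mtx = next((p for p in (d / "matrix.mtx", d / "matrix.mtx.gz") if p.exists()),
                   None)
        if mtx is None:
            raise FileNotFoundError(f"no matrix.mtx[.gz] in {d}")
        matrix = sp.csr_matrix(scipy.io.mmread(str(mtx)))
        barcodes = _read_lines(_existing(d, "barcodes.tsv"))
        feat_path = _existing(d, "features.tsv")
        features = pd.read_csv(feat_path, sep="\t", header=None,
                               names=FEATURE_COLUMNS)
        features["mito"] = features["mito"].astype(str).str.lower().isin(
            ("true", "1"))
        if matrix.shape != (len(barcodes), len(features)):
            raise ValueError(
                f"matrix {matrix.shape} inconsistent with {len(barcodes)} barcodes "
                f"and {len(features)} features"
            )
        return cls(matrix, barcodes, features)


def count_reads(
    tagged: Iterable[tuple[str, str, str, str]],
    index: SubstringIndex | None = None,
    assignments: dict[str, str] | None = None,
    features: pd.DataFrame | None = None,
    barcodes: list[str] | None = None,
) -> tuple[CountMatrix, dict]:
    """Assign tagged reads to features and collapse UMIs into a CountMatrix.

    `tagged` yields (read_id, barcode, umi, read2_sequence); assignment comes
    from the substring index or an imported per-read table (exactly one must
    be given). Returns the matrix and an accounting dict.
    """
    if (index is None) == (assignments is None):
        raise ValueError("provide exactly one of index or assignments")
    if features is None:
        raise ValueError("features table required")
    stats = {"assigned": 0, "unassigned": 0, "multimapped": 0,
             "missing_assignment": 0}
    records: list[UmiRecord] = []
    for read_id, bc, umi, seq in tagged:
        if index is not None:
            fid = index.assign(seq)
        else:
            fid = assignments.get(read_id)
            if fid is None:
                stats["missing_assignment"] += 1
                continue
        if fid is None:
            stats["unassigned"] += 1
            continue
        if fid == MULTIMAPPED:
            stats["multimapped"] += 1
            continue
        stats["assigned"] += 1
        records.append(UmiRecord(bc, umi, fid))
    counts = collapse_umis(records)
    return CountMatrix.from_counts(counts, features, barcodes=barcodes), stats


def _write_lines(path: Path, lines: list[str]) -> None:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for line in lines:
            fh.write(line + "\n")


def _read_lines(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _existing(d: Path, stem: str) -> Path:
    for p in (d / stem, d / f"{stem}.gz"):
        if p.exists():
            return p
    raise FileNotFoundError(f"no {stem}[.gz] in {d}")
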