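"""Stream paired FASTQ, extract and correct bead barcodes, tag read 2.

Read 1 carries the combinatorial bead barcode and UMI; read 2 carries the
biological sequence (cDNA, guide cassette, or antibody tag). Reads whose
barcode matches the whitelist within Hamming distance 1 are written to an
intermediate FASTQ whose headers encode the corrected barcode and UMI
(``CB:Z:`` / ``UR:Z:`` fields, SAM-tag style); everything else is discarded
but accounted for.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pysam

from .barcodes import BarcodeSchema, Whitelist, match_barcode

__all__ = ["TagRecord", "ProcessStats", "extract_tags", "process_fastq",
           "iter_tagged_fastq"]

STATUSES = ("exact", "corrected", "ambiguous", "unmatched", "too_short", "bad_umi")


@dataclass(frozen=True)
class TagRecord:
    read_id: str
    raw_segments: tuple[str, ...]
    umi: str
    status: str
    corrected_barcode: str | None = None

    @property
    def kept(self) -> bool:
        return self.status in ("exact", "corrected")


@dataclass
class ProcessStats:
    counts: dict[str, int] = field(
        default_factory=lambda: {s: 0 for s in STATUSES}
    )

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def kept_reads(self) -> int:
        return self.counts["exact"] + self.counts["corrected"]

    def add(self, status: str) -> None:
        self.counts[status] += 1

    def to_dict(self) -> dict:
        return {**self.counts, "total_reads": self.total_reads,
                "kept_reads": self.kept_reads}


def extract_tags(read1_sequence: str, schema: BarcodeSchema):
    """Slice barcode segments and UMI out of read 1 at the schema's offsets.

    Returns ``(segments, umi, status)`` where status is "ok", "too_short"
    (read shorter than the schema minimum) or "bad_umi" (UMI contains N).
    Linkers, if any, are matched exactly; a linker mismatch makes the read
    unmatchable downstream, so it is flagged here as "bad_linker".
    """
    if len(read1_sequence) < schema.read1_min_length:
        return None, None, "too_short"
    segments = tuple(read1_sequence[a:b] for a, b in schema.segment_offsets())
    if schema.linkers:
        pos = 0
        for i, r in enumerate(schema.rounds[:-1]):
            pos += r.length
            link = schema.linkers[i]
            if read1_sequence[pos:pos + len(link)] != link:
                return segments, None, "bad_linker"
            pos += len(link)
    a, b = schema.umi_offset()
    umi = read1_sequence[a:b]
    if "N" in umi:
        return segments, umi, "bad_umi"
    return segments, umi, "ok"


def tag_read(read_id: str, read1_sequence: str, schema: BarcodeSchema,
             whitelist: Whitelist) -> TagRecord:
    """Full read-1 treatment: extraction then whitelist matching."""
    segments, umi, status = extract_tags(read1_sequence, schema)
    if status == "too_short":
        return TagRecord(read_id, (), "", "too_short")
    if status in ("bad_umi", "bad_linker"):
        # bad_linker reads can never match; fold into unmatched accounting
        st = "bad_umi" if status == "bad_umi" else "unmatched"
        return TagRecord(read_id, segments, umi or "", st)
    m = match_barcode("".join(segments), whitelist, max_dist=1)
    return TagRecord(read_id, segments, umi, m.status, m.corrected_barcode)


def _strip_pair_suffix(name: str) -> str:
    return name[:-2] if name.endswith(("/1", "/2")) else name


def process_fastq(
    r1_path: str | Path,
    r2_path: str | Path,
    schema: BarcodeSchema,
    whitelist: Whitelist,
    out_fastq: str | Path | None = None,
    out_tsv: str | Path | None = None,
    stats_json: str | Path | None = None,
) -> ProcessStats:
    """Stream a read pair, keep exact/corrected barcodes, and write the
    tagged intermediate FASTQ (read 2 with ``CB``/``UR`` header fields) and/or
    a TSV sidecar (read_id, barcode, umi, status). Memory is O(1) in reads.

    Raises on desynchronized pairs (mismatched ids) with the failing index.
    """
    stats = ProcessStats()
    out_fh = _open_write(out_fastq) if out_fastq else None
    tsv_fh = _open_write(out_tsv) if out_tsv else None
    try:
        with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
            it1, it2 = iter(f1), iter(f2)
            idx = 0
            while True:
                r1 = next(it1, None)
                r2 = next(it2, None)
                if r1 is None and r2 is None:
                    break
                if (r1 is None) != (r2 is None):
                    raise ValueError(
                        f"paired FASTQ desynchronized: file ended at read index {idx}"
                    )
                n1, n2 = _strip_pair_suffix(r1.name), _strip_pair_suffix(r2.name)
                if n1 != n2:
                    raise ValueError(
                        f"paired FASTQ desynchronized at read index {idx}: "
                        f"{r1.name!r} vs {r2.name!r}"
                    )
                rec = tag_read(n1, r1.sequence, schema, whitelist)
                stats.add(rec.status)
                if rec.kept:
                    if out_fh is not None:
                        qual = r2.quality if r2.quality is not None else "I" * len(r2.sequence)
                        out_fh.write(
                            f"@{n2} CB:Z:{rec.corrected_barcode} UR:Z:{rec.umi}\n"
                            f"{r2.sequence}\n+\n{qual}\n"
                        )
                    if tsv_fh is not None:
                        tsv_fh.write(
                            f"{n2}\t{rec.corrected_barcode}\t{rec.umi}\t{rec.status}\n"
                        )
                idx += 1
    finally:
        if out_fh is not None:
            out_fh.close()
        if tsv_fh is not None:
            tsv_fh.close()
    if stats_json:
        Path(stats_json).write_text(json.dumps(stats.to_dict(), indent=1))
    return stats


def iter_tagged_fastq(path: str | Path) -> Iterator[tuple[str, str, str, str]]:
    """Yield (read_id, barcode, umi, sequence) from a tagged intermediate FASTQ."""
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            fields = dict(
                item.split(":Z:", 1)
                for item in (rec.comment or "").split()
                if ":Z:" in item
            )
            yield rec.name, fields.get("CB", ""), fields.get("UR", ""), rec.sequence


def _open_write(path: str | Path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    return gzip.open(path, "wt") if path.suffix == ".gz" else open(path, "w")
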