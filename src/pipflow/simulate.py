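"""Synthetic-read generator with full ground truth.

Emulates the generative process behind a particle-templated barnyard
experiment end to end: Poisson loading of human/mouse cells into droplets
(cells sharing a droplet share a bead barcode), per-species
Dirichlet-multinomial expression, ambient RNA contamination injected into
every droplet and filling a sea of low-count background barcodes, lentiviral
guide cassettes with one dominant guide per infected cell, hashtag counts
with background, and per-base substitution errors on both reads. Every
pipeline stage is testable against the returned truth without downloads.

All randomness flows from the single config seed; two runs with one config
are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.optimize import brentq

from .barcodes import ALPHABET, BarcodeSchema, default_schema
from .barnyard import poisson_multiplet_fraction
from .quant import FeatureTable

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_experiment",
    "write_synthetic_fastq",
    "evaluate_recovery",
    "lambda_for_multiplet_fraction",
    "HASH_SEQUENCES",
]

# the two published TotalSeqA hashtag sequences; extra hashes are generated
HASH_SEQUENCES = {"A0253": "TTCCGCCTCTCTTTG", "A0255": "AAGTATCGTTTCGCA"}


def lambda_for_multiplet_fraction(target: float) -> float:
    """Loading rate lambda whose occupied-droplet multiplet fraction equals
    `target` (inverts (1 - e^-l - l e^-l)/(1 - e^-l))."""
    if not (0 < target < 1):
        raise ValueError("target multiplet fraction must be in (0, 1)")
    return float(brentq(lambda l: poisson_multiplet_fraction(l) - target,
                        1e-9, 20.0))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic experiment.

    Defaults describe a 500-cell 50:50 human-mouse barnyard at Poisson
    loading lambda = 0.1 (~4.8% multiplets among occupied droplets), 2%
    ambient contamination per cell, error-free sequencing, with a small
    CROP-seq guide library and two hashtags.
    """

    seed: int = 0
    n_cells: int = 500
    species_proportions: dict = field(
        default_factory=lambda: {"human": 0.5, "mouse": 0.5})
    genes_per_species: int = 100
    mito_genes_per_species: int = 5
    dirichlet_concentration: float = 5.0
    umis_per_cell_log_mean: float = np.log(300.0)
    umis_per_cell_log_sigma: float = 0.35
    ambient_fraction: float = 0.02
    loading_lambda: float | None = 0.1
    doublet_rate: float | None = None  # alternative to loading_lambda
    n_ambient_barcodes: int = 2000
    ambient_barcode_umis_mean: float = 15.0
    error_rate_r1: float = 0.0
    error_rate_r2: float = 0.0
    reads_per_umi_mean: float = 1.0
    n_guides: int = 8
    fraction_infected: float = 0.8
    guide_umis_mean: float = 20.0
    n_hashes: int = 2
    hash_umis_mean: float = 50.0
    hash_background_rate: float = 0.02
    read2_length: int = 50
    transcript_length: int = 200
    schema_seed: int = 7

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.species_proportions.values()), 1.0):
            raise ValueError("species proportions must sum to 1")
        for name in ("ambient_fraction", "error_rate_r1", "error_rate_r2",
                     "fraction_infected", "hash_background_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if (self.loading_lambda is None) == (self.doublet_rate is None):
            raise ValueError("set exactly one of loading_lambda / doublet_rate")
        if self.reads_per_umi_mean < 1:
            raise ValueError("reads_per_umi_mean must be >= 1")


@dataclass
class GroundTruth:
    config: SimConfig
    schema: BarcodeSchema
    cells: pd.DataFrame          # cell_id, barcode, species, droplet_id, is_doublet, guide, hash
    cell_barcodes: list[str]     # distinct barcodes of occupied droplets
    ambient_barcodes: list[str]
    umi_table: pd.DataFrame      # barcode, feature_id, count (RNA molecules incl. ambient)
    guide_table: pd.DataFrame    # barcode, feature_id, count
    hash_table: pd.DataFrame     # barcode, tag_id, count
    features: pd.DataFrame
    transcripts: dict            # feature_id -> sequence (genes + guide cassettes)
    hash_whitelist: dict         # tag_id -> sequence
    ambient_profile: pd.Series   # per-gene proportions of the ambient pool
    multiplet_fraction: float    # realized, among occupied droplets
    molecules: dict = field(repr=False, default_factory=dict)  # modality -> list

    def barcode_species_purity(self) -> pd.DataFrame:
        """True per-barcode species composition of the simulated molecules."""
        sp = self.features.set_index("feature_id")["species"]
        t = self.umi_table.copy()
        t["species"] = t["feature_id"].map(sp)
        piv = t.pivot_table(index="barcode", columns="species", values="count",
                            aggfunc="sum", fill_value=0)
        piv["total"] = piv.sum(axis=1)
        piv["purity"] = piv.drop(columns="total").max(axis=1) / piv["total"]
        return piv


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(ALPHABET), size=length))


def _make_transcripts(rng: np.random.Generator, feature_ids: list[str],
                      length: int, k: int) -> dict[str, str]:
    """Unique random transcript per feature with no k-mer shared across
    features (so a k-length read maps uniquely)."""
    if 4 ** k < 10 * len(feature_ids) * length:
        raise ValueError(f"read length {k} too short for unique {length}-nt "
                         f"transcripts over {len(feature_ids)} features")
    seen: dict[str, str] = {}
    out: dict[str, str] = {}
    for fid in feature_ids:
        for _attempt in range(100):
            seq = _random_seq(rng, length)
            kmers = {seq[i:i + k] for i in range(length - k + 1)}
            rc = str(Seq(seq).reverse_complement())
            kmers |= {rc[i:i + k] for i in range(length - k + 1)}
            if all(km not in seen for km in kmers):
                for km in kmers:
                    seen[km] = fid
                out[fid] = seq
                break
        else:
            raise RuntimeError(f"could not place a unique transcript for {fid}")
    return out


def _distinct_umis(rng: np.random.Generator, n: int, length: int,
                   used: set[str]) -> list[str]:
    """Draw n UMIs distinct from each other and from `used` (rejection)."""
    out: list[str] = []
    while len(out) < n:
        u = _random_seq(rng, length)
        if u not in used:
            used.add(u)
            out.append(u)
    return out


def _draw_occupancy(rng: np.random.Generator, n_cells: int,
                    lam: float | None, doublet_rate: float | None
                    ) -> list[int]:
    """Droplet sizes summing to n_cells. Poisson branch: zero-truncated
    Poisson(lam) per occupied droplet. Explicit branch: a doublet_rate
    fraction of droplets hold exactly 2 cells."""
    sizes: list[int] = []
    if lam is not None:
        remaining = n_cells
        while remaining > 0:
            k = 0
            while k == 0:
                k = int(rng.poisson(lam))
            k = min(k, remaining)
            sizes.append(k)
            remaining -= k
    else:
        n_pairs = int(round(doublet_rate * n_cells / (1 + doublet_rate)))
        sizes = [2] * n_pairs + [1] * (n_cells - 2 * n_pairs)
        rng.shuffle(sizes)
    return sizes


def simulate_experiment(config: SimConfig) -> GroundTruth:
    """Draw the full ground truth (cells, droplets, molecules) plus the toy
    reference (transcripts + feature table)."""
    rng = np.random.default_rng(config.seed)
    schema = default_schema(seed=config.schema_seed)
    species = sorted(config.species_proportions)
    props = np.array([config.species_proportions[s] for s in species])

    # -- feature space ------------------------------------------------------
    feat_records = []
    for s in species:
        for g in range(config.genes_per_species):
            mito = g < config.mito_genes_per_species
            fid = f"{s}_{'mt-' if mito else ''}gene{g:03d}"
            feat_records.append({"feature_id": fid, "feature_type":
                                 "GeneExpression", "species": s, "mito": mito})
    for g in range(config.n_guides):
        feat_records.append({"feature_id": f"guide{g:02d}",
                             "feature_type": "CRISPR", "species": "none"})
    features = FeatureTable(feat_records)
    gene_ids_by_species = {
        s: [r["feature_id"] for r in feat_records
            if r.get("species") == s and r["feature_type"] == "GeneExpression"]
        for s in species
    }
    all_gene_ids = [fid for s in species for fid in gene_ids_by_species[s]]
    guide_ids = [f"guide{g:02d}" for g in range(config.n_guides)]

    transcripts = _make_transcripts(
        rng, all_gene_ids + guide_ids, config.transcript_length,
        config.read2_length)

    # -- hashes -------------------------------------------------------------
    hash_ids = list(HASH_SEQUENCES)[: config.n_hashes]
    hash_whitelist = {h: HASH_SEQUENCES[h] for h in hash_ids}
    while len(hash_whitelist) < config.n_hashes:
        h = f"H{len(hash_whitelist):02d}"
        seq = _random_seq(rng, 15)
        if all(sum(a != b for a, b in zip(seq, s)) > 2
               for s in hash_whitelist.values()):
            hash_whitelist[h] = seq
    hash_ids = list(hash_whitelist)

    # -- expression profiles ------------------------------------------------
    n_g = config.genes_per_species
    base_profiles = {s: rng.dirichlet(np.ones(n_g)) for s in species}
    ambient = np.concatenate(
        [config.species_proportions[s] * base_profiles[s] for s in species])
    ambient = ambient / ambient.sum()
    ambient_series = pd.Series(ambient, index=all_gene_ids)

    # -- droplets and cells -------------------------------------------------
    sizes = _draw_occupancy(rng, config.n_cells, config.loading_lambda,
                            config.doublet_rate)
    n_droplets = len(sizes)
    multiplet_fraction = sum(1 for k in sizes if k >= 2) / n_droplets

    # bead barcodes: one per occupied droplet, plus ambient-only barcodes,
    # all distinct draws from the whitelist product space
    def draw_barcode() -> str:
        return "".join(r.sequences[rng.integers(len(r.sequences))]
                       for r in schema.rounds)

    barcodes: list[str] = []
    seen_bc: set[str] = set()
    while len(barcodes) < n_droplets + config.n_ambient_barcodes:
        b = draw_barcode()
        if b not in seen_bc:
            seen_bc.add(b)
            barcodes.append(b)
    cell_barcodes = barcodes[:n_droplets]
    ambient_barcodes = barcodes[n_droplets:]

    cell_rows = []
    cid = 0
    for d, k in enumerate(sizes):
        for _ in range(k):
            sp = species[rng.choice(len(species), p=props)]
            infected = rng.random() < config.fraction_infected
            guide = guide_ids[rng.integers(len(guide_ids))] if (
                infected and guide_ids) else None
            hsh = hash_ids[rng.integers(len(hash_ids))] if hash_ids else None
            cell_rows.append({
                "cell_id": f"cell{cid:04d}", "barcode": cell_barcodes[d],
                "species": sp, "droplet_id": d, "is_doublet": k >= 2,
                "guide": guide, "hash": hsh,
            })
            cid += 1
    cells = pd.DataFrame(cell_rows)

    # -- RNA molecules ------------------------------------------------------
    gene_index = {fid: i for i, fid in enumerate(all_gene_ids)}
    counts: dict[tuple[str, str], int] = {}

    def add_counts(barcode: str, ids: list[str], vec: np.ndarray) -> None:
        for fid, c in zip(ids, vec):
            if c > 0:
                counts[(barcode, fid)] = counts.get((barcode, fid), 0) + int(c)

    for row in cell_rows:
        n_umis = max(1, int(round(rng.lognormal(
            config.umis_per_cell_log_mean, config.umis_per_cell_log_sigma))))
        n_amb = int(rng.binomial(n_umis, config.ambient_fraction))
        n_own = n_umis - n_amb
        s = row["species"]
        alpha = config.dirichlet_concentration * n_g * base_profiles[s]
        profile = rng.dirichlet(alpha)
        add_counts(row["barcode"], gene_ids_by_species[s],
                   rng.multinomial(n_own, profile))
        if n_amb:
            add_counts(row["barcode"], all_gene_ids,
                       rng.multinomial(n_amb, ambient))
    for b in ambient_barcodes:
        total = 0
        while total == 0:
            total = int(rng.poisson(config.ambient_barcode_umis_mean))
        add_counts(b, all_gene_ids, rng.multinomial(total, ambient))

    umi_table = pd.DataFrame(
        [(b, f, c) for (b, f), c in sorted(counts.items())],
        columns=["barcode", "feature_id", "count"])

    # -- guide molecules ----------------------------------------------------
    gcounts: dict[tuple[str, str], int] = {}
    for row in cell_rows:
        if row["guide"] is None:
            continue
        n = max(1, int(rng.poisson(config.guide_umis_mean)))
        key = (row["barcode"], row["guide"])
        gcounts[key] = gcounts.get(key, 0) + n
    guide_table = pd.DataFrame(
        [(b, f, c) for (b, f), c in sorted(gcounts.items())],
        columns=["barcode", "feature_id", "count"])

    # -- hash molecules -----------------------------------------------------
    hcounts: dict[tuple[str, str], int] = {}
    for row in cell_rows:
        if row["hash"] is None:
            continue
        n = max(1, int(rng.poisson(config.hash_umis_mean)))
        key = (row["barcode"], row["hash"])
        hcounts[key] = hcounts.get(key, 0) + n
        for h in hash_ids:
            if h == row["hash"]:
                continue
            nb = int(rng.poisson(config.hash_background_rate
                                 * config.hash_umis_mean))
            if nb:
                key = (row["barcode"], h)
                hcounts[key] = hcounts.get(key, 0) + nb
    hash_table = pd.DataFrame(
        [(b, t, c) for (b, t), c in sorted(hcounts.items())],
        columns=["barcode", "tag_id", "count"])

    return GroundTruth(
        config=config, schema=schema, cells=cells,
        cell_barcodes=cell_barcodes, ambient_barcodes=ambient_barcodes,
        umi_table=umi_table, guide_table=guide_table, hash_table=hash_table,
        features=features, transcripts=transcripts,
        hash_whitelist=hash_whitelist, ambient_profile=ambient_series,
        multiplet_fraction=multiplet_fraction,
    )


def _inject_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [c for c in ALPHABET if c != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def write_synthetic_fastq(truth: GroundTruth, outdir: str | Path) -> dict:
    """Emit paired FASTQ per modality (rna, guide, hash) plus the toy
    reference FASTA, feature table, truth tables and a manifest.

    Read 1 = barcode segments (+ linkers) + UMI; read 2 = a random substring
    of the source transcript (RNA and guide cassettes) or the tag sequence
    padded with random bases (hash). Per-base substitution errors follow the
    config rates; reads per UMI ~ 1 + Poisson(mean - 1).
    """
    cfg = truth.config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 1)
    umi_len = truth.schema.umi_length

    def emit(table: pd.DataFrame, feature_col: str, read2_of, prefix: str
             ) -> dict:
        r1p, r2p = outdir / f"{prefix}_R1.fastq", outdir / f"{prefix}_R2.fastq"
        n_reads = 0
        used_by_bc: dict[str, set[str]] = {}
        with open(r1p, "w") as f1, open(r2p, "w") as f2:
            for bc, grp in table.groupby("barcode", sort=True):
                used = used_by_bc.setdefault(bc, set())
                for _, row in grp.iterrows():
                    fid = row[feature_col]
                    for u in _distinct_umis(rng, int(row["count"]), umi_len,
                                            used):
                        n_copies = 1 + int(rng.poisson(
                            cfg.reads_per_umi_mean - 1))
                        for _c in range(n_copies):
                            rid = f"{prefix}.{n_reads}"
                            r1 = _inject_errors(rng, bc + u, cfg.error_rate_r1)
                            r2 = _inject_errors(rng, read2_of(fid),
                                                cfg.error_rate_r2)
                            q1, q2 = "I" * len(r1), "I" * len(r2)
                            f1.write(f"@{rid}\n{r1}\n+\n{q1}\n")
                            f2.write(f"@{rid}\n{r2}\n+\n{q2}\n")
                            n_reads += 1
        return {"r1": str(r1p), "r2": str(r2p), "n_reads": n_reads}

    def rna_read2(fid: str) -> str:
        t = truth.transcripts[fid]
        start = rng.integers(len(t) - cfg.read2_length + 1)
        return t[start:start + cfg.read2_length]

    def hash_read2(tag_id: str) -> str:
        seq = truth.hash_whitelist[tag_id]
        pad = cfg.read2_length - len(seq)
        return seq + (_random_seq(rng, pad) if pad > 0 else "")

    manifest: dict = {"modalities": {}}
    manifest["modalities"]["rna"] = emit(truth.umi_table, "feature_id",
                                         rna_read2, "rna")
    if len(truth.guide_table):
        manifest["modalities"]["guide"] = emit(truth.guide_table, "feature_id",
                                               rna_read2, "guide")
    if len(truth.hash_table):
        manifest["modalities"]["hash"] = emit(truth.hash_table, "tag_id",
                                              hash_read2, "hash")

    ref = outdir / "reference.fasta"
    with open(ref, "w") as fh:
        for fid, seq in truth.transcripts.items():
            fh.write(f">{fid}\n{seq}\n")
    truth.features.to_csv(outdir / "features.tsv", sep="\t", index=False)
    truth.cells.to_csv(outdir / "truth_cells.tsv", sep="\t", index=False)
    truth.umi_table.to_csv(outdir / "truth_umis.tsv", sep="\t", index=False)
    with open(outdir / "hash_whitelist.tsv", "w") as fh:
        for t, s in truth.hash_whitelist.items():
            fh.write(f"{t}\t{s}\n")
    manifest.update({
        "reference": str(ref),
        "features": str(outdir / "features.tsv"),
        "n_cells": int(len(truth.cells)),
        "n_cell_barcodes": len(truth.cell_barcodes),
        "n_ambient_barcodes": len(truth.ambient_barcodes),
        "seed": cfg.seed,
    })
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def evaluate_recovery(
    truth: GroundTruth,
    called_cells: list[str] | None = None,
    species_calls: pd.DataFrame | None = None,
    doublet_rate: float | None = None,
    guide_calls: pd.DataFrame | None = None,
    hash_calls: pd.DataFrame | None = None,
) -> dict:
    """Score pipeline outputs against the simulation truth.

    Returns whichever of {cell-call precision/recall, median purity error,
    doublet-rate error, guide accuracy, hash accuracy} the given outputs
    support.
    """
    out: dict = {}
    truth_cells = set(truth.cell_barcodes)
    if called_cells is not None:
        called = set(called_cells)
        tp = len(called & truth_cells)
        out["cell_call_precision"] = tp / len(called) if called else 0.0
        out["cell_call_recall"] = tp / len(truth_cells)
    if species_calls is not None:
        truth_purity = truth.barcode_species_purity()["purity"]
        merged = species_calls.set_index("barcode").join(
            truth_purity.rename("true_purity"), how="inner")
        out["median_purity"] = float(merged["purity"].median())
        out["median_purity_error"] = float(
            (merged["purity"] - merged["true_purity"]).abs().median())
    if doublet_rate is not None:
        # truth doublet rate: fraction of occupied droplets with >= 2 cells
        out["true_doublet_rate"] = truth.multiplet_fraction
        out["inferred_doublet_rate"] = doublet_rate
        out["doublet_rate_error"] = doublet_rate - truth.multiplet_fraction
    if guide_calls is not None:
        # doublet barcodes can legitimately carry two guides; score singlets
        infected = truth.cells[truth.cells["guide"].notna()
                               & ~truth.cells["is_doublet"]]
        truth_guide = infected.set_index("barcode")["guide"]
        gc = guide_calls.set_index("barcode")
        common = truth_guide.index.intersection(gc.index)
        if len(common):
            correct = (gc.loc[common, "top_guide"] == truth_guide.loc[common])
            single = gc.loc[common, "label"] == "single"
            out["guide_accuracy"] = float((correct & single).mean())
            out["n_guide_cells_scored"] = int(len(common))
    if hash_calls is not None:
        singlets = truth.cells[~truth.cells["is_doublet"]]
        truth_hash = singlets.set_index("barcode")["hash"]
        hc = hash_calls.set_index("barcode")
        common = truth_hash.index.intersection(hc.index)
        if len(common):
            ok = ((hc.loc[common, "classification"] == "singlet")
                  & (hc.loc[common, "best_hash"] == truth_hash.loc[common]))
            out["hash_accuracy"] = float(ok.mean())
    return out
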