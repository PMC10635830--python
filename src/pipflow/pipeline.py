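"""End-to-end orchestration: simulated FASTQ through every pipeline stage.

Glue used by the CLI, the test suite and the reproduction script: run
barcode correction, feature counting, cell calling, barnyard, guide and
hash analysis over one synthetic experiment directory and score the result
against the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .barcodes import build_whitelist
from .barnyard import classify_species, contamination_summary, doublet_estimates
from .cell_calling import CellCalls, run_cell_calling
from .multimodal import assign_guides, count_tags, demux_hashes
from .quant import CountMatrix, SubstringIndex, count_reads
from .reads import ProcessStats, iter_tagged_fastq, process_fastq
from .simulate import (GroundTruth, SimConfig, simulate_experiment,
                       write_synthetic_fastq, evaluate_recovery)

__all__ = ["PipelineResult", "run_simulated_pipeline"]


@dataclass
class PipelineResult:
    truth: GroundTruth
    stats: dict[str, ProcessStats]
    matrix: CountMatrix              # genes + guides, all barcodes
    calls: CellCalls
    species: pd.DataFrame
    contamination: dict
    doublets: dict
    guide_calls: pd.DataFrame | None
    hash_calls: pd.DataFrame | None
    recovery: dict


def run_simulated_pipeline(
    config: SimConfig,
    workdir: str | Path,
    n_iterations: int = 2_000,
    alpha: float = 0.001,
    purity_threshold: float = 0.85,
    lower_threshold: float | None = None,
) -> PipelineResult:
    """Simulate one experiment, write its FASTQs, and run the full pipeline
    on them, returning every stage's output plus truth-comparison metrics."""
    workdir = Path(workdir)
    truth = simulate_experiment(config)
    manifest = write_synthetic_fastq(truth, workdir)
    whitelist = build_whitelist(truth.schema)
    index = SubstringIndex(truth.transcripts,
                           {t: t for t in truth.transcripts},
                           k=min(31, config.read2_length))

    # barcode-correct each modality, then count RNA + guide reads together
    stats: dict[str, ProcessStats] = {}
    tagged_paths: dict[str, Path] = {}
    for modality, files in manifest["modalities"].items():
        out = workdir / f"{modality}_tagged.fastq"
        stats[modality] = process_fastq(files["r1"], files["r2"],
                                        truth.schema, whitelist, out_fastq=out)
        tagged_paths[modality] = out

    def tagged_stream():
        for modality in ("rna", "guide"):
            if modality in tagged_paths:
                yield from iter_tagged_fastq(tagged_paths[modality])

    matrix, _count_stats = count_reads(tagged_stream(), index=index,
                                       features=truth.features)

    calls, ambient, curve = run_cell_calling(
        matrix, lower_threshold=lower_threshold, alpha=alpha,
        n_iterations=n_iterations, seed=config.seed)

    cell_matrix = matrix.subset_barcodes(calls.cells)
    gene_matrix = cell_matrix.subset_feature_type("GeneExpression")
    species = classify_species(gene_matrix, purity_threshold=purity_threshold)
    contamination = contamination_summary(species)
    p_mix = truth.config.species_proportions.get("human", 0.5)
    doublets = doublet_estimates(species, mixing_proportion=p_mix,
                                 lam=config.loading_lambda)

    guide_calls = None
    if config.n_guides and "guide" in tagged_paths:
        guide_calls = assign_guides(cell_matrix)

    hash_calls = None
    if "hash" in tagged_paths and config.n_hashes >= 2:
        tag_matrix, _tag_stats = count_tags(
            iter_tagged_fastq(tagged_paths["hash"]), truth.hash_whitelist,
            barcodes=calls.cells)
        hash_calls = demux_hashes(tag_matrix)

    recovery = evaluate_recovery(
        truth,
        called_cells=calls.cells,
        species_calls=species,
        doublet_rate=doublets["inferred_total_doublet_rate"],
        guide_calls=guide_calls,
        hash_calls=hash_calls,
    )
    return PipelineResult(
        truth=truth, stats=stats, matrix=matrix, calls=calls, species=species,
        contamination=contamination, doublets=doublets,
        guide_calls=guide_calls, hash_calls=hash_calls, recovery=recovery,
    )
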