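"""Species-mixing (barnyard) analysis.

Mixing two species' cell lines makes cross-species contamination and
cross-species doublets directly observable: a barcode's purity is the
fraction of its UMIs belonging to its majority species, and a droplet
holding one human and one mouse cell shows up as a mixed transcriptome.
Only a fraction 2p(1-p) of all doublets are cross-species at mixing
proportion p, so the observed mixed fraction is scaled up to a total
doublet rate. The Poisson loading model gives the expected multiplet
fraction among occupied droplets for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quant import CountMatrix

__all__ = [
    "classify_species",
    "contamination_summary",
    "doublet_estimates",
    "poisson_multiplet_fraction",
]


def classify_species(
    cm: CountMatrix,
    purity_threshold: float = 0.85,
) -> pd.DataFrame:
    """Per-barcode species purity and label over gene features.

    purity = max species UMIs / total; a barcode is labeled with its majority
    species when purity > threshold, "mixed" otherwise, "unclassified" at
    zero total. Every gene feature must carry a species label (not "none").
    """
    genes = cm.features[cm.features["feature_type"] == "GeneExpression"]
    if (genes["species"] == "none").any() or genes["species"].isna().any():
        bad = genes.loc[(genes["species"] == "none") | genes["species"].isna(),
                        "feature_id"].tolist()
        raise ValueError(f"gene features without a species label: {bad[:5]}")
    species = sorted(genes["species"].unique())
    mat = cm.matrix.tocsc()
    per_species = {}
    for s in species:
        cols = cm.features.index[
            (cm.features["feature_type"] == "GeneExpression")
            & (cm.features["species"] == s)
        ].to_numpy()
        per_species[s] = np.asarray(mat[:, cols].sum(axis=1)).ravel()
    counts = np.column_stack([per_species[s] for s in species])
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        purity = np.where(totals > 0, counts.max(axis=1) / np.where(totals > 0,
                          totals, 1), np.nan)
    top = np.array(species)[np.argmax(counts, axis=1)]
    label = np.where(totals == 0, "unclassified",
                     np.where(purity > purity_threshold, top, "mixed"))
    df = pd.DataFrame({"barcode": cm.barcodes, "total": totals,
                       "purity": purity, "label": label})
    for s in species:
        df[f"umis_{s}"] = per_species[s].astype(int)
    df.attrs["purity_threshold"] = purity_threshold
    df.attrs["species"] = species
    return df


def contamination_summary(calls: pd.DataFrame) -> dict:
    """Other-species fraction (1 - purity) per classified cell, summarized
    per species as median, mean, and max."""
    classified = calls[~calls["label"].isin(["mixed", "unclassified"])]
    if classified.empty:
        raise ValueError("no classified cells")
    out: dict = {"n_classified": int(len(classified))}
    for s, grp in classified.groupby("label"):
        contam = 1.0 - grp["purity"].to_numpy()
        out[str(s)] = {
            "n_cells": int(len(grp)),
            "median_contamination": float(np.median(contam)),
            "mean_contamination": float(np.mean(contam)),
            "max_contamination": float(np.max(contam)),
        }
    return out


def poisson_multiplet_fraction(lam: float) -> float:
    """Fraction of occupied droplets holding >= 2 cells under Poisson(lam)
    loading: (1 - e^-lam - lam e^-lam) / (1 - e^-lam)."""
    if lam <= 0:
        return 0.0
    e = np.exp(-lam)
    return float((1 - e - lam * e) / (1 - e))


def doublet_estimates(
    calls: pd.DataFrame,
    mixing_proportion: float = 0.5,
    lam: float | None = None,
) -> dict:
    """Observed mixed fraction, inferred total doublet rate, and (optionally)
    the Poisson expectation at loading rate `lam`.

    Only cross-species doublets are visible as "mixed"; under independent
    pairing that is a fraction 2p(1-p) of all doublets, so
    inferred = observed_mixed / (2p(1-p)). Higher-order multiplets are
    ignored (rare at the loading rates modeled).
    """
    if not (0 < mixing_proportion < 1):
        raise ValueError("mixing_proportion must be strictly inside (0, 1)")
    usable = calls[calls["label"] != "unclassified"]
    n = len(usable)
    if n == 0:
        raise ValueError("no classified barcodes")
    n_mixed = int((usable["label"] == "mixed").sum())
    observed = n_mixed / n
    factor = 2 * mixing_proportion * (1 - mixing_proportion)
    out = {
        "n_barcodes": n,
        "n_mixed": n_mixed,
        "observed_mixed_fraction": observed,
        "cross_species_observability": factor,
        "inferred_total_doublet_rate": observed / factor,
    }
    if lam is not None:
        out["poisson_lambda"] = lam
        out["poisson_expected_multiplet_fraction"] = poisson_multiplet_fraction(lam)
    return out
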