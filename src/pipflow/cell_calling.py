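"""Separate cell-containing barcodes from ambient background.

Two mechanisms, composable: a barcode-rank inflection (steepest log-log
slope) that gives a depth threshold, and an ambient-profile Monte-Carlo test
in the emptyDrops style — the per-gene ambient proportions estimated from
sub-threshold barcodes form a multinomial null; each candidate barcode's
multinomial log-likelihood under that null, at its own total, is compared
against simulated draws, and Benjamini–Hochberg control at alpha = 0.001
flags cells. Barcodes sharing a total reuse one null ensemble, which is
identical in distribution and bounds runtime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .quant import CountMatrix

__all__ = [
    "BarcodeRankCurve",
    "AmbientProfile",
    "CellCalls",
    "find_inflection",
    "estimate_ambient",
    "empty_drops_pvalues",
    "call_cells",
    "run_cell_calling",
]


@dataclass
class BarcodeRankCurve:
    """Barcodes sorted by descending total UMIs, with the detected knee."""

    barcodes: list[str]
    totals: np.ndarray  # non-increasing
    inflection_rank: int | None = None
    threshold: float | None = None
    fallback_used: bool = False

    @classmethod
    def from_matrix(cls, cm: CountMatrix) -> "BarcodeRankCurve":
        totals = cm.barcode_totals()
        order = np.argsort(-totals, kind="stable")
        return cls(barcodes=[cm.barcodes[i] for i in order],
                   totals=totals[order].astype(float))


def find_inflection(
    curve: BarcodeRankCurve,
    rank_bounds: tuple[int, int] | None = None,
    window: int = 5,
    slope_floor: float = -0.3,
    fallback_quantile: float = 0.99,
) -> float:
    """UMI threshold at the steepest negative slope of log(total) vs
    log(rank), after moving-average smoothing over `window` ranks.

    The search runs between `rank_bounds` (defaults to [10, n-10]). If no
    slope drops below `slope_floor` (e.g. a flat curve), falls back to the
    `fallback_quantile` of the totals distribution with a warning.
    Mutates the curve in place with the detected rank/threshold.
    """
    totals = np.asarray(curve.totals, dtype=float)
    if np.any(np.diff(totals) > 0):  # unsorted input: sort and re-check
        order = np.argsort(-totals, kind="stable")
        curve.barcodes = [curve.barcodes[i] for i in order]
        totals = totals[order]
        curve.totals = totals
    positive = totals[totals >= 1]
    if len(positive) < 100:
        raise ValueError("need >= 100 barcodes with >= 1 UMI")
    n = len(positive)
    lo, hi = rank_bounds if rank_bounds is not None else (10, n - 10)
    lo, hi = max(1, lo), min(n - 1, hi)
    log_rank = np.log(np.arange(1, n + 1))
    log_tot = np.log(positive)
    if window > 1:
        kernel = np.ones(window) / window
        log_tot = np.convolve(log_tot, kernel, mode="same")
    slope = np.gradient(log_tot, log_rank)
    region = slope[lo:hi]
    if len(region) == 0 or region.min() > slope_floor:
        warnings.warn(
            "no knee detectable; falling back to quantile threshold",
            stacklevel=2,
        )
        curve.fallback_used = True
        curve.inflection_rank = None
        curve.threshold = float(np.quantile(positive, fallback_quantile))
        return curve.threshold
    knee = lo + int(np.argmin(region))
    curve.inflection_rank = knee
    # threshold from the smoothed curve: at an abrupt plateau drop this sits
    # strictly between the two plateaus rather than on one of them
    curve.threshold = float(np.exp(log_tot[knee]))
    return curve.threshold


@dataclass
class AmbientProfile:
    """Per-gene multinomial proportions of the ambient (cell-free) pool."""

    proportions: np.ndarray
    feature_ids: list[str]
    pseudocount: float
    lower_threshold: float
    n_ambient_barcodes: int

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if np.any(p < 0):
            raise ValueError("negative ambient proportions")
        if not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError("ambient proportions must sum to 1")
        self.proportions = p


def estimate_ambient(
    cm: CountMatrix,
    lower_threshold: float,
    pseudocount: float = 0.0,
) -> AmbientProfile:
    """Ambient per-gene proportions from all barcodes whose total is at or
    below `lower_threshold` (no true cells are expected down there)."""
    totals = cm.barcode_totals()
    mask = totals <= lower_threshold
    if not mask.any():
        raise ValueError(f"no barcodes at or below threshold {lower_threshold}")
    sums = np.asarray(cm.matrix[np.where(mask)[0]].sum(axis=0)).ravel().astype(float)
    sums += pseudocount
    if sums.sum() == 0:
        raise ValueError("ambient pool has zero counts; raise the threshold "
                         "or use a pseudocount")
    return AmbientProfile(
        proportions=sums / sums.sum(),
        feature_ids=cm.features["feature_id"].tolist(),
        pseudocount=pseudocount,
        lower_threshold=lower_threshold,
        n_ambient_barcodes=int(mask.sum()),
    )


def _multinomial_loglik(counts: np.ndarray, log_p: np.ndarray,
                        zero_p: np.ndarray) -> np.ndarray:
    """Log-pmf of multinomial counts (rows) under fixed proportions.

    Features with zero ambient probability contribute -inf when counted.
    """
    counts = np.atleast_2d(counts).astype(float)
    n = counts.sum(axis=1)
    ll = gammaln(n + 1) - gammaln(counts + 1).sum(axis=1)
    safe = counts @ np.where(zero_p, 0.0, log_p)
    hit_zero = (counts[:, zero_p] > 0).any(axis=1) if zero_p.any() else np.zeros(
        len(counts), dtype=bool)
    ll = ll + safe
    ll[hit_zero] = -np.inf
    return ll


def empty_drops_pvalues(
    cm: CountMatrix,
    ambient: AmbientProfile,
    candidates: list[str],
    n_iterations: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo p-values for candidate barcodes against the ambient null.

    The statistic is the multinomial log-likelihood of the barcode's counts
    under the ambient proportions at the barcode's own total T. For each
    distinct T, `n_iterations` multinomial draws are simulated once and
    shared; p = (#{simulated LL <= observed LL} + 1) / (n_iterations + 1).
    Barcodes with counts on zero-ambient features get LL = -inf, hence the
    minimum attainable p, and are flagged.
    """
    if n_iterations < 100:
        raise ValueError("n_iterations must be >= 100")
    rng = np.random.default_rng(seed)
    p = ambient.proportions
    with np.errstate(divide="ignore"):
        log_p = np.log(p)
    zero_p = p == 0
    idx = [cm._bc_index[b] for b in candidates]
    counts = np.asarray(cm.matrix[idx].toarray(), dtype=np.int64)
    totals = counts.sum(axis=1)
    obs_ll = _multinomial_loglik(counts, log_p, zero_p)
    pvals = np.empty(len(candidates))
    for t in np.unique(totals):
        where = np.where(totals == t)[0]
        sims = rng.multinomial(int(t), p, size=n_iterations)
        sim_ll = _multinomial_loglik(sims, log_p, zero_p)
        for j in where:
            pvals[j] = (np.count_nonzero(sim_ll <= obs_ll[j]) + 1) / (
                n_iterations + 1)
    return pd.DataFrame({
        "barcode": candidates,
        "total": totals,
        "log_likelihood": obs_ll,
        "pvalue": pvals,
        "zero_ambient_feature": ~np.isfinite(obs_ll),
    })


@dataclass
class CellCalls:
    table: pd.DataFrame  # barcode, total, pvalue, p_adjusted, is_cell
    alpha: float
    n_iterations: int | None
    seed: int | None
    forced: bool = False

    @property
    def cells(self) -> list[str]:
        return self.table.loc[self.table["is_cell"], "barcode"].tolist()

    @property
    def n_cells(self) -> int:
        return int(self.table["is_cell"].sum())


def call_cells(
    pvalue_table: pd.DataFrame | None = None,
    alpha: float = 0.001,
    force_n: int | None = None,
    totals: pd.Series | None = None,
    n_iterations: int | None = None,
    seed: int | None = None,
) -> CellCalls:
    """BH-adjust the Monte-Carlo p-values and flag barcodes with adjusted
    p < alpha as cells; or bypass the test with `force_n` (top n barcodes by
    total UMIs, ties broken lexicographically by barcode)."""
    if force_n is not None:
        if totals is None:
            raise ValueError("force_n requires per-barcode totals")
        if force_n > len(totals):
            raise ValueError(f"force_n {force_n} > {len(totals)} barcodes")
        df = (totals.rename("total").rename_axis("barcode").reset_index()
              .sort_values(["total", "barcode"], ascending=[False, True],
                           kind="stable").reset_index(drop=True))
        df["pvalue"] = np.nan
        df["p_adjusted"] = np.nan
        df["is_cell"] = np.arange(len(df)) < force_n
        return CellCalls(df, alpha=alpha, n_iterations=None, seed=None,
                         forced=True)
    if pvalue_table is None:
        raise ValueError("need a p-value table or force_n")
    df = pvalue_table.copy()
    _, p_adj, _, _ = multipletests(df["pvalue"].to_numpy(), method="fdr_bh")
    df["p_adjusted"] = np.maximum(p_adj, df["pvalue"])  # BH never below raw p
    df["is_cell"] = df["p_adjusted"] < alpha
    return CellCalls(df[["barcode", "total", "pvalue", "p_adjusted", "is_cell"]],
                     alpha=alpha, n_iterations=n_iterations, seed=seed)


def run_cell_calling(
    cm: CountMatrix,
    lower_threshold: float | None = None,
    alpha: float = 0.001,
    n_iterations: int = 2_000,
    seed: int = 0,
    pseudocount: float = 0.0,
) -> tuple[CellCalls, AmbientProfile, BarcodeRankCurve]:
    """End-to-end calling: inflection threshold (unless given), ambient
    estimation below it, Monte-Carlo test of every barcode above it, BH."""
    curve = BarcodeRankCurve.from_matrix(cm)
    if lower_threshold is None:
        lower_threshold = find_inflection(curve)
    ambient = estimate_ambient(cm, lower_threshold, pseudocount=pseudocount)
    totals = cm.barcode_totals()
    candidates = [b for b, t in zip(cm.barcodes, totals) if t > lower_threshold]
    if not candidates:
        raise ValueError("no candidate barcodes above the lower threshold")
    pvals = empty_drops_pvalues(cm, ambient, candidates,
                                n_iterations=n_iterations, seed=seed)
    calls = call_cells(pvals, alpha=alpha, n_iterations=n_iterations, seed=seed)
    return calls, ambient, curve
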