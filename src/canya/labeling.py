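"""Aggregator / non-aggregator labeling from scores and errors.

The selection assay yields, per peptide, a fitness-like aggregation score
and a standard error.  Labeling proceeds library by library: peptides with
fewer than 100 input reads are removed; scores are centered on the mode of
the score distribution (the non-aggregating bulk dominates, so the global
mode is the non-aggregator mode); each score is converted to z = score /
error and tested one-sided against 0; Benjamini-Hochberg-adjusted p <= alpha
marks an aggregator.  Peptides whose score is missing (no output reads
despite passing the input filter) are labeled non-aggregators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class LabeledDataset:
    """Labeled ScoredPeptide table plus provenance of the labeling run."""

    records: pd.DataFrame
    library_id: str = "NNK1"
    shift: float = 0.0
    alpha: float = 0.05

    def report(self) -> dict:
        n_pos = int((self.records["label"] == 1).sum())
        return {
            "library_id": self.library_id,
            "n": len(self.records),
            "n_aggregators": n_pos,
            "n_non_aggregators": len(self.records) - n_pos,
            "shift": self.shift,
            "alpha": self.alpha,
        }


def filter_min_reads(records: pd.DataFrame, threshold: int = 100) -> pd.DataFrame:
    """Keep records with input_reads >= threshold ("fewer than 100" removed)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return records[records["input_reads"] >= threshold].reset_index(drop=True)


def estimate_mode(scores: np.ndarray) -> float:
    """Mode of a continuous score distribution via Gaussian KDE (Silverman
    bandwidth) evaluated on a fine grid."""
    scores = np.asarray(scores, dtype=float)
    if np.ptp(scores) == 0:
        return float(scores[0])
    kde = stats.gaussian_kde(scores, bw_method="silverman")
    grid = np.linspace(scores.min(), scores.max(), 2001)
    return float(grid[np.argmax(kde(grid))])


def center_scores(records: pd.DataFrame, min_records: int = 50) -> tuple[pd.DataFrame, float]:
    """Subtract the estimated score mode; returns (centered records, shift).

    The shift is the mode of the observed (non-missing) scores; with
    non-aggregators forming the bulk of the library this is the
    non-aggregator mode.
    """
    present = records["score"].dropna()
    if len(present) < min_records:
        raise ValueError(
            f"mode estimation needs >= {min_records} scored records, got {len(present)}"
        )
    shift = estimate_mode(present.to_numpy())
    out = records.copy()
    out["score"] = out["score"] - shift
    return out, shift


def classify(records: pd.DataFrame, alpha: float = 0.05) -> LabeledDataset:
    """One-sided Z test with BH-FDR adjustment; adjusted p <= alpha -> aggregator.

    Missing-score records are labeled non-aggregators without entering the
    FDR adjustment.
    """
    out = records.copy()
    present = out["score"].notna()
    err = out.loc[present, "error"]
    if (err <= 0).any():
        raise ValueError("error must be > 0 for every scored record")
    z = out.loc[present, "score"] / err
    p = stats.norm.sf(z)
    label = np.zeros(len(out), dtype=int)
    if present.any():
        rejected, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
        label[np.flatnonzero(present.to_numpy())] = rejected.astype(int)
    out["label"] = label
    return LabeledDataset(records=out, alpha=alpha)


def process_library(records: pd.DataFrame, library_id: str = "NNK1",
                    read_threshold: int = 100, alpha: float = 0.05) -> LabeledDataset:
    """Full labeling pipeline for one library.

    filter reads -> center -> classify -> truncate at stop -> dedup.  Each
    library is processed independently (centering and FDR are per library).
    """
    from canya.encoding import dedup_truncated, truncate_at_stop

    df = filter_min_reads(records, read_threshold)
    df, shift = center_scores(df)
    labeled = classify(df, alpha=alpha)
    df = labeled.records
    df = df.assign(aa_seq=[truncate_at_stop(s) for s in df["aa_seq"]])
    df = dedup_truncated(df)
    return LabeledDataset(records=df.reset_index(drop=True), library_id=library_id,
                          shift=shift, alpha=alpha)
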