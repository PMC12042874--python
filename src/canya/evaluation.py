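"""Metrics with bootstrap CIs, simple baselines, and evaluation-task builders.

Baselines: summed Kyte-Doolittle hydrophobicity (pluggable scale) and a
logistic regression on the 20-dimensional residue-count composition.  Task
builders reproduce the external-dataset constructions: a length/whitespace
filter for peptide repositories and a "context-free" task that pits
annotated amyloidogenic regions against equal-length chunks of the same
proteins with the regions excised.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc, precision_recall_curve, roc_auc_score

from canya.encoding import AA_ALPHABET


def auroc_auprc(scores, labels, n_boot: int = 1000, seed: int = 0) -> dict:
    """Rank-based AUROC and trapezoidal AUPR with percentile-bootstrap CIs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required")
    precision, recall, _ = precision_recall_curve(labels, scores)
    out = {
        "auroc": float(roc_auc_score(labels, scores)),
        "aupr": float(auc(recall, precision)),
        "n_pos": int(labels.sum()),
        "n_neg": int(len(labels) - labels.sum()),
    }
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        rocs, prs = [], []
        for _ in range(n_boot):
            idx = rng.integers(0, len(labels), size=len(labels))
            if len(np.unique(labels[idx])) < 2:
                continue
            rocs.append(roc_auc_score(labels[idx], scores[idx]))
            p, r, _ = precision_recall_curve(labels[idx], scores[idx])
            prs.append(auc(r, p))
        out["auroc_ci"] = (float(np.percentile(rocs, 2.5)), float(np.percentile(rocs, 97.5)))
        out["aupr_ci"] = (float(np.percentile(prs, 2.5)), float(np.percentile(prs, 97.5)))
    return out


def hydrophobicity_baseline(sequences: list[str], scale: dict[str, float] | None = None
                            ) -> np.ndarray:
    """Summed per-residue hydrophobicity (Kyte-Doolittle by default)."""
    if not sequences:
        raise ValueError("sequences must be nonempty")
    if scale is None:
        scale = KYTE_DOOLITTLE
    if not scale:
        raise ValueError("empty hydrophobicity scale")
    try:
        return np.array([sum(scale[aa] for aa in seq) for seq in sequences])
    except KeyError as e:
        raise ValueError(f"residue {e} missing from the hydrophobicity scale") from None


def composition_features(sequences: list[str]) -> np.ndarray:
    """20-dimensional residue-count features."""
    X = np.zeros((len(sequences), 20))
    for i, seq in enumerate(sequences):
        for aa in seq:
            X[i, AA_ALPHABET.index(aa)] += 1
    return X


def composition_baseline(train_sequences: list[str], train_labels,
                         test_sequences: list[str], seed: int = 0) -> np.ndarray:
    """Logistic regression on residue counts; returns test probabilities.

    The fit is L2-regularised, which also covers degenerate (collinear or
    constant) composition features.
    """
    Xtr = composition_features(train_sequences)
    Xte = composition_features(test_sequences)
    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit(Xtr, np.asarray(train_labels, dtype=int))
    return clf.predict_proba(Xte)[:, 1]


def build_context_free_task(proteins: list[tuple[str, list[tuple[int, int]]]],
                            seed: int = 0) -> pd.DataFrame:
    """Amyloidogenic regions vs equal-length chunks of the excised remainder.

    ``proteins`` holds (sequence, spans) with 1-based inclusive region
    spans.  Positives are the region sequences.  Per region, the remainder
    of its protein (all regions removed, parts concatenated) is cut into
    consecutive non-overlapping chunks of the region's length (a short tail
    is discarded).  Negatives are then downsampled (seeded) to match the
    positive count exactly.
    """
    positives, negatives = [], []
    for sequence, spans in proteins:
        if not spans:
            raise ValueError("every protein needs >= 1 region span")
        for start, end in spans:
            if not (1 <= start <= end <= len(sequence)):
                raise ValueError(f"span ({start}, {end}) outside sequence bounds")
        keep = np.ones(len(sequence), dtype=bool)
        for start, end in spans:
            keep[start - 1:end] = False
        remainder = "".join(c for c, k in zip(sequence, keep) if k)
        for start, end in spans:
            region = sequence[start - 1:end]
            positives.append(region)
            L = len(region)
            if len(remainder) < L:
                warnings.warn("region covers (almost) the whole sequence; "
                              "no negatives from this protein")
                continue
            negatives.extend(remainder[i:i + L] for i in range(0, len(remainder) - L + 1, L))
    rng = np.random.default_rng(seed)
    if len(negatives) < len(positives):
        raise ValueError("not enough negative chunks to balance the task")
    idx = rng.choice(len(negatives), size=len(positives), replace=False)
    rows = [{"aa_seq": s, "label": 1} for s in positives]
    rows += [{"aa_seq": negatives[i], "label": 0} for i in idx]
    return pd.DataFrame(rows)


def build_length_filtered_task(records: pd.DataFrame, min_len: int = 10,
                               seq_col: str = "aa_seq",
                               class_col: str = "classification") -> pd.DataFrame:
    """Keep records of length >= min_len without whitespace; the amyloid
    classification field maps to label 1, everything else to 0."""
    if len(records) == 0:
        return records.assign(label=pd.Series(dtype=int))
    seqs = records[seq_col].astype(str)
    ok = (seqs.str.len() >= min_len) & ~seqs.str.contains(r"\s")
    out = records[ok].copy()
    out["label"] = (out[class_col].astype(str).str.lower() == "amyloid").astype(int)
    return out.reset_index(drop=True)
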