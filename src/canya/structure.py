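"""Secondary-structure enrichment of motif clusters.

Given per-residue annotations (strand / coil / disorder) for amyloid
proteins, a cluster's activation profile along each sequence is the maximum
activation energy over its member filters at every kmer window, assigned to
the window's center residue (terminal residues carry no value and are
excluded).  Enrichment of a cluster in a structure class is the AUROC of
the concatenated activation values against the binary structure indicator,
with a percentile-bootstrap CI over residues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

STRUCTURE_LABELS = ("strand", "coil", "disorder")


@dataclass
class StructureAnnotation:
    """One annotated sequence: per-residue labels in {strand, coil, disorder}."""

    seq_id: str
    sequence: str
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequence):
            raise ValueError(
                f"{self.seq_id}: {len(self.labels)} labels for "
                f"{len(self.sequence)} residues")
        bad = set(self.labels) - set(STRUCTURE_LABELS)
        if bad:
            raise ValueError(f"{self.seq_id}: unknown labels {sorted(bad)}")


def annotations_to_tsv(annotations: list[StructureAnnotation], path) -> None:
    rows = [
        {"seq_id": a.seq_id, "position": i + 1, "residue": r, "label": l}
        for a in annotations for i, (r, l) in enumerate(zip(a.sequence, a.labels))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def annotations_from_tsv(path) -> list[StructureAnnotation]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for seq_id, g in df.groupby("seq_id", sort=False):
        g = g.sort_values("position")
        out.append(StructureAnnotation(seq_id=str(seq_id),
                                       sequence="".join(g["residue"]),
                                       labels=g["label"].tolist()))
    return out


def cluster_activation_profile(results, cluster, annotation: StructureAnnotation
                               ) -> np.ndarray:
    """Per-center-residue max activation over the cluster's member filters.

    Returns a vector of length L - 2 aligned to residues 2..L-1 (1-based);
    the first and last residues have no centered kmer and are excluded.
    """
    members = cluster.members if hasattr(cluster, "members") else list(cluster)
    if not members:
        raise ValueError("empty cluster")
    acts = results.filter_activations(annotation.sequence)  # (L-2, n_filters)
    return acts[:, members].max(axis=1)


def enrichment_auroc(results, cluster, annotations: list[StructureAnnotation],
                     structure_label: str, n_boot: int = 200, seed: int = 0
                     ) -> dict:
    """AUROC of cluster activation vs a structure class, concatenated across
    sequences, with a bootstrap CI over residues."""
    if structure_label not in STRUCTURE_LABELS:
        raise ValueError(f"unknown structure label {structure_label!r}")
    values, flags = [], []
    for ann in annotations:
        prof = cluster_activation_profile(results, cluster, ann)
        values.append(prof)
        flags.append(np.array([l == structure_label for l in ann.labels[1:-1]], dtype=int))
    x = np.concatenate(values)
    y = np.concatenate(flags)
    if len(np.unique(y)) < 2:
        raise ValueError(f"both classes required for {structure_label!r} AUROC")
    point = float(roc_auc_score(y, x))
    ci = (np.nan, np.nan)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(y), size=len(y))
            if len(np.unique(y[idx])) < 2:
                continue
            boots.append(roc_auc_score(y[idx], x[idx]))
        if boots:
            ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return {"structure": structure_label, "auroc": point,
            "ci_low": ci[0], "ci_high": ci[1], "n_residues": len(y)}
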