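"""Replicate training and KL-divergence model selection.

Random weight initialisation makes every trained instance a different local
optimum; to pick one for interpretability work, each replicate gets an
*interpretability score*: the KL divergence between the distribution of
3-mers found at each test sequence's top-attributed position (P) and the
distribution of all 3-mers in those sequences (Q).  A model whose
attributions concentrate on recurrent motifs has large KL; a model whose
attributions are diffuse has KL near 0.  The selection rule keeps replicates
whose mean AUPR across libraries exceeds the median of those means and,
among them, returns the one with the highest interpretability score.

The attribution used here is input-gradient saliency, mean-centered across
the 20 channels at each position (removing the off-simplex component of the
gradient, which carries no information for one-hot inputs), read out at the
observed residue; the top-1 position per sequence defines a 3-mer window
centered there and clipped at the sequence edges.  The attribution function
is pluggable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from canya.encoding import AA_ALPHABET, PAD
from canya.evaluation import auroc_auprc
from canya.model import CanyaModel, CanyaResults, ModelConfig

KMER_LEN = 3
ALL_KMERS = ["".join(k) for k in itertools.product(AA_ALPHABET, repeat=KMER_LEN)]
_KMER_INDEX = {k: i for i, k in enumerate(ALL_KMERS)}


@dataclass
class ReplicateSummary:
    model_id: int
    per_library: pd.DataFrame  # columns: library_id, auroc, aupr
    mean_aupr: float
    interpretability_score: float = float("nan")


def saliency_attribution(results: CanyaResults, sequences: list[str]) -> list[int]:
    """Top-attributed residue position (0-based) per sequence.

    Channel-mean-centered input gradient at the observed residue; the
    position with the largest absolute attribution wins.
    """
    grad = results.input_gradient(sequences)  # (B, 24, 20)
    grad = grad - grad.mean(axis=2, keepdims=True)
    tops = []
    for g, seq in zip(grad, sequences):
        L = len(seq)
        attr = np.array([g[PAD + i, AA_ALPHABET.index(aa)] for i, aa in enumerate(seq)])
        tops.append(int(np.argmax(np.abs(attr))) if L else 0)
    return tops


def attributed_kmers(sequences: list[str], top_positions: list[int]) -> list[str]:
    """3-mer window centered at each top position, clipped at the edges."""
    kmers = []
    for seq, c in zip(sequences, top_positions):
        if len(seq) < KMER_LEN:
            continue
        start = min(max(c - 1, 0), len(seq) - KMER_LEN)
        kmers.append(seq[start:start + KMER_LEN])
    return kmers


def sequence_kmers(sequences: list[str]) -> list[str]:
    return [s[i:i + KMER_LEN] for s in sequences for i in range(len(s) - KMER_LEN + 1)]


def kl_from_kmers(attributed: list[str], background: list[str],
                  pseudocount: float = 0.5) -> float:
    """KL(P||Q) in nats between two 3-mer samples over the 8,000-kmer bins."""
    if not attributed or not background:
        raise ValueError("both kmer samples must be nonempty")
    from collections import Counter

    p = np.full(len(ALL_KMERS), pseudocount)
    q = np.full(len(ALL_KMERS), pseudocount)
    for k, c in Counter(attributed).items():
        p[_KMER_INDEX[k]] += c
    for k, c in Counter(background).items():
        q[_KMER_INDEX[k]] += c
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)))


def interpretability_score(results: CanyaResults, sequences: list[str],
                           pseudocount: float = 0.5,
                           attribution=saliency_attribution) -> float:
    """KL divergence (nats) of attributed vs background 3-mer distributions."""
    sequences = [s for s in sequences if len(s) >= KMER_LEN]
    if len(sequences) < 100:
        raise ValueError("interpretability score needs >= 100 sequences")
    tops = attribution(results, sequences)
    return kl_from_kmers(attributed_kmers(sequences, tops),
                         sequence_kmers(sequences), pseudocount)


def select_model(replicates: list[ReplicateSummary]) -> int:
    """Highest interpretability score among replicates whose mean AUPR
    exceeds the median of mean AUPRs; ties break by model_id."""
    if len(replicates) < 2:
        raise ValueError("need >= 2 replicates")
    means = np.array([r.mean_aupr for r in replicates])
    med = float(np.median(means))
    pool = [r for r in replicates if r.mean_aupr > med]
    if not pool:  # degenerate all-equal AUPRs: fall back to >= median
        pool = [r for r in replicates if r.mean_aupr >= med]
    best = max(pool, key=lambda r: (r.interpretability_score, -r.model_id))
    return best.model_id


def train_replicates(dataset: pd.DataFrame, n_replicates: int, base_seed: int,
                     config: ModelConfig | None = None,
                     test_fraction: float = 0.1, epochs: int | None = None,
                     score_interpretability: bool = True,
                     seq_col: str = "aa_seq", label_col: str = "label",
                     library_col: str = "library_id"
                     ) -> list[tuple[CanyaResults, ReplicateSummary]]:
    """Train replicate models (seeds ``base_seed + i``) on a shared
    train/test split; summaries carry per-library test AUROC/AUPR and the
    interpretability score."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    from sklearn.model_selection import train_test_split

    df = dataset.reset_index(drop=True)
    if library_col not in df.columns:
        df = df.assign(**{library_col: "NNK1"})
    idx_train, idx_test = train_test_split(
        np.arange(len(df)), test_size=test_fraction,
        stratify=df[label_col], random_state=base_seed % (2**32))
    train_df, test_df = df.iloc[idx_train], df.iloc[idx_test]
    test_seqs = [s for s in test_df[seq_col] if len(s) >= KMER_LEN]

    out = []
    for i in range(n_replicates):
        seed = base_seed + i
        model = CanyaModel.from_dataframe(train_df, seq_col, label_col, config=config)
        results = model.fit(seed=seed, epochs=epochs)
        rows = []
        for lib, g in test_df.groupby(library_col):
            scores = results.pre_activation(g[seq_col].tolist())
            rep = auroc_auprc(scores, g[label_col].to_numpy(), n_boot=0)
            rows.append({"library_id": lib, "auroc": rep["auroc"], "aupr": rep["aupr"]})
        per_lib = pd.DataFrame(rows)
        summary = ReplicateSummary(model_id=i, per_library=per_lib,
                                   mean_aupr=float(per_lib["aupr"].mean()))
        if score_interpretability:
            summary.interpretability_score = interpretability_score(results, test_seqs)
        out.append((results, summary))
    return out
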