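"""Sequence hygiene and the 24x20 model input encoding.

A library peptide is up to 20 residues; sequences read through an amber stop
are truncated at the first ``*`` and duplicates arising from truncation are
merged (mean score, modal label; exact label ties dropped).  The network
consumes a fixed 24-row x 20-channel matrix laid out as::

    [0, 0, one-hot(L), 0, 0, mask rows of -1]

i.e. two zero-pad rows flank the one-hot residues and, for L < 20, rows of
-1 fill the matrix to 24 rows.  Channels are the 20 canonical amino acids in
alphabetical one-letter order, fixed so saved weights are portable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
N_CHANNELS = 20
N_ROWS = 24
MAX_LEN = 20
PAD = 2


def truncate_at_stop(raw: str) -> str:
    """Prefix of ``raw`` before the first ``*`` (whole sequence if none).

    Raises ``ValueError`` on characters outside the 20 canonical amino acids
    and ``*``.
    """
    if not raw:
        raise ValueError("empty sequence")
    raw = raw.upper()
    bad = set(raw) - set(AA_ALPHABET) - {"*"}
    if bad:
        raise ValueError(f"non-amino-acid characters {sorted(bad)} in {raw!r}")
    stop = raw.find("*")
    return raw if stop < 0 else raw[:stop]


def dedup_truncated(records: pd.DataFrame, seq_col: str = "aa_seq",
                    score_col: str = "score", label_col: str = "label") -> pd.DataFrame:
    """Merge duplicate (post-truncation) sequences.

    Per duplicate group the score becomes the mean and the label the mode;
    groups whose aggregator/non-aggregator counts tie exactly are discarded.
    """
    labels = records[label_col]
    if not set(labels.unique()) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")

    def _merge(g: pd.DataFrame):
        pos = int((g[label_col] == 1).sum())
        neg = len(g) - pos
        if pos == neg:
            return None
        row = g.iloc[0].copy()
        row[score_col] = g[score_col].mean()
        row[label_col] = 1 if pos > neg else 0
        return row

    merged = [
        row for _, g in records.groupby(seq_col, sort=False)
        if (row := _merge(g)) is not None
    ]
    out = pd.DataFrame(merged).reset_index(drop=True)
    return out[records.columns] if len(out) else records.iloc[0:0]


def encode(seq: str) -> np.ndarray:
    """Encode one truncated peptide (L <= 20) into the 24x20 input matrix."""
    if "*" in seq:
        raise ValueError("sequence must be truncated before encoding")
    L = len(seq)
    if L > MAX_LEN:
        raise ValueError(
            f"length {L} > {MAX_LEN}: use the sliding-window scorer for long sequences"
        )
    m = np.zeros((N_ROWS, N_CHANNELS))
    for i, aa in enumerate(seq):
        try:
            m[PAD + i, AA_INDEX[aa]] = 1.0
        except KeyError:
            raise ValueError(f"unknown residue {aa!r}") from None
    # mask rows follow the downstream zero-pad
    m[PAD + L + PAD:, :] = -1.0
    return m


def encode_batch(seqs: list[str]) -> np.ndarray:
    return np.stack([encode(s) for s in seqs])


def decode(matrix: np.ndarray) -> str:
    """Recover the residue string from the one-hot block of an encoding."""
    residues = []
    for row in matrix[PAD:]:
        if np.all(row == 0) or np.all(row == -1):
            break
        residues.append(AA_ALPHABET[int(np.argmax(row))])
    return "".join(residues)


def one_hot(seq: str) -> np.ndarray:
    """Plain L x 20 one-hot (no padding/mask), for arbitrary-length sequences."""
    m = np.zeros((len(seq), N_CHANNELS))
    for i, aa in enumerate(seq):
        try:
            m[i, AA_INDEX[aa]] = 1.0
        except KeyError:
            raise ValueError(f"unknown residue {aa!r}") from None
    return m


# ---------------------------------------------------------------------------
# file formats

def read_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs; wrapped or unwrapped lines, case-insensitive."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[tuple[str, str]], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_score_table(path) -> pd.DataFrame:
    """Tab-delimited ScoredPeptide table; missing scores parse as NaN."""
    return pd.read_csv(path, sep="\t", na_values=["NA", ""])
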