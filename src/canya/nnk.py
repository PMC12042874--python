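"""Synthetic NNK peptide libraries with a planted aggregation grammar.

NNK degenerate codons (N = A/C/G/T, K = G/T) span 32 codons covering all 20
amino acids plus the amber stop (TAG).  Sampling residues directly from the
NNK codon-count distribution reproduces the amino-acid and stop frequencies
of such a library without simulating DNA.  A :class:`GrammarSpec` plants a
known additive motif grammar (signed 3-mer effects with position-dependent
weights, optional pairwise interactions) so that every downstream stage —
labeling, model training, interpretability — can be checked against ground
truth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from canya.encoding import AA_ALPHABET

STOP = "*"

#: residue classes usable in grammar patterns (lowercase codes); an uppercase
#: letter in a pattern matches that literal residue, "x" matches anything.
RESIDUE_CLASSES: dict[str, frozenset[str]] = {
    "h": frozenset("ILVFWYM"),   # hydrophobic
    "q": frozenset("DEKR"),      # charged
    "d": frozenset("DEKRP"),     # charged or proline (aggregation-disrupting)
    "p": frozenset("P"),
    "x": frozenset(AA_ALPHABET),
}


def nnk_codon_counts() -> dict[str, int]:
    """Codon multiplicities per amino acid (and ``*``) under NNK.

    Derived from the standard genetic code by enumerating all N-N-K codons;
    the only reachable stop is the amber TAG.
    """
    table = CodonTable.unambiguous_dna_by_id[1]
    counts: dict[str, int] = {}
    for codon in ("".join(c) for c in itertools.product("ACGT", "ACGT", "GT")):
        aa = table.forward_table.get(codon, STOP)
        counts[aa] = counts.get(aa, 0) + 1
    return counts


def nnk_symbols_and_probs() -> tuple[list[str], np.ndarray]:
    """Alphabetically ordered NNK symbols (incl. ``*``) and their frequencies."""
    counts = nnk_codon_counts()
    symbols = sorted(counts)
    probs = np.array([counts[s] for s in symbols], dtype=float)
    return symbols, probs / probs.sum()


def sample_nnk_peptides(n: int, length: int = 20, seed: int | None = None) -> list[str]:
    """Sample ``n`` random peptides of ``length`` residues from the NNK table.

    Each position is drawn independently with amino acids weighted by their
    NNK codon count; the amber stop appears as ``*`` with probability 1/32.

    Parameters
    ----------
    n : int
        Number of peptides (>= 1).
    length : int
        Residues per peptide, 1..20.
    seed : int, optional
        Seed for bit-reproducible sampling.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 1 <= length <= 20:
        raise ValueError(f"length must be in 1..20, got {length}")
    symbols, probs = nnk_symbols_and_probs()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(symbols), size=(n, length), p=probs)
    arr = np.array(symbols)
    return ["".join(row) for row in arr[idx]]


def _compile_pattern(pattern: str) -> list[frozenset[str]]:
    if len(pattern) != 3:
        raise ValueError(f"grammar patterns must be 3-mers, got {pattern!r}")
    sets = []
    for ch in pattern:
        if ch in RESIDUE_CLASSES:
            sets.append(RESIDUE_CLASSES[ch])
        elif ch in AA_ALPHABET:
            sets.append(frozenset(ch))
        else:
            raise ValueError(f"unknown pattern symbol {ch!r} in {pattern!r}")
    return sets


@dataclass
class GrammarSpec:
    """Planted aggregation grammar for the synthetic library.

    Attributes
    ----------
    motif_effects : list of (pattern, effect)
        3-mer patterns over residue classes (see :data:`RESIDUE_CLASSES`)
        with signed additive effect sizes.  The default plants a
        hydrophobic-positive and a charged/proline-negative motif.
    position_weight : array of 18 positive multipliers
        Per-window weight over the 18 possible 3-mer start positions of a
        length-20 peptide; the default declines linearly from 1.5 (N
        terminus) to 0.5 (C terminus).
    interaction_terms : list of ((patternA, patternB), epsilon)
        Optional pairwise epistasis: epsilon * count(A) * count(B) is added
        to the latent score (unweighted by position).
    noise_sd : float
        SD of the Gaussian measurement error added to the latent score.
    read_mean, read_dispersion : float
        Negative-binomial input-read model; the default mean of 500 leaves a
        small tail below the 100-read filter.
    seed : int
        Generation seed.
    """

    motif_effects: list[tuple[str, float]] = field(
        default_factory=lambda: [("hhh", 1.0), ("ddd", -0.8)]
    )
    position_weight: np.ndarray = field(
        default_factory=lambda: np.linspace(1.5, 0.5, 18)
    )
    interaction_terms: list[tuple[tuple[str, str], float]] = field(default_factory=list)
    noise_sd: float = 0.3
    read_mean: float = 500.0
    read_dispersion: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.position_weight = np.asarray(self.position_weight, dtype=float)
        if self.position_weight.shape != (18,):
            raise ValueError("position_weight must have exactly 18 entries")
        if not np.all(self.position_weight > 0):
            raise ValueError("position_weight entries must all be > 0")
        for pat, eff in self.motif_effects:
            _compile_pattern(pat)
            if not np.isfinite(eff):
                raise ValueError(f"effect for {pat!r} is not finite")
        for (pa, pb), eps in self.interaction_terms:
            _compile_pattern(pa)
            _compile_pattern(pb)
            if not np.isfinite(eps):
                raise ValueError("interaction epsilon is not finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _match_count(seq: str, sets: list[frozenset[str]], weights: np.ndarray) -> tuple[float, int]:
    """Weighted and raw counts of pattern matches over all 3-mer windows."""
    total = 0.0
    raw = 0
    for start in range(len(seq) - 2):
        if seq[start] in sets[0] and seq[start + 1] in sets[1] and seq[start + 2] in sets[2]:
            w = weights[start] if start < len(weights) else weights[-1]
            total += w
            raw += 1
    return total, raw


def latent_score(seq: str, grammar: GrammarSpec) -> float:
    """Ground-truth additive score of one peptide under the grammar.

    Windows containing ``*`` match no pattern (the stop symbol belongs to no
    residue class), so stop-containing peptides only accrue effects from
    windows upstream of the stop.
    """
    score = 0.0
    counts: dict[str, int] = {}
    for pat, eff in grammar.motif_effects:
        weighted, raw = _match_count(seq, _compile_pattern(pat), grammar.position_weight)
        score += eff * weighted
        counts[pat] = raw
    for (pa, pb), eps in grammar.interaction_terms:
        _, ca = _match_count(seq, _compile_pattern(pa), grammar.position_weight)
        _, cb = _match_count(seq, _compile_pattern(pb), grammar.position_weight)
        score += eps * ca * cb
    return score


def score_library(peptides: list[str], grammar: GrammarSpec) -> pd.DataFrame:
    """Score peptides under the grammar; returns the ScoredPeptide table.

    Columns: ``aa_seq``, ``latent``, ``score`` (latent + Gaussian noise),
    ``error`` (= ``noise_sd``), ``input_reads`` (negative binomial) and
    ``truth_label`` (1 where latent > 0).
    """
    rng = np.random.default_rng(grammar.seed)
    latent = np.array([latent_score(p, grammar) for p in peptides])
    noise = rng.normal(0.0, grammar.noise_sd, size=len(peptides)) if grammar.noise_sd > 0 else 0.0
    # NB parameterised by mean m and dispersion k: p = k/(k+m)
    k = grammar.read_dispersion
    p = k / (k + grammar.read_mean)
    reads = rng.negative_binomial(k, p, size=len(peptides))
    return pd.DataFrame(
        {
            "aa_seq": peptides,
            "latent": latent,
            "score": latent + noise,
            "error": float(grammar.noise_sd) if grammar.noise_sd > 0 else 1e-12,
            "input_reads": reads,
            "truth_label": (latent > 0).astype(int),
        }
    )


def write_scored_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_scored_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# structure fixtures

_STRAND_RES = "IVF"
_DISORDER_RES = "DEKRP"
_COIL_RES = "AGSTNQHY"


def make_structure_fixtures(n: int, seed: int | None = None,
                            n_segments: tuple[int, int] = (6, 12),
                            segment_len: tuple[int, int] = (4, 12)):
    """Annotated protein-like sequences with planted secondary structure.

    Strand segments are hydrophobic stretches (residues from ``IVF``),
    disorder segments are charged/proline stretches, coil segments are drawn
    from polar/small residues; every residue carries exactly one label in
    {strand, coil, disorder}.  Returns a list of
    :class:`canya.structure.StructureAnnotation`.
    """
    from canya.structure import StructureAnnotation

    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    pools = {"strand": _STRAND_RES, "disorder": _DISORDER_RES, "coil": _COIL_RES}
    out = []
    for i in range(n):
        segs = rng.integers(n_segments[0], n_segments[1] + 1)
        seq_parts: list[str] = []
        labels: list[str] = []
        prev = None
        for _ in range(segs):
            choices = [s for s in ("strand", "coil", "disorder") if s != prev]
            kind = choices[rng.integers(len(choices))]
            prev = kind
            length = int(rng.integers(segment_len[0], segment_len[1] + 1))
            pool = pools[kind]
            seq_parts.append("".join(pool[j] for j in rng.integers(len(pool), size=length)))
            labels.extend([kind] * length)
        out.append(StructureAnnotation(seq_id=f"fixture_{i}", sequence="".join(seq_parts), labels=labels))
    return out
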