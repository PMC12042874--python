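"""Filter motifs, BLOSUM clustering and Global Importance Analysis (GIA).

A trained filter is summarised by the 3-mers that activate it most: over
the exhaustive universe of all 8,000 3-mers, the filter's activation energy
is computed analytically as exp(sum of the filter weights at the kmer's
one-hot entries + bias); the PWM keeps at most the 10 top-activating kmers,
restricted to those within 75% of the maximum.  PWMs are projected through
BLOSUM62 (PWM . BLOSUM, flattened) and clustered by affinity propagation;
clusters are pruned so all members share the effect-size sign of their
strongest member.

GIA measures effect sizes causally: embed a sampled kmer into background
sequences and average the paired change in the model's pre-sigmoid score.
Five experiment designs are provided: single filter/cluster importance,
multiplicity (1..4 non-overlapping copies, with a linearity R^2),
positional profiles over start positions 1..18, and pairwise interactions
(deviation of the joint effect from the sum of marginals, with a paired t
test Bonferroni-corrected across cluster pairs).

Any object with a ``pre_activation(list[str]) -> ndarray`` method can stand
in for the trained model, which lets additive surrogate models serve as
exact oracles in tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy import stats
from sklearn.cluster import AffinityPropagation

from canya.encoding import AA_ALPHABET, MAX_LEN
from canya.model import CanyaResults

KMER_LEN = 3
N_KMERS = 20 ** KMER_LEN  # 8,000
#: valid 1-based start positions for embedding a 3-mer in a 20-mer: 1..18
N_EMBED_POSITIONS = MAX_LEN - KMER_LEN + 1


@dataclass
class MotifPWM:
    """A filter's motif: selected kmers with activation energies and the
    per-position residue-frequency matrix (3 x 20, rows sum to 1)."""

    filter_id: int
    kmer_set: list[tuple[str, float]]
    pwm: np.ndarray

    @property
    def kmers(self) -> list[str]:
        return [k for k, _ in self.kmer_set]


@dataclass
class MotifCluster:
    cluster_id: int
    members: list[int]
    pwms: dict[int, MotifPWM]
    importances: dict[int, float]
    sign: int
    pruned: list[int] = field(default_factory=list)


@dataclass
class GIAResult:
    experiment: str
    feature_ids: tuple
    importance: float
    ci: tuple[float, float]
    n_backgrounds: int
    positions: tuple | None = None
    p_value: float | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# kmer activation energies and PWMs

def kmer_activation_energies(results: CanyaResults) -> np.ndarray:
    """Analytic activation energies of all 8,000 3-mers: (8000, n_filters).

    Row order is lexicographic over the alphabetical amino-acid channels;
    energy = exp(w[0, a] + w[1, b] + w[2, c] + bias).
    """
    w = results.params["conv_w"]  # (3, 20, F)
    b = results.params["conv_b"]
    z = (w[0][:, None, None, :] + w[1][None, :, None, :] + w[2][None, None, :, :])
    return np.exp(z.reshape(N_KMERS, -1) + b)


def kmer_string(index: int) -> str:
    a, rem = divmod(index, 400)
    b, c = divmod(rem, 20)
    return AA_ALPHABET[a] + AA_ALPHABET[b] + AA_ALPHABET[c]


def extract_pwm(results: CanyaResults, filter_id: int,
                energies: np.ndarray | None = None,
                top_n: int = 10, frac_of_max: float = 0.75) -> MotifPWM:
    """PWM of one filter from its top-activating kmers.

    Selection rule: kmers with activation >= ``frac_of_max`` of the maximum,
    capped at the ``top_n`` strongest; ties break by descending activation
    then lexicographic kmer.
    """
    if energies is None:
        energies = kmer_activation_energies(results)
    act = energies[:, filter_id]
    threshold = frac_of_max * act.max()
    candidates = np.flatnonzero(act >= threshold)
    order = sorted(candidates, key=lambda i: (-act[i], kmer_string(i)))
    chosen = order[:top_n]
    kmer_set = [(kmer_string(i), float(act[i])) for i in chosen]
    pwm = np.zeros((KMER_LEN, 20))
    for kmer, _ in kmer_set:
        for pos, aa in enumerate(kmer):
            pwm[pos, AA_ALPHABET.index(aa)] += 1
    pwm /= len(kmer_set)
    return MotifPWM(filter_id=filter_id, kmer_set=kmer_set, pwm=pwm)


# ---------------------------------------------------------------------------
# clustering

def _blosum62_matrix() -> np.ndarray:
    """BLOSUM62 restricted to the 20 canonical residues, alphabetical order."""
    m = substitution_matrices.load("BLOSUM62")
    idx = [m.alphabet.index(aa) for aa in AA_ALPHABET]
    return np.asarray(m)[np.ix_(idx, idx)]


def blosum_features(pwms: list[MotifPWM]) -> np.ndarray:
    """PWM . BLOSUM62 per filter, flattened to a 60-vector."""
    B = _blosum62_matrix()
    return np.stack([(p.pwm @ B).ravel() for p in pwms])


def blosum_cluster(pwms: list[MotifPWM], filter_importances: dict[int, float],
                   seed: int = 0, damping: float = 0.7) -> list[MotifCluster]:
    """Affinity propagation on BLOSUM-projected PWMs, then sign pruning.

    Within each raw cluster, the member with the largest absolute GIA
    importance sets the cluster sign; members with the opposite sign are
    removed (recorded in ``pruned``).
    """
    if len(pwms) < 2:
        raise ValueError("need >= 2 PWMs to cluster")
    X = blosum_features(pwms)
    labels = None
    for damp in (damping, min(0.95, damping + 0.2)):
        ap = AffinityPropagation(damping=damp, random_state=seed, max_iter=500)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitted = ap.fit(X)
        if len(fitted.cluster_centers_indices_) > 0:
            labels = fitted.labels_
            break
    if labels is None:
        raise RuntimeError("affinity propagation failed to converge")

    clusters = []
    for cid in sorted(set(labels)):
        member_idx = [i for i, l in enumerate(labels) if l == cid]
        fids = [pwms[i].filter_id for i in member_idx]
        imps = {f: filter_importances[f] for f in fids}
        lead = max(fids, key=lambda f: abs(imps[f]))
        sign = 1 if imps[lead] >= 0 else -1
        kept = [f for f in fids if np.sign(imps[f]) == sign or imps[f] == 0]
        pruned = [f for f in fids if f not in kept]
        clusters.append(MotifCluster(
            cluster_id=int(cid), members=kept,
            pwms={pwms[i].filter_id: pwms[i] for i in member_idx
                  if pwms[i].filter_id in kept},
            importances={f: imps[f] for f in kept}, sign=sign, pruned=pruned))
    return clusters


# ---------------------------------------------------------------------------
# GIA machinery

def select_backgrounds(results: CanyaResults, records: pd.DataFrame,
                       n: int = 25_000, thresholds: tuple[float, float] = (0.3, 0.2),
                       seed: int = 0, seq_col: str = "aa_seq",
                       label_col: str = "label") -> list[str]:
    """Confidently predicted full-length training sequences for GIA.

    Keeps length-20, stop-free sequences that are aggregators with predicted
    probability above ``thresholds[0]`` or non-aggregators below
    ``thresholds[1]``; samples ``n`` of them (seeded), warning if fewer
    qualify.
    """
    full = records[records[seq_col].str.len() == MAX_LEN].reset_index(drop=True)
    if len(full) == 0:
        raise ValueError("no full-length sequences available")
    probs = results.predict(full[seq_col].tolist())
    qualify = ((full[label_col] == 1) & (probs > thresholds[0])) | (
        (full[label_col] == 0) & (probs < thresholds[1]))
    pool = full.loc[qualify.to_numpy(), seq_col].tolist()
    if not pool:
        raise ValueError("no sequences pass the confidence thresholds")
    rng = np.random.default_rng(seed)
    if len(pool) < n:
        warnings.warn(f"only {len(pool)} qualifying backgrounds (requested {n})")
        n = len(pool)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in idx]


def _kmer_probs(pwm: MotifPWM) -> tuple[list[str], np.ndarray]:
    acts = np.array([a for _, a in pwm.kmer_set])
    ratios = acts / acts.max()
    return pwm.kmers, ratios / ratios.sum()


def sample_kmer(feature, rng: np.random.Generator) -> str:
    """Activation-ratio sampling from a PWM; filter-first then kmer-second
    (|importance|-ratio weights) for a cluster."""
    if isinstance(feature, MotifCluster):
        fids = feature.members
        imps = np.array([abs(feature.importances[f]) for f in fids])
        if imps.max() == 0:
            probs = np.full(len(fids), 1 / len(fids))
        else:
            ratios = imps / imps.max()
            probs = ratios / ratios.sum()
        fid = fids[rng.choice(len(fids), p=probs)]
        feature = feature.pwms[fid]
    kmers, probs = _kmer_probs(feature)
    return kmers[rng.choice(len(kmers), p=probs)]


def embed_kmer(seq: str, kmer: str, start: int) -> str:
    """Replace ``len(kmer)`` residues of ``seq`` at 0-based ``start``."""
    return seq[:start] + kmer + seq[start + len(kmer):]


def _mean_ci(diffs: np.ndarray) -> tuple[float, tuple[float, float]]:
    mean = float(diffs.mean())
    half = 1.96 * diffs.std(ddof=1) / np.sqrt(len(diffs)) if len(diffs) > 1 else 0.0
    return mean, (mean - half, mean + half)


def _feature_ids(feature) -> tuple:
    if isinstance(feature, MotifCluster):
        return ("cluster", feature.cluster_id)
    return ("filter", feature.filter_id)


def gia_importance(model, feature, backgrounds: list[str],
                   position_policy="uniform", seed: int = 0) -> GIAResult:
    """Mean paired pre-activation difference from embedding one kmer.

    ``position_policy`` is "uniform" (random start in 1..18, seeded) or a
    fixed 1-based start position.
    """
    if not backgrounds:
        raise ValueError("backgrounds must be nonempty")
    rng = np.random.default_rng(seed)
    if position_policy == "uniform":
        starts = rng.integers(0, N_EMBED_POSITIONS, size=len(backgrounds))
    else:
        p = int(position_policy)
        if not 1 <= p <= N_EMBED_POSITIONS:
            raise ValueError(f"position must be in 1..{N_EMBED_POSITIONS}")
        starts = np.full(len(backgrounds), p - 1)
    modified = [embed_kmer(s, sample_kmer(feature, rng), st)
                for s, st in zip(backgrounds, starts)]
    diffs = model.pre_activation(modified) - model.pre_activation(backgrounds)
    mean, ci = _mean_ci(diffs)
    kind = "cluster" if isinstance(feature, MotifCluster) else "single"
    return GIAResult(experiment=kind, feature_ids=_feature_ids(feature),
                     importance=mean, ci=ci, n_backgrounds=len(backgrounds))


def _sample_nonoverlapping(rng: np.random.Generator, existing: list[int],
                           max_tries: int = 100) -> int:
    for _ in range(max_tries):
        s = int(rng.integers(0, N_EMBED_POSITIONS))
        if all(abs(s - e) >= KMER_LEN for e in existing):
            return s
    raise RuntimeError("could not place a non-overlapping kmer")


def gia_multiplicity(model, cluster, backgrounds: list[str],
                     max_copies: int = 4, seed: int = 0) -> tuple[list[GIAResult], float]:
    """Importance at 1..max_copies embedded copies plus the R^2 of
    importance against copy number.

    Copies are added incrementally: the k-copy sequence keeps the k-1
    antecedent kmers at their original positions.
    """
    rng = np.random.default_rng(seed)
    base = model.pre_activation(backgrounds)
    current = list(backgrounds)
    placed: list[list[int]] = [[] for _ in backgrounds]
    out = []
    means = []
    for copies in range(1, max_copies + 1):
        nxt = []
        for i, seq in enumerate(current):
            start = _sample_nonoverlapping(rng, placed[i])
            placed[i].append(start)
            nxt.append(embed_kmer(seq, sample_kmer(cluster, rng), start))
        current = nxt
        diffs = model.pre_activation(current) - base
        mean, ci = _mean_ci(diffs)
        means.append(mean)
        out.append(GIAResult(experiment="multiplicity", feature_ids=_feature_ids(cluster),
                             importance=mean, ci=ci, n_backgrounds=len(backgrounds),
                             extra={"copies": copies}))
    k = np.arange(1, max_copies + 1, dtype=float)
    means = np.array(means)
    if np.allclose(means, means[0]):  # constant response: R^2 undefined
        return out, float("nan")
    r = stats.pearsonr(k, means).statistic
    return out, float(r ** 2)


def gia_positional(model, cluster, backgrounds: list[str], seed: int = 0
                   ) -> pd.DataFrame:
    """One fixed-position GIA per start position 1..18.

    Returns a frame with importance, CI and the percent change of each
    position's importance relative to the position-averaged (global) mean;
    percent change is NaN (flagged) when |global| is below 1e-9.
    """
    rows = []
    for pos in range(1, N_EMBED_POSITIONS + 1):
        res = gia_importance(model, cluster, backgrounds,
                             position_policy=pos, seed=seed + pos)
        rows.append({"position": pos, "importance": res.importance,
                     "ci_low": res.ci[0], "ci_high": res.ci[1]})
    df = pd.DataFrame(rows)
    global_mean = df["importance"].mean()
    if abs(global_mean) < 1e-9:
        df["percent_change"] = np.nan
    else:
        df["percent_change"] = 100.0 * (df["importance"] - global_mean) / abs(global_mean)
    return df


def gia_interaction(model, cluster_a, cluster_b, backgrounds: list[str],
                    seed: int = 0, alpha: float = 0.05,
                    n_clusters: int | None = None) -> GIAResult:
    """Interaction importance of a cluster pair.

    Per background with kmer a at position pa and kmer b at pb (sampled
    non-overlapping): [f(both) + f(bg)] - [f(a only) + f(b only)].  The
    p value is a paired two-sided t test of these per-background deviations
    against 0, compared to alpha / n_clusters^2 when ``n_clusters`` given.
    """
    if not backgrounds:
        raise ValueError("backgrounds must be nonempty")
    rng = np.random.default_rng(seed)
    only_a, only_b, both = [], [], []
    for seq in backgrounds:
        ka, kb = sample_kmer(cluster_a, rng), sample_kmer(cluster_b, rng)
        pa = int(rng.integers(0, N_EMBED_POSITIONS))
        pb = _sample_nonoverlapping(rng, [pa])
        only_a.append(embed_kmer(seq, ka, pa))
        only_b.append(embed_kmer(seq, kb, pb))
        both.append(embed_kmer(embed_kmer(seq, ka, pa), kb, pb))
    f_bg = model.pre_activation(backgrounds)
    f_a = model.pre_activation(only_a)
    f_b = model.pre_activation(only_b)
    f_ab = model.pre_activation(both)
    inter = (f_ab + f_bg) - (f_a + f_b)
    mean, ci = _mean_ci(inter)
    if np.allclose(inter, inter[0]):
        p = 1.0 if abs(mean) < 1e-12 else 0.0
    else:
        p = float(stats.ttest_1samp(inter, 0.0).pvalue)
    corrected_alpha = alpha / (n_clusters ** 2) if n_clusters else alpha
    return GIAResult(experiment="interaction",
                     feature_ids=(_feature_ids(cluster_a), _feature_ids(cluster_b)),
                     importance=mean, ci=ci, n_backgrounds=len(backgrounds),
                     p_value=p, extra={"alpha_corrected": corrected_alpha,
                                       "significant": p <= corrected_alpha})


# ---------------------------------------------------------------------------
# export

def pwm_to_meme(pwms: list[MotifPWM], path) -> None:
    """Write PWMs in MEME minimal motif format (protein alphabet)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= " + AA_ALPHABET + "\n\n")
        for p in pwms:
            fh.write(f"MOTIF filter_{p.filter_id}\n")
            fh.write(f"letter-probability matrix: alength= 20 w= {KMER_LEN} "
                     f"nsites= {len(p.kmer_set)}\n")
            for row in p.pwm:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")
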