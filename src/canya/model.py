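"""Model/Results objects for the convolution-attention aggregation classifier.

Usage follows the statsmodels convention: construct a :class:`CanyaModel`
from labeled sequences, call :meth:`CanyaModel.fit` to train, and work with
the returned :class:`CanyaResults` (prediction, per-filter activations,
checkpointing, ``summary()``).

Training protocol: Adam with default hyperparameters on binary
cross-entropy (equal to the binary KL divergence for hard labels up to a
constant), up to 100 epochs, monitoring validation AUPR on a stratified
10% split; the learning rate decays by a factor of 0.2 after 4 epochs
without improvement and training stops early after 10, restoring the best
weights.  AUPR is computed by trapezoidal integration of the
precision-recall curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc, precision_recall_curve
from sklearn.model_selection import train_test_split

from canya import network
from canya.encoding import MAX_LEN, N_CHANNELS, AA_ALPHABET, encode_batch, one_hot
from canya.labeling import LabeledDataset

PARAM_COUNT_DEFAULT = 17_491


@dataclass
class ModelConfig:
    """Hyperparameters of the network and its training schedule."""

    n_filters: int = 100
    filter_len: int = 3
    stride: int = 1
    attention_heads: int = 1
    key_len: int = 6
    dense_units: int = 64
    dropout_conv: float = 0.1
    dropout_attention: float = 0.1
    dropout_dense: float = 0.4
    elastic_net: float = 0.01
    epochs: int = 100
    lr: float = 1e-3
    lr_factor: float = 0.2
    lr_patience: int = 4
    early_stop_patience: int = 10
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_filters", "filter_len", "stride", "attention_heads",
                     "key_len", "dense_units", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        for name in ("dropout_conv", "dropout_attention", "dropout_dense"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.attention_heads != 1:
            raise ValueError("only a single attention head is supported")
        if self.stride != 1:
            raise ValueError("only stride 1 is supported")


def aupr(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall curve, trapezoidal integration."""
    precision, recall, _ = precision_recall_curve(labels, scores)
    return float(auc(recall, precision))


class CanyaModel:
    """Aggregation classifier over peptides of up to 20 residues.

    Parameters
    ----------
    labels : array of 0/1
        Aggregator (1) / non-aggregator (0) classes.
    sequences : list of str
        Truncated peptide sequences (no ``*``), length 0..20.
    config : ModelConfig, optional
    """

    def __init__(self, labels, sequences: list[str], config: ModelConfig | None = None):
        self.endog = np.asarray(labels, dtype=float)
        self.sequences = list(sequences)
        if len(self.endog) != len(self.sequences):
            raise ValueError("labels and sequences differ in length")
        self.config = config or ModelConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, seq_col: str = "aa_seq",
                       label_col: str = "label", config: ModelConfig | None = None):
        return cls(df[label_col].to_numpy(), df[seq_col].tolist(), config)

    @classmethod
    def from_dataset(cls, dataset: LabeledDataset, config: ModelConfig | None = None):
        return cls.from_dataframe(dataset.records, config=config)

    # -- architecture ------------------------------------------------------

    def build_params(self, seed: int | None = None) -> dict[str, np.ndarray]:
        rng = np.random.default_rng(self.config.seed if seed is None else seed)
        return network.init_params(self.config, rng)

    def param_count(self) -> int:
        return network.parameter_count(self.build_params(0))

    # -- training ----------------------------------------------------------

    def fit(self, seed: int | None = None, epochs: int | None = None,
            val_fraction: float = 0.1, verbose: bool = False) -> "CanyaResults":
        """Train the network; returns a :class:`CanyaResults`.

        Deterministic given ``seed`` (weight init, split, shuffling and
        dropout all derive from it).
        """
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        epochs = cfg.epochs if epochs is None else epochs
        y = self.endog
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        idx_train, idx_val = train_test_split(
            np.arange(len(y)), test_size=val_fraction, stratify=y, random_state=seed % (2**32)
        )
        if len(np.unique(y[idx_val])) < 2:  # pragma: no cover - stratify guards this
            raise ValueError("validation split must contain both classes")

        X = encode_batch(self.sequences)
        Xtr, ytr = X[idx_train], y[idx_train]
        Xval, yval = X[idx_val], y[idx_val]

        ss = np.random.SeedSequence(seed)
        init_rng, shuffle_rng, drop_rng = (np.random.default_rng(s) for s in ss.spawn(3))
        params = network.init_params(cfg, init_rng)
        opt = network.Adam(params, lr=cfg.lr)

        history = []
        best_aupr, best_params, best_epoch = -np.inf, None, -1
        lr_wait = stop_wait = 0
        n = len(ytr)
        for epoch in range(epochs):
            order = shuffle_rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                b = order[start:start + cfg.batch_size]
                logits, cache = network.forward(params, Xtr[b], cfg, train=True, rng=drop_rng)
                loss, dlogits = network.bce_loss(logits, ytr[b])
                grads, _ = network.backward(params, cache, dlogits, cfg)
                if cfg.elastic_net > 0:
                    grads["dense_w"] = grads["dense_w"] + cfg.elastic_net * (
                        np.sign(params["dense_w"]) + 2.0 * params["dense_w"]
                    )
                opt.step(params, grads)
                losses.append(loss)
            val_logits, _ = network.forward(params, Xval, cfg, train=False)
            val_aupr = aupr(yval, val_logits)
            history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                            "val_aupr": val_aupr, "lr": opt.lr})
            if verbose:
                print(f"epoch {epoch}: loss {np.mean(losses):.4f} val_aupr {val_aupr:.4f}")
            if val_aupr > best_aupr:
                best_aupr, best_epoch = val_aupr, epoch
                best_params = {k: v.copy() for k, v in params.items()}
                lr_wait = stop_wait = 0
            else:
                lr_wait += 1
                stop_wait += 1
                if lr_wait >= cfg.lr_patience:
                    opt.lr *= cfg.lr_factor
                    lr_wait = 0
                if stop_wait >= cfg.early_stop_patience:
                    break
        return CanyaResults(config=cfg, params=best_params,
                            history=pd.DataFrame(history), seed=seed,
                            best_epoch=best_epoch, best_val_aupr=float(best_aupr),
                            val_index=idx_val)


@dataclass
class CanyaResults:
    """Trained network: weights, training history and prediction methods."""

    config: ModelConfig
    params: dict[str, np.ndarray]
    history: pd.DataFrame = field(default_factory=pd.DataFrame)
    seed: int = 0
    best_epoch: int = -1
    best_val_aupr: float = float("nan")
    val_index: np.ndarray | None = None

    # -- scoring -----------------------------------------------------------

    def pre_activation(self, sequences: list[str]) -> np.ndarray:
        """Unbounded scores before the output sigmoid."""
        if isinstance(sequences, str):
            raise TypeError("pass a list of sequences")
        logits, _ = network.forward(self.params, encode_batch(sequences), self.config)
        return logits

    def predict(self, sequences: list[str]) -> np.ndarray:
        """Aggregation probabilities, sigmoid(pre_activation)."""
        return 1.0 / (1.0 + np.exp(-self.pre_activation(sequences)))

    def predict_long(self, sequence: str, summarizer: str = "median",
                     scale: str = "probability") -> float:
        """Score a >20-residue sequence via all length-20 windows.

        Every overlapping length-20 window (stride 1) is scored and the
        window scores are summarised (median by default; mean/min/max
        selectable).
        """
        if len(sequence) < MAX_LEN:
            raise ValueError("predict_long needs length >= 20; use predict")
        windows = [sequence[i:i + MAX_LEN] for i in range(len(sequence) - MAX_LEN + 1)]
        scores = self.predict(windows) if scale == "probability" else self.pre_activation(windows)
        fn = {"median": np.median, "mean": np.mean, "min": np.min, "max": np.max}[summarizer]
        return float(fn(scores))

    def score_any(self, sequence: str, summarizer: str = "median") -> float:
        """Probability for a sequence of any length (windowed if > 20)."""
        if len(sequence) > MAX_LEN:
            return self.predict_long(sequence, summarizer)
        return float(self.predict([sequence])[0])

    def filter_activations(self, sequence: str) -> np.ndarray:
        """Post-exponential convolution outputs on the raw (unpadded)
        sequence: an (L - filter_len + 1) x n_filters grid of activation
        energies, one row per kmer start position."""
        flen = self.config.filter_len
        if len(sequence) < flen:
            raise ValueError(f"sequence shorter than filter length {flen}")
        X = one_hot(sequence)[None]
        Xw = network._windows(X, flen)
        Wc = self.params["conv_w"].reshape(flen * N_CHANNELS, -1)
        return np.exp(np.minimum(Xw[0] @ Wc + self.params["conv_b"], network._EXP_CLIP))

    def input_gradient(self, sequences: list[str]) -> np.ndarray:
        """d(pre-activation)/d(input) per sequence: (B, 24, 20) saliency."""
        X = encode_batch(sequences)
        logits, cache = network.forward(self.params, X, self.config)
        _, dX = network.backward(self.params, cache, np.ones_like(logits),
                                 self.config, want_input_grad=True)
        return dX

    # -- bookkeeping -------------------------------------------------------

    def param_count(self) -> int:
        return network.parameter_count(self.params)

    def param_decomposition(self) -> dict[str, int]:
        return network.parameter_decomposition(self.params)

    def save(self, path) -> None:
        """Checkpoint weights + config + channel order to an .npz file."""
        meta = json.dumps({"config": asdict(self.config), "channels": AA_ALPHABET,
                           "seed": self.seed, "best_epoch": self.best_epoch,
                           "best_val_aupr": self.best_val_aupr})
        np.savez(path, __meta__=np.array(meta), **self.params)

    @classmethod
    def load(cls, path) -> "CanyaResults":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        if meta["channels"] != AA_ALPHABET:
            raise ValueError("checkpoint channel order does not match")
        params = {k: data[k] for k in data.files if k != "__meta__"}
        return cls(config=ModelConfig(**meta["config"]), params=params,
                   seed=meta["seed"], best_epoch=meta["best_epoch"],
                   best_val_aupr=meta["best_val_aupr"])

    def summary(self) -> str:
        decomp = self.param_decomposition()
        lines = [
            "Convolution-attention aggregation classifier",
            "=" * 48,
            f"filters: {self.config.n_filters} x len {self.config.filter_len} (exponential)",
            f"attention: {self.config.attention_heads} head, key length {self.config.key_len}",
            f"dense units: {self.config.dense_units}",
            f"trainable parameters: {self.param_count()}",
            "-" * 48,
        ]
        lines += [f"  {name:10s} {count:7d}" for name, count in decomp.items()]
        lines += ["-" * 48,
                  f"seed: {self.seed}  best epoch: {self.best_epoch}  "
                  f"best val AUPR: {self.best_val_aupr:.4f}"]
        return "\n".join(lines)
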