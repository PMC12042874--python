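"""End-to-end pipeline over the synthetic library: simulate -> label ->
train -> select -> interpret -> enrich -> evaluate.

A run is driven by a flat YAML key-value config (unknown keys rejected,
every stochastic stage seeded) and writes its artifacts plus a manifest
recording the config hash, seeds and produced files.  Any contiguous span
of stages can be run; each stage reads the artifacts of its predecessor
from the output directory and raises a dependency error naming the missing
stage otherwise.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

STAGES = ["simulate", "label", "train", "select", "interpret", "enrich", "evaluate"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_peptides": 20_000,
    "peptide_length": 20,
    "noise_sd": 0.3,
    "read_threshold": 100,
    "alpha": 0.05,
    "n_replicates": 2,
    "epochs": 15,
    "n_backgrounds": 2000,
    "n_structure_fixtures": 30,
    "library_id": "NNK1",
}


class ConfigError(ValueError):
    pass


class DependencyError(RuntimeError):
    pass


def load_config(path=None, overrides: dict | None = None) -> dict:
    config = dict(DEFAULT_CONFIG)
    given = {}
    if path is not None:
        with open(path) as fh:
            given = yaml.safe_load(fh) or {}
    given.update(overrides or {})
    unknown = set(given) - set(config)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    config.update(given)
    return config


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DependencyError(f"missing artifact {path.name}: run stage '{stage}' first")
    return path


def run_pipeline(config: dict, out_dir, stages: list[str] | None = None) -> dict:
    """Execute the requested (contiguous) stages; returns the manifest."""
    from canya import interpret, nnk, selection, structure
    from canya.evaluation import auroc_auprc, composition_baseline
    from canya.labeling import process_library
    from canya.model import CanyaResults

    stages = stages or STAGES
    order = [STAGES.index(s) for s in stages]
    if sorted(order) != list(range(min(order), max(order) + 1)):
        raise ConfigError("stages must form a contiguous span of the pipeline")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    artifacts: list[str] = []

    def emit(name: str) -> Path:
        artifacts.append(name)
        return out / name

    if "simulate" in stages:
        grammar = nnk.GrammarSpec(noise_sd=float(config["noise_sd"]), seed=seed)
        peptides = nnk.sample_nnk_peptides(int(config["n_peptides"]),
                                           int(config["peptide_length"]), seed=seed)
        df = nnk.score_library(peptides, grammar)
        nnk.write_scored_table(df, emit("library.tsv"))
        fixtures = nnk.make_structure_fixtures(int(config["n_structure_fixtures"]),
                                               seed=seed + 1)
        structure.annotations_to_tsv(fixtures, emit("structure_fixtures.tsv"))

    if "label" in stages:
        df = pd.read_csv(_require(out / "library.tsv", "simulate"), sep="\t")
        labeled = process_library(df, library_id=str(config["library_id"]),
                                  read_threshold=int(config["read_threshold"]),
                                  alpha=float(config["alpha"]))
        labeled.records.to_csv(emit("labeled.tsv"), sep="\t", index=False)
        with open(emit("labeling_report.json"), "w") as fh:
            json.dump(labeled.report(), fh, indent=2)

    if "train" in stages or "select" in stages:
        df = pd.read_csv(_require(out / "labeled.tsv", "label"), sep="\t",
                         keep_default_na=False, na_values=["NA"])
        df["aa_seq"] = df["aa_seq"].astype(str)
        replicates = selection.train_replicates(
            df, n_replicates=int(config["n_replicates"]), base_seed=seed,
            epochs=int(config["epochs"]))
        rows = []
        for results, summary in replicates:
            results.save(out / f"model_{summary.model_id}.npz")
            artifacts.append(f"model_{summary.model_id}.npz")
            rows.append({"model_id": summary.model_id, "mean_aupr": summary.mean_aupr,
                         "interpretability_score": summary.interpretability_score})
        pd.DataFrame(rows).to_csv(emit("replicates.tsv"), sep="\t", index=False)
        summaries = [s for _, s in replicates]
        chosen = (selection.select_model(summaries) if len(summaries) > 1
                  else summaries[0].model_id)
        with open(emit("selected_model.json"), "w") as fh:
            json.dump({"model_id": chosen}, fh)

    if "interpret" in stages or "enrich" in stages or "evaluate" in stages:
        sel = json.loads(_require(out / "selected_model.json", "select").read_text())
        results = CanyaResults.load(_require(out / f"model_{sel['model_id']}.npz", "train"))
        df = pd.read_csv(_require(out / "labeled.tsv", "label"), sep="\t",
                         keep_default_na=False, na_values=["NA"])
        df["aa_seq"] = df["aa_seq"].astype(str)

    if "interpret" in stages:
        energies = interpret.kmer_activation_energies(results)
        pwms = [interpret.extract_pwm(results, f, energies)
                for f in range(results.config.n_filters)]
        interpret.pwm_to_meme(pwms, emit("motifs.meme"))
        backgrounds = interpret.select_backgrounds(
            results, df, n=int(config["n_backgrounds"]), seed=seed)
        importances = {
            p.filter_id: gia.importance
            for p in pwms
            for gia in [interpret.gia_importance(results, p, backgrounds, seed=seed)]
        }
        clusters = interpret.blosum_cluster(pwms, importances, seed=seed)
        rows = []
        for c in clusters:
            gia = interpret.gia_importance(results, c, backgrounds, seed=seed)
            rows.append({"cluster_id": c.cluster_id, "n_members": len(c.members),
                         "sign": c.sign, "importance": gia.importance,
                         "ci_low": gia.ci[0], "ci_high": gia.ci[1]})
        pd.DataFrame(rows).to_csv(emit("clusters.tsv"), sep="\t", index=False)
        np.save(emit("filter_importances.npy"),
                np.array([importances[p.filter_id] for p in pwms]))

    if "enrich" in stages:
        annotations = structure.annotations_from_tsv(
            _require(out / "structure_fixtures.tsv", "simulate"))
        clusters_df = pd.read_csv(_require(out / "clusters.tsv", "interpret"), sep="\t")
        energies = interpret.kmer_activation_energies(results)
        importances = np.load(_require(out / "filter_importances.npy", "interpret"))
        pwms = [interpret.extract_pwm(results, f, energies)
                for f in range(results.config.n_filters)]
        clusters = interpret.blosum_cluster(
            pwms, {p.filter_id: float(importances[p.filter_id]) for p in pwms}, seed=seed)
        rows = []
        for c in clusters:
            for label in structure.STRUCTURE_LABELS:
                rep = structure.enrichment_auroc(results, c, annotations, label,
                                                 n_boot=100, seed=seed)
                rep["cluster_id"] = c.cluster_id
                rows.append(rep)
        pd.DataFrame(rows).to_csv(emit("enrichment.tsv"), sep="\t", index=False)
        del clusters_df

    if "evaluate" in stages:
        from sklearn.model_selection import train_test_split

        idx_train, idx_test = train_test_split(
            np.arange(len(df)), test_size=0.1, stratify=df["label"],
            random_state=seed % (2**32))
        test = df.iloc[idx_test]
        train = df.iloc[idx_train]
        rows = []
        model_scores = results.pre_activation(test["aa_seq"].tolist())
        rep = auroc_auprc(model_scores, test["label"], seed=seed)
        rows.append({"method": "canya", **{k: v for k, v in rep.items()
                                           if not k.endswith("_ci")},
                     "auroc_ci_low": rep["auroc_ci"][0], "auroc_ci_high": rep["auroc_ci"][1]})
        comp = composition_baseline(train["aa_seq"].tolist(), train["label"],
                                    test["aa_seq"].tolist(), seed=seed)
        rep = auroc_auprc(comp, test["label"], seed=seed)
        rows.append({"method": "composition", **{k: v for k, v in rep.items()
                                                 if not k.endswith("_ci")},
                     "auroc_ci_low": rep["auroc_ci"][0], "auroc_ci_high": rep["auroc_ci"][1]})
        pd.DataFrame(rows).to_csv(emit("evaluation.tsv"), sep="\t", index=False)

    manifest = {"config": config, "config_hash": config_hash(config),
                "seed": seed, "stages": stages, "artifacts": artifacts}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
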