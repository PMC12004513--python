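"""End-to-end orchestration: sanitize -> split -> audit -> train -> AD-gate
-> evaluate -> interpret -> enrichment.

``run_pipeline`` executes the stages in order on either a CSV dataset or a
synthetic one, writes immutable stage artifacts into the output directory
and returns a machine-readable run report; out-of-domain test compounds are
removed before metrics, mirroring standard applicability-domain practice.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np

from . import adomain, chemprep, dmpnn, evalkit, qspr, rationale, simgen, splitkit
from .featurize import DescriptorCalculator, default_descriptor_names


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


DEFAULT_CONFIG: dict = {
    "input": None,                 # CSV path; None -> synthesize
    "simgen": {"n_molecules": 500, "seed": 0},
    "strategy": "cluster_singleton",   # random | cluster_singleton | cluster_centroid
    "butina_cutoff": 0.4,
    "split_seed": 0,
    "model": {
        "hidden_size": 64, "depth": 2, "epochs": 10, "ffn_hidden_size": 64,
        "use_global_descriptors": False, "seed": 0,
    },
    "descriptor_count": 200,
    "ad": {"enabled": True, "variance_target": 0.90, "percentile": 99.0},
    "rationales": {"enabled": False, "max_molecules": 20},
    "qspr": None,                  # QsprConfig kwargs or None to skip
    "threshold": 0.5,
}


def _merged(cfg: Optional[dict]) -> dict:
    out = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (cfg or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key].update(value)
        else:
            out[key] = value
    return out


def run_pipeline(config: Optional[dict], outdir) -> dict:
    """Run all stages; returns (and writes) the JSON run report."""
    cfg = _merged(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": [], "config": cfg}
    artifacts: dict[str, str] = {}

    def stage(name: str):
        report["stages"].append(name)

    # --- load or synthesize -------------------------------------------------
    stage("load")
    if cfg["input"]:
        raw = chemprep.load_dataset(cfg["input"], "csv")
    else:
        recs, truth = simgen.generate_dataset(simgen.GeneratorConfig(**cfg["simgen"]))
        raw = recs
        truth_path = outdir / "truth.csv"
        truth.to_csv(truth_path, index=False)
        artifacts["truth"] = _file_hash(truth_path)

    stage("sanitize")
    clean, san_report = chemprep.sanitize_dataset(raw)
    records, dedup_report = chemprep.deduplicate(clean)
    data_path = outdir / "dataset.csv"
    chemprep.write_dataset(records, data_path)
    artifacts["dataset"] = _file_hash(data_path)
    report["sanitize"] = {
        "n_in": san_report["n_in"], "n_sanitized": san_report["n_out"],
        "n_rejected": len(san_report["rejected"]),
        "n_duplicates_removed": dedup_report["n_removed"],
        "n_label_conflicts": len(dedup_report["label_conflicts"]),
        "n_final": len(records),
    }

    # --- split + audit ------------------------------------------------------
    stage("split")
    strategy = cfg["strategy"]
    if strategy == "random":
        split = splitkit.split_random(records, 0.8, seed=cfg["split_seed"])
    elif strategy == "cluster_singleton":
        split = splitkit.split_cluster_singletons(records, cfg["butina_cutoff"])
    elif strategy == "cluster_centroid":
        split = splitkit.split_cluster_centroids(records, cfg["butina_cutoff"])
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    split_path = outdir / "split.json"
    split_path.write_text(json.dumps({
        "strategy": split.strategy, "train_ids": split.train_ids,
        "test_ids": split.test_ids, "cutoff": split.cutoff, "seed": split.seed,
    }, indent=1))
    artifacts["split"] = _file_hash(split_path)
    report["split"] = {"strategy": strategy, "n_train": len(split.train_ids),
                       "n_test": len(split.test_ids)}

    by_id = {r.id: r for r in records}
    train_recs = [by_id[i] for i in split.train_ids]
    test_recs = [by_id[i] for i in split.test_ids]

    stage("audit")
    iid = splitkit.validate_iid(train_recs, test_recs)
    report["iid_audit"] = dataclasses.asdict(iid)
    profile = splitkit.max_similarity_profile(split, records)
    profile.pop("maxima")
    report["similarity_profile"] = profile

    # --- train --------------------------------------------------------------
    stage("train")
    model_cfg = dmpnn.ModelConfig(**cfg["model"])
    model = dmpnn.train(records, split, model_cfg)
    model_path = outdir / "model.npz"
    model.save(model_path)
    artifacts["model"] = _file_hash(model_path)
    report["train"] = {"final_loss": model.loss_curve[-1],
                       "n_epochs": len(model.loss_curve)}

    # --- applicability domain ----------------------------------------------
    stage("ad")
    if cfg["ad"]["enabled"]:
        fp_train = splitkit.fingerprint_matrix(train_recs)
        fp_test = splitkit.fingerprint_matrix(test_recs)
        calc = DescriptorCalculator(default_descriptor_names(cfg["descriptor_count"]))
        de_train = calc.matrix(train_recs)
        de_test = calc.matrix(test_recs)
        ad_fp = adomain.fit_ad(fp_train, cfg["ad"]["variance_target"],
                               cfg["ad"]["percentile"], representation="fingerprint")
        ad_de = adomain.fit_ad(de_train, cfg["ad"]["variance_target"],
                               cfg["ad"]["percentile"], representation="descriptors")
        _, in_fp = adomain.apply_ad(ad_fp, fp_test)
        _, in_de = adomain.apply_ad(ad_de, de_test)
        in_domain = adomain.combined_verdict([in_fp, in_de])
        report["ad"] = {
            "n_test": len(test_recs),
            "n_out_of_domain": int((~in_domain).sum()),
            "n_in_domain": int(in_domain.sum()),
            "fingerprint": {"n_components": ad_fp.n_components,
                            "threshold": ad_fp.threshold,
                            "n_out": int((~in_fp).sum())},
            "descriptors": {"n_components": ad_de.n_components,
                            "threshold": ad_de.threshold,
                            "n_out": int((~in_de).sum())},
        }
        gated = [r for r, ok in zip(test_recs, in_domain) if ok]
    else:
        report["ad"] = {"enabled": False, "n_test": len(test_recs),
                        "n_in_domain": len(test_recs)}
        gated = list(test_recs)

    # --- evaluate -----------------------------------------------------------
    stage("evaluate")
    predicted = dmpnn.predict(model, gated)
    probs = np.array([r.prediction for r in predicted])
    y = np.array([r.label for r in predicted])
    calls = (probs >= cfg["threshold"]).astype(int)
    rep = evalkit.metrics(evalkit.confusion(y, calls))
    metrics_out = {
        "n_evaluated": len(predicted),
        "accuracy": rep.accuracy, "recall": rep.recall,
        "specificity": rep.specificity, "fpr": rep.fpr,
        "confusion": dataclasses.asdict(rep.confusion),
    }
    if len(np.unique(y)) == 2:
        metrics_out["auc"] = evalkit.roc_auc(y, probs)
    report["metrics"] = metrics_out
    preds_path = outdir / "predictions.csv"
    chemprep.write_dataset(predicted, preds_path)
    artifacts["predictions"] = _file_hash(preds_path)

    # --- interpret ----------------------------------------------------------
    if cfg["rationales"]["enabled"]:
        stage("interpret")
        positives = [r for r in predicted
                     if r.prediction is not None and r.prediction >= cfg["threshold"]]
        subset = positives[: cfg["rationales"]["max_molecules"]]
        rats, table = rationale.collect_rationales(model, subset)
        table_path = outdir / "rationales.csv"
        table.to_csv(table_path, index=False)
        artifacts["rationales"] = _file_hash(table_path)
        ef_rows = []
        for smi in table[table.recurring].substructure:
            try:
                tab = rationale.substructure_counts(smi, records, "experimental")
                ef = evalkit.enrichment_factor(tab)
            except ValueError:
                continue
            ef_rows.append({"substructure": smi, "a": tab.a, "b": tab.b,
                            "c": tab.c, "d": tab.d, "ef": ef})
        report["interpret"] = {"n_rationales": len(rats),
                               "n_substructures": int(len(table)),
                               "enrichment": ef_rows}

    # --- qspr comparison ----------------------------------------------------
    if cfg["qspr"] is not None:
        stage("qspr")
        qcfg = qspr.QsprConfig(**cfg["qspr"]) if cfg["qspr"] else qspr.QsprConfig()
        qcalls = qspr.predict_qspr(predicted, qcfg)
        dl_calls = [(r.prediction >= cfg["threshold"]) for r in predicted]
        cross = evalkit.confusion(
            [int(q) for q in qcalls], [int(c) for c in dl_calls]
        )
        report["qspr"] = {"cross_model_confusion": dataclasses.asdict(cross)}

    report["artifacts"] = artifacts
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=1, default=float))
    return report
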