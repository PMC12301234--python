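"""End-to-end orchestration: simulate -> repertoire -> screen -> enrich ->
triage -> aggregate (-> assays), with a manifest for provenance.

Every stochastic stage receives its own seed derived from the master seed by
hashing the stage name, so stages are independently reproducible and a rerun
with the same config reproduces outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assays as assays_mod
from . import convnet, diversify, enrichment, knn, liabilities, repertoire, synthetic

PIPELINE_VERSION = "0.1.0"

STAGE_ORDER = ("simulate", "repertoire", "screen", "enrich", "triage_knn",
               "triage_conv", "aggregate", "assays")


def stage_seed(master_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGE_ORDER})
    simulate: dict = field(default_factory=dict)
    screen: dict = field(default_factory=dict)
    enrich: dict = field(default_factory=dict)
    triage: dict = field(default_factory=dict)
    assays: dict = field(default_factory=dict)
    version: str = PIPELINE_VERSION

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, False))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate(self) -> None:
        if self.enabled("assays"):
            for key in ("competition_csv", "footprint_csv", "tgi_csv"):
                path = self.assays.get(key)
                if path and not Path(path).exists():
                    raise FileNotFoundError(f"assays input missing: {path}")
        downstream = [s for s in STAGE_ORDER[1:-1] if self.enabled(s)]
        if downstream and not self.enabled("simulate"):
            raise ValueError(
                "repertoire/screen/enrich/triage stages require the simulate "
                "stage in this pipeline")


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute enabled stages, returning the run directory.

    The manifest records, per stage, the parameters, input/output hashes and
    conservation counts (records in = records out + records filtered). A
    stage failure raises :class:`StageFailure` naming the stage; outputs of
    completed stages are retained.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": config.version, "seed": config.seed,
                      "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
                      "stages": {}}
    state: dict = {}
    for stage in STAGE_ORDER:
        if not config.enabled(stage):
            continue
        try:
            entry = _STAGES[stage](config, outdir, state)
        except Exception as exc:  # noqa: BLE001 - halt with stage named
            _write_manifest(outdir, manifest)
            raise StageFailure(stage, exc) from exc
        entry["seed"] = stage_seed(config.seed, stage)
        for fname in entry.get("outputs", []):
            entry.setdefault("sha256", {})[fname] = _sha256(outdir / fname)
        manifest["stages"][stage] = entry
    _write_manifest(outdir, manifest)
    return outdir


def _write_manifest(outdir: Path, manifest: dict) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


# ------------------------------------------------------------------ stages

def _stage_simulate(config: RunConfig, outdir: Path, state: dict) -> dict:
    params = {"n_clones": 500, "reads_per_round": 5000, "error_rate": 0.0,
              "spike_in_fraction": 0.0, "liability_fraction": 0.0,
              "rounds_to_emit": (3, 4), **config.simulate}
    seed = stage_seed(config.seed, "simulate")
    pan_cfg = synthetic.PanningConfig(reads_per_round=params["reads_per_round"],
                                      seed=stage_seed(config.seed, "panning"))
    campaign = synthetic.simulate_campaign(
        n_clones=params["n_clones"], seed=seed, config=pan_cfg,
        liability_fraction=params["liability_fraction"])
    outputs = []
    for rnd in params["rounds_to_emit"]:
        fname = f"round{rnd}.fastq"
        synthetic.emit_fastq(campaign, rnd, outdir / fname,
                             error_rate=params["error_rate"],
                             spike_in_fraction=params["spike_in_fraction"],
                             seed=stage_seed(config.seed, f"fastq{rnd}"))
        outputs.append(fname)
    (outdir / "truth.json").write_text(campaign.truth_json())
    outputs.append("truth.json")
    state["campaign"] = campaign
    state["rounds"] = tuple(params["rounds_to_emit"])
    return {"params": params, "outputs": outputs,
            "counts": {"clones": len(campaign.clones)}}


def _stage_repertoire(config: RunConfig, outdir: Path, state: dict) -> dict:
    campaign = state["campaign"]
    scheme = campaign.design.scheme()
    per_round: dict[int, list[repertoire.VhhRecord]] = {}
    counts: dict[str, int] = {}
    outputs = []
    for rnd in state["rounds"]:
        reads = repertoire.read_fastq(outdir / f"round{rnd}.fastq")
        records, acct = repertoire.process_reads(reads, scheme)
        assert acct["annotated"] + acct["flagged"] + acct["anchorless"] == acct["total"]
        per_round[rnd] = [r for r in records if r.annotated and not r.qc_flags]
        for key, val in acct.items():
            counts[f"r{rnd}_{key}"] = val
        table = pd.DataFrame(
            [{"read_id": r.read_id, "aa_sequence": r.aa_sequence,
              "cdr3": r.cdr3} for r in per_round[rnd]])
        fname = f"round{rnd}_annotated.csv"
        table.to_csv(outdir / fname, index=False)
        outputs.append(fname)
    state["per_round_records"] = per_round
    return {"params": {}, "outputs": outputs, "counts": counts}


def _stage_screen(config: RunConfig, outdir: Path, state: dict) -> dict:
    params = {"policy": sorted(liabilities.DEFAULT_POLICY), **config.screen}
    campaign = state["campaign"]
    records = [c.to_record() for c in campaign.clones]
    result = liabilities.filter_library(records, policy=params["policy"])
    assert len(result.kept) + len(result.removed) == len(records)
    rows = [{"clone_id": cid,
             "findings": ";".join(f"{f.label}@{f.start}" for f in rep.findings)}
            for cid, rep in sorted(result.reports.items())]
    pd.DataFrame(rows).to_csv(outdir / "liability_report.csv", index=False)
    state["screened_out"] = {r.read_id for r in result.removed}
    return {"params": params, "outputs": ["liability_report.csv"],
            "counts": {"in": len(records), "kept": len(result.kept),
                       "removed": len(result.removed)}}


def _variants_from_records(per_round, rounds) -> list[enrichment.Variant]:
    by_aa: dict[str, enrichment.Variant] = {}
    for rnd in rounds:
        for aa, count in repertoire.dereplicate(
                r.aa_sequence for r in per_round[rnd]):
            if aa not in by_aa:
                cdr3 = next(r.cdr3 for r in per_round[rnd]
                            if r.aa_sequence == aa)
                by_aa[aa] = enrichment.Variant(aa_sequence=aa, cdr3=cdr3)
            by_aa[aa].counts[rnd] = count
    return [by_aa[a] for a in sorted(by_aa)]


def _stage_enrich(config: RunConfig, outdir: Path, state: dict) -> dict:
    params = {"n_top_clonotypes": 20, "variants_per_clonotype": 3,
              "min_count_a": 10, "pseudocount": 1.0, **config.enrich}
    rounds = state["rounds"]
    variants = _variants_from_records(state["per_round_records"], rounds)
    screened = state.get("screened_out", set())
    clonotypes, skipped = enrichment.assign_clonotypes(variants)
    table = enrichment.build_enrichment_table(
        clonotypes, round_a=rounds[0], round_b=rounds[1],
        pseudocount=params["pseudocount"])
    table.to_csv(outdir / "enrichment.csv", index=False)
    cands = enrichment.select_enrichment_candidates(
        table, clonotypes, n_top_clonotypes=params["n_top_clonotypes"],
        variants_per_clonotype=params["variants_per_clonotype"],
        min_count_a=params["min_count_a"])
    state["clonotypes"] = clonotypes
    state["enrichment_candidates"] = cands
    state["variants"] = variants
    pd.DataFrame([{"aa_sequence": c.aa_sequence, "clonotype_id": c.clonotype_id}
                  for c in cands]).to_csv(outdir / "enrichment_candidates.csv",
                                          index=False)
    return {"params": params,
            "outputs": ["enrichment.csv", "enrichment_candidates.csv"],
            "counts": {"variants": len(variants), "clonotypes": len(clonotypes),
                       "skipped_no_cdr3": skipped,
                       "candidates": len(cands)}}


def _spr_training_set(config: RunConfig, state: dict, stage: str) -> knn.TrainingSet:
    """Emulated binding-assay labels from campaign truth plus supplements."""
    params = {"spr_sample_size": 200, "neg_sample_size": 200,
              "label_noise": 0.0, **config.triage}
    campaign = state["campaign"]
    rng = np.random.default_rng(stage_seed(config.seed, f"{stage}_labels"))
    clones = list(campaign.clones)
    idx = rng.choice(len(clones), size=min(params["spr_sample_size"],
                                           len(clones)), replace=False)
    spr = []
    for i in sorted(int(j) for j in idx):
        label = bool(clones[i].is_binder)
        if rng.random() < params["label_noise"]:
            label = not label
        spr.append((clones[i].aa_sequence, label))
    enriched = [c.aa_sequence for c in state.get("enrichment_candidates", [])]
    library = [c.aa_sequence for c in clones]
    return knn.build_training_set(
        spr_labels=spr, round4_enriched=enriched,
        initial_library_sample=library,
        neg_sample_size=params["neg_sample_size"],
        seed=stage_seed(config.seed, f"{stage}_negatives"))


def _apply_pool(state: dict) -> list[str]:
    rounds = state["rounds"]
    return sorted({v.aa_sequence for v in state["variants"]
                   if v.count(rounds[1]) > 0})


def _stage_triage_knn(config: RunConfig, outdir: Path, state: dict) -> dict:
    params = {"beta": 1.0, "cv_folds": 5, **config.triage}
    training = _spr_training_set(config, state, "triage_knn")
    model = knn.tune_knn(training, beta=params["beta"],
                         cv_folds=params["cv_folds"],
                         seed=stage_seed(config.seed, "triage_knn"))
    pool = _apply_pool(state)
    probs = model.predict_proba(pool)
    kept = [enrichment.Candidate(aa_sequence=s, provenance=("knn",),
                                 probability=float(p))
            for s, p in zip(pool, probs) if p >= 0.5]
    pd.DataFrame([{"aa_sequence": c.aa_sequence, "probability": c.probability}
                  for c in kept]).to_csv(outdir / "knn_candidates.csv", index=False)
    state["knn_candidates"] = kept
    return {"params": {**params, "selected_components": model.pca_components,
                       "selected_k": model.k_neighbors},
            "outputs": ["knn_candidates.csv"],
            "counts": {"training": len(training.sequences),
                       "scored": len(pool), "candidates": len(kept)}}


def _stage_triage_conv(config: RunConfig, outdir: Path, state: dict) -> dict:
    params = {"epochs": 20, "threshold": 0.5, "n_clusters": 8, **config.triage}
    training = _spr_training_set(config, state, "triage_conv")
    model = convnet.train_conv_classifier(
        training, epochs=params["epochs"],
        seed=stage_seed(config.seed, "triage_conv"))
    pool = _apply_pool(state)
    predicted = convnet.predict_binders(model, pool,
                                        threshold=params["threshold"])
    reps = diversify.diversify(predicted, n_clusters=params["n_clusters"],
                               seed=stage_seed(config.seed, "diversify"))
    kept = [enrichment.Candidate(aa_sequence=s, provenance=("conv",),
                                 probability=p)
            for s, p, _ in reps]
    pd.DataFrame([{"aa_sequence": s, "probability": p, "cluster_id": c}
                  for s, p, c in reps]).to_csv(outdir / "conv_candidates.csv",
                                               index=False)
    state["conv_candidates"] = kept
    return {"params": {k: params[k] for k in ("epochs", "threshold", "n_clusters")},
            "outputs": ["conv_candidates.csv"],
            "counts": {"training": len(training.sequences), "scored": len(pool),
                       "thresholded": len(predicted), "candidates": len(kept)}}


def _stage_aggregate(config: RunConfig, outdir: Path, state: dict) -> dict:
    lists = [state.get("enrichment_candidates", []),
             state.get("knn_candidates", []),
             state.get("conv_candidates", [])]
    merged = enrichment.aggregate_candidates(*lists)
    pd.DataFrame([{"aa_sequence": c.aa_sequence,
                   "provenance": "+".join(c.provenance)}
                  for c in merged]).to_csv(outdir / "aggregated_candidates.csv",
                                           index=False)
    state["aggregated"] = merged
    return {"params": {}, "outputs": ["aggregated_candidates.csv"],
            "counts": {"enrichment": len(lists[0]), "knn": len(lists[1]),
                       "conv": len(lists[2]), "aggregated_unique": len(merged)}}


def _stage_assays(config: RunConfig, outdir: Path, state: dict) -> dict:
    params = {"competition_threshold": 0.30, "alpha": 0.05, **config.assays}
    outputs, counts = [], {}
    if params.get("competition_csv"):
        matrix = pd.read_csv(params["competition_csv"], index_col=0)
        blocked = assays_mod.binarize_competition(
            matrix, threshold=params["competition_threshold"])
        assignment = assays_mod.assign_bins(blocked)
        pd.Series(assignment.bins, name="bin").rename_axis("antibody") \
            .to_csv(outdir / "epitope_bins.csv")
        outputs.append("epitope_bins.csv")
        counts["bins"] = assignment.n_bins
    if params.get("footprint_csv"):
        table = assays_mod.footprint_table(pd.read_csv(params["footprint_csv"]),
                                           alpha=params["alpha"])
        table.to_csv(outdir / "footprint_results.csv", index=False)
        outputs.append("footprint_results.csv")
        counts["peptides"] = len(table)
    if params.get("tgi_csv"):
        tgi_in = pd.read_csv(params["tgi_csv"])
        tgi_in["tgi_percent"] = [
            assays_mod.compute_tgi(r.T0, r.Tt, r.C0, r.Ct)
            for r in tgi_in.itertuples()]
        tgi_in.to_csv(outdir / "tgi_results.csv", index=False)
        outputs.append("tgi_results.csv")
        counts["tgi_groups"] = len(tgi_in)
    return {"params": {k: v for k, v in params.items() if v is not None},
            "outputs": outputs, "counts": counts}


_STAGES = {
    "simulate": _stage_simulate,
    "repertoire": _stage_repertoire,
    "screen": _stage_screen,
    "enrich": _stage_enrich,
    "triage_knn": _stage_triage_knn,
    "triage_conv": _stage_triage_conv,
    "aggregate": _stage_aggregate,
    "assays": _stage_assays,
}


def summarize_run(run_dir) -> pd.DataFrame:
    """Per-workflow candidate accounting from a run's manifest.

    One row per selection workflow (enrichment, knn, conv) with the reads
    in, annotated, liability-removed, clonotype and candidate counts, plus
    the aggregated unique total.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {run_dir}")
    manifest = json.loads(manifest_path.read_text())
    stages = manifest["stages"]

    def count(stage: str, key: str):
        return stages.get(stage, {}).get("counts", {}).get(key, 0)

    shared = {
        "reads_in": sum(v for k, v in
                        stages.get("repertoire", {}).get("counts", {}).items()
                        if k.endswith("_total")),
        "annotated": sum(v for k, v in
                         stages.get("repertoire", {}).get("counts", {}).items()
                         if k.endswith("_annotated")),
        "liability_removed": count("screen", "removed"),
        "clonotypes": count("enrich", "clonotypes"),
        "aggregated_unique": count("aggregate", "aggregated_unique"),
    }
    rows = []
    for workflow, stage, key in (("enrichment", "enrich", "candidates"),
                                 ("knn", "triage_knn", "candidates"),
                                 ("conv", "triage_conv", "candidates")):
        rows.append({"workflow": workflow, **shared,
                     "candidates": count(stage, key)})
    return pd.DataFrame(rows)
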