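"""End-to-end orchestration: simulate -> cohort -> features -> embed -> models.

Two entry points:

* :func:`run_experiment` — in-memory spine used by the analysis drivers, the
  acceptance script and the heavier tests: generate (or accept) a bundle,
  build the labeled cohort and its 11-part split, compute features, train
  per-split embeddings, and evaluate a model grid.
* :func:`run` / the ``stage_*`` functions — the file-based pipeline behind the
  CLI: each stage consumes and produces only files inside one artifact
  directory, and ``run`` writes a ``run_manifest.json`` (config, seeds,
  package versions, row counts) that is identical across reruns of the same
  config.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bundle import RecordBundle, read_bundle, write_bundle
from .cohort import build_cohort, split_cohort
from .config import RunConfig
from .embedding import (
    CBOWConfig,
    CodeEmbedding,
    patient_matrix,
    save_embedding,
    train_embeddings,
)
from .evaluate import MatrixResult, ModelSpec, auc, default_grid, run_matrix
from .features import FeatureEncoder, build_manual_features
from .sentences import build_sentences
from .synth import generate

__all__ = ["run_experiment", "run", "build_embedding_blocks", "ExperimentResult"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.record = {"stage": stage, "error": message}


def _grid(config: RunConfig) -> list[ModelSpec]:
    if config.model_grid == "default":
        return default_grid(seed=config.model_seed)
    return [
        ModelSpec(
            name=row["name"],
            family=row["family"],
            feature_groups=tuple(row["feature_groups"]),
            params=tuple(row.get("params", {}).items()),
            seed=config.model_seed,
        )
        for row in config.model_grid
    ]


def build_embedding_blocks(
    sentences: dict,
    patient_ids,
    parts: np.ndarray,
    cbow: CBOWConfig,
    k_last: int,
    scope: str = "per_split",
) -> tuple[dict[int, np.ndarray], np.ndarray, CodeEmbedding]:
    """Per-fold embedding feature blocks without evaluation-set leakage.

    Returns ``(blocks, block_full, full_embedding)`` where ``blocks[f]`` holds
    every patient's vector under an embedding trained only on patients outside
    fold ``f`` and outside the holdout, and ``block_full`` uses an embedding
    trained on all ten CV parts (for scoring the holdout).  With
    ``scope="global"`` one embedding (still excluding the holdout) serves all
    folds.
    """
    patient_ids = np.asarray(patient_ids)
    parts = np.asarray(parts)
    fold_ids = sorted(p for p in np.unique(parts) if p != 0)

    def corpus_for(mask):
        return [sentences[p].tokens for p in patient_ids[mask]]

    full_embedding = train_embeddings(corpus_for(parts != 0), cbow)
    block_full = patient_matrix(sentences, patient_ids, full_embedding, k_last)
    blocks: dict[int, np.ndarray] = {}
    if scope == "global":
        for f in fold_ids:
            blocks[f] = block_full
    else:
        for f in fold_ids:
            emb = train_embeddings(corpus_for((parts != 0) & (parts != f)), cbow)
            blocks[f] = patient_matrix(sentences, patient_ids, emb, k_last)
    return blocks, block_full, full_embedding


@dataclasses.dataclass
class ExperimentResult:
    bundle: RecordBundle
    cohort: pd.DataFrame
    parts: np.ndarray
    features: pd.DataFrame
    meta: dict
    encoder: FeatureEncoder
    matrix: MatrixResult
    exclusions: dict
    oracle_auc: float | None

    @property
    def labels(self) -> np.ndarray:
        return self.cohort["label"].to_numpy().astype(int)


def run_experiment(
    config: RunConfig, bundle: RecordBundle | None = None
) -> ExperimentResult:
    """Run the whole analysis in memory and return every intermediate."""
    if bundle is None:
        synth_cfg = dataclasses.replace(config.synth, seed=config.synth_seed)
        bundle = generate(synth_cfg)
    cohort, episodes, log = build_cohort(
        bundle, seed=config.select_seed, index_window=config.synth.index_window
    )
    parts = split_cohort(cohort, seed=config.split_seed)
    feats, meta = build_manual_features(cohort, bundle, episodes)
    encoder = FeatureEncoder().fit(feats, meta)
    x_manual = encoder.transform(feats)
    y = cohort["label"].to_numpy().astype(int)

    specs = _grid(config)
    needs_emb = any("embedding" in s.feature_groups for s in specs)
    blocks = block_full = None
    if needs_emb:
        cutoffs = pd.Series(
            cohort["discharge_date"].to_numpy(), index=cohort["patient_id"]
        )
        sents = build_sentences(
            bundle, cutoffs, include_event_tokens=config.include_event_tokens
        )
        cbow = dataclasses.replace(config.embedding, seed=config.embed_seed)
        blocks, block_full, _ = build_embedding_blocks(
            sents, cohort["patient_id"].to_numpy(), parts, cbow,
            config.k_last, config.embedding_scope,
        )
    matrix = run_matrix(
        x_manual, encoder, y, parts, specs,
        emb_blocks=blocks, emb_block_full=block_full,
        target_specificity=config.target_specificity,
        nri_bootstrap=config.nri_bootstrap, nri_seed=config.nri_seed,
    )
    oracle = None
    if bundle.truth is not None:
        risk = (
            bundle.truth.set_index("patient_id")["latent_risk"]
            .reindex(cohort["patient_id"])
            .to_numpy()
        )
        if len(np.unique(y)) > 1:
            oracle = auc(risk, y)
    return ExperimentResult(
        bundle=bundle, cohort=cohort, parts=parts, features=feats, meta=meta,
        encoder=encoder, matrix=matrix, exclusions=log.to_dict(),
        oracle_auc=oracle,
    )


# --------------------------------------------------------------------------
# file-based stages (CLI)
# --------------------------------------------------------------------------

_COHORT_FILE = "cohort.csv"


def _save_cohort(cohort: pd.DataFrame, parts, path: Path) -> None:
    out = cohort.copy()
    out["record_ids"] = out["record_ids"].map(
        lambda ids: ";".join(str(i) for i in ids)
    )
    out["part"] = parts
    for col in ("admit_date", "discharge_date"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def _load_cohort(path: Path) -> tuple[pd.DataFrame, np.ndarray]:
    df = pd.read_csv(
        path,
        dtype={"patient_id": str, "discharge_disposition": str,
               "primary_diagnosis": str},
        parse_dates=["admit_date", "discharge_date"],
    )
    df["record_ids"] = df["record_ids"].map(
        lambda s: [int(x) for x in str(s).split(";") if x != ""]
    )
    df["admitted_via_ed"] = df["admitted_via_ed"].astype(bool)
    df["label"] = df["label"].astype(bool)
    parts = df.pop("part").to_numpy()
    return df, parts


def stage_simulate(config: RunConfig, outdir: Path) -> None:
    synth_cfg = dataclasses.replace(config.synth, seed=config.synth_seed)
    write_bundle(generate(synth_cfg), outdir / "bundle")


def stage_cohort(config: RunConfig, outdir: Path) -> None:
    bundle = read_bundle(outdir / "bundle")
    cohort, episodes, log = build_cohort(
        bundle, seed=config.select_seed, index_window=config.synth.index_window
    )
    parts = split_cohort(cohort, seed=config.split_seed)
    _save_cohort(cohort, parts, outdir / _COHORT_FILE)
    with open(outdir / "exclusions.json", "w") as f:
        json.dump(log.to_dict(), f, indent=2)


def stage_features(config: RunConfig, outdir: Path) -> None:
    bundle = read_bundle(outdir / "bundle")
    cohort, _ = _load_cohort(outdir / _COHORT_FILE)
    from .cohort import build_episodes

    episodes = build_episodes(bundle.hospitalizations)
    feats, meta = build_manual_features(cohort, bundle, episodes)
    feats.to_csv(outdir / "features.csv")
    with open(outdir / "features_meta.json", "w") as f:
        json.dump(meta, f, indent=2)


def stage_embed(config: RunConfig, outdir: Path) -> None:
    """Write sentences and the all-CV-parts embedding as inspectable artifacts."""
    bundle = read_bundle(outdir / "bundle")
    cohort, parts = _load_cohort(outdir / _COHORT_FILE)
    cutoffs = pd.Series(cohort["discharge_date"].to_numpy(), index=cohort["patient_id"])
    sents = build_sentences(bundle, cutoffs, config.include_event_tokens)
    pids = cohort["patient_id"].to_numpy()
    with open(outdir / "sentences.txt", "w") as f:
        for p in pids:
            f.write(sents[p].text() + "\n")
    pd.DataFrame({"patient_id": pids, "line": np.arange(len(pids))}).to_csv(
        outdir / "sentences_index.csv", index=False
    )
    cbow = dataclasses.replace(config.embedding, seed=config.embed_seed)
    emb = train_embeddings([sents[p].tokens for p in pids[parts != 0]], cbow)
    save_embedding(emb, outdir / "embeddings.tsv")


def stage_train(config: RunConfig, outdir: Path) -> None:
    """Fit the model grid (per-split embeddings) and dump the full report."""
    bundle = read_bundle(outdir / "bundle")
    cohort, parts = _load_cohort(outdir / _COHORT_FILE)
    from .cohort import build_episodes

    episodes = build_episodes(bundle.hospitalizations)
    feats, meta = build_manual_features(cohort, bundle, episodes)
    encoder = FeatureEncoder().fit(feats, meta)
    x_manual = encoder.transform(feats)
    y = cohort["label"].to_numpy().astype(int)
    specs = _grid(config)
    blocks = block_full = None
    if any("embedding" in s.feature_groups for s in specs):
        cutoffs = pd.Series(
            cohort["discharge_date"].to_numpy(), index=cohort["patient_id"]
        )
        sents = build_sentences(bundle, cutoffs, config.include_event_tokens)
        cbow = dataclasses.replace(config.embedding, seed=config.embed_seed)
        blocks, block_full, _ = build_embedding_blocks(
            sents, cohort["patient_id"].to_numpy(), parts, cbow,
            config.k_last, config.embedding_scope,
        )
    matrix = run_matrix(
        x_manual, encoder, y, parts, specs,
        emb_blocks=blocks, emb_block_full=block_full,
        target_specificity=config.target_specificity,
        nri_bootstrap=config.nri_bootstrap, nri_seed=config.nri_seed,
    )
    report = {
        "reports": [r.to_dict() for r in matrix.reports],
        "pvalues_bonferroni": {f"{a} vs {b}": p for (a, b), p in matrix.pvalues.items()},
        "nri": {k: v.to_dict() for k, v in matrix.nris.items()},
    }
    with open(outdir / "report.json", "w") as f:
        json.dump(report, f, indent=2)
    # ROC coordinates of every model on the holdout, for plotting
    from sklearn.metrics import roc_curve

    for name, s in matrix.holdout_scores.items():
        fpr, tpr, thr = roc_curve(matrix.holdout_labels, s)
        pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}).to_csv(
            outdir / f"roc_{name}.csv", index=False
        )


def stage_evaluate(config: RunConfig, outdir: Path) -> None:
    """Shape report.json into the grid-style report.csv."""
    with open(outdir / "report.json") as f:
        report = json.load(f)
    rows = [
        {
            "model": r["family"],
            "features": "+".join(r["feature_groups"]),
            "name": r["name"],
            "cv_auc_mean": r["cv_auc_mean"],
            "cv_auc_sd": r["cv_auc_sd"],
            "test_auc": r["test_auc"],
            "sensitivity_at_spec": r["sensitivity_at_spec"],
        }
        for r in report["reports"]
    ]
    pd.DataFrame(rows).to_csv(outdir / "report.csv", index=False)


STAGES = {
    "simulate": stage_simulate,
    "cohort": stage_cohort,
    "features": stage_features,
    "embed": stage_embed,
    "train": stage_train,
    "evaluate": stage_evaluate,
}


def run(config: RunConfig, outdir: str | Path) -> Path:
    """Run every stage in order and write the reproducibility manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, fn in STAGES.items():
        try:
            fn(config, outdir)
        except Exception as exc:
            err = StageError(name, str(exc))
            with open(outdir / "error.json", "w") as f:
                json.dump(err.record, f, indent=2)
            raise err from exc
    counts = {
        "bundle_patients": sum(1 for _ in open(outdir / "bundle" / "demographics.csv")) - 1,
        "cohort_rows": sum(1 for _ in open(outdir / _COHORT_FILE)) - 1,
        "feature_rows": sum(1 for _ in open(outdir / "features.csv")) - 1,
        "sentences": sum(1 for _ in open(outdir / "sentences.txt")),
    }
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "seeds": config.seeds(),
        "row_counts": counts,
    }
    with open(outdir / "run_manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return outdir
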