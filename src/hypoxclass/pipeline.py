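"""Staged pipeline orchestration with digest-keyed caching and a run manifest.

Stages run in order — simulate/load -> qc -> normalize -> score -> label ->
signature -> features -> bench -> predict — each reading its inputs from and
writing its outputs to the run directory, so a rerun with unchanged inputs
and parameters is a cache hit that recomputes nothing.  Every stage records
its parameters, seeds, input/output file digests and headline counts in
``manifest.json``; the manifest alone suffices to re-issue the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from . import __version__
from .bench import BenchConfig, classify_low_confidence, run_benchmark
from .embeddings import EmbeddingProviderSpec, FeatureMatrix, build_features
from .errors import PipelineError, ValidationError
from .formats_io import (
    CountMatrix,
    read_annotation,
    read_counts,
    read_gmt,
    write_annotation,
    write_counts,
    write_gmt,
    write_labels,
)
from .labeling import LOW_CONF, HC_HYPOXIC, HC_NORMOXIC, LabelTable, label_cells
from .preprocess import NormalizedMatrix, QCParams, log_normalize, qc_filter
from .scoring import ScoreMatrix, ssgsea_score
from .signature import derive_signature
from .simulate import SimParams, simulate

logger = logging.getLogger(__name__)

STAGES = ["simulate", "qc", "normalize", "score", "label", "signature", "embed", "bench", "predict"]


def _digest_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _digest_paths(paths: list[Path]) -> dict[str, str]:
    out = {}
    for p in sorted(paths):
        if p.is_dir():
            for sub in sorted(p.rglob("*")):
                if sub.is_file():
                    out[str(sub)] = _digest_file(sub)
        elif p.exists():
            out[str(p)] = _digest_file(p)
    return out


def _stage_key(params: dict, input_digests: dict) -> str:
    payload = json.dumps({"params": params, "inputs": input_digests}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def stage_seed(master: int, stage: str) -> int:
    return (int(master) * 1000003 + STAGES.index(stage)) % (2**31 - 1)


def _write_norm(norm: NormalizedMatrix, d: Path) -> None:
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(d / "matrix.mtx"), norm.values.T.tocoo(), precision=10)
    (d / "features.tsv").write_text("\n".join(norm.gene_ids) + "\n")
    (d / "barcodes.tsv").write_text("\n".join(norm.cell_ids) + "\n")
    (d / "scale.json").write_text(json.dumps({"scale_factor": norm.scale_factor}))


def _read_norm(d: Path) -> NormalizedMatrix:
    m = sp.csr_matrix(scipy.io.mmread(d / "matrix.mtx")).T.tocsr()
    genes = (d / "features.tsv").read_text().splitlines()
    cells = (d / "barcodes.tsv").read_text().splitlines()
    scale = json.loads((d / "scale.json").read_text())["scale_factor"]
    return NormalizedMatrix(cells, genes, m, scale)


def _write_features(fm: FeatureMatrix, path: Path) -> None:
    df = pd.DataFrame(fm.values, index=pd.Index(fm.cell_ids, name="cell_id"),
                      columns=[f"f{i}" for i in range(fm.values.shape[1])])
    df.to_csv(path, sep="\t", float_format="%.10g")


def _read_features(path: Path, mode: str) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FeatureMatrix([str(i) for i in df.index], df.to_numpy(float), mode)


class PipelineRun:
    """One orchestrated run rooted at ``outdir``."""

    def __init__(self, config: dict, outdir: str | Path):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seed = int(config.get("seed", 0))
        self.manifest_path = self.outdir / "manifest.json"
        self.prev_manifest = {}
        if self.manifest_path.exists():
            try:
                self.prev_manifest = json.loads(self.manifest_path.read_text())
            except json.JSONDecodeError:
                self.prev_manifest = {}
        self.manifest: dict = {
            "tool": "hypoxclass",
            "version": __version__,
            "config": config,
            "master_seed": self.seed,
            "stages": {},
        }

    # -- caching machinery --------------------------------------------------

    def _cached(self, stage: str, params: dict, inputs: list[Path], outputs: list[Path]) -> bool:
        digests = _digest_paths(inputs)
        key = _stage_key(params, digests)
        entry = {"params": params, "key": key, "input_digests": digests}
        prev = self.prev_manifest.get("stages", {}).get(stage)
        if prev and prev.get("key") == key:
            out_digests = _digest_paths(outputs)
            if out_digests and out_digests == prev.get("output_digests"):
                entry.update(cache_hit=True, output_digests=out_digests,
                             counts=prev.get("counts", {}))
                self.manifest["stages"][stage] = entry
                logger.info("[%s] cache hit", stage)
                return True
        entry["cache_hit"] = False
        self.manifest["stages"][stage] = entry
        return False

    def _finish(self, stage: str, outputs: list[Path], counts: dict | None = None) -> None:
        self.manifest["stages"][stage]["output_digests"] = _digest_paths(outputs)
        if counts:
            self.manifest["stages"][stage]["counts"] = counts
        self._save_manifest()

    def _save_manifest(self) -> None:
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))

    def _enabled(self, stage: str, default: bool = True) -> bool:
        return bool(self.config.get(stage, {}).get("enabled", default))

    # -- stages -------------------------------------------------------------

    def run(self) -> dict:
        """Execute all enabled stages; abort naming the failing stage."""
        order = [
            ("simulate", self.stage_simulate),
            ("qc", self.stage_qc),
            ("normalize", self.stage_normalize),
            ("score", self.stage_score),
            ("label", self.stage_label),
            ("signature", self.stage_signature),
            ("embed", self.stage_embed),
            ("bench", self.stage_bench),
            ("predict", self.stage_predict),
        ]
        for name, fn in order:
            if not self._enabled(name, default=(name != "simulate" or "inputs" not in self.config)):
                logger.info("[%s] disabled", name)
                continue
            try:
                fn()
            except (ValidationError, PipelineError):
                self._save_manifest()
                raise
            except Exception as exc:  # noqa: BLE001 - stage attribution
                self._save_manifest()
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        self._save_manifest()
        return self.manifest

    def _raw_paths(self) -> dict[str, Path]:
        inp = self.config.get("inputs", {})
        return {
            "counts": Path(inp["counts"]) if inp.get("counts") else self.outdir / "raw_counts",
            "gmt": Path(inp["gmt"]) if inp.get("gmt") else self.outdir / "genesets.gmt",
            "annotation": (Path(inp["annotation"]) if inp.get("annotation")
                           else self.outdir / "annotation.tsv"),
            "doublets": Path(inp["doublets"]) if inp.get("doublets") else None,
            "layout": inp.get("layout", "mtx_triplet"),
        }

    def stage_simulate(self) -> None:
        if "inputs" in self.config:
            return
        params_cfg = dict(self.config.get("simulate", {}))
        params_cfg.pop("enabled", None)
        params_cfg.setdefault("seed", stage_seed(self.seed, "simulate"))
        params = SimParams(**params_cfg)
        outs = [self.outdir / "raw_counts", self.outdir / "genesets.gmt",
                self.outdir / "annotation.tsv", self.outdir / "truth.tsv"]
        if self._cached("simulate", params.to_dict(), [], outs):
            return
        cm, truth, sets, ann = simulate(params)
        write_counts(cm, outs[0])
        write_gmt(sets, outs[1])
        write_annotation(ann, outs[2])
        truth.table.to_csv(outs[3], sep="\t", index=False)
        self._finish("simulate", outs, truth.counts())

    def stage_qc(self) -> None:
        raw = self._raw_paths()
        cfg = self.config.get("qc", {})
        params = QCParams(
            min_genes_per_cell=int(cfg.get("min_genes", 500)),
            max_mito_fraction=float(cfg.get("max_mito", 0.20)),
            min_cells_per_gene_fraction=float(cfg.get("min_cells_frac", 0.001)),
            drop_doublets=bool(cfg.get("drop_doublets", True)),
        )
        inputs = [raw["counts"], raw["annotation"]] + ([raw["doublets"]] if raw["doublets"] else [])
        outs = [self.outdir / "qc_counts", self.outdir / "qc_report.tsv"]
        if self._cached("qc", params.__dict__, inputs, outs):
            return
        cm = read_counts(raw["counts"], layout=raw["layout"])
        ann = read_annotation(raw["annotation"])
        flags = None
        if raw["doublets"]:
            dt = pd.read_csv(raw["doublets"], sep="\t", index_col=0)
            flags = dt.iloc[:, 0].reindex(cm.cell_ids).fillna(False).to_numpy(bool)
        filtered, report = qc_filter(cm, ann, params, flags)
        write_counts(filtered, outs[0])
        pd.DataFrame([report.to_dict()]).to_csv(outs[1], sep="\t", index=False)
        self._finish("qc", outs, report.to_dict())

    def stage_normalize(self) -> None:
        cfg = self.config.get("normalize", {})
        scale = float(cfg.get("scale_factor", 1e4))
        inputs = [self.outdir / "qc_counts"]
        outs = [self.outdir / "normalized"]
        if self._cached("normalize", {"scale_factor": scale}, inputs, outs):
            return
        cm = read_counts(inputs[0])
        norm = log_normalize(cm, scale)
        _write_norm(norm, outs[0])
        self._finish("normalize", outs)

    def stage_score(self) -> None:
        raw = self._raw_paths()
        cfg = self.config.get("score", {})
        params = {"alpha": float(cfg.get("alpha", 0.25)),
                  "min_genes_present": int(cfg.get("min_genes_present", 3))}
        inputs = [self.outdir / "normalized", raw["gmt"]]
        outs = [self.outdir / "scores.tsv"]
        if self._cached("score", params, inputs, outs):
            return
        norm = _read_norm(inputs[0])
        sets = read_gmt(raw["gmt"])
        sm = ssgsea_score(norm, sets, **params)
        df = pd.DataFrame(sm.scores, index=pd.Index(sm.cell_ids, name="cell_id"),
                          columns=sm.set_names)
        df.to_csv(outs[0], sep="\t", float_format="%.10g")
        self._finish("score", outs, {"coverage": sm.coverage})

    def stage_label(self) -> None:
        cfg = self.config.get("label", {})
        seed = int(cfg.get("seed", stage_seed(self.seed, "label")))
        params = {"seed": seed,
                  "posterior_cut": float(cfg.get("posterior_cut", 0.5)),
                  "n_init": int(cfg.get("n_init", 5))}
        inputs = [self.outdir / "scores.tsv"]
        outs = [self.outdir / "labels.tsv"]
        if self._cached("label", params, inputs, outs):
            return
        df = pd.read_csv(inputs[0], sep="\t", index_col=0)
        sm = ScoreMatrix([str(i) for i in df.index], list(df.columns),
                         df.to_numpy(float), alpha=np.nan, coverage={})
        table, _ = label_cells(sm, **params)
        write_labels(table.to_frame(), outs[0])
        self._finish("label", outs, table.counts())

    def stage_signature(self) -> None:
        raw = self._raw_paths()
        cfg = self.config.get("signature", {})
        params = {"p_thresh": float(cfg.get("p", 0.05)),
                  "lfc_thresh": float(cfg.get("lfc", 0.25)),
                  "min_pct": float(cfg.get("min_pct", 0.10))}
        inputs = [self.outdir / "normalized", self.outdir / "labels.tsv", raw["annotation"]]
        outs = [self.outdir / "signature.tsv"]
        if self._cached("signature", params, inputs, outs):
            return
        norm = _read_norm(inputs[0])
        labels = LabelTable.from_frame(pd.read_csv(inputs[1], sep="\t"))
        ann = read_annotation(raw["annotation"])
        sig = derive_signature(norm, labels, ann, **params)
        sig.to_csv(outs[0], sep="\t", index=False, float_format="%.10g")
        self._finish("signature", outs, {"signature_genes": int(sig["passes"].sum())})

    def stage_embed(self) -> None:
        cfg = self.config.get("embed", {})
        provider = cfg.get("provider", "svd")
        kind = {"svd": "svd_fallback", "external": "external_file", "raw": "raw_signature"}.get(
            provider, provider)
        params = {"kind": kind, "dim": int(cfg.get("dim", 50)),
                  "file": str(cfg.get("file")) if cfg.get("file") else None}
        inputs = [self.outdir / "normalized", self.outdir / "signature.tsv"]
        if params["file"]:
            inputs.append(Path(params["file"]))
        outs = [self.outdir / "features_embedding.tsv", self.outdir / "features_raw.tsv"]
        if self._cached("embed", params, inputs, outs):
            return
        norm = _read_norm(inputs[0])
        sig = pd.read_csv(inputs[1], sep="\t")
        emb_spec = EmbeddingProviderSpec(kind=kind, dim=params["dim"],
                                         seed=stage_seed(self.seed, "embed"),
                                         source_path=params["file"])
        emb = build_features(norm, emb_spec, sig)
        raw_fm = build_features(norm, EmbeddingProviderSpec(kind="raw_signature"), sig)
        _write_features(emb, outs[0])
        _write_features(raw_fm, outs[1])
        self._finish("embed", outs, {"embedding_dim": emb.values.shape[1],
                                     "raw_dim": raw_fm.values.shape[1]})

    def stage_bench(self) -> None:
        cfg = self.config.get("bench", {})
        model_names = cfg.get("models") or None
        bc = BenchConfig(
            model_names=model_names or BenchConfig().model_names,
            fractions=[float(f) for f in cfg.get("fractions", BenchConfig().fractions)],
            holdout_fraction=float(cfg.get("holdout", 0.3)),
            seed=int(cfg.get("seed", stage_seed(self.seed, "bench"))),
        )
        params = {"model_names": bc.model_names, "fractions": bc.fractions,
                  "holdout": bc.holdout_fraction, "seed": bc.seed}
        inputs = [self.outdir / "features_embedding.tsv", self.outdir / "features_raw.tsv",
                  self.outdir / "labels.tsv"]
        outs = [self.outdir / "bench_rows.tsv", self.outdir / "bench_summary.json",
                self.outdir / "model.pkl"]
        if self._cached("bench", params, inputs, outs):
            return
        emb = _read_features(inputs[0], "embedding")
        raw_fm = _read_features(inputs[1], "raw_counts")
        labels = pd.read_csv(inputs[2], sep="\t")
        hc = labels[labels.status.isin([HC_HYPOXIC, HC_NORMOXIC])]
        hc_ids = hc.cell_id.astype(str).tolist()
        y = (hc.status == HC_HYPOXIC).to_numpy(int)
        report = run_benchmark(
            {"embedding": emb.subset(hc_ids), "raw_counts": raw_fm.subset(hc_ids)}, y, bc)
        report.rows.to_csv(outs[0], sep="\t", index=False, float_format="%.10g")
        summary = {
            "selected_model": report.selected_model,
            "top3_intersection": report.top3_intersection,
            "mean_ranks": report.mean_ranks.round(6).to_dict(),
            "models_run": sorted(report.rows.model.unique().tolist()),
        }
        outs[1].write_text(json.dumps(summary, indent=2, sort_keys=True))
        with open(self.outdir / "model.pkl", "wb") as fh:
            pickle.dump(report.final_model, fh)
        self._finish("bench", outs, {"selected_model": report.selected_model,
                                     "n_train_cells": int(y.size)})

    def stage_predict(self) -> None:
        cfg = self.config.get("predict", {})
        params = {"threshold": float(cfg.get("threshold", 0.5))}
        model_path = self.outdir / "model.pkl"
        if not model_path.exists() or "bench" not in self.manifest["stages"]:
            raise PipelineError("no trained model: run the bench stage first")
        inputs = [self.outdir / "features_embedding.tsv", self.outdir / "labels.tsv", model_path]
        outs = [self.outdir / "predictions.tsv"]
        if self._cached("predict", params, inputs, outs):
            return
        emb = _read_features(inputs[0], "embedding")
        labels = pd.read_csv(inputs[1], sep="\t")
        low_ids = labels.loc[labels.status == LOW_CONF, "cell_id"].astype(str).tolist()
        with open(model_path, "rb") as fh:
            model = pickle.load(fh)
        if low_ids:
            preds = classify_low_confidence(model, emb.subset(low_ids), params["threshold"])
        else:
            preds = pd.DataFrame(columns=["cell_id", "probability", "predicted"])
        preds.to_csv(outs[0], sep="\t", index=False, float_format="%.10g")
        counts = preds["predicted"].value_counts().to_dict() if len(preds) else {}
        self._finish("predict", outs, {str(k): int(v) for k, v in counts.items()})


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Convenience wrapper: build a :class:`PipelineRun` and execute it."""
    return PipelineRun(config, outdir).run()


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
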