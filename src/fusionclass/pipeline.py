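"""End-to-end experiment: phantoms -> preprocess -> fuse -> features ->
classify -> evaluate, with the three-way track comparison (fused vs
MRI-only vs SPECT-only).

A run is fully reproducible from its config: every stage draws its
randomness from a stream keyed by (master seed, stage name), so adding a
stage never perturbs earlier stages, and all written artifacts are listed
in a manifest with content hashes.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split

from . import classifiers as clf
from .classifiers import LabeledFeatureSet, POSITIVE
from .evaluation import (classification_metrics, comparison_report,
                         confusion_matrix, roc_curve)
from .features import FEATURE_NAMES, feature_vector, segment
from .fusion import fuse_images
from .phantoms import generate_dataset
from .preprocess import clahe, register
from .quality import ncc, psnr, ssim

TRACKS = ("fused", "mri", "spect")
CLASSIFIER_NAMES = ("svm", "knn", "tree")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment run."""

    n_per_class: int = 100
    seed: int = 42
    image_size: tuple = (128, 128)
    clahe_tile: tuple = (8, 8)
    clahe_clip: float = 0.01
    fusion_rule: str = "average"
    fusion_block: int | None = None
    classifiers: tuple = CLASSIFIER_NAMES
    knn_k: int = 5
    tree_max_depth: int | None = None
    tree_min_leaf: int = 1
    svm_c: float = 1.0
    split: float = 0.7
    register_pairs: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for name in ("image_size", "clahe_tile", "classifiers"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for name in ("image_size", "clahe_tile", "classifiers"):
            d[name] = list(d[name])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed keyed by stage name (< 2**31)."""
    ss = np.random.SeedSequence([master_seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class TrackResult:
    features: pd.DataFrame
    report: pd.DataFrame
    runs: dict  # classifier -> {"cm": ConfusionMatrix, "roc": ROCCurve, ...}

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([r["metrics"]["accuracy"]
                              for r in self.runs.values()]))


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    tracks: dict  # name -> TrackResult
    quality: dict
    manifest: dict = field(default_factory=dict)

    def summary(self) -> dict:
        out = {"mean_accuracy": {}, "accuracy": {}, "auc": {},
               "quality": self.quality}
        for name, tr in self.tracks.items():
            out["mean_accuracy"][name] = tr.mean_accuracy
            out["accuracy"][name] = {c: r["metrics"]["accuracy"]
                                     for c, r in tr.runs.items()}
            out["auc"][name] = {c: r["roc"].auc for c, r in tr.runs.items()}
        return out

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2, sort_keys=True)


def _extract_track_features(pairs, config: ExperimentConfig) -> dict:
    """CLAHE -> (optional registration) -> fusion -> per-track features."""
    rows = {t: [] for t in TRACKS}
    qual = {"psnr_mri": [], "psnr_spect": [], "ssim_mri": [],
            "ssim_spect": [], "ncc_mri": [], "ncc_spect": []}
    for idx, pair in enumerate(pairs):
        mri = clahe(pair.mri, config.clahe_tile, config.clahe_clip)
        spect = clahe(pair.spect, config.clahe_tile, config.clahe_clip)
        if config.register_pairs:
            spect = register(spect, mri).registered
        fused = fuse_images(mri, spect, rule=config.fusion_rule,
                            block=config.fusion_block)
        qual["psnr_mri"].append(psnr(mri, fused))
        qual["psnr_spect"].append(psnr(spect, fused))
        qual["ssim_mri"].append(ssim(mri, fused))
        qual["ssim_spect"].append(ssim(spect, fused))
        qual["ncc_mri"].append(ncc(mri, fused))
        qual["ncc_spect"].append(ncc(spect, fused))
        for track, img in (("fused", fused), ("mri", mri), ("spect", spect)):
            try:
                mask = segment(img)
                fv = feature_vector(img, mask)
            except ValueError:
                continue  # empty mask or constant image: skip this sample
            row = {"pair": idx, "label": pair.label, **fv.as_dict()}
            rows[track].append(row)
    tables = {t: pd.DataFrame(rows[t]) for t in TRACKS}
    quality = {k: float(np.mean(v)) for k, v in qual.items()}
    return {"tables": tables, "quality": quality}


def _fit_predict(name: str, train: LabeledFeatureSet, test_X: np.ndarray,
                 config: ExperimentConfig):
    """Train one classifier and return (predictions, positive-class scores)."""
    if name == "svm":
        model = clf.svm_fit(train, margin_penalty=config.svm_c)
        preds = [clf.svm_predict(model, x) for x in test_X]
        scores = [clf.svm_score(model, x) for x in test_X]
    elif name == "knn":
        model = clf.knn_fit(train, k=min(config.knn_k, len(train)))
        preds = [clf.knn_predict(model, x) for x in test_X]
        scores = [clf.knn_score(model, x) for x in test_X]
    elif name == "tree":
        model = clf.id3_fit(train, max_depth=config.tree_max_depth,
                            min_leaf=config.tree_min_leaf)
        preds = [clf.id3_predict(model, x) for x in test_X]
        scores = [clf.id3_score(model, x) for x in test_X]
    else:
        raise ValueError(f"unknown classifier {name!r}")
    return preds, scores


def _evaluate_track(table: pd.DataFrame, config: ExperimentConfig,
                    split_seed: int) -> TrackResult:
    X = table[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
    y = table["label"].to_numpy(dtype=object)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=config.split, random_state=split_seed, stratify=y)
    train = LabeledFeatureSet(X=X_tr, y=y_tr, feature_names=FEATURE_NAMES)
    runs = {}
    for name in config.classifiers:
        preds, scores = _fit_predict(name, train, X_te, config)
        cm = confusion_matrix(y_te, preds, positive=POSITIVE)
        roc = roc_curve(scores, y_te, positive=POSITIVE)
        runs[name] = {"cm": cm, "roc": roc,
                      "metrics": classification_metrics(cm).rounded()}
    report = comparison_report([(n, runs[n]["cm"]) for n in config.classifiers])
    return TrackResult(features=table, report=report, runs=runs)


def run_experiment(config: ExperimentConfig,
                   out_dir: str | Path | None = None) -> ExperimentResult:
    """Run the full experiment; optionally write all artifacts to ``out_dir``.

    Generates ``2 * n_per_class`` phantom pairs, builds the three feature
    tracks (fused, MRI-only, SPECT-only), trains every configured
    classifier on each track with the same stratified split, and returns
    per-track comparison reports plus a cross-track summary.
    """
    pairs = generate_dataset(config.n_per_class,
                             stage_seed(config.seed, "phantoms"),
                             image_size=config.image_size)
    extracted = _extract_track_features(pairs, config)
    split_seed = stage_seed(config.seed, "split")
    tracks = {t: _evaluate_track(extracted["tables"][t], config, split_seed)
              for t in TRACKS}
    result = ExperimentResult(config=config, tracks=tracks,
                              quality=extracted["quality"])
    if out_dir is not None:
        result.manifest = _write_artifacts(result, Path(out_dir))
    return result


def _write_artifacts(result: ExperimentResult, out_dir: Path) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    def _write_text(path: Path, text: str):
        path.write_text(text)
        written.append(path)

    for name, tr in result.tracks.items():
        _write_text(out_dir / f"features_{name}.csv",
                    tr.features.to_csv(index=False))
        _write_text(out_dir / f"report_{name}.csv",
                    tr.report.to_csv(index=False))
        doc = {c: {"counts": {"TP": r["cm"].tp, "FP": r["cm"].fp,
                              "TN": r["cm"].tn, "FN": r["cm"].fn},
                   "metrics": r["metrics"], "auc": r["roc"].auc}
               for c, r in tr.runs.items()}
        _write_text(out_dir / f"report_{name}.json",
                    json.dumps(doc, indent=2, sort_keys=True))
    _write_text(out_dir / "summary.json", result.summary_json())
    result.config.to_yaml(out_dir / "config.yaml")
    written.append(out_dir / "config.yaml")

    manifest = {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                for p in written}
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
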