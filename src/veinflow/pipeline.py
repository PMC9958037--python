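"""End-to-end run: simulate -> qflow -> features -> train -> evaluate -> compare.

A single :class:`RunConfig` (one generator seed, the classifier settings,
feature options) drives all stages; the run report embeds the config
snapshot, every seed, the confusion matrix and the four training-stage
metrics, plus a digest of the per-segment group comparisons.  Evaluation is
on the training set by default (all trials are used for training); an
optional stratified hold-out split gives an honest generalization estimate
instead and is clearly labelled as such in the report.

Given identical configs, regenerating a run reproduces the report bit for
bit (deterministic seeds, sorted JSON, uncompressed NIfTI).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from . import __version__
from .evaluation import confusion, metrics
from .features import build_features, feature_matrix, fit_standardizer
from .group_stats import compare_segments
from .qflow import batch_qflow
from .rbfnn import fit
from .simulate import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full configuration of one pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 42
    ratio: str = "mf"              # second GSV/PV ratio: "mf" or "mv"
    standardize: bool = True
    k: int = 16
    eta: float = 0.5
    epochs: int = 200
    threshold: Union[str, float] = 0.5   # fixed value, or "sweep"
    split: str = "phase"           # forward/backward split convention
    holdout_fraction: float = 0.0  # 0 => evaluate on the training set
    save_images: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        return d

    @classmethod
    def from_dict(cls, d) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _holdout_split(labels: np.ndarray, fraction: float,
                   seed: int) -> np.ndarray:
    """Stratified boolean test mask holding out ``fraction`` per class."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2024]))
    test = np.zeros(len(labels), dtype=bool)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        n_hold = int(round(fraction * len(idx)))
        test[rng.choice(idx, size=n_hold, replace=False)] = True
    return test


def run_pipeline(config: RunConfig,
                 out_dir: Optional[Union[str, Path]] = None) -> dict:
    """Execute every stage on a synthetic cohort and return the run report.

    With ``out_dir`` set, all intermediate artifacts (cohort NIfTI directory,
    qflow.csv, features.csv, model.json, compare.csv, report.json) are
    written and inventoried with SHA-256 hashes.  A stage failure marks the
    report and preserves the artifacts written so far.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "software": {"name": "veinflow", "version": __version__},
        "config": config.to_dict(),
        "seeds": {"generator": config.seed, "classifier": config.seed},
        "stages": [],
        "files": {},
    }
    written: list[Path] = []

    def _emit(name: str, path: Path) -> None:
        report["files"][name] = {"path": path.name,
                                 "sha256": _sha256(path)}
        written.append(path)

    stage = "simulate"
    try:
        cohort = generate_cohort(config.cohort, seed=config.seed)
        report["stages"].append(stage)
        report["cohort"] = {
            "n_reflux": config.cohort.n_reflux,
            "n_control": config.cohort.n_control,
            "n_subjects": len(cohort.subjects),
            "n_scans": len(cohort.records),
        }
        logger.info("stage=simulate subjects=%d scans=%d seed=%d",
                    len(cohort.subjects), len(cohort.records), config.seed)
        if out is not None and config.save_images:
            from .io import save_cohort
            manifest = save_cohort(cohort, out / "cohort")
            report["files"]["manifest"] = {
                "path": str(manifest.relative_to(out)),
                "sha256": _sha256(manifest)}

        stage = "qflow"
        qflow_df = batch_qflow(cohort, split=config.split)
        report["stages"].append(stage)
        report["qflow"] = {"n_rows": int(len(qflow_df)),
                           "n_failures": len(qflow_df.attrs["failures"])}
        if out is not None:
            p = out / "qflow.csv"
            qflow_df.to_csv(p, index=False)
            _emit("qflow", p)

        stage = "features"
        labels = cohort.labels()
        feats, excluded = build_features(qflow_df, labels, ratio=config.ratio)
        X_raw, d = feature_matrix(feats)
        report["stages"].append(stage)
        report["features"] = {"n_subjects": int(len(feats)),
                              "n_positive": int(d.sum()),
                              "n_excluded": len(excluded),
                              "columns": [c for c in feats.columns
                                          if c not in ("subject_id", "label")]}
        if out is not None:
            p = out / "features.csv"
            feats.to_csv(p, index=False)
            _emit("features", p)

        stage = "train"
        if config.standardize:
            std = fit_standardizer(X_raw)
            X = std.transform(X_raw)
        else:
            std = None
            X = X_raw
        test_mask = None
        if config.holdout_fraction > 0:
            test_mask = _holdout_split(d, config.holdout_fraction, config.seed)
        train_mask = ~test_mask if test_mask is not None else np.ones(
            len(d), dtype=bool)
        model = fit(X[train_mask], d[train_mask], k=config.k, eta=config.eta,
                    epochs=config.epochs, seed=config.seed,
                    threshold=config.threshold)
        if std is not None:
            model.metadata["standardizer"] = std.to_dict()
        report["stages"].append(stage)
        report["model"] = {"k": config.k, "threshold": model.threshold,
                           "sigma": float(np.atleast_1d(model.sigma)[0])
                           if np.ndim(model.sigma) else float(model.sigma),
                           "train_f_measure": model.metadata["train_f_measure"]}
        if out is not None:
            p = out / "model.json"
            p.write_text(model.to_json())
            _emit("model", p)

        stage = "evaluate"
        eval_mask = test_mask if test_mask is not None else train_mask
        report["evaluation_on"] = ("holdout" if test_mask is not None
                                   else "training_set")
        scores = model.predict(X[eval_mask])
        pred = (scores > model.threshold).astype(int)
        cm = confusion(d[eval_mask], pred)
        rep = metrics(cm)
        report["stages"].append(stage)
        report["confusion"] = cm.as_dict()
        report["metrics"] = rep.as_dict()
        logger.info("stage=evaluate acc=%s tpr=%s ppv=%s",
                    rep.accuracy, rep.sensitivity, rep.precision)
        if out is not None:
            p = out / "scores.csv"
            feats.loc[eval_mask, ["subject_id", "label"]].assign(
                score=scores, prediction=pred).to_csv(p, index=False)
            _emit("scores", p)

        stage = "compare"
        comp = compare_segments(qflow_df, labels)
        report["stages"].append(stage)
        done = comp[comp["tier"] != "skipped"]
        report["group_comparison"] = {
            "n_rows": int(len(comp)),
            "significant": {
                seg: sorted(done[(done["segment"] == seg)
                                 & (done["p"] < 0.05)]["parameter"])
                for seg in comp["segment"].unique()},
            "note": comp.attrs["note"],
        }
        if out is not None:
            p = out / "compare.csv"
            comp.to_csv(p, index=False)
            _emit("compare", p)
    except Exception as exc:  # stage failure: mark, preserve artifacts
        logger.exception("stage %s failed", stage)
        report["failed_stage"] = stage
        report["error"] = f"{type(exc).__name__}: {exc}"

    if out is not None:
        (out / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=2) + "\n")
    return report
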