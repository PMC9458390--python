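"""End-to-end experiment orchestration.

One call runs the whole study on a labeled record set: extract the
46-feature vectors, split 80/20 (stratified), and for every feature set
(A/B/C) and classifier preset run 10-fold cross-validation on the training
split, fit, and evaluate on the held-out test split.  The report mirrors a
per-feature-set grid of classifier metrics and embeds the per-sample
predictions, so every reported metric can be recomputed from the report
alone.

A single experiment seed expands into named per-stage seeds (simulation,
split, Bayesian optimization, baseline models) so any stage can be re-run
in isolation with unchanged randomness.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .audio_io import AudioRecord, RunConfig, logger
from .classify import (FAMILIES, bo_svm_train, evaluate, split_dataset,
                       train_baseline)
from .features import FEATURE_NAMES, FEATURE_SETS, extract_features

__all__ = ["ExperimentReport", "stage_seeds", "features_table", "run_experiment"]


def stage_seeds(seed: int) -> dict[str, int]:
    """Expand one global seed into named per-stage seeds (< 2^31)."""
    state = np.random.SeedSequence(seed).generate_state(4)
    names = ("simulate", "split", "bo", "models")
    return {name: int(s % 2 ** 31) for name, s in zip(names, state)}


def features_table(records: list[AudioRecord],
                   config: RunConfig | None = None) -> pd.DataFrame:
    """Extract the 46 features of every record into a tidy table.

    Records that fail segmentation (fewer than 2 detected beats) are
    dropped with a log message.
    """
    config = config or RunConfig()
    rows = []
    for rec in records:
        try:
            rows.append(extract_features(rec, config).to_dict())
        except ValueError as exc:
            logger.warning("skipping %s: %s", rec.source_id, exc)
    if not rows:
        raise ValueError("no record could be segmented")
    return pd.DataFrame(rows, columns=FEATURE_NAMES + ["source_id", "label"])


@dataclass
class ExperimentReport:
    """Config echo, per-set per-classifier metrics, CV scores, predictions."""

    config: dict
    seeds: dict
    version: str
    results: dict  # results[set][family] = {metrics, cv_score, hyperparams, predictions}

    def to_dict(self) -> dict:
        return {"config": self.config, "seeds": self.seeds,
                "version": self.version, "results": self.results}

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def body_hash(self) -> str:
        """SHA-256 of the canonical report body (determinism check)."""
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()

    def to_markdown(self) -> str:
        lines = []
        for set_name, grid in self.results.items():
            lines.append(f"## Feature set {set_name}")
            lines.append("| Classifier | Acc | Se | Sp | Ps | F1 | CV acc |")
            lines.append("|---|---|---|---|---|---|---|")
            for family, cell in grid.items():
                m = cell["metrics"]
                cv = cell["cv_score"]
                cv_txt = f"{cv:.3f}" if cv == cv else "-"
                lines.append(
                    f"| {family} | {m['Acc']:.3f} | {m['Se']:.3f} | "
                    f"{m['Sp']:.3f} | {m['Ps']:.3f} | {m['F1']:.3f} | {cv_txt} |")
            lines.append("")
        return "\n".join(lines)


def run_experiment(features: pd.DataFrame, config: RunConfig | None = None,
                   feature_sets: tuple[str, ...] = ("A", "B", "C"),
                   families: list[str] | None = None, seed: int = 0,
                   test_frac: float = 0.2, cv: int = 10,
                   bo_iter: int = 30) -> ExperimentReport:
    """Train and evaluate every preset on every feature set.

    features is a table with the 46 feature columns plus label (and
    optionally source_id); the same stratified row split is reused across
    feature sets and families so the grids are comparable.
    """
    config = config or RunConfig()
    families = families if families is not None else FAMILIES
    y = features["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    seeds = stage_seeds(seed)
    ids = features["source_id"].to_numpy() if "source_id" in features \
        else np.arange(len(features)).astype(str)

    # one shared row split: split indices, then project columns per set
    idx_split = split_dataset(np.arange(len(y))[:, None], y,
                              test_frac=test_frac, seed=seeds["split"])
    train_rows = idx_split.train_X[:, 0].astype(int)
    test_rows = idx_split.test_X[:, 0].astype(int)

    results: dict = {}
    for set_name in feature_sets:
        cols = FEATURE_SETS[set_name]
        X = features[cols].to_numpy(dtype=float)
        train_X, train_y = X[train_rows], y[train_rows]
        test_X, test_y = X[test_rows], y[test_rows]
        grid: dict = {}
        for family in families:
            if family == "bo_svm":
                model = bo_svm_train(train_X, train_y, n_iter=bo_iter,
                                     seed=seeds["bo"], cv=cv)
            else:
                model = train_baseline(family, train_X, train_y,
                                       seed=seeds["models"], cv=cv)
            metrics = evaluate(model, test_X, test_y)
            pred = model.estimator.predict(model.scaler.transform(test_X))
            grid[family] = {
                "metrics": metrics.to_dict(),
                "cv_score": model.cv_score,
                "hyperparams": {k: float(v) if isinstance(v, (int, float)) else v
                                for k, v in model.hyperparams.items()},
                "predictions": [
                    {"source_id": str(ids[r]), "true": str(t), "pred": str(p)}
                    for r, t, p in zip(test_rows, test_y, pred)],
            }
            logger.info("set %s / %s: test Acc %.3f", set_name, family,
                        metrics.Acc)
        results[set_name] = grid
    return ExperimentReport(config=config.to_dict(), seeds=seeds,
                            version=__version__, results=results)
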