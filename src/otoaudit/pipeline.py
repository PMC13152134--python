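"""Full audit battery over one training source and several evaluation sources.

Three stages mirror the three audits:

* an occlusion sweep: the classifier is refit on eclipsed copies of the
  training source at each extent and scored internally and externally
  (evaluation images eclipsed at the same extent);
* the color counterfactual: logistic models on HSV statistics;
* the redundancy audit: cross-fold embeddings, duplicate/style clusters,
  and the leakage AUC comparison on the internal-validation split.

Classifiers are pluggable through a minimal contract: ``fit(images,
labels)`` then ``score(images) -> scores in [0, 1]``, deterministic given
the seed, with no access to evaluation data during fitting. Two desk-scale
classifiers ship: logistic regression on the default embedding, and a
1-nearest-neighbour scorer whose memorisation of leaked duplicates
demonstrates how redundancy inflates internal metrics.
"""
from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from . import __version__
from .cluster import (
    crossfold_embeddings,
    embed_default,
    group_by_threshold,
    leakage_auc_compare,
    redundancy_report,
    style_report,
)
from .color import color_audit
from .data_model import ImageRecord, Manifest, load_image, read_manifest, stratified_split
from .eclipse import apply_eclipse
from .roc import UndefinedAucError, delong_ci

__all__ = [
    "AuditConfig",
    "EmbeddingLogisticClassifier",
    "NearestNeighborClassifier",
    "make_classifier",
    "run_experiment1",
    "run_experiment2",
    "run_redundancy_audit",
    "run_all",
]

ImageProvider = Callable[[ImageRecord], np.ndarray]


@dataclass(frozen=True)
class AuditConfig:
    train_manifest: str | Manifest
    eval_manifests: tuple = ()
    eclipse_extents: tuple[float, ...] = (0.0, 0.9, 1.0)
    feature_sets: tuple[str, ...] = ("hsv6", "sat_std_only")
    classifier_name: str = "logistic_on_embedding"
    alpha_dup: float = 0.003
    alpha_style: float = 0.06
    style_min_size: int = 20
    style_purity_threshold: float = 0.9
    val_fraction: float = 0.2
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for e in self.eclipse_extents:
            if not 0 <= e <= 1:
                raise ValueError(f"eclipse extent {e} outside [0, 1]")


class EmbeddingLogisticClassifier:
    """Logistic regression on the default embedding.

    Weak L2 regularisation (C=10): the embedding is low-dimensional and
    unit-normalised, and the audits need the classifier to latch onto
    subtle artifacts the way an over-parameterised network would.
    """

    def __init__(self, seed: int = 0, C: float = 10.0):
        self.seed = seed
        self.C = C
        self._lr: LogisticRegression | None = None

    def fit(self, images: Sequence[np.ndarray], labels: np.ndarray) -> None:
        X = np.stack([embed_default(im) for im in images])
        self._lr = LogisticRegression(
            C=self.C, max_iter=5000, solver="lbfgs", random_state=self.seed
        ).fit(X, np.asarray(labels, dtype=int))

    def score(self, images: Sequence[np.ndarray]) -> np.ndarray:
        if self._lr is None:
            raise RuntimeError("classifier not fitted")
        X = np.stack([embed_default(im) for im in images])
        return self._lr.predict_proba(X)[:, 1]


class NearestNeighborClassifier:
    """1-NN on the default embedding; the archetypal memoriser.

    The score pushes towards the nearest neighbour's label, harder the
    closer the neighbour — an exact duplicate of a training image scores
    its training label with certainty.
    """

    def __init__(self, seed: int = 0):
        self.seed = seed
        self._X: np.ndarray | None = None
        self._y: np.ndarray | None = None

    def fit(self, images: Sequence[np.ndarray], labels: np.ndarray) -> None:
        self._X = np.stack([embed_default(im) for im in images])
        self._y = np.asarray(labels, dtype=float)

    def score(self, images: Sequence[np.ndarray]) -> np.ndarray:
        if self._X is None:
            raise RuntimeError("classifier not fitted")
        Q = np.stack([embed_default(im) for im in images])
        sims = Q @ self._X.T
        nn = np.argmax(sims, axis=1)
        closeness = np.clip(sims[np.arange(len(Q)), nn], 0.0, 1.0)
        return 0.5 + (self._y[nn] - 0.5) * closeness


_CLASSIFIERS = {
    "logistic_on_embedding": EmbeddingLogisticClassifier,
    "nearest_neighbor": NearestNeighborClassifier,
}


def make_classifier(name: str, seed: int = 0):
    if name not in _CLASSIFIERS:
        raise ValueError(f"unknown classifier {name!r}; options: {list(_CLASSIFIERS)}")
    return _CLASSIFIERS[name](seed=seed)


def _default_provider(record: ImageRecord) -> np.ndarray:
    return load_image(record.path)


def _resolve_manifest(
    source: str | Manifest, val_fraction: float, seed: int, need_split: bool
) -> Manifest:
    manifest = source if isinstance(source, Manifest) else read_manifest(source)
    if need_split and not manifest.subset("internal_val"):
        manifest = stratified_split(manifest, val_fraction, seed)
    return manifest


def _eval_name(manifest: Manifest, index: int) -> str:
    return manifest.dataset_id or f"external_{index}"


def run_experiment1(
    config: AuditConfig, image_provider: ImageProvider | None = None
) -> pd.DataFrame:
    """Occlusion sweep: refit at each eclipse extent, score every evaluation set.

    Evaluation images are eclipsed at the same extent as the training
    images. Returns one row per (extent, evaluation set) with the AUC and
    DeLong CI; classifier failures mark the row ``failed`` and the sweep
    continues.
    """
    provider = image_provider or _default_provider
    train = _resolve_manifest(
        config.train_manifest, config.val_fraction, config.seed, need_split=True
    )
    train_recs = train.subset("train")
    val_recs = train.subset("internal_val")
    train_imgs = [provider(r) for r in train_recs]
    y_train = np.array([r.label for r in train_recs])
    evals: list[tuple[str, list[np.ndarray], np.ndarray]] = []
    if val_recs:
        evals.append(
            (
                "internal_val",
                [provider(r) for r in val_recs],
                np.array([r.label for r in val_recs]),
            )
        )
    for i, source in enumerate(config.eval_manifests):
        m = _resolve_manifest(source, config.val_fraction, config.seed, need_split=False)
        evals.append(
            (
                _eval_name(m, i),
                [provider(r) for r in m.records],
                np.array([r.label for r in m.records]),
            )
        )

    rows = []
    for extent in config.eclipse_extents:
        clf = make_classifier(config.classifier_name, seed=config.seed)
        try:
            clf.fit([apply_eclipse(im, extent) for im in train_imgs], y_train)
        except Exception as exc:  # keep sweeping the other extents
            for name, _, _ in evals:
                rows.append(
                    {"extent": extent, "eval_set": name, "status": f"failed: {exc}"}
                )
            continue
        for name, images, labels in evals:
            row = {
                "extent": extent,
                "eval_set": name,
                "classifier": config.classifier_name,
                "n": len(images),
                "status": "ok",
            }
            try:
                scores = clf.score([apply_eclipse(im, extent) for im in images])
                res = delong_ci(scores, labels)
            except (UndefinedAucError, ValueError) as exc:
                row["status"] = f"undefined: {exc}"
            else:
                row.update(
                    auc=res.auc,
                    ci_low=res.ci_low,
                    ci_high=res.ci_high,
                    n_pos=res.n_pos,
                    n_neg=res.n_neg,
                )
            rows.append(row)
    return pd.DataFrame(rows)


def run_experiment2(
    config: AuditConfig, image_provider: ImageProvider | None = None
) -> dict:
    """Color counterfactual: one audit per configured feature set."""
    train = _resolve_manifest(
        config.train_manifest, config.val_fraction, config.seed, need_split=True
    )
    eval_manifests = [
        _resolve_manifest(s, config.val_fraction, config.seed, need_split=False)
        for s in config.eval_manifests
    ]
    auc_rows = []
    or_tables = {}
    for fs in config.feature_sets:
        result = color_audit(
            train, eval_manifests, feature_set=fs, image_provider=image_provider
        )
        for row in result.auc_rows:
            auc_rows.append({"feature_set": fs, **row})
        or_tables[fs] = pd.DataFrame(
            [
                {
                    "feature": r.feature,
                    "odds_ratio": r.odds_ratio,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p_value": r.p_value,
                }
                for r in result.odds_ratio_rows
            ]
        )
    return {"auc": pd.DataFrame(auc_rows), "odds_ratios": or_tables}


def run_redundancy_audit(
    config: AuditConfig, image_provider: ImageProvider | None = None
) -> dict:
    """Cross-fold embeddings, duplicate sets, redundancy/style reports, and —
    when the internal-validation partition supports it — the leakage AUC
    comparison using the configured classifier."""
    provider = image_provider or _default_provider
    train = _resolve_manifest(
        config.train_manifest, config.val_fraction, config.seed, need_split=True
    )
    emb = crossfold_embeddings(train, image_provider=provider, seed=config.seed)
    sets = group_by_threshold(emb, config.alpha_dup)
    report = redundancy_report(sets, train)
    styles = style_report(
        emb,
        train,
        alpha_style=config.alpha_style,
        min_size=config.style_min_size,
        purity_threshold=config.style_purity_threshold,
    )
    out = {
        "duplicate_sets": sets,
        "redundancy": report,
        "styles": styles,
        "leakage": None,
    }
    val_recs = train.subset("internal_val")
    if val_recs and report.test_with_dup_count > 0:
        clf = make_classifier(config.classifier_name, seed=config.seed)
        train_recs = train.subset("train")
        clf.fit(
            [provider(r) for r in train_recs],
            np.array([r.label for r in train_recs]),
        )
        scores = clf.score([provider(r) for r in val_recs])
        labels = np.array([r.label for r in val_recs])
        leaked = set(report.test_with_dup_ids)
        mask = np.array([r.image_id in leaked for r in val_recs])
        out["leakage"] = leakage_auc_compare(scores, labels, mask)
    return out


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "__dataclass_fields__"):
        from dataclasses import asdict

        return asdict(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _digest(source: str | Manifest) -> str:
    if isinstance(source, Manifest):
        from .data_model import write_manifest

        # hash the canonical CSV serialisation of in-memory manifests
        buf = io.StringIO()
        write_manifest(source, buf)
        data = buf.getvalue().encode()
    else:
        data = Path(source).read_bytes()
    return hashlib.sha256(data).hexdigest()


def run_all(
    config: AuditConfig, image_provider: ImageProvider | None = None
) -> dict:
    """Run all three audits and, if ``config.out_dir`` is set, write the
    bundle: CSV tables, ``report.json``, and a reproducibility manifest
    (seed, package version, input digests). Deterministic given the config:
    re-running writes byte-identical files."""
    bundle: dict = {"status": {}}
    for name, fn in (
        ("experiment1", run_experiment1),
        ("experiment2", run_experiment2),
        ("redundancy", run_redundancy_audit),
    ):
        try:
            bundle[name] = fn(config, image_provider)
            bundle["status"][name] = "ok"
        except Exception as exc:
            bundle[name] = None
            bundle["status"][name] = f"failed: {exc}"

    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        tables = out_dir / "tables"
        tables.mkdir(parents=True, exist_ok=True)
        if bundle["experiment1"] is not None:
            bundle["experiment1"].to_csv(tables / "experiment1_auc.csv", index=False)
        if bundle["experiment2"] is not None:
            bundle["experiment2"]["auc"].to_csv(
                tables / "experiment2_auc.csv", index=False
            )
            for fs, df in bundle["experiment2"]["odds_ratios"].items():
                df.to_csv(tables / f"experiment2_odds_ratios_{fs}.csv", index=False)
        report: dict = {"status": bundle["status"]}
        if bundle["redundancy"] is not None:
            red = bundle["redundancy"]
            report["redundancy"] = {
                "report": red["redundancy"],
                "duplicate_sets": [list(s) for s in red["duplicate_sets"].sets],
                "alpha": red["duplicate_sets"].alpha,
                "styles": red["styles"],
                "leakage": red["leakage"],
            }
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        manifest_meta = {
            "package_version": __version__,
            "seed": config.seed,
            "config": {
                k: ("<in-memory manifest>" if isinstance(v, Manifest) else
                    ["<in-memory manifest>" if isinstance(x, Manifest) else x
                     for x in v] if isinstance(v, tuple) else v)
                for k, v in config.__dict__.items()
            },
            "inputs": {
                "train": _digest(config.train_manifest),
                "eval": [_digest(s) for s in config.eval_manifests],
            },
        }
        with open(out_dir / "bundle_manifest.json", "w") as fh:
            json.dump(manifest_meta, fh, indent=2, sort_keys=True, default=str)
    return bundle
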